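"""pROC-AUC enrichment metrics and preparation-delta significance.

The screening-performance metric used throughout this package is the
semi-logarithmic ROC area (pROC-AUC).  For a benchmark with ``N_a``
bioactives and ``N_d`` decoys, let ``f_i`` be the fraction of decoys ranked
above bioactive *i* in the score-ordered list.  Then

    pROC-AUC = (1/N_a) * sum_i log10(1 / f_i),

with ``f_i`` floored at ``1/N_d`` so a bioactive retrieved before every
decoy contributes ``log10(N_d)`` rather than a divergent term.  The log10
transform of the false-positive axis weights early retrieval: random
scoring gives an expected area of ``log10(e) ~ 0.434`` independent of set
size, and perfect separation attains ``log10(N_d)``.

Differences between two experimental conditions are reported as plain AUC
differences and classified against a non-significance *safety margin*
(default 0.05, the run-to-run spread of a stochastic docking heuristic);
the margin boundary is inclusive, i.e. ``|delta| == margin`` is still
non-significant.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import HIGHER, LOWER, ROLE_ACTIVE, ROLE_DECOY, ScoreTable


@dataclass(frozen=True)
class RankedList:
    """A score-ordered benchmark.

    ``table`` holds molecules best-first with a ``global_rank`` column
    (1..N, bioactives and decoys pooled); ``decoy_fractions`` maps each
    bioactive id to its floored decoy fraction ``f_i``.
    """

    table: pd.DataFrame
    decoy_fractions: pd.Series
    n_actives: int
    n_decoys: int
    floor: float
    orientation: str

    def rank_of(self, molecule_id: str) -> int:
        rows = self.table.loc[self.table["molecule_id"] == molecule_id, "global_rank"]
        if rows.empty:
            raise KeyError(molecule_id)
        return int(rows.iloc[0])


@dataclass(frozen=True)
class PROCResult:
    """pROC-AUC plus the curve points at each bioactive recovery.

    ``curve`` lists ``(log10(f_i), i/N_a)`` pairs in recovery order; the
    true-positive coordinate is non-decreasing by construction.
    """

    auc: float
    curve: tuple
    n_actives: int
    n_decoys: int
    floor: float


class Significance(str, enum.Enum):
    FAVORS_FIRST = "favors_first"
    FAVORS_SECOND = "favors_second"
    NON_SIGNIFICANT = "non_significant"


@dataclass(frozen=True)
class SignificanceResult:
    label: Significance
    delta: float
    margin: float


def _sort_key(scores: np.ndarray, orientation: str) -> np.ndarray:
    """Map scores to an ascending sort key where smaller is better; missing
    scores (NaN) sort strictly last."""
    key = scores.astype(float).copy()
    if orientation == HIGHER:
        key = -key
    key[np.isnan(scores)] = np.inf
    return key


def rank_list(table: ScoreTable, floor: float | None = None) -> RankedList:
    """Order a best-pose-reduced table and compute per-bioactive decoy
    fractions.

    Ranks run 1..N with ties broken deterministically by molecule id; the
    decoy fraction of bioactive *i* counts decoys strictly better than it
    plus half of the decoys with exactly tied scores (average-rank tie
    convention), divided by ``N_d`` and floored at ``floor`` (default
    ``1/N_d``).  Molecules whose docking failed (missing score) rank after
    every scored molecule; a missing-score bioactive therefore has every
    scored decoy above it and ties with missing-score decoys.
    """
    if not table.is_reduced():
        raise ValidationError("table has multiple poses per molecule; call reduce_best_pose first")
    df = table.records
    if df.empty:
        raise ValidationError("empty score table")
    n_a, n_d = table.n_actives, table.n_decoys
    if n_a < 1 or n_d < 1:
        raise ValidationError(f"need >=1 bioactive and >=1 decoy (have {n_a} and {n_d})")
    if floor is None:
        floor = 1.0 / n_d
    scores = df["score"].to_numpy(dtype=float)
    key = _sort_key(scores, table.orientation)
    order = np.lexsort((df["molecule_id"].to_numpy(), key))
    ranked = df.iloc[order].reset_index(drop=True).copy()
    ranked["global_rank"] = np.arange(1, len(ranked) + 1)

    is_decoy = (df["role"] == ROLE_DECOY).to_numpy()
    decoy_key = np.sort(key[is_decoy])
    active_mask = (df["role"] == ROLE_ACTIVE).to_numpy()
    fractions: dict[str, float] = {}
    for mid, k in zip(df.loc[active_mask, "molecule_id"], key[active_mask]):
        strictly_better = np.searchsorted(decoy_key, k, side="left")
        tied = np.searchsorted(decoy_key, k, side="right") - strictly_better
        count = strictly_better + 0.5 * tied
        fractions[str(mid)] = min(max(count / n_d, floor), 1.0)
    decoy_fractions = pd.Series(fractions, name="decoy_fraction", dtype=float)
    # order fractions by recovery rank for downstream curve construction
    rank_order = ranked.loc[ranked["role"] == ROLE_ACTIVE, "molecule_id"]
    decoy_fractions = decoy_fractions.loc[rank_order.to_list()]
    return RankedList(
        table=ranked,
        decoy_fractions=decoy_fractions,
        n_actives=n_a,
        n_decoys=n_d,
        floor=floor,
        orientation=table.orientation,
    )


def proc_auc(ranked: RankedList) -> PROCResult:
    """Semi-log ROC area of a ranked benchmark (see module docstring)."""
    f = ranked.decoy_fractions.to_numpy(dtype=float)
    if f.size < 1 or ranked.n_decoys < 1:
        raise ValidationError("need >=1 bioactive and >=1 decoy")
    auc = float(np.mean(np.log10(1.0 / f)))
    tp = np.arange(1, f.size + 1) / f.size
    curve = tuple((float(np.log10(fi)), float(t)) for fi, t in zip(f, tp))
    return PROCResult(
        auc=auc,
        curve=curve,
        n_actives=ranked.n_actives,
        n_decoys=ranked.n_decoys,
        floor=ranked.floor,
    )


def screen_performance(table: ScoreTable, floor: float | None = None) -> PROCResult:
    """Convenience wrapper: rank a reduced table and score it."""
    return proc_auc(rank_list(table, floor=floor))


def delta_proc_prep(auc_first: float, auc_second: float) -> float:
    """Preparation delta: AUC(first scheme) - AUC(second scheme)."""
    for v in (auc_first, auc_second):
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"pROC-AUC values must be finite and >= 0, got {v!r}")
    return auc_first - auc_second


def classify_significance(delta: float, margin: float = 0.05) -> SignificanceResult:
    """Classify a delta against the inclusive safety margin."""
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    if abs(delta) <= margin:
        label = Significance.NON_SIGNIFICANT
    elif delta > margin:
        label = Significance.FAVORS_FIRST
    else:
        label = Significance.FAVORS_SECOND
    return SignificanceResult(label=label, delta=delta, margin=margin)


def summarize_delta_table(
    deltas: Mapping[str, float], margin: float = 0.05
) -> dict[str, int]:
    """Count significance classes over a per-target delta column."""
    if not deltas:
        raise ValidationError("need at least one target")
    counts = {s.value: 0 for s in Significance}
    for delta in deltas.values():
        counts[classify_significance(delta, margin).label.value] += 1
    return counts
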