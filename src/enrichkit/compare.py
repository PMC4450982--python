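"""Cross-preparation experiments on docking score tables.

Four experiment families attribute a screening-performance difference
between two input-preparation schemes to its causes:

* the 2x2x2 **match/mismatch grid** toggles which scheme prepared the
  target, the bioactives and the decoys, and reports the marginal effect of
  each factor on pROC-AUC;
* **protomer shuffling** swaps only the molecules whose two preparations
  actually differ (e.g. in protonation state) from one scheme's score list
  into the other's, isolating their contribution;
* **deletion** removes those molecules outright and rescores the reduced
  benchmark;
* **rank/score shift analytics** quantify per-molecule changes between the
  two schemes (global-rank deltas, score deltas, preference fractions,
  paired correlations) and flag large-rank-shift outliers with their
  structural causes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ROLE_ACTIVE, ROLE_DECOY, ScoreTable
from .metrics import PROCResult, rank_list, screen_performance

GRID_FACTORS = ("target_prep", "bioactives_prep", "decoys_prep")


@dataclass(frozen=True)
class MatchMismatchGrid:
    """pROC-AUC per grid cell plus per-factor marginal effects.

    ``cells`` maps (target_prep, bioactives_prep, decoys_prep) label triples
    to results; ``marginals`` maps each factor to the mean AUC change when
    toggling that factor from its second label to its first with the other
    two held fixed.
    """

    cells: dict
    labels: dict
    marginals: dict

    def auc(self, key: tuple) -> float:
        return self.cells[key].auc


def match_mismatch_grid(tables: Mapping[tuple, ScoreTable]) -> MatchMismatchGrid:
    """Evaluate all 8 combinations of preparation scheme per factor.

    ``tables`` must be keyed by (target_prep, bioactives_prep, decoys_prep)
    and cover a complete 2x2x2 grid; each table must be best-pose-reduced.
    A *matched* cell is one whose three labels agree.
    """
    keys = list(tables)
    if len(keys) != 8:
        raise ValidationError(f"expected 8 grid cells, got {len(keys)}")
    labels: dict[str, tuple[str, str]] = {}
    for axis, factor in enumerate(GRID_FACTORS):
        values = sorted({key[axis] for key in keys})
        if len(values) != 2:
            raise ValidationError(
                f"factor {factor} must take exactly 2 labels, got {values!r}"
            )
        labels[factor] = (values[0], values[1])
    for combo in itertools.product(*(labels[f] for f in GRID_FACTORS)):
        if combo not in tables:
            raise ValidationError(f"missing grid cell {combo!r}")
    cells = {key: screen_performance(tables[key]) for key in keys}
    marginals: dict[str, float] = {}
    for axis, factor in enumerate(GRID_FACTORS):
        first, second = labels[factor]
        diffs = []
        for combo in itertools.product(*(labels[f] for f in GRID_FACTORS)):
            if combo[axis] != first:
                continue
            other = list(combo)
            other[axis] = second
            diffs.append(cells[combo].auc - cells[tuple(other)].auc)
        marginals[factor] = float(np.mean(diffs))
    return MatchMismatchGrid(cells=cells, labels=labels, marginals=marginals)


@dataclass(frozen=True)
class ShuffleResult:
    auc_before: float
    auc_after: float
    swapped_ids: tuple
    swapped_role: str  # "bioactives", "decoys" or "mixed"
    table_after: ScoreTable | None = None

    @property
    def delta(self) -> float:
        return self.auc_after - self.auc_before


def shuffle_protomers(
    base: ScoreTable, donor: ScoreTable, ids: Iterable[str]
) -> ShuffleResult:
    """Replace the scores of ``ids`` in ``base`` with the donor scheme's
    scores, re-rank, and report the AUC change.

    Typically ``ids`` are the molecules whose two preparations differ (e.g.
    different protomers); the experiment measures how much those molecules
    alone explain of the full between-scheme performance difference.
    """
    ids = [str(i) for i in ids]
    if base.orientation != donor.orientation:
        raise ValidationError("base and donor tables must share score orientation")
    base_ids = set(base.molecule_ids)
    donor_df = donor.records.set_index("molecule_id")
    missing = sorted(set(ids) - set(donor_df.index))
    if missing:
        raise ValidationError(f"id(s) absent from donor table: {missing!r}")
    missing_base = sorted(set(ids) - base_ids)
    if missing_base:
        raise ValidationError(f"id(s) absent from base table: {missing_base!r}")
    roles_base = base.records.set_index("molecule_id")["role"]
    for mid in ids:
        if roles_base[mid] != donor_df.loc[mid, "role"]:
            raise ValidationError(f"role of {mid!r} differs between base and donor")
    df = base.records.copy()
    swap = df["molecule_id"].isin(ids)
    df.loc[swap, "score"] = [donor_df.loc[mid, "score"] for mid in df.loc[swap, "molecule_id"]]
    shuffled = base.with_records(df)
    before = screen_performance(base).auc
    after = screen_performance(shuffled).auc
    swapped_roles = set(roles_base[mid] for mid in ids)
    if swapped_roles == {ROLE_ACTIVE}:
        role = "bioactives"
    elif swapped_roles == {ROLE_DECOY}:
        role = "decoys"
    elif not swapped_roles:
        role = "none"
    else:
        role = "mixed"
    return ShuffleResult(
        auc_before=before,
        auc_after=after,
        swapped_ids=tuple(ids),
        swapped_role=role,
        table_after=shuffled,
    )


def delete_and_rescore(table: ScoreTable, ids: Iterable[str]) -> PROCResult:
    """Drop ``ids`` from the benchmark and recompute pROC-AUC with the
    updated counts and decoy-fraction floor."""
    ids = {str(i) for i in ids}
    present = set(table.molecule_ids)
    missing = sorted(ids - present)
    if missing:
        raise ValidationError(f"id(s) not in table: {missing!r}")
    df = table.records[~table.records["molecule_id"].isin(ids)].reset_index(drop=True)
    reduced = table.with_records(df)
    if reduced.n_actives < 1 or reduced.n_decoys < 1:
        raise ValidationError("deletion would empty a role class")
    return screen_performance(reduced)


# ---------------------------------------------------------------------------
# Rank/score shift analytics
# ---------------------------------------------------------------------------


def squared_pearson(x: Sequence[float], y: Sequence[float]):
    """R² as the squared Pearson correlation; returns ``None`` (undefined)
    when either vector has zero variance instead of propagating NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _box_stats(values: np.ndarray) -> dict[str, float]:
    """Five-number summary (linear-interpolation quartiles) plus mean/sd."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max", "mean", "sd")}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }


@dataclass(frozen=True)
class RankShiftResult:
    """Per-molecule rank/score shifts between two preparations plus summary
    statistics.

    ``records`` columns: molecule_id, role, score_first, score_second,
    delta_fitness (= first - second), rank_first, rank_second (global ranks,
    bioactives and decoys pooled), delta_rank (= first - second), and
    bioactive-only ranks ``active_rank_first``/``active_rank_second`` for
    bioactive rows.
    """

    records: pd.DataFrame
    summary: dict


def rank_shift_analysis(first: ScoreTable, second: ScoreTable) -> RankShiftResult:
    """Compare the same benchmark docked after two preparation schemes."""
    if first.orientation != second.orientation:
        raise ValidationError("tables must share score orientation")
    ids_first = set(first.molecule_ids)
    ids_second = set(second.molecule_ids)
    if ids_first != ids_second:
        raise ValidationError(
            "molecule ids differ between tables; only in first: "
            f"{sorted(ids_first - ids_second)!r}, only in second: "
            f"{sorted(ids_second - ids_first)!r}"
        )
    ranked_first = rank_list(first)
    ranked_second = rank_list(second)
    a = ranked_first.table.set_index("molecule_id")
    b = ranked_second.table.set_index("molecule_id")
    if not a["role"].sort_index().equals(b["role"].sort_index()):
        raise ValidationError("role assignments differ between tables")

    df = pd.DataFrame(
        {
            "molecule_id": a.index,
            "role": a["role"].to_numpy(),
            "score_first": a["score"].to_numpy(),
            "score_second": b.loc[a.index, "score"].to_numpy(),
            "rank_first": a["global_rank"].to_numpy(),
            "rank_second": b.loc[a.index, "global_rank"].to_numpy(),
        }
    )
    df["delta_fitness"] = df["score_first"] - df["score_second"]
    df["delta_rank"] = df["rank_first"] - df["rank_second"]
    # bioactive-only rank (rank within the bioactive subset), as distinct
    # from the pooled global rank
    for side, ranked in (("first", ranked_first), ("second", ranked_second)):
        actives = ranked.table[ranked.table["role"] == ROLE_ACTIVE]
        arank = {mid: i + 1 for i, mid in enumerate(actives["molecule_id"])}
        df[f"active_rank_{side}"] = df["molecule_id"].map(arank).astype("Int64")
    df = df.reset_index(drop=True)

    higher = first.orientation == "higher_is_better"

    def preference(col_first: str, col_second: str, better_is_larger: bool) -> dict[str, float]:
        x = df[col_first].to_numpy(dtype=float)
        y = df[col_second].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            first_wins = (x > y) if better_is_larger else (x < y)
            second_wins = (y > x) if better_is_larger else (y < x)
        both_nan = np.isnan(x) & np.isnan(y)
        ties = (~first_wins & ~second_wins) | both_nan
        n = len(df)
        return {
            "first": float((first_wins.sum() + 0.5 * ties.sum()) / n),
            "second": float((second_wins.sum() + 0.5 * ties.sum()) / n),
        }

    summary = {
        "n": len(df),
        "score_preference": preference("score_first", "score_second", better_is_larger=higher),
        "rank_preference": preference("rank_first", "rank_second", better_is_larger=False),
        "r2_scores": squared_pearson(df["score_first"], df["score_second"]),
        "r2_ranks": squared_pearson(df["rank_first"], df["rank_second"]),
        "box_stats": {
            role: {
                side: {
                    "rank": _box_stats(df.loc[df["role"] == role, f"rank_{side}"].to_numpy()),
                    "score": _box_stats(df.loc[df["role"] == role, f"score_{side}"].to_numpy()),
                }
                for side in ("first", "second")
            }
            for role in (ROLE_ACTIVE, ROLE_DECOY)
        },
    }
    return RankShiftResult(records=df, summary=summary)


CAUSE_FLAGS = ("protonation", "tautomer", "ring_conformation")


def flag_rank_outliers(
    records: pd.DataFrame,
    cutoff: int = 500,
    causes: Mapping[str, Iterable[str]] | None = None,
    n_rot: Mapping[str, int] | None = None,
    rotor_cutoff: int = 8,
) -> pd.DataFrame:
    """Select molecules with ``|delta_rank| > cutoff`` and annotate causes.

    ``causes`` maps molecule id to structural difference flags (subset of
    ``protonation``/``tautomer``/``ring_conformation``, typically from a
    molprops pair audit or from synthetic ground truth); ``n_rot`` supplies
    rotatable-bond counts for the high-flexibility annotation
    (> ``rotor_cutoff`` rotors).  Molecules with no cause are labelled
    ``none``.
    """
    if cutoff < 1:
        raise ValidationError("cutoff must be >= 1")
    out = records.loc[records["delta_rank"].abs() > cutoff].copy()
    causes = causes or {}
    n_rot = n_rot or {}
    for flag in CAUSE_FLAGS:
        out[f"cause_{flag}"] = [
            flag in set(causes.get(mid, ())) for mid in out["molecule_id"]
        ]
    out["cause_high_rotors"] = [
        int(n_rot.get(mid, 0)) > rotor_cutoff for mid in out["molecule_id"]
    ]
    structural = out[[f"cause_{flag}" for flag in CAUSE_FLAGS]].any(axis=1)
    out["cause_none"] = ~structural
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class OutlierIsolation:
    """Result of iteratively isolating the k worst-agreeing molecules from a
    paired-score correlation."""

    outlier_ids: tuple
    core_ids: tuple
    r2_core: float | None
    r2_outlier_vs_property: dict = field(default_factory=dict)


def isolate_outlier_subset(
    score_first: Sequence[float],
    score_second: Sequence[float],
    k: int,
    ids: Sequence[str] | None = None,
    properties: Mapping[str, Sequence[float]] | None = None,
) -> OutlierIsolation:
    """Iteratively remove the k points deviating most from mutual agreement.

    The agreement model is the identity-direction line (slope fixed at 1,
    intercept refit as the mean offset after each removal); the point with
    the largest orthogonal residual is removed, k times, ties broken by id
    order.  The remaining core's R² is reported, and for each supplied
    molecular property the outlier subset's |delta_fitness| is correlated
    against it.
    """
    x = np.asarray(score_first, dtype=float)
    y = np.asarray(score_second, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("paired score vectors must have equal length")
    if k <= 0:
        raise ValidationError("k must be > 0")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of molecules ({n})")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = [str(i) for i in ids]
    remaining = list(range(n))
    outliers: list[int] = []
    for _ in range(k):
        xr, yr = x[remaining], y[remaining]
        intercept = float(np.mean(yr - xr))
        residuals = np.abs(yr - xr - intercept) / np.sqrt(2.0)
        # ties resolved by id order
        worst = max(
            range(len(remaining)), key=lambda j: (residuals[j], ), default=None
        )
        best_res = residuals[worst]
        tied = [j for j in range(len(remaining)) if residuals[j] == best_res]
        worst = min(tied, key=lambda j: ids[remaining[j]])
        outliers.append(remaining.pop(worst))
    r2_core = squared_pearson(x[remaining], y[remaining])
    r2_prop: dict[str, float | None] = {}
    if properties:
        delta = np.abs(x[np.array(outliers)] - y[np.array(outliers)])
        for name, values in properties.items():
            values = np.asarray(values, dtype=float)
            if values.size != n:
                raise ValidationError(f"property {name!r} length mismatch")
            r2_prop[name] = squared_pearson(values[np.array(outliers)], delta)
    return OutlierIsolation(
        outlier_ids=tuple(ids[i] for i in outliers),
        core_ids=tuple(ids[i] for i in remaining),
        r2_core=r2_core,
        r2_outlier_vs_property=r2_prop,
    )
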