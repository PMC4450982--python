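"""Heavy-atom score normalization and the mean-NHA usage guideline.

Empirical docking scores are additive over contacts and therefore drift
upward with molecular size, biasing the top of a score-ranked list toward
heavy molecules.  Dividing each score by a power of the heavy-atom count N
(N^(1/2) or N^(2/3)) is the classical correction.  Whether it helps depends
on the size profile of the benchmark: for bioactive sets with a small mean
heavy-atom count normalization tends to improve enrichment, for large ones
it tends to penalize exactly the molecules the screen should retrieve.  The
guideline encoded in :func:`recommend_mode` reflects that trade-off:
N^(1/2) is worth trying at mean NHA <= 30 and risky above; N^(2/3) is worth
trying at mean NHA <= 28, risky at >= 29, with the in-between band left
neutral.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .io import ROLE_ACTIVE, ScoreTable
from .metrics import PROCResult, screen_performance


class NormalizationMode(enum.Enum):
    NONE = ("none", 0.0)
    SQRT_NHA = ("sqrt_nha", 0.5)
    NHA_TWO_THIRDS = ("nha_two_thirds", 2.0 / 3.0)

    def __init__(self, label: str, exponent: float):
        self.label = label
        self.exponent = exponent

    @classmethod
    def parse(cls, token: "str | NormalizationMode") -> "NormalizationMode":
        if isinstance(token, cls):
            return token
        aliases = {
            "none": cls.NONE,
            "sqrt": cls.SQRT_NHA,
            "sqrt_nha": cls.SQRT_NHA,
            "n12": cls.SQRT_NHA,
            "twothirds": cls.NHA_TWO_THIRDS,
            "nha_two_thirds": cls.NHA_TWO_THIRDS,
            "n23": cls.NHA_TWO_THIRDS,
        }
        key = str(token).strip().lower()
        if key not in aliases:
            raise ValidationError(f"unknown normalization mode {token!r}")
        return aliases[key]


class Recommendation(str, enum.Enum):
    RECOMMEND = "recommend"
    RISKY = "risky"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class NormalizationReport:
    """Before/after screening performance of one normalization mode."""

    mode: NormalizationMode
    result_original: PROCResult
    result_normalized: PROCResult
    mean_nha: float
    recommendation: Recommendation

    @property
    def auc_original(self) -> float:
        return self.result_original.auc

    @property
    def auc_normalized(self) -> float:
        return self.result_normalized.auc

    @property
    def delta_n(self) -> float:
        return self.result_normalized.auc - self.result_original.auc


def normalize_score(score: float, nha: int, mode: NormalizationMode | str) -> float:
    """Divide one score by NHA**exponent (mode ``none`` is the identity)."""
    mode = NormalizationMode.parse(mode)
    if nha < 1:
        raise ValidationError(f"heavy-atom count must be >= 1, got {nha}")
    if not math.isfinite(score):
        raise ValidationError("score must be finite")
    if mode is NormalizationMode.NONE:
        return score
    return score / nha ** mode.exponent


def normalize_table(
    table: ScoreTable,
    nha: Mapping[str, int],
    mode: NormalizationMode | str,
    force: bool = False,
) -> ScoreTable:
    """Return a new table with every score divided by NHA**exponent.

    Normalization applies to bioactives and decoys alike; normalizing only a
    subset of a ranked list is not meaningful and is not offered.  Scores of
    mixed sign are refused unless ``force`` is given, because dividing a
    column that straddles zero by a positive size factor reorders it
    ambiguously (magnitudes shrink on both sides of zero).
    """
    mode = NormalizationMode.parse(mode)
    if mode is NormalizationMode.NONE:
        return table.with_records(table.records.copy())
    df = table.records.copy()
    scored = df["score"].notna()
    missing_nha = sorted(set(df.loc[scored, "molecule_id"]) - set(nha))
    if missing_nha:
        raise ValidationError(f"no heavy-atom count for molecule(s): {missing_nha!r}")
    values = df.loc[scored, "score"].to_numpy(dtype=float)
    if not force and (values > 0).any() and (values < 0).any():
        raise ValidationError(
            "score column mixes signs; size normalization would reorder it "
            "ambiguously (pass force=True to override)"
        )
    divisors = np.array(
        [float(nha[mid]) ** mode.exponent for mid in df.loc[scored, "molecule_id"]]
    )
    bad = [
        mid
        for mid in df.loc[scored, "molecule_id"]
        if nha[mid] < 1
    ]
    if bad:
        raise ValidationError(f"heavy-atom count must be >= 1 for molecule(s): {bad!r}")
    df.loc[scored, "score"] = values / divisors
    return table.with_records(df)


def delta_proc_norm(auc_normalized: float, auc_original: float) -> float:
    """Normalization delta: AUC(normalized scores) - AUC(original scores)."""
    for v in (auc_normalized, auc_original):
        if not math.isfinite(v):
            raise ValidationError(f"pROC-AUC values must be finite, got {v!r}")
    return auc_normalized - auc_original


#: Mean-NHA guideline thresholds per mode (see module docstring).
_SQRT_RECOMMEND_MAX = 30.0
_TWO_THIRDS_RECOMMEND_MAX = 28.0
_TWO_THIRDS_RISKY_MIN = 29.0


def recommend_mode(mean_nha: float) -> dict[NormalizationMode, Recommendation]:
    """Usage guideline per normalization mode given the bioactive-set mean
    heavy-atom count."""
    if not math.isfinite(mean_nha) or mean_nha <= 0:
        raise ValidationError(f"mean_nha must be > 0, got {mean_nha!r}")
    sqrt_rec = (
        Recommendation.RECOMMEND if mean_nha <= _SQRT_RECOMMEND_MAX else Recommendation.RISKY
    )
    if mean_nha <= _TWO_THIRDS_RECOMMEND_MAX:
        tt_rec = Recommendation.RECOMMEND
    elif mean_nha >= _TWO_THIRDS_RISKY_MIN:
        tt_rec = Recommendation.RISKY
    else:
        tt_rec = Recommendation.NEUTRAL
    return {
        NormalizationMode.SQRT_NHA: sqrt_rec,
        NormalizationMode.NHA_TWO_THIRDS: tt_rec,
        NormalizationMode.NONE: Recommendation.NEUTRAL,
    }


def normalization_report(
    table: ScoreTable,
    nha: Mapping[str, int],
    mode: NormalizationMode | str,
    force: bool = False,
) -> NormalizationReport:
    """Compute before/after pROC-AUC for one mode plus the guideline flag.

    ``mean_nha`` is the mean heavy-atom count of the bioactive set, the
    quantity the usage guideline is expressed in.
    """
    mode = NormalizationMode.parse(mode)
    result_original = screen_performance(table)
    normalized = normalize_table(table, nha, mode, force=force)
    result_normalized = screen_performance(normalized)
    active_ids = table.records.loc[table.records["role"] == ROLE_ACTIVE, "molecule_id"]
    missing = sorted(set(active_ids) - set(nha))
    if missing:
        raise ValidationError(f"no heavy-atom count for bioactive(s): {missing!r}")
    mean_nha = float(np.mean([nha[mid] for mid in active_ids]))
    recommendation = recommend_mode(mean_nha)[mode]
    return NormalizationReport(
        mode=mode,
        result_original=result_original,
        result_normalized=result_normalized,
        mean_nha=mean_nha,
        recommendation=recommendation,
    )
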