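"""Reading and writing of docking score tables, paired SD files and run
manifests.

A *score table* is the unit every metric in this package consumes: one row
per docked pose with a molecule id, a role (``bioactive`` or ``decoy``), a
docking score, and optionally a pose index.  Tables carry an explicit score
*orientation* because docking programs disagree about what "better" means:
an empirical fitness (e.g. GOLD ChemPLP) is higher-is-better while a binding
energy estimate (e.g. Glide SP) is lower-is-better.  Orientation is never
inferred from the data.

Before any enrichment metric is computed a table must be reduced to the best
pose per molecule (:func:`reduce_best_pose`); molecules whose docking failed
keep a missing score and are ranked strictly worst downstream rather than
silently dropped, so the benchmark denominator never shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError

ROLE_ACTIVE = "bioactive"
ROLE_DECOY = "decoy"
ROLES = (ROLE_ACTIVE, ROLE_DECOY)

HIGHER = "higher_is_better"
LOWER = "lower_is_better"
ORIENTATIONS = (HIGHER, LOWER)

#: Columns every score table must provide, in canonical order.
REQUIRED_COLUMNS = ("molecule_id", "role", "score")
#: Optional columns that are recognised and typed when present.
OPTIONAL_COLUMNS = ("pose_index", "nha", "n_rot")

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}


@dataclass(frozen=True)
class ScoreTable:
    """Per-molecule docking results for one (target prep x dataset prep x
    program) combination.

    Attributes
    ----------
    records:
        DataFrame with at least ``molecule_id`` (str), ``role`` (str) and
        ``score`` (float; NaN marks a failed docking).  Extra columns such as
        ``pose_index`` or ``nha`` ride along untouched.
    orientation:
        ``"higher_is_better"`` or ``"lower_is_better"``.
    """

    records: pd.DataFrame
    orientation: str
    program: str = ""
    target_prep: str = ""
    dataset_prep: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}"
            )
        validate_records(self.records)

    # -- convenience accessors -------------------------------------------
    @property
    def n_actives(self) -> int:
        return int((self.records["role"] == ROLE_ACTIVE).sum())

    @property
    def n_decoys(self) -> int:
        return int((self.records["role"] == ROLE_DECOY).sum())

    @property
    def molecule_ids(self) -> pd.Series:
        return self.records["molecule_id"]

    def is_reduced(self) -> bool:
        """True when the table holds exactly one row per molecule id."""
        return not self.records["molecule_id"].duplicated().any()

    def with_records(self, records: pd.DataFrame) -> "ScoreTable":
        return replace(self, records=records.reset_index(drop=True))

    def score_of(self, molecule_id: str) -> float:
        rows = self.records.loc[self.records["molecule_id"] == molecule_id, "score"]
        if rows.empty:
            raise KeyError(molecule_id)
        return float(rows.iloc[0])


def validate_records(df: pd.DataFrame) -> None:
    """Contract checks shared by every construction path of a ScoreTable."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"score table lacks required column {col!r}")
    bad_roles = set(df["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown role token(s) {sorted(bad_roles)!r}; expected {ROLES}")
    if "pose_index" in df.columns:
        key = df[["molecule_id", "pose_index"]].apply(tuple, axis=1)
    else:
        key = df["molecule_id"]
    dup = key[key.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate (molecule_id, pose_index) entries: {sorted(set(dup))!r}")
    roles_per_id = df.groupby("molecule_id")["role"].nunique()
    conflicted = roles_per_id[roles_per_id > 1]
    if not conflicted.empty:
        raise ValidationError(
            f"molecule(s) assigned to both roles: {sorted(conflicted.index)!r}"
        )


def _parse_score(token: str, line_no: int) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return math.nan
    try:
        value = float(token)
    except ValueError as exc:
        raise ParseError(f"cannot parse score {token!r}", line=line_no) from exc
    if math.isinf(value):
        raise ParseError(f"non-finite score {token!r}", line=line_no)
    return value


def read_score_table(
    path: str | Path,
    orientation: str,
    program: str = "",
    target_prep: str = "",
    dataset_prep: str = "",
) -> ScoreTable:
    """Read a tab-separated score table.

    The file must carry a header naming at least ``molecule_id``, ``role``
    and ``score``.  Missing scores (empty field, ``NA``, ``nan``) are kept
    as missing, never coerced to zero.  Malformed rows raise
    :class:`ParseError` naming the line; unknown role tokens raise
    :class:`ValidationError`.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file", line=1)
    header = lines[0].rstrip("\n").split("\t")
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise ParseError(f"header lacks required column {col!r}", line=1)
    idx = {name: i for i, name in enumerate(header)}
    rows: list[list[object]] = []
    for line_no, raw in enumerate(lines[1:], start=2):
        if raw.strip() == "":
            continue
        fields = raw.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(fields)}", line=line_no
            )
        row: dict[str, object] = {name: fields[i] for name, i in idx.items()}
        role = str(row["role"]).strip()
        if role not in ROLES:
            raise ValidationError(f"line {line_no}: unknown role token {role!r}")
        record: list[object] = []
        for name in header:
            token = str(row[name])
            if name == "score":
                record.append(_parse_score(token, line_no))
            elif name == "pose_index":
                if token.strip().lower() in _MISSING_TOKENS:
                    record.append(pd.NA)
                else:
                    try:
                        pose = int(token)
                    except ValueError as exc:
                        raise ParseError(f"cannot parse pose_index {token!r}", line=line_no) from exc
                    if pose < 0:
                        raise ParseError(f"negative pose_index {pose}", line=line_no)
                    record.append(pose)
            elif name in ("nha", "n_rot"):
                record.append(pd.NA if token.strip().lower() in _MISSING_TOKENS else int(token))
            else:
                record.append(token)
        rows.append(record)
    df = pd.DataFrame(rows, columns=header)
    df["score"] = df["score"].astype(float)
    for col in ("pose_index", "nha", "n_rot"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return ScoreTable(
        records=df,
        orientation=orientation,
        program=program,
        target_prep=target_prep,
        dataset_prep=dataset_prep,
    )


def _format_value(value: object) -> str:
    if value is None or value is pd.NA:
        return "NA"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_score_table(table: ScoreTable, path: str | Path) -> Path:
    """Write a table as TSV with full-precision scores (round-trip safe)."""
    path = Path(path)
    df = table.records
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")
    return path


def reduce_best_pose(table: ScoreTable) -> ScoreTable:
    """Keep the best-scoring pose per molecule under the table orientation.

    Molecules whose every pose has a missing score are retained with a
    missing score.  Idempotent.
    """
    if table.is_reduced():
        return table
    df = table.records.copy()
    ascending = table.orientation == LOWER
    # NaN scores sort last in either orientation; stable sort keeps pose order
    # deterministic for exact ties.
    order = df.sort_values(
        ["score", "molecule_id"], ascending=[ascending, True], na_position="last", kind="mergesort"
    )
    best = order.drop_duplicates(subset="molecule_id", keep="first")
    # Restore first-appearance order of molecules for reproducible output.
    first_seen = {mid: i for i, mid in enumerate(df["molecule_id"].drop_duplicates())}
    best = best.sort_values("molecule_id", key=lambda s: s.map(first_seen), kind="mergesort")
    return table.with_records(best)


# ---------------------------------------------------------------------------
# Paired SD files
# ---------------------------------------------------------------------------


@dataclass
class PairedStructures:
    """Result of pairing two SD files by molecule id.

    ``pairs`` maps molecule id -> (mol_first, mol_second); ids found in only
    one file are reported, not dropped; unreadable SD blocks are counted.
    """

    pairs: dict
    only_in_first: list[str] = field(default_factory=list)
    only_in_second: list[str] = field(default_factory=list)
    n_skipped_first: int = 0
    n_skipped_second: int = 0
    warnings: list[str] = field(default_factory=list)


def _read_sdf(path: str | Path, id_property: str | None):
    from rdkit import Chem

    mols: dict[str, object] = {}
    skipped = 0
    warnings: list[str] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            warnings.append(f"{path}: unreadable SD block at position {i}")
            continue
        mid = ""
        if mol.HasProp("_Name"):
            mid = mol.GetProp("_Name").strip()
        if not mid and id_property and mol.HasProp(id_property):
            mid = mol.GetProp(id_property).strip()
        if not mid:
            skipped += 1
            warnings.append(f"{path}: molecule at position {i} has no id (title or property)")
            continue
        if mid in mols:
            raise ValidationError(f"{path}: duplicate molecule id {mid!r}")
        mols[mid] = mol
    return mols, skipped, warnings


def read_paired_sdf(
    path_first: str | Path,
    path_second: str | Path,
    id_property: str | None = None,
) -> PairedStructures:
    """Pair two SD files (one per preparation scheme) by molecule title.

    The pairing key is the molecule title line, falling back to the SD
    property ``id_property`` when the title is blank.
    """
    first, skip_a, warn_a = _read_sdf(path_first, id_property)
    second, skip_b, warn_b = _read_sdf(path_second, id_property)
    shared = [mid for mid in first if mid in second]
    return PairedStructures(
        pairs={mid: (first[mid], second[mid]) for mid in shared},
        only_in_first=sorted(set(first) - set(second)),
        only_in_second=sorted(set(second) - set(first)),
        n_skipped_first=skip_a,
        n_skipped_second=skip_b,
        warnings=warn_a + warn_b,
    )


def write_sdf(mols: Iterable, path: str | Path) -> Path:
    """Write molecules (with their ``_Name`` titles) to an SD file."""
    from rdkit import Chem

    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(mol)
    finally:
        writer.close()
    return path


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


@dataclass
class ManifestEntry:
    path: str
    orientation: str
    program: str = ""
    target: str = ""
    target_prep: str = ""
    dataset_prep: str = ""

    def load(self, base_dir: str | Path | None = None) -> ScoreTable:
        p = Path(self.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        return read_score_table(
            p,
            orientation=self.orientation,
            program=self.program,
            target_prep=self.target_prep,
            dataset_prep=self.dataset_prep,
        )


#: Default score orientations for the two docking programs the package is
#: most often pointed at: an empirical fitness is maximised, an energy-like
#: docking score is minimised.
DEFAULT_ORIENTATIONS = {"GOLD": HIGHER, "Glide": LOWER}


@dataclass
class RunManifest:
    """Declares the score tables of a study plus the two analysis knobs that
    are study-wide: the non-significance safety margin on ΔpROC-AUC and the
    global-rank-shift cutoff used to flag outlier molecules."""

    entries: list[ManifestEntry]
    safety_margin: float = 0.05
    rank_shift_cutoff: int = 500

    def __post_init__(self) -> None:
        if self.safety_margin < 0:
            raise ValidationError("safety_margin must be >= 0")
        if self.rank_shift_cutoff < 1:
            raise ValidationError("rank_shift_cutoff must be >= 1")


def load_manifest(path: str | Path) -> RunManifest:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "tables" not in doc:
        raise ValidationError(f"{path}: manifest must be a mapping with a 'tables' list")
    entries = []
    for i, item in enumerate(doc["tables"]):
        if "path" not in item:
            raise ValidationError(f"{path}: tables[{i}] lacks 'path'")
        orientation = item.get("orientation")
        if orientation is None:
            orientation = DEFAULT_ORIENTATIONS.get(item.get("program", ""))
        if orientation not in ORIENTATIONS:
            raise ValidationError(
                f"{path}: tables[{i}] needs orientation in {ORIENTATIONS} "
                "(or a program with a known default)"
            )
        entries.append(
            ManifestEntry(
                path=str(item["path"]),
                orientation=orientation,
                program=str(item.get("program", "")),
                target=str(item.get("target", "")),
                target_prep=str(item.get("target_prep", "")),
                dataset_prep=str(item.get("dataset_prep", "")),
            )
        )
    return RunManifest(
        entries=entries,
        safety_margin=float(doc.get("safety_margin", 0.05)),
        rank_shift_cutoff=int(doc.get("rank_shift_cutoff", 500)),
    )


def save_manifest(manifest: RunManifest, path: str | Path) -> Path:
    doc = {
        "safety_margin": manifest.safety_margin,
        "rank_shift_cutoff": manifest.rank_shift_cutoff,
        "tables": [
            {
                "path": e.path,
                "orientation": e.orientation,
                "program": e.program,
                "target": e.target,
                "target_prep": e.target_prep,
                "dataset_prep": e.dataset_prep,
            }
            for e in manifest.entries
        ],
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def make_score_table(
    molecule_ids: Sequence[str],
    roles: Sequence[str],
    scores: Sequence[float],
    orientation: str = HIGHER,
    **labels: str,
) -> ScoreTable:
    """Convenience constructor used throughout tests and the generator."""
    df = pd.DataFrame(
        {
            "molecule_id": [str(m) for m in molecule_ids],
            "role": list(roles),
            "score": np.asarray(scores, dtype=float),
        }
    )
    return ScoreTable(records=df, orientation=orientation, **labels)
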