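"""Synthetic DEKOIS-shaped paired-preparation benchmarks with known truth.

Real post-docking tables come from commercial docking runs that cannot be
redistributed; this module generates benchmarks of the same shape (40
bioactives, 1200 decoys = 30 per bioactive by default) from an explicit
additive score model so that every pipeline stage can be exercised against
planted ground truth:

    score = base + bias_slope * NHA + affinity_offset * [bioactive] + eps

The ``bias_slope`` term emulates the molecular-size dependence of additive
empirical scoring functions; ``affinity_offset`` is the size-independent
signal separating bioactives from decoys; ``eps`` is Gaussian noise.  A
second "preparation" of the same benchmark perturbs this score: a small
jitter for every molecule (force-field/run-to-run differences), a shift for
molecules planted as differing between the preparations (protonation,
tautomer or ring-conformation variants), and a flexibility-coupled penalty
``coupling * n_rot * |eps'|`` for a planted flexible subset of bioactives
(conformational sampling of floppy molecules is where preparations diverge
most).  The first preparation is therefore the "favorable" scheme by
construction.

These are score lists with planted structure, not docking output.  When
``with_structures`` is set, each molecule is additionally realised as a
small real template molecule whose two SD variants *structurally* carry the
planted flag (different formal charges for protomer pairs, different H
placement/bond orders for tautomer pairs, different ring torsions for ring
pairs), so the molprops detectors can be validated end to end; in that case
NHA and rotor counts come from the template structures rather than from the
configured distributions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .io import HIGHER, ROLE_ACTIVE, ROLE_DECOY, ScoreTable, write_sdf

GENERATOR_VERSION = "1"

# Template molecules used to realise planted flags as real structures.
PLAIN_TEMPLATES = (
    "CC(=O)Oc1ccccc1C(=O)O",          # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",     # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",     # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",             # paracetamol
    "c1ccc2ccccc2c1",                 # naphthalene
    "CCOC(=O)c1ccccc1",               # ethyl benzoate
    "OCCN1CCOCC1",                    # 2-morpholinoethanol
    "CCCCCCCCO",                      # 1-octanol
)
PROTOMER_TEMPLATES = (
    ("CCC(=O)O", "CCC(=O)[O-]"),                  # propanoic acid / propanoate
    ("CCCCN", "CCCC[NH3+]"),                      # butylamine / butylammonium
    ("Oc1ccccc1", "[O-]c1ccccc1"),                # phenol / phenolate
    ("NCc1ccccc1", "[NH3+]Cc1ccccc1"),            # benzylamine / benzylammonium
    ("CC(C)C(=O)O", "CC(C)C(=O)[O-]"),            # isobutyric acid / isobutyrate
    ("c1ccncc1", "c1cc[nH+]cc1"),                 # pyridine / pyridinium
)
TAUTOMER_TEMPLATES = (
    ("O=c1cccc[nH]1", "Oc1ccccn1"),               # 2-pyridone / 2-hydroxypyridine
    ("CC(=O)CC(C)=O", "CC(=O)C=C(C)O"),           # acetylacetone keto / enol
)
RING_TEMPLATES = (
    "OC1CCCCC1",                                  # cyclohexanol
    "OC1CCCC1",                                   # cyclopentanol
    "O=C1CCCCC1",                                 # cyclohexanone
    "NC1CCCCC1",                                  # cyclohexylamine
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a paired-preparation benchmark.

    Defaults emulate the shape and score statistics of a DEKOIS-2.0-style
    benchmark: 40 bioactives with 30 property-matched decoys each; decoy
    scores around 75 with a spread of ~13 units; a bioactive-set mean
    heavy-atom count of 27.6; 2/40 bioactives and 435/1200 decoys planted
    as protomer-differing between the two preparations; and a 10-molecule
    flexible bioactive subset whose score divergence grows with rotor
    count.
    """

    n_actives: int = 40
    n_decoys: int = 1200
    nha_mean_actives: float = 27.6
    nha_sd_actives: float = 5.0
    nha_mean_decoys: float = 27.6
    nha_sd_decoys: float = 5.0
    base_score: float = 0.0
    bias_slope: float = 2.725         # score units per heavy atom
    affinity_offset: float = 15.0     # size-independent bioactive bonus
    noise_sd: float = 8.0
    prep_noise_sd: float = 2.0        # jitter applied to every second-prep score
    protomer_diff_fraction: tuple = (2 / 40, 435 / 1200)  # (actives, decoys)
    protomer_shift_sd: float = 8.0    # score shift of planted structural variants
    flexible_subset_size: int = 10
    flexibility_coupling: float = 1.0
    nrot_mean: float = 6.0
    nrot_sd: float = 3.0
    flexible_nrot_range: tuple = (9, 14)
    tautomer_diff_count: int = 1
    ring_diff_count: int = 2
    seed: int = 0
    with_structures: bool = False
    orientation: str = HIGHER
    program: str = "synthetic"
    first_prep: str = "schemeA"
    second_prep: str = "schemeB"

    def validate(self) -> None:
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ConfigError("need at least one bioactive and one decoy")
        fa, fd = self.protomer_diff_fraction
        if not (0 <= fa <= 1 and 0 <= fd <= 1):
            raise ConfigError("protomer_diff_fraction entries must lie in [0, 1]")
        if self.flexible_subset_size > self.n_actives:
            raise ConfigError("flexible_subset_size exceeds n_actives")
        n_prot_d = round(fd * self.n_decoys)
        if n_prot_d + self.tautomer_diff_count + self.ring_diff_count > self.n_decoys:
            raise ConfigError("planted decoy difference counts exceed n_decoys")
        if self.noise_sd < 0 or self.prep_noise_sd < 0 or self.protomer_shift_sd < 0:
            raise ConfigError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything needed to reproduce and verify a generated benchmark."""

    config: SyntheticConfig
    molecules: pd.DataFrame
    version: str = GENERATOR_VERSION

    def flagged_ids(self, flag: str) -> list[str]:
        """Ids carrying a planted flag: 'protomer', 'tautomer', 'ring' or
        'flexible'."""
        col = {"protomer": "flag_protomer", "tautomer": "flag_tautomer",
               "ring": "flag_ring", "flexible": "flexible"}[flag]
        return self.molecules.loc[self.molecules[col], "molecule_id"].tolist()

    def causes(self) -> dict[str, tuple]:
        """Per-molecule structural-difference cause flags, for rank-outlier
        annotation."""
        out: dict[str, tuple] = {}
        for row in self.molecules.itertuples(index=False):
            flags = []
            if row.flag_protomer:
                flags.append("protonation")
            if row.flag_tautomer:
                flags.append("tautomer")
            if row.flag_ring:
                flags.append("ring_conformation")
            if flags:
                out[row.molecule_id] = tuple(flags)
        return out

    def nha_map(self) -> dict[str, int]:
        return dict(zip(self.molecules["molecule_id"], self.molecules["nha"].astype(int)))

    def nrot_map(self) -> dict[str, int]:
        return dict(zip(self.molecules["molecule_id"], self.molecules["n_rot"].astype(int)))

    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "version": self.version,
            "config": dataclasses.asdict(self.config),
            "molecules": self.molecules.to_dict(orient="list"),
        }
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        cfg = doc["config"]
        for key in ("protomer_diff_fraction", "flexible_nrot_range"):
            cfg[key] = tuple(cfg[key])
        return cls(
            config=SyntheticConfig(**cfg),
            molecules=pd.DataFrame(doc["molecules"]),
            version=str(doc["version"]),
        )


@dataclass
class SyntheticBenchmark:
    """A generated paired benchmark: two score tables, optional paired
    structures, and the generative truth."""

    table_first: ScoreTable
    table_second: ScoreTable
    truth: SyntheticTruth
    structures_first: list = field(default_factory=list)
    structures_second: list = field(default_factory=list)

    def write(self, out_dir: str | Path, stem: str = "benchmark") -> dict[str, Path]:
        """Emit TSV tables, optional SD files and the truth sidecar."""
        from .io import write_score_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.truth.config
        paths = {
            "table_first": write_score_table(
                self.table_first, out_dir / f"{stem}_{cfg.first_prep}.tsv"
            ),
            "table_second": write_score_table(
                self.table_second, out_dir / f"{stem}_{cfg.second_prep}.tsv"
            ),
            "truth": self.truth.to_yaml(out_dir / f"{stem}_truth.yaml"),
        }
        if self.structures_first:
            paths["sdf_first"] = write_sdf(
                self.structures_first, out_dir / f"{stem}_{cfg.first_prep}.sdf"
            )
            paths["sdf_second"] = write_sdf(
                self.structures_second, out_dir / f"{stem}_{cfg.second_prep}.sdf"
            )
        return paths


# ---------------------------------------------------------------------------
# Structure realisation
# ---------------------------------------------------------------------------


def _embed(smiles: str, seed: int):
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigError(f"template SMILES failed to parse: {smiles!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise ConfigError(f"3D embedding failed for template {smiles!r}")
    return Chem.RemoveHs(molh)


def _copy_with_coords(target_smiles: str, source_mol):
    """Build ``target_smiles`` and give it the source's heavy-atom
    coordinates via an element-preserving graph mapping (the two must share
    a heavy skeleton)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    from .molprops import isomorphism_mappings

    target = Chem.MolFromSmiles(target_smiles)
    if target is None:
        raise ConfigError(f"template SMILES failed to parse: {target_smiles!r}")
    mappings = isomorphism_mappings(target, source_mol)
    if not mappings:
        raise ConfigError(
            f"template pair is not isomorphic: {target_smiles!r} vs source"
        )
    mapping = mappings[0]
    conf = Chem.Conformer(target.GetNumAtoms())
    src_conf = source_mol.GetConformer()
    for t_idx, s_idx in mapping.items():
        pos = src_conf.GetAtomPosition(s_idx)
        conf.SetAtomPosition(t_idx, Point3D(pos.x, pos.y, pos.z))
    target.RemoveAllConformers()
    target.AddConformer(conf, assignId=True)
    return target


def _mirror(mol):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    out = Chem.Mol(mol)
    conf = out.GetConformer()
    for i in range(out.GetNumAtoms()):
        pos = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, Point3D(-pos.x, pos.y, pos.z))
    return out


def _ring_conformer_pair(smiles: str, seed: int, threshold_deg: float, margin_deg: float = 15.0):
    """Two conformers of one ring template whose ring torsions verifiably
    differ by more than threshold + margin."""
    from rdkit import Chem

    from .molprops import detect_ring_conformation_difference

    base = _embed(smiles, seed)
    candidates = [_mirror(base)] + [_embed(smiles, seed + 101 + k) for k in range(8)]
    for cand in candidates:
        if detect_ring_conformation_difference(
            base, cand, torsion_threshold_deg=threshold_deg + margin_deg
        ):
            return base, cand
    raise ConfigError(
        f"could not realise a ring-conformation difference for template {smiles!r}"
    )


class _TemplateBank:
    """Deterministic, cached realisation of template structure pairs."""

    def __init__(self, seed: int, torsion_threshold_deg: float = 30.0):
        self.seed = int(seed)
        self.threshold = torsion_threshold_deg
        self._cache: dict[tuple, tuple] = {}

    def pair(self, kind: str, index: int):
        if kind == "plain":
            smiles = PLAIN_TEMPLATES[index % len(PLAIN_TEMPLATES)]
            key = ("plain", smiles)
            if key not in self._cache:
                mol = _embed(smiles, self.seed)
                self._cache[key] = (mol, mol)
        elif kind == "protomer":
            pair = PROTOMER_TEMPLATES[index % len(PROTOMER_TEMPLATES)]
            key = ("protomer", pair)
            if key not in self._cache:
                first = _embed(pair[0], self.seed)
                second = _copy_with_coords(pair[1], first)
                self._cache[key] = (first, second)
        elif kind == "tautomer":
            pair = TAUTOMER_TEMPLATES[index % len(TAUTOMER_TEMPLATES)]
            key = ("tautomer", pair)
            if key not in self._cache:
                first = _embed(pair[0], self.seed)
                second = _copy_with_coords(pair[1], first)
                self._cache[key] = (first, second)
        elif kind == "ring":
            smiles = RING_TEMPLATES[index % len(RING_TEMPLATES)]
            key = ("ring", smiles)
            if key not in self._cache:
                self._cache[key] = _ring_conformer_pair(smiles, self.seed, self.threshold)
        else:  # pragma: no cover - internal
            raise ValueError(kind)
        return self._cache[key]


def _named_copy(mol, molecule_id: str):
    from rdkit import Chem

    out = Chem.Mol(mol)
    out.SetProp("_Name", molecule_id)
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_benchmark(config: SyntheticConfig) -> SyntheticBenchmark:
    """Generate a paired-preparation benchmark from the additive score model
    (see module docstring).  Fully determined by ``config`` incl. its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_a, n_d = config.n_actives, config.n_decoys
    n = n_a + n_d
    width = max(4, len(str(n)))
    ids = [f"A{i + 1:0{width}d}" for i in range(n_a)] + [
        f"D{i + 1:0{width}d}" for i in range(n_d)
    ]
    roles = [ROLE_ACTIVE] * n_a + [ROLE_DECOY] * n_d
    is_active = np.array([r == ROLE_ACTIVE for r in roles])

    nha = np.empty(n, dtype=int)
    nha[:n_a] = np.clip(
        np.rint(rng.normal(config.nha_mean_actives, config.nha_sd_actives, n_a)), 5, None
    )
    nha[n_a:] = np.clip(
        np.rint(rng.normal(config.nha_mean_decoys, config.nha_sd_decoys, n_d)), 5, None
    )
    n_rot = np.clip(np.rint(rng.normal(config.nrot_mean, config.nrot_sd, n)), 0, 16).astype(int)

    # planted flexible bioactive subset with high rotor counts
    flexible = np.zeros(n, dtype=bool)
    flex_idx = rng.choice(n_a, size=config.flexible_subset_size, replace=False)
    flexible[flex_idx] = True
    lo, hi = config.flexible_nrot_range
    n_rot[flex_idx] = rng.integers(lo, hi + 1, size=config.flexible_subset_size)

    # planted structural differences
    frac_a, frac_d = config.protomer_diff_fraction
    n_prot_a, n_prot_d = round(frac_a * n_a), round(frac_d * n_d)
    flag_protomer = np.zeros(n, dtype=bool)
    # bioactive protomer variants drawn from the non-flexible bioactives
    # when possible (the flexible subset models a geometry effect instead)
    candidates_a = np.setdiff1d(np.arange(n_a), flex_idx)
    if candidates_a.size < n_prot_a:
        candidates_a = np.arange(n_a)
    flag_protomer[rng.choice(candidates_a, size=n_prot_a, replace=False)] = True
    flag_protomer[n_a + rng.choice(n_d, size=n_prot_d, replace=False)] = True
    flag_tautomer = np.zeros(n, dtype=bool)
    flag_ring = np.zeros(n, dtype=bool)
    free_decoys = np.flatnonzero(~flag_protomer[n_a:]) + n_a
    picked = rng.choice(
        free_decoys, size=config.tautomer_diff_count + config.ring_diff_count, replace=False
    )
    flag_tautomer[picked[: config.tautomer_diff_count]] = True
    flag_ring[picked[config.tautomer_diff_count:]] = True

    # structures (may override nha / n_rot with the template's real counts)
    structures_first: list = []
    structures_second: list = []
    templates: list[str] = [""] * n
    if config.with_structures:
        bank = _TemplateBank(seed=config.seed)
        counters = {"plain": 0, "protomer": 0, "tautomer": 0, "ring": 0}
        from .molprops import count_heavy_atoms, count_rotatable_bonds

        for i in range(n):
            if flag_protomer[i]:
                kind = "protomer"
            elif flag_tautomer[i]:
                kind = "tautomer"
            elif flag_ring[i]:
                kind = "ring"
            else:
                kind = "plain"
            mol_a, mol_b = bank.pair(kind, counters[kind])
            counters[kind] += 1
            structures_first.append(_named_copy(mol_a, ids[i]))
            structures_second.append(_named_copy(mol_b, ids[i]))
            templates[i] = f"{kind}:{counters[kind] - 1}"
            nha[i] = count_heavy_atoms(mol_a)
            n_rot[i] = max(count_rotatable_bonds(mol_a), count_rotatable_bonds(mol_b))

    # additive score model
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    score_first = (
        config.base_score
        + config.bias_slope * nha
        + config.affinity_offset * is_active
        + noise
    )
    prep_jitter = (
        rng.normal(0.0, config.prep_noise_sd, n) if config.prep_noise_sd > 0 else np.zeros(n)
    )
    struct_flag = flag_protomer | flag_tautomer | flag_ring
    struct_shift = np.where(
        struct_flag, rng.normal(0.0, config.protomer_shift_sd, n), 0.0
    )
    flex_draw = np.abs(rng.normal(0.0, 1.0, n))
    flex_term = np.where(flexible, config.flexibility_coupling * n_rot * flex_draw, 0.0)
    # the second preparation loses score on the flexible subset: the first
    # scheme is the favourable one by construction
    score_second = score_first + prep_jitter + struct_shift - flex_term

    molecules = pd.DataFrame(
        {
            "molecule_id": ids,
            "role": roles,
            "nha": nha,
            "n_rot": n_rot,
            "flag_protomer": flag_protomer,
            "flag_tautomer": flag_tautomer,
            "flag_ring": flag_ring,
            "flexible": flexible,
            "template": templates,
            "noise": noise,
            "prep_jitter": prep_jitter,
            "struct_shift": struct_shift,
            "flex_term": flex_term,
            "score_first": score_first,
            "score_second": score_second,
        }
    )
    truth = SyntheticTruth(config=config, molecules=molecules)

    def table(scores: np.ndarray, prep: str) -> ScoreTable:
        df = pd.DataFrame(
            {
                "molecule_id": ids,
                "role": roles,
                "score": scores,
                "nha": nha,
                "n_rot": n_rot,
            }
        )
        df["nha"] = df["nha"].astype("Int64")
        df["n_rot"] = df["n_rot"].astype("Int64")
        return ScoreTable(
            records=df,
            orientation=config.orientation,
            program=config.program,
            dataset_prep=prep,
            target_prep=prep,
        )

    return SyntheticBenchmark(
        table_first=table(score_first, config.first_prep),
        table_second=table(score_second, config.second_prep),
        truth=truth,
        structures_first=structures_first,
        structures_second=structures_second,
    )


def replay(truth: SyntheticTruth) -> SyntheticBenchmark:
    """Regenerate a benchmark bit-identically from its truth sidecar."""
    if truth.version != GENERATOR_VERSION:
        raise ConfigError(
            f"truth was produced by generator version {truth.version!r}, "
            f"this is version {GENERATOR_VERSION!r}"
        )
    return generate_benchmark(truth.config)
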