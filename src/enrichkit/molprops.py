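"""Structure-level descriptors and pairwise preparation-difference audits.

Ligand preparation pipelines (protonation assignment, tautomer selection,
force-field minimization) can emit two different molecules for the same
input id.  Given the two SD structures this module decides *how* they
differ:

* **protonation** — hydrogens added/removed at ionizable sites, changing
  formal charges and/or the total hydrogen count;
* **tautomer** — same formula, but hydrogens and bond orders rearranged
  over the heavy-atom skeleton;
* **ring conformation** — identical molecule whose non-aromatic 5-7-ring
  pucker differs between the two 3D conformers (circular torsion
  difference above a threshold);

and quantifies geometric divergence as a symmetry-aware heavy-atom RMSD:
the minimum RMSD over all graph isomorphisms between the two heavy-atom
skeletons, optionally after optimal rigid-body superposition (Kabsch) per
mapping.  Hydrogens are excluded throughout, because the preparation
schemes differ precisely in the hydrogens they add and those would swamp
the comparison.

All detectors are symmetric in their two arguments, and a pair whose
heavy-atom graphs are not isomorphic is reported invalid rather than
scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .compare import squared_pearson
from .errors import InvalidPairError, ValidationError

# Enumerating graph isomorphisms of highly symmetric molecules explodes
# combinatorially; above this many mappings a class-based assignment
# fallback is used (see symmetry_aware_rmsd).
DEFAULT_AUTOMORPHISM_CAP = 10_000

RING_SIZES = (5, 6, 7)
DEFAULT_TORSION_THRESHOLD = 30.0  # degrees


# ---------------------------------------------------------------------------
# Basic descriptors
# ---------------------------------------------------------------------------


def count_heavy_atoms(mol) -> int:
    """Number of atoms with atomic number > 1."""
    n = sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() > 1)
    if n == 0:
        raise ValidationError("molecule has no heavy atoms")
    return n


def _heavy_degree(atom) -> int:
    return sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)


def _is_amide_cn(carbon, nitrogen) -> bool:
    from rdkit import Chem

    if carbon.GetAtomicNum() != 6 or nitrogen.GetAtomicNum() != 7:
        return False
    for bond in carbon.GetBonds():
        other = bond.GetOtherAtom(carbon)
        if other.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def count_rotatable_bonds(mol) -> int:
    """Rotatable bonds: acyclic single bonds between two non-terminal heavy
    atoms, excluding amide C-N bonds.

    "Non-terminal" means each end has at least two heavy neighbours; the
    amide exclusion removes C-N bonds where the carbon bears a double-bonded
    oxygen (their rotation is hindered by conjugation).
    """
    from rdkit import Chem

    count = 0
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if _heavy_degree(a) < 2 or _heavy_degree(b) < 2:
            continue
        if _is_amide_cn(a, b) or _is_amide_cn(b, a):
            continue
        count += 1
    return count


@dataclass(frozen=True)
class MolDescriptor:
    """Structure descriptors of one preparation variant of a molecule."""

    molecule_id: str
    nha: int
    n_rot: int
    total_charge: int
    total_h: int
    formal_charges: tuple  # ((heavy atom index, charge), ...) for charged atoms
    tautomer_key: str  # canonical SMILES: heavy-atom graph + hydrogen counts
    has_coordinates: bool


def describe(mol, molecule_id: str = "") -> MolDescriptor:
    from rdkit import Chem

    if not molecule_id and mol.HasProp("_Name"):
        molecule_id = mol.GetProp("_Name")
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    charges = tuple(
        (a.GetIdx(), a.GetFormalCharge()) for a in heavy if a.GetFormalCharge() != 0
    )
    return MolDescriptor(
        molecule_id=molecule_id,
        nha=count_heavy_atoms(mol),
        n_rot=count_rotatable_bonds(mol),
        total_charge=Chem.GetFormalCharge(mol),
        total_h=sum(a.GetTotalNumHs(includeNeighbors=True) for a in heavy),
        formal_charges=charges,
        tautomer_key=Chem.MolToSmiles(Chem.RemoveHs(mol)),
        has_coordinates=mol.GetNumConformers() > 0,
    )


# ---------------------------------------------------------------------------
# Heavy-atom graphs and isomorphism mappings
# ---------------------------------------------------------------------------


def heavy_graph(mol) -> nx.Graph:
    """Heavy-atom graph with element/charge/H-count node data and perceived
    bond orders (aromatic = 1.5) as edge data."""
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
            hcount=atom.GetTotalNumHs(includeNeighbors=True),
        )
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        g.add_edge(a.GetIdx(), b.GetIdx(), order=bond.GetBondTypeAsDouble())
    if g.number_of_nodes() == 0:
        raise ValidationError("molecule has no heavy atoms")
    return g


def isomorphism_mappings(
    mol_first,
    mol_second,
    match_bond_orders: bool = False,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> list[dict]:
    """Heavy-atom graph isomorphisms first -> second (element-preserving;
    optionally bond-order-preserving).  Returns at most ``cap + 1`` mappings
    so callers can detect overflow."""
    ga, gb = heavy_graph(mol_first), heavy_graph(mol_second)

    def node_match(n1, n2):
        return n1["element"] == n2["element"]

    edge_match = (lambda e1, e2: e1["order"] == e2["order"]) if match_bond_orders else None
    matcher = nx.isomorphism.GraphMatcher(ga, gb, node_match=node_match, edge_match=edge_match)
    out: list[dict] = []
    for mapping in matcher.isomorphisms_iter():
        out.append(dict(mapping))
        if len(out) > cap:
            break
    return out


def _require_isomorphic(mol_first, mol_second, cap: int = DEFAULT_AUTOMORPHISM_CAP) -> list[dict]:
    mappings = isomorphism_mappings(mol_first, mol_second, cap=cap)
    if not mappings:
        raise InvalidPairError(
            "heavy-atom graphs are not isomorphic; not two preparations of one molecule"
        )
    return mappings


# ---------------------------------------------------------------------------
# Protonation / tautomer difference detection
# ---------------------------------------------------------------------------


def detect_protonation_difference(mol_first, mol_second) -> tuple[bool, tuple]:
    """Do the two variants differ in protonation state?

    True when the total formal charge or total hydrogen count differs, or —
    for pairs whose heavy-atom bond orders are preserved under some mapping
    — when formal charges moved between atoms (zwitterion shifts).  Returns
    the flag plus per-atom detail ``(idx_first, idx_second, (charge, H)
    first, (charge, H) second)`` for mismatched atoms under the
    best-agreeing mapping.
    """
    from rdkit import Chem

    _require_isomorphic(mol_first, mol_second)
    d1, d2 = describe(mol_first), describe(mol_second)
    totals_differ = (d1.total_charge != d2.total_charge) or (d1.total_h != d2.total_h)

    bond_preserving = isomorphism_mappings(mol_first, mol_second, match_bond_orders=True)
    detail: tuple = ()
    charges_moved = False
    if bond_preserving:
        ga, gb = heavy_graph(mol_first), heavy_graph(mol_second)
        best: list | None = None
        for mapping in bond_preserving:
            mismatches = [
                (
                    i,
                    j,
                    (ga.nodes[i]["charge"], ga.nodes[i]["hcount"]),
                    (gb.nodes[j]["charge"], gb.nodes[j]["hcount"]),
                )
                for i, j in mapping.items()
                if (ga.nodes[i]["charge"], ga.nodes[i]["hcount"])
                != (gb.nodes[j]["charge"], gb.nodes[j]["hcount"])
            ]
            if best is None or len(mismatches) < len(best):
                best = mismatches
            if not best:
                break
        detail = tuple(best or ())
        charges_moved = any(c1 != c2 for _, _, (c1, _h1), (c2, _h2) in detail)
    return bool(totals_differ or charges_moved), detail


def detect_tautomer_difference(mol_first, mol_second) -> bool:
    """Do the two variants differ in tautomeric state?

    Requires identical molecular formula (same heavy skeleton, total H and
    total charge); within that, a tautomer difference is a rearrangement of
    bond orders and/or hydrogen placement: either no bond-order-preserving
    mapping exists, or one exists but hydrogens sit on different (uncharged)
    atoms.  A pure protonation difference never qualifies.
    """
    _require_isomorphic(mol_first, mol_second)
    d1, d2 = describe(mol_first), describe(mol_second)
    if d1.total_charge != d2.total_charge or d1.total_h != d2.total_h:
        raise InvalidPairError(
            "molecular formula differs between variants; compare protonation instead"
        )
    bond_preserving = isomorphism_mappings(mol_first, mol_second, match_bond_orders=True)
    if not bond_preserving:
        return True
    ga, gb = heavy_graph(mol_first), heavy_graph(mol_second)
    for mapping in bond_preserving:
        if all(
            (ga.nodes[i]["charge"], ga.nodes[i]["hcount"])
            == (gb.nodes[j]["charge"], gb.nodes[j]["hcount"])
            for i, j in mapping.items()
        ):
            return False  # some mapping reconciles everything: same tautomer
    # Bond orders preserved but H placement irreconcilable; if charges also
    # moved this is a protonation (zwitterion) difference, not a tautomer.
    protonation, _ = detect_protonation_difference(mol_first, mol_second)
    return not protonation


# ---------------------------------------------------------------------------
# Ring conformation comparison
# ---------------------------------------------------------------------------


def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def _conformer_coords(mol) -> dict[int, np.ndarray]:
    if mol.GetNumConformers() == 0:
        raise ValidationError("molecule has no 3D coordinates")
    conf = mol.GetConformer()
    return {
        atom.GetIdx(): np.array(conf.GetAtomPosition(atom.GetIdx()), dtype=float)
        for atom in mol.GetAtoms()
        if atom.GetAtomicNum() > 1
    }


def flexible_rings(mol) -> list[tuple[int, ...]]:
    """Non-aromatic rings of size 5-7, as ordered heavy-atom index tuples."""
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) not in RING_SIZES:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if any(a.GetIsAromatic() for a in atoms):
            continue
        if any(a.GetAtomicNum() <= 1 for a in atoms):
            continue
        rings.append(tuple(ring))
    return rings


def ring_torsions(mol, ring: Sequence[int], coords: dict | None = None) -> list[float]:
    """Endocyclic torsions (degrees) around an ordered ring atom tuple."""
    if coords is None:
        coords = _conformer_coords(mol)
    n = len(ring)
    out = []
    for i in range(n):
        quad = [ring[(i + k) % n] for k in range(-1, 3)]
        out.append(_dihedral_deg(*(coords[q] for q in quad)))
    return out


def detect_ring_conformation_difference(
    mol_first,
    mol_second,
    torsion_threshold_deg: float = DEFAULT_TORSION_THRESHOLD,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> bool:
    """Did the two conformers pick different flexible-ring conformations?

    For each non-aromatic ring of size 5-7, endocyclic torsions are compared
    under every heavy-atom mapping (circular differences); the pair is
    flagged when even the best-agreeing mapping leaves some ring torsion
    more than ``torsion_threshold_deg`` apart.  Exocyclic torsions are out
    of scope by construction.  Pairs without such a ring are never flagged.
    """
    mappings = _require_isomorphic(mol_first, mol_second, cap=cap)
    coords_a = _conformer_coords(mol_first)
    coords_b = _conformer_coords(mol_second)
    rings = flexible_rings(mol_first)
    if not rings:
        return False
    best_worst = np.inf
    for mapping in mappings:
        worst = 0.0
        for ring in rings:
            t_a = ring_torsions(mol_first, ring, coords_a)
            mapped_ring = [mapping[i] for i in ring]
            t_b = ring_torsions(mol_second, mapped_ring, coords_b)
            worst = max(
                worst,
                max(circular_difference_deg(a, b) for a, b in zip(t_a, t_b)),
            )
        best_worst = min(best_worst, worst)
        if best_worst <= torsion_threshold_deg:
            return False
    return bool(best_worst > torsion_threshold_deg)


# ---------------------------------------------------------------------------
# Symmetry-aware RMSD
# ---------------------------------------------------------------------------


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal rigid-body superposition of P onto Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def _rmsd_for_mapping(
    coords_a: dict, coords_b: dict, mapping: dict, superimpose: bool
) -> float:
    keys = sorted(mapping)
    P = np.array([coords_a[i] for i in keys])
    Q = np.array([coords_b[mapping[i]] for i in keys])
    if superimpose:
        return kabsch_rmsd(P, Q)
    return float(np.sqrt(((P - Q) ** 2).sum() / len(P)))


def _class_fallback_mapping(mol_first, mol_second, seed_mapping: dict) -> dict:
    """Refine a single isomorphism by Hungarian assignment within symmetry
    equivalence classes, used when full automorphism enumeration overflows.

    Atoms of the first molecule are grouped by canonical rank (computed
    without tie-breaking, so symmetry-equivalent atoms share a rank); each
    class is re-assigned to its image under the seed mapping by minimum
    total squared distance after a seed-mapping superposition.  The result
    is an upper bound on the true minimum: the assignment is anchored to
    the seed mapping's frame and may settle in a nearby local optimum.
    """
    from rdkit import Chem
    from scipy.optimize import linear_sum_assignment

    coords_a = _conformer_coords(mol_first)
    coords_b = _conformer_coords(mol_second)
    keys = sorted(seed_mapping)
    P = np.array([coords_a[i] for i in keys])
    Q = np.array([coords_b[seed_mapping[i]] for i in keys])
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    aligned = {i: p for i, p in zip(keys, Pc @ R.T)}
    centered_b = {seed_mapping[i]: q for i, q in zip(keys, Qc)}

    ranks = list(Chem.CanonicalRankAtoms(mol_first, breakTies=False))
    classes: dict[int, list[int]] = {}
    for i in keys:
        classes.setdefault(ranks[i], []).append(i)
    mapping: dict[int, int] = {}
    for members in classes.values():
        targets = [seed_mapping[i] for i in members]
        cost = np.array(
            [[np.sum((aligned[i] - centered_b[j]) ** 2) for j in targets] for i in members]
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            mapping[members[r]] = targets[c]
    return mapping


def symmetry_aware_rmsd(
    mol_first,
    mol_second,
    superimpose: bool = True,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> float:
    """Minimum heavy-atom RMSD over all graph isomorphisms between the two
    structures (the "smart" RMSD that a naive atom-order comparison of a
    symmetric molecule overestimates).

    With ``superimpose`` the optimal rigid-body superposition is computed
    per mapping (Kabsch); without it coordinates are compared in place.
    When the number of mappings exceeds ``cap`` a class-based assignment
    fallback is used (see :func:`_class_fallback_mapping`).
    """
    mappings = _require_isomorphic(mol_first, mol_second, cap=cap)
    coords_a = _conformer_coords(mol_first)
    coords_b = _conformer_coords(mol_second)
    if len(mappings) > cap:
        mapping = _class_fallback_mapping(mol_first, mol_second, mappings[0])
        return _rmsd_for_mapping(coords_a, coords_b, mapping, superimpose)
    return min(
        _rmsd_for_mapping(coords_a, coords_b, mapping, superimpose)
        for mapping in mappings
    )


def identity_rmsd(mol_first, mol_second, superimpose: bool = True) -> float:
    """RMSD under the identity atom-index mapping (no symmetry search)."""
    coords_a = _conformer_coords(mol_first)
    coords_b = _conformer_coords(mol_second)
    if sorted(coords_a) != sorted(coords_b):
        raise ValidationError("identity mapping needs identical heavy-atom indexing")
    mapping = {i: i for i in coords_a}
    return _rmsd_for_mapping(coords_a, coords_b, mapping, superimpose)


# ---------------------------------------------------------------------------
# Pair audit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrepPairRecord:
    """Audit result for one molecule's two preparation variants."""

    molecule_id: str
    valid: bool
    descriptor_first: MolDescriptor | None = None
    descriptor_second: MolDescriptor | None = None
    differs_protonation: bool = False
    differs_tautomer: bool = False
    differs_ring_conformation: bool = False
    pairwise_rmsd: float = float("nan")
    protonation_detail: tuple = ()
    error: str = ""

    @property
    def difference_flags(self) -> tuple:
        flags = []
        if self.differs_protonation:
            flags.append("protonation")
        if self.differs_tautomer:
            flags.append("tautomer")
        if self.differs_ring_conformation:
            flags.append("ring_conformation")
        return tuple(flags)


def audit_pair(
    mol_first,
    mol_second,
    molecule_id: str = "",
    torsion_threshold_deg: float = DEFAULT_TORSION_THRESHOLD,
    superimpose: bool = True,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> PrepPairRecord:
    """Full difference audit of one preparation pair.

    Non-isomorphic pairs come back with ``valid=False`` instead of raising,
    so bulk audits keep going and report the failure.
    """
    if not molecule_id and mol_first.HasProp("_Name"):
        molecule_id = mol_first.GetProp("_Name")
    try:
        _require_isomorphic(mol_first, mol_second, cap=cap)
    except (InvalidPairError, ValidationError) as exc:
        return PrepPairRecord(molecule_id=molecule_id, valid=False, error=str(exc))
    d1 = describe(mol_first, molecule_id)
    d2 = describe(mol_second, molecule_id)
    protonation, detail = detect_protonation_difference(mol_first, mol_second)
    same_formula = d1.total_charge == d2.total_charge and d1.total_h == d2.total_h
    tautomer = (
        detect_tautomer_difference(mol_first, mol_second) if same_formula else False
    )
    has_coords = d1.has_coordinates and d2.has_coordinates
    ring = (
        detect_ring_conformation_difference(
            mol_first, mol_second, torsion_threshold_deg=torsion_threshold_deg, cap=cap
        )
        if has_coords
        else False
    )
    rmsd = (
        symmetry_aware_rmsd(mol_first, mol_second, superimpose=superimpose, cap=cap)
        if has_coords
        else float("nan")
    )
    return PrepPairRecord(
        molecule_id=molecule_id,
        valid=True,
        descriptor_first=d1,
        descriptor_second=d2,
        differs_protonation=protonation,
        differs_tautomer=tautomer,
        differs_ring_conformation=ring,
        pairwise_rmsd=rmsd,
        protonation_detail=detail,
    )


def audit_pairs(
    pairs: dict,
    torsion_threshold_deg: float = DEFAULT_TORSION_THRESHOLD,
    superimpose: bool = True,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> list[PrepPairRecord]:
    """Audit every (mol_first, mol_second) pair in an id-keyed mapping."""
    return [
        audit_pair(
            a,
            b,
            molecule_id=mid,
            torsion_threshold_deg=torsion_threshold_deg,
            superimpose=superimpose,
            cap=cap,
        )
        for mid, (a, b) in pairs.items()
    ]


def audit_summary(records: Iterable[PrepPairRecord]) -> dict:
    """Set-level census of a pair audit (counts and mean pairwise RMSD)."""
    records = list(records)
    valid = [r for r in records if r.valid]
    rmsds = [r.pairwise_rmsd for r in valid if np.isfinite(r.pairwise_rmsd)]
    return {
        "n_pairs": len(records),
        "n_invalid": len(records) - len(valid),
        "n_protonation": sum(r.differs_protonation for r in valid),
        "n_tautomer": sum(r.differs_tautomer for r in valid),
        "n_ring_conformation": sum(r.differs_ring_conformation for r in valid),
        "mean_pairwise_rmsd": float(np.mean(rmsds)) if rmsds else float("nan"),
    }


def correlate_property(delta_fitness: Sequence[float], prop: Sequence[float]):
    """Squared Pearson correlation of a score-difference vector against a
    molecular property; ``None`` flags an undefined result (zero variance)."""
    x = np.asarray(delta_fitness, dtype=float)
    y = np.asarray(prop, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    return squared_pearson(x, y)
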