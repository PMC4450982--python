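import numpy as np
import pytest

import enrichkit as ek


def embed_smiles(smiles: str, seed: int = 7):
    """Small real molecule with a deterministic 3D conformer, no explicit H."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(molh, params) == 0
    return Chem.RemoveHs(molh)


def powers_of_ten_table() -> ek.ScoreTable:
    """2 bioactives among 100 decoys with decoy fractions exactly 0.1 and
    0.01: one decoy outranks the first bioactive, ten outrank the second."""
    ids, roles, scores = [], [], []
    for i in range(100):
        ids.append(f"d{i:03d}")
        roles.append(ek.ROLE_DECOY)
        scores.append(100.0 - i)  # 100 down to 1
    ids += ["a_first", "a_second"]
    roles += [ek.ROLE_ACTIVE, ek.ROLE_ACTIVE]
    scores += [99.5, 90.5]  # 1 decoy above -> f=0.01; 10 above -> f=0.1
    return ek.make_score_table(ids, roles, scores)


@pytest.fixture
def two_active_table() -> ek.ScoreTable:
    return powers_of_ten_table()


@pytest.fixture(scope="session")
def default_benchmark() -> ek.SyntheticBenchmark:
    """Full-size (40 + 1200) structure-free benchmark at the default study
    conditions."""
    return ek.generate_benchmark(ek.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def structure_benchmark() -> ek.SyntheticBenchmark:
    """Down-scaled benchmark with paired SD structures for every molecule."""
    config = ek.SyntheticConfig(
        n_actives=8,
        n_decoys=40,
        protomer_diff_fraction=(2 / 8, 10 / 40),
        flexible_subset_size=3,
        tautomer_diff_count=2,
        ring_diff_count=2,
        with_structures=True,
        seed=5,
    )
    return ek.generate_benchmark(config)


def brute_force_proc_auc(roles, scores, orientation=ek.HIGHER, floor=None):
    """Independent pROC-AUC oracle: walk the explicitly sorted list and
    count decoys ahead of each bioactive (half-weight for exact ties)."""
    n_d = sum(1 for r in roles if r == ek.ROLE_DECOY)
    n_a = len(roles) - n_d
    if floor is None:
        floor = 1.0 / n_d
    terms = []
    for i in range(len(scores)):
        if roles[i] != ek.ROLE_ACTIVE:
            continue
        better = tied = 0
        for j in range(len(scores)):
            if roles[j] != ek.ROLE_DECOY:
                continue
            if scores[j] == scores[i]:
                tied += 1
            elif (scores[j] > scores[i]) == (orientation == ek.HIGHER):
                better += 1
        f = max((better + 0.5 * tied) / n_d, floor)
        terms.append(np.log10(1.0 / f))
    return float(np.mean(terms))
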