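import itertools
import math

import numpy as np
import pandas as pd
import pytest

import enrichkit as ek
from conftest import brute_force_proc_auc
from enrichkit.compare import (
    GRID_FACTORS,
    flag_rank_outliers,
    isolate_outlier_subset,
    squared_pearson,
)
from enrichkit.errors import ValidationError


def small_table(seed=0, n_actives=5, n_decoys=30, bonus=0.0):
    rng = np.random.default_rng(seed)
    n = n_actives + n_decoys
    ids = [f"m{i:03d}" for i in range(n)]
    roles = [ek.ROLE_ACTIVE if i < n_actives else ek.ROLE_DECOY for i in range(n)]
    scores = rng.normal(50, 10, n)
    scores[:n_actives] += 8 + bonus
    return ek.make_score_table(ids, roles, scores)


class TestMatchMismatchGrid:
    def _keys(self):
        return list(itertools.product(("P", "Q"), repeat=3))

    def test_identical_tables_give_flat_grid(self):
        t = small_table(seed=1)
        grid = ek.match_mismatch_grid({k: t for k in self._keys()})
        aucs = {c.auc for c in grid.cells.values()}
        assert len(aucs) == 1
        assert all(abs(m) < 1e-12 for m in grid.marginals.values())

    def test_bioactive_prep_effect_dominates_when_planted(self):
        # only the bioactives-prep toggle changes scores: "P" bioactives
        # carry a score bonus
        tables = {}
        for key in self._keys():
            bonus = 6.0 if key[1] == "P" else 0.0
            tables[key] = small_table(seed=2, bonus=bonus)
        grid = ek.match_mismatch_grid(tables)
        effects = {f: abs(v) for f, v in grid.marginals.items()}
        assert effects["bioactives_prep"] > effects["target_prep"]
        assert effects["bioactives_prep"] > effects["decoys_prep"]
        assert grid.marginals["target_prep"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_random_cells_have_small_marginals(self):
        tables = {k: small_table(seed=100 + i) for i, k in enumerate(self._keys())}
        grid = ek.match_mismatch_grid(tables)
        for effect in grid.marginals.values():
            assert abs(effect) < 0.5  # Monte-Carlo noise scale, no systematic factor

    def test_marginals_agree_with_direct_toggling(self):
        tables = {
            k: small_table(seed=3, bonus=2.0 * (k[0] == "P") + 5.0 * (k[1] == "P"))
            for k in self._keys()
        }
        grid = ek.match_mismatch_grid(tables)
        for axis, factor in enumerate(GRID_FACTORS):
            diffs = []
            for key in self._keys():
                if key[axis] != "P":
                    continue
                other = list(key)
                other[axis] = "Q"
                diffs.append(grid.cells[key].auc - grid.cells[tuple(other)].auc)
            assert grid.marginals[factor] == pytest.approx(np.mean(diffs))

    def test_missing_cell_named(self):
        tables = {k: small_table() for k in self._keys()[:-1]}
        with pytest.raises(ValidationError, match="8"):
            ek.match_mismatch_grid(tables)


class TestShuffleProtomers:
    def test_empty_ids_is_exact_noop(self):
        base, donor = small_table(seed=4), small_table(seed=5)
        res = ek.shuffle_protomers(base, donor, [])
        assert res.delta == 0.0
        assert res.swapped_role == "none"

    def test_full_replacement_matches_donor(self):
        base, donor = small_table(seed=6), small_table(seed=7)
        res = ek.shuffle_protomers(base, donor, list(base.molecule_ids))
        assert res.auc_after == pytest.approx(ek.screen_performance(donor).auc)

    def test_shuffle_back_restores(self):
        base, donor = small_table(seed=8), small_table(seed=9)
        ids = ["m001", "m010", "m020"]
        out = ek.shuffle_protomers(base, donor, ids)
        back = ek.shuffle_protomers(out.table_after, base, ids)
        assert back.auc_after == pytest.approx(out.auc_before)

    def test_unknown_id_rejected(self):
        base, donor = small_table(), small_table(seed=1)
        with pytest.raises(ValidationError, match="nope"):
            ek.shuffle_protomers(base, donor, ["nope"])

    def test_planted_protomer_shuffle_is_smaller_than_full_delta(self, default_benchmark):
        truth = default_benchmark.truth
        first, second = default_benchmark.table_first, default_benchmark.table_second
        full = abs(
            ek.screen_performance(first).auc - ek.screen_performance(second).auc
        )
        res = ek.shuffle_protomers(first, second, truth.flagged_ids("protomer"))
        assert abs(res.delta) < full


class TestDeleteAndRescore:
    def test_delete_nothing_is_identity(self):
        t = small_table(seed=10)
        assert ek.delete_and_rescore(t, []) == ek.screen_performance(t)

    def test_matches_brute_force_after_deleting_last_decoy(self):
        scores = [9.0, 7.0, 8.0, 6.0, 5.0, 4.0, 3.0, 1.0]
        roles = [ek.ROLE_ACTIVE, ek.ROLE_ACTIVE] + [ek.ROLE_DECOY] * 6
        ids = [f"m{i}" for i in range(8)]
        t = ek.make_score_table(ids, roles, scores)
        result = ek.delete_and_rescore(t, ["m7"])  # decoy ranked strictly last
        expected = brute_force_proc_auc(roles[:7], scores[:7])
        assert result.auc == pytest.approx(expected)
        assert result.n_decoys == 5
        assert result.floor == pytest.approx(1 / 5)

    def test_delete_top_active_leaves_single_active_formula(self):
        t = ek.make_score_table(
            ["a1", "a2", "d1", "d2", "d3", "d4"],
            [ek.ROLE_ACTIVE, ek.ROLE_ACTIVE] + [ek.ROLE_DECOY] * 4,
            [10.0, 5.5, 9.0, 8.0, 7.0, 1.0],
        )
        result = ek.delete_and_rescore(t, ["a1"])
        # a2 has 3 of 4 decoys above it
        assert result.auc == pytest.approx(math.log10(1 / 0.75))

    def test_construction_path_independence(self):
        t = small_table(seed=11)
        ids = ["m000", "m012", "m030"]
        direct = ek.delete_and_rescore(t, ids)
        kept = t.records[~t.records["molecule_id"].isin(ids)]
        fresh = ek.make_score_table(
            kept["molecule_id"], kept["role"], kept["score"]
        )
        assert direct == ek.screen_performance(fresh)

    def test_emptying_a_role_class_rejected(self):
        t = small_table(n_actives=1)
        with pytest.raises(ValidationError, match="role"):
            ek.delete_and_rescore(t, ["m000"])


class TestRankShiftAnalysis:
    def test_identical_tables(self):
        t = small_table(seed=12)
        res = ek.rank_shift_analysis(t, t)
        assert (res.records["delta_rank"] == 0).all()
        assert (res.records["delta_fitness"] == 0).all()
        assert res.summary["score_preference"] == {"first": 0.5, "second": 0.5}
        assert res.summary["rank_preference"] == {"first": 0.5, "second": 0.5}
        assert res.summary["r2_scores"] == pytest.approx(1.0)
        assert res.summary["r2_ranks"] == pytest.approx(1.0)

    def test_swapping_two_scores_moves_exactly_those_two(self):
        t = small_table(seed=13)
        df = t.records.copy()
        i, j = 3, 20
        df.loc[i, "score"], df.loc[j, "score"] = (
            df.loc[j, "score"],
            df.loc[i, "score"],
        )
        res = ek.rank_shift_analysis(t, t.with_records(df))
        moved = set(res.records.loc[res.records["delta_rank"] != 0, "molecule_id"])
        assert moved == {t.records.loc[i, "molecule_id"], t.records.loc[j, "molecule_id"]}

    def test_antisymmetry(self):
        a, b = small_table(seed=14), small_table(seed=15)
        ab = ek.rank_shift_analysis(a, b).records.set_index("molecule_id")
        ba = ek.rank_shift_analysis(b, a).records.set_index("molecule_id")
        assert (ab["delta_rank"] + ba.loc[ab.index, "delta_rank"] == 0).all()
        assert np.allclose(ab["delta_fitness"], -ba.loc[ab.index, "delta_fitness"])

    def test_id_mismatch_lists_symmetric_difference(self):
        a = small_table(seed=16)
        b_records = small_table(seed=16).records.copy()
        b_records.loc[0, "molecule_id"] = "stranger"
        b = a.with_records(b_records)
        with pytest.raises(ValidationError, match="stranger"):
            ek.rank_shift_analysis(a, b)

    def test_box_stats_quartiles(self):
        t = small_table(seed=17)
        res = ek.rank_shift_analysis(t, t)
        stats = res.summary["box_stats"][ek.ROLE_DECOY]["first"]["rank"]
        ranks = ek.rank_list(t).table
        decoy_ranks = ranks.loc[ranks["role"] == ek.ROLE_DECOY, "global_rank"].to_numpy()
        assert stats["min"] == decoy_ranks.min()
        assert stats["median"] == pytest.approx(np.percentile(decoy_ranks, 50))

    def test_generator_pair_scores_correlate_better_than_ranks(self, default_benchmark):
        res = ek.rank_shift_analysis(
            default_benchmark.table_first, default_benchmark.table_second
        )
        assert res.summary["r2_scores"] > 0.8
        assert res.summary["r2_ranks"] > 0.5
        assert res.summary["r2_scores"] > res.summary["r2_ranks"]


class TestFlagRankOutliers:
    def test_no_outliers_below_cutoff(self):
        records = pd.DataFrame(
            {"molecule_id": ["a", "b"], "delta_rank": [10, -400]}
        )
        assert flag_rank_outliers(records, cutoff=500).empty

    def test_single_large_shift_flagged(self):
        records = pd.DataFrame(
            {"molecule_id": ["a", "b", "c"], "delta_rank": [600, -10, 0]}
        )
        out = flag_rank_outliers(records, cutoff=500)
        assert list(out["molecule_id"]) == ["a"]
        assert bool(out.loc[0, "cause_none"])

    def test_generator_truth_causes_annotated(self, default_benchmark):
        truth = default_benchmark.truth
        res = ek.rank_shift_analysis(
            default_benchmark.table_first, default_benchmark.table_second
        )
        out = flag_rank_outliers(
            res.records,
            cutoff=truth.config.n_decoys // 4,
            causes=truth.causes(),
            n_rot=truth.nrot_map(),
        )
        assert not out.empty
        flags = truth.molecules.set_index("molecule_id")
        for row in out.itertuples(index=False):
            assert row.cause_protonation == flags.loc[row.molecule_id, "flag_protomer"]
            assert row.cause_tautomer == flags.loc[row.molecule_id, "flag_tautomer"]
            assert row.cause_ring_conformation == flags.loc[row.molecule_id, "flag_ring"]
            structural = (
                row.cause_protonation or row.cause_tautomer or row.cause_ring_conformation
            )
            assert row.cause_none == (not structural)


class TestIsolateOutlierSubset:
    def test_perfect_correlation_tie_break_by_id(self):
        x = np.arange(10.0)
        ids = [f"m{i}" for i in range(10)]
        res = isolate_outlier_subset(x, x, k=2, ids=ids)
        assert res.r2_core == pytest.approx(1.0)
        assert res.outlier_ids == ("m0", "m1")  # all residuals 0 -> id order

    def test_planted_offsets_recovered_exactly(self):
        rng = np.random.default_rng(21)
        n_core, n_out = 30, 10
        x = np.concatenate([rng.uniform(60, 120, n_core), rng.uniform(60, 120, n_out)])
        y = x + 3.0  # identity-direction core
        offsets = rng.uniform(15, 30, n_out) * rng.choice([-1, 1], n_out)
        y[n_core:] += offsets
        ids = [f"core{i}" for i in range(n_core)] + [f"out{i}" for i in range(n_out)]
        res = isolate_outlier_subset(x, y, k=n_out, ids=ids)
        assert sorted(res.outlier_ids) == sorted(f"out{i}" for i in range(n_out))
        assert res.r2_core == pytest.approx(1.0)

    def test_outlier_property_correlation_reported(self):
        rng = np.random.default_rng(22)
        n = 40
        x = rng.uniform(50, 100, n)
        y = x.copy()
        rotors = rng.integers(1, 6, n).astype(float)
        out_idx = np.arange(30, 40)
        rotors[out_idx] = np.arange(8, 18)
        y[out_idx] += 2.5 * rotors[out_idx]  # divergence grows with rotors
        res = isolate_outlier_subset(
            x, y, k=10, ids=[str(i) for i in range(n)], properties={"n_rot": rotors}
        )
        assert sorted(int(i) for i in res.outlier_ids) == list(out_idx)
        assert res.r2_outlier_vs_property["n_rot"] > 0.9

    def test_flexibility_coupled_outliers_on_generator(self, default_benchmark):
        truth = default_benchmark.truth
        actives = truth.molecules[truth.molecules["role"] == ek.ROLE_ACTIVE]
        res = isolate_outlier_subset(
            actives["score_first"].to_numpy(),
            actives["score_second"].to_numpy(),
            k=truth.config.flexible_subset_size,
            ids=actives["molecule_id"].tolist(),
            properties={"n_rot": actives["n_rot"].to_numpy(dtype=float)},
        )
        flexible = set(truth.flagged_ids("flexible"))
        # the flexible molecules dominate the isolated outlier subset
        assert len(set(res.outlier_ids) & flexible) >= 8
        assert res.r2_outlier_vs_property["n_rot"] is not None
        assert res.r2_core > 0.9

    @pytest.mark.parametrize("k", [0, -1, 10])
    def test_invalid_k_rejected(self, k):
        x = np.arange(10.0)
        with pytest.raises(ValidationError):
            isolate_outlier_subset(x, x, k=k)


class TestSquaredPearson:
    def test_zero_variance_flagged_undefined(self):
        assert squared_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        n = len(x)
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        den = math.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * math.sqrt(
            n * np.sum(y * y) - np.sum(y) ** 2
        )
        assert squared_pearson(x, y) == pytest.approx((num / den) ** 2)
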