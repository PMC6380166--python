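import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import refstab as rs
from refstab.containers import RefstabError

from conftest import random_cq
from oracles import (
    bestkeeper_values,
    delta_ct_values,
    genorm_full,
    genorm_m_values,
    normfinder_values,
)


class TestCqToQuantity:
    def test_powers_of_two(self):
        design = rs.generate_design(["C"], [1], 3)
        cq = rs.CqMatrix(["g"], design, [[20.0, 21.0, 22.0]], {"g": 2.0})
        q = rs.cq_to_quantity(cq)
        assert q.q[0].tolist() == [1.0, 0.5, 0.25]

    def test_constant_row_all_ones(self):
        design = rs.generate_design(["C"], [1], 4)
        cq = rs.CqMatrix(["g"], design, [[21.0] * 4])
        assert rs.cq_to_quantity(cq).q[0].tolist() == [1.0] * 4

    def test_measured_efficiency(self):
        design = rs.generate_design(["C"], [1], 2)
        cq = rs.CqMatrix(["UBQ1"], design, [[22.0, 23.0]], {"UBQ1": 2.07})
        q = rs.cq_to_quantity(cq)
        assert q.q[0, 1] == pytest.approx(1 / 2.07)
        assert q.q[0].max() == 1.0

    def test_efficiency_at_most_one_rejected(self):
        design = rs.generate_design(["C"], [1], 2)
        cq = rs.CqMatrix(["g"], design, [[20.0, 21.0]], {"g": 1.0})
        with pytest.raises(RefstabError):
            rs.cq_to_quantity(cq)


class TestGenorm:
    def test_worked_example(self, worked_cq):
        gn, traj = rs.genorm(rs.cq_to_quantity(worked_cq))
        assert gn.stability_value == pytest.approx(
            [0.40824829, 0.40824829, 0.81649658], abs=1e-8
        )
        assert gn.rank.tolist() == [1.5, 1.5, 3.0]
        assert traj[0] == "g3"

    def test_proportional_pair_has_minimal_equal_m(self):
        design = rs.generate_design(["C"], [1], 5)
        rng = np.random.default_rng(3)
        base = rng.uniform(18, 24, 5)
        cq = rs.CqMatrix(
            ["a", "b", "c"],
            design,
            np.vstack([base, base + 0.7, rng.uniform(18, 24, 5)]),
        )
        q = rs.cq_to_quantity(cq)
        m = genorm_m_values([row.tolist() for row in q.q])
        assert m[0] == pytest.approx(m[1])
        gn, traj = rs.genorm(q)
        assert traj[0] == "c"

    def test_scale_invariance_of_m(self, worked_cq):
        q = rs.cq_to_quantity(worked_cq)
        gn, _ = rs.genorm(q)
        scaled = rs.RelativeQuantityMatrix(q.gene_ids, q.design, q.q * np.array([[3.0], [1.0], [0.2]]))
        gn2, _ = rs.genorm(scaled)
        assert gn2.stability_value == pytest.approx(gn.stability_value, abs=1e-12)

    def test_matches_bruteforce_over_seeds(self):
        for seed in range(10):
            cq = random_cq(5, 8, seed=seed)
            q = rs.cq_to_quantity(cq)
            gn, traj = rs.genorm(q)
            expected, order = genorm_full(
                [row.tolist() for row in q.q], list(q.gene_ids)
            )
            for g, val in zip(gn.gene_ids, gn.stability_value):
                assert val == pytest.approx(expected[g], abs=1e-9)
            assert traj == order

    def test_too_few_genes_rejected(self):
        design = rs.generate_design(["C"], [1], 4)
        cq = rs.CqMatrix(["a", "b"], design, [[20, 21, 22, 23], [20, 21, 22, 23]])
        with pytest.raises(RefstabError):
            rs.genorm(rs.cq_to_quantity(cq))


class TestPairwiseVariation:
    def test_identical_rows_zero(self):
        design = rs.generate_design(["C"], [1], 4)
        row = [20.0, 21.0, 19.5, 22.0]
        cq = rs.CqMatrix(["a", "b", "c", "d"], design, [row] * 4)
        q = rs.cq_to_quantity(cq)
        v = rs.genorm_pairwise_variation(q, ["a", "b", "c", "d"])
        assert np.allclose(v, 0.0)

    def test_length_is_k_minus_2(self, worked_cq):
        q = rs.cq_to_quantity(worked_cq)
        v = rs.genorm_pairwise_variation(q, ["g1", "g2", "g3"])
        assert v.shape == (1,)

    def test_duplicate_of_top_pair_gives_zero_v23(self):
        design = rs.generate_design(["C"], [1], 5)
        rng = np.random.default_rng(1)
        a = rng.uniform(19, 23, 5)
        b = rng.uniform(19, 23, 5)
        # gene c's log2 quantity is the mean of a and b's: NF_2 == NF_3
        qa = 2.0 ** (a.min() - a)
        qb = 2.0 ** (b.min() - b)
        qc = np.sqrt(qa * qb)
        q = rs.RelativeQuantityMatrix(
            ["a", "b", "c"], design, np.vstack([qa, qb, qc / qc.max()])
        )
        v = rs.genorm_pairwise_variation(q, ["a", "b", "c"])
        assert v[0] == pytest.approx(0.0, abs=1e-12)

    def test_bad_ranking_rejected(self, worked_cq):
        q = rs.cq_to_quantity(worked_cq)
        with pytest.raises(RefstabError):
            rs.genorm_pairwise_variation(q, ["g1", "g2"])


class TestNormfinder:
    def test_worked_example(self, worked_cq):
        nf = rs.normfinder(worked_cq)
        assert nf.stability_value[0] == pytest.approx(0.272, abs=5e-4)

    def test_constant_rows_zero(self):
        design = rs.generate_design(["C"], [1], 4)
        cq = rs.CqMatrix(["a", "b", "c"], design, [[20.0] * 4, [21.0] * 4, [19.0] * 4])
        assert np.allclose(rs.normfinder(cq).stability_value, 0.0)

    def test_additive_shift_invariance(self, worked_cq):
        shifted = rs.CqMatrix(
            worked_cq.gene_ids,
            worked_cq.design,
            worked_cq.values + np.array([[5.0], [0.0], [0.0]]),
            worked_cq.efficiency,
        )
        assert rs.normfinder(shifted).stability_value == pytest.approx(
            rs.normfinder(worked_cq).stability_value, abs=1e-12
        )

    def test_matches_bruteforce_over_seeds(self):
        for seed in range(10):
            cq = random_cq(5, 8, seed=seed)
            expected = normfinder_values([row.tolist() for row in cq.values])
            assert rs.normfinder(cq).stability_value == pytest.approx(
                expected, abs=1e-9
            )


class TestBestkeeper:
    def test_descriptives(self):
        design = rs.generate_design(["C"], [1], 3)
        cq = rs.CqMatrix(["a", "b"], design, [[19.0, 20.0, 21.0]] * 2)
        res, table = rs.bestkeeper(cq)
        assert table.loc[0, "geo_mean_cq"] == pytest.approx(19.9833, abs=5e-4)
        # mean |Cq - geometric mean|
        assert table.loc[0, "sd_cq"] == pytest.approx(0.6722, abs=5e-4)
        assert table.loc[0, "r_vs_index"] == pytest.approx(1.0)
        assert not table.loc[0, "unstable"]

    def test_constant_row_zero_sd(self):
        design = rs.generate_design(["C"], [1], 3)
        cq = rs.CqMatrix(["a", "b"], design, [[20.0] * 3, [19.0, 20.0, 21.0]])
        res, table = rs.bestkeeper(cq)
        assert table.loc[0, "sd_cq"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[0, "cv_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_not_shift_invariant(self):
        cq = random_cq(4, 10, seed=2)
        res, _ = rs.bestkeeper(cq)
        shifted_vals = cq.values.copy()
        shifted_vals[0] += 5.0
        res2, _ = rs.bestkeeper(
            rs.CqMatrix(cq.gene_ids, cq.design, shifted_vals, cq.efficiency)
        )
        assert not np.allclose(res.stability_value, res2.stability_value)

    def test_matches_bruteforce_over_seeds(self):
        for seed in range(10):
            cq = random_cq(5, 8, seed=seed)
            sd_mad, geo, r = bestkeeper_values([row.tolist() for row in cq.values])
            res, table = rs.bestkeeper(cq)
            assert res.stability_value == pytest.approx(sd_mad, abs=1e-9)
            assert table["geo_mean_cq"].to_numpy() == pytest.approx(geo, abs=1e-9)
            assert table["r_vs_index"].to_numpy() == pytest.approx(r, abs=1e-9)


class TestDeltaCt:
    def test_two_genes_share_stability(self):
        design = rs.generate_design(["C"], [1], 4)
        cq = rs.CqMatrix(["a", "b"], design, [[20, 21, 22, 23], [20.5, 21.2, 22.9, 23.1]])
        res = rs.delta_ct(cq)
        expected = np.std(cq.values[0] - cq.values[1], ddof=1)
        assert res.stability_value == pytest.approx([expected, expected])

    def test_worked_example(self, worked_cq):
        res = rs.delta_ct(worked_cq)
        assert res.stability_value[0] == pytest.approx(0.40824829, abs=1e-8)

    def test_additive_shift_invariance(self, worked_cq):
        shifted = rs.CqMatrix(
            worked_cq.gene_ids,
            worked_cq.design,
            worked_cq.values + np.array([[2.0], [3.0], [4.0]]),
            worked_cq.efficiency,
        )
        assert rs.delta_ct(shifted).stability_value == pytest.approx(
            rs.delta_ct(worked_cq).stability_value, abs=1e-12
        )

    def test_matches_bruteforce_over_seeds(self):
        for seed in range(10):
            cq = random_cq(5, 8, seed=seed)
            expected = delta_ct_values([row.tolist() for row in cq.values])
            assert rs.delta_ct(cq).stability_value == pytest.approx(expected, abs=1e-9)

    def test_correlates_with_genorm_first_round(self):
        """ΔCt stabilities track first-round geNorm M (Spearman >= 0.9).

        On a common efficiency scale (E = 2) the pairwise log2-ratio SD
        equals the SD of the Cq difference, so the two statistics are
        intimately related; gene-specific efficiencies rescale rows and
        can perturb the agreement, hence the common-scale property.
        """
        for seed in range(5):
            cq = random_cq(10, 20, seed=100 + seed, efficiency=2.0)
            dct = rs.delta_ct(cq).stability_value
            q = rs.cq_to_quantity(cq)
            m = genorm_m_values([row.tolist() for row in q.q])
            rho = spearmanr(dct, m).statistic
            assert rho >= 0.9


class TestAggregation:
    @staticmethod
    def _mk(method, genes, ranks):
        return rs.MethodResult(method, genes, np.asarray(ranks, float), np.asarray(ranks, float))

    def test_geometric_mean_arithmetic(self):
        genes = ["a", "b", "c", "d"]
        results = [
            self._mk(m, genes, r)
            for m, r in zip(
                ("genorm", "normfinder", "bestkeeper", "delta_ct"),
                ([1, 2, 3, 4], [2, 1, 3, 4], [2, 1, 3, 4], [3, 1, 2, 4]),
            )
        ]
        rep = rs.aggregate_ranks(results)
        assert rep.comprehensive_score[0] == pytest.approx((1 * 2 * 2 * 3) ** 0.25)
        assert rep.comprehensive_score[3] == pytest.approx(4.0)

    def test_unanimity_gives_score_one(self):
        genes = ["a", "b", "c"]
        results = [self._mk(m, genes, [1, 2, 3]) for m in ("genorm", "normfinder", "bestkeeper", "delta_ct")]
        rep = rs.aggregate_ranks(results)
        assert rep.comprehensive_score[0] == 1.0
        assert rep.comprehensive_rank[0] == 1.0

    def test_method_order_irrelevant(self):
        genes = ["a", "b", "c"]
        results = [
            self._mk("genorm", genes, [1, 2, 3]),
            self._mk("normfinder", genes, [2, 3, 1]),
            self._mk("bestkeeper", genes, [3, 1, 2]),
            self._mk("delta_ct", genes, [1, 3, 2]),
        ]
        a = rs.aggregate_ranks(results)
        b = rs.aggregate_ranks(results[::-1])
        assert np.allclose(a.comprehensive_score, b.comprehensive_score)

    def test_depends_only_on_ranks(self):
        """Monotone transforms of stability values leave the ranking fixed."""
        cq = random_cq(6, 12, seed=5)
        nf = rs.normfinder(cq)
        warped = rs.MethodResult(
            "normfinder",
            nf.gene_ids,
            np.exp(3.0 * nf.stability_value) + 7.0,
            nf.rank,
        )
        others = [rs.delta_ct(cq), rs.bestkeeper(cq)[0]]
        a = rs.aggregate_ranks([nf] + others)
        b = rs.aggregate_ranks([warped] + others)
        assert np.array_equal(a.comprehensive_rank, b.comprehensive_rank)

    def test_mismatched_gene_sets_rejected(self):
        a = self._mk("genorm", ["a", "b", "c"], [1, 2, 3])
        b = self._mk("delta_ct", ["a", "b", "x"], [1, 2, 3])
        with pytest.raises(RefstabError):
            rs.aggregate_ranks([a, b])


@pytest.fixture(scope="module")
def cq45(design45, scenario_specs):
    expr = rs.simulate_expression(scenario_specs, design45, seed=17)
    return rs.cq_from_expression(expr, scenario_specs, cq_noise_sd=0.1, seed=17)


class TestSubsets:
    @pytest.mark.parametrize(
        "subset, n_samples", [("temperature", 27), ("salinity", 27), ("combined", 45)]
    )
    def test_subset_sizes(self, cq45, subset, n_samples):
        report = rs.stability_by_subset(cq45, subset)
        sub = cq45.subset_samples(rs.SUBSET_TREATMENTS[subset])
        assert sub.shape[1] == n_samples
        assert set(report.methods) == {"genorm", "normfinder", "bestkeeper", "delta_ct"}
        assert len(report.pairwise_variation) == len(cq45.gene_ids) - 2

    def test_all_stability_values_nonnegative(self, cq45):
        report = rs.stability_by_subset(cq45, "combined")
        for res in report.methods.values():
            assert (res.stability_value >= 0).all()
        assert (report.comprehensive_score >= 1.0 - 1e-12).all()

    def test_unknown_subset_rejected(self, cq45):
        with pytest.raises(RefstabError):
            rs.stability_by_subset(cq45, "photoperiod")

    def test_tiny_subset_rejected(self):
        design = rs.generate_design(["HT"], [1], 3)  # no control samples
        cq = rs.CqMatrix(
            ["a", "b", "c"], design, np.full((3, 3), 20.0) + np.arange(3)[:, None]
        )
        with pytest.raises(RefstabError):
            rs.stability_by_subset(cq, "salinity")

    def test_ultra_stable_gene_ranks_first(self, design45):
        """A designed ultra-stable gene tops every subset in >=95% of seeds."""
        specs = [rs.GeneSpec("ULTRA", 200.0, "stable", 0.01)]
        for g, (base, eff) in enumerate(
            [(50.0, {("HT", 24): 3.0}), (120.0, {("LS", 48): 0.4}), (300.0, {("HS", 1): 2.0})]
        ):
            specs.append(rs.GeneSpec(f"rsp{g}", base, "responsive", 0.15, eff))
        specs += [rs.GeneSpec(f"nsy{g}", 100.0, "noisy", 0.5) for g in range(2)]
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            expr = rs.simulate_expression(specs, rs.generate_design(), seed=seed)
            cq = rs.cq_from_expression(expr, specs, cq_noise_sd=0.05, seed=seed)
            if all(
                rs.stability_by_subset(cq, s).ranking()[0] == "ULTRA"
                for s in ("temperature", "salinity", "combined")
            ):
                wins += 1
        assert wins / n_seeds >= 0.95


class TestAllConstantLimit:
    def test_all_methods_zero(self):
        design = rs.generate_design(["C"], [1], 5)
        cq = rs.CqMatrix(
            ["a", "b", "c"], design, np.tile([[20.0], [21.0], [22.0]], (1, 5))
        )
        assert np.allclose(rs.normfinder(cq).stability_value, 0.0)
        assert np.allclose(rs.delta_ct(cq).stability_value, 0.0)
        gn, _ = rs.genorm(rs.cq_to_quantity(cq))
        assert np.allclose(gn.stability_value, 0.0)
        bk, _ = rs.bestkeeper(cq)
        assert np.allclose(bk.stability_value, 0.0)
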