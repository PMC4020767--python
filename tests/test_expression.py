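"""Welch statistics, BH adjustment, ranking, CNRQ and Spearman."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bimodalseed import expression, simulate


def _matrix(ctrl_rows, treat_rows, genes=None):
    ctrl = np.asarray(ctrl_rows, dtype=float)
    treat = np.asarray(treat_rows, dtype=float)
    data = np.hstack([ctrl, treat])
    cols = [f"c{i}" for i in range(ctrl.shape[1])] + [f"t{i}" for i in range(treat.shape[1])]
    idx = genes or [f"g{i}" for i in range(data.shape[0])]
    return (
        pd.DataFrame(data, index=idx, columns=cols),
        ["control"] * ctrl.shape[1] + ["treatment"] * treat.shape[1],
    )


class TestPerGeneStats:
    def test_identical_groups_give_zero_t(self):
        mat, labels = _matrix([[1, 2, 3]], [[1, 2, 3]])
        rec = expression.per_gene_stats(mat, labels)
        assert rec.loc[0, "t_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_downregulation_sign_contract(self):
        mat, labels = _matrix([[0.0, 0.001]], [[-1.0, -1.001]])
        rec = expression.per_gene_stats(mat, labels)
        assert rec.loc[0, "log2fc"] == pytest.approx(-1.0, abs=0.01)
        assert rec.loc[0, "t_stat"] < -100

    def test_zero_variance_equal_means_degenerate(self):
        mat, labels = _matrix([[5, 5, 5]], [[5, 5, 5]])
        rec = expression.per_gene_stats(mat, labels)
        assert rec.loc[0, "t_stat"] == 0.0
        assert rec.loc[0, "p"] == 1.0

    def test_planted_effect_recovered(self, small_config, small_cohort, small_records):
        _, truth = small_cohort
        rec = small_records.set_index("gene_id")
        is_only = [g for g, c in truth.classes.items() if c == "IS_only"]
        vals = rec.loc[is_only, "log2fc"]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # 3 SE guard: the small cohort has only ~30 IS-only genes
        assert abs(vals.mean() - small_config.delta_is) < 3 * se

    def test_matches_welch_by_hand(self, rng):
        ctrl = rng.normal(0, 1, (1, 4))
        treat = rng.normal(-1, 2, (1, 5))
        mat, labels = _matrix(ctrl, treat)
        rec = expression.per_gene_stats(mat, labels)
        s1, s2 = treat.var(ddof=1), ctrl.var(ddof=1)
        t_hand = (treat.mean() - ctrl.mean()) / np.sqrt(s1 / 5 + s2 / 4)
        assert rec.loc[0, "t_stat"] == pytest.approx(t_hand, rel=1e-12)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        out = expression.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_unchanged_and_single_p(self):
        assert np.allclose(expression.adjust_bh(np.array([1.0, 1.0])), 1.0)
        assert expression.adjust_bh(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_invariant_under_permutation(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        adj = expression.adjust_bh(p)
        assert np.allclose(expression.adjust_bh(p[perm]), adj[perm])


class TestRankingAndStrata:
    def test_rank_most_down_first(self):
        rec = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "t_stat": [-5.0, 2.0, -1.0]}
        )
        assert expression.rank_by_downregulation(rec) == ["g1", "g3", "g2"]

    def test_ties_break_lexicographically(self):
        rec = pd.DataFrame({"gene_id": ["b", "a", "c"], "t_stat": [0.0, 0.0, 0.0]})
        assert expression.rank_by_downregulation(rec) == ["a", "b", "c"]

    def test_top_down_respects_alpha_and_n(self):
        rec = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(500)],
                "t_stat": np.linspace(-10, -1, 500),
                "p_adj": [0.001] * 500,
            }
        )
        assert len(expression.top_down(rec, n=250, alpha=0.01)) == 250
        rec["p_adj"] = 0.5
        assert expression.top_down(rec, n=250, alpha=0.01) == []

    def test_stratify_boundary_is_strict(self):
        rec = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "t_stat": [-4.0, -4.0001, 3.0]}
        )
        down, rest = expression.stratify_by_t(rec)
        assert down == {"b"} and rest == {"a", "c"}
        down, rest = expression.stratify_by_t(rec, unaffected="t_ge_4")
        assert rest == set()


class TestCnrq:
    def test_constant_cq_gives_unit_cnrq(self):
        cq = pd.DataFrame(
            {"target": [20.0, 20.0], "REF1": [15.0, 15.0]}, index=["s1", "s2"]
        )
        out = expression.cnrq(cq, ["REF1"])
        assert np.allclose(out.to_numpy(), 1.0)

    def test_one_cycle_means_twofold_at_efficiency_two(self):
        cq = pd.DataFrame(
            {"target": [19.0, 20.0], "REF1": [15.0, 15.0]}, index=["A", "B"]
        )
        out = expression.cnrq(cq, ["REF1"])
        assert out.loc["A", "target"] / out.loc["B", "target"] == pytest.approx(2.0)

    def test_scale_free_in_sample_shift(self, rng):
        cq = pd.DataFrame(
            rng.normal(25, 2, size=(6, 4)),
            index=[f"s{i}" for i in range(6)],
            columns=["t1", "t2", "REF1", "REF2"],
        )
        base = expression.cnrq(cq, ["REF1", "REF2"])
        shifted = cq.copy()
        shifted.loc["s0"] += 3.7  # whole-sample Cq offset cancels through NF
        out = expression.cnrq(shifted, ["REF1", "REF2"])
        assert np.allclose(out.to_numpy(), base.to_numpy())

    def test_missing_target_propagates_missing_reference_errors(self):
        cq = pd.DataFrame(
            {"target": [20.0, np.nan], "REF1": [15.0, 15.0]}, index=["A", "B"]
        )
        out = expression.cnrq(cq, ["REF1"])
        assert np.isnan(out.loc["B", "target"])
        cq.loc["B", "REF1"] = np.nan
        with pytest.raises(ValueError, match="reference"):
            expression.cnrq(cq, ["REF1"])

    def test_geometric_mean_calibration(self, rng):
        cq = pd.DataFrame(
            rng.normal(25, 2, size=(5, 3)),
            index=[f"s{i}" for i in range(5)],
            columns=["t1", "REF1", "REF2"],
        )
        out = expression.cnrq(cq, ["REF1", "REF2"])
        assert np.allclose(np.exp(np.log(out).mean(axis=0)), 1.0)

    def test_inverts_generator_construction(self):
        cfg = simulate.SimulationConfig(qpcr_cq_noise=0.0, qpcr_ref_noise=0.0)
        cq, truth = simulate.gen_qpcr(cfg, 7)
        out = expression.cnrq(cq, ["REF1", "REF2", "REF3"])
        for gene in ("mir_sim", "target_gene"):
            q = 2.0 ** np.asarray(truth.qpcr_latent[gene])
            expected = q / np.exp(np.log(q).mean())
            assert np.allclose(out[gene].to_numpy(), expected, atol=1e-9)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.normal(size=30)
        assert expression.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert expression.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_complete_cases_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [1.0, 2.0, np.nan, 4.0, 5.0]
        rho, _ = expression.spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="complete pairs"):
            expression.spearman([1, 2], [3, 4])

    def test_exact_small_sample_p_matches_enumeration(self, rng):
        n = 7
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rho, p = expression.spearman(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        obs = abs(rho)
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r1, p1 = expression.spearman(x, y)
        r2, p2 = expression.spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)
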