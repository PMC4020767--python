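"""Generator guarantees: determinism, clean classes, truth consistency."""

import json

import numpy as np
import pytest

from bimodalseed import simulate
from bimodalseed.seedscan import count_word_occurrences


class TestConfig:
    def test_infeasible_frequencies_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            simulate.SimulationConfig(f_cs=0.5, f_is=0.4, f_both=0.2)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            simulate.SimulationConfig(isomir_proportions=(0.5, 0.2))

    def test_extreme_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            simulate.SimulationConfig(qpcr_rho=-1.0)

    def test_roundtrip_json(self):
        cfg = simulate.small()
        assert simulate.SimulationConfig.from_json(cfg.to_json()) == cfg


class TestGenUtrs:
    def test_zero_frequencies_reject_all_words(self):
        cfg = simulate.SimulationConfig(
            n_genes=60, utr_len_min=150, utr_len_max=300, f_cs=0, f_is=0, f_both=0
        )
        utrs, truth = simulate.gen_utrs(cfg, seed=5)
        for w in simulate.rejection_words(cfg):
            assert all(w not in u.sequence for u in utrs)
        assert set(truth.classes.values()) == {"neither"}

    def test_class_counts_match_config(self, small_config, small_cohort):
        _, truth = small_cohort
        from collections import Counter

        counts = Counter(truth.classes.values())
        n = small_config.n_genes
        assert counts["CS_only"] == round(small_config.f_cs * n)
        assert counts["IS_only"] == round(small_config.f_is * n)
        assert counts["both"] == round(small_config.f_both * n)

    def test_sites_present_exactly_once(self, small_cohort, small_config):
        utrs, truth = small_cohort
        from bimodalseed.seedscan import CANONICAL_SEED, INTERNAL_SEED, derive_target_word

        mirna = small_config.mirna
        words = {
            "CS": derive_target_word(mirna, CANONICAL_SEED).word,
            "IS": derive_target_word(mirna, INTERNAL_SEED).word,
        }
        by_id = {u.gene_id: u.sequence for u in utrs}
        for gene, cls in truth.classes.items():
            for seed_type, word in words.items():
                expected = 1 if seed_type in truth.sites[gene] else 0
                assert count_word_occurrences(by_id[gene], word) == expected

    def test_expected_log2fc_additive(self, small_config, small_cohort):
        _, truth = small_cohort
        for gene, cls in truth.classes.items():
            mu = truth.expected_log2fc[gene]
            expected = {
                "neither": 0.0,
                "CS_only": small_config.delta_cs,
                "IS_only": small_config.delta_is,
                "both": small_config.delta_cs + small_config.delta_is
                + small_config.interaction,
            }[cls]
            assert mu == pytest.approx(expected)

    def test_background_word_frequency_near_expectation(self):
        # chance presence of an inert 7-mer across ~10^6 background bases
        cfg = simulate.SimulationConfig(
            n_genes=800, utr_len_min=1000, utr_len_max=1500,
            f_cs=0, f_is=0, f_both=0, gc=0.5,
        )
        utrs, _ = simulate.gen_utrs(cfg, seed=8)
        word = "ACGTACG"  # not in the rejection set
        total = sum(len(u.sequence) for u in utrs)
        hits = sum(count_word_occurrences(u.sequence, word) for u in utrs)
        expected = total * 0.25**7
        assert hits == pytest.approx(expected, abs=4 * np.sqrt(expected))


class TestDeterminism:
    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        cfg = simulate.SimulationConfig(n_genes=80, utr_len_min=150, utr_len_max=250)
        p1 = simulate.simulate_all(cfg, seed=3, outdir=tmp_path / "a")
        p2 = simulate.simulate_all(cfg, seed=3, outdir=tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        cfg = simulate.SimulationConfig(n_genes=80, utr_len_min=150, utr_len_max=250)
        p1 = simulate.simulate_all(cfg, seed=3, outdir=tmp_path / "a")
        p2 = simulate.simulate_all(cfg, seed=4, outdir=tmp_path / "b")
        assert p1["utrs"].read_bytes() != p2["utrs"].read_bytes()


class TestClipGeneration:
    def test_read_totals_near_poisson_expectation(self, small_config, small_cohort):
        utrs, truth = small_cohort
        treat, ctrl = simulate.gen_clip_reads(utrs, truth, small_config, seed=6)
        n_piles = sum(s["has_pile"] for s in truth.clip_sites)
        tmodel = simulate.transcript_model(utrs, small_config)
        total_len = sum(sum(sp) for sp in tmodel.values())
        exp_bg = small_config.clip_background_rate * total_len
        exp_treat = n_piles * small_config.clip_peak_reads + exp_bg
        assert len(treat) == pytest.approx(exp_treat, abs=4 * np.sqrt(exp_treat))
        assert len(ctrl) == pytest.approx(exp_bg, abs=4 * np.sqrt(exp_bg))

    def test_no_background_control_empty(self, small_cohort):
        utrs, truth = small_cohort
        cfg = simulate.SimulationConfig(
            n_genes=300, utr_len_min=150, utr_len_max=400, clip_background_rate=0.0,
            clip_site_fraction=1.0,
        )
        treat, ctrl = simulate.gen_clip_reads(utrs, truth, cfg, seed=6)
        assert len(ctrl) == 0
        assert len(treat) > 0


class TestLongHybrids:
    def test_planting_extends_is_site(self, small_config):
        utrs, truth = simulate.gen_utrs(small_config, seed=11)
        is_genes = sorted(g for g, s in truth.sites.items() if "IS" in s)[:5]
        new_utrs = simulate.plant_long_hybrids(utrs, truth, small_config, is_genes)
        assert truth.long_hybrid_genes == is_genes
        from bimodalseed import duplex as D

        by_id = {u.gene_id: u for u in new_utrs}
        for gene in is_genes:
            pos = truth.sites[gene]["IS"]
            seq = by_id[gene].sequence
            window = seq[max(0, pos - 15) : pos + 7 + 15]
            res = D.duplex_mfe(small_config.mirna_seq, window, is_window=(6, 12))
            # the MFE structure may trade block pairs for flank helices, but
            # the uninterrupted run stays at or above the 10-nt flag threshold
            assert res.max_run >= 10 and res.covers_is

    def test_gene_without_is_site_rejected(self, small_config):
        utrs, truth = simulate.gen_utrs(small_config, seed=11)
        neither = next(g for g, c in truth.classes.items() if c == "neither")
        with pytest.raises(ValueError, match="IS site"):
            simulate.plant_long_hybrids(utrs, truth, small_config, [neither])

    def test_unplanted_sites_do_not_extend(self, small_config):
        """Non-pairing flanks cap contiguous pairing at the seed length."""
        utrs, truth = simulate.gen_utrs(small_config, seed=12)
        from bimodalseed import duplex as D

        by_id = {u.gene_id: u.sequence for u in utrs}
        checked = 0
        for gene, sites in sorted(truth.sites.items()):
            if "IS" not in sites or checked >= 25:
                continue
            pos = sites["IS"]
            seq = by_id[gene]
            window = seq[max(0, pos - 15) : pos + 7 + 15]
            res = D.duplex_mfe(small_config.mirna_seq, window, is_window=(6, 12))
            if res.covers_is:
                assert res.max_run <= 9
            checked += 1
        assert checked >= 20
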