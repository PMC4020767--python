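"""Seed-anchored CLIP windows, overlap counting and peak calling."""

import pandas as pd
import pytest

from bimodalseed import clip
from bimodalseed.clip import GenomicInterval, Peak
from bimodalseed.seedscan import SeedMatch


def _reads(rows):
    return pd.DataFrame(
        [(c, s, e, f"r{i}", w, "+") for i, (c, s, e, w) in enumerate(rows)],
        columns=clip.READ_COLUMNS,
    )


class TestSeedWindows:
    def test_flank_extension(self):
        w = clip.seed_windows({"tx": 1000}, [SeedMatch("tx", "GAGGTCA", 100, "IS")])
        assert (w[0][0].start, w[0][0].end, w[0][1]) == (90, 117, "IS")

    def test_clipped_at_transcript_bounds(self):
        w = clip.seed_windows({"tx": 20}, [SeedMatch("tx", "GAGGTCA", 0, "CS")])
        assert (w[0][0].start, w[0][0].end) == (0, 17)

    def test_same_type_windows_merged(self):
        matches = [
            SeedMatch("tx", "GAGGTCA", 100, "IS"),
            SeedMatch("tx", "GAGGTCA", 105, "IS"),
        ]
        w = clip.seed_windows({"tx": 1000}, matches)
        assert len(w) == 1
        assert (w[0][0].start, w[0][0].end) == (90, 122)

    def test_different_types_kept_separate(self):
        matches = [
            SeedMatch("tx", "GAGGTCA", 100, "IS"),
            SeedMatch("tx", "TCATACG", 103, "CS"),
        ]
        w = clip.seed_windows({"tx": 1000}, matches)
        assert len(w) == 2
        assert {t for _, t in w} == {"CS", "IS"}

    def test_shifted_variants_collapse_to_base_type(self):
        w = clip.seed_windows({"tx": 1000}, [SeedMatch("tx", "TGAGGTC", 50, "IS+1")])
        assert w[0][1] == "IS"


class TestCountOverlaps:
    def test_no_reads_zero(self):
        assert clip.count_overlaps([GenomicInterval("tx", 0, 10)], _reads([])).tolist() == [0]

    def test_read_equal_to_window(self):
        counts = clip.count_overlaps(
            [GenomicInterval("tx", 10, 40)], _reads([("tx", 10, 40, 1)])
        )
        assert counts.tolist() == [1.0]

    def test_any_overlap_rule_and_weights(self):
        iv = [GenomicInterval("tx", 100, 127)]
        reads = _reads(
            [
                ("tx", 90, 100, 1),   # abuts on the left: no overlap
                ("tx", 99, 101, 2),   # 1-base overlap counts, weight 2
                ("tx", 126, 150, 3),  # 1-base overlap on the right
                ("tx", 127, 150, 1),  # abuts on the right: no overlap
                ("other", 100, 127, 5),
            ]
        )
        assert clip.count_overlaps(iv, reads).tolist() == [5.0]

    def test_matches_naive_oracle(self, rng):
        intervals = [
            GenomicInterval("tx", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 500, 60), rng.integers(5, 60, 60))
        ]
        rows = [
            ("tx", int(s), int(s) + int(l), int(w))
            for s, l, w in zip(
                rng.integers(0, 500, 300), rng.integers(10, 40, 300), rng.integers(1, 4, 300)
            )
        ]
        reads = _reads(rows)
        fast = clip.count_overlaps(intervals, reads)
        for k, iv in enumerate(intervals):
            naive = sum(w for _, s, e, w in rows if s < iv.end and e > iv.start)
            assert fast[k] == naive


class TestCallPeaks:
    def _windows(self):
        return [(GenomicInterval("tx", 100, 127), "IS")]

    def test_zero_treatment_reads_negative(self):
        peaks = clip.call_peaks(
            self._windows(), _reads([("tx", 500, 530, 1)]), _reads([("tx", 500, 530, 1)])
        )
        assert not peaks[0].positive

    def test_equal_normalized_counts_enrichment_one(self):
        reads = _reads([("tx", 100, 130, 10)])
        peaks = clip.call_peaks(self._windows(), reads, reads)
        assert peaks[0].enrichment == pytest.approx(1.0)
        assert not peaks[0].positive

    def test_control_equals_treatment_never_positive(self, rng):
        rows = [
            ("tx", int(s), int(s) + 30, 1) for s in rng.integers(0, 1000, 200)
        ]
        windows = [
            (GenomicInterval("tx", int(s), int(s) + 27), "IS")
            for s in rng.integers(0, 900, 25)
        ]
        reads = _reads(rows)
        peaks = clip.call_peaks(windows, reads, reads)
        assert not any(p.positive for p in peaks)

    def test_scaling_both_libraries_leaves_enrichment_unchanged(self):
        # exact invariance for the pure normalised ratio (pseudocount off)
        treat = _reads([("tx", 100, 130, 8)])
        ctrl = _reads([("tx", 100, 130, 2)])
        p1 = clip.call_peaks(self._windows(), treat, ctrl, pseudocount=0.0)[0]
        treat2 = _reads([("tx", 100, 130, 24)])
        ctrl2 = _reads([("tx", 100, 130, 6)])
        p2 = clip.call_peaks(self._windows(), treat2, ctrl2, pseudocount=0.0)[0]
        assert p1.enrichment == pytest.approx(p2.enrichment)

    def test_order_invariance(self, rng):
        rows = [
            ("tx", int(s), int(s) + 30, 1) for s in rng.integers(0, 500, 100)
        ]
        windows = [(GenomicInterval("tx", 200, 260), "CS")]
        fwd = clip.call_peaks(windows, _reads(rows), _reads(rows[:10]))[0]
        rev = clip.call_peaks(windows, _reads(rows[::-1]), _reads(rows[:10][::-1]))[0]
        assert (fwd.n_treat, fwd.n_ctrl, fwd.enrichment) == (rev.n_treat, rev.n_ctrl, rev.enrichment)

    def test_poisson_mode(self):
        treat = _reads([("tx", 100, 130, 50), ("tx", 500, 530, 50)])
        ctrl = _reads([("tx", 500, 530, 100)])
        peaks = clip.call_peaks(self._windows(), treat, ctrl, test="poisson")
        assert peaks[0].positive


class TestAnnotateRegion:
    MODEL = {"tx": (100, 500, 400)}

    def _peak(self, start, end):
        return Peak(GenomicInterval("tx", start, end), "IS", "tx", 0, 0, 1.0, False)

    def test_region_by_midpoint(self):
        # spans: UTR5 [0,100), CDS [100,600), UTR3 [600,1000)
        assert clip.annotate_region(self._peak(300, 330), self.MODEL) == "CDS"
        assert clip.annotate_region(self._peak(700, 920), self.MODEL) == "UTR3"
        assert clip.annotate_region(self._peak(0, 30), self.MODEL) == "UTR5"

    def test_junction_midpoint_goes_downstream(self):
        # midpoint exactly at the CDS/UTR3 boundary (600)
        assert clip.annotate_region(self._peak(590, 610), self.MODEL) == "UTR3"

    def test_outside_model_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            clip.annotate_region(self._peak(1500, 1600), self.MODEL)
        with pytest.raises(KeyError):
            clip.annotate_region(
                Peak(GenomicInterval("zz", 0, 10), "IS", "zz", 0, 0, 1.0, False),
                self.MODEL,
            )


class TestOverlapWithExpression:
    def _peaks(self, genes, seed_type="IS", positive=True, region="UTR3"):
        return [
            Peak(GenomicInterval(g, 0, 27), seed_type, g, 10, 0, 5.0, positive, region)
            for g in genes
        ]

    def test_disjoint_sets_zero(self):
        out = clip.overlap_with_expression(self._peaks(["a", "b"]), {"x", "y"})
        assert out["IS"]["fraction"] == 0.0

    def test_full_overlap_one(self):
        out = clip.overlap_with_expression(self._peaks(["a", "b"]), {"a", "b"})
        assert out["IS"]["fraction"] == 1.0
        assert out["IS"]["n_genes"] == 2

    def test_empty_peak_set_flagged_undefined(self):
        out = clip.overlap_with_expression([], {"a"})
        assert out["IS"]["fraction"] is None
        assert out["CS"]["fraction"] is None

    def test_only_positive_utr3_peaks_count(self):
        peaks = self._peaks(["a"]) + self._peaks(["b"], positive=False) + self._peaks(
            ["c"], region="CDS"
        )
        out = clip.overlap_with_expression(peaks, {"a", "b", "c"})
        assert out["IS"]["n_genes"] == 1

    def test_planted_coregulation_fraction_recovered(self, rng):
        genes = [f"g{i}" for i in range(200)]
        down = set(rng.choice(genes, size=80, replace=False))
        out = clip.overlap_with_expression(self._peaks(genes), down)
        assert out["IS"]["fraction"] == pytest.approx(0.4, abs=0.01)
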