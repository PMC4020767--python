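"""Synthetic-data generator with ground truth.

Every input the pipeline consumes can be generated here with a known truth
manifest, emulating the statistical structure the analysis assumes:

* 3'UTR sets with seed-match words planted at controlled class frequencies
  (CS only / IS only / both / neither), with rejection-resampling so chance
  occurrences of any active word never contaminate the class labels;
* replicate log2 expression matrices in which seed classes shift the
  treatment mean additively (delta_CS + delta_IS + optional interaction)
  under Gaussian noise;
* AGO-CLIP read piles concentrated on a chosen subset of planted sites in
  the treatment library only, over uniform background in both libraries;
* multinomial 5'-offset read distributions for the isomiR profiler;
* qPCR Cq tables with a planted rank correlation (Gaussian copula) between
  a miRNA and a target gene over reference genes that are constant up to
  noise.

All randomness flows from a master seed through named `numpy` SeedSequence
spawns, so identical configurations produce byte-identical outputs.

Planted sites are written with *non-pairing immediate flanks*: the two bases
adjacent to a planted word are chosen so they cannot pair with the
continuation of the miRNA.  Contiguous miRNA-target complementarity at a
planted site therefore equals the seed length exactly, which keeps the
long-hybrid screen's ground truth clean; deliberately long hybrids are
planted separately with `plant_long_hybrids`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import seedscan
from .clip import GenomicInterval
from .seedscan import (
    CANONICAL_SEED,
    INTERNAL_SEED,
    MatureMiRNA,
    SeedDefinition,
    UtrRecord,
    count_word_occurrences,
    derive_target_word,
    revcomp_rna_to_dna,
    shifted_variants,
)

#: synthetic 25-nt miRNA whose positions 6-12 are UGACCUC, so the planted
#: internal-seed 7-mer word is GAGGTCA (and the canonical-seed word TCATACG)
DEFAULT_MIRNA = MatureMiRNA("mir-sim-1", "ACGUAUGACCUCAGCAUUGCAGGAC")

_RNA_PARTNERS = {  # bases that can pair (WC or GU) with a given RNA base
    "A": {"U"},
    "C": {"G"},
    "G": {"C", "U"},
    "U": {"A", "G"},
}
_DNA_OF_RNA = {"A": "A", "C": "C", "G": "G", "U": "T"}


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults = the `paperlike` preset)."""

    # UTR cohort
    n_genes: int = 5000
    utr_len_min: int = 200
    utr_len_max: int = 2000
    gc: float = 0.45
    f_cs: float = 0.10
    f_is: float = 0.10
    f_both: float = 0.05
    max_shift: int = 2  # chance occurrences of shifts 0..max_shift are rejected
    # expression
    delta_cs: float = -0.25
    delta_is: float = -0.40
    interaction: float = 0.0
    sigma: float = 0.30
    n_reps: int = 6
    baseline: float = 8.0
    # miRNA
    mirna_id: str = DEFAULT_MIRNA.id
    mirna_seq: str = DEFAULT_MIRNA.sequence
    # CLIP
    utr5_len: int = 100
    cds_len: int = 500
    clip_read_len: int = 30
    clip_peak_reads: float = 30.0
    clip_background_rate: float = 0.01  # reads per transcript nt per library
    clip_site_fraction: float = 0.6  # planted sites that actually get a pile
    clip_jitter: int = 5
    # isomiR
    isomir_offsets: tuple[int, ...] = (0, 1, 2)
    isomir_proportions: tuple[float, ...] = (0.6, 0.3, 0.1)
    n_isomir_reads: int = 5000
    isomir_contig: str = "chr17"
    isomir_locus_start: int = 1000
    isomir_mature_len: int = 24
    isomir_strand: str = "+"
    # qPCR
    qpcr_n_samples: int = 19
    qpcr_rho: float = -0.5
    qpcr_spread: float = 1.5
    qpcr_baseline: float = 25.0
    qpcr_cq_noise: float = 0.1
    qpcr_ref_noise: float = 0.05
    qpcr_n_refs: int = 3

    def __post_init__(self) -> None:
        if self.f_cs + self.f_is + self.f_both > 1:
            raise ValueError("class frequencies must sum to <= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(sum(self.isomir_proportions) - 1.0) > 1e-9:
            raise ValueError("isomiR proportions must sum to 1")
        if abs(self.qpcr_rho) >= 1:
            raise ValueError("|qpcr_rho| must be < 1")

    @property
    def mirna(self) -> MatureMiRNA:
        return MatureMiRNA(self.mirna_id, self.mirna_seq)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("isomir_offsets", "isomir_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def paperlike() -> SimulationConfig:
    return SimulationConfig()


def small() -> SimulationConfig:
    """A fast cohort for unit tests and examples."""
    return SimulationConfig(n_genes=300, utr_len_min=150, utr_len_max=400)


@dataclass
class SyntheticTruth:
    """Ground-truth manifest the recovery tests assert against."""

    classes: dict[str, str] = field(default_factory=dict)  # gene -> class
    sites: dict[str, dict[str, int]] = field(default_factory=dict)  # gene -> seed -> pos
    expected_log2fc: dict[str, float] = field(default_factory=dict)
    clip_sites: list[dict] = field(default_factory=list)
    long_hybrid_genes: list[str] = field(default_factory=list)
    isomir_proportions: dict[str, float] = field(default_factory=dict)
    qpcr_latent: dict[str, list[float]] = field(default_factory=dict)
    n_resampled_utrs: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=length, p=_base_probs(gc))])


def rejection_words(config: SimulationConfig) -> list[str]:
    """Every word whose chance occurrence would contaminate class labels:
    CS and IS words for shifts 0..max_shift."""
    mirna = config.mirna
    words = []
    for seed in (CANONICAL_SEED, INTERNAL_SEED):
        for sd in shifted_variants(seed, config.max_shift):
            words.append(derive_target_word(mirna, sd).word)
    return words


def _blocking_base(
    rng: np.random.Generator, mirna_base: str | None
) -> str:
    """A DNA base that cannot pair (WC/GU) with ``mirna_base``."""
    if mirna_base is None:
        return str(rng.choice(list("ACGT")))
    banned = {_DNA_OF_RNA[b] for b in _RNA_PARTNERS[mirna_base]}
    allowed = sorted(set("ACGT") - banned)
    return str(rng.choice(allowed))


def _plant_word(
    seq: list[str],
    pos: int,
    word: str,
    mirna: str,
    seed: SeedDefinition,
    rng: np.random.Generator,
) -> None:
    """Write ``word`` at ``pos`` with non-pairing immediate flanks.

    The target base 5' of the match would pair with the miRNA base just 3'
    of the seed window, and vice versa; both are replaced by bases that
    cannot pair there, so contiguous complementarity stops at the word.
    """
    k = len(word)
    seq[pos : pos + k] = list(word)
    w0 = seed.anchor + seed.isomir_shift - 1  # 0-based window start on miRNA
    after = mirna[w0 + k] if w0 + k < len(mirna) else None
    before = mirna[w0 - 1] if w0 - 1 >= 0 else None
    if pos - 1 >= 0:
        seq[pos - 1] = _blocking_base(rng, after)
    if pos + k < len(seq):
        seq[pos + k] = _blocking_base(rng, before)


def gen_utrs(
    config: SimulationConfig, seed: int
) -> tuple[list[UtrRecord], SyntheticTruth]:
    """Generate the UTR cohort with planted seed sites and its truth.

    Class counts are ``round(f * n_genes)``; each selected gene carries one
    site per planted seed type (both-class genes get one CS and one IS site,
    non-overlapping).  Background sequence is i.i.d. at the configured GC;
    any chance occurrence of an active word (shifts 0..max_shift) triggers a
    resample, so the final classes are exact.
    """
    rng = _rng(seed, 0)
    mirna = config.mirna
    cs_word = derive_target_word(mirna, CANONICAL_SEED)
    is_word = derive_target_word(mirna, INTERNAL_SEED)
    reject = rejection_words(config)
    k = CANONICAL_SEED.length
    margin = 17  # room for the site, its blocking flanks and screen windows
    if config.utr_len_min < 2 * margin + 2 * (k + 2):
        raise ValueError(
            f"utr_len_min={config.utr_len_min} too short to plant sites cleanly"
        )

    n = config.n_genes
    n_both = round(config.f_both * n)
    n_cs = round(config.f_cs * n)
    n_is = round(config.f_is * n)
    classes = (
        ["both"] * n_both
        + ["CS_only"] * n_cs
        + ["IS_only"] * n_is
        + ["neither"] * (n - n_both - n_cs - n_is)
    )
    classes = [classes[i] for i in rng.permutation(n)]
    lengths = rng.integers(config.utr_len_min, config.utr_len_max + 1, size=n)

    truth = SyntheticTruth()
    utrs: list[UtrRecord] = []
    width = len(str(n - 1))
    for gi in range(n):
        gene = f"g{gi:0{width}d}"
        cls = classes[gi]
        planted: dict[str, int] = {}
        expected = {w: 0 for w in reject}
        for _ in range(200):
            seq_str = _random_seq(rng, int(lengths[gi]), config.gc)
            if any(w in seq_str for w in reject):
                truth.n_resampled_utrs += 1
                continue
            seq = list(seq_str)
            planted = {}
            if cls in ("CS_only", "both"):
                pos = int(rng.integers(margin, len(seq) - margin - k))
                _plant_word(seq, pos, cs_word.word, mirna.sequence, CANONICAL_SEED, rng)
                planted["CS"] = pos
            if cls in ("IS_only", "both"):
                for _ in range(50):
                    pos = int(rng.integers(margin, len(seq) - margin - k))
                    if "CS" not in planted or abs(pos - planted["CS"]) > k + 2:
                        break
                _plant_word(seq, pos, is_word.word, mirna.sequence, INTERNAL_SEED, rng)
                planted["IS"] = pos
            final = "".join(seq)
            expected = {w: 0 for w in reject}
            if "CS" in planted:
                expected[cs_word.word] = 1
            if "IS" in planted:
                expected[is_word.word] = 1
            if all(count_word_occurrences(final, w) == c for w, c in expected.items()):
                break
            truth.n_resampled_utrs += 1
        else:
            raise RuntimeError(f"could not generate a clean UTR for {gene}")
        utrs.append(UtrRecord(gene, final))
        truth.classes[gene] = cls
        truth.sites[gene] = planted
        mu = 0.0
        if cls in ("CS_only", "both"):
            mu += config.delta_cs
        if cls in ("IS_only", "both"):
            mu += config.delta_is
        if cls == "both":
            mu += config.interaction
        truth.expected_log2fc[gene] = mu
    return utrs, truth


def gen_expression(
    truth: SyntheticTruth, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Replicate log2 intensity matrix (genes x samples).

    Control replicates ~ Normal(baseline, sigma); treatment ~ Normal(
    baseline + mu_gene, sigma) with mu from the planted class deltas.
    """
    rng = _rng(seed, 1)
    genes = sorted(truth.classes)
    mu = np.array([truth.expected_log2fc[g] for g in genes])
    r = config.n_reps
    ctrl = config.baseline + rng.normal(0, config.sigma, size=(len(genes), r))
    treat = config.baseline + mu[:, None] + rng.normal(0, config.sigma, size=(len(genes), r))
    cols = [f"ctrl_{i + 1}" for i in range(r)] + [f"treat_{i + 1}" for i in range(r)]
    return pd.DataFrame(
        np.hstack([ctrl, treat]), index=pd.Index(genes, name="gene_id"), columns=cols
    )


def group_labels(config: SimulationConfig) -> list[str]:
    return ["control"] * config.n_reps + ["treatment"] * config.n_reps


def transcript_model(
    utrs: Sequence[UtrRecord], config: SimulationConfig
) -> dict[str, tuple[int, int, int]]:
    """(utr5_len, cds_len, utr3_len) spans per gene; sites live in the 3'UTR."""
    return {
        u.gene_id: (config.utr5_len, config.cds_len, len(u.sequence)) for u in utrs
    }


def site_transcript_coords(
    truth: SyntheticTruth, config: SimulationConfig
) -> list[dict]:
    """Planted sites lifted to transcript coordinates."""
    offset = config.utr5_len + config.cds_len
    out = []
    for gene in sorted(truth.sites):
        for seed_type, pos in sorted(truth.sites[gene].items()):
            out.append(
                {"gene_id": gene, "seed_type": seed_type, "start": offset + pos}
            )
    return out


def gen_clip_reads(
    utrs: Sequence[UtrRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment and control CLIP libraries (BED6-style frames).

    Each planted site receives a treatment read pile (Poisson mean
    ``clip_peak_reads``, starts jittered +-``clip_jitter`` around the site
    centre) with probability ``clip_site_fraction``; which sites got piles is
    recorded in ``truth.clip_sites``.  Both libraries carry uniform
    background at ``clip_background_rate`` reads per transcript nt.
    """
    rng = _rng(seed, 2)
    k = CANONICAL_SEED.length
    tmodel = transcript_model(utrs, config)
    tlen = {g: sum(sp) for g, sp in tmodel.items()}
    rl = config.clip_read_len
    truth.clip_sites = []
    rows_t: list[tuple] = []
    for site in site_transcript_coords(truth, config):
        gene = site["gene_id"]
        has_pile = bool(rng.random() < config.clip_site_fraction)
        truth.clip_sites.append({**site, "region": "UTR3", "has_pile": has_pile})
        if not has_pile:
            continue
        n_reads = int(rng.poisson(config.clip_peak_reads))
        centre = site["start"] + k // 2
        for _ in range(n_reads):
            start = centre - rl // 2 + int(rng.integers(-config.clip_jitter, config.clip_jitter + 1))
            start = max(0, min(start, tlen[gene] - rl))
            rows_t.append((gene, start, start + rl))

    def background() -> list[tuple]:
        rows = []
        for u in utrs:
            L = tlen[u.gene_id]
            n_bg = int(rng.poisson(config.clip_background_rate * L))
            for _ in range(n_bg):
                start = int(rng.integers(0, max(1, L - rl)))
                rows.append((u.gene_id, start, start + rl))
        return rows

    rows_t += background()
    rows_c = background()

    def frame(rows: list[tuple], prefix: str) -> pd.DataFrame:
        rows = sorted(rows)
        return pd.DataFrame(
            {
                "contig": [r[0] for r in rows],
                "start": [r[1] for r in rows],
                "end": [r[2] for r in rows],
                "name": [f"{prefix}_{i}" for i in range(len(rows))],
                "score": 1,
                "strand": "+",
            }
        )

    return frame(rows_t, "t"), frame(rows_c, "c")


def gen_isomir_reads(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Small-RNA reads over the miRNA locus with multinomial 5' offsets."""
    rng = _rng(seed, 3)
    counts = rng.multinomial(config.n_isomir_reads, config.isomir_proportions)
    lo = config.isomir_locus_start
    hi = lo + config.isomir_mature_len
    rows = []
    i = 0
    for off, cnt in zip(config.isomir_offsets, counts):
        for _ in range(cnt):
            if config.isomir_strand == "+":
                start, end = lo + off, hi
            else:
                start, end = lo, hi - off
            rows.append((config.isomir_contig, start, end, f"r_{i}", 1, config.isomir_strand))
            i += 1
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])


def isomir_locus(config: SimulationConfig) -> GenomicInterval:
    return GenomicInterval(
        config.isomir_contig,
        config.isomir_locus_start,
        config.isomir_locus_start + config.isomir_mature_len,
        config.isomir_strand,
    )


def gen_qpcr(
    config: SimulationConfig, seed: int, truth: SyntheticTruth | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Cq table (samples x genes) with a planted miRNA-target rank correlation.

    Latent log2 quantities for the miRNA and target come from a Gaussian
    copula whose Pearson correlation ``2*sin(pi*rho_s/6)`` plants the
    requested Spearman ``rho_s``; reference genes are constant up to noise.
    Cq = baseline - log2(quantity) + Normal(0, cq_noise).
    """
    rng = _rng(seed, 4)
    if truth is None:
        truth = SyntheticTruth()
    rho_s = config.qpcr_rho
    r = 2 * np.sin(np.pi * rho_s / 6)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=config.qpcr_n_samples, method="cholesky")
    l_mir = config.qpcr_spread * z[:, 0]
    l_tgt = config.qpcr_spread * z[:, 1]
    n = config.qpcr_n_samples
    samples = [f"s{i + 1:02d}" for i in range(n)]
    data = {
        "mir_sim": config.qpcr_baseline - l_mir + rng.normal(0, config.qpcr_cq_noise, n),
        "target_gene": config.qpcr_baseline - l_tgt + rng.normal(0, config.qpcr_cq_noise, n),
    }
    for i in range(config.qpcr_n_refs):
        data[f"REF{i + 1}"] = config.qpcr_baseline - 5.0 + rng.normal(
            0, config.qpcr_ref_noise, n
        )
    cq = pd.DataFrame(data, index=pd.Index(samples, name="sample"))
    truth.qpcr_latent = {"mir_sim": l_mir.tolist(), "target_gene": l_tgt.tolist()}
    return cq, truth


def plant_long_hybrids(
    utrs: list[UtrRecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
    genes: Sequence[str],
    run_length: int = 12,
) -> list[UtrRecord]:
    """Extend the IS site of the chosen genes into a perfect ``run_length``-nt
    complement of the miRNA (centred so it contains the full IS window).

    Returns a new UTR list; planted genes are recorded in
    ``truth.long_hybrid_genes``.  Genes without an IS site are an error.
    """
    mirna = config.mirna.sequence
    w0 = INTERNAL_SEED.anchor - 1  # 0-based IS window start (5)
    k = INTERNAL_SEED.length
    extra = run_length - k
    left_ext = extra // 2  # extend toward miRNA 3' side => target 5' side
    right_ext = extra - left_ext
    m_lo = w0 - right_ext
    m_hi = w0 + k + left_ext
    if m_lo < 0 or m_hi > len(mirna):
        raise ValueError("run_length does not fit around the IS window")
    # reverse complement of the extended miRNA window, as DNA
    block = revcomp_rna_to_dna(mirna[m_lo:m_hi])
    by_id = {u.gene_id: u for u in utrs}
    out = dict(by_id)
    for gene in genes:
        if gene not in truth.sites or "IS" not in truth.sites[gene]:
            raise ValueError(f"gene {gene!r} has no planted IS site to extend")
        pos = truth.sites[gene]["IS"]
        seq = list(by_id[gene].sequence)
        start = pos - left_ext
        seq[start : start + run_length] = list(block)
        out[gene] = UtrRecord(gene, "".join(seq))
        truth.long_hybrid_genes.append(gene)
    return [out[u.gene_id] for u in utrs]


# ---------------------------------------------------------------------------
# end-to-end emission
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus the truth manifest; returns the paths."""
    from . import io as bio  # local import to avoid cycles

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    utrs, truth = gen_utrs(config, seed)
    expr = gen_expression(truth, config, seed)
    treat, ctrl = gen_clip_reads(utrs, truth, config, seed)
    iso = gen_isomir_reads(config, seed)
    cq, truth = gen_qpcr(config, seed, truth)

    paths = {
        "utrs": outdir / "utrs.fasta",
        "mirna": outdir / "mirna.fasta",
        "expression": outdir / "expression.tsv",
        "clip_treat": outdir / "clip_treatment.bed",
        "clip_ctrl": outdir / "clip_control.bed",
        "isomir_reads": outdir / "isomir_reads.bed",
        "qpcr": outdir / "qpcr_cq.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
    }
    bio.write_fasta([(u.gene_id, u.sequence) for u in utrs], paths["utrs"])
    bio.write_fasta([(config.mirna_id, config.mirna_seq)], paths["mirna"])
    expr.to_csv(paths["expression"], sep="\t")
    bio.write_bed6(treat, paths["clip_treat"])
    bio.write_bed6(ctrl, paths["clip_ctrl"])
    bio.write_bed6(iso, paths["isomir_reads"])
    cq.to_csv(paths["qpcr"], sep="\t")
    paths["truth"].write_text(truth.to_json())
    paths["config"].write_text(config.to_json())
    return paths
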