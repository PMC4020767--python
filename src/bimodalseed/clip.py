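"""Seed-anchored AGO-CLIP peak calling in transcript coordinates.

Candidate interaction regions are windows around seed matches (match
extended by a flank in both directions, default 10 nt, clipped at
transcript bounds; overlapping windows of the same seed type are merged).
Reads from the miRNA-transfected (treatment) and matched control libraries
are counted per window with an any-overlap rule; a window is a positive
peak when its treatment coverage clears a minimum read count and its
library-size-normalised fold change over the control clears a minimum
enrichment (a one-sided Poisson test is available as an alternative
criterion).  Peaks are annotated by transcript region (UTR5/CDS/UTR3) from
the peak midpoint and can be intersected with a down-regulated gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

READ_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class Peak:
    interval: GenomicInterval
    seed_type: str
    gene_id: str
    n_treat: float
    n_ctrl: float
    enrichment: float
    positive: bool
    region: str = ""


def seed_windows(
    transcript_lengths: dict[str, int],
    matches,
    flank: int = 10,
) -> list[tuple[GenomicInterval, str]]:
    """Candidate windows: seed matches extended ``flank`` nt each way.

    ``matches`` are SeedMatch-like objects whose ``start`` is already in
    transcript coordinates and whose ``seed_name`` starts with the seed type
    (CS/IS; shifted variants collapse onto their base type).  Windows are
    clipped at transcript bounds and overlapping same-type windows merged.
    Returns (interval, seed_type) pairs, sorted.
    """
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for mt in matches:
        if mt.gene_id not in transcript_lengths:
            raise KeyError(f"no transcript length for {mt.gene_id!r}")
        seed_type = mt.seed_name.split("+")[0] if mt.seed_name else "?"
        tlen = transcript_lengths[mt.gene_id]
        lo = max(0, mt.start - flank)
        hi = min(tlen, mt.start + len(mt.word) + flank)
        raw.setdefault((mt.gene_id, seed_type), []).append((lo, hi))
    out = []
    for (gene, seed_type), spans in raw.items():
        spans.sort()
        merged = [list(spans[0])]
        for lo, hi in spans[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            out.append((GenomicInterval(gene, lo, hi), seed_type))
    out.sort(key=lambda t: (t[0].contig, t[0].start, t[1]))
    return out


def count_overlaps(
    intervals: Sequence[GenomicInterval], reads: pd.DataFrame
) -> np.ndarray:
    """Read weight overlapping each interval by >= 1 base.

    ``reads`` is a BED6-style frame (contig, start, end, name, score,
    strand); the score column carries the collapsed-duplicate count (>= 1).
    A read overlaps a window iff read.start < window.end and
    read.end > window.start.
    """
    counts = np.zeros(len(intervals), dtype=float)
    if reads.empty:
        return counts
    for contig, sub in reads.groupby("contig", sort=False):
        idxs = [k for k, iv in enumerate(intervals) if iv.contig == contig]
        if not idxs:
            continue
        w = sub["score"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        o_start = np.argsort(starts, kind="stable")
        o_end = np.argsort(ends, kind="stable")
        cs_by_start = np.concatenate([[0.0], np.cumsum(w[o_start])])
        cs_by_end = np.concatenate([[0.0], np.cumsum(w[o_end])])
        s_sorted = starts[o_start]
        e_sorted = ends[o_end]
        for k in idxs:
            iv = intervals[k]
            before_end = cs_by_start[np.searchsorted(s_sorted, iv.end, side="left")]
            ended_before = cs_by_end[np.searchsorted(e_sorted, iv.start, side="right")]
            counts[k] = before_end - ended_before
    return counts


def call_peaks(
    windows: Sequence[tuple[GenomicInterval, str]],
    treat_reads: pd.DataFrame,
    ctrl_reads: pd.DataFrame,
    libsize_treat: float | None = None,
    libsize_ctrl: float | None = None,
    min_treat: float = 5.0,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    test: str = "fold",
    poisson_alpha: float = 0.01,
) -> list[Peak]:
    """Score candidate windows for treatment-specific read enrichment.

    enrichment = ((n_treat + pc) / libsize_treat) / ((n_ctrl + pc) /
    libsize_ctrl); a window is positive when n_treat >= min_treat and
    enrichment >= min_fold.  ``test="poisson"`` instead requires a one-sided
    Poisson p value (treatment count under the scaled control rate) below
    ``poisson_alpha``.  Library sizes default to the total read weight per
    library; they must be positive.
    """
    if libsize_treat is None:
        libsize_treat = float(treat_reads["score"].sum())
    if libsize_ctrl is None:
        libsize_ctrl = float(ctrl_reads["score"].sum())
    if libsize_treat <= 0 or libsize_ctrl <= 0:
        raise ValueError("library sizes must be positive")
    intervals = [w[0] for w in windows]
    n_treat = count_overlaps(intervals, treat_reads)
    n_ctrl = count_overlaps(intervals, ctrl_reads)
    peaks = []
    for (iv, seed_type), nt, nc in zip(windows, n_treat, n_ctrl):
        enr = ((nt + pseudocount) / libsize_treat) / ((nc + pseudocount) / libsize_ctrl)
        if test == "fold":
            positive = (nt >= min_treat) and (enr >= min_fold)
        elif test == "poisson":
            rate = (nc + pseudocount) * libsize_treat / libsize_ctrl
            pval = stats.poisson.sf(nt - 1, rate)
            positive = (nt >= min_treat) and (pval < poisson_alpha)
        else:
            raise ValueError("test must be 'fold' or 'poisson'")
        peaks.append(
            Peak(
                interval=iv,
                seed_type=seed_type,
                gene_id=iv.contig,
                n_treat=float(nt),
                n_ctrl=float(nc),
                enrichment=float(enr),
                positive=bool(positive),
            )
        )
    return peaks


def annotate_region(peak: Peak, transcript_model: dict[str, tuple[int, int, int]]) -> str:
    """Region label (UTR5/CDS/UTR3) by the peak midpoint.

    ``transcript_model`` maps gene id -> (utr5_len, cds_len, utr3_len);
    spans are half-open and consecutive, so a midpoint on a junction belongs
    to the downstream span.  A peak outside the model is an error.
    """
    if peak.gene_id not in transcript_model:
        raise KeyError(f"transcript model missing {peak.gene_id!r}")
    u5, cds, u3 = transcript_model[peak.gene_id]
    mid = (peak.interval.start + peak.interval.end) // 2
    if not (0 <= mid < u5 + cds + u3):
        raise ValueError(
            f"peak midpoint {mid} outside transcript {peak.gene_id!r} "
            f"(length {u5 + cds + u3})"
        )
    if mid < u5:
        return "UTR5"
    if mid < u5 + cds:
        return "CDS"
    return "UTR3"


def annotate_peaks(
    peaks: Iterable[Peak], transcript_model: dict[str, tuple[int, int, int]]
) -> None:
    for p in peaks:
        p.region = annotate_region(p, transcript_model)


def overlap_with_expression(
    peaks: Iterable[Peak], down_genes: set[str]
) -> dict[str, dict[str, float | int | None]]:
    """Per seed type: fraction of positive-UTR3-peak genes that are down.

    Returns {seed_type: {"fraction", "n_down", "n_genes"}}; an empty peak
    set for a seed type yields fraction None (flagged undefined).
    """
    by_type: dict[str, set[str]] = {}
    for p in peaks:
        if p.positive and p.region == "UTR3":
            by_type.setdefault(p.seed_type, set()).add(p.gene_id)
    out: dict[str, dict] = {}
    for seed_type in sorted(set(by_type) | {"CS", "IS"}):
        genes = by_type.get(seed_type, set())
        n_down = len(genes & down_genes)
        out[seed_type] = {
            "fraction": (n_down / len(genes)) if genes else None,
            "n_down": n_down,
            "n_genes": len(genes),
        }
    return out
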