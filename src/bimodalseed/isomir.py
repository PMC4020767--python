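"""5' isomiR profiling from small-RNA alignments.

A mature miRNA locus accumulates reads whose 5' ends scatter around the
canonical start.  The 5' offset of a read (in mature orientation; positive =
truncated) decides which seed windows the loaded guide presents: a guide
shortened by ``s`` nt uses the canonical windows shifted by ``+s``.  This
module tabulates the offset distribution of a locus and selects which
shifted seed definitions are abundant enough to feed into scanning and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clip import GenomicInterval


@dataclass
class IsomirProfile:
    """Offset spectrum of one miRNA locus.

    ``table`` has one row per observed offset (plus an ``other`` bucket for
    reads beyond +-max_offset) with the read count, the fraction of locus
    reads and, when a total was supplied, the fraction of all genome-mapped
    reads.  Locus fractions sum to 1.
    """

    mirna_id: str
    table: pd.DataFrame
    n_locus_reads: float
    total_mapped: float | None = None

    @property
    def empty(self) -> bool:
        return self.n_locus_reads == 0

    def fraction(self, offset: int) -> float:
        row = self.table[self.table["offset"] == offset]
        return float(row["frac_locus"].iloc[0]) if len(row) else 0.0


def five_prime_offsets(
    reads: pd.DataFrame,
    mature_interval: GenomicInterval,
    max_offset: int = 5,
    mirna_id: str = "",
    total_mapped: float | None = None,
) -> IsomirProfile:
    """Tabulate read 5'-end offsets relative to the canonical mature 5' end.

    ``reads`` is BED6-like (contig, start, end, name, score, strand); only
    reads on the mature strand of the locus contig that overlap the locus
    are counted, weighted by score.  On the plus strand the offset is
    ``read.start - locus.start``; on the minus strand ``locus.end -
    read.end``.  Offsets beyond +-``max_offset`` are pooled into an
    ``other`` row.  A locus with zero reads yields an empty (flagged)
    profile.
    """
    iv = mature_interval
    sub = reads[
        (reads["contig"] == iv.contig)
        & (reads["strand"] == iv.strand)
        & (reads["start"] < iv.end)
        & (reads["end"] > iv.start)
    ]
    if sub.empty:
        return IsomirProfile(
            mirna_id,
            pd.DataFrame(columns=["offset", "count", "frac_locus", "frac_genome"]),
            0.0,
            total_mapped,
        )
    if iv.strand == "+":
        offsets = sub["start"].to_numpy() - iv.start
    else:
        offsets = iv.end - sub["end"].to_numpy()
    weights = sub["score"].to_numpy(dtype=float)
    total = float(weights.sum())
    rows = {}
    for off, w in zip(offsets, weights):
        key = int(off) if abs(off) <= max_offset else "other"
        rows[key] = rows.get(key, 0.0) + w
    order = sorted((k for k in rows if k != "other")) + (
        ["other"] if "other" in rows else []
    )
    table = pd.DataFrame(
        {
            "offset": order,
            "count": [rows[k] for k in order],
        }
    )
    table["frac_locus"] = table["count"] / total
    table["frac_genome"] = (
        table["count"] / total_mapped if total_mapped else np.nan
    )
    return IsomirProfile(mirna_id, table, total, total_mapped)


def active_seed_shifts(profile: IsomirProfile, min_fraction: float = 0.10) -> set[int]:
    """Non-negative 5' offsets abundant enough to define active seed shifts.

    A truncation of ``s`` nt with locus fraction >= ``min_fraction``
    activates shift ``s`` (feeding shifted_variants in the scanner).
    5'-extended reads (negative offsets) never shift seeds; an empty profile
    activates the canonical shift only.
    """
    if profile.empty:
        return {0}
    out = {
        int(o)
        for o, f in zip(profile.table["offset"], profile.table["frac_locus"])
        if o != "other" and int(o) >= 0 and f >= min_fraction
    }
    return out or {0}
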