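"""Seed definitions, target words and 3'UTR scanning.

A miRNA can repress a transcript through perfect complementarity between a
short window of the mature guide and the mRNA.  The classical window is the
*canonical seed* (CS), nucleotides 2-8 from the miRNA 5' end; the *internal
seed* (IS) is the analogous window shifted to nucleotides 6-12.  Both windows
behave as position-anchored seeds: a 5' truncation of the mature miRNA by
``s`` nucleotides moves every window ``s`` positions toward the 3' end
(CS+1, IS+1, ...).

This module derives the DNA *target words* (reverse complements of the seed
windows), scans 3'UTR sequences for exact matches, classifies genes by their
seed content (CS only / IS only / both / neither), and extracts the local
sequence context of matches for logo-style summaries.

Coordinate conventions: miRNA positions are 1-based (position 1 is the 5'
nucleotide, so "nt 2-8" reads exactly as written); UTR match coordinates are
0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

RNA_ALPHABET = frozenset("ACGU")
UTR_ALPHABET = frozenset("ACGTN")

#: reverse-complement a 5'->3' RNA window into the 5'->3' DNA search word
_RNA_TO_DNA_COMP = str.maketrans("ACGU", "TGCA")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

#: mature hsa-miR-4728-3p (miRBase MIMAT0019849); its positions 6-12 are
#: UGACCUC, whose reverse complement is the internal-seed word GAGGTCA.
MIR_4728_3P = "CAUGCUGACCUCCCUCCUGCCCUC"


def revcomp_rna_to_dna(window: str) -> str:
    """Reverse complement of an RNA window, written in the DNA alphabet."""
    return window.translate(_RNA_TO_DNA_COMP)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not (16 <= len(self.sequence) <= 30):
            raise ValueError(
                f"mature miRNA {self.id!r} has length {len(self.sequence)}; "
                "expected 16-30 nt"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"mature miRNA {self.id!r} contains non-ACGU characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SeedDefinition:
    """A seed window on the canonical mature miRNA.

    Parameters
    ----------
    name:
        Label, e.g. ``"CS"`` or ``"IS+1"``.
    anchor:
        1-based first position of the window on the *canonical* mature
        sequence (CS: 2, IS: 6).
    length:
        Word size k, 5-9.
    isomir_shift:
        5' truncation (in nt) this definition compensates for; shift ``s``
        moves the effective window ``s`` positions toward the 3' end.
    """

    name: str
    anchor: int
    length: int
    isomir_shift: int = 0

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError(f"seed {self.name!r}: anchor must be >= 1")
        if not (5 <= self.length <= 9):
            raise ValueError(f"seed {self.name!r}: length must be in [5, 9]")
        if self.isomir_shift < 0:
            raise ValueError(f"seed {self.name!r}: isomir_shift must be >= 0")

    def window(self, mirna: MatureMiRNA) -> tuple[int, int]:
        """0-based half-open window on ``mirna``; raises if out of range."""
        start = self.anchor + self.isomir_shift - 1
        end = start + self.length
        if end > len(mirna):
            raise ValueError(
                f"seed {self.name!r} (anchor {self.anchor}, length {self.length}, "
                f"shift {self.isomir_shift}) does not fit inside miRNA "
                f"{mirna.id!r} of length {len(mirna)}"
            )
        return start, end


#: the two seed types of interest, as 7-mers
CANONICAL_SEED = SeedDefinition("CS", anchor=2, length=7)
INTERNAL_SEED = SeedDefinition("IS", anchor=6, length=7)


@dataclass(frozen=True)
class TargetWord:
    """DNA word searched in UTRs: reverse complement of a seed window."""

    word: str
    seed: SeedDefinition
    source_mirna: str


@dataclass(frozen=True)
class UtrRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - UTR_ALPHABET
        if bad:
            raise ValueError(
                f"UTR {self.gene_id!r} contains characters outside ACGTN: {sorted(bad)}"
            )


@dataclass(frozen=True)
class SeedMatch:
    """Exact occurrence of a target word in a UTR, [start, start+k)."""

    gene_id: str
    word: str
    start: int
    seed_name: str = ""


@dataclass(frozen=True)
class SeedClassAnnotation:
    gene_id: str
    n_cs: int
    n_is: int
    cls: str  # CS_only | IS_only | both | neither


@dataclass
class PositionFrequencyMatrix:
    """Per-position nucleotide fractions over extracted site fragments.

    ``matrix`` has shape (4, L) over alphabet ACGT; positions truncated at
    UTR edges are excluded from the corresponding column totals, which are
    tracked in ``coverage``.
    """

    matrix: np.ndarray
    coverage: np.ndarray
    n_fragments: int
    alphabet: str = "ACGT"


def derive_target_word(mirna: MatureMiRNA, seed: SeedDefinition) -> TargetWord:
    """DNA target word matched by ``seed`` of ``mirna``.

    The word is the reverse complement of miRNA positions
    ``anchor+shift .. anchor+shift+length-1`` with U written as T.
    """
    start, end = seed.window(mirna)
    return TargetWord(
        word=revcomp_rna_to_dna(mirna.sequence[start:end]),
        seed=seed,
        source_mirna=mirna.id,
    )


def shifted_variants(seed: SeedDefinition, max_shift: int) -> list[SeedDefinition]:
    """Seed definitions for 5' truncations 0..max_shift.

    Shift ``s`` compensates a 5'-truncated isomiR by moving the window ``s``
    positions toward the miRNA 3' end; names get a ``+s`` suffix.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    out = [seed]
    for s in range(1, max_shift + 1):
        out.append(
            SeedDefinition(
                name=f"{seed.name}+{s}",
                anchor=seed.anchor,
                length=seed.length,
                isomir_shift=seed.isomir_shift + s,
            )
        )
    return out


def scan_utr(utr: UtrRecord, words: Sequence[TargetWord]) -> list[SeedMatch]:
    """All exact, overlapping occurrences of ``words`` in one UTR.

    N never matches (words are pure ACGT so string equality enforces this).
    An empty UTR yields an empty list.
    """
    if not words:
        raise ValueError("scan_utr: words must be non-empty")
    seq = utr.sequence
    hits: list[SeedMatch] = []
    for tw in words:
        pos = seq.find(tw.word)
        while pos != -1:
            hits.append(SeedMatch(utr.gene_id, tw.word, pos, tw.seed.name))
            pos = seq.find(tw.word, pos + 1)
    hits.sort(key=lambda m: (m.start, m.word))
    return hits


def count_word_occurrences(seq: str, word: str) -> int:
    """Overlapping occurrence count of ``word`` in ``seq``."""
    n = 0
    pos = seq.find(word)
    while pos != -1:
        n += 1
        pos = seq.find(word, pos + 1)
    return n


def classify_genes(
    utrs: Sequence[UtrRecord],
    cs_words: Sequence[TargetWord],
    is_words: Sequence[TargetWord],
) -> list[SeedClassAnnotation]:
    """One presence-based seed-class annotation per gene.

    Counts aggregate over the supplied word sets (which should already
    include any active shifted variants).  The two word sets must be
    disjoint; duplicate gene ids are an error.
    """
    cs_set = {w.word for w in cs_words}
    is_set = {w.word for w in is_words}
    common = cs_set & is_set
    if common:
        raise ValueError(f"CS and IS word sets overlap: {sorted(common)}")
    seen: set[str] = set()
    out = []
    for utr in utrs:
        if utr.gene_id in seen:
            raise ValueError(f"duplicate gene_id {utr.gene_id!r}")
        seen.add(utr.gene_id)
        n_cs = sum(count_word_occurrences(utr.sequence, w) for w in cs_set)
        n_is = sum(count_word_occurrences(utr.sequence, w) for w in is_set)
        if n_cs and n_is:
            cls = "both"
        elif n_cs:
            cls = "CS_only"
        elif n_is:
            cls = "IS_only"
        else:
            cls = "neither"
        out.append(SeedClassAnnotation(utr.gene_id, n_cs, n_is, cls))
    return out


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def extract_context(
    utrs: Sequence[UtrRecord], word: str, flank: int = 10
) -> PositionFrequencyMatrix:
    """Position frequency matrix of site fragments with ``flank`` nt context.

    Fragments of length ``len(word) + 2*flank`` are centered on every match;
    positions truncated at UTR edges are simply excluded from the affected
    column totals.  With no matches, ``n_fragments`` is 0 and the matrix is
    all-zero.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    k = len(word)
    L = k + 2 * flank
    counts = np.zeros((4, L), dtype=np.int64)
    coverage = np.zeros(L, dtype=np.int64)
    n_fragments = 0
    for utr in utrs:
        seq = utr.sequence
        pos = seq.find(word)
        while pos != -1:
            n_fragments += 1
            for col in range(L):
                p = pos - flank + col
                if 0 <= p < len(seq):
                    base = seq[p]
                    if base in _BASE_INDEX:
                        counts[_BASE_INDEX[base], col] += 1
                        coverage[col] += 1
            pos = seq.find(word, pos + 1)
    matrix = np.zeros((4, L), dtype=float)
    nonzero = coverage > 0
    matrix[:, nonzero] = counts[:, nonzero] / coverage[nonzero]
    return PositionFrequencyMatrix(matrix=matrix, coverage=coverage, n_fragments=n_fragments)
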