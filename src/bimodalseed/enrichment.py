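"""Word-enrichment landscapes over a ranked gene list.

For every k-mer "word" the engine asks, at each leading bin of a gene list
ranked from most down- to most up-regulated: is the set of genes whose 3'UTR
contains the word over- or under-represented among the leading genes?  The
statistic is the exact one-sided hypergeometric tail (presence-based: a gene
either contains the word or it does not), reported as a signed -log10 p so
that over-representation plots on the positive y axis.  The word matching a
transfected miRNA's seed should rise far above the vocabulary background in
the down-regulated bins.

The tail probabilities are computed in log space by summing the
hypergeometric pmf in the direction in which it decays (complementing when
asked for the fat side), so extremely significant words do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seedscan import UtrRecord

LOG10 = math.log(10.0)


# ---------------------------------------------------------------------------
# exact hypergeometric tails
# ---------------------------------------------------------------------------

def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _logpmf(x: int, K: int, n: int, N: int) -> float:
    return _log_binom(K, x) + _log_binom(N - K, n - x) - _log_binom(N, n)


def _log_sum_decaying(x: int, K: int, n: int, N: int, direction: int) -> float:
    """log sum_{j} pmf, starting at x and stepping by ``direction`` (+-1)
    until the support bound; assumes terms (eventually) decay so the running
    relative term is bounded."""
    lo = max(0, n + K - N)
    hi = min(K, n)
    log_first = _logpmf(x, K, n, N)
    s = 1.0
    t = 1.0
    j = x
    while True:
        if direction > 0:
            if j >= hi:
                break
            # pmf(j+1)/pmf(j)
            ratio = ((K - j) * (n - j)) / ((j + 1.0) * (N - K - n + j + 1.0))
        else:
            if j <= lo:
                break
            # pmf(j-1)/pmf(j)
            ratio = (j * (N - K - n + j)) / ((K - j + 1.0) * (n - j + 1.0))
        t *= ratio
        s += t
        j += direction
        if t < 1e-18 * s:
            break
    return log_first + math.log(s)


def hypergeom_logtail(x: int, K: int, n: int, N: int, side: str = "over") -> float:
    """Exact log one-sided hypergeometric tail.

    ``side="over"`` gives log P(X >= x), ``side="under"`` log P(X <= x), for
    X ~ Hypergeometric(N, K, n) (population N, K marked, n drawn).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible parameters K={K}, n={n}, N={N}")
    lo = max(0, n + K - N)
    hi = min(K, n)
    if side == "over":
        if x <= lo:
            return 0.0
        if x > hi:
            return -math.inf
        if not (0 <= x <= hi):
            raise ValueError(f"x={x} outside [0, min(K, n)]")
        mode = ((n + 1) * (K + 1)) // (N + 2)
        if x > mode:
            return _log_sum_decaying(x, K, n, N, +1)
        other = _log_sum_decaying(x - 1, K, n, N, -1)  # P(X <= x-1), decaying down
        return math.log1p(-math.exp(other)) if other < 0 else -math.inf
    if side == "under":
        if x >= hi:
            return 0.0
        if x < lo:
            return -math.inf
        mode = ((n + 1) * (K + 1)) // (N + 2)
        if x < mode:
            return _log_sum_decaying(x, K, n, N, -1)
        other = _log_sum_decaying(x + 1, K, n, N, +1)  # P(X >= x+1), decaying up
        return math.log1p(-math.exp(other)) if other < 0 else -math.inf
    raise ValueError(f"side must be 'over' or 'under', got {side!r}")


def hypergeom_tail(x: int, K: int, n: int, N: int, side: str = "over") -> float:
    """Exact one-sided hypergeometric tail probability (see hypergeom_logtail)."""
    return math.exp(hypergeom_logtail(x, K, n, N, side))


def _signed_logp(x: int, K: int, n: int, N: int) -> float:
    """Signed -log10 of the smaller one-sided tail; positive = over-represented."""
    lover = hypergeom_logtail(x, K, n, N, "over")
    lunder = hypergeom_logtail(x, K, n, N, "under")
    if lover == lunder:
        return 0.0
    if lover < lunder:
        return -lover / LOG10
    return lunder / LOG10


# ---------------------------------------------------------------------------
# word index
# ---------------------------------------------------------------------------

_ENC = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers of ``seq`` (windows containing N dropped)."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    m = arr.size - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for t in range(k):
        col = arr[t : t + m]
        codes = codes * 4 + np.where(col < 0, 0, col)
        ok &= col >= 0
    return codes[ok]


def _decode_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _encode_word(word: str) -> int:
    code = 0
    for b in word:
        code = code * 4 + _BASE[b]
    return code


_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


class WordIndex:
    """Presence index: word -> set of genes whose UTR contains it.

    Built once per (UTR set, k); genes are listed under a word iff the word
    occurs at least once.  Internally stores sorted (word code, gene index)
    pairs for vectorised landscape computation.
    """

    def __init__(self, utrs: Sequence[UtrRecord], k: int):
        if not (5 <= k <= 9):
            raise ValueError("word size k must be in [5, 9]")
        self.k = k
        self.gene_ids = [u.gene_id for u in utrs]
        chunks = []
        for gi, u in enumerate(utrs):
            codes = _encode_kmers(u.sequence, k)
            if codes.size:
                # fold the gene into the code so one global unique suffices
                chunks.append(codes + (gi << (2 * k)))
        if chunks:
            combined = np.sort(np.concatenate(chunks))
            first = np.empty(combined.size, dtype=bool)
            first[0] = True
            np.not_equal(combined[1:], combined[:-1], out=first[1:])
            combined = combined[first]
            genes = combined >> (2 * k)
            codes = combined & ((1 << (2 * k)) - 1)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._genes = genes[order]
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._genes = np.empty(0, dtype=np.int64)
        if self._codes.size:
            starts_mask = np.empty(self._codes.size, dtype=bool)
            starts_mask[0] = True
            np.not_equal(self._codes[1:], self._codes[:-1], out=starts_mask[1:])
            self._starts = np.nonzero(starts_mask)[0]
            self._words = self._codes[self._starts]
        else:
            self._words = np.empty(0, dtype=np.int64)
            self._starts = np.empty(0, dtype=np.int64)

    def __contains__(self, word: str) -> bool:
        return self.gene_indices(word).size > 0

    def words(self) -> list[str]:
        return [_decode_word(int(c), self.k) for c in self._words]

    def gene_indices(self, word: str) -> np.ndarray:
        if len(word) != self.k:
            raise ValueError(f"word {word!r} has length {len(word)}, index k={self.k}")
        code = _encode_word(word)
        left = np.searchsorted(self._codes, code, side="left")
        right = np.searchsorted(self._codes, code, side="right")
        return self._genes[left:right]

    def genes_with(self, word: str) -> set[str]:
        return {self.gene_ids[i] for i in self.gene_indices(word)}


def build_word_index(utrs: Sequence[UtrRecord], k: int) -> WordIndex:
    return WordIndex(utrs, k)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentLandscape:
    word: str
    bin_edges: np.ndarray  # leading-bin sizes
    signed_logp: np.ndarray
    peak_bin: int  # leading-bin size at the maximum signed value
    peak_value: float


def _bin_edges(N: int, step: int) -> np.ndarray:
    if step < 1:
        raise ValueError("step must be >= 1")
    edges = np.arange(step, N + 1, step, dtype=np.int64)
    if edges.size == 0 or edges[-1] != N:
        edges = np.append(edges, N)
    return edges


def default_step(N: int) -> int:
    return max(1, N // 100)


def _rank_positions(ranked: Sequence[str], index: WordIndex) -> np.ndarray:
    rank_of = {g: r for r, g in enumerate(ranked)}
    missing = [g for g in index.gene_ids if g not in rank_of]
    if missing:
        raise ValueError(
            f"ranked list does not cover the indexed genes (e.g. {missing[:3]})"
        )
    return np.array([rank_of[g] for g in index.gene_ids], dtype=np.int64)


def landscape(
    ranked: Sequence[str], index: WordIndex, word: str, step: int | None = None
) -> EnrichmentLandscape:
    """Signed -log10 hypergeometric landscape of one word over leading bins.

    ``ranked`` orders genes from most down- to most up-regulated; bin ``i``
    covers the first ``step*i`` genes (the final bin is the full list and is
    identically 0).  A word absent from every UTR yields a flat landscape.
    """
    N = len(ranked)
    edges = _bin_edges(N, default_step(N) if step is None else step)
    ranks = _rank_positions(ranked, index)
    word_ranks = np.sort(ranks[index.gene_indices(word)])
    K = int(word_ranks.size)
    values = np.zeros(edges.size, dtype=float)
    if K > 0:
        xs = np.searchsorted(word_ranks, edges, side="left")
        for i, (n_lead, x) in enumerate(zip(edges, xs)):
            values[i] = _signed_logp(int(x), K, int(n_lead), N)
    peak_i = int(np.argmax(values))
    return EnrichmentLandscape(
        word=word,
        bin_edges=edges,
        signed_logp=values,
        peak_bin=int(edges[peak_i]),
        peak_value=float(values[peak_i]),
    )


def _bulk_signed_logp(X: np.ndarray, K: np.ndarray, n: np.ndarray, N: int) -> np.ndarray:
    """Signed -log10 values for a (words x bins) matrix of leading counts.

    Vectorised version of the exact engine: for every cell the tail on the
    decaying side of the pmf mode is summed in scaled log space via the pmf
    ratio recurrence (active cells compressed out as they converge), and the
    fat tail follows from the exact complement 1 - short + pmf(x).  Agrees
    with :func:`hypergeom_logtail` to floating-point rounding.
    """
    from scipy.special import gammaln

    W, B = X.shape
    x = X.astype(np.float64).ravel()
    Kf = np.broadcast_to(K[:, None].astype(np.float64), (W, B)).ravel()
    nf = np.broadcast_to(np.asarray(n, dtype=np.float64)[None, :], (W, B)).ravel()
    Nf = float(N)

    logpmf0 = (
        gammaln(Kf + 1) - gammaln(x + 1) - gammaln(Kf - x + 1)
        + gammaln(Nf - Kf + 1) - gammaln(nf - x + 1) - gammaln(Nf - Kf - nf + x + 1)
        - (gammaln(Nf + 1) - gammaln(nf + 1) - gammaln(Nf - nf + 1))
    )
    lo = np.maximum(0.0, nf + Kf - Nf)
    hi = np.minimum(Kf, nf)
    mode = np.floor((nf + 1) * (Kf + 1) / (Nf + 2))
    up = x >= mode  # sum the over-tail upward; else the under-tail downward

    s = np.ones_like(x)
    t = np.ones_like(x)
    j = x.copy()
    active = np.where(up, j < hi, j > lo)
    idx = np.nonzero(active)[0]
    while idx.size:
        ji = j[idx]
        Ki = Kf[idx]
        ni = nf[idx]
        upi = up[idx]
        ratio = np.where(
            upi,
            ((Ki - ji) * (ni - ji)) / ((ji + 1.0) * (Nf - Ki - ni + ji + 1.0)),
            (ji * (Nf - Ki - ni + ji)) / ((Ki - ji + 1.0) * (ni - ji + 1.0)),
        )
        t[idx] *= ratio
        s[idx] += t[idx]
        j[idx] += np.where(upi, 1.0, -1.0)
        keep = np.where(upi, j[idx] < hi[idx], j[idx] > lo[idx])
        keep &= t[idx] > 1e-18 * s[idx]
        idx = idx[keep]

    log_short = logpmf0 + np.log(s)
    with np.errstate(over="ignore"):
        short_lin = np.exp(log_short)
    fat_lin = np.minimum(1.0, 1.0 - short_lin + np.exp(logpmf0))
    with np.errstate(divide="ignore"):
        log_fat = np.log(fat_lin)
    lover = np.where(up, log_short, log_fat)
    lunder = np.where(up, log_fat, log_short)
    signed = np.where(lover < lunder, -lover, lunder) / LOG10
    signed[lover == lunder] = 0.0
    return signed.reshape(W, B)


def top_words(
    ranked: Sequence[str],
    index: WordIndex,
    m: int | None = None,
    step: int | None = None,
) -> list[tuple[str, int, float]]:
    """Words ranked by their peak signed landscape value, descending.

    Returns (word, peak_bin, peak_value) triples; ties break on the word
    lexicographically.  Words contained in no UTR are skipped.  ``m`` limits
    the output length (all words if None or larger than the vocabulary).
    """
    N = len(ranked)
    edges = _bin_edges(N, default_step(N) if step is None else step)
    ranks = _rank_positions(ranked, index)
    codes = index._codes
    genes = index._genes
    words = index._words
    starts = np.append(index._starts, codes.size)
    W = words.size
    if W == 0:
        return []
    nbins = edges.size
    # leading-bin counts per word via a (word, bin) histogram + cumsum
    word_row = np.repeat(np.arange(W), np.diff(starts))
    gene_rank = ranks[genes]
    # bin index of the first leading bin that contains this rank
    bin_idx = np.searchsorted(edges, gene_rank, side="right")
    flat = word_row * nbins + bin_idx
    hist = np.bincount(flat, minlength=W * nbins).reshape(W, nbins)
    X = np.cumsum(hist, axis=1)
    K = X[:, -1]
    signed = _bulk_signed_logp(X, K, edges, N)
    peak_i = np.argmax(signed, axis=1)
    peak_val = signed[np.arange(W), peak_i]
    out = [
        (_decode_word(int(words[w]), index.k), int(edges[peak_i[w]]), float(peak_val[w]))
        for w in range(W)
    ]
    out.sort(key=lambda t: (-t[2], t[0]))
    if m is not None:
        out = out[:m]
    return out
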