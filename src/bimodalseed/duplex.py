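"""Intermolecular RNA duplex minimum free energy by nearest-neighbor DP.

The model scores a set of base pairs between a miRNA and a short target
window (both read 5'->3'; the strands anneal antiparallel, so pair
coordinates increase on one strand while decreasing on the other).  Allowed
pairs are Watson-Crick plus G-U wobble; pairings must be non-crossing.  The
energy is a duplex initiation penalty, plus a tabulated stacking term for
each pair of adjacent pairs, plus bulge / internal-loop penalties for gaps
between consecutive pairs (capped at 10 nt per side, linear beyond the
table).  No intramolecular structure, dangling ends or temperature scaling.

The parameter table is a small embedded JSON (version-tagged) so a fuller
nearest-neighbor set can be swapped in; numeric agreement with any external
folding program is not a goal — internal consistency is, and the DP is
checked against exhaustive enumeration of all non-crossing pairings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
import numpy as np

_RNA = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA target to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass
class NNParameterSet:
    """Nearest-neighbor duplex parameters (kcal/mol)."""

    version: str
    initiation: float
    stack: dict[str, float]
    bulge_by_size: list[float]
    internal_by_total_size: list[float]
    loop_extension_per_nt: float
    max_loop_per_side: int

    @classmethod
    def load_default(cls) -> "NNParameterSet":
        text = resources.files("bimodalseed.data").joinpath("nn_params.json").read_text()
        raw = json.loads(text)
        return cls(
            version=raw["version"],
            initiation=raw["initiation"],
            stack=raw["stack"],
            bulge_by_size=raw["bulge_by_size"],
            internal_by_total_size=raw["internal_by_total_size"],
            loop_extension_per_nt=raw["loop_extension_per_nt"],
            max_loop_per_side=raw["max_loop_per_side"],
        )

    def bulge(self, size: int) -> float:
        if size <= len(self.bulge_by_size):
            return self.bulge_by_size[size - 1]
        return self.bulge_by_size[-1] + self.loop_extension_per_nt * (
            size - len(self.bulge_by_size)
        )

    def internal(self, total: int) -> float:
        if total - 1 <= len(self.internal_by_total_size):
            return self.internal_by_total_size[total - 2]
        return self.internal_by_total_size[-1] + self.loop_extension_per_nt * (
            total - 1 - len(self.internal_by_total_size)
        )

    def loop_cost(self, gap_a: int, gap_b: int) -> float:
        """Penalty for ``gap_a`` unpaired nt on strand a and ``gap_b`` on b
        between two consecutive pairs (0/0 is a stack, handled separately)."""
        if gap_a == 0 and gap_b == 0:
            raise ValueError("0/0 gap is a stack, not a loop")
        if gap_a == 0 or gap_b == 0:
            return self.bulge(gap_a + gap_b)
        return self.internal(gap_a + gap_b)

    def stack_energy(self, a_prev: str, a_cur: str, b_prev: str, b_cur: str) -> float:
        """Stack of adjacent pairs (a_prev:b_prev) then (a_cur:b_cur); b
        bases are given 3'->5' (antiparallel partner order)."""
        return self.stack[f"{a_prev}{a_cur}/{b_prev}{b_cur}"]


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_params() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = NNParameterSet.load_default()
    return _DEFAULT_PARAMS


@dataclass
class DuplexResult:
    """MFE duplex: energy, pairing and contiguity summaries.

    ``pairing`` lists (miRNA position, target position), both 0-based,
    ascending in the miRNA coordinate and descending in the target
    coordinate (antiparallel).  ``energy`` is +inf with an empty pairing
    when no admissible pair exists.
    """

    energy: float
    pairing: list[tuple[int, int]]
    max_run: int = 0
    covers_is: bool = False

    @property
    def is_empty(self) -> bool:
        return not self.pairing


def _pair_matrix(a: str, b: str) -> np.ndarray:
    pa = np.array(list(a))
    pb = np.array(list(b))
    ok = np.zeros((pa.size, pb.size), dtype=bool)
    for (x, y) in _PAIRABLE:
        ok |= (pa[:, None] == x) & (pb[None, :] == y)
    return ok


def duplex_mfe(
    mirna_seq: str,
    target_seq: str,
    params: NNParameterSet | None = None,
    is_window: tuple[int, int] | None = None,
) -> DuplexResult:
    """Global minimum-free-energy duplex between two sequences.

    ``mirna_seq`` must be RNA; a DNA ``target_seq`` is transcribed
    automatically.  ``is_window`` is an optional 1-based inclusive position
    range on the miRNA; when given, ``covers_is`` reports whether every
    position in that window is paired in the returned structure.  Traceback
    ties break toward more pairs, then lexicographically smallest
    predecessor, so results are deterministic.
    """
    if params is None:
        params = default_params()
    a = mirna_seq.upper()
    b = to_rna(target_seq)
    if len(a) > 60 or len(b) > 60:
        raise ValueError("sequences longer than 60 nt are outside the duplex model")
    for name, seq in (("miRNA", a), ("target", b)):
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{name} sequence contains non-ACGU characters: {sorted(bad)}")
    n, m = len(a), len(b)
    ok = _pair_matrix(a, b)
    if not ok.any():
        return DuplexResult(math.inf, [])

    G = params.max_loop_per_side
    # loop-cost matrix for gaps (gap_a, gap_b), 0..G each; [0,0] replaced by
    # the sequence-dependent stack term at each cell
    L = np.full((G + 1, G + 1), math.inf)
    for ga in range(G + 1):
        for gb in range(G + 1):
            if ga == 0 and gb == 0:
                continue
            L[ga, gb] = params.loop_cost(ga, gb)

    # stack lookup S[ai_prev, ai, bj_prev, bj] as a 4D table
    S = np.full((4, 4, 4, 4), math.inf)
    bases = "ACGU"
    for key, val in params.stack.items():
        x, y = key[0], key[1]
        xp, yp = key[3], key[4]
        S[_RNA[x], _RNA[y], _RNA[xp], _RNA[yp]] = val

    ai = np.array([_RNA[c] for c in a])
    bi = np.array([_RNA[c] for c in b])

    INF = math.inf
    E = np.full((n, m), INF)
    NP = np.zeros((n, m), dtype=np.int32)
    PI = np.full((n, m), -1, dtype=np.int32)
    PJ = np.full((n, m), -1, dtype=np.int32)

    for i in range(n):
        row_ok = ok[i]
        i_lo = max(0, i - 1 - G)
        for j in range(m - 1, -1, -1):
            if not row_ok[j]:
                continue
            best = params.initiation  # open a fresh duplex at (i, j)
            best_np = 1
            best_pi = -1
            best_pj = -1
            if i > 0 and j < m - 1:
                j_hi = min(m, j + 2 + G)
                sub = E[i_lo:i, j + 1 : j_hi]
                if np.isfinite(sub).any():
                    # cost[gi, gj] extends predecessor (i-1-gi, j+1+gj)
                    gi_max = i - i_lo
                    gj_max = j_hi - j - 1
                    cost = L[:gi_max, :gj_max].copy()
                    cost[0, 0] = S[ai[i - 1], ai[i], bi[j + 1], bi[j]]
                    # sub rows run i_lo..i-1, i.e. gi descending: flip them
                    tot = sub[::-1, :] + cost
                    mn = float(tot.min())
                    # an extension tie against a fresh start wins (more pairs)
                    if mn <= best + 1e-9:
                        e_star = min(best, mn)
                        best_key = None
                        for gi, gj in np.argwhere(tot <= e_star + 1e-9):
                            pi_, pj_ = i - 1 - int(gi), j + 1 + int(gj)
                            key = (-int(NP[pi_, pj_]), int(gi), int(gj))
                            if best_key is None or key < best_key:
                                best_key = key
                                best_np = int(NP[pi_, pj_]) + 1
                                best_pi, best_pj = pi_, pj_
                        best = e_star
            E[i, j] = best
            NP[i, j] = best_np
            PI[i, j] = best_pi
            PJ[i, j] = best_pj

    flat = np.argwhere(np.isfinite(E))
    energies = E[flat[:, 0], flat[:, 1]]
    mn = float(energies.min())
    cand = [(int(i), int(j)) for i, j in flat[energies <= mn + 1e-9]]
    most_pairs = max(NP[i, j] for i, j in cand)
    end = min((i, j) for i, j in cand if NP[i, j] == most_pairs)
    pairs: list[tuple[int, int]] = []
    ci, cj = end
    while ci != -1:
        pairs.append((ci, cj))
        ci, cj = int(PI[ci, cj]), int(PJ[ci, cj])
    pairs.reverse()
    result = DuplexResult(float(E[end]), pairs)
    result.max_run = max_contiguous_run(result)
    if is_window is not None:
        lo, hi = is_window
        paired_positions = {i + 1 for i, _ in pairs}
        result.covers_is = all(p in paired_positions for p in range(lo, hi + 1))
    return result


def max_contiguous_run(result: DuplexResult) -> int:
    """Longest stretch of pairs consecutive on both strands (0 if unpaired)."""
    if not result.pairing:
        return 0
    run = best = 1
    for (i0, j0), (i1, j1) in zip(result.pairing, result.pairing[1:]):
        if i1 == i0 + 1 and j1 == j0 - 1:
            run += 1
            best = max(best, run)
        else:
            run = 1
    return best


@dataclass
class ScreenResult:
    """Per-group duplex energies plus long-run hybrid flags (Fig 1F-style)."""

    energies_down: dict[str, float]
    energies_unaffected: dict[str, float]
    flagged: list[dict]
    skipped: list[str]


def screen_targets(
    mirna_seq: str,
    utrs,
    matches,
    down_set: set[str],
    unaffected_set: set[str],
    window_flank: int = 15,
    params: NNParameterSet | None = None,
    is_window: tuple[int, int] | None = (6, 12),
    min_run_flag: int = 10,
    per_site: bool = False,
) -> ScreenResult:
    """Duplex-energy screen of seed-match windows in two gene strata.

    For every gene in ``down_set`` or ``unaffected_set`` that has at least
    one seed match, folds the miRNA against each match window (seed match
    +- ``window_flank`` nt, clipped at UTR bounds) and records the per-gene
    minimum energy (or every site with ``per_site=True``).  Hybrids whose
    MFE structure contains a contiguous run of at least ``min_run_flag``
    pairs covering the IS window are flagged.  Genes in a stratum without
    any match are listed in ``skipped``.
    """
    if params is None:
        params = default_params()
    seq_of = {u.gene_id: u.sequence for u in utrs}
    sites: dict[str, list] = {}
    for mt in matches:
        sites.setdefault(mt.gene_id, []).append(mt)

    groups = {"down": down_set, "unaffected": unaffected_set}
    energies: dict[str, dict[str, float]] = {"down": {}, "unaffected": {}}
    flagged: list[dict] = []
    skipped: list[str] = []
    for label, genes in groups.items():
        for gene in sorted(genes):
            if gene not in sites:
                skipped.append(gene)
                continue
            best = math.inf
            for mt in sites[gene]:
                seq = seq_of[gene]
                lo = max(0, mt.start - window_flank)
                hi = min(len(seq), mt.start + len(mt.word) + window_flank)
                res = duplex_mfe(mirna_seq, seq[lo:hi], params, is_window=is_window)
                key = gene if not per_site else f"{gene}:{mt.start}"
                if per_site:
                    energies[label][key] = res.energy
                else:
                    best = min(best, res.energy)
                if res.max_run >= min_run_flag and res.covers_is:
                    flagged.append(
                        {
                            "gene_id": gene,
                            "window_start": lo,
                            "window_end": hi,
                            "energy": res.energy,
                            "max_run": res.max_run,
                            "group": label,
                        }
                    )
            if not per_site and math.isfinite(best):
                energies[label][gene] = best
    return ScreenResult(
        energies_down=energies["down"],
        energies_unaffected=energies["unaffected"],
        flagged=flagged,
        skipped=skipped,
    )
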