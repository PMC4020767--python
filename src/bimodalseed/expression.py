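"""Differential expression statistics, qPCR normalisation and correlation.

The array arm of the pipeline takes a log2-scale probe x sample matrix with
replicate treatment and control groups, computes per-gene Welch t statistics
and BH-adjusted p values, ranks genes from most down- to most up-regulated,
and exposes the strata the downstream analyses consume (top-N down-regulated
set, t-threshold down/unaffected split).

The qPCR arm implements calibrated normalised relative quantities (CNRQ):
relative quantities from quantification cycles at a fixed amplification
efficiency, normalised per sample to the geometric mean of reference-gene
quantities, then rescaled so each gene's geometric mean over samples is 1.
Spearman correlation on complete cases accompanies it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["gene_id", "log2fc", "t_stat", "p", "p_adj"]


def per_gene_stats(
    matrix: pd.DataFrame, group_labels: pd.Series | dict | list
) -> pd.DataFrame:
    """Welch two-sample t statistics per gene.

    Parameters
    ----------
    matrix:
        genes x samples, log2 scale; the index holds gene ids.
    group_labels:
        per-sample labels, ``"treatment"`` / ``"control"`` (aligned with the
        matrix columns).

    Returns a DataFrame with columns gene_id, log2fc (treatment - control
    mean difference), t_stat, p (two-sided, Welch-Satterthwaite df) and
    p_adj (Benjamini-Hochberg).  Genes with zero variance in both groups and
    equal means get t = 0, p = 1.
    """
    labels = pd.Series(group_labels, index=matrix.columns)
    t_cols = labels[labels == "treatment"].index
    c_cols = labels[labels == "control"].index
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    treat = matrix[t_cols].to_numpy(dtype=float)
    ctrl = matrix[c_cols].to_numpy(dtype=float)
    log2fc = treat.mean(axis=1) - ctrl.mean(axis=1)
    with warnings.catch_warnings():
        # constant rows are handled explicitly below (t=0, p=1)
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(treat, ctrl, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p": p,
        }
    )
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_by_downregulation(records: pd.DataFrame) -> list[str]:
    """Gene ids ordered most down-regulated first (ascending t, ties by id)."""
    df = records.sort_values(["t_stat", "gene_id"], kind="mergesort")
    return df["gene_id"].tolist()


def top_down(records: pd.DataFrame, n: int = 250, alpha: float = 0.01) -> list[str]:
    """First ``n`` of the ranked list restricted to p_adj < alpha."""
    df = records.sort_values(["t_stat", "gene_id"], kind="mergesort")
    df = df[df["p_adj"] < alpha]
    return df["gene_id"].head(n).tolist()


def stratify_by_t(
    records: pd.DataFrame,
    down_cut: float = -4.0,
    unaffected: str = "complement",
) -> tuple[set[str], set[str]]:
    """Split genes into a down-regulated set (t < down_cut) and an
    "unaffected" comparison set.

    ``unaffected="complement"`` (default) takes everything with
    t >= down_cut; ``unaffected="t_ge_4"`` takes t >= +|down_cut| instead
    (the mirror-image stratum), kept as a switch because both readings are
    defensible for a density comparison.
    """
    t = records["t_stat"]
    down = set(records.loc[t < down_cut, "gene_id"])
    if unaffected == "complement":
        rest = set(records.loc[t >= down_cut, "gene_id"])
    elif unaffected == "t_ge_4":
        rest = set(records.loc[t >= abs(down_cut), "gene_id"])
    else:
        raise ValueError("unaffected must be 'complement' or 't_ge_4'")
    return down, rest


def cnrq(
    cq: pd.DataFrame,
    reference_genes: list[str],
    efficiency: float | dict[str, float] = 2.0,
) -> pd.DataFrame:
    """Calibrated normalised relative quantities from a Cq table.

    ``cq`` is samples x genes (quantification cycles; NaN = not measured).
    Per gene, RQ = efficiency ** (mean Cq - Cq); per sample, the
    normalisation factor is the geometric mean of the reference genes' RQs;
    CNRQ rescales each gene's normalised RQ so its geometric mean over
    samples equals 1.  Missing target Cq values propagate to missing CNRQ
    (complete-cases behaviour); a sample with no reference measurement is an
    error.
    """
    missing = [g for g in reference_genes if g not in cq.columns]
    if missing:
        raise ValueError(f"reference genes absent from Cq table: {missing}")
    if isinstance(efficiency, dict):
        eff = pd.Series(
            {g: efficiency.get(g, 2.0) for g in cq.columns}, dtype=float
        )
    else:
        eff = pd.Series(float(efficiency), index=cq.columns)
    if (eff <= 1.0).any():
        raise ValueError("amplification efficiency must exceed 1")
    rq = np.exp((cq.mean(axis=0) - cq) * np.log(eff))
    ref_rq = rq[reference_genes]
    if ref_rq.isna().all(axis=1).any():
        bad = ref_rq.index[ref_rq.isna().all(axis=1)].tolist()
        raise ValueError(f"samples without any reference Cq: {bad}")
    nf = np.exp(np.log(ref_rq).mean(axis=1))  # geometric mean, skipping NaN
    nrq = rq.div(nf, axis=0)
    calib = np.exp(np.log(nrq).mean(axis=0))
    return nrq.div(calib, axis=1)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on complete cases.

    Ranks use average-tie correction.  The two-sided p value comes from the
    t approximation for n > 10 and from exact permutation of the pairings
    for n <= 10.  Fewer than 3 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rho = float(stats.spearmanr(x, y).statistic)
    if n > 10:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        def statistic(xx):
            return stats.spearmanr(xx, y).statistic

        res = stats.permutation_test(
            (x,),
            statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        p = float(res.pvalue)
    return rho, p
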