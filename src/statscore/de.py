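"""Negative-binomial two-group differential expression versus the control.

A deliberately lightweight test in the DESeq2 tradition, without its
shrinkage machinery: median-of-ratios size factors, per-gene
method-of-moments dispersion pooled across the two groups, a Wald statistic
for the log2 fold change of group means based on the delta-method variance
of the NB mean estimator,

    Var(ln mu_hat) ~ (1 / n) * (1 / mu_hat + phi),

and Benjamini-Hochberg step-up adjustment. Genes with adjusted p below
``alpha`` (default 0.05) in either direction are called differentially
regulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io import CountMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-4


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq convention).

    Per sample, the median across all-positive genes of count divided by the
    gene's geometric mean across samples. If no gene is positive in every
    sample, falls back to total-count scaling normalized to geometric mean 1.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise DegenerateInputError("size_factors: all-zero count matrix")
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(mat[all_pos])
        log_geo = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geo, axis=0))
    else:
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise DegenerateInputError("size_factors: sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _normalized(counts: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    return counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]


def estimate_dispersion(
    counts: pd.DataFrame | CountMatrix,
    factors: pd.Series,
    group_a: list[str],
    group_b: list[str],
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion pooled over two groups.

    phi_hat = max(0, (pooled within-group variance - pooled mean) / pooled mean^2),
    floored at ``floor``. Both groups need >= 2 samples.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("estimate_dispersion: each group needs >= 2 samples")
    y_a = _normalized(counts[group_a], factors[group_a])
    y_b = _normalized(counts[group_b], factors[group_b])
    n_a, n_b = y_a.shape[1], y_b.shape[1]
    ss = y_a.var(axis=1, ddof=1) * (n_a - 1) + y_b.var(axis=1, ddof=1) * (n_b - 1)
    var_within = ss / (n_a + n_b - 2)
    mean_pooled = (y_a.sum(axis=1) + y_b.sum(axis=1)) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var_within - mean_pooled) / mean_pooled**2
    phi = np.where(mean_pooled > 0, phi, 0.0)
    phi = np.maximum(phi, floor)
    return pd.Series(phi, index=counts.index, name="dispersion")


def _wald_arrays(
    y_treated: np.ndarray,
    y_control: np.ndarray,
    dispersion: np.ndarray,
    pseudocount: float,
):
    """Vectorized Wald test on normalized counts; rows are genes."""
    n_t, n_c = y_treated.shape[1], y_control.shape[1]
    mu_t = y_treated.mean(axis=1)
    mu_c = y_control.mean(axis=1)
    c = pseudocount
    log2fc = np.log2((mu_t + c) / (mu_c + c))
    # delta-method variance of ln(mu_hat) per group, pseudocount stabilised
    var_ln = (1.0 / n_t) * (1.0 / (mu_t + c) + dispersion) + (1.0 / n_c) * (
        1.0 / (mu_c + c) + dispersion
    )
    se = np.sqrt(var_ln) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sp_stats.norm.sf(np.abs(wald))
    both_zero = (mu_t == 0) & (mu_c == 0)
    log2fc = np.where(both_zero, 0.0, log2fc)
    wald = np.where(both_zero, 0.0, wald)
    p = np.where(both_zero, 1.0, np.minimum(p, 1.0))
    return mu_c, mu_t, log2fc, se, wald, p


def nb_wald_test(
    gene_counts: pd.Series | np.ndarray,
    factors: pd.Series,
    group_treated: list[str],
    group_control: list[str],
    dispersion: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float, float, float]:
    """Wald test for a single gene; returns (log2fc, se, wald, p)."""
    if dispersion < 0:
        raise ParameterError("dispersion must be non-negative")
    gene_counts = pd.Series(gene_counts, index=factors.index)
    y_t = (gene_counts[group_treated] / factors[group_treated]).to_numpy()[None, :]
    y_c = (gene_counts[group_control] / factors[group_control]).to_numpy()[None, :]
    _, _, log2fc, se, wald, p = _wald_arrays(
        y_t, y_c, np.array([dispersion]), pseudocount
    )
    return float(log2fc[0]), float(se[0]), float(wald[0]), float(p[0])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: CountMatrix,
    treated: str,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    dispersion_floor: float = DISPERSION_FLOOR,
    min_total_count: int = 0,
) -> pd.DataFrame:
    """Full DE chain for one treated condition versus the control.

    Returns a DataFrame indexed by gene with columns ``mean_control``,
    ``mean_treated``, ``log2fc``, ``se``, ``wald``, ``p``, ``padj``,
    ``significant`` and ``sign``. ``min_total_count`` optionally drops genes
    whose summed raw counts over the two groups fall below it (off by
    default).
    """
    control = matrix.control_condition
    if treated == control:
        raise ValidationError("treated condition must differ from the control")
    g_t = matrix.samples_of(treated)
    g_c = matrix.samples_of(control)
    sub = matrix.counts[g_t + g_c]
    if min_total_count > 0:
        sub = sub[sub.sum(axis=1) >= min_total_count]
    factors = size_factors(sub)
    phi = estimate_dispersion(sub, factors, g_t, g_c, floor=dispersion_floor)
    y_t = _normalized(sub[g_t], factors[g_t])
    y_c = _normalized(sub[g_c], factors[g_c])
    mu_c, mu_t, log2fc, se, wald, p = _wald_arrays(
        y_t, y_c, phi.to_numpy(), pseudocount
    )
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_control": mu_c,
            "mean_treated": mu_t,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "padj": padj,
        },
        index=sub.index,
    )
    out["significant"] = out["padj"] < alpha
    out["sign"] = np.where(out["log2fc"] > 0, 1, -1)
    return out


def de_genes(
    matrix: CountMatrix,
    treated: str,
    alpha: float = DEFAULT_ALPHA,
    **kwargs,
) -> dict[str, int]:
    """Differentially regulated genes (padj < alpha) with their direction.

    Returns {gene: +1 induced / -1 repressed}; both directions retained.
    """
    table = de_table(matrix, treated, alpha=alpha, **kwargs)
    sig = table[table["significant"]]
    return dict(zip(sig.index, sig["sign"].astype(int)))
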