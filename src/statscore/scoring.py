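"""TPM normalization, per-sample STAT scores, fold changes and PCA.

A sample's STAT score is the mean Pearson correlation, over the STAT's
exclusive gene set in TPM space, between the sample and each reference
sample of that STAT's cytokine panel (e.g. the IL-10- and IL-21-treated
replicates for STAT3). Reference samples scored on their own panel are
correlated only against the *other* panel members (self-exclusion).
Condition-level summaries are unweighted means over replicates; fold
changes are taken against the control condition's mean score, guarded by a
small epsilon because a ratio of correlations is unstable near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCorrelationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from .signatures import DEFAULT_MIN_SIZE, SignatureSet

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.05

#: reason codes for missing scores
REASON_TOO_FEW_GENES = "too_few_genes"
REASON_NO_REFERENCE = "no_valid_reference"
REASON_NO_SIGNATURE = "no_signature"
REASON_OK = ""


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million.

    rate_gs = count_gs / (length_g / 1000); TPM_gs = rate_gs / sum_g rate_gs * 1e6.
    Every column of the result sums to 1e6. Lengths must be positive for
    every gene in ``counts``; all-zero samples are rejected.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ParameterError(f"genes without length annotation: {list(missing[:5])}")
    kb = lengths.reindex(counts.index).to_numpy(dtype=float) / 1000.0
    if (kb <= 0).any() or np.isnan(kb).any():
        raise ParameterError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / kb[:, None]
    totals = rate.sum(axis=0)
    zero = counts.columns[totals == 0].tolist()
    if zero:
        raise DegenerateInputError(f"all-zero samples cannot be TPM-normalized: {zero}")
    return pd.DataFrame(
        rate / totals[None, :] * 1e6, index=counts.index, columns=counts.columns
    )


def log_transform(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional log2(TPM + 1) transform used when ``tpm_transform`` is on."""
    return np.log2(tpm_matrix + 1.0)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson: vectors must be 1-D and equal length")
    if x.size < 3:
        raise ParameterError("pearson: need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise DegenerateCorrelationError("pearson: zero-variance vector")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@dataclass
class ScoreResult:
    """Outcome of scoring one sample against one STAT's reference panel."""

    score: float | None
    n_genes_used: int
    n_reference_samples: int
    reason: str = REASON_OK


def stat_score(
    query: pd.Series,
    signature: SignatureSet,
    reference_tpm: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
) -> ScoreResult:
    """STAT score of one sample: mean Pearson correlation to reference samples.

    All vectors are restricted to the signature's exclusive gene set. If the
    query sample is itself a reference-panel column it is excluded from its
    own panel. Degenerate (zero-variance) pairs are dropped with a log
    entry. Missing when the exclusive set is below ``min_size`` or no valid
    reference pair remains.
    """
    genes = sorted(signature.exclusive & set(query.index))
    refs = [c for c in reference_tpm.columns if c != query.name]
    if len(genes) < min_size:
        return ScoreResult(None, len(genes), len(refs), REASON_TOO_FEW_GENES)
    q = query[genes].to_numpy(dtype=float)
    coeffs = []
    for ref in refs:
        try:
            coeffs.append(pearson(q, reference_tpm.loc[genes, ref].to_numpy()))
        except DegenerateCorrelationError:
            logger.info(
                "dropped degenerate correlation: sample %s vs reference %s (%s)",
                query.name,
                ref,
                signature.stat,
            )
    if not coeffs:
        return ScoreResult(None, len(genes), 0, REASON_NO_REFERENCE)
    return ScoreResult(float(np.mean(coeffs)), len(genes), len(coeffs))


@dataclass
class ScoreTable:
    """Per-sample and per-condition STAT scores.

    ``per_sample`` is a long table (sample, condition, stat, score,
    n_genes_used, n_reference_samples, reason); ``condition_means`` is a
    wide condition x STAT table of mean scores (NaN where missing).
    """

    per_sample: pd.DataFrame
    condition_means: pd.DataFrame
    control_condition: str


def score_all(
    tpm_matrix: pd.DataFrame,
    sigs: dict[str, SignatureSet],
    samples: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    stats: tuple[str, ...] | None = None,
) -> ScoreTable:
    """Score every sample against every STAT signature.

    ``stats`` defaults to the signatures present; a STAT listed there but
    absent from ``sigs`` yields missing scores with reason ``no_signature``.
    """
    if stats is None:
        stats = tuple(sorted(sigs))
    rows = []
    ref_cols: dict[str, list[str]] = {}
    for stat, sig in sigs.items():
        cols = samples.index[samples["condition"].isin(sig.reference_conditions)]
        ref_cols[stat] = list(cols)
    for sample in tpm_matrix.columns:
        condition = samples.loc[sample, "condition"]
        for stat in stats:
            if stat not in sigs:
                rows.append((sample, condition, stat, None, 0, 0, REASON_NO_SIGNATURE))
                continue
            panel = tpm_matrix[ref_cols[stat]]
            res = stat_score(tpm_matrix[sample], sigs[stat], panel, min_size=min_size)
            rows.append(
                (
                    sample,
                    condition,
                    stat,
                    res.score,
                    res.n_genes_used,
                    res.n_reference_samples,
                    res.reason,
                )
            )
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "condition",
            "stat",
            "score",
            "n_genes_used",
            "n_reference_samples",
            "reason",
        ],
    )
    per_sample["score"] = per_sample["score"].astype(float)
    condition_means = (
        per_sample.pivot_table(
            index="condition", columns="stat", values="score", aggfunc="mean"
        )
        .reindex(index=list(dict.fromkeys(samples["condition"])))
        .reindex(columns=list(stats))
    )
    condition_means.columns.name = None
    control = samples.loc[samples["role"] == "control", "condition"].iloc[0]
    return ScoreTable(per_sample, condition_means, control)


def score_fold_change(
    table: ScoreTable,
    control: str | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Condition x STAT fold changes of mean scores versus the control.

    FC = condition mean / control mean where the control mean exceeds
    ``epsilon``; otherwise FC is missing and only the companion difference
    (condition - control), always emitted, carries the signal. Long format:
    condition, stat, mean_score, fold_change, difference, reason.
    """
    control = control or table.control_condition
    if control not in table.condition_means.index:
        raise ValidationError(f"control condition {control!r} not in score table")
    rows = []
    for condition in table.condition_means.index:
        for stat in table.condition_means.columns:
            mean = table.condition_means.loc[condition, stat]
            base = table.condition_means.loc[control, stat]
            diff = mean - base
            if np.isnan(mean) or np.isnan(base):
                fc, reason = np.nan, "missing_score"
            elif base <= epsilon:
                fc, reason = np.nan, "control_mean_below_epsilon"
            else:
                fc, reason = mean / base, ""
            rows.append((condition, stat, mean, fc, diff, reason))
    return pd.DataFrame(
        rows,
        columns=["condition", "stat", "mean_score", "fold_change", "difference", "reason"],
    )


def pca_scores(
    score_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """PCA of a (samples x STATs) score matrix via SVD of the centered data.

    Rows with any missing value are dropped (and logged). Returns sample
    coordinates (columns ``PC1``..) and the variance-explained fractions,
    which sum to 1. Component signs follow the convention that each loading
    vector's largest-magnitude entry is positive.
    """
    complete = score_matrix.dropna(axis=0, how="any")
    dropped = score_matrix.index.difference(complete.index)
    if len(dropped):
        logger.info("pca_scores: dropped %d incomplete row(s): %s",
                    len(dropped), list(dropped[:5]))
    if complete.shape[0] < 2:
        raise DegenerateInputError("pca_scores: fewer than 2 complete samples")
    x = complete.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise DegenerateInputError("pca_scores: zero total variance")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|entry| of each loading vector is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    coords = u * s[None, :] * flip[None, :]
    var = s**2
    frac = var / var.sum()
    k = coords.shape[1]
    coords_df = pd.DataFrame(
        coords, index=complete.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frac_s = pd.Series(frac, index=coords_df.columns, name="variance_fraction")
    return coords_df, frac_s
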