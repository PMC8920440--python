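"""Expression preprocessing, aging-DEG selection and gene-set signature scores.

Preprocessing: log2(x + pseudocount), quantile normalization to the mean
empirical distribution, then gene-wise removal of the total-read-count
covariate from a linear model that also contains the group factor (so group
effects are retained — only the library-size component is subtracted).

Aging-DEGs: genes with linear-scale fold change > 1.5 and raw p < 0.01 between
old and young (moderated t by default; Welch t behind a flag).

Signature scores: gene-wise z across samples averaged over set members; the
global signature (mean z over all genes) is removed from set scores by the
same covariate-removal mechanism, adjusting for the association expected of a
randomly chosen gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import squeeze_variances, t_to_z

__all__ = [
    "preprocess_expression",
    "quantile_normalize",
    "remove_covariate",
    "select_degs",
    "signature_scores",
    "SignatureScores",
]


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the mean empirical distribution.

    Ties share the average of the reference values at their tied ranks, so a
    column with distinct values gets exactly the reference sorted vector.
    """
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _design_with_groups(groups: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, int]:
    """Design [intercept | group dummies | centered covariate]; returns (X, cov column)."""
    levels = list(dict.fromkeys(groups))
    cols = [np.ones(groups.size)]
    for g in levels[1:]:
        cols.append((groups == g).astype(float))
    cov = covariate - covariate.mean()
    cols.append(cov)
    x = np.column_stack(cols)
    return x, x.shape[1] - 1


def remove_covariate(
    df: pd.DataFrame, covariate: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Subtract the covariate component of a gene-wise linear model.

    Fits value ~ group + covariate per gene and removes only
    beta_cov * (covariate - mean), preserving group effects and residuals.
    Constant rows pass through unchanged.
    """
    groups = pd.Series(groups).reindex(df.columns).to_numpy()
    cov = pd.Series(covariate).reindex(df.columns).to_numpy(dtype=float)
    x, cov_col = _design_with_groups(groups, cov)
    y = df.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    corrected = y - np.outer(beta[cov_col], x[:, cov_col])
    return pd.DataFrame(corrected, index=df.index, columns=df.columns)


def preprocess_expression(
    raw: pd.DataFrame,
    total_reads: pd.Series,
    groups: pd.Series,
    pseudocount: float = 1.0,
    log: bool = True,
) -> pd.DataFrame:
    """log2 -> quantile normalization -> total-reads covariate removal."""
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw expression values must be >= 0")
    tr = pd.Series(total_reads).reindex(raw.columns)
    if (tr <= 0).any():
        raise ValueError("total_reads must be positive")
    x = np.log2(raw + pseudocount) if log else raw.astype(float)
    x = quantile_normalize(x)
    return remove_covariate(x, tr, groups)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def _moderated_two_group(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t (b minus a) with empirical-Bayes variance shrinkage."""
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    shrink = squeeze_variances(s2, df)
    se = np.sqrt(shrink.var_post * (1.0 / n_a + 1.0 / n_b))
    t = (b.mean(axis=1) - a.mean(axis=1)) / se
    if np.isinf(shrink.df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), shrink.df_total)
    return t, p, shrink.df_total


def select_degs(
    expr: pd.DataFrame,
    young_ids: list[str],
    old_ids: list[str],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    method: str = "moderated",
) -> pd.DataFrame:
    """Aging differentially expressed genes (old vs young).

    Fold change is 2^(mean_old - mean_young) on preprocessed log2 values; a
    gene is a DEG iff its linear-scale |FC| exceeds ``fc_threshold`` (i.e.
    |log2FC| > log2 threshold, two-sided) AND its raw p is below
    ``p_threshold``.  Zero-variance genes with equal means get p = 1.
    """
    if len(young_ids) < 2 or len(old_ids) < 2:
        raise ValueError("need >=2 samples per group")
    a = expr[list(young_ids)].to_numpy(dtype=float)
    b = expr[list(old_ids)].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    if method == "moderated":
        _, p, _ = _moderated_two_group(a, b)
    elif method == "welch":
        p = _welch(a, b)
    else:
        raise ValueError("method must be 'moderated' or 'welch'")
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    significant = (np.abs(log2fc) > np.log2(fc_threshold)) & (p < p_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0 ** log2fc,
            "p_raw": p,
            "direction": np.where(log2fc > 0, "up_in_old", "down_in_old"),
            "significant": significant,
        },
        index=expr.index,
    )


@dataclass
class SignatureScores:
    """Per-set, per-sample signature scores before and after global adjustment."""

    raw: pd.DataFrame  # sets x samples, unadjusted mean-z scores
    adjusted: pd.DataFrame  # sets x samples after global-signature removal
    global_signature: pd.Series  # per-sample mean z over all genes
    skipped_sets: list[str]


def signature_scores(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    groups: pd.Series,
    min_set_size: int = 5,
) -> SignatureScores:
    """Gene-set signature scores with global-signature correction.

    Expression is z-scored gene-wise across samples; the set score per sample
    is the mean z over member genes, and the global signature is the mean z
    over all genes.  Adjusted scores remove the global-signature component of
    a linear model set_score ~ group + global (group effects retained).
    Sets with fewer than ``min_set_size`` members after intersection with the
    matrix are skipped.
    """
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    z_df = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    global_sig = z_df.mean(axis=0)

    rows, kept, skipped = [], [], []
    index = pd.Index(expr.index)
    for name, members in gene_sets.items():
        present = index.intersection(pd.Index(members))
        if len(present) < min_set_size:
            skipped.append(name)
            continue
        kept.append(name)
        rows.append(z_df.loc[present].mean(axis=0))
    raw = pd.DataFrame(rows, index=kept, columns=expr.columns)
    if len(raw):
        adjusted = remove_covariate(raw, global_sig, groups)
    else:
        adjusted = raw.copy()
    return SignatureScores(
        raw=raw, adjusted=adjusted, global_signature=global_sig, skipped_sets=skipped
    )
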