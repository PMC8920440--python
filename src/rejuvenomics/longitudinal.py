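"""Paired and longitudinal analyses: delta changes, group comparisons,
methylation-age regression and per-metabolite mixed models.

Delta is the within-subject post-minus-pre change.  Between-group delta
comparisons use the Mann-Whitney test (exact for small samples); within-group
mean-delta tests use a paired t gated on a Shapiro-Wilk normality check with a
signed-rank fallback.  The methylation clock is an ordinary least-squares fit
of percent methylation on age.  Metabolite trajectories are modeled with a
linear mixed model (random intercept per specimen, Wald test on the timepoint
effect) with a fixed-effects fallback when the random effect is inestimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_change",
    "mann_whitney_deltas",
    "paired_delta_test",
    "compare_groups",
    "clock_fit",
    "metabolite_mixed_model",
    "TestResult",
    "ClockFit",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    flags: list[str] = field(default_factory=list)


def delta_change(
    table: pd.DataFrame, pre: str = "pre", post: str = "post"
) -> tuple[pd.DataFrame, list]:
    """Per-subject delta = post - pre from a long-format table.

    ``table`` needs columns subject, timepoint, value (group carried through if
    present).  Subjects missing either timepoint are listed and excluded; a
    duplicated (subject, timepoint) raises.  Errors if no complete pair exists.
    """
    required = {"subject", "timepoint", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    sub = table[table["timepoint"].isin([pre, post])]
    dup = sub.duplicated(subset=["subject", "timepoint"])
    if dup.any():
        raise ValueError("duplicated (subject, timepoint) rows")
    wide = sub.pivot(index="subject", columns="timepoint", values="value")
    if pre not in wide.columns or post not in wide.columns:
        raise ValueError("no complete pre/post pairs")
    complete = wide.dropna(subset=[pre, post])
    if complete.empty:
        raise ValueError("no complete pre/post pairs")
    incomplete = [s for s in wide.index if s not in complete.index]
    out = pd.DataFrame({"delta": complete[post] - complete[pre]})
    if "group" in table.columns:
        grp = table.drop_duplicates("subject").set_index("subject")["group"]
        out["group"] = grp.reindex(out.index)
    return out, incomplete


def mann_whitney_deltas(a, b) -> TestResult:
    """Two-sided Mann-Whitney comparison of deltas between two groups.

    Exact p for small samples without ties; mid-rank/normal handling otherwise.
    All-tied data returns p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 values per group")
    if np.unique(np.concatenate([a, b])).size == 1:
        return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0, method="mann_whitney", flags=["all_tied"])
    if max(a.size, b.size) <= 8:
        u, p = _mann_whitney_exact(a, b)
        return TestResult(statistic=u, p_value=p, method="mann_whitney_exact", flags=[])
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="mann_whitney", flags=[])


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration with mid-ranks.

    Enumerates every assignment of the pooled values to the two groups; the
    two-sided p doubles the smaller exact tail (capped at 1), which handles
    ties (shared mid-ranks) exactly.
    """
    from itertools import combinations as _combos

    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)

    def u_of(idx: tuple) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    total = ge = le = 0
    for idx in _combos(range(n1 + n2), n1):
        total += 1
        u = u_of(idx)
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    p = min(1.0, 2.0 * min(ge, le) / total)
    return float(u_obs), p


def paired_delta_test(deltas, alpha_normality: float = 0.05) -> TestResult:
    """Test mean delta = 0 within a group: paired t gated on Shapiro-Wilk.

    If the Shapiro-Wilk test rejects normality of the deltas at
    ``alpha_normality``, falls back to the Wilcoxon signed-rank test (flagged).
    All-zero deltas return p = 1 with a degenerate flag.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size < 3:
        raise ValueError("need >=3 pairs")
    flags = []
    if np.all(d == d[0]):
        if d[0] == 0:
            return TestResult(statistic=0.0, p_value=1.0, method="paired_t", flags=["degenerate_all_equal"])
        # nonzero constant deltas: t undefined (zero variance); report degenerate
        return TestResult(statistic=np.inf, p_value=0.0, method="paired_t", flags=["degenerate_all_equal"])
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p < alpha_normality:
        res = stats.wilcoxon(d)
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method="wilcoxon_signed_rank",
            flags=[f"shapiro_rejected(p={sw_p:.3g})"],
        )
    res = stats.ttest_1samp(d, 0.0)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="paired_t", flags=flags)


def compare_groups(
    deltas: pd.DataFrame | dict, method: str = "mann_whitney"
) -> TestResult:
    """Dispatch on the delta-comparison method.

    ``mann_whitney`` expects two groups of deltas (frame with group/delta
    columns or a {group: values} dict); ``auto_paired_t`` expects one group of
    deltas and tests mean delta = 0 with the normality-gated paired t.
    """
    if method == "mann_whitney":
        if isinstance(deltas, dict):
            groups = list(deltas)
            if len(groups) != 2:
                raise ValueError("mann_whitney needs exactly 2 groups")
            return mann_whitney_deltas(deltas[groups[0]], deltas[groups[1]])
        groups = list(dict.fromkeys(deltas["group"]))
        if len(groups) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        a = deltas.loc[deltas["group"] == groups[0], "delta"]
        b = deltas.loc[deltas["group"] == groups[1], "delta"]
        return mann_whitney_deltas(a, b)
    if method == "auto_paired_t":
        vals = deltas["delta"] if isinstance(deltas, pd.DataFrame) else np.asarray(deltas)
        return paired_delta_test(vals)
    raise ValueError("method must be 'mann_whitney' or 'auto_paired_t'")


@dataclass
class ClockFit:
    slope: float  # percentage points per week
    intercept: float
    r: float
    p_value: float
    stderr: float
    flags: list[str] = field(default_factory=list)


def clock_fit(values, ages) -> ClockFit:
    """OLS fit of percent methylation on chronological age (weeks).

    ``values`` may be (n,) averaged methylation or (n, k) for a k-CpG panel,
    in which case the panel is averaged per animal before fitting.  Constant
    ages raise; a perfectly flat response is flagged (correlation undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 2:
        v = v.mean(axis=1)
    a = np.asarray(ages, dtype=float)
    if v.size != a.size or v.size < 3:
        raise ValueError("need >=3 (value, age) points")
    if np.unique(a).size < 2:
        raise ValueError("constant ages: slope undefined")
    flags = []
    if np.unique(v).size == 1:
        flags.append("flat_response")
        return ClockFit(slope=0.0, intercept=float(v[0]), r=0.0, p_value=1.0, stderr=0.0, flags=flags)
    res = stats.linregress(a, v)
    return ClockFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        flags=flags,
    )


@dataclass
class MixedModelResult:
    metabolite: str
    effect: float  # timepoint effect (post - pre) on the analysis scale
    wald_statistic: float
    p_value: float
    method: str  # "mixed" or "fixed_fallback"
    flags: list[str] = field(default_factory=list)


def metabolite_mixed_model(
    table: pd.DataFrame,
    value_col: str = "value",
    log_scale: bool = True,
    batch_col: str | None = None,
    batch_mode: str = "fixed",
) -> list[MixedModelResult]:
    """Per-metabolite linear mixed model with a specimen random intercept.

    ``table`` needs columns metabolite, specimen, timepoint (pre/post), value,
    and optionally a batch column.  Values are log-transformed by default
    (metabolite intensities).  The Wald statistic and p refer to the timepoint
    effect.  Specimens measured at a single timepoint only, or singular
    random-effect fits, fall back to fixed-effects OLS with a flag.

    Batches (e.g. independent experiments measured separately) are handled
    either as a fixed effect in one joint model (``batch_mode="fixed"``) or by
    fitting each batch separately and combining the Wald z-scores with
    Stouffer's method (``batch_mode="stouffer"``).
    """

    def fit_one(df: pd.DataFrame, fixed: str) -> tuple[float, float, float, str, list[str]]:
        import statsmodels.formula.api as smf

        flags: list[str] = []
        per_spec = df.groupby("specimen")["timepoint"].nunique()
        fit = None
        if (per_spec >= 2).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model = smf.mixedlm(fixed, df, groups=df["specimen"])
                    fit = model.fit(reml=True, method="lbfgs")
                    re_var = float(np.asarray(fit.cov_re)[0, 0])
                    if not np.isfinite(re_var) or re_var <= 1e-10:
                        flags.append("singular_random_effect")
                        fit = None  # refit as fixed effects below
                except Exception:
                    fit = None
                    flags.append("mixed_fit_failed")
        else:
            flags.append("single_timepoint_per_specimen")
        if fit is not None:
            effect = float(fit.params["_t"])
            wald = float(fit.params["_t"] / fit.bse["_t"])
            return effect, wald, float(2 * stats.norm.sf(abs(wald))), "mixed", flags
        ols = smf.ols(fixed, df).fit()
        return (
            float(ols.params["_t"]),
            float(ols.tvalues["_t"]),
            float(ols.pvalues["_t"]),
            "fixed_fallback",
            flags + ["fixed_effects"],
        )

    results = []
    for metab, sub in table.groupby("metabolite"):
        df = sub.copy()
        if log_scale:
            if (df[value_col] <= 0).any():
                raise ValueError(f"non-positive values for {metab}; disable log_scale")
            df["_y"] = np.log(df[value_col])
        else:
            df["_y"] = df[value_col].astype(float)
        df["_t"] = (df["timepoint"] == "post").astype(float)
        if batch_col and batch_mode == "stouffer":
            effects, zs, flags = [], [], []
            for _, bdf in df.groupby(batch_col):
                e, w, _, method, f = fit_one(bdf, "_y ~ _t")
                effects.append(e)
                zs.append(w)
                flags.extend(f)
            z_comb = float(np.sum(zs) / np.sqrt(len(zs)))
            results.append(
                MixedModelResult(
                    metab,
                    float(np.mean(effects)),
                    z_comb,
                    float(2 * stats.norm.sf(abs(z_comb))),
                    "stouffer_per_batch",
                    flags,
                )
            )
            continue
        fixed = "_y ~ _t" + (f" + C({batch_col})" if batch_col else "")
        effect, wald, p, method, flags = fit_one(df, fixed)
        results.append(MixedModelResult(metab, effect, wald, p, method, flags))
    return results
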