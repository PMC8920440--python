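"""Three-group expression-pattern classification under a Normal-Normal model.

Each feature (gene or gene-set signature score) follows one of the set
partitions ("patterns") of the experimental groups: samples are Normal around
their cluster mean with feature-specific variance sigma_g^2, and cluster means
are themselves Normal(mu0, tau^2).  The cluster marginal likelihood is
available in closed form, hyperparameters (mu0, tau^2) and pattern priors pi
are fitted by EM, and features following a target pattern (e.g. the
rejuvenation pattern: young and treated-old share a mean, untreated old
differs) are selected by the Bayesian expected-FDR rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PatternSpec",
    "NNModel",
    "enumerate_patterns",
    "rejuvenation_pattern_id",
    "fit_nn_model",
    "select_by_bayes_fdr",
    "randomization_control",
]

DEFAULT_GROUPS = ("young", "old", "old_OSKM")


@dataclass(frozen=True)
class PatternSpec:
    """A partition of the group labels into equal-mean clusters."""

    pattern_id: str
    clusters: tuple[tuple[str, ...], ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _set_partitions(items: list[str]):
    """All set partitions of ``items`` (order-stable, first item anchors)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def enumerate_patterns(group_labels: tuple[str, ...] = DEFAULT_GROUPS) -> list[PatternSpec]:
    """All equal-mean patterns of the groups (Bell number of them; 5 for 3 groups)."""
    labels = list(dict.fromkeys(group_labels))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    order = {g: i for i, g in enumerate(labels)}
    specs = []
    for partition in _set_partitions(labels):
        clusters = tuple(
            tuple(sorted(c, key=order.get)) for c in partition
        )
        clusters = tuple(sorted(clusters, key=lambda c: order[c[0]]))
        pid = "|".join("+".join(c) for c in clusters)
        specs.append(PatternSpec(pattern_id=pid, clusters=clusters))
    # canonical order: fewer clusters first, then lexicographic by id
    specs.sort(key=lambda s: (s.n_clusters, s.pattern_id))
    return specs


def rejuvenation_pattern_id(
    group_labels: tuple[str, str, str] = DEFAULT_GROUPS,
) -> str:
    """The pattern id where young and treated-old share a mean and old stands apart."""
    young, old, oskm = group_labels
    for spec in enumerate_patterns(group_labels):
        sets = [frozenset(c) for c in spec.clusters]
        if frozenset({young, oskm}) in sets and frozenset({old}) in sets:
            return spec.pattern_id
    raise ValueError("no rejuvenation pattern for these labels")


@dataclass
class NNModel:
    """Fitted Normal-Normal hierarchical model."""

    mu0: float
    tau_sq: float
    pi: pd.Series  # prior probability per pattern id
    sigma_sq: pd.Series  # plug-in observation variance per feature
    patterns: list[PatternSpec]
    log_likelihood: float
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def _cluster_stats(
    x: np.ndarray, groups: np.ndarray, patterns: list[PatternSpec]
) -> tuple[list[list[tuple[int, np.ndarray, np.ndarray]]], dict]:
    """Per-pattern, per-cluster sufficient statistics (n, mean, within-SS)."""
    cache: dict[tuple[str, ...], tuple[int, np.ndarray, np.ndarray]] = {}
    out = []
    for spec in patterns:
        rows = []
        for cluster in spec.clusters:
            if cluster not in cache:
                mask = np.isin(groups, cluster)
                sub = x[:, mask]
                n = int(mask.sum())
                mean = sub.mean(axis=1)
                ss = ((sub - mean[:, None]) ** 2).sum(axis=1)
                cache[cluster] = (n, mean, ss)
            rows.append(cache[cluster])
        out.append(rows)
    return out, cache


def _log_marginals(
    stats_by_pattern, sigma_sq: np.ndarray, mu0: float, tau_sq: float
) -> np.ndarray:
    """(n_features, n_patterns) log marginal likelihoods, closed form.

    Per cluster C with n observations, mean xbar and within-SS:
    log m = -n/2 log(2 pi) - (n-1)/2 log sigma^2 - 1/2 log(sigma^2 + n tau^2)
            - SS/(2 sigma^2) - n (xbar - mu0)^2 / (2 (sigma^2 + n tau^2)).
    """
    n_feat = sigma_sq.size
    out = np.zeros((n_feat, len(stats_by_pattern)))
    for k, clusters in enumerate(stats_by_pattern):
        total = np.zeros(n_feat)
        for n, mean, ss in clusters:
            v = sigma_sq + n * tau_sq
            total += (
                -0.5 * n * np.log(2 * np.pi)
                - 0.5 * (n - 1) * np.log(sigma_sq)
                - 0.5 * np.log(v)
                - ss / (2 * sigma_sq)
                - n * (mean - mu0) ** 2 / (2 * v)
            )
        out[:, k] = total
    return out


def _pooled_within_group_variance(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    ss = np.zeros(x.shape[0])
    df = 0
    for g in np.unique(groups):
        sub = x[:, groups == g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += sub.shape[1] - 1
    if df < 1:
        raise ValueError("need at least 2 samples in some group")
    return ss / df


def fit_nn_model(
    feature_matrix: pd.DataFrame,
    groups: pd.Series | dict,
    patterns: list[PatternSpec] | None = None,
    shrink_weight: float = 0.3,
    max_iter: int = 500,
    tol: float = 1e-8,
    tau_sq_fixed: float | None = None,
) -> tuple[NNModel, pd.DataFrame]:
    """Fit the Normal-Normal pattern mixture by EM and return posteriors.

    ``feature_matrix``: features x samples.  ``groups`` maps sample id to group
    label.  Observation variances are plugged in as the pooled within-group
    variance per feature shrunk toward the cross-feature median with weight
    ``shrink_weight``.  ``tau_sq_fixed`` pins tau^2 (e.g. 0 for the limit where
    posteriors reduce to the priors).
    """
    groups = pd.Series(groups)
    x = feature_matrix.to_numpy(dtype=float)
    grp = groups.reindex(feature_matrix.columns).to_numpy()
    labels = [g for g in dict.fromkeys(grp)]
    if set(labels) <= set(DEFAULT_GROUPS):
        # stable pattern ids regardless of sample/column order
        labels = [g for g in DEFAULT_GROUPS if g in set(labels)]
    for g in labels:
        if (grp == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if patterns is None:
        patterns = enumerate_patterns(tuple(labels))

    s2 = _pooled_within_group_variance(x, grp)
    if (s2 <= 0).all():
        raise ValueError("degenerate variances: zero within-group variance everywhere")
    med = float(np.median(s2[s2 > 0]))
    sigma_sq = np.maximum((1 - shrink_weight) * s2 + shrink_weight * med, 1e-12)

    stats_by_pattern, _ = _cluster_stats(x, grp, patterns)

    # deterministic initial values; tau^2 starts from the structured upper tail
    # of between-group variances (the mean is dominated by null features and a
    # too-small start collapses EM onto the all-distinct pattern)
    mu0 = float(x.mean())
    group_means = np.stack([x[:, grp == g].mean(axis=1) for g in labels], axis=1)
    n_per = np.array([(grp == g).sum() for g in labels], dtype=float)
    noise_floor = float((sigma_sq[:, None] / n_per[None, :]).mean())
    between = group_means.var(axis=1, ddof=1)
    tau_sq = max(float(np.percentile(between, 90) - noise_floor), 4.0 * noise_floor, 1e-6)
    if tau_sq_fixed is not None:
        tau_sq = max(float(tau_sq_fixed), 0.0)
    pi = np.full(len(patterns), 1.0 / len(patterns))

    def observed_ll(mu0_, tau_sq_, pi_):
        lm = _log_marginals(stats_by_pattern, sigma_sq, mu0_, tau_sq_)
        a = lm + np.log(np.maximum(pi_, 1e-300))
        amax = a.max(axis=1, keepdims=True)
        return float((amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))).sum()), a, amax

    trace = []
    converged = False
    ll_prev = -np.inf
    w = None
    for it in range(1, max_iter + 1):
        ll, a, amax = observed_ll(mu0, tau_sq, pi)
        trace.append(ll)
        # E-step
        w = np.exp(a - amax)
        w /= w.sum(axis=1, keepdims=True)
        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
        # M-step: pi in closed form, (mu0, tau^2) numerically
        pi = np.maximum(w.mean(axis=0), 1e-12)
        pi /= pi.sum()
        if tau_sq_fixed is None:

            def neg_q(theta):
                m, log_t = theta
                lm = _log_marginals(stats_by_pattern, sigma_sq, m, np.exp(log_t))
                return -float((w * lm).sum())

            res = optimize.minimize(
                neg_q,
                x0=np.array([mu0, np.log(max(tau_sq, 1e-12))]),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 200},
            )
            if -res.fun >= -neg_q(np.array([mu0, np.log(max(tau_sq, 1e-12))])):
                mu0, tau_sq = float(res.x[0]), float(np.exp(res.x[1]))
        else:

            def neg_q_mu(m):
                lm = _log_marginals(stats_by_pattern, sigma_sq, float(m), tau_sq)
                return -float((w * lm).sum())

            res = optimize.minimize_scalar(neg_q_mu)
            if res.success:
                mu0 = float(res.x)

    pattern_ids = [p.pattern_id for p in patterns]
    posteriors = pd.DataFrame(w, index=feature_matrix.index, columns=pattern_ids)
    model = NNModel(
        mu0=mu0,
        tau_sq=tau_sq,
        pi=pd.Series(pi, index=pattern_ids),
        sigma_sq=pd.Series(sigma_sq, index=feature_matrix.index),
        patterns=patterns,
        log_likelihood=trace[-1],
        n_iter=len(trace),
        converged=converged,
        objective_trace=trace,
    )
    return model, posteriors


def select_by_bayes_fdr(
    posteriors: pd.DataFrame | pd.Series,
    target_pattern: str | None = None,
    fdr: float = 0.05,
) -> list:
    """Largest prefix (by decreasing posterior) with mean(1 - posterior) <= fdr.

    This controls the Bayesian expected false-discovery rate of the selection
    at ``fdr`` when the posteriors are calibrated.  May select nothing.
    """
    if isinstance(posteriors, pd.DataFrame):
        if target_pattern is None:
            raise ValueError("target_pattern required with a posterior matrix")
        probs = posteriors[target_pattern]
    else:
        probs = posteriors
    order = probs.sort_values(ascending=False, kind="mergesort")
    err = (1.0 - order.to_numpy()).cumsum() / np.arange(1, len(order) + 1)
    ok = np.flatnonzero(err <= fdr)
    if ok.size == 0:
        return []
    return list(order.index[: ok[-1] + 1])


def randomization_control(
    feature_matrix: pd.DataFrame,
    groups: pd.Series | dict,
    target_pattern: str,
    fdr: float = 0.05,
    n_permutations: int = 50,
    seed: int = 0,
    include_identity: bool = False,
    **fit_kwargs,
) -> dict:
    """Re-run fit + selection after random sample-to-group reassignment.

    Group sizes are preserved.  Returns the unpermuted selected-feature count
    alongside the count per permutation; under planted rejuvenation structure
    the unpermuted count should dominate the permuted distribution.
    """
    groups = pd.Series(groups).reindex(feature_matrix.columns)
    rng = np.random.default_rng(seed)

    def run(g: pd.Series) -> int:
        _, post = fit_nn_model(feature_matrix, g, **fit_kwargs)
        return len(select_by_bayes_fdr(post, target_pattern, fdr))

    observed = run(groups)
    counts = []
    labels = groups.to_numpy()
    for b in range(n_permutations):
        if include_identity and b == 0:
            perm = labels.copy()
        else:
            perm = rng.permutation(labels)
        counts.append(run(pd.Series(perm, index=groups.index)))
    return {
        "unpermuted_count": observed,
        "permuted_counts": counts,
        "median_permuted": float(np.median(counts)) if counts else np.nan,
        "seed": seed,
    }
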