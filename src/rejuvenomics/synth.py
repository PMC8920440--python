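"""Synthetic three-group methylome, transcriptome and longitudinal data.

The generators emulate the study design the pipeline targets: young, old and
old-treated (transiently reprogrammed, "old_OSKM") groups of mice, with planted
hyper-/hypomethylation aging effects at regulatory regions, partial reversal of
those effects in the treated group, gene-set-coordinated expression shifts with
a shared latent factor and a library-size covariate, and paired pre/post
longitudinal designs.  Every generator returns a truth table recording the
planted structure so downstream calls can be scored against ground truth.

All randomness descends from one seed; per-feature sub-streams are spawned
deterministically so adding features never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .methylome import CpGMethylationTable
from .patterns import enumerate_patterns, rejuvenation_pattern_id, DEFAULT_GROUPS

__all__ = [
    "SynthMethylConfig",
    "SynthExprConfig",
    "SynthLongitudinalConfig",
    "SynthPatternConfig",
    "generate_methylome",
    "generate_expression",
    "generate_longitudinal",
    "generate_pattern_features",
]


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


@dataclass
class SynthMethylConfig:
    """Planted-structure methylome generator settings.

    Effects are in methylation proportion units internally; ``aging_effect_range``
    is stated in percentage points (lower bound >= 10 so planted effects are
    detectable by the 10-point difference rule).  Defaults mirror the study
    design: 5 animals per group, ~30x CpG coverage, slight excess of
    hypermethylation among aging regions, ~40% of aging regions rejuvenated
    with strong (>=0.8) reversal.
    """

    n_regions: int = 500
    cpgs_per_region_mean: float = 8.0
    samples_per_group: int = 5
    baseline_beta_params: tuple[float, float] = (2.0, 2.0)
    frac_aging: float = 0.3
    frac_hyper: float = 0.55
    aging_effect_range: tuple[float, float] = (20.0, 35.0)
    frac_rejuvenated: float = 0.4
    rejuvenation_strength_range: tuple[float, float] = (0.8, 1.0)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    meth_error_floor: float = 0.02
    cpg_jitter_sd: float = 0.03
    frac_promoter: float = 0.55
    include_d7: bool = False
    d7_established_prob: dict = field(
        default_factory=lambda: {"hyper": 0.25, "hypo": 0.7}
    )
    d7_transient_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_aging", "frac_hyper", "frac_rejuvenated", "frac_promoter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.aging_effect_range[0] < 10.0:
            raise ValueError("aging_effect_range lower bound must be >= 10 pp")
        if self.aging_effect_range[0] > self.aging_effect_range[1]:
            raise ValueError("aging_effect_range must be ordered")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0.0 <= self.meth_error_floor < 0.5:
            raise ValueError("meth_error_floor must be in [0, 0.5)")
        lo, hi = self.rejuvenation_strength_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("rejuvenation_strength_range must lie in (0, 1]")


def _nb_counts(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion (var = m + m^2/k)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_methylome(config: SynthMethylConfig):
    """Generate (CpGMethylationTable, regions, sample sheet, truth).

    Per region: young mean p0 ~ Beta(a, b); aging regions shift the old mean by
    +-delta (sign per ``frac_hyper``); rejuvenated regions pull the treated-old
    mean back toward young by strength r (old_OSKM = old - r*(old - young)).
    Baselines of aging regions are drawn inside the interval that leaves room
    for the full effect within [floor, 1 - floor]; a configuration whose effect
    cannot fit anywhere raises a "degenerate effect" error.  Per-CpG jitter is
    drawn once per CpG and shared across groups, so region aggregation is
    meaningful; read counts are negative-binomial coverage with binomial
    methylated counts.  Deterministic given the seed.
    """
    cfg = config
    floor = cfg.meth_error_floor
    eff_hi = cfg.aging_effect_range[1] / 100.0
    if cfg.frac_aging > 0 and eff_hi >= 1.0 - 2.0 * floor:
        raise ValueError(
            "degenerate effect: aging_effect_range leaves no clipping headroom "
            f"within [{floor}, {1 - floor}]"
        )
    groups = list(DEFAULT_GROUPS) + (["old_OSKM_d7"] if cfg.include_d7 else [])
    samples = [f"{g}_{i + 1}" for g in groups for i in range(cfg.samples_per_group)]
    group_of = {s: g for s in samples for g in [s.rsplit("_", 1)[0]]}

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_regions)

    chroms, positions = [], []
    meth_rows, unmeth_rows = [], []
    region_rows, truth_rows = [], []
    degenerate_ids = []
    region_span = 2500
    spacing = 10_000
    for r in range(cfg.n_regions):
        rng = np.random.default_rng(children[r])
        region_id = f"region_{r:05d}"
        start = r * spacing
        end = start + region_span
        kind = "promoter" if rng.random() < cfg.frac_promoter else "enhancer"

        aging = rng.random() < cfg.frac_aging
        direction = "none"
        delta = 0.0
        rejuvenated = False
        strength = 0.0
        if aging:
            direction = "hyper" if rng.random() < cfg.frac_hyper else "hypo"
            delta = rng.uniform(*cfg.aging_effect_range) / 100.0
            rejuvenated = rng.random() < cfg.frac_rejuvenated
            if rejuvenated:
                strength = rng.uniform(*cfg.rejuvenation_strength_range)
        # baseline: aging regions need headroom for the full planted effect
        p0 = np.nan
        for _ in range(1000):
            cand = rng.beta(*cfg.baseline_beta_params)
            cand = min(max(cand, floor), 1.0 - floor)
            if direction == "hyper" and cand + delta > 1.0 - floor:
                continue
            if direction == "hypo" and cand - delta < floor:
                continue
            p0 = cand
            break
        if not np.isfinite(p0):
            degenerate_ids.append(region_id)
            continue

        mu_young = p0
        mu_old = p0 + delta if direction == "hyper" else p0 - delta if direction == "hypo" else p0
        mu_oskm = mu_old - strength * (mu_old - mu_young) if rejuvenated else mu_old

        temporal_class = None
        mu_d7 = mu_old
        if cfg.include_d7 and aging:
            if rejuvenated:
                if rng.random() < cfg.d7_established_prob[direction]:
                    mu_d7 = mu_oskm
                    temporal_class = "established_d7_retained"
                else:
                    temporal_class = "acquired_in_recovery"
            else:
                if rng.random() < cfg.d7_transient_prob:
                    mu_d7 = mu_old - 0.9 * (mu_old - mu_young)
                    temporal_class = "established_d7_lost"
                else:
                    temporal_class = "never"

        group_means = {"young": mu_young, "old": mu_old, "old_OSKM": mu_oskm}
        if cfg.include_d7:
            group_means["old_OSKM_d7"] = mu_d7

        n_cpgs = max(1, int(rng.poisson(cfg.cpgs_per_region_mean)))
        offsets = np.sort(rng.choice(region_span, size=n_cpgs, replace=False))
        jitter = rng.normal(0.0, cfg.cpg_jitter_sd, size=n_cpgs)
        meth_block = np.zeros((n_cpgs, len(samples)), dtype=int)
        unmeth_block = np.zeros_like(meth_block)
        for j, s in enumerate(samples):
            level = np.clip(group_means[group_of[s]] + jitter, floor, 1.0 - floor)
            cov = _nb_counts(rng, cfg.coverage_mean, cfg.coverage_dispersion, n_cpgs)
            m = rng.binomial(cov, level)
            meth_block[:, j] = m
            unmeth_block[:, j] = cov - m

        chroms.extend(["chr1"] * n_cpgs)
        positions.extend((start + offsets).tolist())
        meth_rows.append(meth_block)
        unmeth_rows.append(unmeth_block)
        region_rows.append(
            {
                "region_id": region_id,
                "chrom": "chr1",
                "start": start,
                "end": end,
                "kind": kind,
                "strand": "+",
                "linked_gene": f"gene_{r:05d}",
            }
        )
        truth_rows.append(
            {
                "region_id": region_id,
                "aging_label": direction,
                "rejuvenated": rejuvenated,
                "planted_effect_pp": 100.0 * (mu_old - mu_young),
                "rejuvenation_strength": strength,
                "mu_young": mu_young,
                "mu_old": mu_old,
                "mu_oskm": mu_oskm,
                "mu_d7": mu_d7 if cfg.include_d7 else np.nan,
                "temporal_class": temporal_class,
                "seed": cfg.seed,
            }
        )

    if degenerate_ids:
        raise ValueError(
            "degenerate effect: no clipping headroom for regions "
            + ", ".join(degenerate_ids[:10])
            + ("..." if len(degenerate_ids) > 10 else "")
        )

    table = CpGMethylationTable(
        chrom=np.array(chroms),
        pos=np.array(positions, dtype=int),
        samples=samples,
        meth=np.vstack(meth_rows),
        unmeth=np.vstack(unmeth_rows),
    )
    regions = pd.DataFrame(region_rows)
    sheet = pd.DataFrame(
        {"group": [group_of[s] for s in samples]}, index=pd.Index(samples, name="sample")
    )
    truth = pd.DataFrame(truth_rows).set_index("region_id")
    truth.attrs["generator_params"] = asdict(cfg)
    return table, regions, sheet, truth


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


@dataclass
class SynthExprConfig:
    """Planted gene-set expression generator settings.

    Gene sets are assigned one of the five three-group patterns.  Member genes
    share a group-mean shift (log2 units) plus a rho-weighted common latent
    factor per sample, which makes the competitive null non-trivial.  A
    library-size multiplier acts on the raw (linear) scale so preprocessing
    has a covariate to remove.
    """

    n_genes: int = 2000
    n_sets: int = 40
    set_size: int = 15
    pattern_fracs: dict | None = None  # pattern id -> fraction of sets
    effect_log2: float = 1.0
    rho: float = 0.3
    noise_sd: float = 0.5
    samples_per_group: int = 5
    baseline_log2_range: tuple[float, float] = (3.0, 8.0)
    library_multipliers: tuple[float, ...] | None = None
    library_log2_sd: float = 0.25
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size < 2:
            raise ValueError("set_size must be >= 2")
        if not self.allow_overlap and self.n_sets * self.set_size > self.n_genes:
            raise ValueError("disjoint sets exceed the gene catalogue; set allow_overlap")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")


def _default_pattern_fracs() -> dict:
    ids = [p.pattern_id for p in enumerate_patterns()]
    rejuv = rejuvenation_pattern_id()
    null = [p.pattern_id for p in enumerate_patterns() if p.n_clusters == 1][0]
    fracs = {pid: 0.0 for pid in ids}
    fracs[null] = 0.5
    fracs[rejuv] = 0.2
    rest = [pid for pid in ids if pid not in (null, rejuv)]
    for pid in rest:
        fracs[pid] = 0.3 / len(rest)
    return fracs


def generate_expression(config: SynthExprConfig):
    """Generate (raw expression matrix, gene sets, sample sheet, truth).

    The returned matrix is on the raw RPKM-like scale (2^log2-value times the
    sample's library multiplier); preprocessing is expected to log it,
    quantile-normalize and remove the library covariate.  The truth table
    records each set's planted pattern id and signed effect.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    groups = list(DEFAULT_GROUPS)
    samples = [f"{g}_{i + 1}" for g in groups for i in range(cfg.samples_per_group)]
    group_arr = np.array([s.rsplit("_", 1)[0] for s in samples])
    n_samples = len(samples)

    fracs = cfg.pattern_fracs or _default_pattern_fracs()
    specs = {p.pattern_id: p for p in enumerate_patterns()}
    unknown = set(fracs) - set(specs)
    if unknown:
        raise ValueError(f"unknown pattern ids: {sorted(unknown)}")
    set_ids = [f"set_{i:03d}" for i in range(cfg.n_sets)]
    pids = list(fracs)
    probs = np.array([fracs[p] for p in pids], dtype=float)
    probs /= probs.sum()
    assigned = rng.choice(pids, size=cfg.n_sets, p=probs)

    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    if cfg.allow_overlap:
        membership = {
            sid: sorted(rng.choice(cfg.n_genes, size=cfg.set_size, replace=False))
            for sid in set_ids
        }
    else:
        pool = rng.permutation(cfg.n_genes)
        membership = {
            sid: sorted(pool[i * cfg.set_size : (i + 1) * cfg.set_size])
            for i, sid in enumerate(set_ids)
        }

    baseline = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_genes)
    log2 = np.tile(baseline[:, None], (1, n_samples))
    # independent gene noise everywhere; latent factor added inside sets below
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))

    truth_rows = []
    sqrt_rho = np.sqrt(cfg.rho)
    sqrt_1m = np.sqrt(1.0 - cfg.rho)
    for sid, pid in zip(set_ids, assigned):
        idx = np.array(membership[sid])
        spec = specs[pid]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        shift_by_group: dict[str, float] = {}
        for cluster in spec.clusters:
            if "young" in cluster:
                dev = 0.0
            elif "old" in cluster:
                dev = sign * cfg.effect_log2
            else:
                dev = -sign * cfg.effect_log2
            for g in cluster:
                shift_by_group[g] = dev
        shifts = np.array([shift_by_group[g] for g in group_arr])
        factor = rng.normal(0.0, cfg.noise_sd, size=n_samples)
        log2[idx] += shifts[None, :]
        noise[idx] = sqrt_rho * factor[None, :] + sqrt_1m * noise[idx]
        truth_rows.append(
            {
                "set_id": sid,
                "pattern_id": pid,
                "effect_log2": (0.0 if spec.n_clusters == 1 else sign * cfg.effect_log2),
                "n_genes": cfg.set_size,
                "seed": cfg.seed,
            }
        )
    log2 += noise

    if cfg.library_multipliers is not None:
        if len(cfg.library_multipliers) != n_samples:
            raise ValueError("library_multipliers must match the number of samples")
        lib = np.asarray(cfg.library_multipliers, dtype=float)
    else:
        lib = 2.0 ** rng.normal(0.0, cfg.library_log2_sd, size=n_samples)
    raw = (2.0 ** log2) * lib[None, :]

    expr = pd.DataFrame(raw, index=genes, columns=samples)
    gene_sets = {sid: [genes[i] for i in membership[sid]] for sid in set_ids}
    sheet = pd.DataFrame(
        {"group": group_arr, "total_reads": raw.sum(axis=0)},
        index=pd.Index(samples, name="sample"),
    )
    truth = pd.DataFrame(truth_rows).set_index("set_id")
    truth.attrs["generator_params"] = asdict(cfg)
    return expr, gene_sets, sheet, truth


# ---------------------------------------------------------------------------
# longitudinal
# ---------------------------------------------------------------------------


@dataclass
class SynthLongitudinalConfig:
    """Paired pre/post measurement generator settings.

    ``group_deltas`` maps group name to the true post-minus-pre change (e.g.
    {"control": +4, "treated": -4} mirrors the blood-methylation scenario where
    untreated animals drift up ~4 points while treated animals drop ~4, a total
    between-group difference of 8).
    """

    group_deltas: dict = field(default_factory=lambda: {"control": 4.0, "treated": -4.0})
    n_subjects: int | dict = 4
    baseline: float = 50.0
    between_sd: float = 5.0
    within_sd: float = 1.0
    seed: int = 0

    def n_for(self, group: str) -> int:
        n = self.n_subjects[group] if isinstance(self.n_subjects, dict) else self.n_subjects
        if n < 2:
            raise ValueError("need at least 2 subjects per group")
        return int(n)


def generate_longitudinal(config: SynthLongitudinalConfig):
    """Generate (long-format table, truth): two rows (pre, post) per subject."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rows = []
    for group, delta in cfg.group_deltas.items():
        for i in range(cfg.n_for(group)):
            subject = f"{group}_{i + 1}"
            intercept = cfg.baseline + rng.normal(0.0, cfg.between_sd)
            pre = intercept + rng.normal(0.0, cfg.within_sd)
            post = intercept + delta + rng.normal(0.0, cfg.within_sd)
            rows.append({"subject": subject, "group": group, "timepoint": "pre", "value": pre})
            rows.append({"subject": subject, "group": group, "timepoint": "post", "value": post})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"group": list(cfg.group_deltas), "true_delta": list(cfg.group_deltas.values())}
    ).set_index("group")
    truth.attrs["generator_params"] = asdict(cfg)
    return table, truth


# ---------------------------------------------------------------------------
# pattern-model features
# ---------------------------------------------------------------------------


@dataclass
class SynthPatternConfig:
    """Feature matrix generator for the Normal-Normal pattern model.

    ``mode="model"`` draws cluster means iid Normal(mu0, tau^2) — data exactly
    from the model, for FDR calibration.  ``mode="spaced"`` draws cluster
    means from the same prior but conditions distinct clusters on a minimum
    pairwise separation of ``effect_sd_units`` times sigma, for recovery
    checks with a guaranteed effect size.
    """

    n_features: int = 1000
    samples_per_group: int = 5
    pattern_probs: dict | None = None  # pattern id -> probability
    mode: str = "spaced"
    mu0: float = 0.0
    tau: float = 3.0
    sigma: float = 1.0
    effect_sd_units: float = 3.0
    seed: int = 0


def generate_pattern_features(config: SynthPatternConfig):
    """Generate (feature matrix, groups, truth with planted pattern ids)."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    specs = enumerate_patterns()
    by_id = {p.pattern_id: p for p in specs}
    if cfg.pattern_probs is None:
        rejuv = rejuvenation_pattern_id()
        null = [p.pattern_id for p in specs if p.n_clusters == 1][0]
        probs = {p.pattern_id: 0.0 for p in specs}
        probs[null] = 0.5
        probs[rejuv] = 0.2
        rest = [p.pattern_id for p in specs if p.pattern_id not in (null, rejuv)]
        for pid in rest:
            probs[pid] = 0.3 / len(rest)
    else:
        probs = cfg.pattern_probs
    pids = list(probs)
    pvec = np.array([probs[p] for p in pids], dtype=float)
    pvec /= pvec.sum()

    groups_order = list(DEFAULT_GROUPS)
    samples = [f"{g}_{i + 1}" for g in groups_order for i in range(cfg.samples_per_group)]
    group_arr = np.array([s.rsplit("_", 1)[0] for s in samples])

    x = np.zeros((cfg.n_features, len(samples)))
    assigned = rng.choice(pids, size=cfg.n_features, p=pvec)
    for i, pid in enumerate(assigned):
        spec = by_id[pid]
        k = spec.n_clusters
        if cfg.mode == "model":
            means = rng.normal(cfg.mu0, cfg.tau, size=k)
        elif cfg.mode == "spaced":
            sep = cfg.effect_sd_units * cfg.sigma
            means = rng.normal(cfg.mu0, cfg.tau, size=k)
            for _ in range(500):
                gaps = np.abs(means[:, None] - means[None, :])[np.triu_indices(k, 1)]
                if k == 1 or (gaps >= sep).all():
                    break
                means = rng.normal(cfg.mu0, cfg.tau, size=k)
        else:
            raise ValueError("mode must be 'model' or 'spaced'")
        mean_by_group = {}
        for mu, cluster in zip(means, spec.clusters):
            for g in cluster:
                mean_by_group[g] = mu
        mu_vec = np.array([mean_by_group[g] for g in group_arr])
        x[i] = mu_vec + rng.normal(0.0, cfg.sigma, size=len(samples))

    matrix = pd.DataFrame(
        x, index=[f"feature_{i:05d}" for i in range(cfg.n_features)], columns=samples
    )
    groups = pd.Series(group_arr, index=matrix.columns, name="group")
    truth = pd.DataFrame(
        {"pattern_id": assigned}, index=pd.Index(matrix.index, name="feature_id")
    )
    truth.attrs["generator_params"] = asdict(cfg)
    return matrix, groups, truth
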