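"""Region-level RRBS methylation analysis.

Per-CpG methylated/unmethylated read counts are aggregated over regulatory
regions (promoters: -2000/+500 bp around the TSS; enhancers: H3K27ac peaks not
overlapping promoters, linked to the nearest gene within 1 Mb) and tested for
aging differential methylation with a per-region binomial regression on
group-aggregated counts.  A region is called aging-DM when the raw
likelihood-ratio p-value is below ``p_threshold`` (default 0.05) AND the
difference of group mean methylation is at least ``min_delta`` percentage
points (default 10).

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "CpGMethylationTable",
    "RegionMethylation",
    "define_promoters",
    "call_enhancers",
    "aggregate_regions",
    "dm_test",
]


@dataclass
class CpGMethylationTable:
    """Per-CpG methylated/unmethylated read counts across samples.

    ``meth`` and ``unmeth`` are (n_sites, n_samples) integer arrays aligned with
    ``chrom``/``pos`` (site coordinates) and ``samples`` (ordered sample ids).
    """

    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        self.meth = np.asarray(self.meth, dtype=int)
        self.unmeth = np.asarray(self.unmeth, dtype=int)
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth and unmeth must have identical shape")
        if self.meth.shape != (self.pos.size, len(self.samples)):
            raise ValueError("count arrays must be (n_sites, n_samples)")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def percent(self) -> np.ndarray:
        """Percent methylation per site and sample; NaN where coverage is 0."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, 100.0 * self.meth / cov, np.nan)

    def to_coverage_frames(self) -> dict[str, pd.DataFrame]:
        """One coverage-format DataFrame per sample (for io.write_coverage_file)."""
        out = {}
        pct = self.percent
        for j, s in enumerate(self.samples):
            out[s] = pd.DataFrame(
                {
                    "chrom": self.chrom,
                    "start": self.pos,
                    "end": self.pos + 1,
                    "percent": pct[:, j],
                    "count_methylated": self.meth[:, j],
                    "count_unmethylated": self.unmeth[:, j],
                }
            )
        return out

    @classmethod
    def from_coverage_frames(cls, frames: dict[str, pd.DataFrame]) -> "CpGMethylationTable":
        """Assemble a table from per-sample coverage frames on the union of sites."""
        samples = list(frames)
        keyed = {}
        for s in samples:
            df = frames[s]
            keyed[s] = df.set_index(
                [df["chrom"].astype(str), df["start"].astype(int)]
            )[["count_methylated", "count_unmethylated"]]
        union = sorted(set().union(*[set(k.index) for k in keyed.values()]))
        chrom = np.array([c for c, _ in union])
        pos = np.array([p for _, p in union], dtype=int)
        meth = np.zeros((len(union), len(samples)), dtype=int)
        unmeth = np.zeros_like(meth)
        for j, s in enumerate(samples):
            sub = keyed[s].reindex(union)
            meth[:, j] = sub["count_methylated"].fillna(0).to_numpy(dtype=int)
            unmeth[:, j] = sub["count_unmethylated"].fillna(0).to_numpy(dtype=int)
        return cls(chrom=chrom, pos=pos, samples=samples, meth=meth, unmeth=unmeth)


@dataclass
class RegionMethylation:
    """Region x sample mean methylation plus the aggregated counts behind it.

    ``percent`` holds the unweighted mean of retained-CpG percent methylation;
    ``meth``/``total`` hold the per-sample read counts summed over the retained
    CpGs of each region (the input to the differential-methylation test).
    """

    percent: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame
    n_cpgs: pd.Series
    dropped_regions: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.percent.columns)


def define_promoters(
    tss: pd.DataFrame, upstream: int = 2000, downstream: int = 500
) -> pd.DataFrame:
    """Promoter windows around transcription start sites.

    ``tss`` needs columns chrom, pos, strand, gene.  Plus-strand TSS t maps to
    [t-upstream, t+downstream); minus-strand windows are strand-reflected.
    Windows reaching past the contig start are truncated at 0 and flagged.
    """
    required = {"chrom", "pos", "strand", "gene"}
    if not required.issubset(tss.columns):
        raise ValueError(f"tss table must have columns {sorted(required)}")
    pos = tss["pos"].to_numpy(dtype=int)
    plus = tss["strand"].astype(str).to_numpy() == "+"
    start = np.where(plus, pos - upstream, pos - downstream + 1)
    end = np.where(plus, pos + downstream, pos + upstream + 1)
    truncated = start < 0
    if truncated.any():
        warnings.warn(
            f"{int(truncated.sum())} promoter window(s) truncated at contig start",
            stacklevel=2,
        )
    start = np.maximum(start, 0)
    out = pd.DataFrame(
        {
            "region_id": [f"promoter:{g}" for g in tss["gene"]],
            "chrom": tss["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "kind": "promoter",
            "strand": tss["strand"].to_numpy(),
            "linked_gene": tss["gene"].to_numpy(),
            "truncated": truncated,
        }
    )
    return out


def call_enhancers(
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    genes: pd.DataFrame,
    max_link_dist: int = 1_000_000,
) -> pd.DataFrame:
    """Classify H3K27ac peaks not overlapping any promoter as enhancers.

    ``peaks``: chrom, start, end.  ``genes``: chrom, pos (TSS), gene.  Each
    enhancer is linked to the nearest gene TSS (gap distance; 0 if the TSS lies
    inside the peak) when within ``max_link_dist``; otherwise kept unlinked.
    Equidistant ties are broken toward the smaller TSS coordinate and flagged.
    """
    rows = []
    prom_by_chrom = {c: df for c, df in promoters.groupby("chrom")}
    genes_by_chrom = {c: df for c, df in genes.groupby("chrom")}
    for i, peak in peaks.reset_index(drop=True).iterrows():
        c, s, e = peak["chrom"], int(peak["start"]), int(peak["end"])
        prom = prom_by_chrom.get(c)
        if prom is not None:
            overlap = (prom["start"].to_numpy() < e) & (prom["end"].to_numpy() > s)
            if overlap.any():
                continue
        linked, tie = None, False
        g = genes_by_chrom.get(c)
        if g is not None and len(g):
            tss = g["pos"].to_numpy(dtype=int)
            gap = np.maximum.reduce([s - tss, tss - (e - 1), np.zeros_like(tss)])
            dmin = gap.min()
            if dmin <= max_link_dist:
                cand = np.flatnonzero(gap == dmin)
                if cand.size > 1:
                    tie = True
                    cand = cand[np.argsort(tss[cand])]
                linked = g.iloc[cand[0]]["gene"]
        rows.append(
            {
                "region_id": f"enhancer:{c}:{s}-{e}",
                "chrom": c,
                "start": s,
                "end": e,
                "kind": "enhancer",
                "strand": ".",
                "linked_gene": linked,
                "link_tie": tie,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "chrom",
            "start",
            "end",
            "kind",
            "strand",
            "linked_gene",
            "link_tie",
        ],
    )


def aggregate_regions(
    cpgs: CpGMethylationTable, regions: pd.DataFrame, min_reads: int = 5
) -> RegionMethylation:
    """Region-level mean methylation from CpGs covered in every sample.

    A CpG enters the analysis only if its coverage is >= ``min_reads`` in EVERY
    sample.  The region value per sample is the unweighted mean of the retained
    CpG percentages; regions with no retained CpG are dropped and reported.
    """
    if not cpgs.samples:
        raise ValueError("sample set is empty")
    keep = (cpgs.coverage >= min_reads).all(axis=1)
    pct = cpgs.percent
    percent_rows, meth_rows, total_rows, ncpg, kept_ids, dropped = [], [], [], [], [], []
    for _, reg in regions.iterrows():
        in_region = (
            (cpgs.chrom == reg["chrom"])
            & (cpgs.pos >= int(reg["start"]))
            & (cpgs.pos < int(reg["end"]))
            & keep
        )
        n = int(in_region.sum())
        if n == 0:
            dropped.append(reg["region_id"])
            continue
        kept_ids.append(reg["region_id"])
        ncpg.append(n)
        percent_rows.append(pct[in_region].mean(axis=0))
        meth_rows.append(cpgs.meth[in_region].sum(axis=0))
        total_rows.append(cpgs.coverage[in_region].sum(axis=0))
    cols = cpgs.samples
    if not kept_ids:
        empty = pd.DataFrame(np.empty((0, len(cols))), columns=cols)
        return RegionMethylation(
            percent=empty,
            meth=empty.astype(int),
            total=empty.astype(int),
            n_cpgs=pd.Series(dtype=int),
            dropped_regions=dropped,
        )
    return RegionMethylation(
        percent=pd.DataFrame(percent_rows, index=kept_ids, columns=cols),
        meth=pd.DataFrame(meth_rows, index=kept_ids, columns=cols),
        total=pd.DataFrame(total_rows, index=kept_ids, columns=cols),
        n_cpgs=pd.Series(ncpg, index=kept_ids),
        dropped_regions=dropped,
    )


def _binomial_lrt(meth: np.ndarray, total: np.ndarray, is_b: np.ndarray) -> float:
    """Likelihood-ratio chi-square for a binomial GLM with a group indicator.

    The logit model with an intercept and a group indicator has closed-form
    MLEs (pooled within-group proportions), so the deviance difference against
    the intercept-only model is computed directly.
    """

    def loglik(m, t, p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return float(m.sum()) * np.log(p) + float((t - m).sum()) * np.log(1 - p)

    m_a, t_a = meth[~is_b], total[~is_b]
    m_b, t_b = meth[is_b], total[is_b]
    p_a = m_a.sum() / t_a.sum()
    p_b = m_b.sum() / t_b.sum()
    p_0 = meth.sum() / total.sum()
    lr = 2.0 * (
        loglik(m_a, t_a, p_a) + loglik(m_b, t_b, p_b) - loglik(meth, total, p_0)
    )
    return max(lr, 0.0)


def dm_test(
    region_meth: RegionMethylation,
    groups: pd.Series | dict,
    group_a: str = "young",
    group_b: str = "old",
    p_threshold: float = 0.05,
    min_delta: float = 10.0,
    quasi: bool = False,
) -> pd.DataFrame:
    """Aging differential-methylation test per region.

    Binomial regression (logit link) of the methylated proportion on the group
    indicator, using per-sample counts aggregated over the region's retained
    CpGs; raw p from the likelihood-ratio test.  ``delta`` is the difference of
    group means of the region percentage (group_b - group_a, percentage
    points).  ``significant`` requires p < ``p_threshold`` AND |delta| >=
    ``min_delta``.  With ``quasi=True`` an overdispersion-robust p replaces the
    plain LRT p (deviance scaled by the Pearson dispersion, F reference).
    """
    groups = pd.Series(groups)
    samples = region_meth.samples
    grp = groups.reindex(samples)
    in_a = (grp == group_a).to_numpy()
    in_b = (grp == group_b).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    use = in_a | in_b
    is_b = in_b[use]
    meth = region_meth.meth.to_numpy()[:, use]
    total = region_meth.total.to_numpy()[:, use]
    pct = region_meth.percent.to_numpy()
    delta = pct[:, in_b].mean(axis=1) - pct[:, in_a].mean(axis=1)

    n_regions = meth.shape[0]
    p_raw = np.ones(n_regions)
    degenerate = np.zeros(n_regions, dtype=bool)
    n_use = int(use.sum())
    for i in range(n_regions):
        m, t = meth[i], total[i]
        if m.sum() == 0 or m.sum() == t.sum():
            degenerate[i] = True
            p_raw[i] = 1.0
            continue
        lr = _binomial_lrt(m, t, is_b)
        if quasi:
            # Pearson dispersion from the two-group (full) model
            p_hat = np.where(
                is_b, m[is_b].sum() / t[is_b].sum(), m[~is_b].sum() / t[~is_b].sum()
            )
            expected = t * p_hat
            var = t * p_hat * (1 - p_hat)
            with np.errstate(invalid="ignore", divide="ignore"):
                pearson = np.nansum((m - expected) ** 2 / np.where(var > 0, var, np.nan))
            df_resid = n_use - 2
            phi = max(pearson / df_resid, 1e-12) if df_resid > 0 else 1.0
            p_raw[i] = float(stats.f.sf(lr / phi, 1, df_resid))
        else:
            p_raw[i] = float(stats.chi2.sf(lr, df=1))

    direction = np.where(delta > 0, "hyper", "hypo")
    significant = (p_raw < p_threshold) & (np.abs(delta) >= min_delta)
    return pd.DataFrame(
        {
            "region_id": region_meth.percent.index,
            "delta_pp": delta,
            "p_raw": p_raw,
            "p_bh": bh_adjust(p_raw),
            "direction": direction,
            "significant": significant,
            "degenerate": degenerate,
        }
    ).set_index("region_id")
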