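"""Rejuvenation calls for aging-DM features and their temporal dynamics.

A feature that changes with aging is called rejuvenated when the treated-old
group mean is strictly closer to the young group mean than to the old group
mean.  Exact ties fail the rule (it demands strictly "closer") and are
flagged; features with no aging gap (young mean == old mean) are flagged and
never called rejuvenated.  Overshoot past the young mean still counts — the
rule is purely metric — but is flagged for inspection.

The temporal classifier applies the same predicate at the end of induction
(day 7) and after recovery (day 21) to distinguish changes established during
factor expression from those acquired during recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "classify_rejuvenated",
    "classify_temporal",
    "pca_aging_features",
    "summarize_rejuvenation",
]

TEMPORAL_CLASSES = (
    "established_d7_retained",
    "established_d7_lost",
    "acquired_in_recovery",
    "never",
)


def classify_rejuvenated(
    young_mean, old_mean, oskm_mean, feature_ids=None
) -> pd.DataFrame:
    """Nearest-mean rejuvenation call per feature (vectorized).

    Returns a frame with distance_to_young, distance_to_old, rejuvenated, and
    the tie / no_aging_gap / overshoot flags.  All three means must be on the
    same scale; the call is invariant to a joint affine rescaling.
    """
    young = np.atleast_1d(np.asarray(young_mean, dtype=float))
    old = np.atleast_1d(np.asarray(old_mean, dtype=float))
    oskm = np.atleast_1d(np.asarray(oskm_mean, dtype=float))
    if not (young.shape == old.shape == oskm.shape):
        raise ValueError("mean vectors must share a shape")
    d_young = np.abs(oskm - young)
    d_old = np.abs(oskm - old)
    no_gap = young == old
    tie = (d_young == d_old) & ~no_gap
    rejuvenated = (d_young < d_old) & ~no_gap
    # overshoot: treated mean beyond young on the side away from old
    overshoot = rejuvenated & (
        np.where(old > young, oskm < young, oskm > young)
    )
    aging_direction = np.where(no_gap, "none", np.where(old > young, "hyper", "hypo"))
    if feature_ids is None:
        feature_ids = pd.RangeIndex(young.size)
    return pd.DataFrame(
        {
            "aging_direction": aging_direction,
            "young_mean": young,
            "old_mean": old,
            "oskm_mean": oskm,
            "distance_to_young": d_young,
            "distance_to_old": d_old,
            "rejuvenated": rejuvenated,
            "tie": tie,
            "no_aging_gap": no_gap,
            "overshoot": overshoot,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def classify_temporal(
    young_mean, old_mean, d7_mean, d21_mean, feature_ids=None
) -> pd.DataFrame:
    """Apply the rejuvenation predicate at day 7 and day 21.

    (d7, d21) rejuvenated -> class: (True, True) established_d7_retained;
    (True, False) established_d7_lost; (False, True) acquired_in_recovery;
    (False, False) never.  The four classes partition the features.
    """
    at_d7 = classify_rejuvenated(young_mean, old_mean, d7_mean, feature_ids)
    at_d21 = classify_rejuvenated(young_mean, old_mean, d21_mean, feature_ids)
    r7 = at_d7["rejuvenated"].to_numpy()
    r21 = at_d21["rejuvenated"].to_numpy()
    cls = np.select(
        [r7 & r21, r7 & ~r21, ~r7 & r21],
        ["established_d7_retained", "established_d7_lost", "acquired_in_recovery"],
        default="never",
    )
    return pd.DataFrame(
        {
            "temporal_class": cls,
            "d7_mean": at_d7["oskm_mean"].to_numpy(),
            "d21_mean": at_d21["oskm_mean"].to_numpy(),
            "rejuvenated_d7": r7,
            "rejuvenated_d21": r21,
            "no_aging_gap": at_d21["no_aging_gap"].to_numpy(),
        },
        index=at_d21.index,
    )


def pca_aging_features(
    matrix: pd.DataFrame, scale: bool = False, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on principal components of aging-DM features.

    ``matrix`` is features x samples.  Features are centered (optionally unit
    scaled); zero-variance features are dropped with a warning.  Returns
    (scores: samples x components, explained-variance fractions).
    """
    import warnings

    x = matrix.to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >=2 features and >=3 samples")
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} zero-variance feature(s)", stacklevel=2)
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    if x.shape[1] == 0:
        n = matrix.shape[1]
        k = min(n, 2)
        scores = pd.DataFrame(
            np.zeros((n, k)),
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return scores, np.zeros(k)
    if scale:
        x = x / sd
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def summarize_rejuvenation(
    dm_results: pd.DataFrame,
    calls: pd.DataFrame,
    kinds: pd.Series | None = None,
) -> dict:
    """Counts and fractions of rejuvenated regions by kind and aging direction.

    ``dm_results`` is the differential-methylation table (only rows with
    ``significant`` are summarized); ``calls`` the rejuvenation calls indexed
    by the same region ids; ``kinds`` optionally maps region id to
    promoter/enhancer.  Returns a JSON-serializable dict.
    """
    sig = dm_results[dm_results["significant"]] if len(dm_results) else dm_results
    ids = [i for i in sig.index if i in calls.index]
    sub = calls.loc[ids]
    directions = sig.loc[ids, "direction"] if len(ids) else pd.Series(dtype=object)

    def block(mask) -> dict:
        n = int(mask.sum())
        r = int(sub.loc[mask, "rejuvenated"].sum()) if n else 0
        return {
            "n_regions": n,
            "n_rejuvenated": r,
            "fraction_rejuvenated": (r / n) if n else 0.0,
        }

    out = {
        "overall": block(pd.Series(True, index=sub.index)),
        "by_direction": {
            "hyper_demethylated_by_oskm": block(directions == "hyper"),
            "hypo_remethylated_by_oskm": block(directions == "hypo"),
        },
        "n_ties": int(sub["tie"].sum()) if len(sub) else 0,
        "n_no_aging_gap": int(sub["no_aging_gap"].sum()) if len(sub) else 0,
    }
    if kinds is not None and len(sub):
        kind_series = pd.Series(kinds).reindex(sub.index)
        out["by_kind"] = {
            str(k): block(kind_series == k) for k in kind_series.dropna().unique()
        }
    return out


def write_summary(summary: dict, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write the rejuvenation summary as JSON and (optionally) a flat TSV."""
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    if tsv_path is not None:
        rows = [
            {"stratum": "overall", **summary["overall"]},
            *[
                {"stratum": name, **blk}
                for name, blk in summary["by_direction"].items()
            ],
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
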