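"""Descriptive sensory-panel summaries (13 texture attributes, 150-mm scale)."""

from __future__ import annotations

import pandas as pd

from .synth import SCALE_MM, SENSORY_ATTRIBUTES

__all__ = ["validate_scores", "summarize_sensory", "compare_clusters"]

REQUIRED_COLUMNS = ["sample_id", "panelist_id", "attribute", "intensity_mm"]


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table: known attributes, intensities in range."""
    missing = [c for c in REQUIRED_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    unknown = set(scores["attribute"]) - set(SENSORY_ATTRIBUTES)
    if unknown:
        raise ValueError(f"unknown sensory attributes: {sorted(unknown)}")
    bad = scores[(scores["intensity_mm"] < 0) | (scores["intensity_mm"] > SCALE_MM)]
    if len(bad):
        raise ValueError(
            f"{len(bad)} intensities outside [0, {SCALE_MM:.0f}] mm "
            f"(first: sample {bad.iloc[0]['sample_id']!r})")
    return scores


def summarize_sensory(
    scores: pd.DataFrame,
    cluster_map: pd.Series,
    reference_sample: str | None = None,
) -> pd.DataFrame:
    """Per-cluster mean and SD of each attribute.

    Panelist scores are first averaged per sample, then cluster statistics
    are taken over sample-level means (sample SD, ddof=1) — so with five
    samples per cluster the SD reflects five observations.  An optional
    ``reference_sample`` (the standard served across sessions) is excluded.

    Returns a frame indexed by attribute with (cluster, {mean, sd, n})
    columns.
    """
    scores = validate_scores(scores)
    if reference_sample is not None:
        scores = scores[scores["sample_id"] != reference_sample]
    unassigned = set(scores["sample_id"]) - set(cluster_map.index)
    if unassigned:
        raise ValueError(f"samples without a cluster assignment: {sorted(unassigned)}")

    sample_means = (
        scores.groupby(["sample_id", "attribute"], sort=False)["intensity_mm"]
        .mean().reset_index())
    sample_means["cluster"] = sample_means["sample_id"].map(cluster_map)
    g = sample_means.groupby(["attribute", "cluster"])["intensity_mm"]
    out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()}, axis=1)
    out = out.unstack("cluster").swaplevel(axis=1).sort_index(axis=1, level=0)
    out.columns.names = ["cluster", "stat"]
    # keep the lexicon's canonical attribute order
    order = [a for a in SENSORY_ATTRIBUTES if a in out.index]
    return out.loc[order]


def compare_clusters(summary: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Clusters ordered by mean intensity of one attribute, with differences.

    Purely descriptive (no inferential test): returns cluster, mean, and the
    mean difference to the next-ranked cluster.
    """
    if attribute not in summary.index:
        raise ValueError(f"attribute {attribute!r} not in summary")
    means = summary.loc[attribute].xs("mean", level="stat")
    ordered = means.sort_values(ascending=False)
    diffs = (-ordered.diff(-1)).fillna(0.0)
    return pd.DataFrame({
        "cluster": ordered.index,
        "mean_mm": ordered.to_numpy(),
        "gap_to_next_mm": diffs.to_numpy(),
    })
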