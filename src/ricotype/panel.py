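"""Quality-panel assembly: class bins, replicate averaging, correlation pruning.

The study panel holds 25 cooking-quality variables per accession: routine
indicators (amylose content AC, gelatinisation temperature GT, crude protein
PC), eight RVA pasting parameters, ten rheometry landmarks and four TPA
texture attributes.  Ten of the 25 are pairwise highly correlated
(|r| > 0.75); six are removed as redundant, retaining 19 for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import PANEL_VARIABLES_19, PANEL_VARIABLES_25, REDUNDANT_VARIABLES

__all__ = [
    "KJELDAHL_PROTEIN_FACTOR",
    "AC_CLASSES",
    "GT_CLASSES",
    "protein_from_nitrogen",
    "assign_ac_class",
    "assign_gt_class",
    "average_replicates",
    "pearson_matrix",
    "prune_correlated",
    "CorrelationReport",
    "MissingDataError",
]

#: Conversion factor from % Kjeldahl nitrogen to % crude protein for rice.
KJELDAHL_PROTEIN_FACTOR = 5.95

AC_CLASSES = ("waxy", "very_low", "low", "intermediate", "high")
GT_CLASSES = ("low", "intermediate", "high")


class MissingDataError(ValueError):
    """A sample/variable cell has no replicate data."""


def protein_from_nitrogen(kjeldahl_n: float) -> float:
    """Crude protein (%) from % Kjeldahl N (factor 5.95)."""
    n = np.asarray(kjeldahl_n, dtype=float)
    if np.any(n < 0):
        raise ValueError("Kjeldahl N must be non-negative")
    out = KJELDAHL_PROTEIN_FACTOR * n
    return float(out) if np.isscalar(kjeldahl_n) else out


def assign_ac_class(ac: float) -> str:
    """Amylose-content class on the five-bin breeding scale.

    The conventional bins (waxy 0-2, very low 3-9, low 10-19, intermediate
    20-25, high > 25 %) leave gaps between the printed edges; these are
    closed with half-open bins cut at the midpoints 2.5 / 9.5 / 19.5, and
    25.0 itself is intermediate (the 20-25 bin is inclusive).
    """
    if ac < 0:
        raise ValueError("AC must be non-negative")
    if ac < 2.5:
        return "waxy"
    if ac < 9.5:
        return "very_low"
    if ac < 19.5:
        return "low"
    if ac <= 25.0:
        return "intermediate"
    return "high"


def assign_gt_class(gt: float, low_edge: float = 67.0, high_edge: float = 74.0) -> str:
    """Gelatinisation-temperature class: low < 67, high >= 74 degC.

    The printed class edges (below 67 / 68-73 / >= 74) leave the intervals
    67-68 and 73-74 unassigned; both are resolved into the intermediate
    class so the mapping is total.
    """
    if gt <= 0:
        raise ValueError("GT must be positive")
    if gt < low_edge:
        return "low"
    if gt < high_edge:
        return "intermediate"
    return "high"


def average_replicates(rows: pd.DataFrame, sample_col: str = "sample_id") -> pd.DataFrame:
    """Arithmetic per-sample mean of replicate feature rows.

    ``rows`` is tidy: one row per replicate, one column per variable plus a
    sample-id column.  Returns a panel indexed by sample id with a
    ``.attrs["replicate_counts"]`` frame recording per-cell counts.

    Raises
    ------
    MissingDataError
        if any sample has no observed value for some variable.
    """
    if sample_col not in rows.columns:
        raise ValueError(f"missing {sample_col!r} column")
    grouped = rows.groupby(sample_col, sort=False)
    panel = grouped.mean(numeric_only=True)
    counts = grouped.count()[panel.columns]
    missing = counts == 0
    if missing.to_numpy().any():
        sid = missing.any(axis=1).idxmax()
        var = missing.loc[sid].idxmax()
        raise MissingDataError(f"no replicates for sample {sid!r}, variable {var!r}")
    panel.attrs["replicate_counts"] = counts
    return panel


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with redundancy flags.

    ``matrix``/``pvalues`` are symmetric with unit / zero diagonals;
    ``flagged`` lists pairs with |r| above the pruning threshold; after
    pruning, ``dropped`` + ``retained`` partition the input variables.
    """

    matrix: pd.DataFrame
    pvalues: pd.DataFrame
    threshold: float = 0.75
    flagged: list[tuple[str, str, float]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    constant: list[str] = field(default_factory=list)

    def stars(self) -> pd.DataFrame:
        """Two-sided significance stars (* p<0.1, ** p<0.05, *** p<0.01)."""
        def star(p):
            if np.isnan(p):
                return ""
            if p < 0.01:
                return "***"
            if p < 0.05:
                return "**"
            if p < 0.1:
                return "*"
            return ""
        return self.pvalues.map(star)


def pearson_matrix(panel: pd.DataFrame, threshold: float = 0.75) -> CorrelationReport:
    """All-pairs Pearson r with two-sided t-test p-values.

    Variables with zero variance are flagged in ``report.constant`` and
    their correlations set to NaN.  Pairs with |r| > ``threshold`` are
    recorded in ``report.flagged``.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = panel.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("panel contains non-finite values")
    cols = list(panel.columns)
    constant = [c for c in cols if panel[c].std(ddof=1) == 0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x, rowvar=False)
    n = len(panel)
    # two-sided p via the exact t transform of r under bivariate normality
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    matrix = pd.DataFrame(r, index=cols, columns=cols)
    pvals = pd.DataFrame(p, index=cols, columns=cols)
    for c in constant:
        matrix.loc[c, :] = matrix.loc[:, c] = np.nan
        pvals.loc[c, :] = pvals.loc[:, c] = np.nan

    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            rv = matrix.loc[a, b]
            if np.isfinite(rv) and abs(rv) > threshold:
                flagged.append((a, b, float(rv)))
    return CorrelationReport(matrix=matrix, pvalues=pvals, threshold=threshold,
                             flagged=flagged, constant=constant,
                             retained=cols, dropped=[])


#: The six variables the study removed as redundant (complement of the 19
#: profiled variables within the 25-variable panel).
PAPER_DROP_SET = list(REDUNDANT_VARIABLES)


def prune_correlated(
    panel: pd.DataFrame,
    threshold: float = 0.75,
    drop_policy: str = "paper",
) -> tuple[pd.DataFrame, CorrelationReport]:
    """Remove redundant variables from a correlated panel.

    Policies
    --------
    ``"paper"``
        drop the study's pinned six-variable set (TV, FV, pasting
        temperature, temperature at gel point, G'' at G'max, temperature at
        G'max); every named variable must be present.
    ``"greedy"``
        while any pair exceeds the threshold, drop the member of the worst
        pair with the larger mean absolute correlation to all remaining
        variables.
    """
    report = pearson_matrix(panel, threshold=threshold)
    if drop_policy == "paper":
        missing = [v for v in PAPER_DROP_SET if v not in panel.columns]
        if missing:
            raise ValueError(f"pinned drop list names absent variables: {missing}")
        dropped = list(PAPER_DROP_SET)
    elif drop_policy == "greedy":
        dropped = []
        corr = report.matrix.abs().copy()
        np.fill_diagonal(corr.values, 0.0)
        while True:
            flags = corr.stack()
            flags = flags[flags > threshold]
            if flags.empty:
                break
            a, b = flags.idxmax()
            mean_a = corr.loc[a].mean()
            mean_b = corr.loc[b].mean()
            victim = a if mean_a >= mean_b else b
            dropped.append(victim)
            corr = corr.drop(index=victim, columns=victim)
    else:
        raise ValueError(f"unknown drop_policy {drop_policy!r}")

    retained = [c for c in panel.columns if c not in dropped]
    report.dropped = dropped
    report.retained = retained
    return panel[retained], report
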