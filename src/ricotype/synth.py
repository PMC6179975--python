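"""Synthetic-data generators for every input of the pipeline.

Three families of generators:

* instrument curves (rheometry, RVA pasting, TPA) with *planted* landmarks,
  so extractor output can be checked against known ground truth;
* multivariate-normal feature panels with three-cluster structure, whose
  default moments are the per-cluster means/SDs reported for the 211-accession
  indica study panel (cluster sizes 114/70/27) and whose default correlation
  structure is patterned on the study's Pearson matrix;
* descriptive sensory score sets on the 150-mm line scale, with the study's
  13-attribute per-cluster summary as the default parameterisation.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .curves import RheoCurve, RVACurve, TPACurve

__all__ = [
    "RheoCurveSpec",
    "RVACurveSpec",
    "TPACurveSpec",
    "PanelSpec",
    "gen_rheometry_curve",
    "gen_pasting_curve",
    "gen_tpa_curve",
    "gen_feature_panel",
    "gen_sensory_scores",
    "gen_cooking_study",
    "STUDY_CLUSTER_SIZES",
    "STUDY_PANEL_MOMENTS",
    "STUDY_CORRELATIONS",
    "SENSORY_ATTRIBUTES",
    "STUDY_SENSORY_MOMENTS",
    "PANEL_VARIABLES_19",
    "PANEL_VARIABLES_25",
]


# ----------------------------------------------------------------------------
# canonical variable sets

#: The 19 variables retained after correlation pruning, in the order the
#: study's tables list them.
PANEL_VARIABLES_19 = [
    "GT", "AC", "PV", "BD", "SB", "LO", "PT", "HRD", "ADH", "COH", "SPR",
    "Gmax", "tand_at_Gmax", "Gtrough", "S1", "S2", "S3", "S4", "PC",
]

#: The six redundant variables dropped by the pruning step.
REDUNDANT_VARIABLES = [
    "TV", "FV", "PTemp", "temp_gel", "Gpp_at_Gmax", "temp_Gmax",
]

#: The full 25-variable quality panel.
PANEL_VARIABLES_25 = PANEL_VARIABLES_19 + REDUNDANT_VARIABLES

#: Cluster sizes of the study panel (clusters numbered by decreasing size).
STUDY_CLUSTER_SIZES = (114, 70, 27)

#: Per-cluster (mean, SD) for the 19 retained variables: three (mean, sd)
#: pairs per variable, clusters 1..3.
STUDY_PANEL_MOMENTS: dict[str, tuple[tuple[float, float], ...]] = {
    "GT":            ((74.81, 3.98), (77.10, 1.22), (77.94, 1.38)),
    "AC":            ((25.07, 1.44), (25.51, 1.49), (21.22, 1.24)),
    "PV":            ((2.23, 0.52),  (2.28, 0.43),  (2.49, 0.18)),
    "BD":            ((0.67, 0.20),  (0.78, 0.14),  (1.10, 0.14)),
    "SB":            ((0.69, 0.21),  (0.61, 0.18),  (0.15, 0.18)),
    "LO":            ((1.36, 0.25),  (1.39, 0.19),  (1.24, 0.09)),
    "PT":            ((5.96, 0.30),  (5.84, 0.18),  (5.89, 0.13)),
    "HRD":           ((1.96, 0.50),  (1.94, 0.50),  (1.73, 0.47)),
    "ADH":           ((0.02, 0.01),  (0.02, 0.01),  (0.04, 0.02)),
    "COH":           ((0.44, 0.06),  (0.42, 0.05),  (0.43, 0.04)),
    "SPR":           ((0.11, 0.02),  (0.11, 0.01),  (0.10, 0.01)),
    "Gmax":          ((40.64, 9.62), (28.34, 7.20), (29.83, 7.26)),
    "tand_at_Gmax":  ((0.11, 0.02),  (0.12, 0.04),  (0.11, 0.02)),
    "Gtrough":       ((15.53, 4.31), (11.92, 2.33), (11.66, 1.83)),
    "S1":            ((7.45, 2.66),  (4.66, 1.88),  (5.93, 2.49)),
    "S2":            ((1.66, 0.58),  (1.27, 0.33),  (1.29, 0.22)),
    "S3":            ((1.77, 0.70),  (1.19, 0.58),  (1.38, 0.63)),
    "S4":            ((1.53, 0.81),  (1.09, 0.63),  (1.24, 0.71)),
    "PC":            ((8.66, 1.26),  (8.34, 1.02),  (8.30, 1.00)),
}

#: Optional within-cluster correlation pattern among retained variables:
#: the moderate-to-strong entries (|r| >= ~0.3) of the study's panel-wide
#: Pearson matrix, applied symmetrically (identity elsewhere, then
#: nearest-PSD repair).  The generator's default instead realises only the
#: flagged (|r| > 0.75) redundancy structure — which exclusively involves
#: the six pruned variables — through the redundant-block recipes, leaving
#: the retained variables conditionally independent within a cluster.
STUDY_CORRELATIONS: dict[tuple[str, str], float] = {
    ("GT", "BD"): 0.54, ("GT", "SB"): -0.36, ("GT", "PT"): -0.37,
    ("GT", "Gmax"): -0.34,
    ("AC", "SB"): 0.34, ("AC", "ADH"): -0.31, ("AC", "SPR"): 0.33,
    ("AC", "PC"): -0.37,
    ("PV", "BD"): 0.48, ("PV", "LO"): 0.59, ("PV", "PT"): 0.48,
    ("BD", "SB"): -0.61, ("BD", "PC"): -0.41, ("BD", "Gmax"): -0.35,
    ("BD", "Gtrough"): -0.34,
    ("SB", "LO"): 0.58, ("SB", "PT"): 0.32,
    ("HRD", "SPR"): 0.54, ("HRD", "COH"): 0.36,
    ("COH", "SPR"): 0.39,
    ("Gmax", "Gtrough"): 0.54, ("Gmax", "S1"): 0.39, ("Gmax", "S3"): 0.33,
    ("S1", "S2"): 0.33, ("S1", "S3"): 0.39, ("S1", "S4"): 0.34,
    ("S2", "S3"): 0.34, ("S3", "S4"): 0.49,
}


class SpecError(ValueError):
    """A generator spec has mutually inconsistent landmarks."""


# ----------------------------------------------------------------------------
# rheometry curve generator


@dataclass(frozen=True)
class RheoCurveSpec:
    """Planted landmarks for a synthetic viscoelastic sweep.

    The temperature profile is 35 -> 95 -> 35 degC at ``ramp_rate`` degC/min.
    ``gel_temp`` must fall inside the heating ramp and before
    ``temp_at_Gmax``; ``Gtrough`` strictly below ``Gmax``.
    """

    gel_temp: float = 75.0
    Gmax: float = 40.0
    temp_at_Gmax: float = 90.0
    Gtrough: float = 15.0
    Gpp_max: float = 8.0
    tand_start: float = 2.0
    ramp_rate: float = 4.0
    dt_min: float = 0.05
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (35.0 < self.gel_temp < self.temp_at_Gmax <= 95.0):
            raise SpecError("need 35 < gel_temp < temp_at_Gmax <= 95")
        if not (0 < self.Gtrough < self.Gmax):
            raise SpecError("need 0 < Gtrough < Gmax")
        if not (0 < self.Gpp_max < self.Gmax):
            raise SpecError("need 0 < Gpp_max < Gmax")
        if self.tand_start <= 1:
            raise SpecError("trace must start liquid-like (tand_start > 1)")
        if self.dt_min <= 0 or self.ramp_rate <= 0 or self.noise_sd < 0:
            raise SpecError("rates and noise must be valid")


def _rheo_truth(spec: RheoCurveSpec) -> dict[str, float]:
    """Closed-form landmark record implied by a rheometry spec."""
    t_gel = (spec.gel_temp - 35.0) / spec.ramp_rate
    t_gmax = (spec.temp_at_Gmax - 35.0) / spec.ramp_rate
    ramp_end = 60.0 / spec.ramp_rate  # heating takes (95-35)/rate minutes
    t_trough = ramp_end + 0.35 * ramp_end
    # crossover value sits below the planted G'' maximum so that G'' keeps
    # rising (and G' rises faster) after the gel point
    g_cross = 0.6 * spec.Gpp_max
    t_gppmax = t_gel + 0.8 * (t_gmax - t_gel)
    return {
        "gel_temp": spec.gel_temp,
        "gel_time": t_gel,
        "Gmax": spec.Gmax,
        "temp_at_Gmax": spec.temp_at_Gmax,
        "Gtrough": spec.Gtrough,
        "Gpp_max": spec.Gpp_max,
        "t_gmax": t_gmax,
        "t_gppmax": t_gppmax,
        "t_trough": t_trough,
        "S1": (spec.Gmax - g_cross) / (t_gmax - t_gel),
        "S2": (spec.Gtrough - spec.Gmax) / (t_trough - t_gmax),
        "S3": (spec.Gpp_max - g_cross) / (t_gppmax - t_gel),
        "g_cross": g_cross,
    }


def gen_rheometry_curve(
    spec: RheoCurveSpec, seed: int | np.random.Generator = 0
) -> tuple[RheoCurve, dict[str, float]]:
    """Generate a rheometry sweep with planted landmarks.

    Both moduli are piecewise-monotone PCHIP interpolants through landmark
    control points.  Before the gel point G' is defined as G'' times a
    monotone ratio rising to 1 at the gel time, so tan(delta) = G''/G'
    decreases monotonically and crosses 1 exactly once on the heating ramp;
    afterwards G' rises much faster than G'', keeping tan(delta) < 1.
    Returns the curve and its ground-truth landmark record.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    truth = _rheo_truth(spec)

    ramp_end = 60.0 / spec.ramp_rate
    t_end = 2 * ramp_end
    t = np.arange(0.0, t_end + spec.dt_min / 2, spec.dt_min)
    temp = np.where(t <= ramp_end, 35.0 + spec.ramp_rate * t,
                    95.0 - spec.ramp_rate * (t - ramp_end))

    g_cross = truth["g_cross"]
    t_gel, t_gmax, t_trough = truth["gel_time"], truth["t_gmax"], truth["t_trough"]
    t_gppmax = truth["t_gppmax"]

    pre = t < t_gel
    post = ~pre

    # G'': gentle rise to the crossover, on to its planted maximum, then a
    # decay that levels off to a plateau
    gpp_plateau = 0.55 * spec.Gpp_max
    gpp_knots_t = [0.0, t_gel, t_gppmax, t_gppmax + 0.35 * (t_end - t_gppmax), t_end]
    gpp_knots_v = [0.5 * g_cross, g_cross, spec.Gpp_max, gpp_plateau, gpp_plateau]
    gpp = PchipInterpolator(gpp_knots_t, gpp_knots_v)(t)

    # G' before the gel point: G'' scaled by a ratio < 1 rising to 1 at the
    # gel time (tan(delta) = 1/ratio decreases through 1 exactly there)
    ratio = PchipInterpolator([0.0, t_gel], [1.0 / spec.tand_start, 1.0])
    gp = np.empty_like(t)
    gp[pre] = gpp[pre] * ratio(t[pre])
    # G' after the gel point: steep rise to the peak, decay to the trough,
    # mild recovery so the trough is interior
    gp_knots_t = [t_gel, t_gmax, t_trough, t_end]
    gp_knots_v = [g_cross, spec.Gmax, spec.Gtrough,
                  spec.Gtrough + 0.08 * (spec.Gmax - spec.Gtrough)]
    gp[post] = PchipInterpolator(gp_knots_t, gp_knots_v)(t[post])

    if spec.noise_sd > 0:
        gp = gp + rng.normal(0.0, spec.noise_sd, t.size)
        gpp = gpp + rng.normal(0.0, spec.noise_sd, t.size)
    gp = np.clip(gp, 1e-6, None)
    gpp = np.clip(gpp, 1e-6, None)

    curve = RheoCurve(time_min=t, temp_C=temp, g_prime_kPa=gp, g_double_prime_kPa=gpp)
    return curve, truth


# ----------------------------------------------------------------------------
# RVA pasting curve generator


@dataclass(frozen=True)
class RVACurveSpec:
    """Planted pasting landmarks over the heat-hold-cool RVA profile.

    Times in minutes on the standard ~12.5 min profile: heat 50->95 degC
    over minutes 1-4.8, hold at 95 to minute 7.5, cool to 50 by minute 11.
    """

    PV: float = 2.49
    TV: float = 1.39
    FV: float = 2.64
    PT: float = 5.89
    onset_time: float = 3.0
    trough_time: float = 8.5
    baseline: float = 0.05
    total_time: float = 12.5
    dt_min: float = 0.02
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.TV <= self.PV):
            raise SpecError("need 0 <= TV <= PV")
        if self.FV < 0 or self.baseline < 0:
            raise SpecError("viscosities must be non-negative")
        if not (self.onset_time < self.PT < self.trough_time < self.total_time):
            raise SpecError("need onset < PT < trough_time < total_time")
        if self.PV < self.baseline:
            raise SpecError("PV must exceed the baseline")


def _rva_temperature(t: np.ndarray, total: float) -> np.ndarray:
    """Standard heat-hold-cool profile: 50 -> 95 -> 95 -> 50 degC."""
    heat_start, heat_end, hold_end, cool_end = 1.0, 4.8, 7.5, 11.0
    temp = np.full_like(t, 50.0)
    m = (t > heat_start) & (t <= heat_end)
    temp[m] = 50.0 + (95.0 - 50.0) * (t[m] - heat_start) / (heat_end - heat_start)
    temp[(t > heat_end) & (t <= hold_end)] = 95.0
    m = (t > hold_end) & (t <= cool_end)
    temp[m] = 95.0 - (95.0 - 50.0) * (t[m] - hold_end) / (cool_end - hold_end)
    temp[t > cool_end] = 50.0
    return temp


def gen_pasting_curve(
    spec: RVACurveSpec, seed: int | np.random.Generator = 0
) -> tuple[RVACurve, dict[str, float]]:
    """Generate an RVA pasting trace with planted PV/TV/FV/PT landmarks."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(0.0, spec.total_time + spec.dt_min / 2, spec.dt_min)
    temp = _rva_temperature(t, spec.total_time)

    knots_t = [0.0, spec.onset_time, spec.PT, spec.trough_time, spec.total_time]
    knots_v = [spec.baseline, spec.baseline, spec.PV, spec.TV, spec.FV]
    v = PchipInterpolator(knots_t, knots_v)(t)
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, t.size)
    v = np.clip(v, 0.0, None)

    onset_temp = float(np.interp(spec.onset_time, t, temp))
    truth = {
        "PV": spec.PV, "TV": spec.TV, "FV": spec.FV, "PT": spec.PT,
        "BD": spec.PV - spec.TV, "SB": spec.FV - spec.PV,
        "LO": spec.FV - spec.TV, "onset_temp": onset_temp,
    }
    return RVACurve(time_min=t, temp_C=temp, viscosity=v), truth


# ----------------------------------------------------------------------------
# TPA curve generator


@dataclass(frozen=True)
class TPACurveSpec:
    """Planted two-compression texture profile.

    Each positive lobe is a triangle of the given area whose apex force is
    the given peak; the (optional) negative pull-off lobe sits between them.
    T1 and T2 are the downstroke durations (lobe start to apex).
    """

    area1: float = 2.00
    area2: float = 0.88
    peak1: float = 1.96
    peak2: float = 1.10
    neg_area: float = 0.02
    neg_depth: float = 0.15
    T1: float = 1.8
    T2: float = 0.9
    gap_s: float = 1.5
    dt_s: float = 0.005
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.area1, self.area2, self.peak1, self.peak2) <= 0:
            raise SpecError("lobe areas and peaks must be positive")
        if self.neg_area < 0 or self.neg_depth <= 0:
            raise SpecError("invalid negative lobe")
        if self.T1 <= 0 or self.T2 <= 0 or self.gap_s <= 0:
            raise SpecError("durations must be positive")
        # triangle apex at time T_k after lobe start; base = 2*area/peak must
        # leave room for the downstroke
        if 2 * self.area1 / self.peak1 <= self.T1:
            raise SpecError("lobe 1: area/peak incompatible with T1")
        if 2 * self.area2 / self.peak2 <= self.T2:
            raise SpecError("lobe 2: area/peak incompatible with T2")


def _triangle(t: np.ndarray, t0: float, t_apex: float, t1: float, h: float) -> np.ndarray:
    up = (t >= t0) & (t <= t_apex)
    down = (t > t_apex) & (t <= t1)
    y = np.zeros_like(t)
    y[up] = h * (t[up] - t0) / (t_apex - t0)
    y[down] = h * (t1 - t[down]) / (t1 - t_apex)
    return y


def gen_tpa_curve(
    spec: TPACurveSpec, seed: int | np.random.Generator = 0
) -> tuple[TPACurve, dict[str, float]]:
    """Generate a two-compression TPA trace with planted areas and peaks."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base1 = 2 * spec.area1 / spec.peak1
    base2 = 2 * spec.area2 / spec.peak2
    neg_base = 2 * spec.neg_area / spec.neg_depth if spec.neg_area > 0 else 0.0

    lead = 0.5
    t0_1 = lead
    t1_1 = t0_1 + base1
    neg_start = t1_1 + 0.1
    neg_end = neg_start + neg_base
    t0_2 = neg_end + spec.gap_s
    t1_2 = t0_2 + base2
    total = t1_2 + lead

    t = np.arange(0.0, total + spec.dt_s / 2, spec.dt_s)
    f = _triangle(t, t0_1, t0_1 + spec.T1, t1_1, spec.peak1)
    f = f + _triangle(t, t0_2, t0_2 + spec.T2, t1_2, spec.peak2)
    if spec.neg_area > 0:
        f = f - _triangle(t, neg_start, (neg_start + neg_end) / 2, neg_end, spec.neg_depth)
    if spec.noise_sd > 0:
        f = f + rng.normal(0.0, spec.noise_sd, t.size)

    truth = {
        "HRD": spec.peak1, "ADH": spec.neg_area,
        "COH": spec.area2 / spec.area1, "SPR": spec.T2 / spec.T1,
        "T1": spec.T1, "T2": spec.T2,
        "area1": spec.area1, "area2": spec.area2,
    }
    return TPACurve(time_s=t, force_kg=f), truth


# ----------------------------------------------------------------------------
# feature-panel generator


def _nearest_psd(corr: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped nearest PSD correlation matrix and repair distance."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= min_eig:
        return corr, 0.0
    w = np.clip(w, min_eig, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return fixed, float(np.linalg.norm(fixed - corr, "fro"))


def build_correlation_matrix(
    variables: list[str],
    pairs: dict[tuple[str, str], float] | None = None,
) -> tuple[np.ndarray, float]:
    """Correlation matrix from a sparse pair specification (PSD-repaired).

    Returns the matrix and the Frobenius distance moved by the repair.
    """
    if pairs is None:
        pairs = STUDY_CORRELATIONS
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    corr = np.eye(p)
    for (a, b), r in pairs.items():
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return _nearest_psd(corr)


@dataclass(frozen=True)
class PanelSpec:
    """Parameterisation of a synthetic three-cluster quality panel.

    Defaults reproduce the study conditions: cluster sizes 114/70/27 and the
    per-cluster means/SDs of the 19 retained variables, drawn conditionally
    independent within a cluster (extra within-cluster correlation pairs,
    e.g. :data:`STUDY_CORRELATIONS`, may be supplied).  With
    ``include_redundant`` the six pruned variables (TV, FV, pasting
    temperature, temperature at gel point, G'' at G'max, temperature at
    G'max) are added as noisy functions of the retained ones, reproducing
    the |r| > 0.75 redundancy the pruning step removes.
    """

    sizes: tuple[int, ...] = STUDY_CLUSTER_SIZES
    moments: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(STUDY_PANEL_MOMENTS))
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    include_redundant: bool = False
    psd_tol: float = 0.8

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.sizes):
            raise SpecError("cluster sizes must be >= 1")
        for var, per_cluster in self.moments.items():
            if len(per_cluster) != len(self.sizes):
                raise SpecError(f"{var}: need one (mean, sd) pair per cluster")
            if any(sd < 0 for _, sd in per_cluster):
                raise SpecError(f"{var}: SDs must be non-negative")

    @property
    def variables(self) -> list[str]:
        return list(self.moments)


def _redundant_block(core: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """The six pruned variables as noisy functions of retained ones.

    Noise SDs are chosen in closed form so the panel-wide correlations land
    near the study's printed values given the default cluster moments:
    r(TV, PV) ~ 0.88, r(PTemp, GT) ~ 0.82, r(temp at gel point, GT) ~ 0.8,
    r(G'' at G'max, G'max) ~ 0.78, r(temp at G'max, G'max) ~ -0.79.
    """
    n = len(core)
    return pd.DataFrame({
        "TV": core["PV"] - core["BD"] + rng.normal(0, 0.03, n),
        "FV": core["PV"] + core["SB"] + rng.normal(0, 0.03, n),
        "PTemp": 70.0 + 0.9 * (core["GT"] - 76.0) + rng.normal(0, 2.08, n),
        "temp_gel": 68.0 + 0.8 * (core["GT"] - 76.0) + rng.normal(0, 1.98, n),
        "Gpp_at_Gmax": core["Gmax"] * core["tand_at_Gmax"] + rng.normal(0, 0.15, n),
        "temp_Gmax": 90.0 - 0.30 * (core["Gmax"] - 33.0) + rng.normal(0, 2.43, n),
    }, index=core.index)


def gen_feature_panel(
    spec: PanelSpec = PanelSpec(), seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a clustered feature panel; returns (panel, true labels).

    Per cluster the retained variables are drawn from a multivariate normal
    with the spec's means/SDs and shared correlation pattern (nearest-PSD
    repaired); rows are concatenated and shuffled.  Labels are 1-based and
    returned separately, aligned on sample id.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    variables = spec.variables
    corr, dist = build_correlation_matrix(variables, spec.correlations)
    if dist > spec.psd_tol:
        raise SpecError(f"correlation repair distance {dist:.3f} exceeds tolerance")

    blocks, labels = [], []
    for k, n_k in enumerate(spec.sizes):
        mu = np.array([spec.moments[v][k][0] for v in variables])
        sd = np.array([spec.moments[v][k][1] for v in variables])
        cov = corr * np.outer(sd, sd)
        # eigh factorisation handles singular (zero-SD) covariances
        x = rng.multivariate_normal(mu, cov, size=n_k, method="eigh")
        blocks.append(x)
        labels.extend([k + 1] * n_k)

    data = np.vstack(blocks)
    labels = np.array(labels)
    order = rng.permutation(len(labels))
    ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    panel = pd.DataFrame(data[order], columns=variables, index=ids)
    panel.index.name = "sample_id"
    truth = pd.Series(labels[order], index=panel.index, name="cluster")

    if spec.include_redundant:
        panel = pd.concat([panel, _redundant_block(panel, rng)], axis=1)
        panel = panel[[v for v in PANEL_VARIABLES_25 if v in panel.columns]]
    return panel, truth


# ----------------------------------------------------------------------------
# sensory score generator

#: The 13-attribute texture lexicon of the descriptive panel.
SENSORY_ATTRIBUTES = [
    "initial starchy coating", "slickness", "roughness",
    "stickiness to the lips", "stickiness between grains", "springiness",
    "cohesiveness", "hardness", "uniformity of bite", "cohesiveness of mass",
    "moisture absorption", "residual loose particles", "toothpack",
]

#: Per-cluster (mean, SD) of each attribute on the 150-mm line scale, as
#: summarised for the study's 5-samples-per-cluster tasting.
STUDY_SENSORY_MOMENTS: dict[str, tuple[tuple[float, float], ...]] = {
    "initial starchy coating":   ((64.3, 11.9), (53.4, 4.8),  (72.3, 6.4)),
    "slickness":                 ((66.8, 14.5), (55.8, 8.3),  (69.3, 13.3)),
    "roughness":                 ((45.6, 7.1),  (50.2, 12.7), (40.8, 7.5)),
    "stickiness to the lips":    ((76.7, 16.1), (58.6, 14.2), (99.6, 3.5)),
    "stickiness between grains": ((76.6, 16.6), (55.4, 12.2), (82.5, 4.4)),
    "springiness":               ((59.0, 7.7),  (49.3, 7.6),  (55.2, 4.2)),
    "cohesiveness":              ((69.9, 8.4),  (49.4, 10.2), (68.0, 7.3)),
    "hardness":                  ((56.1, 4.7),  (51.7, 6.3),  (43.5, 8.3)),
    "uniformity of bite":        ((93.3, 5.2),  (65.9, 10.0), (91.6, 9.7)),
    "cohesiveness of mass":      ((90.8, 4.1),  (83.1, 12.8), (107.8, 5.8)),
    "moisture absorption":       ((65.5, 13.1), (64.7, 6.3),  (70.5, 7.6)),
    "residual loose particles":  ((68.9, 5.4),  (75.1, 8.9),  (55.7, 11.1)),
    "toothpack":                 ((71.5, 9.4),  (51.2, 15.1), (66.4, 7.2)),
}

SCALE_MM = 150.0


def gen_sensory_scores(
    moments: dict[str, tuple[tuple[float, float], ...]] | None = None,
    n_samples: int = 5,
    n_panelists: int = 8,
    panelist_sd: float = 6.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate long-format sensory scores; returns (scores, cluster map).

    Sample-level attribute means are drawn from the cluster distribution
    (truncated-normal resampling into [0, 150]); panelist replicates add
    truncated noise of SD ``panelist_sd`` around the sample mean.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if moments is None:
        moments = STUDY_SENSORY_MOMENTS
    n_clusters = len(next(iter(moments.values())))
    for attr, per_cluster in moments.items():
        for mu, sd in per_cluster:
            if not (0 <= mu <= SCALE_MM) or sd < 0:
                raise SpecError(f"{attr}: invalid (mean, sd) = ({mu}, {sd})")

    def trunc_normal(mu, sd, size):
        if sd == 0:
            return np.full(size, float(mu))
        out = rng.normal(mu, sd, size)
        bad = (out < 0) | (out > SCALE_MM)
        while np.any(bad):  # resample (not clip) to keep moments interpretable
            out[bad] = rng.normal(mu, sd, int(bad.sum()))
            bad = (out < 0) | (out > SCALE_MM)
        return out

    rows = []
    cluster_map = {}
    for k in range(n_clusters):
        for s in range(n_samples):
            sid = f"C{k + 1}-S{s + 1}"
            cluster_map[sid] = k + 1
            for attr in moments:
                mu, sd = moments[attr][k]
                sample_mean = trunc_normal(mu, sd, 1)[0]
                scores = trunc_normal(sample_mean, panelist_sd, n_panelists)
                for p, val in enumerate(scores):
                    rows.append((sid, f"P{p + 1:02d}", 1, attr, float(val)))
    scores = pd.DataFrame(
        rows, columns=["sample_id", "panelist_id", "session", "attribute", "intensity_mm"])
    return scores, pd.Series(cluster_map, name="cluster")


# ----------------------------------------------------------------------------
# full study emulation: per-sample instrument curves

#: Per-cluster archetype curve specs for the end-to-end loop: landmark
#: centres follow the cluster profiles, with separation carried by the
#: rheometry and pasting landmarks as in the study.
_RHEO_ARCHETYPES = (
    dict(gel_temp=70.0, Gmax=40.6, temp_at_Gmax=88.0, Gtrough=15.5, Gpp_max=4.5),
    dict(gel_temp=77.0, Gmax=28.3, temp_at_Gmax=91.0, Gtrough=11.9, Gpp_max=3.4),
    dict(gel_temp=78.0, Gmax=29.8, temp_at_Gmax=90.0, Gtrough=11.7, Gpp_max=3.3),
)
_RVA_ARCHETYPES = (
    dict(PV=2.23, TV=1.56, FV=2.92, PT=5.96),
    dict(PV=2.28, TV=1.50, FV=2.89, PT=5.84),
    dict(PV=2.49, TV=1.39, FV=2.64, PT=5.89),
)
_TPA_ARCHETYPES = (
    dict(area1=2.00, area2=0.88, peak1=1.96, neg_area=0.02, T2=1.8 * 0.11),
    dict(area1=2.00, area2=0.84, peak1=1.94, neg_area=0.02, T2=1.8 * 0.11),
    dict(area1=2.00, area2=0.86, peak1=1.73, neg_area=0.04, T2=1.8 * 0.10),
)


def gen_cooking_study(
    sizes: tuple[int, ...] = (20, 12, 8),
    landmark_jitter: float = 0.04,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, dict[str, object]], pd.Series]:
    """Generate a miniature study: one curve triple per sample.

    Per sample, the cluster archetype's landmarks are jittered by a relative
    ``landmark_jitter`` SD and the three instrument curves are generated.
    Returns ``{sample_id: {"rheo": RheoCurve, "rva": RVACurve, "tpa":
    TPACurve, ...truth}}`` plus true cluster labels.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples: dict[str, dict[str, object]] = {}
    labels = {}
    i = 0
    for k, n_k in enumerate(sizes):
        for _ in range(n_k):
            i += 1
            sid = f"S{i:04d}"
            labels[sid] = k + 1

            def jit(x, lo=None, hi=None, rel=landmark_jitter):
                v = x * (1 + rng.normal(0, rel))
                if lo is not None:
                    v = max(v, lo)
                if hi is not None:
                    v = min(v, hi)
                return v

            ra = _RHEO_ARCHETYPES[k]
            rheo_spec = RheoCurveSpec(
                gel_temp=jit(ra["gel_temp"], 40.0, 85.0),
                Gmax=jit(ra["Gmax"], 5.0),
                temp_at_Gmax=jit(ra["temp_at_Gmax"], 86.0, 95.0),
                Gtrough=jit(ra["Gtrough"], 1.0, 0.6 * ra["Gmax"]),
                Gpp_max=jit(ra["Gpp_max"], 0.5, 0.5 * ra["Gmax"]),
                dt_min=0.05, noise_sd=noise_sd)
            va = _RVA_ARCHETYPES[k]
            tv = jit(va["TV"])
            rva_spec = RVACurveSpec(
                PV=max(jit(va["PV"]), tv + 0.05), TV=tv,
                FV=jit(va["FV"]), PT=jit(va["PT"], 4.0, 7.0),
                dt_min=0.02, noise_sd=noise_sd)
            ta = _TPA_ARCHETYPES[k]
            peak1 = jit(ta["peak1"], 0.4, 2.1)
            area1 = max(jit(ta["area1"], 0.5), 0.55 * peak1 * 1.8)
            tpa_spec = TPACurveSpec(
                area1=area1, area2=jit(ta["area2"], 0.2),
                peak1=peak1, neg_area=max(jit(ta["neg_area"]), 0.001),
                T2=jit(ta["T2"], 0.05, 1.2), T1=1.8, peak2=1.10,
                dt_s=0.01, noise_sd=noise_sd)

            rheo, rheo_truth = gen_rheometry_curve(rheo_spec, rng)
            rva, rva_truth = gen_pasting_curve(rva_spec, rng)
            tpa, tpa_truth = gen_tpa_curve(tpa_spec, rng)
            samples[sid] = {
                "rheo": rheo, "rva": rva, "tpa": tpa,
                "rheo_truth": rheo_truth, "rva_truth": rva_truth,
                "tpa_truth": tpa_truth,
            }
    truth = pd.Series(labels, name="cluster")
    truth.index.name = "sample_id"
    return samples, truth
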