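"""Landmark extraction from cooking-quality instrument traces.

Three instruments characterise how rice flour or cooked grains behave
mechanically:

* an oscillatory rheometer records storage (G') and loss (G'') moduli of a
  flour-water paste over a 35-95-35 degC temperature sweep;
* a Rapid Visco Analyser (RVA) records paste viscosity over a
  heat (50-95 degC) - hold (95 degC) - cool (95-50 degC) profile;
* a texture analyser performs a two-cycle compression of cooked grains
  (texture profile analysis, TPA) and records force against time.

Each extractor turns one raw trace into the small set of scalar features
used downstream: gel point and slope features for rheometry; peak / trough /
final viscosity and their differences for pasting; hardness, adhesiveness,
cohesiveness and springiness for TPA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurveConfig",
    "RheoCurve",
    "RVACurve",
    "TPACurve",
    "RheometryFeatures",
    "PastingFeatures",
    "TPAFeatures",
    "CurveError",
    "NoGelPointError",
    "NoCompressionPeaksError",
    "extract_rheometry_features",
    "extract_pasting_features",
    "extract_tpa_features",
]


class CurveError(ValueError):
    """A trace violates the preconditions of an extractor."""


class NoGelPointError(CurveError):
    """tan(delta) never crosses 1 on the heating ramp."""


class NoCompressionPeaksError(CurveError):
    """A TPA trace does not contain two positive compression lobes."""


@dataclass(frozen=True)
class CurveConfig:
    """Tunable thresholds of the landmark detectors.

    Parameters
    ----------
    smoothing_window:
        Width (samples) of the centered moving-average filter applied to
        moduli / viscosity / force before landmark detection. ``1`` disables
        smoothing; use an odd width (default 5) for noisy instrument traces.
    level_off_eps:
        |dG''/dt| threshold (kPa/min) below which the loss modulus is
        considered to have levelled off after its maximum; end point of S4.
    ptemp_rate:
        dV/dt threshold (viscosity units/min) whose first exceedance defines
        the pasting temperature.
    tpa_force_floor:
        Force level (kg) separating "in contact" from baseline when
        segmenting TPA compression lobes.
    gmax_scope:
        Where the G'' maximum is searched for: ``"global"`` over the whole
        sweep or ``"heating"`` restricted to the heating ramp.
    """

    smoothing_window: int = 5
    level_off_eps: float = 0.05
    ptemp_rate: float = 0.10
    tpa_force_floor: float = 0.0
    gmax_scope: str = "global"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.level_off_eps <= 0 or self.ptemp_rate <= 0:
            raise ValueError("thresholds must be positive")
        if self.gmax_scope not in ("global", "heating"):
            raise ValueError("gmax_scope must be 'global' or 'heating'")


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise CurveError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(a)):
        raise CurveError(f"{name} contains non-finite values")
    return a


def _check_time(t: np.ndarray) -> None:
    if np.any(np.diff(t) <= 0):
        raise CurveError("time must be strictly increasing")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window 1 = identity)."""
    if window <= 1 or y.size < window:
        return y
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    # fix edges where the kernel hangs over: renormalise by actual coverage
    cover = np.convolve(np.ones_like(y), kernel, mode="same")
    return out / cover


@dataclass(frozen=True)
class RheoCurve:
    """Oscillatory-rheometry trace over a heating then cooling ramp."""

    time_min: np.ndarray
    temp_C: np.ndarray
    g_prime_kPa: np.ndarray
    g_double_prime_kPa: np.ndarray

    def __post_init__(self) -> None:
        t = _as_array(self.time_min, "time_min")
        temp = _as_array(self.temp_C, "temp_C")
        gp = _as_array(self.g_prime_kPa, "g_prime_kPa")
        gpp = _as_array(self.g_double_prime_kPa, "g_double_prime_kPa")
        if not (t.size == temp.size == gp.size == gpp.size):
            raise CurveError("all channels must have equal length")
        _check_time(t)
        if np.any(gp < 0) or np.any(gpp < 0):
            raise CurveError("moduli must be non-negative")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "temp_C", temp)
        object.__setattr__(self, "g_prime_kPa", gp)
        object.__setattr__(self, "g_double_prime_kPa", gpp)

    @property
    def heating_end_index(self) -> int:
        """Last index of the heating ramp (temperature maximum)."""
        return int(np.argmax(self.temp_C))


@dataclass(frozen=True)
class RVACurve:
    """RVA pasting trace over a heat-hold-cool profile."""

    time_min: np.ndarray
    temp_C: np.ndarray
    viscosity: np.ndarray
    viscosity_unit: str = "instrument"

    def __post_init__(self) -> None:
        t = _as_array(self.time_min, "time_min")
        temp = _as_array(self.temp_C, "temp_C")
        v = _as_array(self.viscosity, "viscosity")
        if not (t.size == temp.size == v.size):
            raise CurveError("all channels must have equal length")
        _check_time(t)
        if np.any(v < 0):
            raise CurveError("viscosity must be non-negative")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "temp_C", temp)
        object.__setattr__(self, "viscosity", v)

    @property
    def cooling_start_index(self) -> int:
        """First index at which cooling begins (end of heat+hold stages)."""
        temp = self.temp_C
        tmax = temp.max()
        # hold stage sits at the maximum temperature; cooling starts after
        # the last sample within 0.5 degC of the plateau
        at_top = np.nonzero(temp >= tmax - 0.5)[0]
        return int(at_top[-1])


@dataclass(frozen=True)
class TPACurve:
    """Two-compression texture-profile trace (positive force = compression)."""

    time_s: np.ndarray
    force_kg: np.ndarray

    def __post_init__(self) -> None:
        t = _as_array(self.time_s, "time_s")
        f = _as_array(self.force_kg, "force_kg")
        if t.size != f.size:
            raise CurveError("time and force must have equal length")
        _check_time(t)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_kg", f)


@dataclass(frozen=True)
class RheometryFeatures:
    """Scalar landmarks of a viscoelastic sweep.

    Slopes are stored signed; ``to_dict(magnitudes=True)`` reports |S2|,
    |S4| the way the study tables do (the sign only encodes direction).
    """

    gel_temp: float
    gel_time: float
    Gmax: float
    Gpp_at_Gmax: float
    tand_at_Gmax: float
    temp_at_Gmax: float
    Gtrough: float | None
    S1: float
    S2: float | None
    S3: float
    S4: float | None
    no_trough: bool = False

    def to_dict(self, magnitudes: bool = True) -> dict[str, float | None]:
        d = {
            "temp_gel": self.gel_temp,
            "Gmax": self.Gmax,
            "Gpp_at_Gmax": self.Gpp_at_Gmax,
            "tand_at_Gmax": self.tand_at_Gmax,
            "temp_Gmax": self.temp_at_Gmax,
            "Gtrough": self.Gtrough,
            "S1": self.S1,
            "S2": self.S2,
            "S3": self.S3,
            "S4": self.S4,
        }
        if magnitudes:
            for k in ("S2", "S4"):
                if d[k] is not None:
                    d[k] = abs(d[k])
        return d


@dataclass(frozen=True)
class PastingFeatures:
    """RVA pasting parameters; BD/SB/LO are exact identities of PV/TV/FV."""

    PV: float
    TV: float
    FV: float
    PT: float
    PTemp: float | None
    viscosity_unit: str = "instrument"
    no_trough: bool = False

    @property
    def BD(self) -> float:
        return self.PV - self.TV

    @property
    def SB(self) -> float:
        return self.FV - self.PV

    @property
    def LO(self) -> float:
        return self.FV - self.TV

    def to_dict(self) -> dict[str, float | None]:
        return {
            "PV": self.PV,
            "TV": self.TV,
            "BD": self.BD,
            "FV": self.FV,
            "SB": self.SB,
            "LO": self.LO,
            "PT": self.PT,
            "PTemp": self.PTemp,
        }


@dataclass(frozen=True)
class TPAFeatures:
    """Two-compression texture attributes.

    ADH is stored as a magnitude; ``adh_is_magnitude`` records the
    convention (the pull-off work is directionally negative).
    """

    HRD: float
    ADH: float
    COH: float
    SPR: float
    T1: float
    T2: float
    adh_is_magnitude: bool = True

    def to_dict(self) -> dict[str, float]:
        return {"HRD": self.HRD, "ADH": self.ADH, "COH": self.COH, "SPR": self.SPR}


def _interp_crossing(t0, t1, y0, y1):
    """Time at which the line through (t0,y0),(t1,y1) crosses zero."""
    return t0 + (t1 - t0) * (-y0) / (y1 - y0)


def extract_rheometry_features(
    curve: RheoCurve, config: CurveConfig = CurveConfig()
) -> RheometryFeatures:
    """Extract gel point, modulus extrema and the four slope features.

    The gel point is the first crossing of tan(delta) = G''/G' through 1 on
    the heating ramp, located by linear interpolation between the bracketing
    samples.  G'max and G''max are trace maxima (earliest sample on ties);
    G'trough is the G' minimum after G'max.  S1 (S3) is the mean rate of
    change of G' (G'') from the gel point to its maximum; S2 runs from G'max
    down to G'trough; S4 from G''max to the first sample where |dG''/dt|
    drops below ``config.level_off_eps``.

    Raises
    ------
    NoGelPointError
        if tan(delta) - 1 never changes sign on the heating ramp (including
        the degenerate G' == G'' trace).
    """
    if curve.time_min.size < 20:
        raise CurveError("rheometry trace needs at least 20 samples")
    t = curve.time_min
    gp = _smooth(curve.g_prime_kPa, config.smoothing_window)
    gpp = _smooth(curve.g_double_prime_kPa, config.smoothing_window)

    heat_end = curve.heating_end_index
    if heat_end == 0 or heat_end == t.size - 1:
        raise CurveError("trace must contain both a heating and a cooling ramp")

    # --- gel point: first strict sign change of tan(delta)-1 while heating
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(gp > 0, gpp / gp, np.inf) - 1.0
    cross = None
    for i in range(heat_end):
        if excess[i] == 0.0 and excess[i + 1] != 0.0:
            cross = (i, t[i])
            break
        if excess[i] * excess[i + 1] < 0:
            tc = _interp_crossing(t[i], t[i + 1], excess[i], excess[i + 1])
            cross = (i, tc)
            break
    if cross is None:
        raise NoGelPointError("no gel point: tan(delta) never crosses 1 on heating")
    i_gel, t_gel = cross
    frac = (t_gel - t[i_gel]) / (t[i_gel + 1] - t[i_gel])
    gel_temp = curve.temp_C[i_gel] + frac * (curve.temp_C[i_gel + 1] - curve.temp_C[i_gel])
    gp_gel = gp[i_gel] + frac * (gp[i_gel + 1] - gp[i_gel])
    gpp_gel = gpp[i_gel] + frac * (gpp[i_gel + 1] - gpp[i_gel])

    # --- modulus extrema (earliest index on ties)
    i_gmax = int(np.argmax(gp))
    gmax = float(gp[i_gmax])
    if config.gmax_scope == "heating":
        i_gppmax = int(np.argmax(gpp[: heat_end + 1]))
    else:
        i_gppmax = int(np.argmax(gpp))
    gppmax = float(gpp[i_gppmax])

    gpp_at_gmax = float(gpp[i_gmax])
    tand_at_gmax = gpp_at_gmax / gmax
    temp_at_gmax = float(curve.temp_C[i_gmax])

    # --- trough of G' after its maximum
    no_trough = i_gmax == t.size - 1
    if no_trough:
        gtrough = None
        s2 = None
    else:
        tail = gp[i_gmax + 1 :]
        i_tr = i_gmax + 1 + int(np.argmin(tail))
        gtrough = float(gp[i_tr])
        s2 = (gtrough - gmax) / (t[i_tr] - t[i_gmax])

    # --- slopes from the gel point
    s1 = (gmax - gp_gel) / (t[i_gmax] - t_gel)
    s3 = (gppmax - gpp_gel) / (t[i_gppmax] - t_gel)

    # --- S4: G''max to the level-off point
    dgpp = np.gradient(gpp, t)
    s4 = None
    level = np.nonzero(np.abs(dgpp[i_gppmax + 1 :]) < config.level_off_eps)[0]
    if level.size:
        i_lo = i_gppmax + 1 + int(level[0])
        if t[i_lo] > t[i_gppmax]:
            s4 = (gpp[i_lo] - gppmax) / (t[i_lo] - t[i_gppmax])

    return RheometryFeatures(
        gel_temp=float(gel_temp),
        gel_time=float(t_gel),
        Gmax=gmax,
        Gpp_at_Gmax=gpp_at_gmax,
        tand_at_Gmax=tand_at_gmax,
        temp_at_Gmax=temp_at_gmax,
        Gtrough=gtrough,
        S1=float(s1),
        S2=None if s2 is None else float(s2),
        S3=float(s3),
        S4=None if s4 is None else float(s4),
        no_trough=no_trough,
    )


def extract_pasting_features(
    curve: RVACurve, config: CurveConfig = CurveConfig()
) -> PastingFeatures:
    """Extract PV/TV/FV (and hence BD/SB/LO), peak time and pasting temperature.

    PV is the maximum viscosity over the heating and holding stages (earliest
    sample on ties), TV the minimum after the peak, FV the final sample.
    PTemp is the temperature at the first sample where dV/dt exceeds
    ``config.ptemp_rate``; absent if the rate is never exceeded.
    """
    t = curve.time_min
    v = _smooth(curve.viscosity, config.smoothing_window)
    i_cool = curve.cooling_start_index

    i_pv = int(np.argmax(v[: i_cool + 1]))
    pv = float(v[i_pv])
    pt = float(t[i_pv])

    no_trough = i_pv == t.size - 1
    if no_trough:
        tv = float(v[-1])
    else:
        tv = float(np.min(v[i_pv:]))
    fv = float(v[-1])

    dv = np.gradient(v, t)
    exceeds = np.nonzero(dv > config.ptemp_rate)[0]
    ptemp = float(curve.temp_C[exceeds[0]]) if exceeds.size else None

    return PastingFeatures(
        PV=pv, TV=tv, FV=fv, PT=pt, PTemp=ptemp,
        viscosity_unit=curve.viscosity_unit, no_trough=no_trough,
    )


def _positive_lobes(t: np.ndarray, f: np.ndarray, floor: float):
    """Contiguous runs where force exceeds ``floor``; returns index slices."""
    above = f > floor
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(f.size)
    return [slice(s, e) for s, e in zip(starts, ends) if e - s >= 2]


def extract_tpa_features(
    curve: TPACurve, config: CurveConfig = CurveConfig()
) -> TPAFeatures:
    """Extract hardness, adhesiveness, cohesiveness and springiness.

    HRD is the peak force of the first positive lobe; ADH the magnitude of
    the trapezoidal area of the negative lobe between the two compressions;
    COH the area ratio lobe2/lobe1; SPR the ratio T2/T1 of downstroke
    durations (lobe start to lobe peak), distance and time being
    proportional at constant probe speed.

    Raises
    ------
    NoCompressionPeaksError
        if fewer than two positive lobes are present.
    """
    t = curve.time_s
    f = _smooth(curve.force_kg, config.smoothing_window)

    lobes = _positive_lobes(t, f, config.tpa_force_floor)
    if len(lobes) < 2:
        raise NoCompressionPeaksError("no compression peaks: need two positive lobes")
    lobe1, lobe2 = lobes[0], lobes[-1]

    def lobe_area(sl: slice) -> float:
        return float(np.trapezoid(np.clip(f[sl], 0, None), t[sl]))

    a1 = lobe_area(lobe1)
    a2 = lobe_area(lobe2)
    if a1 <= 0:
        raise CurveError("COH undefined: first compression lobe has zero area")

    i_pk1 = lobe1.start + int(np.argmax(f[lobe1]))
    i_pk2 = lobe2.start + int(np.argmax(f[lobe2]))
    hrd = float(f[i_pk1])

    # negative lobe between the first upstroke and the second compression
    mid = f[lobe1.stop : lobe2.start]
    tmid = t[lobe1.stop : lobe2.start]
    neg = mid < 0
    adh = 0.0
    if np.any(neg):
        adh = float(abs(np.trapezoid(np.where(neg, mid, 0.0), tmid)))

    t1 = float(t[i_pk1] - t[lobe1.start])
    t2 = float(t[i_pk2] - t[lobe2.start])
    if t1 <= 0:
        raise CurveError("degenerate first downstroke (T1 = 0)")

    return TPAFeatures(HRD=hrd, ADH=adh, COH=a2 / a1, SPR=t2 / t1, T1=t1, T2=t2)
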