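"""Tensile mechanics analysis: stress-strain curves and scalar summaries.

Turns per-step force logs and strain series into the quantities a tensile
test reports: the stress-strain curve (sigma = F/A, with 1 uN/um^2 = 1 MPa
exactly), the linear-region Young's modulus E = d sigma / d eps, the rupture
step and ultimate stress, the onset of plastic yielding, windowed creep
rates, and a slippage diagnosis comparing the grip and landmark strain
pathways.

Strain is a percentage at every external surface and a fraction internally.
The initial cross-sectional area is used throughout (constant-area
convention).  Analysis warns when the selected linear region extends beyond
20 % strain — past that the tissue is outside the range cell walls normally
experience and the linear approximation is suspect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError
from .specimen import SpecimenGeometry, cross_section_area
from .tracking import StrainSeries

__all__ = [
    "StressStrainCurve",
    "MechanicalSummary",
    "CreepProfile",
    "SlippageReport",
    "stress_series",
    "select_linear_region",
    "youngs_modulus",
    "detect_rupture",
    "ultimate_stress",
    "yield_onset",
    "creep_rates",
    "slippage_diagnosis",
    "summarize",
]

#: Strain (%) beyond which the linear-region choice triggers a warning.
STRAIN_CAP_PCT = 20.0


def stress_series(forces_uN, geom: SpecimenGeometry) -> np.ndarray:
    """Engineering stress in MPa: force over initial cross-section.

    With forces in uN and areas in um^2 the ratio is exactly MPa.
    """
    area = cross_section_area(geom)
    if area <= 0:
        raise ConfigError("cross-sectional area must be > 0")
    return np.asarray(forces_uN, dtype=float) / area


@dataclass(frozen=True)
class StressStrainCurve:
    """Per-step stress (MPa) against strain (%), landmark-based by default."""

    stress_MPa: np.ndarray
    strain_pct: np.ndarray

    def __post_init__(self):
        if len(self.stress_MPa) != len(self.strain_pct):
            raise ConfigError("stress and strain series must have equal length")

    def __len__(self) -> int:
        return len(self.stress_MPa)


def _fit_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of the least-squares line; 0 for (near-)constant y."""
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-300:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    ssr = float(np.sum((y - (slope * x + intercept)) ** 2))
    return 1.0 - ssr / sst


def select_linear_region(curve: StressStrainCurve,
                         span_steps: int = 50) -> tuple[int, int]:
    """Most-linear contiguous window ``(start, end)`` (inclusive indices).

    Among all windows of ``span_steps`` points, the one maximising the
    linear-fit R^2 wins; ties break to the earliest start.  Windows touching
    a rupture-scale force collapse (a drop of more than half the running
    maximum) are excluded so the region ends before terminal softening; the
    initial toe, where the curve is still settling, loses naturally on R^2.
    """
    n = len(curve)
    if span_steps < 2:
        raise ConfigError("span must be at least 2 steps")
    if n < span_steps:
        raise ConfigError(f"curve has {n} points, fewer than span {span_steps}")

    drop = detect_rupture(curve.stress_MPa, drop_frac=0.5)
    last_end = n - 1 if drop is None else drop - 1

    best: tuple[int, int] | None = None
    best_r2 = -np.inf
    for start in range(0, last_end - span_steps + 2):
        end = start + span_steps - 1
        x = curve.strain_pct[start:end + 1]
        y = curve.stress_MPa[start:end + 1]
        r2 = _fit_r2(x, y)
        if r2 > best_r2 + 1e-12:
            best_r2 = r2
            best = (start, end)
    if best is None:
        raise ConfigError("no admissible window before the force collapse")

    if curve.strain_pct[best[1]] > STRAIN_CAP_PCT:
        warnings.warn(
            f"linear region extends to {curve.strain_pct[best[1]]:.1f}% strain, "
            f"beyond the {STRAIN_CAP_PCT:.0f}% guidance for elastic analysis",
            stacklevel=2,
        )
    return best


def youngs_modulus(curve: StressStrainCurve, region: tuple[int, int],
                   method: str = "endpoints") -> float:
    """E in MPa over the selected region.

    The default matches the two-point convention E = Delta sigma / Delta eps
    between the region endpoints (strain as a fraction); ``method="least_squares"``
    fits a line through all points of the region instead.
    """
    start, end = region
    if not (0 <= start < end < len(curve)):
        raise ConfigError("region out of curve bounds")
    d_eps = (curve.strain_pct[end] - curve.strain_pct[start]) / 100.0
    if method == "endpoints":
        if d_eps == 0:
            raise ConfigError("zero strain increment over the region")
        return float((curve.stress_MPa[end] - curve.stress_MPa[start]) / d_eps)
    if method == "least_squares":
        x = curve.strain_pct[start:end + 1] / 100.0
        if np.ptp(x) == 0:
            raise ConfigError("zero strain increment over the region")
        slope, _ = np.polyfit(x, curve.stress_MPa[start:end + 1], 1)
        return float(slope)
    raise ConfigError(f"unknown method {method!r}")


def detect_rupture(forces, drop_frac: float = 0.5) -> Optional[int]:
    """Index of the first sudden force drop, or None.

    A rupture is the first step whose force has fallen by at least
    ``drop_frac`` relative to the running maximum of the preceding steps.
    """
    f = np.asarray(forces, dtype=float)
    if f.size < 2:
        return None
    running_max = np.maximum.accumulate(f)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        dropped = f[1:] <= (1.0 - drop_frac) * running_max
    dropped &= running_max > 0
    idx = np.nonzero(dropped)[0]
    return int(idx[0] + 1) if idx.size else None


def ultimate_stress(forces_uN, geom: SpecimenGeometry,
                    drop_frac: float = 0.5,
                    run_to_break: bool = False) -> Optional[float]:
    """Peak stress (MPa) before the detected rupture drop.

    Returns None when no rupture is detected and the run was not flagged as
    run-to-break; with ``run_to_break`` the overall maximum is reported.
    """
    f = np.asarray(forces_uN, dtype=float)
    if f.size == 0 or not np.any(f > 0):
        return None
    rupture = detect_rupture(f, drop_frac=drop_frac)
    if rupture is None and not run_to_break:
        return None
    peak = f.max() if rupture is None else f[:rupture].max()
    return float(stress_series([peak], geom)[0])


@dataclass(frozen=True)
class YieldOnset:
    step: int
    stress_MPa: float


def yield_onset(curve: StressStrainCurve, region: tuple[int, int],
                tolerance_frac: float = 0.05) -> Optional[YieldOnset]:
    """First post-region step falling below the extrapolated elastic line.

    The linear region is fitted by least squares and extrapolated forward;
    the onset of plastic deformation is the first later step whose stress
    deviates below the prediction by more than ``tolerance_frac`` (relative).
    A tolerance of 0 flags the first numerical wiggle — degenerate but
    well-defined.  Returns None when the curve never deviates.
    """
    start, end = region
    x = curve.strain_pct[start:end + 1]
    y = curve.stress_MPa[start:end + 1]
    slope, intercept = np.polyfit(x, y, 1)
    for i in range(end + 1, len(curve)):
        predicted = slope * curve.strain_pct[i] + intercept
        if predicted <= 0:
            continue
        if (predicted - curve.stress_MPa[i]) / predicted > tolerance_frac:
            return YieldOnset(step=i, stress_MPa=float(curve.stress_MPa[i]))
    return None


@dataclass(frozen=True)
class CreepProfile:
    """Windowed displacement rates for the two pathways (um/s).

    Windows are non-overlapping, anchored at the start of the record, each
    ``window_s`` long; a trailing partial window is dropped.
    """

    window_s: float
    window_start_s: np.ndarray
    landmark_rate_um_per_s: np.ndarray
    grip_rate_um_per_s: np.ndarray


def creep_rates(times_s, landmark_um, grip_um, window_s: float = 300.0) -> CreepProfile:
    """Mean displacement rate per window: (end - start) / window.

    Positions at window boundaries are linearly interpolated from the
    sampled series.
    """
    if window_s <= 0:
        raise ConfigError("window must be > 0")
    t = np.asarray(times_s, dtype=float)
    lm = np.asarray(landmark_um, dtype=float)
    gp = np.asarray(grip_um, dtype=float)
    duration = t[-1] - t[0]
    n_windows = int(duration // window_s)
    if n_windows < 1:
        raise ConfigError("record shorter than one window")
    edges = t[0] + window_s * np.arange(n_windows + 1)
    lm_edges = np.interp(edges, t, lm)
    gp_edges = np.interp(edges, t, gp)
    return CreepProfile(
        window_s=window_s,
        window_start_s=edges[:-1] - t[0],
        landmark_rate_um_per_s=np.diff(lm_edges) / window_s,
        grip_rate_um_per_s=np.diff(gp_edges) / window_s,
    )


@dataclass(frozen=True)
class SlippageReport:
    slip_pct: np.ndarray
    verdict: str  # "slip-dominated" | "none"
    inconsistent: bool = False


def slippage_diagnosis(series: StrainSeries,
                       noise_tolerance_pp: float = 0.5) -> SlippageReport:
    """Per-step slip strain and a verdict on who absorbed the displacement.

    The verdict is "slip-dominated" when, at the end of the evaluated span,
    more of the imposed strain went into slip than into the tissue.  Slip
    more negative than the noise tolerance anywhere flags the two pathways
    as mutually inconsistent (tracking error or wrong reference length).
    """
    slip = series.slip_pct
    inconsistent = bool(np.any(slip < -noise_tolerance_pp))
    if inconsistent:
        warnings.warn(
            "negative slip strain beyond noise tolerance: grip and landmark "
            "pathways are inconsistent",
            stacklevel=2,
        )
    verdict = "slip-dominated" if slip[-1] > series.landmark_pct[-1] else "none"
    return SlippageReport(slip_pct=slip, verdict=verdict, inconsistent=inconsistent)


@dataclass(frozen=True)
class MechanicalSummary:
    """Scalar results of one tensile run."""

    youngs_modulus_MPa: float
    linear_region: tuple[int, int]
    ultimate_stress_MPa: Optional[float]
    rupture_step: Optional[int]
    yield_onset_step: Optional[int]
    yield_stress_MPa: Optional[float]
    slip_verdict: Optional[str] = None


def summarize(forces_uN, strain_pct, geom: SpecimenGeometry,
              span_steps: int = 50, series: StrainSeries | None = None,
              yield_tolerance_frac: float = 0.05,
              run_to_break: bool = False) -> MechanicalSummary:
    """One-call pipeline from a force log + strain series to the summary."""
    curve = StressStrainCurve(
        stress_MPa=stress_series(forces_uN, geom),
        strain_pct=np.asarray(strain_pct, dtype=float),
    )
    region = select_linear_region(curve, span_steps=span_steps)
    e_mod = youngs_modulus(curve, region)
    rupture = detect_rupture(forces_uN)
    ult = ultimate_stress(forces_uN, geom, run_to_break=run_to_break)
    onset = yield_onset(curve, region, tolerance_frac=yield_tolerance_frac)
    verdict = None
    if series is not None:
        verdict = slippage_diagnosis(series).verdict
    return MechanicalSummary(
        youngs_modulus_MPa=e_mod,
        linear_region=region,
        ultimate_stress_MPa=ult,
        rupture_step=rupture,
        yield_onset_step=None if onset is None else onset.step,
        yield_stress_MPa=None if onset is None else onset.stress_MPa,
        slip_verdict=verdict,
    )
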