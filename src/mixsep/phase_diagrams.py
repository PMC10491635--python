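"""Binodals and two-component phase boundaries.

Single-axis binodals record, per temperature, the replicate-averaged dilute
and dense concentrations (total and per species).  Fixed-temperature
two-component boundaries record per stoichiometric mixing fraction ``a``
(molecule fraction of component A) the per-species dilute- and dense-phase
volume fractions.  The dilute arm is classified against the additivity line

    c_dilute = a * c_sat_A + (1 - a) * c_sat_B,

whose endpoints are the single-species saturation concentrations: points
below the line (concave arm) mean heterotypic interactions enhance phase
separation, points above (convex) mean they weaken it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .condensate_geometry import (
    find_condensate,
    fit_logistic,
    phase_concentrations,
    radial_density,
)
from .lattice_engine import Trajectory

__all__ = [
    "PhasePoint",
    "TwoComponentBoundary",
    "ArmShape",
    "replicate_concentrations",
    "build_binodal",
    "additivity_line",
    "classify_arm_shape",
]


@dataclass
class PhasePoint:
    """Replicate-averaged coexistence concentrations at one temperature."""

    temperature: float
    c_dilute: dict[str, float]
    c_dense: dict[str, float]
    c_dilute_se: dict[str, float]
    c_dense_se: dict[str, float]
    n_replicates: int

    @property
    def total_dilute(self) -> float:
        return sum(self.c_dilute.values())

    @property
    def total_dense(self) -> float:
        return sum(self.c_dense.values())


def replicate_concentrations(
    traj: Trajectory, min_fraction: float = 0.5
) -> dict[str, tuple[float, float]] | None:
    """Frame-averaged (c_dilute, c_dense) per species for one replicate.

    Frames without a condensate, or whose total-density logistic fit is
    flagged, are skipped; returns None when no frame is usable (the
    replicate carries a no-two-phase flag).
    """
    names = traj.system.species_names
    acc: dict[str, list[tuple[float, float]]] = {n: [] for n in names}
    for i in range(len(traj.frames)):
        state = traj.state_at(i)
        cond = find_condensate(state, min_fraction=min_fraction)
        if not cond.is_condensate:
            continue
        profile = radial_density(state, cond.center)
        fit = fit_logistic(profile)
        if fit.flagged:
            continue
        try:
            for name in names:
                acc[name].append(phase_concentrations(profile, fit, name))
        except ValueError:
            continue
    if not acc[names[0]]:
        return None
    return {
        name: (
            float(np.mean([p[0] for p in acc[name]])),
            float(np.mean([p[1] for p in acc[name]])),
        )
        for name in names
    }


def build_binodal(
    trajectories: dict[float, list[Trajectory]],
    min_fraction: float = 0.5,
) -> list[PhasePoint]:
    """Assemble a binodal from replicate trajectories per temperature.

    Per temperature, phase concentrations are averaged over replicates with
    standard errors about the mean; temperatures where every replicate is
    flagged as single-phase are omitted with a warning, so the binodal
    terminates where two-phase coexistence is lost.
    """
    points: list[PhasePoint] = []
    for T in sorted(trajectories):
        reps = [
            r
            for r in (
                replicate_concentrations(t, min_fraction)
                for t in trajectories[T]
            )
            if r is not None
        ]
        if not reps:
            warnings.warn(
                f"no two-phase replicate at T={T}; binodal point omitted"
            )
            continue
        names = list(reps[0])
        n = len(reps)

        def stats(idx):
            mean, se = {}, {}
            for name in names:
                vals = np.array([r[name][idx] for r in reps])
                mean[name] = float(vals.mean())
                se[name] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            return mean, se

        dil, dil_se = stats(0)
        den, den_se = stats(1)
        points.append(
            PhasePoint(
                temperature=T,
                c_dilute=dil,
                c_dense=den,
                c_dilute_se=dil_se,
                c_dense_se=den_se,
                n_replicates=n,
            )
        )
    return points


def additivity_line(c_sat_A: float, c_sat_B: float, a: float) -> float:
    """Additive expectation c_dilute = a*c_sat_A + (1-a)*c_sat_B."""
    if c_sat_A <= 0 or c_sat_B <= 0:
        raise ValueError("saturation concentrations must be positive")
    if not 0 <= a <= 1:
        raise ValueError("mixing fraction a must lie in [0, 1]")
    return a * c_sat_A + (1 - a) * c_sat_B


@dataclass
class TwoComponentBoundary:
    """Dilute (and optionally dense) arm at fixed temperature.

    ``points`` holds rows (a, c_dil_A, c_dil_B, err_A, err_B, c_den_A,
    c_den_B); ``a`` is the stoichiometric molecule fraction of component A,
    strictly ordered across the list.  Endpoints a=1 and a=0 give the
    single-species saturation concentrations.
    """

    temperature: float
    a: np.ndarray
    c_dilute_A: np.ndarray
    c_dilute_B: np.ndarray
    err_A: np.ndarray | None = None
    err_B: np.ndarray | None = None
    c_dense_A: np.ndarray | None = None
    c_dense_B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if not (np.diff(self.a) > 0).all():
            raise ValueError("stoichiometric fractions must strictly increase")
        if ((self.a < 0) | (self.a > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def c_sat_A(self) -> float:
        if self.a[-1] != 1.0:
            raise ValueError("boundary lacks the a=1 endpoint (pure A)")
        return float(self.c_dilute_A[-1])

    @property
    def c_sat_B(self) -> float:
        if self.a[0] != 0.0:
            raise ValueError("boundary lacks the a=0 endpoint (pure B)")
        return float(self.c_dilute_B[0])


@dataclass
class ArmShape:
    classification: str  # concave | convex | linear
    mean_deviation: float
    deviation_se: float
    deviations: np.ndarray
    signed_area: float


def classify_arm_shape(
    boundary: TwoComponentBoundary, linear_z: float = 1.0
) -> ArmShape:
    """Classify the dilute arm against the additivity chord.

    For each interior stoichiometry the signed deviation is the total
    dilute concentration minus the additivity-line prediction at the same
    stoichiometric fraction (measured along the total-concentration
    direction).  The classification follows the error-weighted mean
    deviation: below the chord = concave (heterotypic enhancement), above
    = convex, and 'linear' when the mean deviation is smaller than
    ``linear_z`` times its standard error (a configurable significance
    threshold, like the tie-line consistency z).  The signed-area statistic
    (trapezoidal integral of deviation over a) is a package metric, not a
    literature quantity.
    """
    c_sat_A = boundary.c_sat_A  # raises if endpoints missing
    c_sat_B = boundary.c_sat_B
    interior = (boundary.a > 0) & (boundary.a < 1)
    if interior.sum() < 1:
        raise ValueError("need at least one interior stoichiometry")
    a = boundary.a[interior]
    total = boundary.c_dilute_A[interior] + boundary.c_dilute_B[interior]
    predicted = np.array([additivity_line(c_sat_A, c_sat_B, x) for x in a])
    dev = total - predicted
    if boundary.err_A is not None and boundary.err_B is not None:
        var = (
            np.asarray(boundary.err_A)[interior] ** 2
            + np.asarray(boundary.err_B)[interior] ** 2
        )
        w = 1.0 / np.maximum(var, 1e-30)
        mean_dev = float(np.sum(w * dev) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    else:
        mean_dev = float(dev.mean())
        se = (
            float(dev.std(ddof=1) / np.sqrt(len(dev)))
            if len(dev) > 1
            else abs(mean_dev)  # single point without errors: undecidable
        )
    area = float(np.trapezoid(dev, a)) if len(a) > 1 else float(dev[0])
    if abs(mean_dev) < linear_z * se:
        cls = "linear"
    elif mean_dev < 0:
        cls = "concave"
    else:
        cls = "convex"
    return ArmShape(
        classification=cls,
        mean_deviation=mean_dev,
        deviation_se=se,
        deviations=dev,
        signed_area=area,
    )
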