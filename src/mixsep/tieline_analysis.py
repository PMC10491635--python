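"""Tie-line construction and interpretation in the (c_A, c_B) plane.

A tie line joins the three points (c_dilute, c_tot, c_dense) for one
mixture: if the system forms precisely two coexisting phases the three
points are collinear, so the slope of the dilute-to-total segment matches
the slope of the total-to-dense segment.  The slope carries the physics:
a consistent slope near 1 means heterotypic interactions dominate (both
components change equally across the phase boundary); a slope below 1
means component A (abscissa) changes more, i.e. homotypic A interactions
dominate, and a slope above 1 points to component B.  The analysis is
unit-agnostic: volume fractions from simulations and mg/mL from
experimental tables are handled identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TieLine",
    "fit_tieline",
    "slope_consistency",
    "interpret_slope",
    "read_tieline_table",
    "tielines_from_table",
]

_Point = tuple[float, float]


@dataclass
class TieLine:
    """Two-segment tie line through (c_dilute, c_tot, c_dense)."""

    c_dilute: _Point
    c_tot: _Point
    c_dense: _Point
    slope_low: float  # dilute -> total
    slope_high: float  # total -> dense
    slope_low_err: float
    slope_high_err: float
    vertical_low: bool = False
    vertical_high: bool = False

    @property
    def slope_whole(self) -> float:
        """Slope of the dilute -> dense segment (the whole tie line)."""
        dx = self.c_dense[0] - self.c_dilute[0]
        dy = self.c_dense[1] - self.c_dilute[1]
        return dy / dx

    def swapped_axes(self) -> "TieLine":
        """The same tie line with components A and B exchanged."""

        def flip(p):
            return (p[1], p[0])

        def inv_err(s, e):
            # first-order propagation of err through s -> 1/s
            return e / (s * s) if s != 0 else math.inf

        return TieLine(
            c_dilute=flip(self.c_dilute),
            c_tot=flip(self.c_tot),
            c_dense=flip(self.c_dense),
            slope_low=1.0 / self.slope_low if self.slope_low != 0 else math.inf,
            slope_high=1.0 / self.slope_high if self.slope_high != 0 else math.inf,
            slope_low_err=inv_err(self.slope_low, self.slope_low_err),
            slope_high_err=inv_err(self.slope_high, self.slope_high_err),
            vertical_low=self.slope_low == 0,
            vertical_high=self.slope_high == 0,
        )


def _segment_slope(
    p: _Point, q: _Point, p_err: _Point, q_err: _Point
) -> tuple[float, float, bool]:
    dx = q[0] - p[0]
    dy = q[1] - p[1]
    scale = max(abs(p[0]), abs(q[0]), abs(p[1]), abs(q[1]), 1e-30)
    if abs(dx) < 1e-12 * scale:
        return math.inf, math.inf, True
    s = dy / dx
    var = (p_err[1] ** 2 + q_err[1] ** 2) / dx**2 + s**2 * (
        p_err[0] ** 2 + q_err[0] ** 2
    ) / dx**2
    return s, math.sqrt(var), False


def fit_tieline(
    c_dilute: _Point,
    c_tot: _Point,
    c_dense: _Point,
    errors: dict[str, _Point] | None = None,
) -> TieLine:
    """Build a tie line from the three coexistence points.

    Component A lies on the abscissa and B on the ordinate (slope values
    are tied to this axis choice).  ``errors`` maps 'dilute'/'tot'/'dense'
    to (err_A, err_B) replicate standard errors; slope uncertainties follow
    by first-order propagation.  Slopes come from the point pairs, not a
    regression: the dilute-to-total and total-to-dense segments are kept
    separate so their consistency can be tested.
    """
    pts = {"dilute": c_dilute, "tot": c_tot, "dense": c_dense}
    errors = errors or {}
    errs = {k: tuple(errors.get(k, (0.0, 0.0))) for k in pts}
    vals = list(pts.values())
    scale = max(abs(v) for p in vals for v in p)
    for i in range(3):
        for j in range(i + 1, 3):
            if (
                abs(vals[i][0] - vals[j][0]) < 1e-12 * max(scale, 1e-30)
                and abs(vals[i][1] - vals[j][1]) < 1e-12 * max(scale, 1e-30)
            ):
                raise ValueError("coincident points: degenerate tie line")
    s_lo, e_lo, v_lo = _segment_slope(
        c_dilute, c_tot, errs["dilute"], errs["tot"]
    )
    s_hi, e_hi, v_hi = _segment_slope(
        c_tot, c_dense, errs["tot"], errs["dense"]
    )
    return TieLine(
        c_dilute=tuple(c_dilute),
        c_tot=tuple(c_tot),
        c_dense=tuple(c_dense),
        slope_low=s_lo,
        slope_high=s_hi,
        slope_low_err=e_lo,
        slope_high_err=e_hi,
        vertical_low=v_lo,
        vertical_high=v_hi,
    )


def slope_consistency(
    tie: TieLine, threshold: float = 2.0
) -> tuple[bool, float]:
    """Two-segment z-test: are the two slopes statistically identical?

    z = |slope_low - slope_high| / sqrt(err_low^2 + err_high^2); consistent
    when z < threshold (default 2).  With zero uncertainties, exactly equal
    slopes give z = 0 and unequal slopes z = inf.  Undefined when either
    segment is vertical.
    """
    if tie.vertical_low or tie.vertical_high:
        raise ValueError("slope consistency undefined for a vertical segment")
    diff = abs(tie.slope_low - tie.slope_high)
    sigma = math.hypot(tie.slope_low_err, tie.slope_high_err)
    if sigma == 0:
        z = 0.0 if diff == 0 else math.inf
    else:
        z = diff / sigma
    return z < threshold, z


def interpret_slope(
    tie: TieLine,
    tol: float | None = None,
    consistency_threshold: float = 2.0,
) -> str:
    """Classify the dominant interactions from a consistent tie line.

    Returns 'A-dominant' (slope < 1 - tol: homotypic interactions of the
    abscissa component dominate), 'B-dominant' (slope > 1 + tol), or
    'balanced/heterotypic'.  ``tol`` defaults to twice the propagated
    uncertainty of the whole-line slope.  Refuses inconsistent tie lines,
    whose system does not form precisely two coexisting phases.
    """
    consistent, z = slope_consistency(tie, threshold=consistency_threshold)
    if not consistent:
        raise ValueError(
            f"tie line segments inconsistent (z={z:.2f}); "
            "interpretation refused"
        )
    s = tie.slope_whole
    if tol is None:
        tol = 2.0 * math.hypot(tie.slope_low_err, tie.slope_high_err)
    if s < 1.0 - tol:
        return "A-dominant"
    if s > 1.0 + tol:
        return "B-dominant"
    return "balanced/heterotypic"


def read_tieline_table(path):
    """Read a tie-line CSV table.

    Expected columns: mixture_id, ratio, phase (dilute|total|dense), c_A,
    c_B, and optional err_A, err_B.  Concentration units are passed through
    unchanged (volume fractions or mg/mL).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"mixture_id", "ratio", "phase", "c_A", "c_B"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tie-line table missing columns: {sorted(missing)}")
    return df


def tielines_from_table(df) -> dict:
    """One fitted TieLine per mixture_id from a long-format table."""
    out = {}
    for mid, grp in df.groupby("mixture_id"):
        rows = {str(r["phase"]): r for _, r in grp.iterrows()}
        needed = {"dilute", "total", "dense"}
        if set(rows) < needed:
            raise ValueError(
                f"mixture {mid!r} lacks phases: {sorted(needed - set(rows))}"
            )
        errors = {}
        for phase, key in (("dilute", "dilute"), ("total", "tot"),
                           ("dense", "dense")):
            r = rows[phase]
            if "err_A" in r and not np.isnan(r.get("err_A", np.nan)):
                errors[key] = (float(r["err_A"]), float(r.get("err_B", 0.0)))
        out[mid] = fit_tieline(
            (float(rows["dilute"]["c_A"]), float(rows["dilute"]["c_B"])),
            (float(rows["total"]["c_A"]), float(rows["total"]["c_B"])),
            (float(rows["dense"]["c_A"]), float(rows["dense"]["c_B"])),
            errors=errors or None,
        )
    return out
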