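"""Per-dive water-column structure: broken-stick breakpoints, mixed-layer
depth, T200, and Southern Ocean frontal-zone classification.

The "greatest inflection point" of a profile is operationalised as the
two-segment piecewise-linear breakpoint minimising the total residual sum
of squares, searched over every interior observed depth between 15 m and
the profile limit (350 m by default, near the light sensor's sensitivity
limit); ties break shallow.  Frontal zones follow subsurface (200 m)
temperature boundaries: the Polar Frontal Zone above 2.8 degC, SACCF-N
between 1.6 and 2.8 degC, SACCF-S below 1.6 degC, with the Subantarctic
Front referenced at 7 degC.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .dives import DiveCycle
from .io import Deployment

# Frontal-zone temperature boundaries at 200 m (degC)
SAF_T200 = 7.0
PF_T200 = 2.8
SACCF_T200 = 1.6

BROKEN_STICK_MAX_DEPTH = 350.0
BROKEN_STICK_MIN_CANDIDATE = 15.0
MLD_DELTA_T = 0.2  # degC surface-to-breakpoint difference required for an MLD


class FrontalZone(enum.Enum):
    PFZ = "PFZ"            # Polar Frontal Zone, T200 > 2.8 degC
    SACCF_N = "SACCF-N"    # 1.6 <= T200 <= 2.8 degC
    SACCF_S = "SACCF-S"    # T200 < 1.6 degC


@dataclass
class BreakpointResult:
    breakpoint_depth: float
    value_at_breakpoint: float
    rss_two_segment: float
    rss_single_line: float


def _segment_rss_prefix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RSS of an OLS line fitted to points [0..i] inclusive, for every i."""
    n = np.arange(1, len(x) + 1, dtype=float)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, sxy, syy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)
    cxx = sxx - sx * sx / n
    cxy = sxy - sx * sy / n
    cyy = syy - sy * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = cyy - np.where(cxx > 1e-12, cxy * cxy / np.where(cxx > 0, cxx, 1.0), 0.0)
    return np.maximum(rss, 0.0)


def broken_stick(depth: np.ndarray, value: np.ndarray,
                 max_depth: float = BROKEN_STICK_MAX_DEPTH,
                 min_candidate_depth: float = BROKEN_STICK_MIN_CANDIDATE,
                 ) -> BreakpointResult | None:
    """RSS-minimising two-segment breakpoint of a depth profile.

    Candidate breakpoints are the interior observed depths in
    ``[min_candidate_depth, max_depth]``; the two segments (surface to
    breakpoint, breakpoint to the deepest retained point) share the
    breakpoint observation.  Returns ``None`` with fewer than 5 usable
    points or no admissible candidate; ties take the shallowest breakpoint.
    """
    depth = np.asarray(depth, dtype=float)
    value = np.asarray(value, dtype=float)
    keep = depth <= max_depth
    x, y = depth[keep], value[keep]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    if n < 5:
        return None
    candidates = np.arange(1, n - 1)
    candidates = candidates[x[candidates] >= min_candidate_depth]
    if candidates.size == 0:
        return None

    rss_pre = _segment_rss_prefix(x, y)
    rss_suf = _segment_rss_prefix(x[::-1], y[::-1])[::-1]
    total = rss_pre[candidates] + rss_suf[candidates]
    best = candidates[int(np.argmin(total))]
    return BreakpointResult(
        breakpoint_depth=float(x[best]),
        value_at_breakpoint=float(y[best]),
        rss_two_segment=float(rss_pre[best] + rss_suf[best]),
        rss_single_line=float(rss_pre[-1]),
    )


def mixed_layer_depth(depth: np.ndarray, temperature: np.ndarray,
                      criterion: str = "surface_vs_breakpoint",
                      max_depth: float = BROKEN_STICK_MAX_DEPTH,
                      delta_t: float = MLD_DELTA_T) -> float | None:
    """Broken-stick MLD from a temperature-depth profile.

    The temperature breakpoint is the MLD when the difference between the
    surface temperature (mean of the 8-12 m band, falling back to the
    shallowest observation above 15 m) and the breakpoint temperature
    exceeds 0.2 degC.  ``criterion="across_breakpoint"`` instead compares
    the temperature just above the breakpoint with the profile 20 m below
    it, which also detects the base of a perfectly isothermal mixed layer.
    """
    depth = np.asarray(depth, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if depth.size == 0 or np.nanmax(depth) < 50.0:
        return None
    bp = broken_stick(depth, temperature, max_depth)
    if bp is None:
        return None

    if criterion == "surface_vs_breakpoint":
        band = (depth >= 8.0) & (depth <= 12.0)
        if band.any():
            t_surface = float(np.mean(temperature[band]))
        else:
            shallow = depth <= 15.0
            if not shallow.any():
                return None
            t_surface = float(temperature[shallow][np.argmin(depth[shallow])])
        return bp.breakpoint_depth if abs(t_surface - bp.value_at_breakpoint) > delta_t else None
    if criterion == "across_breakpoint":
        above = depth <= bp.breakpoint_depth
        t_above = float(temperature[above][np.argmax(depth[above])])
        target = bp.breakpoint_depth + 20.0
        if np.max(depth) < target:
            return None
        order = np.argsort(depth)
        t_below = float(np.interp(target, depth[order], temperature[order]))
        return bp.breakpoint_depth if abs(t_above - t_below) > delta_t else None
    raise ValueError(f"unknown MLD criterion {criterion!r}")


def light_inflection_depth(descent_depth: np.ndarray, descent_light: np.ndarray,
                           ascent_depth: np.ndarray, ascent_light: np.ndarray,
                           max_depth: float = BROKEN_STICK_MAX_DEPTH) -> float | None:
    """Mean of the descent and ascent light-profile breakpoint depths.

    The light sensor's response lag biases descent and ascent profiles in
    opposite directions, so the per-dive inflection depth is the average of
    the two phases; if either phase is unusable no depth is returned
    (averaging is the bias control).
    """
    results = []
    for d, v in ((descent_depth, descent_light), (ascent_depth, ascent_light)):
        bp = broken_stick(d, v, max_depth)
        if bp is None:
            return None
        results.append(bp.breakpoint_depth)
    return float(np.mean(results))


def _interp_at_depth(depth: np.ndarray, value: np.ndarray,
                     target: float) -> float | None:
    depth = np.asarray(depth, dtype=float)
    value = np.asarray(value, dtype=float)
    if depth.size == 0 or depth.min() > target or depth.max() < target:
        return None
    order = np.argsort(depth, kind="stable")
    return float(np.interp(target, depth[order], value[order]))


def t200(descent_depth: np.ndarray, descent_temp: np.ndarray,
         ascent_depth: np.ndarray, ascent_temp: np.ndarray,
         target_depth: float = 200.0) -> float | None:
    """Temperature linearly interpolated at 200 m, averaged over the descent
    and ascent phases; ``None`` when either phase fails to bracket 200 m."""
    td = _interp_at_depth(descent_depth, descent_temp, target_depth)
    ta = _interp_at_depth(ascent_depth, ascent_temp, target_depth)
    if td is None or ta is None:
        return None
    return 0.5 * (td + ta)


def dive_t200(deployment: Deployment, dive: DiveCycle,
              depth: np.ndarray | None = None) -> float | None:
    """T200 of one dive from a deployment's (corrected) depth series."""
    d = deployment.depth if depth is None else depth
    de, asc = dive.descent, dive.ascent_underwater
    return t200(d[de], deployment.temperature[de], d[asc], deployment.temperature[asc])


def daily_noon_t200(values) -> float | None:
    """Mean T200 over one seal-day's local-noon dives; None when empty."""
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.mean(vals))


def classify_frontal_zone(t200_value: float) -> FrontalZone:
    """Frontal zone from T200; boundary temperatures (2.8, 1.6 degC) join the
    colder-side-inclusive zone.  Total over all finite inputs."""
    if not np.isfinite(t200_value):
        raise ValueError("T200 must be finite")
    if t200_value > PF_T200:
        return FrontalZone.PFZ
    if t200_value >= SACCF_T200:
        return FrontalZone.SACCF_N
    return FrontalZone.SACCF_S
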