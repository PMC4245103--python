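"""Depth-series correction and dive-cycle segmentation.

A dive cycle runs from the first record deeper than 10 m after a surface
interval to the last record of the following surface interval (depth
0-10 m); the 10-m tolerance absorbs sub-surface swimming between dives.
Records before the first dive belong to the surface; a deployment ending
mid-dive leaves a final incomplete dive that is flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Deployment

SURFACE_THRESHOLD_M = 10.0  # > 10 m enters a dive; <= 10 m is surface


@dataclass
class DiveCycle:
    """One segmented dive, stored as index bounds into the deployment arrays.

    ``start`` is the first record > 10 m, ``underwater_end`` the index after
    the last submerged record, ``end`` the index after the last record of the
    post-dive surface interval (exclusive).  ``max_depth_index`` is the first
    record attaining the maximum depth, shared by descent and ascent.
    """

    start: int
    underwater_end: int
    end: int
    max_depth_index: int
    max_depth: float
    start_time: np.datetime64 | None = None
    end_time: np.datetime64 | None = None

    @property
    def descent(self) -> slice:
        """First sub-surface record through the max-depth record."""
        return slice(self.start, self.max_depth_index + 1)

    @property
    def ascent(self) -> slice:
        """Max-depth record through the end of the cycle (includes the
        post-dive surface interval, whose shallow records feed LL_0)."""
        return slice(self.max_depth_index, self.end)

    @property
    def ascent_underwater(self) -> slice:
        """Max-depth record through the last submerged record."""
        return slice(self.max_depth_index, self.underwater_end)

    @property
    def post_dive_surface(self) -> slice:
        return slice(self.underwater_end, self.end)

    @property
    def n_records(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    dives: list[DiveCycle]
    n_records: int
    n_surface_records: int       # leading surface records before the first dive
    n_incomplete_records: int    # records of a flagged, excluded final dive

    @property
    def n_dive_records(self) -> int:
        return sum(d.n_records for d in self.dives)

    @property
    def conserved(self) -> bool:
        return (self.n_dive_records + self.n_surface_records
                + self.n_incomplete_records == self.n_records)


def segment_dives(deployment: Deployment | np.ndarray,
                  time: np.ndarray | None = None,
                  threshold: float = SURFACE_THRESHOLD_M) -> SegmentationResult:
    """Segment a (zero-offset-corrected) depth series into dive cycles.

    Accepts a :class:`Deployment` or a bare depth array.  Segments never
    overlap and every record is accounted for: dive records + leading surface
    records + flagged-incomplete records = total records.
    """
    if isinstance(deployment, Deployment):
        depth = deployment.depth
        time = deployment.time
    else:
        depth = np.asarray(deployment, dtype=float)
    n = len(depth)
    if n == 0:
        return SegmentationResult([], 0, 0, 0)

    sub = depth > threshold
    sub_idx = np.flatnonzero(sub)
    if sub_idx.size == 0:
        return SegmentationResult([], n, n, 0)

    prev = np.concatenate(([False], sub[:-1]))
    starts = np.flatnonzero(sub & ~prev)
    ends = np.append(starts[1:], n)
    # index after the last submerged record of each cycle
    uw_ends = sub_idx[np.searchsorted(sub_idx, ends, side="left") - 1] + 1

    n_incomplete = 0
    if sub[-1]:
        # series ends underwater: final dive has no post-dive surface interval
        n_incomplete = n - starts[-1]
        starts, ends, uw_ends = starts[:-1], ends[:-1], uw_ends[:-1]

    if starts.size:
        cid = np.repeat(np.arange(starts.size), uw_ends - starts)
        rec = np.concatenate([np.arange(s, u) for s, u in zip(starts, uw_ends)])
        dmax_first = (
            pd.Series(depth[rec], index=rec).groupby(cid).idxmax().to_numpy()
        )
    else:
        dmax_first = np.array([], dtype=int)

    dives = [
        DiveCycle(
            start=int(s), underwater_end=int(u), end=int(e),
            max_depth_index=int(m), max_depth=float(depth[m]),
            start_time=None if time is None else time[s],
            end_time=None if time is None else time[e - 1],
        )
        for s, u, e, m in zip(starts, uw_ends, ends, dmax_first)
    ]
    return SegmentationResult(dives, n, int(starts[0]) if dives else n - n_incomplete,
                              n_incomplete)


def split_phases(dive: DiveCycle) -> tuple[slice, slice]:
    """Descent/ascent profile index slices, split at the first record
    attaining the maximum depth (the two phases share that record); rejects
    dives too short to carry two usable phases.  The ascent profile ends at
    the last submerged record; the post-dive surface interval is not part
    of either profile."""
    if dive.n_records < 4:
        raise ValueError("dive with fewer than 4 records is unusable")
    descent, ascent = dive.descent, dive.ascent_underwater
    if descent.stop - descent.start < 2 or ascent.stop - ascent.start < 2:
        raise ValueError("each phase needs at least 2 records")
    return descent, ascent


def zero_offset_correct(depth: np.ndarray,
                        sample_interval_s: float = 30.0,
                        window_hours: float = 6.0,
                        stride_hours: float = 1.0,
                        shallow_max_m: float = 15.0,
                        bin_width_m: float = 0.5,
                        return_offsets: bool = False):
    """Remove pressure-sensor drift so surface intervals read ~0 m.

    The offset is tracked along the record in ``stride_hours`` blocks: for
    each block it is the lower edge of the most frequent 0.5-m bin among
    readings shallower than 15 m inside the centred rolling window (default
    6 h) -- the mode of surface readings.  Blocks whose window holds no
    shallow reading carry the previous offset forward.  Corrected values
    below 0 are clamped to 0.  Using the bin's lower edge makes an
    already-correct series a fixed point (up to clamping), and a second
    pass shifts the output by at most one bin; exact bin-count ties take
    the median tied bin so a slow drift is tracked without lag.
    """
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    if n == 0:
        raise ValueError("empty depth series")
    stride = max(1, int(round(stride_hours * 3600.0 / sample_interval_s)))
    half = max(1, int(round(window_hours / stride_hours / 2.0)))
    n_blocks = (n + stride - 1) // stride

    # per-block histograms of shallow readings, then rolling sums
    shallow = depth < shallow_max_m
    bins = np.floor(depth[shallow] / bin_width_m).astype(int)
    if bins.size == 0:
        corrected = np.maximum(depth, 0.0)
        return (corrected, np.zeros(n)) if return_offsets else corrected
    bin_lo = int(bins.min())
    counts = np.zeros((n_blocks, int(bins.max()) - bin_lo + 1), dtype=np.int64)
    np.add.at(counts, (np.flatnonzero(shallow) // stride, bins - bin_lo), 1)
    csum = np.concatenate([np.zeros((1, counts.shape[1]), dtype=np.int64),
                           np.cumsum(counts, axis=0)])
    lo = np.maximum(np.arange(n_blocks) - half, 0)
    hi = np.minimum(np.arange(n_blocks) + half + 1, n_blocks)
    window_counts = csum[hi] - csum[lo]

    block_offsets = np.full(n_blocks, np.nan)
    has_any = window_counts.sum(axis=1) > 0
    # mode bin; exact ties (a drifting offset spreads the surface reads over
    # adjacent bins) resolve to the median tied bin, which tracks the centre
    # of the drift without biasing the correction up or down
    wc = window_counts[has_any]
    is_max = wc == wc.max(axis=1, keepdims=True)
    first = np.argmax(is_max, axis=1)
    last = wc.shape[1] - 1 - np.argmax(is_max[:, ::-1], axis=1)
    block_offsets[has_any] = ((first + last) // 2 + bin_lo) * bin_width_m
    # carry forward (then backward for a leading gap)
    filled = pd.Series(block_offsets).ffill().bfill().fillna(0.0).to_numpy()
    offsets = np.repeat(filled, stride)[:n]
    corrected = np.maximum(depth - offsets, 0.0)
    if return_offsets:
        return corrected, offsets
    return corrected


def clock_time_error(temperature_c: float | np.ndarray) -> float | np.ndarray:
    """Watch-crystal time error in microseconds per second at temperature T:
    TE = (1e-5 - 3.5e-8 * (T - 25)^2) * 1e6 us."""
    t = np.asarray(temperature_c, dtype=float)
    te = (1e-5 - 3.5e-8 * (t - 25.0) ** 2) * 1e6
    return float(te) if np.isscalar(temperature_c) else te


def correct_sensor_lag(values: np.ndarray, tau_s: float,
                       sample_interval_s: float = 30.0,
                       times: np.ndarray | None = None) -> np.ndarray:
    """Invert a first-order sensor lag: y_true = y + tau * dy/dt.

    Finite-difference deconvolution of the exponential response inherent in
    slow thermistors/photodiodes; ``tau_s = 0`` is the identity.  Requires
    uniform sampling (checked when ``times`` is supplied).
    """
    if tau_s < 0:
        raise ValueError("tau must be >= 0")
    values = np.asarray(values, dtype=float)
    if times is not None:
        steps = np.diff(np.asarray(times, dtype="datetime64[ns]").astype("int64"))
        if steps.size and not np.all(steps == steps[0]):
            raise ValueError("sensor-lag correction requires uniform sampling")
        if steps.size:
            sample_interval_s = float(steps[0]) / 1e9
    if tau_s == 0 or len(values) < 2:
        return values.copy()
    return values + tau_s * np.gradient(values, sample_interval_s)


def apply_sensor_lag(values: np.ndarray, tau_s: float,
                     sample_interval_s: float = 30.0) -> np.ndarray:
    """Forward first-order lag filter (discrete exponential response); the
    simulation counterpart of :func:`correct_sensor_lag`."""
    values = np.asarray(values, dtype=float)
    if tau_s <= 0 or len(values) == 0:
        return values.copy()
    alpha = 1.0 - np.exp(-sample_interval_s / tau_s)
    out = np.empty_like(values)
    acc = values[0]
    for i, v in enumerate(values):
        acc += alpha * (v - acc)
        out[i] = acc
    return out
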