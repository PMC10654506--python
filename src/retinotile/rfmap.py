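"""Receptive-field estimation from checkerboard noise and RF/patch geometry.

Receptive fields (RFs) are estimated by reverse correlation: the
response-weighted average of the binary checkerboard stimulus over a 0.5 s
window preceding each activity sample, at 16.7 ms lag resolution.  The
spatial profile at the peak latency is then summarized by an elliptical 2D
Gaussian fit, whose center gives the RF position in visual degrees and
whose axis SDs give the RF size (sum of the long- and short-axis SDs, i.e.
the mean of the two 1-SD diameters).

The module also carries the geometry statistics used on anatomical data:
axonal-patch area/radius/centroid from binary footprint masks, the
intersection-over-union overlap fraction for patches and for 1-SD RF
ellipses, the screen/border inclusion rules, and the outlier-trimmed
Pearson correlation between RF size and patch size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .errors import (
    AlignmentError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    NoSignalError,
)

RC_WINDOW_S = 0.5          # reverse-correlation window before each sample
RC_BIN_S = 1.0 / 60.0      # 16.7 ms lag bin (60 Hz presentation grid)


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEnsemble:
    """Binary checkerboard stimulus: one frame per white-noise update.

    ``frames`` has shape ``(n_frames, n_el, n_az)`` with values in {0, 1};
    fields are ``field_w x field_h`` degrees, updated at ``rate_hz``, tiling
    a screen spanning ±``screen_az`` azimuth and ±``screen_el`` elevation.
    """

    frames: np.ndarray
    field_w: float = 3.7
    field_h: float = 2.9
    rate_hz: float = 4.0
    screen_az: float = 36.5
    screen_el: float = 22.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise InvalidInputError("frames must be (n_frames, n_el, n_az)")
        if not np.isin(f, (0, 1)).all():
            raise InvalidInputError("stimulus frames must be binary {0, 1}")
        n_az = int(2 * self.screen_az // self.field_w)
        n_el = int(2 * self.screen_el // self.field_h)
        if f.shape[1] != n_el or f.shape[2] != n_az:
            raise InvalidInputError(
                f"frame grid {f.shape[1:]} inconsistent with screen "
                f"±{self.screen_el}/±{self.screen_az} at "
                f"{self.field_h}x{self.field_w} deg fields (expect {(n_el, n_az)})"
            )
        object.__setattr__(self, "frames", f.astype(np.uint8))

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate_hz

    def field_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(azimuth, elevation) centers of the stimulus fields, degrees."""
        n_el, n_az = self.frames.shape[1:]
        az = (np.arange(n_az) - (n_az - 1) / 2.0) * self.field_w
        el = (np.arange(n_el) - (n_el - 1) / 2.0) * self.field_h
        return az, el

    def coverage(self) -> tuple[float, float]:
        """Half-extent (az, el) of the screen area tiled by fields, degrees."""
        n_el, n_az = self.frames.shape[1:]
        return n_az * self.field_w / 2.0, n_el * self.field_h / 2.0


# ---------------------------------------------------------------------------
# Receptive-field containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatioTemporalRF:
    """Reverse-correlation estimate: one spatial frame per lag bin.

    ``frames[l]`` is the response-weighted average of the mean-subtracted
    stimulus at lag ``(l + 0.5) * bin_width`` before the response sample;
    ``energy[l]`` is its summed squared deviation, and ``peak_bin`` the lag
    maximizing it.
    """

    frames: np.ndarray           # (n_bins, n_el, n_az)
    energy: np.ndarray           # (n_bins,)
    peak_bin: int
    bin_width: float
    window: float
    az_centers: np.ndarray
    el_centers: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(self.frames.shape[0])

    @property
    def peak_latency_ms(self) -> float:
        return (self.peak_bin + 0.5) * self.bin_width * 1000.0

    @property
    def peak_frame(self) -> np.ndarray:
        return self.frames[self.peak_bin]


@dataclass(frozen=True)
class ReceptiveField:
    """Elliptical 2D Gaussian RF summary.

    ``size`` is ``sd_long + sd_short`` degrees — twice the mean SD of the
    long and short axes, i.e. the mean of the two 1-SD diameters.
    """

    center: tuple[float, float]        # (azimuth, elevation), degrees
    sd_long: float
    sd_short: float
    orientation: float = 0.0           # radians, long axis vs azimuth
    amplitude: float = 1.0
    peak_latency: float = 100.0        # ms
    roi_id: int = -1
    on_screen: bool = True
    fit_ok: bool = True

    def __post_init__(self) -> None:
        if self.fit_ok:
            if not (self.sd_long >= self.sd_short > 0):
                raise InvalidParameterError("require sd_long >= sd_short > 0")

    @property
    def size(self) -> float:
        return self.sd_long + self.sd_short

    def evaluate(self, az: np.ndarray, el: np.ndarray) -> np.ndarray:
        """Gaussian profile (including signed amplitude) at (az, el) degrees."""
        dx = np.asarray(az, dtype=float) - self.center[0]
        dy = np.asarray(el, dtype=float) - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = (dx * c + dy * s) / self.sd_long
        v = (-dx * s + dy * c) / self.sd_short
        return self.amplitude * np.exp(-0.5 * (u**2 + v**2))


@dataclass(frozen=True)
class PatchFootprint:
    """Binary axonal-patch footprint and its derived geometry."""

    mask: np.ndarray
    pixel_size: float = 1.3            # μm per pixel
    # derived
    area: float = 0.0                  # μm²
    radius: float = 0.0                # equivalent-circle radius, μm
    centroid: tuple[float, float] = (0.0, 0.0)  # (x, y) μm


# ---------------------------------------------------------------------------
# Reverse correlation
# ---------------------------------------------------------------------------

def _lag_weight_matrix(
    trace: np.ndarray,
    stimulus: StimulusEnsemble,
    frame_rate: float,
    window: float,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag accumulation of trace weights onto stimulus frames.

    Returns ``(W, totals)`` with ``W[l, f]`` the summed response weight whose
    lag-``l`` look-back lands on stimulus frame ``f``, and ``totals[l]`` the
    per-lag sum of usable weights.
    """
    n_bins = int(round(window / bin_width))
    t = np.arange(trace.size) / frame_rate
    W = np.zeros((n_bins, stimulus.n_frames))
    totals = np.zeros(n_bins)
    for lag in range(n_bins):
        sample_t = t - (lag + 0.5) * bin_width
        valid = sample_t >= 0
        idx = np.floor(sample_t[valid] * stimulus.rate_hz).astype(np.intp)
        np.clip(idx, 0, stimulus.n_frames - 1, out=idx)
        W[lag] = np.bincount(idx, weights=trace[valid], minlength=stimulus.n_frames)
        totals[lag] = trace[valid].sum()
    return W, totals


def reverse_correlate(
    trace: np.ndarray,
    stimulus: StimulusEnsemble,
    frame_rate: float,
    window: float = RC_WINDOW_S,
    bin_width: float = RC_BIN_S,
) -> SpatioTemporalRF:
    """Response-weighted average of the stimulus over a pre-response window.

    For each lag bin ``l`` (bin centers at ``(l + 0.5) * bin_width`` before
    the sample, covering ``[t - window, t]``), the mean-subtracted stimulus
    frames are averaged with the activity trace as weights.  The 4 Hz
    checkerboard is held piecewise-constant on the finer lag grid.  The peak
    latency is the lag whose spatial frame carries the largest summed
    squared deviation from zero.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if trace.size == 0 or trace.sum() <= 0:
        raise NoSignalError("trace has no events to correlate")
    if np.any(trace < 0):
        raise InvalidInputError("trace weights must be nonnegative")
    span = trace.size / frame_rate
    if abs(span - stimulus.duration) > 1.0 / stimulus.rate_hz + 1e-9:
        raise AlignmentError(
            f"trace spans {span:.2f}s but stimulus spans {stimulus.duration:.2f}s"
        )
    W, totals = _lag_weight_matrix(trace, stimulus, frame_rate, window, bin_width)
    s_flat = stimulus.frames.reshape(stimulus.n_frames, -1).astype(float)
    s_flat -= s_flat.mean(axis=0)
    n_el, n_az = stimulus.frames.shape[1:]
    sta = (W @ s_flat) / np.where(totals > 0, totals, 1.0)[:, None]
    frames = sta.reshape(-1, n_el, n_az)
    energy = (frames**2).sum(axis=(1, 2))
    az, el = stimulus.field_centers()
    return SpatioTemporalRF(
        frames=frames, energy=energy, peak_bin=int(np.argmax(energy)),
        bin_width=bin_width, window=window, az_centers=az, el_centers=el,
    )


def peak_zscore(
    trace: np.ndarray,
    stimulus: StimulusEnsemble,
    frame_rate: float,
    n_shuffles: int = 100,
    seed: int | np.random.Generator | None = None,
    window: float = RC_WINDOW_S,
    bin_width: float = RC_BIN_S,
) -> float:
    """Z-score of the peak STRF energy against a circular-shift null.

    The trace is circularly shifted by random offsets (breaking the
    stimulus–response alignment while preserving the event statistics) and
    the peak spatial deviation energy recomputed for each shuffle.  Cells
    with z below ~3 have no detectable stimulus-locked structure.
    """
    rng = np.random.default_rng(seed)
    trace = np.asarray(trace, dtype=float).ravel()
    obs = reverse_correlate(trace, stimulus, frame_rate, window, bin_width)
    s_flat = stimulus.frames.reshape(stimulus.n_frames, -1).astype(float)
    s_flat -= s_flat.mean(axis=0)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shift = int(rng.integers(1, trace.size))
        shuffled = np.roll(trace, shift)
        W, totals = _lag_weight_matrix(
            shuffled, stimulus, frame_rate, window, bin_width
        )
        sta = (W @ s_flat) / np.where(totals > 0, totals, 1.0)[:, None]
        null[i] = (sta**2).sum(axis=1).max()
    sd = null.std()
    excess = obs.energy.max() - null.mean()
    if sd == 0:
        # constant traces yield a degenerate null: every shift gives the same
        # STA, so the observed peak coincides with the null exactly
        return 0.0 if abs(excess) < 1e-12 else np.inf
    return float(excess / sd)


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------

def _gauss2d(params: np.ndarray, azg: np.ndarray, elg: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, theta, offset = params
    dx, dy = azg - x0, elg - y0
    c, s = np.cos(theta), np.sin(theta)
    u = (dx * c + dy * s) / sx
    v = (-dx * s + dy * c) / sy
    return offset + amp * np.exp(-0.5 * (u**2 + v**2))


def fit_rf_gaussian(strf: SpatioTemporalRF) -> ReceptiveField:
    """Elliptical 2D Gaussian fit to the peak-latency STRF frame.

    Nonlinear least squares over (amplitude, center, axis SDs, orientation,
    offset).  Candidate RF locations are the strongest local extrema of the
    3x3-smoothed frame (a genuine RF spans several stimulus fields and
    survives the smoothing; isolated noise pixels do not); each candidate is
    fit with its center bounded to a local window and two initial widths,
    and the lowest-cost solution wins.  Axis SDs are bounded below at half a
    stimulus field — the checkerboard cannot resolve finer structure, so
    smaller SDs are fitting artifacts.  Amplitude is signed so OFF-dominant
    RFs fit with negative amplitude.  Divergent fits or SDs beyond the
    screen extent are flagged ``fit_ok=False`` (excluded from tiling
    analysis downstream) rather than raising.
    """
    frame = strf.peak_frame
    if not np.all(np.isfinite(frame)):
        raise InvalidInputError("peak STRF frame contains non-finite values")
    azg, elg = np.meshgrid(strf.az_centers, strf.el_centers)
    field_w = float(np.diff(strf.az_centers).mean()) if strf.az_centers.size > 1 else 1.0
    field_h = float(np.diff(strf.el_centers).mean()) if strf.el_centers.size > 1 else field_w
    span_az = float(np.ptp(strf.az_centers)) + field_w
    span_el = float(np.ptp(strf.el_centers)) + field_h
    span = max(span_az, span_el)
    sd_min = 0.5 * min(field_w, field_h)

    offset0 = float(np.median(frame))
    resid = frame - offset0
    smoothed = ndimage.uniform_filter(resid, size=3, mode="nearest")
    peaks = ndimage.maximum_filter(np.abs(smoothed), size=3, mode="nearest")
    cand = np.argwhere(np.abs(smoothed) == peaks)
    strength = np.abs(smoothed)[cand[:, 0], cand[:, 1]]
    cand = cand[np.argsort(strength)[::-1][:5]]
    iy0, ix0 = cand[0]

    def _residuals(p: np.ndarray) -> np.ndarray:
        return (_gauss2d(p, azg, elg) - frame).ravel()

    def _failed() -> ReceptiveField:
        return ReceptiveField(
            center=(float(strf.az_centers[ix0]), float(strf.el_centers[iy0])),
            sd_long=np.nan, sd_short=np.nan, orientation=0.0,
            amplitude=0.0, peak_latency=strf.peak_latency_ms,
            on_screen=False, fit_ok=False,
        )

    best = None
    for iy, ix in cand:
        lo = [-np.inf, strf.az_centers[ix] - 2 * field_w,
              strf.el_centers[iy] - 2 * field_h, sd_min, sd_min, -np.pi, -np.inf]
        hi = [np.inf, strf.az_centers[ix] + 2 * field_w,
              strf.el_centers[iy] + 2 * field_h, span, span, np.pi, np.inf]
        for s0 in (0.65 * field_w, 1.3 * field_w):
            p0 = np.array([
                resid[iy, ix], strf.az_centers[ix], strf.el_centers[iy],
                s0, s0, 0.0, offset0,
            ])
            try:
                res = optimize.least_squares(
                    _residuals, p0, bounds=(lo, hi), max_nfev=2000
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        return _failed()
    amp, x0, y0, sx, sy, theta, _ = best.x
    if sx < sy:
        sx, sy = sy, sx
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    if not np.isfinite([amp, x0, y0, sx, sy]).all() or sx > span or sy > span:
        return _failed()
    return ReceptiveField(
        center=(float(x0), float(y0)), sd_long=float(sx), sd_short=float(sy),
        orientation=theta, amplitude=float(amp),
        peak_latency=strf.peak_latency_ms,
    )


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenFilterResult:
    """Outcome of the screen/border inclusion rule for one recording."""

    kept_ids: tuple[int, ...]
    rfs: tuple[ReceptiveField, ...]     # all input RFs, on_screen updated
    recording_excluded: bool
    min_cells: int


def screen_filter(
    rfs: Sequence[ReceptiveField],
    screen_az: float = 36.5,
    screen_el: float = 22.0,
    field_w: float = 3.7,
    field_h: float = 2.9,
    min_cells: int = 10,
) -> ScreenFilterResult:
    """Drop RFs centered on the screen border or off screen.

    A center counts as "on the border" when it falls in the outermost ring
    of stimulus fields tiling the screen.  Cells with failed Gaussian fits
    are dropped as well.  If fewer than ``min_cells`` survive, the whole
    recording is flagged excluded from tiling analysis.
    """
    cov_az = (int(2 * screen_az // field_w) * field_w) / 2.0
    cov_el = (int(2 * screen_el // field_h) * field_h) / 2.0
    kept: list[int] = []
    updated: list[ReceptiveField] = []
    for rf in rfs:
        az, el = rf.center
        inside = (
            rf.fit_ok
            and abs(az) < cov_az - field_w
            and abs(el) < cov_el - field_h
        )
        updated.append(replace(rf, on_screen=bool(inside)))
        if inside:
            kept.append(rf.roi_id)
    return ScreenFilterResult(
        kept_ids=tuple(kept), rfs=tuple(updated),
        recording_excluded=len(kept) < min_cells, min_cells=min_cells,
    )


# ---------------------------------------------------------------------------
# Overlap and patch geometry
# ---------------------------------------------------------------------------

def ellipse_overlap_fraction(
    rfs: Sequence[ReceptiveField], cell: float = 0.2
) -> float:
    """Intersection-over-union overlap of the 1-SD RF ellipses.

    ``area(U_{i!=j} (E_i ∩ E_j)) / area(U_i E_i)``, i.e. the fraction of
    the total footprint covered by at least two ellipses, computed on a
    rasterized grid of ``cell`` degrees (default 0.2°, <1% error at the
    RF scales here).
    """
    if len(rfs) < 2:
        raise InsufficientDataError("overlap fraction needs >= 2 RFs")
    pad = max(rf.sd_long for rf in rfs) * 1.1
    xs = [rf.center[0] for rf in rfs]
    ys = [rf.center[1] for rf in rfs]
    gx = np.arange(min(xs) - pad, max(xs) + pad + cell, cell)
    gy = np.arange(min(ys) - pad, max(ys) + pad + cell, cell)
    azg, elg = np.meshgrid(gx, gy)
    count = np.zeros(azg.shape, dtype=np.int32)
    for rf in rfs:
        dx, dy = azg - rf.center[0], elg - rf.center[1]
        c, s = np.cos(rf.orientation), np.sin(rf.orientation)
        u = (dx * c + dy * s) / rf.sd_long
        v = (-dx * s + dy * c) / rf.sd_short
        count += (u**2 + v**2) <= 1.0
    union = int((count >= 1).sum())
    if union == 0:
        return 0.0
    return float((count >= 2).sum()) / union


def patch_geometry(mask: np.ndarray, pixel_size: float = 1.3) -> PatchFootprint:
    """Area, equivalent-circle radius and binary centroid of a patch mask.

    The radius is ``sqrt(area / pi)``, assuming a circular patch; the
    centroid is the unweighted mean of the true pixels' centers, in μm with
    (x, y) = (column, row) axes.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise InvalidInputError("patch mask must be a nonempty 2D binary array")
    area = float(mask.sum()) * pixel_size**2
    radius = float(np.sqrt(area / np.pi))
    rows, cols = np.nonzero(mask)
    centroid = (
        float((cols.mean() + 0.5) * pixel_size),
        float((rows.mean() + 0.5) * pixel_size),
    )
    return PatchFootprint(
        mask=mask, pixel_size=pixel_size, area=area, radius=radius,
        centroid=centroid,
    )


def pairwise_patch_overlap(masks: Sequence[np.ndarray]) -> float:
    """Intersection-over-union overlap of binary patch masks.

    Fraction of the union of all patches that is covered by at least two,
    mirroring :func:`ellipse_overlap_fraction` on pixel masks.
    """
    if len(masks) < 2:
        raise InsufficientDataError("patch overlap needs >= 2 masks")
    stack = np.stack([np.asarray(m).astype(bool) for m in masks])
    count = stack.sum(axis=0)
    union = int((count >= 1).sum())
    if union == 0:
        return 0.0
    return float((count >= 2).sum()) / union


def rf_patch_size_correlation(
    sizes_rf: Sequence[float], sizes_patch: Sequence[float]
) -> tuple[float, float]:
    """Outlier-trimmed Pearson correlation between RF size and patch size.

    Pairs where either variable falls outside its central 95% interval
    (2.5th–97.5th percentile) are dropped before computing Pearson's r and
    the two-sided p-value.
    """
    x = np.asarray(sizes_rf, dtype=float)
    y = np.asarray(sizes_patch, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("size lists must be paired")
    keep = np.ones(x.size, dtype=bool)
    for v in (x, y):
        lo, hi = np.percentile(v, [2.5, 97.5])
        keep &= (v >= lo) & (v <= hi)
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 pairs remain after trimming")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p)
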