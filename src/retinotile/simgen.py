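"""Generative model of the retinocollicular projection and synthetic inputs.

The model builds, in four steps, the paired point patterns whose tiling
match the analysis modules quantify:

1. RGC somata — equivalently their receptive-field (RF) centers — sit on a
   2D hexagonal lattice (spacing ``l_rf`` in visual degrees) with additive
   Gaussian jitter of SD ``jitter_frac * l_rf`` per axis, emulating the dense
   packing of ganglion cells in the retina.
2. Each RGC's axon terminal in the superior colliculus (SC) is the same
   lattice rescaled to ``l_axon`` μm, displaced by additional isotropic
   Gaussian noise of SD σ — the axonal *projection jitter*.  σ = 0 means
   perfect retinotopy (100% tiling match).
3. SC somata sit on an independent jittered hexagonal lattice with spacing
   ``l_soma`` μm.
4. Each SC neuron receives input from its k nearest RGC axons, k drawn from
   a zero-truncated Poisson with mean parameter λ; connection weights are
   proportional to the overlap area between the SC dendritic field (disk,
   radius 200 μm) and the RGC axonal field (disk, diameter 135 μm), and the
   SC neuron's RF center is the weight-averaged RF center of its inputs.

The module also provides a linear–nonlinear–Poisson (LNP) recording
simulator that turns ground-truth Gaussian RFs and a binary checkerboard
stimulus into event-count traces, for testing the reverse-correlation
pipeline end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConsistencyError,
    InvalidInputError,
    InvalidParameterError,
    UnitError,
)
from .rfmap import ReceptiveField, StimulusEnsemble
from .tiling import TilingPattern


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def substream(seed: int | np.random.Generator | None, name: str) -> np.random.Generator:
    """Named child RNG stream derived deterministically from a root seed.

    Each pipeline stage draws from its own stream, so rerunning any single
    stage with the same root seed reproduces it exactly regardless of what
    other stages consumed.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    key = zlib.crc32(name.encode())
    if seed is None:
        return np.random.default_rng(np.random.SeedSequence(spawn_key=(key,)))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """All generative-model parameters.

    Defaults are the experimentally measured scales: RF lattice spacing
    7.2°, axon lattice 100 μm, SC soma lattice 56 μm, 10% base jitter,
    dendritic-field radius 200 μm and axonal-field diameter 135 μm.  The
    default 9x9 grid with a 1-node margin gives ~49 interior nodes per
    pattern, the order of one experimental field of view.
    """

    l_rf: float = 7.2            # RF lattice spacing, visual degrees
    l_axon: float = 100.0        # axon lattice spacing, μm
    l_soma: float = 56.0         # SC soma lattice spacing, μm
    jitter_frac: float = 0.1     # base lattice jitter SD / spacing
    sigma: float = 27.0          # axonal projection jitter SD, μm
    lambda_mean: float = 5.5     # mean RGC inputs per SC neuron (Poisson λ)
    dend_radius: float = 200.0   # SC dendritic field radius, μm
    axon_field_diam: float = 135.0  # RGC axonal field diameter, μm
    grid_rows: int = 9
    grid_cols: int = 9
    margin_rows: int = 1
    margin_cols: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l_rf", "l_axon", "l_soma", "dend_radius", "axon_field_diam"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.jitter_frac < 0:
            raise InvalidParameterError("jitter_frac must be >= 0")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.lambda_mean < 1:
            raise InvalidParameterError("lambda_mean must be >= 1")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise InvalidParameterError("grid must be at least 2x2")
        if (
            self.margin_rows < 0
            or self.margin_cols < 0
            or 2 * self.margin_rows >= self.grid_rows
            or 2 * self.margin_cols >= self.grid_cols
        ):
            raise InvalidParameterError("margins must leave a nonempty interior")

    def interior_ids(self) -> np.ndarray:
        """Ids of lattice nodes outside the excluded boundary margin."""
        r = np.arange(self.grid_rows)
        c = np.arange(self.grid_cols)
        keep_r = (r >= self.margin_rows) & (r < self.grid_rows - self.margin_rows)
        keep_c = (c >= self.margin_cols) & (c < self.grid_cols - self.margin_cols)
        rr, cc = np.meshgrid(r[keep_r], c[keep_c], indexing="ij")
        return (rr * self.grid_cols + cc).ravel().astype(np.int64)


@dataclass(frozen=True)
class ConnectivityRecord:
    """Inputs of one SC neuron: connected axon ids and normalized weights."""

    sc_id: int
    axon_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.axon_ids, dtype=np.int64)
        w = np.asarray(self.weights, dtype=float)
        if a.size == 0:
            raise InvalidInputError("a connectivity record needs >= 1 connection")
        if a.size != w.size:
            raise InvalidInputError("axon_ids and weights must have equal length")
        if np.any(w < 0):
            raise InvalidInputError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidInputError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "axon_ids", a)
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class ConnectivitySet:
    """RGC→SC connectivity: one record per SC neuron."""

    records: tuple[ConnectivityRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class GroundTruth:
    """All simulated patterns plus the connectivity that generated them."""

    rgc_rf: TilingPattern
    axon: TilingPattern
    sc_soma: TilingPattern
    sc_rf: TilingPattern
    connectivity: ConnectivitySet
    config: SimConfig

    def __post_init__(self) -> None:
        if not np.array_equal(self.rgc_rf.ids, self.axon.ids):
            raise ConsistencyError("rgc_rf and axon must share identical ids")
        if not np.array_equal(self.sc_soma.ids, self.sc_rf.ids):
            raise ConsistencyError("sc_soma and sc_rf must share identical ids")
        axon_ids = set(int(i) for i in self.axon.ids)
        for rec in self.connectivity:
            if not set(int(i) for i in rec.axon_ids) <= axon_ids:
                raise ConsistencyError(
                    f"record {rec.sc_id}: connected axon id missing from axon pattern"
                )


@dataclass(frozen=True)
class SyntheticRecording:
    """LNP-simulated event traces paired with their ground-truth RFs."""

    stimulus: StimulusEnsemble
    traces: np.ndarray           # (n_roi, n_frames) event counts
    frame_rate: float            # imaging frame rate, Hz
    truth_rfs: tuple[ReceptiveField, ...]
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.traces < 0):
            raise InvalidInputError("event traces must be nonnegative")


# ---------------------------------------------------------------------------
# Step 1: jittered hexagonal lattice
# ---------------------------------------------------------------------------

def make_hex_lattice(
    spacing: float,
    jitter_frac: float,
    rows: int,
    cols: int,
    seed: int | np.random.Generator | None = None,
    unit: str = "um",
    space: str = "sc",
) -> TilingPattern:
    """Jittered hexagonal-packing (triangular) lattice, centered at the origin.

    Nodes sit at spacing ``spacing`` with alternate rows offset by half a
    spacing and row pitch ``spacing * sqrt(3)/2``; each node is then
    displaced by i.i.d. per-axis Gaussian noise of SD
    ``jitter_frac * spacing``.  Node ids are ``row * cols + col``.
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be > 0")
    if jitter_frac < 0:
        raise InvalidParameterError("jitter_frac must be >= 0")
    if rows < 2 or cols < 2:
        raise InvalidParameterError("rows and cols must be >= 2")
    rng = np.random.default_rng(seed)
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c * spacing + (r % 2) * (spacing / 2.0)
    y = r * spacing * (np.sqrt(3.0) / 2.0)
    pts = np.stack([x.ravel(), y.ravel()], axis=1).astype(float)
    pts -= pts.mean(axis=0)
    pts += rng.normal(0.0, jitter_frac * spacing, size=pts.shape)
    ids = np.arange(rows * cols, dtype=np.int64)
    return TilingPattern(ids=ids, points=pts, unit=unit, space=space)


# ---------------------------------------------------------------------------
# Step 2: axonal projection
# ---------------------------------------------------------------------------

def project_axons(
    rf_pattern: TilingPattern,
    l_rf: float,
    l_axon: float,
    sigma: float,
    seed: int | np.random.Generator | None = None,
) -> TilingPattern:
    """Project an RF pattern (degrees) into SC coordinates (μm) with jitter σ.

    Each point is scaled by the isotropic magnification ``l_axon / l_rf``
    (μm per degree) and then displaced by i.i.d. per-axis Gaussian noise of
    SD ``sigma`` μm.  Ids are preserved, so the output pairs with the input
    for tiling-match analysis.  With ``sigma = 0`` the map is a pure
    similarity transform and the tiling match is exactly 100%.
    """
    if len(rf_pattern) == 0:
        raise InvalidInputError("rf_pattern must be nonempty")
    if rf_pattern.unit != "deg":
        raise UnitError(f"rf_pattern must be in 'deg', got {rf_pattern.unit!r}")
    if l_rf <= 0 or l_axon <= 0:
        raise InvalidParameterError("lattice spacings must be > 0")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pts = rf_pattern.points * (l_axon / l_rf)
    if sigma > 0:
        pts = pts + rng.normal(0.0, sigma, size=pts.shape)
    return TilingPattern(ids=rf_pattern.ids.copy(), points=pts, unit="um", space="sc")


# ---------------------------------------------------------------------------
# Step 4 building blocks: overlap weights and Poisson convergence
# ---------------------------------------------------------------------------

def circle_overlap_area(r1, r2, d):
    """Exact lens area of two intersecting disks (vectorized).

    Closed-form circular-segment formula; 0 when the disks are disjoint
    (``d >= r1 + r2``) and ``pi * min(r1, r2)**2`` when one disk contains
    the other (``d <= |r1 - r2|``).
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise InvalidParameterError("radii must be > 0")
    if np.any(d < 0):
        raise InvalidParameterError("distance must be >= 0")
    rmin = np.minimum(r1, r2)
    out = np.zeros(np.broadcast(r1, r2, d).shape)
    contained = d <= np.abs(r1 - r2)
    disjoint = d >= r1 + r2
    partial = ~contained & ~disjoint
    out[contained] = np.pi * np.broadcast_to(rmin, out.shape)[contained]**2
    if np.any(partial):
        r1p = np.broadcast_to(r1, out.shape)[partial]
        r2p = np.broadcast_to(r2, out.shape)[partial]
        dp = np.broadcast_to(d, out.shape)[partial]
        d1 = (dp**2 + r1p**2 - r2p**2) / (2.0 * dp)
        d2 = dp - d1
        seg1 = r1p**2 * np.arccos(np.clip(d1 / r1p, -1, 1)) - d1 * np.sqrt(
            np.maximum(r1p**2 - d1**2, 0.0)
        )
        seg2 = r2p**2 * np.arccos(np.clip(d2 / r2p, -1, 1)) - d2 * np.sqrt(
            np.maximum(r2p**2 - d2**2, 0.0)
        )
        out[partial] = seg1 + seg2
    return float(out) if out.ndim == 0 else out


def zero_truncated_poisson(
    lam: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson draws conditioned on k >= 1 (zeros are resampled)."""
    if lam <= 0:
        raise InvalidParameterError("lambda must be > 0")
    k = rng.poisson(lam, size=size)
    zero = k == 0
    while np.any(zero):
        k[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = k == 0
    return k


def _convergence_arrays(
    soma_points: np.ndarray,
    axon_points: np.ndarray,
    lambda_mean: float,
    dend_radius: float,
    axon_field_diam: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core of the convergence draw.

    Returns ``(k, idx, w)`` where ``idx`` is an ``(n_soma, kmax)`` array of
    axon row indices (nearest first), ``w`` the matching normalized weights
    (zero beyond each neuron's k), and ``k`` the per-neuron input counts.
    """
    n_soma = soma_points.shape[0]
    n_axon = axon_points.shape[0]
    k = zero_truncated_poisson(lambda_mean, n_soma, rng)
    k = np.minimum(k, n_axon)
    kmax = int(k.max())
    tree = cKDTree(axon_points)
    dist, idx = tree.query(soma_points, k=kmax)
    dist = np.atleast_2d(dist.reshape(n_soma, kmax))
    idx = np.atleast_2d(idx.reshape(n_soma, kmax))
    sel = np.arange(kmax)[None, :] < k[:, None]
    w = circle_overlap_area(dend_radius, axon_field_diam / 2.0, dist)
    w = np.where(sel, w, 0.0)
    sums = w.sum(axis=1)
    # pathological case: every selected axon beyond overlap range -> uniform
    dead = sums <= 0
    if np.any(dead):
        w[dead] = np.where(sel[dead], 1.0, 0.0)
        sums = w.sum(axis=1)
    w /= sums[:, None]
    return k, idx, w


def draw_convergence(
    sc_soma: TilingPattern,
    axon: TilingPattern,
    lambda_mean: float,
    dend_radius: float,
    axon_field_diam: float,
    seed: int | np.random.Generator | None = None,
) -> ConnectivitySet:
    """Draw RGC→SC connectivity: k ~ zero-truncated Poisson(λ) nearest axons.

    For each SC soma, k is drawn from a zero-truncated Poisson with mean
    parameter ``lambda_mean``; the k axon centers nearest to the soma
    (Euclidean distance) are connected with weights proportional to the
    dendritic-field/axonal-field disk overlap at each soma–axon distance,
    renormalized to sum to 1.  If all overlaps vanish the weights fall back
    to uniform over the selected axons.
    """
    if len(axon) == 0:
        raise InvalidInputError("axon pattern must be nonempty")
    if sc_soma.unit != "um" or axon.unit != "um":
        raise UnitError("both patterns must be in μm (SC space)")
    if lambda_mean < 1:
        raise InvalidParameterError("lambda_mean must be >= 1")
    rng = np.random.default_rng(seed)
    k, idx, w = _convergence_arrays(
        sc_soma.points, axon.points, lambda_mean, dend_radius, axon_field_diam, rng
    )
    records = []
    for i, sc_id in enumerate(sc_soma.ids):
        ki = int(k[i])
        records.append(
            ConnectivityRecord(
                sc_id=int(sc_id),
                axon_ids=axon.ids[idx[i, :ki]],
                weights=w[i, :ki],
            )
        )
    return ConnectivitySet(records=tuple(records))


def compute_sc_rfs(connectivity: ConnectivitySet, rgc_rf: TilingPattern) -> TilingPattern:
    """SC receptive-field centers as weighted averages of input RGC RF centers.

    Each SC neuron's RF center is ``sum_i w_i * rf_i`` over its connected
    axons' RF centers; output ids are the SC soma ids, in visual degrees.
    """
    pos = {int(i): k for k, i in enumerate(rgc_rf.ids)}
    ids = []
    pts = []
    for rec in connectivity:
        try:
            rows = [pos[int(a)] for a in rec.axon_ids]
        except KeyError as exc:
            raise ConsistencyError(
                f"SC neuron {rec.sc_id}: no RF for connected axon {exc.args[0]}"
            ) from exc
        ids.append(rec.sc_id)
        pts.append(rec.weights @ rgc_rf.points[rows])
    return TilingPattern(
        ids=np.array(ids, dtype=np.int64),
        points=np.array(pts),
        unit=rgc_rf.unit,
        space=rgc_rf.space,
    )


# ---------------------------------------------------------------------------
# Full model (steps 1–4)
# ---------------------------------------------------------------------------

def simulate_projection(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[TilingPattern, TilingPattern]:
    """Steps 1–2: RGC RF lattice and its jittered axonal projection."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rf = make_hex_lattice(
        config.l_rf, config.jitter_frac, config.grid_rows, config.grid_cols,
        seed=rng, unit="deg", space="visual",
    )
    axon = project_axons(rf, config.l_rf, config.l_axon, config.sigma, seed=rng)
    return rf, axon


def simulate_model(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> GroundTruth:
    """Run the full four-step retinocollicular model."""
    root = config.seed if seed is None else seed
    if isinstance(root, np.random.Generator):
        rng_rf = rng_soma = rng_conv = root
    else:
        rng_rf = substream(root, "projection")
        rng_soma = substream(root, "soma_lattice")
        rng_conv = substream(root, "convergence")
    rf, axon = simulate_projection(config, seed=rng_rf)
    soma = make_hex_lattice(
        config.l_soma, config.jitter_frac, config.grid_rows, config.grid_cols,
        seed=rng_soma, unit="um", space="sc",
    )
    conn = draw_convergence(
        soma, axon, config.lambda_mean, config.dend_radius,
        config.axon_field_diam, seed=rng_conv,
    )
    sc_rf = compute_sc_rfs(conn, rf)
    return GroundTruth(
        rgc_rf=rf, axon=axon, sc_soma=soma, sc_rf=sc_rf,
        connectivity=conn, config=config,
    )


# ---------------------------------------------------------------------------
# Synthetic recordings (LNP)
# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def make_checkerboard(
    duration: float,
    seed: int | np.random.Generator | None = None,
    field_w: float = 3.7,
    field_h: float = 2.9,
    rate_hz: float = 4.0,
    screen_az: float = 36.5,
    screen_el: float = 22.0,
) -> StimulusEnsemble:
    """Binary white-noise checkerboard at the experimental stimulus geometry.

    Rectangular fields ``field_w x field_h`` degrees tile a screen spanning
    ±``screen_az`` in azimuth and ±``screen_el`` in elevation; every field is
    modulated independently by binary white noise at ``rate_hz``.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n_az = int(2 * screen_az // field_w)
    n_el = int(2 * screen_el // field_h)
    n_frames = int(round(duration * rate_hz))
    frames = rng.integers(0, 2, size=(n_frames, n_el, n_az)).astype(np.uint8)
    return StimulusEnsemble(
        frames=frames, field_w=field_w, field_h=field_h, rate_hz=rate_hz,
        screen_az=screen_az, screen_el=screen_el,
    )


def synth_recording(
    truth_rfs: Sequence[ReceptiveField],
    stimulus: StimulusEnsemble,
    duration: float | None = None,
    gain: float = 8.0,
    baseline: float = -1.5,
    frame_rate: float = 30.0,
    seed: int | np.random.Generator | None = None,
) -> SyntheticRecording:
    """Simulate event-count traces from ground-truth RFs (LNP model).

    Each ROI filters the mean-subtracted stimulus with its RF's spatial
    Gaussian (unit L2 norm) evaluated at its peak latency, passes the drive
    through ``softplus(baseline + gain * drive)`` to get a firing rate in
    Hz, and emits Poisson event counts per imaging frame.
    """
    if len(truth_rfs) == 0:
        raise InvalidInputError("truth_rfs must be nonempty")
    for rf in truth_rfs:
        if not (np.isfinite(rf.center[0]) and np.isfinite(rf.center[1])):
            raise InvalidInputError("all RF centers must be finite")
    if duration is None:
        duration = stimulus.duration
    if duration <= 0 or duration > stimulus.duration + 1e-9:
        raise InvalidParameterError(
            "duration must be positive and within the stimulus span"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate

    s_flat = stimulus.frames.reshape(stimulus.n_frames, -1).astype(float)
    s_flat -= s_flat.mean(axis=0)
    az, el = stimulus.field_centers()
    azg, elg = np.meshgrid(az, el)

    traces = np.empty((len(truth_rfs), n_frames))
    for i, rf in enumerate(truth_rfs):
        g = rf.evaluate(azg, elg).ravel()
        norm = np.linalg.norm(g)
        if norm > 0:
            g = g / norm
        lag = rf.peak_latency / 1000.0
        stim_idx = np.clip(
            np.floor((t - lag) * stimulus.rate_hz).astype(int),
            0, stimulus.n_frames - 1,
        )
        drive = s_flat[stim_idx] @ g
        rate = _softplus(baseline + gain * drive)
        traces[i] = rng.poisson(rate / frame_rate)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SyntheticRecording(
        stimulus=stimulus, traces=traces, frame_rate=frame_rate,
        truth_rfs=tuple(truth_rfs), seed=seed_val,
    )
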