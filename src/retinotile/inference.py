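"""Simulation-based inference of projection jitter σ and convergence λ.

The generative model (:mod:`retinotile.simgen`) is swept over one parameter
at a time; each grid value gets many independent repetitions of the
simulation, and the tiling match between the paired patterns is recorded.
The resulting median match-vs-parameter curve is monotone in expectation —
decreasing in σ (more projection jitter, less precise retinotopy) and
increasing in λ (more convergent inputs, better averaging of the axonal
jitter).  Inverting the curve at an experimentally observed match level
yields the parameter estimate; the 95% CI is the parameter interval whose
simulated 2.5–97.5% match band covers the observed value.

Matches are evaluated on the interior lattice nodes only (boundary nodes of
a Delaunay triangulation have unstable adjacency and would bias the
statistic down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import InvalidParameterError, OutOfRangeError
from .simgen import SimConfig, _convergence_arrays, make_hex_lattice, substream
from .tiling import _edges_from_simplices, _match_fraction_codes, _simplices

SIGMA_GRID_DEFAULT = np.arange(0.0, 51.0, 1.0)          # μm
LAMBDA_GRID_DEFAULT = np.arange(1.0, 10.0 + 1e-9, 0.25)  # RGC inputs / SC cell


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Match-vs-parameter curve with a per-value 95% repetition band."""

    param_name: str              # "sigma" or "lambda"
    grid: np.ndarray
    median: np.ndarray           # percent
    lo95: np.ndarray             # 2.5th percentile over repetitions
    hi95: np.ndarray             # 97.5th percentile over repetitions
    repetitions: int
    config: SimConfig
    seed: int | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise InvalidParameterError("sweep grid must be strictly increasing")
        if np.any(self.lo95 > self.median + 1e-9) or np.any(
            self.hi95 < self.median - 1e-9
        ):
            raise InvalidParameterError("95% band must contain the median")


@dataclass(frozen=True)
class ParamEstimate:
    """Inverted parameter estimate with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    observed_match: float
    param_name: str

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.point <= self.ci_high + 1e-9):
            raise InvalidParameterError("CI must contain the point estimate")

    @property
    def ci_half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


# ---------------------------------------------------------------------------
# Fast interior-node match (shared by both sweeps)
# ---------------------------------------------------------------------------

def _interior_edge_codes(points: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """Delaunay edge codes restricted to edges with both endpoints interior."""
    e = _edges_from_simplices(_simplices(points))
    keep = interior[e[:, 0]] & interior[e[:, 1]]
    e = e[keep]
    n = points.shape[0]
    return np.sort(e[:, 0].astype(np.int64) * n + e[:, 1])


def _interior_match(
    pts_a: np.ndarray, pts_b: np.ndarray, interior: np.ndarray
) -> float:
    """Tiling match (%) between point-paired patterns on interior nodes."""
    return _match_fraction_codes(
        _interior_edge_codes(pts_a, interior),
        _interior_edge_codes(pts_b, interior),
    )


def _interior_mask(config: SimConfig) -> np.ndarray:
    mask = np.zeros(config.grid_rows * config.grid_cols, dtype=bool)
    mask[config.interior_ids()] = True
    return mask


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def sweep_sigma(
    config: SimConfig | None = None,
    grid: np.ndarray | None = None,
    repetitions: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SweepResult:
    """Median tiling match between RF and axon patterns vs projection jitter σ.

    For each σ on the grid (default 0–50 μm in 1 μm steps) and each
    repetition, a fresh jittered hexagonal RF lattice is generated and
    projected to SC with jitter σ; the Delaunay common-edge match between
    the paired patterns is evaluated on interior lattice nodes.  At σ = 0
    the projection is a pure similarity transform, so the match is exactly
    100%.
    """
    config = config or SimConfig()
    grid = SIGMA_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 5 * config.l_axon):
        raise InvalidParameterError("sigma grid must lie within [0, 5*l_axon]")
    if repetitions < 100:
        raise InvalidParameterError("at least 100 repetitions are required")
    rng = substream(seed, "sweep_sigma")
    interior = _interior_mask(config)
    scale = config.l_axon / config.l_rf
    med = np.empty(grid.size)
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    matches = np.empty(repetitions)
    for gi, sig in enumerate(grid):
        for r in range(repetitions):
            rf = make_hex_lattice(
                config.l_rf, config.jitter_frac,
                config.grid_rows, config.grid_cols, seed=rng,
                unit="deg", space="visual",
            )
            axon_pts = rf.points * scale
            if sig > 0:
                axon_pts = axon_pts + rng.normal(0.0, sig, size=axon_pts.shape)
            matches[r] = _interior_match(rf.points, axon_pts, interior)
        med[gi] = np.median(matches)
        lo[gi], hi[gi] = np.percentile(matches, [2.5, 97.5])
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SweepResult(
        param_name="sigma", grid=grid, median=med, lo95=lo, hi95=hi,
        repetitions=repetitions, config=config, seed=seed_val,
    )


def sweep_lambda(
    config: SimConfig | None = None,
    sigma_fixed: float | None = None,
    grid: np.ndarray | None = None,
    repetitions: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SweepResult:
    """Median SC soma-vs-RF tiling match vs mean input convergence λ.

    For each λ (default 1–10 in 0.25 steps) and each repetition the full
    four-step model runs: RF lattice → axonal projection at ``sigma_fixed``
    (default: the config's σ) → SC soma lattice → zero-truncated-Poisson
    convergence with disk-overlap weights → SC RF centers as weighted input
    averages.  The match between the SC soma pattern and the SC RF pattern
    is evaluated on interior nodes.
    """
    config = config or SimConfig()
    sigma = config.sigma if sigma_fixed is None else float(sigma_fixed)
    if sigma < 0:
        raise InvalidParameterError("sigma_fixed must be >= 0")
    grid = LAMBDA_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid < 1):
        raise InvalidParameterError("lambda grid must be >= 1")
    if repetitions < 100:
        raise InvalidParameterError("at least 100 repetitions are required")
    rng = substream(seed, "sweep_lambda")
    interior = _interior_mask(config)
    scale = config.l_axon / config.l_rf
    med = np.empty(grid.size)
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    matches = np.empty(repetitions)
    for gi, lam in enumerate(grid):
        for r in range(repetitions):
            rf = make_hex_lattice(
                config.l_rf, config.jitter_frac,
                config.grid_rows, config.grid_cols, seed=rng,
                unit="deg", space="visual",
            )
            axon_pts = rf.points * scale
            if sigma > 0:
                axon_pts = axon_pts + rng.normal(0.0, sigma, size=axon_pts.shape)
            soma = make_hex_lattice(
                config.l_soma, config.jitter_frac,
                config.grid_rows, config.grid_cols, seed=rng,
                unit="um", space="sc",
            )
            _, idx, w = _convergence_arrays(
                soma.points, axon_pts, lam,
                config.dend_radius, config.axon_field_diam, rng,
            )
            sc_rf_pts = np.einsum("ik,ikj->ij", w, rf.points[idx])
            matches[r] = _interior_match(soma.points, sc_rf_pts, interior)
        med[gi] = np.median(matches)
        lo[gi], hi[gi] = np.percentile(matches, [2.5, 97.5])
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SweepResult(
        param_name="lambda", grid=grid, median=med, lo95=lo, hi95=hi,
        repetitions=repetitions, config=config, seed=seed_val,
    )


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def _isotonic(x: np.ndarray, y: np.ndarray, increasing: bool) -> np.ndarray:
    return IsotonicRegression(increasing=increasing).fit_transform(x, y)


def _crossing_interval(
    x: np.ndarray, y: np.ndarray, target: float
) -> tuple[float, float]:
    """[x_first, x_last] where a nondecreasing piecewise-linear y meets target."""
    if target < y[0] or target > y[-1]:
        raise OutOfRangeError(
            f"observed value {target} outside curve range [{y[0]:.3g}, {y[-1]:.3g}]"
        )
    # first crossing
    i = int(np.searchsorted(y, target, side="left"))
    if i == 0:
        x_first = float(x[0])
    else:
        y0, y1 = y[i - 1], y[i]
        x_first = float(x[i]) if y1 == y0 else float(
            x[i - 1] + (target - y0) / (y1 - y0) * (x[i] - x[i - 1])
        )
    # last crossing
    j = int(np.searchsorted(y, target, side="right"))
    if j == y.size:
        x_last = float(x[-1])
    else:
        y0, y1 = y[j - 1], y[j]
        x_last = float(x[j - 1]) if y1 == y0 else float(
            x[j - 1] + (target - y0) / (y1 - y0) * (x[j] - x[j - 1])
        )
    return min(x_first, x_last), max(x_first, x_last)


def ci_from_band(sweep: SweepResult, observed_match: float) -> tuple[float, float] | None:
    """95% CI: the parameter interval whose simulated band covers ``observed_match``.

    The 2.5/97.5-percentile curves are isotonic-smoothed (same direction as
    the median) and linearly interpolated; returns ``None`` when the band
    never covers the observed value.  Unlike :func:`invert_curve` this does
    not require the observed match to lie within the median curve's range,
    so it also serves pseudo-experiments whose single-repetition match falls
    in the tails.
    """
    x = np.asarray(sweep.grid, dtype=float)
    increasing = bool(sweep.median[-1] >= sweep.median[0])
    lo = _isotonic(x, sweep.lo95, increasing)
    hi = _isotonic(x, sweep.hi95, increasing)
    fine = np.linspace(x[0], x[-1], max(2001, 40 * x.size))
    lo_f = np.interp(fine, x, lo)
    hi_f = np.interp(fine, x, hi)
    inside = (lo_f <= observed_match) & (observed_match <= hi_f)
    if not np.any(inside):
        return None
    return float(fine[inside].min()), float(fine[inside].max())


def invert_curve(sweep: SweepResult, observed_match: float) -> ParamEstimate:
    """Invert a match-vs-parameter curve at an observed match level.

    The median curve is made monotone by isotonic regression (finite
    repetitions leave small non-monotone wiggles) and linearly interpolated
    between grid points; the point estimate is the parameter where it
    crosses ``observed_match`` (midpoint of the crossing interval if the
    curve is locally flat).  The 95% CI is the parameter interval whose
    isotonic-smoothed 2.5–97.5% band covers the observed match.
    """
    x = np.asarray(sweep.grid, dtype=float)
    increasing = bool(sweep.median[-1] >= sweep.median[0])
    med = _isotonic(x, sweep.median, increasing)

    if increasing:
        a, b = _crossing_interval(x, med, observed_match)
    else:
        # mirror the x-axis so the curve is nondecreasing, then map back
        a, b = _crossing_interval(-x[::-1], med[::-1], observed_match)
        a, b = -b, -a
    point = 0.5 * (a + b)

    band = ci_from_band(sweep, observed_match)
    if band is not None:
        ci_low = float(min(band[0], point))
        ci_high = float(max(band[1], point))
    else:
        ci_low = ci_high = point
    return ParamEstimate(
        point=float(point), ci_low=ci_low, ci_high=ci_high,
        observed_match=float(observed_match), param_name=sweep.param_name,
    )
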