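"""Tiling-pattern statistics for paired point sets.

The central question this module answers is: do two labeled point patterns —
typically anatomical positions of cells in one space and the centers of their
receptive fields in another — share the same neighborhood structure?  The
statistic is the *tiling pattern match*: the Delaunay triangulation is
computed independently in each space, edges are identified by the point
labels they join, and the match is the number of edges common to both
triangulations divided by the mean edge count, expressed in percent.  A
bootstrap null (random relabeling of one pattern) gives the chance level,
and a least-squares affine registration between the two spaces yields a
per-point deviation Δ from the topographically ideal position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay as _SciPyDelaunay

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    PairingError,
)

VALID_UNITS = ("um", "deg")
VALID_SPACES = ("sc", "visual")

# Golden-ratio angle used for the deterministic symbolic perturbation that
# resolves cocircular Delaunay ties (e.g. four points on a square).
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_PERTURB_SCALE = 1e-9


# ---------------------------------------------------------------------------
# Point patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TilingPattern:
    """A labeled 2D point set in a single coordinate space.

    Parameters
    ----------
    ids
        Unique integer labels, one per point.  Edges between patterns are
        identified by these labels, so two patterns describing the same cells
        in different spaces must share ids.
    points
        ``(n, 2)`` float coordinates.
    unit
        ``"um"`` (cortical/collicular space) or ``"deg"`` (visual space).
    space
        ``"sc"`` or ``"visual"``.
    """

    ids: np.ndarray
    points: np.ndarray
    unit: str = "um"
    space: str = "sc"

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError("points must be an (n, 2) array")
        if ids.shape[0] != pts.shape[0]:
            raise InvalidInputError("ids and points must have equal length")
        if np.unique(ids).size != ids.size:
            raise InvalidInputError("point ids must be unique")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("point coordinates must be finite")
        if self.unit not in VALID_UNITS:
            raise InvalidInputError(
                f"unknown unit {self.unit!r}; allowed: {list(VALID_UNITS)}"
            )
        if self.space not in VALID_SPACES:
            raise InvalidInputError(
                f"unknown space {self.space!r}; allowed: {list(VALID_SPACES)}"
            )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.ids.size)

    def subset(self, keep_ids: Sequence[int]) -> "TilingPattern":
        """Return the sub-pattern restricted to ``keep_ids`` (order preserved)."""
        keep = np.asarray(keep_ids, dtype=np.int64)
        pos = {int(i): k for k, i in enumerate(self.ids)}
        try:
            idx = np.array([pos[int(i)] for i in keep], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise PairingError(f"id {exc.args[0]} not present in pattern") from exc
        return replace(self, ids=self.ids[idx], points=self.points[idx])


@dataclass(frozen=True)
class Triangulation:
    """Delaunay triangulation of a :class:`TilingPattern`.

    ``edges`` are unordered id pairs stored as a sorted ``(m, 2)`` array;
    ``triangles`` are id triples.
    """

    pattern: TilingPattern
    edges: np.ndarray
    triangles: np.ndarray

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.edges}

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])


@dataclass(frozen=True)
class MatchResult:
    """Common-edge comparison of two paired triangulations."""

    fraction: float  # percent
    common_edges: np.ndarray
    unique_a: np.ndarray
    unique_b: np.ndarray
    n_edges_a: int
    n_edges_b: int

    @property
    def n_common(self) -> int:
        return int(self.common_edges.shape[0])


@dataclass(frozen=True)
class BootstrapNull:
    """Null distribution of the match under random relabeling."""

    null_fractions: np.ndarray
    alpha: float
    threshold: float
    seed: int | None = None

    @property
    def repetitions(self) -> int:
        return int(self.null_fractions.size)


@dataclass(frozen=True)
class AffineFit:
    """Least-squares affine registration of one pattern onto another.

    ``coefficients`` is the 2x3 matrix ``[A | b]`` mapping source coordinates
    ``s`` to ``A s + b``; ``deviations`` are the per-point Euclidean residuals
    Δ in destination units.
    """

    coefficients: np.ndarray
    deviations: np.ndarray
    ids: np.ndarray
    unit: str

    @property
    def summary(self) -> tuple[float, float]:
        """(median, MAD) of the per-point deviations."""
        return deviation_summary(self.deviations)

    def transform(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.coefficients[:, :2].T + self.coefficients[:, 2]


# ---------------------------------------------------------------------------
# Delaunay triangulation
# ---------------------------------------------------------------------------

def _perturb(points: np.ndarray) -> np.ndarray:
    """Index-keyed deterministic micro-displacement.

    Breaks cocircular degeneracies so the triangulation — and in particular
    which diagonal of a perfect square is kept — is reproducible across runs.
    The displacement is ~1e-9 of the pattern extent, far below any physical
    coordinate precision in this domain.
    """
    n = points.shape[0]
    scale = max(float(np.ptp(points[:, 0])), float(np.ptp(points[:, 1])), 1.0)
    k = np.arange(1, n + 1, dtype=float)
    ang = 2.0 * np.pi * _GOLDEN * k
    delta = (_PERTURB_SCALE * scale * k / n)[:, None] * np.stack(
        [np.cos(ang), np.sin(ang)], axis=1
    )
    return points + delta


def _simplices(points: np.ndarray) -> np.ndarray:
    """Delaunay simplices (index triples) of a point array, ties broken."""
    if points.shape[0] < 3:
        raise DegenerateInputError("triangulation requires at least 3 points")
    # collinearity check on the raw points (the tie-break perturbation below
    # would lift them off the line)
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(points).max())) < 2:
        raise DegenerateInputError("all points are collinear")
    pts = _perturb(points)
    try:
        tri = _SciPyDelaunay(pts)
    except Exception as exc:
        raise DegenerateInputError(f"triangulation failed: {exc}") from exc
    if tri.simplices.shape[0] == 0:
        raise DegenerateInputError("degenerate input: no triangles produced")
    return tri.simplices


def _edges_from_simplices(simplices: np.ndarray) -> np.ndarray:
    """Unique undirected edges (index pairs, each row sorted) of a simplex set."""
    e = np.concatenate(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [0, 2]]], axis=0
    )
    e.sort(axis=1)
    return np.unique(e, axis=0)


def _edge_codes(points: np.ndarray) -> np.ndarray:
    """Sorted integer codes i*n+j (i<j) of the Delaunay edges of ``points``."""
    n = points.shape[0]
    e = _edges_from_simplices(_simplices(points))
    return np.sort(e[:, 0].astype(np.int64) * n + e[:, 1])


def delaunay(pattern: TilingPattern) -> Triangulation:
    """Delaunay triangulation of a pattern, edges labeled by point id.

    Cocircular degeneracies (four or more points on one circle) are resolved
    by a deterministic index-keyed perturbation, so repeated calls always
    return the same edge set.

    Raises
    ------
    DegenerateInputError
        If fewer than 3 points are given or all points are collinear.
    """
    simp = _simplices(pattern.points)
    edges_idx = _edges_from_simplices(simp)
    ids = pattern.ids
    edges = np.sort(ids[edges_idx], axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    triangles = np.sort(ids[simp], axis=1)
    return Triangulation(pattern=pattern, edges=edges[order], triangles=triangles)


# ---------------------------------------------------------------------------
# Tiling-pattern match
# ---------------------------------------------------------------------------

def _check_paired(pat_a: TilingPattern, pat_b: TilingPattern) -> np.ndarray:
    """Return index array aligning pat_b's points to pat_a's id order."""
    if len(pat_a) != len(pat_b) or not np.array_equal(
        np.sort(pat_a.ids), np.sort(pat_b.ids)
    ):
        raise PairingError("patterns must contain identical id sets")
    pos_b = {int(i): k for k, i in enumerate(pat_b.ids)}
    return np.array([pos_b[int(i)] for i in pat_a.ids], dtype=np.intp)


def _match_fraction_codes(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    n_common = np.intersect1d(codes_a, codes_b, assume_unique=True).size
    return 100.0 * n_common / (0.5 * (codes_a.size + codes_b.size))


def tiling_match(
    pat_a: TilingPattern,
    pat_b: TilingPattern,
    restrict_ids: Sequence[int] | None = None,
) -> MatchResult:
    """Common-edge fraction between the Delaunay triangulations of two
    patterns paired by point id.

    The match is ``100 * |common edges| / mean(n_edges_a, n_edges_b)``.
    Edges are compared as unordered id pairs; geometry enters only through
    each pattern's own triangulation, so the statistic is invariant under
    any similarity transform of either pattern.

    Parameters
    ----------
    pat_a, pat_b
        Patterns with identical id sets (e.g. axon centroids and the matched
        receptive-field centers).
    restrict_ids
        If given, only edges whose *both* endpoints are in this id set are
        counted (used to exclude unstable boundary nodes); the
        triangulations themselves are still computed on all points.
    """
    _check_paired(pat_a, pat_b)
    tri_a = delaunay(pat_a)
    tri_b = delaunay(pat_b)
    edges_a, edges_b = tri_a.edges, tri_b.edges
    if restrict_ids is not None:
        keep = np.asarray(restrict_ids, dtype=np.int64)
        edges_a = edges_a[np.isin(edges_a, keep).all(axis=1)]
        edges_b = edges_b[np.isin(edges_b, keep).all(axis=1)]

    set_a = {tuple(e) for e in edges_a}
    set_b = {tuple(e) for e in edges_b}
    common = sorted(set_a & set_b)
    only_a = sorted(set_a - set_b)
    only_b = sorted(set_b - set_a)
    n_a, n_b = len(set_a), len(set_b)
    denom = 0.5 * (n_a + n_b)
    frac = 100.0 * len(common) / denom if denom > 0 else 0.0

    def _arr(pairs: list[tuple[int, int]]) -> np.ndarray:
        return np.array(pairs, dtype=np.int64).reshape(-1, 2)

    return MatchResult(
        fraction=frac,
        common_edges=_arr(common),
        unique_a=_arr(only_a),
        unique_b=_arr(only_b),
        n_edges_a=n_a,
        n_edges_b=n_b,
    )


def bootstrap_chance(
    pat_a: TilingPattern,
    pat_b: TilingPattern,
    repetitions: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> BootstrapNull:
    """Chance level of the tiling match under random correspondence.

    The id correspondence of ``pat_b`` is randomly permuted (a full
    permutation, no replacement) ``repetitions`` times; each permutation
    yields one null match fraction.  The chance threshold is the empirical
    ``1 - alpha`` quantile of that null distribution, i.e. the one-sided
    p = alpha level.

    Both triangulations are fixed — only the labeling varies — so the null
    is computed on integer edge codes and is fast even at 10,000 repetitions.
    """
    import warnings

    if repetitions < 100:
        warnings.warn(
            "fewer than 100 bootstrap repetitions give an unreliable threshold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    align = _check_paired(pat_a, pat_b)
    n = len(pat_a)
    # index-space edges, with b's indices re-expressed in a's id order
    codes_a = _edge_codes(pat_a.points)
    edges_b = _edges_from_simplices(_simplices(pat_b.points))
    inv = np.empty(n, dtype=np.int64)
    inv[align] = np.arange(n)  # b-row -> position in a's order
    eb = inv[edges_b]

    null = np.empty(repetitions)
    for r in range(repetitions):
        perm = rng.permutation(n)
        pe = perm[eb]
        pe.sort(axis=1)
        codes = np.sort(pe[:, 0] * n + pe[:, 1])
        null[r] = _match_fraction_codes(codes_a, codes)
    threshold = float(np.quantile(null, 1.0 - alpha))
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return BootstrapNull(
        null_fractions=null, alpha=alpha, threshold=threshold, seed=seed_val
    )


# ---------------------------------------------------------------------------
# Affine-optimal retinotopy deviation
# ---------------------------------------------------------------------------

def affine_fit(src: TilingPattern, dst: TilingPattern) -> AffineFit:
    """Least-squares affine map from ``src`` onto ``dst`` and its residuals.

    Solves for the 6-parameter affine transform ``A s + b`` minimizing
    ``sum_i || A s_i + b - d_i ||^2`` over paired points, then reports the
    per-point Euclidean deviation Δ_i in destination units.  Δ quantifies how
    far each point sits from its topographically ideal (affine-predicted)
    position; the conventional summary is median ± MAD.
    """
    align = _check_paired(src, dst)
    s = src.points
    d = dst.points[align]
    if s.shape[0] < 3:
        raise InvalidInputError("affine fit requires at least 3 paired points")
    design = np.column_stack([s, np.ones(s.shape[0])])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateInputError("source points are collinear; affine fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, d, rcond=None)  # (3, 2)
    pred = design @ coef
    dev = np.linalg.norm(pred - d, axis=1)
    return AffineFit(
        coefficients=coef.T, deviations=dev, ids=src.ids.copy(), unit=dst.unit
    )


def deviation_summary(deviations: np.ndarray | Sequence[float] | AffineFit) -> tuple[float, float]:
    """Median ± median-absolute-deviation summary of per-point deviations."""
    if isinstance(deviations, AffineFit):
        deviations = deviations.deviations
    dev = np.asarray(deviations, dtype=float)
    if dev.size == 0:
        raise InvalidInputError("no deviations to summarize")
    med = float(np.median(dev))
    mad = float(np.median(np.abs(dev - med)))
    return med, mad
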