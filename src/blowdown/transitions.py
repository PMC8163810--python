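"""Canopy height-class transitions and equilibrium projection.

Paired 5 m canopy height rasters are binned into 1 m height classes
(class c covers [c-1, c) m) and tallied into a transition count matrix A
whose entry a_ij is the number of pixels starting in class j and ending in
class i.  Column-normalizing A gives a column-stochastic Markov matrix P;
the projected equilibrium height distribution is the dominant right
eigenvector of P (eigenvalue 1), i.e. the distribution left unchanged by
the observed transition dynamics.

Uncertainty: each column of transition probabilities is multinomial, so
with a uniform Dirichlet prior the column posteriors are
Dirichlet(counts + 1).  Sampling columns from their posteriors and
recomputing the stationary distribution per draw yields per-class 95%
credible envelopes and an interval on the equilibrium mean height.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .rasters import HeightRaster

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionModel",
    "SteadyState",
    "build_transition_matrix",
    "steady_state",
    "steady_state_posterior",
    "compare_distributions",
    "DistributionComparison",
    "height_distribution",
]


@dataclass
class TransitionModel:
    """Height-class transition counts a_ij (start class j -> end class i)."""

    counts: np.ndarray
    class_width_m: float = 1.0
    class_edges: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 height classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.class_edges is None:
            self.class_edges = np.arange(self.n_classes + 1) * self.class_width_m

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def class_midpoints(self) -> np.ndarray:
        return (self.class_edges[:-1] + self.class_edges[1:]) / 2.0

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class SteadyState:
    """Projected equilibrium height distribution with optional posterior."""

    distribution: np.ndarray
    mean_height_m: float
    class_midpoints: np.ndarray = field(repr=False, default=None)
    posterior_envelope: np.ndarray = field(repr=False, default=None)  # (2, n_classes)
    mean_height_ci: tuple[float, float] | None = None
    n_posterior_draws: int = 0
    seed: int | None = None


def _class_index(heights: np.ndarray, n_classes: int, width: float) -> np.ndarray:
    """Half-open 1 m bins; heights at/above the top edge go to the last class."""
    idx = np.floor(heights / width).astype(int)
    return np.clip(idx, 0, n_classes - 1)


def build_transition_matrix(pre: HeightRaster, post: HeightRaster,
                            class_width_m: float = 1.0) -> TransitionModel:
    """Tally paired valid pixels into the height-class transition matrix.

    The class count is the ceiling of the maximum height over both epochs
    divided by the class width (the tallest pixel defines the top class).
    """
    if not pre.same_grid(post):
        raise ValueError("transition matrix requires aligned rasters")
    both = pre.mask & post.mask
    h0 = pre.values[both]
    h1 = post.values[both]
    if h0.size == 0:
        raise ValueError("no paired valid pixels")
    if h0.min() < 0 or h1.min() < 0:
        raise ValueError("heights must be >= 0")
    top = max(h0.max(), h1.max())
    n_classes = max(int(np.ceil(top / class_width_m)), 2)
    j = _class_index(h0, n_classes, class_width_m)
    i = _class_index(h1, n_classes, class_width_m)
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    return TransitionModel(counts, class_width_m)


def _column_stochastic(counts: np.ndarray, warn_empty: bool = True) -> np.ndarray:
    counts = counts.astype(float)
    sums = counts.sum(axis=0)
    p = np.empty_like(counts)
    empty = sums == 0
    if empty.any() and warn_empty:
        warnings.warn(
            f"{int(empty.sum())} empty start-class(es) assigned uniform columns",
            stacklevel=3,
        )
    p[:, ~empty] = counts[:, ~empty] / sums[~empty]
    p[:, empty] = 1.0 / counts.shape[0]
    return p


def _closed_classes(p: np.ndarray) -> list[np.ndarray]:
    """Closed communicating classes of the chain with transition matrix p
    (column-stochastic: p[i, j] = P(j -> i))."""
    adj = (p > 0).T  # adj[j, i]: j -> i
    n_comp, assign = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.flatnonzero(assign == c)
        outside = np.setdiff1d(np.arange(p.shape[0]), members)
        if not adj[np.ix_(members, outside)].any():
            closed.append(members)
    return closed


def _stationary(p: np.ndarray) -> np.ndarray:
    """Dominant right eigenvector of a column-stochastic matrix, as a
    probability vector.  Fails loudly if the dominant eigenvalue is not 1."""
    vals, vecs = np.linalg.eig(p)
    k = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[k] - 1.0) > 1e-9:
        raise RuntimeError(
            f"dominant eigenvalue {vals[k]:.12f} differs from 1; "
            "matrix is not column-stochastic"
        )
    v = vecs[:, k].real
    if v.sum() < 0:
        v = -v
    if (v < -1e-10).any():
        raise RuntimeError("stationary eigenvector has mixed signs (reducible chain?)")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def steady_state(model: TransitionModel, warn_empty: bool = True) -> SteadyState:
    """Point estimate of the equilibrium height distribution.

    Empty start-classes get uniform columns (with a warning).  A reducible
    chain with several closed class sets has no unique equilibrium; this is
    an error listing the closed blocks.
    """
    p = _column_stochastic(model.counts, warn_empty)
    closed = _closed_classes(p)
    if len(closed) > 1:
        blocks = "; ".join(str(list(b)) for b in closed)
        raise ValueError(f"reducible transition matrix: closed class blocks {blocks}")
    dist = _stationary(p)
    mids = model.class_midpoints
    return SteadyState(dist, float(dist @ mids), mids)


def steady_state_posterior(model: TransitionModel, n_draws: int = 10_000,
                           seed: int = 0, max_retries: int = 100) -> SteadyState:
    """Dirichlet-multinomial posterior of the equilibrium distribution.

    Each draw samples every column j from Dirichlet(counts[:, j] + 1) and
    recomputes the stationary distribution.  Per-class 2.5/97.5 percentile
    envelopes and the credible interval of the equilibrium mean height are
    reported.  The point estimate is the stationary distribution of the
    posterior-mean transition matrix (counts + 1 column-normalized), which
    is strictly positive and hence always irreducible — sparse count
    matrices from small rasters often are not.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    n = model.n_classes
    alpha = model.counts.astype(float) + 1.0
    mids = model.class_midpoints
    dists = np.empty((n_draws, n))
    means = np.empty(n_draws)
    for d in range(n_draws):
        for attempt in range(max_retries):
            g = rng.standard_gamma(alpha)  # column-wise Dirichlet via gammas
            p = g / g.sum(axis=0)
            try:
                dist = _stationary(p)
                break
            except RuntimeError:  # pragma: no cover - Dirichlet columns are a.s. positive
                continue
        else:  # pragma: no cover
            raise RuntimeError("could not draw an irreducible transition matrix")
        dists[d] = dist
        means[d] = dist @ mids
    p_mean = alpha / alpha.sum(axis=0)
    point_dist = _stationary(p_mean)
    envelope = np.percentile(dists, [2.5, 97.5], axis=0)
    return SteadyState(
        distribution=point_dist,
        mean_height_m=float(point_dist @ mids),
        class_midpoints=mids,
        posterior_envelope=envelope,
        mean_height_ci=(float(np.percentile(means, 2.5)),
                        float(np.percentile(means, 97.5))),
        n_posterior_draws=n_draws,
        seed=seed,
    )


def height_distribution(raster: HeightRaster, n_classes: int,
                        class_width_m: float = 1.0) -> np.ndarray:
    """Observed height-class probability distribution of a raster."""
    h = raster.values[raster.mask]
    idx = _class_index(h, n_classes, class_width_m)
    counts = np.bincount(idx, minlength=n_classes).astype(float)
    return counts / counts.sum()


@dataclass
class DistributionComparison:
    mean_difference_m: float     # projected minus observed mean height
    total_variation: float
    departure: bool | None       # observed mean outside projected mean CI


def compare_distributions(observed: np.ndarray, projected: SteadyState,
                          class_width_m: float = 1.0) -> DistributionComparison:
    """Compare an observed height distribution with the projected equilibrium.

    Reports the mean-height difference, the total-variation distance, and —
    when the projection carries a posterior — whether the observed mean
    falls outside the projected mean's 95% credible interval (a departure
    from steady-state conditions).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != projected.distribution.shape:
        raise ValueError("distributions must share one class grid")
    mids = (projected.class_midpoints if projected.class_midpoints is not None
            else (np.arange(len(observed)) + 0.5) * class_width_m)
    obs_mean = float(observed @ mids)
    tv = float(0.5 * np.abs(observed - projected.distribution).sum())
    departure = None
    if projected.mean_height_ci is not None:
        lo, hi = projected.mean_height_ci
        departure = not (lo <= obs_mean <= hi)
    return DistributionComparison(projected.mean_height_m - obs_mean, tv, departure)
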