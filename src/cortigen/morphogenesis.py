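"""Anatomical self-organization from the synchrony / wiring-length trade-off.

Two neuron populations — long-axon *patch* cells and short-axon *local*
cells — are placed in a bounded square sheet and relaxed under a force
equilibrium that converts the two developmental objectives into mechanics:

* attraction along potential high-synchrony couplings (strength decays
  with distance over the pair's axonal scale, so short-axon cells must sit
  close together to couple),
* a wiring-length cost on near-neighbour connections, paid per unit
  length relative to the cell's axonal scale,
* a short-range soma repulsion that prevents collapse.

Synchrony-dominated weighting produces tight local-cell clusters
(columns) surrounded by pools of patch cells; wiring-dominated weighting
produces a diffuse layout.  Increasing the patch/local axon-length ratio
moves the outcome from diffuse toward clearly columnar.

The module also scores the outcomes: a columnarity index (nearest-
neighbour clustering statistic against a complete-spatial-randomness
Monte-Carlo reference), lattice tiling classification of the column
centres (square vs hexagonal bond-angle symmetry), mirror-symmetry
scoring with a permutation null, apoptotic selection of cells for
zero-lag synchrony, and reconstruction of the symmetric bidirectional
connection graph implied by maximized synchrony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import (
    DegenerateLayoutError,
    InsufficientClustersError,
    InvalidParameterError,
    OverCullError,
)
from .field import FieldGeometry, GainState, SimulationRecord

__all__ = [
    "CellLayout",
    "ConnectionGraph",
    "MirrorPairReport",
    "apoptotic_selection",
    "cluster_centers",
    "columnarity_index",
    "force_equilibrium_layout",
    "mirror_symmetry_score",
    "reconstruct_symmetric_connections",
    "reflect_points",
    "tiling_classification",
]

PATCH, LOCAL = "patch", "local"


@dataclass
class CellLayout:
    """Two-population soma layout on a bounded square sheet."""

    positions: np.ndarray          # (n, 2)
    population: np.ndarray         # (n,) strings "patch" / "local"
    axon_scale: dict               # population -> axon length scale
    domain: float                  # square side, length units
    tiling_class: str = "unclassified"
    converged: bool = True
    chirality: Optional[np.ndarray] = None   # (n,) +-1, for mirror scoring

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def is_local(self) -> np.ndarray:
        return self.population == LOCAL

    @property
    def is_patch(self) -> np.ndarray:
        return self.population == PATCH

    def pair_axon_scale(self) -> np.ndarray:
        a = np.where(self.is_patch, self.axon_scale[PATCH], self.axon_scale[LOCAL])
        return (a[:, None] + a[None, :]) / 2.0


@dataclass
class ConnectionGraph:
    """Unordered symmetric bidirectional edges with non-negative weights."""

    edges: np.ndarray              # (m, 2) int, i < j
    weights: np.ndarray            # (m,)
    symmetric: np.ndarray          # (m,) bool
    n: int

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n, self.n))
        if len(self.edges):
            adj[self.edges[:, 0], self.edges[:, 1]] = self.weights
            adj[self.edges[:, 1], self.edges[:, 0]] = self.weights
        return adj


@dataclass
class MirrorPairReport:
    """Mirror-symmetry score of a layout about a reflection axis."""

    axis_point: np.ndarray
    axis_normal: np.ndarray        # unit normal of the reflection line
    score: float                   # in [-1, 1]; exact reflection -> 1
    blanket_cells: np.ndarray      # indices within the collision band
    null_mean: float
    null_sd: float
    n_permutations: int


# --------------------------------------------------------------------------
# force-equilibrium layout
# --------------------------------------------------------------------------


def force_equilibrium_layout(
    n_patch: int,
    n_local: int,
    axon_scale_patch: float = 4.0,
    axon_scale_local: float = 0.5,
    w_synchrony: float = 1.0,
    w_wiring: float = 1.0,
    seed: int = 0,
    domain: float = 10.0,
    k_repulsion: float = 0.25,
    r_core: float = 0.3,
    k_neighbours: int = 4,
    max_iter: int = 4000,
    tol: float = 1e-3,
    step0: float = 0.15,
) -> CellLayout:
    """Relax soma positions under synchrony attraction and wiring cost.

    Returns the layout with ``converged=False`` if the maximum
    displacement never fell below ``tol * domain`` within ``max_iter``
    iterations (the best layout found is still returned).
    """
    if w_synchrony < 0 or w_wiring < 0:
        raise InvalidParameterError("weights must be non-negative")
    if w_synchrony == 0 and w_wiring == 0:
        raise InvalidParameterError("at least one objective weight must be positive")
    if n_patch < 4 or n_local < 4:
        raise InvalidParameterError("need at least 4 cells per population")
    if axon_scale_patch < axon_scale_local:
        raise InvalidParameterError("patch axons cannot be shorter than local axons")

    rng = np.random.default_rng(seed)
    n = n_patch + n_local
    pop = np.array([PATCH] * n_patch + [LOCAL] * n_local)
    x = rng.uniform(0, domain, size=(n, 2))
    a = np.where(pop == PATCH, axon_scale_patch, axon_scale_local)
    ell = (a[:, None] + a[None, :]) / 2.0

    step = step0
    converged = False
    knn_idx = None
    eye = np.eye(n, dtype=bool)
    for it in range(max_iter):
        diff = x[:, None, :] - x[None, :, :]          # x_i - x_j
        d = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(d, 1e9)                      # self-force vanishes
        unit = diff / d[:, :, None]

        # soma repulsion (hard-core-ish)
        mag = k_repulsion * (r_core / (d + 0.05 * r_core)) ** 2
        # synchrony attraction along potential couplings: pulls pairs into
        # axonal reach but saturates inside it (no force at d << ell), so
        # the spread of a cluster scales with the local axon length
        if w_synchrony:
            mag = mag - w_synchrony * (d / ell ** 2) * np.exp(-((d / ell) ** 2))
        # wiring-length cost along near-neighbour connections
        if w_wiring:
            if it % 25 == 0 or knn_idx is None:
                order = np.argsort(d, axis=1)[:, :k_neighbours]
                knn = np.zeros((n, n), dtype=bool)
                knn[np.arange(n)[:, None], order] = True
                knn_idx = knn | knn.T
            mag = mag - np.where(knn_idx, w_wiring * (d / domain), 0.0)

        f = (mag[:, :, None] * unit).sum(axis=1)
        disp = step * f
        norm = np.sqrt((disp ** 2).sum(-1))
        cap = 0.05 * domain
        big = norm > cap
        if big.any():
            disp[big] *= (cap / norm[big])[:, None]
        x = np.clip(x + disp, 0.0, domain)
        step *= 0.999
        if np.sqrt((disp ** 2).sum(-1)).max() < tol * domain:
            converged = True
            break

    layout = CellLayout(
        positions=x, population=pop,
        axon_scale={PATCH: axon_scale_patch, LOCAL: axon_scale_local},
        domain=domain, converged=converged,
    )
    try:
        layout.tiling_class = tiling_classification(layout)
    except InsufficientClustersError:
        # clustered but with too few columns to classify a lattice
        layout.tiling_class = "irregular"
    except DegenerateLayoutError:
        layout.tiling_class = "diffuse"
    return layout


# --------------------------------------------------------------------------
# columnarity
# --------------------------------------------------------------------------


def _nn_distances(pts: np.ndarray) -> np.ndarray:
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def columnarity_index(
    layout: CellLayout | np.ndarray,
    n_mc: int = 99,
    seed: int = 0,
    domain: Optional[float] = None,
) -> float:
    """Clustering of local-cell somas against complete spatial randomness.

    The observed mean nearest-neighbour distance is compared with its
    Monte-Carlo expectation under CSR in the same domain (``n_mc`` draws):
    ``index = clip(1 - d_obs / d_csr, 0, 1)``.  0 for Poisson-diffuse (or
    over-dispersed) layouts, -> 1 for strongly clustered ones.  Invariant
    under rotation and translation.
    """
    if isinstance(layout, CellLayout):
        pts = layout.positions[layout.is_local]
        domain = layout.domain
    else:
        pts = np.asarray(layout, dtype=float)
        if domain is None:
            lo, hi = pts.min(0), pts.max(0)
            domain = float(max(hi - lo).item() if hasattr(max(hi - lo), "item")
                           else max(hi - lo))
    if len(pts) < 8:
        raise InvalidParameterError("columnarity needs at least 8 local cells")
    span = np.ptp(pts, axis=0)
    if np.all(span < 1e-12):
        raise DegenerateLayoutError("all positions coincide")

    d_obs = _nn_distances(pts).mean()
    rng = np.random.default_rng(seed)
    d_csr = np.empty(n_mc)
    for k in range(n_mc):
        ref = rng.uniform(0, domain, size=pts.shape)
        d_csr[k] = _nn_distances(ref).mean()
    return float(np.clip(1.0 - d_obs / d_csr.mean(), 0.0, 1.0))


# --------------------------------------------------------------------------
# cluster centres and tiling
# --------------------------------------------------------------------------


def cluster_centers(layout: CellLayout, eps: Optional[float] = None,
                    min_samples: int = 3) -> np.ndarray:
    """Centres of local-cell clusters (density-based grouping)."""
    pts = layout.positions[layout.is_local]
    if len(pts) < min_samples:
        raise InsufficientClustersError("too few local cells")
    if np.ptp(pts, axis=0).max() < 1e-12:
        raise DegenerateLayoutError("all local cells coincide")
    if eps is None:
        nn = np.sort(_nn_distances(pts))
        eps = 2.5 * max(np.median(nn), 1e-6 * layout.domain)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    centers = [pts[labels == k].mean(axis=0) for k in range(labels.max() + 1)]
    return np.asarray(centers) if centers else np.zeros((0, 2))


def tiling_classification(
    layout: CellLayout | np.ndarray,
    columnarity_threshold: float = 0.3,
    symmetry_threshold: float = 0.4,
) -> str:
    """Classify the column-centre lattice: square / hexagonal / irregular.

    Bond angles to near neighbours are tested for 4-fold vs 6-fold
    circular symmetry (``R_k = |mean exp(i k theta)|``).  A layout whose
    local cells are not clustered is classified ``diffuse``.
    """
    if isinstance(layout, CellLayout):
        try:
            if columnarity_index(layout) < columnarity_threshold:
                return "diffuse"
        except InvalidParameterError:
            return "diffuse"
        centers = cluster_centers(layout)
    else:
        centers = np.asarray(layout, dtype=float)
    if len(centers) < 4:
        raise InsufficientClustersError(
            f"need >= 4 cluster centres, found {len(centers)}"
        )
    diff = centers[:, None, :] - centers[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    cutoff = 1.4 * np.median(d.min(axis=1))
    ii, jj = np.where(d <= cutoff)
    if len(ii) == 0:
        return "irregular"
    theta = np.arctan2(diff[ii, jj, 1], diff[ii, jj, 0])
    r4 = np.abs(np.exp(4j * theta).mean())
    r6 = np.abs(np.exp(6j * theta).mean())
    if r4 > max(r6, symmetry_threshold):
        return "square"
    if r6 > max(r4, symmetry_threshold):
        return "hexagonal"
    return "irregular"


# --------------------------------------------------------------------------
# apoptotic selection
# --------------------------------------------------------------------------


def apoptotic_selection(
    geometry: FieldGeometry,
    gains: GainState,
    cull_fraction: float,
    synchrony_scores: Optional[np.ndarray] = None,
    record: Optional[SimulationRecord] = None,
) -> tuple[FieldGeometry, GainState, np.ndarray]:
    """Remove the least zero-lag-synchronous cells from a field.

    ``synchrony_scores`` defaults to each cell's mean zero-lag correlation
    with the rest of the population (computed from ``record.Q``).  Returns
    the reduced geometry and gains plus the indices of surviving cells.
    """
    if not (0.0 <= cull_fraction < 1.0):
        raise InvalidParameterError("cull_fraction must be in [0, 1)")
    n = geometry.n
    n_cull = int(np.floor(cull_fraction * n))
    if n - n_cull < 2:
        raise OverCullError(f"culling {n_cull} of {n} cells leaves fewer than 2")
    if n_cull == 0:
        return geometry, gains, np.arange(n)

    if synchrony_scores is None:
        if record is None:
            raise InvalidParameterError("need synchrony_scores or a record")
        x = record.Q[record.burn_in:]
        c = np.corrcoef((x - x.mean(0)).T)
        np.fill_diagonal(c, np.nan)
        synchrony_scores = np.nanmean(c, axis=1)
    scores = np.asarray(synchrony_scores, dtype=float)
    keep = np.sort(np.argsort(scores)[n_cull:])

    geo = FieldGeometry(
        positions=geometry.positions[keep],
        ei_label=geometry.ei_label[keep],
        v=geometry.v, dt=geometry.dt,
        delay_matrix=geometry.delay_matrix[np.ix_(keep, keep)],
        single_population=geometry.single_population,
    )
    sub = np.ix_(keep, keep)
    g2 = GainState(
        eps=gains.eps[sub], g=gains.g[sub], rho=gains.rho[sub],
        sign=gains.sign[sub], mask=gains.mask[sub],
        row_cap_e=None if gains.row_cap_e is None else gains.row_cap_e[keep],
        row_cap_i=None if gains.row_cap_i is None else gains.row_cap_i[keep],
    )
    return geo, g2, keep


# --------------------------------------------------------------------------
# symmetric connection reconstruction
# --------------------------------------------------------------------------


def surrogate_correlation(layout: CellLayout) -> np.ndarray:
    """Distance-decay stand-in for pairwise zero-lag synchrony.

    ``corr_ij = exp(-d_ij / ell_ij)`` with ``ell`` the pair's mean axon
    scale, so the module is testable without running a field simulation.
    """
    diff = layout.positions[:, None, :] - layout.positions[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    corr = np.exp(-d / layout.pair_axon_scale())
    np.fill_diagonal(corr, 1.0)
    return corr


def reconstruct_symmetric_connections(
    layout: CellLayout,
    record: Optional[SimulationRecord] = None,
    correlation: Optional[np.ndarray] = None,
    threshold: float = 0.5,
    arc_halfwidth_deg: float = 30.0,
) -> ConnectionGraph:
    """Symmetric bidirectional connections implied by maximized synchrony.

    A pair is connected iff its zero-lag correlation exceeds ``threshold``
    AND its separation is within the sum of the two axon scales (distance
    rule).  Patch-to-local connections are additionally constrained to
    arcs radiating from the local cell's column centre: the local cell's
    bearing from its column centre must lie within ``arc_halfwidth_deg``
    of the patch cell's bearing.  An empty result is returned with a
    warning, not an error.
    """
    n = layout.n
    if correlation is None:
        if record is not None:
            x = record.Q[record.burn_in:]
            correlation = np.corrcoef((x - x.mean(0)).T)
        else:
            correlation = surrogate_correlation(layout)
    if correlation.shape != (n, n):
        raise InvalidParameterError("correlation matrix does not match layout")

    diff = layout.positions[:, None, :] - layout.positions[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    a = np.where(layout.is_patch, layout.axon_scale[PATCH],
                 layout.axon_scale[LOCAL])
    reach = a[:, None] + a[None, :]
    ok = (correlation > threshold) & (d <= reach)
    np.fill_diagonal(ok, False)

    # radial-arc constraint on patch -> local connections
    mixed = (layout.is_patch[:, None] & layout.is_local[None, :])
    mixed = mixed | mixed.T
    if mixed.any():
        try:
            centers = cluster_centers(layout)
        except (InsufficientClustersError, DegenerateLayoutError):
            centers = np.zeros((0, 2))
        if len(centers):
            own = centers[
                np.argmin(
                    ((layout.positions[:, None, :] - centers[None, :, :]) ** 2).sum(-1),
                    axis=1,
                )
            ]
            half = np.deg2rad(arc_halfwidth_deg)
            for i in range(n):
                if not layout.is_local[i]:
                    continue
                c = own[i]
                th_local = np.arctan2(*(layout.positions[i] - c)[::-1])
                for j in np.where(ok[i] & layout.is_patch)[0]:
                    th_patch = np.arctan2(*(layout.positions[j] - c)[::-1])
                    dth = np.angle(np.exp(1j * (th_local - th_patch)))
                    if abs(dth) > half:
                        ok[i, j] = ok[j, i] = False

    iu, ju = np.where(np.triu(ok & ok.T, 1))
    if len(iu) == 0:
        warnings.warn("no pair exceeded the synchrony threshold within reach")
    weights = np.asarray(correlation)[iu, ju].astype(float)
    return ConnectionGraph(
        edges=np.stack([iu, ju], axis=1) if len(iu) else np.zeros((0, 2), int),
        weights=np.clip(weights, 0.0, None),
        symmetric=np.ones(len(iu), dtype=bool),
        n=n,
    )


# --------------------------------------------------------------------------
# mirror symmetry
# --------------------------------------------------------------------------


def reflect_points(pts: np.ndarray, point: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Reflect points across the line through ``point`` with unit ``normal``."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    rel = pts - point
    return pts - 2.0 * np.outer(rel @ normal, normal)


def _score_against(
    left: np.ndarray, left_chi: Optional[np.ndarray],
    right: np.ndarray, right_chi: Optional[np.ndarray],
    scale: float,
) -> float:
    """Registration score of a reflected half against the other half."""
    d = np.sqrt(((left[:, None, :] - right[None, :, :]) ** 2).sum(-1))
    match = d.argmin(axis=1)
    dist = d[np.arange(len(left)), match]
    geom = 1.0 - 2.0 * np.minimum(dist / scale, 1.0)
    if left_chi is not None and right_chi is not None:
        # a true mirror image carries the opposite handedness
        geom = geom * (-left_chi * right_chi[match])
    return float(geom.mean())


def mirror_symmetry_score(
    layout: CellLayout,
    axis: str | tuple = "fit",
    n_permutations: int = 99,
    seed: int = 0,
    blanket_width: Optional[float] = None,
) -> MirrorPairReport:
    """Mirror-symmetry of a layout about a reflection line.

    One side is reflected across the axis and registered to the other by
    nearest-neighbour matching; the score combines spatial registration
    with (if present) chirality reversal, reaching 1 only when each cell
    maps onto a counterpart of opposite handedness at zero distance.
    ``axis="fit"`` searches lines through the layout centroid over 5-degree
    orientation steps.  The permutation null redraws the reflected side
    uniformly in its bounding box (``n_permutations`` times).
    """
    pts = layout.positions
    chi = layout.chirality
    nn = _nn_distances(pts)
    scale = max(float(np.median(nn)), 1e-9)

    def eval_axis(point, normal):
        normal_ = np.asarray(normal, float) / np.linalg.norm(normal)
        side = (pts - point) @ normal_
        left, right = side < 0, side >= 0
        if left.sum() < 4 or right.sum() < 4:
            return None
        if abs(left.sum() - right.sum()) > 0.5 * len(pts):
            warnings.warn("unbalanced sides of the candidate axis")
        lrefl = reflect_points(pts[left], point, normal_)
        s = _score_against(
            lrefl, None if chi is None else chi[left],
            pts[right], None if chi is None else chi[right], scale,
        )
        return s, point, normal_, side

    if axis == "fit":
        centroid = pts.mean(axis=0)
        best = None
        for deg in range(0, 180, 5):
            th = np.deg2rad(deg)
            cand = eval_axis(centroid, np.array([np.cos(th), np.sin(th)]))
            if cand is not None and (best is None or cand[0] > best[0]):
                best = cand
        if best is None:
            raise InvalidParameterError("no admissible axis found")
        score, point, normal, side = best
    else:
        point, normal = np.asarray(axis[0], float), np.asarray(axis[1], float)
        got = eval_axis(point, normal)
        if got is None:
            raise InvalidParameterError("fewer than 4 cells on one side of the axis")
        score, point, normal, side = got

    left = side < 0
    rng = np.random.default_rng(seed)
    lo, hi = pts[left].min(0), pts[left].max(0)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        fake = rng.uniform(lo, hi, size=(left.sum(), 2))
        fake_chi = None
        if chi is not None:
            fake_chi = rng.permuted(chi[left])
        null[k] = _score_against(
            reflect_points(fake, point, normal), fake_chi,
            pts[~left], None if chi is None else chi[~left], scale,
        )

    if blanket_width is None:
        blanket_width = scale
    band = np.abs((pts - point) @ normal) <= blanket_width
    return MirrorPairReport(
        axis_point=point, axis_normal=normal, score=float(score),
        blanket_cells=np.where(band)[0],
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
        n_permutations=n_permutations,
    )
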