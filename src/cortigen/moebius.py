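"""Global-to-local conformal projection and orientation-preference maps.

A cortical column (a cluster of short-axon cells centred at ``p0``) holds
a compressed image of the surrounding patch-cell ("global") scale through
an angle-doubling complex projection

    p - p0 = chirality_op( (i / k) * (P - p0)^2 / |P - p0| )

where ``k > 0`` scales global to local distances, the imaginary unit
rotates the projected displacement by exactly 90 degrees, and the
squared-normalized term doubles the polar angle.  Positive chirality
applies the map as written; negative chirality composes it with complex
conjugation, producing the mirror-image (anti-conformal) column.  Because
the angle is doubled, diametrically opposite global directions land on
the same local ray: the column is organised like a Moebius strip, and the
preferred stimulus orientation assigned to a local position is the
preimage direction modulo 180 degrees.  One full 360-degree circuit
around the column centre therefore sweeps orientation preference through
exactly one 180-degree period, the classic pinwheel singularity.

A set of such maps tiling the sheet (an atlas) yields a full OP raster
with singularities (one per map, winding number +-1/2 matching the map's
chirality), low-gradient linear zones, and saddle points between
neighbouring pinwheels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    InvalidParameterError,
    SingularCenterError,
    UnsupportedImageError,
)

__all__ = [
    "GlobalPattern",
    "LocalImage",
    "LocalMap",
    "MapAtlas",
    "OPFeature",
    "OPMap",
    "RepresentationFrame",
    "RigidImageSpec",
    "build_representation_frame",
    "classify_op_features",
    "frame_to_image",
    "global_to_local",
    "local_to_global",
    "op_circuit",
    "orientation_preference",
    "project_image",
    "synthesize_op_map",
]


# --------------------------------------------------------------------------
# maps and atlas
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalMap:
    """One column's global-to-local projection parameters."""

    p0: complex = 0j          # column centre (complex coordinate)
    k: float = 1.0            # global : local scale ratio, > 0
    chirality: int = 1        # +1 as written, -1 mirror (conjugated)

    def __post_init__(self):
        if self.k <= 0:
            raise InvalidParameterError("map scale k must be positive")
        if self.chirality not in (1, -1):
            raise InvalidParameterError("chirality must be +1 or -1")


@dataclass
class MapAtlas:
    """A set of local maps tiling a rectangular domain."""

    maps: list
    extent: tuple = (-2.0, 2.0, -2.0, 2.0)   # xmin, xmax, ymin, ymax
    overlap: float = 0.0                      # allowed inter-map overlap fraction

    def __post_init__(self):
        if not self.maps:
            raise InvalidParameterError("atlas needs at least one map")

    def centers(self) -> np.ndarray:
        return np.array([m.p0 for m in self.maps])

    def owner(self, points: np.ndarray) -> np.ndarray:
        """Index of the governing (nearest-centre) map for each point."""
        pts = np.asarray(points, dtype=complex)
        return np.abs(pts[..., None] - self.centers()).argmin(axis=-1)


def global_to_local(P, m: LocalMap, center_policy: Optional[str] = None):
    """Project global position(s) ``P`` into map ``m``'s local sheet.

    ``|p - p0| = |P - p0| / k``; the local argument is the doubled global
    argument rotated by +90 degrees (mirrored for negative chirality).
    ``P = p0`` is singular; ``center_policy="collapse"`` maps it to p0.
    """
    P_arr = np.asarray(P, dtype=complex)
    z = P_arr - m.p0
    az = np.abs(z)
    singular = az == 0
    if np.any(singular):
        if center_policy != "collapse":
            raise SingularCenterError(
                "P = p0 is the projection singularity (use center_policy='collapse')"
            )
        az = np.where(singular, 1.0, az)
    sq = z ** 2 / az
    if m.chirality < 0:
        sq = np.conj(sq)
    p = m.p0 + (1j / m.k) * sq
    p = np.where(singular, m.p0, p) if np.any(singular) else p
    return complex(p) if np.isscalar(P) else p


def local_to_global(p, m: LocalMap, branch: int = 1):
    """Invert :func:`global_to_local` on one branch of the angle halving.

    The two branches differ by 180 degrees in the global angle; the round
    trip ``P -> p -> P`` is the identity on the matching branch.
    """
    if branch not in (1, -1):
        raise InvalidParameterError("branch must be +1 or -1")
    p_arr = np.asarray(p, dtype=complex)
    w = (p_arr - m.p0) * m.k / 1j        # = z^2/|z| (conjugated if chirality<0)
    if np.any(np.abs(w) == 0):
        raise SingularCenterError("p = p0: both branches meet at the centre")
    if m.chirality < 0:
        w = np.conj(w)
    r = np.abs(w)
    theta = np.angle(w) / 2.0 + (0.0 if branch == 1 else np.pi)
    P = m.p0 + r * np.exp(1j * theta)
    return complex(P) if np.isscalar(p) else P


def orientation_preference(points, m: LocalMap) -> np.ndarray:
    """OP (degrees in [0, 180)) at local position(s) under map ``m``.

    The OP of a local position is the direction of its global preimage,
    defined modulo 180 degrees (both branches share one orientation).
    """
    pts = np.asarray(points, dtype=complex)
    w = (pts - m.p0) * m.k / 1j
    if m.chirality < 0:
        w = np.conj(w)
    theta = np.degrees(np.angle(w)) / 2.0
    return np.mod(theta, 180.0)


def op_circuit(m: LocalMap, radius: float = 1.0, step_deg: float = 1.0) -> dict:
    """OP along one closed circuit around the map centre.

    Samples the synthesized OP at ``step_deg`` increments of physical
    angle over a full 360-degree circuit and reports the unwrapped span
    (total OP rotation; 180 degrees for a pinwheel) and the winding
    number in OP periods (+-1/2 matching chirality).
    """
    if radius <= 0:
        raise InvalidParameterError("radius must be positive")
    ang = np.arange(0.0, 360.0 + step_deg, step_deg)
    pts = m.p0 + radius * np.exp(1j * np.radians(ang))
    op = orientation_preference(pts, m)
    unwrapped = np.unwrap(op, period=180.0)
    span = abs(unwrapped[-1] - unwrapped[0])
    winding = (unwrapped[-1] - unwrapped[0]) / 360.0
    return {"angles": ang, "op": op, "span": float(span), "winding": float(winding)}


# --------------------------------------------------------------------------
# OP raster synthesis and feature classification
# --------------------------------------------------------------------------


@dataclass
class OPFeature:
    type: str              # "singularity" | "saddle" | "linear_zone"
    location: tuple        # (x, y)
    winding: Optional[float] = None   # singularities only, in OP periods
    map_index: Optional[int] = None


@dataclass
class OPMap:
    """Orientation-preference raster over a map atlas."""

    raster: np.ndarray        # (ny, nx) OP degrees in [0, 180)
    xs: np.ndarray
    ys: np.ndarray
    owner: np.ndarray         # (ny, nx) governing map index
    resolution: float
    features: list = field(default_factory=list)

    def grid(self) -> np.ndarray:
        return self.xs[None, :] + 1j * self.ys[:, None]


def _wrap180(delta: np.ndarray) -> np.ndarray:
    """Wrap OP differences into (-90, 90]."""
    return (delta + 90.0) % 180.0 - 90.0


def synthesize_op_map(
    atlas: MapAtlas,
    resolution: float = 0.05,
    classify: bool = True,
) -> OPMap:
    """Rasterize the OP field of an atlas (nearest-centre map assignment)."""
    if resolution <= 0:
        raise InvalidParameterError("resolution must be positive")
    x0, x1, y0, y1 = atlas.extent
    centers = atlas.centers()
    if len(centers) > 1:
        spacing = np.sort(np.abs(centers[:, None] - centers[None, :]), axis=1)[:, 1]
        if resolution > spacing.min() / 2:
            import warnings
            warnings.warn("resolution coarser than half the map spacing; "
                          "the raster will undersample the columns")
    # pixel-centred grid, so a map centre falls inside a plaquette rather
    # than on a node (the singular point itself is never sampled)
    xs = np.arange(x0 + resolution / 2, x1, resolution)
    ys = np.arange(y0 + resolution / 2, y1, resolution)
    pts = xs[None, :] + 1j * ys[:, None]
    owner = atlas.owner(pts)
    raster = np.empty(pts.shape)
    for idx, m in enumerate(atlas.maps):
        sel = owner == idx
        if sel.any():
            raster[sel] = orientation_preference(pts[sel], m)
    # the centre pixel of each map is the singular point; assign the OP
    # limit along +x for definiteness
    opmap = OPMap(raster=raster, xs=xs, ys=ys, owner=owner, resolution=resolution)
    if classify:
        opmap.features = classify_op_features(opmap, atlas)
    return opmap


def classify_op_features(
    opmap: OPMap,
    atlas: Optional[MapAtlas] = None,
    linear_zone_percentile: float = 10.0,
    saddle_gradient_percentile: float = 5.0,
) -> list:
    """Locate singularities, saddle points and linear zones of an OP raster.

    Singularities are plaquettes whose loop of wrapped OP differences
    winds by +-180 degrees (winding +-1/2 in OP periods) with every step
    below 60 degrees (excluding plaquettes that merely straddle an
    inter-map discontinuity).  Saddles are interior low-gradient points
    whose locally unwrapped quadratic fit has an indefinite Hessian.
    Linear zones are connected components of the lowest-gradient decile;
    their centroids are reported.
    """
    z = opmap.raster
    ny, nx = z.shape
    feats: list = []

    # --- singularities: winding of each 2x2 plaquette
    d_right = _wrap180(np.diff(z, axis=1))             # (ny, nx-1)
    d_down = _wrap180(np.diff(z, axis=0))              # (ny-1, nx)
    loop = (d_right[:-1, :] + d_down[:, 1:] - d_right[1:, :] - d_down[:, :-1])
    steps_ok = (
        (np.abs(d_right[:-1, :]) < 60) & (np.abs(d_down[:, 1:]) < 60)
        & (np.abs(d_right[1:, :]) < 60) & (np.abs(d_down[:, :-1]) < 60)
    )
    wind = np.rint(loop / 180.0) / 2.0                 # in OP periods
    sing = (np.abs(wind) >= 0.5 - 1e-9) & steps_ok
    for iy, ix in zip(*np.where(sing)):
        x = (opmap.xs[ix] + opmap.xs[ix + 1]) / 2
        y = (opmap.ys[iy] + opmap.ys[iy + 1]) / 2
        map_idx = None
        if atlas is not None:
            map_idx = int(atlas.owner(np.array(x + 1j * y)))
        feats.append(OPFeature("singularity", (float(x), float(y)),
                               winding=float(wind[iy, ix]), map_index=map_idx))

    # --- gradient magnitude (wrapped central differences)
    gx = np.zeros_like(z)
    gy = np.zeros_like(z)
    gx[:, 1:-1] = _wrap180(z[:, 2:] - z[:, :-2]) / 2.0
    gy[1:-1, :] = _wrap180(z[2:, :] - z[:-2, :]) / 2.0
    grad = np.hypot(gx, gy) / opmap.resolution

    sing_mask = np.zeros_like(z, dtype=bool)
    for f in feats:
        ix = np.argmin(np.abs(opmap.xs - f.location[0]))
        iy = np.argmin(np.abs(opmap.ys - f.location[1]))
        sing_mask[max(iy - 2, 0): iy + 3, max(ix - 2, 0): ix + 3] = True

    # --- saddles: interior critical points (local minima of the gradient
    # magnitude at near-zero gradient) with indefinite local Hessian.
    # Away from singularities the OP phase is harmonic, so a genuine
    # critical point is necessarily a saddle; the Hessian test confirms.
    from scipy.ndimage import minimum_filter
    interior = np.zeros_like(z, dtype=bool)
    interior[3:-3, 3:-3] = True
    cand_mask = interior & ~sing_mask
    if cand_mask.any():
        cut = np.percentile(grad[cand_mask], saddle_gradient_percentile)
        is_min = grad <= minimum_filter(grad, size=5) + 1e-12
        for iy, ix in zip(*np.where(cand_mask & is_min & (grad <= cut))):
            patch = z[iy - 2: iy + 3, ix - 2: ix + 3]
            if patch.shape != (5, 5):
                continue
            # unwrap the patch around its centre value
            ref = patch[2, 2]
            u = ref + _wrap180(patch - ref)
            yy, xx = np.mgrid[-2:3, -2:3]
            A = np.column_stack([
                np.ones(25), xx.ravel(), yy.ravel(),
                xx.ravel() ** 2, xx.ravel() * yy.ravel(), yy.ravel() ** 2,
            ])
            coef, *_ = np.linalg.lstsq(A, u.ravel(), rcond=None)
            hess = np.array([[2 * coef[3], coef[4]], [coef[4], 2 * coef[5]]])
            ev = np.linalg.eigvalsh(hess)
            if ev[0] < -1e-9 and ev[1] > 1e-9:
                feats.append(OPFeature(
                    "saddle", (float(opmap.xs[ix]), float(opmap.ys[iy]))
                ))

    # --- linear zones: lowest-gradient decile, connected components
    ok = ~sing_mask
    if ok.any():
        cut = np.percentile(grad[ok], linear_zone_percentile)
        low = ok & (grad <= cut)
        from scipy.ndimage import label as cc_label
        lab, n_lab = cc_label(low)
        for comp in range(1, n_lab + 1):
            iy, ix = np.where(lab == comp)
            if len(iy) < 4:
                continue
            feats.append(OPFeature(
                "linear_zone",
                (float(opmap.xs[ix].mean()), float(opmap.ys[iy].mean())),
            ))
    return feats


# --------------------------------------------------------------------------
# image dispersal across the atlas
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalPattern:
    """Activity samples at the global (patch-network) scale."""

    positions: np.ndarray    # (m,) complex global coordinates
    times: np.ndarray        # (m,) sample times
    values: np.ndarray       # (m,) activity


@dataclass(frozen=True)
class LocalImage:
    """One map's projected copy of a global pattern."""

    map_index: int
    positions: np.ndarray    # (m,) complex local coordinates
    times: np.ndarray        # (m,) arrival times (delayed)
    values: np.ndarray
    delays: np.ndarray       # (m,) >= 0


def project_image(
    pattern: GlobalPattern,
    atlas: MapAtlas,
    v: Optional[float] = None,
    support_radius: Optional[float] = None,
) -> list:
    """Disperse a global pattern into every covering local map.

    Each sample is placed at its angle-doubled projected position; its
    time is shifted by the conduction delay ``|P - p| / v`` (``v=None``
    means infinite conduction speed, zero delay).  Sample count is
    conserved per covering map.
    """
    if v is not None and v <= 0:
        raise InvalidParameterError("conduction speed must be positive (or None)")
    out = []
    covered = 0
    for idx, m in enumerate(atlas.maps):
        P = np.asarray(pattern.positions, dtype=complex)
        if support_radius is not None:
            keep = np.abs(P - m.p0) <= support_radius
        else:
            keep = np.ones(len(P), dtype=bool)
        if not keep.any():
            continue
        covered += 1
        p = global_to_local(P[keep], m, center_policy="collapse")
        delay = np.zeros(keep.sum()) if v is None else np.abs(P[keep] - p) / v
        out.append(LocalImage(
            map_index=idx, positions=p,
            times=np.asarray(pattern.times)[keep] - delay,
            values=np.asarray(pattern.values)[keep], delays=delay,
        ))
    if covered == 0:
        import warnings
        warnings.warn("pattern lies outside the support of every map")
    return out


# --------------------------------------------------------------------------
# twelve-point representation frames
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidImageSpec:
    """A rigid moving image: pose in 3-space plus its rates of change.

    Pose needs an object scale/rotation frame (scale + two rotation
    angles) and a position frame (x, y, z); motion adds a translation
    within each frame (rates of the three pose coordinates and the three
    position coordinates).
    """

    scale: float = 1.0
    rotation: tuple = (0.0, 0.0)          # two angles, radians
    position: tuple = (0.0, 0.0, 0.0)
    pose_velocity: tuple = (0.0, 0.0, 0.0)      # d/dt (scale, rot1, rot2)
    position_velocity: tuple = (0.0, 0.0, 0.0)  # d/dt (x, y, z)
    rigid: bool = True


#: Coordinate packing of the twelve frame points, in storage order.
FRAME_LABELS = (
    "scale", "rotation_1", "rotation_2",
    "position_x", "position_y", "position_z",
    "pose_velocity_scale", "pose_velocity_rot1", "pose_velocity_rot2",
    "velocity_x", "velocity_y", "velocity_z",
)


@dataclass(frozen=True)
class RepresentationFrame:
    """Twelve reference points encoding one rigid moving image.

    3 object scale/rotation coordinates + 3 position coordinates +
    a 3-component translation within each of the two frames = 12 points,
    independent of the image; a static image has all six translation
    components exactly zero.
    """

    points: np.ndarray      # (12,)
    image_id: Optional[str] = None

    def __post_init__(self):
        if self.points.shape != (12,):
            raise InvalidParameterError("a representation frame has exactly 12 points")

    def labelled(self) -> dict:
        return dict(zip(FRAME_LABELS, self.points.tolist()))


def build_representation_frame(
    image: RigidImageSpec, image_id: Optional[str] = None
) -> RepresentationFrame:
    """Encode a rigid moving image as its twelve-point frame."""
    if not image.rigid:
        raise UnsupportedImageError("only rigid images have a twelve-point frame")
    vals = [image.scale, *image.rotation, *image.position,
            *image.pose_velocity, *image.position_velocity]
    pts = np.asarray(vals, dtype=float)
    if pts.shape != (12,) or not np.all(np.isfinite(pts)):
        raise UnsupportedImageError("image spec must provide 12 finite coordinates")
    return RepresentationFrame(points=pts, image_id=image_id)


def frame_to_image(frame: RepresentationFrame) -> RigidImageSpec:
    """Invert :func:`build_representation_frame` (exact round trip)."""
    p = frame.points
    return RigidImageSpec(
        scale=float(p[0]), rotation=(float(p[1]), float(p[2])),
        position=tuple(map(float, p[3:6])),
        pose_velocity=tuple(map(float, p[6:9])),
        position_velocity=tuple(map(float, p[9:12])),
    )
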