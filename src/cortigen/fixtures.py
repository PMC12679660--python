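"""Seeded synthetic fixtures for every module, generated in memory.

Each fixture kind builds the minimal object exercising one claim of the
theory: synchronous/antiphase channel pairs (eigenmode and free-energy
identities), a small coupled field record (emergence), clustered and
lattice layouts (columnarity and tiling), chiral patch arrays on square
vs hexagonal tilings (mirror symmetry and its frustration), and rigid
moving test images (twelve-point frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .field import FieldConfig, SimulationRecord, simulate
from .moebius import RigidImageSpec
from .morphogenesis import LOCAL, PATCH, CellLayout

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_KINDS"]


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: dict = dc_field(default_factory=dict)


def _pair(steps: int, antiphase: bool, noise: float, rng) -> np.ndarray:
    t = np.arange(steps)
    base = np.sin(2 * np.pi * t / 25.0)
    a = base + noise * rng.normal(size=steps)
    b = (-base if antiphase else base) + noise * rng.normal(size=steps)
    return np.column_stack([a, b])


def _lattice_centers(kind: str, rows: int, cols: int, spacing: float) -> np.ndarray:
    """Square or hexagonal (triangular) lattice of column centres."""
    pts = []
    for r in range(rows):
        for c in range(cols):
            x = c * spacing
            y = r * spacing
            if kind == "hex":
                x += (r % 2) * spacing / 2.0
                y = r * spacing * np.sqrt(3) / 2.0
            pts.append((x, y))
    return np.asarray(pts, dtype=float)


def _lattice_layout(kind: str, rng, rows=4, cols=4, spacing=2.5,
                    per_cluster=6, jitter=0.0) -> CellLayout:
    centers = _lattice_centers(kind, rows, cols, spacing)
    local = []
    for cx, cy in centers:
        ang = rng.uniform(0, 2 * np.pi, per_cluster)
        rad = rng.uniform(0, 0.15 * spacing, per_cluster)
        pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        local.append(pts)
    local = np.concatenate(local)
    if jitter:
        local = local + rng.normal(0, jitter * spacing, local.shape)
    patch = rng.uniform(local.min() - spacing / 2, local.max() + spacing / 2,
                        size=(rows * cols, 2))
    positions = np.concatenate([patch, local])
    population = np.array([PATCH] * len(patch) + [LOCAL] * len(local))
    return CellLayout(
        positions=positions, population=population,
        axon_scale={PATCH: 2 * spacing, LOCAL: 0.3 * spacing},
        domain=float(positions.max() + spacing),
    )


#: chiral motif bearings (degrees); asymmetric under reflection
_MOTIF_DEG = np.array([0.0, 50.0, 130.0])


def _patch_array(kind: str, rows=4, cols=4, spacing=2.0, motif_radius=0.5
                 ) -> CellLayout:
    """Lattice of columns, each a 3-point chiral patch-cell motif.

    Column chirality alternates in a checkerboard; on the square lattice
    the alternation is perfect (every neighbour pair is a mirror pair),
    on the hexagonal lattice the triangular adjacency is not 2-colourable
    and some neighbour pairs are frustrated (broken symmetry).  A motif
    of chirality -1 is the exact reflection (about the vertical axis) of
    the +1 motif, so a vertical mirror line maps a +1 column onto a -1
    column exactly.
    """
    centers = _lattice_centers(kind, rows, cols, spacing)
    chi = []
    for r in range(rows):
        for c in range(cols):
            chi.append(1 if (r + c) % 2 == 0 else -1)
    chi = np.asarray(chi)
    pts, cell_chi = [], []
    for (cx, cy), ch in zip(centers, chi):
        deg = _MOTIF_DEG if ch > 0 else 180.0 - _MOTIF_DEG
        ang = np.radians(deg)
        pts.append(np.column_stack(
            [cx + motif_radius * np.cos(ang), cy + motif_radius * np.sin(ang)]
        ))
        cell_chi.extend([ch] * len(ang))
    positions = np.concatenate(pts)
    return CellLayout(
        positions=positions,
        population=np.array([PATCH] * len(positions)),
        axon_scale={PATCH: 2 * spacing, LOCAL: 0.3 * spacing},
        domain=float(positions.max() + spacing),
        chirality=np.asarray(cell_chi),
    )


def make_fixture(spec: FixtureSpec) -> Any:
    """Build the deterministic fixture described by ``spec``.

    Same spec (kind, seed, params) always returns a bit-identical object.
    """
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    kind = spec.kind

    if kind == "synchronous-pair":
        return _pair(p.get("steps", 2000), antiphase=False,
                     noise=p.get("noise", 0.0), rng=rng)
    if kind == "antiphase-pair":
        return _pair(p.get("steps", 2000), antiphase=True,
                     noise=p.get("noise", 0.0), rng=rng)
    if kind == "white-noise-record":
        return rng.normal(size=(p.get("steps", 2000), p.get("n", 8)))
    if kind == "coupled-field":
        cfg = FieldConfig(n=p.get("n", 16), seed=spec.seed)
        return simulate(cfg, p.get("steps", 1500),
                        record_phi=p.get("record_phi", True))
    if kind == "clustered-layout":
        return _lattice_layout("square", rng,
                               rows=p.get("rows", 2), cols=p.get("cols", 2),
                               spacing=p.get("spacing", 4.0),
                               per_cluster=p.get("per_cluster", 10),
                               jitter=p.get("jitter", 0.0))
    if kind == "square-lattice":
        return _lattice_layout("square", rng,
                               rows=p.get("rows", 4), cols=p.get("cols", 4),
                               spacing=p.get("spacing", 2.5),
                               per_cluster=p.get("per_cluster", 6),
                               jitter=p.get("jitter", 0.0))
    if kind == "hex-lattice":
        return _lattice_layout("hex", rng,
                               rows=p.get("rows", 4), cols=p.get("cols", 4),
                               spacing=p.get("spacing", 2.5),
                               per_cluster=p.get("per_cluster", 6),
                               jitter=p.get("jitter", 0.0))
    if kind == "patch-array-square":
        return _patch_array("square", rows=p.get("rows", 4),
                            cols=p.get("cols", 4), spacing=p.get("spacing", 2.0))
    if kind == "patch-array-hex":
        return _patch_array("hex", rows=p.get("rows", 4),
                            cols=p.get("cols", 4), spacing=p.get("spacing", 2.0))
    if kind == "rigid-image":
        return RigidImageSpec(
            scale=p.get("scale", 1.0),
            rotation=tuple(p.get("rotation", (0.3, -0.2))),
            position=tuple(p.get("position", (1.0, 2.0, 0.5))),
            pose_velocity=tuple(p.get("pose_velocity", (0.0, 0.0, 0.0))),
            position_velocity=tuple(p.get("position_velocity", (0.0, 0.0, 0.0))),
        )
    raise InvalidParameterError(
        f"unknown fixture kind {kind!r}; available: {sorted(FIXTURE_KINDS)}"
    )


FIXTURE_KINDS = {
    "synchronous-pair", "antiphase-pair", "white-noise-record",
    "coupled-field", "clustered-layout", "square-lattice", "hex-lattice",
    "patch-array-square", "patch-array-hex", "rigid-image",
}
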