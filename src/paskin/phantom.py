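"""Synthetic photoacoustic skin phantoms with exhaustively known ground truth.

The generator produces three things on a shared voxel grid:

* branching vessel trees — polyline centerlines with per-point radii,
  rasterized to a binary mask as a union of capsules, with per-tree oxygen
  saturation painted onto the voxels as HbO2/Hb concentration fields;
* torus-like superficial melanin structures confined to a shallow depth band,
  emulating the annular melanin pattern around pores;
* multi-wavelength amplitude volumes via a single-scatter forward model:
  amplitude(λ, r) = Σ_c ε_c(λ)·C_c(r) · exp(−µ_eff · depth) + Gaussian noise.

Every derived quantity the analysis pipeline later estimates (voxel volume,
centerline radii, bifurcation count, per-voxel SO2, melanin volume) is
recorded at generation time, so each pipeline stage can be tested against
exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid
from .io import MultiwavelengthScan
from .spectra import ChromophoreSpectra

__all__ = [
    "VesselTreeSpec",
    "TorusParams",
    "PhantomTruth",
    "generate_vessel_tree",
    "generate_melanin_layer",
    "synthesize_pa_volumes",
    "rasterize_polylines",
    "digital_cylinder",
    "straight_tube_truth",
    "y_tree_truth",
]


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of the random branching-tree vessel generator."""

    n_trees: int = 8
    depth_range_mm: tuple[float, float] = (0.15, 1.7)
    radius_range_um: tuple[float, float] = (50.0, 120.0)
    branching_prob: float = 0.25
    segment_length_um: float = 250.0
    so2_per_vessel: tuple[float, ...] | None = None
    #: std of the vertical component of growth directions; small values keep
    #: each tree near its root depth so depth-stratified volumes are controlled
    vertical_drift: float = 0.12
    #: optional absolute depth band (mm) that the whole tree must stay inside
    #: (centerline plus radius); defaults to a band around each root depth
    confine_depth_mm: tuple[float, float] | None = None
    max_points_per_branch: int = 14
    seed: int = 0

    def validate(self, grid: VoxelGrid) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching_prob must lie in [0, 1]")
        lo, hi = self.radius_range_um
        if lo > hi or lo <= 0:
            raise ValueError("radius_range_um must be 0 < min <= max")
        min_voxels = lo / max(grid.spacing_um)
        if min_voxels < 1.5:
            raise ValueError(
                f"minimum vessel radius {lo} µm is {min_voxels:.2f} voxels on this "
                f"grid (spacing {grid.spacing_um} µm); radii below 1.5 voxels are "
                "unresolvable — refuse rather than silently clip"
            )
        dlo, dhi = self.depth_range_mm
        if dlo < 0 or dhi * 1000.0 > grid.extent_um[0]:
            raise ValueError(
                f"depth range {self.depth_range_mm} mm exceeds grid depth "
                f"{grid.extent_um[0] / 1000:.2f} mm"
            )
        if self.so2_per_vessel is not None:
            arr = np.asarray(self.so2_per_vessel, float)
            if len(arr) != self.n_trees:
                raise ValueError("so2_per_vessel must have one entry per tree")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("per-vessel SO2 must lie in [0, 1]")


@dataclass(frozen=True)
class TorusParams:
    """Annular melanin structures in a superficial depth band.

    ``inner_radius_um``/``outer_radius_um`` bound the ring in-plane; the tube
    (minor) radius is half their difference, so the structure has thickness.
    """

    n_tori: int = 6
    inner_radius_um: float = 120.0
    outer_radius_um: float = 260.0
    depth_band_um: tuple[float, float] = (0.0, 300.0)

    @property
    def major_radius_um(self) -> float:
        return 0.5 * (self.inner_radius_um + self.outer_radius_um)

    @property
    def minor_radius_um(self) -> float:
        return 0.5 * (self.outer_radius_um - self.inner_radius_um)

    def validate(self, grid: VoxelGrid) -> None:
        if self.n_tori < 0:
            raise ValueError("n_tori must be >= 0")
        if not 0 < self.inner_radius_um < self.outer_radius_um:
            raise ValueError("need 0 < inner_radius_um < outer_radius_um")
        lo, hi = self.depth_band_um
        if not 0 <= lo < hi <= grid.extent_um[0]:
            raise ValueError(
                f"depth band {self.depth_band_um} µm must lie within the grid "
                f"depth [0, {grid.extent_um[0]:.0f}) µm"
            )
        if 2 * self.minor_radius_um > (hi - lo):
            raise ValueError(
                f"torus tube diameter {2 * self.minor_radius_um:.0f} µm does not "
                f"fit the depth band {self.depth_band_um} µm"
            )


@dataclass
class PhantomTruth:
    """Generator-side ground truth for one phantom.

    ``centerlines`` is a list of (M, 4) float arrays with columns
    (z_um, y_um, x_um, radius_um); each polyline is one unbranched run, and a
    child polyline starts exactly at an interior point of its parent, so the
    point-adjacency graph of all polylines has one degree-≥3 node per
    bifurcation.  Concentration fields are in arbitrary units with total
    hemoglobin 1 inside vessels; ``per_voxel_so2`` equals
    C_HbO2 / (C_HbO2 + C_Hb) wherever total hemoglobin is positive.
    """

    grid: VoxelGrid
    centerlines: list[np.ndarray] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None
    melanin_mask: np.ndarray | None = None
    branch_count_per_tree: list[int] = field(default_factory=list)
    per_voxel_so2: np.ndarray | None = None
    c_hbo2: np.ndarray | None = None
    c_hb: np.ndarray | None = None
    c_melanin: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.grid.shape
        if self.vessel_mask is None:
            self.vessel_mask = np.zeros(shape, bool)
        if self.melanin_mask is None:
            self.melanin_mask = np.zeros(shape, bool)
        for name in ("per_voxel_so2", "c_hbo2", "c_hb", "c_melanin"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape, np.float64))

    @property
    def branch_count(self) -> int:
        return int(sum(self.branch_count_per_tree))

    @property
    def vessel_volume_voxels(self) -> int:
        return int(np.count_nonzero(self.vessel_mask))

    @property
    def melanin_volume_voxels(self) -> int:
        return int(np.count_nonzero(self.melanin_mask))


# ---------------------------------------------------------------------------
# rasterization


def _segment_mask(
    grid: VoxelGrid,
    p0: np.ndarray,
    p1: np.ndarray,
    r0: float,
    r1: float,
    out: np.ndarray,
    caps: str = "round",
) -> None:
    """OR a capsule (or flat-ended cylinder) between p0 and p1 into ``out``.

    Points and radii are in µm, (z, y, x) order.  A voxel belongs to the
    segment when its centre lies within the locally interpolated radius of the
    axis.  ``caps='flat'`` restricts to the slab 0 <= t <= 1 (a true finite
    cylinder for constant radius), used for analytic test cylinders.
    """
    spacing = np.asarray(grid.spacing_um, float)
    rmax = max(r0, r1)
    lo_um = np.minimum(p0, p1) - rmax - spacing
    hi_um = np.maximum(p0, p1) + rmax + spacing
    lo = np.maximum(np.floor(lo_um / spacing - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil(hi_um / spacing - 0.5).astype(int) + 1, grid.shape)
    if np.any(lo >= hi):
        return
    axes = [
        (np.arange(lo[i], hi[i], dtype=float) + 0.5) * spacing[i] for i in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = p1 - p0
    seg_len2 = float(d @ d)
    vz, vy, vx = zz - p0[0], yy - p0[1], xx - p0[2]
    if seg_len2 == 0.0:
        dist2 = vz**2 + vy**2 + vx**2
        inside = dist2 <= r0**2
    else:
        t = (vz * d[0] + vy * d[1] + vx * d[2]) / seg_len2
        tc = np.clip(t, 0.0, 1.0)
        dz = vz - tc * d[0]
        dy = vy - tc * d[1]
        dx = vx - tc * d[2]
        dist2 = dz**2 + dy**2 + dx**2
        r = r0 + (r1 - r0) * tc
        inside = dist2 <= r**2
        if caps == "flat":
            inside &= (t >= 0.0) & (t <= 1.0)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside


def rasterize_polylines(
    grid: VoxelGrid, polylines: list[np.ndarray], caps: str = "round"
) -> np.ndarray:
    """Union-of-capsules mask of centerline polylines with per-point radii."""
    out = np.zeros(grid.shape, bool)
    for poly in polylines:
        pts = np.asarray(poly, float)
        if len(pts) == 1:
            _segment_mask(grid, pts[0, :3], pts[0, :3], pts[0, 3], pts[0, 3], out, caps)
        for a, b in zip(pts[:-1], pts[1:]):
            _segment_mask(grid, a[:3], b[:3], a[3], b[3], out, caps)
    return out


def digital_cylinder(
    grid: VoxelGrid,
    radius_vox: float,
    axis: str = "x",
    length_vox: int | None = None,
    center_offset_vox: tuple[float, float] = (0.0, 0.0),
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Flat-ended digital cylinder mask for estimator validation.

    ``radius_vox`` is a continuous radius in voxel units (isotropic spacing
    assumed for the voxel-unit reading); the cylinder runs along ``axis``
    (or an arbitrary unit ``direction``, (z, y, x) µm frame) through the grid
    centre plus ``center_offset_vox`` (applied to the two transverse axes).
    """
    spacing = np.asarray(grid.spacing_um, float)
    center = (np.floor(np.asarray(grid.shape, float) / 2.0) + 0.5) * spacing
    if direction is None:
        d = {"z": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "x": np.array([0, 0, 1.0])}[axis]
    else:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
    # offset applied in a plane orthogonal to d
    ref = np.array([0.0, 1.0, 0.0]) if abs(d[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    center = center + center_offset_vox[0] * spacing.mean() * u + center_offset_vox[1] * spacing.mean() * v
    half = (length_vox if length_vox is not None else 4 * max(grid.shape)) / 2.0 * spacing.mean()
    p0 = center - half * d
    p1 = center + half * d
    r_um = radius_vox * spacing.mean()
    out = np.zeros(grid.shape, bool)
    _segment_mask(grid, p0, p1, r_um, r_um, out, caps="flat")
    return out


# ---------------------------------------------------------------------------
# vessel trees


def _random_unit(rng: np.random.Generator, vertical_drift: float) -> np.ndarray:
    """Mostly-horizontal unit direction in (z, y, x)."""
    phi = rng.uniform(0, 2 * np.pi)
    d = np.array([rng.normal(0.0, vertical_drift), np.sin(phi), np.cos(phi)])
    return d / np.linalg.norm(d)


def _perturb(rng: np.random.Generator, d: np.ndarray, ang_sd: float, vertical_drift: float) -> np.ndarray:
    out = d + rng.normal(0.0, ang_sd, 3) * np.array([vertical_drift * 2, 1.0, 1.0])
    n = np.linalg.norm(out)
    return d if n == 0 else out / n


def _child_direction(
    rng: np.random.Generator, d: np.ndarray, vertical_drift: float
) -> np.ndarray:
    """Child departure direction at a controlled angle to the parent.

    Near-parallel children merge with the parent over a long seam and smear
    the junction; near-orthogonal ones separate within about one radius, so
    the rasterized bifurcation stays compact.  Angle constrained to
    roughly 30–75 degrees.
    """
    for _ in range(40):
        cand = _perturb(rng, d, 0.9, vertical_drift)
        cosang = abs(float(np.dot(cand, d)))
        if 0.25 < cosang < 0.87:
            return cand
    return cand


def _segment_distance(q0: np.ndarray, q1: np.ndarray, p0s: np.ndarray, p1s: np.ndarray) -> np.ndarray:
    """Min distance between segment (q0,q1) and each segment (p0s[i], p1s[i]).

    Sampled approximation: both segments are sampled densely relative to the
    segment lengths involved; exact enough for clearance testing.
    """
    ts = np.linspace(0.0, 1.0, 9)
    qa = q0[None, :] + ts[:, None] * (q1 - q0)[None, :]  # (9, 3)
    us = np.linspace(0.0, 1.0, 9)
    pa = p0s[:, None, :] + us[None, :, None] * (p1s - p0s)[:, None, :]  # (N, 9, 3)
    d = np.linalg.norm(pa[:, :, None, :] - qa[None, None, :, :], axis=-1)  # (N, 9, 9)
    return d.reshape(len(p0s), -1).min(axis=1)


class _SegmentStore:
    """Placed segments with polyline ownership, for collision avoidance."""

    def __init__(self) -> None:
        self.p0: list[np.ndarray] = []
        self.p1: list[np.ndarray] = []
        self.r: list[float] = []
        self.owner: list[int] = []
        self.next_id: int = 0

    def collides(
        self, q0: np.ndarray, q1: np.ndarray, radius: float,
        exempt: set[int], clearance_um: float,
    ) -> bool:
        if not self.p0:
            return False
        sel = [i for i, o in enumerate(self.owner) if o not in exempt]
        if not sel:
            return False
        p0s = np.asarray([self.p0[i] for i in sel])
        p1s = np.asarray([self.p1[i] for i in sel])
        rs = np.asarray([self.r[i] for i in sel])
        dist = _segment_distance(q0, q1, p0s, p1s)
        return bool(np.any(dist < rs + radius + clearance_um))

    def add(self, poly: np.ndarray, owner: int) -> None:
        for a, b in zip(poly[:-1], poly[1:]):
            self.p0.append(a[:3])
            self.p1.append(b[:3])
            self.r.append(float(max(a[3], b[3])))
            self.owner.append(owner)


def _grow_branch(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    radius_um: float,
    spec: VesselTreeSpec,
    grid: VoxelGrid,
    depth_lo_um: float,
    depth_hi_um: float,
    store: _SegmentStore | None = None,
    exempt: set[int] | None = None,
    clearance_um: float = 0.0,
) -> np.ndarray:
    """Grow one unbranched polyline; returns (M, 4) array (may be length 1).

    Steps that would bring the new segment within ``clearance_um`` of any
    non-exempt placed segment are re-aimed a few times and then abandoned, so
    distinct branches never merge in the rasterized mask and every mask
    junction corresponds to a constructed bifurcation.
    """
    margin = radius_um
    ext = np.asarray(grid.extent_um, float)
    pts = [np.concatenate([start, [radius_um]])]
    pos, d = start.copy(), direction.copy()
    d_prev: np.ndarray | None = None
    n_pts = rng.integers(spec.max_points_per_branch // 2, spec.max_points_per_branch + 1)
    exempt = set(exempt or ())
    own_p0: list[np.ndarray] = []
    own_p1: list[np.ndarray] = []
    for _ in range(int(n_pts)):
        step = spec.segment_length_um * rng.uniform(0.7, 1.3)
        # the parent polyline is only exempt near the attachment point
        step_exempt = exempt if len(pts) <= 2 else set()
        placed = False
        for _attempt in range(6):
            nxt = pos + d * step
            # reflect off the depth band so trees stay in their layer
            if nxt[0] < depth_lo_um or nxt[0] > depth_hi_um:
                d[0] = -d[0]
                nxt = pos + d * step
            # cap the turn per step: hairpin kinks make the rasterized tube
            # self-adjacent, which the thinning reads as a spurious junction
            if d_prev is not None and float(np.dot(d, d_prev)) < 0.5:
                d = _perturb(rng, 0.5 * (d + d_prev), 0.3, spec.vertical_drift)
                continue
            if np.any(nxt[:3] < margin) or np.any(nxt[:3] > ext - margin):
                d = _perturb(rng, d, 0.6, spec.vertical_drift)
                continue
            if store is not None and store.collides(pos, nxt, radius_um, step_exempt, clearance_um):
                d = _perturb(rng, d, 0.6, spec.vertical_drift)
                continue
            # never fold back onto this polyline's own older segments
            if len(own_p0) > 2 and np.any(
                _segment_distance(pos, nxt, np.asarray(own_p0[:-2]), np.asarray(own_p1[:-2]))
                < 2 * radius_um + clearance_um
            ):
                d = _perturb(rng, d, 0.6, spec.vertical_drift)
                continue
            placed = True
            break
        if not placed:
            break
        own_p0.append(pos.copy())
        own_p1.append(nxt.copy())
        pts.append(np.concatenate([nxt, [radius_um]]))
        d_prev = (nxt - pos) / np.linalg.norm(nxt - pos)
        pos = nxt
        d = _perturb(rng, d, 0.25, spec.vertical_drift)
    return np.asarray(pts, float)


def generate_vessel_tree(
    spec: VesselTreeSpec, grid: VoxelGrid, store: _SegmentStore | None = None
) -> PhantomTruth:
    """Generate branching vessel trees with full ground truth.

    Each tree grows from a root at a random lateral position and a root depth
    drawn from ``depth_range_mm``, with a mostly-horizontal random-walk
    centerline.  Children are spawned at interior points of the parent
    polyline with probability ``branching_prob`` per point, at ~0.8× the
    parent radius; a bifurcation is only counted when the child polyline has
    at least one segment, which makes the recorded per-tree count equal the
    number of degree-≥3 nodes of the polyline point-adjacency graph by
    construction.  Deterministic given ``spec.seed``.

    Passing a shared ``store`` keeps collision avoidance active across
    several calls on the same grid (e.g. a subject assembled tree by tree).
    """
    spec.validate(grid)
    rng = np.random.default_rng(spec.seed)
    ext = np.asarray(grid.extent_um, float)
    min_r_um = 1.5 * max(grid.spacing_um)
    so2_values = (
        np.asarray(spec.so2_per_vessel, float)
        if spec.so2_per_vessel is not None
        else rng.uniform(0.45, 0.95, spec.n_trees)
    )

    truth = PhantomTruth(grid=grid)
    tree_polylines: list[list[np.ndarray]] = []
    if store is None:
        store = _SegmentStore()
    clearance_um = 2.5 * max(grid.spacing_um)
    next_poly_id = store.next_id
    for tree_idx in range(spec.n_trees):
        root_depth = rng.uniform(*spec.depth_range_mm) * 1000.0
        if spec.confine_depth_mm is not None:
            depth_lo = spec.confine_depth_mm[0] * 1000.0 + spec.radius_range_um[1]
            depth_hi = spec.confine_depth_mm[1] * 1000.0 - spec.radius_range_um[1]
        else:
            band_half = 3.0 * spec.vertical_drift * spec.segment_length_um + 2 * spec.radius_range_um[1]
            depth_lo = max(root_depth - band_half, spec.radius_range_um[1])
            depth_hi = min(root_depth + band_half, ext[0] - spec.radius_range_um[1])
        depth_lo = max(depth_lo, spec.radius_range_um[1])
        depth_hi = min(depth_hi, ext[0] - spec.radius_range_um[1])
        if depth_hi <= depth_lo:
            raise ValueError(
                f"depth confinement band {spec.confine_depth_mm} mm leaves no room "
                f"for vessels of radius up to {spec.radius_range_um[1]} um"
            )
        root = np.array(
            [
                root_depth,
                rng.uniform(0.08, 0.92) * ext[1],
                rng.uniform(0.08, 0.92) * ext[2],
            ]
        )
        radius = rng.uniform(*spec.radius_range_um)
        polylines: list[np.ndarray] = []
        n_bifurcations = 0
        # breadth-first growth over (start, direction, radius, parent poly id)
        queue = [(root, _random_unit(rng, spec.vertical_drift), radius, -1)]
        while queue:
            start, d, r, parent_id = queue.pop(0)
            poly_id = next_poly_id
            next_poly_id += 1
            exempt = {poly_id, parent_id}
            poly = _grow_branch(
                rng, start, d, r, spec, grid, depth_lo, depth_hi,
                store=store, exempt=exempt, clearance_um=clearance_um,
            )
            if len(poly) < 2:
                continue
            store.add(poly, poly_id)
            polylines.append(poly)
            # children attach at interior points, away from the parent's ends
            # (skeleton ends retract by about one radius during thinning, so a
            # junction at the very end of the parent would be unrecoverable)
            i = 2
            while i < len(poly) - 2:
                if rng.random() < spec.branching_prob:
                    child_r = max(r * rng.uniform(0.7, 0.9), min_r_um)
                    child_d = _child_direction(rng, d, spec.vertical_drift)
                    child_id = next_poly_id
                    next_poly_id += 1
                    child = _grow_branch(
                        rng, poly[i, :3].copy(), child_d, child_r, spec, grid,
                        depth_lo, depth_hi,
                        store=store, exempt={child_id, poly_id}, clearance_um=clearance_um,
                    )
                    # keep only substantial children: very short twigs are
                    # indistinguishable from thinning spurs downstream
                    if len(child) >= 4:
                        store.add(child, child_id)
                        polylines.append(child)
                        n_bifurcations += 1
                        i += 3  # keep bifurcations separated along the parent
                        continue
                i += 1
        truth.centerlines.extend(polylines)
        truth.branch_count_per_tree.append(n_bifurcations)
        tree_polylines.append(polylines)

    store.next_id = next_poly_id
    # rasterize per tree so per-tree SO2 can be painted
    full = np.zeros(grid.shape, bool)
    for tree_idx, polylines in enumerate(tree_polylines):
        mask = rasterize_polylines(grid, polylines, caps="round")
        s = float(so2_values[tree_idx]) if len(so2_values) else 0.0
        newly = mask & ~full
        truth.c_hbo2[newly] = s
        truth.c_hb[newly] = 1.0 - s
        truth.per_voxel_so2[newly] = s
        full |= mask
    truth.vessel_mask = full
    return truth


# ---------------------------------------------------------------------------
# melanin layer


def generate_melanin_layer(
    grid: VoxelGrid,
    torus_params: TorusParams,
    seed: int = 0,
    max_tries: int = 2000,
) -> np.ndarray:
    """Union of non-overlapping torus-like melanin structures, top depth band.

    A torus with vertical axis at centre c satisfies
    ``(sqrt((x-cx)² + (y-cy)²) - R_major)² + (z-cz)² <= r_minor²``.
    Placement is rejection-sampled to keep tori disjoint; an impossible
    placement (too many tori for the field) raises rather than overlapping.
    """
    torus_params.validate(grid)
    rng = np.random.default_rng(seed)
    ext = grid.extent_um
    lo_band, hi_band = torus_params.depth_band_um
    R, r = torus_params.major_radius_um, torus_params.minor_radius_um
    centers: list[np.ndarray] = []
    margin = torus_params.outer_radius_um
    tries = 0
    while len(centers) < torus_params.n_tori:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {torus_params.n_tori} disjoint tori of outer "
                f"radius {torus_params.outer_radius_um} µm in a "
                f"{ext[2]:.0f}×{ext[1]:.0f} µm field after {max_tries} tries"
            )
        c = np.array(
            [
                rng.uniform(lo_band + r, hi_band - r),
                rng.uniform(margin, ext[1] - margin),
                rng.uniform(margin, ext[2] - margin),
            ]
        )
        if all(np.hypot(c[1] - p[1], c[2] - p[2]) > 2 * margin for p in centers):
            centers.append(c)

    mask = np.zeros(grid.shape, bool)
    zc, yc, xc = grid.voxel_centers_um()
    band = (zc >= lo_band) & (zc < hi_band)
    for c in centers:
        rho = np.sqrt((yc - c[1]) ** 2 + (xc - c[2]) ** 2)
        inside = (rho - R) ** 2 + (zc - c[0]) ** 2 <= r**2
        mask |= inside & band
    return mask


def add_melanin_to_truth(
    truth: PhantomTruth, melanin_mask: np.ndarray, concentration: float = 1.0
) -> PhantomTruth:
    """Attach a melanin mask (and its concentration field) to a truth record."""
    truth.melanin_mask = melanin_mask.astype(bool)
    truth.c_melanin = np.where(truth.melanin_mask, float(concentration), 0.0)
    return truth


# ---------------------------------------------------------------------------
# forward model


def synthesize_pa_volumes(
    truth: PhantomTruth,
    spectra: ChromophoreSpectra,
    wavelengths_nm: tuple[float, ...] = (575.0, 586.0, 650.0),
    noise_sd: float = 0.0,
    attenuation_per_mm: float = 0.4,
    seed: int = 0,
    subject_id: str = "",
) -> MultiwavelengthScan:
    """Single-scatter absorption-proportional forward model.

    amplitude(λ, r) = [ε_HbO2(λ)·C_HbO2 + ε_Hb(λ)·C_Hb + ε_mel(λ)·C_mel]
                      · exp(−attenuation_per_mm · depth_mm)
                      + N(0, noise_sd · signal_scale)

    where ``signal_scale`` is the maximum noiseless amplitude over all
    requested wavelengths.  The noiseless call is deterministic; noise uses
    ``seed``.  Amplitudes are clipped at zero (the device reports energies).
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    depth_mm = ((np.arange(grid.nz, dtype=float) + 0.5) * grid.spacing_um[0] / 1000.0)[
        :, None, None
    ]
    atten = np.exp(-attenuation_per_mm * depth_mm)
    clean = {}
    for wl in wavelengths_nm:
        mu = (
            spectra.hbo2(wl) * truth.c_hbo2
            + spectra.hb(wl) * truth.c_hb
            + spectra.melanin(wl) * truth.c_melanin
        )
        clean[float(wl)] = mu * atten
    scale = max((float(v.max()) for v in clean.values()), default=0.0)
    volumes = {}
    for wl, v in clean.items():
        if noise_sd > 0 and scale > 0:
            v = v + rng.normal(0.0, noise_sd * scale, v.shape)
            v = np.maximum(v, 0.0)
        volumes[wl] = v
    return MultiwavelengthScan(
        volumes=volumes, spacing_um=grid.spacing_um, subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# simple deterministic phantoms for tests and examples


def straight_tube_truth(
    grid: VoxelGrid,
    radius_um: float,
    depth_um: float | None = None,
    so2: float = 0.8,
    axis: str = "x",
) -> PhantomTruth:
    """One straight flat-ended tube spanning the grid; branch count 0."""
    spacing = np.asarray(grid.spacing_um, float)
    ext = np.asarray(grid.extent_um, float)
    z = depth_um if depth_um is not None else ext[0] / 2.0
    # snap the axis to a voxel-centre depth: axes on voxel boundaries make the
    # mask even-symmetric in z, which parallel thinning handles poorly
    z = (np.floor(z / spacing[0]) + 0.5) * spacing[0]
    if axis == "x":
        p0 = np.array([z, ext[1] / 2, radius_um])
        p1 = np.array([z, ext[1] / 2, ext[2] - radius_um])
    elif axis == "y":
        p0 = np.array([z, radius_um, ext[2] / 2])
        p1 = np.array([z, ext[1] - radius_um, ext[2] / 2])
    else:
        raise ValueError("axis must be 'x' or 'y'")
    poly = np.array([np.concatenate([p0, [radius_um]]), np.concatenate([p1, [radius_um]])])
    truth = PhantomTruth(grid=grid, centerlines=[poly], branch_count_per_tree=[0])
    mask = np.zeros(grid.shape, bool)
    _segment_mask(grid, p0, p1, radius_um, radius_um, mask, caps="flat")
    truth.vessel_mask = mask
    truth.c_hbo2 = np.where(mask, so2, 0.0)
    truth.c_hb = np.where(mask, 1.0 - so2, 0.0)
    truth.per_voxel_so2 = np.where(mask, so2, 0.0)
    return truth


def y_tree_truth(grid: VoxelGrid, radius_um: float = 90.0, so2: float = 0.8) -> PhantomTruth:
    """A single Y-bifurcation: one parent with a child at an interior point."""
    ext = np.asarray(grid.extent_um, float)
    sp = np.asarray(grid.spacing_um, float)
    z = (np.floor(ext[0] / 2.0 / sp[0]) + 0.5) * sp[0]
    y0 = (np.floor(ext[1] / 2.0 / sp[1]) + 0.5) * sp[1]
    xa, xb, xc = 0.1 * ext[2], 0.5 * ext[2], 0.9 * ext[2]
    parent = np.array(
        [[z, y0, xa, radius_um], [z, y0, xb, radius_um], [z, y0, xc, radius_um]]
    )
    child = np.array(
        [[z, y0, xb, radius_um * 0.8], [z, 0.85 * ext[1], 0.85 * ext[2], radius_um * 0.8]]
    )
    truth = PhantomTruth(
        grid=grid, centerlines=[parent, child], branch_count_per_tree=[1]
    )
    mask = rasterize_polylines(grid, [parent, child], caps="round")
    truth.vessel_mask = mask
    truth.c_hbo2 = np.where(mask, so2, 0.0)
    truth.c_hb = np.where(mask, 1.0 - so2, 0.0)
    truth.per_voxel_so2 = np.where(mask, so2, 0.0)
    return truth
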