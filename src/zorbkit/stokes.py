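"""Meshfree Stokes solver for rigid bodies in a circular microdrop.

The microdrop is a 2D incompressible Stokes domain: a circular no-slip wall
of radius ``drop_radius`` containing rigid bodies (disks for microcolonies,
capsules for rod-shaped bacteria) that translate with prescribed velocities
(resistance problem) or move force-free (mobility problem).  The governing
equations are

    grad(p)/rho - nu lap(u) = f,   div(u) = 0   in the fluid,
    u = 0 (wall),  u = V_n + omega_n x r  on body n,

solved by GMLS collocation: velocity Laplacians come from local
divergence-free polynomial reconstructions, pressure gradients from scalar
reconstructions, and the discrete problem is a sparse weighted least-squares
system (momentum + continuity at every node, Dirichlet data on boundaries,
and a zero-mean pressure gauge) solved through its normal equations.

Internal unit system: lengths in micrometers, time in seconds, dynamic
viscosity scaled out (the pressure unknown is ``q = p / mu`` with units 1/s).
Forces are converted back to newtons at the reporting edge using ``mu`` and
the configurable slab depth ``depth_scale_um`` (a 2D solver yields force per
unit depth; absolute newtons depend on this normalization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import (
    ArgumentError,
    AdaptiveError,
    GeometryError,
    SolverError,
)
from .gmls import (
    BODY_BOUNDARY,
    DROP_BOUNDARY,
    FLUID,
    GMLSConfig,
    GMLSNodeSet,
    Neighborhood,
    build_neighborhoods,
    gmls_reconstruct,
    scalar_stencils,
    vector_laplacian_stencil,
    weight,
)

__all__ = [
    "FluidDomain",
    "RigidBody",
    "StokesSolution",
    "BodyForce",
    "SpacingField",
    "discretize",
    "solve_stokes",
    "StokesSystem",
    "resistance_matrix",
    "traction_force",
    "adaptive_solve",
    "benchmark_wannier",
    "convergence_order",
    "scene_gliding_bacteria",
    "scene_colonies",
    "GlidingSceneConfig",
    "ColonySceneConfig",
]


# ---------------------------------------------------------------------------
# Domain and bodies


@dataclass(frozen=True)
class FluidDomain:
    """Circular under-oil microdrop treated as a bounded Stokes domain.

    ``nu`` and ``rho`` default to a dilute aqueous buffer; forces scale
    linearly with ``mu = rho * nu`` so any correction is multiplicative.
    ``depth_scale_um`` converts 2D force-per-depth into reported force.
    """

    drop_radius_um: float
    nu_m2_s: float = 1.0e-6
    rho_kg_m3: float = 1000.0
    depth_scale_um: float = 1.0

    def __post_init__(self):
        if min(self.drop_radius_um, self.nu_m2_s, self.rho_kg_m3,
               self.depth_scale_um) <= 0:
            raise ArgumentError("all domain parameters must be positive")

    @property
    def mu_pa_s(self) -> float:
        return self.nu_m2_s * self.rho_kg_m3


@dataclass
class RigidBody:
    """A rigid disk (microcolony) or capsule (rod-shaped bacterium).

    ``velocity_um_s`` may be ``None`` ("free") for the mobility problem.
    ``angular_velocity_rad_s`` supports validation flows with rotating
    boundaries; production microcolony scenes keep it zero (rotation of the
    bodies is treated as negligible).
    """

    body_id: int
    shape: Literal["disk", "capsule"]
    position: tuple[float, float]
    radius_um: float = 0.0                  # disk
    length_um: float = 0.0                  # capsule, total tip-to-tip
    width_um: float = 0.0                   # capsule
    orientation_rad: float = 0.0            # capsule axis angle
    velocity_um_s: tuple[float, float] | None = (0.0, 0.0)
    angular_velocity_rad_s: float = 0.0

    def __post_init__(self):
        if self.shape == "disk":
            if self.radius_um <= 0:
                raise ArgumentError("disk body needs radius_um > 0")
        elif self.shape == "capsule":
            if not (self.length_um >= self.width_um > 0):
                raise ArgumentError("capsule needs length_um >= width_um > 0")
        else:
            raise ArgumentError(f"unknown body shape {self.shape!r}")

    @property
    def is_free(self) -> bool:
        return self.velocity_um_s is None

    @property
    def half_segment(self) -> float:
        return max(self.length_um - self.width_um, 0.0) / 2.0

    @property
    def cap_radius(self) -> float:
        return self.radius_um if self.shape == "disk" else self.width_um / 2.0

    @property
    def bounding_radius(self) -> float:
        return self.cap_radius + self.half_segment

    @property
    def perimeter(self) -> float:
        if self.shape == "disk":
            return 2 * np.pi * self.radius_um
        return 4 * self.half_segment + np.pi * self.width_um

    def _axis(self) -> np.ndarray:
        return np.array(
            [math.cos(self.orientation_rad), math.sin(self.orientation_rad)]
        )

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the body surface (< 0 inside)."""
        pts = np.atleast_2d(pts)
        rel = pts - np.asarray(self.position)
        if self.shape == "disk":
            return np.linalg.norm(rel, axis=1) - self.radius_um
        ax = self._axis()
        t = np.clip(rel @ ax, -self.half_segment, self.half_segment)
        closest = t[:, None] * ax
        return np.linalg.norm(rel - closest, axis=1) - self.cap_radius

    def boundary_points(self, spacing_fn) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample the outline at local arc spacing; returns
        (points, outward normals, local spacing)."""
        pos = np.asarray(self.position)
        pts, normals, hs = [], [], []
        if self.shape == "disk":
            R = self.radius_um
            probe_th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
            probe = pos + R * np.column_stack(
                [np.cos(probe_th), np.sin(probe_th)]
            )
            hvals = spacing_fn(probe)
            if np.ptp(hvals) < 1e-9 * hvals.mean():
                # constant spacing: uniform angles, even count, so mirror
                # symmetric scenes discretize mirror symmetrically
                n = int(math.ceil(2 * np.pi * R / hvals[0]))
                n = max(n + (n % 2), 8)
                th_all = 2 * np.pi * np.arange(n) / n
                for th in th_all:
                    p = pos + R * np.array([math.cos(th), math.sin(th)])
                    pts.append(p)
                    normals.append((p - pos) / R)
                    hs.append(float(hvals[0]))
                return np.array(pts), np.array(normals), np.array(hs)
            th = 0.0
            while th < 2 * np.pi - 1e-12:
                p = pos + R * np.array([math.cos(th), math.sin(th)])
                h = float(spacing_fn(p[None, :])[0])
                pts.append(p)
                normals.append((p - pos) / R)
                hs.append(h)
                th += min(h, 2 * np.pi * R / 8) / R
            return np.array(pts), np.array(normals), np.array(hs)
        # capsule: walk the outline by arc length
        a = self.half_segment
        r = self.cap_radius
        ax = self._axis()
        perp = np.array([-ax[1], ax[0]])

        def at_arclength(s: float):
            straight = 2 * a
            cap = np.pi * r
            s = s % self.perimeter
            if s < straight:  # top edge, +perp side, from -a to +a
                local = (-a + s) * ax + r * perp
                n = perp
            elif s < straight + cap:  # right cap: +perp -> +ax -> -perp
                phi = (s - straight) / r
                n = math.sin(phi) * ax + math.cos(phi) * perp
                local = a * ax + r * n
            elif s < 2 * straight + cap:  # bottom edge, from +a to -a
                local = (a - (s - straight - cap)) * ax - r * perp
                n = -perp
            else:  # left cap
                phi = (s - 2 * straight - cap) / r
                nvec = -math.sin(phi) * ax - math.cos(phi) * perp
                local = -a * ax + r * nvec
                n = nvec
            return pos + local, n

        s = 0.0
        while s < self.perimeter - 1e-12:
            p, n = at_arclength(s)
            h = float(spacing_fn(p[None, :])[0])
            pts.append(p)
            normals.append(n)
            hs.append(h)
            s += min(h, self.perimeter / 16)
        return np.array(pts), np.array(normals), np.array(hs)

    def boundary_velocity(self, pts: np.ndarray) -> np.ndarray:
        if self.is_free:
            raise ArgumentError(
                f"body {self.body_id} has no prescribed velocity"
            )
        pts = np.atleast_2d(pts)
        v = np.tile(np.asarray(self.velocity_um_s, dtype=float), (len(pts), 1))
        if self.angular_velocity_rad_s:
            rel = pts - np.asarray(self.position)
            v[:, 0] += -self.angular_velocity_rad_s * rel[:, 1]
            v[:, 1] += self.angular_velocity_rad_s * rel[:, 0]
        return v


@dataclass
class BodyForce:
    """Integrated hydrodynamic load on one body."""

    body_id: int
    force_N: np.ndarray            # (2,) in newtons (uses depth_scale)
    torque_Nm: float               # about the body position
    force_per_depth_N_per_m: np.ndarray
    torque_per_depth_N: float
    quadrature_points: int
    depth_scale_um: float


@dataclass
class StokesSolution:
    """Solved velocity/pressure fields on a node set plus diagnostics."""

    nodes: GMLSNodeSet
    velocity: np.ndarray           # (N, 2) um/s
    q: np.ndarray                  # (N,) pressure / mu, 1/s
    domain: FluidDomain
    bodies: list[RigidBody]
    config: GMLSConfig
    residuals: dict
    refinement_history: list = field(default_factory=list)
    resolved_velocities: dict = field(default_factory=dict)

    _tree: cKDTree = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self._tree = cKDTree(self.nodes.positions)

    @property
    def pressure_pa(self) -> np.ndarray:
        return self.q * self.domain.mu_pa_s

    def _local_neighborhood(self, point: np.ndarray) -> Neighborhood:
        i = self._tree.query(point)[1]
        eps = float(self.nodes.support[i])
        for _ in range(6):
            idx = np.array(self._tree.query_ball_point(point, eps), dtype=int)
            if len(idx) >= self.config.resolved_min_neighbors:
                break
            eps *= 1.25
        d = np.linalg.norm(self.nodes.positions[idx] - point, axis=1)
        keep = d < eps
        idx, d = idx[keep], d[keep]
        return Neighborhood(
            center_index=-1, center=np.asarray(point, dtype=float), eps=eps,
            neighbor_indices=idx, positions=self.nodes.positions[idx],
            distances=d, weights=weight(d, eps, self.config.weight_exponent),
        )

    def fields_at(self, points: np.ndarray):
        """Reconstruct (u, grad u, q) at arbitrary points.

        Velocity and its gradient come from the divergence-free vector
        reconstruction; q from the scalar reconstruction.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.empty((len(points), 2))
        gradu = np.empty((len(points), 2, 2))
        qv = np.empty(len(points))
        for k, pt in enumerate(points):
            nb = self._local_neighborhood(pt)
            rec_v = gmls_reconstruct(
                pt, nb, self.velocity[nb.neighbor_indices], self.config,
                kind="divergence_free_vector",
            )
            u[k] = rec_v(pt[None, :])[0]
            dux = rec_v.derivative((1, 0))
            duy = rec_v.derivative((0, 1))
            gradu[k, :, 0] = dux
            gradu[k, :, 1] = duy
            rec_q = gmls_reconstruct(
                pt, nb, self.q[nb.neighbor_indices], self.config
            )
            qv[k] = rec_q(pt[None, :])[0]
        return u, gradu, qv

    def divergence_diagnostics(self) -> dict:
        """Native (divergence-free reconstruction) and independent scalar
        stencil divergence of the solved field at interior nodes."""
        nbrs = build_neighborhoods(self.nodes, self.config, self._tree)
        interior = self.nodes.subset_indices(FLUID)
        native = 0.0
        indep = 0.0
        for i in interior:
            nb = nbrs[i]
            rec = gmls_reconstruct(
                self.nodes.positions[i], nb,
                self.velocity[nb.neighbor_indices], self.config,
                kind="divergence_free_vector",
            )
            native = max(native, abs(rec.divergence_at_center()))
            S = scalar_stencils(nb, self.config, [(1, 0), (0, 1)])
            div = (
                S[0] @ self.velocity[nb.neighbor_indices, 0]
                + S[1] @ self.velocity[nb.neighbor_indices, 1]
            )
            indep = max(indep, abs(div))
        return {"native_divergence_linf": native,
                "scalar_stencil_divergence_linf": indep}


# ---------------------------------------------------------------------------
# Spacing field + discretization


@dataclass
class SpacingField:
    """Target node spacing h(x): a base value refined inside patches.

    Each patch (center, radius, h) imposes spacing ``h`` inside ``radius``
    and relaxes linearly (grading 0.7 per unit distance) outside.
    """

    base: float
    patches: list = field(default_factory=list)  # (center(2,), radius, h)
    grade: float = 0.2

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        h = np.full(len(pts), self.base)
        for center, radius, hp in self.patches:
            d = np.linalg.norm(pts - np.asarray(center), axis=1)
            local = np.where(d <= radius, hp, hp + self.grade * (d - radius))
            h = np.minimum(h, local)
        return h

    def refined(self, extra) -> "SpacingField":
        return SpacingField(self.base, list(self.patches) + list(extra),
                            self.grade)


def _min_separation(b1: RigidBody, b2: RigidBody, n_sample: int = 64):
    """Approximate surface-to-surface separation and the midpoint."""
    if b1.shape == "disk" and b2.shape == "disk":
        d = np.linalg.norm(np.asarray(b1.position) - np.asarray(b2.position))
        sep = d - b1.radius_um - b2.radius_um
        mid = (
            np.asarray(b1.position)
            + (b1.radius_um + sep / 2)
            * (np.asarray(b2.position) - np.asarray(b1.position))
            / max(d, 1e-300)
        )
        return sep, mid
    th = np.linspace(0, 2 * np.pi, n_sample, endpoint=False)
    const = SpacingField(max(b1.perimeter, b2.perimeter) / n_sample)
    p1 = b1.boundary_points(const)[0]
    p2 = b2.boundary_points(const)[0]
    d2 = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return float(d2[i, j]), (p1[i] + p2[j]) / 2


def _wall_separation(domain: FluidDomain, body: RigidBody):
    pos = np.asarray(body.position)
    r = np.linalg.norm(pos)
    if body.shape == "disk":
        sep = domain.drop_radius_um - r - body.radius_um
        direction = pos / r if r > 0 else np.array([1.0, 0.0])
        mid = direction * (domain.drop_radius_um - sep / 2)
        return sep, mid
    const = SpacingField(body.perimeter / 64)
    pts = body.boundary_points(const)[0]
    d = domain.drop_radius_um - np.linalg.norm(pts, axis=1)
    i = int(np.argmin(d))
    direction = pts[i] / np.linalg.norm(pts[i])
    return float(d[i]), direction * (np.linalg.norm(pts[i]) + d[i] / 2)


def _validate_geometry(domain: FluidDomain, bodies: Sequence[RigidBody]):
    for b in bodies:
        sep, _ = _wall_separation(domain, b)
        if sep <= 0:
            raise GeometryError(
                f"body {b.body_id} touches or crosses the drop wall "
                f"(separation {sep:g} um)"
            )
    for i, b1 in enumerate(bodies):
        for b2 in bodies[i + 1:]:
            sep, _ = _min_separation(b1, b2)
            if sep <= 0:
                raise GeometryError(
                    f"bodies {b1.body_id} and {b2.body_id} overlap "
                    f"(separation {sep:g} um)"
                )


def _gap_patches(domain: FluidDomain, bodies: Sequence[RigidBody],
                 h0: float) -> list:
    """Refinement patches for narrow gaps (body-body and body-wall):
    local spacing at most half the gap width."""
    patches = []

    def add(sep, mid, r_char):
        if sep < 2.5 * h0:
            hp = min(h0, sep / 2.5)
            # cover the lubrication zone, which extends ~ sqrt(r * gap)
            # along the surfaces, not just the gap width itself
            radius = max(2.5 * sep, 2.0 * math.sqrt(max(r_char * sep, 0.0)))
            patches.append((np.asarray(mid), radius, hp))

    for i, b1 in enumerate(bodies):
        for b2 in bodies[i + 1:]:
            sep, mid = _min_separation(b1, b2)
            add(sep, mid, min(b1.bounding_radius, b2.bounding_radius))
    for b in bodies:
        sep, mid = _wall_separation(domain, b)
        add(sep, mid, b.bounding_radius)
    return patches


def _quadtree_points(domain: FluidDomain, bodies: Sequence[RigidBody],
                     spacing: SpacingField,
                     clearance: float = 2.1) -> tuple[np.ndarray, np.ndarray]:
    """Interior fluid nodes from recursive cell subdivision driven by the
    spacing field; returns (points, local spacing)."""
    R = domain.drop_radius_um
    pts_out, h_out = [], []
    stack = [(-R, -R, 2 * R)]
    while stack:
        x0, y0, s = stack.pop()
        c = np.array([x0 + s / 2, y0 + s / 2])
        # cell entirely outside the drop?
        corner_dist = np.linalg.norm(c) - s * 0.7071
        if corner_dist > R:
            continue
        h = float(spacing(c[None, :])[0])
        if s > h * 1.45:
            half = s / 2
            stack.extend([
                (x0, y0, half), (x0 + half, y0, half),
                (x0, y0 + half, half), (x0 + half, y0 + half, half),
            ])
            continue
        # keep cell center if clearly inside the fluid; boundary-fitted
        # ring nodes cover the first ~2 spacings off each boundary
        clear = clearance * s
        if np.linalg.norm(c) > R - clear:
            continue
        if any(b.sdf(c[None, :])[0] < clear for b in bodies):
            continue
        pts_out.append(c)
        h_out.append(s)
    if not pts_out:
        return np.empty((0, 2)), np.empty(0)
    return np.array(pts_out), np.array(h_out)


def discretize(
    domain: FluidDomain,
    bodies: Sequence[RigidBody],
    target_spacing: float,
    config: GMLSConfig | None = None,
    extra_patches: Sequence = (),
    boundary_rings: bool = True,
) -> GMLSNodeSet:
    """Seed boundary and interior GMLS nodes for the given geometry.

    Boundary nodes are placed on the drop wall and each body outline at the
    local arc spacing; interior nodes come from a quadtree driven by the
    spacing field (base ``target_spacing``, automatically refined in narrow
    gaps so gap spacing is at most half the gap width).  Per-node supports
    are grown where needed so every node satisfies the neighborhood floor.
    """
    if target_spacing <= 0:
        raise ArgumentError("target_spacing must be positive")
    config = config or GMLSConfig()
    bodies = list(bodies)
    _validate_geometry(domain, bodies)
    # snap the base spacing to the dyadic quadtree cell size so boundary and
    # interior node spacings match (mismatched spacings degrade the
    # one-sided reconstructions at the surface)
    R = domain.drop_radius_um
    k = max(int(round(math.log2(2 * R / target_spacing))), 1)
    cell = 2 * R / 2**k
    quantized = []
    for center, radius, hp in (
        _gap_patches(domain, bodies, cell) + list(extra_patches)
    ):
        m = max(int(math.ceil(math.log2(cell / hp))), 0) if hp < cell else 0
        quantized.append((center, radius, cell / 2**m))
    spacing = SpacingField(cell, quantized)

    def bnd_spacing(pts):
        # boundaries honor the requested spacing exactly; only the interior
        # quadtree is quantized to dyadic cell sizes
        return np.minimum(spacing(np.atleast_2d(pts)), target_spacing)

    positions, kinds, spacings, body_ids = [], [], [], []

    # drop wall
    R = domain.drop_radius_um
    wall_pts = []
    probe_th = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    probe = R * np.column_stack([np.cos(probe_th), np.sin(probe_th)])
    hvals = bnd_spacing(probe)
    if np.ptp(hvals) < 1e-9 * hvals.mean():
        n = int(math.ceil(2 * np.pi * R / hvals[0]))
        n = max(n + (n % 2), 16)
        for th in 2 * np.pi * np.arange(n) / n:
            wall_pts.append((R * np.array([math.cos(th), math.sin(th)]),
                             float(hvals[0])))
    else:
        th = 0.0
        while th < 2 * np.pi - 1e-12:
            p = R * np.array([math.cos(th), math.sin(th)])
            h = float(bnd_spacing(p[None, :])[0])
            wall_pts.append((p, h))
            th += min(h, 2 * np.pi * R / 16) / R
    for p, h in wall_pts:
        positions.append(p)
        kinds.append(DROP_BOUNDARY)
        spacings.append(h)
        body_ids.append(-1)

    for b in bodies:
        pts, _, hs = b.boundary_points(bnd_spacing)
        for p, h in zip(pts, hs):
            positions.append(p)
            kinds.append(BODY_BOUNDARY)
            spacings.append(h)
            body_ids.append(b.body_id)

    # boundary-fitted rings of fluid nodes just inside each boundary: they
    # give boundary-adjacent stencils locally structured support along the
    # curve, which sharply improves the near-wall truncation constants
    def add_ring(p, inward, h, off):
        c = p + off * h * inward
        if np.linalg.norm(c) >= R - 0.35 * h:
            return
        if any(b.sdf(c[None, :])[0] < 0.35 * h for b in bodies):
            return
        positions.append(c)
        kinds.append(FLUID)
        spacings.append(h)
        body_ids.append(-1)

    if boundary_rings:
        for p, h in wall_pts:
            inward = -p / np.linalg.norm(p)
            for off in (0.8, 1.6):
                add_ring(p, inward, h, off)
        for b in bodies:
            pts, nrm, hs = b.boundary_points(spacing)
            for p, n, h in zip(pts, nrm, hs):
                for off in (0.8, 1.6):
                    add_ring(p, n, h, off)

    interior, hint = _quadtree_points(
        domain, bodies, spacing,
        clearance=2.1 if boundary_rings else 0.5,
    )
    for p, h in zip(interior, hint):
        positions.append(p)
        kinds.append(FLUID)
        spacings.append(h)
        body_ids.append(-1)

    positions = np.array(positions)
    spacings = np.array(spacings)
    nodes = GMLSNodeSet(
        positions=positions,
        node_kind=np.array(kinds, dtype=object),
        spacing=spacings,
        support=config.support_factor * spacings,
        body_id=np.array(body_ids, dtype=int),
    )
    _grow_supports(nodes, config)
    return nodes


def _grow_supports(nodes: GMLSNodeSet, config: GMLSConfig) -> None:
    """Enlarge individual supports until every node has enough strictly
    interior neighbors (small head-room added to avoid edge ties)."""
    tree = cKDTree(nodes.positions)
    need = config.resolved_min_neighbors
    for i in range(len(nodes)):
        eps = nodes.support[i]
        for _ in range(25):
            idx = tree.query_ball_point(nodes.positions[i], eps)
            d = np.linalg.norm(
                nodes.positions[idx] - nodes.positions[i], axis=1
            )
            if np.count_nonzero((d > 0) & (d < eps * 0.999)) >= need:
                break
            eps *= 1.15
        nodes.support[i] = eps * 1.001


# ---------------------------------------------------------------------------
# Assembly and solve


@dataclass(frozen=True)
class _LSWeights:
    momentum: float = 1.0
    continuity: float = 1.0
    dirichlet: float = 4.0
    gauge: float = 1.0
    pressure_poisson: float = 1.0


class StokesSystem:
    """Factorized discrete Stokes operator for one geometry.

    The least-squares matrix depends only on the node set and GMLS
    configuration (boundary data and forcing enter the right-hand side), so
    one sparse factorization serves any number of boundary-condition sets —
    resistance-matrix columns, mobility solves, linearity sweeps.
    """

    def __init__(self, nodes: GMLSNodeSet, domain: FluidDomain,
                 config: GMLSConfig | None = None,
                 ls_weights: "_LSWeights | None" = None):
        self.nodes = nodes
        self.domain = domain
        self.config = config or GMLSConfig()
        self.weights = ls_weights or _LSWeights()
        self._build()

    def _build(self) -> None:
        nodes, config, weights = self.nodes, self.config, self.weights
        nbrs = build_neighborhoods(nodes, config)
        N = len(nodes)
        rows_i, cols_j, vals = [], [], []
        row = 0
        mom_rows = np.full((N, 2), -1, dtype=int)
        mom_w = np.zeros(N)
        dir_rows = np.full((N, 2), -1, dtype=int)
        ppe_rows = np.full(N, -1, dtype=int)
        ppe_data: list = []

        def put(r, cols, vs):
            rows_i.extend([r] * len(cols))
            cols_j.extend(cols)
            vals.extend(vs)

        for i in range(N):
            nb = nbrs[i]
            idx = nb.neighbor_indices
            h = nodes.spacing[i]
            wm = weights.momentum * h * h
            S = scalar_stencils(nb, config, [(1, 0), (0, 1)])
            L = vector_laplacian_stencil(nb, config)  # (2, 2, n)
            # momentum: dq/dx_c - lap(u)_c = f_c
            for c in range(2):
                put(row, list(2 * N + idx), list(wm * S[c]))
                put(row, list(idx), list(-wm * L[c, 0]))
                put(row, list(N + idx), list(-wm * L[c, 1]))
                mom_rows[i, c] = row
                row += 1
            mom_w[i] = wm
            # continuity (independent scalar stencils)
            wc = weights.continuity * h
            put(row, list(idx), list(wc * S[0]))
            put(row, list(N + idx), list(wc * S[1]))
            row += 1
            # pressure Poisson: lap q = div f (divergence of the momentum
            # equation under incompressibility; exact, not a stabilizer in
            # the consistency sense, and it pins down the pressure modes the
            # momentum rows control only weakly)
            if weights.pressure_poisson > 0:
                Lq = scalar_stencils(nb, config, ["lap"])[0]
                wq = weights.pressure_poisson * h * h
                put(row, list(2 * N + idx), list(wq * Lq))
                ppe_rows[i] = row
                ppe_data.append((i, idx, S[0].copy(), S[1].copy(), wq))
                row += 1
            if nodes.node_kind[i] != FLUID:
                wb = weights.dirichlet
                put(row, [i], [wb])
                dir_rows[i, 0] = row
                row += 1
                put(row, [N + i], [wb])
                dir_rows[i, 1] = row
                row += 1
        # pressure gauge: pin one fluid node (keeps the normal equations
        # sparse; pressure is re-centered to zero mean after the solve)
        fluid_idx = np.flatnonzero(nodes.node_kind == FLUID)
        pin = int(fluid_idx[0]) if len(fluid_idx) else 0
        put(row, [2 * N + pin], [weights.gauge])
        row += 1
        A = sp.csr_matrix((vals, (rows_i, cols_j)), shape=(row, 3 * N))
        self.A = A
        self.n_rows = row
        self._mom_rows = mom_rows
        self._mom_w = mom_w
        self._dir_rows = dir_rows
        self._ppe_rows = ppe_rows
        self._ppe_data = ppe_data
        K = (A.T @ A).tocsc()
        try:
            self._lu = spla.splu(K)
        except RuntimeError as exc:
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        self._K = K

    def _rhs(self, bodies, drop_velocity, forcing) -> np.ndarray:
        nodes = self.nodes
        b_vec = np.zeros(self.n_rows)
        body_by_id = {b.body_id: b for b in bodies}
        wb = self.weights.dirichlet
        for i in range(len(nodes)):
            if forcing is not None and self._mom_rows[i, 0] >= 0:
                f = np.asarray(
                    forcing(nodes.positions[i][None, :])
                ).reshape(-1)[:2]
                b_vec[self._mom_rows[i, 0]] = self._mom_w[i] * f[0]
                b_vec[self._mom_rows[i, 1]] = self._mom_w[i] * f[1]
            if self._dir_rows[i, 0] >= 0:
                g = self._boundary_value(i, body_by_id, drop_velocity)
                b_vec[self._dir_rows[i, 0]] = wb * g[0]
                b_vec[self._dir_rows[i, 1]] = wb * g[1]
        if forcing is not None:
            for i, idx, Sx, Sy, wq in self._ppe_data:
                fn = np.asarray(forcing(nodes.positions[idx]))
                div_f = float(Sx @ fn[:, 0] + Sy @ fn[:, 1])
                b_vec[self._ppe_rows[i]] = wq * div_f
        return b_vec

    def _boundary_value(self, i, body_by_id, drop_velocity):
        nodes = self.nodes
        if nodes.node_kind[i] == DROP_BOUNDARY:
            if drop_velocity is None:
                return np.zeros(2)
            return np.asarray(
                drop_velocity(nodes.positions[i][None, :])
            ).reshape(-1)[:2]
        return body_by_id[int(nodes.body_id[i])].boundary_velocity(
            nodes.positions[i][None, :]
        )[0]

    def solve(self, bodies: Sequence[RigidBody],
              drop_velocity: Callable | None = None,
              forcing: Callable | None = None) -> StokesSolution:
        bodies = list(bodies)
        for b in bodies:
            if b.is_free:
                raise ArgumentError(
                    f"body {b.body_id} has no prescribed velocity; use "
                    "mobility mode"
                )
        b_vec = self._rhs(bodies, drop_velocity, forcing)
        rhs = self.A.T @ b_vec
        z = self._lu.solve(rhs)
        # one step of iterative refinement recovers digits lost to the
        # squared conditioning of the normal equations
        z = z + self._lu.solve(rhs - self._K @ z)
        if not np.all(np.isfinite(z)):
            raise SolverError("solution contains non-finite values")
        normal_res = np.linalg.norm(self._K @ z - rhs)
        scale = max(np.linalg.norm(rhs), 1e-300)
        if scale > 1e-250 and normal_res / scale > 1e-6:
            raise SolverError(
                f"normal-equation residual {normal_res / scale:.3g} exceeds "
                "1e-6; system is ill-conditioned"
            )
        N = len(self.nodes)
        u = np.column_stack([z[:N], z[N:2 * N]])
        q = z[2 * N:]
        q = q - q.mean()
        body_by_id = {b.body_id: b for b in bodies}
        bc_err = 0.0
        for i in range(N):
            if self._dir_rows[i, 0] < 0:
                continue
            g = self._boundary_value(i, body_by_id, drop_velocity)
            bc_err = max(bc_err, float(np.max(np.abs(u[i] - g))))
        ls_res = float(np.linalg.norm(self.A @ z - b_vec))
        return StokesSolution(
            nodes=self.nodes, velocity=u, q=q, domain=self.domain,
            bodies=bodies, config=self.config,
            residuals={
                "normal_equation_rel": float(normal_res / scale),
                "ls_residual": ls_res,
                "bc_linf": bc_err,
            },
        )


def solve_stokes(
    nodes: GMLSNodeSet,
    domain: FluidDomain,
    bodies: Sequence[RigidBody],
    gmls_config: GMLSConfig | None = None,
    mode: Literal["resistance", "mobility"] = "resistance",
    forcing: Callable | None = None,
    drop_velocity: Callable | None = None,
    ls_weights: "_LSWeights | None" = None,
) -> StokesSolution:
    """Solve the boundary-value Stokes problem on a prepared node set.

    In resistance mode every body carries a prescribed velocity.  In
    mobility mode bodies with ``velocity_um_s=None`` are solved for the
    translational velocity that makes them force-free (rotation is held at
    zero and body torque balance is not imposed, matching the assumption
    that rotation of the bacteria and microcolonies is negligible).
    """
    system = StokesSystem(nodes, domain, gmls_config, ls_weights)
    bodies = list(bodies)
    if mode == "mobility":
        return _solve_mobility(system, bodies, forcing, drop_velocity)
    return system.solve(bodies, drop_velocity, forcing)


def resistance_matrix(system: StokesSystem,
                      bodies: Sequence[RigidBody]) -> np.ndarray:
    """Grand resistance matrix (translations only) for the given bodies.

    Column (k, d) holds the per-depth forces on all bodies when body k
    translates with unit velocity along axis d and everything else is at
    rest; by the reciprocal theorem the exact matrix is symmetric.
    Forces are in solver units (dynamic viscosity scaled out).
    """
    bodies = list(bodies)
    nb = len(bodies)
    R = np.zeros((2 * nb, 2 * nb))
    for k, bk in enumerate(bodies):
        for d in range(2):
            probe = [
                replace(b, velocity_um_s=(
                    (1.0, 0.0) if d == 0 else (0.0, 1.0)
                ) if b.body_id == bk.body_id else (0.0, 0.0))
                for b in bodies
            ]
            sol = system.solve(probe)
            for j, bj in enumerate(probe):
                f = traction_force(sol, bj, rel_tol=1e-6,
                                   m_start=128).force_per_depth_N_per_m
                f = f / (1e-6 * system.domain.mu_pa_s)
                R[2 * j:2 * j + 2, 2 * k + d] = f
    return R


def _solve_mobility(system: StokesSystem, bodies, forcing, drop_velocity):
    free = [b for b in bodies if b.is_free]
    if not free:
        raise ArgumentError("mobility mode needs at least one free body")
    held = [
        replace(b, velocity_um_s=(0.0, 0.0)) if b.is_free else b
        for b in bodies
    ]
    base = system.solve(held, drop_velocity, forcing)
    free_ids = {f.body_id for f in free}
    base_forces = {
        b.body_id: traction_force(base, b).force_per_depth_N_per_m
        for b in held if b.body_id in free_ids
    }
    unit_solutions = []
    columns = []
    for fb in free:
        for d in range(2):
            vel = (1.0, 0.0) if d == 0 else (0.0, 1.0)
            probe = [
                replace(b, velocity_um_s=vel if b.body_id == fb.body_id
                        else (0.0, 0.0))
                for b in bodies
            ]
            sol = system.solve(probe)
            col = []
            for gb in probe:
                if gb.body_id in free_ids:
                    col.extend(
                        traction_force(sol, gb).force_per_depth_N_per_m
                    )
            unit_solutions.append(sol)
            columns.append(col)
    R = np.array(columns).T  # (2f, 2f)
    rhs = -np.concatenate([base_forces[b.body_id] for b in free])
    V = np.linalg.solve(R, rhs)
    u = base.velocity.copy()
    q = base.q.copy()
    for k, sol in enumerate(unit_solutions):
        u += V[k] * sol.velocity
        q += V[k] * sol.q
    resolved = {
        b.body_id: (float(V[2 * i]), float(V[2 * i + 1]))
        for i, b in enumerate(free)
    }
    final_bodies = [
        replace(b, velocity_um_s=resolved[b.body_id]) if b.is_free else b
        for b in bodies
    ]
    return StokesSolution(
        nodes=system.nodes, velocity=u, q=q, domain=system.domain,
        bodies=final_bodies, config=system.config,
        residuals=dict(base.residuals), resolved_velocities=resolved,
    )


# ---------------------------------------------------------------------------
# Traction forces


def _quad_points(body: RigidBody, m: int):
    """m quadrature points, outward normals and arc weights on the outline."""
    if body.shape == "disk":
        th = 2 * np.pi * (np.arange(m) + 0.5) / m
        n = np.column_stack([np.cos(th), np.sin(th)])
        pts = np.asarray(body.position) + body.radius_um * n
        dl = np.full(m, 2 * np.pi * body.radius_um / m)
        return pts, n, dl
    per = body.perimeter
    svals = per * (np.arange(m) + 0.5) / m
    pts = np.empty((m, 2))
    nrm = np.empty((m, 2))
    a = body.half_segment
    r = body.cap_radius
    ax = body._axis()
    perp = np.array([-ax[1], ax[0]])
    pos = np.asarray(body.position)
    straight = 2 * a
    cap = np.pi * r
    for k, s in enumerate(svals):
        if s < straight:
            local = (-a + s) * ax + r * perp
            n = perp
        elif s < straight + cap:
            phi = (s - straight) / r
            n = math.sin(phi) * ax + math.cos(phi) * perp
            local = a * ax + r * n
        elif s < 2 * straight + cap:
            local = (a - (s - straight - cap)) * ax - r * perp
            n = -perp
        else:
            phi = (s - 2 * straight - cap) / r
            n = -math.sin(phi) * ax - math.cos(phi) * perp
            local = -a * ax + r * n
        pts[k] = pos + local
        nrm[k] = n
    dl = np.full(m, per / m)
    return pts, nrm, dl


def traction_force(solution: StokesSolution, body: RigidBody,
                   rel_tol: float = 1e-3, m_start: int = 64,
                   m_max: int = 1024) -> BodyForce:
    """Integrate the total stress over the body outline.

    sigma = -p I + mu (grad u + grad u^T); the quadrature point count is
    doubled until the force magnitude changes by less than ``rel_tol``
    (0.1 % by default).
    """
    domain = solution.domain
    m = m_start
    prev = None
    while True:
        pts, normals, dl = _quad_points(body, m)
        u, gradu, q = solution.fields_at(pts)
        sig = gradu + np.transpose(gradu, (0, 2, 1))
        sig[:, 0, 0] -= q
        sig[:, 1, 1] -= q
        trac = np.einsum("nij,nj->ni", sig, normals)
        F = (trac * dl[:, None]).sum(axis=0)          # solver units (um/s)
        rel = pts - np.asarray(body.position)
        T = float(((rel[:, 0] * trac[:, 1] - rel[:, 1] * trac[:, 0]) * dl).sum())
        if prev is not None:
            ref = max(np.linalg.norm(F), 1e-300)
            if np.linalg.norm(F - prev[0]) / ref < rel_tol or m >= m_max:
                break
        prev = (F, T)
        if m >= m_max:
            break
        m *= 2
    mu = domain.mu_pa_s
    f_per_depth = mu * F * 1e-6                       # N per meter depth
    t_per_depth = mu * T * 1e-12                      # N (per meter depth)
    depth_m = domain.depth_scale_um * 1e-6
    return BodyForce(
        body_id=body.body_id,
        force_N=f_per_depth * depth_m,
        torque_Nm=t_per_depth * depth_m,
        force_per_depth_N_per_m=f_per_depth,
        torque_per_depth_N=t_per_depth,
        quadrature_points=m,
        depth_scale_um=domain.depth_scale_um,
    )


# ---------------------------------------------------------------------------
# Adaptive refinement


def _error_indicators(solution: StokesSolution) -> np.ndarray:
    """Recovered-gradient jump indicator per node."""
    nodes = solution.nodes
    tree = solution._tree
    config = solution.config
    nbrs = build_neighborhoods(nodes, config, tree)
    recs = []
    for i in range(len(nodes)):
        nb = nbrs[i]
        recs.append(
            gmls_reconstruct(
                nodes.positions[i], nb,
                solution.velocity[nb.neighbor_indices], config,
                kind="divergence_free_vector",
            )
        )

    def grad_at(rec, pt):
        # derivative of the local fit evaluated away from its center
        eps = rec.eps
        X = (pt - rec.center) / eps
        from .gmls import DivFreeVectorBasis, ScalarBasis  # local import

        basis = DivFreeVectorBasis(rec.order)
        sb = ScalarBasis(rec.order)
        # d/dx and d/dy of each scalar monomial at X
        def dmat(alpha):
            a1, a2 = alpha
            cols = []
            for (i1, j1) in sb.exponents:
                if i1 < a1 or j1 < a2:
                    cols.append(np.zeros(1))
                    continue
                coef = (
                    math.factorial(i1) // math.factorial(i1 - a1)
                    * math.factorial(j1) // math.factorial(j1 - a2)
                )
                cols.append(coef * X[0] ** (i1 - a1) * X[1] ** (j1 - a2)
                            * np.ones(1))
            return np.concatenate(cols)

        C = basis.coefficients
        g = np.empty((2, 2))
        for d, alpha in enumerate([(1, 0), (0, 1)]):
            dv = dmat(alpha)
            g[0, d] = (C[:, 0, :] @ dv) @ rec.coefficients / eps
            g[1, d] = (C[:, 1, :] @ dv) @ rec.coefficients / eps
        return g

    eta = np.zeros(len(nodes))
    for i in range(len(nodes)):
        nb = nbrs[i]
        order = np.argsort(nb.distances)[:6]
        jump = 0.0
        for k in order:
            j = int(nb.neighbor_indices[k])
            mid = 0.5 * (nodes.positions[i] + nodes.positions[j])
            gi = grad_at(recs[i], mid)
            gj = grad_at(recs[j], mid)
            jump = max(jump, float(np.max(np.abs(gi - gj))))
        eta[i] = nodes.spacing[i] * jump
    return eta


def adaptive_solve(
    domain: FluidDomain,
    bodies: Sequence[RigidBody],
    gmls_config: GMLSConfig | None = None,
    target_estimate: float = 1e-4,
    initial_spacing: float | None = None,
    max_iterations: int = 8,
    theta: float = 0.3,
    drop_velocity: Callable | None = None,
) -> StokesSolution:
    """SOLVE -> ESTIMATE -> MARK -> REFINE loop.

    Doerfler (bulk) marking with fraction ``theta``; marked nodes spawn
    spacing-field patches that halve the local spacing, and the node set is
    regenerated.  Raises :class:`AdaptiveError` carrying the last estimate
    if the budget is exhausted before the global estimator (root sum of
    squared indicators) reaches ``target_estimate``.
    """
    config = gmls_config or GMLSConfig()
    if initial_spacing is None:
        initial_spacing = domain.drop_radius_um / 12
    patches: list = []
    history = []
    solution = None
    for _ in range(max_iterations):
        nodes = discretize(domain, bodies, initial_spacing, config,
                           extra_patches=patches)
        solution = solve_stokes(nodes, domain, bodies, config,
                                drop_velocity=drop_velocity)
        eta = _error_indicators(solution)
        global_eta = float(np.sqrt(np.sum(eta**2)))
        history.append({"estimate": global_eta, "nodes": len(nodes)})
        solution.refinement_history = history
        if global_eta <= target_estimate:
            return solution
        # Doerfler marking
        order = np.argsort(eta)[::-1]
        cum = np.cumsum(eta[order] ** 2)
        n_mark = int(np.searchsorted(cum, theta * cum[-1])) + 1
        for i in order[:n_mark]:
            h = nodes.spacing[i]
            patches.append((nodes.positions[i].copy(), 1.5 * h, h / 2))
    raise AdaptiveError(
        f"adaptive refinement did not reach {target_estimate:g} in "
        f"{max_iterations} iterations (last estimate "
        f"{history[-1]['estimate']:g})",
        last_estimate=history[-1]["estimate"],
    )


# ---------------------------------------------------------------------------
# Benchmarks


def benchmark_wannier(
    r1: float = 0.25,
    r2: float = 0.5,
    gap_fractions: Sequence[float] = (0.5, 0.2, 0.05),
    omega1: float = 1.0,
    spacing: float = 0.015625,
    gmls_config: GMLSConfig | None = None,
    adaptive: bool = False,
    target_estimate: float = 5e-3,
) -> list[dict]:
    """Numeric vs analytic drag for rotating eccentric cylinders.

    The outer cylinder is the drop wall at rest; the inner cylinder is a
    rotating disk body offset so the minimum gap is ``gap_fraction * r1``.
    Returns one record per geometry with the relative force error against
    the independent analytic solution.
    """
    from .wannier import WannierFlow

    config = gmls_config or GMLSConfig()
    out = []
    for frac in gap_fractions:
        gap = frac * r1
        ds = r2 - r1 - gap
        domain = FluidDomain(drop_radius_um=r2, nu_m2_s=1.0, rho_kg_m3=1.0,
                             depth_scale_um=1.0)
        body = RigidBody(
            body_id=0, shape="disk", position=(ds, 0.0), radius_um=r1,
            velocity_um_s=(0.0, 0.0), angular_velocity_rad_s=omega1,
        )
        # resolve the lubrication zone beyond the automatic gap patches
        mid = np.array([ds + r1 + gap / 2, 0.0])
        patch = [(mid, 2.5 * math.sqrt(r1 * gap), gap / 5.0)]
        if adaptive:
            sol = adaptive_solve(domain, [body], config,
                                 target_estimate=target_estimate,
                                 initial_spacing=spacing, max_iterations=6)
        else:
            nodes = discretize(domain, [body], spacing, config,
                               extra_patches=patch)
            sol = solve_stokes(nodes, domain, [body], config)
        bf = traction_force(sol, body)
        # compare in nondimensional per-depth units (mu = 1, lengths as given)
        exact = WannierFlow(r1=r1, r2=r2, ds=ds, omega1=omega1, omega2=0.0,
                            mu=1.0)
        f_exact = exact.inner_force(1024)
        f_num = bf.force_per_depth_N_per_m / (1e-6 * domain.mu_pa_s)
        t_num = bf.torque_per_depth_N / (1e-12 * domain.mu_pa_s)
        err = np.linalg.norm(f_num - f_exact) / max(
            np.linalg.norm(f_exact), abs(exact.inner_torque(1024)) / r1
        )
        t_err = abs(t_num - exact.inner_torque(1024)) / abs(
            exact.inner_torque(1024)
        )
        out.append({
            "gap_fraction": frac,
            "gap": gap,
            "nodes": len(sol.nodes),
            "force_numeric": f_num,
            "force_analytic": f_exact,
            "torque_numeric": t_num,
            "torque_analytic": exact.inner_torque(1024),
            "force_rel_error": float(err),
            "torque_rel_error": float(t_err),
        })
    return out


def convergence_order(
    spacings: Sequence[float],
    gmls_config: GMLSConfig | None = None,
    case: dict | None = None,
) -> dict:
    """Observed convergence order on a manufactured Stokes solution.

    Solves on the unit disk with manufactured forcing and boundary data,
    measures the L2 velocity error at interior nodes for each spacing, and
    returns the least-squares slope of log(error) vs log(spacing).
    """
    if len(spacings) < 3:
        raise ArgumentError("need at least 3 spacings")
    config = gmls_config or GMLSConfig()
    case = case or manufactured_case()
    domain = FluidDomain(drop_radius_um=1.0, nu_m2_s=1.0, rho_kg_m3=1.0)
    errors = []
    ns = []
    for h in spacings:
        nodes = discretize(domain, [], h, config)
        sol = solve_stokes(
            nodes, domain, [], config,
            forcing=case["forcing"], drop_velocity=case["velocity"],
        )
        interior = nodes.subset_indices(FLUID)
        u_ex = case["velocity"](nodes.positions[interior])
        err = np.sqrt(
            np.mean(np.sum((sol.velocity[interior] - u_ex) ** 2, axis=1))
        )
        errors.append(err)
        ns.append(len(nodes))
    errors = np.array(errors)
    warn = bool(np.any(np.diff(errors) > 0))
    slope = float(np.polyfit(np.log(spacings), np.log(errors), 1)[0])
    return {"order": slope, "errors": errors.tolist(),
            "spacings": list(spacings), "nodes": ns,
            "non_monotone_warning": warn}


def manufactured_case() -> dict:
    """Smooth non-polynomial manufactured solution on the unit disk.

    Velocity is the curl of psi = sin(1.3 x) cos(1.1 y) (exactly
    divergence-free); q = sin(x + 2 y); forcing f = grad q - lap u.
    """
    a, b = 1.3, 1.1

    def velocity(pts):
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        return np.column_stack([
            -b * np.sin(a * x) * np.sin(b * y),
            -a * np.cos(a * x) * np.cos(b * y),
        ])

    def q_exact(pts):
        pts = np.atleast_2d(pts)
        return np.sin(pts[:, 0] + 2 * pts[:, 1])

    def forcing(pts):
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        lap_u = (a**2 + b**2) * np.column_stack([
            b * np.sin(a * x) * np.sin(b * y),
            a * np.cos(a * x) * np.cos(b * y),
        ])
        gq = np.column_stack([
            np.cos(x + 2 * y), 2 * np.cos(x + 2 * y)
        ])
        return gq - lap_u

    return {"velocity": velocity, "q": q_exact, "forcing": forcing}


# ---------------------------------------------------------------------------
# Scenes


@dataclass(frozen=True)
class GlidingSceneConfig:
    """Parallel gliding bacteria in a cropped microdrop.

    Eight capsules stacked side by side (the target cell centered), all
    gliding rightward at the literature maximum single-cell speed.
    """

    n_cells: int = 8
    cell_length_um: float = 6.7
    cell_width_um: float = 0.716
    pitch_um: float = 1.5
    drop_radius_um: float = 18.0
    speed_um_s: float = 2.0
    depth_scale_um: float = 1.0


def scene_gliding_bacteria(
    config: GlidingSceneConfig | None = None,
) -> tuple[FluidDomain, list[RigidBody]]:
    """Scene for the single-cell gliding drag computation."""
    cfg = config or GlidingSceneConfig()
    if cfg.n_cells < 1:
        raise ArgumentError("need at least one cell")
    if cfg.pitch_um <= cfg.cell_width_um:
        raise GeometryError(
            f"pitch {cfg.pitch_um} um cannot pack cells of width "
            f"{cfg.cell_width_um} um without overlap"
        )
    domain = FluidDomain(drop_radius_um=cfg.drop_radius_um,
                         depth_scale_um=cfg.depth_scale_um)
    # target cell first, then alternating above/below
    offsets = [0.0]
    k = 1
    while len(offsets) < cfg.n_cells:
        offsets.append(k * cfg.pitch_um)
        if len(offsets) < cfg.n_cells:
            offsets.append(-k * cfg.pitch_um)
        k += 1
    bodies = [
        RigidBody(
            body_id=i, shape="capsule", position=(0.0, dy),
            length_um=cfg.cell_length_um, width_um=cfg.cell_width_um,
            orientation_rad=0.0, velocity_um_s=(cfg.speed_um_s, 0.0),
        )
        for i, dy in enumerate(offsets)
    ]
    _validate_geometry(domain, bodies)
    return domain, bodies


@dataclass(frozen=True)
class ColonySceneConfig:
    """Randomly placed microcolonies moving in random directions."""

    n_colonies: int = 21
    colony_diameter_um: float = 50.0
    drop_diameter_um: float = 2000.0
    speed_um_s: float = 0.031
    seed: int = 0
    margin_um: float = 10.0
    depth_scale_um: float = 1.0
    max_tries: int = 20000


def scene_colonies(
    config: ColonySceneConfig | None = None,
) -> tuple[FluidDomain, list[RigidBody]]:
    """Scene for the microcolony propulsion-drag computation.

    Colony 0 (the measurement target) sits at the drop center; the rest are
    rejection-sampled without overlap.  All colonies move at the measured
    mean speed with random unit directions; reproducible for a fixed seed.
    """
    cfg = config or ColonySceneConfig()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.drop_diameter_um / 2
    r = cfg.colony_diameter_um / 2
    domain = FluidDomain(drop_radius_um=R, depth_scale_um=cfg.depth_scale_um)
    centers = [np.zeros(2)]
    tries = 0
    while len(centers) < cfg.n_colonies:
        tries += 1
        if tries > cfg.max_tries:
            raise GeometryError(
                f"could not place {cfg.n_colonies} colonies of diameter "
                f"{cfg.colony_diameter_um} um in the drop after "
                f"{cfg.max_tries} tries"
            )
        rho = (R - r - cfg.margin_um) * np.sqrt(rng.random())
        phi = 2 * np.pi * rng.random()
        c = rho * np.array([np.cos(phi), np.sin(phi)])
        if all(np.linalg.norm(c - e) > 2 * r + cfg.margin_um for e in centers):
            centers.append(c)
    bodies = []
    for i, c in enumerate(centers):
        phi = 2 * np.pi * rng.random()
        v = cfg.speed_um_s * np.array([np.cos(phi), np.sin(phi)])
        bodies.append(
            RigidBody(body_id=i, shape="disk", position=tuple(c),
                      radius_um=r, velocity_um_s=tuple(v))
        )
    _validate_geometry(domain, bodies)
    return domain, bodies
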