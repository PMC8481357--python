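"""Generalized moving least squares (GMLS) approximation on 2D node clouds.

A field sampled at scattered nodes is approximated near a node ``x_i`` by a
polynomial ``psi_h(x) = P(x)^T c*`` whose coefficients minimise the weighted
residual ``J = sum_j (psi_j - P(x_j)^T c)^2 W_ij`` over the epsilon-neighborhood
of ``x_i``.  The weight is compactly supported, ``W(r) = 1 - (r/eps)^4`` for
``r < eps`` and zero beyond, so every reconstruction is local.  Differential
operators of any order up to the basis order are obtained by differentiating
the basis: ``D^a psi(x_i) ~ (D^a P)(x_i)^T c*``.

Two bases are provided: scalar monomials (for pressure and generic fields) and
a divergence-free vector polynomial basis (for incompressible velocity).  The
divergence-free basis is built as curls of scalar stream monomials, which in
2D spans the full space of divergence-free polynomial fields and is exactly
solenoidal term by term.

Internally every local problem is shifted to the center node and scaled by the
support radius before solving; raw monomials at physical coordinates would be
catastrophically ill-conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.spatial import cKDTree

from .errors import ArgumentError, ConfigurationError, DegenerateGeometryError

__all__ = [
    "GMLSConfig",
    "GMLSNodeSet",
    "Neighborhood",
    "LocalReconstruction",
    "weight",
    "build_neighborhoods",
    "polynomial_basis",
    "gmls_reconstruct",
    "apply_operator",
    "scalar_basis_dimension",
]

FLUID = "fluid"
DROP_BOUNDARY = "drop_boundary"
BODY_BOUNDARY = "body_boundary"

_GRAM_COND_LIMIT = 1e13


def scalar_basis_dimension(order: int) -> int:
    """Number of 2D monomials of total degree <= order."""
    return (order + 1) * (order + 2) // 2


@dataclass(frozen=True)
class GMLSConfig:
    """Polynomial order and neighborhood policy for GMLS reconstructions.

    Parameters
    ----------
    order:
        Total polynomial order ``r`` of the reconstruction (default 4).
    support_factor:
        Dimensionless multiplier converting the local node spacing ``h_i``
        into the compact support radius ``eps_i = support_factor * h_i``.
    weight_exponent:
        Exponent of the compact weight ``1 - (r/eps)^k``.
    min_neighbors:
        Safety floor on neighborhood size; defaults to
        ``ceil(1.5 * scalar basis dimension)`` for least-squares robustness
        on irregular clouds.
    """

    order: int = 4
    support_factor: float = 3.0
    weight_exponent: int = 4
    min_neighbors: int | None = None

    def __post_init__(self):
        if self.order < 1:
            raise ArgumentError(f"order must be >= 1, got {self.order}")
        if self.support_factor <= 1:
            raise ArgumentError(
                f"support_factor must be > 1, got {self.support_factor}"
            )
        if self.weight_exponent < 1:
            raise ArgumentError("weight_exponent must be a positive integer")
        if self.min_neighbors is not None and self.min_neighbors < scalar_basis_dimension(self.order):
            raise ArgumentError(
                "min_neighbors must be at least the dimension of the "
                f"order-{self.order} polynomial basis "
                f"({scalar_basis_dimension(self.order)})"
            )

    @property
    def basis_dimension(self) -> int:
        return scalar_basis_dimension(self.order)

    @property
    def resolved_min_neighbors(self) -> int:
        if self.min_neighbors is not None:
            return self.min_neighbors
        return math.ceil(1.5 * self.basis_dimension)


def weight(r_ij, eps, exponent: int = 4):
    """Compact GMLS weight ``1 - (r/eps)^exponent`` for ``r < eps``, else 0.

    Accepts scalars or arrays.  Raises :class:`ArgumentError` for negative
    distances or a non-positive support radius.
    """
    r = np.asarray(r_ij, dtype=float)
    e = np.asarray(eps, dtype=float)
    if np.any(e <= 0):
        raise ArgumentError("support radius eps must be > 0")
    if np.any(r < 0):
        raise ArgumentError("distance must be >= 0")
    w = np.where(r < e, 1.0 - (r / e) ** exponent, 0.0)
    if np.isscalar(r_ij) and np.isscalar(eps):
        return float(w)
    return w


@dataclass
class GMLSNodeSet:
    """Collocation points with per-node kind, spacing and support radius.

    ``positions`` is an (N, 2) array; ``node_kind`` holds one of
    ``{"fluid", "drop_boundary", "body_boundary"}`` per node with the owning
    body recorded in ``body_id`` (-1 for non-body nodes).
    """

    positions: np.ndarray
    node_kind: np.ndarray
    spacing: np.ndarray
    support: np.ndarray
    body_id: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        self.node_kind = np.asarray(self.node_kind, dtype=object)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        if self.body_id is None:
            self.body_id = np.full(n, -1, dtype=int)
        else:
            self.body_id = np.asarray(self.body_id, dtype=int)
        if not (
            len(self.node_kind) == len(self.spacing) == len(self.support) == len(self.body_id) == n
        ):
            raise ArgumentError("node set field lengths disagree")
        if np.any(self.support <= 0) or np.any(self.spacing <= 0):
            raise ArgumentError("spacing and support must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def is_boundary(self) -> np.ndarray:
        return self.node_kind != FLUID

    def subset_indices(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.node_kind == kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "kind": self.node_kind,
                "body_id": self.body_id,
                "spacing": self.spacing,
                "support": self.support,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GMLSNodeSet":
        df = pd.read_csv(path)
        return cls(
            positions=df[["x", "y"]].to_numpy(),
            node_kind=df["kind"].to_numpy(dtype=object),
            spacing=df["spacing"].to_numpy(),
            support=df["support"].to_numpy(),
            body_id=df["body_id"].to_numpy(dtype=int),
        )


@dataclass
class Neighborhood:
    """Indices, offsets and weights of the epsilon-neighborhood of one node."""

    center_index: int
    center: np.ndarray
    eps: float
    neighbor_indices: np.ndarray
    positions: np.ndarray  # (n, 2) absolute neighbor coordinates
    distances: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.neighbor_indices)


def build_neighborhoods(
    nodes: GMLSNodeSet, config: GMLSConfig, tree: cKDTree | None = None
) -> list[Neighborhood]:
    """Find, for every node, all other nodes strictly inside its support.

    The node itself is excluded; membership uses the strict inequality
    ``r_ij < eps_i`` so a node exactly on the support edge (zero weight) is
    dropped.  A node with fewer than ``config.resolved_min_neighbors``
    neighbors raises :class:`ConfigurationError` naming the node.
    """
    if len(nodes) == 0:
        raise ArgumentError("node set is empty")
    if tree is None:
        tree = cKDTree(nodes.positions)
    min_nbrs = config.resolved_min_neighbors
    out: list[Neighborhood] = []
    for i in range(len(nodes)):
        eps = float(nodes.support[i])
        idx = tree.query_ball_point(nodes.positions[i], eps)
        idx = np.array([j for j in idx if j != i], dtype=int)
        if idx.size:
            d = np.linalg.norm(nodes.positions[idx] - nodes.positions[i], axis=1)
            keep = d < eps  # strict: weight vanishes at r = eps
            idx, d = idx[keep], d[keep]
        else:
            d = np.empty(0)
        if len(idx) < min_nbrs:
            raise ConfigurationError(
                f"node {i} at {tuple(nodes.positions[i])} has only "
                f"{len(idx)} neighbors within eps={eps:g}; "
                f"min_neighbors={min_nbrs}"
            )
        out.append(
            Neighborhood(
                center_index=i,
                center=nodes.positions[i],
                eps=eps,
                neighbor_indices=idx,
                positions=nodes.positions[idx],
                distances=d,
                weights=weight(d, eps, config.weight_exponent),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Polynomial bases


@lru_cache(maxsize=None)
def _monomial_exponents(order: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        (d - j, j) for d in range(order + 1) for j in range(d + 1)
    )


@dataclass(frozen=True)
class ScalarBasis:
    """All 2D monomials x^i y^j with i + j <= order."""

    order: int

    @property
    def exponents(self) -> tuple[tuple[int, int], ...]:
        return _monomial_exponents(self.order)

    @property
    def dimension(self) -> int:
        return scalar_basis_dimension(self.order)

    def design(self, pts: np.ndarray) -> np.ndarray:
        """Vandermonde-type matrix (n_pts, dimension)."""
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        cols = [x**i * y**j for i, j in self.exponents]
        return np.column_stack(cols)

    def derivative_at_origin(self, alpha: tuple[int, int]) -> np.ndarray:
        """(D^alpha P)(0): one-hot vector scaled by alpha!."""
        a1, a2 = alpha
        v = np.zeros(self.dimension)
        for k, (i, j) in enumerate(self.exponents):
            if i == a1 and j == a2:
                v[k] = math.factorial(a1) * math.factorial(a2)
        return v


@lru_cache(maxsize=None)
def _divfree_coefficients(order: int) -> np.ndarray:
    """Coefficients of the divergence-free vector basis over scalar monomials.

    Element k is curl of the k-th stream monomial ``m`` of degree 1..order+1:
    ``Phi_k = (d m / d y, -d m / d x)``, expressed over the order-``order``
    scalar monomial basis.  Returns an array (n_elems, 2, scalar_dim).
    """
    exps = _monomial_exponents(order)
    index = {e: k for k, e in enumerate(exps)}
    elems = []
    for d in range(1, order + 2):
        for j in range(d + 1):
            i = d - j  # stream monomial x^i y^j
            comp = np.zeros((2, len(exps)))
            if j >= 1:  # d/dy -> j * x^i y^(j-1)
                comp[0, index[(i, j - 1)]] = j
            if i >= 1:  # -d/dx -> -i * x^(i-1) y^j
                comp[1, index[(i - 1, j)]] = -i
            elems.append(comp)
    return np.array(elems)


@dataclass(frozen=True)
class DivFreeVectorBasis:
    """Divergence-free 2D vector polynomials spanning all such fields <= order.

    Built as curls of scalar stream monomials of degree 1..order+1, hence each
    element has identically zero divergence and the span is complete
    (dimension ``2*T(order) - T(order-1)`` with ``T`` the scalar dimensions).
    """

    order: int

    @property
    def coefficients(self) -> np.ndarray:
        return _divfree_coefficients(self.order)

    @property
    def dimension(self) -> int:
        return len(self.coefficients)

    @property
    def scalar(self) -> ScalarBasis:
        return ScalarBasis(self.order)

    def design(self, pts: np.ndarray) -> np.ndarray:
        """Stacked design matrix (2 * n_pts, dimension); rows alternate
        (u, v) per point blockwise: first all u rows, then all v rows."""
        P = self.scalar.design(pts)  # (n, m_scalar)
        C = self.coefficients  # (m, 2, m_scalar)
        u_cols = P @ C[:, 0, :].T  # (n, m)
        v_cols = P @ C[:, 1, :].T
        return np.vstack([u_cols, v_cols])

    def derivative_at_origin(self, alpha: tuple[int, int]) -> np.ndarray:
        """(2, dimension): D^alpha of each element's (u, v) at the origin."""
        d = self.scalar.derivative_at_origin(alpha)
        C = self.coefficients
        return np.stack([C[:, 0, :] @ d, C[:, 1, :] @ d], axis=0)


def polynomial_basis(
    order: int, kind: Literal["scalar", "divergence_free_vector"] = "scalar"
):
    """Return the scalar monomial or divergence-free vector basis."""
    if order < 0:
        raise ArgumentError(f"order must be >= 0, got {order}")
    if kind == "scalar":
        return ScalarBasis(order)
    if kind == "divergence_free_vector":
        return DivFreeVectorBasis(order)
    raise ArgumentError(f"unknown basis kind: {kind!r}")


# ---------------------------------------------------------------------------
# Local reconstruction


@dataclass
class LocalReconstruction:
    """A solved local weighted least-squares polynomial fit.

    Coordinates inside the fit are shifted to ``center`` and scaled by
    ``eps``; evaluation and differentiation undo the scaling.
    """

    kind: str
    order: int
    center: np.ndarray
    eps: float
    coefficients: np.ndarray
    gram_condition_number: float

    @property
    def basis_description(self) -> str:
        return f"{self.kind} polynomials of total order <= {self.order}"

    def _basis(self):
        if self.kind == "scalar":
            return ScalarBasis(self.order)
        return DivFreeVectorBasis(self.order)

    def __call__(self, pts: np.ndarray):
        """Evaluate the reconstruction at absolute coordinates."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        X = (pts - self.center) / self.eps
        if self.kind == "scalar":
            return ScalarBasis(self.order).design(X) @ self.coefficients
        D = DivFreeVectorBasis(self.order).design(X) @ self.coefficients
        n = len(pts)
        return np.column_stack([D[:n], D[n:]])

    def derivative(self, alpha: tuple[int, int]):
        """D^alpha of the reconstruction at the center node."""
        a1, a2 = alpha
        if a1 < 0 or a2 < 0:
            raise ArgumentError("multi-index entries must be >= 0")
        if a1 + a2 > self.order:
            raise ArgumentError(
                f"|alpha|={a1 + a2} exceeds polynomial order {self.order}"
            )
        scale = self.eps ** (a1 + a2)
        d = self._basis().derivative_at_origin((a1, a2))
        if self.kind == "scalar":
            return float(d @ self.coefficients) / scale
        return (d @ self.coefficients) / scale

    def divergence_at_center(self) -> float:
        """Divergence of the local field at the center (identically zero for
        the divergence-free basis, up to rounding)."""
        if self.kind == "scalar":
            raise ArgumentError("divergence is defined for vector fits only")
        du = DivFreeVectorBasis(self.order).derivative_at_origin((1, 0))[0]
        dv = DivFreeVectorBasis(self.order).derivative_at_origin((0, 1))[1]
        return float((du + dv) @ self.coefficients) / self.eps


def _gram_solve(M: np.ndarray, rhs: np.ndarray, node_index: int) -> np.ndarray:
    """Cholesky solve of the SPD Gram system; degenerate local geometry
    (rank-deficient M, e.g. collinear neighbors) raises with the condition
    number as a diagnostic."""
    try:
        return sla.cho_solve(sla.cho_factor(M), rhs)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        cond = float(np.linalg.cond(M))
        raise DegenerateGeometryError(
            f"GMLS Gram matrix singular at node {node_index} "
            f"(cond={cond:.3g})",
            condition_number=cond,
        ) from None


def _solve_weighted_ls(design: np.ndarray, w: np.ndarray, rhs: np.ndarray):
    """Solve min || sqrt(W) (design c - rhs) ||; returns (c, cond(Gram))."""
    Wd = design * w[:, None]
    M = design.T @ Wd
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > _GRAM_COND_LIMIT:
        raise DegenerateGeometryError(
            f"GMLS Gram matrix is numerically singular (cond={cond:.3g}); "
            "node geometry is degenerate (e.g. collinear neighbors)",
            condition_number=cond,
        )
    c = np.linalg.solve(M, Wd.T @ rhs)
    return c, cond


def gmls_reconstruct(
    center: Sequence[float],
    neighborhood: Neighborhood,
    samples: np.ndarray,
    config: GMLSConfig,
    kind: Literal["scalar", "divergence_free_vector"] = "scalar",
) -> LocalReconstruction:
    """Fit the local polynomial minimising the weighted residual functional.

    ``samples`` holds the field values at ``neighborhood.positions``: shape
    (n,) for a scalar field or (n, 2) for a vector field fitted with the
    divergence-free basis.
    """
    center = np.asarray(center, dtype=float)
    eps = neighborhood.eps
    basis = polynomial_basis(config.order, kind)
    samples = np.asarray(samples, dtype=float)
    n = len(neighborhood)
    n_data = n if kind == "scalar" else 2 * n
    if n_data < basis.dimension:
        raise ArgumentError(
            f"{n} neighbors provide {n_data} equations < basis dimension "
            f"{basis.dimension}"
        )
    X = (neighborhood.positions - center) / eps
    if kind == "scalar":
        design = basis.design(X)
        w = neighborhood.weights
        rhs = samples
    else:
        design = basis.design(X)
        w = np.concatenate([neighborhood.weights, neighborhood.weights])
        rhs = np.concatenate([samples[:, 0], samples[:, 1]])
    c, cond = _solve_weighted_ls(design, w, rhs)
    return LocalReconstruction(
        kind=kind,
        order=config.order,
        center=center,
        eps=eps,
        coefficients=c,
        gram_condition_number=cond,
    )


def apply_operator(reconstruction: LocalReconstruction, alpha: tuple[int, int]):
    """Evaluate ``(D^alpha P)(center)^T c*`` — the GMLS derivative estimate."""
    return reconstruction.derivative(alpha)


# ---------------------------------------------------------------------------
# Stencils (linear maps from neighbor samples to derivatives at the center)


def scalar_stencils(
    neighborhood: Neighborhood,
    config: GMLSConfig,
    operators: Iterable[tuple[int, int] | str],
) -> np.ndarray:
    """Rows mapping neighbor scalar samples to operator values at the center.

    ``operators`` entries are multi-indices or the string ``"lap"`` for the
    Laplacian.  Returns (n_ops, n_neighbors).
    """
    basis = ScalarBasis(config.order)
    eps = neighborhood.eps
    X = (neighborhood.positions - neighborhood.center) / eps
    P = basis.design(X)
    w = neighborhood.weights
    Wd = P * w[:, None]
    M = P.T @ Wd
    B = _gram_solve(M, Wd.T, neighborhood.center_index)  # (m, n)
    rows = []
    for op in operators:
        if op == "lap":
            d = basis.derivative_at_origin((2, 0)) + basis.derivative_at_origin((0, 2))
            scale = eps**2
        else:
            a1, a2 = op  # type: ignore[misc]
            d = basis.derivative_at_origin((a1, a2))
            scale = eps ** (a1 + a2)
        rows.append((d @ B) / scale)
    return np.array(rows)


def vector_laplacian_stencil(
    neighborhood: Neighborhood, config: GMLSConfig
) -> np.ndarray:
    """Map neighbor (u, v) samples to the vector Laplacian at the center.

    Uses the divergence-free basis, so the implied local velocity field is
    exactly solenoidal.  Returns (2, 2, n): ``out[c, comp, j]`` is the weight
    of neighbor j's ``comp`` velocity component in ``(lap u)_c``.
    """
    basis = DivFreeVectorBasis(config.order)
    eps = neighborhood.eps
    X = (neighborhood.positions - neighborhood.center) / eps
    design = basis.design(X)  # (2n, m)
    n = len(neighborhood)
    w = np.concatenate([neighborhood.weights, neighborhood.weights])
    Wd = design * w[:, None]
    M = design.T @ Wd
    B = _gram_solve(M, Wd.T, neighborhood.center_index)  # (m, 2n)
    lap = (
        basis.derivative_at_origin((2, 0)) + basis.derivative_at_origin((0, 2))
    )  # (2, m)
    S = (lap @ B) / eps**2  # (2, 2n)
    return np.stack([S[:, :n], S[:, n:]], axis=1)
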