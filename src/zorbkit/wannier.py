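"""Exact Stokes flow between two rotating eccentric cylinders (Wannier flow).

The classical configuration: an inner cylinder of radius ``r1`` whose center
is offset by ``ds`` from the center of an outer cylinder of radius ``r2``;
both rotate about their own axes at constant rates, and the creeping flow in
the eccentric annulus admits an exact solution.  This module evaluates that
solution to machine ("analytic") precision without any volumetric
discretization, so it can serve as an independent oracle for the meshfree
solver.

Construction.  Every planar Stokes stream function is biharmonic and can be
written in Goursat form ``psi = Re(conj(z) * phi(z) + chi(z))`` with ``phi``,
``chi`` analytic in the fluid domain.  In the eccentric annulus both
potentials are Laurent series about the inner center plus the rotlet/Stokeslet
logarithm (the log in ``phi`` must be paired with ``(z - z_in) log(z - z_in)``
in ``chi`` to keep the velocity single valued).  The boundary conditions —
rigid rotation of each cylinder about its own center — determine the
coefficients; they are found here by least-squares collocation on the two
circles, with the mode count increased until the boundary residual reaches
machine precision.  Because the true solution lies in the span of the basis,
the result is the exact solution evaluated through a convergent series, not a
numerical PDE solve.

Closed-form fields derived from the Goursat potentials:

* velocity        ``u + i v = -i (phi + z conj(phi') + conj(chi'))``
* vorticity source ``lap psi = 4 Re phi'``
* pressure        ``p = -4 mu Im phi'``
* velocity gradient from the second Wirtinger derivative
  ``S2 = (conj(z) phi'' + chi'') / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, GeometryError

__all__ = ["WannierFlow", "wannier_analytic", "taylor_couette_velocity",
           "taylor_couette_inner_torque"]


def taylor_couette_velocity(r, a, b, omega_inner, omega_outer=0.0):
    """Azimuthal velocity of concentric-cylinder (Taylor-Couette) Stokes flow.

    ``u_theta(r) = A r + B / r`` with no-slip at ``r=a`` (rate
    ``omega_inner``) and ``r=b`` (rate ``omega_outer``).
    """
    r = np.asarray(r, dtype=float)
    A = (omega_outer * b**2 - omega_inner * a**2) / (b**2 - a**2)
    B = (omega_inner - omega_outer) * a**2 * b**2 / (b**2 - a**2)
    return A * r + B / r


def taylor_couette_inner_torque(a, b, omega_inner, omega_outer, mu):
    """Torque per unit depth on the inner cylinder, concentric case:
    ``4 pi mu (omega_outer - omega_inner) a^2 b^2 / (b^2 - a^2)``."""
    return 4.0 * np.pi * mu * (omega_outer - omega_inner) * a**2 * b**2 / (
        b**2 - a**2
    )


@dataclass
class _Potentials:
    """Goursat potential values (phi, phi', phi'', chi', chi'') at points z."""

    phi: np.ndarray
    dphi: np.ndarray
    d2phi: np.ndarray
    dchi: np.ndarray
    d2chi: np.ndarray


@dataclass
class WannierFlow:
    """Exact rotating eccentric-cylinder Stokes flow.

    Outer cylinder: radius ``r2``, centered at the origin, rotation rate
    ``omega2`` (rad/time, counter-clockwise positive).  Inner cylinder:
    radius ``r1``, centered at ``(ds, 0)``, rotation rate ``omega1``.
    ``mu`` is the dynamic viscosity.  Lengths, times and viscosity are taken
    in any consistent unit system; forces come out per unit depth.
    """

    r1: float
    r2: float
    ds: float
    omega1: float
    omega2: float
    mu: float = 1.0
    u1: complex = 0.0 + 0.0j  # inner-cylinder translation velocity (ux + i uy)
    u2: complex = 0.0 + 0.0j  # outer-cylinder translation velocity
    target_residual: float = 1e-12
    max_modes: int = 220

    _coeffs: np.ndarray = field(init=False, repr=False, default=None)
    _elements: list = field(init=False, repr=False, default=None)
    _residual: float = field(init=False, default=np.nan)
    _modes: int = field(init=False, default=0)

    def __post_init__(self):
        if self.r1 <= 0 or self.r2 <= 0:
            raise ArgumentError("cylinder radii must be positive")
        if not (np.isfinite(self.omega1) and np.isfinite(self.omega2)):
            raise ArgumentError("rotation rates must be finite")
        if self.ds < 0:
            raise ArgumentError("center offset ds must be >= 0")
        if self.r1 + self.ds >= self.r2:
            raise GeometryError(
                f"gap width r2 - r1 - ds = {self.r2 - self.r1 - self.ds:g} "
                "must be positive"
            )
        self._zin = complex(self.ds, 0.0)
        self._set_coaxal_frame()
        self._fit()

    def _set_coaxal_frame(self) -> None:
        """Limit points (a, b) of the coaxal pencil through the two circles.

        The Moebius variable ``t = (z - a)/(z - b)`` maps the eccentric
        annulus onto a concentric one, so Laurent series in ``t`` are the
        geometry-adapted basis; ``a`` lies inside the inner cylinder and
        ``b`` outside the outer one.  For the concentric case the limit
        points degenerate to (center, infinity) and ``t`` reduces to ``z``.
        """
        if self.ds < 1e-12 * self.r2:
            self._limit_a = self._zin
            self._limit_b = None  # t = z - a
            return
        beta = self.r2**2 + self.ds**2 - self.r1**2
        disc = beta**2 - 4 * self.ds**2 * self.r2**2
        root = np.sqrt(max(disc, 0.0))
        a = (beta - root) / (2 * self.ds)
        self._limit_a = complex(a, 0.0)
        self._limit_b = complex(self.r2**2 / a, 0.0)

    def _tvar(self, z: np.ndarray):
        """(t, t', t'') of the coaxal Moebius variable at points z."""
        a, b = self._limit_a, self._limit_b
        if b is None:
            one = np.ones_like(z)
            return z - a, one, np.zeros_like(z)
        t = (z - a) / (z - b)
        dt = (a - b) / (z - b) ** 2
        d2t = -2 * (a - b) / (z - b) ** 3
        return t, dt, d2t

    # -- fitting -----------------------------------------------------------

    def _element_list(self, n_modes: int) -> list:
        """Basis elements as (family, power, scale) descriptors.

        family: 'phi' or 'chi' Laurent powers with real (scale=1) and
        imaginary (scale=1j) coefficients, plus the single real
        Stokeslet-log pair.  The n = -1 imaginary chi' element is omitted:
        it would make the stream function multivalued (net flux through the
        annulus), which rigid rotations cannot drive.
        """
        elems: list = [("logpair", 0, 1.0), ("logpair", 0, 1j)]
        for n in range(-n_modes, n_modes + 1):
            for scale in (1.0, 1j):
                elems.append(("phi", n, scale))
                elems.append(("chi", n, scale))
        return elems

    def _eval_element(self, elem, z: np.ndarray) -> _Potentials:
        family, n, s = elem
        zero = np.zeros_like(z)
        if family == "logpair":
            # Stokeslet: phi = s log(w) must pair with chi = conj(s) w log(w)
            # to keep the velocity single valued around the inner cylinder
            w = z - self._limit_a
            logw = np.log(w)
            sc = np.conj(s)
            return _Potentials(
                phi=s * logw, dphi=s / w, d2phi=-s / w**2,
                dchi=sc * (logw + 1.0), d2chi=sc / w,
            )
        t, dt, d2t = self._tvar(z)
        pw = t**n
        if n != 0:
            dpw = n * t ** (n - 1) * dt
            d2pw = n * (n - 1) * t ** (n - 2) * dt**2 + n * t ** (n - 1) * d2t
        else:
            dpw = zero
            d2pw = zero
        if family == "phi":
            return _Potentials(phi=s * pw, dphi=s * dpw, d2phi=s * d2pw,
                               dchi=zero, d2chi=zero)
        return _Potentials(phi=zero, dphi=zero, d2phi=zero,
                           dchi=s * pw, d2chi=s * dpw)

    def _velocity_of(self, pot: _Potentials, z: np.ndarray) -> np.ndarray:
        G = pot.phi + z * np.conj(pot.dphi) + np.conj(pot.dchi)
        return -1j * G

    def _boundary_points(self, m: int):
        th = 2 * np.pi * (np.arange(m) + 0.5) / m
        if self._limit_b is None:
            z_out = self.r2 * np.exp(1j * th)
            z_in = self._zin + self.r1 * np.exp(1j * th)
            return np.concatenate([z_out, z_in])
        # collocate uniformly in the concentric t-plane image: the basis is a
        # Fourier series there, so this clusters points near the gap exactly
        # where the solution varies fastest and keeps the fit well posed
        a, b = self._limit_a, self._limit_b
        rho_out = abs(self._tvar(np.array([self.r2 + 0j]))[0][0])
        rho_in = abs(self._tvar(np.array([self._zin + self.r1]))[0][0])

        def circle(rho):
            t = rho * np.exp(1j * th)
            return (t * b - a) / (t - 1)

        z_out = circle(rho_out)
        z_in = circle(rho_in)
        # snap tiny Moebius rounding back onto the exact circles
        z_out = self.r2 * z_out / np.abs(z_out)
        z_in = self._zin + self.r1 * (z_in - self._zin) / np.abs(
            z_in - self._zin
        )
        return np.concatenate([z_out, z_in])

    def _boundary_velocity(self, z: np.ndarray, m: int) -> np.ndarray:
        u_out = self.u2 + 1j * self.omega2 * z[:m]
        u_in = self.u1 + 1j * self.omega1 * (z[m:] - self._zin)
        return np.concatenate([u_out, u_in])

    def _fit(self) -> None:
        speed = max(abs(self.omega1) * self.r1, abs(self.omega2) * self.r2,
                    abs(self.u1), abs(self.u2), 1.0)
        # Laurent coefficients in t decay like the concentric-image annulus
        # modulus, so size the first attempt from the gap geometry.
        n_modes = 16
        if self._limit_b is not None:
            rho_out = abs(self._tvar(np.array([self.r2 + 0j]))[0][0])
            rho_in = abs(
                self._tvar(np.array([self._zin + self.r1]))[0][0]
            )
            decay = abs(np.log(rho_in / rho_out))
            if decay > 0:
                n_modes = int(np.clip(30.0 / decay, 16, self.max_modes))
        best = None
        while True:
            elems = self._element_list(n_modes)
            m = max(6 * n_modes, 128)
            z = self._boundary_points(m)
            target = self._boundary_velocity(z, m)
            cols = []
            scales = []
            for e in elems:
                ue = self._velocity_of(self._eval_element(e, z), z)
                s = np.max(np.abs(ue))
                s = s if s > 0 else 1.0
                cols.append(ue / s)
                scales.append(s)
            A = np.column_stack(cols)
            Ar = np.vstack([A.real, A.imag])
            br = np.concatenate([target.real, target.imag])
            sol, *_ = np.linalg.lstsq(Ar, br, rcond=None)
            resid = np.max(np.abs(A @ sol - target)) / speed
            best = (elems, sol / np.asarray(scales), resid, n_modes)
            if resid <= self.target_residual or n_modes >= self.max_modes:
                break
            n_modes = min(int(n_modes * 1.8) + 4, self.max_modes)
        self._elements, self._coeffs, self._residual, self._modes = best

    # -- field evaluation --------------------------------------------------

    def _potentials(self, z: np.ndarray) -> _Potentials:
        z = np.asarray(z, dtype=complex)
        acc = [np.zeros_like(z) for _ in range(5)]
        for e, c in zip(self._elements, self._coeffs):
            pot = self._eval_element(e, z)
            for a, v in zip(acc, (pot.phi, pot.dphi, pot.d2phi,
                                  pot.dchi, pot.d2chi)):
                a += c * v
        return _Potentials(*acc)

    @property
    def boundary_residual(self) -> float:
        """Max no-slip violation on the two cylinders, relative to the
        largest surface speed."""
        return self._residual

    def velocity(self, points) -> np.ndarray:
        """Velocity (n, 2) at Cartesian points (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 0] + 1j * pts[:, 1]
        U = self._velocity_of(self._potentials(z), z)
        return np.column_stack([U.real, U.imag])

    def pressure(self, points) -> np.ndarray:
        """Pressure (defined up to a constant) at Cartesian points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 0] + 1j * pts[:, 1]
        return -4.0 * self.mu * self._potentials(z).dphi.imag

    def velocity_gradient(self, points) -> np.ndarray:
        """(n, 2, 2) array of d u_i / d x_j."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 0] + 1j * pts[:, 1]
        pot = self._potentials(z)
        S2 = 0.5 * (np.conj(z) * pot.d2phi + pot.d2chi)
        rephi = pot.dphi.real
        psi_xx = 2 * S2.real + 2 * rephi
        psi_yy = -2 * S2.real + 2 * rephi
        psi_xy = -2 * S2.imag
        out = np.empty((len(z), 2, 2))
        out[:, 0, 0] = psi_xy          # u_x = psi_yx
        out[:, 0, 1] = psi_yy          # u_y
        out[:, 1, 0] = -psi_xx         # v_x
        out[:, 1, 1] = -psi_xy         # v_y
        return out

    def stress(self, points) -> np.ndarray:
        """Total stress sigma = -p I + mu (grad u + grad u^T), (n, 2, 2)."""
        p = self.pressure(points)
        g = self.velocity_gradient(points)
        sig = self.mu * (g + np.transpose(g, (0, 2, 1)))
        sig[:, 0, 0] -= p
        sig[:, 1, 1] -= p
        return sig

    def inner_traction(self, n_quad: int = 720):
        """Traction vectors and quadrature nodes on the inner cylinder."""
        th = 2 * np.pi * (np.arange(n_quad) + 0.5) / n_quad
        normals = np.column_stack([np.cos(th), np.sin(th)])
        pts = np.column_stack(
            [self.ds + self.r1 * np.cos(th), self.r1 * np.sin(th)]
        )
        sig = self.stress(pts)
        trac = np.einsum("nij,nj->ni", sig, normals)
        return pts, normals, trac

    def inner_force(self, n_quad: int = 720) -> np.ndarray:
        """Net hydrodynamic force per unit depth on the inner cylinder."""
        _, _, trac = self.inner_traction(n_quad)
        dl = 2 * np.pi * self.r1 / n_quad
        return trac.sum(axis=0) * dl

    def inner_torque(self, n_quad: int = 720) -> float:
        """Torque per unit depth about the inner-cylinder center."""
        pts, _, trac = self.inner_traction(n_quad)
        arm = pts - np.array([self.ds, 0.0])
        dl = 2 * np.pi * self.r1 / n_quad
        return float(
            (arm[:, 0] * trac[:, 1] - arm[:, 1] * trac[:, 0]).sum() * dl
        )


def wannier_analytic(
    r1: float,
    r2: float,
    ds: float,
    omega1: float,
    omega2: float,
    mu: float = 1.0,
) -> WannierFlow:
    """Build the exact eccentric rotating-cylinder flow (see
    :class:`WannierFlow`).  Raises :class:`GeometryError` for a non-positive
    gap."""
    return WannierFlow(r1=r1, r2=r2, ds=ds, omega1=omega1, omega2=omega2,
                       mu=mu)
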