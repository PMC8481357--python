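"""Net-force-percentage (NFP) force balance for microcolony propulsion.

At the micrometer scale inertia is negligible (Re ~ 1e-6), so the propulsion
force of a gliding cell or a moving microcolony is always balanced by the
hydrodynamic drag.  The chain implemented here runs:

1. ``F_gliding`` — drag on a single gliding cell at its maximum speed
   (2 um/s), from simulation or from a measured/published value.
2. ``F_stroking = F_gliding * S_W / S_L`` — the per-base-cell force, scaling
   the gliding force by the ratio of substrate contact areas between a cell
   standing on its pole (``S_W = pi (W/2)^2``) and lying flat
   (``S_L = L * W``).
3. ``N(D)`` — the number of base cells under a microcolony of diameter D,
   from one of three scaling models (measured power law ``N = a D^b``, or
   the constant-areal-density and constant-linear-density hypotheses).
4. ``F_max = F_stroking * N`` — all base cells pushing one way.
5. ``NFP = F_prop / F_max * 100`` — the equivalent fraction of base cells
   needed to explain the measured colony drag ``F_prop``.

Uncertainty follows the colony-speed standard deviation only: ``F_max`` and
``F_stroking`` are treated as exact, so ``sd(NFP) = sd(F_prop)/F_max * 100``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ArgumentError, ConsistencyError

__all__ = [
    "CellGeometry",
    "ScalingModel",
    "ForceChain",
    "stroking_force",
    "base_cell_count",
    "hypothesisA_coefficient",
    "base_cell_density",
    "max_prop_force",
    "nfp",
    "chain_from_scene",
    "round_half_up",
    "POWER_LAW_A",
    "POWER_LAW_B",
    "BASE_DENSITY_N",
    "BASE_TO_DIAMETER_RATIO",
    "CANONICAL_CELL",
]

# Measured scaling constants (hyper-motile strain, 12 h cultures)
POWER_LAW_A = 0.2
POWER_LAW_B = 1.36
BASE_DENSITY_N = 0.25          # cells per um^2 of base contact area
BASE_TO_DIAMETER_RATIO = 0.48  # mean base diameter d over colony diameter D


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the spreadsheet convention used for
    the printed derived values, as opposed to banker's rounding)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CellGeometry:
    """Rod-cell dimensions in micrometers (length >= width)."""

    length_um: float
    width_um: float

    def __post_init__(self):
        if not (self.length_um >= self.width_um > 0):
            raise ArgumentError(
                f"need L >= W > 0, got L={self.length_um}, W={self.width_um}"
            )

    @property
    def contact_area_flat_um2(self) -> float:
        """S_L = L * W: substrate contact of a cell lying flat."""
        return self.length_um * self.width_um

    @property
    def contact_area_pole_um2(self) -> float:
        """S_W = pi (W/2)^2: substrate contact of a semi-vertical cell."""
        return math.pi * (self.width_um / 2.0) ** 2

    @property
    def contact_ratio(self) -> float:
        """S_W / S_L = pi W / (4 L) <= pi/4."""
        return self.contact_area_pole_um2 / self.contact_area_flat_um2


# Mean cell length 6.7 um; width back-solved so the contact-area ratio
# reproduces the published stroking/gliding force ratio (0.46/5.48).
CANONICAL_CELL = CellGeometry(length_um=6.7, width_um=0.716)


@dataclass(frozen=True)
class ScalingModel:
    """Base-cell count versus colony diameter, N(D).

    kinds:
      * ``power_fit``    — N = a D^b (measured; a=0.2, b=1.36)
      * ``hypothesis_A`` — constant areal density on the base disk:
        N = n pi (d_over_D * D / 2)^2
      * ``hypothesis_B`` — constant linear density: N = n D
    """

    kind: Literal["power_fit", "hypothesis_A", "hypothesis_B"] = "power_fit"
    a: float = POWER_LAW_A
    b: float = POWER_LAW_B
    n: float = BASE_DENSITY_N
    d_over_D: float = BASE_TO_DIAMETER_RATIO

    def __post_init__(self):
        if self.kind not in ("power_fit", "hypothesis_A", "hypothesis_B"):
            raise ArgumentError(f"unknown scaling model kind {self.kind!r}")
        if not 0 < self.d_over_D <= 1:
            raise ArgumentError("d_over_D must be in (0, 1]")
        if self.n < 0 or self.a < 0:
            raise ArgumentError("coefficients must be non-negative")

    def expected_count(self, D_um: float) -> float:
        if D_um <= 0:
            raise ArgumentError(f"diameter must be positive, got {D_um}")
        if self.kind == "power_fit":
            return self.a * D_um**self.b
        if self.kind == "hypothesis_A":
            return self.n * math.pi * (self.d_over_D * D_um / 2.0) ** 2
        return self.n * D_um

    def quadratic_coefficient(self) -> float:
        """c in N = c D^2 for hypothesis A."""
        return hypothesisA_coefficient(self.n, self.d_over_D)


def base_cell_count(D_um: float, model: ScalingModel) -> tuple[float, int]:
    """Expected (real-valued) and half-up-rounded base-cell count at D."""
    expected = model.expected_count(D_um)
    return expected, int(round_half_up(expected))


def hypothesisA_coefficient(n: float, d_over_D: float) -> float:
    """Quadratic coefficient ``n pi (d_over_D / 2)^2`` of hypothesis A."""
    if n < 0:
        raise ArgumentError("density n must be >= 0")
    if not 0 < d_over_D <= 1:
        raise ArgumentError("d_over_D must be in (0, 1]")
    return n * math.pi * (d_over_D / 2.0) ** 2


def base_cell_density(N: float, D_um: float, d_over_D: float) -> float:
    """Areal density n = N / (pi (d_over_D * D / 2)^2) in cells/um^2."""
    if D_um <= 0:
        raise ArgumentError("diameter must be positive")
    area = math.pi * (d_over_D * D_um / 2.0) ** 2
    if area <= 0:
        raise ArgumentError("base contact area is zero")
    return N / area


def stroking_force(F_gliding_N: float, geom: CellGeometry) -> float:
    """Per-base-cell stroking force: F_gliding scaled by the contact-area
    ratio S_W / S_L (force generation assumed proportional to the
    motor-carrying contact area)."""
    if F_gliding_N < 0:
        raise ArgumentError("gliding force must be >= 0")
    return F_gliding_N * geom.contact_ratio


def max_prop_force(F_stroking_N: float, N_base: int) -> float:
    """Theoretical maximum colony propulsion: every base cell pushes in the
    direction of motion."""
    if N_base < 0:
        raise ArgumentError("base-cell count must be >= 0")
    return F_stroking_N * N_base


def nfp(F_prop_N: float, F_max_N: float,
        F_prop_sd_N: float = 0.0) -> tuple[float, float]:
    """Net force percentage (mean, sd): F_prop / F_max * 100.

    ``F_max`` is treated as exact; the sd propagates linearly from the
    propulsion-force sd.
    """
    if F_max_N <= 0:
        raise ArgumentError("F_max must be positive")
    if F_prop_N < 0 or F_prop_sd_N < 0:
        raise ArgumentError("forces must be >= 0")
    return (F_prop_N / F_max_N * 100.0, F_prop_sd_N / F_max_N * 100.0)


@dataclass
class ForceChain:
    """Fully assembled force-balance chain with provenance of normalization.

    All forces are in newtons.  ``depth_scale_um`` records the slab depth
    used to convert 2D force-per-depth into newtons; chains mixing forces
    computed under different depth scales are refused.
    """

    F_gliding_N: float
    F_stroking_N: float
    N_base: int
    F_max_N: float
    F_prop_N: float
    nfp_percent: float
    F_gliding_sd_N: float = 0.0
    F_prop_sd_N: float = 0.0
    nfp_sd_percent: float = 0.0
    v_glide_um_s: float = float("nan")
    v_colony_um_s: float = float("nan")
    v_colony_sd_um_s: float = float("nan")
    colony_diameter_um: float = float("nan")
    geometry: CellGeometry = CANONICAL_CELL
    model: ScalingModel = field(default_factory=ScalingModel)
    depth_scale_um: float = float("nan")

    def __post_init__(self):
        for name in ("F_gliding_N", "F_stroking_N", "F_max_N", "F_prop_N"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")

    def as_dict(self) -> dict:
        return {
            "F_gliding_N": self.F_gliding_N,
            "F_gliding_sd_N": self.F_gliding_sd_N,
            "F_stroking_N": self.F_stroking_N,
            "N_base": self.N_base,
            "F_max_N": self.F_max_N,
            "F_prop_N": self.F_prop_N,
            "F_prop_sd_N": self.F_prop_sd_N,
            "nfp_percent": self.nfp_percent,
            "nfp_sd_percent": self.nfp_sd_percent,
            "v_glide_um_s": self.v_glide_um_s,
            "v_colony_um_s": self.v_colony_um_s,
            "v_colony_sd_um_s": self.v_colony_sd_um_s,
            "colony_diameter_um": self.colony_diameter_um,
            "cell_length_um": self.geometry.length_um,
            "cell_width_um": self.geometry.width_um,
            "scaling_model": self.model.kind,
            "depth_scale_um": self.depth_scale_um,
        }


def chain_from_scene(
    gliding_drag_N: float,
    colony_drag_N: float,
    colony_diameter_um: float = 50.0,
    geometry: CellGeometry = CANONICAL_CELL,
    model: ScalingModel | None = None,
    v_glide_um_s: float = 2.0,
    v_colony_um_s: float = 0.031,
    v_colony_sd_um_s: float = 0.021,
    gliding_depth_scale_um: float | None = None,
    colony_depth_scale_um: float | None = None,
) -> ForceChain:
    """Assemble the full force chain from two drag computations.

    ``gliding_drag_N`` is the drag magnitude on the target cell in the
    gliding scene (giving ``F_gliding`` by force balance);
    ``colony_drag_N`` the drag on the target microcolony (giving
    ``F_prop``).  The colony-force sd scales linearly with the velocity sd
    (Stokes linearity).  Forces computed under different depth
    normalizations cannot be compared and raise :class:`ConsistencyError`.
    """
    model = model or ScalingModel()
    if gliding_depth_scale_um is not None and colony_depth_scale_um is not None:
        if not math.isclose(gliding_depth_scale_um, colony_depth_scale_um,
                            rel_tol=1e-12):
            raise ConsistencyError(
                "gliding and colony forces were computed under different "
                f"depth scales ({gliding_depth_scale_um} vs "
                f"{colony_depth_scale_um} um); refusing to form their ratio"
            )
    if v_colony_um_s <= 0:
        raise ArgumentError("colony velocity must be positive")
    F_strk = stroking_force(gliding_drag_N, geometry)
    _, N_base = base_cell_count(colony_diameter_um, model)
    F_max = max_prop_force(F_strk, N_base)
    F_prop_sd = colony_drag_N * (v_colony_sd_um_s / v_colony_um_s)
    mean, sd = nfp(colony_drag_N, F_max, F_prop_sd)
    return ForceChain(
        F_gliding_N=gliding_drag_N,
        F_stroking_N=F_strk,
        N_base=N_base,
        F_max_N=F_max,
        F_prop_N=colony_drag_N,
        F_prop_sd_N=F_prop_sd,
        nfp_percent=mean,
        nfp_sd_percent=sd,
        v_glide_um_s=v_glide_um_s,
        v_colony_um_s=v_colony_um_s,
        v_colony_sd_um_s=v_colony_sd_um_s,
        colony_diameter_um=colony_diameter_um,
        geometry=geometry,
        model=model,
        depth_scale_um=(gliding_depth_scale_um
                        if gliding_depth_scale_um is not None
                        else float("nan")),
    )
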