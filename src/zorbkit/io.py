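"""File formats and result serialization.

TIFF image stacks in, CSV/JSON tables and results out, YAML for scene and
run configuration.  Physical metadata (pixel size, frame interval) is never
guessed from image files: it must come from configuration, and its absence
is an explicit error.  Every result file records the tool version, a hash
of the configuration that produced it, and the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, FormatError
from .stokes import BodyForce, FluidDomain, RigidBody

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_results",
    "read_scene_yaml",
    "write_scene_yaml",
    "stokes_result_dict",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_image_stack(path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as (frames, H, W).

    RGB/multichannel input raises :class:`FormatError`; physical metadata is
    deliberately not read from the file (supply it via configuration).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(
            f"expected 2D frames, got array of shape {arr.shape}"
        )
    # a trailing small axis means per-pixel channels (RGB/RGBA)
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise FormatError(
            "RGB/multichannel TIFF is not supported; convert to grayscale"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(
            f"expected 8- or 16-bit grayscale, got dtype {arr.dtype}"
        )
    return arr


def write_image_stack(path, stack: np.ndarray) -> None:
    # explicit photometric tag: 3- or 4-frame grayscale stacks must not be
    # guessed to be RGB planes
    tifffile.imwrite(Path(path), np.asarray(stack),
                     photometric="minisblack")


def _provenance(config: dict | None, seed) -> dict:
    from . import __version__

    cfg = dict(config or {})
    return {
        "tool": "zorbkit",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
    }


def write_results(
    out_dir,
    tracks_df: pd.DataFrame | None = None,
    events_df: pd.DataFrame | None = None,
    chain: dict | None = None,
    config: dict | None = None,
    seed=None,
) -> dict[str, Path]:
    """Write tracking tables and/or a force-chain JSON under ``out_dir``.

    Empty tables produce header-only CSVs.  The JSON result carries the
    provenance block (tool version, config hash, seed).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FormatError(f"cannot create output directory: {exc}") from exc
    written: dict[str, Path] = {}
    if tracks_df is not None:
        p = out_dir / "tracks.csv"
        tracks_df.to_csv(p, index=False)
        written["tracks"] = p
    if events_df is not None:
        p = out_dir / "events.csv"
        events_df.to_csv(p, index=False)
        written["events"] = p
    if chain is not None:
        p = out_dir / "chain.json"
        payload = {"provenance": _provenance(config, seed), "chain": chain}
        p.write_text(json.dumps(payload, indent=2, default=float))
        written["chain"] = p
    return written


# ---------------------------------------------------------------------------
# Scene files


def write_scene_yaml(path, domain: FluidDomain, bodies, seed=None) -> None:
    doc = {
        "drop_radius_um": float(domain.drop_radius_um),
        "nu_m2_s": float(domain.nu_m2_s),
        "rho_kg_m3": float(domain.rho_kg_m3),
        "depth_scale_um": float(domain.depth_scale_um),
        "seed": seed,
        "bodies": [],
    }
    for b in bodies:
        entry = {
            "body_id": int(b.body_id),
            "shape": b.shape,
            "x_um": float(b.position[0]),
            "y_um": float(b.position[1]),
        }
        if b.shape == "disk":
            entry["dims_um"] = [float(b.radius_um)]
        else:
            entry["dims_um"] = [float(b.length_um), float(b.width_um)]
            entry["orientation_rad"] = float(b.orientation_rad)
        if b.velocity_um_s is None:
            entry["vx_um_s"] = entry["vy_um_s"] = "free"
        else:
            entry["vx_um_s"] = float(b.velocity_um_s[0])
            entry["vy_um_s"] = float(b.velocity_um_s[1])
        if b.angular_velocity_rad_s:
            entry["omega_rad_s"] = float(b.angular_velocity_rad_s)
        doc["bodies"].append(entry)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_scene_yaml(path) -> tuple[FluidDomain, list[RigidBody], dict]:
    """Load a simulation scene; returns (domain, bodies, raw document)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"scene file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "drop_radius_um" not in doc:
        raise FormatError("scene file must define drop_radius_um")
    domain = FluidDomain(
        drop_radius_um=float(doc["drop_radius_um"]),
        nu_m2_s=float(doc.get("nu_m2_s", 1.0e-6)),
        rho_kg_m3=float(doc.get("rho_kg_m3", 1000.0)),
        depth_scale_um=float(doc.get("depth_scale_um", 1.0)),
    )
    bodies = []
    for entry in doc.get("bodies", []):
        free = entry.get("vx_um_s") == "free"
        vel = None if free else (float(entry.get("vx_um_s", 0.0)),
                                 float(entry.get("vy_um_s", 0.0)))
        dims = entry.get("dims_um", [])
        common = dict(
            body_id=int(entry["body_id"]),
            position=(float(entry["x_um"]), float(entry["y_um"])),
            velocity_um_s=vel,
            angular_velocity_rad_s=float(entry.get("omega_rad_s", 0.0)),
        )
        if entry["shape"] == "disk":
            bodies.append(RigidBody(shape="disk", radius_um=float(dims[0]),
                                    **common))
        elif entry["shape"] == "capsule":
            bodies.append(RigidBody(
                shape="capsule", length_um=float(dims[0]),
                width_um=float(dims[1]),
                orientation_rad=float(entry.get("orientation_rad", 0.0)),
                **common))
        else:
            raise FormatError(f"unknown body shape {entry['shape']!r}")
    return domain, bodies, doc


def stokes_result_dict(solution, forces: list[BodyForce]) -> dict:
    """JSON-ready summary of a Stokes solve."""
    return {
        "per_body": {
            str(f.body_id): {
                "force_N": [float(f.force_N[0]), float(f.force_N[1])],
                "torque_Nm": float(f.torque_Nm),
                "force_per_depth_N_per_m": [
                    float(f.force_per_depth_N_per_m[0]),
                    float(f.force_per_depth_N_per_m[1]),
                ],
                "depth_scale_um": float(f.depth_scale_um),
            }
            for f in forces
        },
        "residuals": {k: float(v) for k, v in solution.residuals.items()},
        "node_count": int(len(solution.nodes)),
        "estimator_history": [
            {k: float(v) for k, v in h.items()}
            for h in solution.refinement_history
        ],
        "resolved_velocities": {
            str(k): [float(v[0]), float(v[1])]
            for k, v in solution.resolved_velocities.items()
        },
    }
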