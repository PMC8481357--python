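"""Time-lapse microcolony quantification.

Segmentation of bright-field frames into labeled microcolony masks,
frame-to-frame tracking with merge/split handling, morphometrics and
volume-weighted time series, uncoupler-experiment (CCCP-style) size and
abundance tables, base-cell spot counting, power-law fitting, and
neighbor-weighted cell-orientation statistics.

Conventions: images are single-channel 2D arrays with pixel centers at
integer coordinates, origin top-left, y increasing downward; physical
conversion uses ``pixel_size_um`` (um/px); frames are 0-based; the default
frame interval is 300 s (5 min time lapse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.spatial import cKDTree
from skimage import exposure, filters, measure, morphology, restoration

from .errors import ArgumentError, ConfigurationError, FormatError

__all__ = [
    "ColonyRecord",
    "Track",
    "TrackSet",
    "EventLog",
    "SegmentationParams",
    "segment_frame",
    "morphometrics",
    "link_tracks",
    "weighted_timeseries",
    "cccp_table",
    "count_base_cells",
    "fit_power_law",
    "orientation_stats",
    "equivalent_diameter_um",
    "sphere_volume_um3",
]

DEFAULT_FRAME_INTERVAL_S = 300.0
DEFAULT_MIN_DIAMETER_UM = 10.0
DEFAULT_ROI_DIAMETER_UM = 1840.0


def equivalent_diameter_um(area_um2: float) -> float:
    """D = 2 sqrt(area / pi): diameter of the equal-area circle."""
    if area_um2 < 0:
        raise ArgumentError("area must be >= 0")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def sphere_volume_um3(diameter_um: float) -> float:
    """V = (4/3) pi (D/2)^3: equivalent sphere volume."""
    return (4.0 / 3.0) * math.pi * (diameter_um / 2.0) ** 3


@dataclass
class ColonyRecord:
    """Per-frame morphometrics of one segmented microcolony."""

    frame_index: int
    colony_id: int
    centroid_um: tuple[float, float]  # (x, y) in the image frame
    area_um2: float
    diameter_um: float
    volume_um3: float
    inside_roi: bool = True

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ArgumentError("area must be positive")


@dataclass
class Track:
    records: list[ColonyRecord]
    # per-step displacement (um) and velocity (um/s); NaN at event steps
    displacements_um: list[float] = field(default_factory=list)
    velocities_um_s: list[float] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [r.frame_index for r in self.records]


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tid, tr in enumerate(self.tracks):
            for k, rec in enumerate(tr.records):
                v = tr.velocities_um_s[k - 1] if k > 0 else np.nan
                rows.append({
                    "frame": rec.frame_index,
                    "colony_id": tid,
                    "x_um": rec.centroid_um[0],
                    "y_um": rec.centroid_um[1],
                    "area_um2": rec.area_um2,
                    "diameter_um": rec.diameter_um,
                    "volume_um3": rec.volume_um3,
                    "velocity_um_s": v,
                })
        cols = ["frame", "colony_id", "x_um", "y_um", "area_um2",
                "diameter_um", "volume_um3", "velocity_um_s"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class EventLog:
    """Merge/split events; areas let the caller audit mass conservation."""

    events: list[dict] = field(default_factory=list)

    def add(self, type_: str, frame_index: int, parent_ids: list[int],
            child_ids: list[int], area_before: float, area_after: float):
        self.events.append({
            "type": type_, "frame_index": frame_index,
            "parent_ids": list(parent_ids), "child_ids": list(child_ids),
            "area_before": float(area_before),
            "area_after": float(area_after),
        })

    def of_type(self, type_: str) -> list[dict]:
        return [e for e in self.events if e["type"] == type_]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events,
            columns=["type", "frame_index", "parent_ids", "child_ids",
                     "area_before", "area_after"],
        )


# ---------------------------------------------------------------------------
# Segmentation


@dataclass(frozen=True)
class SegmentationParams:
    """Dual-path mask parameters.

    Path A: gamma adjust (0.7) -> invert -> background subtract ->
    Gaussian-then-mean filter -> threshold.  Path B: background subtract ->
    invert -> same filter -> threshold.  The two raw masks are OR-combined,
    which makes the result robust to either contrast polarity.
    """

    gamma: float = 0.7
    rolling_ball_radius_px: int = 50
    gaussian_sigma_px: float = 2.0
    mean_size_px: int = 3
    threshold: str | float = "otsu"
    min_component_px: int = 4


def _subtract_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background subtraction for bright-feature images.

    For large radii the background is estimated on a downscaled copy and
    rescaled (the shrink trick classic rolling-ball implementations use);
    the background is smooth at the ball scale, so the approximation error
    is negligible while the cost drops by the square of the factor.
    """
    shrink = max(1, int(radius // 12))
    if shrink > 1 and min(img.shape) >= 8 * shrink:
        from skimage.transform import resize

        small = resize(img, (img.shape[0] // shrink, img.shape[1] // shrink),
                       anti_aliasing=True, preserve_range=True)
        bg_small = restoration.rolling_ball(small, radius=radius / shrink)
        bg = resize(bg_small, img.shape, preserve_range=True)
    else:
        bg = restoration.rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0.0, None)


def _gaussian_mean(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    sm = filters.gaussian(img, sigma=params.gaussian_sigma_px,
                          preserve_range=True)
    k = params.mean_size_px
    kernel = np.ones((k, k)) / (k * k)
    from scipy.ndimage import convolve

    return convolve(sm, kernel, mode="nearest")


def _threshold(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if np.ptp(img) < 1e-12 or np.std(img) < 1e-9 * max(abs(img).max(), 1.0):
        return np.zeros(img.shape, dtype=bool)
    if params.threshold == "otsu":
        t = filters.threshold_otsu(img)
    else:
        t = float(params.threshold)
    mask = img > t
    # foreground is the minority class: if thresholding picked the
    # background (over half the frame), flip
    if mask.mean() > 0.5:
        mask = ~mask
    return mask


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Dual-path segmentation of one grayscale frame into a label mask.

    Returns an integer label image (8-connectivity components of the OR of
    the two path masks).  A constant (blank) frame yields an empty mask.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise FormatError(
            f"expected a single-channel 2D image, got shape {img.shape}"
        )
    if np.ptp(img) < 1e-12:
        return np.zeros(img.shape, dtype=int)
    # work on a 0-255 scale: the rolling-ball geometry couples intensity
    # and pixel units, and the classic radius convention assumes 8-bit-like
    # intensities
    norm = (img - img.min()) / np.ptp(img) * 255.0

    # path A: gamma -> invert -> background subtract -> filter -> threshold
    a = exposure.adjust_gamma(norm / 255.0, params.gamma) * 255.0
    a = 255.0 - a
    a = _subtract_background(a, params.rolling_ball_radius_px)
    a = _gaussian_mean(a, params)
    mask_a = _threshold(a, params)

    # path B: background subtract (light background) -> invert -> filter
    # -> threshold; on the inverted scale this is a standard subtraction
    # with the features bright
    inv = norm.max() - norm
    b = _subtract_background(inv, params.rolling_ball_radius_px)
    b = _gaussian_mean(b, params)
    mask_b = _threshold(b, params)

    mask = mask_a | mask_b
    if params.min_component_px > 1:
        mask = morphology.remove_small_objects(
            mask, max_size=params.min_component_px - 1
        )
    return measure.label(mask, connectivity=2)


# ---------------------------------------------------------------------------
# Morphometrics


def morphometrics(
    label_mask: np.ndarray,
    pixel_size_um: float,
    frame_index: int = 0,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    roi_diameter_um: float | None = DEFAULT_ROI_DIAMETER_UM,
    roi_center_um: tuple[float, float] | None = None,
) -> list[ColonyRecord]:
    """Per-component centroid, area, equivalent diameter and sphere volume.

    Components with D below ``min_diameter_um`` are dropped (smaller objects
    are single cells, not microcolonies), as are components whose centroid
    falls outside the circular region of interest.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be provided and positive")
    mask = np.asarray(label_mask)
    if roi_center_um is None:
        roi_center_um = (
            mask.shape[1] * pixel_size_um / 2.0,
            mask.shape[0] * pixel_size_um / 2.0,
        )
    out: list[ColonyRecord] = []
    for prop in measure.regionprops(mask):
        area = prop.area * pixel_size_um**2
        D = equivalent_diameter_um(area)
        cy, cx = prop.centroid
        x_um, y_um = cx * pixel_size_um, cy * pixel_size_um
        inside = True
        if roi_diameter_um is not None:
            r = math.hypot(x_um - roi_center_um[0], y_um - roi_center_um[1])
            inside = r <= roi_diameter_um / 2.0
        if D < min_diameter_um or not inside:
            continue
        out.append(
            ColonyRecord(
                frame_index=frame_index,
                colony_id=prop.label,
                centroid_um=(x_um, y_um),
                area_um2=area,
                diameter_um=D,
                volume_um3=sphere_volume_um3(D),
                inside_roi=inside,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tracking


def _disks_overlap(a: ColonyRecord, b: ColonyRecord,
                   slack: float = 1.0) -> bool:
    d = math.hypot(a.centroid_um[0] - b.centroid_um[0],
                   a.centroid_um[1] - b.centroid_um[1])
    return d < slack * (a.diameter_um + b.diameter_um) / 2.0


def _assign(prev: list[ColonyRecord], curr: list[ColonyRecord],
            max_link_um: float) -> list[tuple[int, int]]:
    """Linear-assignment linking with a gating cost for non-assignment."""
    if not prev or not curr:
        return []
    cost = np.full((len(prev) + len(curr), len(curr) + len(prev)),
                   max_link_um)
    for i, p in enumerate(prev):
        for j, c in enumerate(curr):
            d = math.hypot(p.centroid_um[0] - c.centroid_um[0],
                           p.centroid_um[1] - c.centroid_um[1])
            cost[i, j] = d if d <= max_link_um else 1e9
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < len(prev) and j < len(curr) and cost[i, j] < max_link_um
    ]


def link_tracks(
    frames: Sequence[Sequence[ColonyRecord]],
    max_link_um: float = 30.0,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    area_slack: float = 0.3,
) -> tuple[TrackSet, EventLog]:
    """Frame-to-frame linear-assignment tracking with merge/split events.

    Links minimise total centroid displacement under a gating distance.  A
    colony that disappears while its disk overlaps a linked current colony
    is a merge parent; the converse is a split.  Steps carrying an event are
    excluded from displacement/velocity statistics (recorded as NaN), which
    removes the spurious center-of-mass jumps merges would otherwise inject.
    """
    if len(frames) < 2:
        raise ArgumentError("need at least 2 frames to track")
    events = EventLog()
    # active tracks: list of (Track, last ColonyRecord)
    active: list[Track] = [Track(records=[r]) for r in frames[0]]
    for fidx in range(1, len(frames)):
        prev_recs = [t.records[-1] for t in active
                     if t.records[-1].frame_index == fidx - 1]
        prev_tracks = [t for t in active
                       if t.records[-1].frame_index == fidx - 1]
        curr = list(frames[fidx])
        links = _assign(prev_recs, curr, max_link_um)
        linked_prev = {i for i, _ in links}
        linked_curr = {j for _, j in links}
        link_of_curr = {j: i for i, j in links}

        # merges: unmatched previous colony overlapping a matched current one
        merge_children: dict[int, list[int]] = {}
        for i, p in enumerate(prev_recs):
            if i in linked_prev:
                continue
            for j, c in enumerate(curr):
                if j in linked_curr and _disks_overlap(p, c):
                    merge_children.setdefault(j, []).append(i)
                    break
        # splits: unmatched current colony overlapping a matched previous one
        split_parents: dict[int, list[int]] = {}
        for j, c in enumerate(curr):
            if j in linked_curr:
                continue
            for i, p in enumerate(prev_recs):
                if i in linked_prev and _disks_overlap(p, c):
                    split_parents.setdefault(i, []).append(j)
                    break

        event_curr: set[int] = set()
        for j, extra_parents in merge_children.items():
            parents = [link_of_curr[j]] + extra_parents
            area_before = sum(prev_recs[i].area_um2 for i in parents)
            events.add("merge", fidx, parents, [j],
                       area_before, curr[j].area_um2)
            event_curr.add(j)
        for i, children in split_parents.items():
            kids = children + [j for (pi, j) in links if pi == i]
            area_after = sum(curr[j].area_um2 for j in kids)
            events.add("split", fidx, [i], kids,
                       prev_recs[i].area_um2, area_after)
            event_curr.update(children)

        # extend linked tracks
        for i, j in links:
            tr = prev_tracks[i]
            p, c = prev_recs[i], curr[j]
            disp = math.hypot(p.centroid_um[0] - c.centroid_um[0],
                              p.centroid_um[1] - c.centroid_um[1])
            if j in event_curr or any(
                e["frame_index"] == fidx and (
                    i in e["parent_ids"] if e["type"] == "split"
                    else j in e["child_ids"]
                )
                for e in events.events
            ):
                tr.displacements_um.append(np.nan)
                tr.velocities_um_s.append(np.nan)
            else:
                tr.displacements_um.append(disp)
                tr.velocities_um_s.append(disp / frame_interval_s)
            tr.records.append(c)
        # new tracks for unmatched current colonies
        for j, c in enumerate(curr):
            if j not in linked_curr:
                active.append(Track(records=[c]))
    return TrackSet(tracks=active, frame_interval_s=frame_interval_s), events


# ---------------------------------------------------------------------------
# Weighted statistics


def weighted_timeseries(tracks: TrackSet) -> pd.DataFrame:
    """Per-frame volume-weighted mean diameter and velocity, plus counts.

    Weights are the equivalent sphere volumes; frames with no colonies (or
    no finite velocities) report NaN, never zero.
    """
    df = tracks.to_dataframe()
    rows = []
    if df.empty:
        return pd.DataFrame(columns=["frame", "weighted_mean_diameter_um",
                                     "weighted_mean_velocity_um_s",
                                     "colony_count"])
    for frame, g in df.groupby("frame"):
        w = g["volume_um3"].to_numpy()
        D = g["diameter_um"].to_numpy()
        v = g["velocity_um_s"].to_numpy()
        wd = float(np.sum(w * D) / np.sum(w)) if w.sum() > 0 else np.nan
        ok = np.isfinite(v)
        wv = (float(np.sum(w[ok] * v[ok]) / np.sum(w[ok]))
              if ok.any() and w[ok].sum() > 0 else np.nan)
        rows.append({"frame": int(frame),
                     "weighted_mean_diameter_um": wd,
                     "weighted_mean_velocity_um_s": wv,
                     "colony_count": int(len(g))})
    return pd.DataFrame(rows)


def cccp_table(
    masks: Sequence[np.ndarray],
    pixel_size_um: float,
    min_area_px2: float = 1000.0,
    timepoint_labels: Sequence | None = None,
) -> pd.DataFrame:
    """Mature-microcolony size/abundance table across timepoints.

    Only components strictly greater than ``min_area_px2`` pixels are
    counted (with a ~1.04 um/px pixel size the 1000 px^2 cutoff corresponds
    to a mature-colony baseline of D > 37 um).  Returns one row per
    component with its equivalent diameter, plus summary medians/counts
    accessible by grouping on ``timepoint``.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be provided and positive")
    labels = (list(timepoint_labels) if timepoint_labels is not None
              else list(range(len(masks))))
    rows = []
    for label, mask in zip(labels, masks):
        for prop in measure.regionprops(np.asarray(mask)):
            if prop.area <= min_area_px2:
                continue
            area_um2 = prop.area * pixel_size_um**2
            rows.append({
                "timepoint": label,
                "component": prop.label,
                "area_px2": int(prop.area),
                "area_um2": area_um2,
                "diameter_um": equivalent_diameter_um(area_um2),
            })
    return pd.DataFrame(rows, columns=["timepoint", "component", "area_px2",
                                       "area_um2", "diameter_um"])


# ---------------------------------------------------------------------------
# Base-cell counting


def count_base_cells(
    image: np.ndarray,
    prominence: float,
    pixel_size_um: float = 1.0,
    rolling_ball_radius_px: int = 50,
    saturated_fraction: float = 0.03,
    colony_center_px: tuple[float, float] | None = None,
    colony_diameter_um: float | None = None,
    d_over_D: float = 0.48,
    min_distance_px: int = 2,
) -> tuple[int, np.ndarray]:
    """Count bright base-cell poles in a colony-base image.

    Pipeline: rolling-ball background subtraction -> contrast stretch
    saturating ``saturated_fraction`` of pixels -> local maxima with the
    given prominence (h-maxima), restricted to the base region (the inner
    circle of diameter ``d_over_D * D``) when the colony geometry is given.
    Two spots closer than the suppression distance merge into one maximum.

    Returns (count, spot coordinates as (x, y) pixel positions).
    """
    if prominence is None:
        raise ConfigurationError(
            "prominence must be supplied (it is image-specific)"
        )
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise FormatError("expected a 2D grayscale image")
    if np.ptp(img) < 1e-12:
        return 0, np.empty((0, 2))
    img = _subtract_background(img, rolling_ball_radius_px)
    lo, hi = np.percentile(
        img, [100 * saturated_fraction / 2, 100 * (1 - saturated_fraction / 2)]
    )
    if hi <= lo:
        return 0, np.empty((0, 2))
    # rescale to an 8-bit-like range so the prominence is interpreted in
    # the usual intensity units
    img = exposure.rescale_intensity(img, in_range=(lo, hi)) * 255.0
    peaks = morphology.h_maxima(img, prominence)
    if min_distance_px > 1:
        peaks = morphology.dilation(
            peaks, morphology.disk(min_distance_px // 2)
        )
    lab = measure.label(peaks, connectivity=2)
    coords = []
    for prop in measure.regionprops(lab):
        cy, cx = prop.centroid
        coords.append((cx, cy))
    coords = np.array(coords) if coords else np.empty((0, 2))
    if colony_center_px is not None and colony_diameter_um is not None:
        base_radius_px = d_over_D * colony_diameter_um / 2.0 / pixel_size_um
        if len(coords):
            d = np.hypot(coords[:, 0] - colony_center_px[0],
                         coords[:, 1] - colony_center_px[1])
            coords = coords[d <= base_radius_px + 2.0]
    return len(coords), coords


# ---------------------------------------------------------------------------
# Power-law fitting


def fit_power_law(
    D: np.ndarray,
    N: np.ndarray,
    method: str = "loglog",
) -> dict:
    """Fit N = a D^b.

    ``loglog`` (default): ordinary least squares on (log D, log N) — the
    spreadsheet "power fit".  ``nls``: nonlinear least squares on the
    original scale, for comparison.  Returns a, b with standard errors.
    """
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if len(D) != len(N) or len(D) < 3:
        raise ArgumentError("need at least 3 (D, N) pairs of equal length")
    if np.any(D <= 0) or np.any(N <= 0):
        raise ArgumentError("power-law fitting requires positive D and N")
    if method == "loglog":
        res = stats.linregress(np.log(D), np.log(N))
        a = math.exp(res.intercept)
        return {
            "a": a,
            "b": float(res.slope),
            "b_stderr": float(res.stderr),
            "a_stderr": a * float(res.intercept_stderr),
            "r_value": float(res.rvalue),
            "method": "loglog",
        }
    if method == "nls":
        popt, pcov = curve_fit(lambda x, a, b: a * x**b, D, N,
                               p0=(1.0, 1.0), maxfev=10000)
        perr = np.sqrt(np.diag(pcov))
        return {"a": float(popt[0]), "b": float(popt[1]),
                "a_stderr": float(perr[0]), "b_stderr": float(perr[1]),
                "method": "nls"}
    raise ArgumentError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Orientation statistics


def orientation_stats(
    cells: pd.DataFrame,
    search_radius_um: float = 9.8,
) -> pd.DataFrame:
    """Distance-weighted mean relative orientation per cell.

    ``cells`` needs columns x_um, y_um, angle_deg (orientation in
    [0, 180)).  For each cell, neighbors within the search radius are
    weighted by ``1 - distance/search_radius``; the relative angle is the
    acute angle between orientations (in [0, 90]).  Cells without neighbors
    are omitted from the output.
    """
    if search_radius_um <= 0:
        raise ArgumentError("search radius must be positive")
    pts = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ang = cells["angle_deg"].to_numpy(dtype=float) % 180.0
    tree = cKDTree(pts)
    rows = []
    for i in range(len(pts)):
        idx = [j for j in tree.query_ball_point(pts[i], search_radius_um)
               if j != i]
        if not idx:
            continue
        d = np.linalg.norm(pts[idx] - pts[i], axis=1)
        keep = d <= search_radius_um
        idx = np.asarray(idx)[keep]
        d = d[keep]
        if len(idx) == 0:
            continue
        w = 1.0 - d / search_radius_um
        rel = np.abs(ang[idx] - ang[i])
        rel = np.minimum(rel, 180.0 - rel)  # acute angle in [0, 90]
        mean_rel = float(np.sum(w * rel) / np.sum(w)) if w.sum() > 0 else np.nan
        rows.append({"cell_index": i, "n_neighbors": int(len(idx)),
                     "weighted_mean_relative_angle_deg": mean_rel})
    return pd.DataFrame(rows, columns=["cell_index", "n_neighbors",
                                       "weighted_mean_relative_angle_deg"])
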