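"""Regional quantification of super-resolved vascular maps and track sets.

Implements the per-region metrics used to compare cohorts: blood volume
(mean number of distinct microbubble tracks entering an ROI per
acquisition), vascularity (percent of the ROI perfused after binarizing the
density map), track-weighted regional mean velocity and SOAM tortuosity,
K-means stratification of the density map into large and small vessels,
intervessel distance from the distance transform of the large-vessel mask,
and the sample skewness of the whole-field velocity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.stats import skew
from shapely.geometry import LineString
from skimage.draw import polygon as draw_polygon
from sklearn.cluster import KMeans

from .hobby import hobby_closed
from .mapping import ULMImage
from .tracking import TrackSet, track_soam, track_velocity


@dataclass
class ROIPolygon:
    """Closed region built from control vertices by Hobby interpolation.

    ``vertices`` are the control knots (µm); ``boundary`` is the sampled
    closed spline; ``mask`` marks super-resolved pixels whose centers fall
    inside the boundary.
    """

    name: str
    vertices: np.ndarray
    boundary: np.ndarray
    mask: np.ndarray
    pitch_um: float = 4.928


def _check_simple(boundary: np.ndarray, n_segments: int) -> None:
    """Reject self-intersecting boundaries, naming the offending segment pair."""
    per_seg = len(boundary) // n_segments
    segs = []
    for i in range(n_segments):
        pts = boundary[i * per_seg:(i + 1) * per_seg + 1]
        if i == n_segments - 1:
            pts = np.vstack([boundary[i * per_seg:], boundary[:1]])
        segs.append(LineString(pts))
    for i in range(n_segments):
        for j in range(i + 1, n_segments):
            adjacent = (j == i + 1) or (i == 0 and j == n_segments - 1)
            if adjacent:
                continue
            if segs[i].intersects(segs[j]):
                raise ValueError(
                    f"self-intersecting ROI boundary: segments {i} and {j} cross")


def roi_from_vertices(vertices: np.ndarray, grid_shape: tuple[int, int],
                      pitch_um: float = 4.928, tension: float = 1.0,
                      name: str = "roi") -> ROIPolygon:
    """Build an ROI from control vertices via a closed Hobby spline.

    The mask contains the super-resolved pixels whose centers lie inside the
    boundary (even-odd rule). Degenerate (zero-area) vertex rings and
    self-intersecting boundaries raise ``ValueError``.
    """
    verts = np.asarray(vertices, dtype=float).reshape(-1, 2)
    if len(verts) < 3:
        raise ValueError("need at least 3 control vertices")
    # shoelace area of the control polygon; collinear rings are degenerate
    z, x = verts[:, 0], verts[:, 1]
    area2 = np.abs(np.dot(z, np.roll(x, -1)) - np.dot(x, np.roll(z, -1)))
    if area2 < 1e-9:
        raise ValueError("degenerate (zero-area) vertex ring")
    boundary = hobby_closed(verts, tension=tension)
    _check_simple(boundary, n_segments=len(verts))
    rr, cc = draw_polygon(boundary[:, 0] / pitch_um - 0.5,
                          boundary[:, 1] / pitch_um - 0.5, shape=grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("ROI mask is empty on this grid")
    return ROIPolygon(name=name, vertices=verts, boundary=boundary, mask=mask,
                      pitch_um=pitch_um)


def mask_roi(mask: np.ndarray, name: str = "roi", pitch_um: float = 4.928) -> ROIPolygon:
    """Wrap a precomputed boolean mask (e.g., a simulator region) as an ROI."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return ROIPolygon(name=name, vertices=np.empty((0, 2)), boundary=np.empty((0, 2)),
                      mask=mask, pitch_um=pitch_um)


def _tracks_in_roi(trackset: TrackSet, roi: ROIPolygon) -> list:
    """Tracks with at least one sample whose pixel falls inside the ROI mask."""
    shape = roi.mask.shape
    hits = []
    for tr in trackset:
        idx = np.floor(tr.positions / roi.pitch_um).astype(int)
        ok = ((idx[:, 0] >= 0) & (idx[:, 0] < shape[0])
              & (idx[:, 1] >= 0) & (idx[:, 1] < shape[1]))
        if ok.any() and roi.mask[idx[ok, 0], idx[ok, 1]].any():
            hits.append(tr)
    return hits


def blood_volume(tracksets_per_acquisition: list[TrackSet], roi: ROIPolygon) -> float:
    """Mean number of distinct tracks entering the ROI per acquisition.

    A track is counted once per acquisition no matter how often it crosses
    the boundary.
    """
    if not tracksets_per_acquisition:
        raise ValueError("need at least one acquisition")
    counts = [len(_tracks_in_roi(ts, roi)) for ts in tracksets_per_acquisition]
    return float(np.mean(counts))


def vascularity(image: ULMImage, roi: ROIPolygon, binarize_threshold: int = 1) -> float:
    """Percent of ROI pixels perfused (density >= threshold) in the binarized map."""
    if image.shape != roi.mask.shape:
        raise ValueError("image and ROI grids differ")
    roi_n = int(roi.mask.sum())
    perfused = int(np.sum((image.density >= binarize_threshold) & roi.mask))
    return 100.0 * perfused / roi_n


def region_velocity_and_soam(trackset: TrackSet, roi: ROIPolygon,
                             frame_rate: float = 1000.0) -> tuple[float, float]:
    """Track-weighted regional mean speed (mm/s) and mean SOAM (deg/mm).

    Each intersecting track contributes once (its mean speed; its SOAM when
    it has >= 3 points). Raises ``ValueError`` when no track intersects.
    """
    hits = _tracks_in_roi(trackset, roi)
    if not hits:
        raise ValueError(f"no tracks intersect ROI {roi.name!r}")
    speeds = [track_velocity(t, frame_rate)[1] for t in hits if len(t) >= 2]
    soams = [track_soam(t)[0] for t in hits if len(t) >= 3]
    if not speeds:
        raise ValueError("no track with >= 2 points intersects the ROI")
    return float(np.mean(speeds)), float(np.mean(soams)) if soams else float("nan")


@dataclass
class VesselSegmentation:
    """K-means stratification of the density map into large and small vessels."""

    labels: np.ndarray  # cluster index (0..k-1 by ascending centroid), -1 outside support
    large_mask: np.ndarray
    small_mask: np.ndarray
    centroids: np.ndarray  # ascending log10-density cluster centers


def kmeans_vessel_split(density: np.ndarray, k: int = 6, n_large: int = 2,
                        seed: int = 0) -> VesselSegmentation:
    """Cluster nonzero density values (log-compressed) into k groups.

    Clusters are ranked by centroid; the top ``n_large`` form the
    large-vessel mask and the rest the small-vessel mask. Initialization is
    deterministic (centroids at quantiles of the value distribution), so the
    segmentation is invariant to pixel ordering.
    """
    density = np.asarray(density)
    support = density > 0
    vals = np.log10(density[support].astype(float))
    if len(np.unique(vals)) < k:
        raise ValueError(
            f"only {len(np.unique(vals))} distinct nonzero density values; "
            f"use a smaller k than {k}")
    init = np.quantile(np.sort(vals), (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    raw_labels = km.fit_predict(vals.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank_of = np.empty(k, dtype=int)
    rank_of[order] = np.arange(k)
    ranked = rank_of[raw_labels]

    labels = np.full(density.shape, -1, dtype=int)
    labels[support] = ranked
    large = np.isin(labels, np.arange(k - n_large, k)) & support
    small = support & ~large
    return VesselSegmentation(labels=labels, large_mask=large, small_mask=small,
                              centroids=km.cluster_centers_.ravel()[order])


def intervessel_distance(large_mask: np.ndarray, roi: ROIPolygon) -> float:
    """Characteristic wall-to-wall spacing of large vessels inside an ROI, µm.

    Twice the mean (over non-vessel ROI pixels) distance to the nearest
    large-vessel pixel; the factor 2 converts nearest-wall distance to
    wall-to-wall spacing.
    """
    large = np.asarray(large_mask, dtype=bool)
    if not large.any():
        raise ValueError("large-vessel mask is empty")
    dist = distance_transform_edt(~large, sampling=(roi.pitch_um, roi.pitch_um))
    off_vessel = roi.mask & ~large
    if not off_vessel.any():
        return 0.0
    return float(2.0 * dist[off_vessel].mean())


def velocity_skewness(speeds: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness (G1) of per-track mean speeds."""
    speeds = np.asarray(speeds, dtype=float).reshape(-1)
    if len(speeds) < 3:
        raise ValueError("skewness needs at least 3 tracks")
    if np.ptp(speeds) == 0:
        warnings.warn("zero-variance speed sample: skewness undefined", stacklevel=2)
        return float("nan")
    return float(skew(speeds, bias=False))


@dataclass
class RegionMetrics:
    """Per-subject, per-region record feeding the statistics layer."""

    subject: str
    age_group: str
    sex: str
    region: str
    blood_volume: float
    vascularity: float
    mean_speed: float
    mean_soam: float
    n_tracks: int
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.vascularity <= 100:
            raise ValueError("vascularity must lie in [0, 100]")
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
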