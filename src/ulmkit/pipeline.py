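"""Configuration-driven end-to-end orchestration.

``run_pipeline`` drives simulate -> SVD filter -> noise equalization ->
separation -> upsample/localize -> link/filter -> register/accumulate ->
quantify -> group statistics for a synthetic cohort, writing every stage
artifact plus a manifest (config snapshot, per-stage counts, file checksums)
under the output directory. One master seed derives per-subject, per-
acquisition child seeds, so subjects are independent yet the whole run is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clutter import noise_equalization, svd_filter
from .iq import IQStack
from .localization import (CorrelationLocalizer, PSFModel, make_bank,
                           separation_filter, upsample_frame)
from .mapping import accumulate, register_accumulations, shift_trackset
from .params import AcquisitionParams
from .quantify import (RegionMetrics, ROIPolygon, mask_roi, blood_volume,
                       region_velocity_and_soam, vascularity, velocity_skewness)
from .stats import compare_skewness, multivariate_regression, two_way_anova_tukey
from .synthetic import SceneConfig, make_scene, preset_cohort, simulate_iq
from .tracking import Track, TrackSet, filter_tracks, link_frames

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest or {}


@dataclass
class PipelineConfig:
    """Every stage's parameters, exactly once; YAML round-trippable."""

    # cohort / scene
    n_young: int = 8
    n_aged: int = 8
    grid_shape: tuple[int, int] = (64, 64)
    scale: str = "reduced"  # "reduced" | "full"
    n_frames: int = 400  # reduced-scale frames per acquisition; short clips
    n_acquisitions: int = 1  # leave visible bubble-trail residue after filtering
    # clutter filter (clamp floor 1: synthetic tissue is near-rank-1; raise
    # toward the in vivo 10-20 range for data with tissue motion)
    svd_cutoff: int | str = "adaptive"
    svd_clamp: tuple[int, int] = (1, 30)
    equalize_noise: bool = True
    # separation ("none": preset scenes are already sparse; "direction" /
    # "direction_speed" dilute high-concentration data at the cost of
    # ringing ghosts around zero-Doppler flow)
    separation_mode: str = "none"
    speed_edge_mm_s: float = 5.0
    # localization
    corr_threshold: float = 0.5
    min_amplitude_frac: float = 0.30  # of the stack's 99.5th |IQ| percentile
    subpixel_refine: bool = True  # correlation-weighted centroid refinement
    psf_sigma: tuple[float, float] = (60.0, 65.0)
    # tracking
    max_speed_mm_s: float = 50.0
    gap_close: int = 0
    min_track_length: int = 20
    # quantification
    kmeans_k: int = 6
    kmeans_n_large: int = 2
    roi_geometry: str | None = None  # path to a geometry file; None = simulator bands
    # bookkeeping
    output_dir: str = "ulm_output"
    seed: int = 0
    params: AcquisitionParams = field(default_factory=AcquisitionParams)

    def effective(self) -> tuple[int, int]:
        """(frames per acquisition, acquisitions per subject) at current scale."""
        if self.scale == "full":
            return self.params.frames_per_acquisition, self.params.n_acquisitions
        return self.n_frames, self.n_acquisitions

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["grid_shape"] = list(self.grid_shape)
        d["svd_clamp"] = list(self.svd_clamp)
        d["psf_sigma"] = list(self.psf_sigma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d:
            d["params"] = AcquisitionParams.from_dict(d["params"])
        for key in ("grid_shape", "svd_clamp", "psf_sigma"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def child_seed(master: int, *key: int) -> int:
    """Deterministic per-stage child seed below 2^31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def reconstruct_acquisition(stack: IQStack, config: PipelineConfig
                            ) -> tuple[TrackSet, dict]:
    """Filter, separate, localize, and link one acquisition into tracks.

    Returns the length-filtered TrackSet (track ids unique within the
    acquisition) and per-stage counts for the manifest.
    """
    params = stack.params
    filtered, spectrum = svd_filter(stack, cutoff=config.svd_cutoff,
                                    clamp=config.svd_clamp)
    if config.equalize_noise:
        filtered, _ = noise_equalization(filtered)
    bank = make_bank(stack.data.shape, params, mode=config.separation_mode,
                     speed_edge_mm_s=config.speed_edge_mm_s)
    subsets = separation_filter(filtered, bank)
    psf = PSFModel(sigma_axial=config.psf_sigma[0], sigma_lateral=config.psf_sigma[1])
    factor = params.upsampling_factor[0]
    pitch = params.superres_pixel

    sr_shape = (stack.n_depth * factor, stack.n_lateral * params.upsampling_factor[1])
    localizer = CorrelationLocalizer(psf, sr_shape, pitch_um=pitch,
                                     corr_threshold=config.corr_threshold)
    all_tracks: list[Track] = []
    n_detections = 0
    next_id = 0
    for sub in subsets:
        floor = None
        if config.min_amplitude_frac > 0:
            floor = config.min_amplitude_frac * np.percentile(np.abs(sub.data), 99.5)
        locs = []
        for f in range(sub.n_frames):
            sr = upsample_frame(sub.data[:, :, f], factor)
            fl = localizer.localize(sr, frame_index=f, min_amplitude=floor,
                                    refine=config.subpixel_refine)
            locs.append(fl)
            n_detections += len(fl.corr)
        ts = link_frames(locs, max_speed=config.max_speed_mm_s,
                         gap_close=config.gap_close, frame_rate=params.frame_rate)
        for t in ts:
            all_tracks.append(Track(next_id, t.frames, t.positions))
            next_id += 1
    trackset = TrackSet(tracks=all_tracks,
                        provenance={"n_subsets": len(subsets),
                                    "svd_cutoff": spectrum.cutoff})
    kept = filter_tracks(trackset, min_length=config.min_track_length)
    counts = {"frames": stack.n_frames, "svd_cutoff": spectrum.cutoff,
              "detections": n_detections, "tracks": len(trackset),
              "tracks_after_length_filter": len(kept)}
    return kept, counts


def default_region_rois(grid_shape: tuple[int, int], params: AcquisitionParams
                        ) -> dict[str, ROIPolygon]:
    """Simulator-aligned analysis bands: a cortical band (upper part of the
    field, columnar vessels) and a deep band (lateral vessels below it)."""
    fz, fx = params.upsampling_factor
    sr = (grid_shape[0] * fz, grid_shape[1] * fx)
    cortex = np.zeros(sr, dtype=bool)
    cortex[int(0.08 * sr[0]):int(0.47 * sr[0]), int(0.05 * sr[1]):int(0.95 * sr[1])] = True
    deep = np.zeros(sr, dtype=bool)
    deep[int(0.53 * sr[0]):int(0.92 * sr[0]), int(0.05 * sr[1]):int(0.95 * sr[1])] = True
    return {"cortex": mask_roi(cortex, "cortex", params.superres_pixel),
            "deep": mask_roi(deep, "deep", params.superres_pixel)}


def run_subject(group: str, subject_index: int, config: PipelineConfig
                ) -> tuple[list[TrackSet], "np.ndarray", dict]:
    """Simulate and reconstruct all acquisitions of one synthetic subject.

    Returns registered per-acquisition tracksets, the merged density image,
    and the per-stage counts.
    """
    seed = child_seed(config.seed, 0 if group == "young" else 1, subject_index)
    scene_cfg = preset_cohort(group, seed=seed, grid_shape=config.grid_shape)
    scene = make_scene(scene_cfg, config.params)
    n_frames, n_acq = config.effective()
    tracksets, images, counts = [], [], []
    for a in range(n_acq):
        stack, _truth = simulate_iq(scene, config.params, n_frames=n_frames,
                                    seed=child_seed(seed, a))
        ts, c = reconstruct_acquisition(stack, config)
        tracksets.append(ts)
        sr_shape = scene.superres_shape
        images.append(accumulate(ts, sr_shape, config.params.superres_pixel,
                                 config.params.frame_rate))
        counts.append(c)
    shifts, _ = register_accumulations(images)
    tracksets = [shift_trackset(ts, sh, config.params.superres_pixel)
                 for ts, sh in zip(tracksets, shifts)]
    merged = accumulate([t for t in tracksets], scene.superres_shape,
                        config.params.superres_pixel, config.params.frame_rate)
    return tracksets, merged, {"acquisitions": counts, "shifts": shifts}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full cohort pipeline and write the artifact bundle.

    Returns the manifest. Raises :class:`StageError` (with the manifest so
    far) when a stage fails.
    """
    from .io import save_tracks_csv, save_ulm_image, render_ulm_png

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    n_frames, n_acq = config.effective()
    if n_acq < 1 or n_frames < 2:
        raise StageError("simulate", "0 simulated acquisitions requested", manifest)

    rng_age = np.random.default_rng(child_seed(config.seed, 99))
    rows = []
    skew_by_group: dict[str, list[float]] = {"young": [], "aged": []}
    rois = None
    for group, n_subj in (("young", config.n_young), ("aged", config.n_aged)):
        for i in range(n_subj):
            subject = f"{group}{i:02d}"
            try:
                tracksets, merged, counts = run_subject(group, i, config)
            except Exception as e:  # noqa: BLE001
                raise StageError("reconstruct", f"subject {subject}: {e}", manifest) from e
            manifest["stages"][subject] = counts
            if rois is None:
                rois = default_region_rois(config.grid_shape, config.params)
            combined = TrackSet(tracks=[t for ts in tracksets for t in ts])
            speeds = [np.hypot(*np.diff(t.positions, axis=0).T).sum()
                      / (len(t) - 1) * config.params.frame_rate / 1000.0
                      for t in combined if len(t) >= 2]
            if len(speeds) >= 3:
                skew_by_group[group].append(velocity_skewness(np.array(speeds)))
            sex = "F" if i % 2 == 0 else "M"  # balanced, as in the cohort design
            age_weeks = float(rng_age.normal(27.7 if group == "young" else 106.8, 3.0))
            for rname, roi in rois.items():
                try:
                    speed, soam = region_velocity_and_soam(
                        combined, roi, config.params.frame_rate)
                except ValueError:
                    speed, soam = float("nan"), float("nan")
                bv = blood_volume(tracksets, roi)
                vasc = vascularity(merged, roi)
                metrics = RegionMetrics(
                    subject=subject, age_group=group, sex=sex, region=rname,
                    blood_volume=bv, vascularity=vasc, mean_speed=speed,
                    mean_soam=soam, n_tracks=len(combined))
                for metric_name, value in (("blood_volume", metrics.blood_volume),
                                           ("vascularity", metrics.vascularity),
                                           ("mean_speed", metrics.mean_speed),
                                           ("mean_soam", metrics.mean_soam)):
                    rows.append({"subject": subject, "age_group": group, "sex": sex,
                                 "age_weeks": age_weeks, "region": rname,
                                 "metric_name": metric_name, "value": value})
            save_tracks_csv(combined, out / f"tracks_{subject}.csv")
            save_ulm_image(merged, out / f"ulm_{subject}.tiff")
            if i == 0:
                render_ulm_png(merged, out / f"ulm_{subject}.png")

    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.csv", index=False)

    # statistics stage
    try:
        stats_rows = []
        for metric in ("blood_volume", "vascularity", "mean_speed", "mean_soam"):
            sub = table[table["metric_name"] == metric]
            if sub["value"].isna().any():
                sub = sub.dropna(subset=["value"])
            try:
                results = two_way_anova_tukey(sub, metric)
            except ValueError as e:
                # undefined at this scale (e.g., a cell with < 2 subjects whose
                # metric could be computed); record the gap instead of aborting
                logger.warning("ANOVA for %s skipped: %s", metric, e)
                stats_rows.append({"metric": metric, "effect": "age_group",
                                   "F": float("nan"), "p_value": float("nan")})
                continue
            for r in results:
                stats_rows.append({"metric": metric, "effect": r.effect,
                                   "F": r.statistic, "p_value": r.p_value})
            for region in sub["region"].unique():
                reg = multivariate_regression(sub, metric, region)
                for term, row in reg.iterrows():
                    stats_rows.append({"metric": metric,
                                       "effect": f"regression[{region}]:{term}",
                                       "F": float("nan"), "p_value": row["p_value"]})
        if len(skew_by_group["young"]) >= 2 and len(skew_by_group["aged"]) >= 2:
            sk = compare_skewness(np.array(skew_by_group["young"]),
                                  np.array(skew_by_group["aged"]))
            stats_rows.append({"metric": "velocity_skewness", "effect": sk.effect,
                               "F": sk.statistic, "p_value": sk.p_value})
        stats_df = pd.DataFrame(stats_rows)
        stats_df.to_csv(out / "stats.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", str(e), manifest) from e

    manifest["skewness"] = {g: list(map(float, v)) for g, v in skew_by_group.items()}
    config.save(out / "config.yaml")
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return manifest
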