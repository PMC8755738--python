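"""Self-contained verification experiments for the reconstruction pipeline.

Each function builds its own synthetic inputs (with an explicit seed), runs
one capability of the package, and measures the result against ground truth
or an independent oracle. They are used by the acceptance test suite and by
``scripts/acceptance.py``; all problem sizes are desk-scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clutter import svd_filter
from .iq import IQStack
from .localization import CorrelationLocalizer, PSFModel, upsample_frame
from .mapping import ULMImage, color_flow, register_accumulations
from .params import AcquisitionParams
from .pipeline import PipelineConfig, reconstruct_acquisition
from .stats import two_way_anova_tukey
from .synthetic import SceneConfig, VesselSpec, make_scene, simulate_iq
from .tracking import track_velocity


# --- SVD filter vs covariance-eigendecomposition oracle ---------------------

def svd_oracle_comparison(shape=(32, 32, 64), k=10, seed=0) -> dict:
    """Relative error of the SVD clutter filter against an independent
    eigendecomposition of the space-space covariance, plus the energy
    identity error |sum(sigma^2) - ||X||_F^2| / ||X||_F^2."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    stack = IQStack(data.astype(np.complex64), AcquisitionParams())
    filtered, spec = svd_filter(stack, cutoff=k)
    X = stack.casorati().astype(np.complex128)
    C = X @ X.conj().T
    w, V = np.linalg.eigh(C)
    top = V[:, ::-1][:, :k]
    oracle = (X - top @ (top.conj().T @ X)).reshape(shape)
    rel_err = float(np.linalg.norm(filtered.data - oracle) / np.linalg.norm(oracle))
    fro2 = float(np.sum(np.abs(X) ** 2))
    energy_err = float(abs(np.sum(spec.values ** 2) - fro2) / fro2)
    return {"rel_err": rel_err, "energy_identity_err": energy_err,
            "n": int(np.prod(shape))}


# --- clutter suppression ----------------------------------------------------

def clutter_suppression(seed=0, n_frames=96) -> dict:
    """Static tissue 30 dB above bubbles: post-filter tissue-region energy
    reduction (dB) and the strongest correlation coefficient at a true
    bubble after filtering (detectability)."""
    params = AcquisitionParams()
    cfg = SceneConfig(grid_shape=(32, 32), vessels=[
        VesselSpec(kind="straight", start=(400.0, 100.0), end=(400.0, 1400.0),
                   radius=15.0, peak_speed=6.0, flow_sign=1, bubble_rate=12.0),
        VesselSpec(kind="straight", start=(1100.0, 100.0), end=(1100.0, 1400.0),
                   radius=15.0, peak_speed=6.0, flow_sign=-1, bubble_rate=12.0)],
        tissue_amplitude=10 ** (30 / 20), noise_floor=1e-4, seed=seed)
    scene = make_scene(cfg, params)
    for attempt in range(8):  # Poisson arrivals can come up empty at small n
        stack, truth = simulate_iq(scene, params, n_frames=n_frames,
                                   seed=seed + 1 + attempt)
        if truth.tracks:
            break
    filtered, _ = svd_filter(stack, cutoff="adaptive", clamp=(1, 30))

    fz, fx = params.upsampling_factor
    bubble_region = scene.mask.reshape(32, fz, 32, fx).any((1, 3))
    tissue_region = ~bubble_region
    e_in = float(np.sum(np.abs(stack.data[tissue_region, :]) ** 2))
    e_out = float(np.sum(np.abs(filtered.data[tissue_region, :]) ** 2))
    suppression_db = 10 * np.log10(e_in / e_out)

    # detectability: correlation at a true bubble position after filtering
    psf = PSFModel(60.0, 65.0)
    factor = params.upsampling_factor[0]
    loc = CorrelationLocalizer(psf, (32 * factor, 32 * factor),
                               params.superres_pixel, 0.5)
    peak = 0.0
    for tid, arr in truth.tracks.items():
        f, z, x = arr[len(arr) // 2]
        corr = loc.correlate(upsample_frame(filtered.data[:, :, int(f)], factor))
        iz = int(z / params.superres_pixel)
        ix = int(x / params.superres_pixel)
        win = corr[max(0, iz - 10):iz + 11, max(0, ix - 10):ix + 11]
        peak = max(peak, float(win.max()))
        if peak > 0.9:
            break
    return {"suppression_db": float(suppression_db), "bubble_peak_corr": peak,
            "n": n_frames}


# --- localization precision -------------------------------------------------

def localization_precision(n_frames=500, snr_db=30.0, seed=0) -> dict:
    """Mean absolute localization error (µm) over seeded single-bubble frames
    at the given SNR, using the full upsample + correlate + peak pipeline."""
    params = AcquisitionParams()
    pitch = params.superres_pixel
    factor = params.upsampling_factor[0]
    nz = nx = 24
    sig_z, sig_x = 60.0, 65.0
    psf = PSFModel(sig_z, sig_x)
    localizer = CorrelationLocalizer(psf, (nz * factor, nx * factor), pitch, 0.5)
    rng = np.random.default_rng(seed)
    noise_amp = 10 ** (-snr_db / 20)
    zg = (np.arange(nz) + 0.5) * params.native_pixel[0]
    xg = (np.arange(nx) + 0.5) * params.native_pixel[1]
    errors = []
    for _ in range(n_frames):
        true_z = rng.uniform(0.3, 0.7) * nz * params.native_pixel[0]
        true_x = rng.uniform(0.3, 0.7) * nx * params.native_pixel[1]
        frame = np.exp(-((zg[:, None] - true_z) ** 2) / (2 * sig_z ** 2)
                       - ((xg[None, :] - true_x) ** 2) / (2 * sig_x ** 2))
        frame = frame + noise_amp * rng.standard_normal(frame.shape)
        fl = localizer.localize(upsample_frame(frame, factor))
        if len(fl.corr) == 0:
            continue
        d = np.hypot(fl.positions[:, 0] - true_z, fl.positions[:, 1] - true_x)
        errors.append(d.min())
    return {"mean_abs_error_um": float(np.mean(errors)), "n": len(errors)}


# --- velocity recovery ------------------------------------------------------

def velocity_recovery(speeds=(2.0, 5.0, 10.0), min_tracks=100, seed=0,
                      max_acquisitions=30) -> dict:
    """Plug-flow vessels at the given speeds: mean recovered track speed and
    its relative error, accumulating acquisitions until ``min_tracks``."""
    params = AcquisitionParams()
    out = {}
    cfg_pipe = PipelineConfig(separation_mode="none", equalize_noise=False,
                              svd_cutoff=0, corr_threshold=0.65,
                              max_speed_mm_s=25.0)
    for speed in speeds:
        vessels = [VesselSpec(kind="straight", start=(z, 100.0), end=(z, 2260.0),
                              radius=12.0, peak_speed=speed, flow_sign=1,
                              bubble_rate=3.0)
                   for z in (300.0, 550.0, 800.0, 1050.0, 1300.0)]
        scene = make_scene(SceneConfig(grid_shape=(32, 48), vessels=vessels,
                                       tissue_amplitude=0.0, noise_floor=0.0),
                           params)
        recovered = []
        for a in range(max_acquisitions):
            stack, _ = simulate_iq(scene, params, n_frames=100,
                                   seed=seed * 1000 + a)
            ts, _ = reconstruct_acquisition(stack, cfg_pipe)
            recovered.extend(track_velocity(t, params.frame_rate)[1] for t in ts)
            if len(recovered) >= min_tracks:
                break
        mean = float(np.mean(recovered))
        out[speed] = {"mean_mm_s": mean, "rel_err": float(mean / speed - 1.0),
                      "n": len(recovered)}
    return out


# --- registration -----------------------------------------------------------

def registration_recovery(seed=0, shape=(64, 64)) -> dict:
    """Apply integer shifts up to 1/4 of the image extent and measure the
    worst-case recovery error (super-resolved pixels)."""
    rng = np.random.default_rng(seed)
    dens = (rng.random(shape) < 0.05).astype(np.int64) * rng.integers(1, 5, shape)
    ref = ULMImage(density=dens, speed_sum=np.zeros(shape),
                   direction_sum=np.zeros(shape))
    worst = 0
    quarter = shape[0] // 4
    trials = 0
    for dz in (-quarter, -3, 0, 5, quarter):
        for dx in (-quarter, -2, 0, 7, quarter):
            moved = ULMImage(density=np.roll(dens, (-dz, -dx), axis=(0, 1)),
                             speed_sum=ref.speed_sum,
                             direction_sum=ref.direction_sum)
            shifts, _ = register_accumulations([ref, moved])
            worst = max(worst, abs(shifts[1][0] - dz), abs(shifts[1][1] - dx))
            trials += 1
    return {"max_shift_error_px": int(worst), "n": trials}


# --- color flow -------------------------------------------------------------

def color_flow_accuracy(v_mm_s=5.0, seed=0, n_frames=64) -> dict:
    """Loupas autocorrelation estimate on simulated uniform axial motion, and
    the largest |velocity| returned for a purely static scene."""
    params = AcquisitionParams()
    f0, c, prf = params.center_frequency, params.sound_speed, params.frame_rate
    t = np.arange(n_frames) / prf
    phase = -4 * np.pi * f0 * (v_mm_s * 1e-3) * t / c
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.5, 1.0, (16, 16))
    moving = IQStack(amp[:, :, None] * np.exp(1j * phase)[None, None, :], params)
    est = float(np.mean(color_flow(moving, params).velocity))
    static = IQStack(np.repeat(amp[:, :, None], n_frames, axis=2).astype(complex),
                     params)
    static_max = float(np.max(np.abs(color_flow(static, params).velocity)))
    return {"estimate_mm_s": est, "rel_err": est / v_mm_s - 1.0,
            "static_max_mm_s": static_max, "n": n_frames}


# --- statistics calibration -------------------------------------------------

def _null_table(rng, n_per_group=8, effect=0.0) -> pd.DataFrame:
    rows = []
    for g, delta in (("young", 0.0), ("aged", effect)):
        for r in ("r1", "r2"):
            for i in range(n_per_group):
                rows.append({"subject": f"{g}{r}{i}", "age_group": g, "sex": "F",
                             "region": r, "metric_name": "m",
                             "value": rng.normal(delta, 1.0)})
    return pd.DataFrame(rows)


def stats_calibration(n_null=1000, n_power=300, seed=0) -> dict:
    """Type-I error of the age main effect under the null, power under a
    5-pooled-SD injected effect, and the worst relative deviation of the
    ANOVA F statistics from a from-scratch sums-of-squares oracle."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_null):
        res = two_way_anova_tukey(_null_table(rng), "m", tukey=False)
        rejections += res[0].p_value < 0.05
    type1 = rejections / n_null

    hits = 0
    for _ in range(n_power):
        res = two_way_anova_tukey(_null_table(rng, effect=5.0), "m", tukey=False)
        hits += res[0].p_value < 0.05
    power = hits / n_power

    # worked 2x2 table vs the textbook balanced decomposition
    table = _null_table(np.random.default_rng(seed + 1), n_per_group=6, effect=1.0)
    results = {r.effect: r.statistic
               for r in two_way_anova_tukey(table, "m", tukey=False)}
    y = table["value"].to_numpy()
    A = table["age_group"].to_numpy()
    B = table["region"].to_numpy()
    grand = y.mean()
    ss_a = sum((y[A == a].size) * (y[A == a].mean() - grand) ** 2 for a in set(A))
    ss_b = sum((y[B == b].size) * (y[B == b].mean() - grand) ** 2 for b in set(B))
    ss_cells = sum((y[(A == a) & (B == b)].size)
                   * (y[(A == a) & (B == b)].mean() - grand) ** 2
                   for a in set(A) for b in set(B))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = np.sum((y - grand) ** 2) - ss_cells
    df_err = y.size - 4
    oracle = {"age_group": (ss_a / 1) / (ss_err / df_err),
              "region": (ss_b / 1) / (ss_err / df_err),
              "age_group:region": (ss_ab / 1) / (ss_err / df_err)}
    f_err = max(abs(results[k] - oracle[k]) / oracle[k] for k in oracle)
    return {"type1_rate": type1, "power": power, "f_oracle_rel_err": float(f_err),
            "n_null": n_null, "n_power": n_power}


# --- end-to-end cohort ------------------------------------------------------

def cohort_contrasts(metrics: pd.DataFrame) -> dict:
    """Group-mean contrasts from a tidy cohort metrics table: per-region
    aged/young ratios for speed and SOAM, and the cortical vascularity
    ratio."""
    g = (metrics.groupby(["metric_name", "region", "age_group"])["value"]
         .mean().unstack("age_group"))
    out = {}
    for region in metrics["region"].unique():
        out[f"speed_ratio_{region}"] = float(
            g.loc[("mean_speed", region), "aged"] / g.loc[("mean_speed", region),
                                                          "young"])
        out[f"soam_ratio_{region}"] = float(
            g.loc[("mean_soam", region), "aged"] / g.loc[("mean_soam", region),
                                                         "young"])
    out["vascularity_ratio_cortex"] = float(
        g.loc[("vascularity", "cortex"), "aged"]
        / g.loc[("vascularity", "cortex"), "young"])
    return out
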