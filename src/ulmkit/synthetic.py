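"""Synthetic vascular scenes and simulated contrast-enhanced IQ acquisitions.

The simulator emulates the statistical structure of ultrafast contrast
imaging of the rodent brain: a strong, spatiotemporally coherent tissue
background (optionally drifting slowly in-plane), sparse microbubbles
advected along vascular centerlines, and circular white noise whose
amplitude grows with depth. Every acquisition carries its ground truth
(bubble tracks at frame resolution, per-vessel masks, assigned speeds,
centerline tortuosity) so each downstream stage can be verified.

Microbubbles are rendered as an anisotropic Gaussian point-spread function
whose complex carrier phase advances with the bubble's axial position as
``-4*pi*f0*z/c``, so autocorrelation (Doppler) velocity estimators see the
physically correct phase progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .iq import IQStack
from .params import AcquisitionParams

_CENTERLINE_KINDS = ("straight", "sinusoid", "points")


@dataclass
class VesselSpec:
    """One vessel: a planar centerline plus flow and contrast parameters.

    Parameters
    ----------
    kind : {"straight", "sinusoid", "points"}
        Centerline family. "straight" runs start -> end; "sinusoid" adds a
        perpendicular sinusoidal displacement of the given amplitude and
        wavelength to that chord; "points" interpolates piecewise-linearly
        through ``points``.
    start, end : (z, x) in µm
        Chord endpoints (ignored for "points").
    amplitude, wavelength : float
        Sinusoid displacement amplitude and wavelength, µm.
    radius : float
        Vessel lumen radius, µm.
    peak_speed : float
        Centerline flow speed, mm/s (plug flow by default).
    flow_sign : int
        +1 for net flow away from the transducer (z increasing), -1 toward.
        For purely lateral vessels it selects the traversal orientation.
    bubble_rate : float
        Microbubble arrival rate, bubbles/s (Poisson).
    """

    kind: str = "straight"
    start: tuple[float, float] = (0.0, 0.0)
    end: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 0.0
    wavelength: float = 500.0
    points: list[tuple[float, float]] | None = None
    radius: float = 20.0
    peak_speed: float = 5.0
    flow_sign: int = 1
    bubble_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in _CENTERLINE_KINDS:
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")
        if self.flow_sign not in (-1, 1):
            raise ValueError("flow_sign must be +1 or -1")

    def polyline(self, step_um: float = 1.0) -> np.ndarray:
        """Densely sampled centerline, shape (n, 2) as (z, x) µm.

        Oriented so traversal matches ``flow_sign`` (net axial motion away
        from / toward the transducer where the chord has an axial component).
        """
        if self.kind == "points":
            pts = np.asarray(self.points, dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 2:
                raise ValueError("points centerline needs >= 2 control points")
            # resample each segment at ~step_um
            out = [pts[0]]
            for a, b in zip(pts[:-1], pts[1:]):
                n = max(2, int(np.ceil(np.hypot(*(b - a)) / step_um)) + 1)
                seg = np.linspace(a, b, n)[1:]
                out.append(seg)
            line = np.vstack([np.atleast_2d(p) for p in out])
        else:
            a = np.asarray(self.start, dtype=float)
            b = np.asarray(self.end, dtype=float)
            chord = b - a
            length = float(np.hypot(*chord))
            if length <= 0:
                raise ValueError("degenerate centerline: start == end")
            n = max(2, int(np.ceil(length / step_um)) + 1)
            t = np.linspace(0.0, 1.0, n)
            line = a[None, :] + t[:, None] * chord[None, :]
            if self.kind == "sinusoid":
                if self.amplitude < 0 or self.wavelength <= 0:
                    raise ValueError("sinusoid needs amplitude >= 0 and wavelength > 0")
                perp = np.array([-chord[1], chord[0]]) / length
                line = line + (self.amplitude * np.sin(2 * np.pi * t * length / self.wavelength))[:, None] * perp[None, :]
        dz_net = line[-1, 0] - line[0, 0]
        if dz_net != 0.0:
            if np.sign(dz_net) != self.flow_sign:
                line = line[::-1].copy()
        elif self.flow_sign < 0:
            line = line[::-1].copy()
        return line


@dataclass
class SceneConfig:
    """Scene content and imaging-degradation parameters.

    ``tissue_amplitude`` is linear relative to the unit microbubble peak
    amplitude (the default ~31.6 puts tissue 30 dB above bubbles).
    ``noise_depth_slope`` is in dB/mm of depth. ``seed`` fixes all randomness.
    """

    grid_shape: tuple[int, int] = (64, 64)
    vessels: list[VesselSpec] = field(default_factory=list)
    tissue_amplitude: float = 10 ** (30 / 20)
    tissue_motion_amplitude: float = 0.0
    noise_floor: float = 0.03
    noise_depth_slope: float = 1.0
    psf_sigma: tuple[float, float] = (60.0, 65.0)
    flow_profile: str = "plug"
    min_bubble_separation: float = 250.0  # µm along a vessel; ~2.5 lateral sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_amplitude < 0 or self.noise_floor < 0:
            raise ValueError("tissue_amplitude and noise_floor must be >= 0")
        if self.flow_profile not in ("plug", "parabolic"):
            raise ValueError("flow_profile must be 'plug' or 'parabolic'")


@dataclass
class GroundTruth:
    """Frame-resolution truth for one simulated acquisition.

    ``tracks`` maps track id -> array of (frame, z_um, x_um); ``vessel_of``
    maps track id -> vessel index.
    """

    tracks: dict[int, np.ndarray] = field(default_factory=dict)
    vessel_of: dict[int, int] = field(default_factory=dict)

    def to_records(self) -> np.ndarray:
        rows = []
        for tid, arr in self.tracks.items():
            for f, z, x in arr:
                rows.append((tid, int(f), z, x))
        return np.array(rows, dtype=float).reshape(-1, 4)


@dataclass
class SyntheticScene:
    """Scene geometry: rasterized masks and per-vessel analytics."""

    config: SceneConfig
    params: AcquisitionParams
    polylines: list[np.ndarray]
    vessel_masks: np.ndarray  # (n_vessels, sr_depth, sr_lateral) bool
    centerline_soam: list[float]  # deg/mm; 0 for straight vessels

    @property
    def mask(self) -> np.ndarray:
        """Union of vessel masks on the super-resolved grid."""
        if len(self.vessel_masks) == 0:
            shp = self.superres_shape
            return np.zeros(shp, dtype=bool)
        return self.vessel_masks.any(axis=0)

    @property
    def superres_shape(self) -> tuple[int, int]:
        fz, fx = self.params.upsampling_factor
        return (self.config.grid_shape[0] * fz, self.config.grid_shape[1] * fx)

    @property
    def extent_um(self) -> tuple[float, float]:
        pz, px = self.params.native_pixel
        return (self.config.grid_shape[0] * pz, self.config.grid_shape[1] * px)


def polyline_arclength(line: np.ndarray) -> np.ndarray:
    """Cumulative arc length (µm) along a polyline, starting at 0."""
    seg = np.hypot(*np.diff(line, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_soam(line: np.ndarray) -> float:
    """Sum-of-angles tortuosity of a polyline, degrees per mm of path."""
    v = np.diff(line, axis=0)
    lengths = np.hypot(v[:, 0], v[:, 1])
    keep = lengths > 0
    v = v[keep]
    lengths = lengths[keep]
    if len(v) < 2:
        return 0.0
    dot = np.sum(v[:-1] * v[1:], axis=1)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    path_mm = lengths.sum() / 1000.0
    return float(ang.sum() / path_mm)


def make_scene(config: SceneConfig, params: AcquisitionParams | None = None) -> SyntheticScene:
    """Build scene geometry and rasterize per-vessel masks on the super-resolved grid.

    Raises ``ValueError`` naming the first vessel whose centerline leaves the
    field of view.
    """
    params = params or AcquisitionParams()
    pz, px = params.native_pixel
    extent = (config.grid_shape[0] * pz, config.grid_shape[1] * px)
    fz, fx = params.upsampling_factor
    sr_shape = (config.grid_shape[0] * fz, config.grid_shape[1] * fx)
    sp = params.superres_pixel

    polylines: list[np.ndarray] = []
    masks = np.zeros((len(config.vessels),) + sr_shape, dtype=bool)
    soams: list[float] = []
    for i, vessel in enumerate(config.vessels):
        line = vessel.polyline()
        if (line[:, 0].min() < 0 or line[:, 0].max() > extent[0]
                or line[:, 1].min() < 0 or line[:, 1].max() > extent[1]):
            raise ValueError(
                f"vessel {i} centerline leaves the field of view "
                f"(extent {extent[0]:.0f} x {extent[1]:.0f} µm)"
            )
        polylines.append(line)
        # rasterize: mark centerline pixels, then threshold the distance transform
        on = np.zeros(sr_shape, dtype=bool)
        iz = np.clip(np.round(line[:, 0] / sp - 0.5).astype(int), 0, sr_shape[0] - 1)
        ix = np.clip(np.round(line[:, 1] / sp - 0.5).astype(int), 0, sr_shape[1] - 1)
        on[iz, ix] = True
        dist = distance_transform_edt(~on, sampling=(sp, sp))
        masks[i] = dist <= vessel.radius
        soams.append(0.0 if vessel.kind == "straight" else polyline_soam(line))
    return SyntheticScene(config=config, params=params, polylines=polylines,
                          vessel_masks=masks, centerline_soam=soams)


def _tissue_field(shape: tuple[int, int], rng: np.random.Generator,
                  correlation_px: float = 2.0) -> np.ndarray:
    """Spatially correlated unit-RMS complex field (speckle-like tissue)."""
    w = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    t = gaussian_filter(w.real, correlation_px) + 1j * gaussian_filter(w.imag, correlation_px)
    rms = np.sqrt(np.mean(np.abs(t) ** 2))
    return (t / rms).astype(np.complex128) if rms > 0 else t


def _fourier_shift(field: np.ndarray, shift_px: tuple[float, float]) -> np.ndarray:
    """Subpixel 2-D shift via Fourier phase ramp (periodic boundary)."""
    fz = np.fft.fftfreq(field.shape[0])
    fx = np.fft.fftfreq(field.shape[1])
    ramp = np.exp(-2j * np.pi * (shift_px[0] * fz[:, None] + shift_px[1] * fx[None, :]))
    return np.fft.ifft2(np.fft.fft2(field) * ramp)


def simulate_iq(scene: SyntheticScene, params: AcquisitionParams | None = None,
                n_frames: int = 256, seed: int = 0) -> tuple[IQStack, GroundTruth]:
    """Simulate one contrast-enhanced ultrafast acquisition.

    Bubbles arrive per vessel as a Poisson process (plus a steady-state
    population present at frame 0), are advected along the centerline at the
    vessel speed with a fixed perpendicular offset inside the lumen, and are
    rendered as the scene's Gaussian PSF times the depth-dependent carrier.
    Tissue and depth-graded circular white noise are added on top.

    Returns the IQ stack and the ground-truth tracks/masks.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    params = params or scene.params
    cfg = scene.config
    rng = np.random.default_rng(seed)
    nz, nx = cfg.grid_shape
    pz, px = params.native_pixel
    sig_z, sig_x = cfg.psf_sigma
    dt = 1.0 / params.frame_rate
    f0, c = params.center_frequency, params.sound_speed

    stack = np.zeros((nz, nx, n_frames), dtype=np.complex128)

    # --- microbubbles -------------------------------------------------------
    truth = GroundTruth()
    zg = (np.arange(nz) + 0.5) * pz  # native pixel centers, µm
    xg = (np.arange(nx) + 0.5) * px
    half_z = max(3, int(np.ceil(4 * sig_z / pz)))
    half_x = max(3, int(np.ceil(4 * sig_x / px)))
    next_tid = 0
    for vi, vessel in enumerate(cfg.vessels):
        if vessel.peak_speed <= 0 or vessel.bubble_rate <= 0:
            continue
        line = scene.polylines[vi]
        s_cum = polyline_arclength(line)
        length = s_cum[-1]
        speed_um_s = vessel.peak_speed * 1000.0
        if vessel.peak_speed / params.frame_rate * 1000.0 > 2 * max(sig_z, sig_x):
            warnings.warn(
                f"vessel {vi}: per-frame displacement exceeds the PSF width; "
                "frame-to-frame pairing may fail by design", stacklevel=2)
        transit = length / speed_um_s
        # steady-state population + fresh arrivals; arrivals closer along the
        # vessel than min_bubble_separation are thinned (microbubbles cannot
        # co-locate, and the localization model presumes sparse point targets)
        min_sep = cfg.min_bubble_separation
        starts: list[tuple[int, float]] = []  # (first frame, arc position at that frame)
        init_s = np.sort(rng.uniform(0, length,
                                     size=rng.poisson(vessel.bubble_rate * transit)))
        last_s = -np.inf
        for s0 in init_s:
            if s0 - last_s >= min_sep:
                starts.append((0, float(s0)))
                last_s = s0
        # plug flow preserves separations, so only the bubble nearest the
        # entrance (the most recently admitted one) gates new arrivals
        nearest = (0, float(init_s[0])) if len(starts) else None
        arrivals = rng.poisson(vessel.bubble_rate * dt, size=n_frames)
        for f in range(n_frames):
            for _ in range(arrivals[f]):
                s_new = float(rng.uniform(0, speed_um_s * dt))
                if nearest is not None:
                    f_prev, s_prev = nearest
                    ahead = s_prev + speed_um_s * dt * (f - f_prev)
                    if ahead - s_new < min_sep:
                        continue
                starts.append((f, s_new))
                nearest = (f, s_new)
        # unit tangent/normal along the line for lumen offsets
        tang = np.gradient(line, s_cum, axis=0)
        norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        nlen = np.hypot(norm[:, 0], norm[:, 1])
        nlen[nlen == 0] = 1.0
        norm /= nlen[:, None]
        for f_start, s_start in starts:
            offset = float(rng.uniform(-vessel.radius, vessel.radius))
            if cfg.flow_profile == "parabolic":
                speed_b = speed_um_s * max(0.0, 1.0 - (offset / vessel.radius) ** 2)
            else:
                speed_b = speed_um_s
            if speed_b <= 0:
                continue
            phase0 = float(rng.uniform(0, 2 * np.pi))
            frames = np.arange(f_start, n_frames)
            s_at = s_start + speed_b * dt * (frames - f_start)
            inside = s_at <= length
            frames, s_at = frames[inside], s_at[inside]
            if len(frames) == 0:
                continue
            cz = np.interp(s_at, s_cum, line[:, 0])
            cx = np.interp(s_at, s_cum, line[:, 1])
            oz = np.interp(s_at, s_cum, norm[:, 0]) * offset
            ox = np.interp(s_at, s_cum, norm[:, 1]) * offset
            bz, bx = cz + oz, cx + ox
            in_fov = (bz >= 0) & (bz < nz * pz) & (bx >= 0) & (bx < nx * px)
            if in_fov.sum() < 1:
                continue
            frames, bz, bx = frames[in_fov], bz[in_fov], bx[in_fov]
            truth.tracks[next_tid] = np.column_stack([frames, bz, bx])
            truth.vessel_of[next_tid] = vi
            next_tid += 1
            # render
            for f, z_b, x_b in zip(frames, bz, bx):
                iz = int(round(z_b / pz - 0.5))
                ix = int(round(x_b / px - 0.5))
                z0, z1 = max(0, iz - half_z), min(nz, iz + half_z + 1)
                x0, x1 = max(0, ix - half_x), min(nx, ix + half_x + 1)
                if z0 >= z1 or x0 >= x1:
                    continue
                env = np.exp(-((zg[z0:z1, None] - z_b) ** 2) / (2 * sig_z ** 2)
                             - ((xg[None, x0:x1] - x_b) ** 2) / (2 * sig_x ** 2))
                carrier = np.exp(1j * (phase0 - 4 * np.pi * f0 * (z_b * 1e-6) / c))
                stack[z0:z1, x0:x1, f] += env * carrier

    # --- tissue -------------------------------------------------------------
    if cfg.tissue_amplitude > 0:
        tissue = _tissue_field((nz, nx), rng) * cfg.tissue_amplitude
        if cfg.tissue_motion_amplitude > 0:
            t = np.arange(n_frames)
            drift_z = cfg.tissue_motion_amplitude * np.sin(2 * np.pi * t / n_frames) / pz
            drift_x = cfg.tissue_motion_amplitude * np.cos(2 * np.pi * t / n_frames) / px
            for f in range(n_frames):
                stack[:, :, f] += _fourier_shift(tissue, (drift_z[f], drift_x[f]))
        else:
            stack += tissue[:, :, None]

    # --- depth-graded noise -------------------------------------------------
    if cfg.noise_floor > 0:
        depth_mm = zg / 1000.0
        gain = cfg.noise_floor * 10 ** (cfg.noise_depth_slope * depth_mm / 20.0)
        w = (rng.standard_normal((nz, nx, n_frames))
             + 1j * rng.standard_normal((nz, nx, n_frames))) / np.sqrt(2)
        stack += gain[:, None, None] * w

    return IQStack(data=stack.astype(np.complex64), params=params), truth


# --- cohort presets ---------------------------------------------------------

#: multiplicative contrasts applied to the young preset to produce "aged"
AGED_FACTORS = {
    "cortical_vessel_count": 0.7,
    "speed": 0.8,
    "tortuosity": 1.5,  # centerline curvature scale (wavelength / sqrt(factor))
    "speed_sigma": 1.4,  # heavier-tailed lognormal speed assignment
}


def preset_cohort(group: str, seed: int = 0, grid_shape: tuple[int, int] = (64, 64),
                  factors: dict | None = None) -> SceneConfig:
    """Scene configuration for a synthetic "young" or "aged" subject.

    The scene has a cortical band of near-vertical penetrating vessels in the
    upper part of the field and a deep band of lateral sinusoidal vessels
    below it. Both groups share the same base layout for a given seed; the
    aged preset applies documented multiplicative contrasts: a subset of
    cortical vessels is dropped (count x0.7), every centerline's tortuosity
    is raised x1.5 (sinusoid wavelength shortened at constant amplitude, so
    vessel caliber and swept area stay comparable), and speeds are reshaped
    to a heavier-tailed distribution then rescaled so the aged group mean
    speed is exactly x0.8 the young group mean.
    """
    if group not in ("young", "aged"):
        raise ValueError(f"unknown cohort group {group!r}; expected 'young' or 'aged'")
    f = dict(AGED_FACTORS)
    if factors:
        f.update(factors)
    rng = np.random.default_rng(seed)
    params = AcquisitionParams()
    pz, px = params.native_pixel
    ez, ex = grid_shape[0] * pz, grid_shape[1] * px  # extent µm

    n_cortical_young = 10
    n_deep = 5
    sigma = 0.30

    # base layout, identical draws for both groups at a given seed; lateral
    # spacing keeps concurrent bubbles in adjacent vessels at least ~2.5
    # lateral sigma apart so their PSFs do not interfere
    xs = np.linspace(0.08 * ex, 0.92 * ex, n_cortical_young)
    jitter = rng.uniform(-0.02, 0.02, size=n_cortical_young) * ex
    base_speed_cort = 5.0 * np.exp(rng.normal(0, sigma, size=n_cortical_young))
    signs_cort = rng.choice([-1, 1], size=n_cortical_young)
    base_speed_deep = 8.0 * np.exp(rng.normal(0, sigma, size=n_deep))
    signs_deep = rng.choice([-1, 1], size=n_deep)
    n_cortical_aged = int(round(n_cortical_young * f["cortical_vessel_count"]))
    drop = rng.permutation(n_cortical_young)[n_cortical_aged:]

    aged = group == "aged"
    keep_cort = [i for i in range(n_cortical_young) if not (aged and i in drop)]
    young_mean = np.concatenate([base_speed_cort, base_speed_deep]).mean()
    speeds = np.concatenate([base_speed_cort[keep_cort], base_speed_deep])
    if aged:
        # heavier tail: exponentiate the lognormal draws, clip at the slowest
        # resolvable flow, then rescale so the aged group mean is exactly
        # f["speed"] x the young group mean (rescale last keeps the ratio
        # exact; the clip floor moves by at most a few percent)
        heavy = speeds ** f["speed_sigma"]
        target = f["speed"] * young_mean
        for _ in range(2):
            heavy = np.maximum(heavy * (target / heavy.mean()), 2.4)
        speeds = heavy * (target / heavy.mean())
    # sinusoid curvature scales with amplitude * (2 pi / wavelength)^2, so a
    # x1.5 tortuosity contrast shortens the wavelength by sqrt(1.5) while the
    # amplitude (and hence each vessel's swept band) stays fixed
    wl_scale = 1.0 / np.sqrt(f["tortuosity"]) if aged else 1.0

    vessels: list[VesselSpec] = []
    for j, i in enumerate(keep_cort):
        x = float(xs[i] + jitter[i])
        vessels.append(VesselSpec(
            kind="sinusoid", start=(0.10 * ez, x), end=(0.45 * ez, x),
            amplitude=15.0, wavelength=450.0 * wl_scale,
            radius=14.0, peak_speed=float(speeds[j]), flow_sign=int(signs_cort[i]),
            bubble_rate=2.5))
    zs = np.linspace(0.55 * ez, 0.90 * ez, n_deep)
    for j, z in enumerate(zs):
        vessels.append(VesselSpec(
            kind="sinusoid", start=(float(z), 0.06 * ex), end=(float(z), 0.94 * ex),
            amplitude=40.0, wavelength=700.0 * wl_scale,
            radius=18.0, peak_speed=float(speeds[len(keep_cort) + j]),
            flow_sign=int(signs_deep[j]), bubble_rate=3.0))
    return SceneConfig(grid_shape=grid_shape, vessels=vessels, seed=seed)
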