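"""PSF fitting, microbubble separation, spline upsampling, and per-frame localization.

The super-resolution step localizes bubbles by normalized 2-D
cross-correlation of the (magnitude) super-resolved frame with an
empirically fitted anisotropic Gaussian PSF; detections are the regional
maxima of the thresholded correlation map, one centroid per maximum at the
maximum's super-resolved pixel center.

High-concentration data are first diluted into sparser subsets with a
Fourier-domain separation bank: a partition-of-unity set of transfer
functions over temporal frequency (axial flow direction x Doppler speed
band), exactly invertible by summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .iq import IQStack
from .params import AcquisitionParams


@dataclass
class PSFModel:
    """Anisotropic Gaussian point-spread-function model.

    ``sigma_axial``/``sigma_lateral`` are in µm; ``support_sigmas`` sets the
    template half-width in units of sigma (>= 3 so the template captures the
    main lobe).
    """

    sigma_axial: float
    sigma_lateral: float
    amplitude: float = 1.0
    support_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma_axial <= 0 or self.sigma_lateral <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if self.support_sigmas < 3:
            raise ValueError("support must be >= 3 sigma in each axis")

    def template(self, pitch_um: float) -> np.ndarray:
        """Render the unit-amplitude PSF on a grid of the given pixel pitch."""
        hz = int(np.ceil(self.support_sigmas * self.sigma_axial / pitch_um))
        hx = int(np.ceil(self.support_sigmas * self.sigma_lateral / pitch_um))
        z = np.arange(-hz, hz + 1) * pitch_um
        x = np.arange(-hx, hx + 1) * pitch_um
        return np.exp(-(z[:, None] ** 2) / (2 * self.sigma_axial ** 2)
                      - (x[None, :] ** 2) / (2 * self.sigma_lateral ** 2))


def fit_psf(patch: np.ndarray, pitch_um: tuple[float, float]) -> PSFModel:
    """Least-squares separable Gaussian fit to an isolated-bubble patch.

    ``patch`` is a (magnitude or complex) image crop containing a single
    dominant peak; ``pitch_um`` is its (axial, lateral) pixel pitch.
    Raises ``ValueError`` when the fit residual exceeds 50% of the patch
    energy (the patch is not bubble-like).
    """
    mag = np.abs(np.asarray(patch, dtype=complex)).astype(float)
    if mag.ndim != 2 or min(mag.shape) < 3:
        raise ValueError("patch must be a 2-D crop of at least 3x3 pixels")
    energy = float(np.sum(mag ** 2))
    if energy == 0:
        raise ValueError("patch is all zeros: not a bubble-like patch")
    pz, px = pitch_um
    zc = (np.arange(mag.shape[0]) + 0.5) * pz
    xc = (np.arange(mag.shape[1]) + 0.5) * px
    Z, X = np.meshgrid(zc, xc, indexing="ij")

    iz, ix = np.unravel_index(np.argmax(mag), mag.shape)
    p0 = [float(mag.max()), zc[iz], xc[ix], max(pz, 0.3 * mag.shape[0] * pz / 3),
          max(px, 0.3 * mag.shape[1] * px / 3)]

    def model(coords, amp, z0, x0, sz, sx):
        z, x = coords
        return amp * np.exp(-((z - z0) ** 2) / (2 * sz ** 2) - ((x - x0) ** 2) / (2 * sx ** 2))

    try:
        popt, _ = curve_fit(model, (Z.ravel(), X.ravel()), mag.ravel(), p0=p0,
                            bounds=([0, zc[0] - pz, xc[0] - px, 1e-3, 1e-3],
                                    [np.inf, zc[-1] + pz, xc[-1] + px,
                                     mag.shape[0] * pz, mag.shape[1] * px]),
                            maxfev=20000)
    except RuntimeError as e:
        raise ValueError(f"PSF fit did not converge: {e}") from e
    resid = mag.ravel() - model((Z.ravel(), X.ravel()), *popt)
    if float(np.sum(resid ** 2)) > 0.5 * energy:
        raise ValueError("fit residual exceeds 50% of patch energy: not a bubble-like patch")
    return PSFModel(sigma_axial=float(popt[3]), sigma_lateral=float(popt[4]),
                    amplitude=float(popt[0]))


# --- separation filter ------------------------------------------------------

@dataclass
class SeparationBank:
    """Partition-of-unity bank of 3-D Fourier transfer functions.

    Each transfer function has the shape of the target stack's 3-D spectrum
    (depth, lateral, frames) with values in [0, 1]; the functions sum to 1
    at every frequency bin, so summing the filtered subsets restores the
    input exactly.
    """

    transfer: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transfer:
            raise ValueError("bank must contain at least one transfer function")
        total = sum(np.asarray(h, dtype=float) for h in self.transfer)
        for h in self.transfer:
            h = np.asarray(h)
            if h.min() < -1e-9 or h.max() > 1 + 1e-9:
                raise ValueError("transfer functions must lie in [0, 1]")
        if np.max(np.abs(total - 1.0)) > 1e-6:
            raise ValueError("bank is not a partition of unity (sum != 1)")


def default_bank(shape: tuple[int, int, int], params: AcquisitionParams,
                 speed_edge_mm_s: float = 5.0) -> SeparationBank:
    """Direction x speed-band bank: 4 subsets split on temporal-frequency sign
    (axial flow toward/away from the transducer) and on the Doppler band edge
    corresponding to ``speed_edge_mm_s``."""
    n_frames = shape[2]
    ft = np.fft.fftfreq(n_frames, d=1.0 / params.frame_rate)
    f_edge = 2.0 * params.center_frequency * (speed_edge_mm_s * 1e-3) / params.sound_speed
    pos = ft >= 0  # DC assigned to the positive-frequency side
    slow = np.abs(ft) < f_edge
    masks_1d = [pos & slow, pos & ~slow, ~pos & slow, ~pos & ~slow]
    transfer = [np.broadcast_to(m[None, None, :].astype(float), shape).copy()
                for m in masks_1d]
    return SeparationBank(transfer=transfer)


def make_bank(shape: tuple[int, int, int], params: AcquisitionParams,
              mode: str = "direction_speed", speed_edge_mm_s: float = 5.0) -> SeparationBank:
    """Build a separation bank by name.

    mode "none" -> single all-pass subset; "direction" -> 2 subsets split on
    temporal-frequency sign; "direction_speed" -> the 4-subset default of
    :func:`default_bank`.
    """
    if mode == "direction_speed":
        return default_bank(shape, params, speed_edge_mm_s)
    n_frames = shape[2]
    if mode == "none":
        return SeparationBank(transfer=[np.ones(shape)])
    if mode == "direction":
        ft = np.fft.fftfreq(n_frames, d=1.0 / params.frame_rate)
        pos = ft >= 0
        return SeparationBank(transfer=[
            np.broadcast_to(m[None, None, :].astype(float), shape).copy()
            for m in (pos, ~pos)])
    raise ValueError(f"unknown separation mode {mode!r}")


def separation_filter(stack: IQStack, bank: SeparationBank) -> list[IQStack]:
    """Split a stack into sparser subsets via the Fourier-domain bank.

    Each subset is the inverse 3-D FFT of (spectrum x transfer function);
    the subsets sum back to the input to within numerical precision.
    """
    spec = np.fft.fftn(stack.data.astype(np.complex128))
    out = []
    for h in bank.transfer:
        if h.shape != stack.data.shape:
            raise ValueError(f"transfer function shape {h.shape} != stack shape {stack.data.shape}")
        sub = np.fft.ifftn(spec * h)
        out.append(stack.with_data(sub.astype(np.complex64)))
    return out


# --- upsampling and localization -------------------------------------------

def upsample_frame(frame: np.ndarray, factor: int) -> np.ndarray:
    """Cubic-spline upsample of a frame's magnitude by an integer factor.

    The grids are registered so native pixel centers map exactly onto
    super-resolved pixel centers: native index i sits at super-resolved
    index i*factor + (factor-1)/2.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"upsampling factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    mag = np.abs(frame) if np.iscomplexobj(frame) else np.asarray(frame, dtype=float)
    if factor == 1:
        return mag.copy()
    nz, nx = mag.shape
    spl = RectBivariateSpline(np.arange(nz), np.arange(nx), mag, kx=3, ky=3)
    zq = (np.arange(nz * factor) + 0.5) / factor - 0.5
    xq = (np.arange(nx * factor) + 0.5) / factor - 0.5
    return spl(zq, xq)


@dataclass
class FrameLocalizations:
    """Detected bubble centroids for one frame.

    Positions are µm at super-resolved pixel centers; ``corr`` holds the
    normalized cross-correlation coefficient of each detection.
    """

    frame: int
    positions: np.ndarray  # (n, 2) as (z_um, x_um)
    corr: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.corr = np.asarray(self.corr, dtype=float).reshape(-1)


class CorrelationLocalizer:
    """Normalized cross-correlation detector with a cached template spectrum.

    Equivalent to correlating the frame with the PSF template under zero
    padding (coefficient in [-1, 1]); caching the template FFT makes
    per-frame correlation cheap when many frames share one shape.
    """

    def __init__(self, psf: PSFModel, frame_shape: tuple[int, int],
                 pitch_um: float = 4.928, corr_threshold: float = 0.5):
        from scipy import fft as sfft

        self.psf = psf
        self.pitch_um = pitch_um
        self.corr_threshold = corr_threshold
        tmpl = psf.template(pitch_um)
        if tmpl.shape[0] >= frame_shape[0] or tmpl.shape[1] >= frame_shape[1]:
            raise ValueError("PSF support must be smaller than the frame")
        self.tmpl_shape = tmpl.shape
        self.frame_shape = frame_shape
        self._fshape = tuple(sfft.next_fast_len(f + t - 1)
                             for f, t in zip(frame_shape, tmpl.shape))
        t0 = tmpl - tmpl.mean()
        self._tnorm = float(np.sqrt(np.sum(t0 ** 2)))
        self._n = tmpl.size
        # correlation = convolution with the flipped zero-mean template
        self._tf = sfft.rfft2(t0[::-1, ::-1], self._fshape)

    def correlate(self, frame: np.ndarray) -> np.ndarray:
        """Normalized correlation coefficient map, same shape as the frame."""
        from scipy import fft as sfft

        f = np.abs(frame) if np.iscomplexobj(frame) else np.asarray(frame, dtype=float)
        if f.shape != self.frame_shape:
            raise ValueError(f"frame shape {f.shape} != {self.frame_shape}")
        tz, tx = self.tmpl_shape
        num_full = sfft.irfft2(sfft.rfft2(f, self._fshape) * self._tf, self._fshape)
        z0, x0 = (tz - 1) // 2, (tx - 1) // 2
        num = num_full[z0:z0 + f.shape[0], x0:x0 + f.shape[1]]
        # local window sums via zero-padded integral images
        s1 = _window_sum(f, (tz, tx))
        s2 = _window_sum(f ** 2, (tz, tx))
        var = np.maximum(s2 - s1 ** 2 / self._n, 0.0)
        denom = np.sqrt(var) * self._tnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 1e-12 * self._tnorm ** 2 + 1e-30, num / denom, 0.0)
        return np.clip(corr, -1.0, 1.0)

    def localize(self, frame: np.ndarray, frame_index: int = 0,
                 min_amplitude: float | None = None,
                 refine: bool = False, refine_halfwidth: int = 8) -> FrameLocalizations:
        """Detect centroids on one frame.

        ``min_amplitude`` optionally rejects correlation peaks whose image
        amplitude falls below an absolute floor (normalized correlation is
        blind to amplitude, so PSF-shaped low-level residue would otherwise
        be detected alongside real bubbles). ``refine`` replaces each
        regional-maximum pixel center with the correlation-weighted centroid
        of its neighborhood (subpixel refinement; off by default).
        """
        mag = np.abs(frame) if np.iscomplexobj(frame) \
            else np.asarray(frame, dtype=float)
        if not np.any(mag):
            return FrameLocalizations(frame=frame_index, positions=np.empty((0, 2)),
                                      corr=np.empty(0))
        corr = self.correlate(mag)
        peaks = peak_local_max(corr, threshold_abs=self.corr_threshold,
                               exclude_border=False)
        if len(peaks) and min_amplitude is not None:
            keep = mag[peaks[:, 0], peaks[:, 1]] >= min_amplitude
            peaks = peaks[keep]
        if len(peaks) == 0:
            return FrameLocalizations(frame=frame_index, positions=np.empty((0, 2)),
                                      corr=np.empty(0))
        pos = (peaks + 0.5) * self.pitch_um
        if refine:
            w = refine_halfwidth
            excess = np.maximum(corr - self.corr_threshold, 0.0)
            for i, (iz, ix) in enumerate(peaks):
                z0, z1 = max(0, iz - w), min(corr.shape[0], iz + w + 1)
                x0, x1 = max(0, ix - w), min(corr.shape[1], ix + w + 1)
                win = excess[z0:z1, x0:x1]
                tot = win.sum()
                if tot <= 0:
                    continue
                zc = (np.arange(z0, z1) + 0.5) @ win.sum(axis=1) / tot
                xc = (np.arange(x0, x1) + 0.5) @ win.sum(axis=0) / tot
                pos[i] = (zc * self.pitch_um, xc * self.pitch_um)
        return FrameLocalizations(frame=frame_index, positions=pos,
                                  corr=corr[peaks[:, 0], peaks[:, 1]])


def _window_sum(image: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Sliding-window sum (zero padding outside), window centered per pixel."""
    wz, wx = window
    hz, hx = (wz - 1) // 2, (wx - 1) // 2
    pad = np.pad(image, ((hz + 1, wz - hz), (hx + 1, wx - hx)))
    ii = pad.cumsum(axis=0).cumsum(axis=1)
    nz, nx = image.shape
    return (ii[wz:wz + nz, wx:wx + nx] - ii[0:nz, wx:wx + nx]
            - ii[wz:wz + nz, 0:nx] + ii[0:nz, 0:nx])


def localize_frame(superres_frame: np.ndarray, psf: PSFModel, corr_threshold: float = 0.5,
                   pitch_um: float = 4.928, frame_index: int = 0) -> FrameLocalizations:
    """Detect bubble centroids on one super-resolved frame.

    Normalized 2-D cross-correlation with the PSF template, thresholding of
    the coefficient map, then regional maxima; each maximum contributes one
    centroid at its pixel center. An empty or featureless frame yields an
    empty localization list.
    """
    frame = np.abs(superres_frame) if np.iscomplexobj(superres_frame) \
        else np.asarray(superres_frame, dtype=float)
    loc = CorrelationLocalizer(psf, frame.shape, pitch_um, corr_threshold)
    return loc.localize(frame, frame_index)
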