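"""Spatiotemporal SVD clutter filtering and depth-noise equalization.

Tissue echoes are far stronger than microbubble signal but highly coherent
in space and time, so they concentrate in the leading singular components of
the Casorati (space x time) matrix. Zeroing a low-order block of singular
values removes the clutter; an adaptive elbow criterion on the log singular
spectrum chooses how many, typically in the 10-20 range on realistic scenes.
After filtering, a per-depth noise profile estimated from the trailing
(noise-dominated) singular components equalizes bubble intensity over depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .iq import IQStack


@dataclass
class SingularSpectrum:
    """Singular values of the Casorati matrix and the chosen low-order cutoff."""

    values: np.ndarray  # non-increasing, >= 0
    cutoff: int  # components 1..cutoff zeroed (cutoff == k)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12) or np.any(np.diff(v) > 1e-9 * max(v[0], 1.0)):
            raise ValueError("singular values must be non-negative and non-increasing")
        if not 0 <= self.cutoff < len(v):
            raise ValueError(f"cutoff {self.cutoff} outside [0, {len(v)})")
        self.values = v


@dataclass
class NoiseProfile:
    """Per-depth linear amplitude gain used for noise equalization."""

    gain: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if np.any(g <= 0):
            raise ValueError("noise profile must be strictly positive")
        self.gain = g


def adaptive_cutoff(singular_values: np.ndarray, clamp: tuple[int, int] = (5, 30)) -> int:
    """Choose the low-order cutoff k as the elbow of the log10 singular-value curve.

    The elbow is the index of maximum discrete curvature (second difference)
    of log10(sigma); the result is clamped to ``clamp``. A flat spectrum
    (no curvature maximum above numerical noise) returns the lower clamp
    with a warning.
    """
    s = np.asarray(singular_values, dtype=float)
    if len(s) < 10:
        raise ValueError("need at least 10 singular values")
    lo, hi = clamp
    hi = min(hi, len(s) - 1)
    lo = max(1, lo)
    y = np.log10(np.maximum(s, np.finfo(float).tiny * s.max() if s.max() > 0 else 1.0))
    curv = y[:-2] - 2 * y[1:-1] + y[2:]  # curvature at interior index i+1
    if len(curv) == 0 or np.ptp(curv) < 1e-9:
        warnings.warn("flat singular spectrum: no curvature elbow, using lower clamp",
                      stacklevel=2)
        return lo
    elbow = int(np.argmax(curv)) + 1
    return int(np.clip(elbow, lo, hi))


def svd_filter(stack: IQStack, cutoff: int | str = "adaptive",
               clamp: tuple[int, int] = (5, 30),
               upper_cutoff: int | None = None) -> tuple[IQStack, SingularSpectrum]:
    """Remove the low-order (tissue) singular components of the Casorati matrix.

    Parameters
    ----------
    stack : IQStack
        Input frames; at least 2 frames, finite values.
    cutoff : int or "adaptive"
        Number k of leading singular components to zero. "adaptive" picks k
        by :func:`adaptive_cutoff`.
    upper_cutoff : int, optional
        Additionally zero components with index > upper_cutoff (high-order
        noise truncation); off by default.

    Returns
    -------
    (filtered IQStack, SingularSpectrum)
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    X = stack.casorati().astype(np.complex128)
    if not np.all(np.isfinite(X.real)) or not np.all(np.isfinite(X.imag)):
        raise ValueError("stack contains non-finite values")
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    k = adaptive_cutoff(s, clamp=clamp) if cutoff == "adaptive" else int(cutoff)
    if k >= stack.n_frames or k >= len(s):
        raise ValueError(f"cutoff {k} >= number of components {len(s)}: nothing would remain")
    if k < 0:
        raise ValueError("cutoff must be >= 0")
    keep = s.copy()
    keep[:k] = 0.0
    if upper_cutoff is not None:
        keep[upper_cutoff:] = 0.0
    Xf = (U * keep) @ Vh
    filtered = stack.with_data(Xf.reshape(stack.data.shape).astype(np.complex64))
    return filtered, SingularSpectrum(values=s, cutoff=k)


def noise_equalization(stack: IQStack, signal_fraction: float = 0.10,
                       smooth_fraction: float = 0.05) -> tuple[IQStack, NoiseProfile]:
    """Equalize microbubble intensity over depth by dividing out the noise profile.

    The per-depth noise amplitude is estimated from a noise surrogate: the
    reconstruction from the trailing singular components (everything below
    the strongest ``signal_fraction`` of components, which carry bubble and
    residual-tissue energy), averaged (mean |.|) over lateral position and
    time, then smoothed by a moving window spanning ``smooth_fraction`` of
    the depth rows. The stack is divided row-wise by the profile, which is
    returned for audit.
    """
    X = stack.casorati().astype(np.complex128)
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    n_signal = max(1, int(round(signal_fraction * len(s))))
    tail = np.zeros_like(s)
    tail[n_signal:] = s[n_signal:]
    noise = ((U * tail) @ Vh).reshape(stack.data.shape)
    profile = np.abs(noise).mean(axis=(1, 2))
    win = max(1, int(round(smooth_fraction * stack.n_depth)))
    profile = uniform_filter1d(profile, size=win, mode="nearest")
    if np.any(profile <= 0):
        raise ValueError("noise profile contains zeros; cannot equalize")
    eq = stack.with_data((stack.data / profile[:, None, None]).astype(np.complex64))
    return eq, NoiseProfile(gain=profile)
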