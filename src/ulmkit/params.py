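"""Acquisition parameters shared across the pipeline.

Defaults mirror a high-frequency ultrafast mouse-brain protocol: 20 MHz
center frequency, 1000 Hz compounded frame rate, 1600 frames per
acquisition, 80 acquisitions, and a 4.928 µm isotropic super-resolved
grid obtained by ×10 spline upsampling of the native IQ grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class AcquisitionParams:
    """Physical and sampling constants of one contrast-enhanced acquisition.

    Attributes
    ----------
    center_frequency : float
        Transmit center frequency f0 in Hz.
    frame_rate : float
        Post-compounding frame rate (PRF of the slow-time ensemble), Hz.
    sound_speed : float
        Assumed tissue sound speed c, m/s.
    native_pixel : tuple of float
        (axial, lateral) pitch of the native IQ grid, µm per pixel.
    superres_pixel : float
        Isotropic pitch of the super-resolved grid, µm.
    frames_per_acquisition : int
        Slow-time ensemble length of one acquisition.
    n_acquisitions : int
        Number of acquisitions accumulated into a final reconstruction.
    """

    center_frequency: float = 2.0e7
    frame_rate: float = 1000.0
    sound_speed: float = 1540.0
    native_pixel: tuple[float, float] = (49.28, 49.28)
    superres_pixel: float = 4.928
    frames_per_acquisition: int = 1600
    n_acquisitions: int = 80

    def __post_init__(self) -> None:
        scalars = {
            "center_frequency": self.center_frequency,
            "frame_rate": self.frame_rate,
            "sound_speed": self.sound_speed,
            "superres_pixel": self.superres_pixel,
            "frames_per_acquisition": self.frames_per_acquisition,
            "n_acquisitions": self.n_acquisitions,
        }
        for name, v in scalars.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if len(self.native_pixel) != 2 or any(p <= 0 for p in self.native_pixel):
            raise ValueError(f"native_pixel must be two positive pitches, got {self.native_pixel!r}")
        for p in self.native_pixel:
            ratio = p / self.superres_pixel
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValueError(
                    "superres_pixel must divide native_pixel by an integer factor; "
                    f"got {p} / {self.superres_pixel} = {ratio}"
                )

    @property
    def upsampling_factor(self) -> tuple[int, int]:
        """Integer (axial, lateral) upsampling factor from native to super-resolved grid."""
        return (
            round(self.native_pixel[0] / self.superres_pixel),
            round(self.native_pixel[1] / self.superres_pixel),
        )

    @property
    def nyquist_velocity(self) -> float:
        """Maximum unambiguous axial velocity c·PRF/(4·f0), in mm/s."""
        return self.sound_speed * self.frame_rate / (4.0 * self.center_frequency) * 1e3

    def to_dict(self) -> dict:
        d = asdict(self)
        d["native_pixel"] = list(self.native_pixel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        if "native_pixel" in d:
            d["native_pixel"] = tuple(d["native_pixel"])
        return cls(**d)
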