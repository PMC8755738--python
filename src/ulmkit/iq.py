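"""The IQ frame-stack container and its HDF5 round trip.

An :class:`IQStack` holds complex beamformed in-phase/quadrature frames as a
``(depth, lateral, frames)`` array plus the acquisition metadata needed
downstream (center frequency for Doppler scaling, frame rate, pixel pitch).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .params import AcquisitionParams


@dataclass
class IQStack:
    """Complex beamformed frame stack.

    ``data`` has shape (depth, lateral, frames); axial depth z grows away
    from the transducer along axis 0. Positions are reported in µm at pixel
    centers, row-major (z, x), 0-based.
    """

    data: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"IQStack data must be 3-D (depth, lateral, frames), got shape {self.data.shape}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex64)

    @property
    def n_depth(self) -> int:
        return self.data.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def casorati(self) -> np.ndarray:
        """Space-vectorized × time (Casorati) view, shape (depth*lateral, frames)."""
        return self.data.reshape(self.n_depth * self.n_lateral, self.n_frames)

    def with_data(self, data: np.ndarray) -> "IQStack":
        return IQStack(data=data, params=self.params)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the stack to an HDF5 file (dataset "iq" + params as attributes)."""
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("iq", data=self.data.astype(np.complex64))
            for k, v in self.params.to_dict().items():
                ds.attrs[k] = v

    @classmethod
    def load(cls, path: str | Path) -> "IQStack":
        with h5py.File(path, "r") as f:
            ds = f["iq"]
            data = ds[...]
            attrs = {k: ds.attrs[k] for k in ds.attrs}
            attrs["native_pixel"] = tuple(float(p) for p in attrs["native_pixel"])
            for k in ("frames_per_acquisition", "n_acquisitions"):
                if k in attrs:
                    attrs[k] = int(attrs[k])
            for k in ("center_frequency", "frame_rate", "sound_speed", "superres_pixel"):
                if k in attrs:
                    attrs[k] = float(attrs[k])
        return cls(data=data, params=AcquisitionParams(**attrs))
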