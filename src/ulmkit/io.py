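"""Plain-text and image export/import helpers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from .clutter import NoiseProfile, SingularSpectrum
from .localization import FrameLocalizations
from .mapping import ULMImage
from .synthetic import GroundTruth
from .tracking import TrackSet, track_summary


def save_ulm_image(image: ULMImage, path: str | Path) -> None:
    """Write the density/speed/direction channels as a multi-page float32 TIFF."""
    pages = np.stack([image.density.astype(np.float32),
                      np.nan_to_num(image.speed).astype(np.float32),
                      np.nan_to_num(image.direction).astype(np.float32)])
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata={"axes": "CYX", "pitch_um": image.pitch_um})


def render_ulm_png(image: ULMImage, path: str | Path) -> None:
    """Render a log-compressed density map to PNG for quick inspection."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.log1p(image.density), cmap="inferno", interpolation="nearest")
    ax.set_title("ULM density (log1p traversals)")
    ax.set_xlabel("lateral [px]")
    ax.set_ylabel("depth [px]")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8))


def tracks_to_frame(trackset: TrackSet, frame_rate: float = 1000.0) -> pd.DataFrame:
    """Long-format per-sample track table (track_id, frame, z_um, x_um)."""
    rows = []
    for t in trackset:
        for f, (z, x) in zip(t.frames, t.positions):
            rows.append((t.track_id, int(f), z, x))
    return pd.DataFrame(rows, columns=["track_id", "frame", "z_um", "x_um"])


def save_tracks_csv(trackset: TrackSet, path: str | Path,
                    frame_rate: float = 1000.0) -> None:
    tracks_to_frame(trackset, frame_rate).to_csv(path, index=False)


def save_track_summary_csv(trackset: TrackSet, path: str | Path,
                           frame_rate: float = 1000.0) -> None:
    pd.DataFrame(track_summary(trackset, frame_rate)).to_csv(path, index=False)


def save_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    rec = truth.to_records()
    pd.DataFrame(rec, columns=["track_id", "frame", "z_um", "x_um"]).to_csv(
        path, index=False)


def save_localizations_csv(locs: list[FrameLocalizations], path: str | Path) -> None:
    rows = [(fl.frame, z, x, c)
            for fl in locs for (z, x), c in zip(fl.positions, fl.corr)]
    pd.DataFrame(rows, columns=["frame", "z_um", "x_um", "corr"]).to_csv(
        path, index=False)


def save_spectrum_csv(spectrum: SingularSpectrum, path: str | Path) -> None:
    pd.DataFrame({"index": np.arange(1, len(spectrum.values) + 1),
                  "singular_value": spectrum.values,
                  "zeroed": np.arange(1, len(spectrum.values) + 1) <= spectrum.cutoff
                  }).to_csv(path, index=False)


def save_noise_profile_csv(profile: NoiseProfile, path: str | Path) -> None:
    pd.DataFrame({"depth_row": np.arange(len(profile.gain)),
                  "gain": profile.gain}).to_csv(path, index=False)


# --- ROI geometry text files -------------------------------------------------

def save_roi_geometry(rois: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named polygons as a plain-text geometry file.

    Format: one block per ROI — a line ``# name`` followed by ``z_um x_um``
    vertex lines.
    """
    with open(path, "w") as fh:
        for name, verts in rois.items():
            fh.write(f"# {name}\n")
            for z, x in np.asarray(verts, dtype=float).reshape(-1, 2):
                fh.write(f"{z:.6g} {x:.6g}\n")


def load_roi_geometry(path: str | Path) -> dict[str, np.ndarray]:
    rois: dict[str, list] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            name = line[1:].strip()
            rois[name] = []
        else:
            if name is None:
                raise ValueError("vertex line before any ROI name")
            z, x = line.split()
            rois[name].append((float(z), float(x)))
    return {k: np.asarray(v, dtype=float) for k, v in rois.items()}
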