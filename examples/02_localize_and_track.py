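"""Localize microbubbles on the super-resolved grid and link them into tracks.

Runs the full per-acquisition reconstruction (filter, upsample, correlate,
link, 20-frame length filter) on a simulated plug-flow vessel and compares
the recovered track speeds with the simulated flow speed.
"""

import numpy as np

from ulmkit import (AcquisitionParams, PipelineConfig, SceneConfig, VesselSpec,
                    make_scene, simulate_iq, track_soam, track_velocity)
from ulmkit.pipeline import reconstruct_acquisition

params = AcquisitionParams()
scene = make_scene(SceneConfig(
    grid_shape=(32, 48),
    vessels=[VesselSpec(kind="straight", start=(800.0, 100.0),
                        end=(800.0, 2260.0), radius=12.0, peak_speed=5.0,
                        flow_sign=1, bubble_rate=8.0)],
    tissue_amplitude=0.0, noise_floor=0.0), params)
stack, truth = simulate_iq(scene, params, n_frames=300, seed=11)

config = PipelineConfig(separation_mode="none", equalize_noise=False,
                        svd_cutoff=0, corr_threshold=0.65, max_speed_mm_s=25.0)
tracks, counts = reconstruct_acquisition(stack, config)

print(f"detections: {counts['detections']}, tracks: {counts['tracks']}, "
      f"surviving 20-frame filter: {counts['tracks_after_length_filter']}")
speeds = [track_velocity(t, params.frame_rate)[1] for t in tracks]
soams = [track_soam(t)[0] for t in tracks if len(t) >= 3]
print(f"recovered mean speed {np.mean(speeds):.2f} mm/s (simulated: 5.00 mm/s)")
print(f"mean SOAM {np.mean(soams):.0f} deg/mm (straight vessel; residual is "
      "localization jitter)")
# Expected: mean speed within a few percent of 5 mm/s; SOAM well below a
# tortuous vessel's (compare with examples/04).
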