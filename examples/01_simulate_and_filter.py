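"""Simulate a contrast-enhanced acquisition and remove tissue clutter.

Builds a two-vessel scene with tissue 30 dB above the microbubbles, runs the
spatiotemporal SVD filter with the adaptive cutoff, and reports how much
tissue energy was removed.
"""

import numpy as np

from ulmkit import (AcquisitionParams, SceneConfig, VesselSpec, make_scene,
                    noise_equalization, simulate_iq, svd_filter)

params = AcquisitionParams()
scene = make_scene(SceneConfig(
    grid_shape=(48, 48),
    vessels=[
        VesselSpec(kind="straight", start=(600.0, 200.0), end=(600.0, 2100.0),
                   radius=15.0, peak_speed=6.0, flow_sign=1, bubble_rate=5.0),
        VesselSpec(kind="sinusoid", start=(1600.0, 200.0), end=(1600.0, 2100.0),
                   amplitude=60.0, wavelength=700.0,
                   radius=18.0, peak_speed=9.0, flow_sign=-1, bubble_rate=5.0),
    ],
    tissue_amplitude=10 ** (30 / 20),  # tissue 30 dB above bubble peak
), params)

stack, truth = simulate_iq(scene, params, n_frames=200, seed=7)
filtered, spectrum = svd_filter(stack, cutoff="adaptive", clamp=(1, 30))
equalized, profile = noise_equalization(filtered)

e_in = np.sum(np.abs(stack.data) ** 2)
e_out = np.sum(np.abs(filtered.data) ** 2)
print(f"simulated {stack.n_frames} frames, {len(truth.tracks)} true bubble tracks")
print(f"adaptive cutoff removed the first {spectrum.cutoff} singular value(s)")
print(f"stack energy reduced by {10 * np.log10(e_in / e_out):.1f} dB "
      "(dominated by tissue clutter)")
print(f"noise profile spans {profile.gain.min():.4f}..{profile.gain.max():.4f} "
      "(linear amplitude vs depth row)")
# Expected: cutoff 1-3 (static tissue is low-rank), energy drop near the 30 dB
# tissue excess, and a noise profile growing with depth.
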