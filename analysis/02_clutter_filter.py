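#!/usr/bin/env python
"""SVD clutter filtering of the simulated acquisition.

Reshapes the IQ stack into its Casorati matrix, picks the tissue cutoff
adaptively at the knee of the log singular-value spectrum, zeroes the
low-order components, equalizes depth-dependent noise against a
noise-only reference, and accumulates the diffraction-limited contrast
power image.  Reports the chosen cutoff (expected in the 10–20 range for
this clutter regime) and the bubble-recovery fidelity against the
rendered ground truth.

Reads results/scene/, writes results/filtering/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from camulm.config import SceneConfig
from camulm.iq import IQEnsemble
from camulm.scene import synthesize_noise_reference
from camulm.svdfilter import (apply_noise_equalization, estimate_noise_profile,
                              power_doppler, svd_clutter_filter)

IN, OUT = Path("results/scene"), Path("results/filtering")
OUT.mkdir(parents=True, exist_ok=True)

iq = IQEnsemble.load(IN / "iq.h5")
truth = IQEnsemble.load(IN / "iq_bubbles_truth.h5")
cfg = SceneConfig.from_dict(json.load(open(IN / "scene_config.json")))

filtered, spectrum = svd_clutter_filter(iq, cutoff="adaptive")
print(f"adaptive cutoff: {spectrum.cutoff} singular values zeroed "
      f"(in vivo acquisitions typically need 10-20)")

ref = synthesize_noise_reference(cfg)
profile = estimate_noise_profile(ref, filtered, cutoff=spectrum.cutoff)
equalized = apply_noise_equalization(filtered, profile)

b, f = truth.data.ravel(), filtered.data.ravel()
corr = np.abs(np.vdot(b, f)) / (np.linalg.norm(b) * np.linalg.norm(f))
print(f"bubble-stack recovery correlation vs ground truth: {corr:.3f}")

equalized.save(OUT / "iq_filtered.h5")
pd.DataFrame({"singular_value": spectrum.values}).to_csv(
    OUT / "singular_values.csv", index_label="index")
power = power_doppler(equalized)
tifffile.imwrite(OUT / "power.tiff", power.astype(np.float32))
with open(OUT / "summary.json", "w") as fjson:
    json.dump({"cutoff": spectrum.cutoff, "recovery_correlation": float(corr)},
              fjson, indent=2)
print(f"wrote {OUT}/iq_filtered.h5, power.tiff, singular_values.csv")
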