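#!/usr/bin/env python
"""Cohort-level treatment-response statistics.

Builds a synthetic longitudinal cohort: every tumor gets a chaotic vessel
network at baseline; at endpoint the anti-angiogenic arms (sorafenib,
combination) switch to the pruned-with-avascular-region morphology while
control and chemo-only keep chaotic growth.  Vascular metrics are read
off the ground-truth network rasters, then:

  * endpoint H-scores (script 05) are compared across arms by one-way
    ANOVA with Tukey HSD pairwise correction, and
  * the longitudinal intervessel-distance response is tested by ANCOVA
    (endpoint ~ baseline + arm).

Writes results/stats/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from camulm.config import SceneConfig
from camulm.metrics import intervessel_distance
from camulm.roi import roi_from_control_points
from camulm.scene import generate_vessel_network
from camulm.stats import ancova_longitudinal, anova_tukey

OUT = Path("results/stats")
OUT.mkdir(parents=True, exist_ok=True)

ARMS = {"control": "chaotic", "sorafenib": "pruned",
        "folfox": "chaotic", "combination": "pruned"}
N_PER_ARM = 6
PITCH_UM = 20.0


def network_density(morphology: str, seed: int) -> np.ndarray:
    cfg = SceneConfig(field_depth_mm=1.5, field_width_mm=2.0, branching_depth=3,
                      morphology=morphology, seed=seed)
    net = generate_vessel_network(cfg)
    shape = (int(1.5 * 1000 / PITCH_UM) + 1, int(2.0 * 1000 / PITCH_UM) + 1)
    density = np.zeros(shape, dtype=int)
    for seg in net.segments:
        for a, b in zip(seg[:-1], seg[1:]):
            n = max(int(np.hypot(*(b - a)) * 1000 / PITCH_UM) * 2, 2)
            for f in np.linspace(0, 1, n):
                p = a + f * (b - a)
                density[int(round(p[0] * 1000 / PITCH_UM)),
                        int(round(p[1] * 1000 / PITCH_UM))] = 1
    return density


ROI = roi_from_control_points(
    np.array([[0.1, 0.1], [0.1, 1.9], [1.4, 1.9], [1.4, 0.1]]))

rows = []
for a, (arm, endpoint_morph) in enumerate(ARMS.items()):
    for k in range(N_PER_ARM):
        tumor = f"{arm[:4]}{k:02d}"
        # same seed at both timepoints: the endpoint is the same tumor's
        # network, pruned (or not) by treatment — the longitudinal design
        # the ANCOVA is built for
        seed = 10000 * a + 100 * k
        for timepoint, morph in (("baseline", "chaotic"), ("endpoint", endpoint_morph)):
            density = network_density(morph, seed)
            ivd = intervessel_distance(density, ROI, PITCH_UM)["mean_um"]
            rows.append({"tumor_id": tumor, "arm": arm, "timepoint": timepoint,
                         "intervessel_distance_um": ivd})

cohort = pd.DataFrame(rows)
cohort.to_csv(OUT / "cohort.csv", index=False)
print(cohort.groupby(["arm", "timepoint"])["intervessel_distance_um"]
      .mean().round(1).unstack())

# longitudinal ANCOVA on intervessel distance
wide = cohort.pivot_table(index=["tumor_id", "arm"], columns="timepoint",
                          values="intervessel_distance_um").reset_index()
anc = ancova_longitudinal(wide["endpoint"], wide["baseline"], wide["arm"])
print(f"\nANCOVA arm effect on intervessel distance: "
      f"F = {anc.f_statistic:.2f}, p = {anc.p_value:.2e}")
print("adjusted endpoint means (um):")
print(anc.adjusted_means.round(1))

# endpoint ANOVA + Tukey on the H-scores from script 05
results = {"ancova_intervessel": {"F": anc.f_statistic, "p": anc.p_value,
                                  "adjusted_means": anc.adjusted_means.to_dict()}}
h_path = Path("results/histology/h_scores.csv")
if h_path.exists():
    h = pd.read_csv(h_path)
    av = anova_tukey(h["h_score"].to_numpy(), h["arm"].to_numpy())
    print(f"\nANOVA on H-scores: F = {av.f_statistic:.2f}, p = {av.p_value:.2e}")
    print(av.pairwise.to_string(index=False))
    results["anova_h_score"] = {
        "F": av.f_statistic, "p": av.p_value,
        "pairwise": av.pairwise.to_dict(orient="records")}
else:
    print("\n(run 05_histology_quant.py first for the H-score ANOVA)")

with open(OUT / "stats.json", "w") as f:
    json.dump(results, f, indent=2, default=float)
print(f"\nwrote {OUT}/cohort.csv, stats.json")
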