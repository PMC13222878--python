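"""Quantify enzyme-activity hotspots on a synthetic soil zymogram.

Generates a membrane image with a known root footprint, calibrates grey
values to activity, applies the mean+2SD hotspot rule and summarises
activity per root compartment.
"""

import numpy as np

from rhizonet import (
    compartment_stats,
    detect_hotspots,
    fit_calibration,
    generate_zymogram,
    grey_to_activity,
    segment_compartments,
)

zymogram, truth = generate_zymogram(shape=(128, 128), seed=1,
                                    background_mean=100, background_sd=5,
                                    hotspot_gain=50, band_width_px=3)

# calibration standards: (known activity in nmol cm^-2 h^-1, observed grey)
curve = fit_calibration([(0, 100), (200, 300), (400, 500)])
activity = grey_to_activity(zymogram, curve)

roi = np.ones(zymogram.image.shape, bool)
hot = detect_hotspots(zymogram, roi)
masks = segment_compartments(truth.root_mask, band_width_px=3, roi=roi)
stats = compartment_stats(activity, masks, zymogram)

recall = (hot.mask & truth.hotspot_mask).sum() / truth.hotspot_mask.sum()
print(f"hotspot threshold (grey): {hot.threshold:.2f}")
print(f"%hotspot area (whole membrane): {hot.percent_area:.2f}%  "
      f"(recall vs planted truth: {recall:.3f})")
for name in ("rhizoplane", "rhizosphere", "background"):
    s = stats[name]
    print(f"{name:>12}: activity {s['mean_activity']:.1f} ± {s['sd_activity']:.1f} "
          f"nmol cm^-2 h^-1, hotspots {s['percent_hotspot']:.1f}%")
print("Activity is highest on the root surface (rhizoplane) and decays into "
      "the surrounding soil — the spatial pattern zymography is designed to show.")
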