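"""Full TDS pipeline on a synthetic two-band measurement.

Builds a scene with an uncoupled-amide band (TDS 0.12 D^2) and a long-helix
band (0.26 D^2), generates the linear OD, pump, 2D IR and calibrant spectra,
then runs the analysis: airPLS baseline correction, diagonal slice,
calibrant normalization, and per-window peak read-out.
"""

import numpy as np

from tdspec import BandSpec, SceneSpec, compute_tds, generate_measurement, peak_tds

scene = SceneSpec(
    bands=(BandSpec(center=1618.0, fwhm=20.0, od_amplitude=4.0, tds=0.12),
           BandSpec(center=1662.0, fwhm=24.0, od_amplitude=5.0, tds=0.26)),
    baseline_poly=(0.05, 3e-4),          # sloped background in OD units
    axis=(1560.0, 1740.0, 1.0),
)
m = generate_measurement(scene)
result = compute_tds(m["sample_2d"], m["sample_od"], m["cal_2d"],
                     m["cal_od"], m["pump"])

print(f"calibrant band maximum: {result.calibrant.omega_max:.0f} cm^-1, "
      f"|mu|^2 = {result.calibrant.mu_sq} D^2")
print("recovered per-mode TDS (vs ground truth):")
for band in scene.bands:
    pk = peak_tds(result.tds, (band.center - 5, band.center + 5),
                  reference=result.sample_diagonal)
    truth = float(np.interp(pk.omega, scene.grid(), m["truth_tds"]))
    print(f"  mode at {pk.omega:6.1f} cm^-1: d = {pk.tds:.4f} D^2 "
          f"(truth {truth:.4f}, error {100 * abs(pk.tds / truth - 1):.2f}%)")
print("\nThe 0.12 D^2 mode reads as uncoupled/disordered; the 0.26 D^2 mode "
      "corresponds to a ~21-residue helix on the calibration line.")
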