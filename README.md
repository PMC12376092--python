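# tdspec

Transition-dipole-strength (TDS) analysis of two-dimensional infrared
(2D IR) protein spectra, for vibrational spectroscopists studying protein
secondary structure: TDS spectra from 2D IR + linear IR measurements,
airPLS baseline correction, circular-dichroism (CD) percent helicity, and
the linear TDS-vs-helix-length calibration that predicts the longest
α-helix in a protein from a single measured number.

## The science

A linear IR signal scales with the squared transition dipole |μ|² of a
vibrational mode, while a 2D IR signal scales with |μ|⁴.  Their ratio
therefore isolates |μ|² — the transition dipole strength — independent of
concentration, path length and beam overlap.  With an uncoupled-amide
calibrant (N-methylacetamide, |μ|² = 0.12 D²) and the pump spectrum
I_pump(ω), the TDS spectrum is

    d(ω) = |ΔOD_s(ω,ω)| / OD_s(ω)
         · OD_c(ω_max) / |ΔOD_c(ω_max,ω_max)|
         · I_pump(ω_max) / I_pump(ω)
         · |μ_calibrant|²

where ΔOD(ω,ω) is the diagonal slice of the 2D spectrum and OD the
baseline-corrected linear optical density (airPLS — adaptive iteratively
reweighted penalized least squares — handles the baseline).

Backbone amide I′ oscillators in a continuous α-helix couple, delocalizing
the vibration and raising the apparent TDS linearly with helix length.
Model [EK]_N peptides of CD-derived helicity anchor the calibration line
`TDS = b + m·L`; inverting it at a protein's measured amide I′ TDS predicts
the length L of its *longest* helix (delocalization tracks the longest
continuous stretch, not the average).

CD helicity uses the standard two-point estimate: mean residue ellipticity
[θ] = θ/(l·C·n) (θ in mdeg, l in mm, C in mol/L, n residues), the
length-dependent theoretical maximum [θ]_H = −40000·(1 − x/n) + 100·T, and
% helicity = 100·[θ]₂₂₂/[θ]_H.

A synthetic-data module generates linear OD, pump, 2D IR and CD spectra
with known ground truth (band TDS profiles, baselines, noise) by inverting
the TDS relation, so the whole pipeline is testable without experimental
data.

## Worked example

```sh
python examples/predict_helix_length.py
```

```
fit: TDS = 0.1220 + 0.00667 * L   (r^2 = 0.981)

predicted longest alpha-helix:
  HEWL                 TDS 0.21 D^2 ->  13.2 +/- 0.8 residues
  Myo                  TDS 0.30 D^2 ->  26.7 +/- 1.8 residues  (extrapolated)
  BLG helix shoulder   TDS 0.20 D^2 ->  11.7 +/- 0.8 residues
  AKA                  TDS 0.26 D^2 ->  20.7 +/- 1.3 residues  (extrapolated)
  rIAPP (membrane)     TDS 0.20 D^2 ->  11.7 +/- 0.8 residues
```

The fit is ordinary least squares through the four [EK]_N calibration
points; each prediction inverts the line at the protein's measured TDS and
carries first-order propagated uncertainty.  Lysozyme's 13.2 residues
matches the longest of its four helices; myoglobin's 26.7 the longest of
its eight — the TDS reports the longest helix even when many helices
overlap in the spectrum.  Other examples: `examples/tds_pipeline.py`
(full synthetic 2D IR → TDS round trip), `examples/cd_helicity.py`,
`examples/baseline_correction.py`.

A thin CLI mirrors the library (`tds compute`, `tds helicity`,
`tds calibrate`, `tds predict-helix`, `tds simulate`); see `tds --help`.

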