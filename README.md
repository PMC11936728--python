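# capflow

Quantitative analysis of cortical capillary flow dynamics from optical
imaging: capillary **stall statistics** from OCT-angiography time
series, **single-capillary velocimetry** (RBC velocity, cell flux,
diameter) from two-photon line scans, **mean transit time (MTT) and
capillary transit-time heterogeneity (CTH)** from indicator-dilution
deconvolution, **pO₂ / SO₂ / oxygen extraction fraction** from
phosphorescence lifetimes, and **vessel & amyloid-plaque
morphometrics** from segmented 3-D volumes.

The package is aimed at labs studying capillary dysfunction in models
of Alzheimer's disease and related small-vessel pathology, where the
readouts above — stalled capillary segments, heterogeneous transit
times, altered diameters — precede symptomatic decline. A synthetic-
data module generates every input with known ground truth, so each
stage is validated by parameter recovery.

## The models at the core

* **Stall-o-gram statistics.** OCT-A contrast requires moving
  scatterers, so a stalled capillary disappears for whole acquisition
  volumes (8.5 s each, 60 per recording). From the binary
  segments x volumes raster: incidence rate (fraction of examined
  capillaries that ever stall), point prevalence (mean stalled
  fraction per volume), and cumulative stall time (stalled fraction of
  total scan time per segment).
* **Gamma transport function.** The venous dye curve is the arterial
  curve convolved with an f-scaled gamma density h(t; α, β):
  `MTT = α·β`, `CTH = √α·β`, `RTH = CTH/MTT = 1/√α`. Fits are QC'd on
  R² and detector saturation and verified by time-shifting the VOF
  back by the fitted MTT.
* **Radon velocimetry.** In axial space-time line-scan images red
  cells are dark streaks; per 150 ms window the streak angle maximizes
  the variance of the Radon projection, and `v = tan(θ)·pixel/period`.
* **Lifetime oximetry.** Phosphorescence decays fit a·exp(−t/τ) + b;
  τ converts to pO₂ through a Stern–Volmer or tabulated calibration,
  pO₂ to SO₂ through a Hill curve, and arterial/venous pairs give
  `OEF = (Sa − Sv)/Sa`.
* **Morphometrics.** Segment diameter is twice the mean skeleton-to-
  boundary distance (anisotropic EDT); capillaries are segments
  ≤ 9.2 µm; tortuosity is arc/chord; plaques are 26-connected 3-D
  objects with volumes, densities and burden.

See `docs/methods.md` for assumptions, parameter defaults and
numerical choices.

## Worked example

Simulate a full synthetic dataset and run two stages on it:

```bash
echo "{}" > config.yaml
capflow simulate --config config.yaml --seed 3 --out sim/
capflow stalls sim/angiogram_series.tif sim/segment_labels.tif --out-prefix stall
capflow dilution sim/bolus_pair.csv --out fit.json
capflow linescan sim/linescan_axial.tif sim/linescan_transverse.tif \
    --pixel-size 0.23 --line-period 1.0 --out flow.csv
```

prints

```
5 stalling segments / 50 examined (incidence 10.0%)
MTT=2.000 s CTH=1.000 s (accepted=True)
v=1.002 mm/s, flux=80.0 cells/s, d=4.83 µm
```

Reading the numbers: 5 of the 50 simulated capillary segments stalled
at least once during the 60-volume recording (10% incidence). The
dilution fit recovered the generator's transport function (α = 4,
β = 0.5 s → MTT = 2.0 s, CTH = 1.0 s) and passed QC. The line-scan
stage recovered the simulated 1.0 mm/s red-cell velocity within 0.2%,
the 80 cells/s flux exactly, and the 5 µm diameter within 0.2 µm.

The same operations are available as library calls
(`capflow.stalls.stall_metrics`, `capflow.dilution.fit_transport`,
`capflow.linescan.radon_velocity`, ...), which is the intended
interface for scripted analyses.

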