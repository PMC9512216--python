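# plumetrack

Measure the impulse dispersion of exhaled vapor clouds from multi-view video,
and compare the acoustic effect of instrument safety devices via long-term
average spectra (LTAS).

A spotlit white vapor cloud on a dark studio background is filmed by a
side-view camera (`C1_side`: frontal x and vertical z) and a top-view camera
(`C3_top`: lateral y, reported as a diameter). The pipeline:

1. **simulate** — render synthetic ground-truthed two-view footage
   (`plumetrack.simulate`), so every stage is testable without studio data.
2. **preprocess** — load PNG stacks / AVI, optional photographic negative,
   polygon exclusion masking of body parts and stray clouds
   (`plumetrack.frames`).
3. **segment** — per-frame global threshold (fixed or Otsu with a clamp) plus
   small-component removal (`plumetrack.segmentation`).
4. **track** — scale-bar calibration and per-frame metric extents from the
   mouth origin, with t = 0 at the task-end frame (`plumetrack.geometry`).
5. **smooth** — moving median (window 30) then cubic-spline smoothing through
   subsampled knots (`plumetrack.smoothing`).
6. **summarize** — cross-subject medians/maxima at 0/3/10 s, per-direction
   median curves, and the inclusive ±0.1 m HIGHER/LOWER/COMPARABLE comparison
   markup against reference tasks (`plumetrack.summary`).
7. **ltas** — Hanning/512-point Welch-averaged spectra, dB re spectrum
   maximum with a −110 dB floor, averaging across players and spectral MSE
   (`plumetrack.acoustics`).

`plumetrack.reference_data` bundles a published summary table (six tasks ×
two dimensions × median/maximum × 0/3/10 s, with printed comparison marks)
used as the worked-example dataset for the markup classifier.

## CLI

```sh
plumetrack simulate   --config scenario.yaml --out sim/ --seed 1
plumetrack preprocess --frames sim/C1_side --masks sim/masks.json --out pre/
plumetrack segment    --frames pre/ --threshold otsu --min-area 20 --out seg/
plumetrack track      --masks seg/ --calibration sim/calibration.json \
                      --view C1_side --task-end-frame 200 --out extents.csv
plumetrack merge      --side side.csv --top top.csv --out merged.csv
plumetrack smooth     --extents merged.csv --window 30 --knot-stride 5 --out smoothed.csv
plumetrack summarize  --smoothed smoothed.csv --out summary/
plumetrack ltas       --audio a.wav --audio b.wav --out spectra/
plumetrack ltas-mse   --a spectra/a_ltas.csv --b spectra/b_ltas.csv
```

A scenario YAML holds the fields of `plumetrack.simulate.PlumeScenario`
(see `plumetrack.simulate.scenario_to_dict` for the exact shape).

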