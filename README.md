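# collmig

Quantification of collective cell migration in scratch-wound assays.

When cells in a wounded monolayer are coupled to their neighbours — for
example through engineered, light-switchable cell-cell adhesions — they stop
wandering individually and advance as a coordinated sheet. `collmig`
implements the measurement chain used to quantify that transition from
time-lapse microscopy, and a synthetic active-particle monolayer with known
ground truth to validate every stage of it:

- **PIV** (`collmig.piv`): dense velocity fields from consecutive frames by
  zero-normalized windowed cross-correlation with sub-pixel peak fitting.
- **Collectivity statistics** (`collmig.fieldstats`): the spatial velocity
  autocorrelation `C(r) = <δv_i·δv_j> / <|δv|²>` and the **correlation
  length** (first 1/e crossing of `C(r)`; exponential fit as a cross-check),
  polar order parameter, and rose histograms of migration direction.
- **Wound analysis** (`collmig.wound`): variance-based wound segmentation,
  area time series, closure rate (least-squares slope, µm²/h and %/h), and
  front/rear classification with the 60 µm edge band (~three nuclei).
- **Single-cell tracking** (`collmig.tracking`): LoG nucleus detection,
  greedy nearest-neighbour linking, trajectory filters (tracks shorter than
  four steps excluded), straightness index `|net| / Σ|steps|`, median speed
  in nm/s, and orientation relative to the inward wound normal.
- **Membrane-order imaging** (`collmig.gp`): ratiometric generalized
  polarization `GP = (I445 − G·I525)/(I445 + G·I525)` with the
  solvent-calibrated correction factor
  `G = (G_ref + G_ref·G_m − G_m − 1)/(G_m + G_ref·G_m − G_ref − 1)`
  (`G_ref = 0.207`), interface ROI time courses normalized to t₀.
- **Morphometry** (`collmig.morphometry`): focal-adhesion / pERM punctum
  counting (background removal → CLAHE → exponential remap → contrast
  stretch → Otsu → components > 0.5 µm²), spreading area, and nuclear /
  cytoplasmic intensity ratio.
- **Expression** (`collmig.expression`): relative qPCR fold changes by
  2^(−ΔΔCt) against a housekeeping gene.
- **Synthetic monolayer** (`collmig.simulate`): a Vicsek-style
  active-particle model of a scratch-wounded sheet (tunable alignment,
  angular noise, wound-edge bias, 2–7 nm/s speeds) rendered to nuclei and
  phase-contrast-like channels, plus exact forward models for GP pairs and
  punctum images.

## Worked example

The `analysis/` scripts run the full chain on two simulated conditions that
differ only in the cell-cell alignment coupling (0.9 vs 0.1):

```bash
python analysis/01_simulate_conditions.py
python analysis/02_piv_collectivity.py
python analysis/03_wound_closure.py
python analysis/04_track_metrics.py
python analysis/05_gp_morphometry_expression.py
```

Output (abridged) from a run of scripts 02–05:

```
[adhesive]    correlation length 136.4 um (exp fit 134.7), order parameter 0.212
[nonadhesive] correlation length  77.8 um (exp fit  79.4), order parameter 0.109
[adhesive]    closure rate 9880 um^2/h (12.8 %/h); 194 front / 406 rear cells
[nonadhesive] closure rate 7836 um^2/h (10.1 %/h); 194 front / 406 rear cells
[adhesive]    855 tracks kept; median straightness 0.67, median speed 5.0 nm/s
[nonadhesive] 1138 tracks kept; median straightness 0.59, median speed 4.9 nm/s
GP: correction factor G = 0.803; interface GP rises by +0.064 after the step (truth +0.060)
puncta: 4 of 6 constructed puncta pass the 0.5 um^2 filter (ground truth 4)
```

Strongly coupled cells migrate with a ~1.75× longer velocity correlation
length, close the wound faster, and move straighter — the kinematic
signature of adhesion-driven collective migration — while the molecular
readouts (GP step, punctum counts, fold changes) are recovered against
their constructed ground truth. Tables land under `results/`.

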