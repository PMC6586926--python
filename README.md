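# osteotherm

Colourimetric estimation of the temperature human bone was exposed to during
burning.

When bone is heated it traverses a characteristic colour sequence — ivory
white, brownish-black (carbonisation of the collagen), grey (inversion),
and finally pure white (calcination, once the residual carbon has burned
away).  Measured objectively in CIE 1976 L\*a\*b\* colour space, the
lightness L\* and the blue–yellow coordinate b\* carry almost all of the
temperature information, and fixed thresholds on those two coordinates
partition the (L\*, b\*) plane into **seven temperature clusters**, each
with an associated exposure-temperature range and heat-induced (HI) change
stage:

| cluster | decision rule                          | T range (°C) | HI stage                |
|--------:|----------------------------------------|--------------|-------------------------|
| 1       | b\* > 11 and L\* ≥ 40                  | 0–350        | Unheated – carbonization |
| 2       | b\* > 11 and L\* < 40                  | 250–350      | Carbonization           |
| 3       | b\* ≤ 11 and L\* < 32.5                | 300–600      | Completely charred      |
| 4       | b\* ∈ [6.5, 11] and 32.5 ≤ L\* < 75    | 450–600      | Inversion               |
| 5       | b\* < 6.5 and 32.5 ≤ L\* < 75          | 450–700      | Inversion – calcination |
| 6       | b\* ≤ 11, L\* ≥ 75, L\* ≤ −25·b\* + 200 | 700–(≥900)   | Completely calcined     |
| 7       | b\* ≤ 11, L\* ≥ 75, L\* > −25·b\* + 200 | 800–(≥900)   | Completely calcined     |

The package is aimed at forensic anthropologists and archaeologists who
need an objective, non-destructive temperature estimate from scanned or
photographed bone fragments.  It provides:

* **`osteotherm.colour` / `osteotherm.calibration`** — sRGB ↔ CIELAB
  conversion (D65 default, D50 available) and least-squares colour
  correction against a 24-patch ColorChecker Classic chart, fitted in
  linear RGB with per-patch ΔE\*ab quality control;
* **`osteotherm.roi`** — segmentation of a sample from its white scanning
  background, exclusion of a 1–2 mm rim from the outer skirts (chromatic
  aberration, overexposure and soot live there), and mean RGB / mean
  per-pixel Lab measurement;
* **`osteotherm.decision`** — the seven-cluster decision model, a total and
  mutually exclusive partition with documented tie handling;
* **`osteotherm.heatmap`** — per-pixel cluster maps showing the thermal
  gradient across a fragment, with a combined temperature envelope;
* **`osteotherm.stats`** — Pearson correlation matrices, standardized
  multiple linear regression with semi-partial (part) correlations, and
  empirical per-cluster temperature ranges;
* **`osteotherm.evaluation`** — [1]/[0] range-containment scoring and
  per-partition accuracy reports;
* **`osteotherm.synthetic`** — a generator of learning/test-set-like colour
  tables and rendered bone-slice images for testing and simulation.

## Worked example

Classify a single measured colour:

```python
>>> import osteotherm as ot
>>> a = ot.assign_cluster((85.2, 0.6, 1.8))   # (L*, a*, b*)
>>> a.cluster, a.temperature.display(), a.stage
(6, '700–(≥900) °C', 'Completely calcined')
```

A fragment with L\* = 85.2 and b\* = 1.8 is completely calcined: it was
exposed to at least 700 °C, with no upper bound distinguishable by colour.
The a\* coordinate is accepted but ignored — it adds no discrimination.

The same round trip from the shell, on synthetic data:

```
$ osteotherm simulate --out learning.csv --seed 7
wrote 450 records -> learning.csv (seed 7)
$ osteotherm classify --input learning.csv --output clusters.csv
classified 450 samples -> clusters.csv
$ osteotherm evaluate --input learning.csv --output report.json --partition-col duration_min
{
  "partitions": {
    "10.0": {"n": 150, "accuracy_pct": 99.33333333333333},
    "20.0": {"n": 150, "accuracy_pct": 100.0},
    "30.0": {"n": 150, "accuracy_pct": 98.66666666666667}
  },
  "mean_weighted_pct": 99.3333333333,
  "mean_unweighted_pct": 99.3333333333
}
```

`accuracy_pct` is the percentage of samples whose known exposure
temperature falls inside the temperature range of their assigned cluster;
the weighted mean pools all samples, the unweighted mean averages the
partition percentages.

For images, `osteotherm measure` segments each sample, strips a 1.5 mm rim
(configurable) and writes one row of mean colour per file, and
`osteotherm heatmap` writes an indexed PNG of per-pixel cluster labels plus
a JSON temperature envelope.  Scanner or camera calibration comes from
`osteotherm calibrate` applied to measured ColorChecker patch values.

## Scope notes

The package operates downstream of image acquisition: it expects
white-balanced TIFF/PNG input (8- or 16-bit RGB) with known dpi.  RAW
development, ICC profiles and the physical heating protocol are out of
scope, and the cluster thresholds are fixed published constants — they are
not re-derived from data.  See `docs/methods.md` for the model's
assumptions, tie-handling choices, and the limits of what synthetic-data
tests can show.
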