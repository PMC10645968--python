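# spikegrain

Smartphone-image phenomics for wheat spikes: per-grain morphometrics and
the **intra-spike variation as standard deviation (ISVAD)** statistic.

## The problem

In wheat, grain size varies with position along the spike: proximal
florets and middle spikelets fill better than distal ones, and terminal
drought or heat stress sharpens that unevenness. Quantifying the
*within-spike* spread of grain size is informative for breeders screening
for uniform grain filling, but X-ray CT or NMR instruments that image
grains in situ are out of reach for most programs. A far cheaper protocol
is to thresh one spike, lay its grains out by spikelet position on a dark
background next to a scale object, photograph the layout with a phone, and
measure every grain from the image.

`spikegrain` implements that pipeline end to end for anyone doing seed or
grain phenotyping from flatbed or smartphone images:

* **calibration** — pixels are converted to millimetres from a line of
  known length (`set_scale`), one global calibration per session;
* **segmentation** — per-image auto-thresholding (Otsu or IsoData),
  8-connected particle labelling with hole filling, and a physical-area
  lower limit (default 2.5 mm²) that discards non-grain debris;
* **ordering** — grains are numbered bottom-left → top-right, grouped into
  spikelet rows and tagged by spike region (bottom / middle / top thirds);
* **morphometrics** — per grain: projected area, perimeter, maximum
  (Feret) and minimum (MinFeret) caliper diameters via convex hull and
  rotating calipers, the equal-area best-fit ellipse, circularity
  4πA/P², aspect ratio, roundness 4A/(π·major²) and solidity. Feret and
  MinFeret serve as grain length and width;
* **ISVAD** — for each spike and each spike region, the population
  standard deviation (divisor N) of grain width, length, area and
  perimeter:  σ = √(Σᵢ (xᵢ − µ)²) / √N;
* **validation statistics** — OLS calibration of image values against
  reference caliper measurements with seeded k-fold cross-validation;
* **trial statistics** — split-plot / RCBD ANOVA for genotype ×
  environment trials and Duncan's multiple range test letter displays;
* **synthetic generator** — renders spike layouts of anti-aliased
  elliptical grains with exact per-grain ground truth, so every stage is
  testable without photographs.

## Worked example

```python
from spikegrain import process_image, set_scale
from spikegrain.simulate import SpikeSimConfig, generate_spike_image

config = SpikeSimConfig(seed=42, noise_sd=0.02)      # 20 rows x 2 grains
image, truth, bar = generate_spike_image(config)
calibration = set_scale(bar.length_px, bar.length_mm, global_flag=True)
morphs, layout, summary = process_image(image, calibration)
print(summary.n_grains, round(summary.mean["length"], 2),
      round(summary.isvad["area"], 3))
```

prints

```
40 7.06 1.79
```

i.e. all 40 rendered grains were recovered, their mean length (Feret) is
7.06 mm against a ground-truth mean of 7.02 mm, and the ISVAD of grain
area of this simulated spike is 1.79 mm² (it matches the ground-truth
table's own ISVAD; across seeds the generator's default within-spike
variability averages ≈2.6 mm²). The scripts in `examples/` walk through
each capability
(simulation and measurement, region-level ISVAD, stress-response indices,
trial ANOVA + Duncan letters) and print the numbers with interpretation.

A thin CLI wraps the same functions:

```bash
spikegrain simulate --rows 20 --seed 1 --out-dir sim
spikegrain measure --image sim/spike_000.png --scale-px 100 --scale-mm 10
spikegrain isvad --results-csv sim/spike_000_results.csv
spikegrain run-all --image a.png --image b.png --scale-px 100 --scale-mm 10
```

Measurement tables use the classic particle-analysis CSV dialect
(`Area, Perim., Circ., Feret, FeretAngle, MinFeret, Major, Minor, Angle,
AR, Round, Solidity` with a leading index column), so existing exports
from interactive tools can feed `spikegrain isvad` directly.

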