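# crrc — Cytometry of Reaction Rate Constant

Cytometry of Reaction Rate Constant (CRRC) characterizes cell-population
heterogeneity by following a reaction in every cell of a time-lapse
fluorescence experiment, fitting each cell's intensity-vs-time trace with a
single-exponential decay

    y(t) = A · exp(−k t) + y0,

and summarizing the population as a kinetic histogram "number of cells vs
rate constant k" (median = peak position, skewness = peak asymmetry).
The rate constant — e.g. `k_efflux` for cross-membrane dye efflux — is
robust to illumination and loading variability in a way raw intensities
are not.

The catch is cell motility. The classical ("original") workflow outlines
cells once, in the first fluorescence frame, and freezes those contours for
the whole stack; once a motile cell drifts out of its outline, the trace
collapses faster than the true kinetics and k is overestimated — shifting
the whole histogram to the right and faking fast subpopulations. This
package implements both that workflow and the motility-robust ("new") one:
a transmitted-light image is taken a short gap `t1` (~3 s) before every
fluorescence image; cells are segmented in every transmitted frame
(threshold → 8-connected components → 3–12 μm equivalent-radius filter),
linked frame to frame by optimal assignment gated at one cell diameter,
incomplete tracks are discarded, and each fluorescence frame is integrated
inside that frame's own contour. The design is justified by two bounds:

* within a frame pair, the fastest cell (v = 400 μm/h) shifts only
  x = v·t1 ≈ 0.33 μm, an x/d ≈ 2.5% intensity error for d = 13 μm cells —
  contours from the transmitted frame apply to the fluorescence frame;
* between frame pairs (t2 = 1 min), the fastest cell moves 6.7 μm < d,
  so nearest-within-a-diameter linking is valid (`t2 ≪ d/v`).

Accepted fits (k > 0, relative standard error ≤ 100%) from the two
workflows are compared with a two-sample Kolmogorov–Smirnov test
(α = 0.001 by default).

Because every stage needs ground truth to be testable, the package ships a
first-class synthetic generator: a monolayer of non-overlapping motile
cells (diameter 13 ± 3 μm; right-skewed speeds with mode 150 μm/h, IQR
40 μm/h, truncated at 400 μm/h; persistent random walk) whose per-pixel
fluorescence decays with per-cell log-normal rate constants, rendered into
paired 16-bit transmitted/fluorescence stacks with masks, centroids and
rate constants saved alongside.

## Worked example

```python
import numpy as np
from crrc import PipelineConfig, run_pipeline
from crrc.simulate import SimulationConfig

result = run_pipeline(PipelineConfig(simulation=SimulationConfig(rng_seed=1), seed=1))
comp = result.comparison
true_median = float(np.median(result.ground_truth.cells["k_per_min"]))
print(f"complete tracks:       {result.tracks_frame['track_id'].nunique()}")
print(f"accepted k (original): {comp.ks.n1}")
print(f"accepted k (new):      {comp.ks.n2}")
print(f"median k original:     {comp.histogram_original.median:.4f} min^-1")
print(f"median k new:          {comp.histogram_new.median:.4f} min^-1")
print(f"true median k:         {true_median:.4f} min^-1")
print(f"KS: D={comp.ks.D:.3f}, D_alpha={comp.ks.D_alpha:.3f}, p={comp.ks.p_value:.3g}")
```

prints

```
complete tracks:       197
accepted k (original): 183
accepted k (new):      197
median k original:     0.3193 min^-1
median k new:          0.0451 min^-1
true median k:         0.0452 min^-1
KS: D=0.881, D_alpha=0.200, p=2.24e-64
```

On this default motile population (200 cells, 61 frame pairs at 1/min,
512 × 512 px at 0.65 μm/px) the tracked workflow recovers the true median
rate constant to 0.2%, while the frozen-contour workflow overestimates it
seven-fold; the Kolmogorov–Smirnov test separates the two k distributions
decisively (D far above the α = 0.001 critical value D_α). With motility
switched off the two workflows agree and both recover every cell's k to a
fraction of a percent — the motility sensitivity of the original workflow
is the only thing that differs between them.

The same pipeline is scriptable from the shell:

```sh
crrc simulate --outdir run/ --seed 1
crrc segment  --stack run/transmitted.tif --outdir run/
crrc track    --detections run/detections.csv --timestamps run/timestamps.csv --outdir run/
crrc traces   --workflow new --tracks run/tracks.csv --masks run/label_masks.tif \
              --fluo run/fluorescence.tif --timestamps run/timestamps.csv --out run/traces_new.csv
crrc fit      --traces run/traces_new.csv --out run/fits_new.csv
crrc compare  --fits-a run/fits_original.csv --fits-b run/fits_new.csv --out run/comparison.json
# or everything at once:
crrc run --outdir run/ --seed 1
```

All intermediates are plain CSV / multi-page TIFF with a versioned schema;
see `docs/methods.md` for the model, parameter and design details.

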