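# marquant

Quantifying metal-artifact reduction (MAR) in cone-beam CT by **automatic
edge counting**.

Dense dental prostheses (amalgam, gold, PFM, zirconia crowns) cast
bright/dark streak artifacts across CBCT slices. Vendors ship MAR
reconstruction options, but judging how much artifact they actually remove
is hard: CBCT gray values are too unstable for ROI-based metrics. This
package implements a gray-value-independent alternative: detect edges with
a noise-hardened Canny pipeline, count each 8-connected component of edge
pixels as one "edge" (a continuous line with no breaks), and score MAR by
how many such edges it removes. Streak bands add edges; anatomy is shared
between the paired MAR-off/MAR-on acquisitions, so the difference isolates
the artifact.

The headline metric for a paired acquisition is the **edge reduction
ratio**

```
reduction ratio (%) = 100 · (E_off − E_on) / E_off
```

where `E_off`, `E_on` are total edge counts of the MAR-off and MAR-on
stacks. Per-slice count differences `d_i = off_i − on_i` (mean ± SD) feed
condition-level comparisons. Because slice counts differ between
acquisitions, the statistics layer is heteroscedasticity-robust
throughout: Shapiro–Wilk normality (advisory), Welch's one-way ANOVA with
the Games–Howell post hoc test across prosthesis types, and Welch t-tests
for the voxel-size × tube-voltage factorial margins.

Since clinical CBCT volumes of this kind are not freely available, the
package ships a synthetic **arch-phantom simulator**: horseshoe arch, one
dense insert, and a controllable number of radial bright/dark streak
bands. MAR is modelled as streak-subset removal, so every simulated pair
carries exact ground-truth streak counts — something no physical
reconstruction can provide — and the whole pipeline can be validated
end-to-end.

## Worked example

```python
from marquant import analyze_pair, make_pair

sim = make_pair(k_off=10, k_on=4, noise_sigma=5.0, seed=1)
report = analyze_pair(sim.pair)
print(report.total_off, report.total_on, report.reduction_ratio_pct)
```

prints

```
120 60 50.0
```

The MAR-off stack has 10 streaks per slice plus two anatomical contours
(arch outline, insert boundary) → 12 edges × 10 slices = 120. The MAR-on
stack keeps 4 streaks → 6 × 10 = 60. The measured ratio, 50.0%, sits
below the true streak reduction (60%) by exactly the dilution the two
shared anatomy edges cause — the same effect anatomy has in real scans.
Running with `noise_sigma=5.0` (shown) or noise-free gives identical
counts: the detector's noise gate keeps the component structure exact.

The `examples/` scripts each demonstrate one capability (pipeline-stage
audit, prosthesis-group statistics, factorial margin tests) and print a
short interpretation of their numbers.

## Command line

```
marquant simulate --seed 1 --out pair/          # phantom pair + ground truth
marquant count pair/mar_off --out counts.csv    # per-slice edge counts
marquant compare pair/mar_off pair/mar_on --out report.json --format json
marquant stats --group gold=report.json ... --out stats.csv
```

Real acquisitions are read from BMP/PNG/TIFF slice directories
(natural-sorted) or DICOM series; blank slices outside the object are
trimmed before pairing.

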