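# morphodist

Quantitative pairwise comparison of 3D-scanned anatomical specimens,
built for the hard case palaeontologists actually face: a **fragmentary
target** (an isolated, broken fossil) that must be compared against more
complete **reference** specimens when sample sizes are far too small for
conventional geometric morphometrics.

The pipeline is the standard two-registration workflow:

1. **First registration** — ≥3 homologous landmarks picked on both
   specimens give a closed-form least-squares similarity transform
   (scale *s*, rotation **R**, translation **t** minimising
   Σ‖s**R**xᵢ + **t** − yᵢ‖²; reflections excluded).
2. **Mesh editing** — fractured surfaces and preparation/excavation
   artefacts are trimmed away (vertex masks, sphere/plane selectors), and
   the higher-resolution scan is decimated by quadric edge collapse to
   match the polygon count of the lower-resolution one. Upsampling is
   refused by design.
3. **Second registration** — point-to-point ICP with per-iteration scale
   re-estimation (default 20 iterations) minimises the RMS distance from
   each target vertex to its nearest reference vertex; the RMS trace is
   recorded and is provably non-increasing.
4. **Distance field** — per-vertex absolute distances, either
   cloud-to-cloud (C2C: nearest reference vertex) or cloud-to-mesh (C2M:
   exact nearest point on any reference triangle). Summaries (mean MD,
   sample SD, range, directed Hausdorff = field max), 256-bin histograms,
   and blue→green→yellow→red heat maps exportable as colored PLY. Low
   MD/SD = high shape fidelity.
5. **Trial ANOVA** — outcomes of a set of comparisons crossed over design
   factors (artefact removal, C2C vs C2M, final ICP, reference specimen)
   are decomposed with type-II sums of squares and permutation inference
   (p = (count+1)/(B+1), B = 999 by default; Z = standardised log-F).

Because scan data cannot ship with a library, a synthetic-specimen module
generates claw-like unguals (curved tapering shell, lateral blood grooves,
bulbous ventral flexor tubercle), degrades them like real fossils (missing
distal end, excavation hole, surface noise) and plants known similarity
transforms — so every stage is testable against exact ground truth.

## Worked example

`examples/` holds one short script per capability. Registration recovery
(`examples/02_registration.py`) plants a known transform and recovers it:

```
planted: the registration should recover scale 0.769231
first registration (landmarks): scale 0.769231
second registration (ICP): scale 0.769231, final RMS 7.81e-15 after 2 iteration(s)
iteration sweep (5..100 step 5): RMS plateaus at budget 10
```

A full fragmentary comparison (`examples/03_distance_heatmap.py`) shows
the fine alignment doing its job — the mean distance drops by an order of
magnitude once ICP refines the landmark fit:

```
before ICP: MD = 0.6199, SD = 0.2806
after ICP:  MD = 0.0386, SD = 0.0288, range [0.0009, 0.1312], n = 252
```

The trial decomposition (`examples/04_trial_anova.py`) runs on the bundled
table of twelve ungual comparisons (fragmentary theropod ungual
NMV P186153 vs two *Australovenator* reference unguals, AODF604 MCII-3
and MCI-2):

```
           df       SS       MS       R2          F        Z        p
removal     1 0.075661 0.075661 0.024661   5.271181 1.209512 0.066000
method      1 0.014709 0.014709 0.004794   1.024744 0.530972 0.367000
icp         1 0.203619 0.203619 0.066368  14.185762 1.564493 0.010000
reference   1 2.413573 2.413573 0.786691 168.149566 2.664962 0.001000
Residuals   7 0.100476 0.014354 0.032750
Total      11 3.068004
```

Choice of reference specimen explains ~79 % of the variance in mean
distance; the final ICP is the only other significant term. SS/MS/R²/F are
deterministic; p and Z depend on the permutation seed.

A `morphodist` command-line tool exposes the same stages
(`simulate`, `register`, `sweep`, `trim`, `decimate`, `compare`, `anova`);
every run writes a provenance JSON with its parameters and seed.

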