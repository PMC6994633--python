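# mobflim

Label-free metabolic profiling of single hematopoietic cells from
fluorescence-lifetime imaging (FLIM) of NAD(P)H and FAD autofluorescence.

Hematopoietic stem cells (HSCs) carry a metabolic fingerprint that can be
read out optically, without staining or fixation: they are less oxidative
and more glycolytic than downstream progenitors and leukocytes, and their
NAD(P)H is peripherally enriched and asymmetrically distributed. `mobflim`
implements the full analysis chain that turns raw time-correlated
single-photon-counting (TCSPC) decay stacks into five per-cell **metabolic
optical biomarkers (MOBs)** and population-level calls:

1. **ORR** — optical redox ratio, FAD / (FAD + NAD(P)H) intensity;
2. **α_bound** — fraction of NAD(P)H photons from the enzyme-bound species;
3. **τ_bound** — lifetime (ns) of enzyme-bound NAD(P)H;
4. **edge/center ratio** — peripheral-band vs eroded-center NAD(P)H intensity;
5. **polarity** — ‖intensity-weighted centroid − geometric centroid‖ / √(area/π).

## The phasor model

Each pixel's decay histogram `I(t)` is mapped to first-harmonic phasor
coordinates

    g = Σ I(t)·cos(ωt) / Σ I(t),   s = Σ I(t)·sin(ωt) / Σ I(t),   ω = 2π/T

(T the laser period, default 12.5 ns / 80 MHz). Single-exponential decays
fall on the universal semicircle `(g − ½)² + s² = ¼`; mixtures fall on
chords, weighted by fractional photon contribution. Because the three
hematopoietic populations share a free-NAD(P)H lifetime of ≈ 0.45 ns, a
cell's pooled phasor can be unmixed by intersecting the line through the
free-lifetime point with the semicircle: the other intersection is the
bound species, giving `τ_bound = s_b/(ω·g_b)` and `α_bound` as the cell's
fractional position along the chord. A total-least-squares trajectory fit
through a pixel cloud estimates both lifetimes when neither is fixed.

Downstream, cells are standardized in MOB space, projected onto three
principal components, and gated by a binary linear-discriminant plane
(`w ∝ Σ_pooled⁻¹ Δμ`, equal priors); an RBF-SVM with Platt-scaled
probabilities identifies HSCs vs multipotent progenitors (MPPs), scored by
sensitivity = TP/(TP+FN) over reporter-positive cells and specificity =
TN/(TN+FP) over reporter-negative cells.

Because no public single-cell FLIM dataset accompanies this analysis, the
package ships a first-class synthetic generator: two-component exponential
decays folded over one laser period (so the analytic phasor is exact),
Poisson photon statistics, optional Gaussian instrument response, disk
cells with peripheral enrichment and polarized intensity ramps, an FAD
channel tuned to each cell's true ORR, and population presets encoding the
HSC / Lin⁻CD45⁺ / CD45⁺ / MPP orderings.

## Worked example

```sh
python examples/02_extract_mobs.py
```

renders 15 cells per population and extracts all five MOBs:

```
              orr  alpha_bound  tau_bound_ns  edge_center_ratio  polarity
population
CD45        0.479        0.615         2.939              1.054     0.064
HSC         0.242        0.776         3.548              1.521     0.156
LinNegCD45  0.488        0.613         2.658              1.008     0.036
```

HSCs come out lowest in ORR and highest in the four other biomarkers, and
the extracted `tau_bound_ns` recovers the generator's 3.56 ns HSC preset to
~0.01 ns. `examples/03_population_gate.py` continues to the PCA+LDA gate
(100% of HSCs vs 0% of differentiated cells on the HSC side of the plane
for these presets), `examples/04_perturbation_tracking.py` shows the paired
τ_bound response to simulated LDH inhibition, and
`examples/05_hsc_classifier.py` trains and scores the HSC-vs-MPP SVM.

The same stages are scriptable from the shell:

```sh
mobflim run --config examples/run_config.json --out out/
mobflim extract --field out/field_HSC --tau-free 0.45 --out cells.csv
mobflim gate fit --cells out/cells.csv --target HSC --out gate.json
```

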