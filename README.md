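# uriscreen

Simulation and decision statistics for spectrophotometric uricase assays
and crude-lysate mutant screening.

Uricase oxidizes uric acid to 5-hydroxyisourate (HIU), which decomposes
spontaneously to non-absorbing allantoin. Because uric acid absorbs at
293 nm (ε = 11.5 mM⁻¹cm⁻¹) and HIU near 302 nm, absorbance-based activity
assays are biased while HIU accumulates toward its steady state — at
308 nm the trace can rise for over a minute before falling. `uriscreen`
models the reaction

    dS/dt = −Vmax·S/(Km+S),   dH/dt = Vmax·S/(Km+S) − k_d·H

renders Beer–Lambert traces A(t) = l·(ε_UA·S + ε_HIU·H) + noise,
reproduces the initial-rate protocol (40-s lag, < 10% consumption,
Lineweaver–Burk with r² > 0.97), and quantifies how the HIU intermediate
inflates apparent Km as a function of enzyme activity, buffer and pH.

A second layer addresses screening decisions: given clone panels of total
protein P, activity concentration AC, and specific activity SA = AC/P, it
computes empirical ROC curves and Mann–Whitney AUCs for recognizing a
higher-activity mutant against its starting material, and evaluates the
practical threshold

    threshold = mean_SM + 1.4·SD_SM

whose normalized cutoff of 1.4 targets Φ(1.4) ≈ 92% specificity. A
synthetic panel generator (SA and P independent, AC = SA·P, which induces
the positive AC–protein correlation real lysates show) makes the whole
decision layer testable without laboratory data; a four-candidate summary
fixture (A–D, n = 30 clones each) ships with the package.

See `docs/methods.md` for the model, parameter conventions, and
limitations.

## Worked example

Simulate the interference showcase — Tris–HCl pH 7.4, 308 nm, 103 U/L,
0.30 mM uric acid — and try to measure a rate from it:

```sh
$ uriscreen simulate-trace --buffer tris --ph 7.4 --wavelength 308 \
    --activity 103 --ua0 0.30 --noise 0 --out tris74.csv
wrote tris74.csv (61 samples, k_d = 0.00332261 /s)
$ uriscreen estimate-rate tris74.csv --ua0 0.30 --eps 2.9
v0_mM_per_min=0.010435
activity_U_per_L=10.435
window_s=40,300
consumption_fraction=0.0956621
linearity_r2=0.816539
interference_flag=True
```

The trace rises to a peak near 100 s (HIU out-absorbs uric acid at
308 nm), so the apparent "rate" corresponds to 10 U/L for a 103 U/L
enzyme — and the estimator flags the trace as interfered (non-linear
window, r² = 0.82). The same enzyme under assay conditions — alkaline
borate, 293 nm — is measured cleanly:

```sh
$ uriscreen simulate-trace --buffer borate --ph 9.2 --wavelength 293 \
    --activity 8 --ua0 0.075 --noise 0.002 --seed 1 --out borate92.csv
$ uriscreen estimate-rate borate92.csv --ua0 0.075 --dilution 16
v0_mM_per_min=0.00176116
activity_U_per_L=28.1786
...
interference_flag=False
```

(0.00176 mM/min in the cuvette ≈ 1.76 U/L at S = 0.075 mM with
Km = 0.25 mM; the 16× dilution factor reports the original sample's
activity concentration.)

The screening report over all fixture pairs — mean-index ratios plus
replicate-averaged empirical AUCs (2000 replicates of n = 30 gaussian
panels per group):

```sh
$ uriscreen screen --reps 2000 --seed 11 --out table_repro.csv
pair  ratio_purified  ratio_ac   auc_ac  ratio_sa   auc_sa
 A-B            1.37  1.071429 0.584213  1.139535 0.720425
 B-C            1.58  1.555556 0.900732  1.535714 0.982976
 A-C            2.15  1.666667 0.916969  1.750000 0.979608
 C-D            1.90  5.454545 0.998275  5.600000 1.000000
 B-D            3.00  8.484848 0.999970  8.600000 1.000000
 A-D            4.10  9.090909 0.999882  9.800000 1.000000
```

Pairs with capacity ratios ≥ 3 are perfectly separable by either index;
for close pairs (A-B, B-C, A-C) specific activity clearly beats activity
concentration — the package's central decision-layer result. One
simulated pair with the threshold rule:

```sh
$ uriscreen roc --pair A,C --index sa --k 1.4 --n 30 --seed 3
auc=0.99
threshold=0.343827
sensitivity=0.966667
specificity=0.866667
```

The same operations are available as library calls
(`uriscreen.simulate_reaction`, `estimate_initial_rate`,
`km_bias_experiment`, `generate_panel`, `roc_curve`,
`apply_threshold_rule`, `screen_report`, ...).

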