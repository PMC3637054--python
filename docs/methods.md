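# Methods

## The measurement problem

Uricase (urate oxidase) activity is most cheaply assayed by following the
UV absorbance of its substrate: uric acid absorbs strongly at 293 nm
(ε = 11.5 mM⁻¹cm⁻¹), and the final product allantoin does not absorb above
280 nm. The catch is the reaction intermediate, 5-hydroxyisourate (HIU),
which absorbs near 302 nm and decomposes to allantoin only spontaneously,
at a buffer- and pH-dependent first-order rate. Until HIU reaches its
steady state, the recorded absorbance is a mixture of substrate loss and
intermediate accumulation; at wavelengths where HIU out-absorbs uric acid
(e.g. 308 nm, needed to keep 0.4 mM substrate on scale) the trace can
*rise* for more than a minute before falling. Initial rates, and the
Michaelis constants fitted from them, inherit that bias.

`uriscreen` simulates this system end to end, reproduces the measurement
protocol that contains the bias, and quantifies when the protocol is
reliable. A second, independent layer addresses the downstream decision
problem: recognizing a higher-activity enzyme mutant from crude-lysate
screening panels.

## Kinetic model

State variables are substrate S (uric acid), intermediate H (HIU), and
product (allantoin), all in mM:

    dS/dt = −v(S),   dH/dt = v(S) − k_d·H,   v(S) = Vmax·S/(Km + S)

with allantoin obtained by difference, so mass conservation holds to
solver round-off by construction. Integration uses `scipy`'s LSODA with
rtol 1e-8 / atol 1e-13 — the system is two stiff-capable ODEs, so accuracy
costs nothing. A clamped-substrate mode (S held constant) exposes the HIU
steady state v/k_d for closed-form checks. Oxygen, hydrogen peroxide,
product inhibition and enzyme inactivation are not modeled; none has a
spectral role in this assay.

Absorbance follows Beer–Lambert over the two absorbers:

    A(t) = l·(ε_UA(λ)·S(t) + ε_HIU(λ)·H(t)) + N(0, σ)

with additive Gaussian instrument noise (default σ = 0.002 AU, a typical
bench spectrophotometer figure; under it, 11-fold repeated activity
estimates at 3–12 U/L show CVs of 1–3%, comfortably inside the 5.5%
repeatability bound the protocol is validated against).

### Units

One enzyme unit (U) oxidizes 1 µmol uric acid per minute, so a cuvette
activity of a U/L corresponds to a rate of a×10⁻³ mM·min⁻¹. The
`activity_to_vmax` conversion treats the stated activity as the cuvette
Vmax; activity and measured rate coincide only for an enzyme saturated at
the calibration substrate level (0.075 mM), which is how the round-trip
identity is tested.

### Parameter conventions

No published rate constants or HIU extinction coefficients exist for this
system; all interference magnitudes in the source material are
qualitative. The package therefore fixes a minimal set of conventions and
calibrates the one free rate against the single quantitative anchor
available:

| parameter | default | basis |
|---|---|---|
| ε_UA(293) | 11.5 mM⁻¹cm⁻¹ | published assay coefficient |
| ε_UA(308) | 2.9 mM⁻¹cm⁻¹ | bounded by "0.4 mM reads < 1.200 AU" (< 3.0) |
| ε_HIU(293) | 1.4 mM⁻¹cm⁻¹ | convention; small vs 11.5 (weak 293-nm interference) |
| ε_HIU(308) | 4.2 mM⁻¹cm⁻¹ | convention; 3× the 293-nm value, > ε_UA(308) so the documented 308-nm rise can occur |
| k_d(buffer, pH) | k_ref·10^(0.6·(pH−7.4))·m_buffer | see below |
| m_tris, m_borate | 1, 10 | borate strongly accelerates HIU decay |
| Mg²⁺ multiplier | 1.0 (off) | optional k_d multiplier only; no quantitative claim |

k_ref (HIU decay in Tris–HCl at pH 7.4) is found by log-scale bisection so
that the simulated A₃₀₈ trace at 103 U/L with 0.30 mM uric acid peaks at
100 s, the observed anchor; the calibrated value is ≈ 3.3×10⁻³ s⁻¹ and is
cached per process. The pH slope of 0.6 decades per pH unit makes the
Tris pH 8.9 rise visibly (≈ 7×) smaller than at pH 7.4, and m_borate = 10
makes every borate trace at pH ≥ 7.4 non-increasing after the 40-s lag
while leaving enough pre-steady-state HIU at pH 7.4 to bias apparent Km —
both observed behaviors. Because only the peak-time anchor is
quantitative, simulated curve *shapes* are meaningful but amplitudes are
conventions; tests assert orderings and timings, not absolute AU values.

## Rate-extraction protocol

The estimator deliberately knows less than the simulator: absorbance is
converted to apparent substrate concentration using ε_UA alone (ignoring
HIU — that blindness is the artifact under study), and consumption is
reckoned against the nominal load. The initial rate is the average
velocity over the window from the 40-s steady-state lag to the last
sample with apparent consumption strictly below 10% (samples recorded
every 5 s by default; recording in practice starts after a 20-s handling
lag). The window slope comes from an OLS line; evaluating the window
endpoints on that line is identical to the raw endpoint difference for
noiseless traces and is what keeps the repeatability CV low under noise.
A trace is flagged for interference when absorbance rises after the lag
(net rise > 0.005 AU) or the window is non-linear (r² < 0.99). Windows
with no sample below the limit beyond lag + 10 s raise a saturated-trace
error; this genuinely happens at high activity and low substrate and is
recorded, not hidden, in sweep results.

Km and Vmax come from unweighted OLS on the double-reciprocal
(Lineweaver–Burk) plot, accepted only when r² > 0.97 — deliberately the
classical procedure, reproduced faithfully rather than replaced by
error-weighted or nonlinear fitting (a nonlinear Michaelis–Menten fit is
provided for comparison only).

### Substrate attribution in the Km sweep

Each average velocity must be paired with a substrate concentration for
the Michaelis–Menten design. Pairing with the *nominal* load is the
textbook shortcut, but the averaging window itself consumes up to 10% of
the substrate, and the resulting rate deficit — largest, fractionally, at
the lowest substrate levels — is amplified by double-reciprocal leverage
into an apparent-Km inflation of several percent that grows with activity
regardless of any intermediate interference. `km_bias_experiment`
therefore defaults to pairing each velocity with the window-mean
*apparent* concentration, a quantity the experimenter reads off the same
trace (the standard depletion correction). Under this protocol the
depletion artifact cancels and HIU interference is the only bias source:
apparent Km converges to truth at low activity, rises with activity at
pH 7.4 where HIU is slow, stays flat at pH 9.2 until the protocol
saturates, and a low-Km (0.030 mM) enzyme read at 293 nm drifts < 0.1%
across a 50-fold activity range. With `substrate_attribution="nominal"`
the depletion bias is retained for study; in that regime (and only there)
tightening the consumption limit from 10% to 5% monotonically reduces the
bias, whereas under apparent attribution the residual interference bias
*grows* as the window shrinks toward the lag, because the early window
samples are the interference-contaminated ones.

Sweep conditions: activities 3–103 U/L; substrate grids 0.070–0.33 mM at
pH 7.4 and 0.10–0.50 mM at pH 8.2/9.2 (true Km 0.25 mM); the low-Km check
uses 0.01–0.10 mM substrate and activities 0.06–3.0 U/L — the largest
50-fold range for which the 10%-consumption window at the smallest
substrate level still clears the 40-s lag (at ≥ 6 U/L that level is
consumed past 10% before measurement can begin, a protocol limit, not a
solver one).

## Synthetic lysate panels

A screening campaign measures, per clone lysate: total protein P
(Bradford, mg/mL), activity concentration AC (U/mL), and specific
activity SA = AC/P (U/mg). The generator draws SA and P *independently*
from per-candidate marginals and sets AC = SA·P. This factorization
encodes the causal story that expression and lysis variability drive AC:
it induces the positive AC–protein correlation seen in real panels, with
the delta-method prediction

    r(AC, P) = μ_sa·σ_p / √(μ_sa²σ_p² + μ_p²σ_sa² + σ_sa²σ_p²)

(≈ 0.62 for candidate A), and it reproduces the printed AC summaries from
the SA and protein ones (e.g. 0.49 × 0.63 ≈ 0.31 vs the printed mean
0.30). Marginals are gaussian with resampling (not clipping) below zero,
so moments are preserved; a moment-matched lognormal family is available
because real SA panels are often right-skewed, but gaussian is the
default everywhere results are compared against closed forms. Duplicate
activity assays per clone are not simulated; panel values represent
clone-level averages. The four-candidate fixture (A–D, n = 30, capacity
descending) ships in `uriscreen/data/table1_candidates.json`, including
the purified-enzyme capacity ratios as metadata that is never recomputed
— those derive from measurements outside the simulation's scope.

What the generator does *not* emulate: colony-picking and growth
mechanics, induction kinetics, sonication efficiency, plate-position or
batch effects, and any SA–P dependence beyond the product structure.
Passing tests therefore validate the decision layer's statistics under an
idealized independence assumption, not the full messiness of a wet
screen.

## Decision layer

In each pair the lower-capacity enzyme is the starting material and the
higher is the positive candidate; either AC or SA serves as the decision
index. Separability is the empirical ROC AUC in its Mann–Whitney form
(fraction of positive/negative pairs with the positive higher, ties 0.5);
the ROC curve built over all observed cutoff values has a trapezoidal
area identical to it (asserted to 1e-12). A clone calls positive only
when its index strictly *exceeds* a cutoff — ties fall to the starting
material, keeping specificity conservative. Cutoffs are normalized as
(cutoff − mean_SM)/SD_SM; the practical rule fixes the normalized cutoff
at k = 1.4, i.e. threshold = mean + 1.4·SD of the starting material,
targeting Φ(1.4) ≈ 92% specificity under a normal index.

Replicate-averaged quantities (pair AUCs, threshold operating points)
draw 2000+ gaussian panels of n = 30 per group from the fixture's printed
index summaries and average the per-replicate statistic; the averages sit
on the binormal closed form Φ(Δμ/√(σ₁²+σ₂²)) to within Monte-Carlo error,
which is the oracle every reported AUC is checked against. Each pair uses
its own spawned child of the run seed, so adding a pair never perturbs
another's draws. Supporting kernels (sample CV, Shapiro–Wilk via
Royston's approximation, two-sided variance-ratio F test, equal-variance
Student t, Pearson r) wrap scipy with the validation contracts a report
needs; no multiple-testing correction is applied, matching the screening
practice being modeled. Known limitation: for pairs whose real SA
distributions are non-normal, the gaussian replicate average and the
reported empirical AUC can differ by a few hundredths; such cells are
covered by ordering properties (SA separates close pairs better than AC)
rather than point values.

## Numerical and degenerate-input choices

- Windows shorter than 3 samples raise insufficient-data; numerically
  flat windows report zero rate with r² = 1.
- Double-reciprocal fits with non-positive intercept raise a
  non-saturating-data error; identical substrate levels are rejected.
- Zero-SD starting material makes normalized cutoffs (and CV with zero
  mean, Pearson r and Shapiro–Wilk on constant input) undefined errors
  rather than NaNs.
- All stochastic entry points take either a seed or a Generator; CLI
  commands seed one PCG64 stream and spawn children per stage.
- Calibration bisects k_d on a log scale over [1e-4, 1] s⁻¹ and reports
  the bracket's peak times on failure.
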