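# Methods

## Scope and data model

porekit analyzes voltage-clamp current recordings from planar lipid
bilayers containing peptide-induced pores. A recording is a uniformly
sampled current vector (pA) with a piecewise-constant voltage protocol
(mV), solution metadata (salt, concentrations in mM per side, temperature)
and free-form provenance. Units are chosen so that arithmetic needs no
conversion factors: I[pA] = G[nS]·V[mV], and the sizing formula
G = κπr²/L gives nS directly with κ in S/m and r, L in nm.

## Synthetic trace simulator

Because public single-pore recordings of this kind are not generally
available, the simulator is a first-class component: every analysis stage
is validated against traces whose ground truth is known exactly.

The current model is

    I(t) = [G(t) + δG(t)]·(V(t) − V_rev) + ξ(t),

with the following parts.

**Gating.** G(t) is an optional permanent baseline conductance plus
N(t)·G_unit, where the pore count N(t) follows a birth–death process:
insertions arrive as a Poisson process at `insertion_rate` (events/s) and
each open pore retracts independently at `retraction_rate` (1/s),
simulated exactly (Gillespie). Experimental reports of this preparation
give no gating kinetics — only that step-wise insertions and retractions
occur — so the default rates (≈ 2/s) are order-of-magnitude choices that
produce a few events per second, comparable to what published traces show;
they are ordinary configuration parameters, not calibrated constants. An
optional telegraph "flicker" process multiplies the pore conductance by a
sublevel fraction to emulate fast flickering.

**Equilibrium conductance noise.** δG(t) is a Gaussian 1/f^α process
(α ∈ [0, 2], default 1) with RMS equal to `conductance_noise_fraction`
times the instantaneous conductance. Because δG multiplies the driving
force, the low-frequency current noise power scales as (V − V_rev)²
*emergently*: the parabolic S(V) law is a consequence of the model, not an
imposed curve. Colored noise is synthesized spectrally — a white complex
Gaussian spectrum shaped by f^(−α/2), inverse-transformed, and rescaled so
the sample RMS is exact — which gives the exact target spectrum at
O(n log n) cost.

**Instrument chain.** White noise ξ (pA RMS) is added, then the whole
current is passed causally through a digital Bessel low-pass that stands
for the in-line analog anti-alias filter (defaults 10 kHz, 8 poles at
50 kHz sampling; the validation experiments use a scaled chain of 400 Hz
at 2 kHz, see below). The filter state is initialized at steady state for
the first sample, since a real instrument has settled long before the
recording starts; this avoids a spurious start-of-trace step. The filter
is realized at the acquisition rate rather than on a finer internal grid —
adequate because every simulated component is band-limited or white.

**Reproducibility.** One master seed is split with `numpy` SeedSequence
into fixed-order substreams (gating, flicker, conductance noise, white
noise, IV noise). The order is append-only, so enabling one noise term
never perturbs the draws of another, and identical configs give
bit-identical traces.

**What the simulator does not emulate:** capacitive transients, electrode
drift, line pickup, membrane rupture, voltage-dependent gating, or any
structural realism of the peptide–lipid assembly. Passing tests on these
traces therefore demonstrates correctness of the analysis algorithms under
the stated statistical model, not robustness to every artifact of real
recordings.

## Filtering and I/O

Digital filtering uses the analog Bessel prototype mapped by bilinear
transform with magnitude prewarping (scipy, `norm="mag"`), so DC gain is
exactly 1 and the gain at the cutoff is exactly −3 dB; it is applied
causally (forward only), matching instrument-style digital filters rather
than zero-phase offline filtering. Decimation applies an 8-pole Bessel at
0.4× the new sampling rate before subsampling. Traces are stored as
ATF-style tab-delimited text or CSV with `# key: value` headers; a time
column, when present, must be uniform to 1 ppm. Synthetic traces can carry
a JSON ground-truth sidecar.

## Step idealization

Published analyses of such recordings idealize steps manually; porekit
uses exact L0-penalised least squares instead: the changepoints of a
piecewise-constant mean minimizing RSS + β·(number of breaks), solved by
PELT with pruning. The single sensitivity knob is `penalty_factor` (default
10) in β = penalty_factor·σ̂²·log n, with σ̂ estimated robustly from the
median absolute successive difference (divided by √2·0.6745); this keeps
the penalty scale-free in the noise level. Segments shorter than twice the
acquisition-filter rise time (t_r ≈ 0.34/f_c) are disallowed so filter
edges are not counted as events. Events carry signed ΔG = ΔI/(V − V_rev)
using the epoch voltage; with an unknown protocol amplitudes are reported
in pA with a warning. On noiseless piecewise-constant input the recovery
is exact, and the signed ΔG of a trace telescopes to the net level change
by construction.

## Level statistics

Gaussian mixtures are fitted with EM (scikit-learn), components selected
by BIC over k = 1…5 by default (published histograms of this preparation
show at most three peaks; 5 leaves headroom). Fits are seeded and
reproducible; zero-variance input returns a flagged delta component.
Conductance histograms weight every event equally regardless of dwell —
matching the convention that step events count "regardless of stability or
duration" — with dwell-weighting available via the all-points histogram
instead. When building absolute-conductance histograms from idealized
levels, levels below a floor of 5σ̂/|V| are treated as the closed state
and excluded; the floor is derived from the trace's own noise estimate,
not from ground truth. The lowest-mean fitted peak is reported as the
minimal conductive unit.

## Noise analysis

PSDs are one-sided averaged periodograms over non-overlapping,
mean-subtracted, rectangular-window segments; the DC bin is dropped and
the Nyquist bin is not doubled. Resolution is f_s/L (e.g. 0.76 Hz for
65536-sample segments at 50 kHz), and Parseval holds to machine precision
against the mean per-segment variance. The plain rectangular window is
deliberate: it matches the unwindowed segment-averaged FFT convention of
acquisition-software PSD tools, and for the near-power-law spectra of
interest leakage is immaterial to band averages. The default 1 kHz 8-pole
Bessel prefilter is applied when the sampling rate allows it (auto mode
skips it below 2.5 kHz).

The 1/f^α exponent is −slope of an ordinary least-squares line on
log S vs log f, by default over 1–100 Hz: above the 1–10 Hz band used for
low-frequency averaging, and well below the prefilter rolloff. Per-bin
chi-squared scatter biases log S by a constant offset only, so the slope
is unbiased; recovery tests show |bias| < 0.1 for α ∈ {0.5, 0.8, 1.0, 1.2}.

S_lf is the arithmetic mean of PSD bins with 1 ≤ f ≤ 10 Hz. The
voltage dependence is fitted twice: constrained (S = aV² + c, vertex at 0)
and unconstrained (aV² + bV + c, vertex −b/2a). Classification:
**equilibrium** requires a > 0, constrained R² ≥ 0.95 and |vertex| ≤ 5 mV
(both configurable); **non-equilibrium** when an added V⁴ term is accepted
against the quadratic by a nested F-test at p < 0.01 (≥ 5 distinct
voltages needed), as for mechanisms whose noise grows faster than V²;
otherwise **inconclusive**.

## Selectivity

Reversal potentials come from the zero crossing of a least-squares line
through IV points that bracket zero current — appropriate because these
pores are ohmic over the measured range; the slope is reported as the
conductance. The orientation convention is V = V_cis − V_trans with trans
grounded and the peptide added on cis; "100/500 mM" reads cis/trans, so a
cation-selective pore under a higher trans concentration has RP > 0. The
convention is unit-tested for sign consistency and configurable through
the solution metadata.

Liquid-junction corrections use the single-salt Henderson reduction,
E(bath) − E(bridge) = (RT/F)·((u₊−u₋)/(u₊+u₋))·ln(c_bridge/c_bath), with
limiting mobilities tabulated for KCl, NaCl and LiCl; the two-bridge
correction is the cis-junction minus trans-junction difference (for 2 M
KCl bridges into 100/500 mM baths it is below 1 mV, KCl being nearly
equitransferent). A manual offset override exists for measured-LJP
workflows.

GHK conversion uses activities a = γ·c with the activity model selectable:
ideal (γ = 1, the default, since typical reports of this assay quote
concentrations), Davies (log₁₀γ = −0.509[√I/(1+√I) − 0.3I]) or a user
table. The forward map and its algebraic inverse round-trip to 1e-9
relative; the inverse raises, reporting the Nernst bound
(RT/F)·ln(a_t/a_c), when |RP| reaches it.

## Pore geometry

The cylinder model r = √(GL/(κπ)) is the primary estimate, with defaults
κ = 1.8 S/m (150 mM KCl, pH 7.4) and L = 4 nm (bilayer thickness), both
overridable. For a 50 pS unit this gives r = 0.188 nm and for 2 nS
r = 1.189 nm; rougher order-of-magnitude treatments sometimes quote these
as ≈ 0.25 nm and ≈ 1.5 nm, which the closed form does not reproduce — the
package reports the closed-form values and leaves the rounding to the
reader. The optional `cylinder+access` model adds the two pore-mouth
convergence resistances (1/G = L/(κπr²) + 1/(2κr), Hall's access
resistance) and is solved by bracketed root finding; it is clearly
labelled an extension — short wide pores are systematically undersized
without it. Because conductivity inside a nanoscale pore can differ from
bulk, formula sizing is rough; `compare_reference_channels` brackets a
measured G between user-supplied reference channels (gramicidin A ~0.4 nm,
alamethicin levels ~0.75/1.2 nm, VDAC ~1.25 nm, OmpF ≤1 nm are shipped as
radius annotations only) and interpolates radius on a log-log scale.
Reference conductances are user-supplied since they depend on the
electrolyte.

## Validation experiments and problem sizes

The canned experiments (`porekit.experiments`, driven by
`scripts/acceptance.py` and the validation tests) use a scaled acquisition
chain — 2 kHz sampling, 400 Hz 8-pole Bessel, 4× decimation to 500 Hz for
idealization — which preserves every bandwidth ratio that matters for the
analyses while keeping each experiment in the seconds range:

- **Permeability-ratio recovery**: ohmic IV sets (±50 mV in 10 mV steps,
  noise 5% of the current span) generated through the GHK forward map for
  ρ = 2.7 under 100/500 mM and ρ = 1.3 under 100/1000 mM KCl; 20 seeds.
- **Reversal-potential recovery**: 3 nS channel, true RP 30 mV, −10…+70 mV,
  5 pA noise; 20 seeds.
- **Minimal-unit recovery**: 50 s birth–death traces (≈ 200 events) of
  44 pS units at +50 mV and 66 pS units at −50 mV, 0.5 pA white noise;
  idealization → level histogram → mixture fit → lowest peak; 20 seeds.
- **Step-mode recovery**: 0.1 nS events (mean dwell 0.2 s) on a 3 nS
  stable pore at +70 mV, 1 pA white noise; mode of the |ΔG| histogram at
  0.02 nS bins; 20 seeds.
- **Spectral-exponent recovery**: conductance-noise traces with α = 0.9;
  fitted over 1–100 Hz; 20 seeds.
- **Equilibrium-noise law**: pure conductance-noise traces at
  0, ±25, ±50 mV, S_lf averaged over seeds per voltage, parabolic fit.

## Known limitations

- Step detection assumes piecewise-constant levels; ramps or strongly
  flickering sublevels are idealized as bursts of small steps.
- The Gaussian-mixture SE used for peak uncertainty is the naive
  sd/√(w·n), ignoring component-assignment uncertainty.
- The Henderson correction covers a single 1:1 salt; bi-ionic or divalent
  conditions are out of scope, as is multi-salt GHK.
- The F-test in the noise classification assumes independent Gaussian
  errors across voltages, which band-averaged PSDs only approximate.
- The simulator's dwell-time distributions are exponential by
  construction; real pores may show dynamic disorder (non-exponential
  lifetimes) that is not modelled.
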