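# Methods

## The system being modeled

`polbind` analyzes single-molecule fluorescence trajectories of a DNA
polymerase (the exonuclease-deficient Klenow fragment of *E. coli* DNA
polymerase I) binding surface-immobilized DNA primer–templates, with or
without a carcinogenic arylamine adduct (AF-dG or AAF-dG) at or across from
the primer terminus. Two observables report on the binding orientation:

- **apparent FRET**, E = I_A / (I_A + I_D), between a Cy3 donor on the DNA
  and a Cy5 acceptor on the polymerase — distinct binding orientations give
  distinct FRET levels (pol site ≈ 0.59 or 0.4 depending on primer length,
  intermediate site ≈ 0.50, exo site ≈ 0.63);
- **PIFE** (protein-induced fluorescence enhancement), the Cy3 intensity
  normalized to 1.0 for unbound DNA, which rises when the polymerase
  footprint reaches the dye.

Binding kinetics are modeled as a continuous-time Markov chain (CTMC) over
a small state set; each state carries a FRET and a PIFE level. The package
implements both directions of the analysis: simulating trajectories from a
kinetic scheme through a realistic camera model, and reducing (real or
simulated) traces back to populations, rates, free energies and pathway
fractions.

## Kinetic schemes and simulation

A `KineticScheme` is a labeled rate matrix (s⁻¹, diagonal zero) plus
per-state emission levels. `simulate_path` draws exact Gillespie
realizations: the dwell in state *i* is exponential with the summed
outgoing rate, the destination multinomial in the individual rates, and
the trajectory is truncated (right-censored) at the requested duration.

The preset catalog encodes the characterized constructs with their
measured dissociation rate constants: unmodified templating-base k_off =
0.40 s⁻¹; AF 0.10 s⁻¹; AAF 0.07 s⁻¹; ternary complex with an AF adduct
2.5 s⁻¹; and for the AAF-adducted n+1 construct, intermediate↔exo
shuttling at k_exo = 2.1 s⁻¹ (intermediate→exo) and k_int = 4.3 s⁻¹
(exo→intermediate), with dissociation from the intermediate at the AAF
binary-complex k_off. Association is pseudo-first-order at 0.5 s⁻¹ by
default — the association rate is not an estimation target here; the
value is chosen so a 60–100 s trace contains several binding events, and
it is overridable everywhere.

`add_direct_dissociation` augments the unbound ← intermediate ↔ exo
topology with a direct exo→unbound exit such that a requested fraction
*f* of dissociation events terminates at the exo site. The rate follows in
closed form from the embedded jump chain (derivation in the function's
docstring); *f* is bounded above by the branching probability
a = k_IX/(k_IX + k_IU) ≈ 0.968 for the AAF scheme, and f = 1 is reachable
only by closing the intermediate exit.

## Camera model

Frames are half-open windows of `frame_time` = 50 ms (a partial final
frame is discarded). The ideal per-frame signal is the time-weighted mean
of the state emission levels over the exposure — this exposure-time
integration is what blurs transitions faster than the frame time and
produces apparent intermediate levels. Detection adds independent Gaussian
noise per channel; defaults (1000 counts/frame total, 30 counts noise per
FRET channel; 100 counts on a 1000-count PIFE baseline) are calibrated so
the apparent-FRET standard deviation is ≈ 0.02 and the normalized-PIFE
standard deviation ≈ 0.1, the stated experimental uncertainties.
Single-step photobleaching (exponential bleach times; acceptor bleach
zeroes the transfer, donor bleach drops everything to background) is
available but off by default. Blinking, spectral crosstalk and gamma
corrections are out of scope — the analysis starts from extracted traces.
The optional centered moving average (5 or 7 points, shrinking windows at
the edges so the length is preserved for idealization) mirrors the
smoothing applied to the experimental traces.

What the generator does *not* emulate: non-exponential dwells, static
heterogeneity between molecules, baseline drift, and correlated noise.
Passing recovery tests on these data therefore demonstrates estimator
correctness under the stated model, not robustness to every artifact of
real recordings.

## Rate estimation

**Dissociation rates (slow, dwell ≫ frame).** Bound events come from
thresholding (events must clear the threshold for ≥ 2 frames; the
midpoint between baseline and bound level is the default threshold). The
rate is the censored-exponential MLE k = n_uncensored / Σ durations, with
stderr k/√n_uncensored. First and last events of each trace and
bleach-terminated events are censored: their boundary is unobserved, and
ignoring that inflates k (the naive inverse-mean is ~2× too fast at 50%
censoring).

**Shuttling rates (dwells of a few frames).** Traces are idealized with a
shared Gaussian-emission HMM (Baum–Welch, relative log-likelihood
tolerance 10⁻⁶, ≤ 500 iterations, 5 restarts with jittered means, best
likelihood kept) followed by Viterbi decoding; states are mapped to
(unbound, intermediate, exo) by sorted emission means, deterministically.
Emissions are initialized from a pooled mixture fit — the 0.50 and 0.63
components are close enough that random initialization makes them swap —
and the EM monotonicity guarantee is asserted at every iteration (the
underlying library is driven one step at a time with a vanishing
covariance prior, so the M-step is maximum likelihood, not MAP).

Three estimators are implemented, because frame integration biases them
differently:

1. `rates_from_idealization` — transition-count MLE k(i→j) = N(i→j)/T(i)
   on the Viterbi path, with segments < 2 frames merged into their longer
   neighbor (the 50 ms resolution floor) and final segments censored.
   Simple and right for slow kinetics, but dwells shorter than the
   detection limit are invisible: for the AAF shuttling rates this
   estimator reads ~30% low, which is precisely the artifact that
   motivates pushing candidate models through the full pipeline.
2. `rates_from_transition_matrix` — Q = logm(P)/Δt from the fitted
   per-frame transition matrix, correcting for multiple jumps per frame
   (~10% low for the same data; the residual comes from emission
   blurring at transitions).
3. `rates_from_lagged_transitions` — the default for fast shuttling:
   transition counts at a lag of several frames (default 3, i.e. 150 ms,
   below typical dwell lengths), then Q = logm(P_lag)/(lag·Δt). The
   single-frame assignment blur at each transition is amortized over the
   lag, recovering the generating 2.1/4.3 s⁻¹ within a few percent.

The disagreement between (1) and (3) is itself a useful diagnostic of how
close the kinetics are to the camera resolution.

## Populations and free energies

Pooled bound-frame values are fit with Gaussian mixtures (EM, 10
k-means++-seeded restarts, relative total-log-likelihood tolerance 10⁻⁸,
components reported sorted by mean, BIC-based component selection on
request). Bound frames are selected by ground truth when it exists,
otherwise by threshold — the zero-FRET population also contains inactive
acceptors, so FRET population ratios are treated as upper bounds on the
unbound fraction. The fast-exchange average (occupancy-weighted mean
level) quantifies what shuttling faster than the frame time would read:
equal-time pol/exo exchange would give PIFE ≈ 1.5, whose absence in the
data rules out that explanation of the 0.50-FRET state.

Rate ratios convert to binding free-energy differences via
ΔΔG = RT ln(k₁/k₂), R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, T defaulting to
295.15 K (room temperature); errors propagate to first order. The
measured rate set gives 0.8 kcal/mol (AF, 4-fold), 1.0 kcal/mol (AAF) and
~2.9–3.0 kcal/mol (the ~150-fold ternary destabilization).

## Pathway inference

For every binding event the **association pause** is the idealized
intermediate time between leaving the unbound state and first reaching
exo, and the **dissociation pause** the intermediate time between the
final exo visit and unbinding; zero pauses are direct transitions. Events
whose relevant boundary is unobserved (trace start/end) are excluded.

Candidate schemes are compared with observed data only after passing
through the identical pipeline — Gillespie path, camera integration,
noise, moving average, HMM/Viterbi — so both sides carry the same
integration and smoothing artifacts. Two artifacts matter and are
reproduced deliberately: (i) under the obligatory model a small fraction
of transitions still *looks* direct (unbound↔exo) in frame-integrated
data, shrinking as the frame time shrinks; (ii) through the smoothed
pipeline literally-zero pauses disappear, because every direct exit
acquires one or two spurious intermediate frames on the way down. The fit
is therefore a comparison of full pause-length histograms (0.1 s bins,
summed squared differences of normalized histograms by default;
Kolmogorov–Smirnov distance as an alternative — the choice of objective
was open and least squares was adopted for its insensitivity to single
bins), not of literal zero fractions.

`fit_direct_fraction` scans the direct-dissociation fraction on a grid
(default 0–1 in 0.05 steps with 0.01 refinement around the minimum). Two
implementation details proved essential and are part of the method: all
candidates and the observed data must be decoded with the *same* HMM
(otherwise transition-matrix differences, not kinetics, dominate the
objective), and when the pipeline fits that HMM itself, Baum–Welch is
initialized at the scheme's emission levels — a blind mixture
initialization on smoothed data can seed EM in a degenerate optimum with
one wide component straddling both bound levels. A ground-truth mode
(no camera, no HMM) is retained as the analytic oracle: there the
obligatory model yields strictly positive association pauses distributed
Exp(k_IX + k_IU), and the zero-pause fraction equals the generating
direct fraction.

## Problem sizes and numerics

The shipped test suite runs the full pipeline at reduced but statistically
meaningful sizes: 60–120 traces of 80–100 s for idealization and
transition-density checks, 1,500–2,000 observed traces and 300 traces per
grid candidate for pathway recovery, 200 replicates for estimator
bias/coverage. The acceptance script uses 10,000 observed traces of 60 s
and 600 traces per candidate. Every stochastic operation takes an
explicit seed (NumPy `SeedSequence` spawning per trace), and identical
seeds reproduce trajectories bitwise.

Degenerate inputs are handled explicitly: absorbing states yield a single
full-length segment; thresholds outside the data range segment nothing and
warn; all-censored dwell sets, empty selections, unreachable pathway
fractions and non-converged EM raise with actionable messages rather than
returning numbers.

## Known limitations

- The lagged-rate estimator assumes the lag time stays below typical
  dwells; for kinetics another ~3× faster than the AAF shuttling the
  50 ms camera simply cannot support rate estimation.
- PIFE baseline estimation assumes an identifiable unbound population; a
  molecule bound throughout normalizes incorrectly unless a baseline is
  supplied.
- The direct-dissociation fit inherits Monte-Carlo noise from its
  candidate simulations; with 600 traces per candidate the argmin is
  reproducible to about one coarse grid step.
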