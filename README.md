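# polbind

Single-molecule FRET/PIFE kinetics of DNA polymerase–DNA binding:
simulation of multi-state binding trajectories through a realistic camera
model, trace idealization, dwell-time rate estimation, transition-density
analysis, free-energy differences from rate ratios, and pause-length-based
discrimination of dissociation pathways.

## The scientific problem

Bulky carcinogenic adducts such as 2-aminofluorene (AF-dG) and
*N*-acetyl-2-aminofluorene (AAF-dG) on a DNA template stall or block
high-fidelity polymerases. Single-molecule fluorescence resolves *how*: a
Cy3/Cy5 FRET pair reports the binding orientation of the Klenow fragment
on a primer–template (apparent FRET E = I_A/(I_A+I_D); pol site ≈ 0.59 or
0.4, a newly resolved intermediate site ≈ 0.50, proofreading exo site
≈ 0.63), while PIFE (Cy3 enhancement, normalized to 1.0 for unbound DNA)
reports binding independently of the acceptor.

The quantitative core is a continuous-time Markov chain over binding
states. Dissociation rate constants come from censored-exponential maximum
likelihood on bound dwell times, k = n_uncensored/Σt, and convert to
binding free-energy differences via ΔΔG = RT ln(k₁/k₂). Fast
intermediate↔exo shuttling (k_exo = 2.1 s⁻¹, k_int = 4.3 s⁻¹) is
estimated from hidden-Markov idealization of the 50 ms-frame traces — with
explicit treatment of the exposure-time-integration artifacts that bias
naive estimators when dwells approach the frame time. Whether exo-site
binding requires an obligatory intermediate visit, and what fraction of
dissociations leaves the exo site directly, is decided by simulating
candidate kinetic schemes through the *full* measurement pipeline (camera
integration → noise → moving average → HMM/Viterbi) and fitting their
pause-length distributions to the observed one on a grid of direct
fractions. This package is aimed at single-molecule spectroscopists who
want that entire analysis chain as tested, seedable library code.

## Worked example

Simulate the AAF-adducted n+1 construct (unbound/intermediate/exo at
FRET 0/0.50/0.63, shuttling 2.1/4.3 s⁻¹) through the camera model, then
recover everything from the traces alone:

```python
import numpy as np
import polbind as pb

ds = pb.generate_dataset("aaf_n1", n_traces=120, duration=100.0, seed=42)
fret = [np.nan_to_num(pb.apparent_fret(t.donor, t.acceptor), nan=0.0)
        for t in ds.traces]

bound = np.concatenate([v[ds.bound_mask(i)] for i, v in enumerate(fret)])
mix = pb.fit_population_mixture(bound, n_components=2, seed=0)
print(f"FRET populations: {mix.means[0]:.3f} / {mix.means[1]:.3f} "
      f"(weights {mix.weights[0]:.2f} / {mix.weights[1]:.2f})")

fit = pb.fit_hmm(fret, n_states=3, seed=1)
print(f"HMM emission means: {np.round(fit.means, 3).tolist()}")

paths = pb.viterbi(fit, fret, 0.05)
Q = pb.rates_from_lagged_transitions(paths)
print(f"k_exo (intermediate -> exo): {Q[1, 2]:.2f} s^-1")
print(f"k_int (exo -> intermediate): {Q[2, 1]:.2f} s^-1")

td = pb.transition_density(paths)
print(f"direct unbound<->exo transitions: "
      f"{100 * td.class_fraction(('unbound', 'exo')):.1f}%")

dg = pb.delta_g(0.40, 0.07, temperature=295.0)
print(f"AAF stabilization: {dg.value:.2f} kcal/mol")
```

Output:

```
FRET populations: 0.503 / 0.625 (weights 0.68 / 0.32)
HMM emission means: [0.014, 0.502, 0.624]
k_exo (intermediate -> exo): 2.00 s^-1
k_int (exo -> intermediate): 4.10 s^-1
direct unbound<->exo transitions: 0.6%
AAF stabilization: 1.02 kcal/mol
```

Reading it: the two bound-state populations sit at the intermediate
(0.50) and exo (0.63) levels; the lag-corrected rate estimator recovers
the generating shuttling rates within a few percent despite the 50 ms
camera blur; fewer than 1% of idealized transitions look like direct
unbound↔exo binding, the signature of an obligatory intermediate; and the
4-fold → 5.7-fold slowdowns of dissociation translate to 0.8 and
1.0 kcal/mol of binary-complex stabilization by AF and AAF.

The same steps are available as a CLI
(`polbind simulate | reduce | histogram | dwell | hmm | tdp | pauses |
fit-fraction | report`); `polbind report --config cfg.yaml --out-dir out`
writes a delimited summary of rates, fold changes, ΔΔG values and
population means from an archived config + seed.

## Layout

- `polbind.kinetics` — schemes, presets, Gillespie simulation, the
  direct-dissociation construction
- `polbind.synthetic_data` — camera integration, emission noise,
  photobleaching, moving average, dataset generation
- `polbind.trace_metrics` — apparent FRET, PIFE normalization, histograms,
  Gaussian-mixture population fits
- `polbind.dwell_kinetics` — event segmentation, censored-exponential MLE,
  fold changes, ΔΔG
- `polbind.hmm_idealization` — Baum–Welch/Viterbi idealization, rate
  estimators, transition density plots
- `polbind.pathway_inference` — pause measurement, pipeline simulation,
  direct-fraction fitting
- `polbind.io`, `polbind.cli` — plain-text trace/dataset formats, config,
  command-line interface

See `docs/methods.md` for the model, estimators, numerical choices and
known limitations.
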