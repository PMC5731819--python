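# smswitch

Simulation and analysis of multi-color CoSMoS (co-localization single-molecule
spectroscopy) experiments on the *E. coli* DNA replication machinery: the
loading and unloading of the β sliding clamp by the clamp loader complex, and
the competition of the replicative polymerase Pol IIIcore with the translesion
polymerases Pol II and Pol IV for the clamp's hydrophobic binding groove.

In these experiments, fluorescently labeled proteins bind individual
surface-tethered primer-template DNA molecules, and up to three laser channels
are exposed in rapid alternation (50 ms exposure; one frame per channel every
220 ms, so a 0.66 s cycle for 3 colors, 0.44 s for 2, and 0.086 s for a single
channel). Binding events appear as intensity bursts; their durations (dwell
times τ_on = 1/k_off), the timing relations between channels (co-arrival,
co-departure, release-to-arrival lags), and the classification of polymerase
switching versus co-localization carry the mechanism.

`smswitch` provides both directions of that measurement:

- **Forward model** — continuous-time Markov chain (Gillespie) simulation of
  the binding schemes (clamp loading with ATP or ATPγS, unloading of
  pre-loaded clamps with a productive/non-productive branch, Pol IIIcore on
  clamp-DNA, the τ-complex with tethered Pol IIIcore, open multi-polymerase
  competition with optional two-groove co-occupancy), rendered into realistic
  traces with interleaved channel sampling, incomplete labeling (a Bernoulli
  draw per binding protein copy), photobleaching (constant hazard per
  illuminated second, so apparent dye lifetime scales with the duty cycle),
  background and Gaussian noise. Optionally, full synthetic image stacks with
  Gaussian spots.
- **Inverse pipeline** — robust per-trace interval detection (hysteresis
  thresholds in background-SD units, gap bridging, censoring flags), interval
  algebra and event classification (loading, productive/non-productive
  unloading, switches with lags, co-localizations with first-in/first-out
  order), the co-localization-based labeling-efficiency estimator, and
  dwell-time fitting: the field-standard one-parameter exponential histogram
  fit with bin width ≈ τ/2 (iterated re-binning, optional first-bin
  exclusion), plus a censored/frame-quantized maximum-likelihood estimator and
  bootstrap errors.

Every scenario preset installs published kinetic parameters (lifetimes, lags,
branch fractions, labeling efficiencies, dye bleach lifetimes) as generator
truth, and the run report pairs each recovered value with that truth. The key
dwell model throughout is single-step dissociation: dwell times are
exponential with mean τ = 1/k_off, and an apparent lifetime under
photobleaching obeys the competing-risk composition
1/τ_app = 1/τ + 1/τ_bleach.

## Worked example

Simulate the Pol IIIcore-on-clamp-DNA experiment (dissociation rate 1/15.7 s⁻¹
installed as truth, 3-color schedule, 60% labeling, Atto 488 bleaching) and
recover the lifetime with the histogram fit:

```python
import smswitch as sw

cfg = sw.scenario_config("fig3_pol3", n_molecules=500)
report = sw.run_scenario(cfg, seed=7)
print(report.summary())
```

```
scenario fig3_pol3 (seed 7, 500 molecules, config b704927241ee28e6)
  tau_pol3_raw: tau = 14.8 +/- 0.16 s (histogram_1p, n=4331)
  tau_pol3_corrected: tau = 15.7 +/- 0.18 s (histogram_1p, n=4331)
  tau_pol3: tau = 14.8 +/- 0.16 s (histogram_1p, n=4331)
  n[intervals] = 4434
  recovery vs truth:
    tau_pol3: truth 15.7, recovered 14.85 +/- 0.16 [pass]
```

4331 complete dwells were detected and fitted. The raw apparent lifetime
(14.8 s) sits below the installed 15.7 s because the Atto 488 dye bleaches
with an apparent lifetime of 274.4 s under this schedule; inverting the
composition law recovers 15.7 s (`tau_pol3_corrected`). The recovery line
compares against the installed truth with combined standard errors.

The same interface runs `fig2_loading`, `fig2_atpgs`, `fig2_unloading`,
`fig2_clamp` (10 s interval mode), `fig3_pol1`, `fig3_tau_complex`,
`fig4_competition`, `table2_mutants` (clamp-groove/rim mutants), and
`table3_lesion` (the substrate-tag null). There is also a CLI:

```sh
smswitch run --preset fig2_unloading --seed 1 --out runs/unloading
smswitch report --run runs/unloading
smswitch fixtures --preset fig2_atpgs --out fixtures/atpgs
```

Published reference values with their provenance descriptions ship in
`src/smswitch/data/reference_values.csv`;
`smswitch.compare_to_reference` z-tests any recovered table against them.

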