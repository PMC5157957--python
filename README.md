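# cole2sim

Deterministic and stochastic simulation of **colicin E2 expression dynamics
in *Escherichia coli***: the hierarchical post-transcriptional regulation of
the lysis-carrying long transcript by the RNA-binding protein CsrA and the
CsrA-sequestering small RNAs CsrB/CsrC, coupled to the LexA–RecA SOS stress
response that drives toxin release.

The package is for systems biologists studying molecular-titration
thresholds, post-transcriptional noise control, and the timing of
stress-induced lysis — anyone who wants to go from a table of per-cell rate
constants to steady states, Fano-factor maps, exact Gillespie ensembles and
lysis-time distributions.

## The model

The post-transcriptional core reduces to three free species per cell — long
mRNA `M`, CsrA dimers `A` and an effective one-binding-site sRNA `S` (one
real CsrB/CsrC with N ≈ 22 sites is book-kept as N one-site molecules, so
the effective production is *Nα*<sub>S</sub>):

```
dM/dt = α_M − δ_M·M − k_M·M·A
dA/dt = α_A − δ_A·A − k_M·p_M·M·A − k_S·p_S·A·S
dS/dt = N·α_S − δ_S·S − k_S·A·S
```

Complex formation, dissociation and decay are folded into *coupled
degradation*: an encounter removes the RNA, and the CsrA dimer with
probability `p_M` (resp. `p_S`). The stationary state follows from a single
cubic in `A` (solved exactly, plus a two-branch quadratic approximation),
and exhibits a sharp **expression threshold** at

```
p_M·α_M + p_S·N·α_S = α_A
```

— free mRNA/sRNA and free CsrA are mutually exclusive across it.
Fluctuations are quantified by the Fano factor Var(M)/⟨M⟩ from the
leading-order van Kampen (linear-noise) expansion: exactly 1 in the
unregulated birth–death limit, maximal just above the threshold, and damped
by raising sRNA production.

The full model adds the LexA–RecA layer: LexA dimers repress their own
gene, *recA* and the 20 plasmid-borne SOS promoters; a stress signal steps
the RecA-mediated LexA-cleavage level `c_p` from 0 to 6 (t = 200–500 min),
derepressing transcription. The CsrA buffer then filters short activity
bursts and delays the first burst of long mRNA (onset: M > 8 molecules),
which serves as the lysis proxy for per-cell lysis times and the population
survival function.

All stochastic simulation is the exact direct-method Gillespie algorithm
(numba-compiled, piecewise-constant signals handled exactly); deterministic
integration uses a stiff adaptive solver.

## Worked example

Stationary state and threshold classification at the default rates
(α_A = 58.52, effective sRNA production Nα_S = 57.5, α_M = 20):

```console
$ cole2sim steady --out out/steady
{
  "exact":  {"M": 24.49, "A": 0.154, "S": 70.41, "regime": "super_threshold"},
  "approx": {"M": 24.49, "A": 0.154, "S": 70.41, "branch": "low_abundance_approx"},
  "threshold": {"super_threshold": true, "margin": 18.98}
}
```

With 20 + 57.5 > 58.52 the system sits above the titration threshold:
CsrA is titrated to a fraction of a molecule while mRNA and sRNA are
abundant, and the quadratic approximation agrees with the exact cubic root
to four digits.

Lysis timing under the standard SOS protocol (c_p stepped 0 → 6 at
t = 200 min, off at t = 500 min), 100 stochastic cells:

```console
$ cole2sim lysis --seed 1 --n-realizations 100 --out out/lysis
{
  "n_realizations": 100,
  "n_censored": 0,
  "mode_delay": 60.0,
  "mean_onset_delay": 55.09,
  "mean_peak_delay": 59.5
}
```

Every cell shows a long-mRNA burst (no censoring), but only after a broad
delay: the first-peak histogram (10-min bins from signal onset) is maximal
in the 60-min bin, i.e. the population lyses heterogeneously about an hour
after induction, long after the promoters themselves derepress. Per-cell
onset/peak times, the survival curve and a reproducibility manifest are
written to `out/lysis/`.

Other subcommands: `phase` (stationary-abundance maps with the threshold
line), `fano` (linear-noise heatmap), `ssa` (single realization + reaction
audit), `sos-run` (deterministic vs ensemble time courses), `sweep` (mean
lysis delay vs stress level c_p).

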