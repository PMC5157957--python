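# Methods

## Model

### Reduced post-transcriptional core

The colicin E2 operon produces two transcripts from its LexA-repressed SOS
promoter; only the long one carries the lysis gene *cel*. Its translation is
blocked — and its decay accelerated — by dimers of the carbon storage
regulator CsrA binding at the ribosome-binding site, and CsrA is in turn
sequestered by the small RNAs CsrB and CsrC ("the regulator's regulator").
The package models the free copy numbers of three species per cell: long
mRNA `M`, CsrA dimers `A`, and an effective sRNA `S`:

    dM/dt = alpha_M − delta_M·M − k_M·M·A
    dA/dt = alpha_A − delta_A·A − k_M·p_M·M·A − k_S·p_S·A·S
    dS/dt = N·alpha_S − delta_S·S − k_S·A·S

Two model reductions stand behind these equations, both implemented as
explicit operations so their assumptions are auditable:

* **Effective transcription rate** (`effective_transcription_rate`):
  promoter binding/unbinding is fast relative to RNA production and decay
  (adiabatic elimination), so transcription from `n_sos` plasmid copies
  becomes a single rate `n_sos · per-plasmid rate · P(promoter free)` with
  `P(free) = k_off/(k_off + k_on·LexA)`.
* **Effective sRNA** (`effective_srna_reduction`): a real sRNA with N
  binding sites (N ≈ 22 for CsrB, with ~9 dimers bound on average) is
  replaced by N independent one-site molecules, i.e. production `N·alpha_S`.
  Under per-site quasi-equilibrium (on/off fast against production and
  decay) the complex pathway collapses to coupled degradation with
  `k_S = delta_complex · k_on/k_off`, and the bound CsrA dies with its
  carrier (`p_S = 1`). The package also ships the detailed (N+5)-species
  scheme — all occupancy configurations C_0..C_N with combinatorial
  binding factors, the mRNA–CsrA complex, and a lysis-protein readout — as
  a consistency tool (`reduced_vs_detailed_equivalence`).

  One caveat the equivalence scan makes visible: the reduction preserves
  mean-field behavior and free-site statistics, but when all effective
  sites ride on a handful of multi-site carriers, Poisson dips of the
  *carrier* pool transiently collapse the titration capacity and let free
  CsrA surge. This granularity effect is invisible to the one-site model
  at any complex speed; free-site and mRNA means still agree.

### Stationary solutions and the threshold

Eliminating `M` and `S` leaves a strictly decreasing scalar balance for
free CsrA whose cleared form is a cubic; the non-negative root is unique
and found by bracketing + Brent iteration (`steady_state_exact`). Dropping
the cubic term gives a quadratic valid at small `A` (super-threshold side);
dropping the constant term gives one valid at large `A` (sub-threshold
side); the branch whose omitted term is smaller at its own root is
returned, and equating the omitted terms defines the transition line
(`steady_state_approx`, white-line analog in phase surfaces).

The expression threshold is the zero set of the large-A branch,
`p_M·alpha_M + p_S·N·alpha_S = alpha_A`: below it, every transcript is
captured by abundant CsrA; above it, mRNA and sRNA titrate CsrA away. It is
computed generically from `p_M`, `p_S` (not hard-coded for p = 1), and its
sharpness rests on CsrA decaying much more slowly than the RNAs
(`delta_A ≪ delta_M, delta_S`).

### Linear-noise analysis

Reformulating the reduced scheme as a master equation and expanding to
leading order (van Kampen) gives Gaussian fluctuations around the
macroscopic fixed point; the stationary covariance solves the continuous
Lyapunov equation `J C + C Jᵀ + D = 0` with `J` the drift Jacobian and
`D = Σ a_r ν_r ν_rᵀ` (solved densely via `scipy.linalg.solve_continuous_lyapunov`).
Only leading-order terms enter the second moments — the `order` flag exists
but higher orders are deliberately not implemented. Known breakdown: at the
threshold the copy numbers are O(1), the expansion overestimates the Fano
factor (the SSA comparison in the tests shows this directly), and heatmap
cells with ⟨M⟩ < 5 molecules are flagged `LNA-unreliable`. `empirical_fano`
estimates the same quantity from SSA ensembles (time-and-ensemble pooled
Var/mean, bootstrap over realizations, split-half stationarity flag).

### SOS-coupled full network

The transcriptional layer follows the canonical LexA–RecA topology: LexA
dimers repress *lexA*, *recA* and the `n_sos = 20` SOS promoters (modelled
as one free/bound counter pair with mass-action propensities — identical
copies, large state-space saving); RecA mediates LexA auto-cleavage. Long
and short mRNAs are transcribed in proportion to open SOS promoters; the
short transcript is a promoter-activity proxy with first-order decay only
(its translation products are not tracked), the long one feeds the
post-transcriptional core and translates the lysis protein `L`.

The cleavage propensity is mass action, `c_p(t) · gamma_cleave · R · Le`.
`c_p` is the dimensionless stress level of the schedule (default step
0 → 6 → 0 at t = 200/500 min); `gamma_cleave` (2·10⁻³ per molecule² per
min) normalises the product of realistic LexA/RecA copy numbers so that the
LexA clearance time moves through the minutes-to-tens-of-minutes range as
`c_p` spans 1–90 — without it, any stress level would clear LexA in
seconds and stress levels would be indistinguishable. A saturating form was
considered and rejected for the same reason at one more parameter; the
functional form is recorded in every run manifest.

Simulation protocol: runs start from the rounded deterministic fixed point
at `c_p = 0` (computed by long stiff integration + root polishing, with
promoter-count conservations restored exactly after rounding), so the
200-min pre-signal window verifies stationarity rather than creating it —
the CsrA pool relaxes on the 1/delta_A ≈ 500 min timescale and could not be
equilibrated by burn-in alone.

### Lysis statistics

Onset of the first peak = first time `M` exceeds 8 molecules; peak = the
maximum of the contiguous excursion above that threshold; cells that never
cross are censored. Histograms use 10-min left-closed bins with origin at
signal onset; the mode carries a bootstrap CI. The survival function is the
fraction of cells with no peak by time t (censored mass at +∞), so it is
exactly the complement of the peak-time CDF. For the stress sweep
(`stress_sweep`) the default delay statistic is the burst *onset* rather
than the excursion peak: under a sustained strong signal the mRNA plateau
never re-crosses the threshold, the excursion maximum degenerates into the
argmax of a long noisy plateau, and only the onset remains an informative
delay measure. `lysis_time_distribution` keeps the peak-based definition.

## Parameters

Rates are per cell (V ≈ 0.65 µm³) per minute. Headline values shipped as
defaults: `alpha_A = 58.52`, effective sRNA production
`N·alpha_S = 57.5` (stored as `N = 22`, `alpha_S = 57.5/22` — the
printed production values are only consistent with the threshold balance
at `alpha_A ≈ 58.5` if they denote the *effective* production, and the run
manifest records this convention), `n_sos = 20`, onset threshold 8
molecules, `c_p` schedule 0/6/0 at 0/200/500 min.

The remaining rates are package defaults chosen once on literature-scale
reasoning and then frozen:

| parameter | default | rationale |
| --- | --- | --- |
| `delta_M`, `delta_S`, `delta_Ms`, mRNA decays | 0.2 /min | bacterial mRNA/sRNA half-lives of a few minutes |
| `delta_A` | 0.002 /min | CsrA is highly stable; decay ≈ dilution over several generations; `delta_A ≪ delta_RNA` makes the threshold sharp and sets the free-CsrA buffer (≈ 440 dimers at the default operating point) |
| `k_M`, `k_S` | 4 /(molecule·min) | effective bimolecular association near the diffusion-limited per-cell scale; large `k/delta_A` makes sub-threshold abundances effectively zero |
| `p_M`, `p_S` | 1 | complexes are degraded as a unit; gives the clean threshold balance |
| LexA module | `alpha_lexA = 0.125`, `beta_lexA = 20`, `delta_lexA = 0.025`, operator `k_on = 0.01`, `k_off = 1` | ≈ 180 free dimers uninduced with strongly bursty translation (few mRNAs × large burst size), as SOS promoter activity is known to be |
| RecA module | `alpha_recA = 0.25`, `beta_recA = 8`, `delta_recA = 0.004` | ≈ 900 RecA uninduced, rising a few-fold under stress |
| SOS operator | `k_on_sos = k_off_sos = 0.05` | ≥ 99% repression at uninduced LexA levels; ~20-min dwell times give bursty promoter activity after induction |
| `alpha_Ml` / `alpha_Ms` | 1.2 / 5 per open promoter | short transcripts are the majority; the long-mRNA influx at full induction (~11/min) empties the CsrA buffer in tens of minutes |
| `gamma_cleave` | 2e-3 | see cleavage normalisation above |
| `beta_L`, `delta_L` | 0.1, 0.02 | lysis-protein readout only |

These defaults emulate the *stated study conditions*: complete uninduced
repression with promoter-noise filtering, a post-induction expression delay
of tens of minutes (deterministically ≈ 1 h at `c_p = 6`), a broad
heterogeneous lysis-time distribution, full lysis within a 300-min signal,
and earlier lysis at stronger stress. They are not fits to any dataset:
absolute times and abundances should be read as order-of-magnitude
biology, not calibrated predictions, and passing tests show internal
consistency of the model's mechanisms — threshold, filtering, delay,
noise control — not agreement with any particular cell. Two published
features that hinge on the reference network's exact rate table are not
reproduced at these defaults and are asserted only in their weaker form in
the tests: the stochastic ensemble mean tracks (rather than undershoots)
the deterministic curve after induction, and doubling-level increases of
sRNA production accelerate lysis without producing pre-signal lysis.

## Numerical choices

* ODEs: LSODA with `rtol = atol = 1e-8` (absolute tolerance ≪ 1 molecule;
  near-threshold abundances are O(1)); the full network is integrated
  piecewise between schedule breakpoints so the `c_p` step is exact.
  Sub-tolerance negative excursions are clipped to zero.
* SSA: direct method (two uniforms per event), numba-compiled, legacy
  MT19937 seeding for bit-for-bit reproducibility; waiting times are capped
  at schedule breakpoints and redrawn (exact for piecewise-constant
  propensities). Event-sampled paths are projected onto a 1-min grid by
  last-value-carried-forward for ensemble statistics; a pure-Python path
  records full event logs for audits of small systems.
* Ensembles: child seeds are spawned from the base seed via
  `numpy.random.SeedSequence` (kept < 2³¹), so each realization is
  independently re-runnable from the manifest.
* Cubic root: bracketed Brent iteration on the monotone CsrA balance
  (machine precision), residuals of all three rate equations checked
  against `1e-6 · max(alpha)`. When several cubic roots were admissible the
  design rule is forward integration from the empty state, but monotonicity
  of the balance makes the non-negative root unique for `alpha_A > 0`.
* Map convention: stationary abundances below 1e-3 molecules are reported
  as 0 in surfaces (raw values remain accessible).

## Test problem sizes

The suite favours many small, decorrelated SSA runs over few long ones:
ensembles of 100–500 realizations for the SOS protocol (700 min),
500 × 200 min for the uninduced filtering check, 8 × 40 for the stress
sweep, and 10⁴ decorrelated samples for the Poisson goodness-of-fit; the
whole suite runs in about a minute on one core. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances; they are a
deliberate package choice to keep the suite quick to iterate on.

## Known limitations

* No cell growth, division, or volume changes; plasmid number is fixed
  (or drawn once per cell in the Poisson variant), never replicated.
* Colicin and immunity proteins are not tracked; the short mRNA is a
  promoter-activity proxy only, and lysis is identified with the first
  long-mRNA burst rather than explicit lysis-protein accumulation
  (`L` is tracked for sensitivity checks).
* Sequestration of CsrA by other cellular targets enters only through the
  effective production rate, not as explicit competing species.
* The linear-noise module is leading-order only and unreliable below ~5
  mean molecules (flagged, not hidden).
* The detailed complex scheme assumes `p_M = p_S = 1`; partial CsrA
  survival is only available in the reduced scheme's split reactions.
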