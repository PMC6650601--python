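# Methods

## Model and procedure

The analysis treats one test tube as one observation: `n_exposed` animals,
`n_immobilized` at test end, under a nominal suspended-solids concentration
`C` (mg/L) of which `m` percent by mass is the test particle (%MP). The
three-stage procedure is:

1. **Validation and background correction.** Particle-free controls
   (`ss_conc = 0`) give the pooled background mortality `p_c`; runs whose
   control mortality exceeds 10% are flagged (the usual acute-immobilization
   validity criterion) but not excluded — the gate warns, it does not abort.
   Every treatment proportion is Abbott-corrected,
   `p' = (p − p_c)/(1 − p_c)`, clipped to [0, 1].

2. **Per-mixture dose-response.** For each %MP level, the corrected replicate
   proportions are fitted by the constrained logistic
   `p(C) = 1/(1 + (LC50/C)^h)` — the log(dose) logistic family with the lower
   asymptote fixed at 0 and the upper at 1 so that curves are comparable
   across mixtures. The default estimates only `θ = log10 LC50` with the Hill
   slope fixed at `h = 1` (`hill_fixed=False` frees the slope). Estimation is
   ordinary least squares on the proportion scale (one tube = one unweighted
   observation), not a binomial GLM: replicate-level proportions are the unit
   the assay reports, and OLS on them matches the conventional curve-fitting
   treatment of such data. `LCx = LC50·(x/(100−x))^(1/h)`; 95% CIs are
   t-based linearization intervals on `θ` (df = n − p), exponentiated so
   bounds are positive, with the delta method on
   `log10 LCx = θ + log10(x/(100−x))/h` when the slope is estimated.
   Non-overlap of two LC50 CIs is read as evidence of a significant
   treatment difference.

   Two dataset-level rules precede fitting. Only SS concentrations common to
   all %MP levels are used, so every curve spans the same dose range. Cells
   with more replicates than the design target (endpoint treatments are
   typically rerun across batches) are balanced by repeated subsampling
   without replacement to the target (default 5) — each iteration refits the
   curve, and the point estimate and CI bounds are medians over iterations,
   with the min–max spread reported. The number of draws (default 100) and
   the aggregation are configurable because no single convention is canonical;
   the reported spread quantifies how much that choice matters.

3. **Thresholds.** The per-mixture LC10 values are fitted by the one-phase
   exponential decay `Y(m) = (Y0 − plateau)·e^(−k·m) + plateau` (unweighted
   least squares; plateau constrained ≥ 0; optional inverse-CI-width
   weights). The NOEC for suspended solids is the lower 95% bound of the
   reference-level (0% MP) LC10 — a deliberately conservative surrogate for a
   no-observed-effect concentration. NOE%MP is the closed-form crossing
   `m* = −(1/k)·ln((NOEC − plateau)/(Y0 − plateau))`, with honest boundary
   semantics: 0 when the curve starts at or below the NOEC, and an unbounded
   sentinel ("no %MP threshold within model range") when the curve never
   reaches it — never an extrapolated number. The effect level is
   configurable (`x_level`, default 10) since the same construction applies
   to LC50.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `hill` / `hill_fixed` | 1, fixed | Hill slope of the logistic; fixing it makes the fit a stable 1-parameter problem |
| `x_level` | 10 | effect percentage anchoring the decay and the NOEC |
| `subsample_target` | 5 | replicates per cell after balancing (the design's per-cell count) |
| `subsample_iterations` | 100 | subsample draws; median-aggregated |
| `control_flag_threshold` | 0.10 | per-run control-mortality validity gate (warn only) |
| `ci_level` | 0.95 | all intervals are 95% two-sided |

Numerical choices: `θ` is optimized within
`[log10 min C − 2, log10 max C + 2]` from three deterministic starts (no seed
dependence in a 1–2 parameter problem); the decay fit restarts from three
rate guesses spanning the %MP range and falls back — with a warning — to the
flat model when no decaying curve improves on it (then `k` is reported as
unidentifiable rather than as a spurious number). Subsampling streams are
keyed by `(seed, iteration, cell)`, so results are independent of execution
order and of input record order. A series whose corrected mortalities are all
identical is rejected as degenerate rather than fitted.

## The synthetic-data generator

`mpratio.synthetic` draws per-tube deaths from
`Binomial(n_per_tube, p_total)` with
`p_total = c + (1 − c)·p_model` — background mortality `c` composed with the
dose effect by independence, which makes Abbott's correction exactly right on
expectations — and an LC50 surface decaying exponentially in %MP. Default
conditions mirror a study-scale 96-h *Daphnia magna* assay with a PET/kaolin
dilution series: 6 %MP levels (0–100%), SS grids of 0.1–10 000 mg/L at the
endpoints and 10–10 000 mg/L for mixtures (28 planned cells), 5 replicates of
10 animals, background mortality 0.046, and an LC50 surface with
`Y0 = 411` mg/L, `plateau = 56` mg/L, `k = 0.08` per %MP — magnitudes chosen
once to be realistic for that assay (the rate puts the mixture LC50s in the
56–130 mg/L range typical of plastic-containing suspensions). Per-cell random
streams are keyed by cell identity, so extending the design never perturbs
existing cells. `extra_replicates` over-replicates chosen levels to emulate
unbalanced real-world layouts and exercise the subsampling stage.

What the generator does **not** emulate: particle aggregation and settling at
high concentrations (the real-world cause of non-monotone mid-range LC
values, which the decay fit absorbs as noise rather than modelling), run
(batch) effects on mortality, time-resolved death, or deviations from the
logistic form. Passing recovery tests therefore show that the estimators
invert the assumed data-generating process at realistic noise and sample
sizes — not that real suspensions obey that process.

## Recovery experiments and frozen bounds

`recover_log10_lc50` (500 simulated series at the study-scale design) checks
near-unbiasedness of the LC50 estimator (|bias| < 0.05 on the log10 scale).
`noe_recovery` (200 end-to-end simulations) measures NOE%MP error. Because
the NOEC is itself a sampling quantity (a CI bound), the target is the
design-implied analytic value: the asymptotic OLS variance of `θ` under
binomial tube noise gives the expected lower LC10 bound, and the true decay
is solved at it (`analytic_noe_reference`). Acceptance bounds — median
relative error < 0.25, relative RMSE < 0.75 — were calibrated once across
seeds and frozen; the RMSE is dominated by a right tail where a shallow
estimated `k` inflates the crossing point, a known sensitivity of
exponential-threshold constructions at only six %MP levels.

With the default unit Hill slope, LC10 is exactly LC50/9 for every mixture,
so the LC10 and LC50 decay fits share the same R²; the two are reported
separately because they differ whenever the slope is estimated.

## Known limitations

* Run effects are carried (`run_id`) but not modelled; no mixed-effects
  structure.
* Only two-component mixtures; no concentration-addition/independent-action
  interaction models.
* The NOE%MP has no confidence interval of its own (the `power` command's
  Monte-Carlo spread is the substitute).
* Nominal concentrations only; measured TSS/turbidity ingestion is out of
  scope.
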