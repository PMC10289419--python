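# Methods

This note records the model assumptions, numerical choices, and known
limitations of the `shelterchron` pipeline. It makes no empirical claims
beyond what the package computes.

## Calibration (`calcurve`, `calibrate`)

- A calibration curve is a table of knots `(cal BP, 14C age, sigma_curve)`;
  between knots both the mean and the uncertainty are linearly interpolated.
  The convention throughout is cal BP with larger = older.
- A date `(r, sigma)` is calibrated on a regular calendar grid (default step
  5 yr) with the error-in-variables Gaussian likelihood
  `p(theta) ∝ exp(-(r - mu(theta))^2 / (2 (sigma^2 + sigma_c(theta)^2)))
  / sqrt(sigma^2 + sigma_c(theta)^2)`, normalized to unit mass on the grid.
  Log-space evaluation avoids underflow; a density is flagged `truncated`
  when non-negligible mass (> 1e-6) touches the grid edge.
- The point summary is the probability-weighted mean ("mean intercept").
  Highest-posterior-density regions are built greedily by adding grid cells
  in decreasing mass order (ties resolved toward the older cell) until the
  requested level is reached, then merging contiguous cells into intervals;
  reported ranges are rounded outward.

## Phase model (`phase_model`)

- Uniform-phase prior: given boundaries, member ages are i.i.d.
  `Uniform(beta_p, alpha_p)`, contributing the span penalty
  `(alpha_p - beta_p)^(-N_p)`. Boundaries are flat on the study window
  subject to the ordering chain
  `W_old >= alpha_0 >= beta_0 >= alpha_1 >= ... >= beta_{P-1} >= W_young`.
  Continuous use collapses `beta_p` and `alpha_{p+1}` into one parameter; a
  hiatus keeps two. Boundaries may be pinned to known values
  (`fixed_start`/`fixed_end`), which also enables flat-prior oracle tests.
- Only intact-context dates may enter the model; disturbed, unprovenienced,
  pre-occupation, and modern dates are excluded up front and accounted for
  in the exclusion ledger, which never reconciles arithmetic silently: a
  stated sample size that disagrees with `total - excluded` is surfaced as
  a note.
- Sampling is Metropolis-within-Gibbs: one vectorized Gaussian random-walk
  sweep over all per-date ages (conditionally independent given boundaries),
  then single-site updates of each unique boundary. Proposal scales adapt
  during burn-in toward 20–40% acceptance (window 100, factors 0.8/1.25,
  clipped to [0.5, 5000]). Defaults: 50,000 iterations after 10,000 burn-in,
  thinning 10. Retained draws satisfy every ordering constraint by
  construction. Convergence is reported via effective sample size (Geyer
  initial-positive-sequence) and split-R̂ rather than OxCal's convergence
  index.
- Correctness is certified against an independent brute-force oracle
  (`tests/oracles.py`): dense-grid dynamic-programming integration of the
  2-phase/2-date joint posterior; the MCMC marginals must be within total
  variation 0.02 of the exact grid answer. A flat-prior (pinned-boundary)
  configuration must likewise reproduce the single-date calibrated density.
- Agreement index: `A_i = 100 * sum(p' p) / sum(p^2)` with `p` the
  unmodelled calibrated density and `p'` the modelled marginal histogrammed
  onto the same grid; `A_i = 100` when the model leaves a date unchanged.
  The combined index is `100 * prod(A_i/100)^(1/sqrt(n))`. The same
  combined formula is reported as both `A_model` and `A_overall`; treating
  the two as one statistic is a deliberate simplification — conventions that
  distinguish them (e.g., over modelled parameters only vs over all dates)
  coincide here because only modelled dates carry marginals.
- Screening removes the single worst date with `A_i < 60` per round and
  refits (round k reuses seed + k), aborting loudly if more than 20% of the
  dates would be removed.

## Event density (`event_density`)

- The site-use proxy is a Gaussian KDE over the mean intercepts,
  `f(x) = (1/nh) Σ K((x - x_i)/h)` with bandwidth h = 50 yr, evaluated on
  the 50-year analysis grid from 11,000 to 300 cal BP (215 points). The KDE
  uses all dates except modern and pre-occupation outliers — disturbed
  material still witnesses deposition at the site — while the phase model
  uses intact dates only.

## Deposition rates (`deposition`)

- Stratum thickness is the mean over the recorded unit corners (≤ 4 per
  unit). A stratum's time span `d` is the minimum bounding span of its dated
  events (≥ 2 events required; degenerate spans are errors, not zeros); its
  sedimentation rate is `s = Σ z̄ / d`, so `s · d = Σ z̄` holds exactly.
  The sitewide rate at a grid point sums `s` over all strata whose closed
  span covers it.
- Botanical specimens are assigned to modeled phases through a
  stratum→phase concordance (with optional per-level disambiguation);
  specimens whose context resolves to no phase, or ambiguously to several,
  are kept in explicit `unassigned` categories so counts are conserved. The
  botanical deposition rate per phase is count / modeled duration, painted
  onto the grid over the phase's mean-boundary interval.

## Crop proxies (`crop_proxies`)

- Crop index = `(field - tree) / (field + tree)` ∈ [−1, +1]; an assemblage
  with neither category is missing (NaN), not zero; `other` taxa are
  excluded from the index. Series are resampled to the shared grid by
  linear interpolation (never extrapolation), and Pearson correlations are
  computed pairwise-complete with two-sided t-test p-values; constant
  series yield NaN.

## Synthetic generator (`synthetic_data`)

- Forward model: true ages uniform within each configured phase (matching
  the phase model's likelihood, so recovery is well-posed); measured ages
  `Normal(mu_curve(theta), sqrt(sigma_lab^2 + sigma_c^2))`; default curve is
  the identity with sigma_c = 5 to keep oracles closed-form. Disturbance is
  simulated by re-labelling a date's stratum to a younger phase
  (re-deposition) without touching its age; looter backdirt specimens get a
  stratum with no concordance entry. Thickness corners are true thickness
  plus noise; botanical counts are multinomial from per-phase crop mixes
  scaled by intensity × duration. Output is byte-identical for a fixed
  (config, seed).
- The default scenario is a 16-phase episodic occupation over
  ~11,000–300 cal BP with inter-phase gaps of 100–2,000 years (one shared
  boundary), 300 intact dates (≥ 15 per phase, 7 carrying a +500 ¹⁴C-yr
  offset), 68 disturbed, 2 pre-occupation, 2 modern, 3 unprovenienced, and
  9,800 botanical specimens whose mix shifts from tree-dominant to
  field-dominant after ~4,000 cal BP, strongest in the Late Estanzuela
  phases.
- Scope: no calibration-curve reversals or plateaus beyond piecewise-linear
  test curves, no taphonomic loss, uniform within-phase deposition only.

## Known limitations

- Outlier absorption at hiatuses: a date shifted +500 ¹⁴C yr whose phase
  follows a long gap can be accommodated by stretching the phase-start
  boundary into the gap; the likelihood gain dwarfs the span-penalty cost,
  so agreement screening cannot flag it and the affected boundary estimate
  degrades. This is an identifiability limit of the ordering-chain model
  itself (verified analytically in the single-phase case, where the
  posterior start sits near `max theta + span/(N-1)`), not a sampler
  defect. Shifts that cross into the *preceding phase's* date range are
  detected and removed. Accordingly, boundary-recovery experiments use the
  outlier-free variant of the default scenario, and screening is validated
  with detectable constructions.
- Screening can also remove unshifted dates that happen to sit near a
  boundary tail (false positives at the ~1% level in the default scenario).
- `A_model`/`A_overall` are a single statistic here (see above).
- Single-chain MCMC: ESS and split-R̂ are computed from one chain; run
  several seeds for multi-chain diagnostics.
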