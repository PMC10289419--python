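"""Bayesian phase/boundary sequence model for stratified radiocarbon dates.

The model orders occupation phases stratigraphically (index 0 = oldest) and
treats each phase as a block of uniformly deposited events between a start
boundary alpha (older) and an end boundary beta (younger):

    theta_i | alpha_p, beta_p  ~  Uniform(beta_p, alpha_p)

which contributes the span penalty (alpha_p - beta_p)^(-N_p) per phase, the
standard uniform-phase prior. Boundaries are uniform on the model window
subject to the ordering chain

    window_old >= alpha_0 >= beta_0 >= alpha_1 >= ... >= beta_{P-1} >= window_young

Continuous use between two phases is encoded by a *shared* boundary
(beta_p and alpha_{p+1} are one parameter); a depositional gap is encoded by
a *double* boundary (two free parameters with beta_p >= alpha_{p+1}).

Sampling is Metropolis-within-Gibbs with Gaussian random-walk proposals whose
scales adapt during burn-in toward 20-40% acceptance. Per-date calendar ages
are conditionally independent given the boundaries, so the theta sweep is
vectorized.

Agreement between each date's unmodelled calibrated density p and its
model-constrained marginal p' is quantified as

    A_i = 100 * sum(p' p) / sum(p^2)

with the combined indices A_model / A_overall defined as
100 * prod(A_i/100)^(1/sqrt(n)). Dates with poor agreement can be screened
out iteratively (worst-first), mirroring manual outlier rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from shelterchron.calcurve import CalibrationCurve
from shelterchron.calibrate import CalibratedDensity, RadiocarbonDate, calibrate_date, hpd, mean_intercept

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (13_000.0, 0.0)
AGREEMENT_THRESHOLD = 60.0


class ModelSpecError(ValueError):
    """Invalid phase-model specification."""


class InfeasibleModelError(RuntimeError):
    """No parameter state satisfies the ordering constraints."""


@dataclass(frozen=True)
class PhaseSpec:
    """One ordered phase: its name, boundary type, and member lab ids.

    ``start_boundary`` is "gap" when the phase follows a depositional hiatus
    (double boundary) and "shared_with_previous" when use was continuous
    (single boundary). The oldest phase must use "gap". A boundary may be
    pinned to a known age with ``fixed_start`` / ``fixed_end`` (e.g., a
    terminus from an independent source, or to make a prior effectively flat
    in oracle tests).
    """

    name: str
    start_boundary: str = "gap"
    members: tuple[str, ...] = ()
    fixed_start: float | None = None
    fixed_end: float | None = None

    def __post_init__(self) -> None:
        if self.start_boundary not in ("gap", "shared_with_previous"):
            raise ModelSpecError(f"phase {self.name}: bad start_boundary {self.start_boundary!r}")
        if not self.members:
            raise ModelSpecError(f"phase {self.name}: empty phase")
        if self.fixed_start is not None and self.fixed_end is not None:
            if self.fixed_start <= self.fixed_end:
                raise ModelSpecError(f"phase {self.name}: fixed start must be older than fixed end")
        object.__setattr__(self, "members", tuple(self.members))


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC settings; iterations are post-burn-in."""

    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    proposal_scale: float = 20.0

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0 or self.thinning < 1:
            raise ModelSpecError("invalid sampler settings")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered phases (index 0 = oldest) plus window and sampler settings."""

    phases: tuple[PhaseSpec, ...]
    window: tuple[float, float] = DEFAULT_WINDOW
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ModelSpecError("model needs at least one phase")
        if self.phases[0].start_boundary != "gap":
            raise ModelSpecError("the oldest phase must start with a 'gap' boundary")
        if self.window[0] <= self.window[1]:
            raise ModelSpecError("window must be (oldest, youngest) with oldest > youngest")
        seen: set[str] = set()
        for ph in self.phases:
            dup = seen & set(ph.members)
            if dup:
                raise ModelSpecError(f"lab ids in more than one phase: {sorted(dup)}")
            seen |= set(ph.members)
        object.__setattr__(self, "phases", tuple(self.phases))


@dataclass
class PhaseModel:
    """A validated model: member dates in phase order plus precomputed densities."""

    spec: ModelSpec
    curve: CalibrationCurve
    dates: list[RadiocarbonDate]           # members only, grouped by phase
    phase_of_date: np.ndarray              # phase index per member date
    densities: list[CalibratedDensity]     # unmodelled single-date posteriors
    intercepts: np.ndarray                 # mean intercept per member date

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    @property
    def n_phases(self) -> int:
        return len(self.spec.phases)

    def counts_per_phase(self) -> dict[str, int]:
        return {ph.name: len(ph.members) for ph in self.spec.phases}


@dataclass
class ChronologyPosterior:
    """Retained MCMC draws plus per-parameter summaries.

    ``theta_draws`` is (n_draws, n_dates); ``alpha_draws`` / ``beta_draws``
    are (n_draws, n_phases) with shared boundaries expanded so that
    beta_p == alpha_{p+1} column-wise where use was continuous.
    """

    lab_ids: list[str]
    phase_names: list[str]
    theta_draws: np.ndarray
    alpha_draws: np.ndarray
    beta_draws: np.ndarray
    acceptance: dict[str, float]

    def summaries(self) -> pd.DataFrame:
        """Mean, sd, HPD68 / HPD95.4 and ESS per parameter."""
        rows = []
        cols = (
            [(f"theta[{lid}]", self.theta_draws[:, i]) for i, lid in enumerate(self.lab_ids)]
            + [(f"alpha[{nm}]", self.alpha_draws[:, p]) for p, nm in enumerate(self.phase_names)]
            + [(f"beta[{nm}]", self.beta_draws[:, p]) for p, nm in enumerate(self.phase_names)]
        )
        for name, draws in cols:
            h68 = _hpd_from_draws(draws, 0.68)
            h95 = _hpd_from_draws(draws, 0.954)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(draws.mean()),
                    "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                    "hpd68_older": h68[0],
                    "hpd68_younger": h68[1],
                    "hpd954_older": h95[0],
                    "hpd954_younger": h95[1],
                    "ess": effective_sample_size(draws),
                }
            )
        return pd.DataFrame(rows)


def _hpd_from_draws(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the draws, as (older, younger)."""
    x = np.sort(draws)
    n = x.size
    k = max(1, int(np.ceil(level * n)))
    if k >= n:
        return float(x[-1]), float(x[0])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j + k]), float(x[j])


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    # sum pairs of consecutive autocorrelations while positive (Geyer)
    s = 0.0
    for t in range(1, n // 2):
        pair = acf[2 * t - 1] + acf[2 * t] if 2 * t < n else acf[2 * t - 1]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for a single chain."""
    x = np.asarray(draws, dtype=float)
    n = x.size // 2
    if n < 2 or np.ptp(x) == 0:
        return 1.0
    halves = np.stack([x[:n], x[n: 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + b / (n * w)))


# --- model construction -----------------------------------------------------


def build_model(
    dates: list[RadiocarbonDate],
    spec: ModelSpec,
    curve: CalibrationCurve,
    step: float = 5.0,
) -> PhaseModel:
    """Validate a spec against the dates table and precompute single-date densities.

    Every member lab id must resolve to a date with intact context; dates
    excluded for disturbance, missing provenience, or pre-occupation/modern
    age cannot enter the stratigraphic model.
    """
    by_id = {d.lab_id: d for d in dates}
    members: list[RadiocarbonDate] = []
    phase_of: list[int] = []
    for p, ph in enumerate(spec.phases):
        for lid in ph.members:
            if lid not in by_id:
                raise ModelSpecError(f"phase {ph.name}: unknown lab id {lid!r}")
            d = by_id[lid]
            if d.context_status != "intact":
                raise ModelSpecError(
                    f"phase {ph.name}: date {lid} has context_status={d.context_status!r}; "
                    "only intact contexts may enter the model"
                )
            members.append(d)
            phase_of.append(p)
    lo, hi = spec.window[1], spec.window[0]
    grid = np.arange(lo, hi + 0.5 * step, step, dtype=float)
    densities = [calibrate_date(d, curve, grid=grid) for d in members]
    intercepts = np.array([mean_intercept(dd) for dd in densities])
    model = PhaseModel(
        spec=spec,
        curve=curve,
        dates=members,
        phase_of_date=np.asarray(phase_of, dtype=int),
        densities=densities,
        intercepts=intercepts,
    )
    logger.info("model built: %d dates in %d phases", model.n_dates, model.n_phases)
    return model


# --- exclusion ledger -------------------------------------------------------

EXCLUSION_REASONS = {
    "disturbed": "looting or stratigraphic disturbance",
    "pre_occupation": "pre-dates site occupation",
    "modern": "modern outlier",
    "missing_provenience": "missing provenience information",
    "poor_agreement": "poor model agreement (iterative screening)",
}


def exclusion_ledger(
    all_dates: list[RadiocarbonDate],
    agreement_excluded: list[str] = (),
    model_count: int | None = None,
) -> pd.DataFrame:
    """Tabulate excluded dates by reason, with a consistency check row.

    The ledger always satisfies
    total = included + sum(per-category exclusions); when a ``model_count``
    is supplied that disagrees with the implied included count, the tension
    is surfaced in a note column rather than silently reconciled.
    """
    flagged = set(agreement_excluded)
    counts = {k: 0 for k in EXCLUSION_REASONS}
    for d in all_dates:
        if d.lab_id in flagged:
            counts["poor_agreement"] += 1
        elif d.context_status != "intact":
            counts[d.context_status] += 1
    total = len(all_dates)
    excluded = sum(counts.values())
    included = total - excluded
    rows = [
        {"category": k, "description": EXCLUSION_REASONS[k], "n": v} for k, v in counts.items()
    ]
    rows.append({"category": "total_excluded", "description": "all exclusions", "n": excluded})
    note = ""
    if model_count is not None and model_count != included:
        note = (
            f"arithmetic tension: {total} total - {excluded} excluded = {included}, "
            f"but the stated model sample is {model_count}"
        )
    rows.append({"category": "included", "description": note or "dates entering the model", "n": included})
    return pd.DataFrame(rows)


# --- MCMC -------------------------------------------------------------------


class _Chain:
    """Internal boundary-chain bookkeeping.

    Unique boundary parameters are listed oldest-first; shared boundaries
    collapse beta_p and alpha_{p+1} onto one slot.
    """

    def __init__(self, spec: ModelSpec):
        self.alpha_idx = np.empty(len(spec.phases), dtype=int)
        self.beta_idx = np.empty(len(spec.phases), dtype=int)
        k = 0
        for p, ph in enumerate(spec.phases):
            if p > 0 and ph.start_boundary == "shared_with_previous":
                self.alpha_idx[p] = self.beta_idx[p - 1]
            else:
                self.alpha_idx[p] = k
                k += 1
            self.beta_idx[p] = k
            k += 1
        self.n_params = k
        # phases whose alpha / beta is each unique param
        self.alpha_phases = [np.where(self.alpha_idx == j)[0] for j in range(k)]
        self.beta_phases = [np.where(self.beta_idx == j)[0] for j in range(k)]
        # pinned boundary values (NaN = free)
        self.fixed = np.full(k, np.nan)
        for p, ph in enumerate(spec.phases):
            for value, j in ((ph.fixed_start, self.alpha_idx[p]), (ph.fixed_end, self.beta_idx[p])):
                if value is None:
                    continue
                if not np.isnan(self.fixed[j]) and self.fixed[j] != value:
                    raise ModelSpecError(f"conflicting fixed values for a shared boundary of {ph.name}")
                self.fixed[j] = float(value)
        if np.any(np.diff(self.fixed[~np.isnan(self.fixed)]) >= 0):
            raise ModelSpecError("fixed boundary values violate the ordering chain")


def _initial_state(model: PhaseModel, chain: _Chain) -> tuple[np.ndarray, np.ndarray]:
    """A feasible (theta, boundary) starting state.

    Boundary guesses bracket each phase's mean intercepts, are projected onto
    a strictly descending chain, and thetas are clipped inside their phase.
    Falls back to an evenly spaced chain if the projection runs out of room.
    """
    win_old, win_young = model.spec.window
    P = model.n_phases
    guesses = np.empty(chain.n_params)
    for j in range(chain.n_params):
        lows, highs = [], []
        for p in chain.alpha_phases[j]:
            sel = model.phase_of_date == p
            lows.append(model.intercepts[sel].max() + 25.0)
        for p in chain.beta_phases[j]:
            sel = model.phase_of_date == p
            highs.append(model.intercepts[sel].min() - 25.0)
        cands = lows + highs
        guesses[j] = float(np.mean(cands))
    b = np.minimum(guesses, win_old - 1.0)
    for j in range(1, chain.n_params):
        b[j] = min(b[j], b[j - 1] - 1.0)
    if b[-1] <= win_young:
        b = np.linspace(win_old - 1.0, win_young + 1.0, chain.n_params)
    pinned = ~np.isnan(chain.fixed)
    if pinned.any():
        b[pinned] = chain.fixed[pinned]
        for j in range(1, chain.n_params):
            if not pinned[j] and b[j] >= b[j - 1]:
                b[j] = b[j - 1] - 1.0
            if pinned[j] and b[j] >= b[j - 1]:
                raise InfeasibleModelError("fixed boundaries leave no feasible chain")
    theta = model.intercepts.copy()
    for p in range(P):
        sel = model.phase_of_date == p
        lo = b[chain.beta_idx[p]] + 1e-3
        hi = b[chain.alpha_idx[p]] - 1e-3
        if lo >= hi:
            raise InfeasibleModelError(f"no room for phase {model.spec.phases[p].name} in initial chain")
        theta[sel] = np.clip(theta[sel], lo, hi)
    return theta, b


def sample_posterior(model: PhaseModel, settings: SamplerSettings | None = None) -> ChronologyPosterior:
    """Draw from the joint posterior of per-date ages and phase boundaries.

    Metropolis-within-Gibbs: a vectorized random-walk sweep over all
    per-date ages (conditionally independent given the boundaries) followed
    by single-site updates of each unique boundary parameter. Proposal
    scales adapt during burn-in; retained draws satisfy every ordering
    constraint by construction. Reproducible given the seed.
    """
    if settings is None:
        settings = model.spec.sampler
    rng = np.random.default_rng(settings.seed)
    chain = _Chain(model.spec)
    theta, b = _initial_state(model, chain)
    win_old, win_young = model.spec.window
    P, n = model.n_phases, model.n_dates
    pod = model.phase_of_date
    n_per_phase = np.bincount(pod, minlength=P).astype(float)

    cal, c14, sig = model.curve.cal_bp, model.curve.c14_age, model.curve.sigma_curve
    r = np.array([d.c14_age for d in model.dates])
    s2 = np.array([d.c14_sigma for d in model.dates]) ** 2

    def date_loglik(th: np.ndarray) -> np.ndarray:
        mu = np.interp(th, cal, c14)
        var = s2 + np.interp(th, cal, sig) ** 2
        return -0.5 * (r - mu) ** 2 / var - 0.5 * np.log(var)

    loglik = date_loglik(theta)
    scale_theta = np.sqrt(s2 + np.interp(theta, cal, sig) ** 2)  # ~1 sigma in 14C yr
    scale_b = np.full(chain.n_params, float(settings.proposal_scale))

    # per-phase theta extremes, updated incrementally after each sweep
    def phase_minmax(th):
        mins = np.full(P, np.inf)
        maxs = np.full(P, -np.inf)
        np.minimum.at(mins, pod, th)
        np.maximum.at(maxs, pod, th)
        return mins, maxs

    th_min, th_max = phase_minmax(theta)

    total_iters = settings.burn_in + settings.iterations
    n_ret = settings.iterations // settings.thinning
    theta_draws = np.empty((n_ret, n))
    b_draws = np.empty((n_ret, chain.n_params))
    acc_theta = np.zeros(n)
    acc_b = np.zeros(chain.n_params)
    prop_count = 0
    adapt_acc_t = np.zeros(n)
    adapt_acc_b = np.zeros(chain.n_params)
    adapt_window = 100
    ret = 0

    alpha_of_date = chain.alpha_idx[pod]
    beta_of_date = chain.beta_idx[pod]

    for it in range(total_iters):
        # --- vectorized theta sweep ---
        prop = theta + rng.normal(0.0, scale_theta)
        ok = (prop <= b[alpha_of_date]) & (prop >= b[beta_of_date])
        ok &= (prop <= cal[-1]) & (prop >= cal[0])
        new_ll = np.where(ok, 0.0, -np.inf)
        if ok.any():
            new_ll_ok = date_loglik(np.where(ok, prop, theta))
            new_ll = np.where(ok, new_ll_ok, -np.inf)
        logu = np.log(rng.random(n))
        accept = ok & (logu < new_ll - loglik)
        theta = np.where(accept, prop, theta)
        loglik = np.where(accept, new_ll, loglik)
        if accept.any():
            th_min, th_max = phase_minmax(theta)
        adapt_acc_t += accept
        if it >= settings.burn_in:
            acc_theta += accept

        # --- single-site boundary sweeps ---
        for j in range(chain.n_params):
            if not np.isnan(chain.fixed[j]):
                continue
            cur = b[j]
            newv = cur + rng.normal(0.0, scale_b[j])
            lo = b[j + 1] if j + 1 < chain.n_params else win_young
            hi = b[j - 1] if j > 0 else win_old
            for p in chain.alpha_phases[j]:
                lo = max(lo, th_max[p])
            for p in chain.beta_phases[j]:
                hi = min(hi, th_min[p])
            if not (lo < newv < hi):
                continue
            logratio = 0.0
            bad = False
            for p in chain.alpha_phases[j]:
                old_span = cur - b[chain.beta_idx[p]]
                new_span = newv - b[chain.beta_idx[p]]
                if new_span <= 0:
                    bad = True
                    break
                logratio += -n_per_phase[p] * (np.log(new_span) - np.log(old_span))
            if not bad:
                for p in chain.beta_phases[j]:
                    old_span = b[chain.alpha_idx[p]] - cur
                    new_span = b[chain.alpha_idx[p]] - newv
                    if new_span <= 0:
                        bad = True
                        break
                    logratio += -n_per_phase[p] * (np.log(new_span) - np.log(old_span))
            if bad:
                continue
            if np.log(rng.random()) < logratio:
                b[j] = newv
                adapt_acc_b[j] += 1
                if it >= settings.burn_in:
                    acc_b[j] += 1

        prop_count += 1
        # --- adaptation during burn-in ---
        if it < settings.burn_in and (it + 1) % adapt_window == 0:
            rate_t = adapt_acc_t / adapt_window
            scale_theta *= np.where(rate_t > 0.4, 1.25, np.where(rate_t < 0.2, 0.8, 1.0))
            scale_theta = np.clip(scale_theta, 0.5, 5_000.0)
            rate_b = adapt_acc_b / adapt_window
            scale_b *= np.where(rate_b > 0.4, 1.25, np.where(rate_b < 0.2, 0.8, 1.0))
            scale_b = np.clip(scale_b, 0.5, 5_000.0)
            adapt_acc_t[:] = 0.0
            adapt_acc_b[:] = 0.0

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == settings.thinning - 1:
            if ret < n_ret:
                theta_draws[ret] = theta
                b_draws[ret] = b
                ret += 1

    theta_draws = theta_draws[:ret]
    b_draws = b_draws[:ret]
    if ret == 0:
        raise InfeasibleModelError("no draws retained; increase iterations")
    post_iters = float(settings.iterations)
    acceptance = {
        "theta_mean": float(np.mean(acc_theta) / post_iters),
        "boundary_mean": float(np.mean(acc_b) / post_iters),
    }
    if acceptance["theta_mean"] < 1e-3:
        raise InfeasibleModelError("sampler could not move the per-date ages; check the model spec")
    return ChronologyPosterior(
        lab_ids=[d.lab_id for d in model.dates],
        phase_names=[ph.name for ph in model.spec.phases],
        theta_draws=theta_draws,
        alpha_draws=b_draws[:, chain.alpha_idx],
        beta_draws=b_draws[:, chain.beta_idx],
        acceptance=acceptance,
    )


# --- agreement and screening -------------------------------------------------


def _marginal_on_grid(draws: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Histogram MCMC draws onto a regular grid as probability mass per cell."""
    step = grid[1] - grid[0]
    edges = np.concatenate((grid - 0.5 * step, [grid[-1] + 0.5 * step]))
    counts, _ = np.histogram(draws, bins=edges)
    total = counts.sum()
    if total == 0:
        return np.zeros_like(grid)
    return counts / total


def agreement_index(p: np.ndarray, p_prime: np.ndarray) -> float:
    """Agreement between an unmodelled density p and a modelled marginal p'.

    A = 100 * sum(p' p) / sum(p^2); 100 when p' == p, 0 with no overlap.
    Both arguments are probability masses on the same grid.
    """
    p = np.asarray(p, dtype=float)
    p_prime = np.asarray(p_prime, dtype=float)
    denom = float(np.sum(p * p))
    if denom <= 0:
        return 0.0
    return 100.0 * float(np.sum(p_prime * p)) / denom


def agreement_indices(
    posterior: ChronologyPosterior, model: PhaseModel
) -> tuple[pd.Series, float, float]:
    """Per-date agreement A_i plus combined A_model and A_overall (percent).

    A_i compares the unmodelled calibrated density p with the modelled
    marginal p' binned to the same grid: A_i = 100 sum(p'p)/sum(p^2); it is
    100 when the model leaves a date's density unchanged and 0 with no
    overlap. The combined indices take the geometric mean damped by
    1/sqrt(n): 100 * prod(A_i/100)^(1/sqrt(n)). A_model is computed over the
    model-constrained date parameters; A_overall over all dates supplied.
    """
    a_vals = {}
    for i, lid in enumerate(posterior.lab_ids):
        dens = model.densities[i]
        p_prime = _marginal_on_grid(posterior.theta_draws[:, i], dens.grid)
        a_vals[lid] = agreement_index(dens.mass, p_prime)
    a_i = pd.Series(a_vals, name="A_i")
    n = len(a_i)
    with np.errstate(divide="ignore"):
        logs = np.log(np.maximum(a_i.to_numpy() / 100.0, 1e-300))
    combined = 100.0 * float(np.exp(logs.sum() / np.sqrt(n)))
    a_model = combined
    a_overall = combined
    return a_i, a_model, a_overall


def screen_outliers(
    dates: list[RadiocarbonDate],
    spec: ModelSpec,
    curve: CalibrationCurve,
    threshold: float = AGREEMENT_THRESHOLD,
    settings: SamplerSettings | None = None,
    max_fraction: float = 0.2,
) -> tuple[list[str], ChronologyPosterior, PhaseModel]:
    """Iteratively remove the single worst-agreeing date until all pass.

    Each round samples the posterior, computes A_i, and removes the worst
    date if its agreement is below ``threshold`` (one per round, mirroring a
    manual sequential workflow). Deterministic given the seed: round k uses
    seed + k. Aborts if more than ``max_fraction`` of the starting dates
    would be removed.

    Returns (removal order, final posterior, final model).
    """
    if settings is None:
        settings = spec.sampler
    removed: list[str] = []
    cur_spec = spec
    n0 = sum(len(ph.members) for ph in spec.phases)
    max_removals = int(max_fraction * n0)
    rounds = 0
    while True:
        model = build_model(dates, cur_spec, curve)
        rs = replace(settings, seed=(settings.seed + rounds) % (2**31 - 1))
        posterior = sample_posterior(model, rs)
        if threshold <= 0:
            return removed, posterior, model
        a_i, _, _ = agreement_indices(posterior, model)
        worst = a_i.idxmin()
        if a_i[worst] >= threshold:
            return removed, posterior, model
        if len(removed) >= max_removals:
            raise RuntimeError(
                f"outlier screening would remove more than {max_fraction:.0%} of dates "
                f"({removed + [worst]}); aborting — the model spec likely misassigns phases"
            )
        logger.info("screening round %d: removing %s (A=%.1f)", rounds, worst, a_i[worst])
        removed.append(str(worst))
        new_phases = []
        for ph in cur_spec.phases:
            members = tuple(m for m in ph.members if m != worst)
            if not members:
                raise RuntimeError(f"screening emptied phase {ph.name}")
            new_phases.append(replace(ph, members=members))
        cur_spec = replace(cur_spec, phases=tuple(new_phases))
        rounds += 1


def phase_durations(posterior: ChronologyPosterior) -> dict[str, tuple[float, float]]:
    """Per-phase (mean start BP, mean end BP) from the boundary draws.

    The phase interval used for specimen assignment is the duration between
    the mean start and mean end boundaries; duration = mean alpha - mean beta.
    """
    out = {}
    for p, name in enumerate(posterior.phase_names):
        out[name] = (float(posterior.alpha_draws[:, p].mean()), float(posterior.beta_draws[:, p].mean()))
    return out


def boundary_hpds(posterior: ChronologyPosterior, level: float = 0.954) -> dict[str, dict[str, tuple[float, float]]]:
    """HPD intervals (older, younger) for every phase boundary."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for p, name in enumerate(posterior.phase_names):
        out[name] = {
            "start": _hpd_from_draws(posterior.alpha_draws[:, p], level),
            "end": _hpd_from_draws(posterior.beta_draws[:, p], level),
        }
    return out
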