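"""Empirical-Bayesian calibration: SSE likelihood, adaptive MCMC, diagnostics.

The calibration machinery treats the model as a black-box map from a
parameter vector to predicted measurand series and scores it against an
:class:`~b16sim.synthetic_data.ObservationSet` with a summed-squared-error
likelihood

    P(Y | theta, M)  proportional to  [1 / SSE(theta)]^(N_obs / 2),

i.e. ``log L = -(N_obs/2) * log(SSE)``.  Sampling proceeds in log10
parameter space under a uniform prior on a bounded box (default
[1e-8, 1e8] per rate; the deactivation decay factor ``gamma`` is sampled
on a linear scale in (0, 1]).  A simulated-annealing search supplies the
starting point; an adaptive Metropolis-Hastings sampler with a learned
proposal covariance and a target acceptance fraction of 0.2 generates the
chains; adaptation is frozen after the learning period so the post-learning
segment is a valid Metropolis-Hastings chain.  Convergence is judged with
the Gelman-Rubin potential scale reduction factor applied to the predicted
series (not raw parameters), and the converged pool is thinned by retaining
every 200th step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .model_core import (
    B16SimError,
    CompartmentGeometry,
    DEFAULT_GEOMETRY,
    ParameterSet,
    SchemaError,
    ValidationError,
    IntegrationError,
    _event_jumps,
    _initial_state,
    _integrate_packed,
    build_parameters,
    free_parameter_names,
)
from .observables import POSITIVE_MEASURANDS, PredictedSeries, predict_series
from .synthetic_data import ObservationSet, group_protocol

__all__ = [
    "ConvergenceError",
    "SSEResult",
    "sse",
    "log_likelihood",
    "AnnealSchedule",
    "anneal_start",
    "ChainArchive",
    "run_amcmc",
    "PosteriorEnsemble",
    "psrf",
    "pool",
    "CredibleBand",
    "credible_band",
    "map_estimate",
    "CalibrationProblem",
    "calibrate",
]

#: floor below which the SSE is clamped (the likelihood is improper at 0)
SSE_FLOOR = 1e-12
#: floor applied before log10-transforming strictly positive measurands
LOG_FLOOR = 1e-12


class ConvergenceError(B16SimError, RuntimeError):
    """Chains failed a convergence criterion required by the operation."""


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSEResult:
    """Total SSE plus per-(group, measurand) partial sums."""

    total: float
    per_measurand: Mapping[tuple[str, str], float]
    n_obs: Mapping[tuple[str, str], int]

    @property
    def n_total(self) -> int:
        return int(sum(self.n_obs.values()))


def _fit_scale(measurand: str) -> str:
    return "log10" if measurand in POSITIVE_MEASURANDS else "linear"


def _transform(values: np.ndarray, measurand: str, scale: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if scale == "linear":
        return values
    if scale == "log10":
        return np.log10(np.maximum(values, LOG_FLOOR))
    if scale == "auto":
        return _transform(values, measurand, _fit_scale(measurand))
    raise SchemaError(f"unknown SSE scale {scale!r}")


def sse(obs: ObservationSet, pred: Sequence[PredictedSeries],
        scale: str = "auto") -> SSEResult:
    """Summed squared residual between observations and predictions.

    Every observation record must have a matching prediction at its
    (group, measurand, day); otherwise a join error lists the offenders.
    ``scale="auto"`` uses log10 residuals for strictly positive measurands
    and linear residuals for the percent readout, equalizing the widely
    different measurand magnitudes; ``"linear"``/``"log10"`` force one
    scale everywhere.
    """
    lookup: dict[tuple[str, str], PredictedSeries] = {
        (s.group, s.measurand): s for s in pred
    }
    per: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    unmatched = []
    for (group, measurand), block in obs.frame.groupby(["group", "measurand"], sort=False):
        series = lookup.get((group, measurand))
        if series is None:
            unmatched.append((group, measurand, "no predicted series"))
            continue
        day_to_value = dict(zip(series.times, series.values))
        y = block["value"].to_numpy(dtype=float)
        ym = np.empty_like(y)
        ok = True
        for i, day in enumerate(block["day"].to_numpy(dtype=float)):
            if day in day_to_value:
                ym[i] = day_to_value[day]
            else:
                unmatched.append((group, measurand, f"day {day:g} not predicted"))
                ok = False
                break
        if not ok:
            continue
        use = scale if scale != "auto" else _fit_scale(measurand)
        resid = _transform(y, measurand, use) - _transform(ym, measurand, use)
        per[(group, measurand)] = float(np.sum(resid * resid))
        counts[(group, measurand)] = int(y.size)
    if unmatched:
        raise SchemaError(f"unmatched observation record(s): {unmatched}")
    return SSEResult(total=float(sum(per.values())), per_measurand=per, n_obs=counts)


def log_likelihood(sse_total: float, n_obs: int) -> float:
    """``(N_obs/2) * log(1/SSE)``; SSE below 1e-12 is clamped with a warning."""
    if sse_total < 0:
        raise ValidationError(f"SSE must be non-negative, got {sse_total!r}")
    if n_obs < 1:
        raise ValidationError("n_obs must be >= 1")
    if sse_total < SSE_FLOOR:
        warnings.warn(
            f"SSE={sse_total:g} below floor {SSE_FLOOR:g}; clamping "
            "(the SSE likelihood is improper as SSE -> 0)",
            RuntimeWarning, stacklevel=2,
        )
        sse_total = SSE_FLOOR
    return -0.5 * n_obs * float(np.log(sse_total))


# ---------------------------------------------------------------------------
# Simulated annealing start
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule for the annealed start search.

    With ``t_start=None`` the starting temperature is set to the standard
    deviation of the log-likelihood over the initial uniform draws (floored
    at 1), so the early walk accepts moves on the natural scale of the
    objective regardless of the number of observations.
    """

    n_steps: int = 3000
    n_init: int = 64
    n_restarts: int = 3         # independent runs; the best end point wins
    t_start: float | None = None
    t_ratio: float = 1e-4       # final temperature as a fraction of t_start
    step_scale: float = 0.25

    def temperature(self, i: int, t0: float) -> float:
        if self.n_steps <= 1:
            return t0 * self.t_ratio
        return t0 * self.t_ratio ** (i / (self.n_steps - 1))


def anneal_start(log_density: Callable, bounds: np.ndarray,
                 schedule: AnnealSchedule = AnnealSchedule(),
                 seed: int | None = None) -> np.ndarray:
    """Best point found by simulated annealing over a bounded box.

    ``bounds`` is a (d, 2) array of [low, high] in sampling coordinates.
    The search starts from the best of ``n_init`` uniform draws and runs a
    random-walk annealing with geometric cooling whose step width shrinks
    with the temperature; with ``n_steps=0`` only the initial draws are
    used.  Deterministic under a fixed seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo):
        raise ValidationError("each bound must satisfy low < high")

    def f(x):
        value = log_density(x)
        return value[0] if isinstance(value, tuple) else value

    overall_x, overall_lp = None, -np.inf
    for restart_seed in np.random.SeedSequence(seed).spawn(max(schedule.n_restarts, 1)):
        rng = np.random.default_rng(restart_seed)
        x, lp = _anneal_once(f, lo, hi, schedule, rng)
        if lp > overall_lp:
            overall_x, overall_lp = x, lp
    if overall_x is None or not np.isfinite(overall_lp):
        raise ConvergenceError("no finite-likelihood start found in the initial draws")
    return overall_x


def _anneal_once(f, lo, hi, schedule: AnnealSchedule, rng) -> tuple[np.ndarray, float]:
    best_x, best_lp = None, -np.inf
    init_lps = []
    for _ in range(max(schedule.n_init, 1)):
        x = rng.uniform(lo, hi)
        lp = f(x)
        if np.isfinite(lp):
            init_lps.append(lp)
        if lp > best_lp:
            best_x, best_lp = x, lp
    if not np.isfinite(best_lp):
        return np.full(lo.size, np.nan), -np.inf
    t0 = schedule.t_start
    if t0 is None:
        t0 = max(float(np.std(init_lps)) if len(init_lps) > 1 else 1.0, 1.0)
    x, lp = best_x.copy(), best_lp
    width = (hi - lo) * schedule.step_scale
    for i in range(schedule.n_steps):
        t = schedule.temperature(i, t0)
        frac = (t / t0) ** 0.5  # step width cools slower than temperature
        prop = x + width * frac * rng.standard_normal(lo.size)
        if np.any(prop < lo) or np.any(prop > hi):
            continue
        lp_prop = f(prop)
        if not np.isfinite(lp_prop):
            continue
        if lp_prop >= lp or rng.random() < np.exp((lp_prop - lp) / t):
            x, lp = prop, lp_prop
            if lp > best_lp:
                best_x, best_lp = x.copy(), lp
    return best_x, best_lp


# ---------------------------------------------------------------------------
# Adaptive Metropolis-Hastings
# ---------------------------------------------------------------------------


@dataclass
class ChainArchive:
    """Complete record of one chain: states, likelihoods, cached predictions."""

    thetas: np.ndarray          # (n_steps, d) sampling coordinates
    logps: np.ndarray           # (n_steps,)
    accepted: np.ndarray        # (n_steps,) proposal accepted at this step
    learn_steps: int
    target_accept: float
    seed: int | None
    proposal_cov: np.ndarray    # frozen covariance (post-learning)
    proposal_scale: float
    extras: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return int(self.logps.size)

    @property
    def acceptance_fraction(self) -> float:
        """Realized acceptance over the post-learning segment."""
        post = self.accepted[self.learn_steps:]
        return float(post.mean()) if post.size else float("nan")


def run_amcmc(log_density: Callable, theta0: Sequence[float], n_steps: int,
              learn_steps: int = 100_000, target_accept: float = 0.2,
              seed: int | None = None, bounds: np.ndarray | None = None,
              cov0: np.ndarray | None = None, adapt_interval: int = 100,
              meta: dict | None = None) -> ChainArchive:
    """Adaptive Metropolis-Hastings over a generic log-density.

    A multivariate Gaussian proposal is used.  During the learning period
    the proposal covariance is re-estimated from the chain history and its
    global scale is tuned toward ``target_accept`` (Robbins-Monro on the
    log scale, decaying gain); after ``learn_steps`` both are frozen so
    the remainder of the chain has the correct invariant distribution.
    Proposals outside ``bounds`` are rejected.  ``log_density`` may return
    a float or ``(float, extras_dict)``; extras of the current state are
    archived at every step (e.g. per-measurand SSE and predictions).
    """
    if not 0.0 < target_accept < 1.0:
        raise ValidationError("target_accept must lie in (0, 1)")
    if n_steps <= learn_steps:
        raise ValidationError("n_steps must exceed learn_steps")
    rng = np.random.default_rng(seed)
    x = np.asarray(theta0, dtype=float).copy()
    d = x.size
    if bounds is not None:
        bounds = np.asarray(bounds, dtype=float)
        lo, hi = bounds[:, 0], bounds[:, 1]
        if np.any(x < lo) or np.any(x > hi):
            raise ValidationError("theta0 violates the prior bounds")

    def evaluate(xx):
        value = log_density(xx)
        if isinstance(value, tuple):
            return float(value[0]), value[1]
        return float(value), None

    lp, extras = evaluate(x)
    if not np.isfinite(lp):
        raise ValidationError("log-density is non-finite at theta0")

    cov = np.asarray(cov0, dtype=float) if cov0 is not None else np.eye(d) * 0.01
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(d))
    scale = 2.38 / np.sqrt(d)

    thetas = np.empty((n_steps, d))
    logps = np.empty(n_steps)
    accepted = np.zeros(n_steps, dtype=bool)
    extras_store: dict[str, np.ndarray] = {}
    if extras is not None:
        for key, value in extras.items():
            arr = np.asarray(value, dtype=float)
            extras_store[key] = np.empty((n_steps,) + arr.shape, dtype=np.float64)

    batch_accepts = 0
    batch_index = 0
    for step in range(n_steps):
        prop = x + scale * (chol @ rng.standard_normal(d))
        in_bounds = bounds is None or (np.all(prop >= lo) and np.all(prop <= hi))
        if in_bounds:
            lp_prop, extras_prop = evaluate(prop)
            if np.isfinite(lp_prop) and np.log(rng.random()) < lp_prop - lp:
                x, lp, extras = prop, lp_prop, extras_prop
                accepted[step] = True
                batch_accepts += 1
        thetas[step] = x
        logps[step] = lp
        if extras is not None:
            for key, value in extras.items():
                extras_store[key][step] = value
        if step < learn_steps and (step + 1) % adapt_interval == 0:
            batch_index += 1
            frac = batch_accepts / adapt_interval
            batch_accepts = 0
            gain = batch_index ** -0.6
            scale *= np.exp(gain * (frac - target_accept))
            if step + 1 >= max(10 * d, 200):
                # trailing window: drop the early climb toward the mode so
                # the proposal matches the local posterior geometry
                emp = np.cov(thetas[(step + 1) // 2: step + 1].T)
                emp = np.atleast_2d(emp)
                chol = np.linalg.cholesky(emp + 1e-12 * np.eye(d))
    return ChainArchive(
        thetas=thetas, logps=logps, accepted=accepted, learn_steps=learn_steps,
        target_accept=target_accept, seed=seed,
        proposal_cov=chol @ chol.T, proposal_scale=float(scale),
        extras=extras_store, meta=dict(meta or {}),
    )


# ---------------------------------------------------------------------------
# Convergence, pooling, summaries
# ---------------------------------------------------------------------------


def _gelman_rubin(samples: np.ndarray) -> np.ndarray:
    """R-hat per column; ``samples`` has shape (m_chains, n_steps, k).

    A column that is constant within every chain *and* identical across
    chains (e.g. a prediction pinned by an event, like LV at the
    immunization day) is converged by construction and reports 1.0; a
    column constant within chains but different between them has degenerate
    within-chain variance and raises.
    """
    m, n, _ = samples.shape
    means = samples.mean(axis=1)                    # (m, k)
    variances = samples.var(axis=1, ddof=1)         # (m, k)
    W = variances.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    tol = 1e-24 * (1.0 + means.mean(axis=0) ** 2)
    degenerate = W <= tol
    if np.any(degenerate & (B_over_n > tol)):
        raise ConvergenceError(
            "zero within-chain variance with distinct chain values: "
            "the selected quantity is degenerate"
        )
    rhat = np.ones(W.size)
    ok = ~degenerate
    v_hat = (n - 1) / n * W[ok] + (1.0 + 1.0 / m) * B_over_n[ok]
    rhat[ok] = np.sqrt(v_hat / W[ok])
    return rhat


def psrf(chains: Sequence[ChainArchive], quantity: str, burn: int) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor of a predicted quantity.

    ``quantity`` names an archived extras series (e.g. ``"pred:hDCT:
    ifng_mrna"``); the statistic is computed per time point over the
    post-burn samples of two or more chains.
    """
    if len(chains) < 2:
        raise ValidationError("PSRF needs at least two chains")
    arrays = []
    for chain in chains:
        if quantity not in chain.extras:
            raise SchemaError(f"quantity {quantity!r} not archived in chain")
        arr = chain.extras[quantity][burn:]
        if arr.shape[0] < 2:
            raise ValidationError("burn leaves fewer than two samples per chain")
        arrays.append(arr.reshape(arr.shape[0], -1))
    n = min(a.shape[0] for a in arrays)
    stacked = np.stack([a[:n] for a in arrays])
    return _gelman_rubin(stacked)


@dataclass
class PosteriorEnsemble:
    """Pooled post-burn-in, thinned samples from two or more chains."""

    thetas: np.ndarray           # (n_samples, d)
    logps: np.ndarray
    chain_index: np.ndarray
    step_index: np.ndarray
    extras: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.logps.size)

    def parameter_column(self, name: str) -> np.ndarray:
        """Natural-scale values of one free parameter across the ensemble."""
        names = list(self.meta["free_names"])
        scales = self.meta["scales"]
        j = names.index(name)
        column = self.thetas[:, j]
        return 10.0 ** column if scales[j] == "log10" else column.copy()

    def params_at(self, i: int) -> ParameterSet:
        """Reconstruct the full ParameterSet of sample ``i``."""
        base = build_parameters(self.meta["base_values"], self.meta["variant"])
        names = list(self.meta["free_names"])
        scales = self.meta["scales"]
        updates = {}
        for j, name in enumerate(names):
            value = self.thetas[i, j]
            updates[name] = 10.0 ** value if scales[j] == "log10" else value
        return base.replace(**updates)


def pool(chains: Sequence[ChainArchive], burn: int, stride: int = 200,
         rhat_threshold: float = 1.1, force: bool = False) -> PosteriorEnsemble:
    """Thin and concatenate converged chains.

    Keeps steps ``burn, burn+stride, ...`` from each chain.  Before pooling,
    the Gelman-Rubin statistic of every archived predicted series must fall
    below ``rhat_threshold``; otherwise the pool refuses (override with
    ``force=True``, e.g. for diagnostics).
    """
    if not chains:
        raise ValidationError("no chains to pool")
    n_steps = chains[0].n_steps
    if burn >= n_steps:
        raise ValidationError("burn leaves no samples to pool")
    pred_keys = [k for k in chains[0].extras if k.startswith("pred:")]
    if len(chains) >= 2 and pred_keys and not force:
        worst_key, worst = None, -np.inf
        for key in pred_keys:
            rhat = np.nanmax(psrf(chains, key, burn))
            if rhat > worst:
                worst_key, worst = key, rhat
        if worst > rhat_threshold:
            raise ConvergenceError(
                f"PSRF {worst:.3f} for {worst_key!r} exceeds {rhat_threshold}; "
                "chains not converged (pass force=True to pool anyway)"
            )
    idx = np.arange(burn, n_steps, stride)
    thetas, logps, ch_ix, st_ix = [], [], [], []
    extras: dict[str, list] = {k: [] for k in chains[0].extras}
    for c, chain in enumerate(chains):
        thetas.append(chain.thetas[idx])
        logps.append(chain.logps[idx])
        ch_ix.append(np.full(idx.size, c))
        st_ix.append(idx)
        for key in extras:
            extras[key].append(chain.extras[key][idx])
    return PosteriorEnsemble(
        thetas=np.concatenate(thetas), logps=np.concatenate(logps),
        chain_index=np.concatenate(ch_ix), step_index=np.concatenate(st_ix),
        extras={k: np.concatenate(v) for k, v in extras.items()},
        meta=dict(chains[0].meta, burn=int(burn), stride=int(stride)),
    )


@dataclass(frozen=True)
class CredibleBand:
    """Pointwise posterior median and 95% credible limits of one series."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray   # 2.5th percentile
    upper: np.ndarray   # 97.5th percentile

    def __post_init__(self):
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValidationError("credible band ordering violated")


def credible_band(ens: PosteriorEnsemble, quantity: str,
                  times: np.ndarray | None = None) -> CredibleBand:
    """Pointwise median and 2.5/97.5 percentiles of an archived prediction."""
    if len(ens) == 0:
        raise ValidationError("empty ensemble")
    if quantity not in ens.extras:
        raise SchemaError(f"quantity {quantity!r} not archived in ensemble")
    values = ens.extras[quantity]
    if times is None:
        times = np.asarray(ens.meta.get("days", {}).get(quantity,
                                                        np.arange(values.shape[1])))
    lower, med, upper = np.percentile(values, [2.5, 50.0, 97.5], axis=0)
    return CredibleBand(times=np.asarray(times, float), median=med,
                        lower=lower, upper=upper)


def map_estimate(ens: PosteriorEnsemble):
    """Best-likelihood retained sample (the point estimate of the pipeline).

    Ties resolve to the first sample in chain/step order.  Returns a
    :class:`ParameterSet` when the ensemble carries calibration metadata,
    otherwise the raw sampling-coordinate vector.
    """
    if len(ens) == 0:
        raise ValidationError("empty ensemble")
    i = int(np.argmax(ens.logps))
    if "free_names" in ens.meta and "base_values" in ens.meta:
        return ens.params_at(i)
    return ens.thetas[i].copy()


# ---------------------------------------------------------------------------
# Model-bound calibration problem
# ---------------------------------------------------------------------------

DEFAULT_LOG10_BOUNDS = (-8.0, 8.0)


class CalibrationProblem:
    """Posterior log-density of a model variant given an observation set.

    Free parameters are sampled on log10 scale inside ``log10_bounds``
    (``gamma`` on a linear scale in (0, 1]); all other parameters are fixed
    at the values of ``base``.  Every evaluation simulates one protocol per
    observed treatment group on the grid of designed observation days and
    caches per-(group, measurand) SSE partial sums and natural-scale
    predictions, which the chain archives for convergence diagnostics,
    credible bands and Bayes Ratios.
    """

    def __init__(self, variant: str, obs: ObservationSet, base: ParameterSet,
                 free_names: Sequence[str] | None = None,
                 geom: CompartmentGeometry = DEFAULT_GEOMETRY,
                 log10_bounds: tuple[float, float] = DEFAULT_LOG10_BOUNDS,
                 bounds_halfwidth: float | None = None,
                 rtol: float = 1e-6, atol: float = 1e-9):
        if base.variant != variant:
            raise SchemaError(f"base parameters are for {base.variant}, not {variant}")
        self.variant = variant
        self.obs = obs
        self.base = base
        self.geom = geom
        self.rtol, self.atol = rtol, atol
        all_names = free_parameter_names(variant)
        self.free_names = tuple(free_names) if free_names is not None else all_names
        unknown = [n for n in self.free_names if n not in all_names]
        if unknown:
            raise SchemaError(f"unknown free parameter(s): {unknown}")
        self.scales = tuple("linear" if n == "gamma" else "log10"
                            for n in self.free_names)
        lo, hi = log10_bounds
        self.bounds = np.array([
            (1e-6, 1.0) if s == "linear" else (lo, hi) for s in self.scales
        ])
        if bounds_halfwidth is not None:
            # desk-scale prior box: +/- halfwidth decades around the initial
            # guess (full-scale runs keep the [1e-8, 1e8] box)
            for j, (name, s) in enumerate(zip(self.free_names, self.scales)):
                if s == "log10":
                    center = np.log10(max(base[name], 10.0 ** lo))
                    self.bounds[j] = (max(lo, center - bounds_halfwidth),
                                      min(hi, center + bounds_halfwidth))
        # --- pre-index the observations -----------------------------------
        frame = obs.frame
        self.groups = tuple(dict.fromkeys(frame["group"]))
        self._tables: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray]] = []
        self._grids: dict[str, np.ndarray] = {}
        self.n_obs: dict[tuple[str, str], int] = {}
        self.days: dict[str, np.ndarray] = {}
        for group in self.groups:
            gdf = frame[frame["group"] == group]
            prot = group_protocol(group)
            event_days = [prot.immunization_day] if prot.immunogen != "none" else []
            grid = np.unique(np.concatenate([
                [0.0], np.asarray(event_days, float),
                gdf["day"].to_numpy(dtype=float),
            ]))
            self._grids[group] = grid
            for measurand, mdf in gdf.groupby("measurand", sort=False):
                days = mdf["day"].to_numpy(dtype=float)
                idx = np.searchsorted(grid, days)
                yscale = _fit_scale(measurand)
                yobs = _transform(mdf["value"].to_numpy(dtype=float), measurand, yscale)
                self._tables.append((group, measurand, idx, yobs, days))
                self.n_obs[(group, measurand)] = int(days.size)
                self.days[f"pred:{group}:{measurand}"] = np.unique(days)
        self.n_total = int(sum(self.n_obs.values()))

    # -- coordinate transforms ---------------------------------------------

    def theta_from_params(self, p: ParameterSet) -> np.ndarray:
        out = np.empty(len(self.free_names))
        for j, (name, scale) in enumerate(zip(self.free_names, self.scales)):
            value = p[name]
            out[j] = np.log10(max(value, 10.0 ** self.bounds[j, 0])) \
                if scale == "log10" else value
        return out

    def params_from_theta(self, theta: Sequence[float]) -> ParameterSet:
        updates = {}
        for j, (name, scale) in enumerate(zip(self.free_names, self.scales)):
            updates[name] = 10.0 ** theta[j] if scale == "log10" else float(theta[j])
        return self.base.replace(**updates)

    # -- likelihood ---------------------------------------------------------

    def log_density(self, theta: Sequence[float]):
        try:
            p = self.params_from_theta(theta)
        except (ValidationError, SchemaError):
            return -np.inf, None
        extras: dict[str, np.ndarray] = {}
        total = 0.0
        per: dict[tuple[str, str], float] = {}
        preds_cache: dict[str, np.ndarray] = {}
        for group in self.groups:
            prot = group_protocol(group)
            grid = self._grids[group]
            pp = p.pack(prot.effective_antigen, self.geom)
            y0 = _initial_state(self.variant, prot, p, self.geom)
            jumps = _event_jumps(prot, self.geom)
            try:
                states = _integrate_packed(self.variant, pp, y0, grid, jumps,
                                           self.rtol, self.atol, mxstep=4000)
            except IntegrationError:
                return -np.inf, None
            from .model_core import Trajectory
            traj = Trajectory(t=grid, y=states, variant=self.variant,
                              protocol=prot, params=p, geom=self.geom)
            for g, measurand, idx, yobs, days in self._tables:
                if g != group:
                    continue
                key = f"{g}:{measurand}"
                if key not in preds_cache:
                    preds_cache[key] = predict_series(traj, p, measurand)
                series = preds_cache[key]
                ym_nat = series[idx]
                ym = _transform(ym_nat, measurand, _fit_scale(measurand))
                resid = yobs - ym
                s = float(resid @ resid)
                per[(g, measurand)] = s
                total += s
                udays = self.days[f"pred:{g}:{measurand}"]
                uidx = np.searchsorted(grid, udays)
                extras[f"pred:{g}:{measurand}"] = series[uidx]
        if not np.isfinite(total):
            return -np.inf, None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lp = log_likelihood(total, self.n_total)
        for (g, m), s in per.items():
            extras[f"sse:{g}:{m}"] = np.float64(s)
        extras["sse:total"] = np.float64(total)
        return lp, extras

    def __call__(self, theta):
        return self.log_density(theta)

    @property
    def meta(self) -> dict:
        return {
            "variant": self.variant,
            "free_names": list(self.free_names),
            "scales": list(self.scales),
            "base_values": dict(self.base.values),
            "bounds": self.bounds.tolist(),
            "n_obs": {f"{g}:{m}": n for (g, m), n in self.n_obs.items()},
            "n_total": self.n_total,
            "days": dict(self.days),
        }


def calibrate(variant: str, obs: ObservationSet, base: ParameterSet, *,
              chains: int = 4, n_steps: int = 50_000, learn_steps: int = 10_000,
              free_names: Sequence[str] | None = None, seed: int | None = None,
              target_accept: float = 0.2, dispersal: float = 0.1,
              anneal_schedule: AnnealSchedule | None = None,
              geom: CompartmentGeometry = DEFAULT_GEOMETRY,
              bounds_halfwidth: float | None = None,
              theta0: np.ndarray | None = None) -> tuple[CalibrationProblem, list[ChainArchive]]:
    """Run the full calibration: annealed start + parallel adaptive chains.

    The annealed start is shared and each chain starts from a jittered
    (dispersed) copy, with per-chain seeds derived from ``seed``.  Returns
    the problem (for coordinate transforms) and one archive per chain.
    """
    problem = CalibrationProblem(variant, obs, base, free_names=free_names,
                                 geom=geom, bounds_halfwidth=bounds_halfwidth)
    ss = np.random.SeedSequence(seed)
    anneal_seed, *chain_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                                 for s in ss.spawn(chains + 1)]
    if theta0 is None:
        theta0 = anneal_start(problem, problem.bounds,
                              anneal_schedule or AnnealSchedule(), seed=anneal_seed)
    archives = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        start = theta0 + dispersal * rng.standard_normal(theta0.size)
        start = np.clip(start, problem.bounds[:, 0], problem.bounds[:, 1])
        lp, _ = problem.log_density(start)
        if not np.isfinite(lp):
            start = theta0.copy()
        archives.append(run_amcmc(
            problem, start, n_steps=n_steps, learn_steps=learn_steps,
            target_accept=target_accept, seed=chain_seeds[c],
            bounds=problem.bounds, meta=problem.meta,
        ))
    return problem, archives
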