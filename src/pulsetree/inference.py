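"""Residuals, bounded SQP optimization and multistart identifiability loop.

Calibration matches model flow waveforms at measurement sites (residuals
normalized by the per-site data maximum) plus relative systolic/diastolic
pressure residuals at a cuff location, minimizing

    RSS = sum_i sum_j rq_i(t_j)^2 + rp_sys^2 + rp_dia^2

with a bounded sequential-quadratic-programming local optimizer on
log-magnitude scaled parameters.  Identifiability is probed by multistart
inference: optimizations from uniformly perturbed starts; a parameter whose
estimates vary across starts with a coefficient of variation above a
threshold is pruned - either collapsed from per-group copies to a single
global value (when its group family allows) or removed - and the multistart
repeats until every retained parameter has CV below the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .network import Network
from .parameters import ModelParameters
from .solver import Solution, SolverConfig, SolverError, solve
from .waveforms import FlowWaveform

__all__ = [
    "PatientData",
    "ResidualSet",
    "InferenceConfig",
    "OptimizeOutcome",
    "InferenceResult",
    "CalibrationProblem",
    "residuals",
    "rss",
    "optimize",
    "multistart",
    "r_squared",
    "default_bounds",
]


@dataclass(frozen=True)
class PatientData:
    """Calibration data: per-site flow waveforms plus one cuff pressure pair.

    sites: ((vessel_id, fraction), ...) matching ``flows`` order;
    flows: FlowWaveform per site (the site-mean measured waveform, already
    rescaled for mass conservation);
    cuff: (systolic, diastolic) in mmHg at ``cuff_site``.
    """

    sites: tuple
    flows: tuple
    cuff: tuple
    cuff_site: tuple

    @property
    def Tp(self) -> int:
        return self.flows[0].Tp

    @property
    def T(self) -> float:
        return self.flows[0].T


@dataclass(frozen=True)
class ResidualSet:
    """Flow residual blocks (one per site, length Tp) + two pressure residuals."""

    rq: tuple  # tuple of np.ndarray
    rp: tuple  # (r_sys, r_dia)

    def flat(self) -> np.ndarray:
        return np.concatenate([*self.rq, np.asarray(self.rp)])


def residuals(model_flows, model_sys: float, model_dia: float,
              data: PatientData) -> ResidualSet:
    """Build the residual set from model output sampled at the data times.

    Flow blocks are (q_model - q_data) / max(q_data) per site; pressure
    residuals are relative to the measured cuff values.
    """
    rq = []
    for qm, wd in zip(model_flows, data.flows):
        qmax = float(np.max(wd.q))
        if qmax == 0.0:
            raise ValueError("zero maximum data flow at a calibration site")
        rq.append((np.asarray(qm, dtype=float) - wd.q) / qmax)
    sys_d, dia_d = data.cuff
    rp = ((model_sys - sys_d) / sys_d, (model_dia - dia_d) / dia_d)
    return ResidualSet(rq=tuple(rq), rp=rp)


def rss(res: ResidualSet) -> float:
    """Residual sum of squares over all flow and pressure residuals."""
    return float(sum(np.sum(b**2) for b in res.rq) + sum(r**2 for r in res.rp))


def r_squared(model_flows, data: PatientData) -> tuple:
    """Per-site coefficient of determination 1 - SS_res/SS_tot."""
    out = []
    for qm, wd in zip(model_flows, data.flows):
        ss_res = float(np.sum((np.asarray(qm) - wd.q) ** 2))
        ss_tot = float(np.sum((wd.q - wd.q.mean()) ** 2))
        out.append(1.0 - ss_res / ss_tot)
    return tuple(out)


def default_bounds(nominal: dict, factor: float = 2.0) -> dict:
    """Magnitude bounds [|v|/factor, |v|*factor] preserving each sign."""
    out = {}
    for name, v in nominal.items():
        lo, hi = v / factor, v * factor
        out[name] = (min(lo, hi), max(lo, hi))
    return out


@dataclass(frozen=True)
class InferenceConfig:
    """Multistart/optimizer settings.

    Starts are sampled uniformly within +-start_range of nominal; bounds are
    in natural scale per parameter; optimizer tolerance applies to the SQP
    convergence test.  tree_alpha, when inferred, is additionally capped
    below 1 (a radius ratio).
    """

    bounds: dict | None = None
    tol: float = 1.0e-8
    n_starts: int = 12
    start_range: float = 0.30
    cv_threshold: float = 0.10
    seed: int = 0
    fd_step: float = 1e-4
    maxiter: int = 40
    max_rounds: int = 4
    rss_window: float = 0.10

    def __post_init__(self):
        if self.n_starts < 2:
            raise ValueError("need at least two starts")


@dataclass(frozen=True)
class OptimizeOutcome:
    theta: dict
    rss: float
    success: bool
    nfev: int
    message: str


def _to_internal(theta: dict, names) -> np.ndarray:
    return np.array([math.log(abs(theta[n])) for n in names])


def _from_internal(x: np.ndarray, names, signs: dict) -> dict:
    return {n: signs[n] * math.exp(v) for n, v in zip(names, x)}


def optimize(theta0: dict, bounds: dict, objective, tol: float = 1.0e-8,
             fd_step: float = 1e-4, maxiter: int = 60,
             grad=None) -> OptimizeOutcome:
    """Bounded SQP minimization of a scalar objective on log-scaled parameters.

    ``objective(theta_dict) -> float``; gradients are forward finite
    differences with step ``fd_step`` on the log-magnitude coordinates, or
    chain-ruled from ``grad(theta_dict) -> {name: df/dtheta}`` when supplied.
    Returns the best iterate with a failure flag if the optimizer errors out.
    """
    names = tuple(theta0)
    signs = {n: math.copysign(1.0, theta0[n]) for n in names}
    x0 = _to_internal(theta0, names)
    bnds = []
    for n in names:
        lo, hi = bounds[n]
        mags = sorted((abs(lo), abs(hi)))
        if mags[0] <= 0:
            raise ValueError(f"bounds for {n} must exclude zero")
        bnds.append((math.log(mags[0]), math.log(mags[1])))
    x0 = np.clip(x0, [b[0] for b in bnds], [b[1] for b in bnds])

    best = {"x": x0.copy(), "f": math.inf}

    def fun(x):
        f = float(objective(_from_internal(x, names, signs)))
        if f < best["f"]:
            best["f"] = f
            best["x"] = x.copy()
        return f

    def jac(x):
        if grad is not None:
            theta = _from_internal(x, names, signs)
            g_nat = grad(theta)
            # chain rule: d theta_n / d x_n = theta_n (log-magnitude coords)
            return np.array([g_nat[n] * theta[n] for n in names])
        f0 = fun(x)
        g = np.empty(len(x))
        for i in range(len(x)):
            xp = x.copy()
            xp[i] += fd_step
            g[i] = (fun(xp) - f0) / fd_step
        return g

    try:
        res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=bnds,
                       options={"ftol": tol, "maxiter": maxiter})
        success = bool(res.success) or res.fun <= best["f"] + 1e-15
        nfev = int(res.nfev)
        msg = str(res.message)
    except Exception as e:  # noqa: BLE001 - return best iterate on failure
        success = False
        nfev = -1
        msg = f"optimizer failure: {e}"
    return OptimizeOutcome(theta=_from_internal(best["x"], names, signs),
                           rss=best["f"], success=success, nfev=nfev, message=msg)


@dataclass(frozen=True)
class InferenceResult:
    """Multistart outcome: estimates per start, dispersion, pruning history."""

    subset: tuple
    starts: tuple  # OptimizeOutcome per start of the final round
    estimates: dict  # name -> np.ndarray over converged starts
    cv: dict  # name -> coefficient of variation
    best_theta: dict
    best_rss: float
    identifiable: bool
    history: tuple  # log lines of the pruning loop
    r2: tuple = ()


def _family_of(name: str) -> str:
    base, _, grp = name.partition("_")
    return base if grp.isdigit() else name


def multistart(objective, nominal: dict, config: InferenceConfig,
               rng: np.random.Generator | None = None,
               verbose: bool = False) -> InferenceResult:
    """Multistart inference with CV-based pruning.

    Runs ``n_starts`` bounded optimizations from uniform +-start_range
    perturbations of the nominal subset.  The final cost of every start is
    recorded and convergence across optimizations is checked first: starts
    stuck in inferior local optima (final RSS more than ``rss_window`` above
    the best) indicate multimodality, not dispersion of the estimate, and are
    excluded from the CV.  If any parameter's CV (sd/mean of estimates over
    the converged starts) exceeds the threshold, the offending parameter
    family is collapsed to a single global value (per-group copies such as
    ks2_1..ks2_4 become one ks2) or, if already global, removed; the loop
    repeats.  Terminates when all CVs pass or reports the subset as
    non-identifiable.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    subset = dict(nominal)
    history = []
    for round_no in range(config.max_rounds):
        names = tuple(subset)
        bounds = dict(config.bounds) if config.bounds else default_bounds(subset)
        if "tree_alpha" in bounds:
            lo, hi = bounds["tree_alpha"]
            bounds["tree_alpha"] = (lo, min(hi, 0.99))
        outcomes = []
        for s in range(config.n_starts):
            fac = 1.0 + config.start_range * rng.uniform(-1.0, 1.0, size=len(names))
            theta0 = {n: subset[n] * fac[i] for i, n in enumerate(names)}
            for n in names:
                lo, hi = sorted((bounds[n][0], bounds[n][1]))
                theta0[n] = min(max(theta0[n], lo), hi)
            out = optimize(theta0, bounds, objective, tol=config.tol,
                           fd_step=config.fd_step, maxiter=config.maxiter)
            outcomes.append(out)
            if verbose:
                print(f"  start {s + 1}/{config.n_starts}: rss={out.rss:.5g} "
                      f"nfev={out.nfev} success={out.success}", flush=True)
        finite = [o for o in outcomes if o.success and math.isfinite(o.rss)]
        if len(finite) < 2:
            raise RuntimeError("fewer than two successful multistart optimizations")
        best_rss = min(o.rss for o in finite)
        # relative window plus an absolute floor at the finite-difference
        # gradient noise level (near-zero costs all count as one optimum)
        cut = best_rss * (1.0 + config.rss_window) + math.sqrt(config.tol)
        ok = [o for o in finite if o.rss <= cut]
        if len(ok) < 2:
            ok = sorted(finite, key=lambda o: o.rss)[:2]
        est = {n: np.array([o.theta[n] for o in ok]) for n in names}
        cv = {n: float(np.std(est[n], ddof=1) / abs(np.mean(est[n]))) for n in names}
        worst = max(cv, key=lambda n: cv[n])
        history.append(
            f"round {round_no + 1}: {len(finite)}/{len(outcomes)} starts succeeded, "
            f"{len(ok)} converged to the common optimum; "
            f"max CV {cv[worst]:.4f} ({worst})")
        if cv[worst] <= config.cv_threshold:
            best = min(ok, key=lambda o: o.rss)
            return InferenceResult(subset=names, starts=tuple(outcomes),
                                   estimates=est, cv=cv, best_theta=best.theta,
                                   best_rss=best.rss, identifiable=True,
                                   history=tuple(history))
        fam = _family_of(worst)
        members = [n for n in names if _family_of(n) == fam]
        if len(members) > 1:
            pooled = float(np.mean([subset[n] for n in members]))
            for n in members:
                subset.pop(n)
            subset[fam] = pooled
            history.append(f"collapse {members} -> global {fam}")
        else:
            subset.pop(worst)
            history.append(f"remove {worst} (CV {cv[worst]:.3f} > "
                           f"{config.cv_threshold})")
            if not subset:
                break
    best = min(ok, key=lambda o: o.rss)
    return InferenceResult(subset=tuple(subset), starts=tuple(outcomes),
                           estimates=est, cv=cv, best_theta=best.theta,
                           best_rss=best.rss, identifiable=False,
                           history=tuple(history))


class CalibrationProblem:
    """Forward model + data => residuals, RSS and calibrated estimates.

    Fixes the discretization (grid and n_t) once at the nominal parameters
    and runs every evaluation cold-started for a fixed number of cycles, so
    the objective is a smooth deterministic function of the parameters.
    """

    def __init__(self, network: Network, inflow: FlowWaveform, base: ModelParameters,
                 data: PatientData, solver_config: SolverConfig | None = None):
        self.network = network
        self.inflow = inflow
        self.base = base
        self.data = data
        cfg = solver_config or SolverConfig()
        probe = solve(network, inflow, base, cfg)
        cycles = probe.cycles_used + 1
        self.config = replace(cfg, n_t=probe.n_t, cycles_fixed=cycles,
                              cycles_max=max(cfg.cycles_max, cycles))
        self.nominal_solution = probe
        self.n_solves = 0

    # -- forward pieces ---------------------------------------------------

    def _solve(self, theta: dict | None) -> Solution:
        params = self.base if not theta else self.base.update(theta)
        self.n_solves += 1
        return solve(self.network, self.inflow, params, self.config)

    def model_flows(self, sol: Solution):
        """Model flows at the calibration sites, sampled at the data times."""
        out = []
        for (vid, frac), wd in zip(self.data.sites, self.data.flows):
            out.append(sol.flow_waveform(vid, frac).evaluate(wd.t))
        return out

    def model_cuff(self, sol: Solution) -> tuple:
        vid, frac = self.data.cuff_site
        p = sol.pressure(vid, frac)
        return float(p.max()), float(p.min())

    def residual_set(self, theta: dict | None = None) -> ResidualSet:
        sol = self._solve(theta)
        sys_m, dia_m = self.model_cuff(sol)
        return residuals(self.model_flows(sol), sys_m, dia_m, self.data)

    # -- objectives -------------------------------------------------------

    def flow_residual(self, theta: dict) -> np.ndarray:
        """Concatenated flow residual blocks (the SA quantity of interest)."""
        return np.concatenate(self.residual_set(theta).rq)

    def rss(self, theta: dict) -> float:
        try:
            return rss(self.residual_set(theta))
        except (SolverError, ValueError):
            return 1e8  # failed/invalid forward solve: heavily penalized plateau

    def r_squared(self, theta: dict | None = None) -> tuple:
        sol = self._solve(theta)
        return r_squared(self.model_flows(sol), self.data)

    def calibrate(self, nominal_subset: dict, config: InferenceConfig,
                  verbose: bool = False) -> InferenceResult:
        """Multistart inference of a parameter subset against the data."""
        result = multistart(self.rss, nominal_subset, config, verbose=verbose)
        r2 = self.r_squared(result.best_theta)
        return replace_result(result, r2=tuple(r2))


def replace_result(res: InferenceResult, **kw) -> InferenceResult:
    from dataclasses import replace as _replace

    return _replace(res, **kw)
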