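"""Sensitivity analysis and identifiable-subset selection.

Three complementary analyses of a residual function r(theta):

* **Local**: centred finite differences of r with respect to log-magnitude
  scaled parameters, ranked by the 2-norm of each sensitivity column.
* **Global (Morris screening)**: one-at-a-time elementary effects on an
  M-level grid over stated perturbation ranges, summarized per parameter by
  the mean absolute effect norm mu* and its sample variance sigma^2, ranked
  by mu*^2 + sigma^2.
* **Covariance/correlation**: V = s^2 (S^T S)^-1 from the local sensitivity
  matrix; parameter pairs with |correlation| above a threshold are flagged as
  practically indistinguishable.

``select_subset`` combines the three into a deterministic rule: drop
uninfluential parameters, then break each flagged correlated pair by fixing
its lower-ranked member, with an audit trail of every decision.

Parameters are handled as ordered name->value dicts; log-magnitude scaling
(theta = sign * exp(theta_tilde)) keeps relative perturbations meaningful for
the negative exponential-decay rates (k2, ks2) as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SAConfig",
    "SensitivityResult",
    "MorrisResult",
    "CovarianceResult",
    "local_sensitivity",
    "morris_screening",
    "correlation_analysis",
    "select_subset",
    "morris_step",
]

#: Perturbation half-ranges (fraction of nominal magnitude) by parameter kind.
_TREE_NAMES = ("tree_alpha", "tree_beta", "lrr")


@dataclass(frozen=True)
class SAConfig:
    """Settings of the sensitivity analyses.

    psi: centred-difference step on log-magnitude parameters.
    K, M: Morris sample count and grid levels; the Morris step is
    Delta = M / (2 (M - 1)).
    stiffness_range/tree_range: one-sided perturbation fractions (stiffness
    +-10%, tree geometry ratios +-5%).
    corr_threshold: |correlation| above which a pair is flagged.
    s2: observation variance scaling the covariance (correlations are
    invariant to it).
    influence_cutoff: fraction of the top-ranked statistic below which a
    parameter is considered uninfluential in subset selection.
    """

    psi: float = 0.01
    K: int = 100
    M: int = 60
    stiffness_range: float = 0.10
    tree_range: float = 0.05
    corr_threshold: float = 0.9
    s2: float = 1.0
    influence_cutoff: float = 0.05

    def __post_init__(self):
        if not (0 < self.psi < 1):
            raise ValueError("psi must be in (0, 1)")
        if self.M % 2 != 0:
            raise ValueError("Morris level count M must be even")

    @property
    def delta(self) -> float:
        """Morris step Delta = M / (2(M-1)) in unit-hypercube coordinates."""
        return morris_step(self.M)

    def range_for(self, name: str) -> float:
        return self.tree_range if name in _TREE_NAMES else self.stiffness_range


def morris_step(M: int) -> float:
    """Morris elementary-effect step Delta = M / (2 (M - 1))."""
    return M / (2.0 * (M - 1.0))


@dataclass(frozen=True)
class SensitivityResult:
    names: tuple
    S: np.ndarray  # (len(residual), n_params) d r / d theta_tilde
    S_bar: np.ndarray  # column 2-norms
    ranking: tuple  # names, most to least influential
    warnings: tuple = ()

    def rank_of(self, name: str) -> int:
        return self.ranking.index(name)


@dataclass(frozen=True)
class MorrisResult:
    names: tuple
    d_tilde: np.ndarray  # (K, n_params) elementary-effect norms
    mu_star: np.ndarray
    sigma2: np.ndarray
    score: np.ndarray  # mu*^2 + sigma^2
    ranking: tuple

    def rank_of(self, name: str) -> int:
        return self.ranking.index(name)


@dataclass(frozen=True)
class CovarianceResult:
    names: tuple
    V: np.ndarray
    corr: np.ndarray
    flagged: tuple  # ((name_a, name_b, |corr|), ...) sorted by |corr| desc
    rank_deficient: bool


def _log_perturb(value: float, step: float) -> float:
    # theta = sign(theta) * exp(log|theta| + step)
    return value * math.exp(step)


def local_sensitivity(residual_fn, theta_nominal: dict, config: SAConfig = SAConfig()
                      ) -> SensitivityResult:
    """Centred-difference sensitivities of a residual on log-scaled parameters.

    Columns are (r(theta_n e^psi) - r(theta_n e^-psi)) / (2 psi); a failed
    evaluation at one side falls back to a one-sided difference with a
    recorded warning.
    """
    names = tuple(theta_nominal)
    psi = config.psi
    r0 = None
    cols = []
    warnings = []
    for name in names:
        theta_p = dict(theta_nominal)
        theta_m = dict(theta_nominal)
        theta_p[name] = _log_perturb(theta_nominal[name], psi)
        theta_m[name] = _log_perturb(theta_nominal[name], -psi)
        rp = rm = None
        try:
            rp = np.asarray(residual_fn(theta_p), dtype=float)
        except Exception as e:  # noqa: BLE001 - forward model may abort
            warnings.append(f"{name}: +psi evaluation failed ({e})")
        try:
            rm = np.asarray(residual_fn(theta_m), dtype=float)
        except Exception as e:  # noqa: BLE001
            warnings.append(f"{name}: -psi evaluation failed ({e})")
        if rp is not None and rm is not None:
            cols.append((rp - rm) / (2.0 * psi))
        else:
            if r0 is None:
                r0 = np.asarray(residual_fn(theta_nominal), dtype=float)
            if rp is not None:
                cols.append((rp - r0) / psi)
            elif rm is not None:
                cols.append((r0 - rm) / psi)
            else:
                raise RuntimeError(f"residual evaluation failed on both sides for {name}")
    S = np.column_stack(cols)
    S_bar = np.linalg.norm(S, axis=0)
    order = np.argsort(-S_bar, kind="stable")
    return SensitivityResult(names=names, S=S, S_bar=S_bar,
                             ranking=tuple(names[i] for i in order),
                             warnings=tuple(warnings))


def _unit_to_theta(u: np.ndarray, names, nominal: dict, config: SAConfig) -> dict:
    theta = {}
    for i, name in enumerate(names):
        v = nominal[name]
        half = config.range_for(name)
        theta[name] = v * (1.0 - half + 2.0 * half * u[i])
    return theta


def morris_screening(residual_fn, theta_nominal: dict, config: SAConfig = SAConfig(),
                     seed: int = 0) -> MorrisResult:
    """Morris elementary-effects screening over the stated perturbation ranges.

    K base points are drawn from an M-level grid on the unit hypercube (each
    parameter spans nominal +- its perturbation range); each parameter is
    stepped by Delta = M/(2(M-1)) one at a time and the elementary-effect
    vector norm recorded.  Deterministic for a fixed seed; a failed model
    evaluation resamples that trajectory (logged).
    """
    names = tuple(theta_nominal)
    B = len(names)
    K, M, delta = config.K, config.M, config.delta
    rng = np.random.default_rng(seed)
    levels = np.arange(M) / (M - 1.0)
    base_levels = levels[levels <= 1.0 - delta + 1e-12]

    d_tilde = np.empty((K, B))
    k = 0
    attempts = 0
    while k < K:
        attempts += 1
        if attempts > 20 * K:
            raise RuntimeError("Morris screening: too many failed trajectories")
        u0 = rng.choice(base_levels, size=B)
        try:
            r_base = np.asarray(residual_fn(_unit_to_theta(u0, names, theta_nominal,
                                                           config)), dtype=float)
            row = np.empty(B)
            for i in range(B):
                u1 = u0.copy()
                u1[i] += delta
                r_pert = np.asarray(residual_fn(_unit_to_theta(u1, names, theta_nominal,
                                                               config)), dtype=float)
                row[i] = np.linalg.norm((r_pert - r_base) / delta)
        except Exception:  # noqa: BLE001 - resample the trajectory
            continue
        d_tilde[k] = row
        k += 1

    mu_star = np.abs(d_tilde).mean(axis=0)
    sigma2 = d_tilde.var(axis=0, ddof=1) if K > 1 else np.zeros(B)
    score = mu_star**2 + sigma2
    # rank by score, tie-break by mu*
    order = sorted(range(B), key=lambda i: (-score[i], -mu_star[i]))
    return MorrisResult(names=names, d_tilde=d_tilde, mu_star=mu_star,
                        sigma2=sigma2, score=score,
                        ranking=tuple(names[i] for i in order))


def correlation_analysis(sens: SensitivityResult, config: SAConfig = SAConfig()
                         ) -> CovarianceResult:
    """Covariance V = s^2 (S^T S)^-1 and the derived correlation matrix.

    A singular information matrix (structural non-identifiability) falls back
    to the pseudo-inverse and is flagged.
    """
    S = sens.S
    G = S.T @ S
    rank_deficient = False
    try:
        V = config.s2 * np.linalg.inv(G)
    except np.linalg.LinAlgError:
        V = config.s2 * np.linalg.pinv(G)
        rank_deficient = True
    if not rank_deficient and np.linalg.cond(G) > 1e14:
        rank_deficient = True
    d = np.sqrt(np.abs(np.diag(V)))
    corr = V / np.outer(d, d)
    flagged = []
    n = len(sens.names)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) > config.corr_threshold:
                flagged.append((sens.names[i], sens.names[j], abs(corr[i, j])))
    flagged.sort(key=lambda t: -t[2])
    return CovarianceResult(names=sens.names, V=V, corr=corr,
                            flagged=tuple(flagged), rank_deficient=rank_deficient)


@dataclass(frozen=True)
class SubsetSelection:
    subset: tuple
    fixed: tuple
    log: tuple


def select_subset(sens_local: SensitivityResult, sens_morris: MorrisResult,
                  corr: CovarianceResult, config: SAConfig = SAConfig()
                  ) -> SubsetSelection:
    """Deterministic subset-selection rule.

    1. A parameter is *influential* if its local or its Morris statistic is
       at least ``influence_cutoff`` times the respective maximum;
       uninfluential parameters are fixed.
    2. Flagged correlated pairs are visited in order of decreasing
       |correlation|; if both members are still retained, the lower-ranked
       one (by combined local+Morris rank) is fixed.

    Every decision is recorded in the audit log.
    """
    names = sens_local.names
    if sens_morris.names != names or corr.names != names:
        raise ValueError("analyses must share the same parameter vector")
    log = []
    local_rel = sens_local.S_bar / max(sens_local.S_bar.max(), 1e-300)
    morris_rel = sens_morris.score / max(sens_morris.score.max(), 1e-300)
    retained = []
    for i, name in enumerate(names):
        if max(local_rel[i], morris_rel[i]) >= config.influence_cutoff:
            retained.append(name)
        else:
            log.append(f"fix {name}: uninfluential (local {local_rel[i]:.3g}, "
                       f"Morris {morris_rel[i]:.3g} of max)")
    combined_rank = {n: sens_local.rank_of(n) + sens_morris.rank_of(n) for n in names}
    for a, b, v in corr.flagged:
        if a in retained and b in retained:
            drop = b if combined_rank[b] >= combined_rank[a] else a
            keep = a if drop == b else b
            retained.remove(drop)
            log.append(f"fix {drop}: |corr|={v:.3f} with higher-ranked {keep}")
    if not retained:
        raise ValueError("subset selection removed every parameter")
    fixed = tuple(n for n in names if n not in retained)
    return SubsetSelection(subset=tuple(retained), fixed=fixed, log=tuple(log))
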