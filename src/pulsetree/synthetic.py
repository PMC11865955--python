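"""Synthetic single-ventricle patients for end-to-end pipeline testing.

A synthetic patient is a ground-truth forward model (jittered cohort-mean
geometry + nominal cohort parameters) whose output is degraded the way
velocity-encoded MRI flow data are degraded in practice: a Tp-point (19-28
samples/cycle) inflow waveform, five noisy replicate flow waveforms at each
measurement site, deliberately non-conservative branch flows (each branch
scaled by a random 5-15% factor, emulating divergence error), and a single
systolic/diastolic "cuff" pressure pair with measurement offset.  Because the
truth is known, every downstream stage - replicate averaging, mass rescaling,
sensitivity analysis, subset selection and multistart calibration - can be
tested for recovery without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PatientData
from .network import Network, build_network, canonical_network
from .parameters import ModelParameters
from .solver import Solution, SolverConfig, SolverError, solve
from .waveforms import FlowWaveform, WaveformEnsemble, average_ensemble, conserve_mass

__all__ = [
    "NoiseConfig",
    "SyntheticPatient",
    "make_inflow",
    "generate",
    "three_vessel_network",
]

#: Per-cohort measured ranges: cardiac output (l/min) and cycle length (s).
_CO_RANGE = {"DORV": (3.3, 4.0), "HLHS": (2.8, 5.4)}
_T_RANGE = (0.598, 0.942)
_T_NOMINAL = {"DORV": (0.710, 0.090), "HLHS": (0.770, 0.190)}


@dataclass(frozen=True)
class NoiseConfig:
    """Degradation applied to the truth: all levels are fractions except
    ``cuff_noise_mmhg`` (additive sd, mmHg)."""

    flow_noise: float = 0.05
    n_replicates: int = 5
    deconservation: tuple = (0.05, 0.15)
    cuff_noise_mmhg: float = 1.0
    geometry_sigma: float = 0.05


@dataclass(frozen=True)
class SyntheticPatient:
    """A generated patient: truth + degraded measurements."""

    cohort: str
    seed: int
    network: Network
    theta_true: ModelParameters
    inflow: FlowWaveform
    sites: tuple  # ((vessel_id, fraction), ...)
    ensembles: tuple  # WaveformEnsemble per site (noisy, non-conservative)
    cuff: tuple  # (sys, dia) mmHg
    cuff_site: tuple
    truth_solution: Solution
    solver_config: SolverConfig
    noise: NoiseConfig

    @property
    def Tp(self) -> int:
        return self.inflow.Tp

    def patient_data(self) -> PatientData:
        """Averaged, mass-rescaled calibration data (the pipeline's input).

        Branch rescaling factors are computed per calibration vessel from the
        site-ensemble means and applied to every site on that vessel; the
        inlet cardiac output is held fixed.
        """
        means = [e.mean for e in self.ensembles]
        branch_vessels = list(dict.fromkeys(v for v, _ in self.sites))
        branch_of = {v: next(m for (vv, _), m in zip(self.sites, means) if vv == v)
                     for v in branch_vessels}
        res = conserve_mass(self.inflow, [branch_of[v] for v in branch_vessels])
        alpha = dict(zip(branch_vessels, res.alpha))
        flows = tuple(m.scaled(1.0 + alpha[v]) for (v, _), m in zip(self.sites, means))
        return PatientData(sites=self.sites, flows=flows, cuff=self.cuff,
                           cuff_site=self.cuff_site)

    def inference_subset(self) -> dict:
        """The protocol's final inference subset for this network: tree_alpha,
        one k3 per large group present, a single global ks2, one ks3 per
        small group present among the terminals."""
        large = sorted({v.group_large for v in self.network.vessels.values()})
        small = sorted({v.group_small for v in self.network.vessels.values()
                        if v.terminal})
        p = self.theta_true
        sub = {"tree_alpha": p.tree_alpha}
        for g in large:
            sub[f"k3_{g}"] = p.k3[g - 1]
        sub["ks2"] = p.ks2[0]
        for g in small:
            sub[f"ks3_{g}"] = p.ks3[g - 1]
        return sub

    def save_dir(self, path) -> None:
        """Write the patient as plain-text files (CSV/JSON)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.network.to_csv(path / "vessels.csv", path / "edges.csv")
        self.inflow.to_csv(path / "inflow.csv")
        for i, ((vid, frac), ens) in enumerate(zip(self.sites, self.ensembles)):
            df = pd.DataFrame({"time_s": ens.mean.t})
            for k, rep in enumerate(ens.replicates):
                df[f"replicate_{k + 1}"] = rep.q
            df["mean"] = ens.mean.q
            df["sd"] = ens.sd
            with open(path / f"site_{i + 1}_vessel{vid}.csv", "w") as fh:
                fh.write(f"# period_s={ens.mean.T} vessel={vid} fraction={frac}\n")
                df.to_csv(fh, index=False)
        (path / "cuff.json").write_text(json.dumps(
            {"systolic_mmhg": self.cuff[0], "diastolic_mmhg": self.cuff[1],
             "site": list(self.cuff_site)}))
        truth = {
            "cohort": self.cohort, "seed": self.seed, "T_s": self.theta_true.blood.T,
            "tree_alpha": self.theta_true.tree_alpha,
            "tree_beta": self.theta_true.tree_beta, "lrr": self.theta_true.lrr,
            "k1": self.theta_true.k1, "k2": self.theta_true.k2,
            "k3": self.theta_true.k3, "ks1": self.theta_true.ks1,
            "ks2": self.theta_true.ks2, "ks3": self.theta_true.ks3,
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=1))


def make_inflow(CO_l_min: float, T: float, Tp: int, seed: int | None = None,
                systolic_fraction: float = 0.35) -> FlowWaveform:
    """Parametric cardiac-ejection inflow waveform.

    Half-sine systolic ejection over ``systolic_fraction`` of the cycle plus
    a small (2% of peak) diastolic baseline, scaled so the period-averaged
    flow equals the cardiac output CO (l/min -> ml/s: CO*1000/60).  ``seed``
    jitters the systolic fraction slightly (+-0.02) for between-patient shape
    variety.
    """
    lo, hi = 2.8, 5.4
    if not (lo <= CO_l_min <= hi):
        raise ValueError(f"cardiac output {CO_l_min} l/min outside measured range "
                         f"[{lo}, {hi}]")
    if not (_T_RANGE[0] <= T <= _T_RANGE[1]):
        raise ValueError(f"cycle length {T} s outside measured range {_T_RANGE}")
    if seed is not None:
        systolic_fraction += 0.02 * np.random.default_rng(seed).uniform(-1.0, 1.0)
    target = CO_l_min * 1000.0 / 60.0
    t = np.arange(Tp) * T / Tp
    ts = systolic_fraction * T
    shape = np.where(t < ts, np.sin(np.pi * t / ts), 0.0)
    shape = shape + 0.02 * shape.max()
    q = shape * target / shape.mean()
    return FlowWaveform(t, q, T)


def three_vessel_network(cohort: str = "DORV") -> Network:
    """Reduced 3-vessel subnetwork: ascending aorta -> descending aorta +
    innominate, with cohort-mean dimensions.

    Both daughters are terminal here; the descending aorta keeps its 0.01 cm
    tree truncation radius and small group 1, the innominate gets the
    arteriolar 0.001 cm truncation and small group 2.
    """
    full = canonical_network(cohort)
    rows = []
    for vid, gs, rmin in ((1, None, None), (7, 1, 0.01), (3, 2, 0.001)):
        v = full.vessels[vid]
        rows.append(dict(id=vid, name=v.name, length_cm=v.length_cm,
                         r_in_cm=v.r_in_cm, r_out_cm=v.r_out_cm,
                         group_large=v.group_large, group_small=gs, r_min_cm=rmin))
    return build_network(pd.DataFrame(rows), [(1, 7), (1, 3)])


#: Calibration sites (vessel id, fraction) and cuff location per network kind.
_CANONICAL_SITES = ((7, 0.1), (3, 0.5), (5, 0.1), (6, 0.5))
_CANONICAL_CUFF = (8, 0.5)
_TWIN_SITES = ((7, 0.25), (7, 0.75), (3, 0.4), (3, 0.8))
_TWIN_CUFF = (3, 0.5)


def _jitter(net: Network, rng, sigma: float) -> Network:
    """Length and radius jitter with one radius factor per vessel, so each
    vessel's taper direction (e.g. the widening HLHS ascending aorta) is
    preserved by construction."""
    vessels = {}
    for vid, v in net.vessels.items():
        fL = math.exp(sigma * rng.standard_normal())
        fR = math.exp(sigma * rng.standard_normal())
        vessels[vid] = replace(v, length_cm=v.length_cm * fL,
                               r_in_cm=v.r_in_cm * fR, r_out_cm=v.r_out_cm * fR)
    return Network(vessels=vessels, children=dict(net.children), root_id=net.root_id)


def generate(cohort: str, seed: int, noise: NoiseConfig = NoiseConfig(),
             network: Network | None = None, sites: tuple | None = None,
             cuff_site: tuple | None = None,
             solver_config: SolverConfig | None = None,
             Tp: int | None = None) -> SyntheticPatient:
    """Generate a complete synthetic patient.

    The truth model is forward-solved once; measurements are sampled at Tp
    uniformly spaced times, replicated with multiplicative Gaussian noise,
    and branch flows are deliberately de-conserved.  Regeneration with the
    same arguments is bit-identical.  If the jittered geometry fails to
    solve, it is re-jittered (logged to the returned patient's seed history
    via the retry offset).
    """
    rng = np.random.default_rng(seed)
    base_net = network if network is not None else canonical_network(cohort)
    if sites is None:
        sites = _TWIN_SITES if len(base_net) == 3 else _CANONICAL_SITES
    if cuff_site is None:
        cuff_site = _TWIN_CUFF if len(base_net) == 3 else _CANONICAL_CUFF
    cfg = solver_config or SolverConfig(periodicity_tol=1e-5)

    mu_T, sd_T = _T_NOMINAL[cohort]
    T = float(np.clip(rng.normal(mu_T, sd_T), *_T_RANGE))
    CO = float(rng.uniform(*_CO_RANGE[cohort]))
    Tp = int(rng.integers(19, 29)) if Tp is None else Tp
    inflow = make_inflow(CO, T, Tp, seed=seed)
    theta_true = ModelParameters.nominal(cohort, T=T)

    sol = None
    net = base_net
    for attempt in range(5):
        net = _jitter(base_net, rng, noise.geometry_sigma)
        try:
            sol = solve(net, inflow, theta_true, cfg)
            break
        except SolverError:  # re-jitter and retry
            continue
    if sol is None:
        raise RuntimeError("forward solve failed for five jittered geometries")

    t_j = inflow.t
    branch_vessels = list(dict.fromkeys(v for v, _ in sites))
    gamma = {}
    for v in branch_vessels:
        mag = rng.uniform(*noise.deconservation)
        gamma[v] = float(rng.choice([-1.0, 1.0]) * mag)
    ensembles = []
    for vid, frac in sites:
        q_true = sol.flow_waveform(vid, frac).evaluate(t_j)
        q_site = q_true * (1.0 + gamma[vid])
        reps = []
        for _ in range(noise.n_replicates):
            eps = noise.flow_noise * rng.standard_normal(Tp)
            reps.append(FlowWaveform(t_j, q_site * (1.0 + eps), T))
        ensembles.append(average_ensemble(reps))

    p_cuff = sol.pressure(*cuff_site)
    cuff = (float(p_cuff.max() + noise.cuff_noise_mmhg * rng.standard_normal()),
            float(p_cuff.min() + noise.cuff_noise_mmhg * rng.standard_normal()))

    return SyntheticPatient(cohort=cohort, seed=seed, network=net,
                            theta_true=theta_true, inflow=inflow, sites=tuple(sites),
                            ensembles=tuple(ensembles), cuff=cuff,
                            cuff_site=tuple(cuff_site), truth_solution=sol,
                            solver_config=cfg, noise=noise)
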