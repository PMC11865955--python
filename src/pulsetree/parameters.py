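"""Physical parameters of the 1-D haemodynamics model.

All quantities are stored in CGS units (g, cm, s); pressures are converted to
mmHg only at the reporting surface.  Vessel-wall stiffness ``Eh/r0`` follows an
exponential-plus-offset law of the unstressed radius,

    Eh/r0 = k1 * exp(k2 * r0) + k3,          k2 < 0,

so small vessels are stiffer than large ones.  Large vessels carry one (k1, k2,
k3) triple per stiffness group g = 1..4; the small vessels of the structured
trees carry an analogous (ks1, ks2, ks3) triple per terminal-vessel group.

Named parameter access (``get``/``set``/``update``) uses flat names such as
``"k3_1"`` (group 1 large-vessel offset), ``"ks2_3"``, or group-free names like
``"ks2"`` which address every group at once (used when a per-group family is
collapsed to a single global value during identifiability pruning), plus
``"tree_alpha"``, ``"tree_beta"`` and ``"lrr"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

MMHG = 1333.22  # g cm^-1 s^-2 per mmHg

_GROUPS = (1, 2, 3, 4)
_STIFF_FIELDS = ("k1", "k2", "k3", "ks1", "ks2", "ks3")
_TREE_FIELDS = ("tree_alpha", "tree_beta", "lrr")


@dataclass(frozen=True)
class BloodParams:
    """Fluid constants and cycle timing.

    rho : blood density (g cm^-3)
    mu  : dynamic viscosity (g cm^-1 s^-1)
    nu  : kinematic viscosity (cm^2 s^-1); tabulated separately from mu/rho,
          which it equals up to rounding
    T   : cardiac cycle length (s)
    p0  : reference (unstressed) pressure, mmHg
    """

    rho: float = 1.06
    mu: float = 0.032
    nu: float = 0.030
    T: float = 0.710
    p0_mmhg: float = 0.0

    def __post_init__(self):
        for name in ("rho", "mu", "nu", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BloodParams.{name} must be positive")

    @property
    def delta(self) -> float:
        """Stokes boundary-layer thickness sqrt(nu*T/2pi) (cm)."""
        return math.sqrt(self.nu * self.T / (2.0 * math.pi))

    @property
    def p0(self) -> float:
        """Reference pressure in CGS units."""
        return self.p0_mmhg * MMHG


@dataclass(frozen=True)
class StiffnessLaw:
    """One (k1, k2, k3) stiffness triple; evaluates Eh/r0 = k1*exp(k2*r0)+k3."""

    k1: float
    k2: float
    k3: float

    def __post_init__(self):
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if self.k3 <= 0:
            raise ValueError("k3 must be positive")

    def __call__(self, r0):
        import numpy as np

        return self.k1 * np.exp(self.k2 * r0) + self.k3

    def deriv(self, r0):
        """d(Eh/r0)/dr0."""
        import numpy as np

        return self.k1 * self.k2 * np.exp(self.k2 * r0)


@dataclass(frozen=True)
class TreeParams:
    """Structured-tree geometry and small-vessel stiffness for one terminal.

    tree_alpha, tree_beta : daughter radius ratios (asymmetry; beta <= alpha)
    lrr                   : vessel length-to-radius ratio
    r_min_cm              : termination radius of the tree
    ks1, ks2, ks3         : small-vessel stiffness constants
    """

    tree_alpha: float = 0.9
    tree_beta: float = 0.6
    lrr: float = 50.0
    r_min_cm: float = 0.001
    ks1: float = 2.0e7
    ks2: float = -35.0
    ks3: float = 3.8e5

    def __post_init__(self):
        if not (0.0 < self.tree_beta <= self.tree_alpha < 1.0):
            raise ValueError("require 0 < tree_beta <= tree_alpha < 1")
        if self.lrr <= 0:
            raise ValueError("lrr must be positive")
        if self.r_min_cm <= 0:
            raise ValueError("r_min_cm must be positive")

    def stiffness(self, r0):
        """Small-vessel Eh/r0 at radius r0."""
        import numpy as np

        return self.ks1 * np.exp(self.ks2 * r0) + self.ks3


# Table-derived nominal stiffness values per cohort.  k3/ks3 nominals are the
# cohort means, identical across groups at the nominal point.
_NOMINAL = {
    "DORV": dict(k1=2.0e7, k2=-25.0, k3=5.6e5, ks1=2.0e7, ks2=-35.0, ks3=3.8e5, T=0.710),
    "HLHS": dict(k1=2.0e7, k2=-35.0, k3=7.3e5, ks1=2.0e7, ks2=-30.0, ks3=5.4e5, T=0.770),
}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the forward model.

    Stiffness constants are stored per group as 4-tuples indexed by group-1.
    ``rmin`` for each terminal vessel lives on the Network, not here.
    """

    blood: BloodParams = field(default_factory=BloodParams)
    k1: tuple = (2.0e7,) * 4
    k2: tuple = (-25.0,) * 4
    k3: tuple = (5.6e5,) * 4
    ks1: tuple = (2.0e7,) * 4
    ks2: tuple = (-35.0,) * 4
    ks3: tuple = (3.8e5,) * 4
    tree_alpha: float = 0.9
    tree_beta: float = 0.6
    lrr: float = 50.0

    @staticmethod
    def nominal(cohort: str, T: float | None = None) -> "ModelParameters":
        """Nominal parameters for a patient cohort ("DORV" or "HLHS")."""
        try:
            v = _NOMINAL[cohort]
        except KeyError:
            raise ValueError(f"unknown cohort {cohort!r}; expected 'DORV' or 'HLHS'")
        blood = BloodParams(T=v["T"] if T is None else T)
        return ModelParameters(
            blood=blood,
            k1=(v["k1"],) * 4,
            k2=(v["k2"],) * 4,
            k3=(v["k3"],) * 4,
            ks1=(v["ks1"],) * 4,
            ks2=(v["ks2"],) * 4,
            ks3=(v["ks3"],) * 4,
        )

    # -- named flat access ------------------------------------------------

    def large_law(self, group: int) -> StiffnessLaw:
        return StiffnessLaw(self.k1[group - 1], self.k2[group - 1], self.k3[group - 1])

    def tree_params(self, group: int, r_min_cm: float) -> TreeParams:
        g = group - 1
        return TreeParams(
            tree_alpha=self.tree_alpha,
            tree_beta=self.tree_beta,
            lrr=self.lrr,
            r_min_cm=r_min_cm,
            ks1=self.ks1[g],
            ks2=self.ks2[g],
            ks3=self.ks3[g],
        )

    def get(self, name: str) -> float:
        if name in _TREE_FIELDS:
            return getattr(self, name)
        base, _, grp = name.partition("_")
        if base in _STIFF_FIELDS:
            tup = getattr(self, base)
            if grp == "":  # global name: defined when all groups agree
                if len(set(tup)) != 1:
                    raise ValueError(f"{name!r} is group-specific; use {base}_g")
                return tup[0]
            return tup[int(grp) - 1]
        raise KeyError(name)

    def update(self, values: dict) -> "ModelParameters":
        """Return a copy with the named entries replaced.

        Group-free stiffness names ("ks2") set every group; suffixed names
        ("k3_2") set one group.
        """
        out = {}
        for name, val in values.items():
            if name in _TREE_FIELDS:
                out[name] = float(val)
                continue
            base, _, grp = name.partition("_")
            if base not in _STIFF_FIELDS:
                raise KeyError(name)
            tup = list(out.get(base, getattr(self, base)))
            if grp == "":
                tup = [float(val)] * 4
            else:
                tup[int(grp) - 1] = float(val)
            out[base] = tuple(tup)
        return replace(self, **out)
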