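"""Structured-tree outflow impedance.

Each terminal vessel of the large-vessel network is loaded with a self-similar
asymmetric binary tree of small vessels: a parent of radius r spawns daughters
of radii ``tree_alpha * r`` and ``tree_beta * r``; every vessel has length
``lrr * r``; a branch is not generated once its radius falls below ``r_min``.
In the small vessels inertia is negligible, so the linearized, periodic flow
equations admit an analytic transmission-line solution whose input impedance

    Z(0, w) = [ i g^-1 sin(wL/c) + Z(L, w) cos(wL/c) ]
              / [ cos(wL/c) + i g Z(L, w) sin(wL/c) ]

propagates the load Z(L, w) through one vessel, with complex wave speed
``c = sqrt(A0 (1 - F_J) / (rho C))``, shunt admittance factor
``g = sqrt(C A0 (1 - F_J) / rho)``, compliance ``C = 3 A0 / (2 Eh/r0)`` and
Womersley factor ``F_J = 2 J1(w0) / (w0 J0(w0))`` with ``w0^2 = i^3 r0^2 w/nu``.
Terminal branches carry zero load; junctions combine daughters in parallel
(pressure continuity + mass conservation).  At w = 0 the transfer reduces to
the Poiseuille resistance ``8 mu L / (pi r0^4)`` in series with the load.

Because a node's radius depends only on how many alpha- and beta-steps lead to
it, the recursion is memoized on those two counts, collapsing the binary tree
to a lattice of O(depth^2) distinct nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .parameters import BloodParams, TreeParams

__all__ = [
    "ImpedanceSpectrum",
    "ImpedanceKernel",
    "small_vessel_stiffness",
    "vessel_input_impedance",
    "root_impedance",
    "impedance_to_kernel",
    "cyclic_convolve",
]

_SQRT_I3 = np.exp(3j * np.pi / 4)  # principal sqrt of i^3


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Root input impedance at harmonics omega_k = 2 pi k / T, k = 0..K_f."""

    omega: np.ndarray
    Z: np.ndarray
    T: float

    def __post_init__(self):
        if abs(self.Z[0].imag) > 1e-12 * max(abs(self.Z[0]), 1.0) or self.Z[0].real <= 0:
            raise ValueError("DC impedance must be real and positive")


@dataclass(frozen=True)
class ImpedanceKernel:
    """Real time-domain kernel z_m over one period; p = z (*) q cyclically."""

    z: np.ndarray
    dt: float


def small_vessel_stiffness(r0, params: TreeParams):
    """Small-vessel wall stiffness Eh/r0 = ks1 exp(ks2 r0) + ks3."""
    return params.stiffness(r0)


def _omf_exact(x):
    """1 - F_J as a function of the real Womersley number x = r0 sqrt(w/nu).

    w0 = x * exp(3 pi i/4); F_J = 2 J1(w0)/(w0 J0(w0)).  Series for small x
    (1 minus the Bessel ratio cancels catastrophically there) and the
    J1/J0 -> i asymptote where the Bessel functions would overflow.
    """
    x = np.asarray(x, dtype=float)
    w0 = _SQRT_I3 * x
    out = np.empty(x.shape, dtype=complex)
    big = x > 420.0  # Im w0 > ~300: Bessel overflow
    tiny = x < 0.1
    mid = ~(big | tiny)
    z = w0[mid]
    out[mid] = 1.0 - 2.0 * jv(1, z) / (z * jv(0, z))
    out[big] = 1.0 - 2j / w0[big]
    s = w0[tiny] ** 2  # 1 - F_J = (-s/8 + s^2/96 - s^3/3072) / D
    D = 1.0 - s / 4.0 + s**2 / 64.0 - s**3 / 2304.0
    out[tiny] = (-s / 8.0 + s**2 / 96.0 - s**3 / 3072.0) / D
    return out


_OMF_SPLINE = None
_OMF_RANGE = (0.1, 2000.0)


def _omf_spline():
    # 1 - F_J is smooth and non-oscillatory along the e^{3 pi i/4} ray, so a
    # dense log-spaced cubic spline reproduces it to ~1e-10 and removes the
    # complex-Bessel evaluations from the impedance inner loop
    global _OMF_SPLINE
    if _OMF_SPLINE is None:
        from scipy.interpolate import CubicSpline

        lo, hi = _OMF_RANGE
        xs = np.logspace(math.log10(lo * 0.98), math.log10(hi * 1.02), 6000)
        _OMF_SPLINE = CubicSpline(np.log(xs), _omf_exact(xs))
    return _OMF_SPLINE


def _one_minus_womersley(omega, r0, nu):
    """1 - F_J for (arrays of) angular frequency and radius."""
    x = np.asarray(r0 * np.sqrt(np.asarray(omega) / nu))
    out = np.empty(x.shape, dtype=complex)
    lo, hi = _OMF_RANGE
    mid = (x >= lo) & (x <= hi)
    out[mid] = _omf_spline()(np.log(x[mid]))
    rest = ~mid
    if np.any(rest):
        out[rest] = _omf_exact(x[rest])
    return out


def vessel_input_impedance(Z_L, omega, r0, L, params: TreeParams, blood: BloodParams):
    """Input impedance of one small vessel given its terminal load Z_L.

    ``omega`` may be an array; w = 0 entries use the analytic Poiseuille limit
    Z(0,0) = 8 mu L / (pi r0^4) + Z_L.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    Z_L = np.broadcast_to(np.asarray(Z_L, dtype=complex), omega.shape)
    if not np.all(np.isfinite(Z_L)):
        raise ValueError("non-finite terminal impedance")
    out = np.empty(omega.shape, dtype=complex)
    dc = omega == 0.0
    if np.any(dc):
        # Poiseuille limit with the same viscosity (rho*nu) the Womersley
        # equations use, so Z is continuous at omega -> 0 even when the
        # tabulated nu is a rounded mu/rho
        out[dc] = 8.0 * blood.rho * blood.nu * L / (math.pi * r0**4) + Z_L[dc]
    ac = ~dc
    if np.any(ac):
        w = omega[ac]
        A0 = math.pi * r0**2
        f = float(params.stiffness(r0))  # Eh/r0
        C = 3.0 * A0 / (2.0 * f)
        omf = _one_minus_womersley(w, r0, blood.nu)
        g = np.sqrt(C * A0 * omf / blood.rho)
        c = np.sqrt(A0 * omf / (blood.rho * C))
        kL = w * L / c
        s, co = np.sin(kL), np.cos(kL)
        zl = Z_L[ac]
        out[ac] = (1j * s / g + zl * co) / (co + 1j * g * zl * s)
    return out if out.size > 1 else complex(out[0])


def _tree_nodes(r_root: float, alpha: float, beta: float, r_min: float):
    """Lattice nodes (a, b) with radius r_root * alpha^a * beta^b >= r_min.

    Returned deepest-first (children before parents).  The root must exceed
    r_min; branches below r_min are not generated.
    """
    if not r_root > r_min:
        raise ValueError(f"empty tree: r_root={r_root} must exceed r_min={r_min}")
    nodes = []
    a = 0
    while True:
        r_a = r_root * alpha**a
        if a > 0 and r_a < r_min:
            break
        b = 0
        while True:
            r = r_a * beta**b
            if (a or b) and r < r_min:
                break
            nodes.append((a, b, r))
            b += 1
        a += 1
    nodes.sort(key=lambda ab: -(ab[0] + ab[1]))
    return nodes


def root_impedance(
    r_root: float,
    params: TreeParams,
    blood: BloodParams,
    T: float | None = None,
    K_f: int = 512,
) -> ImpedanceSpectrum:
    """Input-impedance spectrum at the root of a structured tree.

    Evaluates Z at omega_k = 2 pi k / T for k = 0..K_f by propagating the
    zero terminal load up through the memoized (alpha-count, beta-count)
    lattice, combining daughters in parallel at each bifurcation.
    """
    T = blood.T if T is None else T
    alpha, beta, r_min, lrr = params.tree_alpha, params.tree_beta, params.r_min_cm, params.lrr
    nodes = _tree_nodes(r_root, alpha, beta, r_min)
    omega_ac = 2.0 * math.pi * np.arange(1, K_f + 1) / T

    # batch-precompute the per-vessel transmission-line factors for all
    # distinct (alpha-count, beta-count) lattice nodes at once
    radii = np.array([r for _, _, r in nodes])
    A0 = math.pi * radii**2
    f = np.asarray(params.stiffness(radii), dtype=float)
    C = 3.0 * A0 / (2.0 * f)
    omf = _one_minus_womersley(omega_ac[None, :], radii[:, None], blood.nu)
    g = np.sqrt(C[:, None] * A0[:, None] * omf / blood.rho)
    c = np.sqrt(A0[:, None] * omf / (blood.rho * C[:, None]))
    kL = omega_ac[None, :] * (lrr * radii)[:, None] / c
    sin_kL = np.sin(kL)
    cos_kL = np.cos(kL)

    index = {(a, b): i for i, (a, b, _) in enumerate(nodes)}
    n = len(nodes)
    child1 = np.array([index.get((a + 1, b), -1) for a, b, _ in nodes])
    child2 = np.array([index.get((a, b + 1), -1) for a, b, _ in nodes])
    R_seg = 8.0 * blood.rho * blood.nu * (lrr * radii) / (math.pi * radii**4)

    # process whole depth levels (a + b) at once, children before parents
    levels: dict = {}
    for i, (a, b, _) in enumerate(nodes):
        levels.setdefault(a + b, []).append(i)
    Zin = np.empty((n, K_f), dtype=complex)
    Rin = np.empty(n)
    for s_lvl in sorted(levels, reverse=True):
        rows = np.array(levels[s_lvl])
        Y = np.zeros((len(rows), K_f), dtype=complex)
        Ydc = np.zeros(len(rows))
        has_kid = np.zeros(len(rows), dtype=bool)
        for kids in (child1[rows], child2[rows]):
            m = kids >= 0
            if np.any(m):
                Y[m] += 1.0 / Zin[kids[m]]
                Ydc[m] += 1.0 / Rin[kids[m]]
                has_kid |= m
        Z_L = np.zeros((len(rows), K_f), dtype=complex)
        Z_L[has_kid] = 1.0 / Y[has_kid]
        R_L = np.zeros(len(rows))
        R_L[has_kid] = 1.0 / Ydc[has_kid]
        s, co, gi = sin_kL[rows], cos_kL[rows], g[rows]
        Zin[rows] = (1j * s / gi + Z_L * co) / (co + 1j * gi * Z_L * s)
        Rin[rows] = R_seg[rows] + R_L

    root = index[(0, 0)]
    Z = np.empty(K_f + 1, dtype=complex)
    Z[0] = Rin[root]
    Z[1:] = Zin[root]
    omega = 2.0 * math.pi * np.arange(K_f + 1) / T
    return ImpedanceSpectrum(omega=omega, Z=Z, T=T)


def impedance_to_kernel(spec: ImpedanceSpectrum, n_t: int) -> ImpedanceKernel:
    """Real time-domain kernel of a half-spectrum via conjugate-symmetric IDFT.

    Requires the spectrum to hold exactly the n_t//2 + 1 non-negative
    harmonics of an n_t-point cycle.  The Nyquist bin is symmetrized to its
    real part.  Cyclic convolution of the kernel with a constant flow returns
    the DC response Z_0 * q.
    """
    if len(spec.Z) != n_t // 2 + 1:
        raise ValueError(
            f"spectrum has {len(spec.Z)} harmonics; need n_t//2+1 = {n_t // 2 + 1}"
        )
    half = spec.Z.astype(complex).copy()
    if n_t % 2 == 0:
        half[-1] = half[-1].real
    z = np.fft.irfft(half, n=n_t)
    return ImpedanceKernel(z=z, dt=spec.T / n_t)


def cyclic_convolve(kernel: ImpedanceKernel, q: np.ndarray) -> np.ndarray:
    """Periodic convolution p_j = sum_m z_m q_{j-m} over one cycle."""
    q = np.asarray(q, dtype=float)
    n = len(kernel.z)
    if len(q) != n:
        raise ValueError("flow history must have the kernel's length")
    return np.fft.irfft(np.fft.rfft(kernel.z) * np.fft.rfft(q), n=n)
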