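"""Periodic flow waveforms: replicate averaging, resampling, mass rescaling.

Measured volumetric flows are periodic with the cardiac cycle and sampled at
Tp (typically 19-28) points per cycle.  Because velocity-field measurements
are noisy and cycle-averaged, the branch flows generally do not sum to the
inlet flow; :func:`conserve_mass` computes the minimum-norm multiplicative
rescaling that restores conservation of the period-averaged flows while
holding the inlet cardiac output fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlowWaveform",
    "WaveformEnsemble",
    "ScalingResult",
    "average_ensemble",
    "conserve_mass",
    "resample_periodic",
]


@dataclass(frozen=True)
class FlowWaveform:
    """A T-periodic sampled flow q(t) (ml/s) with sample times in [0, T)."""

    t: np.ndarray
    q: np.ndarray
    T: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        if self.T <= 0:
            raise ValueError("period T must be positive")
        if t.ndim != 1 or t.shape != q.shape:
            raise ValueError("t and q must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.T:
            raise ValueError("sample times must be strictly increasing in [0, T)")

    @property
    def Tp(self) -> int:
        return len(self.t)

    def mean(self) -> float:
        """Period-averaged flow (cardiac output in ml/s).

        For a uniform grid this is the plain sample mean (exact DC mode of
        the trigonometric interpolant); otherwise the periodic trapezoid rule.
        """
        t, q = self.t, self.q
        if _is_uniform(t, self.T):
            return float(np.mean(q))
        tt = np.concatenate([t, [t[0] + self.T]])
        qq = np.concatenate([q, [q[0]]])
        return float(np.trapezoid(qq, tt) / self.T)

    def scaled(self, factor: float) -> "FlowWaveform":
        return FlowWaveform(self.t, self.q * factor, self.T)

    def evaluate(self, t_eval) -> np.ndarray:
        """Trigonometric-interpolant value at arbitrary times (uniform grid only)."""
        if not _is_uniform(self.t, self.T):
            raise ValueError("evaluate() requires a uniform sample grid")
        n = self.Tp
        coeffs = np.fft.rfft(self.q) / n
        k = np.arange(coeffs.size)
        tau = (np.asarray(t_eval, dtype=float) - self.t[0]) / self.T
        phase = np.exp(2j * np.pi * np.outer(tau, k))
        w = np.full(coeffs.size, 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0  # Nyquist mode is not doubled
        return (phase @ (w * coeffs)).real

    # -- io ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.t, "flow_ml_per_s": self.q})
        with open(path, "w") as fh:
            fh.write(f"# period_s={self.T}\n")
            df.to_csv(fh, index=False)

    @staticmethod
    def from_csv(path) -> "FlowWaveform":
        with open(path) as fh:
            header = fh.readline().strip()
            T = float(header.split("period_s=")[1])
            df = pd.read_csv(fh)
        return FlowWaveform(df["time_s"].to_numpy(), df["flow_ml_per_s"].to_numpy(), T)


def _is_uniform(t: np.ndarray, T: float) -> bool:
    n = len(t)
    return bool(np.allclose(t, t[0] + np.arange(n) * T / n, rtol=0, atol=1e-9 * T))


@dataclass(frozen=True)
class WaveformEnsemble:
    """Replicate waveforms on a shared grid with their pointwise mean and sd."""

    replicates: tuple
    mean: FlowWaveform
    sd: np.ndarray


def average_ensemble(replicates) -> WaveformEnsemble:
    """Average replicate extractions of one waveform (pointwise mean and sd)."""
    replicates = tuple(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    ref = replicates[0]
    for w in replicates[1:]:
        if w.T != ref.T or not np.allclose(w.t, ref.t, rtol=0, atol=1e-12):
            raise ValueError("replicates must share the time grid and period")
    Q = np.stack([w.q for w in replicates])
    mean = FlowWaveform(ref.t, Q.mean(axis=0), ref.T)
    sd = Q.std(axis=0, ddof=1) if len(replicates) > 1 else np.zeros(ref.Tp)
    return WaveformEnsemble(replicates=replicates, mean=mean, sd=sd)


@dataclass(frozen=True)
class ScalingResult:
    """Branch rescaling factors alpha_i and the rescaled waveforms."""

    alpha: np.ndarray
    scaled: tuple  # FlowWaveform, (1 + alpha_i) * q_i


def conserve_mass(q_inlet: FlowWaveform, branches) -> ScalingResult:
    """Rescale branch flows so their cardiac outputs sum to the inlet's.

    Solves  min (1/2n) sum alpha_i^2  s.t.  sum (1+alpha_i) Q_i = Q_inlet,
    where Q are period-averaged flows; the stationarity conditions give the
    closed form alpha_i = (Q_inlet - sum Q_j) Q_i / sum Q_j^2.  The inlet is
    held fixed.
    """
    branches = tuple(branches)
    if not branches:
        raise ValueError("need at least one branch waveform")
    for w in branches:
        if not np.isclose(w.T, q_inlet.T, rtol=1e-12):
            raise ValueError("all waveforms must share the cardiac period")
    Q = np.array([w.mean() for w in branches])
    if np.allclose(Q, 0.0):
        raise ValueError("degenerate constraint: all branch cardiac outputs are zero")
    alpha = (q_inlet.mean() - Q.sum()) * Q / np.dot(Q, Q)
    scaled = tuple(w.scaled(1.0 + a) for w, a in zip(branches, alpha))
    return ScalingResult(alpha=alpha, scaled=scaled)


def resample_periodic(w: FlowWaveform, n_out: int, t0: float = 0.0) -> FlowWaveform:
    """Resample onto a uniform grid of ``n_out`` points starting at ``t0``.

    Evaluates the trigonometric (Fourier-series) interpolant of the input on
    the new grid: exact at the original nodes when the original grid is
    uniform, and the period average (DC mode) is preserved to machine
    precision for n_out >= Tp.
    """
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    t_new = t0 + np.arange(n_out) * w.T / n_out
    q_new = w.evaluate(t_new)
    return FlowWaveform(np.arange(n_out) * w.T / n_out, q_new, w.T)
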