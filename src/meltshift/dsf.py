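"""Two-state thermal unfolding fits for dye-fluorescence (DSF) melting curves.

The scaled signal S as a function of absolute temperature T follows a
two-state folded/unfolded equilibrium with linear pre- and post-transition
baselines:

    S(T) = ((Sf + mf*T) + (Su + mu*T) * exp(g)) / (1 + exp(g)),
    g = (dHm / (R*T)) * ((T - Tm) / Tm)

with Sf, Su the folded/unfolded signals extrapolated to 0 K, mf, mu the
baseline slopes (K^-1), Tm the melting temperature (K), dHm the unfolding
enthalpy at Tm (J/mol) and R = 8.314 J/(K mol).  Temperatures are handled in
kelvin internally; all I/O is in deg C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import expit

R_GAS = 8.314          # J / (K mol), fixed
KELVIN = 273.15


@dataclass(frozen=True)
class DSFModelParams:
    """Two-state model parameters (temperatures in kelvin)."""

    Sf: float
    Su: float
    mf: float
    mu: float
    Tm: float            # K
    dHm: float           # J / mol

    @property
    def Tm_C(self) -> float:
        return self.Tm - KELVIN


@dataclass
class DSFFitResult:
    params: DSFModelParams
    stderr: dict[str, float]
    rss: float
    rss_flat: float          # RSS of the flat-mean null model
    n_points: int
    converged: bool = True

    @property
    def Tm_C(self) -> float:
        return self.params.Tm_C

    def summary(self) -> str:
        p, se = self.params, self.stderr
        lines = [
            "Two-state melting fit",
            "=====================",
            f"  Tm      {p.Tm_C:10.3f} C   (+/- {se.get('Tm', float('nan')):.3f})",
            f"  dHm     {p.dHm / 1000:10.1f} kJ/mol (+/- {se.get('dHm', float('nan')) / 1000:.1f})",
            f"  Sf, mf  {p.Sf:10.4f}, {p.mf:.5f}",
            f"  Su, mu  {p.Su:10.4f}, {p.mu:.5f}",
            f"  RSS     {self.rss:10.5f} (flat model: {self.rss_flat:.5f})",
            f"  n       {self.n_points:10d}",
        ]
        return "\n".join(lines)


def two_state_model(params: DSFModelParams, T_kelvin: np.ndarray) -> np.ndarray:
    """Evaluate the two-state equation at absolute temperatures.

    Written as folded_baseline + (unfolded_baseline - folded_baseline) *
    sigmoid(g), which is the overflow-safe (log-sum-exp) form of the ratio.
    """
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    g = (params.dHm / (R_GAS * T)) * ((T - params.Tm) / params.Tm)
    folded = params.Sf + params.mf * T
    unfolded = params.Su + params.mu * T
    return folded + (unfolded - folded) * expit(g)


def scale_curve(raw: np.ndarray) -> np.ndarray:
    """Min-max scale x' = (x - min)/(max - min); constant input is unfittable."""
    x = np.asarray(raw, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        raise ValueError("constant fluorescence curve cannot be scaled or fitted")
    return (x - lo) / (hi - lo)


def _model_vec(T, Sf, Su, mf, mu, Tm, dHm):
    return two_state_model(DSFModelParams(Sf, Su, mf, mu, Tm, dHm), T)


def fit_two_state(
    temperatures_C: np.ndarray,
    scaled_signal: np.ndarray,
    n_restarts: int = 3,
) -> DSFFitResult:
    """Nonlinear least-squares fit of the two-state equation.

    Initialisation: Tm from the derivative peak (:func:`derivative_tm`),
    dHm = 200 kJ/mol, baselines from straight-line fits to the first/last 15%
    of points.  Tm is bounded to the data range and dHm to 10-2000 kJ/mol.
    Replicates may be passed stacked (the fit is joint with shared
    parameters).
    """
    tC = np.asarray(temperatures_C, dtype=float)
    y = np.asarray(scaled_signal, dtype=float)
    ok = np.isfinite(tC) & np.isfinite(y)
    tC, y = tC[ok], y[ok]
    if tC.size < 20:
        raise ValueError("two-state fit needs at least 20 points across the transition")
    order = np.argsort(tC)
    tC, y = tC[order], y[order]
    T = tC + KELVIN

    n_edge = max(3, int(0.15 * tC.size))
    mf0, bf0 = np.polyfit(T[:n_edge], y[:n_edge], 1)
    mu0, bu0 = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
    peaks = derivative_tm(tC, y)
    Tm0_C = peaks[0] if peaks else float(np.median(tC))
    names = ["Sf", "Su", "mf", "mu", "Tm", "dHm"]

    lower = [-10.0, -10.0, -1.0, -1.0, T.min(), 1e4]
    upper = [10.0, 10.0, 1.0, 1.0, T.max(), 2e6]
    inits = [
        (bf0, bu0, mf0, mu0, Tm0_C + KELVIN, 2e5),
        (bf0, bu0, 0.0, 0.0, float(np.median(T)), 4e5),
        (float(y[:n_edge].mean()), float(y[-n_edge:].mean()), 0.0, 0.0,
         Tm0_C + KELVIN, 1e5),
    ]
    best = None
    for p0 in inits[:max(1, n_restarts)]:
        p0 = np.clip(p0, lower, upper)
        try:
            popt, pcov = curve_fit(
                _model_vec, T, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _model_vec(T, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("two-state fit failed to converge after restarts")
    popt, pcov, rss = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.sqrt(np.diag(pcov))
    params = DSFModelParams(*[float(v) for v in popt])
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    return DSFFitResult(
        params=params,
        stderr={k: float(s) for k, s in zip(names, se)},
        rss=rss,
        rss_flat=rss_flat,
        n_points=int(tC.size),
    )


class TwoStateMeltModel:
    """Model-object interface to the two-state melting fit.

    Raw replicate curves are min-max scaled (jointly, so the fit is invariant
    to affine transformations of the raw signal) and fitted with shared
    parameters.  ``fit()`` returns a :class:`DSFFitResult`.
    """

    def __init__(self, temperature_C, signal, scale: bool = True):
        self.temperature_C = np.asarray(temperature_C, dtype=float)
        raw = np.asarray(signal, dtype=float)
        self.signal = scale_curve(raw) if scale else raw

    @classmethod
    def from_dataframe(cls, df, scale: bool = True) -> "TwoStateMeltModel":
        return cls(df["temperature_C"], df["signal"], scale=scale)

    def fit(self, n_restarts: int = 3) -> DSFFitResult:
        return fit_two_state(self.temperature_C, self.signal, n_restarts=n_restarts)

    def derivative_tm(self, **kwargs) -> list[float]:
        return derivative_tm(self.temperature_C, self.signal, **kwargs)


def derivative_tm(
    temperatures_C: np.ndarray,
    signal: np.ndarray,
    window: int = 5,
    prominence: float = 0.05,
) -> list[float]:
    """Melting-temperature estimates from the first derivative of the curve.

    The signal is smoothed with a centred moving average, |dS/dT| is taken by
    finite differences, and every local maximum above the prominence
    threshold is reported (multi-domain proteins can show several
    transitions).  Returns temperatures sorted by peak height, highest first.
    """
    t = np.asarray(temperatures_C, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 5:
        raise ValueError("derivative Tm needs at least 5 points")
    order = np.argsort(t)
    t, y = t[order], y[order]
    kernel = np.ones(window) / window
    half = window // 2
    ys = np.convolve(y, kernel, mode="valid")   # drop edges: no pad artifacts
    ts = t[half: t.size - half] if window > 1 else t
    dy = np.abs(np.gradient(ys, ts))
    t = ts
    scale = dy.max()
    if scale == 0:
        return []
    dy = dy / scale  # peak prominence is judged relative to the largest slope
    peaks, _ = find_peaks(dy, prominence=prominence)
    if peaks.size == 0:
        return []
    heights = dy[peaks]
    order = np.argsort(heights)[::-1]
    return [float(t[p]) for p in peaks[order]]
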