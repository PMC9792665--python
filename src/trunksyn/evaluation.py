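"""Evaluation metrics: moment RMSE and EMD-swept activation correlation.

Two quantities judge a trunk-activation estimate.  First, the per-DoF root
mean squared error between the moments generated by the estimated muscle
forces and the inverse-dynamics reference.  Second, the Pearson correlation
between the mean estimated activation curve of a muscle and its measured,
electromechanically delayed excitation: excitation precedes mechanical
activation by an electromechanical delay (EMD) of roughly 100-165 ms for the
erector spinae, so the measured excitation is shifted over that grid (5 ms
steps) and the delay giving the highest correlation is reported, per side.

Gait cycles are treated as periodic, so a delay is a circular shift of the
time-normalized cycle.  Shifts are applied at fractional-sample resolution
via linear interpolation on the periodic extension: with 101 samples per
cycle the sample period (~10 ms for a 1 s cycle) is coarser than the 5 ms
delay grid, and nearest-sample rounding would alias neighbouring delays onto
the same shift, making the best delay ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: The standard electromechanical-delay grid, ms.
EMD_GRID_MS = tuple(range(100, 170, 5))

#: Threshold for classifying a correlation as strong.
STRONG_CORRELATION = 0.7


def moment_rmse(m_est: np.ndarray, m_ref: np.ndarray) -> np.ndarray:
    """Per-DoF root mean squared moment error (Nm)."""
    m_est = np.asarray(m_est, dtype=float)
    m_ref = np.asarray(m_ref, dtype=float)
    if m_est.shape != m_ref.shape:
        raise ValueError("moment arrays must have matching shapes")
    if np.isnan(m_est).any() or np.isnan(m_ref).any():
        raise ValueError("moment arrays contain NaN")
    return np.sqrt(np.mean((m_est - m_ref) ** 2, axis=0))


def _circular_shift(signal: np.ndarray, shift_samples: float) -> np.ndarray:
    """Circularly shift a periodic signal by a (possibly fractional) number
    of samples; positive shifts move content later in the cycle."""
    n = signal.size
    idx = (np.arange(n) - shift_samples) % n
    base = np.floor(idx).astype(int)
    frac = idx - base
    base %= n  # float modulo can land exactly on n
    return (1.0 - frac) * signal[base] + frac * signal[(base + 1) % n]


def apply_emd(cycle_signal: np.ndarray, delay_ms: float,
              cycle_duration_s: float) -> np.ndarray:
    """Delay a time-normalized cyclic signal by ``delay_ms``.

    The delay is converted to samples using the cycle's true duration and
    applied as a fractional circular shift; a zero delay is the identity.
    """
    x = np.asarray(cycle_signal, dtype=float).ravel()
    if delay_ms < 0:
        raise ValueError("delay must be non-negative")
    if cycle_duration_s <= 0:
        raise ValueError("cycle duration must be positive")
    if delay_ms / 1000.0 >= cycle_duration_s:
        raise ValueError("delay must be shorter than the cycle")
    shift = delay_ms / 1000.0 / cycle_duration_s * x.size
    return _circular_shift(x, shift)


def pearson_mean_curves(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation between two mean curves."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("curves must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant curve")
    return float(stats.pearsonr(x, y).statistic)


def emd_sweep(estimated_mean: np.ndarray, measured_mean: np.ndarray,
              delays_ms=EMD_GRID_MS,
              cycle_duration_s: float = 1.0) -> tuple[float, float]:
    """Best (delay, Pearson r) over a delay grid applied to the measured
    excitation; ties break toward the smallest delay."""
    delays = list(delays_ms)
    if not delays:
        raise ValueError("delay grid is empty")
    best_delay, best_r = None, -np.inf
    for d in delays:
        shifted = apply_emd(measured_mean, d, cycle_duration_s)
        r = pearson_mean_curves(estimated_mean, shifted)
        if r > best_r:
            best_delay, best_r = d, r
    return float(best_delay), float(best_r)


def scale_to_match(reference: np.ndarray, signal: np.ndarray) -> np.ndarray:
    """Least-squares amplitude scaling of ``signal`` onto ``reference``
    (display only; Pearson r is scale-invariant)."""
    signal = np.asarray(signal, dtype=float)
    denom = float(signal @ signal)
    if denom == 0:
        return signal.copy()
    return (float(np.asarray(reference) @ signal) / denom) * signal


@dataclass
class EvaluationReport:
    """Sweep summaries shaped like the standard reporting tables:
    correlation per muscle/side per configuration, and per-DoF moment RMSE
    mean +/- SD across cycles per configuration."""

    correlations: pd.DataFrame
    rmse: pd.DataFrame

    def strong(self) -> pd.DataFrame:
        """Boolean view of the correlation table at the r > 0.7 threshold."""
        return self.correlations[["r"]].gt(STRONG_CORRELATION) \
            if "r" in self.correlations else pd.DataFrame()


def summarize(cycle_results: dict, dof_labels: list[str] | None = None
              ) -> EvaluationReport:
    """Aggregate per-cycle metrics over an (nSyn, Allow_a) sweep.

    Parameters
    ----------
    cycle_results : dict
        ``{(n_syn, allow_a): {"rmse": list of per-cycle (nDoF,) arrays,
        "correlations": {(muscle, side): (best_delay, best_r)}}}``.
        Missing cells are simply absent from the output.
    """
    rmse_rows, corr_rows = [], []
    for (n_syn, allow_a), res in sorted(cycle_results.items()):
        rmses = np.asarray(res.get("rmse", []), dtype=float)
        if rmses.size:
            labels = dof_labels or [f"dof{j}" for j in range(rmses.shape[1])]
            mean = rmses.mean(axis=0)
            sd = (rmses.std(axis=0, ddof=1) if rmses.shape[0] > 1
                  else np.zeros(rmses.shape[1]))
            for j, lbl in enumerate(labels):
                rmse_rows.append({"n_syn": n_syn, "allow_a": allow_a,
                                  "dof": lbl, "rmse_mean": mean[j],
                                  "rmse_sd": sd[j]})
        for (muscle, side), (delay, r) in res.get("correlations",
                                                  {}).items():
            corr_rows.append({"n_syn": n_syn, "allow_a": allow_a,
                              "muscle": muscle, "side": side,
                              "best_emd_ms": delay, "r": r})
    return EvaluationReport(pd.DataFrame(corr_rows), pd.DataFrame(rmse_rows))
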