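"""Muscle synergy extraction by non-negative matrix factorization.

A muscle synergy is a time-invariant non-negative vector of weights (one per
muscle) paired with a single time-varying synergy activation; ``k`` synergies
approximate an activation matrix ``A (nMusc x nPt)`` as ``W @ H`` with
``W (nMusc x k)`` and ``H (k x nPt)`` both non-negative.  Synergy activations
are conventionally rescaled so each row of ``H`` peaks at exactly 1, with the
inverse scale folded into ``W`` so the product is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning


class DegenerateSynergyError(ValueError):
    """A synergy activation is identically zero and cannot be normalized."""


@dataclass
class SynergySet:
    """``k`` synergies: activations ``H (k x nPt)`` and weights ``W (nMusc x k)``."""

    W: np.ndarray
    H: np.ndarray
    muscle_labels: list[str] = field(default_factory=list)
    side: str = "right"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.W.ndim != 2 or self.H.ndim != 2:
            raise ValueError("W and H must be 2-D")
        if self.W.shape[1] != self.H.shape[0]:
            raise ValueError(
                f"W has {self.W.shape[1]} synergies but H has "
                f"{self.H.shape[0]}"
            )
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("synergy weights and activations must be >= 0")
        if not self.muscle_labels:
            self.muscle_labels = [f"m{i}" for i in range(self.W.shape[0])]

    @property
    def k(self) -> int:
        return self.W.shape[1]

    @property
    def n_pt(self) -> int:
        return self.H.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.W @ self.H

    @property
    def is_normalized(self) -> bool:
        return bool(np.allclose(self.H.max(axis=1), 1.0, atol=1e-9))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        syn = [f"syn{i + 1}" for i in range(self.k)]
        return (pd.DataFrame(self.W, index=self.muscle_labels, columns=syn),
                pd.DataFrame(self.H, index=syn))


def extract_synergies(A: np.ndarray, k: int, restarts: int = 20,
                      seed: int = 0, tol: float = 1e-6,
                      max_iter: int = 2000,
                      muscle_labels: list[str] | None = None,
                      side: str = "right") -> SynergySet:
    """Factorize a non-negative activation matrix into ``k`` synergies.

    Runs ``restarts`` random non-negative initializations of Frobenius-norm
    NMF and keeps the factorization with the lowest reconstruction error;
    deterministic for a fixed ``seed``.

    Parameters
    ----------
    A : ndarray, shape (nMusc, nPt)
        Non-negative muscle activations, one row per muscle.
    k : int
        Number of synergies, ``1 <= k <= min(nMusc, nPt)``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError("A must be 2-D (nMusc x nPt)")
    if (A < 0).any():
        raise ValueError("activation matrix must be non-negative")
    if not 1 <= k <= min(A.shape):
        raise ValueError(
            f"k={k} outside valid range [1, {min(A.shape)}]"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, restarts)):
        rs = int(rng.integers(0, 2**31 - 1))
        nmf = NMF(n_components=k, init="random", solver="cd",
                  beta_loss="frobenius", tol=tol, max_iter=max_iter,
                  random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = nmf.fit_transform(A)
        H = nmf.components_
        err = float(np.linalg.norm(A - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H)
    _, W, H = best
    return SynergySet(W, H, list(muscle_labels or []), side)


def normalize_activations(s: SynergySet) -> SynergySet:
    """Rescale each synergy activation to peak at 1, preserving ``W @ H``.

    Row ``i`` of ``H`` is divided by its maximum ``m_i`` and column ``i`` of
    ``W`` multiplied by ``m_i``; idempotent, product preserved to 1e-12.
    """
    peaks = s.H.max(axis=1)
    if (peaks <= 0).any():
        bad = int(np.argmin(peaks))
        raise DegenerateSynergyError(
            f"synergy {bad} has an all-zero activation"
        )
    return SynergySet(s.W * peaks[np.newaxis, :], s.H / peaks[:, np.newaxis],
                      list(s.muscle_labels), s.side)


def variance_accounted_for(A: np.ndarray, s: SynergySet) -> float:
    """VAF = 1 - ||A - WH||_F^2 / ||A||_F^2, clipped to [0, 1]."""
    A = np.asarray(A, dtype=float)
    denom = float(np.linalg.norm(A) ** 2)
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    resid = float(np.linalg.norm(A - s.reconstruct()) ** 2)
    return float(np.clip(1.0 - resid / denom, 0.0, 1.0))
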