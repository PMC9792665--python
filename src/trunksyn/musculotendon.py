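"""Rigid-tendon Hill-type force generation and lumbosacral moment assembly.

With a rigid tendon the fiber operates at ``lM = lMT - lTs`` so the
normalized fiber length is an algebraic function of musculotendon length.
The force-velocity multiplier is fixed at 1, which makes muscle force --
and therefore every joint moment -- affine in activation; the trunk-weight
optimization in :mod:`trunksyn.estimator` relies on that affinity.

Units are SI internally (meters, Newtons); the literature parameter table in
:mod:`trunksyn.trunk_tables` stores lengths in cm and is converted on ingest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .trunk_tables import reduced_trunk_set

logger = logging.getLogger(__name__)

#: Maximum muscle stress used to convert ACSA to peak isometric force.
MAX_MUSCLE_STRESS = 100.0  # N / cm^2

#: Width of the Gaussian active force-length curve.
ACTIVE_FL_GAMMA = 0.45

#: Normalized fiber length is clamped to this band to survive degenerate
#: geometry; clamp events are logged.
LNORM_CLAMP = (0.01, 1.8)


@dataclass
class MTU:
    """One musculotendon unit (one head of an anatomical muscle)."""

    name: str
    group: str
    side: str
    fmo: float          # peak isometric force, N
    lmo: float          # optimal fiber length, m
    lts: float          # tendon slack length, m
    acsa: float = 0.0   # anatomical cross-sectional area, cm^2

    def __post_init__(self) -> None:
        if self.fmo <= 0:
            raise ValueError(f"{self.name}: peak isometric force must be > 0")
        if self.lmo <= 0:
            raise ValueError(f"{self.name}: optimal fiber length must be > 0")
        if self.lts < 0:
            raise ValueError(f"{self.name}: tendon slack length must be >= 0")
        if self.acsa < 0:
            raise ValueError(f"{self.name}: ACSA must be >= 0")


@dataclass
class MuscleGeometrySeries:
    """Per-sample musculotendon lengths and moment arms.

    ``lmt`` has shape ``(nPt, nMusc)`` (m); ``moment_arms`` has shape
    ``(nPt, nMusc, nDoF)`` (m), signed so a positive arm produces a positive
    moment about that degree of freedom.
    """

    lmt: np.ndarray
    moment_arms: np.ndarray
    dof_labels: list[str] = field(default_factory=lambda: [
        "lumbar_extension", "lumbar_bending", "lumbar_rotation"])

    def __post_init__(self) -> None:
        self.lmt = np.asarray(self.lmt, dtype=float)
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        if self.lmt.ndim != 2 or self.moment_arms.ndim != 3:
            raise ValueError("lmt must be 2-D and moment_arms 3-D")
        if self.moment_arms.shape[:2] != self.lmt.shape:
            raise ValueError("moment_arms and lmt shapes disagree")
        if len(self.dof_labels) != self.moment_arms.shape[2]:
            raise ValueError("one dof label per moment-arm slice required")

    @property
    def n_pt(self) -> int:
        return self.lmt.shape[0]

    @property
    def n_musc(self) -> int:
        return self.lmt.shape[1]

    @property
    def n_dof(self) -> int:
        return self.moment_arms.shape[2]


@dataclass
class TrunkModel:
    """Trunk MTU set plus its gait geometry and muscle-group structure."""

    mtus: list[MTU]
    geometry: MuscleGeometrySeries

    def __post_init__(self) -> None:
        if len(self.mtus) != self.geometry.n_musc:
            raise ValueError(
                f"{len(self.mtus)} MTUs but geometry covers "
                f"{self.geometry.n_musc} muscles"
            )

    @property
    def n_musc(self) -> int:
        return len(self.mtus)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.mtus]

    @property
    def grouping(self) -> dict[tuple[str, str], list[int]]:
        """Map (group, side) -> member MTU indices."""
        groups: dict[tuple[str, str], list[int]] = {}
        for i, m in enumerate(self.mtus):
            groups.setdefault((m.group, m.side), []).append(i)
        return groups

    def side_indices(self, side: str) -> list[int]:
        return [i for i, m in enumerate(self.mtus) if m.side == side]

    def subset(self, indices) -> "TrunkModel":
        idx = list(indices)
        geom = MuscleGeometrySeries(self.geometry.lmt[:, idx],
                                    self.geometry.moment_arms[:, idx, :],
                                    list(self.geometry.dof_labels))
        return TrunkModel([self.mtus[i] for i in idx], geom)


# --------------------------------------------------------------------------
# Hill-model primitives
# --------------------------------------------------------------------------

def normalized_fiber_length(lmt, mtu: MTU) -> np.ndarray | float:
    """Rigid-tendon normalized fiber length ``(lMT - lTs) / lMo``.

    Clamped to ``LNORM_CLAMP`` so degenerate geometry cannot produce
    non-physical lengths; clamps are logged at DEBUG level.
    """
    lmt = np.asarray(lmt, dtype=float)
    lnorm = (lmt - mtu.lts) / mtu.lmo
    lo, hi = LNORM_CLAMP
    clipped = np.clip(lnorm, lo, hi)
    n_clamped = int(np.sum(clipped != lnorm))
    if n_clamped:
        logger.debug("%s: clamped %d normalized fiber lengths to [%g, %g]",
                     mtu.name, n_clamped, lo, hi)
    return clipped if clipped.ndim else float(clipped)


def active_fl(lnorm, gamma: float = ACTIVE_FL_GAMMA) -> np.ndarray | float:
    """Gaussian active force-length multiplier, 1 at optimal length."""
    lnorm = np.asarray(lnorm, dtype=float)
    out = np.exp(-((lnorm - 1.0) ** 2) / gamma)
    return out if out.ndim else float(out)


def passive_fl(lnorm, k: float = 4.0) -> np.ndarray | float:
    """Exponential passive force-length multiplier: 0 below optimal length,
    reaching 1 at a normalized length of 1.7."""
    lnorm = np.asarray(lnorm, dtype=float)
    stretch = np.clip(lnorm - 1.0, 0.0, None)
    out = np.expm1(k * stretch) / np.expm1(k * 0.7)
    return out if out.ndim else float(out)


def mtu_force(a, mtu: MTU, lmt, passive: bool = False) -> np.ndarray | float:
    """Rigid-tendon Hill force ``FMo (a fl_active + fl_passive)``.

    Force-velocity multiplier is fixed at 1, so force is affine in ``a``
    for fixed geometry.
    """
    a = np.asarray(a, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("activation must lie in [0, 1]")
    lnorm = normalized_fiber_length(lmt, mtu)
    f = mtu.fmo * (a * active_fl(lnorm) + (passive_fl(lnorm) if passive else 0.0))
    return f if np.ndim(f) else float(f)


def force_gains(model: TrunkModel, passive: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample active gain and passive offset of each MTU's force.

    Returns ``(gain, offset)``, both ``(nPt, nMusc)``, so
    ``F[t, i] = gain[t, i] * a[t, i] + offset[t, i]``.
    """
    lnorm = np.column_stack([
        normalized_fiber_length(model.geometry.lmt[:, i], m)
        for i, m in enumerate(model.mtus)
    ])
    fmo = np.array([m.fmo for m in model.mtus])
    gain = fmo[np.newaxis, :] * active_fl(lnorm)
    offset = (fmo[np.newaxis, :] * passive_fl(lnorm) if passive
              else np.zeros_like(gain))
    return gain, offset


def joint_moments(A: np.ndarray, model: TrunkModel,
                  passive: bool = False) -> np.ndarray:
    """Net joint moments ``(nPt, nDoF)`` produced by activations ``A``.

    ``M[t, j] = sum_i r[t, i, j] * F_i(A[t, i])`` with rigid-tendon Hill
    forces; affine in ``A``.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (model.geometry.n_pt, model.n_musc):
        raise ValueError(
            f"activations shape {A.shape} does not match geometry "
            f"({model.geometry.n_pt}, {model.n_musc})"
        )
    if np.isnan(model.geometry.lmt).any() or np.isnan(
            model.geometry.moment_arms).any():
        raise ValueError("geometry contains NaN")
    gain, offset = force_gains(model, passive=passive)
    forces = gain * A + offset
    return np.einsum("tij,ti->tj", model.geometry.moment_arms, forces)


# --------------------------------------------------------------------------
# personalization
# --------------------------------------------------------------------------

def fmax_from_acsa(acsa: float, stress: float = MAX_MUSCLE_STRESS) -> float:
    """Peak isometric force from ACSA (cm^2) at the maximum muscle stress."""
    if acsa < 0:
        raise ValueError("ACSA must be >= 0")
    return stress * acsa


def distribute_group_acsa(total_acsa: float, generic_member_acsas) -> np.ndarray:
    """Split a muscle group's total ACSA over its member MTUs in proportion
    to their generic ACSA fractions; the output sums to the total."""
    generic = np.asarray(generic_member_acsas, dtype=float)
    if total_acsa < 0:
        raise ValueError("total ACSA must be >= 0")
    s = generic.sum()
    if s <= 0:
        raise ValueError("generic member ACSAs must have a positive sum")
    return total_acsa * generic / s


def tune_fiber_lengths(mtu: MTU, lmt_series, target: float = 0.95) -> MTU:
    """Rescale (lMo, lTs) jointly so the peak normalized fiber length over
    the gait trial equals ``target``.

    The ratio ``lTs / (lTs + lMo)`` is held fixed; a target slightly below 1
    puts the fiber near-optimal for force generation throughout gait.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target normalized length must lie in (0, 1)")
    lmt = np.asarray(lmt_series, dtype=float)
    if lmt.size == 0:
        raise ValueError("lMT series is empty")
    if (lmt <= 0).any():
        raise ValueError("lMT values must be positive")
    lmax = float(lmt.max())
    # (lmax - s*lts) / (s*lmo) = target  =>  s = lmax / (target*lmo + lts)
    s = lmax / (target * mtu.lmo + mtu.lts)
    return replace(mtu, lmo=s * mtu.lmo, lts=s * mtu.lts)


def reduce_mtu_set(original: TrunkModel,
                   mapping: dict[int, list[int]],
                   pose_sampler,
                   n_poses: int,
                   seed: int = 0) -> np.ndarray:
    """Peak isometric forces for a reduced MTU set that best reproduces the
    original set's joint moments over random poses.

    Each reduced MTU (a key of ``mapping``) inherits the geometry of a
    representative original MTU; its unknown peak isometric force scales a
    full-activation force along that geometry.  Solves non-negative least
    squares over ``n_poses`` poses drawn from ``pose_sampler(rng)``, which
    must return ``(lmt_row, arms_row)`` for one pose: shapes ``(nMusc,)`` and
    ``(nMusc, nDoF)`` over the *original* muscle indexing.

    Returns the reduced-set FMo values in ``mapping`` key order.
    """
    reduced_idx = list(mapping)
    if n_poses < len(reduced_idx):
        raise ValueError("need at least as many poses as reduced MTUs")
    rng = np.random.default_rng(seed)
    n_dof = original.geometry.n_dof
    rows_A, rows_b = [], []
    for _ in range(n_poses):
        lmt, arms = pose_sampler(rng)
        lmt = np.asarray(lmt, dtype=float)
        arms = np.asarray(arms, dtype=float)
        # original-set moments at full activation
        f_unit = np.array([
            m.fmo * active_fl(normalized_fiber_length(lmt[i], m))
            for i, m in enumerate(original.mtus)
        ])
        rows_b.append(arms.T @ f_unit)  # (nDoF,)
        # reduced-set moment per unit FMo of each representative
        cols = np.zeros((n_dof, len(reduced_idx)))
        for j, ri in enumerate(reduced_idx):
            m = original.mtus[ri]
            fl = active_fl(normalized_fiber_length(lmt[ri], m))
            cols[:, j] = arms[ri] * fl
        rows_A.append(cols)
    A = np.vstack(rows_A)
    b = np.concatenate(rows_b)
    if np.linalg.matrix_rank(A) < len(reduced_idx):
        warnings.warn("reduced-set system is rank deficient; returning the "
                      "minimum-norm least-squares solution", RuntimeWarning)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(sol, 0.0, None)
    sol, _ = nnls(A, b)
    return sol


def build_trunk_model(geometry: MuscleGeometrySeries,
                      params: pd.DataFrame | None = None,
                      sides: tuple[str, ...] = ("right", "left"),
                      length_unit: str = "cm") -> TrunkModel:
    """Assemble a two-sided TrunkModel from a parameter table and geometry.

    ``params`` defaults to the published reduced trunk set (29 MTUs/side);
    rows are replicated per side in ``sides`` order, matching the muscle
    ordering of ``geometry``.
    """
    if params is None:
        params = reduced_trunk_set()
    scale = 0.01 if length_unit == "cm" else 1.0
    mtus = [
        MTU(name=f"{row['name']}_{side[0]}", group=row["group"], side=side,
            fmo=float(row["fmo_personalized"]),
            lmo=scale * float(row["lmo_personalized"]),
            lts=scale * float(row["lts_personalized"]),
            acsa=float(row["acsa_personalized"]))
        for side in sides for _, row in params.iterrows()
    ]
    return TrunkModel(mtus, geometry)
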