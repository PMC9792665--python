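"""Synergy-based estimation of trunk muscle activations (the SYN method).

Trunk muscles carry no EMG during routine gait analysis.  SYN reconstructs
their activations as non-negative combinations of the time-varying synergy
activations extracted from the ipsilateral leg muscles: with row-max-
normalized synergy activations ``H`` the trunk activations are
``a = w H`` and the only unknowns are the synergy-vector weights ``w``.
The weights are found by minimizing

    J = J_M + J_a + J_a_dev (+ J_w_dev)

subject to ``w >= 0`` and ``0 <= a <= 1``, where ``J_M`` tracks the
inverse-dynamics lumbosacral moments (psoas contribution removed), ``J_a``
penalizes activation magnitude, and the deviation terms keep the heads of
each anatomical muscle consistent with one another.  Each term is scaled by
an allowable value (``AllowDM`` Nm, ``Allow_a``, ``AllowDa``, ``AllowDw``) so
it evaluates to 1 when every deviation equals its allowance.

Because the rigid-tendon Hill force is affine in activation and ``a`` is
linear in ``w``, the objective is a convex quadratic and the constraints are
linear: the estimation is a convex QP with a unique optimum (up to
degeneracy).  It is solved with analytic gradients by bound-constrained
quasi-Newton iteration, lazily generating the upper activation-bound
constraints (which are rarely active because the activation-minimization
term keeps activations well below 1).

A conventional per-frame static-optimization baseline
(:class:`StaticOptimization`, minimize the sum of squared activations under
moment equality) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import lsq_linear, minimize

from .musculotendon import TrunkModel, force_gains, joint_moments
from .synergy import SynergySet


class InfeasibleFrameError(RuntimeError):
    """A static-optimization frame has no feasible activation set."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    """Allowable-value ledger and solver settings for the SYN optimization.

    Parameters
    ----------
    n_syn : int
        Number of synergies per side (5-8 typical).
    allow_dm : float
        Allowable moment-tracking error, Nm (default 5).
    allow_a : float
        Allowable activation magnitude; one of 1.00/0.75/0.50/0.25 in the
        standard sweep (default 0.50).
    allow_da, allow_dw : float
        Allowable within-muscle deviation of head activations and weights
        (default 0.05 each).
    include_jw_dev : bool
        Include the weight-deviation term; turning it off gives the literal
        three-term objective.
    passive : bool
        Include passive fiber force in the moment computation (default off:
        fibers are tuned below optimal length where the passive curve is 0).
    """

    n_syn: int = 7
    allow_dm: float = 5.0
    allow_a: float = 0.50
    allow_da: float = 0.05
    allow_dw: float = 0.05
    include_jw_dev: bool = True
    passive: bool = False
    tol: float = 1e-9
    max_iter: int = 500
    multi_start: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("allow_dm", "allow_a", "allow_da", "allow_dw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_syn < 1:
            raise ValueError("n_syn must be >= 1")

    @classmethod
    def from_file(cls, path) -> "EstimatorConfig":
        """Load a config from a YAML file whose keys mirror the fields."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# --------------------------------------------------------------------------
# cost terms (each == 1 when every deviation equals its allowance)
# --------------------------------------------------------------------------

def activations_from_weights(w: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Trunk activations ``a[t, i] = sum_k w[i, k] H[k, t]`` -> (nPt, nMusc)."""
    w = np.asarray(w, dtype=float)
    H = np.asarray(H, dtype=float)
    if w.ndim != 2 or H.ndim != 2 or w.shape[1] != H.shape[0]:
        raise ValueError(
            f"weights {w.shape} incompatible with activations {H.shape}"
        )
    return (w @ H).T


def cost_moment_tracking(m_est: np.ndarray, m_id: np.ndarray,
                         allow_dm: float = 5.0) -> float:
    """Mean squared moment error in units of the allowable error."""
    m_est = np.asarray(m_est, dtype=float)
    m_id = np.asarray(m_id, dtype=float)
    if m_est.shape != m_id.shape:
        raise ValueError("moment arrays must have matching shapes")
    if np.isnan(m_est).any() or np.isnan(m_id).any():
        raise ValueError("moment arrays contain NaN")
    return float(np.mean(((m_est - m_id) / allow_dm) ** 2))


def cost_activation(a_est: np.ndarray, allow_a: float = 0.50) -> float:
    """Mean squared activation in units of the allowable activation."""
    a_est = np.asarray(a_est, dtype=float)
    if np.isnan(a_est).any():
        raise ValueError("activations contain NaN")
    return float(np.mean((a_est / allow_a) ** 2))


def _deviation_cost(values: np.ndarray, grouping: Mapping, allow: float,
                    axis_label: str) -> float:
    total = 0.0
    for key, members in grouping.items():
        members = list(members)
        if not members:
            raise ValueError(f"empty muscle group {key!r}")
        block = values[:, members]
        dev = (block - block.mean(axis=1, keepdims=True)) / allow
        total += float(np.mean(dev ** 2))
    return total


def cost_activation_deviation(a_est: np.ndarray, grouping: Mapping,
                              allow_da: float = 0.05) -> float:
    """Per-group mean squared deviation of head activations from the group
    mean, summed over groups."""
    return _deviation_cost(np.asarray(a_est, dtype=float), grouping,
                           allow_da, "activation")


def cost_weight_deviation(w: np.ndarray, grouping: Mapping,
                          allow_dw: float = 0.05) -> float:
    """Per-group mean squared deviation of synergy weights from the group
    mean weight, summed over groups."""
    w = np.asarray(w, dtype=float)
    return _deviation_cost(w.T, grouping, allow_dw, "weight")


def subtract_muscle_moments(m_id_total: np.ndarray,
                            subset_activations: np.ndarray,
                            subset_model: TrunkModel,
                            passive: bool = False) -> np.ndarray:
    """Remove a muscle subset's moment contribution (e.g. the psoas heads,
    whose activations come from the calibrated leg model) from the
    inverse-dynamics moments before tracking."""
    m_id_total = np.asarray(m_id_total, dtype=float)
    m_sub = joint_moments(subset_activations, subset_model, passive=passive)
    if m_sub.shape != m_id_total.shape:
        raise ValueError("subset moments do not match total moment shape")
    return m_id_total - m_sub


# --------------------------------------------------------------------------
# the SYN model
# --------------------------------------------------------------------------

@dataclass
class _Quadratic:
    """J(x) = x' P x + q' x + c, with P symmetric PSD."""

    P: np.ndarray
    q: np.ndarray
    c: float

    def value(self, x: np.ndarray) -> float:
        return float(x @ self.P @ x + self.q @ x + self.c)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (self.P @ x) + self.q


class TrunkActivationModel:
    """SYN estimator: trunk synergy weights fitted to track lumbosacral
    inverse-dynamics moments.

    Parameters
    ----------
    model : TrunkModel
        Trunk MTUs with gait geometry (both sides).
    m_id : ndarray, shape (nPt, nDoF)
        Inverse-dynamics lumbosacral moments with the psoas contribution
        already removed (see :func:`subtract_muscle_moments`).
    synergies : mapping side -> SynergySet
        Row-max-normalized synergy activations per side; each trunk MTU uses
        the ipsilateral set.
    config : EstimatorConfig

    Examples
    --------
    >>> fit = TrunkActivationModel(model, m_id, synergies, config).fit()
    >>> fit.costs["J_M"], fit.moment_rmse()
    """

    def __init__(self, model: TrunkModel, m_id: np.ndarray,
                 synergies: Mapping[str, SynergySet],
                 config: EstimatorConfig | None = None):
        self.model = model
        self.m_id = np.asarray(m_id, dtype=float)
        self.config = config or EstimatorConfig()
        n_pt = model.geometry.n_pt
        if self.m_id.shape != (n_pt, model.geometry.n_dof):
            raise ValueError(
                f"m_id shape {self.m_id.shape} does not match geometry "
                f"({n_pt}, {model.geometry.n_dof})"
            )
        self.synergies = dict(synergies)
        for side, s in self.synergies.items():
            if not s.is_normalized:
                raise ValueError(
                    f"{side} synergy activations must be max-normalized "
                    "(see synergy.normalize_activations)"
                )
            if s.n_pt != n_pt:
                raise ValueError(f"{side} H has {s.n_pt} samples, "
                                 f"geometry has {n_pt}")
        sides = {m.side for m in model.mtus}
        missing = sides - set(self.synergies)
        if missing:
            raise ValueError(f"no synergy set for side(s) {sorted(missing)}")
        self._build_operators()

    # -- operator assembly -------------------------------------------------

    def _build_operators(self) -> None:
        model, cfg = self.model, self.config
        n_pt, n_dof = model.geometry.n_pt, model.geometry.n_dof
        n_musc = model.n_musc
        # per-muscle weight-block layout in the design vector
        self._k = [self.synergies[m.side].k for m in model.mtus]
        offs = np.concatenate([[0], np.cumsum(self._k)])
        self._offsets = offs
        self.n_var = int(offs[-1])
        # a = A_op x  (sparse block diagonal of H_side^T)
        blocks = [self.synergies[m.side].H.T for m in model.mtus]
        A_op = sp.block_diag(blocks, format="csr")  # (nMusc*nPt, nvar) in col-major muscle blocks
        # A_op rows ordered muscle-major: rows [i*nPt:(i+1)*nPt] are a[:, i]
        self._A_op = A_op
        gain, f_off = force_gains(model, passive=cfg.passive)
        # moments: M[t, j] = sum_i r[t,i,j] gain[t,i] a[t,i] + const
        G = np.zeros((n_pt * n_dof, self.n_var))
        for i in range(n_musc):
            Bi = blocks[i]  # (nPt, k_i)
            scaled = model.geometry.moment_arms[:, i, :] * gain[:, [i]]
            # contribution to vec(M) ordered (j-major): rows j*nPt + t
            for j in range(n_dof):
                G[j * n_pt:(j + 1) * n_pt, offs[i]:offs[i + 1]] += \
                    scaled[:, [j]] * Bi
        self._G = G
        m0 = np.einsum("tij,ti->tj", model.geometry.moment_arms, f_off)
        self._m_resid = (self.m_id - m0).T.ravel()  # j-major, matches G
        self._gain = gain

    def _weights_to_x(self, w_list: list[np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(wi, float).ravel()
                               for wi in w_list])

    def _x_to_weights(self, x: np.ndarray) -> np.ndarray:
        """Design vector -> (nMusc, k) weight matrix (equal k per side)."""
        k = self._k[0]
        if any(ki != k for ki in self._k):
            raise ValueError("sides use different synergy counts")
        return x.reshape(self.model.n_musc, k)

    def _quadratic(self) -> _Quadratic:
        """Assemble the full objective as a convex quadratic in x."""
        cfg = self.config
        model = self.model
        n_pt, n_dof = model.geometry.n_pt, model.geometry.n_dof
        n_musc = model.n_musc
        # J_M = ||G x - m_resid||^2 / (nPt nDoF allow_dm^2)
        sM = 1.0 / (n_pt * n_dof * cfg.allow_dm ** 2)
        P = sM * (self._G.T @ self._G)
        q = -2.0 * sM * (self._G.T @ self._m_resid)
        c = sM * float(self._m_resid @ self._m_resid)
        # J_a = ||A x||^2 / (nPt nMusc allow_a^2)
        sA = 1.0 / (n_pt * n_musc * cfg.allow_a ** 2)
        AtA = (self._A_op.T @ self._A_op).toarray()
        P += sA * AtA
        # J_a_dev: per group, mean over (t, members) of centred a / allow_da
        offs = self._offsets
        for key, members in self.model.grouping.items():
            n_mem = len(members)
            sD = 1.0 / (n_pt * n_mem * cfg.allow_da ** 2)
            # rows of A_op for the member block, centred across members
            rows = sp.vstack([self._A_op[i * n_pt:(i + 1) * n_pt]
                              for i in members]).toarray()
            # centering: D = (I - 1/n J) applied across the member dimension
            rows3 = rows.reshape(n_mem, n_pt, self.n_var)
            centred = rows3 - rows3.mean(axis=0, keepdims=True)
            Dm = centred.reshape(n_mem * n_pt, self.n_var)
            P += sD * (Dm.T @ Dm)
        # J_w_dev: same centring on the weights themselves
        if cfg.include_jw_dev:
            for key, members in self.model.grouping.items():
                n_mem = len(members)
                k = self._k[members[0]]
                sW = 1.0 / (k * n_mem * cfg.allow_dw ** 2)
                sel = np.zeros((n_mem * k, self.n_var))
                for r, i in enumerate(members):
                    sel[r * k:(r + 1) * k, offs[i]:offs[i + 1]] = np.eye(k)
                sel3 = sel.reshape(n_mem, k, self.n_var)
                centred = (sel3 - sel3.mean(axis=0, keepdims=True)
                           ).reshape(n_mem * k, self.n_var)
                P += sW * (centred.T @ centred)
        return _Quadratic(0.5 * (P + P.T), q, c)

    # -- fitting -----------------------------------------------------------

    def _starts(self) -> list[np.ndarray]:
        starts = [np.zeros(self.n_var)]
        if self.config.multi_start >= 2:
            # non-negative least-squares warm start on moment tracking alone
            res = lsq_linear(self._G, self._m_resid,
                             bounds=(0.0, np.inf), tol=1e-10)
            starts.insert(0, np.clip(res.x, 0.0, None))
        if self.config.multi_start >= 3:
            starts.append(np.full(self.n_var, 0.1))
        return starts[: max(1, self.config.multi_start)]

    def _solve_from(self, quad: _Quadratic, x0: np.ndarray
                    ) -> tuple[np.ndarray, bool, int]:
        """Solve the convex QP by bound-constrained minimization with lazy
        generation of the (rarely active) ``a <= 1`` constraints."""
        n_var = self.n_var
        bounds_lbfgs = [(0.0, None)] * n_var
        active_rows: list[int] = []
        x = x0
        n_iter = 0
        converged = False
        for _ in range(10):  # constraint-generation rounds
            if not active_rows:
                res = minimize(quad.value, x, jac=quad.grad,
                               method="L-BFGS-B", bounds=bounds_lbfgs,
                               options={"maxiter": 4000,
                                        "ftol": 1e-13,
                                        "gtol": 1e-9})
            else:
                C = self._A_op[active_rows].toarray()
                res = minimize(quad.value, x, jac=quad.grad,
                               method="SLSQP", bounds=bounds_lbfgs,
                               constraints=[{"type": "ineq",
                                             "fun": lambda z: 1.0 - C @ z,
                                             "jac": lambda z: -C}],
                               options={"maxiter": self.config.max_iter,
                                        "ftol": 1e-14})
            x = np.clip(res.x, 0.0, None)
            n_iter += int(res.nit)
            converged = bool(res.success)
            a_flat = self._A_op @ x
            viol = a_flat - 1.0
            if viol.max() <= 1e-7:
                break
            # add the worst violated sample of each violating muscle
            n_pt = self.model.geometry.n_pt
            per_musc = viol.reshape(self.model.n_musc, n_pt)
            for i in np.flatnonzero(per_musc.max(axis=1) > 1e-7):
                row = i * n_pt + int(np.argmax(per_musc[i]))
                if row not in active_rows:
                    active_rows.append(row)
        else:
            converged = False
        return x, converged, n_iter

    def fit(self) -> "TrunkActivationResults":
        """Solve the convex QP and return the fitted results."""
        quad = self._quadratic()
        best = None
        for x0 in self._starts():
            x, conv, nit = self._solve_from(quad, x0)
            val = quad.value(x)
            if best is None or val < best[0]:
                best = (val, x, conv, nit)
        _, x, converged, n_iter = best
        return TrunkActivationResults(self, x, converged, n_iter=n_iter)


class TrunkActivationResults:
    """Fitted SYN estimates: weights, activations, moments and cost split."""

    def __init__(self, model: TrunkActivationModel, x: np.ndarray,
                 converged: bool, n_iter: int = 0):
        self.estimator = model
        self.x = x
        self.converged = converged
        self.n_iter = n_iter
        self.config = model.config
        cfg = model.config
        n_pt = model.model.geometry.n_pt
        a = (model._A_op @ x).reshape(model.model.n_musc, n_pt).T
        self.a_est = np.clip(a, 0.0, 1.0)
        self.w_est = model._x_to_weights(x)
        self.m_est = joint_moments(self.a_est, model.model,
                                   passive=cfg.passive)
        grouping = model.model.grouping
        self.costs = {
            "J_M": cost_moment_tracking(self.m_est, model.m_id, cfg.allow_dm),
            "J_a": cost_activation(self.a_est, cfg.allow_a),
            "J_a_dev": cost_activation_deviation(self.a_est, grouping,
                                                 cfg.allow_da),
        }
        if cfg.include_jw_dev:
            self.costs["J_w_dev"] = cost_weight_deviation(self.w_est,
                                                          grouping,
                                                          cfg.allow_dw)
        self.costs["total"] = float(sum(v for k, v in self.costs.items()
                                        if k != "total"))
        self.diagnostics = {"seed": cfg.seed, "n_iter": n_iter,
                            "converged": converged,
                            "n_var": model.n_var}

    def moment_rmse(self) -> np.ndarray:
        """Per-DoF RMSE (Nm) between estimated and tracked moments."""
        err = self.m_est - self.estimator.m_id
        return np.sqrt(np.mean(err ** 2, axis=0))

    def group_mean_activations(self) -> dict[tuple[str, str], np.ndarray]:
        """Mean activation curve per (group, side)."""
        return {key: self.a_est[:, members].mean(axis=1)
                for key, members in self.estimator.model.grouping.items()}

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "SYN trunk activation estimation",
            "=" * 47,
            f"synergies/side: {cfg.n_syn}    Allow_a: {cfg.allow_a:.2f}    "
            f"AllowDM: {cfg.allow_dm:g} Nm",
            f"design variables: {self.estimator.n_var}    "
            f"converged: {self.converged} ({self.n_iter} iterations)",
            "-" * 47,
            "cost term        value",
        ]
        for name, val in self.costs.items():
            lines.append(f"{name:<15s} {val:10.4f}")
        rmse = self.moment_rmse()
        lines.append("-" * 47)
        for lbl, r in zip(self.estimator.model.geometry.dof_labels, rmse):
            lines.append(f"RMSE {lbl:<22s} {r:7.3f} Nm")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# static-optimization baseline
# --------------------------------------------------------------------------

class StaticOptimization:
    """Per-frame baseline: minimize the sum of squared activations subject
    to lumbosacral moment equality and activation bounds.

    Each time frame is solved independently.  When ``reserves`` is on,
    reserve actuator torques (one per DoF, quadratically penalized with
    weight ``reserve_weight``) guarantee feasibility.
    """

    def __init__(self, model: TrunkModel, m_id: np.ndarray,
                 passive: bool = False, reserves: bool = False,
                 reserve_weight: float = 1000.0):
        self.model = model
        self.m_id = np.asarray(m_id, dtype=float)
        self.passive = passive
        self.reserves = reserves
        self.reserve_weight = reserve_weight
        if self.m_id.shape != (model.geometry.n_pt, model.geometry.n_dof):
            raise ValueError("m_id shape does not match model geometry")

    def fit(self) -> "StaticOptimizationResults":
        model = self.model
        n_pt, n_dof = model.geometry.n_pt, model.geometry.n_dof
        n_musc = model.n_musc
        gain, f_off = force_gains(model, passive=self.passive)
        A = np.zeros((n_pt, n_musc))
        reserves = np.zeros((n_pt, n_dof))
        for t in range(n_pt):
            E = (model.geometry.moment_arms[t].T * gain[t])  # (nDoF, nMusc)
            b = self.m_id[t] - model.geometry.moment_arms[t].T @ f_off[t]
            a_t, r_t = self._solve_frame(E, b, t)
            A[t] = a_t
            reserves[t] = r_t
        return StaticOptimizationResults(self, A, reserves)

    def _solve_frame(self, E: np.ndarray, b: np.ndarray, frame: int
                     ) -> tuple[np.ndarray, np.ndarray]:
        n_musc = E.shape[1]
        n_dof = E.shape[0]
        if self.reserves:
            w = self.reserve_weight

            def obj(z):
                return float(z[:n_musc] @ z[:n_musc]
                             + w * z[n_musc:] @ z[n_musc:])

            def jac(z):
                g = 2.0 * z.copy()
                g[n_musc:] *= w
                return g

            Eext = np.hstack([E, np.eye(n_dof)])
            lb = np.concatenate([np.zeros(n_musc), np.full(n_dof, -np.inf)])
            ub = np.concatenate([np.ones(n_musc), np.full(n_dof, np.inf)])
            z0 = np.concatenate([np.full(n_musc, 0.1), np.zeros(n_dof)])
            res = minimize(obj, z0, jac=jac, method="SLSQP",
                           bounds=list(zip(lb, ub)),
                           constraints=[{"type": "eq",
                                         "fun": lambda z: Eext @ z - b,
                                         "jac": lambda z: Eext}],
                           options={"maxiter": 300, "ftol": 1e-12})
            return np.clip(res.x[:n_musc], 0.0, 1.0), res.x[n_musc:]

        def obj(a):
            return float(a @ a)

        def jac(a):
            return 2.0 * a

        a0 = np.full(n_musc, 0.1)
        res = minimize(obj, a0, jac=jac, method="SLSQP",
                       bounds=[(0.0, 1.0)] * n_musc,
                       constraints=[{"type": "eq",
                                     "fun": lambda a: E @ a - b,
                                     "jac": lambda a: E}],
                       options={"maxiter": 300, "ftol": 1e-12})
        if not res.success or np.max(np.abs(E @ res.x - b)) > 1e-5:
            raise InfeasibleFrameError(
                f"static optimization infeasible at frame {frame} "
                "(enable reserves to proceed)"
            )
        return np.clip(res.x, 0.0, 1.0), np.zeros(n_dof)


class StaticOptimizationResults:
    """Per-frame static-optimization activations and reserve torques."""

    def __init__(self, model: StaticOptimization, a_est: np.ndarray,
                 reserves: np.ndarray):
        self.estimator = model
        self.a_est = a_est
        self.reserve_torques = reserves
        self.m_est = joint_moments(a_est, model.model, passive=model.passive)

    def moment_rmse(self) -> np.ndarray:
        err = (self.m_est + self.reserve_torques) - self.estimator.m_id
        return np.sqrt(np.mean(err ** 2, axis=0))

    def summary(self) -> str:
        rmse = self.moment_rmse()
        lines = ["Static optimization baseline", "-" * 38]
        for lbl, r in zip(self.estimator.model.geometry.dof_labels, rmse):
            lines.append(f"RMSE {lbl:<22s} {r:7.3f} Nm")
        lines.append(f"peak reserve torque: "
                     f"{np.max(np.abs(self.reserve_torques)):.3g} Nm")
        return "\n".join(lines)
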