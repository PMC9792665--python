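"""Synthetic gait datasets with known ground truth.

Every generated dataset mirrors the structure of a single-subject treadmill
gait study: per-side leg muscle activations composed from a small set of
shared time-varying synergy activations, a two-sided trunk MTU set with
smooth gait geometry, lumbosacral moments generated by the same rigid-tendon
Hill model from known trunk weights, optional additive noise, and a
"measured excitation" surrogate that leads a trunk activation by a known
electromechanical delay.  Because the ground-truth weights, activations and
moments are all retained, estimator recovery, the RMSE-vs-synergy-count
trend and delay recovery can all be tested without any external download.

Defaults follow the study conditions: 15 leg channels and 29 trunk MTUs per
side, 3 lumbosacral DoFs, 10 cycles of 101 samples, ~1 s cycles (1 m/s
treadmill walking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import _circular_shift
from .musculotendon import (MTU, MuscleGeometrySeries, TrunkModel,
                            joint_moments, tune_fiber_lengths)
from .trunk_tables import TRUNK_GROUPS, reduced_trunk_set


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic gait dataset."""

    k_true: int = 7
    n_leg_musc: int = 15
    n_trunk_musc: int = 29          # per side
    n_pt: int = 101
    n_cycles: int = 10
    n_dof: int = 3
    activation_noise_sd: float = 0.02
    moment_noise_sd: float = 1.0    # Nm; well below the 5 Nm allowance
    minimal_recruitment_fraction: float = 0.15
    sparsity: float = 0.3
    injected_emd_ms: float = 120.0
    cycle_duration_s: float = 1.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_true", "n_leg_musc", "n_trunk_musc", "n_pt",
                     "n_cycles", "n_dof"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("activation_noise_sd", "moment_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated gait data plus the ground truth that produced it."""

    spec: SyntheticSpec
    H_true: dict                      # side -> (k, nPt), rows peak at 1
    leg_weights: dict                 # side -> (nLegMusc, k)
    leg_activations: dict             # side -> list of (nLegMusc, nPt)/cycle
    trunk_true_weights: dict          # side -> (nTrunkMusc, k)
    trunk_true_activations: np.ndarray  # (nPt, 2*nTrunkMusc)
    model: TrunkModel
    m_id_clean: np.ndarray            # (nPt, nDoF)
    m_id: list                        # per-cycle noisy (nPt, nDoF)
    footstrike_times: np.ndarray      # (nCycles + 1,)
    measured_excitation: dict         # side -> (nPt,) delayed ES surrogate
    excitation_source: dict           # side -> (nPt,) the underlying truth


def make_synergy_activations(k: int, n_pt: int, seed: int = 0) -> np.ndarray:
    """``k`` unimodal wrapped-Gaussian synergy activations with peaks spread
    across the gait cycle, each row max-normalized to 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    phase = np.arange(n_pt) / n_pt
    # evenly spaced peaks with mild jitter keeps peaks distributed
    centers = (np.arange(k) / k + rng.uniform(-0.2 / k, 0.2 / k, size=k)
               + rng.uniform(0, 1.0 / k)) % 1.0
    # narrow bursts (SDs of 4-7% of the cycle) keep neighbouring synergy
    # activations nearly disjoint, which also makes their factorization
    # from the composed activations well determined
    widths = rng.uniform(0.04, 0.07, size=k)
    H = np.empty((k, n_pt))
    for i in range(k):
        d = phase - centers[i]
        d = (d + 0.5) % 1.0 - 0.5  # wrapped distance
        H[i] = np.exp(-(d ** 2) / (2 * widths[i] ** 2))
    return H / H.max(axis=1, keepdims=True)


def make_weights(n_musc: int, k: int, sparsity: float = 0.3,
                 minimal_fraction: float = 0.0, seed: int = 0,
                 anchors: bool = False) -> np.ndarray:
    """Non-negative synergy weights with row sums <= 1.

    A ``minimal_fraction`` share of synergy columns is scaled below 0.01,
    emulating synergies the muscles barely recruit; ``sparsity`` zeroes a
    random share of the remaining entries.  With ``anchors`` the first ``k``
    muscles each load a single distinct synergy, the pattern seen in leg
    EMG where some muscles are dominated by one synergy (e.g. soleus by
    push-off, tibialis anterior by swing); anchor muscles make the
    factorization essentially unique.
    """
    if not 0 <= sparsity <= 1 or not 0 <= minimal_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, 1.0, size=(n_musc, k))
    W[rng.uniform(size=W.shape) < sparsity] = 0.0
    # keep every row alive so each muscle has some drive
    dead = W.sum(axis=1) == 0
    W[dead, rng.integers(0, k, size=int(dead.sum()))] = rng.uniform(
        0.2, 0.8, size=int(dead.sum()))
    if anchors and n_musc >= k:
        W[:k] = 0.0
        W[np.arange(k), np.arange(k)] = rng.uniform(0.4, 0.9, size=k)
    n_min = int(np.ceil(minimal_fraction * k)) if minimal_fraction > 0 else 0
    if n_min:
        cols = rng.choice(k, size=n_min, replace=False)
        W[:, cols] = rng.uniform(0.0, 0.009, size=(n_musc, n_min))
    # scale rows so activations w @ H stay within [0, 1] (H rows peak at 1)
    sums = W.sum(axis=1, keepdims=True)
    target = rng.uniform(0.35, 0.85, size=(n_musc, 1))
    scale = np.where(sums > 0, np.minimum(1.0, target * 1.0 / np.maximum(
        sums, 1e-12)), 1.0)
    # don't rescale rows already below target; cap row sums at 1 regardless
    W = W * np.minimum(scale, 1.0 / np.maximum(sums, 1e-12))
    return W


#: Mean moment arms (m) of each trunk muscle group about
#: (extension, ipsilateral bending, axial rotation) for the right side;
#: bending/rotation flip sign on the left.  Signs follow trunk anatomy:
#: ES/MF/QL extend, RA and the obliques flex; every muscle side-bends
#: ipsilaterally; the external oblique rotates contralaterally and the
#: internal oblique ipsilaterally.
#: Each group dominates one moment direction (extensors ES/MF, flexor RA,
#: lateral bender QL, axial rotators EO/IO) with only small off-axis arms.
#: This is deliberately more orthogonal than real trunk anatomy, where
#: bending leverage in particular is shared across groups: it keeps the
#: moment-to-muscle inverse problem well posed so that recovery tests
#: measure estimator correctness rather than anatomical redundancy.
GROUP_ARM_ROLES = {
    "RA": (-0.055, 0.004, 0.001),
    "ES": (0.055, 0.006, -0.001),
    "QL": (0.006, 0.050, 0.002),
    "MF": (0.042, 0.005, 0.002),
    "EO": (-0.008, 0.006, -0.040),
    "IO": (-0.007, 0.006, 0.038),
}


def make_geometry(n_musc: int, n_dof: int, n_pt: int, seed: int = 0,
                  groups: list[str] | None = None,
                  side: str = "right"
                  ) -> tuple[MuscleGeometrySeries, list[MTU]]:
    """Smooth gait geometry and matching MTU parameters.

    Moment arms are low-frequency periodic curves within +/-0.08 m with both
    agonists and antagonists at every DoF; musculotendon lengths keep
    normalized fiber lengths inside [0.7, 1.0]; peak isometric forces span
    the literature range [57, 892] N.  When ``groups`` is given (trunk
    groups with ``n_dof == 3``) the mean arms follow the anatomical roles in
    :data:`GROUP_ARM_ROLES`, mirrored for the left side; otherwise signs
    alternate muscle-by-muscle so every DoF keeps agonists and antagonists.
    """
    rng = np.random.default_rng(seed)
    phase = 2 * np.pi * np.arange(n_pt) / n_pt
    arms = np.empty((n_pt, n_musc, n_dof))
    use_roles = groups is not None and n_dof == 3 and all(
        g in GROUP_ARM_ROLES for g in groups)
    for j in range(n_dof):
        if use_roles:
            mirror = 1.0 if side == "right" or j == 0 else -1.0
            base = np.array([GROUP_ARM_ROLES[g][j] for g in groups])
            base = mirror * base * rng.uniform(0.8, 1.2, size=n_musc)
        else:
            signs = np.where((np.arange(n_musc) + j) % 2 == 0, 1.0, -1.0)
            base = signs * rng.uniform(0.02, 0.06, size=n_musc)
        amp = rng.uniform(0.0, 0.2, size=n_musc) * np.abs(base)
        ph = rng.uniform(0, 2 * np.pi, size=n_musc)
        arms[:, :, j] = base[np.newaxis, :] + amp[np.newaxis, :] * np.sin(
            phase[:, np.newaxis] + ph[np.newaxis, :])
    arms = np.clip(arms, -0.08, 0.08)
    # lengths: smooth excursion, parameters chosen so lnorm in [0.7, 1.0]
    L0 = rng.uniform(0.10, 0.35, size=n_musc)
    exc = rng.uniform(0.01, 0.03, size=n_musc)
    ph = rng.uniform(0, 2 * np.pi, size=n_musc)
    lmt = L0[np.newaxis, :] * (1.0 + exc[np.newaxis, :] * np.sin(
        phase[:, np.newaxis] + ph[np.newaxis, :]))
    lts = 0.45 * L0
    peak_target = rng.uniform(0.88, 0.98, size=n_musc)
    lmo = (lmt.max(axis=0) - lts) / peak_target
    fmo = rng.uniform(57.0, 892.0, size=n_musc)
    if groups is None:
        groups = [TRUNK_GROUPS[i % len(TRUNK_GROUPS)] for i in range(n_musc)]
    mtus = [MTU(name=f"syn_mtu_{i}", group=groups[i], side=side,
                fmo=float(fmo[i]), lmo=float(lmo[i]), lts=float(lts[i]))
            for i in range(n_musc)]
    geom = MuscleGeometrySeries(
        lmt, arms,
        dof_labels=[f"dof{j}" for j in range(n_dof)] if n_dof != 3 else
        ["lumbar_extension", "lumbar_bending", "lumbar_rotation"])
    return geom, mtus


def make_trunk_weights(group_labels: list[str], k: int,
                       minimal_fraction: float = 0.0,
                       seed: int = 0) -> np.ndarray:
    """Group-structured trunk synergy weights with low co-contraction.

    The heads of one anatomical muscle share nearly identical weights (the
    deviation penalties in the estimator encode the same anatomy), and
    extensor (ES/MF/QL) and flexor (RA/EO/IO) groups recruit disjoint
    subsets of the synergies so that antagonistic co-contraction -- which is
    invisible in net joint moments and therefore unrecoverable from them --
    stays small.  A ``minimal_fraction`` share of synergy columns is kept
    below 0.01 for every muscle.  Row sums stay <= 1.
    """
    rng = np.random.default_rng(seed)
    n_musc = len(group_labels)
    n_min = int(np.ceil(minimal_fraction * k)) if minimal_fraction > 0 else 0
    minimal_cols = (rng.choice(k, size=n_min, replace=False) if n_min
                    else np.array([], dtype=int))
    active = np.setdiff1d(np.arange(k), minimal_cols)
    rng.shuffle(active)
    half = max(1, active.size // 2) if active.size else 0
    pools = {"extensor": list(active[:half]), "flexor": list(active[half:])}
    if not pools["flexor"]:
        pools["flexor"] = pools["extensor"]
    role = {"ES": "extensor", "MF": "extensor", "QL": "extensor",
            "RA": "flexor", "EO": "flexor", "IO": "flexor"}
    # deal each pool's synergies round-robin to its groups so groups sharing
    # a mechanical role fire at distinct phases of the cycle
    groups = list(dict.fromkeys(group_labels))
    assigned: dict[str, list[int]] = {g: [] for g in groups}
    counters = {"extensor": 0, "flexor": 0}
    by_role = {"extensor": [g for g in groups
                            if role.get(g, "extensor") == "extensor"],
               "flexor": [g for g in groups
                          if role.get(g, "extensor") == "flexor"]}
    for r, pool in pools.items():
        members = by_role[r] or groups
        for j, col in enumerate(pool):
            assigned[members[j % len(members)]].append(col)
    W = np.zeros((n_musc, k))
    for g in groups:
        cols = assigned[g] or [int(rng.choice(
            pools[role.get(g, "extensor")]))]
        # trunk muscles run at modest fractions of maximum during gait
        base = rng.uniform(0.08, 0.35, size=len(cols))
        members = [i for i, lbl in enumerate(group_labels) if lbl == g]
        for i in members:
            W[i, cols] = base * rng.uniform(0.9, 1.1, size=len(cols))
    if n_min:
        W[:, minimal_cols] = rng.uniform(0.0, 0.009,
                                         size=(n_musc, n_min))
    sums = W.sum(axis=1, keepdims=True)
    W *= np.minimum(1.0, 1.0 / np.maximum(sums, 1e-12))
    return W


def _trunk_group_labels(n_per_side: int) -> list[str]:
    """Assign the 6 anatomical trunk groups over one side's MTUs, in the
    canonical proportions (1 RA, 13 ES, 5 QL, 5 MF, 2 EO, 3 IO for 29)."""
    if n_per_side == 29:
        counts = {"RA": 1, "ES": 13, "QL": 5, "MF": 5, "EO": 2, "IO": 3}
    else:
        base = n_per_side // len(TRUNK_GROUPS)
        counts = {g: base for g in TRUNK_GROUPS}
        for i in range(n_per_side - base * len(TRUNK_GROUPS)):
            counts[TRUNK_GROUPS[i]] += 1
    labels = []
    for g in TRUNK_GROUPS:
        labels.extend([g] * counts[g])
    return labels


def _project_truth(trunk_W: dict, H_true: dict, model: TrunkModel,
                   sides, n_passes: int = 6) -> tuple[dict, np.ndarray]:
    """Project drawn trunk weights onto the estimator's identifiable set.

    Net lumbosacral moments cannot determine antagonistic co-contraction or
    the split of load between mechanically equivalent muscles, so weights
    drawn freely are not recoverable from the moments they generate.  The
    ground truth is therefore defined by contraction: the drawn weights seed
    a forward pass, and repeated passes of the weight optimization (against
    the true synergy basis) settle onto a direction-stable, moment-
    consistent solution.  Synergies the moments do not demand contract to
    minimal recruitment (weights below 0.01) of their own accord, mirroring
    the behaviour of the estimator on real gait data; a muscle group whose
    moment contribution is never demanded legitimately contracts to silence.
    """
    from .estimator import EstimatorConfig, TrunkActivationModel
    from .synergy import SynergySet

    a0 = np.concatenate([(trunk_W[s] @ H_true[s]).T for s in sides], axis=1)
    m_target = joint_moments(a0, model, passive=False)
    syn_true = {s: SynergySet(trunk_W[s], H_true[s], side=s) for s in sides}
    cfg = EstimatorConfig()
    w_proj = None
    for _ in range(n_passes):
        fit = TrunkActivationModel(model, m_target, syn_true, cfg).fit()
        w_proj = fit.w_est
        m_target = joint_moments(fit.a_est, model, passive=False)
    out_W = {}
    offset = 0
    for s in sides:
        n_side = trunk_W[s].shape[0]
        out_W[s] = w_proj[offset:offset + n_side]
        offset += n_side
    a_true = np.concatenate([(out_W[s] @ H_true[s]).T for s in sides],
                            axis=1)
    return out_W, a_true


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one complete synthetic gait dataset (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    sides = ("right", "left")
    group_labels = _trunk_group_labels(spec.n_trunk_musc)
    H_true, leg_W, trunk_W = {}, {}, {}
    # left synergy activations are the right ones advanced by half a cycle,
    # the usual symmetry of steady treadmill gait
    H_right = make_synergy_activations(spec.k_true, spec.n_pt,
                                       seed=int(rng.integers(2**31)))
    H_true["right"] = H_right
    H_left = np.stack([_circular_shift(row, spec.n_pt / 2.0)
                       for row in H_right])
    H_true["left"] = H_left / H_left.max(axis=1, keepdims=True)
    for side in sides:
        leg_W[side] = make_weights(
            spec.n_leg_musc, spec.k_true, spec.sparsity, 0.0,
            seed=int(rng.integers(2**31)), anchors=True)
        trunk_W[side] = make_trunk_weights(
            group_labels, spec.k_true, spec.minimal_recruitment_fraction,
            seed=int(rng.integers(2**31)))

    # two-sided trunk model sharing one geometry block per side; strength
    # and fiber parameters follow the published reduced trunk set, with
    # fiber lengths tuned to the synthetic geometry so fibers stay
    # near-optimal during gait
    table = reduced_trunk_set()
    geoms, mtus = [], []
    for side in sides:
        g, m = make_geometry(spec.n_trunk_musc, spec.n_dof, spec.n_pt,
                             seed=int(rng.integers(2**31)),
                             groups=group_labels, side=side)
        for i, mt in enumerate(m):
            row = table.iloc[i % len(table)]
            mt.name = f"{group_labels[i]}_{i}_{side[0]}"
            mt.fmo = float(row["fmo_personalized"])
            mt.acsa = float(row["acsa_personalized"])
            tuned = tune_fiber_lengths(
                MTU(mt.name, mt.group, mt.side, mt.fmo,
                    0.01 * float(row["lmo_personalized"]),
                    max(0.01 * float(row["lts_personalized"]), 1e-6)),
                g.lmt[:, i], target=0.95)
            mt.lmo, mt.lts = tuned.lmo, tuned.lts
        geoms.append(g)
        mtus.extend(m)
    geometry = MuscleGeometrySeries(
        np.concatenate([g.lmt for g in geoms], axis=1),
        np.concatenate([g.moment_arms for g in geoms], axis=1),
        list(geoms[0].dof_labels))
    model = TrunkModel(mtus, geometry)

    trunk_W, a_true = _project_truth(trunk_W, H_true, model, sides)
    m_clean = joint_moments(a_true, model, passive=False)

    leg_acts = {side: [] for side in sides}
    m_noisy = []
    for _ in range(spec.n_cycles):
        for side in sides:
            a = leg_W[side] @ H_true[side]
            if spec.activation_noise_sd > 0:
                a = a + rng.normal(0.0, spec.activation_noise_sd,
                                   size=a.shape)
            leg_acts[side].append(np.clip(a, 0.0, 1.0))
        m = m_clean.copy()
        if spec.moment_noise_sd > 0:
            m = m + rng.normal(0.0, spec.moment_noise_sd, size=m.shape)
        m_noisy.append(m)

    footstrikes = spec.cycle_duration_s * np.arange(spec.n_cycles + 1)

    # surrogate measured excitation: the ES group-mean activation advanced
    # by the injected EMD, on a deliberately different amplitude scale
    measured, source = {}, {}
    shift = spec.injected_emd_ms / 1000.0 / spec.cycle_duration_s * spec.n_pt
    grouping = model.grouping
    for side in sides:
        es = a_true[:, grouping[("ES", side)]].mean(axis=1)
        exc = _circular_shift(es, -shift) * rng.uniform(1.3, 2.2)
        if spec.activation_noise_sd > 0:
            exc = np.clip(exc + rng.normal(0.0, spec.activation_noise_sd,
                                           size=exc.shape), 0.0, None)
        measured[side] = exc
        source[side] = es

    return SyntheticDataset(
        spec=spec, H_true=H_true, leg_weights=leg_W,
        leg_activations=leg_acts, trunk_true_weights=trunk_W,
        trunk_true_activations=a_true, model=model, m_id_clean=m_clean,
        m_id=m_noisy, footstrike_times=footstrikes,
        measured_excitation=measured, excitation_source=source)
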