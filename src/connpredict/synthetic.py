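"""Synthetic adult-lifespan cohorts with network-structured connectomes.

The generator emulates the statistical structure the downstream analysis
assumes: an age variable approximately uniform over the adult lifespan,
cognitive scores negatively coupled to age through a single shared
standardized slope, a lognormal head-motion confound mildly correlated with
age, and Fisher-z connectome edges that load on standardized age and on the
age-independent cognition residual with network-structured, oppositely signed
loadings — connections within associative/sensory networks (DMN-, VAN-,
SMN-like) weaken with age and support cognition, while limbic within-network
and sensorimotor-to-associative between-network connections strengthen with
age and track lower cognition.

Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectome import (
    Atlas,
    Connectome,
    ParcellatedTimeSeries,
    devectorize,
    edge_pairs,
    n_edges,
)
from .exceptions import InvalidAtlasError, InvalidParameterError, InvalidTargetError

__all__ = [
    "COGNITIVE_METRICS",
    "SyntheticSpec",
    "default_effect_map",
    "default_spec",
    "simulate_cohort",
    "simulate_timeseries",
]

#: the eight cognitive metrics of the emulated behavioural battery
COGNITIVE_METRICS = (
    "gF",
    "force_matching",
    "hotel_task",
    "motor_learning",
    "TOT",
    "VSTM",
    "face_recognition",
    "emotion_recognition",
)

# network roles used by the default effect map when canonical labels are
# present; within-segregating networks lose within-network connectivity with
# age and support cognition, the limbic network does the opposite, and the
# sensorimotor network hyper-connects to associative networks with age
_WITHIN_NEG_AGE = ("DMN", "VAN", "SMN", "SUB")
_WITHIN_POS_AGE = ("LIM",)
_BETWEEN_POS_AGE = (("SMN", "DAN"), ("SMN", "VAN"), ("SMN", "FPN"), ("DMN", "VAN"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a synthetic cohort.

    Edge loadings are in Fisher-z units per standardized predictor;
    ``confound_slope`` is in z-units per mm of mean framewise displacement.
    """

    n_subjects: int
    n_nodes: int
    network_sizes: tuple
    edge_effect_map: np.ndarray  # (n_edges, 2): columns (beta_age, beta_cog)
    age_range: tuple = (19.0, 89.0)
    age_cog_slope: float = -0.6
    confound_slope: float = -0.3
    noise_sd: float = 0.5
    baseline: np.ndarray | float = 0.0
    fd_age_corr: float = 0.3
    fd_log_mean: float = float(np.log(0.12))
    fd_log_sd: float = 0.35
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise InvalidParameterError("n_nodes must be >= 2")
        if any(s < 1 for s in self.network_sizes):
            raise InvalidParameterError("all network sizes must be >= 1")
        if sum(self.network_sizes) != self.n_nodes:
            raise InvalidParameterError("network_sizes must sum to n_nodes")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not -1.0 <= self.age_cog_slope <= 1.0:
            raise InvalidParameterError("age_cog_slope must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidParameterError("missing_rate must be in [0, 1)")
        emap = np.asarray(self.edge_effect_map, dtype=float)
        if emap.shape != (n_edges(self.n_nodes), 2):
            raise InvalidParameterError(
                f"edge_effect_map must have shape ({n_edges(self.n_nodes)}, 2), "
                f"got {emap.shape}"
            )
        object.__setattr__(self, "edge_effect_map", emap)
        object.__setattr__(self, "network_sizes", tuple(self.network_sizes))

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_nodes)

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _network_roles(atlas: Atlas) -> tuple[set, set, set]:
    """Resolve which network pairs carry which effect signs.

    Returns (within_neg_age, within_pos_age, between_pos_age) as sets of
    canonical pair positions.  Canonical labels (DMN/VAN/SMN/LIM/...) are used
    when present; otherwise roles fall back to network order: the first
    ``min(3, K-1)`` networks act as the segregating (DMN/VAN/SMN-like) set
    with the last of them sensorimotor-like, the final network is limbic-like,
    and any others are associative.
    """
    names = atlas.network_names
    k = len(names)
    if k < 2:
        raise InvalidAtlasError("default effect map needs at least 2 networks")
    idx = {name: i for i, name in enumerate(names)}

    canonical = {"DMN", "VAN", "SMN", "LIM"}.issubset(set(names))
    if canonical:
        within_neg = [idx[n] for n in _WITHIN_NEG_AGE if n in idx]
        within_pos = [idx[n] for n in _WITHIN_POS_AGE]
        between = [
            (idx[a], idx[b]) for a, b in _BETWEEN_POS_AGE if a in idx and b in idx
        ]
    else:
        seg = list(range(min(3, k - 1)))
        within_neg = seg
        within_pos = [k - 1]
        smn_like = seg[-1]
        associative = [i for i in range(k) if i != smn_like]
        between = [(smn_like, i) for i in associative]

    pos = atlas.pair_position
    return (
        {pos(i, i) for i in within_neg},
        {pos(i, i) for i in within_pos},
        {pos(a, b) for a, b in between},
    )


def default_effect_map(
    atlas: Atlas,
    seed: int = 0,
    *,
    magnitude: tuple = (0.1, 0.3),
    cog_jitter: float = 0.1,
) -> np.ndarray:
    """Network-structured per-edge (beta_age, beta_cog) loadings.

    Within-network edges of the segregating networks get ``beta_age < 0`` and
    ``beta_cog > 0``; limbic within-network edges get ``beta_age > 0`` and
    ``beta_cog < 0``; sensorimotor-to-associative between-network edges get
    ``beta_age > 0`` and ``beta_cog < 0``.  All other edges carry no effect.

    The age and cognition loadings are anti-mirrored edge by edge — the
    connections that strengthen with age are exactly those that track lower
    cognition — with a mild per-edge magnitude jitter
    (``beta_cog = -beta_age · U(1 ± cog_jitter)``) so that the age and
    cognition-residual latents remain separately identifiable.  The beta_age
    and beta_cog vectors are therefore strongly negatively correlated across
    edges.  Magnitudes are drawn uniformly from ``magnitude`` per edge,
    seeded.
    """
    within_neg, within_pos, between_pos = _network_roles(atlas)
    eclass = atlas.edge_class_index()
    m = eclass.shape[0]
    rng = np.random.default_rng(seed)
    mag = rng.uniform(*magnitude, size=m)

    beta_age = np.zeros(m)
    neg_age_mask = np.isin(eclass, list(within_neg))
    pos_age_mask = np.isin(eclass, list(within_pos | between_pos))
    beta_age[neg_age_mask] = -mag[neg_age_mask]
    beta_age[pos_age_mask] = mag[pos_age_mask]
    jitter = rng.uniform(1.0 - cog_jitter, 1.0 + cog_jitter, size=m)
    return np.column_stack([beta_age, -beta_age * jitter])


def _default_atlas_for_sizes(network_sizes: tuple) -> Atlas:
    labels = [f"NET{k + 1}" for k in range(len(network_sizes))]
    node_ids, node_labels, nets = [], [], []
    i = 0
    for lab, size in zip(labels, network_sizes):
        for _ in range(size):
            i += 1
            node_ids.append(f"n{i:03d}")
            node_labels.append(f"{lab}_{i:03d}")
            nets.append(lab)
    return Atlas(tuple(node_ids), tuple(node_labels), tuple(nets))


def default_spec(
    atlas: Atlas,
    n_subjects: int = 400,
    *,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticSpec:
    """A ready-to-run spec for ``atlas`` with the default effect map.

    Baseline connectivity is 0.3 (z-units) within networks and 0.1 between,
    the typical ordering of resting-state connectomes.
    """
    emap = default_effect_map(atlas, seed=seed)
    eclass = atlas.edge_class_index()
    k = atlas.n_networks
    within_positions = [atlas.pair_position(i, i) for i in range(k)]
    baseline = np.where(np.isin(eclass, within_positions), 0.3, 0.1)
    return SyntheticSpec(
        n_subjects=n_subjects,
        n_nodes=atlas.n_nodes,
        network_sizes=tuple(atlas.network_sizes),
        edge_effect_map=emap,
        noise_sd=noise_sd,
        baseline=baseline,
        seed=seed,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_cohort(spec: SyntheticSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a cohort and its connectomes.

    Returns
    -------
    phenotypes : DataFrame
        Columns ``subject_id, age, gender, mean_fd`` plus one column per
        cognitive metric (z-scores; NaN where missing).
    edges : ndarray, shape (n_subjects, n_edges)
        Fisher-z edge values, canonical edge order.  Each edge is
        ``baseline + beta_age·z(age) + beta_cog·z(cog_resid)
        + confound_slope·mean_fd + N(0, noise_sd)`` where ``cog_resid`` is
        the component of the shared cognition factor independent of age.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = rng.uniform(*spec.age_range, size=n)
    z_age = _standardize(age)

    # shared cognition factor: slope·z_age + independent residual, unit scale
    resid = rng.standard_normal(n)
    z_resid = _standardize(resid)
    slope = spec.age_cog_slope
    cog_g = slope * z_age + np.sqrt(1.0 - slope**2) * z_resid

    # the primary metric (gF) is the shared factor itself; the other metrics
    # mix the shared factor with private noise, keeping them intercorrelated
    scores = {COGNITIVE_METRICS[0]: cog_g}
    for metric in COGNITIVE_METRICS[1:]:
        private = rng.standard_normal(n)
        scores[metric] = np.sqrt(0.75) * cog_g + np.sqrt(0.25) * private

    gender = rng.integers(0, 2, size=n)
    fd_latent = spec.fd_age_corr * z_age + np.sqrt(
        1.0 - spec.fd_age_corr**2
    ) * rng.standard_normal(n)
    mean_fd = np.exp(spec.fd_log_mean + spec.fd_log_sd * fd_latent)

    beta_age = spec.edge_effect_map[:, 0]
    beta_cog = spec.edge_effect_map[:, 1]
    edges = (
        np.asarray(spec.baseline, dtype=float)
        + np.outer(z_age, beta_age)
        + np.outer(z_resid, beta_cog)
        + spec.confound_slope * mean_fd[:, None]
    )
    if spec.noise_sd > 0:
        edges = edges + rng.normal(0.0, spec.noise_sd, size=edges.shape)

    phen = pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:04d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "mean_fd": mean_fd,
        }
    )
    for metric in COGNITIVE_METRICS:
        col = scores[metric]
        if spec.missing_rate > 0:
            drop = rng.random(n) < spec.missing_rate
            col = np.where(drop, np.nan, col)
        phen[metric] = col
    return phen, edges


def connectomes_from_edges(edges: np.ndarray, subject_ids=None) -> list[Connectome]:
    """Wrap per-subject edge rows as :class:`Connectome` objects."""
    ids = subject_ids if subject_ids is not None else [None] * len(edges)
    return [Connectome(row, subject_id=sid) for row, sid in zip(edges, ids)]


def simulate_timeseries(
    target: Connectome,
    n_timepoints: int,
    seed: int = 0,
    *,
    repair_tol: float = 0.1,
) -> ParcellatedTimeSeries:
    """Gaussian time series whose sample correlations converge to ``target``.

    The target's Fisher-z edges are mapped back to correlations, the implied
    matrix is repaired to the nearest valid (positive semi-definite, unit
    diagonal) correlation matrix by eigenvalue clipping, and i.i.d. Gaussian
    timepoints are drawn with that covariance.  If the repair moves any
    correlation by more than ``repair_tol``, the target is rejected.
    """
    if n_timepoints < 2:
        raise InvalidParameterError("need at least 2 timepoints")
    r_target = np.tanh(devectorize(target.edge_values))
    np.fill_diagonal(r_target, 1.0)

    w, v = np.linalg.eigh(r_target)
    w_clipped = np.clip(w, 1e-8, None)
    fixed = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)

    iu, ju = edge_pairs(r_target.shape[0])
    drift = np.max(np.abs(fixed[iu, ju] - r_target[iu, ju]))
    if drift > repair_tol:
        raise InvalidTargetError(
            f"target is not repairable to a valid correlation matrix "
            f"(max correlation shift {drift:.3f} > {repair_tol})"
        )

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(fixed + 1e-10 * np.eye(fixed.shape[0]))
    data = chol @ rng.standard_normal((fixed.shape[0], n_timepoints))
    sid = target.subject_id if target.subject_id is not None else "sim"
    return ParcellatedTimeSeries(subject_id=sid, data=data)
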