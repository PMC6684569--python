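"""Synthetic cohort generator with known ground truth.

Emulates the study conditions every downstream stage is tested against:
~129 adults aged 21-86 (uniform ages, ~72% female), 14 RSNs holding 142
of 499 parcellation nodes, node time series drawn from a block-structured
correlation matrix whose within-network coupling declines and selected
cross-network couplings rise with age, subject spatial maps drifting away
from their group template with age, motion traces with a configurable
high-motion fraction, and ACE-R scores generated from a mediation model
age -> connectivity integrity -> ACE-R with sex as covariate.

One latent per-subject innovation (``eps``) is shared between the spatial
maps' template-mixing coefficient and the ACE-R generative model, so the
planted mediation is recoverable from the *measured* similarity values,
not only from the latent mediator.

All generators are deterministic under the cohort seed: per-subject,
per-stream child generators are derived as SeedSequence([seed, stream,
subject_index]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .confounds import MotionTrace, NodeTimeSeries
from .dualreg import SpatialMap, TemplateSet
from .exceptions import GenerationError, ParameterError, ValidationError
from .parcellation import OTHER_LABEL, Parcellation, default_parcellation

AGE_CENTER = 50.0
AGE_SCALE = 35.0

# internal stream ids for child-seed derivation
_STREAM_COHORT = 0
_STREAM_TIMESERIES = 1
_STREAM_MOTION = 2
_STREAM_MAPS = 3
_STREAM_TEMPLATES = 4

#: Cross-network age slopes mirroring the planted pattern of interest:
#: the visuospatial (dorsal attention) network gains coupling with
#: sensorimotor, primary visual, precuneus and anterior salience with age
#: and loses coupling with language.
DEFAULT_BETWEEN_SLOPES: dict[frozenset, float] = {
    frozenset({"visuospatial", "sensorimotor"}): 0.08,
    frozenset({"visuospatial", "primary_visual"}): 0.08,
    frozenset({"visuospatial", "precuneus"}): 0.08,
    frozenset({"visuospatial", "anterior_salience"}): 0.08,
    frozenset({"visuospatial", "language"}): -0.08,
}


def age_centered(age) -> np.ndarray:
    """(age - 50) / 35: roughly [-0.83, 1.03] over ages 21-86."""
    return (np.asarray(age, dtype=float) - AGE_CENTER) / AGE_SCALE


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: int  # 0 = male, 1 = female
    ace_r_total: float
    index: int
    cognitive_pass: bool = True
    included: bool = True

    def __post_init__(self):
        if not (0.0 <= self.ace_r_total <= 100.0):
            raise ValidationError("ace_r_total must lie in [0, 100]")


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters.  Defaults are the study conditions."""

    n_subjects: int = 129
    n_volumes: int = 193  # 198 acquired minus 5 dropped
    tr_seconds: float = 2.5
    seed: int = 0
    age_range: tuple[float, float] = (21.0, 86.0)
    female_fraction: float = 0.72  # 93/129
    # node-covariance structure
    within_base: float = 0.35
    within_slope: float | Mapping[str, float] = -0.10
    between_base: float = 0.08
    between_slope: float | Mapping[frozenset, float] | None = None  # None -> defaults
    other_coupling: float = 0.03
    ar_phi: float = 0.0
    # spatial maps
    lambda_base: float = 0.20
    eta_decay: float = 0.22  # age slope of the template-mixing coefficient
    map_latent_sd: float = 0.05  # latent innovation -> mixing coefficient
    map_noise_sd: float = 0.10
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    # mediation model (units: mediator per centered-age unit; ACE-R points)
    mediation_a: float = -0.8
    mediation_b: float = 1.2
    mediation_cprime: float = -0.8
    mediator_noise_sd: float = 1.0
    sex_coef: float = 0.5
    ace_base: float = 96.0
    noise_sd: float = 1.5
    # motion
    high_motion_fraction: float = 0.0
    motion_scale_low: float = 0.02
    motion_scale_high: float = 0.06
    motion_jitter_sd: float = 0.15
    head_radius_mm: float = 50.0


@dataclass(frozen=True)
class CohortGroundTruth:
    """Full generative parameter record plus per-subject latents."""

    within_slope_k: dict
    between_slope_kl: dict
    eta_decay: float
    mediation_a: float
    mediation_b: float
    mediation_cprime: float
    noise_sd: float
    seed: int
    config: CohortConfig
    latents: dict = field(default_factory=dict, repr=False)


def _child_rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, index]))


def _slope_map(spec, networks: Sequence[str], default: float = 0.0) -> dict:
    if spec is None:
        return {n: default for n in networks}
    if isinstance(spec, Mapping):
        return {n: float(spec.get(n, default)) for n in networks}
    return {n: float(spec) for n in networks}


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], CohortGroundTruth]:
    """Sample demographics, latent mediators and ACE-R scores.

    ACE-R = base + c'*age_c + b*M + sex_coef*sex + noise, clipped to
    [0, 100], where the mediator M = a*age_c + eps emulates a
    connectivity-integrity feature.  Deterministic under ``config.seed``.
    """
    if config.n_subjects < 2:
        raise ParameterError("n_subjects must be >= 2")
    lo, hi = config.age_range
    if not (lo < hi):
        raise ParameterError("age_range must be increasing")
    rng = _child_rng(config.seed, _STREAM_COHORT)
    n = config.n_subjects
    ages = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) < config.female_fraction).astype(int)
    eps = rng.standard_normal(n)
    age_c = age_centered(ages)
    mediator = config.mediation_a * age_c + config.mediator_noise_sd * eps
    noise = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
    ace = (
        config.ace_base
        + config.mediation_cprime * age_c
        + config.mediation_b * mediator
        + config.sex_coef * sex
        + noise
    )
    ace = np.clip(ace, 0.0, 100.0)
    high = rng.random(n) < config.high_motion_fraction
    scale = np.where(high, config.motion_scale_high, config.motion_scale_low)
    scale = scale * np.exp(config.motion_jitter_sd * rng.standard_normal(n))

    subjects = [
        SubjectRecord(
            subject_id=f"sub-{i:04d}",
            age=float(ages[i]),
            sex=int(sex[i]),
            ace_r_total=float(ace[i]),
            index=i,
            cognitive_pass=bool(ace[i] >= 89.0),
        )
        for i in range(n)
    ]
    networks = [n_ for n_ in default_parcellation().rsn_networks]
    between = (
        dict(DEFAULT_BETWEEN_SLOPES)
        if config.between_slope is None
        else (
            {k: float(v) for k, v in config.between_slope.items()}
            if isinstance(config.between_slope, Mapping)
            else {"__all__": float(config.between_slope)}
        )
    )
    truth = CohortGroundTruth(
        within_slope_k=_slope_map(config.within_slope, networks),
        between_slope_kl=between,
        eta_decay=config.eta_decay,
        mediation_a=config.mediation_a,
        mediation_b=config.mediation_b,
        mediation_cprime=config.mediation_cprime,
        noise_sd=config.noise_sd,
        seed=config.seed,
        config=config,
        latents={
            "eps": eps,
            "mediator": mediator,
            "high_motion": high,
            "motion_scale": scale,
        },
    )
    return subjects, truth


def _pair_slope(truth: CohortGroundTruth, n1: str, n2: str) -> float:
    key = frozenset({n1, n2})
    slopes = truth.between_slope_kl
    if "__all__" in slopes:
        return slopes["__all__"]
    return float(slopes.get(key, 0.0))


def build_covariance(
    parc: Parcellation, truth: CohortGroundTruth, age: float
) -> np.ndarray:
    """Age-dependent block correlation matrix Sigma(age).

    Within-network block value w + within_slope_k * age_c; cross blocks
    b + between_slope_kl * age_c; any pair involving an 'other' node gets
    the weak ``other_coupling``.  Eigenvalue-clipped to positive definite
    (then rescaled to unit diagonal) when needed.
    """
    cfg = truth.config
    ac = float(age_centered(age))
    N = parc.n_nodes
    C = np.full((N, N), cfg.other_coupling)
    nets = parc.rsn_networks
    for i, n1 in enumerate(nets):
        idx1 = parc.network_nodes(n1)
        fallback = cfg.within_slope if not isinstance(cfg.within_slope, Mapping) else 0.0
        w = cfg.within_base + truth.within_slope_k.get(n1, fallback) * ac
        if not (-0.99 < w < 0.99):
            raise GenerationError(
                f"within-network coupling {w:.3f} for block {n1!r} out of (-0.99, 0.99)"
            )
        C[np.ix_(idx1, idx1)] = w
        for n2 in nets[i + 1 :]:
            idx2 = parc.network_nodes(n2)
            b = cfg.between_base + _pair_slope(truth, n1, n2) * ac
            if not (-0.99 < b < 0.99):
                raise GenerationError(
                    f"between-network coupling {b:.3f} for block "
                    f"({n1!r}, {n2!r}) out of (-0.99, 0.99)"
                )
            C[np.ix_(idx1, idx2)] = b
            C[np.ix_(idx2, idx1)] = b
    np.fill_diagonal(C, 1.0)
    return _ensure_pd(C)


def _ensure_pd(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    try:
        np.linalg.cholesky(C)
        return C
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(C)
        vals = np.clip(vals, floor, None)
        C = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        return C


def generate_node_timeseries(
    subject: SubjectRecord,
    parc: Parcellation,
    truth: CohortGroundTruth,
    n_volumes: int | None = None,
) -> NodeTimeSeries:
    """Sample T x N node signals from Sigma(age).

    Volumes are i.i.d. Gaussian by default; ``ar_phi`` > 0 adds AR(1)
    serial correlation with unit marginal variance.
    """
    cfg = truth.config
    T = cfg.n_volumes if n_volumes is None else int(n_volumes)
    if T < 20:
        raise ParameterError("n_volumes must be >= 20")
    C = build_covariance(parc, truth, subject.age)
    L = np.linalg.cholesky(C)
    rng = _child_rng(truth.seed, _STREAM_TIMESERIES, subject.index)
    Z = rng.standard_normal((T, parc.n_nodes))
    phi = cfg.ar_phi
    if phi:
        if not (-1.0 < phi < 1.0):
            raise ParameterError("ar_phi must lie in (-1, 1)")
        E = np.empty_like(Z)
        E[0] = Z[0]
        s = np.sqrt(1.0 - phi * phi)
        for t in range(1, T):
            E[t] = phi * E[t - 1] + s * Z[t]
        Z = E
    return NodeTimeSeries(Z @ L.T, cfg.tr_seconds)


def generate_motion_trace(
    subject: SubjectRecord,
    truth: CohortGroundTruth,
    n_volumes: int | None = None,
) -> MotionTrace:
    """Random-walk 6-parameter motion trace at the subject's motion scale.

    Translation increments are N(0, scale) mm; rotation increments
    N(0, scale / head_radius) rad, so both contribute equally to FD.
    """
    cfg = truth.config
    T = cfg.n_volumes if n_volumes is None else int(n_volumes)
    if T < 2:
        raise ParameterError("n_volumes must be >= 2")
    scale = float(truth.latents["motion_scale"][subject.index])
    rng = _child_rng(truth.seed, _STREAM_MOTION, subject.index)
    steps = rng.standard_normal((T - 1, 6))
    steps[:, :3] *= scale
    steps[:, 3:] *= scale / cfg.head_radius_mm
    R = np.vstack([np.zeros((1, 6)), np.cumsum(steps, axis=0)])
    return MotionTrace(R)


def make_templates(
    labels: Sequence[str],
    grid_shape: tuple[int, int, int] = (24, 24, 12),
    seed: int = 0,
    n_blobs: int = 3,
    smooth_vox: float = 2.0,
    peak: float = 3.0,
) -> TemplateSet:
    """Smooth random blob maps standing in for group-ICA templates.

    Each template places ``n_blobs`` impulses at random voxels, smooths
    them with a Gaussian kernel, and rescales to a peak value of ``peak``
    (z-map-like units).
    """
    from scipy.ndimage import gaussian_filter

    rng = _child_rng(seed, _STREAM_TEMPLATES)
    maps = []
    for lab in labels:
        g = np.zeros(grid_shape)
        for _ in range(n_blobs):
            pos = tuple(rng.integers(0, s) for s in grid_shape)
            g[pos] += rng.uniform(0.5, 1.0)
        g = gaussian_filter(g, smooth_vox)
        g *= peak / g.max()
        maps.append(SpatialMap(g, lab))
    return TemplateSet(tuple(maps), tuple(labels))


def generate_spatial_maps(
    subject: SubjectRecord,
    truth: CohortGroundTruth,
    templates: TemplateSet,
) -> dict[str, SpatialMap]:
    """Subject-specific RSN maps drifting from their template with age.

    map_k = (1 - lam) * template_k + lam * mean(other templates) + noise,
    with lam = clip(lambda_base + eta_decay * age_c - map_latent_sd * eps,
    0, 0.95).  The shared latent eps ties map integrity to the ACE-R
    generative model.
    """
    cfg = truth.config
    shapes = {m.shape for m in templates.maps}
    if len(shapes) != 1:
        raise ValidationError("templates must share one grid shape")
    eps = float(truth.latents["eps"][subject.index])
    lam = float(
        np.clip(
            cfg.lambda_base
            + truth.eta_decay * age_centered(subject.age)
            - cfg.map_latent_sd * eps,
            0.0,
            0.95,
        )
    )
    rng = _child_rng(truth.seed, _STREAM_MAPS, subject.index)
    K = templates.n_components
    stack = np.stack([m.grid for m in templates.maps])
    out: dict[str, SpatialMap] = {}
    for k, lab in enumerate(templates.labels):
        if K > 1:
            mix = (stack.sum(axis=0) - stack[k]) / (K - 1)
        else:
            mix = np.zeros_like(stack[k])
        g = (1.0 - lam) * stack[k] + lam * mix
        if cfg.map_noise_sd > 0:
            g = g + cfg.map_noise_sd * rng.standard_normal(g.shape)
        out[lab] = SpatialMap(g, lab)
    return out


def generate_voxel_data(
    subject: SubjectRecord,
    truth: CohortGroundTruth,
    maps: Mapping[str, SpatialMap],
    n_volumes: int | None = None,
    course_noise_sd: float = 0.5,
) -> np.ndarray:
    """Voxels x T data synthesized as subject maps x random time courses.

    Gives the dual-regression stage a meaningful input in the synthetic
    path: stage 2 should recover (up to noise) the generating maps.
    """
    cfg = truth.config
    T = cfg.n_volumes if n_volumes is None else int(n_volumes)
    rng = _child_rng(truth.seed, _STREAM_MAPS, subject.index + 1_000_000)
    M = np.column_stack([m.grid.ravel() for m in maps.values()])
    tc = rng.standard_normal((M.shape[1], T))
    data = M @ tc
    if course_noise_sd > 0:
        data = data + course_noise_sd * rng.standard_normal(data.shape)
    return data


def demographics_frame(subjects: Sequence[SubjectRecord]):
    """Demographics table (subject_id, age, sex, ace_r_total, flags)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "ace_r_total": s.ace_r_total,
                "cognitive_pass": s.cognitive_pass,
                "included": s.included,
            }
            for s in subjects
        ]
    )


def truth_to_dict(truth: CohortGroundTruth) -> dict:
    """YAML-serializable ground-truth record (latents summarized)."""
    d = {
        "within_slope_k": dict(truth.within_slope_k),
        "between_slope_kl": {
            "|".join(sorted(k)) if isinstance(k, frozenset) else str(k): v
            for k, v in truth.between_slope_kl.items()
        },
        "eta_decay": truth.eta_decay,
        "mediation_a": truth.mediation_a,
        "mediation_b": truth.mediation_b,
        "mediation_cprime": truth.mediation_cprime,
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "config": asdict(truth.config),
    }
    cfg = d["config"]
    if isinstance(cfg.get("between_slope"), Mapping):
        cfg["between_slope"] = {
            "|".join(sorted(k)): v for k, v in cfg["between_slope"].items()
        }
    return d
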