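"""Synthetic resting-state cohorts with planted brain-behaviour effects.

The generator emulates the statistical structure the analysis pipeline
assumes, at the study's scale: 30 subjects, 90 atlas regions, 990 time points
at 0.5 s, streamline counts at 5000 samples per seed voxel, a ~19-measure
behavioural table and the five confound covariates.  Every generator is a
pure function of (config, seed).

Effect planting manipulates graph topology, not metric values: a latent
severity u per subject scales the within-module correlation level of the
target matrix from which that subject's time series are drawn, so the
designated network metric varies monotonically with u and the full pipeline
— preprocessing, connectome construction, metric computation — is exercised
end to end.  The behaviour is then a noisy monotone function of the true
metric, with the signal amplitude calibrated by a large-sample rehearsal so
the population Spearman correlation between behaviour and true metric hits
the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from . import graph as _graph
from .association import CONFOUND_COLUMNS, mean_framewise_displacement
from .atlas import AAL90_LABELS
from .connectome import (
    StreamlineCountSet,
    StructuralConnectome,
    symmetrize_connection_matrix,
)
from .preprocess import NuisanceSet, RoiTimeSeriesSet

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticCohort",
    "MEASURE_SCALES",
    "target_correlation_matrix",
    "simulate_roi_timeseries",
    "simulate_streamline_counts",
    "simulate_motion_parameters",
    "simulate_cohort_with_planted_effect",
]

#: Group mean and SD used to put each synthetic measure on a realistic scale
#: (questionnaire points, ms or s as appropriate for the instrument).
MEASURE_SCALES: dict[str, tuple[float, float]] = {
    "AQ": (-19.24, 23.17),
    "EQ": (42.57, 11.97),
    "SQ": (69.74, 16.57),
    "SSQ": (4.63, 1.98),
    "SRS": (37.88, 19.27),
    "RMET": (26.54, 4.81),
    "COWA": (46.06, 11.08),
    "AnNT": (17.25, 5.09),
    "FC_EFT": (10112.95, 5282.13),
    "ANT_alerting": (49.97, 31.54),
    "ANT_orienting": (53.11, 29.31),
    "ANT_conflict": (115.49, 39.35),
    "ANT_grand_mean": (638.43, 47.24),
    "ToM_second_order": (-2.63, 7.78),
    "ToM_ego_first_order": (4.08, 16.33),
    "ToM_allo_first_order": (2.24, 8.31),
    "WASI_verbal_IQ": (109.54, 8.90),
    "WASI_performance_IQ": (105.58, 6.87),
    "WASI_fsiq": (108.86, 7.53),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A single metric-behaviour association to plant in the cohort."""

    behaviour: str = "SRS"
    metric: str = "global_efficiency"
    modality: str = "functional"
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("target rho must lie in (-1, 1)")
        if self.modality not in ("functional", "structural"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters; defaults mirror the study design."""

    n_subjects: int = 30
    n_regions: int = 90
    n_timepoints: int = 990
    sampling_interval: float = 0.5  # s, i.e. 2 Hz sampling
    n_modules: int = 6
    within_module_corr: float = 0.45
    between_module_corr: float = 0.10
    drift_amplitude: float = 1.0  # signal units across the scan
    cardiac_hz: float = 0.9
    cardiac_amplitude: float = 0.5
    respiratory_hz: float = 0.3
    respiratory_amplitude: float = 0.5
    voxels_per_region: tuple[int, int] = (200, 1200)
    samples_per_voxel: int = 5000
    structural_within_p: float = 0.008
    structural_between_p: float = 0.0005
    planted_effect: PlantedEffect | None = PlantedEffect()
    # severity moves both correlation levels through s = 2 tanh(u/2), which is
    # strictly monotone and saturates smoothly instead of clipping
    effect_gain_within: float = 0.22
    effect_gain_between: float = 0.06
    confound_coefs: tuple[tuple[str, float], ...] = (
        ("age", 0.15),
        ("sex", 0.10),
        ("fsiq", 0.15),
        ("mean_fd", 0.10),
        ("brain_volume", 0.10),
    )
    motion_step_range: tuple[float, float] = (0.01, 0.10)  # mm per frame, per subject
    seed: int = 0

    def __post_init__(self) -> None:
        # coerce YAML-friendly containers so the config stays hashable
        object.__setattr__(self, "voxels_per_region", tuple(self.voxels_per_region))
        object.__setattr__(self, "motion_step_range", tuple(self.motion_step_range))
        coefs = self.confound_coefs
        if isinstance(coefs, dict):
            coefs = tuple(sorted(coefs.items()))
        else:
            coefs = tuple((str(k), float(v)) for k, v in coefs)
        object.__setattr__(self, "confound_coefs", coefs)
        if not (0.0 <= self.between_module_corr < self.within_module_corr < 1.0):
            raise ValueError("need 0 <= between < within < 1 module correlations")
        # validate positive definiteness of the extreme planted matrices
        for u in (-2.5, 0.0, 2.5):
            w, b = self._levels_at(u)
            m = target_correlation_matrix(self.n_regions, self.n_modules, w, b)
            if np.linalg.eigvalsh(m).min() <= 1e-10:
                raise ValueError(
                    f"target correlation matrix is not positive definite at severity {u}"
                )
        bad = [k for k, _ in self.confound_coefs if k not in CONFOUND_COLUMNS]
        if bad:
            raise ValueError(f"unknown confound(s) in confound_coefs: {bad}")

    def _levels_at(self, u: float) -> tuple[float, float]:
        """(within, between) correlation levels at latent severity u."""
        if self.planted_effect is None or self.planted_effect.modality != "functional":
            return self.within_module_corr, self.between_module_corr
        s = 2.0 * np.tanh(u / 2.0)
        within = float(np.clip(self.within_module_corr + self.effect_gain_within * s, 0.01, 0.95))
        between = float(
            np.clip(self.between_module_corr + self.effect_gain_between * s, 0.005, within - 0.005)
        )
        return within, between


@dataclass
class SyntheticCohort:
    """Observables plus the ground truth they were generated from."""

    config: SimulationConfig
    subjects: list[str]
    timeseries: list[RoiTimeSeriesSet]
    nuisance: list[NuisanceSet]
    motion: list[np.ndarray]
    streamline_counts: list[StreamlineCountSet]
    structural_truth: list[StructuralConnectome]
    behaviour: pd.DataFrame
    confounds: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def target_correlation_matrix(
    n_regions: int, n_modules: int, within: float, between: float
) -> np.ndarray:
    """Module-structured target correlation matrix (unit diagonal)."""
    modules = np.repeat(np.arange(n_modules), int(np.ceil(n_regions / n_modules)))[:n_regions]
    same = modules[:, None] == modules[None, :]
    m = np.where(same, within, between).astype(float)
    np.fill_diagonal(m, 1.0)
    return m


def _region_labels(n: int) -> list[str]:
    return AAL90_LABELS if n == 90 else [f"region_{i + 1}" for i in range(n)]


def simulate_roi_timeseries(
    cfg: SimulationConfig,
    subject_seed: int | np.random.SeedSequence,
    severity: float = 0.0,
) -> tuple[RoiTimeSeriesSet, NuisanceSet]:
    """ROI series with prescribed covariance plus drift and physiological noise.

    Gaussian noise is coloured by the Cholesky square root of the target
    correlation matrix, then a linear drift and cardiac/respiratory sinusoids
    (global phase, per-region loadings) are added.  The returned nuisance set
    carries sine/cosine proxies of the physiological components; the drift is
    left to polynomial detrending.
    """
    rng = np.random.default_rng(subject_seed)
    within, between = cfg._levels_at(severity)
    target = target_correlation_matrix(cfg.n_regions, cfg.n_modules, within, between)
    chol = np.linalg.cholesky(target)
    data = rng.standard_normal((cfg.n_timepoints, cfg.n_regions)) @ chol.T

    t = np.arange(cfg.n_timepoints) * cfg.sampling_interval
    ramp = t / t[-1] - 0.5
    drift_load = cfg.drift_amplitude * rng.uniform(0.5, 1.5, cfg.n_regions)
    data += np.outer(ramp, drift_load)

    nuis_cols, nuis_names = [], []
    for name, freq, amp in (
        ("cardiac", cfg.cardiac_hz, cfg.cardiac_amplitude),
        ("respiratory", cfg.respiratory_hz, cfg.respiratory_amplitude),
    ):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(2.0 * np.pi * freq * t + phase)
        load = amp * rng.uniform(0.5, 1.5, cfg.n_regions)
        data += np.outer(wave, load)
        nuis_cols += [np.sin(2.0 * np.pi * freq * t), np.cos(2.0 * np.pi * freq * t)]
        nuis_names += [f"{name}_sin", f"{name}_cos"]

    ts = RoiTimeSeriesSet(data, cfg.sampling_interval, _region_labels(cfg.n_regions))
    nuis = NuisanceSet(np.column_stack(nuis_cols), nuis_names)
    return ts, nuis


def simulate_streamline_counts(
    p_true: np.ndarray,
    voxels_per_region: np.ndarray,
    samples_per_voxel: int = 5000,
    seed: int | np.random.SeedSequence | None = 0,
    region_labels: list[str] | None = None,
) -> StreamlineCountSet:
    """Binomial streamline tallies from a directed probability matrix.

    ``counts[i, j] ~ Binomial(voxels_i * samples_per_voxel, p_true[i, j])``;
    each row of ``p_true`` must sum to at most 1 (the remainder are
    streamlines that reach no target region).
    """
    p_true = np.asarray(p_true, dtype=float)
    if np.any(p_true < 0.0) or np.any(p_true > 1.0):
        raise ValueError("directed probabilities must lie in [0, 1]")
    offdiag = p_true.copy()
    np.fill_diagonal(offdiag, 0.0)
    row_sums = offdiag.sum(axis=1)
    if np.any(row_sums > 1.0 + 1e-12):
        raise ValueError(
            f"row sums of the directed probability matrix exceed 1 "
            f"(max {row_sums.max():.4f})"
        )
    voxels = np.asarray(voxels_per_region)
    rng = np.random.default_rng(seed)
    trials = (voxels.astype(np.int64) * samples_per_voxel)[:, None]
    counts = rng.binomial(np.broadcast_to(trials, offdiag.shape), offdiag)
    np.fill_diagonal(counts, 0)
    return StreamlineCountSet(counts, voxels, samples_per_voxel, region_labels)


def simulate_motion_parameters(
    n_timepoints: int,
    step_scale: float,
    seed: int | np.random.SeedSequence | None = 0,
    sphere_radius: float = 50.0,
) -> np.ndarray:
    """Bounded (AR(1)) random-walk head-motion trace, time x 6.

    Translations in mm with innovation SD ``step_scale``; rotations in rad
    scaled by 1/sphere_radius so their arc-length FD contribution is
    commensurate.  Expected mean FD scales linearly with ``step_scale``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    innovations = rng.standard_normal((n_timepoints, 6))
    innovations[:, :3] *= step_scale
    innovations[:, 3:] *= step_scale / sphere_radius
    # AR(1) with phi = 0.97 keeps the trace bounded while preserving step scaling
    trace = _signal.lfilter([1.0], [1.0, -0.97], innovations, axis=0)
    return trace


def _structural_base(cfg: SimulationConfig) -> np.ndarray:
    """Directed base connection-probability matrix (modular, asymmetric)."""
    base = target_correlation_matrix(
        cfg.n_regions, cfg.n_modules, cfg.structural_within_p, cfg.structural_between_p
    )
    np.fill_diagonal(base, 0.0)
    # mild fixed asymmetry so the two directed probabilities genuinely differ
    n = cfg.n_regions
    skew = 1.0 + 0.2 * np.sin(np.arange(n)[:, None] - np.arange(n)[None, :])
    return base * skew


def _structural_directed(cfg: SimulationConfig, u: float) -> np.ndarray:
    planted = cfg.planted_effect
    p = _structural_base(cfg)
    if planted is not None and planted.modality == "structural":
        p = p * float(np.clip(1.0 + 0.2 * u, 0.3, 1.8))
    return np.clip(p, 0.0, 1.0)


_TRUE_METRIC_POLICY = _graph.WeightPolicy()


def _true_metric_value(cfg: SimulationConfig, u: float) -> float:
    """Designated metric evaluated on the noise-free target connectome."""
    planted = cfg.planted_effect
    assert planted is not None
    if planted.modality == "functional":
        within, between = cfg._levels_at(u)
        m = target_correlation_matrix(cfg.n_regions, cfg.n_modules, within, between)
        np.fill_diagonal(m, 0.0)
    else:
        directed = _structural_directed(cfg, u)
        m = symmetrize_connection_matrix(directed).matrix
    g = _graph.WeightedGraph(m)
    prepared = _graph.prepare_weights(g, _TRUE_METRIC_POLICY)
    if planted.metric == "global_efficiency":
        return _graph.global_efficiency(_graph.shortest_path_distances(prepared.graph))
    if planted.metric == "characteristic_path_length":
        return _graph.characteristic_path_length(_graph.shortest_path_distances(prepared.graph))
    if planted.metric == "global_clustering":
        return _graph.global_clustering(_graph.nodal_clustering(g, _TRUE_METRIC_POLICY))
    raise ValueError(f"unsupported planted metric {planted.metric!r}")


def _calibrated_noise(cfg: SimulationConfig) -> tuple[float, float, float, float, float]:
    # the calibration does not depend on the cohort seed; normalize it so the
    # cache is shared across cohorts drawn from the same design
    return _calibrated_noise_cached(replace(cfg, seed=0))


@lru_cache(maxsize=8)
def _calibrated_noise_cached(cfg: SimulationConfig) -> tuple[float, float, float, float, float]:
    """Noise level such that Spearman(behaviour, true metric) hits the target.

    The behaviour model is  b = sign * m~(u) + sum_k c_k z_k + sigma * eps
    with m~ the true metric standardized by its population moments, z_k
    independent standardized confound contributions and sigma >= 0 the
    calibrated extra noise.  A 5000-draw rehearsal evaluates the population
    Spearman as a function of sigma (monotone decreasing), solved by
    bisection to +/- 0.005.  Returns (amplitude sign, sigma, rehearsal rho,
    metric population mean, metric population SD).  Raises when even
    noise-free behaviour cannot reach the target because of the irreducible
    confound contribution.
    """
    planted = cfg.planted_effect
    assert planted is not None
    target = planted.rho

    grid_u = np.linspace(-3.0, 3.0, 25)
    grid_m = np.array([_true_metric_value(cfg, u) for u in grid_u])
    rng = np.random.default_rng(1234567)  # fixed rehearsal stream: pure in cfg
    u = np.clip(rng.standard_normal(5000), -2.5, 2.5)
    m = np.interp(u, grid_u, grid_m)
    m_mean, m_sd = float(m.mean()), float(m.std())
    if target == 0.0:
        return 0.0, 0.0, 0.0, m_mean, m_sd
    m_z = (m - m_mean) / m_sd
    conf_sd = float(np.sqrt(sum(c**2 for _, c in cfg.confound_coefs)))
    conf_noise = conf_sd * rng.standard_normal(5000)
    eps = rng.standard_normal(5000)
    sign = 1.0 if target > 0 else -1.0

    def achieved(sigma: float) -> float:
        return sign * stats.spearmanr(sign * m_z + conf_noise + sigma * eps, m).statistic

    if achieved(0.0) < abs(target) - 0.05:
        raise ValueError(
            f"target Spearman rho {target} is unachievable: the confound "
            "contribution alone caps the correlation below the target"
        )
    lo, hi = 0.0, 100.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if achieved(mid) > abs(target):
            lo = mid
        else:
            hi = mid
    sigma = (lo + hi) / 2.0
    return sign, float(sigma), float(sign * achieved(sigma)), m_mean, m_sd


def simulate_cohort_with_planted_effect(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort: imaging observables, behaviour, confounds, truth.

    Fully reproducible from ``(cfg, cfg.seed)``.  When a planted effect is
    configured, the designated behaviour tracks the designated true network
    metric at the calibrated Spearman level; all other behaviours carry only
    confound contributions and noise.
    """
    cfg = cfg or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    (
        seed_u,
        seed_conf,
        seed_beh,
        seed_struct,
        seed_ts,
        seed_motion,
    ) = root.spawn(6)

    subjects = [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]
    labels = _region_labels(cfg.n_regions)

    rng_u = np.random.default_rng(seed_u)
    u = np.clip(rng_u.standard_normal(cfg.n_subjects), -2.5, 2.5)

    # --- confounds -------------------------------------------------------
    rng_c = np.random.default_rng(seed_conf)
    age = np.clip(rng_c.normal(27.3, 2.9, cfg.n_subjects), 22.0, 33.0)
    sex = (rng_c.random(cfg.n_subjects) < 18 / 30).astype(float)  # 1 = male
    fsiq = np.clip(rng_c.normal(108.9, 7.5, cfg.n_subjects), 90.0, 130.0)
    brain_volume = np.clip(rng_c.normal(1.35e6, 1.0e5, cfg.n_subjects), 1.1e6, 1.6e6)
    step_scales = rng_c.uniform(*cfg.motion_step_range, cfg.n_subjects)

    motion_seeds = seed_motion.spawn(cfg.n_subjects)
    motion = [
        simulate_motion_parameters(cfg.n_timepoints, s, ms)
        for s, ms in zip(step_scales, motion_seeds)
    ]
    mean_fd = np.array([mean_framewise_displacement(m) for m in motion])

    confounds = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "fsiq": fsiq,
            "mean_fd": mean_fd,
            "brain_volume": brain_volume,
        },
        index=pd.Index(subjects, name="subject"),
    )

    # --- imaging ---------------------------------------------------------
    planted = cfg.planted_effect
    ts_seeds = seed_ts.spawn(cfg.n_subjects)
    timeseries, nuisance = [], []
    for i in range(cfg.n_subjects):
        sev = u[i] if (planted is not None and planted.modality == "functional") else 0.0
        ts, nuis = simulate_roi_timeseries(cfg, ts_seeds[i], severity=sev)
        # full nuisance set: physiological proxies plus the motion trace
        full = NuisanceSet(
            np.column_stack([nuis.regressors, motion[i]]),
            nuis.names + [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")],
        )
        timeseries.append(ts)
        nuisance.append(full)

    struct_seeds = seed_struct.spawn(cfg.n_subjects)
    rng_s = np.random.default_rng(seed_struct)
    counts_list, struct_truth = [], []
    for i in range(cfg.n_subjects):
        sev = u[i] if (planted is not None and planted.modality == "structural") else 0.0
        directed = _structural_directed(cfg, sev)
        voxels = rng_s.integers(
            cfg.voxels_per_region[0], cfg.voxels_per_region[1] + 1, cfg.n_regions
        )
        counts_list.append(
            simulate_streamline_counts(
                directed, voxels, cfg.samples_per_voxel, struct_seeds[i], labels
            )
        )
        struct_truth.append(symmetrize_connection_matrix(directed, labels))

    # --- behaviour -------------------------------------------------------
    rng_b = np.random.default_rng(seed_beh)
    conf_z = {
        name: (confounds[name] - confounds[name].mean()) / confounds[name].std(ddof=1)
        for name in CONFOUND_COLUMNS
    }
    coefs = dict(cfg.confound_coefs)
    conf_sd = float(np.sqrt(sum(c**2 for c in coefs.values())))
    sigma0 = float(np.sqrt(max(1.0 - conf_sd**2, 0.04)))

    true_metric = None
    behaviour = {}
    for name, (mu, sd) in MEASURE_SCALES.items():
        conf_part = sum(c * conf_z[k].to_numpy() for k, c in coefs.items())
        if planted is not None and name == planted.behaviour and planted.rho != 0.0:
            sign, sigma, _, m_mean, m_sd = _calibrated_noise(cfg)
            true_metric = np.array([_true_metric_value(cfg, ui) for ui in u])
            m_z = (true_metric - m_mean) / m_sd
            latent = sign * m_z + conf_part + sigma * rng_b.standard_normal(cfg.n_subjects)
            latent = latent / np.sqrt(1.0 + conf_sd**2 + sigma**2)  # unit-ish scale
        else:
            latent = conf_part + sigma0 * rng_b.standard_normal(cfg.n_subjects)
        behaviour[name] = mu + sd * latent
    behaviour_table = pd.DataFrame(behaviour, index=confounds.index)
    # full-scale IQ doubles as a confound, as in the real design
    behaviour_table["WASI_fsiq"] = confounds["fsiq"]

    if planted is not None and true_metric is None:
        true_metric = np.array([_true_metric_value(cfg, ui) for ui in u])

    if planted is not None:
        amp_sign, noise_sd, rehearsal_rho, _, _ = _calibrated_noise(cfg)
    else:
        amp_sign = noise_sd = rehearsal_rho = 0.0
    ground_truth = {
        "severity": u,
        "true_metric": true_metric,
        "planted_effect": planted,
        "signal_amplitude": amp_sign,
        "calibrated_noise_sd": noise_sd,
        "rehearsal_rho": rehearsal_rho,
    }

    return SyntheticCohort(
        config=cfg,
        subjects=subjects,
        timeseries=timeseries,
        nuisance=nuisance,
        motion=motion,
        streamline_counts=counts_list,
        structural_truth=struct_truth,
        behaviour=behaviour_table,
        confounds=confounds,
        ground_truth=ground_truth,
    )
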