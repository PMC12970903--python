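"""Synthetic cohorts with the statistical structure the SCN analysis assumes.

The generator emulates a three-group motor-expertise design (expert golfers,
novice golfers, non-athlete controls; 20 per group by default) with:

* correlated regional gray-matter volumes (modular block correlation
  structure on a log scale, then exponentiated so volumes are positive),
* linear covariate confounds (age, sex, total intracranial volume),
* optional planted group effects on named regions (mean shifts in SD units),
* an embedded mediation chain: training duration drives a latent
  "network tightness" variable that (i) makes a golfer's deviation pattern
  more coherent within covariance modules — which is exactly what the
  downstream clustering/local-efficiency metrics respond to — and
  (ii) feeds the stroke-performance outcome.

Every draw flows from a single seed, so a fixed config yields a
bit-identical cohort. Full ground truth (generating covariance, planted
effects, latent mediator, true indirect effect) is returned for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aal import make_region_names

GROUPS = ("expert", "novice", "control")
GOLFER_GROUPS = ("expert", "novice")
#: Fixed demographic/behavioral prefix of a cohort CSV; every later column is a region.
RESERVED_COLUMNS = (
    "subject_id", "group", "age", "sex", "tiv", "training_duration", "strokes",
)


@dataclass(frozen=True)
class CovarianceSpec:
    """Block (modular) region-region correlation structure.

    Regions are partitioned into ``n_modules`` contiguous, near-equal blocks;
    the correlation is ``within`` inside a block and ``between`` across
    blocks. ``within = between = 0`` gives independent regions.
    """

    n_modules: int = 8
    within: float = 0.60
    between: float = 0.08

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not (0.0 <= self.within < 1.0):
            raise ValueError("within-block correlation must be in [0, 1)")
        if not (0.0 <= self.between <= self.within):
            raise ValueError("between-block correlation must be in [0, within]")

    def module_assignment(self, n_regions: int) -> np.ndarray:
        """Module index (0-based) of each region, contiguous blocks."""
        return (np.arange(n_regions) * self.n_modules) // n_regions

    def correlation_matrix(self, n_regions: int) -> np.ndarray:
        mod = self.module_assignment(n_regions)
        same = mod[:, None] == mod[None, :]
        corr = np.where(same, self.within, self.between).astype(float)
        np.fill_diagonal(corr, 1.0)
        return corr


@dataclass(frozen=True)
class MediationSpec:
    """Planted standardized X -> M -> Y chain.

    X is training duration (z-scored across golfers), M the latent network
    tightness, Y the standardized stroke outcome. ``a``, ``b`` and
    ``c_prime`` are the standardized path coefficients; noise SDs default to
    the values that give M and Y unit variance. ``tightness_base`` /
    ``tightness_gain`` map M onto the mixing weight w in [0, 0.95] that
    blends a golfer's independent deviations with module-shared deviations.
    """

    a: float = 0.33
    b: float = -0.31
    c_prime: float = -0.22
    mediator_noise_sd: float | None = None
    outcome_noise_sd: float | None = None
    tightness_base: float = 0.35
    tightness_gain: float = 0.20

    @property
    def true_indirect(self) -> float:
        return self.a * self.b

    def resolved_mediator_noise(self) -> float:
        if self.mediator_noise_sd is not None:
            return self.mediator_noise_sd
        var = 1.0 - self.a**2
        if var <= 0:
            raise ValueError("|a| must be < 1 for a unit-variance mediator")
        return float(np.sqrt(var))

    def resolved_outcome_noise(self) -> float:
        if self.outcome_noise_sd is not None:
            return self.outcome_noise_sd
        total = self.c_prime + self.a * self.b
        var = 1.0 - total**2 - self.b**2 * (1.0 - self.a**2)
        if var <= 0:
            raise ValueError("mediation paths imply outcome variance <= 0")
        return float(np.sqrt(var))

    def validate(self) -> None:
        self.resolved_mediator_noise()
        self.resolved_outcome_noise()
        if not (0.0 <= self.tightness_base <= 0.95):
            raise ValueError("tightness_base must be in [0, 0.95]")


@dataclass(frozen=True)
class BehaviorParams:
    """Group means/SDs of training duration (years) and strokes per 18 holes."""

    training: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "expert": (12.4, 1.2),
        "novice": (1.8, 1.1),
        "control": (0.0, 0.0),
    })
    strokes: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "expert": (72.05, 4.3),
        "novice": (86.15, 5.63),
    })

    def validate(self) -> None:
        for grp in GOLFER_GROUPS:
            if self.training[grp][1] <= 0:
                raise ValueError(f"training-duration SD for {grp} must be > 0")
            if self.strokes[grp][1] <= 0:
                raise ValueError(f"strokes SD for {grp} must be > 0")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    ``covariate_effects`` are log-scale coefficients per standardized
    covariate (scalar, broadcast over regions, or a length-``n_regions``
    array). ``group_effects`` is a list of ``(region_index, group,
    shift_in_sd_units)`` mean shifts on the latent deviations.
    ``group_tightness`` plants a deterministic offset on the golfer groups'
    module-coherence mixing weight, on top of the duration-driven mediation
    chain: positive for experts means their deviation patterns are tighter
    within covariance modules, the condition that raises clustering and
    local efficiency downstream.
    """

    n_per_group: int = 20
    n_regions: int = 116
    covariance: CovarianceSpec = field(default_factory=CovarianceSpec)
    covariate_effects: dict[str, float | np.ndarray] = field(
        default_factory=lambda: {"age": -0.02, "sex": 0.03, "tiv": 0.15})
    group_effects: list[tuple[int, str, float]] = field(default_factory=list)
    group_tightness: dict[str, float] = field(
        default_factory=lambda: {"expert": 0.25, "novice": -0.15})
    mediation: MediationSpec | None = field(default_factory=MediationSpec)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    age_params: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "expert": (27.4, 3.1), "novice": (27.1, 2.8), "control": (27.6, 2.2),
    })
    tiv_mean: float = 1.45e6
    tiv_sd: float = 1.3e5
    latent_sd: float = 0.06     # log-scale SD of regional volumes
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4")
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        self.covariance.validate()
        self.behavior.validate()
        if self.mediation is not None:
            self.mediation.validate()
        for grp, (_, sd) in self.age_params.items():
            if sd <= 0:
                raise ValueError(f"age SD for {grp} must be > 0")
        if self.tiv_sd <= 0 or self.latent_sd <= 0:
            raise ValueError("tiv_sd and latent_sd must be > 0")
        for name in self.covariate_effects:
            if name not in ("age", "sex", "tiv"):
                raise ValueError(f"unknown covariate effect: {name}")
        for region, grp, _ in self.group_effects:
            if not (0 <= region < self.n_regions):
                raise ValueError(f"group-effect region {region} out of range")
            if grp not in GROUPS:
                raise ValueError(f"group-effect group {grp!r} not in {GROUPS}")
        for grp in self.group_tightness:
            if grp not in GOLFER_GROUPS:
                raise ValueError(
                    f"group_tightness applies to golfer groups only, got {grp!r}")


@dataclass
class CohortTable:
    """Subjects x regions volume table plus covariates, labels and behavior."""

    frame: pd.DataFrame
    region_labels: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        missing_regions = [r for r in self.region_labels if r not in self.frame.columns]
        if missing_regions:
            raise ValueError(f"cohort table missing region columns: {missing_regions[:5]}")
        bad_groups = set(self.frame["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(
                f"unknown group labels {sorted(bad_groups)}; accepted: {list(GROUPS)}")
        if self.frame["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id values")
        for cov in ("age", "sex", "tiv"):
            if self.frame[cov].isna().any():
                raise ValueError(f"missing values in covariate {cov!r}")
        vols = self.volumes
        if not np.all(np.isfinite(vols)):
            bad = np.argwhere(~np.isfinite(vols))[0]
            raise ValueError(
                f"non-finite volume for subject "
                f"{self.frame['subject_id'].iloc[bad[0]]!r}, "
                f"region {self.region_labels[bad[1]]!r}")
        if np.any(vols <= 0):
            bad = np.argwhere(vols <= 0)[0]
            raise ValueError(
                f"non-positive volume for subject "
                f"{self.frame['subject_id'].iloc[bad[0]]!r}, "
                f"region {self.region_labels[bad[1]]!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def volumes(self) -> np.ndarray:
        return self.frame[self.region_labels].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; accepted: {list(GROUPS)}")
        return self.groups == group

    def covariate_matrix(self, covariates: list[str]) -> np.ndarray:
        missing = [c for c in covariates if c not in self.frame.columns]
        if missing:
            raise ValueError(f"covariates not in cohort table: {missing}")
        return self.frame[list(covariates)].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        cols = list(RESERVED_COLUMNS) + list(self.region_labels)
        self.frame[cols].to_csv(path, index=False)


@dataclass
class GroundTruth:
    """Everything the generator knew: for tests, never for the analysis."""

    true_covariance: np.ndarray
    planted_effects: list[tuple[int, str, float]]
    true_indirect: float
    latent_mediator: np.ndarray     # per subject; NaN for controls / no chain
    mixing_weight: np.ndarray       # per subject tightness weight w in [0, 0.95]
    module_assignment: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_covariance": self.true_covariance.tolist(),
            "planted_effects": [list(e) for e in self.planted_effects],
            "true_indirect": self.true_indirect,
            "latent_mediator": [None if np.isnan(v) else float(v)
                                for v in self.latent_mediator],
            "mixing_weight": self.mixing_weight.tolist(),
            "module_assignment": self.module_assignment.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


#: golfer mixing-weight baseline used when no mediation chain is configured
_BASELINE_TIGHTNESS = 0.35


def _sample_balanced_sex(n: int) -> np.ndarray:
    # 0/1 alternating -> balanced to within one subject for odd n
    return np.arange(n) % 2


def generate_cohort(config: CohortConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort from ``config``; deterministic for a fixed seed.

    Controls are drawn exactly from the block covariance (mixing weight 0),
    so their sample correlations converge to ``config.covariance`` as the
    group grows; the tightness/mediation mechanism acts on golfers only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, n = config.n_regions, config.n_per_group
    N = 3 * n

    corr = config.covariance.correlation_matrix(R)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance_spec does not define a positive-definite correlation "
            f"matrix (n_modules={config.covariance.n_modules}, "
            f"within={config.covariance.within}, "
            f"between={config.covariance.between})") from exc
    modules = config.covariance.module_assignment(R)

    groups = np.repeat(list(GROUPS), n)
    subject_ids = np.array([f"S{i + 1:03d}" for i in range(N)])

    age = np.empty(N)
    duration = np.empty(N)
    for grp in GROUPS:
        mask = groups == grp
        mu, sd = config.age_params[grp]
        age[mask] = rng.normal(mu, sd, mask.sum())
        mu_d, sd_d = config.behavior.training[grp]
        if sd_d > 0:
            duration[mask] = np.clip(rng.normal(mu_d, sd_d, mask.sum()), 0.0, None)
        else:
            duration[mask] = mu_d
    sex = np.concatenate([_sample_balanced_sex(n) for _ in GROUPS]).astype(float)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, N)

    golfers = np.isin(groups, GOLFER_GROUPS)
    n_golf = int(golfers.sum())
    latent_m = np.full(N, np.nan)
    weight = np.zeros(N)
    offset = np.zeros(N)
    for grp, shift in config.group_tightness.items():
        offset[groups == grp] = shift
    if config.mediation is not None:
        med = config.mediation
        x = duration[golfers]
        x_sd = x.std(ddof=0)
        if x_sd == 0:
            raise ValueError("training duration is constant across golfers; "
                             "cannot plant a mediation chain")
        xz = (x - x.mean()) / x_sd
        m = med.a * xz + med.resolved_mediator_noise() * rng.standard_normal(n_golf)
        latent_m[golfers] = m
        weight[golfers] = np.clip(
            med.tightness_base + med.tightness_gain * m + offset[golfers],
            0.0, 0.95)
    else:
        weight[golfers] = np.clip(
            _BASELINE_TIGHTNESS + offset[golfers], 0.0, 0.95)

    eps = rng.standard_normal((N, R)) @ chol.T
    shared = rng.standard_normal((N, config.covariance.n_modules))
    u = shared[:, modules]
    delta = (np.sqrt(1.0 - weight)[:, None] * eps
             + np.sqrt(weight)[:, None] * u)

    for region, grp, shift in config.group_effects:
        delta[groups == grp, region] += shift

    # deterministic base volumes spanning a realistic mm^3 range
    base = 3000.0 * np.exp(np.log(4.0) * np.arange(R) / max(R - 1, 1))
    log_v = np.log(base)[None, :] + config.latent_sd * delta

    cov_z = {
        "age": (age - 27.4) / 3.0,
        "sex": sex - 0.5,
        "tiv": (tiv - config.tiv_mean) / config.tiv_sd,
    }
    for name, coef in config.covariate_effects.items():
        coef_arr = np.broadcast_to(np.asarray(coef, dtype=float), (R,))
        log_v = log_v + cov_z[name][:, None] * coef_arr[None, :]
    volumes = np.exp(log_v)

    strokes = np.full(N, np.nan)
    if config.mediation is not None:
        med = config.mediation
        yz = (med.c_prime * xz + med.b * latent_m[golfers]
              + med.resolved_outcome_noise() * rng.standard_normal(n_golf))
        s0 = float(np.mean([config.behavior.strokes[g][0] for g in GOLFER_GROUPS]))
        s1 = float(np.mean([config.behavior.strokes[g][1] for g in GOLFER_GROUPS]))
        strokes[golfers] = s0 + s1 * yz
    else:
        for grp in GOLFER_GROUPS:
            mask = groups == grp
            mu_s, sd_s = config.behavior.strokes[grp]
            strokes[mask] = rng.normal(mu_s, sd_s, mask.sum())

    labels = make_region_names(R)
    frame = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "age": age,
        "sex": sex,
        "tiv": tiv,
        "training_duration": duration,
        "strokes": strokes,
    })
    frame = pd.concat([frame, pd.DataFrame(volumes, columns=labels)], axis=1)

    truth = GroundTruth(
        true_covariance=corr,
        planted_effects=list(config.group_effects),
        true_indirect=(config.mediation.true_indirect
                       if config.mediation is not None else 0.0),
        latent_mediator=latent_m,
        mixing_weight=weight,
        module_assignment=modules,
    )
    return CohortTable(frame=frame, region_labels=labels), truth
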