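"""End-to-end orchestration: cohort -> individual SCNs -> AUC metrics ->
group comparison -> correlations -> mediation.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so downstream stages can be rerun from cached upstream files
with identical results. All randomness derives from a single root seed
split into fixed per-stage substreams; outputs carry no timestamps, making
a fixed (config, seed) run byte-reproducible. A manifest records the config
echo, per-stage row counts, flagged sparsity levels, and a SHA-256 checksum
inventory of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph_metrics import (ALL_METRICS, SparsityGrid, cohort_auc_table,
                            validate_sparsity_grid)
from .group_stats import compare_cohorts, gated_correlation
from .mediation import bootstrap_indirect, mediator_key, select_mediators
from .scn import build_group_scn, build_individual_scns, control_reference, residualize
from .synthetic_data import (GOLFER_GROUPS, GROUPS, RESERVED_COLUMNS,
                             CohortConfig, CohortTable, generate_cohort)

log = logging.getLogger("scnkit")

_STAGE_NAMES = ("simulate", "build_scn", "metrics", "compare", "mediate")


@dataclass
class PipelineConfig:
    """Knobs of a full analysis run; see module docstrings for semantics."""

    out_dir: str = "scnkit_run"
    cohort_csv: str | None = None          # user cohort; None -> synthetic
    synthetic: CohortConfig = field(default_factory=CohortConfig)
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "tiv"])
    esd_transform: str = "exponential"
    binarization: str = "absolute"         # absolute | positive
    k_min: float = 0.14
    k_max: float = 0.50
    step: float = 0.01
    metrics: tuple[str, ...] = ALL_METRICS
    n_perm: int = 5000
    n_boot: int = 5000
    fdr_mode: str = "within-family"
    alpha: float = 0.05
    validate_grid: bool = True
    n_random_surrogates: int = 20
    mediation_groups: tuple[str, ...] = GOLFER_GROUPS
    primary_mediator: str = "Cp"           # always fitted, besides selected ones
    seed: int = 0

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.k_min, self.k_max, self.step)

    def stage_seed(self, stage: str) -> int:
        idx = _STAGE_NAMES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGE_NAMES))[idx]
        return int(child.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            from .synthetic_data import BehaviorParams, CovarianceSpec, MediationSpec
            cov = synth.pop("covariance", None)
            med = synth.pop("mediation", "unset")
            beh = synth.pop("behavior", None)
            sc = CohortConfig(**synth)
            if cov is not None:
                sc.covariance = CovarianceSpec(**cov)
            if med != "unset":
                sc.mediation = None if med is None else MediationSpec(**med)
            if beh is not None:
                sc.behavior = BehaviorParams(**beh)
            cfg.synthetic = sc
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["synthetic"]["covariate_effects"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d["synthetic"]["covariate_effects"].items()}
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict[str, int]
    flagged_k: list[float]
    files: dict[str, str]      # relative path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_cohort_csv(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV.

    The reserved column prefix is ``subject_id, group, age, sex, tiv,
    training_duration, strokes``; every subsequent column is a region.
    Behavioral columns may be empty for controls only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort CSV not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in RESERVED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    region_labels = [c for c in frame.columns if c not in RESERVED_COLUMNS]
    if not region_labels:
        raise ValueError("cohort CSV has no region columns after the "
                         f"reserved prefix {list(RESERVED_COLUMNS)}")
    bad = sorted(set(frame["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown group label(s) {bad}; accepted labels: "
                         f"{list(GROUPS)}")
    for col in region_labels:
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"non-numeric or missing volume at row {row} "
                f"(subject {frame['subject_id'].iloc[row]!r}), column {col!r}: "
                f"{frame[col].iloc[row]!r}")
        frame[col] = vals
    golfer = frame["group"].isin(GOLFER_GROUPS)
    for col in ("training_duration", "strokes"):
        bad_rows = frame.loc[golfer, col].isna()
        if bad_rows.any():
            row = int(bad_rows.idxmax())
            raise ValueError(f"missing {col!r} for non-control subject "
                             f"{frame['subject_id'].iloc[row]!r} (row {row})")
    return CohortTable(frame=frame, region_labels=region_labels)


def stage_simulate(config: PipelineConfig) -> CohortTable:
    """Write cohort.csv (+ ground_truth.json when synthetic)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.cohort_csv is not None:
        cohort = load_cohort_csv(config.cohort_csv)
        cohort.to_csv(out / "cohort.csv")
        log.info("simulate: loaded %d subjects x %d regions from %s",
                 cohort.n_subjects, cohort.n_regions, config.cohort_csv)
        return cohort
    synth = config.synthetic
    synth.seed = config.stage_seed("simulate")
    cohort, truth = generate_cohort(synth)
    cohort.to_csv(out / "cohort.csv")
    truth.to_json(out / "ground_truth.json")
    log.info("simulate: generated %d subjects x %d regions",
             cohort.n_subjects, cohort.n_regions)
    return cohort


def stage_build_scn(config: PipelineConfig) -> None:
    """cohort.csv -> group_scn.csv + scn/<subject>.csv for comparison groups."""
    out = Path(config.out_dir)
    cohort = load_cohort_csv(out / "cohort.csv")
    residual_table, coef = residualize(cohort, config.covariates)
    controls = residual_table.subset(cohort.group_mask("control"))
    group_scn = build_group_scn(controls)
    ref = control_reference(controls, coef, config.covariates)
    group_scn.to_csv(out / "group_scn.csv")
    scn_dir = out / "scn"
    scn_dir.mkdir(exist_ok=True)
    subjects = cohort.subject_ids[np.isin(cohort.groups, GOLFER_GROUPS)]
    for scn in build_individual_scns(residual_table, ref, group_scn,
                                     subjects, config.esd_transform):
        scn.to_csv(scn_dir / f"{scn.subject_id}.csv")
    log.info("build_scn: wrote group SCN and %d individual SCNs", len(subjects))


def _read_matrix_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, index_col=0)
    return frame.to_numpy(dtype=float), list(frame.columns)


def stage_metrics(config: PipelineConfig) -> None:
    """scn/*.csv -> curves.csv, auc.csv (+ validation.csv)."""
    out = Path(config.out_dir)
    cohort = load_cohort_csv(out / "cohort.csv")
    groups = dict(zip(cohort.subject_ids, cohort.groups))
    scn_files = sorted((out / "scn").glob("*.csv"))
    if not scn_files:
        raise FileNotFoundError(f"no individual SCNs under {out / 'scn'}; "
                                "run the build-scn stage first")
    from .scn import IndividualSCN
    scns = []
    for f in scn_files:
        matrix, labels = _read_matrix_csv(f)
        scns.append(IndividualSCN(subject_id=f.stem, weight_matrix=np.ones_like(matrix),
                                  matrix=matrix, region_labels=labels))
    grid = config.grid
    curves, aucs = cohort_auc_table(scns, groups, grid, mode=config.binarization,
                                    metrics=config.metrics)
    curves.to_csv(out / "curves.csv", index=False)
    aucs.to_csv(out / "auc.csv", index=False)
    log.info("metrics: %d curve rows, %d AUC rows", len(curves), len(aucs))
    if config.validate_grid:
        report = validate_sparsity_grid(
            [s.matrix for s in scns], grid, mode=config.binarization,
            n_random=config.n_random_surrogates,
            seed=config.stage_seed("metrics"))
        report.to_csv(out / "validation.csv", index=False)
        flagged = report.loc[report["flagged"], "k"].tolist()
        if flagged:
            log.warning("metrics: %d sparsity levels flagged: %s",
                        len(flagged), flagged)


def stage_compare(config: PipelineConfig) -> pd.DataFrame:
    """auc.csv -> comparisons.csv (expert vs novice, permutation + FDR + d)."""
    out = Path(config.out_dir)
    aucs = pd.read_csv(out / "auc.csv", keep_default_na=False)
    comparisons = compare_cohorts(aucs, group_a="expert", group_b="novice",
                                  n_perm=config.n_perm,
                                  seed=config.stage_seed("compare"),
                                  fdr_mode=config.fdr_mode)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    log.info("compare: %d comparisons, %d significant at FDR %.2f",
             len(comparisons), int((comparisons["p_fdr"] < config.alpha).sum()),
             config.alpha)
    return comparisons


def stage_mediate(config: PipelineConfig) -> dict:
    """auc.csv + comparisons.csv + cohort.csv -> correlations.csv, mediation.json.

    Correlations (normality-gated) of each candidate metric AUC with
    training duration and strokes are computed over the mediation groups;
    mediators must associate with both. The primary mediator (global Cp by
    default) is always fitted in addition to any selected ones.
    """
    out = Path(config.out_dir)
    cohort = load_cohort_csv(out / "cohort.csv")
    aucs = pd.read_csv(out / "auc.csv", keep_default_na=False)
    comparisons = pd.read_csv(out / "comparisons.csv", keep_default_na=False)

    mask = np.isin(cohort.groups, list(config.mediation_groups))
    subjects = cohort.subject_ids[mask]
    behav = cohort.frame.set_index("subject_id").loc[subjects]
    x = behav["training_duration"].to_numpy(float)
    y = behav["strokes"].to_numpy(float)

    wide = aucs.pivot_table(index="subject_id", columns=["metric", "node"],
                            values="auc", aggfunc="first").loc[subjects]

    candidates = {mediator_key(m, n): (m, n)
                  for m, n in wide.columns
                  if n == ""}      # all global metrics
    for _, row in comparisons.iterrows():
        if row["p_fdr"] < config.alpha:
            candidates[mediator_key(row["metric"], row["node"])] = (
                row["metric"], row["node"])

    corr_rows = []
    for key, (metric, node) in sorted(candidates.items()):
        m_vals = wide[(metric, node)].to_numpy(float)
        for var_name, var in (("training_duration", x), ("strokes", y)):
            r = gated_correlation(m_vals, var, name_x=key, name_y=var_name)
            corr_rows.append(asdict(r))
    correlations = pd.DataFrame(corr_rows)
    correlations.to_csv(out / "correlations.csv", index=False)

    selected = select_mediators(comparisons, correlations, alpha=config.alpha)
    to_fit = list(dict.fromkeys([config.primary_mediator] + selected))
    seed = config.stage_seed("mediate")
    results = {"selected_mediators": selected, "models": {}}
    for key in to_fit:
        metric, node = candidates.get(key, (key, ""))
        if (metric, node) not in wide.columns:
            continue
        m_vals = wide[(metric, node)].to_numpy(float)
        res = bootstrap_indirect(x, m_vals, y, n_boot=config.n_boot, seed=seed)
        results["models"][key] = asdict(res)
    (out / "mediation.json").write_text(json.dumps(results, indent=2))
    log.info("mediate: selected %s; fitted %s", selected, to_fit)
    return results


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order and write the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = stage_simulate(config)
    n_controls = int(cohort.group_mask("control").sum())
    if n_controls < len(config.covariates) + 2:
        raise ValueError("pipeline requires a control group with at least "
                         f"{len(config.covariates) + 2} subjects")
    stage_build_scn(config)
    stage_metrics(config)
    comparisons = stage_compare(config)
    mediation = stage_mediate(config)

    flagged: list[float] = []
    if config.validate_grid:
        report = pd.read_csv(out / "validation.csv")
        flagged = report.loc[report["flagged"], "k"].tolist()

    counts = {
        "subjects": cohort.n_subjects,
        "regions": cohort.n_regions,
        "comparisons": len(comparisons),
        "mediation_models": len(mediation["models"]),
    }
    files = {}
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            files[str(f.relative_to(out))] = _sha256(f)
    manifest = RunManifest(config=config.echo(), version=__version__,
                           seed=config.seed, stage_counts=counts,
                           flagged_k=flagged, files=files)
    manifest.to_json(out / "manifest.json")
    return manifest
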