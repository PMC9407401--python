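"""Stage orchestration: config, artifact IO and the end-to-end pipeline.

Stages (mirrored by the command-line interface):

* ``simulate`` — write a synthetic connectome, subject time series, task
  design and manifest from a :class:`~boldcomplexity.synthetic.SyntheticSpec`;
* ``complexity`` — per-subject complexity maps (H, β, MSE/CI);
* ``glm`` — residual time series after regressing out a task design;
* ``surrogate`` — sign-vector ensembles per subject (manifest + TSV);
* ``group`` — surrogate-null thresholding and binomial group testing;
* ``classify`` — pairwise SVM loss matrix over per-run feature tables;
* ``report`` — aggregate a run directory into one JSON summary.

Every stage is deterministic given (config, seed) and echoes the resolved
configuration beside its outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as bc_io
from .complexity import (
    DEFAULT_BAND,
    DEFAULT_M,
    DEFAULT_R_FRAC,
    DEFAULT_SCALES,
    complexity_index,
    complexity_map,
    dfa_hurst_batch,
    mse_curve,
)
from .containers import RoiTimeSeries, StructuralConnectome
from .exceptions import ValidationError
from .glm import build_design, regress_out
from .inference import group_map, rsn_percentages, threshold_subject
from .surrogates import GraphBasis, basis_from_connectome, surrogate_ensemble
from .synthetic import SyntheticSpec, gen_connectome, gen_population

logger = logging.getLogger("boldcomplexity")

STAGES = ("simulate", "complexity", "glm", "surrogate", "group",
          "classify", "report")

STATISTICS = ("complexity_index", "hurst")


@dataclass
class PipelineConfig:
    """Validated parameters for every stage; unused sections may stay None."""

    out_dir: str = "."
    seed: int = 0
    # synthetic
    synthetic: Optional[dict] = None
    n_subj: int = 10
    connectome_density: float = 0.3
    # estimators
    dfa_n_windows: int = 15
    dfa_detrend_order: int = 1
    psd_band: tuple[float, float] = DEFAULT_BAND
    mse_scales: tuple[int, ...] = tuple(DEFAULT_SCALES)
    mse_m: int = DEFAULT_M
    mse_r_frac: float = DEFAULT_R_FRAC
    # surrogates
    n_surr: int = 100
    laplacian_variant: str = "normalized"
    # inference
    statistic: str = "complexity_index"
    alpha_subj: float = 0.01
    alpha_group: float = 0.001
    n_comparisons: int = 1
    # classifier
    cv_folds: int = 5
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        for name in ("alpha_subj", "alpha_group"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {value}")
        if self.statistic not in STATISTICS:
            raise ValidationError(
                f"statistic must be one of {STATISTICS}, got {self.statistic!r}")
        if self.kernel not in ("rbf", "linear"):
            raise ValidationError("kernel must be 'rbf' or 'linear'")
        if self.n_surr < 1:
            raise ValidationError("n_surr must be ≥ 1")
        if self.n_subj < 1:
            raise ValidationError("n_subj must be ≥ 1")
        if self.n_comparisons < 1:
            raise ValidationError("n_comparisons must be ≥ 1")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["psd_band"] = list(self.psd_band)
        d["mse_scales"] = list(self.mse_scales)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "psd_band" in raw:
            raw["psd_band"] = tuple(raw["psd_band"])
        if "mse_scales" in raw:
            raw["mse_scales"] = tuple(raw["mse_scales"])
        return cls(**raw)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# statistic maps and surrogate nulls
# ---------------------------------------------------------------------------

def statistic_map(
    data: RoiTimeSeries,
    statistic: str = "complexity_index",
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = DEFAULT_M,
    r_frac: float = DEFAULT_R_FRAC,
    n_windows: int = 15,
    detrend_order: int = 1,
) -> np.ndarray:
    """Per-ROI subject-level statistic (complexity index or DFA Hurst)."""
    if statistic == "hurst":
        return dfa_hurst_batch(data.values, n_windows=n_windows,
                               detrend_order=detrend_order)
    if statistic == "complexity_index":
        return np.array([
            complexity_index(mse_curve(data.values[:, j], scales=scales,
                                       m=m, r_frac=r_frac))
            for j in range(data.n_roi)])
    raise ValidationError(f"unknown statistic {statistic!r}")


def surrogate_null(
    data: RoiTimeSeries,
    basis: GraphBasis,
    n_surr: int,
    master_seed: int,
    statistic: str = "complexity_index",
    **params,
) -> np.ndarray:
    """(n_surr × n_roi) statistic matrix over a surrogate ensemble.

    For the Hurst statistic all surrogates are concatenated column-wise and
    estimated in a single batched DFA call.
    """
    ensemble = surrogate_ensemble(data, basis, n_surr=n_surr,
                                  master_seed=master_seed)
    if statistic == "hurst":
        stacked = np.concatenate([s.values for s in ensemble], axis=1)
        flat = dfa_hurst_batch(
            stacked,
            n_windows=params.get("n_windows", 15),
            detrend_order=params.get("detrend_order", 1))
        return flat.reshape(n_surr, data.n_roi)
    return np.vstack([
        statistic_map(s, statistic=statistic, **params) for s in ensemble])


def detection_pipeline(
    population: Sequence[RoiTimeSeries],
    basis: GraphBasis,
    n_surr: int,
    master_seed: int,
    alpha_subj: float,
    alpha_group: float,
    n_comparisons: int,
    statistic: str = "complexity_index",
    **params,
):
    """Subject-level surrogate thresholding + binomial group map.

    Surrogate ensembles for subject ``i`` are seeded with
    ``master_seed + i`` so the whole pipeline is reproducible from one seed.
    """
    binary_maps = []
    for i, subject in enumerate(population):
        observed = statistic_map(subject, statistic=statistic, **params)
        null = surrogate_null(subject, basis, n_surr, master_seed + i,
                              statistic=statistic, **params)
        binary_maps.append(threshold_subject(observed, null, alpha_subj))
    return group_map(np.asarray(binary_maps, dtype=int), alpha_subj,
                     alpha_group, n_comparisons,
                     roi_labels=population[0].roi_labels)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig) -> list[Path]:
    out = _outdir(config)
    if config.synthetic is None:
        raise ValidationError("simulate stage requires a 'synthetic' section")
    spec = SyntheticSpec.from_dict(config.synthetic)
    connectome = gen_connectome(spec.n_roi, config.connectome_density,
                                seed=config.seed)
    population = gen_population(spec, connectome, config.n_subj,
                                seed=config.seed)
    written = []
    path = out / "connectome.tsv"
    bc_io.write_connectome(connectome, path)
    written.append(path)
    for i, subject in enumerate(population):
        path = out / f"subject{i:03d}.tsv"
        bc_io.write_timeseries(subject, path)
        written.append(path)
    if spec.task_design is not None:
        path = out / "task_design.json"
        bc_io.write_task_design(spec.task_design, path)
        written.append(path)
    manifest = {"spec": spec.to_dict(), "n_subj": config.n_subj,
                "connectome_density": config.connectome_density,
                "seed": config.seed}
    bc_io.write_json(manifest, out / "manifest.json")
    written.append(out / "manifest.json")
    config.write(out / "config_resolved.yaml")
    logger.info("simulate: wrote %d files to %s", len(written), out)
    return written


def _estimator_kwargs(config: PipelineConfig) -> dict:
    return dict(n_windows=config.dfa_n_windows,
                detrend_order=config.dfa_detrend_order,
                band=config.psd_band, scales=config.mse_scales,
                m=config.mse_m, r_frac=config.mse_r_frac)


def run_complexity(config: PipelineConfig,
                   data_files: Sequence[str | Path]) -> list[Path]:
    out = _outdir(config)
    written = []
    for path in data_files:
        data = bc_io.read_timeseries(path)
        cmap = complexity_map(data, **_estimator_kwargs(config))
        stem = Path(path).stem
        map_path = out / f"{stem}_complexity.tsv"
        cmap.to_frame().to_csv(map_path, sep="\t", index=False,
                               float_format="%.10g")
        mse_path = out / f"{stem}_mse.tsv"
        cmap.mse_frame().to_csv(mse_path, sep="\t", index=False,
                                float_format="%.10g")
        bc_io.write_json(cmap.metadata, out / f"{stem}_params.json")
        written.extend([map_path, mse_path])
    config.write(out / "config_resolved.yaml")
    logger.info("complexity: %d runs processed", len(data_files))
    return written


def run_glm(config: PipelineConfig, data_files: Sequence[str | Path],
            design_file: str | Path, trialwise: bool = True) -> list[Path]:
    out = _outdir(config)
    design = bc_io.read_task_design(design_file)
    written = []
    for path in data_files:
        data = bc_io.read_timeseries(path)
        dm = build_design(design, data.n_time, trialwise=trialwise)
        residuals = regress_out(data, dm)
        res_path = out / f"{Path(path).stem}_residuals.tsv"
        bc_io.write_timeseries(residuals, res_path)
        written.append(res_path)
    config.write(out / "config_resolved.yaml")
    logger.info("glm: %d runs regressed", len(data_files))
    return written


def run_surrogate(config: PipelineConfig, data_files: Sequence[str | Path],
                  connectome_file: str | Path) -> list[Path]:
    out = _outdir(config)
    connectome = bc_io.read_connectome(connectome_file)
    basis = basis_from_connectome(connectome,
                                  variant=config.laplacian_variant)
    written = []
    for i, path in enumerate(data_files):
        data = bc_io.read_timeseries(path)
        ens = surrogate_ensemble(data, basis, n_surr=config.n_surr,
                                 master_seed=config.seed + i)
        stem = Path(path).stem
        sign_path = out / f"{stem}_signs.tsv"
        bc_io.write_matrix_tsv(ens.sign_vectors, sign_path,
                               columns=connectome.roi_labels)
        bc_io.write_json({"n_surr": config.n_surr,
                          "master_seed": config.seed + i,
                          "laplacian_variant": config.laplacian_variant,
                          "data_file": str(path)},
                         out / f"{stem}_surrogates.json")
        written.append(sign_path)
    config.write(out / "config_resolved.yaml")
    logger.info("surrogate: %d ensembles written", len(data_files))
    return written


def run_group(config: PipelineConfig, data_files: Sequence[str | Path],
              connectome_file: str | Path,
              partition_file: Optional[str | Path] = None) -> list[Path]:
    out = _outdir(config)
    connectome = bc_io.read_connectome(connectome_file)
    basis = basis_from_connectome(connectome,
                                  variant=config.laplacian_variant)
    population = [bc_io.read_timeseries(p) for p in data_files]
    detection = detection_pipeline(
        population, basis, config.n_surr, config.seed,
        config.alpha_subj, config.alpha_group, config.n_comparisons,
        statistic=config.statistic, scales=config.mse_scales,
        m=config.mse_m, r_frac=config.mse_r_frac,
        n_windows=config.dfa_n_windows,
        detrend_order=config.dfa_detrend_order)
    det_path = out / "group_detections.tsv"
    detection.to_frame().to_csv(det_path, sep="\t", index=False)
    written = [det_path]
    if partition_file is not None:
        partition = bc_io.read_partition(partition_file)
        rsn_path = out / "rsn_percentages.csv"
        rsn_percentages(detection, partition).to_csv(rsn_path, index=False)
        written.append(rsn_path)
    config.write(out / "config_resolved.yaml")
    logger.info("group: threshold_n=%d, %d suprathreshold ROI(s)",
                detection.threshold_n, int(detection.suprathreshold.sum()))
    return written


def run_classify(config: PipelineConfig,
                 feature_files: dict[str, str | Path]) -> list[Path]:
    from .classify import loss_matrix

    out = _outdir(config)
    features = {name: bc_io.read_matrix_tsv(path).to_numpy(dtype=float)
                for name, path in feature_files.items()}
    result = loss_matrix(features, cv_folds=config.cv_folds,
                         kernel=config.kernel, seed=config.seed)
    loss_path = out / "loss_matrix.csv"
    result.to_frame().to_csv(loss_path)
    bc_io.write_json(result.selected_params, out / "selected_params.json")
    config.write(out / "config_resolved.yaml")
    logger.info("classify: %d runs, mean off-diagonal loss %.3f",
                len(result.runs),
                float(np.nanmean(result.loss)))
    return [loss_path]


def run_stage(name: str, config: PipelineConfig, **kwargs):
    """Dispatch a stage by name (simulate | complexity | glm | surrogate |
    group | classify | report); stage-specific inputs go in ``kwargs``.

    Missing upstream artifacts surface as errors naming the file, so the
    producing stage is evident from the artifact's conventional name.
    """
    dispatch = {
        "simulate": run_simulate,
        "complexity": run_complexity,
        "glm": run_glm,
        "surrogate": run_surrogate,
        "group": run_group,
        "classify": run_classify,
        "report": run_report,
    }
    if name not in dispatch:
        raise ValidationError(f"unknown stage {name!r}; one of {STAGES}")
    for key in ("data_files", "connectome_file", "design_file",
                "partition_file", "run_dir"):
        value = kwargs.get(key)
        paths = value if isinstance(value, (list, tuple)) else [value]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ValidationError(
                    f"stage {name!r}: missing input {p} — run the stage "
                    "that produces it first (simulate/complexity/surrogate)")
    return dispatch[name](config, **kwargs)


def run_report(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Aggregate the text artifacts of a run directory into one JSON."""
    run_dir = Path(run_dir)
    summary: dict = {"run_dir": str(run_dir), "artifacts": {}}
    for pattern in ("*_complexity.tsv", "group_detections.tsv",
                    "loss_matrix.csv", "rsn_percentages.csv"):
        for path in sorted(run_dir.glob(pattern)):
            import pandas as pd

            df = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
            numeric = df.select_dtypes("number")
            summary["artifacts"][path.name] = {
                "rows": int(len(df)),
                "columns": list(df.columns),
                "means": {c: float(numeric[c].mean()) for c in numeric.columns},
            }
    out = _outdir(config) / "report.json"
    bc_io.write_json(summary, out)
    logger.info("report: %d artifacts summarised", len(summary["artifacts"]))
    return out
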