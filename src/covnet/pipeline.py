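"""End-to-end orchestration of the group network comparison.

One run covers, per imaging modality: deconfounding, group-level sparse
precision estimation for both groups, bootstrap edge-difference detection,
and then a pooled network summary and (when any edge is flagged) the
brain-behavior CCA.  The full-sample analysis and the diagnosis-positive
subsample analysis are the same pipeline with a subgroup filter.

All randomness flows from a single seed through named substreams, so e.g.
changing the bootstrap replicate count does not perturb fold assignment.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .atlas import RoiAtlas
from .cca import BEHAVIOR_COLUMNS, CcaResult, build_feature_sets, run_cca, variate_loadings
from .deconfound import deconfound_structural, deconfound_timeseries
from .extract import MEASURES, StructuralMatrix, TimeSeriesSet, condition_timeseries
from .groupdiff import (
    EdgeDifferenceResult,
    EstimatorConfig,
    compare_groups,
    group_matrix,
    roi_mean_tests,
)
from .netsummary import NetworkSummary, summarize
from .precision import PrecisionModel, fit_group_network
from .simulate import StudyData, substream

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    modalities: tuple[str, ...] = ("GMM", "GMV", "GMD", "RS")
    subgroup: str = "all"  # "all" or "diagnosis_only"
    n_boot: int = 10_000
    alpha_sig: float = 1e-5
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    n_discard: int = 4
    band: tuple[float, float] = (0.01, 0.08)
    cca_threshold: float = 0.2
    cca_allow_overfit: bool = False
    cca_structural_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subgroup not in ("all", "diagnosis_only"):
            raise ValueError("subgroup must be 'all' or 'diagnosis_only'")
        unknown = set(self.modalities) - set(MEASURES) - {"RS"}
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")


@dataclass
class ModalityResult:
    modality: str
    model_v: PrecisionModel
    model_nv: PrecisionModel
    edges: EdgeDifferenceResult
    roi_tests: pd.DataFrame


@dataclass
class RunResult:
    per_modality: dict[str, ModalityResult]
    summary: NetworkSummary
    cca: CcaResult | None
    cca_loadings: pd.DataFrame | None
    config: PipelineConfig
    manifest: dict


def config_from_manifest(manifest: dict) -> PipelineConfig:
    """Rebuild the exact run configuration from a run manifest."""
    raw = dict(manifest["config"])
    est = raw.pop("estimator")
    raw["modalities"] = tuple(raw["modalities"])
    raw["band"] = tuple(raw["band"])
    return PipelineConfig(estimator=EstimatorConfig(**est), **raw)


def _seed_for(cfg: PipelineConfig, name: str) -> int:
    # small deterministic per-stage seed derived from the master seed
    return int(substream(cfg.seed, name).integers(0, 2**31 - 1))


def run_pipeline(
    study: StudyData, cfg: PipelineConfig, atlas: RoiAtlas | None = None
) -> RunResult:
    """Run the full comparison on an in-memory study dataset."""
    from .simulate import make_test_atlas

    atlas = atlas or make_test_atlas()
    phen = study.phenotype
    if cfg.subgroup == "diagnosis_only":
        keep = phen.index[phen["diagnosis_current"]]
        logger.info("diagnosis-positive subgroup: %d subjects", len(keep))
    else:
        keep = phen.index
    subjects_v = sorted(phen.index[(phen["group"] == "V") & phen.index.isin(keep)])
    subjects_nv = sorted(phen.index[(phen["group"] == "NV") & phen.index.isin(keep)])

    structural_dec: dict[str, StructuralMatrix] = {}
    functional_dec: TimeSeriesSet | None = None
    per_modality: dict[str, ModalityResult] = {}

    for modality in cfg.modalities:
        stage_seed = _seed_for(cfg, f"bootstrap:{modality}")
        if modality == "RS":
            ts = study.timeseries
            sel = {
                s: ts.series[s] for s in subjects_v + subjects_nv if s in ts.series
            }
            ts = dataclasses.replace(ts, series=sel)
            conditioned = condition_timeseries(ts, cfg.n_discard, cfg.band)
            dec = deconfound_timeseries(conditioned, phen)
            functional_dec = dec
            data_v = dataclasses.replace(
                dec, series={s: dec.series[s] for s in subjects_v}
            )
            data_nv = dataclasses.replace(
                dec, series={s: dec.series[s] for s in subjects_nv}
            )
            frame_v = pd.DataFrame(group_matrix(data_v), columns=dec.roi_names)
            frame_nv = pd.DataFrame(group_matrix(data_nv), columns=dec.roi_names)
        else:
            sm = study.structural[modality]
            sm_v = dataclasses.replace(sm, values=sm.values.loc[subjects_v])
            sm_nv = dataclasses.replace(sm, values=sm.values.loc[subjects_nv])
            data_v = deconfound_structural(sm_v, phen, include_tiv=True)
            data_nv = deconfound_structural(sm_nv, phen, include_tiv=True)
            # CCA features use deconfounding over all included subjects
            all_dec = deconfound_structural(
                dataclasses.replace(
                    sm, values=sm.values.loc[subjects_v + subjects_nv]
                ),
                phen,
                include_tiv=True,
            )
            structural_dec[modality] = all_dec
            frame_v, frame_nv = data_v.values, data_nv.values
            data_v, data_nv = data_v.values, data_nv.values

        tests = roi_mean_tests(frame_v, frame_nv)
        model_v = fit_group_network(
            group_matrix(data_v),
            penalty=cfg.estimator.penalty,
            folds=cfg.estimator.folds,
            n_grid=cfg.estimator.n_grid,
            n_refinements=cfg.estimator.n_refinements,
            seed=stage_seed,
            roi_names=list(atlas.roi_names),
        )
        model_nv = fit_group_network(
            group_matrix(data_nv),
            penalty=cfg.estimator.penalty,
            folds=cfg.estimator.folds,
            n_grid=cfg.estimator.n_grid,
            n_refinements=cfg.estimator.n_refinements,
            seed=stage_seed,
            roi_names=list(atlas.roi_names),
        )
        edges = compare_groups(
            data_v,
            data_nv,
            modality=modality,
            n_boot=cfg.n_boot,
            cfg=cfg.estimator,
            alpha_sig=cfg.alpha_sig,
            seed=stage_seed,
            roi_names=list(atlas.roi_names),
        )
        logger.info(
            "%s: %d/%d edges flagged (effective level %.3g)",
            modality,
            edges.n_flagged,
            len(edges.flags),
            edges.alpha_effective,
        )
        per_modality[modality] = ModalityResult(
            modality=modality,
            model_v=model_v,
            model_nv=model_nv,
            edges=edges,
            roi_tests=tests,
        )

    summary = summarize([m.edges for m in per_modality.values()], atlas)

    cca_res = None
    loadings = None
    if summary.n_flagged == 0:
        logger.info("no flagged edges; brain-behavior CCA skipped")
    else:
        behavior = phen.loc[sorted(set(subjects_v + subjects_nv))]
        try:
            X, Y = build_feature_sets(
                [m.edges for m in per_modality.values()],
                structural_dec,
                functional_dec,
                behavior,
                atlas,
                structural_only=cfg.cca_structural_only,
            )
            cca_res = run_cca(X, Y, allow_overfit=cfg.cca_allow_overfit)
            if cca_res.wilks["significant"].any():
                _, loadings = variate_loadings(
                    X, Y, cca_res, threshold=cfg.cca_threshold
                )
        except ValueError as exc:
            logger.warning("CCA skipped: %s", exc)

    manifest = {
        "covnet_version": __version__,
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(cfg).items()
            },
        },
        "n_subjects": {"V": len(subjects_v), "NV": len(subjects_nv)},
        "behavior_columns": list(BEHAVIOR_COLUMNS),
        "flagged_edges": {m: r.edges.n_flagged for m, r in per_modality.items()},
    }
    return RunResult(
        per_modality=per_modality,
        summary=summary,
        cca=cca_res,
        cca_loadings=loadings,
        config=cfg,
        manifest=manifest,
    )


def write_run(result: RunResult, atlas: RoiAtlas, out_dir: str | Path) -> None:
    """Serialize a run to TSV/JSON under ``out_dir``."""
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for modality, res in result.per_modality.items():
        cio.write_matrix_tsv(
            out / f"{modality}_pcorr_V.tsv", res.model_v.pcorr, list(atlas.roi_names)
        )
        cio.write_matrix_tsv(
            out / f"{modality}_pcorr_NV.tsv", res.model_nv.pcorr, list(atlas.roi_names)
        )
        for grp, model in (("V", res.model_v), ("NV", res.model_nv)):
            cio.write_json(
                out / f"{modality}_model_{grp}.json",
                cio.precision_model_to_dict(model),
            )
        cio.write_edges_tsv(out / f"{modality}_edges.tsv", res.edges, atlas.network_of)
        res.roi_tests.to_csv(
            out / f"{modality}_roi_tests.tsv",
            sep="\t",
            float_format=cio.FLOAT_FMT,
            index=False,
        )
        cio.write_json(
            out / f"{modality}_edges.json", cio.edge_result_to_dict(res.edges)
        )
    cio.write_summary(out / "summary", result.summary, atlas)
    if result.cca is not None:
        result.cca.wilks.to_csv(
            out / "cca_wilks.tsv", sep="\t", float_format=cio.FLOAT_FMT, index=False
        )
        scores = pd.DataFrame(
            {
                "CCX_1": result.cca.x_scores[:, 0],
                "CCY_1": result.cca.y_scores[:, 0],
            }
        )
        scores.to_csv(
            out / "cca_scores.tsv", sep="\t", float_format=cio.FLOAT_FMT, index=False
        )
        if result.cca_loadings is not None:
            result.cca_loadings.to_csv(
                out / "cca_loadings.tsv",
                sep="\t",
                float_format=cio.FLOAT_FMT,
                index=False,
            )
    cio.write_json(out / "manifest.json", result.manifest)
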