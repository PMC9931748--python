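"""Bit-stable serialization: TSV matrices/edge lists and JSON bundles.

Floats are written with 12 significant digits so repeated runs with the
same seed produce byte-identical output across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .groupdiff import EdgeDifferenceResult
from .netsummary import NetworkSummary
from .precision import PrecisionModel

FLOAT_FMT = "%.12g"


def fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, names: list[str]) -> None:
    df = pd.DataFrame(matrix, index=names, columns=names)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="roi")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="roi")


def write_values_tsv(path: str | Path, values: pd.DataFrame) -> None:
    values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="subject_id")


def read_values_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def precision_model_to_dict(model: PrecisionModel) -> dict:
    return {
        "roi_names": model.roi_names,
        "penalty": model.penalty,
        "n_samples": model.n_samples,
        "covariance_emp": model.covariance_emp.tolist(),
        "precision": model.precision.tolist(),
        "pcorr": model.pcorr.tolist(),
        "cv_grid": model.cv_grid,
    }


def precision_model_from_dict(d: dict) -> PrecisionModel:
    return PrecisionModel(
        covariance_emp=np.asarray(d["covariance_emp"]),
        precision=np.asarray(d["precision"]),
        pcorr=np.asarray(d["pcorr"]),
        penalty=d["penalty"],
        n_samples=d["n_samples"],
        cv_grid=[tuple(g) for g in d["cv_grid"]] if d.get("cv_grid") else None,
        roi_names=d.get("roi_names"),
    )


def write_edges_tsv(
    path: str | Path, result: EdgeDifferenceResult, network_of: dict[str, str]
) -> None:
    frame = result.to_frame()
    frame.insert(2, "network_a", [network_of[r] for r in frame["roi_a"]])
    frame.insert(3, "network_b", [network_of[r] for r in frame["roi_b"]])
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)


def edge_result_to_dict(result: EdgeDifferenceResult) -> dict:
    return {
        "modality": result.modality,
        "roi_names": result.roi_names,
        "victim_pcorr": result.victim_pcorr.tolist(),
        "lo": result.lo.tolist(),
        "hi": result.hi.tolist(),
        "flags": result.flags.tolist(),
        "alpha_sig": result.alpha_sig,
        "alpha_effective": result.alpha_effective,
        "n_boot": result.n_boot,
        "seed": result.seed,
    }


def edge_result_from_dict(d: dict) -> EdgeDifferenceResult:
    return EdgeDifferenceResult(
        modality=d["modality"],
        roi_names=d["roi_names"],
        victim_pcorr=np.asarray(d["victim_pcorr"]),
        lo=np.asarray(d["lo"]),
        hi=np.asarray(d["hi"]),
        flags=np.asarray(d["flags"], dtype=np.int8),
        alpha_sig=d["alpha_sig"],
        alpha_effective=d["alpha_effective"],
        n_boot=d["n_boot"],
        seed=d["seed"],
    )


def write_summary(path_prefix: Path, summary: NetworkSummary, atlas) -> None:
    summary.category_frame().to_csv(
        f"{path_prefix}_categories.tsv", sep="\t", float_format=FLOAT_FMT, index=False
    )
    summary.node_frame(atlas).to_csv(
        f"{path_prefix}_nodes.tsv", sep="\t", float_format=FLOAT_FMT, index=False
    )


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Load the per-subject phenotype table (confounds + behavior).

    Requires ``subject_id`` and ``group`` columns; subject ids must be
    unique and group labels must be V or NV.  A ``diagnosis_current``
    column is derived from ``diagnosis`` when absent.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("phenotype table must have subject_id and group columns")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id values: {dupes}")
    bad = sorted(set(df["group"]) - {"V", "NV"})
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    df = df.set_index("subject_id").sort_index()
    if "diagnosis_current" not in df.columns and "diagnosis" in df.columns:
        df["diagnosis_current"] = df["diagnosis"] == "yes"
    return df
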