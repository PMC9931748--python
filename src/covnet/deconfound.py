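"""Confound residualization for ROI data.

Nuisance covariates (sex, age, psychiatric diagnosis, antidepressant use,
number of other psychotropic drugs, and — for structural data — total
intracranial volume) are removed from each ROI column by ordinary least
squares: numeric confounds are z-scored, categorical confounds are
dummy-encoded with the reference level dropped, an intercept is always
included, and each column is replaced by its OLS residual and then
re-standardized.  Residualization on a fixed design is a projection, so
applying it twice equals applying it once.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .extract import StructuralMatrix, TimeSeriesSet

#: default confound roles for the phenotype tables this package consumes
NUMERIC_CONFOUNDS = ("age", "n_other_psychotropics")
CATEGORICAL_CONFOUNDS = ("sex", "diagnosis", "antidepressants")
TIV_COLUMN = "tiv"


class CollinearDesignError(ValueError):
    """Confound design is rank deficient; names the offending columns."""


def build_design(
    confounds: pd.DataFrame,
    numeric: tuple[str, ...] = NUMERIC_CONFOUNDS,
    categorical: tuple[str, ...] = CATEGORICAL_CONFOUNDS,
    include_tiv: bool = False,
) -> pd.DataFrame:
    """Build the confound design matrix (with intercept) for regression."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(confounds))}
    numeric = tuple(numeric) + ((TIV_COLUMN,) if include_tiv else ())
    for name in numeric:
        v = np.asarray(confounds[name], dtype=np.float64)
        if np.isnan(v).any():
            raise ValueError(f"missing values in numeric confound {name!r}")
        sd = v.std()
        cols[name] = (v - v.mean()) / sd if sd > 0 else v - v.mean()
    for name in categorical:
        series = confounds[name].astype("category")
        if series.isna().any():
            raise ValueError(f"missing values in categorical confound {name!r}")
        levels = list(series.cat.categories)
        for level in levels[1:]:  # drop reference level
            cols[f"{name}[{level}]"] = (series == level).to_numpy(dtype=np.float64)
    design = pd.DataFrame(cols, index=confounds.index)
    _check_rank(design)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return
    # identify columns expressible from the preceding ones
    offenders = []
    for j in range(1, mat.shape[1]):
        sub = mat[:, :j]
        beta, *_ = np.linalg.lstsq(sub, mat[:, j], rcond=None)
        if np.abs(mat[:, j] - sub @ beta).max() < 1e-8:
            offenders.append(design.columns[j])
    raise CollinearDesignError(
        f"confound design is rank deficient; collinear columns: {offenders}"
    )


def residualize(X: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of X on the design (with intercept)."""
    X = np.asarray(X, dtype=np.float64)
    design = np.asarray(design, dtype=np.float64)
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def deconfound_structural(
    data: StructuralMatrix,
    confounds: pd.DataFrame,
    include_tiv: bool = True,
    numeric: tuple[str, ...] = NUMERIC_CONFOUNDS,
    categorical: tuple[str, ...] = CATEGORICAL_CONFOUNDS,
) -> StructuralMatrix:
    """Residualize each ROI column on the confounds, then z-score.

    ``confounds`` must be indexed by subject id and cover every subject in
    ``data`` (row order is aligned here, not assumed).
    """
    conf = confounds.loc[data.values.index]
    design = build_design(conf, numeric, categorical, include_tiv=include_tiv)
    resid = residualize(data.values.to_numpy(), design.to_numpy())
    out = pd.DataFrame(
        _zscore_cols(resid), index=data.values.index, columns=data.values.columns
    )
    return replace(data, values=out, standardized=True, deconfounded=True)


def deconfound_timeseries(
    ts: TimeSeriesSet,
    confounds: pd.DataFrame,
    numeric: tuple[str, ...] = NUMERIC_CONFOUNDS,
    categorical: tuple[str, ...] = CATEGORICAL_CONFOUNDS,
) -> TimeSeriesSet:
    """Remove subject-level confound effects from pooled ROI series.

    Subject-level confound rows are expanded to one row per retained
    timepoint, the pooled (concatenated) series of each ROI is residualized
    on that expanded design, and the per-subject blocks are re-standardized
    over time.  Total intracranial volume is never used for time series.
    """
    subjects = sorted(ts.series)
    conf = confounds.loc[subjects]
    design = build_design(conf, numeric, categorical, include_tiv=False)
    lengths = [ts.series[s].shape[0] for s in subjects]
    expanded = np.repeat(design.to_numpy(), lengths, axis=0)
    pooled = np.concatenate([ts.series[s] for s in subjects], axis=0)
    resid = residualize(pooled, expanded)
    out: dict[str, np.ndarray] = {}
    start = 0
    for s, n in zip(subjects, lengths):
        out[s] = _zscore_cols(resid[start : start + n])
        start += n
    return replace(ts, series=out)
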