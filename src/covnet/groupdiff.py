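"""Bootstrap-null detection of edge differences between two groups.

The control group's partial-correlation network is re-estimated on B
bootstrap resamples (subjects drawn with replacement at the original group
size; for functional data the resampling unit is the whole subject series,
respecting temporal dependence).  Each edge's percentile interval at the
requested two-sided level forms the null envelope; an edge of the
comparison (victim) group is flagged +1/-1 when its partial correlation
falls above/below the envelope.  With B resamples the finest attainable
two-sided level is 2/(B+1); finer requests are clamped to the min/max
envelope and the effective level is recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .extract import TimeSeriesSet
from .precision import (
    EstimationError,
    empirical_covariance,
    fit_graphical_lasso,
    fit_group_network,
)

logger = logging.getLogger(__name__)


@dataclass
class EstimatorConfig:
    """How the group precision matrix is (re-)estimated.

    ``penalty=None`` re-runs cross-validated penalty selection on every
    fit (including every bootstrap replicate); a fixed float penalty is the
    fast mode.
    """

    penalty: float | None = None
    folds: int = 3
    n_grid: int = 10
    n_refinements: int = 4
    #: solver settings for repeated (bootstrap) refits; envelope estimation
    #: does not need the tight duality gap of a point-estimate fit
    tol: float = 1e-3
    max_iter: int = 50


@dataclass
class EdgeIntervals:
    """Bootstrap percentile envelope per edge (upper-triangle order)."""

    lo: np.ndarray
    hi: np.ndarray
    alpha_nominal: float
    alpha_effective: float
    n_boot: int
    n_failed: int
    seed: int
    roi_names: list[str]

    def __post_init__(self) -> None:
        if np.any(self.lo > self.hi):
            raise ValueError("interval lower bounds exceed upper bounds")


@dataclass
class EdgeDifferenceResult:
    """Signed edge flags of one modality's group comparison."""

    modality: str
    roi_names: list[str]
    victim_pcorr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    flags: np.ndarray
    alpha_sig: float
    alpha_effective: float
    n_boot: int
    seed: int

    @property
    def pairs(self) -> list[tuple[str, str]]:
        names = self.roi_names
        iu = zip(*np.triu_indices(len(names), k=1))
        return [(names[i], names[j]) for i, j in iu]

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))

    def flag_counts(self) -> dict[str, int]:
        return {
            "increase": int(np.sum(self.flags == 1)),
            "decrease": int(np.sum(self.flags == -1)),
        }

    def to_frame(self) -> pd.DataFrame:
        pairs = self.pairs
        return pd.DataFrame(
            {
                "roi_a": [a for a, _ in pairs],
                "roi_b": [b for _, b in pairs],
                "victim_value": self.victim_pcorr,
                "lo": self.lo,
                "hi": self.hi,
                "flag": self.flags,
            }
        )


def effective_level(alpha_sig: float, n_boot: int) -> float:
    """Two-sided level actually achievable with ``n_boot`` resamples.

    The finest percentile pair resolvable from B draws is (min, max),
    corresponding to a two-sided level of 2/(B+1); a requested level below
    that is clamped to it.
    """
    finest = 2.0 / (n_boot + 1)
    return max(alpha_sig, finest)


def roi_mean_tests(X_v: pd.DataFrame, X_nv: pd.DataFrame) -> pd.DataFrame:
    """Independent two-sample t-test per ROI with Bonferroni adjustment.

    This is the screen run before the network comparison: it asks whether
    the groups differ in the ROI values themselves (they should not, in a
    well-matched sample), as opposed to differing in covariance structure.
    """
    if list(X_v.columns) != list(X_nv.columns):
        raise ValueError("groups have different ROI columns")
    k = X_v.shape[1]
    t_stats, p_vals = [], []
    for col in X_v.columns:
        a, b = X_v[col].to_numpy(), X_nv[col].to_numpy()
        if a.std() == 0 and b.std() == 0:
            warnings.warn(f"ROI {col!r} has zero variance in both groups", stacklevel=2)
            t_stats.append(0.0)
            p_vals.append(1.0)
            continue
        t, p = stats.ttest_ind(a, b)
        t_stats.append(float(t))
        p_vals.append(float(p))
    p_vals = np.asarray(p_vals)
    return pd.DataFrame(
        {
            "roi": list(X_v.columns),
            "t": t_stats,
            "p": p_vals,
            "p_bonferroni": np.minimum(p_vals * k, 1.0),
        }
    )


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def _fit_pcorr_edges(X: np.ndarray, cfg: EstimatorConfig, seed: int) -> np.ndarray:
    """Upper-triangle partial correlations of one group sample."""
    X = _zscore_cols(np.asarray(X, dtype=np.float64))
    if cfg.penalty is None:
        model = fit_group_network(
            X,
            penalty=None,
            folds=cfg.folds,
            n_grid=cfg.n_grid,
            n_refinements=cfg.n_refinements,
            seed=seed,
            cv_tol=cfg.tol,
            cv_max_iter=cfg.max_iter,
        )
    else:
        model = fit_graphical_lasso(
            empirical_covariance(X),
            cfg.penalty,
            n_samples=X.shape[0],
            tol=cfg.tol,
            max_iter=cfg.max_iter,
        )
    return model.edge_values()


def _resample_matrix(
    data: np.ndarray | TimeSeriesSet, idx: np.ndarray, subjects: list[str]
) -> np.ndarray:
    if isinstance(data, TimeSeriesSet):
        return np.concatenate([data.series[subjects[i]] for i in idx], axis=0)
    return data[idx]


def group_matrix(data: np.ndarray | pd.DataFrame | TimeSeriesSet) -> np.ndarray:
    """Samples-by-ROI matrix used for estimation (pooled time for fMRI)."""
    if isinstance(data, TimeSeriesSet):
        return np.concatenate([data.series[s] for s in sorted(data.series)], axis=0)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=np.float64)
    return np.asarray(data, dtype=np.float64)


def bootstrap_edge_intervals(
    control_data: np.ndarray | pd.DataFrame | TimeSeriesSet,
    n_boot: int = 10_000,
    cfg: EstimatorConfig | None = None,
    alpha_sig: float = 1e-5,
    seed: int = 0,
    roi_names: list[str] | None = None,
    max_failure_rate: float = 0.05,
) -> EdgeIntervals:
    """Percentile envelope of control-group edge values over B resamples.

    Subjects are resampled with replacement at the original group size; for
    a :class:`TimeSeriesSet` each drawn subject contributes its whole
    series.  Replicates whose estimation fails are dropped and counted; a
    failure rate above ``max_failure_rate`` aborts.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    if not (0 < alpha_sig < 1):
        raise ValueError("alpha_sig must be in (0, 1)")
    cfg = cfg or EstimatorConfig()

    if isinstance(control_data, TimeSeriesSet):
        subjects = sorted(control_data.series)
        mat = control_data
        p = len(control_data.roi_names)
        roi_names = roi_names or list(control_data.roi_names)
    else:
        if isinstance(control_data, pd.DataFrame):
            roi_names = roi_names or list(control_data.columns)
        mat = np.asarray(
            control_data.to_numpy()
            if isinstance(control_data, pd.DataFrame)
            else control_data,
            dtype=np.float64,
        )
        subjects = [str(i) for i in range(mat.shape[0])]
        p = mat.shape[1]
    n_subj = len(subjects)
    if n_subj < 10:
        raise ValueError(f"need at least 10 sampling units, got {n_subj}")
    roi_names = roi_names or [f"ROI{i + 1}" for i in range(p)]

    rng = np.random.default_rng(seed)
    n_edges = p * (p - 1) // 2
    draws = np.empty((n_boot, n_edges))
    n_failed = 0
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        X = _resample_matrix(mat, idx, subjects)
        try:
            draws[kept] = _fit_pcorr_edges(X, cfg, seed=seed)
        except (EstimationError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        kept += 1
    if n_failed > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed estimation"
        )
    draws = draws[:kept]

    alpha_eff = effective_level(alpha_sig, kept)
    if alpha_eff > alpha_sig:
        lo = draws.min(axis=0)
        hi = draws.max(axis=0)
        logger.info(
            "requested two-sided level %.3g below bootstrap resolution; "
            "clamped to min/max envelope, effective level %.3g",
            alpha_sig,
            alpha_eff,
        )
    else:
        lo = np.quantile(draws, alpha_sig / 2, axis=0)
        hi = np.quantile(draws, 1 - alpha_sig / 2, axis=0)
    return EdgeIntervals(
        lo=lo,
        hi=hi,
        alpha_nominal=alpha_sig,
        alpha_effective=alpha_eff,
        n_boot=kept,
        n_failed=n_failed,
        seed=seed,
        roi_names=list(roi_names),
    )


def flag_edges(
    victim_pcorr: np.ndarray,
    intervals: EdgeIntervals,
    modality: str,
    roi_names: list[str] | None = None,
) -> EdgeDifferenceResult:
    """Signed comparison of victim edges against the control envelope.

    ``victim_pcorr`` may be the full symmetric matrix or the upper-triangle
    vector; a flag of -1 marks relatively lower covariance in the victim
    group, +1 relatively higher.
    """
    roi_names = roi_names or intervals.roi_names
    if roi_names != intervals.roi_names:
        raise ValueError("ROI order mismatch between victim matrix and intervals")
    v = np.asarray(victim_pcorr, dtype=np.float64)
    if v.ndim == 2:
        v = v[np.triu_indices(v.shape[0], k=1)]
    if v.shape[0] != intervals.lo.shape[0]:
        raise ValueError("edge count mismatch")
    flags = np.zeros(v.shape[0], dtype=np.int8)
    flags[v > intervals.hi] = 1
    flags[v < intervals.lo] = -1
    return EdgeDifferenceResult(
        modality=modality,
        roi_names=list(roi_names),
        victim_pcorr=v,
        lo=intervals.lo,
        hi=intervals.hi,
        flags=flags,
        alpha_sig=intervals.alpha_nominal,
        alpha_effective=intervals.alpha_effective,
        n_boot=intervals.n_boot,
        seed=intervals.seed,
    )


def compare_groups(
    victim_data: np.ndarray | pd.DataFrame | TimeSeriesSet,
    control_data: np.ndarray | pd.DataFrame | TimeSeriesSet,
    modality: str,
    n_boot: int = 10_000,
    cfg: EstimatorConfig | None = None,
    alpha_sig: float = 1e-5,
    seed: int = 0,
    roi_names: list[str] | None = None,
) -> EdgeDifferenceResult:
    """Full edge-difference comparison of one modality (victim vs control)."""
    cfg = cfg or EstimatorConfig()
    intervals = bootstrap_edge_intervals(
        control_data,
        n_boot=n_boot,
        cfg=cfg,
        alpha_sig=alpha_sig,
        seed=seed,
        roi_names=roi_names,
    )
    victim_edges = _fit_pcorr_edges(group_matrix(victim_data), cfg, seed=seed)
    return flag_edges(victim_edges, intervals, modality=modality)
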