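"""Canonical correlation analysis between brain features and behavior.

CCA finds paired linear combinations (canonical variates) of two variable
sets X (brain) and Y (behavior) with maximal correlation.  Mode
significance is tested sequentially with Wilks' Lambda,
Lambda_k = prod_{i>=k} (1 - r_i^2), via Rao's F approximation, Bonferroni
corrected over modes.  Modes are interpreted through loadings: the Pearson
correlation of every input variable with the canonical variates.

The brain feature set is assembled from flagged edges: for each structural
modality, the deconfounded ROI values of every node incident to a flagged
edge; for each flagged functional edge, the subject-level correlation of
the two conditioned ROI series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RoiAtlas
from .extract import StructuralMatrix, TimeSeriesSet
from .groupdiff import EdgeDifferenceResult

logger = logging.getLogger(__name__)

#: behavioral / neuropsychological variables entering the Y set
BEHAVIOR_COLUMNS = (
    "BDI",
    "STAI_trait",
    "SCI_stress",
    "TMT",
    "VFT_1",
    "VFT_2",
    "MWT_B",
    "ZNS",
)


@dataclass
class CcaResult:
    correlations: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_names: list[str]
    y_names: list[str]
    n: int
    wilks: pd.DataFrame | None = None

    @property
    def n_modes(self) -> int:
        return len(self.correlations)


def _standardize(X: np.ndarray, names: list[str]) -> np.ndarray:
    sd = X.std(axis=0)
    zero = [names[i] for i in np.nonzero(sd == 0)[0]]
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return (X - X.mean(axis=0)) / sd


def cca(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    allow_overfit: bool = False,
    n_components: int | None = None,
) -> CcaResult:
    """Canonical correlations and variates of two standardized sets.

    Refuses to fit when ``n <= p + q`` (canonical correlations of 1 are
    then guaranteed regardless of any real association) unless
    ``allow_overfit=True``.  Variates are unit-variance; per mode, signs
    are fixed so that the X variable with the largest-magnitude loading
    loads positively.
    """
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    n, p = X.shape
    q = Y.shape[1]
    x_names = x_names or [f"x{i + 1}" for i in range(p)]
    y_names = y_names or [f"y{i + 1}" for i in range(q)]
    if Y.shape[0] != n:
        raise ValueError("X and Y have different numbers of rows")
    if n <= p + q and not allow_overfit:
        raise ValueError(
            f"n={n} <= p+q={p + q}: canonical correlations would be degenerate; "
            "reduce dimensions (e.g. PCA) or pass allow_overfit=True"
        )
    Xs = _standardize(X, x_names)
    Ys = _standardize(Y, y_names)

    qx, rx = np.linalg.qr(Xs)
    qy, ry = np.linalg.qr(Ys)
    rank_x = np.sum(np.abs(np.diag(rx)) > 1e-10 * np.abs(rx).max())
    rank_y = np.sum(np.abs(np.diag(ry)) > 1e-10 * np.abs(ry).max())
    if rank_x < p or rank_y < q:
        side = "X" if rank_x < p else "Y"
        raise ValueError(f"within-set covariance of {side} is singular (collinear columns)")

    u, s, vt = np.linalg.svd(qx.T @ qy)
    m = min(p, q)
    if n_components is not None:
        m = min(m, n_components)
    corr = np.clip(s[:m], 0.0, 1.0)
    # variates: unit sample variance (ddof=1)
    x_scores = qx @ u[:, :m] * np.sqrt(n - 1)
    y_scores = qy @ vt.T[:, :m] * np.sqrt(n - 1)
    x_weights = np.linalg.solve(rx, u[:, :m]) * np.sqrt(n - 1)
    y_weights = np.linalg.solve(ry, vt.T[:, :m]) * np.sqrt(n - 1)

    # sign convention: largest-|loading| X variable loads positively
    load_x = (Xs.T @ x_scores) / (n - 1)  # columns standardized, scores unit var
    for k in range(m):
        j = int(np.argmax(np.abs(load_x[:, k])))
        if load_x[j, k] < 0:
            x_scores[:, k] *= -1
            x_weights[:, k] *= -1
            y_scores[:, k] *= -1
            y_weights[:, k] *= -1
    return CcaResult(
        correlations=corr,
        x_weights=x_weights,
        y_weights=y_weights,
        x_scores=x_scores,
        y_scores=y_scores,
        x_names=x_names,
        y_names=y_names,
        n=n,
    )


def wilks_test(
    correlations: np.ndarray, n: int, p: int, q: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Sequential Wilks' Lambda tests with Rao's F approximation.

    For mode k the remaining correlations r_k..r_m form
    Lambda_k = prod (1 - r_i^2), tested on the reduced dimensions
    p_k = p - k + 1, q_k = q - k + 1.  P-values are Bonferroni-multiplied
    by the number of modes (capped at 1); mode k is labeled significant
    only if every earlier mode is also significant (sequential rule).
    """
    r = np.asarray(correlations, dtype=np.float64)
    m = len(r)
    rows = []
    for k in range(m):
        pk = p - k
        qk = q - k
        lam = float(np.prod(1.0 - r[k:] ** 2))
        df1 = pk * qk
        denom = pk**2 + qk**2 - 5
        s = np.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 else 1.0
        mm = n - 1 - (pk + qk + 1) / 2.0
        df2 = mm * s - df1 / 2.0 + 1.0
        if lam <= 0.0:
            f_stat, p_val = np.inf, 0.0
        else:
            lam_s = lam ** (1.0 / s)
            f_stat = (1.0 - lam_s) / lam_s * df2 / df1
            p_val = float(stats.f.sf(f_stat, df1, df2))
        rows.append(
            {
                "mode": k + 1,
                "r": float(r[k]),
                "wilks_lambda": lam,
                "F": float(f_stat),
                "df1": float(df1),
                "df2": float(df2),
                "p": p_val,
                "p_bonferroni": min(p_val * m, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    significant = []
    chain = True
    for pb in table["p_bonferroni"]:
        chain = chain and (pb < alpha)
        significant.append(chain)
    table["significant"] = significant
    return table


def run_cca(
    X: pd.DataFrame, Y: pd.DataFrame, alpha: float = 0.05, allow_overfit: bool = False
) -> CcaResult:
    """CCA plus sequential Wilks tests in one call."""
    res = cca(X, Y, allow_overfit=allow_overfit)
    res.wilks = wilks_test(res.correlations, res.n, len(res.x_names), len(res.y_names), alpha)
    return res


def variate_loadings(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    result: CcaResult,
    threshold: float = 0.2,
    modes: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlations of every input variable with the canonical variates.

    Returns ``(full, reported)``: the full loadings table, and the report
    filtered to the requested modes (default: significant ones) with
    |loading| strictly greater than ``threshold``.
    """
    Xa = np.asarray(X, dtype=np.float64)
    Ya = np.asarray(Y, dtype=np.float64)
    if modes is None:
        if result.wilks is None:
            raise ValueError("no Wilks table on result; pass modes explicitly")
        modes = [int(m) for m in result.wilks.loc[result.wilks["significant"], "mode"]]
    rows = []
    for side, data, names, scores in (
        ("X", Xa, result.x_names, result.x_scores),
        ("Y", Ya, result.y_names, result.y_scores),
    ):
        for k in range(result.n_modes):
            for j, name in enumerate(names):
                col = data[:, j]
                if col.std() == 0:
                    logger.warning("zero-variance variable %r: loading undefined", name)
                    loading = np.nan
                else:
                    loading = float(np.corrcoef(col, scores[:, k])[0, 1])
                rows.append(
                    {"set": side, "variable": name, "mode": k + 1, "loading": loading}
                )
    full = pd.DataFrame(rows)
    reported = full[
        full["mode"].isin(modes) & (full["loading"].abs() > threshold)
    ].reset_index(drop=True)
    return full, reported


def subject_edge_correlations(
    ts: TimeSeriesSet, edges: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-subject Pearson correlation of each flagged functional edge."""
    idx = {r: i for i, r in enumerate(ts.roi_names)}
    cols = {}
    for a, b in edges:
        name = f"RS {a}-{b}"
        cols[name] = [
            float(np.corrcoef(ts.series[s][:, idx[a]], ts.series[s][:, idx[b]])[0, 1])
            for s in sorted(ts.series)
        ]
    return pd.DataFrame(cols, index=sorted(ts.series))


def feature_name(measure: str, atlas: RoiAtlas, roi: str) -> str:
    """Column label like ``"GMD DMN.PCUN"``."""
    return f"{measure} {atlas.network_of[roi]}.{roi}"


def build_feature_sets(
    flag_results: list[EdgeDifferenceResult],
    structural: dict[str, StructuralMatrix],
    functional: TimeSeriesSet | None,
    behavior: pd.DataFrame,
    atlas: RoiAtlas,
    structural_only: bool = False,
    behavior_columns: tuple[str, ...] = BEHAVIOR_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble (X_brain, Y_behavior) from flagged edges.

    Structural modalities contribute the ROI values of nodes incident to
    their flagged edges; the functional modality contributes per-subject
    correlations of its flagged edges.  Subjects with any missing
    behavioral score are dropped (logged).
    """
    x_parts: list[pd.DataFrame] = []
    for res in flag_results:
        flagged = [pair for pair, f in zip(res.pairs, res.flags) if f != 0]
        if not flagged:
            continue
        if res.modality == "RS":
            if structural_only:
                continue
            if functional is None:
                raise ValueError("functional flags present but no time series given")
            x_parts.append(subject_edge_correlations(functional, flagged))
        else:
            nodes: list[str] = []
            for a, b in flagged:
                for roi in (a, b):
                    if roi not in nodes:
                        nodes.append(roi)
            sm = structural[res.modality]
            part = sm.values[nodes].copy()
            part.columns = [feature_name(res.modality, atlas, r) for r in nodes]
            x_parts.append(part)
    if not x_parts:
        raise ValueError("no flagged edges: brain feature set is empty")
    X = pd.concat(x_parts, axis=1)

    missing_cols = [c for c in behavior_columns if c not in behavior.columns]
    if missing_cols:
        raise ValueError(f"behavior table lacks columns {missing_cols}")
    Y = behavior.loc[:, list(behavior_columns)]
    common = X.index.intersection(Y.index)
    complete = common[~Y.loc[common].isna().any(axis=1)]
    dropped = sorted(set(common) - set(complete))
    if dropped:
        logger.info("dropping %d subjects with missing behavior: %s", len(dropped), dropped)
    X = X.loc[complete]
    Y = Y.loc[complete]
    return X, Y
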