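"""Synthetic multi-subject ROI datasets with known network structure.

Emulates the data model of a two-group ROI covariance study: per subject,
19 ROI values per structural gray-matter measure drawn from a group-level
sparse precision matrix, plus an ROI time series with network-structured
cross-correlation and AR(1) temporal autocorrelation (250 volumes at
TR = 1.6 s by default); confound effects (age, sex, diagnosis, medication,
intracranial volume) shift the structural values; behavioral scores share
a latent factor with selected brain nodes so the brain-behavior stage has
a recoverable ground-truth mode.  Group differences are planted directly
on the partial-correlation scale — the pipeline's readout.

Volumetric rendering paints each ROI's voxels with the subject's ROI value
plus voxel noise, producing NIfTI fixtures whose extraction round-trips.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import DEFAULT_NODES, N_ROIS, RoiAtlas, default_network_table
from .extract import MEASURES, StructuralMatrix, TimeSeriesSet
from .precision import partial_correlations

logger = logging.getLogger(__name__)

MODALITIES = MEASURES + ("RS",)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class PlantedEdge:
    """A between-group difference planted on one edge of one modality."""

    modality: str
    roi_a: str
    roi_b: str
    delta: float  # change in partial correlation in the target group
    group: str = "V"


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic two-group dataset.

    Defaults mirror the emulated study: 32 subjects per group, 19 nodes in
    the canonical four-network parcellation, 250 volumes at TR = 1.6 s.
    The base network has within-network partial correlation ``within_pcorr``
    and between-network ``between_pcorr``; these defaults are the largest
    round values for which the implied block precision matrix is
    comfortably positive definite given a seven-node network.
    """

    n_v: int = 32
    n_nv: int = 32
    timepoints: int = 250
    tr: float = 1.6
    within_pcorr: float = 0.12
    between_pcorr: float = 0.02
    ar_coeff: float = 0.4
    planted_edges: tuple[PlantedEdge, ...] = ()
    #: per-ROI shift per z-unit of confound: {confound: slope}
    confound_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.3, "sex": 0.2, "tiv": 0.4}
    )
    #: correlation of behavior scores / brain nodes with the latent factor
    behavior_latent_corr: float = 0.5
    brain_latent_corr: float = 0.3
    #: brain nodes tied to the latent factor (defaults to planted-edge nodes)
    latent_nodes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_v, self.n_nv) < 4:
            raise ValueError("group sizes must be >= 4")
        if self.timepoints < 32:
            raise ValueError("need at least 32 timepoints")
        if not abs(self.ar_coeff) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        for e in self.planted_edges:
            if e.modality not in MODALITIES:
                raise ValueError(f"unknown modality {e.modality!r}")
        # fail fast on infeasible precision specs
        make_group_precisions(self)


ROI_NAMES = [n for n, _ in DEFAULT_NODES]

#: behavioral score scales per group: (mean_v, sd_v, mean_nv, sd_nv)
BEHAVIOR_SCALES = {
    "BDI": (15.5, 11.2, 8.9, 10.4),
    "STAI_trait": (46.1, 12.5, 35.5, 16.3),
    "SCI_stress": (64.0, 19.8, 47.9, 22.3),
    "TMT": (-20.4, 12.5, -14.1, 10.6),
    "VFT_1": (35.2, 8.6, 39.4, 6.5),
    "VFT_2": (29.5, 6.2, 33.3, 4.8),
    "MWT_B": (28.3, 6.0, 30.9, 3.2),
    "ZNS": (14.9, 3.8, 15.3, 3.8),
}


def block_partial_corr(
    within: float, between: float, nodes: tuple[tuple[str, str], ...] = DEFAULT_NODES
) -> np.ndarray:
    """Target partial-correlation matrix with network-block structure."""
    nets = [w for _, w in nodes]
    p = len(nodes)
    P = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            P[i, j] = within if nets[i] == nets[j] else between
    np.fill_diagonal(P, 1.0)
    return P


def precision_from_pcorr(P: np.ndarray, min_eig: float = 0.05) -> np.ndarray:
    """Unit-diagonal precision matrix realizing a partial-correlation target.

    Uses Theta = I - P_off (so off-diagonal partial correlations equal the
    target exactly when feasible).  If the result is not positive definite
    with margin ``min_eig``, the off-diagonals are shrunk uniformly until
    it is (logged); the realized partial correlations are then a scaled
    version of the target.
    """
    p = P.shape[0]
    off = P - np.diag(np.diag(P))
    theta = np.eye(p) - off
    lo = np.linalg.eigvalsh(theta)[0]
    if lo >= min_eig:
        return theta
    # shrink off-diagonals: eigenvalues are affine in the shrink factor
    # for the pencil I - c*off; solve for c giving margin min_eig
    lam_min_off = np.linalg.eigvalsh(-off).min()  # most negative of -off
    # theta(c) = I - c*off has min eig = 1 + c * lam_min_off (lam_min_off < 0)
    c = (min_eig - 1.0) / lam_min_off
    c = min(c, 1.0)
    logger.info("precision target infeasible; off-diagonals shrunk by %.3f", c)
    return np.eye(p) - c * off


def _apply_planted(
    theta: np.ndarray, edges: list[PlantedEdge], roi_names: list[str]
) -> np.ndarray:
    """Plant partial-correlation deltas, rebuild, and re-check feasibility."""
    P = partial_correlations(theta)
    idx = {r: i for i, r in enumerate(roi_names)}
    for e in edges:
        i, j = idx[e.roi_a], idx[e.roi_b]
        new = P[i, j] + e.delta
        if abs(new) >= 1.0:
            raise ValueError(
                f"planted delta on ({e.roi_a}, {e.roi_b}) gives |pcorr| {abs(new):.3f} >= 1"
            )
        P[i, j] = P[j, i] = new
    return precision_from_pcorr(P)


def make_group_precisions(
    cfg: SimulationConfig,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per modality: (control precision, victim precision)."""
    base = precision_from_pcorr(
        block_partial_corr(cfg.within_pcorr, cfg.between_pcorr)
    )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for modality in MODALITIES:
        edges_v = [
            e for e in cfg.planted_edges if e.modality == modality and e.group == "V"
        ]
        edges_nv = [
            e for e in cfg.planted_edges if e.modality == modality and e.group == "NV"
        ]
        theta_v = _apply_planted(base, edges_v, ROI_NAMES) if edges_v else base.copy()
        theta_nv = (
            _apply_planted(base, edges_nv, ROI_NAMES) if edges_nv else base.copy()
        )
        out[modality] = (theta_nv, theta_v)
    return out


def make_confounds(
    n: int, group: str, rng: np.random.Generator, id_offset: int = 0
) -> pd.DataFrame:
    """Phenotype/confound rows emulating a matched clinical sample."""
    diag_rate = 0.781 if group == "V" else 0.625
    ad_rate = 0.38 if group == "V" else 0.25
    age_mu, age_sd = (33.3, 10.1) if group == "V" else (32.5, 11.7)
    ids = [f"{group.lower()}{i + 1 + id_offset:03d}" for i in range(n)]
    age = np.clip(rng.normal(age_mu, age_sd, n), 18, 60)
    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "sex": rng.choice(["F", "M"], size=n, p=[0.6, 0.4]),
            "age": np.round(age, 1),
            "diagnosis": np.where(rng.random(n) < diag_rate, "yes", "no"),
            "antidepressants": np.where(rng.random(n) < ad_rate, "yes", "no"),
            "n_other_psychotropics": rng.binomial(2, 0.1, n),
            "tiv": np.round(rng.normal(1_450_000.0, 120_000.0, n), 1),
        }
    ).set_index("subject_id")


def sample_structural(
    theta: np.ndarray,
    confounds: pd.DataFrame,
    confound_effects: dict[str, float],
    rng: np.random.Generator,
    measure: str = "GMM",
    roi_names: list[str] | None = None,
) -> StructuralMatrix:
    """Draw subject ROI values from N(0, theta^{-1}) plus confound shifts."""
    roi_names = roi_names or ROI_NAMES
    n = len(confounds)
    cov = np.linalg.inv(theta)
    X = rng.multivariate_normal(np.zeros(theta.shape[0]), cov, size=n)
    for name, slope in confound_effects.items():
        if slope == 0 or name not in confounds.columns:
            continue
        v = confounds[name]
        if v.dtype == object:
            z = (v == sorted(v.unique())[-1]).to_numpy(dtype=np.float64)
            z = (z - z.mean()) / (z.std() or 1.0)
        else:
            arr = v.to_numpy(dtype=np.float64)
            z = (arr - arr.mean()) / (arr.std() or 1.0)
        X += slope * z[:, None]
    values = pd.DataFrame(X, index=confounds.index, columns=roi_names)
    return StructuralMatrix(values=values, measure=measure)


def sample_timeseries(
    theta: np.ndarray,
    subjects: list[str],
    timepoints: int,
    ar_coeff: float,
    tr: float,
    rng: np.random.Generator,
    roi_names: list[str] | None = None,
    burn_in: int = 50,
) -> TimeSeriesSet:
    """Stationary AR(1) series with cross-sectional covariance theta^{-1}.

    x_t = phi * x_{t-1} + sqrt(1 - phi^2) * L z_t with L the Cholesky
    factor of theta^{-1}, so the stationary marginal covariance equals
    theta^{-1} and every ROI has lag-1 autocorrelation phi.
    """
    if not abs(ar_coeff) < 1:
        raise ValueError("|ar_coeff| must be < 1")
    p = theta.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(theta))
    scale = np.sqrt(1.0 - ar_coeff**2)
    series = {}
    for subj in subjects:
        z = rng.standard_normal((timepoints + burn_in, p)) @ L.T
        x = np.empty_like(z)
        x[0] = z[0]
        for t in range(1, z.shape[0]):
            x[t] = ar_coeff * x[t - 1] + scale * z[t]
        series[subj] = x[burn_in:]
    return TimeSeriesSet(
        series=series, roi_names=list(roi_names or ROI_NAMES), tr=tr
    )


def sample_behavior(
    confounds: pd.DataFrame,
    latent: np.ndarray,
    latent_corr: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Behavioral scores sharing a latent factor, on realistic scales."""
    n = len(confounds)
    is_v = (confounds["group"] == "V").to_numpy()
    cols = {}
    rho = latent_corr
    for name, (mu_v, sd_v, mu_nv, sd_nv) in BEHAVIOR_SCALES.items():
        z = rho * latent + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        mu = np.where(is_v, mu_v, mu_nv)
        sd = np.where(is_v, sd_v, sd_nv)
        cols[name] = np.round(mu + sd * z, 1)
    return pd.DataFrame(cols, index=confounds.index)


@dataclass
class StudyData:
    """A complete synthetic study: all modalities plus phenotype table."""

    structural: dict[str, StructuralMatrix]  # measure -> subjects x 19 (both groups)
    timeseries: TimeSeriesSet  # both groups
    phenotype: pd.DataFrame  # confounds + behavior + group, indexed by subject
    precisions: dict[str, tuple[np.ndarray, np.ndarray]]  # modality -> (nv, v)
    config: SimulationConfig

    def subjects(self, group: str | None = None) -> list[str]:
        idx = self.phenotype.index
        if group is not None:
            idx = idx[self.phenotype["group"] == group]
        return sorted(idx)

    def structural_group(self, measure: str, group: str) -> StructuralMatrix:
        sm = self.structural[measure]
        subs = self.subjects(group)
        return replace(sm, values=sm.values.loc[subs])

    def timeseries_group(self, group: str) -> TimeSeriesSet:
        subs = self.subjects(group)
        return replace(
            self.timeseries,
            series={s: self.timeseries.series[s] for s in subs},
        )


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Generate the full synthetic study deterministically from cfg.seed."""
    precisions = make_group_precisions(cfg)
    conf_rng = substream(cfg.seed, "confounds")
    conf = pd.concat(
        [
            make_confounds(cfg.n_nv, "NV", conf_rng),
            make_confounds(cfg.n_v, "V", conf_rng),
        ]
    ).sort_index()
    conf["diagnosis_current"] = conf["diagnosis"] == "yes"

    latent = substream(cfg.seed, "latent").standard_normal(len(conf))

    structural: dict[str, StructuralMatrix] = {}
    for measure in MEASURES:
        rng = substream(cfg.seed, f"structural:{measure}")
        theta_nv, theta_v = precisions[measure]
        parts = []
        for group, theta in (("NV", theta_nv), ("V", theta_v)):
            rows = conf[conf["group"] == group]
            parts.append(
                sample_structural(
                    theta, rows, cfg.confound_effects, rng, measure=measure
                ).values
            )
        values = pd.concat(parts).sort_index()
        # latent-factor loading on selected nodes (gives CCA a true mode)
        nodes = cfg.latent_nodes or tuple(
            sorted(
                {
                    r
                    for e in cfg.planted_edges
                    if e.modality == measure
                    for r in (e.roi_a, e.roi_b)
                }
            )
        )
        for node in nodes:
            values[node] = values[node] + cfg.brain_latent_corr * latent
        structural[measure] = StructuralMatrix(values=values, measure=measure)

    ts_rng = substream(cfg.seed, "timeseries")
    theta_nv, theta_v = precisions["RS"]
    subs_nv = sorted(conf.index[conf["group"] == "NV"])
    subs_v = sorted(conf.index[conf["group"] == "V"])
    ts_nv = sample_timeseries(
        theta_nv, subs_nv, cfg.timepoints, cfg.ar_coeff, cfg.tr, ts_rng
    )
    ts_v = sample_timeseries(
        theta_v, subs_v, cfg.timepoints, cfg.ar_coeff, cfg.tr, ts_rng
    )
    ts = TimeSeriesSet(
        series={**ts_nv.series, **ts_v.series}, roi_names=ROI_NAMES, tr=cfg.tr
    )

    behavior = sample_behavior(
        conf, latent, cfg.behavior_latent_corr, substream(cfg.seed, "behavior")
    )
    phenotype = pd.concat([conf, behavior], axis=1)
    return StudyData(
        structural=structural,
        timeseries=ts,
        phenotype=phenotype,
        precisions=precisions,
        config=cfg,
    )


def study_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """The bundled study-scale preset: 32 + 32 subjects, 19 nodes, 250 TRs."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# volumetric fixtures


def make_test_atlas(
    shape: tuple[int, int, int] = (12, 12, 12), voxel_size: float = 2.0
) -> RoiAtlas:
    """Small label image with the 19 canonical ROIs painted as blocks."""
    labels = np.zeros(shape, dtype=np.int32)
    nx, ny, nz = shape
    # 19 blocks on a 3 x 3 x 3 coarse grid (8 cells left empty)
    coarse = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)][:N_ROIS]
    bx, by, bz = nx // 3, ny // 3, nz // 3
    for label, (i, j, k) in enumerate(coarse, start=1):
        labels[
            i * bx : i * bx + max(bx - 1, 1),
            j * by : j * by + max(by - 1, 1),
            k * bz : k * bz + max(bz - 1, 1),
        ] = label
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    table = default_network_table()
    return RoiAtlas(
        labels=labels,
        affine=affine,
        roi_names=list(table["roi_name"]),
        network_of=dict(zip(table["roi_name"], table["network"])),
        label_of=dict(zip(table["roi_name"], (int(v) for v in table["label"]))),
    )


def render_structural_volume(
    roi_values: np.ndarray,
    atlas: RoiAtlas,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> nib.Nifti1Image:
    """Paint one subject's 19 ROI values into a 3D image (+ voxel noise)."""
    rng = rng or np.random.default_rng(0)
    data = np.zeros(atlas.labels.shape, dtype=np.float64)
    for k, roi in enumerate(atlas.roi_names):
        mask = atlas.mask(roi)
        data[mask] = roi_values[k]
        if noise_sd > 0:
            data[mask] += rng.normal(0, noise_sd, int(mask.sum()))
    return nib.Nifti1Image(data, atlas.affine)


def render_timeseries_volume(
    series: np.ndarray,
    atlas: RoiAtlas,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> nib.Nifti1Image:
    """Paint a timepoints x 19 series into a 4D image (+ voxel noise)."""
    rng = rng or np.random.default_rng(0)
    n_t = series.shape[0]
    data = np.zeros(atlas.labels.shape + (n_t,), dtype=np.float64)
    for k, roi in enumerate(atlas.roi_names):
        mask = atlas.mask(roi)
        block = np.broadcast_to(series[:, k], (int(mask.sum()), n_t)).copy()
        if noise_sd > 0:
            block += rng.normal(0, noise_sd, block.shape)
        data[mask, :] = block
    return nib.Nifti1Image(data, atlas.affine)
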