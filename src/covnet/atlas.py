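"""ROI atlas handling for the four large-scale brain networks.

The analyses operate on 19 regions of interest (ROIs) belonging to four
canonical resting-state networks: the default mode network (DMN), the
salience network (SN), the dorsal attention network (DAN) and the
fronto-parietal network (FPN).  An atlas is a 3D integer label image
(0 = background) plus a table assigning every label a ROI name and a
network.  All downstream matrices use the atlas ROI order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

NETWORKS: tuple[str, ...] = ("DMN", "SN", "DAN", "FPN")

#: Canonical 19-node parcellation: (roi_name, network), in atlas label order
#: (label i+1 corresponds to entry i).
DEFAULT_NODES: tuple[tuple[str, str], ...] = (
    ("MPFC", "DMN"),
    ("LPC-L", "DMN"),
    ("LPC-R", "DMN"),
    ("PCUN", "DMN"),
    ("ACC", "SN"),
    ("AI-L", "SN"),
    ("AI-R", "SN"),
    ("RPFC-L", "SN"),
    ("RPFC-R", "SN"),
    ("SMG-L", "SN"),
    ("SMG-R", "SN"),
    ("FEF-L", "DAN"),
    ("FEF-R", "DAN"),
    ("IPS-L", "DAN"),
    ("IPS-R", "DAN"),
    ("LPFC-L", "FPN"),
    ("LPFC-R", "FPN"),
    ("PPC-L", "FPN"),
    ("PPC-R", "FPN"),
)

N_ROIS = len(DEFAULT_NODES)


class AtlasError(ValueError):
    """Raised when a label image / network table pair is inconsistent."""


@dataclass
class RoiAtlas:
    """A labeled ROI parcellation with network membership.

    Attributes
    ----------
    labels : 3D integer array, 0 = background, positive values = ROI labels.
    affine : 4x4 voxel-to-world affine of the label image.
    roi_names : ROI names in label order.
    network_of : mapping ROI name -> network name.
    """

    labels: np.ndarray
    affine: np.ndarray
    roi_names: list[str]
    network_of: dict[str, str]
    label_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_of:
            present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
            self.label_of = dict(zip(self.roi_names, present))

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (determinant of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def networks(self) -> list[str]:
        return [self.network_of[r] for r in self.roi_names]

    def network_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for net in self.networks:
            sizes[net] = sizes.get(net, 0) + 1
        return sizes

    def mask(self, roi: str) -> np.ndarray:
        """Boolean voxel mask of one ROI."""
        return self.labels == self.label_of[roi]

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered ROI pairs in row-major upper-triangle order."""
        names = self.roi_names
        return [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]


def default_network_table() -> pd.DataFrame:
    """The canonical 19-node table (columns: label, roi_name, network)."""
    return pd.DataFrame(
        {
            "label": np.arange(1, N_ROIS + 1),
            "roi_name": [n for n, _ in DEFAULT_NODES],
            "network": [w for _, w in DEFAULT_NODES],
        }
    )


def _validate(labels: np.ndarray, table: pd.DataFrame, strict: bool) -> None:
    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    table_labels = set(int(v) for v in table["label"])
    missing = [lab for lab in present if lab not in table_labels]
    if missing:
        raise AtlasError(f"labels present in image but missing from table: {missing}")
    empty = sorted(table_labels - set(present))
    if empty:
        raise AtlasError(f"labels listed in table but with 0 voxels in image: {empty}")
    bad_net = sorted(set(table["network"]) - set(NETWORKS))
    if bad_net:
        raise AtlasError(f"unknown network names: {bad_net}")
    if len(present) != N_ROIS:
        msg = f"expected {N_ROIS} ROIs, found {len(present)}"
        if strict:
            raise AtlasError(msg)
        warnings.warn(msg, stacklevel=3)


def load_atlas(
    label_image: str | Path | nib.Nifti1Image,
    network_table: str | Path | pd.DataFrame,
    strict: bool = False,
) -> RoiAtlas:
    """Load a ROI atlas from a NIfTI label image and a network CSV.

    The CSV must have columns ``label``, ``roi_name``, ``network``; every
    nonzero label in the image must be listed.  With ``strict=True`` a
    parcellation that does not have exactly 19 ROIs is rejected instead of
    producing a warning.
    """
    img = (
        label_image
        if isinstance(label_image, nib.spatialimages.SpatialImage)
        else nib.load(str(label_image))
    )
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise AtlasError("label image is not integer-valued")
    labels = np.round(data).astype(np.int32)

    table = (
        network_table
        if isinstance(network_table, pd.DataFrame)
        else pd.read_csv(network_table)
    )
    required = {"label", "roi_name", "network"}
    if not required.issubset(table.columns):
        raise AtlasError(f"network table must have columns {sorted(required)}")

    _validate(labels, table, strict=strict)

    table = table.sort_values("label")
    present = set(int(v) for v in np.unique(labels) if v != 0)
    table = table[table["label"].isin(present)]
    roi_names = list(table["roi_name"])
    network_of = dict(zip(table["roi_name"], table["network"]))
    label_of = dict(zip(table["roi_name"], (int(v) for v in table["label"])))
    return RoiAtlas(
        labels=labels,
        affine=np.asarray(img.affine),
        roi_names=roi_names,
        network_of=network_of,
        label_of=label_of,
    )
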