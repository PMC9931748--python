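"""Aggregation of flagged edges into network categories and node tallies.

With four networks there are exactly ten unordered network-pair
categories: four within-network (DMN-DMN, SN-SN, DAN-DAN, FPN-FPN) and six
between-network.  Flagged edges are tallied per category and per node,
pooled across imaging modalities and separately per modality; category
shares are percentages of flagged edges, node shares are percentages of
2 x flagged edges (each edge touches two nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .atlas import NETWORKS, RoiAtlas
from .groupdiff import EdgeDifferenceResult


def count_pairs(n_nodes: int) -> int:
    """Number of unordered node pairs, C(n, 2)."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def network_categories() -> list[str]:
    """The ten network-pair categories in canonical order (within first)."""
    within = [f"{n}-{n}" for n in NETWORKS]
    between = [
        f"{NETWORKS[i]}-{NETWORKS[j]}"
        for i in range(len(NETWORKS))
        for j in range(i + 1, len(NETWORKS))
    ]
    return within + between


def pair_category(atlas: RoiAtlas, roi_a: str, roi_b: str) -> str:
    """Network-pair category of an unordered ROI pair, e.g. ``"SN-DAN"``."""
    if roi_a == roi_b:
        raise ValueError("pair must consist of two distinct ROIs")
    for roi in (roi_a, roi_b):
        if roi not in atlas.network_of:
            raise ValueError(f"unknown ROI {roi!r}")
    na, nb = atlas.network_of[roi_a], atlas.network_of[roi_b]
    na, nb = sorted((na, nb), key=NETWORKS.index)
    return f"{na}-{nb}"


def is_within(category: str) -> bool:
    a, b = category.split("-")
    return a == b


@dataclass
class NetworkSummary:
    """Category and node tallies of flagged edges across modalities."""

    category_counts: dict[str, int]
    node_counts: dict[str, int]
    per_modality_category: dict[str, dict[str, int]]
    per_modality_node: dict[str, dict[str, int]]
    n_flagged: int

    def category_percent(self) -> dict[str, float]:
        total = max(self.n_flagged, 1)
        return {c: 100.0 * v / total for c, v in self.category_counts.items()}

    def node_percent(self) -> dict[str, float]:
        total = max(2 * self.n_flagged, 1)
        return {n: 100.0 * v / total for n, v in self.node_counts.items()}

    def network_node_percent(self, atlas: RoiAtlas) -> dict[str, float]:
        """Share of node involvements per network (sums to 100)."""
        shares = self.node_percent()
        out = {net: 0.0 for net in NETWORKS}
        for roi, pct in shares.items():
            out[atlas.network_of[roi]] += pct
        return out

    def most_affected_networks(self, atlas: RoiAtlas) -> list[str]:
        """Networks with maximal node involvement; ties reported as ties."""
        if self.n_flagged == 0:
            return []
        shares = self.network_node_percent(atlas)
        best = max(shares.values())
        return [n for n, v in shares.items() if v == best]

    def category_frame(self) -> pd.DataFrame:
        pct = self.category_percent()
        return pd.DataFrame(
            {
                "category": list(self.category_counts),
                "within": [is_within(c) for c in self.category_counts],
                "count": list(self.category_counts.values()),
                "percent": [pct[c] for c in self.category_counts],
            }
        )

    def node_frame(self, atlas: RoiAtlas) -> pd.DataFrame:
        pct = self.node_percent()
        return pd.DataFrame(
            {
                "node": list(self.node_counts),
                "network": [atlas.network_of[n] for n in self.node_counts],
                "count": list(self.node_counts.values()),
                "percent": [pct[n] for n in self.node_counts],
            }
        )


def summarize(
    results: list[EdgeDifferenceResult], atlas: RoiAtlas
) -> NetworkSummary:
    """Tally flagged edges per network category and per node.

    All results must share the atlas's ROI order.  Counts are over nonzero
    flags regardless of sign.
    """
    if not results:
        raise ValueError("no edge-difference results to summarize")
    cats = network_categories()
    category_counts = {c: 0 for c in cats}
    node_counts = {r: 0 for r in atlas.roi_names}
    per_mod_cat: dict[str, dict[str, int]] = {}
    per_mod_node: dict[str, dict[str, int]] = {}
    n_flagged = 0
    for res in results:
        if res.roi_names != list(atlas.roi_names):
            raise ValueError(
                f"result for {res.modality!r} does not share the atlas ROI order"
            )
        mc = per_mod_cat.setdefault(res.modality, {c: 0 for c in cats})
        mn = per_mod_node.setdefault(res.modality, {r: 0 for r in atlas.roi_names})
        for (a, b), flag in zip(res.pairs, res.flags):
            if flag == 0:
                continue
            cat = pair_category(atlas, a, b)
            category_counts[cat] += 1
            mc[cat] += 1
            for roi in (a, b):
                node_counts[roi] += 1
                mn[roi] += 1
            n_flagged += 1
    return NetworkSummary(
        category_counts=category_counts,
        node_counts=node_counts,
        per_modality_category=per_mod_cat,
        per_modality_node=per_mod_node,
        n_flagged=n_flagged,
    )
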