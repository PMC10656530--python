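"""Characterization of significant FC-traits.

A trait that survives screening is described by (i) its strongest edges
(top 1% by absolute loading by default), (ii) the nodal strength each ROI
accumulates from those edges, and (iii) a per-network contribution score
with the conventional absent / medium / high ("-", "+", "++") labels.
All steps use absolute loadings, so the description is invariant to the
trait's global sign.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import devectorize
from .parcellation import ParcellationScheme
from .traits import FCTrait

__all__ = [
    "TraitSummary",
    "top_percent_edges",
    "nodal_strength",
    "network_contribution",
    "summarize_trait",
    "export_plot_data",
]

NORMALIZATIONS = ("zscore", "maxabs", "none")


def _normalize_loadings(pattern: np.ndarray, normalization: str) -> np.ndarray:
    """Normalize loadings over the whole pattern (not just selected edges)."""
    if normalization == "zscore":
        sd = pattern.std()
        if sd == 0:
            return pattern - pattern.mean()
        return (pattern - pattern.mean()) / sd
    if normalization == "maxabs":
        peak = np.abs(pattern).max()
        return pattern / peak if peak else pattern
    if normalization == "none":
        return pattern
    raise ValueError(f"unknown normalization {normalization!r}; use one of {NORMALIZATIONS}")


def top_percent_edges(
    trait: FCTrait, parcellation: ParcellationScheme, pct: float = 1.0
) -> pd.DataFrame:
    """The ceil(pct/100 * E) strongest edges of a trait by |loading|.

    Ties break by edge index (the fixed vectorization order), so the
    selection is deterministic.  Returned table resolves both endpoints
    through the parcellation (roi id, name, hemisphere, network).
    """
    if not 0 < pct <= 100:
        raise ValueError("pct must lie in (0, 100]")
    pattern = np.asarray(trait.pattern, dtype=float)
    if pattern.size == 0 or not pattern.any():
        raise ValueError("trait pattern is empty")
    e = pattern.size
    n_top = max(1, math.ceil(pct / 100.0 * e))
    order = np.lexsort((np.arange(e), -np.abs(pattern)))
    chosen = np.sort(order[:n_top])
    i, j = np.triu_indices(parcellation.n_rois, k=1)
    lut = parcellation.table.set_index("roi_id")
    rows = pd.DataFrame(
        {
            "edge_index": chosen,
            "roi_i": i[chosen] + 1,
            "roi_j": j[chosen] + 1,
            "loading": pattern[chosen],
        }
    )
    for side in ("i", "j"):
        ids = rows[f"roi_{side}"]
        rows[f"roi_name_{side}"] = lut.loc[ids, "roi_name"].to_numpy()
        rows[f"hemisphere_{side}"] = lut.loc[ids, "hemisphere"].to_numpy()
        rows[f"network_{side}"] = lut.loc[ids, "network"].to_numpy()
    return rows.sort_values("loading", key=np.abs, ascending=False, kind="stable").reset_index(
        drop=True
    )


def nodal_strength(
    trait: FCTrait,
    edges: pd.DataFrame,
    parcellation: ParcellationScheme,
    normalization: str = "zscore",
) -> pd.Series:
    """Per-ROI sum of |normalized loading| over the selected edges.

    Loadings are normalized over the full pattern under the chosen scheme,
    then each selected edge contributes its absolute normalized loading to
    both endpoints.  ROIs touching no selected edge score 0.
    """
    normalized = _normalize_loadings(np.asarray(trait.pattern, dtype=float), normalization)
    strength = np.zeros(parcellation.n_rois)
    contrib = np.abs(normalized[edges["edge_index"].to_numpy()])
    np.add.at(strength, edges["roi_i"].to_numpy() - 1, contrib)
    np.add.at(strength, edges["roi_j"].to_numpy() - 1, contrib)
    return pd.Series(strength, index=parcellation.table["roi_id"].to_numpy(), name="strength")


def network_contribution(
    trait: FCTrait,
    parcellation: ParcellationScheme,
    t_low: float = 1.0,
    t_high: float = 1.5,
) -> tuple[dict[str, float], dict[str, str]]:
    """Relative network scores and absent/medium/high labels.

    score(network) = mean |loading| over edges with >= 1 endpoint in the
    network, divided by the pattern-wide mean |loading|, so 1.0 means "as
    loaded as an average edge".  Labels: score < t_low -> "-";
    t_low <= score < t_high -> "+" (t_low inclusive, so a perfectly uniform
    pattern is labelled medium everywhere); score >= t_high -> "++".
    """
    if not 0 <= t_low <= t_high:
        raise ValueError("need 0 <= t_low <= t_high")
    pattern = np.abs(np.asarray(trait.pattern, dtype=float))
    overall = pattern.mean()
    i, j = np.triu_indices(parcellation.n_rois, k=1)
    net = parcellation.network_of()
    scores: dict[str, float] = {}
    labels: dict[str, str] = {}
    for network in parcellation.networks:
        member = (net[i] == network) | (net[j] == network)
        score = float(pattern[member].mean() / overall) if member.any() and overall > 0 else 0.0
        scores[network] = score
        labels[network] = "-" if score < t_low else ("+" if score < t_high else "++")
    return scores, labels


@dataclass
class TraitSummary:
    """Everything needed to describe and plot one significant trait."""

    trait_id: int
    top_edges: pd.DataFrame = field(repr=False)
    nodal_strength: pd.Series = field(repr=False)
    network_scores: dict[str, float]
    network_labels: dict[str, str]


def summarize_trait(
    trait: FCTrait,
    parcellation: ParcellationScheme,
    pct: float = 1.0,
    normalization: str = "zscore",
    t_low: float = 1.0,
    t_high: float = 1.5,
) -> TraitSummary:
    """Run the full characterization of one trait."""
    edges = top_percent_edges(trait, parcellation, pct=pct)
    strength = nodal_strength(trait, edges, parcellation, normalization=normalization)
    scores, labels = network_contribution(trait, parcellation, t_low=t_low, t_high=t_high)
    return TraitSummary(trait.trait_id, edges, strength, scores, labels)


def export_plot_data(summary: TraitSummary, out_dir) -> dict[str, Path]:
    """Write plot-ready artifacts for one trait summary.

    Produces an edge-list TSV ordered by network then hemisphere (for
    circular/chord plotting), a nodal-strength TSV keyed by roi_id, and a
    network-label JSON.  Returns the written paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"trait{summary.trait_id:03d}"

    edge_cols = [
        "edge_index",
        "roi_i",
        "roi_j",
        "roi_name_i",
        "roi_name_j",
        "hemisphere_i",
        "hemisphere_j",
        "network_i",
        "network_j",
        "loading",
    ]
    edges = summary.top_edges[edge_cols].sort_values(
        ["network_i", "hemisphere_i", "network_j", "hemisphere_j", "edge_index"],
        kind="stable",
    )
    paths = {
        "edges": out_dir / f"{tag}_edges.tsv",
        "nodal_strength": out_dir / f"{tag}_nodal_strength.tsv",
        "network_labels": out_dir / f"{tag}_networks.json",
    }
    edges.to_csv(paths["edges"], sep="\t", index=False)
    summary.nodal_strength.rename_axis("roi_id").to_frame().to_csv(
        paths["nodal_strength"], sep="\t"
    )
    with open(paths["network_labels"], "w") as fh:
        json.dump(
            {
                "trait_id": summary.trait_id,
                "scores": summary.network_scores,
                "labels": summary.network_labels,
            },
            fh,
            indent=2,
        )
    return paths


def trait_as_matrix(trait: FCTrait, n_rois: int) -> np.ndarray:
    """Devectorized square view of a trait pattern (diagonal set to 1)."""
    return devectorize(trait.pattern, n_rois)
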