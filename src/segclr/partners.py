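"""Cell typing of synaptic partners and axonal-sorting profiles.

Each synapse has a pre- and a postsynaptic segment; the fragment around
the nearest embedding node on each side is classified through a fixed
uncertainty cascade:

1. fragments whose furthest aggregation distance R_max is below 2.5 um
   are too small to type -> UNC;
2. fragments whose coarse-model (excitatory/inhibitory/glia)
   Dempster-Shafer uncertainty exceeds 0.45 -> UNC;
3. fragments coarsely predicted glia -> UNC (glia do not form synapses
   in this analysis);
4. inhibitory fragments receive the highest-probability inhibitory
   subtype when the fine-model uncertainty is below 0.05, else I-UNC;
5. excitatory fragments receive, when the fine-model uncertainty is
   below 0.05, the thalamocortical label if its probability exceeds the
   summed pyramidal-subtype probability and the best pyramidal subtype
   otherwise; else P-UNC.

Axonal sorting bins a presynaptic cell's output synapses by path length
from the soma (20 um bins) and tracks the excitatory:inhibitory ratio of
postsynaptic partners across bins, averaged over cells.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeleton import Skeleton
from .store import AggregatedEmbedding, EmbeddingStore

UNC = "UNC"
I_UNC = "I-UNC"
P_UNC = "P-UNC"

DEFAULT_AGG_RADIUS_NM = 25_000.0


@dataclass(frozen=True)
class CascadeThresholds:
    r_max_min_nm: float = 2500.0
    u_coarse_max: float = 0.45
    u_fine_max: float = 0.05


@dataclass(frozen=True)
class ClassTaxonomy:
    """Names tying coarse and fine model outputs to the cascade rules."""

    excitatory: str = "excitatory"
    inhibitory: str = "inhibitory"
    glia: str = "glia"
    inhibitory_subtypes: tuple[str, ...] = ()
    pyramidal_subtypes: tuple[str, ...] = ()
    thalamocortical: str | None = None

    def is_excitatory_label(self, label: str) -> bool:
        return (label == self.excitatory or label == P_UNC
                or label in self.pyramidal_subtypes
                or label == self.thalamocortical)

    def is_inhibitory_label(self, label: str) -> bool:
        return (label == self.inhibitory or label == I_UNC
                or label in self.inhibitory_subtypes)


@dataclass
class PartnerLabel:
    synapse_id: int
    side: str                  # "pre" | "post"
    segment_id: int
    label: str
    stage: str                 # cascade stage that fixed the label
    u_coarse: float = math.nan
    u_fine: float = math.nan
    r_max_nm: float = math.nan


def _subset_prob(output, names) -> dict[str, float]:
    p = output.probabilities[0]
    return {c: float(p[i]) for i, c in enumerate(output.class_names)
            if c in names}


def classify_fragment(agg: AggregatedEmbedding | None, coarse_model,
                      fine_model, taxonomy: ClassTaxonomy,
                      thresholds: CascadeThresholds = CascadeThresholds()):
    """Run the uncertainty cascade on one aggregated fragment embedding.

    Returns (label, stage, u_coarse, u_fine). ``agg`` may be None when the
    fragment has no embedding at all.
    """
    if agg is None:
        return UNC, "no_embedding", math.nan, math.nan
    if agg.r_max_nm < thresholds.r_max_min_nm:
        return UNC, "short_fragment", math.nan, math.nan
    x = agg.mean_vector[None, :]
    coarse = coarse_model.predict_uncertainty(x)
    u_c = float(coarse.uncertainty[0])
    if u_c > thresholds.u_coarse_max:
        return UNC, "uncertain_coarse", u_c, math.nan
    coarse_label = str(coarse.predicted[0])
    if coarse_label == taxonomy.glia:
        return UNC, "glia", u_c, math.nan
    fine = fine_model.predict_uncertainty(x)
    u_f = float(fine.uncertainty[0])
    if coarse_label == taxonomy.inhibitory:
        if u_f < thresholds.u_fine_max:
            probs = _subset_prob(fine, taxonomy.inhibitory_subtypes)
            if probs:
                best = max(sorted(probs), key=lambda c: probs[c])
                return best, "inhibitory_subtype", u_c, u_f
        return I_UNC, "inhibitory_uncertain", u_c, u_f
    # excitatory
    if u_f < thresholds.u_fine_max:
        pyr = _subset_prob(fine, taxonomy.pyramidal_subtypes)
        tc_p = 0.0
        if taxonomy.thalamocortical is not None:
            tc_p = _subset_prob(fine, (taxonomy.thalamocortical,)).get(
                taxonomy.thalamocortical, 0.0)
        if tc_p > sum(pyr.values()):
            return taxonomy.thalamocortical, "thalamocortical", u_c, u_f
        if pyr:
            best = max(sorted(pyr), key=lambda c: pyr[c])
            return best, "pyramidal_subtype", u_c, u_f
    return P_UNC, "excitatory_uncertain", u_c, u_f


def _nearest_embedded_node(store: EmbeddingStore, skeleton: Skeleton,
                           xyz_nm) -> int | None:
    """Embedded skeleton node closest in Euclidean space to ``xyz_nm``."""
    idx = store.node_index.get(skeleton.segment_id, {})
    if not idx:
        return None
    nids = sorted(idx)
    coords = skeleton.coords_array(nids)
    d2 = ((coords - np.asarray(xyz_nm, float)) ** 2).sum(axis=1)
    best = np.flatnonzero(d2 == d2.min())
    if len(best) > 1:
        order = np.lexsort((coords[best, 2], coords[best, 1], coords[best, 0]))
        return nids[best[order[0]]]
    return nids[best[0]]


def type_synapses(synapses, store: EmbeddingStore,
                  skeletons: dict[int, Skeleton], coarse_model, fine_model,
                  taxonomy: ClassTaxonomy,
                  thresholds: CascadeThresholds = CascadeThresholds(),
                  radius_nm: float = DEFAULT_AGG_RADIUS_NM):
    """Type both partners of every synapse; no synapse is ever dropped.

    Returns (typed DataFrame, filter report). The report counts, per
    side, how many fragments each cascade stage labeled.
    """
    table = synapses.table if hasattr(synapses, "table") else synapses
    if len(table) == 0:
        raise ValueError("empty synapse table")
    rows = []
    report: dict[str, dict[str, int]] = {"pre": {}, "post": {}}
    for rec in table.itertuples(index=False):
        xyz = (rec.x, rec.y, rec.z)
        entry = {"synapse_id": int(rec.synapse_id),
                 "x": float(rec.x), "y": float(rec.y), "z": float(rec.z)}
        for side, seg in (("pre", int(rec.pre_segment_id)),
                          ("post", int(rec.post_segment_id))):
            agg = None
            if seg in skeletons:
                node = _nearest_embedded_node(store, skeletons[seg], xyz)
                if node is not None:
                    agg = store.aggregate(skeletons[seg], node, radius_nm)
            label, stage, u_c, u_f = classify_fragment(
                agg, coarse_model, fine_model, taxonomy, thresholds)
            report[side][stage] = report[side].get(stage, 0) + 1
            entry.update({
                f"{side}_segment_id": seg,
                f"{side}_label": label,
                f"{side}_stage": stage,
                f"{side}_u_coarse": u_c,
                f"{side}_u_fine": u_f,
                f"{side}_r_max_nm": agg.r_max_nm if agg is not None else math.nan,
            })
        rows.append(entry)
    typed = pd.DataFrame(rows)
    n = len(typed)
    for side in ("pre", "post"):
        report[side] = {"counts": report[side],
                        "fractions": {k: v / n for k, v in report[side].items()}}
    report["n_synapses"] = n
    return typed, report


# ---------------------------------------------------------------------------
# axonal sorting


@dataclass
class SortingProfile:
    bin_width_nm: float
    table: pd.DataFrame  # bin_index, bin_lo_um, mean_exc_ratio, sem, n_cells


def cell_sorting_ratios(typed: pd.DataFrame, skeleton: Skeleton,
                        soma_node: int, taxonomy: ClassTaxonomy,
                        bin_width_nm: float = 20_000.0) -> dict[int, tuple[int, int]]:
    """Per-bin (excitatory, inhibitory) counts of one presynaptic cell.

    Synapse distance is the path length from the soma to the presynaptic
    skeleton node nearest the synapse; postsynaptic partners labeled
    uncertain (UNC) are ignored.
    """
    if soma_node not in skeleton.graph:
        raise KeyError(f"soma node {soma_node} not on skeleton")
    dists = skeleton.distances_from(soma_node)
    nids = skeleton.node_ids
    coords = skeleton.coords_array(nids)
    bins: dict[int, list[int]] = {}
    for rec in typed.itertuples(index=False):
        label = rec.post_label
        if label == UNC:
            continue
        if taxonomy.is_excitatory_label(label):
            kind = 0
        elif taxonomy.is_inhibitory_label(label):
            kind = 1
        else:
            continue
        xyz = np.array([rec.x, rec.y, rec.z]) if hasattr(rec, "x") else None
        if xyz is None:
            raise ValueError("typed table must carry synapse x, y, z")
        d2 = ((coords - xyz) ** 2).sum(axis=1)
        node = nids[int(np.argmin(d2))]
        dist = dists.get(node, math.inf)
        if not math.isfinite(dist):
            continue
        b = int(dist // bin_width_nm)
        bins.setdefault(b, [0, 0])[kind] += 1
    return {b: tuple(v) for b, v in bins.items()}


def axonal_sorting(per_cell_typed: dict[int, pd.DataFrame],
                   skeletons: dict[int, Skeleton], soma_nodes: dict[int, int],
                   taxonomy: ClassTaxonomy,
                   bin_width_nm: float = 20_000.0) -> SortingProfile:
    """Mean +/- s.e.m. excitatory ratio per distance bin across cells.

    Bins with a single contributing cell report s.e.m. 0 with n_cells=1;
    bins with no contributing cell are omitted.
    """
    per_bin: dict[int, list[float]] = {}
    for cell_id, typed in per_cell_typed.items():
        counts = cell_sorting_ratios(typed, skeletons[cell_id],
                                     soma_nodes[cell_id], taxonomy,
                                     bin_width_nm)
        for b, (ne, ni) in counts.items():
            if ne + ni:
                per_bin.setdefault(b, []).append(ne / (ne + ni))
    rows = []
    for b in sorted(per_bin):
        vals = np.asarray(per_bin[b])
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"bin_index": b, "bin_lo_um": b * bin_width_nm / 1000.0,
                     "bin_hi_um": (b + 1) * bin_width_nm / 1000.0,
                     "mean_exc_ratio": float(vals.mean()), "sem": sem,
                     "n_cells": len(vals)})
    return SortingProfile(bin_width_nm, pd.DataFrame(rows))


def depth_profile(values: np.ndarray, coordinate: np.ndarray,
                  bin_width: float) -> pd.DataFrame:
    """Generic 1-D histogram of label values along a user-supplied axis
    coordinate (e.g. cortical depth after an external alignment)."""
    order = np.argsort(coordinate)
    coord = np.asarray(coordinate)[order]
    vals = np.asarray(values, dtype=object)[order]
    rows = []
    for b in range(int(coord.min() // bin_width),
                   int(coord.max() // bin_width) + 1):
        mask = (coord >= b * bin_width) & (coord < (b + 1) * bin_width)
        if mask.any():
            sub = vals[mask]
            counts = pd.Series(sub).value_counts().to_dict()
            rows.append({"bin_lo": b * bin_width, "n": int(mask.sum()),
                         "counts": counts})
    return pd.DataFrame(rows)
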