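"""Synaptic-partner cascade and axonal-sorting profiles."""
import math

import numpy as np
import pandas as pd
import pytest

from segclr.partners import (CascadeThresholds, ClassTaxonomy, I_UNC, P_UNC,
                             UNC, axonal_sorting, cell_sorting_ratios,
                             classify_fragment, type_synapses)
from segclr.skeleton import polyline_skeleton
from segclr.sngp import UncertaintyOutput
from segclr.store import AggregatedEmbedding

TAXONOMY = ClassTaxonomy(
    inhibitory_subtypes=("BC", "MC"),
    pyramidal_subtypes=("P2", "P3"),
    thalamocortical="THLC",
)

COARSE_CLASSES = ["excitatory", "glia", "inhibitory"]
FINE_CLASSES = ["BC", "MC", "P2", "P3", "THLC"]


class StubModel:
    """Returns preset (probabilities, u) keyed by the embedding's first
    component, which the fixtures use as a lookup index."""

    def __init__(self, class_names, table):
        self.class_names = class_names
        self.table = table  # idx -> (probs, u)

    def predict_uncertainty(self, x):
        probs, u = self.table[int(round(float(x[0, 0])))]
        p = np.asarray(probs, float)[None]
        logits = np.log(np.maximum(p, 1e-12))
        return UncertaintyOutput(self.class_names, logits,
                                 np.zeros(1), logits, np.array([u]), 0.0)


def agg(idx, r_max=20_000.0):
    vec = np.zeros(64)
    vec[0] = idx
    return AggregatedEmbedding(1, 0, (0, 0, 0), 25_000.0, vec, 5, r_max)


def coarse(p_exc, p_glia, p_inh, u):
    return ([p_exc, p_glia, p_inh], u)


class TestCascadeRules:
    def make_models(self, coarse_table, fine_table):
        return (StubModel(COARSE_CLASSES, coarse_table),
                StubModel(FINE_CLASSES, fine_table))

    def test_short_fragment_is_unc_regardless(self):
        cm, fm = self.make_models({0: coarse(1, 0, 0, 0.01)},
                                  {0: ([0, 0, 0, 0, 1], 0.01)})
        label, stage, *_ = classify_fragment(agg(0, r_max=1000.0), cm, fm,
                                             TAXONOMY)
        assert label == UNC and stage == "short_fragment"

    def test_missing_embedding_is_unc(self):
        cm, fm = self.make_models({}, {})
        label, stage, *_ = classify_fragment(None, cm, fm, TAXONOMY)
        assert label == UNC and stage == "no_embedding"

    def test_coarse_uncertainty_above_threshold(self):
        cm, fm = self.make_models({0: coarse(0.9, 0.05, 0.05, 0.5)}, {})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == UNC and stage == "uncertain_coarse"

    def test_glia_prediction_goes_uncertain(self):
        cm, fm = self.make_models({0: coarse(0.1, 0.8, 0.1, 0.1)}, {})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == UNC and stage == "glia"

    def test_inhibitory_subtype_when_fine_certain(self):
        cm, fm = self.make_models({0: coarse(0.1, 0.0, 0.9, 0.1)},
                                  {0: ([0.2, 0.7, 0.05, 0.03, 0.02], 0.01)})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == "MC" and stage == "inhibitory_subtype"

    def test_inhibitory_fallback_i_unc(self):
        cm, fm = self.make_models({0: coarse(0.1, 0.0, 0.9, 0.1)},
                                  {0: ([0.5, 0.4, 0.05, 0.03, 0.02], 0.2)})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == I_UNC

    def test_thalamocortical_beats_summed_pyramidal(self):
        # P(THLC)=0.4 vs P2+P3=0.35 -> thalamocortical
        cm, fm = self.make_models({0: coarse(0.9, 0.0, 0.1, 0.1)},
                                  {0: ([0.1, 0.15, 0.2, 0.15, 0.4], 0.01)})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == "THLC" and stage == "thalamocortical"

    def test_best_pyramidal_otherwise(self):
        cm, fm = self.make_models({0: coarse(0.9, 0.0, 0.1, 0.1)},
                                  {0: ([0.05, 0.05, 0.45, 0.25, 0.2], 0.01)})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == "P2" and stage == "pyramidal_subtype"

    def test_excitatory_fallback_p_unc(self):
        cm, fm = self.make_models({0: coarse(0.9, 0.0, 0.1, 0.1)},
                                  {0: ([0.1, 0.1, 0.3, 0.3, 0.2], 0.3)})
        label, stage, *_ = classify_fragment(agg(0), cm, fm, TAXONOMY)
        assert label == P_UNC


def build_typed_world(short_pre=()):
    """Mini world: segments 1..4 with straight skeletons and an embedding
    store carrying index-coded vectors; synapses between 1->2, 3->4."""
    from segclr.store import EmbeddingStore

    skeletons, store = {}, EmbeddingStore(dim=64)
    for sid in (1, 2, 3, 4):
        n = 3 if sid in short_pre else 25
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n) * 1000.0
        pts[:, 1] = sid * 10_000.0
        sk = polyline_skeleton(sid, pts)
        skeletons[sid] = sk
        emb = np.zeros((n, 64))
        emb[:, 0] = sid  # model lookup key
        store.add_rows(sid, sk.coords_array(), emb, node_ids=sk.node_ids)
    return skeletons, store


class TestTypeSynapses:
    def models(self):
        coarse_table = {
            1: coarse(0.9, 0.02, 0.08, 0.1),   # excitatory
            2: coarse(0.05, 0.05, 0.9, 0.1),   # inhibitory
            3: coarse(0.9, 0.02, 0.08, 0.1),
            4: coarse(0.1, 0.85, 0.05, 0.1),   # glia
        }
        fine_table = {
            1: ([0.02, 0.02, 0.7, 0.16, 0.1], 0.01),   # P2
            2: ([0.8, 0.1, 0.04, 0.03, 0.03], 0.01),   # BC
            3: ([0.05, 0.05, 0.2, 0.15, 0.55], 0.01),  # THLC
            4: ([0.2, 0.2, 0.2, 0.2, 0.2], 0.5),
        }
        return (StubModel(COARSE_CLASSES, coarse_table),
                StubModel(FINE_CLASSES, fine_table))

    def synapses(self):
        rows = [(0, 1, 2, 5000.0, 15_000.0, 0.0),
                (1, 3, 4, 5000.0, 35_000.0, 0.0),
                (2, 1, 2, 9000.0, 15_000.0, 0.0)]
        return pd.DataFrame(rows, columns=["synapse_id", "pre_segment_id",
                                           "post_segment_id", "x", "y", "z"])

    def test_labels_and_conservation(self):
        skeletons, store = build_typed_world()
        cm, fm = self.models()
        typed, report = type_synapses(self.synapses(), store, skeletons, cm,
                                      fm, TAXONOMY)
        assert len(typed) == 3
        assert typed.pre_label.tolist() == ["P2", "THLC", "P2"]
        assert typed.post_label.tolist() == ["BC", UNC, "BC"]
        assert report["post"]["counts"]["glia"] == 1
        assert report["n_synapses"] == 3

    def test_stage_counts_sum_to_input(self):
        skeletons, store = build_typed_world()
        cm, fm = self.models()
        typed, report = type_synapses(self.synapses(), store, skeletons, cm,
                                      fm, TAXONOMY)
        for side in ("pre", "post"):
            assert sum(report[side]["counts"].values()) == len(typed)

    def test_short_fraction_reported(self):
        skeletons, store = build_typed_world(short_pre=(1,))
        cm, fm = self.models()
        syn = self.synapses()
        typed, report = type_synapses(syn, store, skeletons, cm, fm, TAXONOMY)
        # segment 1 (2 um long) feeds two of the three presynaptic sides
        assert report["pre"]["counts"]["short_fragment"] == 2
        assert report["pre"]["fractions"]["short_fragment"] == pytest.approx(2 / 3)
        assert (typed.loc[typed.pre_segment_id == 1, "pre_label"] == UNC).all()

    def test_missing_store_segment_goes_unc(self):
        skeletons, store = build_typed_world()
        cm, fm = self.models()
        syn = self.synapses()
        syn.loc[0, "post_segment_id"] = 99
        typed, report = type_synapses(syn, store, skeletons, cm, fm, TAXONOMY)
        assert typed.loc[0, "post_label"] == UNC
        assert report["post"]["counts"]["no_embedding"] == 1

    def test_empty_table_rejected(self):
        skeletons, store = build_typed_world()
        cm, fm = self.models()
        with pytest.raises(ValueError):
            type_synapses(self.synapses().iloc[:0], store, skeletons, cm, fm,
                          TAXONOMY)


def typed_frame(entries):
    return pd.DataFrame(entries, columns=["synapse_id", "x", "y", "z",
                                          "post_label"])


class TestAxonalSorting:
    def straight_skeleton(self, length_um=60.0):
        n = int(length_um) + 1
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n) * 1000.0
        return polyline_skeleton(1, pts)

    def test_hand_binned_example(self):
        sk = self.straight_skeleton()
        typed = typed_frame([
            (0, 5_000.0, 0, 0, "excitatory"),
            (1, 25_000.0, 0, 0, "inhibitory"),
            (2, 45_000.0, 0, 0, "excitatory")])
        counts = cell_sorting_ratios(typed, sk, 0, TAXONOMY)
        assert counts == {0: (1, 0), 1: (0, 1), 2: (1, 0)}

    def test_all_excitatory_ratio_one(self):
        sk = self.straight_skeleton()
        typed = typed_frame([(i, d, 0, 0, "excitatory")
                             for i, d in enumerate([3e3, 22e3, 41e3, 59e3])])
        profile = axonal_sorting({1: typed}, {1: sk}, {1: 0}, TAXONOMY)
        assert (profile.table.mean_exc_ratio == 1.0).all()

    def test_uncertain_synapses_ignored(self):
        sk = self.straight_skeleton()
        typed = typed_frame([(0, 5e3, 0, 0, "excitatory"),
                             (1, 6e3, 0, 0, UNC)])
        counts = cell_sorting_ratios(typed, sk, 0, TAXONOMY)
        assert counts == {0: (1, 0)}

    def test_subtype_labels_count_toward_coarse_ratio(self):
        sk = self.straight_skeleton()
        typed = typed_frame([(0, 5e3, 0, 0, "BC"), (1, 7e3, 0, 0, "THLC"),
                             (2, 8e3, 0, 0, I_UNC)])
        counts = cell_sorting_ratios(typed, sk, 0, TAXONOMY)
        assert counts == {0: (1, 2)}

    def test_sem_zero_for_single_cell(self):
        sk = self.straight_skeleton()
        typed = typed_frame([(0, 5e3, 0, 0, "excitatory")])
        profile = axonal_sorting({1: typed}, {1: sk}, {1: 0}, TAXONOMY)
        row = profile.table.iloc[0]
        assert row["sem"] == 0.0 and row.n_cells == 1

    def test_mean_and_sem_across_cells(self):
        sk = self.straight_skeleton()
        t1 = typed_frame([(0, 5e3, 0, 0, "excitatory"),
                          (1, 6e3, 0, 0, "inhibitory")])
        t2 = typed_frame([(0, 5e3, 0, 0, "excitatory")])
        sk2 = self.straight_skeleton()
        profile = axonal_sorting({1: t1, 2: t2}, {1: sk, 2: sk2},
                                 {1: 0, 2: 0}, TAXONOMY)
        row = profile.table.iloc[0]
        vals = np.array([0.5, 1.0])
        assert row.mean_exc_ratio == pytest.approx(vals.mean())
        assert row["sem"] == pytest.approx(vals.std(ddof=1) / math.sqrt(2))
        assert row.n_cells == 2

    def test_missing_soma_raises(self):
        sk = self.straight_skeleton()
        with pytest.raises(KeyError):
            cell_sorting_ratios(typed_frame([]), sk, 999, TAXONOMY)


def test_depth_profile_bins_counts():
    from segclr.partners import depth_profile

    values = ["E", "I", "E", "E"]
    coord = np.array([5.0, 15.0, 25.0, 27.0])
    prof = depth_profile(values, coord, bin_width=10.0)
    assert prof.bin_lo.tolist() == [0.0, 10.0, 20.0]
    assert prof.n.tolist() == [1, 1, 2]
    assert prof.counts.iloc[2] == {"E": 2}
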