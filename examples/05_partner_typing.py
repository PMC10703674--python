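"""Type synaptic partners through the uncertainty cascade.

Every synapse's pre- and postsynaptic fragment is classified from its
aggregated embedding: fragments shorter than 2.5 um (R_max) or with
coarse uncertainty above 0.45 stay uncertain (UNC), glia predictions are
excluded, and subtype labels are assigned only below 0.05 fine-model
uncertainty (thalamocortical when its probability beats the summed
pyramidal probability).
"""
import numpy as np

from segclr import (EncoderConfig, LossConfig, PairPools, SynthConfig,
                    build_encoder, generate, infer_all, train)
from segclr.partners import ClassTaxonomy, type_synapses
from segclr.sngp import fit_sngp

out = generate(SynthConfig(seed=7))
pools = PairPools.from_skeletons(out.skeletons)
encoder, _ = build_encoder(EncoderConfig.toy(), seed=0)
train(pools, out.volume, out.skeletons, encoder, LossConfig(batch_pairs=8),
      steps=150, seed=0)
store = infer_all(encoder, out.volume, out.skeletons)

labels = dict(zip(out.labels.cells.segment_id, out.labels.cells.class_name))
x, y = [], []
for sid in store.segment_ids:
    sk = out.skeletons[sid]
    for node in sorted(store.node_index[sid]):
        x.append(store.aggregate(sk, node, 5000.0).mean_vector)
        y.append(labels[sid])
x, y = np.array(x), np.array(y)

# coarse 3-class model; the synthetic world has no subtypes, so the same
# model doubles as the fine model with an empty subtype taxonomy
coarse = fit_sngp(x, y, seed=0, epochs=40, rff_dim=256)
taxonomy = ClassTaxonomy()
typed, report = type_synapses(out.synapses, store, out.skeletons, coarse,
                              coarse, taxonomy, radius_nm=10_000.0)

print(f"typed {report['n_synapses']} synapses")
for side in ("pre", "post"):
    stages = report[side]["counts"]
    print(f"  {side:>4}-side cascade stages: {stages}")
print("label counts (postsynaptic):")
print(typed.post_label.value_counts().to_string())
print("UNC marks fragments too short or too uncertain to type; "
      "every synapse keeps a row.")
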