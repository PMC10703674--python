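"""Classify cell fragments from aggregated embeddings.

Embeddings within a path-length radius R of a center node are averaged
per dimension; a linear probe (or a shallow residual MLP) then predicts
the cell class of the fragment. Larger R aggregates more context and
makes fragments easier to type.
"""
import numpy as np

from segclr import (EncoderConfig, LossConfig, PairPools, SynthConfig,
                    build_encoder, generate, infer_all, train)
from segclr.classify import macro_f1, train_linear

out = generate(SynthConfig(seed=7))
pools = PairPools.from_skeletons(out.skeletons)
encoder, _ = build_encoder(EncoderConfig.toy(), seed=0)
train(pools, out.volume, out.skeletons, encoder, LossConfig(batch_pairs=8),
      steps=150, seed=0)
store = infer_all(encoder, out.volume, out.skeletons)

labels = dict(zip(out.labels.cells.segment_id, out.labels.cells.class_name))
for radius_nm in (0.0, 2500.0, 10_000.0):
    x, y, segs = [], [], []
    for sid in store.segment_ids:
        sk = out.skeletons[sid]
        for node in sorted(store.node_index[sid]):
            agg = store.aggregate(sk, node, radius_nm)
            x.append(agg.mean_vector)
            y.append(labels[sid])
            segs.append(sid)
    x, y, segs = np.array(x), np.array(y), np.array(segs)
    # hold out one whole cell per class (no cell on both sides)
    rng = np.random.default_rng(0)
    test = np.zeros(len(y), bool)
    for cls in np.unique(y):
        test |= segs == rng.choice(np.unique(segs[y == cls]))
    probe = train_linear(x[~test], y[~test], seed=0)
    f1 = macro_f1(y[test], probe.predict(x[test]))
    print(f"aggregation radius {radius_nm / 1000:4.1f} um: "
          f"held-out-cell macro F1 = {f1:.3f} "
          f"({int(test.sum())} test fragments)")
print("On this easy synthetic task even single nodes classify perfectly; "
      "on harder data F1 rises with the aggregation radius.")
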