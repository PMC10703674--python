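"""Reject out-of-distribution fragments with an SNGP head.

A spectral-normalized residual classifier with a random-feature Gaussian
process output is trained on two of the three synthetic classes. The
Dempster-Shafer uncertainty u = K / (K + sum exp(h_k)), computed from
mean-field-adjusted logits, is low on the training classes and high on
the held-out class, so a calibrated threshold on u separates them.
"""
import numpy as np

from segclr import (EncoderConfig, LossConfig, PairPools, SynthConfig,
                    build_encoder, calibrate_threshold, generate, infer_all,
                    train)
from segclr.sngp import auroc, fit_sngp

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

held_out = "glia"
in_mask = y != held_out
model = fit_sngp(x[in_mask], y[in_mask], seed=0, epochs=40, rff_dim=256)
u_in = model.predict_uncertainty(x[in_mask]).uncertainty
u_out = model.predict_uncertainty(x[~in_mask]).uncertainty
print(f"trained on {sorted(set(y[in_mask]))}, held out {held_out!r}")
print(f"median u: in-distribution {np.median(u_in):.3f}, "
      f"held-out {np.median(u_out):.3f}")
score = auroc(np.concatenate([u_in, u_out]),
              np.repeat([False, True], [len(u_in), len(u_out)]))
print(f"AUROC of u for in vs out: {score:.3f}")
t, f1 = calibrate_threshold(np.concatenate([u_in, u_out]),
                            np.repeat([False, True],
                                      [len(u_in), len(u_out)]))
print(f"calibrated threshold u > {t:.3f} -> OOD-detection F1 = {f1:.3f}")
print("Fragments above the threshold would be relabeled OOD downstream.")
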