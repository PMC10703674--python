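"""Generate a synthetic segmented volume and inspect its ground truth.

Each "cell" is a random-walk tube with a class-specific radius regime and
intensity texture; the generating centerline is kept as an exact skeleton
and synapses are placed where two cells come within two voxels.
"""
import numpy as np

from segclr import SynthConfig, generate

out = generate(SynthConfig(seed=7, volume_shape=(96, 96, 96), n_cells=6,
                           target_length_nm=15_000.0))
vol = out.volume

print(f"volume: {vol.shape} voxels at {vol.voxel_size_nm} nm/voxel")
counts = vol.voxel_counts()
for row in out.labels.cells.itertuples(index=False):
    sk = out.skeletons[row.segment_id]
    print(f"  segment {row.segment_id}: {row.class_name:<11} "
          f"{counts.get(row.segment_id, 0):>7} voxels, "
          f"{sk.total_path_length() / 1000:5.1f} um of skeleton, "
          f"{len(sk)} nodes")
print(f"synapses: {len(out.synapses)} "
      f"(pre/post pairs where two segments touch)")
print(f"subcompartment node labels: "
      f"{out.labels.nodes.subcompartment.value_counts().to_dict()}")
print(f"voxel collisions resolved first-writer-wins: "
      f"{out.n_collision_voxels}")

# the class textures are separable by design: per-segment mean intensity
means = {s: float(vol.intensity[vol.segmentation == s].mean())
         for s in counts}
print("per-segment mean intensity (the separability knob):")
for s, m in sorted(means.items()):
    print(f"  segment {s}: {m:.3f}")
print("Distinct per-class means are what downstream probes learn to read.")
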