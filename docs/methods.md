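# Methods

This note documents the models, parameters, numerical choices and open
design decisions behind the package, and what the synthetic-data tests
do and do not establish about real EM data.

## Contrastive model

The encoder is a 3D ResNet-18: a 7³ stride-2 stem convolution, 3³
stride-2 max pooling, four stages of two basic residual blocks (widths
64/128/256/512, 1³ projection shortcuts where shape changes, batch
normalization after every convolution, no convolution biases), global
average pooling, then three fully connected bottleneck layers
512 → 512 → 512 → 64 producing the embedding. During training three
projection layers 64 → 144 → 64 → 16 feed the contrastive loss and are
dropped at inference. The published total for this training-time network
is 33,737,824 trainable parameters; the trunk fixes 33,160,000 of them,
and since the bottleneck/projection hidden widths are not published we
fixed them (512, 512 hidden in the bottleneck; 144, 64 hidden in the
projection) as the reconstruction that reproduces the printed total
exactly. No conventional width pattern (e.g. a SimCLR-style 64-wide
projection) matches the total under any standard parameter-counting
convention we enumerated, so the 144-wide projection hidden layer is a
deliberate choice, not a claim about the original implementation.

Losses. NT-Xent uses cosine similarity, temperature τ = 0.1, and all
2N−2 other batch examples as negatives; positive pairs are interleaved
rows (2i, 2i+1). Log-probabilities are computed by exact log-sum-exp (no
epsilon) so the loss matches a brute-force similarity-matrix oracle to
1e−6 even for saturated batches. The decorrelation term is the mean
squared off-diagonal Pearson correlation between embedding dimensions
over the batch; dimensions with zero variance contribute zero
correlation and zero gradient. Its weight `w_dec` defaults to 1.0 — the
relative weighting is not published — and is configurable.

Pair sampling. Candidate pairs are unordered, deduplicated, and assigned
to half-open distance buckets (lo, hi] with boundaries 0, 2,500, 10,000,
30,000, 150,000 nm; a distance of exactly 0 (the same node) is excluded.
At sampling time a bucket is drawn uniformly among the *segment's
non-empty* buckets, then a pair uniformly within it; segments in a batch
are drawn without replacement so batch negatives always come from other
segments. Both conventions (dedup, non-empty-bucket uniformity) resolve
points the published description leaves open.

Views and augmentation. Views are cubes in voxel index space
(anisotropic in nm), centered by flooring the nm coordinate to a voxel
index. Intensities are centered on the dataset mean so the fill value 0
outside the mask is photometrically neutral. Contrastive augmentation is
independent per-axis reflection (p = 0.5) plus an affine photometric
jitter of the masked-in voxels (brightness ±0.1, contrast ±10% —
magnitudes are not published and are exposed as arguments); supervised
augmentation replaces the jitter with axis-aligned 90° rotations. A
CLAHE hook exists for real volumes and is not applied to synthetic data.

Optimization. Momentum SGD (0.9) under a linear-warmup (5%) +
cosine-decay schedule with base rate 0.2 at a reference batch of 512
positive pairs, scaled linearly with the actual batch size; only "a
decay schedule starting at 0.2" is published, the shape is our choice.
Refinement continues training with no frozen layers at batch 8 and the
linearly scaled rate. Checkpoints store weights, batch-norm running
statistics and optimizer momentum, so a restarted run reproduces the
original loss trace bit-for-bit at equal seeds.

## Inference, storage, aggregation

Embeddings are computed in evaluation mode at skeleton nodes resampled
by a greedy depth-first walk from each component's lowest node id,
emitting a node whenever the cumulative path length since the last
emission reaches the spacing (default 1,500 nm). Segments below 1,000
voxels are skipped as trivial. Rows are keyed by segment id and XYZ nm
and shard to plain CSV (`segment_id,x,y,z,e0..e63`, hashed by segment
id, optionally zipped), mirroring the layout of the public embedding
releases. Aggregation is the per-dimension mean over all embedding rows
within path radius R on the segment's own skeleton (other segments never
contribute); R_max, the distance of the furthest contributing row, is
kept as a fragment-size proxy. Path length is Dijkstra over Euclidean
edge weights — "skeleton path length" read as arc length — and
cross-component distances are infinite. Nearest-row queries break exact
ties toward lexicographically smaller (x, y, z).

## Classifiers and protocols

The linear probe is multinomial logistic regression (scikit-learn). The
"ResNet-2" is two fully connected residual modules (default width 128,
unpublished in the source description) with input standardization,
trained by Adam; the supervised baseline shares the contrastive trunk
exactly and replaces bottleneck/projection with a classification softmax,
trained with supervised augmentation and class rebalancing. Subsampling
enforces each class to hold at least three examples and at least 10% of
the drawn sample (the published "10% of the examples" is ambiguous
between per-class floor and share-of-sample; we apply the per-class
floor `max(3, ceil(0.10·n))` and expose both knobs). Rebalancing repeats
each minority class's indices cyclically until all classes match the
largest. Cell-level cross-validation splits 75/25 *by cell* per class,
10 repeats, equal-class sampling of training embeddings, minority
repetition on the test side, unweighted macro F1, and pools confusion
matrices over runs before an equal-class resample.

## SNGP and out-of-distribution detection

Hidden layers of the ResNet-2 are constrained to spectral norm ≤ 0.95 by
one-step power iteration after each update. The output layer is a
random-Fourier-feature Gaussian process: φ(h) = √(2/D)·cos(Wh + b) with
W ~ N(0, 1/ℓ²) (D = 1024 features by default, length scale ℓ = 2 — the
original defers these to its cited construction, so they are exposed as
config), and trainable weights β. After training, a Laplace
approximation Σ⁻¹ = I + Σᵢ pᵢ(1−pᵢ) φᵢφᵢᵀ (class-shared, using the
maximum softmax probability) yields the predictive logit variance
σ²(x) = φᵀΣφ shared across classes. Logits are mean-field adjusted,
h/√(1+λσ²) with λ = 3/π², *before* the Dempster–Shafer uncertainty
u = K/(K + Σ exp h) is computed, matching the adjusted-logit usage. Far
from the training data φ decorrelates from the posterior, σ² grows, the
adjusted logits shrink toward zero and u rises toward the DS value at
zero logits (0.5) and beyond as logits go negative. Threshold
calibration scans midpoints between sorted unique u values and maximizes
OOD-detection F1, ties toward the smaller threshold. The cross-validated
OOD protocol trains on in-distribution cells only, scores held-out
in-distribution plus the full OOD pool, calibrates on a set-aside half,
relabels above-threshold predictions as OOD, and reports class-wise F1
with OOD examples weighted to 50% of the evaluation mass.

## Partner cascade and axonal sorting

The cascade is a total function — every fragment gets exactly one label
and one stage, and stage counts sum to the synapse count. λ = 2 is the
published choice for the partner analysis's adjusted logits and is set
on the models passed in. "Best subtype" is the argmax over the fine
model's member-class probabilities; the fine model's u uses its own
class count K. For the excitatory/inhibitory axonal-sorting ratio,
subtype-uncertain labels (I-UNC, P-UNC) still count toward their coarse
class — they passed the coarse-certainty gate — while UNC synapses are
excluded; synapse distance is the path length from the soma to the
*presynaptic* skeleton node nearest the synapse (the published analysis
is along the axon; whether the pre- or postsynaptic node anchors the
distance when they disagree is not specified). Bins of 20 µm report mean
and s.e.m. of the per-cell ratios; single-cell bins report s.e.m. 0 with
n = 1.

## Synthetic data: what it emulates and what it does not

Cells are persistent random-walk tubes (step 64 nm, angular diffusion
0.25 rad/step, up to 3 branches) swept as per-axis-scaled ellipsoids
into an anisotropic voxel grid (default 128³ voxels at 32×32×33 nm,
12 cells, ~25 µm target path length each), with first-writer-wins
collision handling and collision counting. Walks steer away from other
cells' territory (probe-and-retry, giving up when boxed in), so skeleton
nodes verifiably lie inside their own segment; trapped walks end early,
which naturally produces the small fragments the min-voxel and R_max
filters exist for. Three classes differ in radius regime, branch rate
and texture (mean/contrast/correlation-length of smoothed Gaussian
noise); texture means (0.30/0.55/0.80) are disjoint by design, giving
the documented separability floor (a mean-intensity classifier reaches
macro F1 ≥ 0.95). Node-level "subcompartment" labels follow the local
tube radius (thin < 160 nm = axon-like, < 320 nm = dendrite-like, else
soma-like). Synapses are sampled (Poisson, 0.5/µm of skeleton) at voxels
where another segment lies within two voxels. A merge switch relabels
one cell into another and bridges their skeletons at the closest node
pair, emulating an agglomeration merge error for the OOD uncertainty-map
test.

What passing tests show: the losses, geometry, protocols and cascade are
implemented correctly, and the pipeline end-to-end can learn and exploit
morphological/photometric class structure. What they do not show:
performance on real EM texture (no imaging artifacts, section
misalignment, staining gradients or realistic ultrastructure are
simulated), at real scale (billions of embeddings), or under real
segmentation error modes beyond the single merge switch. Note one
consequence observed in testing: voxel-level merges of *interwoven*
tubes contaminate the masked views of both cells (each view's mask now
includes the other cell), pushing the whole merged object off-manifold;
the uncertainty-map test therefore merges at the skeleton level, the
regime the figure-style analysis describes.

## Problem sizes and toy configuration

The test suite and examples use a toy encoder (33³ views, base width 8,
3³ stem kernel, bottleneck to the same 64-d embedding) trained for 200
steps at 8 positive pairs per batch, inference at 1,500 nm spacing, and
aggregation at R = 5 µm, sizes chosen so the complete synthetic study —
generation, contrastive training over three seeds, label-efficiency and
OOD protocols — runs in minutes on a single CPU. The full-size
configuration (129³ views, 64 base channels) is instantiated for the
parameter-count check and is runnable through the same code paths.

## Known limitations

- Pure-numpy training is single-threaded GEMM-bound; it is meant for
  fixture-scale experiments, not production training.
- Batch normalization uses batch statistics in training mode, so batch
  composition affects training dynamics (as usual); evaluation uses
  running averages and is deterministic.
- The SNGP Laplace covariance uses the class-shared max-probability
  approximation; per-class covariances are not implemented.
- The synthetic generator's placement can fail in very small volumes
  (bounded retries then an explicit error) and cells in dense volumes
  may end shorter than the target length.
- Coordinate transforms for anatomically aligned depth profiles are out
  of scope; `depth_profile` accepts a user-supplied axis instead.
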