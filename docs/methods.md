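# Methods

## Problem and data model

Myocardial-perfusion SPECT studies are read from *polar maps*: a compact 2-D
bullseye of relative tracer uptake over the left ventricle, apex at the
center, base at the rim. `polargcn` classifies single polar maps as normal
or abnormal (CAD-suspect) and localizes the suspect region, operating on
maps sampled at 460 points. The package fixes a 20-ring x 23-sector grid
(ring 0 = apex), consistent with the 23 x 20 raster used by the 2-D CNN
baseline; the true vendor sampling pattern is not public, so this layout is
a declared convention. Every map is normalized by its own maximum ("peak
uptake = 1"); no clipping or z-scoring is applied.

The grid carries the standard AHA 17-segment division (basal 1-6, mid 7-12,
apical 13-16, apical cap 17), realised as four equal 5-ring radial bands
with segments assigned by each node's angular center (angle 0 at the
anterior wall, counterclockwise; 6 x 60-degree spans for basal/mid, 4 x
90-degree spans for the apical band). Segments map onto coronary beds by
the standard Cerqueira assignment: LAD {1,2,7,8,13,14,17}, RCA
{3,4,9,10,15}, LCX {5,6,11,12,16}. Conventions differ at segments 15/17 in
parts of the literature; the mapping is centralised in one table so it can
be swapped.

## Graph model

The polar grid becomes an undirected unit-weight graph: angular neighbours
on the same ring (with wrap-around) and radial neighbours on adjacent rings
are connected (897 edges; interior degree 4, apex/base rings degree 3; the
apex ring is not connected across the pole). The combinatorial Laplacian
L = D - A drives both filter families; for Chebyshev filtering it is
rescaled to L~ = (2/lambda_max) L - I so the spectrum lies in [-1, 1],
with lambda_max from a dense symmetric eigensolver (n = 460 makes Lanczos
pointless).

Pooling uses a Graclus-style hierarchy: greedy pair matching with the
normalized-cut score A_ij (1/d_i + 1/d_j), nodes visited in
ascending-degree order, ties to the lowest index, unmatched nodes becoming
singletons. Coarse edges sum the merged weights (self-loops dropped).
After the requested number of halvings, singleton branches are padded with
isolated fake nodes so every level has exactly twice the nodes of the
next; a one-off permutation makes each coarse node's descendants a
contiguous block, so max-pooling is a reshape-and-reduce. Fake entries are
forced to -inf before each pool (pooling precedes the ReLU, so activations
can be negative) and all-fake blocks are zeroed afterwards. The whole
construction is deterministic for a fixed seed.

## Spectral filters

*Chebyshev*: y = sum_{k=0}^{K-1} T_k(L~) x theta_k + b, evaluated by the
three-term recurrence on signals only (never forming T_k as a matrix);
cost O(K |E|) per feature pair, K-hop localised.

*Cayley*: y = x c0 + 2 Re{ sum_{k=1}^K (M^k x) c_k } + b with
M = (hL - iI)(hL + iI)^{-1} and trainable spectral zoom h > 0. M is
applied by exact sparse complex LU solves (graphs here are <= ~500 nodes;
the Jacobi-iterated approximation used on large graphs is out of scope).
M is unitary for symmetric L, so the backward pass solves with
(hL - iI) = conj-system of the same factorisation, and dM/dh =
2i (hL+iI)^{-1} L (hL+iI)^{-1} gives the zoom gradient in closed form.

Both operators are verified against a dense eigendecomposition oracle
(random graphs, relative error <= 1e-8) and all trainable layers against
central finite differences.

## Architectures and training

All classifiers end in a 2-way softmax trained with categorical
cross-entropy and plain SGD (lr 1e-3, no momentum/decay/schedule, no
augmentation); mini-batch 64 for the dense/CNN baselines (70 epochs) and
30 / 20 for the Chebyshev / Cayley graph models (60 epochs). Separate
classifiers are trained for rest and stress maps.

- **FCN**: 460 -> dense 460 (ReLU) -> dense 2; exactly 212,982 trainable
  scalars.
- **CNN**: 23 x 20 raster -> conv 64@5x5 (same) -> 2x2 max-pool -> conv
  128@3x3 (same) -> 2x2 max-pool -> dense 256 -> dense 2. Pooling is
  ceil-mode, giving the 23x20 -> 12x10 -> 6x5 spatial chain.
- **GCNN (Chebyshev / Cayley)**: graph conv (order 16 / 4, width 32) ->
  pool 4 -> ReLU -> graph conv (order 32 / 6, width 64) -> pool 2 -> ReLU
  -> dense 2, over a 3-halving hierarchy. Feature widths are not pinned by
  the printed parameter counts and are exposed in `ModelConfig`
  (defaults 32/64).

The engine is hand-written numpy/scipy with explicit backward passes,
float32 compute (standard deep-learning precision; the pure filter
operators stay float64), and bit-deterministic behaviour for fixed seeds.
Filter coefficients initialise as He-style uniform
(+-sqrt(6/(K F_in)); for Cayley the 2K+1 real coefficient planes count as
fan-in): the layers feed ReLU stacks, so variance preservation requires
the sqrt(2) ReLU gain — a gain-1 scale measurably shrinks activations
~3x per layer and stalls SGD at this learning rate. Dense and conv layers
use Glorot uniform, biases zero, zoom h starts at 1.0. Exact softmax ties
resolve to "normal".

Evaluation: label-stratified 4-fold cross-validation (seeded shuffle);
agreement / sensitivity / specificity in percent with abnormal as the
positive class; pooled confusion counts across folds (so pooled agreement
is the sample-weighted fold mean). Cohen's kappa
(p_o - p_e)/(1 - p_e) is provided; a p_e of 1 raises a dedicated
"undefined" error rather than propagating NaN.

## Occlusion localization

For an abnormal map and a trained classifier, each AHA segment in turn is
replaced by the segment-mean uptake of the *training-set normal maps*
(computed per condition, never from test maps), the modified map is
re-classified, and the abnormal probability is recorded; the 17 values
render node-wise as a heatmap. Calls threshold at 0.4. Two polarities are
supported because the published description is ambiguous: the default
"abnormal" polarity calls a segment pathological when the recorded
post-occlusion probability is >= 0.4 (the literal reading); the "healing"
polarity calls it when occlusion drops the probability *below* threshold
(occluding the culprit segment "heals" the map — the reading consistent
with low-sensitivity/high-specificity behaviour). Under either, the
argmin-probability segment is the strongest localization candidate.
Territory calls OR the segment calls of each coronary bed; metrics pool
decisions across maps (micro-averaging) at 17-segment and 3-territory
granularity, plus per-vessel reports.

## Synthetic cohorts

No public polar-map archive exists for this task, so the generator
emulates the study conditions: 266 normal / 237 abnormal rest maps and
237 normal / 206 abnormal stress maps (rest and stress drawn
independently; no paired-patient structure). A normal map is
`base_level * (1 + field_sd * s) * (1 + noise_sd * eps)`, clipped at zero
and max-normalized, where `s` is white noise averaged over graph
neighbourhoods `smoothness` times (spatially correlated inter-patient
variation) and `eps` is i.i.d. node noise. An abnormal map multiplies the
nodes of `defect_extent` contiguous segments of one sampled territory by
`1 - defect_severity`, with a two-pass neighbour-averaged falloff at the
lesion border; ground truth is recorded at segment and territory level
(territory flags are always the OR of segment flags).

Defaults: base_level 0.85, smoothness 4, noise_sd 0.05, defect_severity
0.5, defect_extent 4, field_sd 0.04, territory weights proportional to
segment counts (7/5/5). The severity is the separability dial and the
defaults are calibrated so the dial's endpoints are meaningful under the
training protocol above: severity 0.1 leaves a trained graph network near
chance, severity 0.5 reaches the near-perfect regime. The defaults
therefore model a severe, territory-spanning perfusion deficit over an
idealised homogeneous normal population.

Fidelity limits, hence what passing tests do *not* show about clinical
data: real lesions are not segment-aligned; real normal variation is
larger and structured (gender, habitus, camera position); rest/stress
pairs are correlated; acquisition artifacts are absent. Synthetic
recovery demonstrates that the pipeline can learn and localize
territory-confined deficits, not that clinical accuracy figures transfer.

## Numerical and protocol choices

- Epoch counts follow the published recipe (60 graph / 70 baseline): the
  cross-entropy is still mid-descent at a third of that budget at this
  learning rate, and all reported synthetic results use the converged
  schedule.
- lambda_max always by dense eigensolver; coarsening seeded (default 0).
- Cayley solves guard against a singular factorisation even though
  h > 0 on a PSD Laplacian makes one impossible.
- Degenerate inputs fail loudly: all-zero maps cannot be normalized,
  empty or single-class training sets raise, kappa with chance agreement
  1 raises, wrong-length CSV rows name their line number.
- Problem sizes in the test-suite and acceptance runs: paper-sized
  cohorts (503 rest maps), 4-fold cross-validation, 30 held-out abnormal
  maps for localization — the full protocol, scaled only in that the
  data are synthetic.

## Known limitations

- The Cayley model trains an order of magnitude slower per step than the
  Chebyshev model (complex LU factorisation per update for the trainable
  zoom) and is exercised at reduced sizes in routine tests.
- Printed parameter counts of the original GCNNs are not reproducible
  because per-layer widths are unpublished; only the FCN count (212,982)
  is asserted.
- Single-threaded CPU training only; the engine exists to make the method
  testable end-to-end, not to be a general DL framework.
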