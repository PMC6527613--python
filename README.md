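# polargcn

Graph-convolutional classification of myocardial-perfusion polar maps and
occlusion-based localization of pathological segments.

Myocardial perfusion imaging (SPECT/PET) is read from *polar maps*:
bullseye displays of left-ventricular tracer uptake, apex at the center,
base at the rim, acquired at rest and under stress. `polargcn` is for
researchers in automated nuclear-cardiology reading who want a fully
testable, dependency-light implementation of spectral graph-network
classification on such maps — including the graph construction, coarsening
and pooling machinery, two baseline networks, the occlusion localization
procedure, and a synthetic cohort generator so the entire pipeline runs
without patient data.

## The method

A polar map is a signal `x ∈ R^460` on a fixed unit-weight graph
G = (V, E, A) encoding the 20-ring × 23-sector sampling grid. With the
combinatorial Laplacian `L = D − A = U Λ Uᵀ`, spectral convolution is
`x ⋆ z = U g(Λ) Uᵀ x`, parametrised either by Chebyshev polynomials

    g_θ(Λ) = Σ_{k=0}^{K−1} θ_k T_k(Λ̃),   Λ̃ = (2/λ_max) Λ − I ∈ [−1, 1],

evaluated by the three-term recurrence in O(K|E|), or by Cayley rational
filters

    g_{c,h}(Λ) = c₀ + 2 Re{ Σ_{k=1}^K c_k (hΛ − i)^k (hΛ + i)^{−k} },

with trainable spectral zoom `h`, applied through exact sparse complex
solves. Classifiers stack two such convolution layers with Graclus-style
graph coarsening and max-pooling (sizes 4 and 2) and a softmax head, and
are trained with plain SGD on the cross-entropy; fully-connected and 2-D
CNN baselines are included. A trained classifier localizes disease by
*occlusion*: each AHA-17 segment in turn is replaced by the segment-mean
uptake of the normal population and the change in abnormal probability is
read out per segment, thresholded at 0.4, and aggregated into LAD/RCA/LCX
coronary-territory calls.

## Worked example

`examples/02_train_classifier.py` trains a Chebyshev graph network on a
small synthetic cohort (120 train / 40 test maps, severe
territory-confined defects) and prints:

```
cross-entropy: epoch 1 = 0.879 -> epoch 150 = 0.342
held-out agreement   = 92.5%
held-out sensitivity = 85.7%  (abnormal maps caught)
held-out specificity = 100.0%  (normal maps cleared)
```

The falling loss shows the spectral filters learning localized uptake
patterns; agreement is the percentage of held-out maps whose predicted
normal/abnormal label matches ground truth. `examples/03_localize_defect.py`
continues with occlusion localization and prints the 17 post-occlusion
probabilities for one abnormal map; the minimum marks the defect
("healing" the lesion segment drops the abnormal probability):

```
map rest-a0068: true defect segments [3, 9, 10, 15]
post-occlusion abnormal probability per segment:
  seg  1  0.891
  ...
  seg  9* 0.762
  ...
lowest probability at segment 9 (territory RCA); true territory RCA.
```

All four ground-truth lesion segments (starred) sit ~0.13 below the other
thirteen, and the argmin lands in the correct coronary territory.

Other entry points: `examples/01_simulate_cohort.py` (generator),
and a CLI — `polargcn simulate | train | evaluate | crossval |
compute-means | localize | export-grid` — over the same library.

## Layout

    src/polargcn/
      polarmap.py    # 460-node data model, AHA segments, territories, CSV I/O
      graph.py       # polar graph, Laplacians, Graclus-style coarsening
      filters.py     # Chebyshev & Cayley operators + dense spectral oracles
      nn.py          # numpy NN engine (layers, backprop, SGD)
      models.py      # FCN / CNN / GCNN architectures and configs
      training.py    # training loop, 4-fold CV, metrics, checkpoints
      localize.py    # occlusion heatmaps, 0.4-threshold calls, territories
      synthetic.py   # seeded synthetic cohort generator with ground truth
      cli.py         # click CLI
    docs/methods.md  # model, conventions, calibration, limitations
    examples/        # narrative scripts, one per capability
    tests/           # pytest suite incl. end-to-end acceptance checks
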