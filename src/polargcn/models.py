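"""The four polar-map classifiers and their configuration.

All models map a 460-value polar map to two softmax outputs
(normal / abnormal):

* ``fcn`` — dense 460 -> 460 (ReLU) -> 2; the classical direct approach.
* ``cnn`` — the map reshaped to a 23 x 20 raster; conv 64@5x5 -> pool 2x2 ->
  conv 128@3x3 -> pool 2x2 -> dense 256 -> 2 (ceil-mode pooling keeps the
  6 x 5 spatial tail well defined).
* ``gcnn_cheb`` — Chebyshev graph convolutions of order 16 then 32 on the
  polar graph, graph max pooling of size 4 then 2, dense softmax head.
* ``gcnn_cayley`` — the same topology with Cayley filters of order 4 and 6
  and a trainable spectral zoom.

Graph models share one coarsening hierarchy (three halvings of the padded
polar graph) so that pooling 4 and then 2 lands on the coarsest level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .graph import GraphHierarchy, polar_hierarchy, rescale_laplacian
from .polarmap import N_NODES

MODEL_KINDS = ("fcn", "cnn", "gcnn_cheb", "gcnn_cayley")


@dataclass
class ModelConfig:
    kind: str = "gcnn_cheb"
    fcn_hidden: int = 460
    cnn_filters: tuple[int, int] = (64, 128)
    cnn_kernels: tuple[int, int] = (5, 3)
    cnn_dense: int = 256
    gcnn_widths: tuple[int, int] = (32, 64)
    cheb_orders: tuple[int, int] = (16, 32)
    cayley_orders: tuple[int, int] = (4, 6)
    pool_sizes: tuple[int, int] = (4, 2)
    coarsen_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainConfig:
    """The published recipe: plain SGD, lr 1e-3, cross-entropy.

    Batch sizes and epochs differ per family: 64/70 for the dense and CNN
    baselines, 30/60 for the Chebyshev model and 20/60 for the Cayley model.
    """

    learning_rate: float = 1e-3
    batch_size: int = 30
    epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("training settings must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def default_train_config(kind: str, seed: int = 0, epochs: int | None = None) -> TrainConfig:
    batch = {"fcn": 64, "cnn": 64, "gcnn_cheb": 30, "gcnn_cayley": 20}[kind]
    default_epochs = {"fcn": 70, "cnn": 70, "gcnn_cheb": 60, "gcnn_cayley": 60}[kind]
    return TrainConfig(
        batch_size=batch, epochs=epochs if epochs is not None else default_epochs, seed=seed
    )


def build_fcn(cfg: ModelConfig | None = None) -> nn.Model:
    cfg = cfg or ModelConfig(kind="fcn")
    rng = np.random.default_rng(cfg.seed)
    return nn.Model(
        [
            nn.Dense(N_NODES, cfg.fcn_hidden, rng),
            nn.ReLU(),
            nn.Dense(cfg.fcn_hidden, 2, rng),
        ]
    )


def build_cnn(cfg: ModelConfig | None = None) -> nn.Model:
    cfg = cfg or ModelConfig(kind="cnn")
    rng = np.random.default_rng(cfg.seed)
    f1, f2 = cfg.cnn_filters
    k1, k2 = cfg.cnn_kernels
    # 23x20 -> pool -> 12x10 -> pool -> 6x5 (ceil mode)
    tail = 6 * 5 * f2
    return nn.Model(
        [
            nn.RasterInput(),
            nn.Conv2DSame(k1, k1, 1, f1, rng),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Conv2DSame(k2, k2, f1, f2, rng),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Flatten(),
            nn.Dense(tail, cfg.cnn_dense, rng),
            nn.ReLU(),
            nn.Dense(cfg.cnn_dense, 2, rng),
        ]
    )


def build_gcnn(cfg: ModelConfig, hierarchy: GraphHierarchy | None = None) -> nn.Model:
    """Two graph-conv blocks (pool 4 then 2) over a 3-level hierarchy."""
    if cfg.kind not in ("gcnn_cheb", "gcnn_cayley"):
        raise ValueError(f"not a graph model: {cfg.kind!r}")
    hierarchy = hierarchy or polar_hierarchy(n_levels=3, seed=cfg.coarsen_seed)
    if hierarchy.n_levels != 3:
        raise ValueError("graph models need a hierarchy with exactly 3 halvings")
    rng = np.random.default_rng(cfg.seed)
    g0, g2, g3 = hierarchy.levels[0], hierarchy.levels[2], hierarchy.levels[3]
    f1, f2 = cfg.gcnn_widths

    if cfg.kind == "gcnn_cheb":
        k1, k2 = cfg.cheb_orders
        lt0 = rescale_laplacian(g0.laplacian, g0.lambda_max)
        lt2 = rescale_laplacian(g2.laplacian, g2.lambda_max)
        conv1 = nn.ChebConv(lt0, k1, 1, f1, rng)
        conv2 = nn.ChebConv(lt2, k2, f1, f2, rng)
    else:
        k1, k2 = cfg.cayley_orders
        conv1 = nn.CayleyConv(g0.laplacian, k1, 1, f1, rng)
        conv2 = nn.CayleyConv(g2.laplacian, k2, f1, f2, rng)

    return nn.Model(
        [
            nn.GraphSignalInput(hierarchy),
            conv1,
            nn.GraphMaxPool(4, hierarchy.fake_mask[0], hierarchy.fake_mask[2]),
            nn.ReLU(),
            conv2,
            nn.GraphMaxPool(2, hierarchy.fake_mask[2], hierarchy.fake_mask[3]),
            nn.ReLU(),
            nn.Flatten(),
            nn.Dense(g3.n * f2, 2, rng),
        ]
    )


def build_model(cfg: ModelConfig, hierarchy: GraphHierarchy | None = None) -> nn.Model:
    if cfg.kind == "fcn":
        return build_fcn(cfg)
    if cfg.kind == "cnn":
        return build_cnn(cfg)
    return build_gcnn(cfg, hierarchy)
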