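"""Synthetic polar-map cohorts with territory-localized perfusion defects.

No public polar-map archive exists for the clinical cohorts this method is
aimed at, so this module generates labelled cohorts with the statistical
structure the classifiers rely on: smooth, high-uptake normal maps with
multiplicative acquisition noise, and abnormal maps carrying a contiguous
perfusion defect confined to one coronary territory, with ground truth at
map, segment and territory level.

A normal map is ``base_level x (1 + field_sd * s) x (1 + noise_sd * eps)``
where ``s`` is spatially correlated unit-variance noise (white noise
averaged over graph neighbourhoods ``smoothness`` times) and ``eps`` is
i.i.d. node noise; the map is clipped at zero and max-normalized.  An
abnormal map additionally multiplies the nodes of 1-4 contiguous segments
of one territory by ``1 - defect_severity``, with a smooth falloff at the
lesion border.  Severity is the separability dial: near 0 the classes are
indistinguishable, at the default 0.5 they are cleanly separable.

Default cohort sizes mirror the clinical study conditions: 266 normal /
237 abnormal rest maps and 237 normal / 206 abnormal stress maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import build_polar_adjacency
from .polarmap import (
    N_NODES,
    N_SEGMENTS,
    PolarGrid,
    PolarMap,
    TERRITORIES,
    normalize_map,
    territory_truth_from_segments,
)

#: Per-territory chains of spatially adjacent AHA segments; a defect is a
#: contiguous slice of one chain, so multi-segment lesions stay connected.
TERRITORY_CHAINS = {
    "LAD": [2, 1, 7, 8, 14, 13, 17],
    "RCA": [4, 3, 9, 10, 15],
    "LCX": [5, 6, 12, 11, 16],
}

REST_COHORT = {"n_normal": 266, "n_abnormal": 237}
STRESS_COHORT = {"n_normal": 237, "n_abnormal": 206}


@dataclass
class SyntheticConfig:
    n_normal: int = 266
    n_abnormal: int = 237
    condition: str = "rest"
    base_level: float = 0.85
    smoothness: int = 4
    field_sd: float = 0.04
    noise_sd: float = 0.05
    defect_severity: float = 0.5
    defect_extent: int = 4
    territory_weights: tuple[float, float, float] = (7 / 17, 5 / 17, 5 / 17)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.defect_severity < 1.0:
            raise ValueError("defect_severity must be in (0, 1)")
        if not 1 <= self.defect_extent <= 4:
            raise ValueError("defect_extent must be 1..4")
        if self.condition not in ("rest", "stress"):
            raise ValueError(f"unknown condition {self.condition!r}")
        w = np.asarray(self.territory_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("territory_weights must be 3 nonnegative weights")

    @classmethod
    def rest(cls, **kwargs) -> "SyntheticConfig":
        return cls(condition="rest", **{**REST_COHORT, **kwargs})

    @classmethod
    def stress(cls, **kwargs) -> "SyntheticConfig":
        return cls(condition="stress", **{**STRESS_COHORT, **kwargs})


@dataclass
class SyntheticSample:
    polar_map: PolarMap
    segment_truth: np.ndarray
    territory_truth: np.ndarray


class _FieldSmoother:
    """Neighbour-averaging operator on the polar graph (cached)."""

    _instance: "_FieldSmoother | None" = None

    def __init__(self) -> None:
        A = build_polar_adjacency().adjacency
        d = np.asarray(A.sum(axis=1)).ravel()
        self.half_step = (sp.identity(N_NODES) + sp.diags(1.0 / d) @ A) * 0.5

    @classmethod
    def get(cls) -> "_FieldSmoother":
        if cls._instance is None:
            cls._instance = cls()
        return cls._instance

    def smooth(self, g: np.ndarray, iterations: int) -> np.ndarray:
        for _ in range(iterations):
            g = self.half_step @ g
        return g


def _smooth_unit_field(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_normal(N_NODES)
    g = _FieldSmoother.get().smooth(g, cfg.smoothness)
    g = (g - g.mean()) / max(g.std(), 1e-12)
    return 1.0 + cfg.field_sd * g


def _raw_normal_values(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    uptake = cfg.base_level * _smooth_unit_field(cfg, rng)
    uptake = uptake * (1.0 + cfg.noise_sd * rng.standard_normal(N_NODES))
    return np.clip(uptake, 0.0, None)


def generate_normal(
    cfg: SyntheticConfig, rng: np.random.Generator, sample_id: str = "normal"
) -> SyntheticSample:
    pm = PolarMap(
        values=_raw_normal_values(cfg, rng),
        condition=cfg.condition,
        label="normal",
        segment_truth=np.zeros(N_SEGMENTS, dtype=int),
        sample_id=sample_id,
    )
    return SyntheticSample(
        polar_map=normalize_map(pm),
        segment_truth=np.zeros(N_SEGMENTS, dtype=int),
        territory_truth=np.zeros(3, dtype=int),
    )


def generate_abnormal(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "abnormal",
    grid: PolarGrid | None = None,
) -> SyntheticSample:
    grid = grid or PolarGrid()
    uptake = _raw_normal_values(cfg, rng)

    w = np.asarray(cfg.territory_weights, dtype=float)
    territory = rng.choice(TERRITORIES, p=w / w.sum())
    chain = TERRITORY_CHAINS[territory]
    extent = min(cfg.defect_extent, len(chain))
    start = int(rng.integers(0, len(chain) - extent + 1))
    lesion_segments = chain[start : start + extent]

    mask = np.zeros(N_NODES)
    for seg in lesion_segments:
        mask[grid.nodes_of_segment(seg)] = 1.0
    # two averaging passes soften the lesion border while the core stays ~1
    mask = _FieldSmoother.get().smooth(mask, 2)
    uptake = uptake * (1.0 - cfg.defect_severity * mask)

    truth = np.zeros(N_SEGMENTS, dtype=int)
    truth[np.array(lesion_segments) - 1] = 1
    pm = PolarMap(
        values=np.clip(uptake, 0.0, None),
        condition=cfg.condition,
        label="abnormal",
        segment_truth=truth,
        sample_id=sample_id,
    )
    return SyntheticSample(
        polar_map=normalize_map(pm),
        segment_truth=truth,
        territory_truth=territory_truth_from_segments(truth),
    )


def generate_cohort(cfg: SyntheticConfig) -> list[SyntheticSample]:
    """n_normal + n_abnormal seeded samples in a seeded shuffle order."""
    if cfg.n_normal < 0 or cfg.n_abnormal < 0 or cfg.n_normal + cfg.n_abnormal == 0:
        raise ValueError("cohort sizes must be nonnegative and not both zero")
    rng = np.random.default_rng(cfg.seed)
    samples = [
        generate_normal(cfg, rng, sample_id=f"{cfg.condition}-n{i:04d}")
        for i in range(cfg.n_normal)
    ]
    samples += [
        generate_abnormal(cfg, rng, sample_id=f"{cfg.condition}-a{i:04d}")
        for i in range(cfg.n_abnormal)
    ]
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def cohort_maps(samples: list[SyntheticSample]) -> list[PolarMap]:
    return [s.polar_map for s in samples]
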