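"""Occlusion-based localization of pathological myocardial segments.

Given a classifier trained to separate normal from abnormal polar maps, the
evidence carried by each AHA segment is probed by *occlusion*: the segment's
node intensities are replaced with the segment-wise mean uptake of the
normal population, the modified map is re-classified, and the abnormal-class
probability is recorded.  Doing this for all 17 segments yields a
per-segment probability heatmap; thresholding the probabilities (default
0.4) produces binary segment calls, which aggregate by OR into calls for
the three coronary territories (LAD, RCA, LCX).

Two polarities of the threshold rule are supported.  ``"abnormal"``
(default) calls a segment pathological when the recorded post-occlusion
abnormal probability is at or above the threshold.  ``"healing"`` calls a
segment pathological when occluding it *drops* the probability below the
threshold — i.e. normalising that segment "heals" the map, so the segment
carried the decisive evidence.  Under either polarity, the segment whose
occlusion yields the *lowest* abnormal probability is the strongest
localization candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .polarmap import (
    N_SEGMENTS,
    PolarGrid,
    PolarMap,
    TERRITORIES,
    segments_of_territory,
    territory_truth_from_segments,
)
from .training import EvalReport, evaluate

DEFAULT_THRESHOLD = 0.4
POLARITIES = ("abnormal", "healing")


@dataclass
class SegmentMeans:
    """Mean normal-population uptake per AHA segment, one condition."""

    means: np.ndarray  # (17,)
    condition: str = "rest"

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (N_SEGMENTS,):
            raise ValueError("need one mean per AHA segment (17)")


@dataclass
class LocalizationResult:
    sample_id: str
    seg_prob: np.ndarray  # (17,) abnormal probability after occluding each segment
    seg_call: np.ndarray  # (17,) binary
    territory_call: np.ndarray  # (3,) binary, LAD/RCA/LCX order
    threshold: float
    polarity: str


def compute_segment_means(
    normal_maps: list[PolarMap], grid: PolarGrid | None = None
) -> SegmentMeans:
    """Pool every node value per segment across all normal maps."""
    if not normal_maps:
        raise ValueError("need at least one normal map")
    grid = grid or PolarGrid()
    values = np.stack([pm.values for pm in normal_maps])
    means = np.array(
        [values[:, grid.nodes_of_segment(s)].mean() for s in range(1, N_SEGMENTS + 1)]
    )
    return SegmentMeans(means=means, condition=normal_maps[0].condition)


def occlude_segment(
    pm: PolarMap, seg: int, means: SegmentMeans, grid: PolarGrid | None = None
) -> PolarMap:
    """Replace one segment's intensities with the normal-population mean."""
    grid = grid or PolarGrid()
    nodes = grid.nodes_of_segment(seg)
    values = pm.values.copy()
    values[nodes] = means.means[seg - 1]
    return replace(pm, values=values)


def localization_heatmap(
    model: nn.Model,
    pm: PolarMap,
    means: SegmentMeans,
    grid: PolarGrid | None = None,
) -> np.ndarray:
    """Abnormal-class probability after occluding each of the 17 segments."""
    grid = grid or PolarGrid()
    occluded = np.stack(
        [occlude_segment(pm, s, means, grid).values for s in range(1, N_SEGMENTS + 1)]
    )
    return model.predict_proba(occluded)[:, 1]


def heatmap_to_nodes(seg_prob: np.ndarray, grid: PolarGrid | None = None) -> np.ndarray:
    """Render 17 segment probabilities as a 460-node map for display."""
    grid = grid or PolarGrid()
    return np.asarray(seg_prob, dtype=float)[grid.segment_of - 1]


def call_segments(
    seg_prob: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    polarity: str = "abnormal",
) -> np.ndarray:
    """Binary pathological calls from the occlusion probabilities."""
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    p = np.asarray(seg_prob, dtype=float)
    if polarity == "abnormal":
        return (p >= threshold).astype(int)
    return (p < threshold).astype(int)


def aggregate_territories(seg_call: np.ndarray) -> np.ndarray:
    """OR the segment calls of each coronary bed (LAD, RCA, LCX order)."""
    return territory_truth_from_segments(seg_call)


def localize(
    model: nn.Model,
    pm: PolarMap,
    means: SegmentMeans,
    threshold: float = DEFAULT_THRESHOLD,
    polarity: str = "abnormal",
    grid: PolarGrid | None = None,
) -> LocalizationResult:
    seg_prob = localization_heatmap(model, pm, means, grid)
    seg_call = call_segments(seg_prob, threshold, polarity)
    return LocalizationResult(
        sample_id=pm.sample_id,
        seg_prob=seg_prob,
        seg_call=seg_call,
        territory_call=aggregate_territories(seg_call),
        threshold=threshold,
        polarity=polarity,
    )


def evaluate_localization(
    results: list[LocalizationResult], truths: list[np.ndarray]
) -> dict[str, EvalReport]:
    """Micro-pooled agreement at segment and territory granularity.

    ``truths`` holds one 17-flag ground-truth vector per result.  The
    17-division report pools all 17 x N segment decisions; the 3-division
    report pools all 3 x N territory decisions; per-vessel reports score
    each bed's decisions separately.
    """
    if len(results) != len(truths) or not results:
        raise ValueError("need one ground-truth vector per localization result")
    seg_calls = np.stack([r.seg_call for r in results])
    seg_true = np.stack([np.asarray(t, dtype=int) for t in truths])
    if seg_true.shape[1] != N_SEGMENTS:
        raise ValueError("ground truth must have 17 flags per map")
    ter_calls = np.stack([r.territory_call for r in results])
    ter_true = np.stack([territory_truth_from_segments(t) for t in seg_true])
    out = {
        "segments17": evaluate(seg_calls.ravel(), seg_true.ravel()),
        "territories3": evaluate(ter_calls.ravel(), ter_true.ravel()),
    }
    for j, t in enumerate(TERRITORIES):
        out[t] = evaluate(ter_calls[:, j], ter_true[:, j])
    return out


def frequency_heatmap(flag_vectors: list[np.ndarray]) -> np.ndarray:
    """Per-segment count of set flags across a cohort (annotated or detected)."""
    if not flag_vectors:
        return np.zeros(N_SEGMENTS, dtype=int)
    flags = np.stack([np.asarray(v, dtype=int) for v in flag_vectors])
    if flags.shape[1] != N_SEGMENTS:
        raise ValueError("each flag vector needs 17 entries")
    return flags.sum(axis=0)
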