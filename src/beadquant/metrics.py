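"""Detection evaluation against ground truth (optimal one-to-one matching)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import BeadBox

__all__ = ["DetectionEvaluation", "evaluate_detections"]


@dataclass(frozen=True)
class DetectionEvaluation:
    n_true: int
    n_detected: int
    n_matched: int
    match_distances_px: np.ndarray  # center distance per matched pair

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0

    @property
    def max_match_distance(self) -> float:
        return float(self.match_distances_px.max()) if self.n_matched else 0.0


def evaluate_detections(
    true_centers: np.ndarray, boxes: list[BeadBox], max_distance_px: float
) -> DetectionEvaluation:
    """Match detections to true centers (Hungarian assignment on center
    distance, pairs beyond ``max_distance_px`` rejected) and report
    recall/precision and matched-center distances."""
    true_centers = np.atleast_2d(np.asarray(true_centers, dtype=float))
    if true_centers.size == 0:
        true_centers = true_centers.reshape(0, 2)
    det = np.array([b.center for b in boxes], dtype=float).reshape(len(boxes), 2)
    nt, nd = true_centers.shape[0], det.shape[0]
    if nt == 0 or nd == 0:
        return DetectionEvaluation(nt, nd, 0, np.empty(0))
    cost = np.linalg.norm(true_centers[:, None, :] - det[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    d = cost[rows, cols]
    keep = d <= max_distance_px
    return DetectionEvaluation(nt, nd, int(keep.sum()), d[keep])
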