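"""Recovery metrics against ground truth (one-to-one point matching)."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["match_points", "recall_precision"]


def match_points(
    truth: np.ndarray, detected: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected points to truth points.

    Candidate pairs within ``radius`` (Euclidean, same units on all axes)
    are taken in order of increasing distance; each truth and each detected
    point is used at most once.  Returns (truth_index, detected_index)
    pairs.
    """
    truth = np.asarray(truth, dtype=float).reshape(-1, np.shape(truth)[-1] if len(truth) else 3)
    detected = np.asarray(detected, dtype=float).reshape(-1, truth.shape[1] if len(detected) else 3)
    if len(truth) == 0 or len(detected) == 0:
        return []
    tree = cKDTree(truth)
    pairs = tree.query_ball_point(detected, r=radius)
    cand = [
        (np.linalg.norm(detected[di] - truth[ti]), ti, di)
        for di, tis in enumerate(pairs)
        for ti in tis
    ]
    cand.sort()
    used_t, used_d, out = set(), set(), []
    for _, ti, di in cand:
        if ti not in used_t and di not in used_d:
            used_t.add(ti)
            used_d.add(di)
            out.append((ti, di))
    return out


def recall_precision(
    truth: np.ndarray, detected: np.ndarray, radius: float
) -> tuple[float, float, int]:
    """(recall, precision, n_matched) for detected vs truth points."""
    matches = match_points(truth, detected, radius)
    n = len(matches)
    recall = n / len(truth) if len(truth) else 1.0
    precision = n / len(detected) if len(detected) else 1.0
    return recall, precision, n
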