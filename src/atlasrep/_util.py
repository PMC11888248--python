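"""Small shared helpers: seeded substreams and rank/normalise kernels."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.stats import rankdata


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Named, reproducible child RNG derived from one global seed.

    Each distinct label path yields an independent stream, so pipeline stages
    can be regenerated in isolation without replaying earlier draws.
    """
    key = tuple(zlib.crc32(lab.encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def rank_rows(x: np.ndarray) -> np.ndarray:
    """Mid-rank every row of a 2-D array (ties share the average rank)."""
    return rankdata(x, axis=1)


def center_unit_rows(x: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center rows and scale to unit Euclidean norm.

    Degenerate (constant) rows become all-zero. Returns (normalized, degenerate_mask).
    """
    x = np.asarray(x, dtype=np.float64)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= tol
    safe = np.where(degenerate, 1.0, norms)
    out = centered / safe[:, None]
    out[degenerate] = 0.0
    return out, degenerate


def grouped_auroc(scores: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """AUROC of `scores` for each group label vs the rest, from one shared ranking.

    Mid-rank (Mann-Whitney) formulation; groups with zero positives or zero
    negatives yield NaN.
    """
    n = scores.shape[0]
    ranks = rankdata(scores)
    out = np.full(groups.shape[0], np.nan)
    for i, g in enumerate(groups):
        pos = labels == g
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        r_pos = ranks[pos].sum()
        out[i] = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return out
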