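"""Independent oracles used by the test suite.

These are deliberately written without reference to the package's own code
paths: an exhaustive search over global alignments (with and without
memoization) and a random-restart numerical optimizer over rigid
transforms. They exist so each nontrivial computation is checked by two
unrelated routes.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def exhaustive_alignment_score(a: str, b: str,
                               score: Callable[[str, str], float],
                               gap_open: float,
                               gap_extend: float) -> float:
    """Exact optimal global-alignment score by exhaustive recursion over
    (i, j, previous move) states, memoized.

    Gap convention: a run of k gap positions costs
    gap_open + (k - 1) * gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            step = gap_extend if prev == "D" else gap_open
            cands.append(step + best(i + 1, j, "D"))
        if j < len(b):
            step = gap_extend if prev == "I" else gap_open
            cands.append(step + best(i, j + 1, "I"))
        return max(cands)

    result = best(0, 0, "")
    best.cache_clear()
    return result


def enumerate_alignment_score(a: str, b: str,
                              score: Callable[[str, str], float],
                              gap_open: float,
                              gap_extend: float) -> float:
    """Optimal score by literally listing every global alignment (pair of
    gapped strings) and scoring each. Exponential; only for tiny inputs.
    Validates the memoized oracle above."""

    def alignments(i: int, j: int):
        if i == len(a) and j == len(b):
            yield ("", "")
            return
        if i < len(a) and j < len(b):
            for ra, rb in alignments(i + 1, j + 1):
                yield (a[i] + ra, b[j] + rb)
        if i < len(a):
            for ra, rb in alignments(i + 1, j):
                yield (a[i] + ra, "-" + rb)
        if j < len(b):
            for ra, rb in alignments(i, j + 1):
                yield ("-" + ra, b[j] + rb)

    def score_alignment(ra: str, rb: str) -> float:
        total = 0.0
        prev_gap = None  # which row was gapped at the previous column
        for ca, cb in zip(ra, rb):
            if ca == "-" or cb == "-":
                gap_row = 0 if ca == "-" else 1
                total += gap_extend if prev_gap == gap_row else gap_open
                prev_gap = gap_row
            else:
                total += score(ca, cb)
                prev_gap = None
        return total

    return max(score_alignment(ra, rb) for ra, rb in alignments(0, 0))


def optimizer_min_rmsd(P: np.ndarray, Q: np.ndarray, n_restarts: int = 12,
                       seed: int = 0) -> float:
    """Minimum RMSD of Q onto P over rigid transforms, found numerically.

    Parametrizes the transform as rotation-vector + translation and runs
    BFGS from random starting points; knows nothing of the SVD solution.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    rng = np.random.default_rng(seed)

    def msd(params: np.ndarray) -> float:
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = Q @ R.T + params[3:]
        return float(np.mean(np.sum((moved - P) ** 2, axis=1)))

    best = np.inf
    center_shift = P.mean(axis=0) - Q.mean(axis=0)
    for k in range(n_restarts):
        rotvec = rng.uniform(-np.pi, np.pi, 3)
        start = np.concatenate([rotvec, center_shift
                                + rng.normal(0, 1.0, 3)])
        res = minimize(msd, start, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation and translation."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, 3)
    return R, t
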