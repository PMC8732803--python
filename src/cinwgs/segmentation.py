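"""Circular binary segmentation of normalized coverage profiles.

Each chromosome arm is treated as a ring. The core statistic compares the
bins inside an arc ``[i, j)`` against the rest of the arm with a two-sample
t-like statistic (pooled within-group variance); the arc maximizing ``|T|``
is the candidate split, and its significance is assessed by permuting the
bins within the arm. Splits with permutation ``p < alpha`` are accepted and
the pieces are segmented recursively.

Because ``|T|`` is invariant under swapping the arc with its complement,
enumerating all non-wrapping arcs ``0 <= i < j <= n`` covers every circular
partition; results are therefore reported in the canonical non-wrap
representation (a wrapping arc appears as the prefix and suffix pieces of
the ternary split).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageProfile

_TINY = 1e-12

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERMUTATIONS = 1000
MIN_SPLIT_LENGTH = 4


@dataclass
class Segment:
    chrom: str
    arm: str
    start_bin: int  # grid bin indices, half-open
    end_bin: int
    start_bp: int
    end_bp: int
    mean_z: float
    n_bins: int
    p_value: float | None
    bin_indices: np.ndarray = field(repr=False, default=None)


@dataclass
class SegmentSet:
    sample_id: str
    segments: list[Segment]
    alpha: float
    n_permutations: int
    seed: int

    def to_seg_frame(self) -> pd.DataFrame:
        """SEG-format table (sample, chrom, start, end, num_bins, seg_mean)."""
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start_bp for s in self.segments],
                "end": [s.end_bp for s in self.segments],
                "num_bins": [s.n_bins for s in self.segments],
                "seg_mean": [s.mean_z for s in self.segments],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "alpha": self.alpha,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "segments": [
                    {
                        "chrom": s.chrom,
                        "arm": s.arm,
                        "start_bin": s.start_bin,
                        "end_bin": s.end_bin,
                        "start_bp": s.start_bp,
                        "end_bp": s.end_bp,
                        "mean_z": s.mean_z,
                        "n_bins": s.n_bins,
                        "p_value": s.p_value,
                    }
                    for s in self.segments
                ],
            },
            indent=2,
        )


def _t_from_sums(sum_in, sq_in, k, total, total_sq, n):
    """|t| for arc vs complement from sufficient statistics (vectorized)."""
    m = n - k
    sum_out = total - sum_in
    sq_out = total_sq - sq_in
    d = sum_in / k - sum_out / m
    ssw = (sq_in - sum_in**2 / k) + (sq_out - sum_out**2 / m)
    ssw = np.maximum(ssw, 0.0)
    denom2 = (ssw / max(n - 2, 1)) * (1.0 / k + 1.0 / m)
    # variance floor keeps zero-within-variance steps finite and ranked by |d|
    return np.abs(d) / np.sqrt(np.maximum(denom2, _TINY))


def max_t_statistic(z: np.ndarray) -> tuple[int, int, float]:
    """Arc ``[i, j)`` maximizing the circular two-sample |t| statistic.

    Returns ``(i, j, T)`` with ``0 <= i < j <= n`` (canonical non-wrap
    representation); ties are broken by smallest ``i`` then smallest ``j``.
    Vectors shorter than 4 yield the no-split result ``(0, n, 0.0)``.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < MIN_SPLIT_LENGTH:
        return 0, n, 0.0
    S = np.concatenate([[0.0], np.cumsum(z)])
    Q = np.concatenate([[0.0], np.cumsum(z * z)])
    total, total_sq = S[n], Q[n]
    best = (0, 1, -1.0)
    # scan k ascending, start ascending -> first maximum wins the tie-break
    for k in range(1, n):
        i = np.arange(0, n - k + 1)
        t = _t_from_sums(S[i + k] - S[i], Q[i + k] - Q[i], k, total, total_sq, n)
        a = int(np.argmax(t))
        if t[a] > best[2]:
            best = (int(i[a]), int(i[a]) + k, float(t[a]))
    i, j, T = best
    # tie-break across k: re-rank all argmax candidates by (i, j)
    cands = []
    for k in range(1, n):
        i_arr = np.arange(0, n - k + 1)
        t = _t_from_sums(
            S[i_arr + k] - S[i_arr], Q[i_arr + k] - Q[i_arr], k, total, total_sq, n
        )
        hit = np.flatnonzero(t == T)
        cands.extend((int(h), int(h) + k) for h in hit)
    if cands:
        # arcs [i, n) duplicate the partition of [0, i); use the canonical rep
        cands = [(0, ci) if cj == n and ci > 0 else (ci, cj) for ci, cj in cands]
        i, j = min(cands)
    elif j == n and i > 0:
        i, j = 0, i
    return i, j, T


def _max_t_rows(Z: np.ndarray) -> np.ndarray:
    """Max circular |t| per row of a (m, n) matrix (statistic only)."""
    m_rows, n = Z.shape
    S = np.concatenate([np.zeros((m_rows, 1)), np.cumsum(Z, axis=1)], axis=1)
    Q = np.concatenate([np.zeros((m_rows, 1)), np.cumsum(Z * Z, axis=1)], axis=1)
    total = S[:, [n]]
    total_sq = Q[:, [n]]
    best = np.zeros(m_rows)
    for k in range(1, n):
        sum_in = S[:, k:] - S[:, : n - k + 1]
        sq_in = Q[:, k:] - Q[:, : n - k + 1]
        t = _t_from_sums(sum_in, sq_in, k, total, total_sq, n)
        best = np.maximum(best, t.max(axis=1))
    return best


def split_significance(
    z: np.ndarray,
    t_obs: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng_seed: int = 0,
) -> float:
    """Permutation p-value: p = (1 + #{max-T_perm >= T_obs}) / (1 + B)."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(rng_seed)
    perms = np.tile(z, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    max_t = _max_t_rows(perms)
    exceed = int(np.sum(max_t >= t_obs))
    return (1 + exceed) / (1 + n_permutations)


def segment_profile(
    profile: CoverageProfile,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> SegmentSet:
    """Recursive circular binary segmentation, one arm at a time.

    Missing bins are dropped before segmentation; segment coordinates are
    re-expanded to genomic bp afterwards. Arms with fewer than 4 usable bins
    become a single segment with ``p_value`` None.
    """
    if profile.kind != "normalized":
        raise ValueError("segment_profile expects a normalized profile")
    grid = profile.grid
    usable = profile.usable
    segments: list[Segment] = []

    for arm_index, arm in enumerate(grid.arms):
        idx = grid.bins_of_arm(arm.name)
        idx = idx[usable[idx]]
        if len(idx) == 0:
            continue
        z = profile.values[idx]
        rng = np.random.default_rng([seed, arm_index])
        # FIFO left-to-right traversal keeps the seed draw order deterministic
        queue: deque[tuple[int, int]] = deque([(0, len(z))])
        finals: list[tuple[int, int, float | None]] = []
        while queue:
            lo, hi = queue.popleft()
            length = hi - lo
            if length < MIN_SPLIT_LENGTH:
                finals.append((lo, hi, None))
                continue
            piece = z[lo:hi]
            i, j, t_obs = max_t_statistic(piece)
            child_seed = int(rng.integers(0, 2**31 - 1))
            p = split_significance(piece, t_obs, n_permutations, child_seed)
            if p < alpha and not (i == 0 and j == length):
                for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                    if b > a:
                        queue.append((a, b))
            else:
                finals.append((lo, hi, p))
        for lo, hi, p in sorted(finals):
            members = idx[lo:hi]
            segments.append(
                Segment(
                    chrom=arm.chrom,
                    arm=arm.name,
                    start_bin=int(members[0]),
                    end_bin=int(members[-1]) + 1,
                    start_bp=int(grid.start[members[0]]),
                    end_bp=int(grid.end[members[-1]]),
                    mean_z=float(np.mean(z[lo:hi])),
                    n_bins=hi - lo,
                    p_value=p,
                    bin_indices=members,
                )
            )

    segments.sort(key=lambda s: (list(grid._chrom_slices).index(s.chrom), s.start_bin))
    return SegmentSet(
        sample_id=profile.sample_id,
        segments=segments,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )
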