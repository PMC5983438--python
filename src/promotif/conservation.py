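"""Conserved-region detection between orthologous promoters.

Significantly conserved sequence is modelled as ungapped local alignment:
maximal-scoring ungapped segment pairs under a match/mismatch score, with
significance from Karlin-Altschul statistics, E = K * m * n * exp(-lambda*S),
and a default acceptance threshold of E < 0.001. Segments are located by
exact-word seeding followed by ungapped X-drop extension and trimming to the
maximal-scoring sub-segment, then reported greedily by score, non-overlapping
on the reference promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .motifs import PromoterRecord


@dataclass
class ConservationParams:
    """Scoring scheme and significance model for ungapped conservation.

    ``karlin_k`` is the Karlin-Altschul prefactor (configured constant;
    0.173 is the standard ungapped value for +5/-4 nucleotide scoring);
    ``lambda_`` is solved numerically from the scores and background
    frequencies. ``word_size`` is the exact-match seed length and ``xdrop``
    the score drop-off terminating extension.
    """

    match: float = 5.0
    mismatch: float = -4.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    karlin_k: float = 0.173
    evalue_max: float = 1e-3
    word_size: int = 9
    xdrop: float = 50.0
    lambda_: float = field(init=False)

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9 or any(p <= 0 for p in self.background):
            raise ValueError("background frequencies must be positive and sum to 1")
        if self.karlin_k <= 0 or self.evalue_max <= 0:
            raise ValueError("karlin_k and evalue_max must be positive")
        self.lambda_ = karlin_altschul_lambda(self)

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_k * m * n * float(np.exp(-self.lambda_ * score))


def karlin_altschul_lambda(params: ConservationParams) -> float:
    """Positive root of sum_{i,j} p_i p_j exp(lambda * s_ij) = 1.

    Requires a negative expected score and a positive maximum score; the
    root is then unique. Solved by Brent bracketing to |residual| < 1e-10.
    For uniform bases with +1/-1 scoring the root is ln 3.
    """
    p = np.asarray(params.background)
    s = np.full((4, 4), params.mismatch)
    np.fill_diagonal(s, params.match)
    pp = p[:, None] * p[None, :]
    expected = float((pp * s).sum())
    if expected >= 0:
        raise ValueError(f"expected score {expected:.4g} must be negative")
    if s.max() <= 0:
        raise ValueError("maximum score must be positive")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    hi = 1.0 / max(params.match, 1e-12)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))
    assert abs(f(lam)) < 1e-10
    return lam


@dataclass(frozen=True)
class ConservedRegion:
    """An ungapped conserved segment pair (half-open intervals, equal length)."""

    ref_start: int
    ref_end: int
    orth_start: int
    orth_end: int
    score: float
    evalue: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


def _extend_segment(
    match_scores: np.ndarray, start: int, end: int, xdrop: float
) -> tuple[int, int, float]:
    """Extend [start, end) along a diagonal, then trim to the maximal-scoring
    sub-segment. ``match_scores`` holds per-position +match/-mismatch values."""
    n = len(match_scores)
    # extend right
    best, run = 0.0, 0.0
    best_end = end
    i = end
    while i < n:
        run += match_scores[i]
        i += 1
        if run > best:
            best, best_end = run, i
        elif best - run > xdrop:
            break
    right_gain = best
    # extend left
    best, run = 0.0, 0.0
    best_start = start
    i = start - 1
    while i >= 0:
        run += match_scores[i]
        if run > best:
            best, best_start = run, i
        elif best - run > xdrop:
            break
        i -= 1
    left_gain = best
    score = float(match_scores[start:end].sum()) + right_gain + left_gain
    # trim to the maximal-scoring sub-segment (prefix/suffix with net <= 0)
    seg = match_scores[best_start:best_end]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    lo = int(np.argmin(cum[: len(seg)]))
    hi = int(np.argmax(cum[lo + 1 :])) + lo + 1
    trimmed = float(cum[hi] - cum[lo])
    return best_start + lo, best_start + hi, trimmed if trimmed > 0 else score


def find_conserved_regions(
    ref: PromoterRecord,
    orth: PromoterRecord,
    params: ConservationParams | None = None,
) -> list[ConservedRegion]:
    """Significantly conserved ungapped segment pairs between two promoters.

    Seeds exact ``word_size``-mers shared between the sequences, extends each
    seed without gaps along its diagonal, trims to the maximal-scoring
    segment, and keeps segments with E = K*m*n*exp(-lambda*S) below
    ``evalue_max``. Reported greedily by score, non-overlapping on the
    reference.
    """
    if params is None:
        params = ConservationParams()
    a, b = ref.sequence, orth.sequence
    m, n = len(a), len(b)
    w = params.word_size
    if min(m, n) < w:
        return []
    index: dict[str, list[int]] = {}
    for j in range(n - w + 1):
        word = b[j : j + w]
        if "N" not in word:
            index.setdefault(word, []).append(j)

    # per-diagonal cache of already-extended intervals to skip nested seeds
    done: dict[int, list[tuple[int, int]]] = {}
    candidates: list[ConservedRegion] = []
    score_cache: dict[int, np.ndarray] = {}
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    n_code = ord("N")

    for i in range(m - w + 1):
        word = a[i : i + w]
        for j in index.get(word, ()):
            diag = i - j
            covered = done.setdefault(diag, [])
            if any(s <= i < e for s, e in covered):
                continue
            if diag not in score_cache:
                lo_a = max(0, diag)
                lo_b = max(0, -diag)
                L = min(m - lo_a, n - lo_b)
                sa, sb = arr_a[lo_a : lo_a + L], arr_b[lo_b : lo_b + L]
                eq = (sa == sb) & (sa != n_code)
                scores = np.where(eq, params.match, params.mismatch)
                scores[(sa == n_code) | (sb == n_code)] = params.mismatch
                score_cache[diag] = scores
            scores = score_cache[diag]
            off = i - max(0, diag)
            s0, s1, score = _extend_segment(scores, off, off + w, params.xdrop)
            ref_start = s0 + max(0, diag)
            ref_end = s1 + max(0, diag)
            covered.append((ref_start, ref_end))
            ev = params.evalue(score, m, n)
            if ev < params.evalue_max:
                candidates.append(
                    ConservedRegion(
                        ref_start=ref_start,
                        ref_end=ref_end,
                        orth_start=ref_start - diag,
                        orth_end=ref_end - diag,
                        score=score,
                        evalue=ev,
                    )
                )

    # greedy non-overlapping selection on the reference, by score
    candidates.sort(key=lambda r: (-r.score, r.ref_start))
    chosen: list[ConservedRegion] = []
    for cand in candidates:
        if all(
            cand.ref_end <= c.ref_start or cand.ref_start >= c.ref_end for c in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.ref_start)
    return chosen
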