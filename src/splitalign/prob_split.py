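"""Probabilistic split-alignment: Forward-Backward column error probabilities.

Over the same A/D profile layout as the Viterbi split, define the
exponentiated scores A' = exp(A/t), D' = exp(D/t), f' = exp(f/t).  The
Forward pass

    F[i][beg(i)] = 0,  G[beg] = 1
    F[i][j+1] = (F[i][j] D'[i][j] + G[j] / f') A'[i][j]
    G[j+1]   = G[j] + sum_i F[i][j+1]

sums exp(score/t) over every set of disjoint candidate fragments ending
by position j (the empty set contributes 1), and the Backward pass is
its mirror.  The partition function is z = G[end] = C[beg].  The model
probability of the column of candidate i at query letter j is

    P[i][j] = (F[i][j+1] B[i][j] / A'[i][j]) / z

and for a deletion column between letters j-1 and j,

    Pdel[i][j] = F[i][j] B[i][j] D'[i][j] / z.

A column's error probability is one minus its model probability.

Numerics: the implementation rescales F and G (and B and C) by the
running G (C) at every position and accumulates the log scale, the
standard HMM scaling; the ratios above are scale-free, so probabilities
are recovered exactly in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from splitalign.core import GAP, SplitFragment
from splitalign.split_align import SplitProfiles


class NumericalError(ArithmeticError):
    """Forward and Backward totals disagree beyond tolerance."""


@dataclass
class ForwardBackwardState:
    """Scaled Forward-Backward arrays over a SplitProfiles layout.

    Stored values are scaled: the true value at global position j is the
    stored value times exp(LF[j]) (forward) or exp(LB[j]) (backward).
    """

    F: list[np.ndarray]
    G: np.ndarray
    LF: np.ndarray
    B: list[np.ndarray]
    C: np.ndarray
    LB: np.ndarray
    logz: float
    logz_backward: float
    t: float

    @property
    def z(self) -> float:
        return math.exp(self.logz)


def forward_backward(
    profiles: SplitProfiles, t: float, rel_tol: float = 1e-9
) -> ForwardBackwardState:
    """Run the scaled Forward and Backward passes; verify both give one z."""
    if t <= 0:
        raise ValueError("t must be positive")
    cands = profiles.candidates
    beg, end = profiles.beg, profiles.end
    gspan = max(end - beg, 0)
    fprime = math.exp(profiles.f / t)
    Ap = [np.exp(c.A / t) for c in cands]
    Dp = [np.exp(c.D / t) for c in cands]

    F = [np.zeros(c.span + 1) for c in cands]
    G = np.ones(gspan + 1)
    LF = np.zeros(gspan + 1)
    starts: dict[int, list[int]] = {}
    for i, c in enumerate(cands):
        starts.setdefault(c.beg, []).append(i)
    active: list[int] = []
    for j in range(beg, end):
        jj = j - beg
        active.extend(starts.get(j, ()))
        active = [i for i in active if cands[i].end > j]
        tot = G[jj]
        for i in active:
            ji = j - cands[i].beg
            d = Dp[i][ji] if ji > 0 else 0.0
            fnew = (F[i][ji] * d + G[jj] / fprime) * Ap[i][ji]
            F[i][ji + 1] = fnew
            tot += fnew
        # tot >= G[jj] = stored 1, so the scale is safe to log
        G[jj + 1] = 1.0
        for i in active:
            F[i][j - cands[i].beg + 1] /= tot
        LF[jj + 1] = LF[jj] + math.log(tot)
        if not math.isfinite(LF[jj + 1]):
            raise NumericalError("forward pass overflowed despite scaling")
    logz = float(LF[gspan])

    B = [np.zeros(c.span + 1) for c in cands]
    C = np.ones(gspan + 1)
    LB = np.zeros(gspan + 1)
    ends: dict[int, list[int]] = {}
    for i, c in enumerate(cands):
        ends.setdefault(c.end, []).append(i)
    bactive: list[int] = []
    for j in range(end, beg, -1):
        jj = j - beg
        bactive.extend(ends.get(j, ()))
        bactive = [i for i in bactive if cands[i].beg < j]
        tot = C[jj]
        for i in bactive:
            ji = j - cands[i].beg
            d = Dp[i][ji] if ji < cands[i].span else 0.0
            bnew = (B[i][ji] * d + C[jj]) * Ap[i][ji - 1]
            B[i][ji - 1] = bnew
            tot += bnew / fprime
        C[jj - 1] = 1.0
        for i in bactive:
            B[i][j - cands[i].beg - 1] /= tot
        LB[jj - 1] = LB[jj] + math.log(tot)
    logz_b = float(LB[0])

    if cands and abs(logz - logz_b) > rel_tol * max(1.0, abs(logz)):
        raise NumericalError(
            f"forward/backward mismatch: log z {logz} vs {logz_b}"
        )
    return ForwardBackwardState(
        F=F, G=G, LF=LF, B=B, C=C, LB=LB,
        logz=logz, logz_backward=logz_b, t=t,
    )


def column_probs(
    state: ForwardBackwardState, profiles: SplitProfiles
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-column aligned probabilities for every candidate.

    Returns (P, Pdel): P[i][jj] is the model probability of the column
    of candidate i at query letter beg(i)+jj; Pdel[i][jj] the
    probability of a deletion between letters beg(i)+jj-1 and beg(i)+jj
    (entry 0 unused).
    """
    beg = profiles.beg
    t = state.t
    P: list[np.ndarray] = []
    Pdel: list[np.ndarray] = []
    for i, cand in enumerate(profiles.candidates):
        span = cand.span
        p = np.zeros(span)
        pdel = np.zeros(span)
        for jj in range(span):
            j = cand.beg + jj
            fval = state.F[i][jj + 1]
            bval = state.B[i][jj]
            if fval > 0.0 and bval > 0.0:
                logp = (
                    math.log(fval) + state.LF[j + 1 - beg]
                    + math.log(bval) + state.LB[j - beg]
                    - cand.A[jj] / t
                    - state.logz
                )
                p[jj] = math.exp(min(logp, 0.0))
            if jj > 0:
                fv = state.F[i][jj]
                if fv > 0.0 and bval > 0.0:
                    logp = (
                        math.log(fv) + state.LF[j - beg]
                        + math.log(bval) + state.LB[j - beg]
                        + cand.D[jj] / t
                        - state.logz
                    )
                    pdel[jj] = math.exp(min(logp, 0.0))
        P.append(p)
        Pdel.append(pdel)
    return P, Pdel


def annotate_fragments(
    fragments: list[SplitFragment],
    state: ForwardBackwardState,
    profiles: SplitProfiles,
) -> None:
    """Attach per-column error probabilities and mismap values in place.

    Deletion columns take the deletion-event probability of their run
    (reported at the position of the following query letter); the
    fragment mismap is the minimum error over columns that contain a
    query letter.
    """
    P, Pdel = column_probs(state, profiles)
    by_input = {c.input_index: (i, c) for i, c in enumerate(profiles.candidates)}
    for frag in fragments:
        i, cand = by_input[frag.source_index]
        j = frag.query.fwd_start
        errs: list[float] = []
        best = 1.0
        for rchar, qchar in zip(frag.ref.text, frag.query.text):
            jj = j - cand.beg
            if qchar == GAP:
                errs.append(1.0 - float(Pdel[i][jj]))
            else:
                err = 1.0 - float(P[i][jj])
                errs.append(err)
                best = min(best, err)
                j += 1
        frag.column_error_probs = errs
        frag.mismap = best


def mismap_filter(
    fragments: list[SplitFragment], threshold: float = 0.00001
) -> list[SplitFragment]:
    """Keep fragments with at least one position with error <= threshold."""
    return [
        fr for fr in fragments if fr.mismap is not None and fr.mismap <= threshold
    ]
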