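"""Fixture and truth generation: pair-HMM simulation, toy rearranged
genomes, a small-scale exhaustive local aligner, and brute-force oracles.

Everything here is test harness for the alignment machinery: the
simulator emits sequence pairs from the same probabilistic model the
calibration inverts, the rearrangement generator produces toy genomes
with a known one-to-one orthology map, and the enumeration oracle
computes optimal fragment sets, partition functions, and column
marginals exhaustively at small scale.  All randomness flows through a
single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from splitalign.core import (
    ALPHABET,
    GAP,
    AlnRow,
    LocalAlignment,
    PairProbModel,
    ScoreScheme,
    revcomp,
)
from splitalign.split_align import SplitProfiles


# ---------------------------------------------------------------------------
# pair-HMM simulation

def simulate_pair(
    model: PairProbModel,
    length: int,
    seed: int,
    flank: int = 0,
    ref_name: str = "ref",
    query_name: str = "query",
) -> tuple[str, str, LocalAlignment]:
    """Sample an aligned sequence pair from the match/insert/delete automaton.

    The match state emits aligned pairs x:y with probability pi[x, y];
    from a match, each gap type opens with probability alpha and extends
    with probability beta (geometric run lengths).  Emission stops after
    the match that consumes the ``length``-th query letter, so the true
    alignment starts and ends with aligned letters.  Optional unaligned
    flanks are drawn from phi (reference) and psi (query).

    Returns (ref_seq, query_seq, truth alignment); deterministic per seed.
    """
    p_stay = 1.0 - 2.0 * model.alpha
    if p_stay <= 0.0 or model.pi.sum() <= 0.0:
        raise ValueError("degenerate model: no match-state mass")
    rng = np.random.default_rng(seed)
    pi_flat = (model.pi / model.pi.sum()).ravel()
    phi = model.phi / model.phi.sum()
    psi = model.psi / model.psi.sum()
    letters = np.array(list(ALPHABET.upper()))

    rcols: list[str] = []
    qcols: list[str] = []
    nq = 0
    state = "M"
    while True:
        if state == "M":
            k = rng.choice(16, p=pi_flat)
            rcols.append(letters[k // 4])
            qcols.append(letters[k % 4])
            nq += 1
            if nq == length:
                break
            u = rng.random()
            if u < model.alpha:
                state = "D"
            elif u < 2.0 * model.alpha:
                state = "I"
        elif state == "D":
            rcols.append(letters[rng.choice(4, p=phi)])
            qcols.append(GAP)
            if rng.random() >= model.beta:
                state = "M"
        else:  # I
            rcols.append(GAP)
            qcols.append(letters[rng.choice(4, p=psi)])
            nq += 1
            if rng.random() >= model.beta:
                state = "M"
            if nq == length:  # trim a trailing insertion run back to a match
                while qcols and (rcols[-1] == GAP or qcols[-1] == GAP):
                    nq -= qcols.pop() != GAP
                    rcols.pop()
                state = "M"
                continue

    rtext = "".join(rcols)
    qtext = "".join(qcols)
    rcore = rtext.replace(GAP, "")
    qcore = qtext.replace(GAP, "")
    rflank_l = "".join(letters[rng.choice(4, p=phi, size=flank)])
    rflank_r = "".join(letters[rng.choice(4, p=phi, size=flank)])
    qflank_l = "".join(letters[rng.choice(4, p=psi, size=flank)])
    qflank_r = "".join(letters[rng.choice(4, p=psi, size=flank)])
    ref_seq = rflank_l + rcore + rflank_r
    query_seq = qflank_l + qcore + qflank_r
    truth = LocalAlignment(
        ref=AlnRow(ref_name, flank, len(rcore), "+", len(ref_seq), rtext),
        query=AlnRow(query_name, flank, len(qcore), "+", len(query_seq), qtext),
    )
    return ref_seq, query_seq, truth


# ---------------------------------------------------------------------------
# toy rearranged genomes

@dataclass(frozen=True)
class TruthSegment:
    """One orthology segment of a rearranged query against its reference."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    primary: bool = True  # False for extra duplicate copies (many-to-one)


class IncompatibleOpsError(ValueError):
    """Rearrangement operations overlap in an unsupported way."""


@dataclass
class _Piece:
    ref_start: int
    ref_end: int
    strand: str
    primary: bool


def _find_piece(pieces: list[_Piece], s: int, e: int) -> int:
    for k, p in enumerate(pieces):
        if p.primary and p.strand == "+" and p.ref_start <= s and e <= p.ref_end:
            return k
    raise IncompatibleOpsError(
        f"interval [{s}, {e}) not inside a single unrearranged segment"
    )


def _split_piece(pieces: list[_Piece], k: int, s: int, e: int) -> int:
    """Split pieces[k] at [s, e); return the index of the middle part."""
    p = pieces.pop(k)
    parts = []
    if s > p.ref_start:
        parts.append(_Piece(p.ref_start, s, "+", p.primary))
    mid = len(parts)
    parts.append(_Piece(s, e, "+", p.primary))
    if e < p.ref_end:
        parts.append(_Piece(e, p.ref_end, "+", p.primary))
    pieces[k:k] = parts
    return k + mid


def make_rearranged_query(
    ref_seq: str,
    ops: list[tuple],
    seed: int = 0,
    sub_rate: float = 0.0,
) -> tuple[str, list[TruthSegment]]:
    """Apply rearrangement edits to a reference; return query and truth map.

    Supported ops (reference coordinates, half-open):
      ('inversion', s, e)            reverse-complement [s, e)
      ('deletion', s, e)             remove [s, e) from the query
      ('tandem_dup', s, e)           duplicate [s, e) in place
      ('dispersed_dup', s, e, at)    insert a copy of [s, e) at position `at`
    Duplicate copies are marked non-primary in the truth map (they make
    the query many-to-one against the reference).  ``sub_rate`` sprinkles
    point substitutions over the query.
    """
    n = len(ref_seq)
    pieces = [_Piece(0, n, "+", True)]
    for op in ops:
        kind, s, e = op[0], int(op[1]), int(op[2])
        if not 0 <= s < e <= n:
            raise IncompatibleOpsError(f"op {op} out of bounds")
        if kind == "inversion":
            mid = _split_piece(pieces, _find_piece(pieces, s, e), s, e)
            pieces[mid].strand = "-"
        elif kind == "deletion":
            mid = _split_piece(pieces, _find_piece(pieces, s, e), s, e)
            pieces.pop(mid)
        elif kind == "tandem_dup":
            mid = _split_piece(pieces, _find_piece(pieces, s, e), s, e)
            pieces.insert(mid + 1, _Piece(s, e, "+", False))
        elif kind == "dispersed_dup":
            at = int(op[3])
            k = next(
                (
                    idx
                    for idx, p in enumerate(pieces)
                    if p.primary
                    and p.strand == "+"
                    and p.ref_start <= at <= p.ref_end
                ),
                None,
            )
            if k is None:
                raise IncompatibleOpsError(f"insertion point {at} unavailable")
            p = pieces.pop(k)
            parts = []
            if at > p.ref_start:
                parts.append(_Piece(p.ref_start, at, "+", p.primary))
            parts.append(_Piece(s, e, "+", False))
            if at < p.ref_end:
                parts.append(_Piece(at, p.ref_end, "+", p.primary))
            pieces[k:k] = parts
        else:
            raise ValueError(f"unknown op {kind!r}")

    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    truth: list[TruthSegment] = []
    qpos = 0
    for p in pieces:
        seq = ref_seq[p.ref_start : p.ref_end]
        if p.strand == "-":
            seq = revcomp(seq)
        chunks.append(seq)
        truth.append(
            TruthSegment(
                query_start=qpos,
                query_end=qpos + len(seq),
                ref_start=p.ref_start,
                ref_end=p.ref_end,
                strand=p.strand,
                primary=p.primary,
            )
        )
        qpos += len(seq)
    query = "".join(chunks)
    if sub_rate > 0.0:
        letters = ALPHABET.upper()
        chars = list(query)
        hits = np.flatnonzero(rng.random(len(chars)) < sub_rate)
        for k in hits:
            old = chars[k].upper()
            choices = [c for c in letters if c != old]
            chars[k] = choices[rng.integers(3)]
        query = "".join(chars)
    return query, truth


def truthmap_to_tsv(truth: list[TruthSegment]) -> str:
    lines = ["#query_start\tquery_end\tref_start\tref_end\tstrand\tprimary"]
    for seg in truth:
        lines.append(
            f"{seg.query_start}\t{seg.query_end}\t{seg.ref_start}\t"
            f"{seg.ref_end}\t{seg.strand}\t{int(seg.primary)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# exhaustive small-scale local aligner (stand-in for seed-and-extend)

def _gotoh_best(
    ref: str, qseq: str, scheme: ScoreScheme, banned: set[tuple[int, int]]
):
    """One full affine local DP; returns (best score, end cell) or None."""
    m, n = len(ref), len(qseq)
    NEG = -math.inf
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ed = [[NEG] * (n + 1) for _ in range(m + 1)]  # ref letter vs gap
    Ei = [[NEG] * (n + 1) for _ in range(m + 1)]  # query letter vs gap
    go, ge = scheme.gap_open, scheme.gap_extend
    best, best_cell = 0.0, None
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            Ed[i][j] = max(H[i - 1][j] - go - ge, Ed[i - 1][j] - ge)
            Ei[i][j] = max(H[i][j - 1] - go - ge, Ei[i][j - 1] - ge)
            if (i, j) in banned:
                diag = NEG
            else:
                diag = H[i - 1][j - 1] + scheme.sub_score(
                    ref[i - 1], qseq[j - 1], on_unknown="zero"
                )
            h = max(0.0, diag, Ed[i][j], Ei[i][j])
            H[i][j] = h
            if h > best:
                best, best_cell = h, (i, j)
    return best, best_cell, H, Ed, Ei


def _gotoh_traceback(ref, qseq, scheme, banned, cell, H, Ed, Ei):
    go, ge = scheme.gap_open, scheme.gap_extend
    i, j = cell
    rcols: list[str] = []
    qcols: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0.0:
                break
            diag = (
                -math.inf
                if (i, j) in banned
                else H[i - 1][j - 1]
                + scheme.sub_score(ref[i - 1], qseq[j - 1], on_unknown="zero")
            )
            if H[i][j] == diag:
                rcols.append(ref[i - 1])
                qcols.append(qseq[j - 1])
                i -= 1
                j -= 1
            elif H[i][j] == Ed[i][j]:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            rcols.append(ref[i - 1])
            qcols.append(GAP)
            if Ed[i][j] == H[i - 1][j] - go - ge:
                state = "H"
            i -= 1
        else:
            rcols.append(GAP)
            qcols.append(qseq[j - 1])
            if Ei[i][j] == H[i][j - 1] - go - ge:
                state = "H"
            j -= 1
    return i, j, "".join(reversed(rcols)), "".join(reversed(qcols))


def exhaustive_local_alignments(
    query: str,
    ref: str,
    scheme: ScoreScheme,
    min_score: int,
    ref_name: str = "ref",
    query_name: str = "query",
    max_alignments: int = 30,
    both_strands: bool = True,
) -> list[LocalAlignment]:
    """All strong local alignments by iterated full DP (test scale only).

    Runs Smith-Waterman-Gotoh repeatedly, banning previously reported
    aligned pairs, until the best remaining score drops below
    ``min_score``.  Both query strands are searched.  Deterministic
    tie-breaks: diagonal over deletion over insertion; among alignments,
    output is sorted by (score desc, ref start, query name/start).
    """
    if len(query) * len(ref) > 10**6:
        raise ValueError("sequences too large for the exhaustive aligner")
    out: list[LocalAlignment] = []
    strands = "+-" if both_strands else "+"
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        banned: set[tuple[int, int]] = set()
        for _ in range(max_alignments):
            best, cell, H, Ed, Ei = _gotoh_best(ref, qseq, scheme, banned)
            if cell is None or best < min_score:
                break
            i0, j0, rtext, qtext = _gotoh_traceback(
                ref, qseq, scheme, banned, cell, H, Ed, Ei
            )
            ii, jj = i0, j0
            for rchar, qchar in zip(rtext, qtext):
                ii += rchar != GAP
                jj += qchar != GAP
                if rchar != GAP and qchar != GAP:
                    banned.add((ii, jj))
            out.append(
                LocalAlignment(
                    ref=AlnRow(
                        ref_name, i0, cell[0] - i0, "+", len(ref), rtext
                    ),
                    query=AlnRow(
                        query_name, j0, cell[1] - j0, strand, len(query), qtext
                    ),
                    score=int(best),
                )
            )
    out.sort(
        key=lambda a: (-a.score, a.ref.start, a.query.name, a.query.fwd_start)
    )
    return out


# ---------------------------------------------------------------------------
# brute-force fragment-set oracles

def _fragment_weight(cand, k: int, e: int) -> float:
    """Total score of candidate fragment covering query letters [k, e)."""
    kk, ee = k - cand.beg, e - cand.beg
    return float(cand.A[kk:ee].sum() + cand.D[kk + 1 : ee].sum())


def enumerate_fragment_sets(
    profiles: SplitProfiles,
    f: float | None = None,
    t: float = 1.0,
    max_span: int = 64,
    max_candidates: int = 8,
):
    """Exhaustive optimum, partition function, and column marginals.

    Considers every set of pairwise query-disjoint contiguous fragments
    of the candidates (the empty set included).  Returns
    ``(max_score, z, P, Pdel)`` where ``z = sum exp((sum scores - k f)/t)``
    over all sets and P/Pdel map ``(candidate_index, query_pos)`` to the
    exact marginal probability that the column (or the deletion between
    pos-1 and pos) is part of the set.

    Independent of the split recurrences: uses prefix/suffix sums over
    fragment end positions.
    """
    if f is None:
        f = profiles.f
    cands = profiles.candidates
    if not cands:
        return 0.0, 1.0, {}, {}
    beg, end = profiles.beg, profiles.end
    gspan = end - beg
    if gspan > max_span or len(cands) > max_candidates:
        raise ValueError("instance too large for exhaustive enumeration")

    frags = []  # (i, k, e, weight_exp, score)
    for i, cand in enumerate(cands):
        for k in range(cand.beg, cand.end):
            for e in range(k + 1, cand.end + 1):
                w = _fragment_weight(cand, k, e)
                frags.append((i, k, e, math.exp((w - f) / t), w))

    Zl = [1.0] * (gspan + 1)  # sets confined to [beg, beg+jj)
    Ml = [0.0] * (gspan + 1)
    for jj in range(1, gspan + 1):
        Zl[jj] = Zl[jj - 1]
        Ml[jj] = Ml[jj - 1]
        for i, k, e, wexp, w in frags:
            if e - beg == jj:
                Zl[jj] += Zl[k - beg] * wexp
                Ml[jj] = max(Ml[jj], Ml[k - beg] + w - f)
    Zr = [1.0] * (gspan + 1)  # sets confined to [beg+jj, end)
    for jj in range(gspan - 1, -1, -1):
        Zr[jj] = Zr[jj + 1]
        for i, k, e, wexp, w in frags:
            if k - beg == jj:
                Zr[jj] += wexp * Zr[e - beg]
    z = Zl[gspan]

    P: dict[tuple[int, int], float] = {}
    Pdel: dict[tuple[int, int], float] = {}
    for i, k, e, wexp, w in frags:
        contrib = wexp / z
        for j in range(k, e):
            P[(i, j)] = P.get((i, j), 0.0) + Zl[k - beg] * contrib * Zr[e - beg]
        for j in range(k + 1, e):
            Pdel[(i, j)] = (
                Pdel.get((i, j), 0.0) + Zl[k - beg] * contrib * Zr[e - beg]
            )
    return Ml[gspan], z, P, Pdel


def enumerate_sets_bruteforce(profiles: SplitProfiles, f: float, t: float):
    """Plain recursive enumeration of all disjoint fragment sets (tiny n).

    Validates the prefix/suffix oracle; returns (max_score, z).
    """
    cands = profiles.candidates
    beg, end = profiles.beg, profiles.end
    if end - beg > 14:
        raise ValueError("too large for plain recursion")
    frags_at: dict[int, list[tuple[float, int]]] = {}
    for i, cand in enumerate(cands):
        for k in range(cand.beg, cand.end):
            for e in range(k + 1, cand.end + 1):
                frags_at.setdefault(k, []).append((_fragment_weight(cand, k, e), e))

    best = 0.0
    z = 0.0

    def rec(j: int, score: float, nfrag: int) -> None:
        nonlocal best, z
        if j >= end:
            total = score - nfrag * f
            best = max(best, total)
            z += math.exp(total / t)
            return
        rec(j + 1, score, nfrag)
        for w, e in frags_at.get(j, ()):
            rec(e, score + w, nfrag + 1)

    rec(beg, 0.0, 0)
    return best, z
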