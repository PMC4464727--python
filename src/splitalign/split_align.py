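"""Viterbi split-alignment: profile construction, the DP with traceback, 2-split.

Given candidate local alignments of one query sequence, split-alignment
finds the set of disjoint alignment pieces maximizing

    sum over pieces of (piece score - f)

where f is the alignment existence cost.  Per candidate i, A[i][j] is
the score at query letter j (match, mismatch, or insertion) and D[i][j]
the score between letters j-1 and j (deletions).  The recurrences

    V[i][j+1] = max(V[i][j] + D[i][j], W[j] - f) + A[i][j]
    W[j+1]    = max(W[j], max_i V[i][j+1])

with V[i][beg(i)] = -inf and W[beg] = 0 give the optimal total W[end];
fragments are recovered by traceback.  A second pass with query and
reference roles swapped ("2-split") yields one-to-one alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from splitalign.core import (
    GAP,
    AlnRow,
    LocalAlignment,
    ScoreScheme,
    SplitFragment,
    orient_fragment_to_query_forward,
    orient_to_query_forward,
    score_alignment,
)

NEG = -math.inf


class ProfileError(ValueError):
    """Candidate unsuitable for profile construction."""


@dataclass
class CandidateProfile:
    """Per-query-position score layout of one oriented candidate."""

    alignment: LocalAlignment  # query row on '+' strand
    input_index: int
    beg: int  # first query letter (forward coords)
    end: int  # one past the last query letter
    A: np.ndarray  # score at letter j, index j - beg
    D: np.ndarray  # score between letters j-1 and j, index j - beg (0 at beg)
    col_of: np.ndarray  # column index consuming letter j
    ref_prefix: np.ndarray  # ref letters consumed before each column

    @property
    def span(self) -> int:
        return self.end - self.beg


@dataclass
class SplitProfiles:
    """A/D profiles of all candidates for one query sequence."""

    candidates: list[CandidateProfile]
    f: float
    scheme: ScoreScheme
    beg: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.candidates:
            self.beg = min(c.beg for c in self.candidates)
            self.end = max(c.end for c in self.candidates)


def _profile_one(
    aln: LocalAlignment, scheme: ScoreScheme, input_index: int, on_unknown: str
) -> CandidateProfile:
    if aln.query.strand != "+":
        raise ProfileError("candidate not oriented to forward query strand")
    beg = aln.query.start
    span = aln.query.size
    A = np.zeros(span, dtype=np.int64)
    D = np.zeros(span, dtype=np.int64)
    col_of = np.zeros(span, dtype=np.int64)
    ncols = aln.ncols
    ref_prefix = np.zeros(ncols + 1, dtype=np.int64)
    rtext, qtext = aln.ref.text, aln.query.text
    if GAP in (rtext[0], qtext[0], rtext[-1], qtext[-1]):
        raise ProfileError("candidate must start and end with aligned letters")
    jj = 0  # letter offset within the span
    pending_del = 0
    prev_ins = False
    for c in range(ncols):
        rchar, qchar = rtext[c], qtext[c]
        ref_prefix[c + 1] = ref_prefix[c] + (rchar != GAP)
        if qchar == GAP:
            pending_del += 1
            prev_ins = False
            continue
        if pending_del:
            D[jj] = -(scheme.gap_open + scheme.gap_extend * pending_del)
            pending_del = 0
        if rchar == GAP:  # insertion: this query letter is gapped in the reference
            A[jj] = -(scheme.gap_extend + (0 if prev_ins else scheme.gap_open))
            prev_ins = True
        else:
            A[jj] = scheme.sub_score(rchar, qchar, on_unknown=on_unknown)
            prev_ins = False
        col_of[jj] = c
        jj += 1
    assert jj == span and pending_del == 0
    return CandidateProfile(
        alignment=aln,
        input_index=input_index,
        beg=beg,
        end=beg + span,
        A=A,
        D=D,
        col_of=col_of,
        ref_prefix=ref_prefix,
    )


def build_profiles(
    candidates: list[LocalAlignment],
    scheme: ScoreScheme,
    f: float,
    input_indices: list[int] | None = None,
    on_unknown: str = "error",
) -> SplitProfiles:
    """Build per-letter score profiles for candidates of one query.

    Candidates must share a query name and be oriented to the forward
    query strand.  An insertion run of length L contributes -gap_extend
    to each inserted letter plus -gap_open on the first; a deletion run
    between letters j-1 and j contributes -(gap_open + L gap_extend) to
    D at j.  The profile sums reproduce each candidate's scheme score.
    """
    if f < 0:
        raise ValueError("alignment existence cost f must be >= 0")
    names = {c.query.name for c in candidates}
    if len(names) > 1:
        raise ProfileError(f"mixed query names: {sorted(names)}")
    if input_indices is None:
        input_indices = list(range(len(candidates)))
    profiles = [
        _profile_one(aln, scheme, idx, on_unknown)
        for aln, idx in zip(candidates, input_indices)
    ]
    return SplitProfiles(candidates=profiles, f=f, scheme=scheme)


def _slice_fragment(cand: CandidateProfile, k: int, e: int) -> SplitFragment:
    """Cut query letters [k, e) out of a candidate, with internal deletions."""
    aln = cand.alignment
    lo = int(cand.col_of[k - cand.beg])
    hi = int(cand.col_of[e - 1 - cand.beg]) + 1
    rtext = aln.ref.text[lo:hi]
    qtext = aln.query.text[lo:hi]
    rp = int(cand.ref_prefix[lo])
    rsize = int(cand.ref_prefix[hi]) - rp
    score = int(
        cand.A[k - cand.beg : e - cand.beg].sum()
        + cand.D[k + 1 - cand.beg : e - cand.beg].sum()
    )
    return SplitFragment(
        source_index=cand.input_index,
        ref=AlnRow(
            name=aln.ref.name,
            start=aln.ref.start + rp,
            size=rsize,
            strand=aln.ref.strand,
            srcsize=aln.ref.srcsize,
            text=rtext,
        ),
        query=AlnRow(
            name=aln.query.name,
            start=k,
            size=e - k,
            strand="+",
            srcsize=aln.query.srcsize,
            text=qtext,
        ),
        score=score,
    )


def split(profiles: SplitProfiles) -> tuple[list[SplitFragment], float]:
    """Run the split DP; return fragments (query order) and the total W[end].

    Tie-breaking: continuation is preferred over restart, and the carried
    W over an equal V (so among equal optima the one with fewer, earlier
    merged fragments is reported).
    """
    cands = profiles.candidates
    if not cands:
        return [], 0.0
    f = profiles.f
    beg, end = profiles.beg, profiles.end
    gspan = end - beg
    W = np.zeros(gspan + 1)
    wfrom = np.full(gspan + 1, -1, dtype=np.int64)  # candidate index or -1 (carry)
    V = [np.full(c.span + 1, NEG) for c in cands]
    is_cont = [np.zeros(c.span + 1, dtype=bool) for c in cands]
    # candidates whose span covers position j, maintained by start events
    starts: dict[int, list[int]] = {}
    for i, c in enumerate(cands):
        starts.setdefault(c.beg, []).append(i)
    active: list[int] = []
    for j in range(beg, end):
        jj = j - beg
        for i in starts.get(j, ()):
            active.append(i)
        active = [i for i in active if cands[i].end > j]
        restart = W[jj] - f
        best_v = NEG
        best_i = -1
        for i in active:
            ji = j - cands[i].beg
            cont_val = V[i][ji] + (cands[i].D[ji] if ji > 0 else 0)
            if cont_val >= restart:
                base, is_c = cont_val, True
            else:
                base, is_c = restart, False
            v = base + cands[i].A[ji]
            V[i][ji + 1] = v
            is_cont[i][ji + 1] = is_c
            if v > best_v:
                best_v, best_i = v, i
        if best_v > W[jj]:
            W[jj + 1] = best_v
            wfrom[jj + 1] = best_i
        else:
            W[jj + 1] = W[jj]
    total = float(W[gspan])
    # traceback
    fragments: list[SplitFragment] = []
    jj = gspan
    while jj > 0:
        i = int(wfrom[jj])
        if i < 0:
            jj -= 1
            continue
        cand = cands[i]
        e = beg + jj  # fragment end (one past last letter)
        ji = (beg + jj) - cand.beg
        while is_cont[i][ji]:
            ji -= 1
        k = cand.beg + ji - 1  # restart consumed letter k = position ji-1 + beg
        fragments.append(_slice_fragment(cand, k, e))
        jj = (k - beg)  # resume at W[k]
    fragments.reverse()
    return fragments, total


def _group_by_query(alignments: list[LocalAlignment]):
    groups: dict[str, list[tuple[int, LocalAlignment]]] = {}
    for idx, aln in enumerate(alignments):
        groups.setdefault(aln.query.name, []).append((idx, aln))
    return groups


def one_split(
    alignments: list[LocalAlignment],
    scheme: ScoreScheme,
    f: float,
    t: float | None = None,
    mismap_threshold: float | None = None,
    on_unknown: str = "error",
) -> list[SplitFragment]:
    """Split-align each query sequence independently (many-to-one output).

    Candidates are grouped by query name and oriented to the forward
    query strand.  When ``t`` is given, a Forward-Backward pass attaches
    per-column error probabilities and a fragment mismap; when
    ``mismap_threshold`` is also given, fragments lacking any position
    with error probability <= threshold are dropped.
    """
    from splitalign import prob_split  # local import; prob_split builds on this module

    out: list[SplitFragment] = []
    for _, group in _group_by_query(alignments).items():
        indices = [idx for idx, _ in group]
        oriented = [orient_to_query_forward(aln) for _, aln in group]
        profiles = build_profiles(
            oriented, scheme, f, input_indices=indices, on_unknown=on_unknown
        )
        fragments, _ = split(profiles)
        if t is not None:
            state = prob_split.forward_backward(profiles, t)
            prob_split.annotate_fragments(fragments, state, profiles)
            if mismap_threshold is not None:
                fragments = prob_split.mismap_filter(fragments, mismap_threshold)
        out.extend(fragments)
    return out


def two_split(
    alignments: list[LocalAlignment],
    scheme: ScoreScheme,
    f: float,
    t: float | None = None,
    mismap_threshold: float | None = None,
    on_unknown: str = "error",
) -> list[SplitFragment]:
    """Two passes of split-alignment, giving one-to-one alignments.

    The first pass makes the output many-to-one in the query; the second
    pass, run with query and reference roles swapped and the same f,
    makes it one-to-one.  Error probabilities come from the second pass.
    """
    first = one_split(alignments, scheme, f, on_unknown=on_unknown)
    swapped_in = [frag.to_alignment().swapped() for frag in first]
    second = one_split(
        swapped_in, scheme, f, t=t,
        mismap_threshold=mismap_threshold, on_unknown=on_unknown,
    )
    out = []
    for frag in second:
        back = frag.swapped()  # restore original roles
        back.source_index = first[frag.source_index].source_index
        out.append(orient_fragment_to_query_forward(back))
    out.sort(key=lambda fr: (fr.query.name, fr.query.fwd_start))
    return out
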