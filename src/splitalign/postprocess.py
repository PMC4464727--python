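"""Gapless-alignment culling and soft-mask-aware post-filtering.

Culling discards a gapless alignment whose query segment lies inside
those of two or more other alignments with strictly greater
score-per-length (score-per-length is computed for whole alignments).
It thins overwhelming repeat-induced candidate sets while keeping the
strongest matches to each query region.

Post-masking implements "gentle masking": after aligning
case-insensitively, each alignment is rescored with lowercase-touching
columns capped at score 0 (gap costs unchanged) and is kept only if
some contiguous column segment still reaches score >= e.  This discards
alignments of independently evolved simple sequence without forbidding
alignments from extending through masked regions.
"""

from __future__ import annotations

from dataclasses import dataclass

from splitalign.core import (
    GAP,
    AlnRow,
    LocalAlignment,
    ScoreScheme,
    SplitFragment,
    revcomp,
)


@dataclass(frozen=True)
class CullRecord:
    """Query interval and whole-alignment score density of one candidate."""

    query_beg: int
    query_end: int
    score: int
    length: int
    density: float

    @classmethod
    def from_alignment(cls, aln: LocalAlignment) -> "CullRecord":
        length = aln.query.size
        if length <= 0:
            raise ValueError("empty alignment")
        return cls(
            query_beg=aln.query.fwd_start,
            query_end=aln.query.fwd_end,
            score=aln.score,
            length=length,
            density=aln.score / length,
        )


def cull_gapless(
    alignments: list[LocalAlignment], limit: int = 2
) -> list[LocalAlignment]:
    """Cull gapless alignments contained in >= limit denser alignments.

    An alignment is discarded iff at least ``limit`` others with
    strictly greater score-per-length have query intervals that each
    fully contain its own (within the same query sequence).  Density
    ties never count toward the limit, so the survivor set is
    independent of input order.
    """
    for aln in alignments:
        if GAP in aln.ref.text or GAP in aln.query.text:
            raise ValueError("cull_gapless: gapped alignment in input")
        if aln.score is None:
            raise ValueError("cull_gapless: alignment without a score")
    groups: dict[str, list[int]] = {}
    for k, aln in enumerate(alignments):
        groups.setdefault(aln.query.name, []).append(k)
    keep = [True] * len(alignments)
    for members in groups.values():
        recs = [CullRecord.from_alignment(alignments[k]) for k in members]
        for a_pos, a in enumerate(recs):
            covering = sum(
                1
                for b_pos, b in enumerate(recs)
                if b_pos != a_pos
                and b.density > a.density
                and b.query_beg <= a.query_beg
                and b.query_end >= a.query_end
            )
            if covering >= limit:
                keep[members[a_pos]] = False
    return [aln for k, aln in enumerate(alignments) if keep[k]]


def _row_letters(row: AlnRow, seq: str | None) -> str:
    """Letters of a row in row orientation, taking case from seq if given."""
    if seq is None:
        return row.text.replace(GAP, "")
    if row.strand == "+":
        return seq[row.start : row.start + row.size]
    lo = row.srcsize - row.start - row.size
    return revcomp(seq[lo : lo + row.size])


def _column_values(
    ref_letters: str,
    query_letters: str,
    rtext: str,
    qtext: str,
    scheme: ScoreScheme,
) -> list[float]:
    """Per-column rescored values with gentle masking of lowercase letters."""
    vals: list[float] = []
    ri = qi = 0
    in_rgap = in_qgap = False
    for rchar, qchar in zip(rtext, qtext):
        if rchar == GAP:
            vals.append(-(scheme.gap_extend + (0 if in_rgap else scheme.gap_open)))
            in_rgap, in_qgap = True, False
            qi += 1
            continue
        if qchar == GAP:
            vals.append(-(scheme.gap_extend + (0 if in_qgap else scheme.gap_open)))
            in_rgap, in_qgap = False, True
            ri += 1
            continue
        in_rgap = in_qgap = False
        r = ref_letters[ri]
        q = query_letters[qi]
        s = scheme.sub_score(r, q, on_unknown="zero")
        if r.islower() or q.islower():
            s = min(s, 0)
        vals.append(s)
        ri += 1
        qi += 1
    return vals


def max_segment_score(values) -> float:
    """Maximum contiguous-segment sum (empty segment scores 0)."""
    best = run = 0.0
    for v in values:
        run = max(0.0, run + v)
        best = max(best, run)
    return best


def postmask(
    fragments: list[SplitFragment | LocalAlignment],
    scheme: ScoreScheme,
    e: int,
    query_seqs: dict[str, str] | None = None,
    ref_seqs: dict[str, str] | None = None,
) -> list[SplitFragment | LocalAlignment]:
    """Keep fragments whose gently-masked max segment score reaches e.

    Lowercase (soft-masked) letters come from the provided genome
    sequences when given, otherwise from the alignment texts themselves.
    """
    if e <= 0:
        raise ValueError("score threshold e must be positive")
    kept = []
    for frag in fragments:
        qseq = rseq = None
        if query_seqs is not None:
            if frag.query.name not in query_seqs:
                raise KeyError(f"missing query sequence {frag.query.name}")
            qseq = query_seqs[frag.query.name]
        if ref_seqs is not None:
            if frag.ref.name not in ref_seqs:
                raise KeyError(f"missing reference sequence {frag.ref.name}")
            rseq = ref_seqs[frag.ref.name]
        vals = _column_values(
            _row_letters(frag.ref, rseq),
            _row_letters(frag.query, qseq),
            frag.ref.text,
            frag.query.text,
            scheme,
        )
        if max_segment_score(vals) >= e:
            kept.append(frag)
    return kept
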