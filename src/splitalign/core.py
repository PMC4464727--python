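"""Domain types shared by all modules, plus coordinate/strand normalization.

Conventions
-----------
* Coordinates are 0-based half-open.  Row starts follow the MAF
  convention: the start is counted on the row's own strand, so a '-'
  strand start of ``s`` corresponds to forward-strand position
  ``srcsize - s - size`` (of the interval end).
* Case (soft-masking) is preserved through all operations; only the
  post-masking filter consults it.
* 'n' and other ambiguity codes never score and are never counted as
  matches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

ALPHABET = "acgt"
LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}
GAP = "-"

_COMPLEMENT = str.maketrans(
    "acgtnrykmbdhvswACGTNRYKMBDHVSW",
    "tgcanyrmkvhdbswTGCANYRMKVHDBSW",
)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse-complement, preserving case and ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input record (MAF block, matrix file, strand symbol...)."""


@dataclass(frozen=True)
class AlnRow:
    """One sequence row of a pairwise alignment, MAF 's'-line semantics.

    ``start`` is counted on ``strand``; ``size`` counts non-gap letters;
    ``text`` is the aligned sequence including '-' gaps.
    """

    name: str
    start: int
    size: int
    strand: str
    srcsize: int
    text: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"unknown strand symbol {self.strand!r}")
        ngaps = self.text.count(GAP)
        if len(self.text) - ngaps != self.size:
            raise FormatError(
                f"row {self.name}: size {self.size} != "
                f"{len(self.text) - ngaps} non-gap letters"
            )
        if self.start < 0 or self.start + self.size > self.srcsize:
            raise FormatError(f"row {self.name}: interval outside [0, srcSize)")

    @property
    def end(self) -> int:
        return self.start + self.size

    @property
    def fwd_start(self) -> int:
        """Start in forward-strand coordinates."""
        if self.strand == "+":
            return self.start
        return self.srcsize - self.start - self.size

    @property
    def fwd_end(self) -> int:
        return self.fwd_start + self.size

    def flipped(self) -> "AlnRow":
        """The same interval expressed on the opposite strand."""
        return AlnRow(
            name=self.name,
            start=self.srcsize - self.start - self.size,
            size=self.size,
            strand="-" if self.strand == "+" else "+",
            srcsize=self.srcsize,
            text=revcomp(self.text),
        )


@dataclass
class LocalAlignment:
    """One candidate local alignment between a reference and a query row.

    Row texts have equal length; columns pair one reference character
    with one query character, '-' marking a gap.  ``score`` is the
    integer alignment score under whatever scheme produced it.
    """

    ref: AlnRow
    query: AlnRow
    score: int | None = None
    mismap: float | None = None
    column_error_probs: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.ref.text) != len(self.query.text):
            raise FormatError(
                f"alignment {self.ref.name}/{self.query.name}: "
                "row texts differ in length"
            )

    def columns(self) -> Iterator[tuple[str, str]]:
        """Yield (ref_char, query_char) pairs."""
        return zip(self.ref.text, self.query.text)

    @property
    def ncols(self) -> int:
        return len(self.ref.text)

    def swapped(self) -> "LocalAlignment":
        """Exchange the roles of reference and query."""
        return LocalAlignment(
            ref=self.query,
            query=self.ref,
            score=self.score,
            mismap=self.mismap,
            column_error_probs=self.column_error_probs,
        )


@dataclass
class SplitFragment:
    """An output piece of one candidate alignment.

    ``source_index`` identifies the candidate it was cut from.  The query
    row is always on the forward strand.  ``column_error_probs`` holds one
    error probability per alignment column; ``mismap`` is the minimum
    error probability over columns that contain a query letter.
    """

    source_index: int
    ref: AlnRow
    query: AlnRow
    score: int
    column_error_probs: list[float] | None = None
    mismap: float | None = None

    @property
    def query_beg(self) -> int:
        return self.query.fwd_start

    @property
    def query_end(self) -> int:
        return self.query.fwd_end

    def to_alignment(self) -> LocalAlignment:
        return LocalAlignment(
            ref=self.ref,
            query=self.query,
            score=self.score,
            mismap=self.mismap,
            column_error_probs=(
                None
                if self.column_error_probs is None
                else list(self.column_error_probs)
            ),
        )

    def swapped(self) -> "SplitFragment":
        return replace(self, ref=self.query, query=self.ref)


@dataclass
class ScoreScheme:
    """Integer substitution matrix with affine gap costs.

    A gap run of length L costs ``gap_open + gap_extend * L`` (the "gap
    existence cost" plus a per-letter extension cost).  ``t`` is the
    scale factor in score units per nat, set by calibration; scores
    relate to model probabilities via prob proportional to exp(score/t).
    """

    matrix: np.ndarray
    gap_open: int
    gap_extend: int
    t: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4 (a,c,g,t)")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.t is not None and self.t <= 0:
            raise ValueError("scale factor t must be positive")

    def sub_score(self, a: str, b: str, on_unknown: str = "error") -> int:
        """Score of aligning letters a:b, case-insensitively.

        'n' in either position scores 0.  Other letters outside acgt
        raise by default, or score 0 with ``on_unknown='zero'``.
        """
        a = a.lower()
        b = b.lower()
        ia = LETTER_INDEX.get(a)
        ib = LETTER_INDEX.get(b)
        if ia is not None and ib is not None:
            return int(self.matrix[ia, ib])
        if a == "n" or b == "n" or on_unknown == "zero":
            return 0
        raise FormatError(f"letter outside acgtn: {a!r}:{b!r}")


@dataclass
class PairProbModel:
    """Probability parameters of the pairwise alignment model.

    ``pi[x, y]`` is the probability that a match-state column emits the
    aligned pair x:y.  ``phi`` and ``psi`` are the reference and query
    letter frequencies emitted in deletion and insertion states.
    ``alpha`` opens a gap, ``beta`` extends it, ``gamma`` starts an
    alignment, and ``omega`` continues the unaligned background.
    """

    pi: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    alpha: float
    beta: float
    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.pi.shape != (4, 4) or self.phi.shape != (4,) or self.psi.shape != (4,):
            raise ValueError("pi must be 4x4; phi, psi must be 4-vectors")
        for v, label in [
            (self.alpha, "alpha"),
            (self.beta, "beta"),
            (self.gamma, "gamma"),
            (self.omega, "omega"),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} outside [0, 1]")
        if (self.pi < 0).any() or (self.phi < 0).any() or (self.psi < 0).any():
            raise ValueError("negative emission probability")
        if self.phi.sum() > 1 + 1e-9 or self.psi.sum() > 1 + 1e-9:
            raise ValueError("phi/psi must each sum to <= 1")


@dataclass
class SegmentModel:
    """1-D segment model: foreground letter runs against a background.

    Foreground letters have frequencies ``pi_seg``, background letters
    ``theta``; ``omega``/``gamma`` continue background/foreground and
    ``alpha`` starts a new segment.  The derived letter score is
    S(x) = t ln(gamma/omega * pi_x/theta_x), and the segment existence
    cost is f = -t ln(alpha (1 - gamma) / gamma).
    """

    pi_seg: np.ndarray
    theta: np.ndarray
    omega: float
    gamma: float
    alpha: float
    t: float = 1.0

    def __post_init__(self) -> None:
        self.pi_seg = np.asarray(self.pi_seg, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        for v in (self.pi_seg, self.theta):
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError("probability vectors must sum to 1")
        if (self.theta <= 0).any():
            raise ValueError("background frequencies must be positive")

    def letter_scores(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.t * np.log(
                self.gamma / self.omega * self.pi_seg / self.theta
            )

    def existence_cost(self) -> float:
        return -self.t * float(
            np.log(self.alpha * (1.0 - self.gamma) / self.gamma)
        )


def orient_to_query_forward(aln: LocalAlignment) -> LocalAlignment:
    """Return the alignment expressed on the forward strand of the query.

    If the query row is on '-', both rows are flipped together (texts
    reverse-complemented, starts re-expressed on the opposite strand) so
    the alignment content and score are unchanged.
    """
    if aln.query.strand == "+":
        return aln
    probs = aln.column_error_probs
    return LocalAlignment(
        ref=aln.ref.flipped(),
        query=aln.query.flipped(),
        score=aln.score,
        mismap=aln.mismap,
        column_error_probs=None if probs is None else probs[::-1],
    )


def orient_fragment_to_query_forward(frag: SplitFragment) -> SplitFragment:
    if frag.query.strand == "+":
        return frag
    probs = frag.column_error_probs
    return replace(
        frag,
        ref=frag.ref.flipped(),
        query=frag.query.flipped(),
        column_error_probs=None if probs is None else probs[::-1],
    )


def score_alignment(
    aln: LocalAlignment, scheme: ScoreScheme, on_unknown: str = "error"
) -> int:
    """Evaluate the scheme over the alignment columns.

    Substitution columns score via the matrix; each gap run of length L
    (in either row) costs gap_open + gap_extend * L.
    """
    total = 0
    in_ref_gap = False
    in_query_gap = False
    for rchar, qchar in aln.columns():
        rgap = rchar == GAP
        qgap = qchar == GAP
        if rgap and qgap:
            raise FormatError("column with gaps in both rows")
        if rgap:  # insertion in query
            total -= scheme.gap_extend + (0 if in_ref_gap else scheme.gap_open)
            in_ref_gap, in_query_gap = True, False
        elif qgap:  # deletion in query
            total -= scheme.gap_extend + (0 if in_query_gap else scheme.gap_open)
            in_ref_gap, in_query_gap = False, True
        else:
            total += scheme.sub_score(rchar, qchar, on_unknown=on_unknown)
            in_ref_gap = in_query_gap = False
    return total
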