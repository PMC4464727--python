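"""Readers and writers: MAF alignment blocks, FASTA, score-matrix files.

MAF dialect
-----------
Each block is an 'a' line with ``score=`` (and optionally ``mismap=``),
exactly two 's' lines -- reference first, query second, matching the
output convention of seed-and-extend aligners run against a reference
database -- and an optional 'p' line with per-column error probabilities.

The 'p' line uses a phred+33 encoding: for error probability ``err`` the
character is ``chr(33 + min(round(-10 log10 max(err, 1e-9)), 93))``,
capped at '~'.  This loses less than 0.1 dB per column.

Readers reject inconsistent records rather than repairing them; writer
output is byte-stable for identical inputs.
"""

from __future__ import annotations

import io
import math
import re
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from Bio import SeqIO

from splitalign.core import (
    ALPHABET,
    GAP,
    AlnRow,
    FormatError,
    LocalAlignment,
    ScoreScheme,
    SplitFragment,
)

_PROB_CAP = 93
_FLOOR = 1e-9


def encode_error_probs(errs: Sequence[float]) -> str:
    chars = []
    for err in errs:
        phred = round(-10.0 * math.log10(max(err, _FLOOR)))
        chars.append(chr(33 + min(phred, _PROB_CAP)))
    return "".join(chars)


def decode_error_probs(text: str) -> list[float]:
    out = []
    for ch in text:
        phred = ord(ch) - 33
        if not 0 <= phred <= _PROB_CAP:
            raise FormatError(f"bad probability character {ch!r}")
        out.append(10.0 ** (-phred / 10.0))
    return out


def _open(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_maf(source) -> list[LocalAlignment]:
    """Parse MAF blocks into LocalAlignments (reference row first).

    Blocks with other than two 's' lines are rejected.  Input order is
    preserved.
    """
    stream = _open(source)
    alignments: list[LocalAlignment] = []
    attrs: dict[str, str] = {}
    srows: list[tuple[int, AlnRow]] = []
    probs: list[float] | None = None
    in_block = False

    def flush(lineno: int) -> None:
        nonlocal attrs, srows, probs, in_block
        if not in_block:
            return
        if len(srows) != 2:
            raise FormatError(
                f"line {lineno}: MAF block with {len(srows)} 's' lines (need 2)"
            )
        score = None
        if "score" in attrs:
            score = int(round(float(attrs["score"])))
        mismap = float(attrs["mismap"]) if "mismap" in attrs else None
        aln = LocalAlignment(
            ref=srows[0][1],
            query=srows[1][1],
            score=score,
            mismap=mismap,
            column_error_probs=probs,
        )
        if probs is not None and len(probs) != aln.ncols:
            raise FormatError(
                f"line {lineno}: 'p' line length != alignment columns"
            )
        alignments.append(aln)
        attrs, srows, probs, in_block = {}, [], None, False

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            continue
        tag = line.split(None, 1)[0]
        if tag == "a":
            flush(lineno)
            in_block = True
            for part in line.split()[1:]:
                if "=" not in part:
                    raise FormatError(f"line {lineno}: bad 'a' attribute {part!r}")
                key, _, val = part.partition("=")
                attrs[key] = val
        elif tag == "s":
            if not in_block:
                raise FormatError(f"line {lineno}: 's' line outside a block")
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(f"line {lineno}: 's' line needs 7 fields")
            try:
                row = AlnRow(
                    name=fields[1],
                    start=int(fields[2]),
                    size=int(fields[3]),
                    strand=fields[4],
                    srcsize=int(fields[5]),
                    text=fields[6],
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            srows.append((lineno, row))
        elif tag == "p":
            if not in_block:
                raise FormatError(f"line {lineno}: 'p' line outside a block")
            probs = decode_error_probs(line.split(None, 1)[1].strip())
        elif tag in ("q", "i", "e", "track"):
            continue
        else:
            raise FormatError(f"line {lineno}: unrecognized line {line[:30]!r}")
    flush(lineno + 1)
    return alignments


def write_maf(
    blocks: Iterable[LocalAlignment | SplitFragment],
    stream: IO[str],
    include_probs: bool = False,
) -> None:
    """Write blocks in deterministic order (query name, query start, input order)."""
    items = list(blocks)
    order = sorted(
        range(len(items)),
        key=lambda k: (items[k].query.name, items[k].query.fwd_start, k),
    )
    for k in order:
        blk = items[k]
        aline = "a" if blk.score is None else f"a score={int(blk.score)}"
        if blk.mismap is not None:
            aline += f" mismap={blk.mismap:g}"
        stream.write(aline + "\n")
        for row in (blk.ref, blk.query):
            stream.write(
                f"s {row.name} {row.start} {row.size} {row.strand} "
                f"{row.srcsize} {row.text}\n"
            )
        if include_probs and blk.column_error_probs is not None:
            stream.write("p " + encode_error_probs(blk.column_error_probs) + "\n")
        stream.write("\n")


def maf_to_string(blocks, include_probs: bool = False) -> str:
    buf = io.StringIO()
    write_maf(blocks, buf, include_probs=include_probs)
    return buf.getvalue()


_GAP_KEY = re.compile(r"#\s*gap[_ ]?(open|existence|extend|extension)\D*?(\d+)", re.I)


def read_matrix(
    source,
    gap_open: int | None = None,
    gap_extend: int | None = None,
) -> ScoreScheme:
    """Parse a BLAST/LAST-style score matrix into a,c,g,t order.

    The header row gives column letters, each following row a letter and
    its integer scores; row/column order in the file is arbitrary.  Gap
    costs may come from ``# gap_open=N`` / ``# gap_extend=N`` comment
    keys or from the arguments (arguments win).
    """
    stream = _open(source)
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    file_open = file_extend = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _GAP_KEY.match(line)
            if m:
                if m.group(1).lower() in ("open", "existence"):
                    file_open = int(m.group(2))
                else:
                    file_extend = int(m.group(2))
            continue
        fields = line.split()
        if header is None:
            header = [c.lower() for c in fields]
            if sorted(header) != sorted(ALPHABET):
                raise FormatError(
                    f"line {lineno}: header letters {header} != a,c,g,t"
                )
            continue
        letter = fields[0].lower()
        if letter not in ALPHABET or len(fields) != 5:
            raise FormatError(f"line {lineno}: bad matrix row {line!r}")
        try:
            rows[letter] = [int(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer entry") from exc
    if header is None or sorted(rows) != sorted(ALPHABET):
        raise FormatError("matrix file missing letters")
    matrix = np.zeros((4, 4), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            matrix[i, j] = rows[a][header.index(b)]
    gap_open = gap_open if gap_open is not None else file_open
    gap_extend = gap_extend if gap_extend is not None else file_extend
    if gap_open is None or gap_extend is None:
        raise FormatError("gap costs not given (file keys or arguments)")
    return ScoreScheme(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)


def read_fasta(source) -> dict[str, str]:
    """Read FASTA sequences, preserving case (soft-masking)."""
    stream = _open(source)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(stream, "fasta")}


def write_fasta(seqs: dict[str, str], stream: IO[str], width: int = 60) -> None:
    for name in seqs:
        stream.write(f">{name}\n")
        seq = seqs[name]
        for k in range(0, len(seq), width):
            stream.write(seq[k : k + width] + "\n")
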