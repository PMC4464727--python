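"""Built-in nucleotide scoring schemes.

Three schemes widely used for genome-to-genome alignment: HoxD70 and
HoxD55 (Chiaromonte-style matrices for diverged genomes), and
human-chimp.v2 for closely related primates.  Stored as matrix text so
the file reader is the single parsing path.
"""

from __future__ import annotations

import io

from splitalign.core import ScoreScheme

HUMAN_CHIMP_V2 = """\
# human-chimp.v2
# gap_open=600
# gap_extend=150
   a    c    g    t
a  90 -330 -236 -356
c -330 100 -318 -236
g -236 -318 100 -330
t -356 -236 -330  90
"""

HOXD70 = """\
# HoxD70
# gap_open=400
# gap_extend=30
   a    c    g    t
a  91 -114  -31 -123
c -114 100 -125  -31
g  -31 -125 100 -114
t -123  -31 -114  91
"""

HOXD55 = """\
# HoxD55
# gap_open=400
# gap_extend=30
   a    c    g    t
a  91  -90  -25 -100
c -90  100 -100  -25
g -25 -100  100  -90
t -100 -25  -90   91
"""

_BUILTINS = {
    "human-chimp.v2": HUMAN_CHIMP_V2,
    "hoxd70": HOXD70,
    "hoxd55": HOXD55,
}

BUILTIN_NAMES = ("human-chimp.v2", "HoxD70", "HoxD55")


def builtin_scheme(name: str) -> ScoreScheme:
    """Look up a built-in scheme by (case-insensitive) name."""
    from splitalign.maf_io import read_matrix

    key = name.lower()
    if key not in _BUILTINS:
        raise KeyError(
            f"unknown scheme {name!r}; built-ins: {', '.join(BUILTIN_NAMES)}"
        )
    scheme = read_matrix(io.StringIO(_BUILTINS[key]))
    scheme.name = name
    return scheme
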