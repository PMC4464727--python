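import numpy as np
import pytest

from splitalign.core import AlnRow, LocalAlignment, ScoreScheme
from splitalign.matrices import builtin_scheme


@pytest.fixture(scope="session")
def hoxd70():
    return builtin_scheme("HoxD70")


@pytest.fixture(scope="session")
def human_chimp():
    return builtin_scheme("human-chimp.v2")


@pytest.fixture(scope="session")
def hoxd55():
    return builtin_scheme("HoxD55")


@pytest.fixture(scope="session")
def toy_scheme():
    """Match +2 / mismatch -3, gap cost 3 + 1 per letter."""
    return ScoreScheme(
        np.where(np.eye(4, dtype=bool), 2, -3).astype(int),
        gap_open=3,
        gap_extend=1,
    )


@pytest.fixture(scope="session")
def fig10_scheme():
    """Match +1 / mismatch -1, gap cost 2 + 1 per letter."""
    return ScoreScheme(
        np.where(np.eye(4, dtype=bool), 1, -1).astype(int),
        gap_open=2,
        gap_extend=1,
    )


def make_alignment(
    rtext,
    qtext,
    qstart=0,
    rstart=0,
    qname="q",
    rname="r",
    qstrand="+",
    rstrand="+",
    qsrc=None,
    rsrc=None,
    score=None,
):
    """Build a LocalAlignment from aligned texts; source sizes get margins."""
    qsize = len(qtext.replace("-", ""))
    rsize = len(rtext.replace("-", ""))
    return LocalAlignment(
        ref=AlnRow(rname, rstart, rsize, rstrand, rsrc or rstart + rsize + 30, rtext),
        query=AlnRow(qname, qstart, qsize, qstrand, qsrc or qstart + qsize + 30, qtext),
        score=score,
    )


def random_candidate(rng, scheme, qstart, span, qname="q", rstart=0):
    """Random match-bounded candidate consuming `span` query letters."""
    letters = "ACGT"
    cols = []
    nq = 0
    while nq < span:
        u = rng.random()
        if nq == 0 or nq == span - 1 or u < 0.7:
            cols.append((letters[rng.integers(4)], letters[rng.integers(4)]))
            nq += 1
        elif u < 0.85:
            cols.append((letters[rng.integers(4)], "-"))
        else:
            cols.append(("-", letters[rng.integers(4)]))
            nq += 1
    if "-" in cols[-1]:
        cols.append(("A", "A"))
    rtext = "".join(c[0] for c in cols)
    qtext = "".join(c[1] for c in cols)
    return make_alignment(rtext, qtext, qstart=qstart, rstart=rstart, qname=qname)
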