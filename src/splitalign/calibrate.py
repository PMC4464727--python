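"""Score <-> probability calibration, event counting, and the 1-D segment-set analog.

An integer substitution matrix S is a scaled log-odds matrix for some
(unique, when the matrix is valid) triple of a scale lambda > 0 and
background frequency vectors p (reference) and q (query):

    pi[x, y] = p[x] q[y] exp(lambda S[x, y]),   sum(pi) = 1,
    row sums of pi = p,   column sums of pi = q.

``compute_scale`` recovers lambda (and t = 1/lambda, in score units per
nat) by the implicit-frequencies method: with Y = exp(lambda S), the
marginal conditions reduce to Y q = 1 and Y' p = 1, so lambda is the
positive root of  1' Y(lambda)^-1 1 = 1.

Gap probabilities relate to the affine gap costs through

    gap existence cost = -t ln(alpha (1 - beta) / beta)
    gap extension cost = -t ln(beta / omega)

with the background-continue probability omega taken as 1 when
inverting (the model assumes the alignment-start probability
gamma ~ omega^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from splitalign.core import (
    ALPHABET,
    GAP,
    LETTER_INDEX,
    LocalAlignment,
    PairProbModel,
    ScoreScheme,
)

_PROB_FLOOR = 1e-12


class CalibrationError(ValueError):
    """The matrix admits no valid log-odds decomposition, or the solve failed."""


class ModelError(ValueError):
    """Probability parameters violate stochasticity bounds."""


@dataclass
class CalibrationResult:
    """Scale factor and implied frequencies of a substitution matrix."""

    t: float
    lam: float
    p: np.ndarray
    q: np.ndarray
    pi: np.ndarray

    def residuals(self) -> tuple[float, float, float]:
        """Max abs deviation of (sum pi - 1, row sums - p, col sums - q)."""
        return (
            abs(float(self.pi.sum()) - 1.0),
            float(np.abs(self.pi.sum(axis=1) - self.p).max()),
            float(np.abs(self.pi.sum(axis=0) - self.q).max()),
        )


def _marginal_gap(lam: float, S: np.ndarray) -> float:
    """1' Y(lam)^-1 1 - 1 with Y = exp(lam S); NaN-safe for overflow."""
    with np.errstate(over="ignore"):
        Y = np.exp(lam * S)
    if not np.isfinite(Y).all():
        return -1.0
    try:
        q = np.linalg.solve(Y, np.ones(4))
    except np.linalg.LinAlgError:
        return math.nan
    return float(q.sum()) - 1.0


def compute_scale(scheme: ScoreScheme, max_lambda: float = 100.0) -> CalibrationResult:
    """Solve for the scale factor t and implied frequencies of a matrix.

    Scans for the sign change of the marginal condition at the largest
    lambda (the function is not monotone near zero) and polishes with
    Brent's method to machine precision.

    Raises CalibrationError for matrices with no valid decomposition.
    """
    S = scheme.matrix.astype(float)
    grid = np.logspace(-7, math.log10(max_lambda), 800)
    vals = [_marginal_gap(lam, S) for lam in grid]
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if math.isfinite(fa) and math.isfinite(fb) and fa > 0 >= fb:
            bracket = (a, b)
    if bracket is None:
        raise CalibrationError(
            f"no scale factor found for matrix {scheme.name or '<unnamed>'}"
        )
    lam = brentq(_marginal_gap, *bracket, args=(S,), xtol=1e-15, rtol=8.9e-16)
    Y = np.exp(lam * S)
    q = np.linalg.solve(Y, np.ones(4))
    p = np.linalg.solve(Y.T, np.ones(4))
    if (p <= 0).any() or (q <= 0).any():
        raise CalibrationError(
            f"matrix {scheme.name or '<unnamed>'}: implied frequencies "
            "not all positive; no valid decomposition"
        )
    pi = p[:, None] * q[None, :] * Y
    result = CalibrationResult(t=1.0 / lam, lam=lam, p=p, q=q, pi=pi)
    if max(result.residuals()) > 1e-9:
        raise CalibrationError(
            f"calibration of {scheme.name or '<unnamed>'} did not converge"
        )
    return result


def scores_to_probs(
    scheme: ScoreScheme, result: CalibrationResult | None = None
) -> PairProbModel:
    """Invert a scoring scheme into its implied probability parameters.

    beta = exp(-gap_extend / t) (omega taken as 1);
    alpha = beta exp(-gap_open / t) / (1 - beta);  gamma = omega^2.
    """
    if result is None:
        result = compute_scale(scheme)
    t = result.t
    beta = math.exp(-scheme.gap_extend / t)
    if beta >= 1.0:
        raise ModelError("gap extension cost of 0 gives beta = 1")
    alpha = beta * math.exp(-scheme.gap_open / t) / (1.0 - beta)
    if 2.0 * alpha > 1.0:
        raise ModelError(
            "gap costs too small: match-state transitions exceed probability 1"
        )
    return PairProbModel(
        pi=result.pi,
        phi=result.p,
        psi=result.q,
        alpha=alpha,
        beta=beta,
        gamma=1.0,
        omega=1.0,
    )


def probs_to_scores(model: PairProbModel, t: float) -> ScoreScheme:
    """Convert probability parameters into an integer scoring scheme.

    S(x, y) = t ln(pi[x, y] / (phi[x] psi[y]) * gamma / omega^2), rounded;
    gap costs from the inverse of the scores_to_probs relations.  Zero
    probabilities are floored at 1e-12 before the logs.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    pi = np.maximum(model.pi, _PROB_FLOOR)
    phi = np.maximum(model.phi, _PROB_FLOOR)
    psi = np.maximum(model.psi, _PROB_FLOOR)
    ratio = pi / (phi[:, None] * psi[None, :]) * model.gamma / model.omega**2
    matrix = np.rint(t * np.log(ratio)).astype(np.int64)
    alpha = max(model.alpha, _PROB_FLOOR)
    beta = min(max(model.beta, _PROB_FLOOR), 1.0 - _PROB_FLOOR)
    gap_open = int(round(-t * math.log(alpha * (1.0 - beta) / beta)))
    gap_extend = int(round(-t * math.log(beta / model.omega)))
    return ScoreScheme(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend, t=t)


def pair_model_from_pi(pi: np.ndarray, alpha: float, beta: float) -> PairProbModel:
    """Build a model from aligned-pair probabilities alone.

    phi and psi are the row/column marginals of pi over substitution
    columns (no gap-column mass).
    """
    pi = np.asarray(pi, dtype=float)
    return PairProbModel(
        pi=pi,
        phi=pi.sum(axis=1),
        psi=pi.sum(axis=0),
        alpha=alpha,
        beta=beta,
    )


def count_events(
    alignments: list[LocalAlignment],
    max_fit_gap: int = 10,
) -> tuple[PairProbModel, dict]:
    """Count substitutions and gaps over alignments; fit model parameters.

    Substitution counts are normalized to pi; a gap run counts one
    "existence" event plus one extension per additional column.  The gap
    extension probability beta is fitted by least squares to the log
    frequencies of gap lengths 1..max_fit_gap, because longer gaps
    deviate from the geometric model.  alpha is the rate of run openings
    per gap-open opportunity (two per match column).
    """
    if not alignments:
        raise ValueError("empty alignment set")
    pi_counts = np.zeros((4, 4), dtype=np.int64)
    gap_lengths: dict[int, int] = {}
    runs = extensions = match_cols = 0
    for aln in alignments:
        run = 0
        for rchar, qchar in aln.columns():
            if rchar == GAP or qchar == GAP:
                run += 1
                continue
            if run:
                runs += 1
                extensions += run - 1
                gap_lengths[run] = gap_lengths.get(run, 0) + 1
                run = 0
            ri = LETTER_INDEX.get(rchar.lower())
            qi = LETTER_INDEX.get(qchar.lower())
            match_cols += 1
            if ri is not None and qi is not None:
                pi_counts[ri, qi] += 1
        if run:
            runs += 1
            extensions += run - 1
            gap_lengths[run] = gap_lengths.get(run, 0) + 1
    if pi_counts.sum() == 0:
        raise ValueError("no substitution columns with acgt letters")
    pi = pi_counts / pi_counts.sum()
    alpha = runs / (2.0 * match_cols) if match_cols else 0.0
    beta = _fit_gap_extension(gap_lengths, runs, extensions, max_fit_gap)
    model = PairProbModel(
        pi=pi, phi=pi.sum(axis=1), psi=pi.sum(axis=0),
        alpha=min(alpha, 0.5), beta=beta,
    )
    counts = {
        "pi_counts": pi_counts,
        "match_columns": match_cols,
        "gap_runs": runs,
        "gap_extensions": extensions,
        "gap_length_hist": dict(sorted(gap_lengths.items())),
    }
    return model, counts


def _fit_gap_extension(
    gap_lengths: dict[int, int], runs: int, extensions: int, max_fit_gap: int
) -> float:
    # geometric run lengths: freq(L) ~ beta^L, so log freq is linear in L
    pts = [(L, n) for L, n in gap_lengths.items() if 1 <= L <= max_fit_gap and n > 0]
    if len(pts) >= 2:
        L = np.array([p[0] for p in pts], dtype=float)
        logn = np.log(np.array([p[1] for p in pts], dtype=float))
        slope = np.polyfit(L, logn, 1)[0]
        return float(np.clip(math.exp(slope), 0.0, 1.0 - 1e-9))
    if runs == 0:
        return 0.0
    return extensions / (extensions + runs)  # geometric MLE fallback


def window_identity(
    alignments: list[LocalAlignment], window: int = 200
) -> np.ndarray:
    """Per-window substitution fractions, gap columns deleted first.

    Windows are non-overlapping within each alignment; a final short
    window is dropped.  Columns with non-acgt letters are excluded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rates = []
    for aln in alignments:
        subs = [
            rchar.lower() != qchar.lower()
            for rchar, qchar in aln.columns()
            if rchar.lower() in LETTER_INDEX and qchar.lower() in LETTER_INDEX
        ]
        for k in range(0, len(subs) - window + 1, window):
            rates.append(sum(subs[k : k + window]) / window)
    return np.asarray(rates, dtype=float)


def segment_set(
    letter_scores, f: float
) -> tuple[list[tuple[int, int]], float]:
    """Maximal-scoring set of disjoint segments under sum(score - f).

    1-D analog of the split-alignment recurrence:
        V[j+1] = max(V[j], W[j] - f) + s[j]
        W[j+1] = max(W[j], V[j+1])
    Ties prefer continuing the current segment, so a dip of exactly -f
    does not split.  Returns half-open segments and the total.
    """
    if f < 0:
        raise ValueError("f must be >= 0")
    s = list(map(float, letter_scores))
    n = len(s)
    NEG = -math.inf
    V = [NEG] * (n + 1)
    W = [0.0] * (n + 1)
    cont = [False] * (n + 1)  # V[j] came from V[j-1] (not a restart)
    wfrom_v = [False] * (n + 1)  # W[j] came from V[j] (not carried)
    for j in range(n):
        restart = W[j] - f
        base = V[j] if V[j] >= restart else restart
        cont[j + 1] = V[j] >= restart
        V[j + 1] = base + s[j]
        if V[j + 1] > W[j]:
            W[j + 1] = V[j + 1]
            wfrom_v[j + 1] = True
        else:
            W[j + 1] = W[j]
    segments = []
    j = n
    while j > 0:
        if not wfrom_v[j]:
            j -= 1
            continue
        end = j
        while cont[j]:
            j -= 1
        segments.append((j - 1, end))
        j -= 1
    segments.reverse()
    return segments, W[n]
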