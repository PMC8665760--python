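"""Pairwise local alignment with affine gaps and extreme-value statistics.

This is the similarity primitive behind every search and clustering stage:
Smith-Waterman/Gotoh alignment under a substitution matrix (BLOSUM62 by
default), with E-values from a Karlin-Altschul-style Gumbel null fitted on
shuffled random sequences,

    P(S >= s) ~ 1 - exp(-K * m * n * exp(-lambda * s)),

and pairwise P-values P = 1 - exp(-E).

Internally every alignment is a *profile* alignment: a sequence is turned
into the (L, 21) matrix of substitution-matrix rows of its residues, so the
same code path scores PSSM-vs-sequence alignments in the search stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels
from .alphabet import encode, load_matrix, random_sequence


@dataclass
class AlignParams:
    """Scoring parameters: 21x21 matrix (code space) and affine gap penalties.

    Gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix: np.ndarray = field(default_factory=lambda: load_matrix("BLOSUM62"))
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (21, 21):
            raise ValueError("substitution matrix must be 21x21 over the residue code space")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass
class LocalAlignment:
    """A local alignment: score, half-open coordinates, identity, coverage.

    ``identity`` counts identical residue pairs over all alignment columns
    (gap columns in the denominator). ``coverage`` is the aligned span on the
    shorter sequence divided by that sequence's full length. ``path`` holds
    per-column positions (-1 = gap) on each sequence.
    """

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float
    coverage: float
    n_columns: int = 0
    n_identical: int = 0
    path: tuple[np.ndarray, np.ndarray] | None = None

    def identity_over_shorter(self, len_a: int, len_b: int) -> float:
        """Identical pairs over the shorter sequence length (global-style identity)."""
        return self.n_identical / min(len_a, len_b)


@dataclass
class KAParams:
    """Gumbel parameters of the chance-score distribution (lambda, K)."""

    lam: float
    K: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


def profile_of(codes: np.ndarray, params: AlignParams) -> np.ndarray:
    """Substitution-matrix row profile of an encoded sequence."""
    return np.ascontiguousarray(params.matrix[codes.astype(np.int64)])


def align_profile(
    prof: np.ndarray,
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    params: AlignParams,
    traceback: bool = True,
) -> LocalAlignment:
    """Align a profile (with underlying residues ``a_codes``) to a sequence.

    ``a_codes`` supplies the residues used for identity; for a PSSM this is
    the seed sequence. Pass ``traceback=False`` for score-only (faster).
    """
    if not traceback:
        s = _kernels.local_score(prof, b_codes, params.gap_open, params.gap_extend)
        return LocalAlignment(float(s), 0, 0, 0, 0, 0.0, 0.0)
    score, a0, a1, b0, b1, ai, bi, k = _kernels.local_align(
        prof, b_codes, params.gap_open, params.gap_extend
    )
    ident = 0
    for t in range(k):
        if ai[t] >= 0 and bi[t] >= 0 and a_codes[ai[t]] == b_codes[bi[t]] and a_codes[ai[t]] < 20:
            ident += 1
    identity = ident / k if k else 0.0
    short = min(len(a_codes), len(b_codes))
    span = (a1 - a0) if len(a_codes) <= len(b_codes) else (b1 - b0)
    coverage = span / short if short else 0.0
    return LocalAlignment(
        float(score), int(a0), int(a1), int(b0), int(b1), identity, coverage,
        n_columns=int(k), n_identical=ident, path=(ai, bi),
    )


def sw_align(a: str, b: str, params: AlignParams | None = None, traceback: bool = True) -> LocalAlignment:
    """Optimal local alignment of two residue strings.

    Raises ``ValueError`` on empty input; non-standard residues are mapped to
    a neutral code (score 0 against everything) with a warning.
    """
    params = params or AlignParams()
    a_codes = encode(a)
    b_codes = encode(b)
    return align_profile(profile_of(a_codes, params), a_codes, b_codes, params, traceback=traceback)


def _fit_gumbel(scores: np.ndarray, m: int, n: int) -> KAParams:
    scores = np.asarray(scores, dtype=np.float64)
    if np.ptp(scores) == 0:
        raise ValueError("degenerate score distribution: all scores equal")
    if np.allclose(scores, np.round(scores)):
        # integer score lattice (integer matrix + integer gap costs): continuity
        # correction places each observation at its bin midpoint
        scores = scores + 0.5
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (m * n)
    return KAParams(lam=lam, K=K)


def calibrate_evalue(
    params: AlignParams,
    length: int,
    n_shuffles: int = 500,
    rng_seed: int = 0,
) -> KAParams:
    """Fit lambda/K by aligning ``n_shuffles`` pairs of random background sequences.

    Scores of unrelated sequences follow a Gumbel law; the fit is a direct
    MLE on the observed maxima, with K normalized by the calibration search
    space (length x length). Deterministic under ``rng_seed``.
    """
    if n_shuffles < 200:
        raise ValueError("n_shuffles must be >= 200 for a stable Gumbel fit")
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        a = random_sequence(rng, length)
        b = random_sequence(rng, length)
        scores[i] = _kernels.local_score(
            profile_of(a, params), b, params.gap_open, params.gap_extend
        )
    return _fit_gumbel(scores, length, length)


def calibrate_profile_evalue(
    prof: np.ndarray,
    params: AlignParams,
    length: int,
    n_shuffles: int = 500,
    rng_seed: int = 0,
) -> KAParams:
    """Gumbel calibration for an arbitrary score profile (e.g. a PSSM)."""
    if n_shuffles < 200:
        raise ValueError("n_shuffles must be >= 200 for a stable Gumbel fit")
    rng = np.random.default_rng(rng_seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        b = random_sequence(rng, length)
        scores[i] = _kernels.local_score(prof, b, params.gap_open, params.gap_extend)
    return _fit_gumbel(scores, prof.shape[0], length)


def alignment_significance(
    score: float,
    len_a: int,
    len_b: int,
    ka: KAParams,
    db_residues: int | None = None,
) -> tuple[float, float]:
    """(E-value, P-value) for a local alignment score.

    E = K * m * n' * exp(-lambda * s) with n' the database residue count
    (pairwise mode: n' = len_b); P = 1 - exp(-E).
    """
    nprime = len_b if db_residues is None else db_residues
    log_e = math.log(ka.K) + math.log(len_a) + math.log(nprime) - ka.lam * score
    e = math.exp(min(log_e, 700.0))
    p = -math.expm1(-e)
    return e, p


def log10_evalue(score: float, len_a: int, len_b: int, ka: KAParams, db_residues: int | None = None) -> float:
    """log10 of the E-value, safe against underflow (used for map weights)."""
    nprime = len_b if db_residues is None else db_residues
    return (math.log(ka.K) + math.log(len_a) + math.log(nprime) - ka.lam * score) / math.log(10.0)
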