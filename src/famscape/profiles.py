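"""Per-family alignments, consensus/representative selection, and pairwise
profile-profile comparison.

Families are summarized as column log-odds profiles built from a progressive
multiple alignment (average-linkage guide tree on pairwise identity). Two
family profiles are compared with a local column-to-column dynamic program
whose match score is the symmetrized dot product of one profile's log-odds
with the other's residue probabilities; significance comes from a Gumbel fit
to scores of column-shuffled profile pairs. Results are reported as negative
E-value exponents (-log10 E, floored at 0), the conventional heatmap scale
for profile-profile similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import _kernels
from .align import AlignParams, sw_align
from .alphabet import BACKGROUND, RESIDUES, encode
from .records import SequenceRecord


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class FamilyProfile:
    family_id: str
    msa: MSA
    column_logodds: np.ndarray  # (n_retained, 20), half-bit log-odds
    column_probs: np.ndarray  # (n_retained, 20)
    consensus: str
    representative_id: str

    def __post_init__(self) -> None:
        if len(self.consensus) != self.column_logodds.shape[0]:
            raise ValueError("consensus length must equal retained column count")


@dataclass
class NullConfig:
    n_shuffles: int = 200
    rng_seed: int = 0


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies of gapped rows, gaps contributing zero."""
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, 20))
    for row in rows:
        for i, ch in enumerate(row):
            k = RESIDUES.find(ch)
            if k >= 0:
                freqs[i, k] += 1.0
    return freqs / len(rows)


def _merge(rows_a: list[str], rows_b: list[str], params: AlignParams) -> list[str]:
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    m20 = params.matrix[:20, :20]
    S = fa @ m20 @ fb.T
    _, ai, bi, k = _kernels.global_align_from_matrix(S, params.gap_open, params.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for t in range(k):
        ca = [r[ai[t]] for r in rows_a] if ai[t] >= 0 else ["-"] * len(rows_a)
        cb = [r[bi[t]] for r in rows_b] if bi[t] >= 0 else ["-"] * len(rows_b)
        for x in range(len(rows_a)):
            out_a[x] += ca[x]
        for x in range(len(rows_b)):
            out_b[x] += cb[x]
    return out_a + out_b


def progressive_msa(records: list[SequenceRecord], params: AlignParams | None = None) -> MSA:
    """Progressive alignment along an average-linkage guide tree.

    Pairwise distances are 1 - local-alignment identity; profile-profile
    steps use the global affine DP on expected substitution scores.
    Deterministic for a fixed input order.
    """
    if not records:
        raise ValueError("progressive_msa requires at least one record")
    params = params or AlignParams()
    if len(records) == 1:
        return MSA(ids=[records[0].id], rows=[records[0].seq])
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = sw_align(records[i].seq, records[j].seq, params).identity
            dist[i, j] = dist[j, i] = 1.0 - ident
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    groups: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [records[i].seq]) for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(linkage):
        a_ids, a_rows = groups.pop(int(left))
        b_ids, b_rows = groups.pop(int(right))
        merged = _merge(a_rows, b_rows, params)
        groups[n + step] = (a_ids + b_ids, merged[: len(a_rows)] + merged[len(a_rows):])
    ids, rows = groups.popitem()[1]
    return MSA(ids=ids, rows=rows)


def consensus_and_representative(
    msa: MSA, params: AlignParams | None = None, max_gap_fraction: float = 0.5
) -> tuple[str, str]:
    """Column-majority consensus over columns with < 50% gaps; the
    representative is the member with the highest local-alignment score to
    the consensus (ties by id)."""
    params = params or AlignParams()
    cols = retained_columns(msa, max_gap_fraction)
    consensus = []
    for i in cols:
        counts: dict[str, int] = {}
        for row in msa.rows:
            if row[i] != "-":
                counts[row[i]] = counts.get(row[i], 0) + 1
        consensus.append(max(sorted(counts, key=RESIDUES.index), key=lambda r: counts[r]))
    cons = "".join(consensus)
    best_id = None
    best_score = -1.0
    for rid, row in sorted(zip(msa.ids, msa.rows)):
        score = sw_align(cons, row.replace("-", ""), params, traceback=False).score
        if score > best_score:
            best_score = score
            best_id = rid
    return cons, best_id


def retained_columns(msa: MSA, max_gap_fraction: float = 0.5) -> list[int]:
    n = len(msa.rows)
    return [
        i
        for i in range(msa.n_columns)
        if sum(row[i] == "-" for row in msa.rows) / n < max_gap_fraction
    ]


def family_profile(
    family_id: str,
    records: list[SequenceRecord],
    params: AlignParams | None = None,
    pseudocount_weight: float = 20.0,
) -> FamilyProfile:
    """Build a family's MSA, log-odds columns, consensus and representative."""
    params = params or AlignParams()
    msa = progressive_msa(records, params)
    cols = retained_columns(msa)
    counts = np.zeros((len(cols), 20))
    for row in msa.rows:
        for t, i in enumerate(cols):
            k = RESIDUES.find(row[i])
            if k >= 0:
                counts[t, k] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount_weight * BACKGROUND) / (totals + pseudocount_weight)
    logodds = 2.0 * np.log2(probs / BACKGROUND)
    consensus, representative = consensus_and_representative(msa, params)
    return FamilyProfile(
        family_id=family_id,
        msa=msa,
        column_logodds=logodds,
        column_probs=probs,
        consensus=consensus,
        representative_id=representative,
    )


def _pair_score_matrix(a: FamilyProfile, b: FamilyProfile) -> np.ndarray:
    return 0.5 * (a.column_logodds @ b.column_probs.T + (b.column_logodds @ a.column_probs.T).T)


@dataclass
class PairSignificance:
    score: float
    e_value: float
    log10_e: float


def profile_pair_significance(
    a: FamilyProfile, b: FamilyProfile, null: NullConfig | None = None,
    params: AlignParams | None = None,
) -> PairSignificance:
    """Local profile-profile alignment score with a column-shuffle null.

    Shuffling the columns of both profiles permutes the rows/columns of the
    pair-score matrix, so the null is sampled without recomputing scores.
    The E-value follows the fitted Gumbel: E = exp(-lambda*(s - mu)).
    Symmetric in (a, b) by construction.
    """
    null = null or NullConfig()
    params = params or AlignParams()
    if b.family_id < a.family_id:  # canonical orientation => exact symmetry
        a, b = b, a
    S = _pair_score_matrix(a, b)
    obs = _kernels.local_score_from_matrix(S, params.gap_open, params.gap_extend)
    rng = np.random.default_rng([null.rng_seed, S.shape[0], S.shape[1]])
    scores = np.empty(null.n_shuffles)
    for t in range(null.n_shuffles):
        perm = S[rng.permutation(S.shape[0])][:, rng.permutation(S.shape[1])]
        scores[t] = _kernels.local_score_from_matrix(
            np.ascontiguousarray(perm), params.gap_open, params.gap_extend
        )
    if np.ptp(scores) == 0:
        raise ValueError("degenerate null score distribution")
    from scipy import stats

    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    log_e = -lam * (obs - loc)
    e = math.exp(min(log_e, 700.0))
    return PairSignificance(score=float(obs), e_value=e, log10_e=log_e / math.log(10.0))


def profile_profile_evalue(
    a: FamilyProfile, b: FamilyProfile, null: NullConfig | None = None,
    params: AlignParams | None = None,
) -> float:
    return profile_pair_significance(a, b, null, params).e_value


@dataclass
class HeatmapMatrix:
    families: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.families), len(self.families)):
            raise ValueError("heatmap must be square over the family labels")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\t" + "\t".join(self.families) + "\n")
            for name, row in zip(self.families, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.2f}" for v in row) + "\n")


def heatmap_matrix(
    profiles: list[FamilyProfile], null: NullConfig | None = None,
    params: AlignParams | None = None,
) -> HeatmapMatrix:
    """Symmetric matrix of negative E-value exponents, floored at 0."""
    if len(profiles) < 2:
        raise ValueError("heatmap requires at least 2 profiles")
    n = len(profiles)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sig = profile_pair_significance(profiles[i], profiles[j], null, params)
            values[i, j] = values[j, i] = max(0.0, -sig.log10_e)
    return HeatmapMatrix(families=[p.family_id for p in profiles], values=values)
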