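"""Seeded, profile-iterated database search with an active-site motif screen.

A search starts from a single seed sequence (round 0 scores with the seed's
substitution-matrix rows, i.e. plain local alignment), accepts database hits
at the E-value cutoff that also conserve the seed's active-site residues,
rebuilds a position-specific scoring model (PSSM) from the accepted hits,
and repeats until the accepted set stops growing. The motif screen stands in
for manual inspection of hit alignments: a hit passes if the residues
aligned to the seed's catalytic positions match, with a tolerance of one
mismatch by default (the nucleophile position commonly alternates Thr/Ser).

E-values for each profile are recalibrated against the profile itself on
shuffled background sequences, because log-odds profile scores are not on
the substitution-matrix scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .align import (
    AlignParams,
    KAParams,
    LocalAlignment,
    align_profile,
    alignment_significance,
    calibrate_profile_evalue,
    profile_of,
)
from .alphabet import BACKGROUND, encode
from .config import PipelineConfig
from .records import SequenceRecord


@dataclass
class PSSM:
    """Per-column log-odds profile in the seed coordinate frame.

    Scores are half-bit log-odds (2*log2(freq/background)), the scale of the
    BLOSUM matrices, so the substitution gap penalties remain applicable.
    With zero hits the matrix reduces exactly to the substitution-matrix rows
    of the seed sequence.
    """

    matrix: np.ndarray
    seed: SequenceRecord
    pseudocount_weight: float
    n_sequences: int = 1

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.seed.seq), 21):
            raise ValueError("PSSM column count must equal the seed length")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PSSM entries must be finite")


@dataclass
class Hit:
    record_id: str
    e_value: float
    alignment: LocalAlignment


@dataclass
class SearchRound:
    round_index: int
    hits: list[Hit]
    accepted: list[str] = field(default_factory=list)


def build_pssm(
    seed: SequenceRecord,
    hit_alignments: list[tuple[SequenceRecord, LocalAlignment]],
    pseudocount_weight: float = 20.0,
    params: AlignParams | None = None,
) -> PSSM:
    """Column frequencies from seed + aligned hit residues, with
    background-proportional pseudocounts of total weight beta, as half-bit
    log-odds. Alignments must be in the seed coordinate frame."""
    params = params or AlignParams()
    seed_codes = encode(seed.seq)
    L = len(seed_codes)
    if not hit_alignments:
        return PSSM(profile_of(seed_codes, params), seed, pseudocount_weight, 1)

    counts = np.zeros((L, 20))
    for i, c in enumerate(seed_codes):
        if c < 20:
            counts[i, c] += 1.0
    for rec, aln in hit_alignments:
        if aln.path is None:
            raise ValueError(f"hit {rec.id}: alignment has no traceback path")
        ai, bi = aln.path
        if len(ai) and ai.max() >= L:
            raise ValueError(f"hit {rec.id}: alignment not in the seed coordinate frame")
        codes = encode(rec.seq, warn_unknown=False)
        for t in range(len(ai)):
            if ai[t] >= 0 and bi[t] >= 0 and codes[bi[t]] < 20:
                counts[ai[t], codes[bi[t]]] += 1.0

    beta = pseudocount_weight
    totals = counts.sum(axis=1, keepdims=True)
    freq = (counts + beta * BACKGROUND) / (totals + beta)
    matrix = np.zeros((L, 21))
    matrix[:, :20] = 2.0 * np.log2(freq / BACKGROUND)
    return PSSM(matrix, seed, pseudocount_weight, 1 + len(hit_alignments))


def motif_screen(
    alignment: LocalAlignment,
    hit_seq: str,
    seed_motif: list[tuple[int, str]],
    max_mismatches: int = 1,
) -> bool:
    """Check conservation of the seed's active-site residues in a hit.

    A motif position not covered by the alignment, aligned to a gap, or
    aligned to a different residue counts as a mismatch; the hit passes if
    mismatches <= ``max_mismatches``.
    """
    if alignment.path is None:
        raise ValueError("motif screen requires an alignment traceback path")
    ai, bi = alignment.path
    aligned_to = {int(ai[t]): int(bi[t]) for t in range(len(ai)) if ai[t] >= 0}
    mismatches = 0
    for pos, res in seed_motif:
        j = aligned_to.get(pos, -1)
        if j < 0 or hit_seq[j] != res:
            mismatches += 1
    return mismatches <= max_mismatches


def seed_motif_of(seed: SequenceRecord) -> list[tuple[int, str]]:
    return [(p, seed.seq[p]) for p in seed.motif_positions]


def calibration_seed(base_seed: int, tag: str, round_index: int) -> int:
    """Stable per-profile calibration seed derived from a string tag."""
    return (base_seed * 1000003 + zlib.crc32(tag.encode()) + round_index) % (2**31 - 1)


def profile_search(
    pssm: PSSM,
    db: list[SequenceRecord],
    e_cutoff: float,
    ka: KAParams,
    params: AlignParams | None = None,
    seed_motif: list[tuple[int, str]] | None = None,
    max_mismatches: int = 1,
    round_index: int = 0,
) -> SearchRound:
    """Score every database record against the profile; hits sorted by E-value.

    ``accepted`` holds record ids with E <= cutoff that pass the motif
    screen (when a motif is supplied). The E-value search space is the total
    residue count of the database.
    """
    params = params or AlignParams()
    seed_codes = encode(pssm.seed.seq, warn_unknown=False)
    db_residues = sum(len(r.seq) for r in db)
    hits: list[Hit] = []
    for rec in db:
        aln = align_profile(pssm.matrix, seed_codes, encode(rec.seq, warn_unknown=False), params)
        e, _ = alignment_significance(aln.score, pssm.matrix.shape[0], len(rec.seq), ka, db_residues)
        hits.append(Hit(rec.id, e, aln))
    hits.sort(key=lambda h: (h.e_value, h.record_id))
    accepted = []
    for h in hits:
        if h.e_value > e_cutoff:
            continue
        if seed_motif is not None:
            rec = next(r for r in db if r.id == h.record_id)
            if not motif_screen(h.alignment, rec.seq, seed_motif, max_mismatches):
                continue
        accepted.append(h.record_id)
    return SearchRound(round_index=round_index, hits=hits, accepted=accepted)


@dataclass
class IterativeSearchResult:
    seed_id: str
    accepted: list[str]
    rounds: list[SearchRound]
    converged: bool

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def iterative_search(
    seed: SequenceRecord,
    db: list[SequenceRecord],
    config: PipelineConfig | None = None,
) -> IterativeSearchResult:
    """Iterate profile search to convergence from one seed.

    The accepted set is the union over rounds (monotone non-decreasing);
    iteration stops when it no longer grows or at ``psearch_max_rounds``.
    """
    config = config or PipelineConfig()
    params = AlignParams(gap_open=config.gap_open, gap_extend=config.gap_extend)
    by_id = {r.id: r for r in db}
    motif = seed_motif_of(seed) or None
    lengths = sorted(len(r.seq) for r in db)
    calib_len = max(50, lengths[len(lengths) // 2]) if lengths else len(seed.seq)

    accepted: dict[str, LocalAlignment] = {}
    rounds: list[SearchRound] = []
    converged = False
    for round_index in range(config.psearch_max_rounds):
        if round_index == 0:
            pssm = build_pssm(seed, [], config.pseudocount_weight, params)
        else:
            hit_alns = [
                (by_id[rid], aln) for rid, aln in sorted(accepted.items()) if rid != seed.id
            ]
            pssm = build_pssm(seed, hit_alns, config.pseudocount_weight, params)
        ka = calibrate_profile_evalue(
            pssm.matrix,
            params,
            calib_len,
            n_shuffles=config.calib_shuffles,
            rng_seed=calibration_seed(config.rng_seed, seed.id, round_index),
        )
        rnd = profile_search(
            pssm, db, config.e_cutoff, ka, params,
            seed_motif=motif, max_mismatches=config.motif_max_mismatches,
            round_index=round_index,
        )
        before = set(accepted)
        for h in rnd.hits:
            if h.record_id in rnd.accepted:
                accepted[h.record_id] = h.alignment
        rounds.append(rnd)
        if set(accepted) == before:
            converged = True
            break
    return IterativeSearchResult(
        seed_id=seed.id,
        accepted=sorted(accepted),
        rounds=rounds,
        converged=converged,
    )
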