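"""Profile construction, profile search, motif screen and iterated search."""

import numpy as np
import pytest

from famscape.align import AlignParams, calibrate_profile_evalue, profile_of, sw_align
from famscape.alphabet import BACKGROUND, RESIDUES, decode, encode, random_sequence
from famscape.config import PipelineConfig
from famscape.psearch import (
    build_pssm,
    iterative_search,
    motif_screen,
    profile_search,
    seed_motif_of,
)
from famscape.records import SequenceRecord
from famscape.synth import FamilySpec, evolve_family, make_fold_template


@pytest.fixture(scope="module")
def planted():
    """Small planted family + decoys for search tests."""
    template = make_fold_template(120, [(0, "T"), (16, "D"), (32, "K"), (46, "G")], rng_seed=9)
    family = evolve_family(template, FamilySpec("fam", 15, 0.35, rng_seed=9))
    rng = np.random.default_rng(99)
    decoys = [
        SequenceRecord(f"decoy_{i}", decode(random_sequence(rng, 120)))
        for i in range(25)
    ]
    return family, decoys


class TestBuildPssm:
    def test_zero_hits_reduces_to_matrix_rows(self, params):
        seed = SequenceRecord("s", "TACDEGHIKLMNPQRSTVWY")
        pssm = build_pssm(seed, [], 20.0, params)
        expected = params.matrix[encode(seed.seq).astype(int)]
        assert np.array_equal(pssm.matrix, expected)

    def test_observed_residue_dominates_at_small_pseudocount(self, params):
        seed = SequenceRecord("s", "D" * 60)
        hits = []
        for i in range(100):
            rec = SequenceRecord(f"h{i}", "D" * 60)
            aln = sw_align(seed.seq, rec.seq, params)
            hits.append((rec, aln))
        pssm = build_pssm(seed, hits, pseudocount_weight=1e-6, params=params)
        col = pssm.matrix[30]
        d = RESIDUES.index("D")
        assert col[d] == max(col[:20])
        assert col[RESIDUES.index("W")] < 0  # unobserved rare residue penalized

    def test_logodds_shrink_toward_zero_as_beta_grows(self, params):
        seed = SequenceRecord("s", "TDKG" * 15)
        rec = SequenceRecord("h", "TDKG" * 15)
        hits = [(rec, sw_align(seed.seq, rec.seq, params))]
        norms = [
            np.abs(build_pssm(seed, hits, beta, params).matrix[:, :20]).mean()
            for beta in (2.0, 20.0, 200.0, 2000.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_alien_coordinate_frame_rejected(self, params):
        seed = SequenceRecord("s", "TDKG")
        long_seed = SequenceRecord("s2", "TDKG" * 20)
        rec = SequenceRecord("h", "TDKG" * 20)
        aln = sw_align(long_seed.seq, rec.seq, params)
        with pytest.raises(ValueError, match="coordinate frame"):
            build_pssm(seed, [(rec, aln)], 20.0, params)


class TestMotifScreen:
    def test_seed_vs_itself_passes_with_zero_mismatches(self, params, planted):
        family, _ = planted
        seed = family[0]
        aln = sw_align(seed.seq, seed.seq, params)
        assert motif_screen(aln, seed.seq, seed_motif_of(seed), max_mismatches=0)

    def test_ser_for_thr_substitution_tolerated(self, params, planted):
        family, _ = planted
        seed = family[0]
        t_pos = seed.motif_positions[0]
        hit_seq = seed.seq[:t_pos] + "S" + seed.seq[t_pos + 1 :]
        aln = sw_align(seed.seq, hit_seq, params)
        assert motif_screen(aln, hit_seq, seed_motif_of(seed), max_mismatches=1)
        assert not motif_screen(aln, hit_seq, seed_motif_of(seed), max_mismatches=0)

    def test_three_mismatches_fail(self, params, planted):
        family, _ = planted
        seed = family[0]
        mutated = list(seed.seq)
        for p in seed.motif_positions[:3]:
            mutated[p] = "A" if seed.seq[p] != "A" else "V"
        hit_seq = "".join(mutated)
        aln = sw_align(seed.seq, hit_seq, params)
        assert not motif_screen(aln, hit_seq, seed_motif_of(seed), max_mismatches=1)


class TestProfileSearch:
    def test_seed_is_top_hit_in_its_own_database(self, params, planted):
        family, decoys = planted
        seed = family[0]
        db = family + decoys
        pssm = build_pssm(seed, [], 20.0, params)
        ka = calibrate_profile_evalue(pssm.matrix, params, 120, 300, rng_seed=1)
        rnd = profile_search(pssm, db, e_cutoff=1.0, ka=ka, params=params)
        assert rnd.hits[0].record_id == seed.id
        evs = [h.e_value for h in rnd.hits]
        assert evs == sorted(evs)
        assert set(rnd.accepted) <= {h.record_id for h in rnd.hits}

    def test_family_members_hit_at_default_cutoff(self, params, planted):
        family, decoys = planted
        seed = family[0]
        db = family + decoys
        pssm = build_pssm(seed, [], 20.0, params)
        ka = calibrate_profile_evalue(pssm.matrix, params, 120, 300, rng_seed=1)
        rnd = profile_search(pssm, db, 1.0, ka, params, seed_motif=seed_motif_of(seed))
        assert set(r.id for r in family) <= set(rnd.accepted)


class TestIterativeSearch:
    def test_db_of_only_the_seed_converges_immediately(self, planted):
        family, _ = planted
        seed = family[0]
        res = iterative_search(seed, [seed], PipelineConfig(rng_seed=3))
        assert res.converged
        assert res.accepted == [seed.id]

    def test_planted_family_recall(self, planted):
        family, decoys = planted
        res = iterative_search(family[0], family + decoys, PipelineConfig(rng_seed=3))
        recall = len(set(res.accepted) & {r.id for r in family}) / len(family)
        assert recall >= 0.9
        assert res.converged

    def test_accepted_set_monotone_across_rounds(self, planted):
        family, decoys = planted
        res = iterative_search(family[0], family + decoys, PipelineConfig(rng_seed=3))
        seen: set = set()
        for rnd in res.rounds:
            seen |= set(rnd.accepted)
            # nothing once accepted ever leaves the final set
            assert seen <= set(res.accepted)
        assert seen == set(res.accepted)
        assert len(res.rounds) <= PipelineConfig().psearch_max_rounds

    def test_decoy_only_database_accepts_nothing_foreign(self, planted):
        family, decoys = planted
        seed = family[0]
        res = iterative_search(seed, decoys, PipelineConfig(rng_seed=3))
        assert res.accepted == []

    def test_seed_only_pssm_reproduces_pairwise_scores(self, params, planted):
        family, decoys = planted
        seed = family[0]
        pssm = build_pssm(seed, [], 20.0, params)
        from famscape.align import align_profile

        for rec in (family[3], decoys[0]):
            via_profile = align_profile(
                pssm.matrix, encode(seed.seq), encode(rec.seq), params, traceback=False
            ).score
            assert via_profile == sw_align(seed.seq, rec.seq, params).score
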