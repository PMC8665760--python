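"""Family MSAs, consensus/representative and profile-profile comparison."""

import numpy as np
import pytest

from famscape.profiles import (
    MSA,
    NullConfig,
    consensus_and_representative,
    family_profile,
    heatmap_matrix,
    profile_pair_significance,
    progressive_msa,
)
from famscape.align import sw_align
from famscape.records import SequenceRecord
from famscape.alphabet import decode, random_sequence
from famscape.synth import FamilySpec, evolve_family, make_fold_template

MOTIF = [(0, "T"), (16, "D"), (32, "K"), (46, "G")]


@pytest.fixture(scope="module")
def family():
    template = make_fold_template(100, MOTIF, rng_seed=21)
    return evolve_family(template, FamilySpec("fam", 10, 0.4, rng_seed=21))


@pytest.fixture(scope="module")
def unrelated_family():
    template = make_fold_template(100, MOTIF, rng_seed=77)
    return evolve_family(template, FamilySpec("other", 10, 0.4, rng_seed=77))


class TestProgressiveMsa:
    def test_single_record(self):
        msa = progressive_msa([SequenceRecord("a", "ACDEFGHIK" * 8)])
        assert msa.rows == ["ACDEFGHIK" * 8]

    def test_two_identical_records_align_gap_free(self):
        seq = decode(random_sequence(np.random.default_rng(3), 80))
        msa = progressive_msa([SequenceRecord("a", seq), SequenceRecord("b", seq)])
        assert msa.rows == [seq, seq]

    def test_motif_residues_recovered_in_shared_columns(self, family):
        msa = progressive_msa(family)
        by_id = {rid: row for rid, row in zip(msa.ids, msa.rows)}
        rec_by_id = {r.id: r for r in family}
        # map each member's motif positions to MSA columns
        recovered = 0
        total = 0
        columns_per_motif = {}
        for rid, row in by_id.items():
            rec = rec_by_id[rid]
            res_cols = [i for i, ch in enumerate(row) if ch != "-"]
            for k, p in enumerate(rec.motif_positions):
                columns_per_motif.setdefault(k, []).append(res_cols[p])
        for k, cols in columns_per_motif.items():
            total += len(cols)
            most_common = max(set(cols), key=cols.count)
            recovered += cols.count(most_common)
        assert recovered / total >= 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([])


class TestConsensus:
    def test_identical_msa_consensus_is_the_sequence(self):
        msa = MSA(ids=["b", "a"], rows=["TDKG" * 10, "TDKG" * 10])
        cons, rep = consensus_and_representative(msa)
        assert cons == "TDKG" * 10
        assert rep == "a"  # lexicographic tie-break

    def test_column_majority(self):
        msa = MSA(ids=["x", "y", "z"], rows=["DAAAAAAAAAAAAA", "DAAAAAAAAAAAAA", "EAAAAAAAAAAAAA"])
        cons, _ = consensus_and_representative(msa)
        assert cons[0] == "D"

    def test_gappy_columns_dropped(self):
        msa = MSA(ids=["x", "y"], rows=["A-CDEFGHIKLMNP", "A-CDEFGHIKLMNP"])
        cons, _ = consensus_and_representative(msa)
        assert cons == "ACDEFGHIKLMNP"

    def test_representative_is_most_consensus_like(self, family, params):
        profile = family_profile("fam", family, params)
        scores = {
            r.id: sw_align(profile.consensus, r.seq, params, traceback=False).score
            for r in family
        }
        assert scores[profile.representative_id] == max(scores.values())


class TestProfileComparison:
    def test_self_comparison_beats_unrelated(self, family, unrelated_family):
        pa = family_profile("fam", family)
        pb = family_profile("other", unrelated_family)
        null = NullConfig(n_shuffles=200, rng_seed=5)
        self_sig = profile_pair_significance(pa, pa, null)
        cross_sig = profile_pair_significance(pa, pb, null)
        assert self_sig.log10_e < cross_sig.log10_e

    def test_symmetric(self, family, unrelated_family):
        pa = family_profile("fam", family)
        pb = family_profile("other", unrelated_family)
        null = NullConfig(n_shuffles=200, rng_seed=5)
        assert profile_pair_significance(pa, pb, null).e_value == pytest.approx(
            profile_pair_significance(pb, pa, null).e_value
        )

    def test_null_pvalues_uniform(self, family, unrelated_family):
        # P-values of fresh column-shuffled pairs against the fitted null
        pa = family_profile("fam", family)
        pb = family_profile("other", unrelated_family)
        from famscape.profiles import _pair_score_matrix
        from famscape import _kernels
        from scipy import stats

        S = _pair_score_matrix(pa, pb)
        rng = np.random.default_rng(6)

        def null_score():
            perm = S[rng.permutation(S.shape[0])][:, rng.permutation(S.shape[1])]
            return _kernels.local_score_from_matrix(np.ascontiguousarray(perm), 11.0, 1.0)

        fit_scores = np.array([null_score() for _ in range(300)])
        loc, scale = stats.gumbel_r.fit(fit_scores)
        fresh = np.array([null_score() for _ in range(500)])
        pvals = 1.0 - np.exp(-np.exp(-(fresh - loc) / scale))
        frac = (pvals <= 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestHeatmap:
    def test_two_copies_off_diagonal_equals_self(self, family):
        pa = family_profile("fam", family)
        pb = family_profile("fam2", family)
        hm = heatmap_matrix([pa, pb], NullConfig(n_shuffles=200, rng_seed=5))
        assert hm.values[0, 1] == pytest.approx(hm.values[0, 0], rel=0.05)

    def test_symmetric_and_floored(self, family, unrelated_family):
        pa = family_profile("fam", family)
        pb = family_profile("other", unrelated_family)
        hm = heatmap_matrix([pa, pb], NullConfig(n_shuffles=200, rng_seed=5))
        assert np.allclose(hm.values, hm.values.T, atol=1e-9)
        assert (hm.values >= 0).all()

    def test_tsv_export(self, family, unrelated_family, tmp_path):
        pa = family_profile("fam", family)
        pb = family_profile("other", unrelated_family)
        hm = heatmap_matrix([pa, pb], NullConfig(n_shuffles=200, rng_seed=5))
        out = tmp_path / "hm.tsv"
        hm.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "family\tfam\tother"
        assert len(lines) == 3
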