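"""Sequence descriptors: ORFs, GC, length model, composition, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptrace.features import (
    DisorderScale,
    GeometricLengthModel,
    aa_frequencies,
    build_feature_table,
    enumerate_short_peptides,
    expected_length_distribution,
    extract_random_part,
    find_first_orf,
    gc_content,
    group_aa_difference,
    ingest_external_scores,
    mean_disorder_propensity,
    summarize_groups,
    translate,
)
from peptrace.simulate import (
    PositionProbMatrix,
    generate_clone_library,
    insert_matrix,
)


class TestFindFirstOrf:
    def test_stop_terminates_orf(self):
        orf = find_first_orf("ATGAAGCTTAGCTAA")
        assert orf.sequence == "ATGAAGCTTAGC"
        assert (orf.start, orf.end) == (0, 12)

    def test_short_orf_below_minsize_skipped(self):
        assert find_first_orf("CCCATGAA") is None

    def test_leftmost_of_two_orfs_returned(self):
        seq = "ATGAAACCCGGGTAG" + "ATGTTTCCCAAATAA"
        orf = find_first_orf(seq)
        assert orf.sequence == "ATGAAACCCGGG"

    def test_no_stop_runs_to_last_complete_codon(self):
        orf = find_first_orf("ATGAAACCCGGGTT")
        assert orf.sequence == "ATGAAACCCGGG"

    def test_minsize_counts_start_codon(self):
        # 12-nt ORF (ATG + 3 codons) meets the default minimum exactly
        assert find_first_orf("ATGAAACCCGGGTAA") is not None
        assert find_first_orf("ATGAAACCCTAA", min_orf_nt=12) is None


class TestTranslate:
    def test_vector_flank_gives_mkls(self, layout):
        assert translate(layout.flank5) == "MKLS"

    def test_single_codon(self):
        assert translate("ATG") == "M"

    def test_full_construct_gives_65_residues(self, rng, layout):
        pool = generate_clone_library(5, layout, rng=rng)
        for clone in pool.clones:
            orf = find_first_orf(clone.sequence)
            pep = translate(orf.sequence)
            insert = extract_random_part(clone.sequence[:-3])
            first_stop = next(
                (j for j in range(0, 150, 3)
                 if insert[j:j + 3] in {"TAA", "TAG", "TGA"}), None
            )
            if first_stop is None:
                assert len(pep) == 65
            else:
                assert len(pep) == 4 + first_stop // 3

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGTAAAAA")


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("ACGT", 50.0), ("AATT", 0.0)]
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_equimolar_library_mean_50(self, rng):
        probs = PositionProbMatrix.uniform(150)
        arr = insert_matrix(100_000, probs, rng)
        gc = ((arr == ord("G")) | (arr == ord("C"))).mean(axis=1) * 100
        assert abs(gc.mean() - 50.0) < 0.2


class TestExtractRandomPart:
    def test_195_gives_150(self, rng, layout):
        pool = generate_clone_library(1, layout, rng=rng)
        clean = pool.sequences[0][:-3]
        assert len(extract_random_part(clean)) == 150

    def test_empty_vector_has_no_random_part(self, layout):
        clean = layout.assemble_empty_vector()[:-3]
        with pytest.raises(ValueError):
            extract_random_part(clean)

    def test_round_trip(self, layout):
        x = "ACG" * 50
        assert extract_random_part(layout.assemble(x)[:-3]) == x


class TestGeometricLengthModel:
    def test_p_quarter_first_term(self):
        m = GeometricLengthModel(p=0.25)
        assert m.pmf().loc[4] == pytest.approx(0.25)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_pmf_sums_to_one_for_any_p(self, p):
        m = GeometricLengthModel(p=p)
        assert m.pmf().sum() == pytest.approx(1.0, abs=1e-12)

    def test_survival_term_equimolar(self):
        m = GeometricLengthModel(p=3 / 64)
        assert m.pmf().loc[65] == pytest.approx((61 / 64) ** 50, abs=1e-12)
        assert m.pmf().loc[65] == pytest.approx(0.0908, abs=5e-4)

    def test_expected_counts_scale_with_n(self):
        m = GeometricLengthModel(p=0.1, n_sequences=1000)
        tab = expected_length_distribution(m)
        assert tab["expected_count"].sum() == pytest.approx(1000.0)

    def test_monte_carlo_insert_lengths_match_model(self, rng, layout):
        """Simulated equimolar library fits the geometric model (chi2)."""
        from scipy import stats as sps

        probs = PositionProbMatrix.uniform(150)
        pool_arr = insert_matrix(100_000, probs, rng)
        stops = {b"TAA", b"TAG", b"TGA"}
        buf = pool_arr.tobytes()
        lengths = []
        for i in range(0, len(buf), 150):
            ins = buf[i : i + 150]
            ln = 65
            for j in range(0, 150, 3):
                if ins[j : j + 3] in stops:
                    ln = 4 + j // 3
                    break
            lengths.append(ln)
        observed = pd.Series(lengths).value_counts()
        model = GeometricLengthModel(p=3 / 64)
        pmf = model.pmf()
        support = [k for k in range(4, 54)]
        obs = np.array([observed.get(k, 0) for k in support])
        probs_cond = np.array([pmf.loc[k] for k in support])
        probs_cond = probs_cond / probs_cond.sum()
        stat, p = sps.chisquare(obs, obs.sum() * probs_cond)
        assert p > 0.01


class TestEnumerateShortPeptides:
    def test_zero_random_codons_only_mkls(self):
        n, peps = enumerate_short_peptides(random_codons=0)
        assert n == 1 and peps == {"MKLS"}

    def test_one_random_codon_20_peptides(self):
        n, peps = enumerate_short_peptides(random_codons=1)
        assert n == 20
        assert all(p.startswith("MKLS") and len(p) == 5 for p in peps)

    def test_two_random_codons_400_peptides(self):
        n, _ = enumerate_short_peptides(random_codons=2)
        assert n == 400

    def test_matches_independent_enumeration(self):
        """Cross-check against translation-table arithmetic: 20**k."""
        from Bio.Data.CodonTable import standard_dna_table

        n_aas = len(set(standard_dna_table.forward_table.values()))
        for k in (0, 1, 2):
            n, _ = enumerate_short_peptides(random_codons=k)
            assert n == n_aas**k


class TestAAFrequencies:
    def test_mkls_pooled_quarter_each(self):
        freqs = aa_frequencies(["MKLS"])
        for aa in "MKLS":
            assert freqs[aa] == pytest.approx(25.0)

    def test_sums_to_100(self, rng):
        peps = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 10))
                for _ in range(20)]
        assert aa_frequencies(peps).sum() == pytest.approx(100.0)

    def test_pooled_equals_length_weighted_mean_of_per_sequence(self, rng):
        peps = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                   rng.integers(5, 30)))
                for _ in range(15)]
        pooled = aa_frequencies(peps)
        per_seq = aa_frequencies(peps, per_sequence=True)
        weights = np.array([len(p) for p in peps], dtype=float)
        weighted = (per_seq.mul(weights, axis=0).sum() / weights.sum())
        assert np.allclose(pooled, weighted[pooled.index])

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            aa_frequencies(["MKXS"])


class TestDisorderScale:
    def test_covers_20_residues(self):
        scale = DisorderScale.top_idp()
        assert len(scale.values) == 20

    def test_ordering_runs_order_to_disorder(self):
        scale = DisorderScale.top_idp()
        order = scale.ordering
        assert order[0] == "W" and order[-1] == "P"
        assert scale["W"] < 0 < scale["P"]

    def test_single_residue_mean(self):
        scale = DisorderScale.top_idp()
        assert mean_disorder_propensity("S", scale) == scale["S"]

    def test_homopolymer_length_invariant(self):
        scale = DisorderScale.top_idp()
        assert mean_disorder_propensity("AAAA", scale) == pytest.approx(
            mean_disorder_propensity("AAAAAAAA", scale)
        )

    def test_ten_mer_mean_equals_brute_sum(self):
        scale = DisorderScale.top_idp()
        pep = "WFYIMLVNCT"
        expected = sum(scale[a] for a in pep) / 10
        assert mean_disorder_propensity(pep, scale) == pytest.approx(expected)


class TestGroupAADifference:
    def test_identical_groups_zero(self, rng):
        peps = ["MKLSAAA", "MKLSGGG"]
        diff = group_aa_difference(peps, peps)
        assert np.allclose(diff, 0.0)

    def test_serine_enrichment_positive(self):
        base = ["ACDEFG"] * 10
        group = ["ACDEFG"] * 5 + ["SSSSSS"] * 5
        diff = group_aa_difference(group, base)
        assert diff["S"] > 0

    def test_output_ordered_by_scale(self):
        diff = group_aa_difference(["MKLS"], ["MKLS"])
        assert list(diff.index) == DisorderScale.top_idp().ordering


class TestIngestExternalScores:
    def _scores(self, **kw):
        base = {"clone_id": ["clone0001"], "ids": [0.7], "peu": [-4.0]}
        base.update(kw)
        return pd.DataFrame(base)

    def test_peu_boundary_flags_aggregation(self):
        out = ingest_external_scores(
            self._scores(peu=[-5.0]), ["clone0001"]
        )
        assert bool(out["aggregation_prone"].iloc[0])
        out2 = ingest_external_scores(
            self._scores(peu=[-4.9]), ["clone0001"]
        )
        assert not bool(out2["aggregation_prone"].iloc[0])

    def test_ids_boundaries(self):
        out = ingest_external_scores(self._scores(ids=[1.0]), ["clone0001"])
        assert bool(out["high_disorder"].iloc[0])
        with pytest.raises(ValueError):
            ingest_external_scores(self._scores(ids=[1.2]), ["clone0001"])

    def test_unknown_clone_listed(self):
        with pytest.raises(ValueError, match="cloneX"):
            ingest_external_scores(
                self._scores(clone_id=["cloneX"]), ["clone0001"]
            )


class TestFeatureTableAndGroups:
    def _db_frame(self, rng, layout, n=20):
        pool = generate_clone_library(n, layout, include_empty_vector=True, rng=rng)
        return pd.DataFrame(
            {"clone_id": pool.ids,
             "sequence": [s[:-3] for s in pool.sequences]}
        )

    def test_feature_table_lengths_and_gc(self, rng, layout):
        frame = self._db_frame(rng, layout)
        feats = build_feature_table(frame)
        assert (feats["pep_len"] >= 4).all()
        full = feats[feats["pep_len"] == 65]
        assert np.allclose(
            full["gc_read"].dropna(),
            [gc_content(s) for s in
             frame.set_index("clone_id").loc[full.index, "sequence"]],
        )

    def test_all_ns_gives_no_pos_neg_rows(self, rng, layout):
        frame = self._db_frame(rng, layout)
        feats = build_feature_table(frame)
        consensus = pd.Series("NS", index=feats.index)
        out = summarize_groups(feats, consensus)
        assert set(out["lengths"]["consensus"]) == {"NS"}
        assert list(out["aa_difference"].columns) == ["NS"]

    def test_group_frequencies_consistent(self, rng, layout):
        frame = self._db_frame(rng, layout, n=30)
        feats = build_feature_table(frame)
        consensus = pd.Series(
            rng.choice(["POS", "NEG", "NS"], len(feats)), index=feats.index
        )
        out = summarize_groups(feats, consensus)
        assert out["lengths"]["n_clones"].sum() == (
            consensus.isin(["POS", "NEG", "NS"]).sum()
        )

    def test_scores_by_length_present_when_scores_given(self, rng, layout):
        frame = self._db_frame(rng, layout)
        feats = build_feature_table(frame)
        consensus = pd.Series("POS", index=feats.index)
        scores = pd.DataFrame(
            {"clone_id": feats.index,
             "ids": rng.random(len(feats)),
             "peu": -rng.random(len(feats)) * 10}
        )
        ext = ingest_external_scores(scores, feats.index)
        out = summarize_groups(feats, consensus, scores=ext)
        assert "scores_by_length" in out
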