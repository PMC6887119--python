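import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import (
    g4_oracle,
    ggc_oracle,
    mannwhitney_enumeration,
    max_pairs_bruteforce,
)
from ribopath.utr import (
    G2_SPEC,
    G4_SPEC,
    GGC_SPEC,
    MotifSpec,
    feature_pca,
    flag_top,
    gc_content,
    mannwhitney_u,
    motif_enrichment,
    scan_g4,
    scan_ggc_repeats,
    structure_score,
    utr_feature_table,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)
g_rich = st.text(alphabet="ACGTG", min_size=0, max_size=40)  # G twice as likely


class TestGcContent:
    def test_all_gc(self):
        assert gc_content("GCGC") == 100.0

    def test_no_gc(self):
        assert gc_content("ATAT") == 0.0

    def test_hand_count(self):
        assert gc_content("GGCATT") == 50.0

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 100.0

    def test_u_equivalent_to_t(self):
        assert gc_content("GCAU") == gc_content("GCAT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestScanG4:
    def test_minimal_perfect_g4(self):
        hits = scan_g4("GGGAGGGAGGGAGGG")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 15)

    def test_too_few_tracts(self):
        assert scan_g4("GGG") == []

    def test_long_first_loop_breaks_chain(self):
        seq = "GGG" + "A" * 13 + "GGGAGGGAGGG"
        assert scan_g4(seq) == []

    def test_loop_max_12_boundary(self):
        seq = "GGG" + "A" * 12 + "GGGAGGGAGGG"
        assert len(scan_g4(seq)) == 1

    def test_g2_variant(self):
        seq = "GGAGGAGGAGG"
        assert scan_g4(seq, G4_SPEC) == []
        hits = scan_g4(seq, G2_SPEC)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 11)

    def test_u_t_invariance(self):
        seq = "GGGAGGGAGGGAGGG".replace("A", "U")
        assert scan_g4(seq)[0].start == 1

    def test_maximal_tract_extension(self):
        hits = scan_g4("GGGGGAGGGAGGGAGGG")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 17)

    @pytest.mark.parametrize("tract", [2, 3])
    def test_matches_oracle_random(self, rng, tract):
        spec = MotifSpec(kind="g_quadruplex", tract_length=tract)
        letters = np.array(list("ACGT"))
        probs = np.array([0.2, 0.2, 0.4, 0.2])
        for _ in range(300):
            n = int(rng.integers(0, 41))
            seq = "".join(rng.choice(letters, size=n, p=probs))
            got = [(h.start, h.end) for h in scan_g4(seq, spec)]
            assert got == g4_oracle(seq, tract_length=tract), seq


class TestScanGgc:
    def test_four_repeats(self):
        hits = scan_ggc_repeats("GGCGGCGGCGGC")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].n_repeats) == (1, 12, 4)

    def test_mixed_units(self):
        hits = scan_ggc_repeats("GGCGGAGGCGGA")
        assert len(hits) == 1
        assert hits[0].n_repeats == 4

    def test_three_repeats_not_reported(self):
        assert scan_ggc_repeats("GGCGGCGGC") == []

    def test_five_repeats_single_run(self):
        hits = scan_ggc_repeats("GGCGGCGGCGGCGGC")
        assert len(hits) == 1
        assert hits[0].n_repeats == 5

    def test_u_t_invariance_irrelevant_chars(self):
        assert scan_ggc_repeats("ggcggcggcggc")[0].n_repeats == 4

    def test_matches_oracle_random(self, rng):
        letters = np.array(list("ACG"))
        probs = np.array([0.2, 0.3, 0.5])
        for _ in range(400):
            n = int(rng.integers(0, 41))
            seq = "".join(rng.choice(letters, size=n, p=probs))
            got = [(h.start, h.end, h.n_repeats) for h in scan_ggc_repeats(seq)]
            assert got == ggc_oracle(seq), seq


class TestStructureScore:
    def test_no_pairs(self):
        assert structure_score("AAAA") == 0

    def test_gc_helix(self):
        assert structure_score("GGGGAAAACCCC") == 4

    def test_min_loop_enforced(self):
        # hairpin loop of 3 required: GAAAC can pair, GAAC cannot
        assert structure_score("GAAAC") == 1
        assert structure_score("GAAC") == 0

    def test_gu_wobble_counts(self):
        assert structure_score("GAAAT") == 1

    def test_counting_bound(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert structure_score(seq) <= n // 2

    def test_matches_bruteforce(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert structure_score(seq) == max_pairs_bruteforce(seq), seq


class TestFlagTop:
    def test_canonical_top(self):
        assert flag_top("CTTTTCAGGA") is True

    def test_purine_start(self):
        assert flag_top("GTTTTCAGGA") is False

    def test_short_tract(self):
        assert flag_top("CTTAGAAAA") is False

    def test_rna_alphabet(self):
        assert flag_top("CUUUUCAGG") is True

    def test_too_short_sequence(self):
        assert flag_top("CTT") is False


class TestMannWhitney:
    def test_separated_pairs(self):
        u, p = mannwhitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_groups(self):
        u, p = mannwhitney_u([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n_a = int(rng.integers(1, 7))
            n_b = int(rng.integers(1, 7))
            # discrete values force ties
            a = rng.integers(0, 5, size=n_a).astype(float)
            b = rng.integers(0, 5, size=n_b).astype(float)
            u, p = mannwhitney_u(a, b)
            u_ref, p_ref = mannwhitney_enumeration(list(a), list(b))
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_exact_vs_approximate_agree(self, rng):
        diffs = []
        for _ in range(100):
            a = rng.normal(size=8)
            b = rng.normal(0.3, 1.0, size=8)
            _, p_exact = mannwhitney_u(a, b, exact_max_n=16)
            _, p_approx = mannwhitney_u(a, b, exact_max_n=0)
            diffs.append(abs(p_exact - p_approx))
        # the discrete exact distribution limits worst-case agreement of the
        # continuity-corrected normal approximation to ~0.011 at n=8 vs 8
        assert np.median(diffs) < 0.01
        assert max(diffs) < 0.015

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_u([], [1.0])

    def test_u_statistic_matches_scipy(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=25)
        u, _ = mannwhitney_u(a, b)
        assert u == sps.mannwhitneyu(a, b).statistic


class TestMotifEnrichment:
    def test_independence(self):
        stat, p = motif_enrichment([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0

    def test_closed_form_value(self):
        # n(ad-bc)^2 / product of margins = 50 * 375^2 / 25^4 = 18
        stat, p = motif_enrichment([[20, 5], [5, 20]])
        assert stat == pytest.approx(18.0)
        ref = sps.chi2_contingency(
            [[20, 5], [5, 20]], correction=False
        )
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_row_swap_invariant(self):
        s1, _ = motif_enrichment([[20, 5], [5, 20]])
        s2, _ = motif_enrichment([[5, 20], [20, 5]])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            motif_enrichment([[0, 0], [5, 20]])

    def test_matches_scipy_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(1, 50, size=(2, 2))
            stat, p = motif_enrichment(t)
            ref = sps.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestFeaturePca:
    def test_correlated_features_pc1_everything(self, rng):
        x = rng.normal(size=200)
        table = np.column_stack([x, 2 * x + 1])
        loadings, var, names = feature_pca(table)
        assert var[0] == pytest.approx(1.0)

    def test_identity_covariance_equal_shares(self, rng):
        table = rng.normal(size=(20000, 3))
        _, var, _ = feature_pca(table)
        assert np.allclose(var, 1 / 3, atol=0.02)

    def test_variance_fractions_sum_to_one(self, rng):
        table = rng.normal(size=(50, 4))
        _, var, _ = feature_pca(table)
        assert var.sum() == pytest.approx(1.0)

    def test_zero_variance_dropped_with_warning(self, rng):
        table = np.column_stack(
            [rng.normal(size=30), np.full(30, 7.0), rng.normal(size=30)]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            loadings, var, names = feature_pca(table)
        assert loadings.shape[0] == 2

    def test_orthonormal_loadings(self, rng):
        table = rng.normal(size=(100, 3))
        loadings, _, _ = feature_pca(table)
        assert np.allclose(loadings.T @ loadings, np.eye(3), atol=1e-9)

    def test_sign_convention(self, rng):
        table = rng.normal(size=(100, 3))
        loadings, _, _ = feature_pca(table)
        for k in range(loadings.shape[1]):
            imax = np.argmax(np.abs(loadings[:, k]))
            assert loadings[imax, k] > 0


class TestFeatureTable:
    def test_columns_and_values(self):
        records = [("u1", "GGGAGGGAGGGAGGGTTTT"), ("u2", "CTTTTTAAA")]
        table = utr_feature_table(records)
        assert table.loc["u1", "has_g4"]
        assert not table.loc["u2", "has_g4"]
        assert table.loc["u2", "is_top"]
        assert table.loc["u1", "length"] == 19

    def test_external_dg_joined(self):
        table = utr_feature_table(
            [("u1", "ACGT" * 5)], external_dg={"u1": -12.5}
        )
        assert table.loc["u1", "dG_kcal_per_mol"] == -12.5


@settings(max_examples=400, deadline=None)
@given(seq=g_rich)
def test_property_g4_scanner_equals_oracle(seq):
    for tract in (2, 3):
        spec = MotifSpec(kind="g_quadruplex", tract_length=tract)
        got = [(h.start, h.end) for h in scan_g4(seq, spec)]
        assert got == g4_oracle(seq, tract_length=tract)


@settings(max_examples=300, deadline=None)
@given(seq=g_rich)
def test_property_ggc_scanner_equals_oracle(seq):
    got = [(h.start, h.end, h.n_repeats) for h in scan_ggc_repeats(seq)]
    assert got == ggc_oracle(seq)


@settings(max_examples=200, deadline=None)
@given(seq=dna)
def test_property_scanners_u_t_invariant(seq):
    rna = seq.replace("T", "U")
    assert scan_g4(rna) == scan_g4(seq)
    assert scan_ggc_repeats(rna) == scan_ggc_repeats(seq)


@settings(max_examples=150, deadline=None)
@given(seq=st.text(alphabet="ACGU", min_size=1, max_size=12))
def test_property_structure_score_equals_bruteforce(seq):
    assert structure_score(seq) == max_pairs_bruteforce(seq)
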