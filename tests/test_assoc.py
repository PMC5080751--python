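"""Fisher's exact test, counting models, dominant screen, sliding windows."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polysd import (
    GenomeLayout,
    Marker,
    MarkerSpec,
    SDLocus,
    SexDeterminationModel,
    ValidationError,
    allelic_table,
    assoc_scan,
    dominant_screen,
    fisher_exact_2x2,
    simulate_family,
    sliding_window,
    transmission_table,
    transmitted_allele,
)
from polysd.assoc import NOT_INFORMATIVE, AssocResult

from conftest import build_matrix


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    total = 0.0
    for x in range(lo, hi + 1):
        px = comb(r1, x) * comb(n - r1, c1 - x) / denom
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),  # 3 tables with these margins; tail 2/6
            ([[5, 0], [0, 5]], 2 / 252),  # two perfect-separation tables of 252
        ],
    )
    def test_known_small_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-7)

    def test_all_zero_table_is_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0
        assert "all-zero" in caplog.text

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_for_small_totals(self):
        """Exhaustive agreement with the enumeration oracle, totals <= 12."""
        for n in range(13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = fisher_exact_2x2([[a, b], [c, d]])
                        want = fisher_enumeration(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 25)] * 4))
    def test_symmetry_invariances(self, counts):
        """p is invariant to transposition and to swapping both rows+columns."""
        a, b, c, d = counts
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert fisher_exact_2x2([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2([[d, c], [b, a]]) == pytest.approx(p, rel=1e-9)
        assert 0 < p <= 1 or (a + b + c + d) == 0


SNP_AB = lambda mid: Marker(mid, alleles=("A", "a"))


class TestAllelicTable:
    def test_complete_separation(self):
        markers = [SNP_AB("m1")]
        matrix = build_matrix(
            markers,
            {"o1": {"m1": "A/A"}, "o2": {"m1": "A/A"}, "o3": {"m1": "a/a"}, "o4": {"m1": "a/a"}},
        )
        offspring = [("o1", "M"), ("o2", "M"), ("o3", "F"), ("o4", "F")]
        table = allelic_table(markers[0], matrix, offspring)
        assert table.tolist() == [[4, 0], [0, 4]]

    def test_heterozygotes_split(self):
        markers = [SNP_AB("m1")]
        matrix = build_matrix(markers, {"o1": {"m1": "A/a"}, "o2": {"m1": "A/a"}})
        table = allelic_table(markers[0], matrix, [("o1", "M"), ("o2", "F")])
        assert table.tolist() == [[1, 1], [1, 1]]

    def test_missing_individuals_excluded(self):
        markers = [SNP_AB("m1")]
        genotypes = {f"o{i}": {"m1": "A/a"} for i in range(20)}
        genotypes.update({f"o{i}": {"m1": None} for i in range(20, 24)})
        matrix = build_matrix(markers, genotypes)
        offspring = [(f"o{i}", "M" if i % 2 else "F") for i in range(24)]
        table = allelic_table(markers[0], matrix, offspring)
        assert table.sum() == 2 * 20

    def test_multiallelic_skipped(self):
        m = Marker("ssr", kind="SSR", alleles=("120", "122", "124"))
        matrix = build_matrix([m], {"o1": {"ssr": "120/122"}})
        assert allelic_table(m, matrix, [("o1", "M")]) is None


class TestTransmission:
    def test_forced_deduction(self):
        assert transmitted_allele(("A", "B"), ("C", "C"), ("A", "C")) == "A"

    def test_double_het_ambiguous(self):
        assert transmitted_allele(("A", "B"), ("A", "B"), ("A", "B")) is None

    def test_homozygous_parent_uninformative(self):
        assert transmitted_allele(("A", "A"), ("C", "C"), ("A", "C")) is None

    def test_unknown_other_parent_still_forced_when_unshared(self):
        assert transmitted_allele(("A", "B"), None, ("A", "C")) == "A"

    def _family(self):
        from polysd import Family

        markers = [Marker("m1", kind="SSR", alleles=("A", "B", "C"))]
        genotypes = {"s": {"m1": "A/B"}, "d": {"m1": "C/C"}}
        sexes = []
        for i in range(10):
            allele = "A" if i < 5 else "B"
            genotypes[f"o{i}"] = {"m1": f"{allele}/C"}
            sexes.append((f"o{i}", "M" if i < 5 else "F"))
        fam = Family("f1", "s", "d", tuple(sexes))
        return build_matrix(markers, genotypes), fam, markers[0]

    def test_transmission_table_counts(self):
        matrix, fam, m = self._family()
        table, trans = transmission_table(m, matrix, fam, "sire")
        # rows sorted alleles (A, B) x columns (M, F)
        assert table.tolist() == [[5, 0], [0, 5]]
        assert trans["o0"] == "A" and trans["o9"] == "B"

    def test_homozygous_sire_not_informative(self):
        matrix, fam, m = self._family()
        from polysd import GenotypeCall

        matrix.set_call("s", "m1", GenotypeCall("A", "A"))
        assert transmission_table(m, matrix, fam, "sire") is NOT_INFORMATIVE

    def test_min_informative_threshold(self):
        matrix, fam, m = self._family()
        assert transmission_table(m, matrix, fam, "sire", min_informative=11) is NOT_INFORMATIVE


class TestScan:
    def test_perfect_marker_p_is_composition_of_fisher(self, zw_family):
        matrix, fam, truth = zw_family
        results = assoc_scan(matrix, fam, mode="transmission", parent="dam")
        best = min(results, key=lambda r: r.p_value)
        assert best.p_value == fisher_exact_2x2(best.table)
        assert best.p_value < 0.001

    def test_qc_filtered_markers_absent(self, xy_family):
        from polysd import qc_filter, simulate_depth_noise

        matrix, fam, _ = xy_family
        noisy = simulate_depth_noise(matrix, mean_depth=3.0, seed=0)
        filtered = qc_filter(noisy, fam.offspring_ids, min_called=20, min_hom_depth=10)
        results = assoc_scan(filtered, fam, mode="allelic")
        kept = {r.marker_id for r in results}
        for mid in kept:
            assert filtered.called_count(mid, fam.offspring_ids) >= 20

    def test_null_scan_type_one_error_conservative(self):
        """Markers unlinked to any SD locus reject at <= nominal 1% rate."""
        layout = GenomeLayout((("LG1", 30_000_000),))
        model = SexDeterminationModel((), 1.0)  # sex by coin flip: default F...
        # no SD locus: all offspring genotypically F; use phenotype shuffling
        # instead - simulate sexes independently of genotype via penetrance .5
        rng = np.random.default_rng(13)
        n_tests = 0
        n_sig = 0
        for _ in range(40):
            matrix, fam, _ = simulate_family(
                layout,
                SexDeterminationModel((SDLocus("LG1", 0, "Y", "sire"),), 0.5),
                24,
                MarkerSpec(markers_per_lg=50, ssr_fraction=0.0),
                seed=rng,
            )
            # penetrance 0.5 makes phenotype a fair coin, independent of genotype
            results = assoc_scan(matrix, fam, mode="allelic")
            n_tests += len(results)
            n_sig += sum(r.p_value < 0.01 for r in results)
        assert n_tests > 1500
        assert n_sig / n_tests <= 0.013

    def test_association_peak_localizes_at_sd_locus(self):
        """With full penetrance the minimum-p marker sits at or immediately
        beside the SD locus (the lowest p can be shared by several fully
        linked markers, so peak position, not identity, is the stable
        power property)."""
        positions = tuple(("LG1", p) for p in range(3_000_000, 30_000_000, 3_000_000))
        layout = GenomeLayout((("LG1", 30_000_000),), marker_positions=positions)
        model = SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), 1.0)
        spec = MarkerSpec(ssr_fraction=1.0)
        rng = np.random.default_rng(14)
        n_rep = 200
        localized = 0
        for _ in range(n_rep):
            matrix, fam, _ = simulate_family(layout, model, 24, spec, seed=rng)
            results = assoc_scan(matrix, fam, mode="transmission", parent="sire")
            best = min(results, key=lambda r: (r.p_value, r.marker_id))
            if abs(best.position - 15_000_000) <= 3_000_000:
                localized += 1
        assert localized / n_rep >= 0.95


class TestDominantScreen:
    def _result(self, p, fm, ff):
        return AssocResult("m", np.zeros((2, 2), dtype=int), p, fm, ff)

    def test_y_like_signature_flagged(self):
        hits = dominant_screen([self._result(1e-4, 0.25, 0.0)])
        assert len(hits) == 1
        assert hits[0].allele_class == "Y-like"

    def test_w_like_signature_flagged(self):
        hits = dominant_screen([self._result(1e-4, 0.0, 0.25)])
        assert hits and hits[0].allele_class == "W-like"

    def test_balanced_marker_not_flagged(self):
        assert dominant_screen([self._result(0.5, 0.5, 0.5)]) == []

    def test_low_frequency_outside_window_not_flagged(self):
        assert dominant_screen([self._result(0.005, 0.05, 0.05)]) == []

    def test_present_in_both_sexes_not_flagged(self):
        assert dominant_screen([self._result(1e-4, 0.25, 0.10)]) == []


def _results_with_ps(ps):
    return [
        AssocResult(f"m{i}", np.zeros((2, 2), dtype=int), p, position=i * 100)
        for i, p in enumerate(ps)
    ]


class TestSlidingWindow:
    def test_window_count(self):
        ws = sliding_window(_results_with_ps([0.5] * 12), w=10)
        assert len(ws) == 3
        assert ws[0].marker_ids == tuple(f"m{i}" for i in range(10))

    def test_all_null_scores_zero(self):
        ws = sliding_window(_results_with_ps([1.0] * 10), w=10)
        assert all(w.score == 0.0 for w in ws)

    def test_mean_of_single_hit(self):
        ps = [1.0] * 9 + [1e-6]
        ws = sliding_window(_results_with_ps(ps), w=10)
        assert ws[0].score == pytest.approx(0.6)

    def test_frac_sig_statistic(self):
        ps = [1.0] * 8 + [1e-6, 1e-3]
        ws = sliding_window(_results_with_ps(ps), w=10, stat="frac_sig")
        assert ws[0].score == pytest.approx(0.2)

    def test_too_few_markers_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert sliding_window(_results_with_ps([0.5] * 5), w=10) == []
        assert "window" in caplog.text

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=10, max_size=30))
    def test_score_bounded_by_max_marker(self, ps):
        """A window's mean -log10 p never exceeds its best single marker."""
        for w in sliding_window(_results_with_ps(ps), w=10):
            best = max(-math.log10(p) for p in ps)
            assert w.score <= best + 1e-9
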