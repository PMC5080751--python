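"""Family system classification, penetrance and sex-reversal flags."""

import numpy as np
import pytest

from polysd import (
    Family,
    Marker,
    MarkerSpec,
    Region,
    SDLocus,
    SexDeterminationModel,
    ValidationError,
    classify_family,
    default_layout,
    flag_sex_reversal,
    penetrance,
    shared_haplotype_check,
    simulate_family,
    zw_locus,
)
from polysd.sysclass import SystemCall

from conftest import build_matrix

REGIONS = [Region("LG1", "LG1"), Region("LG2", "LG2")]


def _calls_by_region(calls):
    return {(c.region.name, c.system): c for c in calls}


class TestClassify:
    def test_paternal_y_called_xy(self, xy_family):
        matrix, fam, _ = xy_family
        calls = classify_family(matrix, fam, REGIONS)
        systems = {c.region.name: c.system for c in calls if c.system in ("XY", "ZW")}
        assert systems.get("LG1") == "XY"
        xy = next(c for c in calls if c.system == "XY")
        assert xy.parent_role == "sire" and xy.best_p < 0.05
        assert xy.penetrance == 1.0 and xy.mismatches == ()

    def test_maternal_w_called_zw(self, zw_family):
        matrix, fam, _ = zw_family
        calls = classify_family(matrix, fam, REGIONS)
        zw = next(c for c in calls if c.region.name == "LG2" and c.system == "ZW")
        assert zw.parent_role == "dam" and zw.best_p < 0.05

    def test_no_sd_locus_is_unknown_or_ni(self):
        layout = default_layout(n_lgs=2, markers_per_lg=8)
        model = SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), 0.5)
        # penetrance 0.5: phenotype is a fair coin, no real association anywhere
        spec = MarkerSpec(ssr_fraction=1.0)
        rng = np.random.default_rng(21)
        outcomes = []
        for _ in range(20):
            matrix, fam, _ = simulate_family(layout, model, 24, spec, seed=rng)
            calls = classify_family(matrix, fam, REGIONS)
            outcomes.extend(c.system for c in calls)
        # spurious calls possible at alpha=0.05 but unknown must dominate
        assert outcomes.count("unknown") / len(outcomes) > 0.75

    def test_empty_regions_rejected(self, xy_family):
        matrix, fam, _ = xy_family
        with pytest.raises(ValidationError):
            classify_family(matrix, fam, [])

    def test_relabeling_symmetry_maps_xy_to_zw(self, xy_family):
        """Swapping parent roles and offspring sexes turns an XY call into a
        ZW call with the same best marker and p-value."""
        matrix, fam, _ = xy_family
        flipped = Family(
            fam.family_id,
            fam.dam_id,
            fam.sire_id,
            tuple((o, "F" if s == "M" else "M") for o, s in fam.offspring),
        )
        calls = classify_family(matrix, fam, REGIONS)
        mirrored = classify_family(matrix, flipped, REGIONS)
        xy = sorted((c.region.name, c.best_marker, c.best_p) for c in calls if c.system == "XY")
        zw = sorted((c.region.name, c.best_marker, c.best_p) for c in mirrored if c.system == "ZW")
        assert xy == zw and xy


def _manual_zw_family(n_mismatch=2):
    """Dam A/B with A linked to W; sire C/C; ``n_mismatch`` A-carrying sons."""
    markers = [Marker("m1", scaffold="LG1", position=100, kind="SSR", alleles=("A", "B", "C"))]
    genotypes = {"s": {"m1": "C/C"}, "d": {"m1": "A/B"}}
    offspring = []
    for i in range(8):
        genotypes[f"f{i}"] = {"m1": "A/C"}
        offspring.append((f"f{i}", "F"))
    for i in range(7):
        genotypes[f"m{i}"] = {"m1": "B/C"}
        offspring.append((f"m{i}", "M"))
    for i in range(n_mismatch):
        genotypes[f"r{i}"] = {"m1": "A/C"}  # W haplotype, male phenotype
        offspring.append((f"r{i}", "M"))
    fam = Family("f1", "s", "d", tuple(offspring))
    return build_matrix(markers, genotypes), fam


class TestPenetrance:
    def test_mismatch_fraction(self):
        """17 informative offspring, 2 carrying the W haplotype as males."""
        matrix, fam = _manual_zw_family(2)
        calls = classify_family(matrix, fam, [Region("LG1", "LG1")])
        zw = next(c for c in calls if c.system == "ZW")
        assert zw.penetrance == pytest.approx(15 / 17)
        assert set(zw.mismatches) == {"r0", "r1"}
        assert zw.sex_linked_haplotype == "A"

    def test_sixteen_informative_two_mismatch(self):
        markers = [Marker("m1", kind="SSR", alleles=("A", "B", "C"))]
        genotypes = {"s": {"m1": "A/B"}, "d": {"m1": "C/C"}}
        offspring = []
        for i in range(7):
            genotypes[f"a{i}"] = {"m1": "A/C"}
            offspring.append((f"a{i}", "M"))
        for i in range(7):
            genotypes[f"b{i}"] = {"m1": "B/C"}
            offspring.append((f"b{i}", "F"))
        genotypes["x0"] = {"m1": "A/C"}
        offspring.append(("x0", "F"))
        genotypes["x1"] = {"m1": "B/C"}
        offspring.append(("x1", "M"))
        fam = Family("f1", "s", "d", tuple(offspring))
        matrix = build_matrix(markers, genotypes)
        call = SystemCall("f1", Region("LG1", "."), "XY", "s", "sire", "m1")
        assert penetrance(call, matrix, fam) == pytest.approx(0.875)
        assert len(call.mismatches) == 2

    def test_full_penetrance_iff_no_mismatches(self, xy_family):
        matrix, fam, _ = xy_family
        calls = classify_family(matrix, fam, REGIONS)
        for c in calls:
            if c.system in ("XY", "ZW"):
                assert (c.penetrance == 1.0) == (c.mismatches == ())
                assert 0.0 <= c.penetrance <= 1.0

    def test_undefined_for_unknown_calls(self, xy_family):
        matrix, fam, _ = xy_family
        call = SystemCall("f", Region("LG1", "LG1"), "unknown")
        with pytest.raises(ValidationError):
            penetrance(call, matrix, fam)


class TestSexReversal:
    def test_w_carrying_males_flagged(self):
        matrix, fam = _manual_zw_family(2)
        calls = classify_family(matrix, fam, [Region("LG1", "LG1")])
        zw = next(c for c in calls if c.system == "ZW")
        flags = flag_sex_reversal(zw, matrix, fam)
        assert sorted(flags) == [("r0", "F", "M"), ("r1", "F", "M")]

    def test_full_penetrance_family_has_no_flags(self):
        matrix, fam = _manual_zw_family(0)
        calls = classify_family(matrix, fam, [Region("LG1", "LG1")])
        zw = next(c for c in calls if c.system == "ZW")
        assert flag_sex_reversal(zw, matrix, fam) == []

    def test_flags_match_simulated_truth(self):
        """With a fully informative marker at the SD locus, flagged offspring
        are exactly the simulated sex-reversed ones."""
        from polysd import GenomeLayout

        positions = tuple(("LG1", p) for p in (5_000_000, 15_000_000, 25_000_000))
        layout = GenomeLayout((("LG1", 30_000_000),), marker_positions=positions)
        model = SexDeterminationModel((zw_locus("LG1", 15_000_000),), 0.8)
        spec = MarkerSpec(ssr_fraction=1.0)
        rng = np.random.default_rng(22)
        checked = 0
        for _ in range(20):
            matrix, fam, truth = simulate_family(layout, model, 30, spec, seed=rng)
            calls = classify_family(matrix, fam, [Region("LG1", "LG1")])
            zw = [c for c in calls if c.system == "ZW"]
            if not zw:
                continue
            call = zw[0]
            best = matrix.marker(call.best_marker)
            # only evaluable when the best marker sits exactly at the SD locus
            # (zero recombination: a mismatch can only be sex reversal) and
            # every offspring's transmission is deducible
            if best.position != 15_000_000:
                continue
            if call.n_informative < len(fam.offspring):
                continue
            true_rev = {o for o in fam.offspring_ids if truth.sex_reversed[o]}
            assert set(call.mismatches) == true_rev
            checked += 1
        assert checked >= 3


class TestSharedHaplotype:
    def _two_families_one_sire(self):
        layout = default_layout(n_lgs=1, markers_per_lg=6)
        model = SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), 1.0)
        spec = MarkerSpec(ssr_fraction=1.0)
        matrix, fam, _ = simulate_family(layout, model, 40, spec, seed=23)
        half = list(fam.offspring)
        fam_a = Family("famA", fam.sire_id, fam.dam_id, tuple(half[:20]))
        fam_b = Family("famB", fam.sire_id, fam.dam_id, tuple(half[20:]))
        return matrix, fam_a, fam_b

    def test_same_sire_consistent_y_haplotype(self):
        matrix, fam_a, fam_b = self._two_families_one_sire()
        region = [Region("LG1", "LG1")]
        calls = classify_family(matrix, fam_a, region) + classify_family(matrix, fam_b, region)
        xy = [c for c in calls if c.system == "XY"]
        assert len(xy) == 2
        reports = shared_haplotype_check(xy)
        shared = [r for r in reports if r.comparable]
        assert len(shared) == 1 and shared[0].consistent

    def test_unrelated_parents_not_comparable(self, xy_family, zw_family):
        m1, f1, _ = xy_family
        m2, f2, _ = zw_family
        calls = classify_family(m1, f1, REGIONS) + classify_family(m2, f2, REGIONS)
        reports = shared_haplotype_check([c for c in calls if c.system in ("XY", "ZW")])
        assert reports and all(not r.comparable for r in reports)

    def test_engineered_disagreement_flagged(self):
        matrix, fam_a, fam_b = self._two_families_one_sire()
        region = [Region("LG1", "LG1")]
        calls = [
            next(c for c in classify_family(matrix, fam_a, region) if c.system == "XY"),
            next(c for c in classify_family(matrix, fam_b, region) if c.system == "XY"),
        ]
        calls[1].sex_linked_haplotype = "not-the-same-allele"
        reports = shared_haplotype_check(calls)
        assert any(r.comparable and not r.consistent for r in reports)


class TestRecovery:
    def test_full_penetrance_recovery_without_noise(self):
        """Penetrance-1, noise-free 24-offspring families typed at a
        high-polymorphism confirmation panel classify to the configured
        system every time."""
        from polysd.evaluation import _confirmation_layout, _CONFIRMATION_SPEC

        layout = _confirmation_layout()
        spec = _CONFIRMATION_SPEC
        rng = np.random.default_rng(24)
        configs = [
            (SexDeterminationModel((SDLocus("LG1", 15_000_000, "Y", "sire"),), 1.0), "XY", "LG1"),
            (SexDeterminationModel((zw_locus("LG2", 15_000_000),), 1.0), "ZW", "LG2"),
        ]
        n_ok = n_tot = 0
        for model, want, region_name in configs:
            for _ in range(25):
                matrix, fam, _ = simulate_family(layout, model, 24, spec, seed=rng)
                calls = classify_family(matrix, fam, REGIONS)
                sig = [c for c in calls if c.system in ("XY", "ZW")]
                best = min(sig, key=lambda c: (c.best_p, -c.n_informative, c.best_marker))
                n_tot += 1
                n_ok += best.system == want and best.region.name == region_name
        assert n_ok == n_tot == 50
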