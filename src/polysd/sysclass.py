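"""Per-family sex-determination system calls, penetrance, and sex reversal.

For each candidate locus region, the sire's allele transmissions are tested
for Y-type association (an allele co-segregating with sons) and the dam's
for W-type association (an allele co-segregating with daughters).  A family
significant on the sire side is called XY at the region, on the dam side
ZW; both sides significant emit two calls (a multi-locus family — per-family
data cannot distinguish a true XYW configuration from occasional sex
reversal, so the cross-family view is left to
:func:`shared_haplotype_check`).

Penetrance is the fraction of informative offspring whose phenotypic sex
matches the majority allele->sex mapping at the region's best (lowest-p)
marker; the mismatching offspring are the putative sex-reversed
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .assoc import NOT_INFORMATIVE, fisher_exact_2x2, transmission_table
from .dataio import Family, GenotypeMatrix, ValidationError


@dataclass(frozen=True)
class Region:
    """A candidate locus: a linkage group, optionally an interval within it."""

    name: str
    lg: str
    start: int = 0
    end: Optional[int] = None

    def contains(self, lg: str, pos: int) -> bool:
        if lg != self.lg:
            return False
        return pos >= self.start and (self.end is None or pos < self.end)


@dataclass
class SystemCall:
    """Inference for one family at one region.

    ``system`` is XY (sire-linked), ZW (dam-linked), ``unknown``
    (informative markers but no significant association) or ``NI`` (no
    informative markers for either parent).  ``sex_linked_haplotype`` is the
    parental allele at the best marker associated with the determining sex
    (Y-like allele for XY, W-like for ZW).
    """

    family_id: str
    region: Region
    system: str
    parent_id: Optional[str] = None
    parent_role: Optional[str] = None
    best_marker: Optional[str] = None
    best_p: Optional[float] = None
    n_informative: int = 0
    sex_linked_haplotype: Optional[str] = None
    penetrance: Optional[float] = None
    mismatches: tuple[str, ...] = ()


def _marker_in_region(marker, region: Region, anchor_map=None) -> bool:
    if anchor_map is not None:
        lifted = anchor_map.liftover(marker.scaffold, marker.position)
        if lifted is None:
            return False
        return region.contains(*lifted)
    return region.contains(marker.scaffold, marker.position)


def _parent_confounded(matrix, family, marker) -> bool:
    """True when sire and dam share an identical heterozygous genotype.

    At such markers only homozygous offspring are deducible and the deduced
    sire and dam transmissions coincide, so an association cannot be
    attributed to either parent (the intercross "hk x hk" configuration of
    linkage-mapping practice); the classifier skips them.
    """
    s = matrix.call(family.sire_id, marker.id)
    d = matrix.call(family.dam_id, marker.id)
    if s.is_missing or d.is_missing or s.is_hom:
        return False
    return set(s.alleles) == set(d.alleles)


def _best_parent_test(matrix, family, region, parent, min_informative, anchor_map):
    """Min Fisher p over region markers for one parent's transmissions.

    Ties resolved by more informative offspring, then lexicographic marker
    id.  Parent-confounded markers are skipped.  Returns
    (marker, p, table, transmissions, n_informative) or None.
    """
    best = None
    for m in matrix.markers:
        if not _marker_in_region(m, region, anchor_map):
            continue
        if _parent_confounded(matrix, family, m):
            continue
        tt = transmission_table(m, matrix, family, parent, min_informative)
        if tt is NOT_INFORMATIVE:
            continue
        table, trans = tt
        p = fisher_exact_2x2(table)
        key = (p, -int(table.sum()), m.id)
        if best is None or key < best[0]:
            best = (key, m, p, table, trans)
    if best is None:
        return None
    _, m, p, table, trans = best
    return m, p, table, trans, int(table.sum())


def _majority_mapping(table: np.ndarray, alleles: tuple[str, str], target_sex: str):
    """Allele most associated with ``target_sex`` under the majority rule.

    The expected allele->sex mapping at a marker is the one matched by the
    most offspring: the diagonal pairing (allele0->M, allele1->F) or its
    swap, whichever explains more counts.  Returns the allele mapped to
    ``target_sex``.
    """
    diag = table[0, 0] + table[1, 1]  # allele0 with males, allele1 with females
    anti = table[0, 1] + table[1, 0]
    if diag >= anti:
        male_allele, female_allele = alleles[0], alleles[1]
    else:
        male_allele, female_allele = alleles[1], alleles[0]
    return male_allele if target_sex == "M" else female_allele


def _score_call(call: SystemCall, table, trans, family, alleles):
    """Fill penetrance / mismatches / sex-linked allele on a call in place."""
    target_sex = "M" if call.system == "XY" else "F"
    linked = _majority_mapping(table, alleles, target_sex)
    matches, mismatches = 0, []
    for oid, allele in trans.items():
        sex = family.sex_of(oid)
        expected_sex = target_sex if allele == linked else ("F" if target_sex == "M" else "M")
        if sex == expected_sex:
            matches += 1
        else:
            mismatches.append(oid)
    n = len(trans)
    call.sex_linked_haplotype = linked
    call.penetrance = matches / n if n else None
    call.mismatches = tuple(sorted(mismatches))


def classify_family(
    matrix: GenotypeMatrix,
    family: Family,
    regions: Sequence[Region],
    alpha: float = 0.05,
    min_informative: int = 5,
    anchor_map=None,
) -> list[SystemCall]:
    """Call the segregating sex-determination system(s) for one family.

    Per region: the minimum transmission-test p over region markers is taken
    separately for sire and dam (no multiple-testing correction — each
    region carries few markers and calls are replicated across families).
    Sire significant -> XY call; dam significant -> ZW call; both -> both
    calls; neither -> ``unknown``; no informative markers at all -> ``NI``.
    Penetrance and mismatch lists are filled for XY/ZW calls.
    """
    if not regions:
        raise ValidationError("regions must be non-empty")
    calls: list[SystemCall] = []
    for region in regions:
        sire_best = _best_parent_test(matrix, family, region, "sire", min_informative, anchor_map)
        dam_best = _best_parent_test(matrix, family, region, "dam", min_informative, anchor_map)
        emitted = False
        for parent, best, system in (("sire", sire_best, "XY"), ("dam", dam_best, "ZW")):
            if best is None:
                continue
            m, p, table, trans, n_inf = best
            if p < alpha:
                pid = family.sire_id if parent == "sire" else family.dam_id
                call = SystemCall(
                    family.family_id, region, system, pid, parent, m.id, p, n_inf
                )
                pcall = matrix.call(pid, m.id)
                _score_call(call, table, trans, family, tuple(sorted(pcall.alleles)))
                calls.append(call)
                emitted = True
        if not emitted:
            if sire_best is None and dam_best is None:
                calls.append(SystemCall(family.family_id, region, "NI"))
            else:
                # keep the stronger (smaller-p) parent as context for "unknown"
                cands = [b for b in (sire_best, dam_best) if b is not None]
                cands.sort(key=lambda b: (b[1], -b[4], b[0].id))
                m, p, _, _, n_inf = cands[0]
                calls.append(
                    SystemCall(family.family_id, region, "unknown", best_marker=m.id, best_p=p, n_informative=n_inf)
                )
    return calls


def penetrance(call: SystemCall, matrix: GenotypeMatrix, family: Family) -> float:
    """Penetrance at the call's best marker (recomputed from genotypes).

    The expected genotype->sex mapping is the majority mapping at the best
    marker; penetrance is the matching fraction of informative offspring.
    Raises when the call is not XY/ZW or no offspring are informative.
    """
    if call.system not in ("XY", "ZW"):
        raise ValidationError("penetrance defined only for XY/ZW calls")
    m = matrix.marker(call.best_marker)
    tt = transmission_table(m, matrix, family, call.parent_role, min_informative=1)
    if tt is NOT_INFORMATIVE:
        raise ValidationError("no informative offspring at best marker")
    table, trans = tt
    pid = family.sire_id if call.parent_role == "sire" else family.dam_id
    alleles = tuple(sorted(matrix.call(pid, m.id).alleles))
    scored = SystemCall(call.family_id, call.region, call.system, pid, call.parent_role, call.best_marker)
    _score_call(scored, table, trans, family, alleles)
    call.penetrance = scored.penetrance
    call.mismatches = scored.mismatches
    call.sex_linked_haplotype = scored.sex_linked_haplotype
    return scored.penetrance


def flag_sex_reversal(
    call: SystemCall, matrix: GenotypeMatrix, family: Family
) -> list[tuple[str, str, str]]:
    """Offspring whose phenotypic sex contradicts their sex-linked genotype.

    Returns (offspring id, genotype-implied sex, phenotypic sex) for each
    member of the call's mismatch set (identical membership to the
    penetrance calculation's mismatches).
    """
    if call.system not in ("XY", "ZW"):
        raise ValidationError("sex-reversal flags defined only for XY/ZW calls")
    if call.penetrance is None:
        penetrance(call, matrix, family)
    out = []
    for oid in call.mismatches:
        psex = family.sex_of(oid)
        out.append((oid, "F" if psex == "M" else "M", psex))
    return out


@dataclass(frozen=True)
class HaplotypeConsistency:
    """Cross-family agreement of the sex-linked parental allele."""

    parent_id: str
    region_name: str
    system: str
    family_ids: tuple[str, ...]
    alleles: tuple[str, ...]
    comparable: bool
    consistent: Optional[bool]  # None when not comparable


def shared_haplotype_check(calls: Sequence[SystemCall]) -> list[HaplotypeConsistency]:
    """Check that families sharing a parent implicate the same haplotype.

    A parent carrying a genuine sex-determination allele should show the
    same sex-linked allele in every family it heads; disagreement flags
    either marker inconsistency or a spurious call.  Groups with fewer than
    two calls are reported as not comparable.
    """
    groups: dict[tuple, list[SystemCall]] = {}
    for c in calls:
        if c.system not in ("XY", "ZW") or c.parent_id is None:
            continue
        groups.setdefault((c.parent_id, c.region.name, c.system), []).append(c)
    out = []
    for (pid, rname, system), members in sorted(groups.items()):
        alleles = tuple(c.sex_linked_haplotype for c in members)
        fams = tuple(c.family_id for c in members)
        if len(members) < 2:
            out.append(HaplotypeConsistency(pid, rname, system, fams, alleles, False, None))
        else:
            out.append(
                HaplotypeConsistency(
                    pid, rname, system, fams, alleles, True, len(set(alleles)) == 1
                )
            )
    return out
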