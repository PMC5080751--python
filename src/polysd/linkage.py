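"""Two-point linkage from parental transmissions and fusion detection.

Estimation uses the pseudo-testcross configuration: only meioses of a
parent heterozygous at both markers, with the transmitted allele deducible
in the offspring, are scored.  The recombination fraction is estimated
phase-unknown — the recombinant count is the smaller of the two mismatch
counts under the two possible parental phases — and the LOD score compares
the binomial likelihood at the estimated fraction to free recombination
(rf = 0.5).

Chromosome fusions appear as significant linkage between markers anchored
to two different reference linkage groups; LG pairs whose best cross-pair
LOD exceeds a threshold (default 4) are called fused, with transitive
chains merged into one multi-LG group.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .assoc import NOT_INFORMATIVE, transmission_table
from .dataio import Family, GenotypeMatrix, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkageResult:
    """Recombination estimate for a marker pair or an LG pair."""

    pair: tuple[str, str]
    informative_meioses: int
    recombinants: int
    rf: float
    lod: float
    best_marker_pair: Optional[tuple[str, str]] = None
    continuous_haplotype: bool = False


def count_recombinants(
    marker_a: str,
    marker_b: str,
    matrix: GenotypeMatrix,
    family: Family,
    parent: str,
    min_informative: int = 1,
):
    """(N, R) for one parent between two markers, phase-unknown.

    N counts offspring whose transmitted parental allele is deducible at
    both markers; R is the minority pairing count (the recombinant class
    under whichever phase makes it the minority).  Returns
    ``NOT_INFORMATIVE`` when the parent is homozygous or unscorable at
    either marker.
    """
    ta = transmission_table(matrix.marker(marker_a), matrix, family, parent, min_informative)
    tb = transmission_table(matrix.marker(marker_b), matrix, family, parent, min_informative)
    if ta is NOT_INFORMATIVE or tb is NOT_INFORMATIVE:
        return NOT_INFORMATIVE
    _, trans_a = ta
    _, trans_b = tb
    shared = sorted(set(trans_a) & set(trans_b))
    if not shared:
        return NOT_INFORMATIVE
    alleles_a = sorted({trans_a[o] for o in shared} | set(trans_a.values()))
    # pairing classes: allele_a[0] with each observed b-allele
    n = len(shared)
    first_a = alleles_a[0]
    b_with_first = [trans_b[o] for o in shared if trans_a[o] == first_a]
    b_alleles = sorted(set(trans_b[o] for o in shared))
    if len(b_alleles) == 1:
        # no segregation observed at b among shared meioses: R = 0 by convention
        return n, 0
    b0 = b_alleles[0]
    # phase 1: (first_a, b0) parental; phase 2: (first_a, b1) parental
    mism1 = sum(
        1
        for o in shared
        if (trans_a[o] == first_a) != (trans_b[o] == b0)
    )
    r = min(mism1, n - mism1)
    return n, r


def two_point_lod(N: int, R: int) -> tuple[float, float]:
    """(rf, LOD) from informative meioses N and recombinants R.

    rf = min(R, N-R)/N (phase-unknown estimate, capped at 0.5); the LOD is
    the log10 likelihood ratio of the binomial at rf versus rf = 0.5, with
    the rf = 0 limit handled exactly (LOD = N log10 2).
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    if not (0 <= R <= N):
        raise ParameterError("R must be in [0, N]")
    r = min(R, N - R)
    rf = r / N
    if r == 0:
        lod = N * math.log10(2.0)
    else:
        lod = r * math.log10(2.0 * rf) + (N - r) * math.log10(2.0 * (1.0 - rf))
    return rf, max(0.0, lod)


def lg_pair_linkage(
    matrix: GenotypeMatrix,
    families: Sequence[Family],
    marker_lg: Optional[dict[str, str]] = None,
    parents: tuple[str, ...] = ("sire", "dam"),
    min_informative: int = 1,
    min_continuity_n: int = 5,
) -> list[LinkageResult]:
    """Best cross-LG two-point linkage for every pair of linkage groups.

    Markers are grouped by reference LG (``marker_lg`` maps marker id ->
    LG; defaults to each marker's scaffold field, the convention of the
    simulator).  For each cross-LG marker pair, per-family/per-parent
    (N, R) counts are summed before the LOD computation (LOD additivity
    under a shared recombination fraction; small families are individually
    underpowered), and the pair with the highest LOD represents the LG
    pair.  ``continuous_haplotype`` is set when the best pair shows zero
    recombinants in at least one family with >= ``min_continuity_n``
    informative meioses.
    """
    if marker_lg is None:
        marker_lg = {m.id: m.scaffold for m in matrix.markers}
    by_lg: dict[str, list[str]] = {}
    for m in matrix.markers:
        lg = marker_lg.get(m.id)
        if lg is not None:
            by_lg.setdefault(lg, []).append(m.id)
    results = []
    for lg1, lg2 in itertools.combinations(sorted(by_lg), 2):
        best = None
        for ma, mb in itertools.product(by_lg[lg1], by_lg[lg2]):
            total_n = total_r = 0
            zero_r_family = False
            for fam in families:
                for parent in parents:
                    nr = count_recombinants(ma, mb, matrix, fam, parent, min_informative)
                    if nr is NOT_INFORMATIVE:
                        continue
                    n, r = nr
                    total_n += n
                    total_r += r
                    if r == 0 and n >= min_continuity_n:
                        zero_r_family = True
            if total_n == 0:
                continue
            rf, lod = two_point_lod(total_n, total_r)
            if best is None or lod > best[0]:
                best = (lod, rf, total_n, total_r, (ma, mb), zero_r_family)
        if best is None:
            logger.info("lg_pair_linkage: no informative cross-LG pairs for (%s, %s)", lg1, lg2)
            continue
        lod, rf, n, r, pair, cont = best
        results.append(LinkageResult((lg1, lg2), n, r, rf, lod, pair, cont))
    return results


@dataclass(frozen=True)
class FusionCall:
    """A group of reference LGs inferred to form one physical chromosome."""

    lgs: tuple[str, ...]
    name: str
    max_lod: float
    supporting_pairs: tuple[tuple[str, str], ...]
    continuous_haplotype: bool


def _fusion_name(lgs: Sequence[str]) -> str:
    nums = [lg[2:] if lg.startswith("LG") else lg for lg in lgs]
    return "LG" + "-".join(nums)


def detect_fusions(results: Sequence[LinkageResult], lod_threshold: float = 4.0) -> list[FusionCall]:
    """Call fused LG groups from pairwise linkage results.

    LG pairs with max LOD above the threshold define edges; connected
    components of two or more LGs become one fusion call (transitive chains
    such as A-B and B-C merge into one A-B-C group, named by joining LG
    numbers).
    """
    above = [r for r in results if r.lod > lod_threshold]
    adj: dict[str, set[str]] = {}
    for r in above:
        a, b = r.pair
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    calls = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node] - seen)
        comp = sorted(comp)
        members = set(comp)
        edges = [r for r in above if set(r.pair) <= members]
        calls.append(
            FusionCall(
                tuple(comp),
                _fusion_name(comp),
                max(r.lod for r in edges),
                tuple(r.best_marker_pair for r in edges if r.best_marker_pair),
                any(r.continuous_haplotype for r in edges),
            )
        )
    return calls
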