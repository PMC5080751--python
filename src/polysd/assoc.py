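"""Marker-by-marker association of genotype with phenotypic sex.

Two counting models feed a two-sided Fisher's exact test:

- *allelic*: each called offspring contributes its two alleles to an
  allele x sex 2x2 table (biallelic markers only);
- *transmission*: for a chosen parent heterozygous at the marker, each
  offspring whose transmitted parental allele is deducible contributes one
  count to a transmitted-allele x sex table (the informative-meiosis model
  used to test a sire's alleles for Y association and a dam's for W).

On top of the per-marker scan sit a dominant-model screen (minor allele at
intermediate frequency in one sex, absent in the other — the signature of a
heterozygous dominant sex-determination allele) and a sliding-window summary
along anchored coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataio import Family, GenotypeMatrix, Marker, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Uses the minimum-likelihood convention: the p-value sums hypergeometric
    point probabilities (margins fixed) over all tables at most as probable
    as the observed one, within relative tolerance 1e-7 — the convention of
    the common association-testing packages.  The all-zero table returns 1
    with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("negative count in 2x2 table")
    if t.sum() == 0:
        logger.warning("fisher_exact_2x2: all-zero table, p = 1")
        return 1.0
    return _fisher_cached(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))


@lru_cache(maxsize=500_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# counting models


def allelic_table(
    marker: Marker, matrix: GenotypeMatrix, offspring: Sequence[tuple[str, str]]
):
    """Allele x sex counts over called offspring; None for non-biallelic.

    Rows are the marker's two alleles (in marker order), columns (M, F);
    each called individual contributes two allele counts to its sex column.
    """
    if len(marker.alleles) != 2:
        logger.info("allelic_table: marker %s is not biallelic, skipped", marker.id)
        return None
    idx = {a: i for i, a in enumerate(marker.alleles)}
    table = np.zeros((2, 2), dtype=np.int64)
    col = {"M": 0, "F": 1}
    for oid, sex in offspring:
        call = matrix.call(oid, marker.id)
        if call.is_missing:
            continue
        for allele in call.alleles:
            table[idx[allele], col[sex]] += 1
    return table


def transmitted_allele(parent_gt, other_gt, off_gt) -> Optional[str]:
    """Deduce which allele a heterozygous parent transmitted to an offspring.

    Returns the allele when exactly one of the parent's two alleles is
    consistent with the offspring genotype given the other parent's
    genotype; None when missing data or phase ambiguity (e.g. both parents
    and the offspring share the same heterozygous genotype) prevents the
    deduction.  ``other_gt`` may be None (other parent ungenotyped), which
    relaxes the consistency check to the offspring's own alleles.
    """
    if parent_gt is None or off_gt is None:
        return None
    p1, p2 = parent_gt
    if p1 == p2:
        return None
    candidates = []
    off = list(off_gt)
    for t in (p1, p2):
        if t not in off:
            continue
        rest = off.copy()
        rest.remove(t)
        other_allele = rest[0]
        if other_gt is None or other_allele in other_gt:
            candidates.append(t)
    uniq = set(candidates)
    if len(uniq) == 1:
        return candidates[0]
    return None


class NotInformative:
    """Sentinel result: the tested parent's transmissions cannot be scored."""

    def __repr__(self):  # pragma: no cover - cosmetic
        return "NotInformative"


NOT_INFORMATIVE = NotInformative()


def transmission_table(
    marker: Marker,
    matrix: GenotypeMatrix,
    family: Family,
    parent: str,
    min_informative: int = 5,
):
    """Transmitted-allele x sex counts for one parent at one marker.

    Requires the tested parent heterozygous; offspring with ambiguous or
    missing transmission are excluded.  Returns ``NOT_INFORMATIVE`` when the
    parent is homozygous/missing or fewer than ``min_informative`` offspring
    are deducible.  Rows are the parent's two alleles (sorted), columns
    (M, F); a per-offspring transmission map is returned alongside.
    """
    if parent not in ("sire", "dam"):
        raise ValidationError("parent must be 'sire' or 'dam'")
    pid = family.sire_id if parent == "sire" else family.dam_id
    oid_other = family.dam_id if parent == "sire" else family.sire_id
    pcall = matrix.call(pid, marker.id)
    if pcall.is_missing or pcall.is_hom:
        return NOT_INFORMATIVE
    ocall = matrix.call(oid_other, marker.id)
    other_gt = None if ocall.is_missing else ocall.alleles
    p_alleles = tuple(sorted(pcall.alleles))
    row = {p_alleles[0]: 0, p_alleles[1]: 1}
    col = {"M": 0, "F": 1}
    table = np.zeros((2, 2), dtype=np.int64)
    transmissions: dict[str, str] = {}
    for oid, sex in family.offspring:
        c = matrix.call(oid, marker.id)
        t = transmitted_allele(pcall.alleles, other_gt, None if c.is_missing else c.alleles)
        if t is None:
            continue
        table[row[t], col[sex]] += 1
        transmissions[oid] = t
    if table.sum() < min_informative:
        return NOT_INFORMATIVE
    return table, transmissions


# ---------------------------------------------------------------------------
# scan


@dataclass
class AssocResult:
    """Per-marker association outcome."""

    marker_id: str
    table: np.ndarray
    p_value: float
    minor_freq_m: float = math.nan
    minor_freq_f: float = math.nan
    informative: bool = True
    mode: str = "allelic"
    scaffold: str = "."
    position: int = 0
    anchored_lg: Optional[str] = None
    anchored_pos: Optional[int] = None

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.p_value)


def assoc_scan(
    matrix: GenotypeMatrix,
    family: Family,
    mode: str = "allelic",
    parent: str = "sire",
    anchor_map=None,
    min_informative: int = 5,
) -> list[AssocResult]:
    """Fisher-test every applicable marker against offspring sex.

    ``mode='allelic'`` counts offspring alleles by sex (biallelic markers);
    ``mode='transmission'`` counts the chosen parent's deducible
    transmissions.  Skipped markers (non-biallelic / not informative) are
    counted and logged, not returned.  When an anchor map is given, results
    are ordered by (linkage group, anchored position); otherwise input
    order.
    """
    if mode not in ("allelic", "transmission"):
        raise ValidationError(f"unknown mode {mode!r}")
    results = []
    n_skipped = 0
    for m in matrix.markers:
        if mode == "allelic":
            table = allelic_table(m, matrix, family.offspring)
            if table is None or table.sum() == 0:
                n_skipped += 1
                continue
            p = fisher_exact_2x2(table)
            fm, ff = _minor_freqs(table, m)
            res = AssocResult(m.id, table, p, fm, ff, True, "allelic", m.scaffold, m.position)
        else:
            tt = transmission_table(m, matrix, family, parent, min_informative)
            if tt is NOT_INFORMATIVE:
                n_skipped += 1
                continue
            table, _ = tt
            p = fisher_exact_2x2(table)
            res = AssocResult(m.id, table, p, mode="transmission", scaffold=m.scaffold, position=m.position)
        if anchor_map is not None:
            lifted = anchor_map.liftover(m.scaffold, m.position)
            if lifted is not None:
                res.anchored_lg, res.anchored_pos = lifted
        results.append(res)
    if n_skipped:
        logger.info("assoc_scan: skipped %d markers (non-biallelic or not informative)", n_skipped)
    if anchor_map is not None:
        results.sort(
            key=lambda r: (r.anchored_lg is None, r.anchored_lg or "", r.anchored_pos or 0)
        )
    return results


def _minor_freqs(table: np.ndarray, marker: Marker) -> tuple[float, float]:
    """Frequency of the overall-minor allele within each sex column."""
    totals = table.sum(axis=1)
    minor_row = int(np.argmin(totals))  # ties -> first allele
    colsums = table.sum(axis=0)
    fm = table[minor_row, 0] / colsums[0] if colsums[0] else math.nan
    ff = table[minor_row, 1] / colsums[1] if colsums[1] else math.nan
    return float(fm), float(ff)


# ---------------------------------------------------------------------------
# dominant-model screen


@dataclass(frozen=True)
class DominantHit:
    marker_id: str
    p_value: float
    carrier_sex: str  # "M" -> Y-like, "F" -> W-like
    carrier_freq: float

    @property
    def allele_class(self) -> str:
        return "Y-like" if self.carrier_sex == "M" else "W-like"


def dominant_screen(
    results: Sequence[AssocResult],
    p_thresh: float = 0.01,
    freq_window: tuple[float, float] = (0.15, 0.60),
    absent_eps: float = 0.0,
) -> list[DominantHit]:
    """Flag markers matching a dominant sex-determination signature.

    A heterozygous dominant SD allele carried by one parent shows up as a
    minor allele at ~0.25 allelic frequency among offspring of the carrier
    sex and absent in the other; the screen keeps significant markers
    (p < ``p_thresh``) whose minor-allele frequency lies inside
    ``freq_window`` in one sex and is <= ``absent_eps`` in the other.
    """
    lo, hi = freq_window
    hits = []
    for r in results:
        if math.isnan(r.minor_freq_m) or r.p_value >= p_thresh:
            continue
        if lo <= r.minor_freq_m <= hi and r.minor_freq_f <= absent_eps:
            hits.append(DominantHit(r.marker_id, r.p_value, "M", r.minor_freq_m))
        elif lo <= r.minor_freq_f <= hi and r.minor_freq_m <= absent_eps:
            hits.append(DominantHit(r.marker_id, r.p_value, "F", r.minor_freq_f))
    return hits


# ---------------------------------------------------------------------------
# sliding window


@dataclass(frozen=True)
class WindowScore:
    index: int
    marker_ids: tuple[str, ...]
    score: float
    span: tuple[str, int, int]  # (scaffold/lg of first marker, start, end)


def sliding_window(
    results: Sequence[AssocResult],
    w: int = 10,
    step: int = 1,
    stat: str = "mean",
    p_sig: float = 0.01,
) -> list[WindowScore]:
    """Windowed summary of an ordered association scan.

    ``stat='mean'`` scores each window of ``w`` consecutive markers by the
    mean -log10 p; ``stat='frac_sig'`` by the fraction of markers with
    p < ``p_sig``.  Fewer than ``w`` results yields an empty list with a
    warning.
    """
    if stat not in ("mean", "frac_sig"):
        raise ValidationError(f"unknown window statistic {stat!r}")
    n = len(results)
    if n < w:
        logger.warning("sliding_window: %d results < window size %d", n, w)
        return []
    out = []
    for i in range(0, n - w + 1, step):
        chunk = results[i : i + w]
        if stat == "mean":
            score = float(np.mean([r.neglog10p for r in chunk]))
        else:
            score = float(np.mean([r.p_value < p_sig for r in chunk]))
        positions = [r.anchored_pos if r.anchored_pos is not None else r.position for r in chunk]
        ref = chunk[0].anchored_lg if chunk[0].anchored_lg is not None else chunk[0].scaffold
        out.append(
            WindowScore(i, tuple(r.marker_id for r in chunk), score, (ref, min(positions), max(positions)))
        )
    return out
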