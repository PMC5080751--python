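"""Reference-guided scaffold anchoring from filtered window alignments.

A fragmented assembly is anchored to a chromosome-level reference by
cutting scaffolds into fixed-size windows, aligning each window, filtering
alignments (uniqueness, suboptimal-hit count, identity), voting each
scaffold onto a linkage group, then ordering scaffolds by the median target
position of their windows and orienting them by the rank correlation
between window index and target position.  Marker coordinates lift onto
the resulting pseudo-chromosomes for genome-wide plotting and region
queries.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dataio import AlignmentRecord, ValidationError

logger = logging.getLogger(__name__)


def filter_alignments(
    records: Sequence[AlignmentRecord],
    min_identity: float = 0.90,
    max_suboptimal: int = 4,
    require_unique: bool = True,
) -> list[AlignmentRecord]:
    """Keep windows that map uniquely, with < 5 suboptimal hits by default,
    and identity >= ``min_identity`` (the boundary value is kept: only
    windows *below* the identity threshold are removed)."""
    out = []
    for r in records:
        if require_unique and not r.unique:
            continue
        if r.n_suboptimal > max_suboptimal:
            continue
        if r.identity < min_identity:
            continue
        out.append(r)
    return out


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold: str
    lg: Optional[str]  # None -> unplaced
    n_windows: int
    vote_fraction: float
    junction_candidate: bool = False


def assign_scaffold_lg(
    records: Sequence[AlignmentRecord],
    min_vote: float = 0.60,
    min_windows: int = 3,
) -> list[ScaffoldAssignment]:
    """Majority-vote each scaffold onto a linkage group.

    A scaffold is placed on the LG receiving strictly more than
    ``min_vote`` of its windows, provided it has at least ``min_windows``
    mapped windows; otherwise unplaced.  An unplaced scaffold whose windows
    split mostly between exactly two LGs is flagged as a fusion-junction
    candidate.
    """
    by_scaf: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        by_scaf[r.scaffold].append(r)
    out = []
    for scaf in sorted(by_scaf):
        recs = by_scaf[scaf]
        votes = Counter(r.target_lg for r in recs)
        n = len(recs)
        top_lg, top_n = votes.most_common(1)[0]
        frac = top_n / n
        if n >= min_windows and frac > min_vote:
            out.append(ScaffoldAssignment(scaf, top_lg, n, frac))
        else:
            junction = False
            if n >= min_windows and len(votes) >= 2:
                (lg1, n1), (lg2, n2) = votes.most_common(2)
                junction = (n1 + n2) / n >= 0.9 and n2 / n >= 0.2
            out.append(ScaffoldAssignment(scaf, None, n, frac, junction))
    return out


@dataclass(frozen=True)
class Placement:
    lg: str
    order_index: int
    orientation: str  # "+" or "-"
    lg_offset: int
    length: int
    n_windows: int
    orientation_ambiguous: bool = False


@dataclass
class AnchorMap:
    """Scaffold placements along pseudo-chromosomes."""

    placements: dict[str, Placement] = field(default_factory=dict)
    lg_scaffolds: dict[str, list[str]] = field(default_factory=dict)
    unplaced: list[str] = field(default_factory=list)

    def liftover(self, scaffold: str, position: int) -> Optional[tuple[str, int]]:
        """Scaffold coordinate -> (LG, pseudo-chromosome position).

        Plus-orientation scaffolds map positions directly past their
        offset; minus scaffolds reflect (position 0 maps to the scaffold's
        far end).  Returns None for unplaced scaffolds.
        """
        p = self.placements.get(scaffold)
        if p is None:
            return None
        if position < 0 or position >= p.length:
            raise ValidationError(f"position {position} outside scaffold {scaffold} (length {p.length})")
        if p.orientation == "+":
            return p.lg, p.lg_offset + position
        return p.lg, p.lg_offset + (p.length - 1 - position)

    def inverse_liftover(self, lg: str, anchored_pos: int) -> Optional[tuple[str, int]]:
        """Pseudo-chromosome position -> (scaffold, scaffold coordinate)."""
        for scaf in self.lg_scaffolds.get(lg, []):
            p = self.placements[scaf]
            if p.lg_offset <= anchored_pos < p.lg_offset + p.length:
                rel = anchored_pos - p.lg_offset
                return scaf, rel if p.orientation == "+" else p.length - 1 - rel
        return None


def order_orient(
    records: Sequence[AlignmentRecord],
    assignments: Sequence[ScaffoldAssignment],
    gap: int = 1000,
) -> AnchorMap:
    """Order and orient placed scaffolds along each linkage group.

    Scaffolds sort by the median reference position of their windows (ties:
    minimum target position, then scaffold id); orientation is the sign of
    the Spearman correlation between window start and target position
    (undefined correlation -> "+" with an ambiguity flag).  Offsets are
    cumulative scaffold lengths plus a fixed inter-scaffold gap — pseudo
    coordinates for ordering, not physical distances.
    """
    placed = {a.scaffold: a.lg for a in assignments if a.lg is not None}
    by_scaf: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        if r.scaffold in placed and r.target_lg == placed[r.scaffold]:
            by_scaf[r.scaffold].append(r)

    per_lg: dict[str, list[tuple]] = defaultdict(list)
    for scaf, lg in placed.items():
        recs = sorted(by_scaf[scaf], key=lambda r: r.window_start)
        if not recs:
            continue
        tpos = np.array([r.target_pos for r in recs], dtype=float)
        wstart = np.array([r.window_start for r in recs], dtype=float)
        ambiguous = False
        if len(recs) < 2 or np.all(tpos == tpos[0]) or np.all(wstart == wstart[0]):
            orientation = "+"
            ambiguous = True
        else:
            rho = stats.spearmanr(wstart, tpos).statistic
            if not np.isfinite(rho) or rho == 0:
                orientation = "+"
                ambiguous = True
            else:
                orientation = "+" if rho > 0 else "-"
        length = recs[0].scaffold_length or int(max(r.window_end for r in recs))
        per_lg[lg].append(
            (float(np.median(tpos)), float(tpos.min()), scaf, orientation, length, len(recs), ambiguous)
        )

    amap = AnchorMap()
    for lg in sorted(per_lg):
        entries = sorted(per_lg[lg], key=lambda e: (e[0], e[1], e[2]))
        offset = 0
        order = []
        for idx, (_, _, scaf, orientation, length, nwin, amb) in enumerate(entries):
            amap.placements[scaf] = Placement(lg, idx, orientation, offset, length, nwin, amb)
            order.append(scaf)
            offset += length + gap
        amap.lg_scaffolds[lg] = order
    amap.unplaced = sorted(
        {a.scaffold for a in assignments if a.lg is None}
        | {a.scaffold for a in assignments if a.lg is not None and a.scaffold not in amap.placements}
    )
    return amap


def build_anchor_map(
    records: Sequence[AlignmentRecord],
    min_identity: float = 0.90,
    max_suboptimal: int = 4,
    min_vote: float = 0.60,
    min_windows: int = 3,
    gap: int = 1000,
) -> AnchorMap:
    """filter -> assign -> order/orient in one call."""
    kept = filter_alignments(records, min_identity, max_suboptimal)
    assignments = assign_scaffold_lg(kept, min_vote, min_windows)
    return order_orient(kept, assignments, gap)


def write_anchor_tsv(amap: AnchorMap, assignments: Sequence[ScaffoldAssignment], path) -> None:
    votes = {a.scaffold: a for a in assignments}
    with open(path, "w") as fh:
        fh.write("scaffold\tlg\torder\torientation\toffset\tn_windows\tvote_fraction\n")
        for lg in sorted(amap.lg_scaffolds):
            for scaf in amap.lg_scaffolds[lg]:
                p = amap.placements[scaf]
                v = votes.get(scaf)
                fh.write(
                    f"{scaf}\t{lg}\t{p.order_index}\t{p.orientation}\t{p.lg_offset}\t"
                    f"{p.n_windows}\t{v.vote_fraction if v else float('nan'):.3f}\n"
                )
        for scaf in amap.unplaced:
            v = votes.get(scaf)
            fh.write(f"{scaf}\tNA\tNA\tNA\tNA\t{v.n_windows if v else 0}\t{v.vote_fraction if v else 0:.3f}\n")
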