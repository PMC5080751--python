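"""Anchor fragmented-assembly scaffolds to a reference and lift markers.

Simulates window alignments of randomly cut scaffolds against two
reference linkage groups, filters them (unique, < 5 suboptimal hits,
identity >= 90%), votes each scaffold onto a linkage group, orders and
orients the placed scaffolds, and lifts a marker coordinate onto the
pseudo-chromosome.
"""

from polysd import (
    assign_scaffold_lg,
    default_layout,
    filter_alignments,
    order_orient,
    random_scaffolds,
    simulate_alignments,
)

layout = default_layout(n_lgs=2, lg_length=1_000_000)
scaffolds = random_scaffolds(layout, mean_length=150_000, seed=13)
records = simulate_alignments(layout, scaffolds, window=5000, noise=0.05, seed=14)
print(f"{len(scaffolds)} scaffolds, {len(records)} window alignments (5% noise)")

kept = filter_alignments(records)
assignments = assign_scaffold_lg(kept)
amap = order_orient(kept, assignments)

for lg, order in sorted(amap.lg_scaffolds.items()):
    oriented = [f"{s}({amap.placements[s].orientation})" for s in order]
    print(f"{lg}: {' '.join(oriented)}")
print(f"unplaced: {amap.unplaced or 'none'}")

scaf = amap.lg_scaffolds["LG1"][0]
lifted = amap.liftover(scaf, 1000)
print(f"marker at {scaf}:1000 -> pseudo-chromosome {lifted[0]}:{lifted[1]}")

truth_ok = sum(
    amap.placements[s.id].orientation == s.orientation
    for s in scaffolds if s.id in amap.placements
)
print(f"orientation recovered for {truth_ok}/{len(amap.placements)} placed scaffolds")
# Ordering uses the median reference position of each scaffold's windows;
# orientation is the sign of the window-index/target-position rank
# correlation. Marker liftover onto these pseudo-chromosomes is what lets
# an association scan be plotted in reference coordinates.
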