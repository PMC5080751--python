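"""Detect a chromosome fusion from cross-linkage-group linkage.

Simulates a genome where LG1 and LG2 are fused into one physical
chromosome (markers co-segregate across the junction), genotypes two
24-offspring families, and calls fusions from the best two-point LOD
between every pair of reference linkage groups.
"""

from polysd import (
    GenomeLayout,
    MarkerSpec,
    SexDeterminationModel,
    detect_fusions,
    lg_pair_linkage,
    simulate_families,
)

layout = GenomeLayout(
    (("LG1", 25_000_000), ("LG2", 25_000_000), ("LG3", 25_000_000)),
    fusions=(("LG1-2", ("LG1", "LG2")),),
    marker_positions=tuple(
        (lg, p) for lg in ("LG1", "LG2", "LG3") for p in range(2_000_000, 25_000_000, 4_000_000)
    ),
)
model = SexDeterminationModel((), 1.0)
matrix, families, _ = simulate_families(
    layout, model, [24, 24], MarkerSpec(ssr_fraction=1.0), seed=9
)

results = lg_pair_linkage(matrix, families)
for r in sorted(results, key=lambda r: -r.lod):
    print(f"{r.pair[0]} x {r.pair[1]}: rf = {r.rf:.3f}, LOD = {r.lod:.1f} "
          f"(N = {r.informative_meioses}, R = {r.recombinants}, "
          f"continuous haplotype: {r.continuous_haplotype})")

for call in detect_fusions(results, lod_threshold=4.0):
    print(f"\nfusion call: {call.name} (max LOD {call.max_lod:.1f})")
# The fused pair shows a high LOD (co-segregating cross-LG haplotypes with
# few recombinants) while unfused pairs sit near LOD 0 at rf ~ 0.5 - the
# same contrast that distinguishes a real fusion (LOD >> 4) from an
# unlinked control pair in family linkage data.
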