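"""Synthetic genomes, crosses and alignments with known ground truth.

This module emulates the data structure of a mouth-brooder cichlid mapping
study: single-pair families of 10-40 offspring, genotyped at SNP and SSR
markers, where phenotypic sex is set by one to three segregating sex
determination (SD) alleles.  A dominant Y allele promotes male development
and a dominant W allele promotes female development, with W epistatic over
Y; an individual carrying no SD allele develops female (the XX-female
convention).  Phenotypic sex matches this genotypic sex with probability
``penetrance`` (sex reversal is an i.i.d. flip, independent of genotype).

Meiosis uses the Haldane model: crossover counts are Poisson in the map
length, positions uniform, no interference.  Chromosome fusions are modeled
as two reference linkage groups concatenated into one physical chromosome,
so markers from both constituent groups co-segregate through meiosis.

All stochastic operations accept a seed (or a ``numpy`` Generator); one
global integer seed reproduces a whole scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dataio import (
    SNP,
    SSR,
    AlignmentRecord,
    Family,
    GenotypeCall,
    GenotypeMatrix,
    Marker,
    ValidationError,
)


class ConfigError(ValueError):
    """A simulation scenario is internally inconsistent."""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# genome layout


@dataclass(frozen=True)
class GenomeLayout:
    """Reference linkage groups, optional fusions, and marker positions.

    ``fusions`` lists physical chromosomes made of two reference LGs joined
    end to end (the second LG's coordinates are offset by the first's
    length).  Unfused LGs are their own chromosome.  ``morgans_per_bp``
    converts physical length to map length (default 1 cM/Mb, a typical
    teleost genome-wide average).
    """

    linkage_groups: tuple[tuple[str, int], ...]
    fusions: tuple[tuple[str, tuple[str, str]], ...] = ()
    marker_positions: tuple[tuple[str, int], ...] = ()
    morgans_per_bp: float = 1e-8

    def __post_init__(self):
        lengths = dict(self.linkage_groups)
        if any(v <= 0 for v in lengths.values()):
            raise ConfigError("linkage group lengths must be positive")
        fused = [lg for _, pair in self.fusions for lg in pair]
        if len(set(fused)) != len(fused):
            raise ConfigError("a linkage group appears in more than one fusion")
        for lg in fused:
            if lg not in lengths:
                raise ConfigError(f"fusion references unknown linkage group {lg}")
        for lg, pos in self.marker_positions:
            if lg not in lengths:
                raise ConfigError(f"marker on unknown linkage group {lg}")
            if not (0 <= pos < lengths[lg]):
                raise ConfigError(f"marker position {pos} outside {lg}")

    @property
    def lg_lengths(self) -> dict[str, int]:
        return dict(self.linkage_groups)

    def chromosomes(self) -> list[tuple[str, tuple[str, ...]]]:
        """Physical chromosomes as (chrom_id, constituent LGs in order)."""
        fused_members = {lg for _, pair in self.fusions for lg in pair}
        out = [(cid, tuple(pair)) for cid, pair in self.fusions]
        out.extend((lg, (lg,)) for lg, _ in self.linkage_groups if lg not in fused_members)
        return out

    def chrom_of(self, lg: str) -> str:
        for cid, members in self.chromosomes():
            if lg in members:
                return cid
        raise KeyError(lg)

    def chrom_pos(self, lg: str, pos: int) -> tuple[str, int]:
        """Map an (LG, position) to (chromosome, position on the chromosome)."""
        lengths = self.lg_lengths
        for cid, members in self.chromosomes():
            if lg in members:
                offset = 0
                for m in members:
                    if m == lg:
                        return cid, offset + pos
                    offset += lengths[m]
        raise KeyError(lg)

    def chrom_length(self, chrom_id: str) -> int:
        lengths = self.lg_lengths
        for cid, members in self.chromosomes():
            if cid == chrom_id:
                return sum(lengths[m] for m in members)
        raise KeyError(chrom_id)


def default_layout(
    n_lgs: int = 3,
    lg_length: int = 30_000_000,
    fusion: Optional[tuple[str, str]] = None,
    markers_per_lg: int = 0,
    seed: Optional[int] = None,
) -> GenomeLayout:
    """Convenience layout: equal-length LGs, optional single fusion, evenly
    spaced markers (or uniform-random if a seed is given)."""
    lgs = tuple((f"LG{i+1}", lg_length) for i in range(n_lgs))
    fusions = ()
    if fusion is not None:
        a, b = fusion
        fusions = ((f"{a}-{b.replace('LG','')}", (a, b)),)
    positions: list[tuple[str, int]] = []
    if markers_per_lg:
        rng = np.random.default_rng(seed) if seed is not None else None
        for lg, L in lgs:
            if rng is None:
                pts = np.linspace(0, L - 1, markers_per_lg + 2)[1:-1].astype(int)
            else:
                pts = np.sort(rng.integers(0, L, markers_per_lg))
            positions.extend((lg, int(p)) for p in pts)
    return GenomeLayout(lgs, fusions, tuple(positions))


# ---------------------------------------------------------------------------
# sex determination model


@dataclass(frozen=True)
class SDLocus:
    """A segregating sex-determination allele carried het by one parent.

    ``background`` is the allele filling the other three parental slots at
    the locus: ``"-"`` (no sex-determining activity, the default) gives the
    plain heterozygous-carrier configuration; ``"Y"`` puts the carried
    allele on a homozygous-Y background, the single-locus X/Y/W
    configuration of platyfish-style systems — a dam carrying W with
    background Y is W/Y, the sire Y/Y, so non-W offspring are Y/Y males
    and the family segregates 1:1, while the sire is structurally
    uninformative at the locus (the pattern seen in ZW families).
    """

    lg: str
    position: int
    allele: str  # "Y" or "W"
    carrier_parent: str  # "sire" or "dam"
    background: str = "-"

    def __post_init__(self):
        if self.allele not in ("Y", "W"):
            raise ConfigError("SD allele must be Y or W")
        if self.carrier_parent not in ("sire", "dam"):
            raise ConfigError("carrier_parent must be sire or dam")
        if self.background not in ("-", "Y", "W"):
            raise ConfigError("background must be '-', 'Y' or 'W'")


def zw_locus(lg: str, position: int) -> SDLocus:
    """A maternal W on a homozygous-Y background (classifiable ZW family)."""
    return SDLocus(lg, position, "W", "dam", background="Y")


@dataclass(frozen=True)
class SexDeterminationModel:
    """SD loci plus penetrance; default sex (no SD allele) is female."""

    loci: tuple[SDLocus, ...] = ()
    penetrance: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.penetrance <= 1.0):
            raise ConfigError("penetrance must be in (0, 1]")
        pos = [(l.lg, l.position) for l in self.loci]
        if len(set(pos)) != len(pos):
            raise ConfigError("two SD loci at the same position")


def assign_sex(carried_alleles) -> str:
    """Genotypic sex from the multiset of carried SD alleles.

    W is epistatic over Y (any W -> female); otherwise any Y -> male;
    no SD allele -> female.  This hierarchy makes a cross segregating both
    a paternal Y and a maternal W produce a 1:3 male:female expectation.
    """
    alleles = list(carried_alleles)
    if "W" in alleles:
        return "F"
    if "Y" in alleles:
        return "M"
    return "F"


# ---------------------------------------------------------------------------
# meiosis


def simulate_gamete(
    parent_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
    locus_positions: dict[str, np.ndarray],
    chrom_morgans: dict[str, float],
    rng,
) -> dict[str, np.ndarray]:
    """One recombinant haplotype per physical chromosome.

    ``parent_haplotypes[chrom]`` holds the parent's two allele vectors over
    that chromosome's loci, whose map positions (Morgans) are
    ``locus_positions[chrom]``.  Crossover count ~ Poisson(map length),
    positions uniform (Haldane, no interference); the starting haplotype is
    chosen equiprobably.  A fused chromosome is a single unit here, so its
    constituent LGs' markers co-segregate.
    """
    rng = _rng(rng)
    gamete = {}
    for chrom, (hap0, hap1) in parent_haplotypes.items():
        L = chrom_morgans[chrom]
        pos = locus_positions[chrom]
        n_xo = rng.poisson(L) if L > 0 else 0
        current = int(rng.integers(2))
        if n_xo == 0:
            gamete[chrom] = (hap0 if current == 0 else hap1).copy()
            continue
        xo = np.sort(rng.uniform(0.0, L, n_xo))
        # phase at each locus = start phase + number of crossovers to its left
        flips = np.searchsorted(xo, pos)
        phase = (current + flips) % 2
        gamete[chrom] = np.where(phase == 0, hap0, hap1)
    return gamete


# ---------------------------------------------------------------------------
# family simulation


@dataclass(frozen=True)
class MarkerSpec:
    """Marker density and founder-allele model for simulated crosses.

    SNP founder allele frequencies are Beta(2, 2) draws (an intermediate-
    frequency-biased spectrum that still yields uninformative markers); SSR
    founder alleles are drawn uniformly from 4-8 equifrequent labels.
    """

    markers_per_lg: int = 20
    ssr_fraction: float = 0.2
    snp_beta: tuple[float, float] = (2.0, 2.0)
    ssr_allele_range: tuple[int, int] = (4, 8)


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    genotypic_sex: dict[str, str]
    phenotypic_sex: dict[str, str]
    sex_reversed: dict[str, bool]
    carried_sd_alleles: dict[str, tuple[str, ...]]
    sd_loci: tuple[SDLocus, ...]
    # per offspring, per chromosome: transmitted haplotype vectors (sire, dam)
    transmitted: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)


def _chrom_loci(layout: GenomeLayout, markers: Sequence[Marker], sd_loci: Sequence[SDLocus]):
    """Order markers + SD loci along each physical chromosome.

    Returns (per-chrom locus id lists, per-chrom map positions in Morgans,
    per-chrom map lengths).  Marker ids double as locus ids; SD loci get
    synthetic ids ``__sd<i>``.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {cid: [] for cid, _ in layout.chromosomes()}
    for m in markers:
        cid, cpos = layout.chrom_pos(m.scaffold, m.position)
        by_chrom[cid].append((cpos, m.id))
    for i, locus in enumerate(sd_loci):
        cid, cpos = layout.chrom_pos(locus.lg, locus.position)
        by_chrom[cid].append((cpos, f"__sd{i}"))
    locus_ids: dict[str, list[str]] = {}
    positions: dict[str, np.ndarray] = {}
    morgans: dict[str, float] = {}
    for cid in by_chrom:
        entries = sorted(by_chrom[cid])
        locus_ids[cid] = [lid for _, lid in entries]
        positions[cid] = np.array([p for p, _ in entries], dtype=float) * layout.morgans_per_bp
        morgans[cid] = layout.chrom_length(cid) * layout.morgans_per_bp
    return locus_ids, positions, morgans


def make_markers(layout: GenomeLayout, spec: MarkerSpec, rng) -> list[Marker]:
    """Build the marker panel implied by a layout and marker spec.

    Positions come from ``layout.marker_positions`` when given, else
    ``spec.markers_per_lg`` evenly spaced markers per LG.  A shared panel
    lets several simulated families be merged into one genotype matrix.
    """
    positions = list(layout.marker_positions)
    if not positions:
        for lg, L in layout.linkage_groups:
            pts = np.linspace(0, L - 1, spec.markers_per_lg + 2)[1:-1].astype(int)
            positions.extend((lg, int(p)) for p in pts)
    markers = []
    for lg, pos in positions:
        is_ssr = rng.random() < spec.ssr_fraction
        mid = f"{lg}_{pos}"
        if is_ssr:
            k = int(rng.integers(spec.ssr_allele_range[0], spec.ssr_allele_range[1] + 1))
            alleles = tuple(str(120 + 2 * i) for i in range(k))  # fragment lengths
            markers.append(Marker(mid, scaffold=lg, position=pos, kind=SSR, alleles=alleles))
        else:
            markers.append(Marker(mid, scaffold=lg, position=pos, kind=SNP, alleles=("A", "B")))
    return markers


def _founder_haplotypes(markers, sd_loci, locus_ids, spec, carrier: str, rng):
    """Two allele vectors per chromosome for one founder.

    The carrier parent holds each of its SD alleles on haplotype 0 of the
    relevant chromosome ('-' marks the non-determining allele elsewhere).
    """
    marker_by_id = {m.id: m for m in markers}
    freqs = {}
    for m in markers:
        if m.kind == SNP:
            freqs[m.id] = rng.beta(*spec.snp_beta)
    haps = {}
    for cid, lids in locus_ids.items():
        h0, h1 = [], []
        for lid in lids:
            if lid.startswith("__sd"):
                locus = sd_loci[int(lid[4:])]
                if locus.carrier_parent == carrier:
                    h0.append(locus.allele)
                    h1.append(locus.background)
                else:
                    h0.append(locus.background)
                    h1.append(locus.background)
            else:
                m = marker_by_id[lid]
                if m.kind == SNP:
                    p = freqs[m.id]
                    h0.append(m.alleles[0] if rng.random() < p else m.alleles[1])
                    h1.append(m.alleles[0] if rng.random() < p else m.alleles[1])
                else:
                    h0.append(m.alleles[int(rng.integers(len(m.alleles)))])
                    h1.append(m.alleles[int(rng.integers(len(m.alleles)))])
        haps[cid] = (np.array(h0, dtype=object), np.array(h1, dtype=object))
    return haps


def simulate_family(
    layout: GenomeLayout,
    sd_model: SexDeterminationModel,
    n_offspring: int,
    marker_spec: Optional[MarkerSpec] = None,
    seed: Union[int, np.random.Generator, None] = None,
    family_id: str = "fam1",
    markers: Optional[list[Marker]] = None,
) -> tuple[GenotypeMatrix, Family, SimTruth]:
    """Simulate one sire x dam cross with genotypes, sexes and ground truth.

    Founder parents are heterozygous carriers of the SD alleles assigned to
    them; offspring genotypes come from two independent Haldane meioses.
    Phenotypic sex equals genotypic sex (``assign_sex`` over carried SD
    alleles) flipped with probability 1 - penetrance.  Pass ``markers``
    (from :func:`make_markers`) to type several families at one panel.
    """
    if n_offspring < 1:
        raise ConfigError("n_offspring must be >= 1")
    for locus in sd_model.loci:
        if locus.lg not in layout.lg_lengths:
            raise ConfigError(f"SD locus on unknown linkage group {locus.lg}")
    rng = _rng(seed)
    spec = marker_spec or MarkerSpec()
    if markers is None:
        markers = make_markers(layout, spec, rng)
    locus_ids, positions, morgans = _chrom_loci(layout, markers, sd_model.loci)

    sire_id, dam_id = f"{family_id}_sire", f"{family_id}_dam"
    sire_haps = _founder_haplotypes(markers, sd_model.loci, locus_ids, spec, "sire", rng)
    dam_haps = _founder_haplotypes(markers, sd_model.loci, locus_ids, spec, "dam", rng)

    off_ids = [f"{family_id}_o{i+1}" for i in range(n_offspring)]
    matrix = GenotypeMatrix(markers, [sire_id, dam_id] + off_ids)
    truth = SimTruth({}, {}, {}, {}, sd_model.loci)

    # parents' own genotypes
    def _fill(ind, haps):
        for cid, lids in locus_ids.items():
            h0, h1 = haps[cid] if isinstance(haps[cid], tuple) else (haps[cid], haps[cid])
            for k, lid in enumerate(lids):
                if lid.startswith("__sd"):
                    continue
                matrix.set_call(ind, lid, GenotypeCall(str(h0[k]), str(h1[k])))

    _fill(sire_id, sire_haps)
    _fill(dam_id, dam_haps)

    offspring = []
    for oid in off_ids:
        gam_s = simulate_gamete(sire_haps, positions, morgans, rng)
        gam_d = simulate_gamete(dam_haps, positions, morgans, rng)
        carried = []
        for cid, lids in locus_ids.items():
            for k, lid in enumerate(lids):
                if lid.startswith("__sd"):
                    for g in (gam_s, gam_d):
                        if g[cid][k] != "-":
                            carried.append(str(g[cid][k]))
                else:
                    matrix.set_call(oid, lid, GenotypeCall(str(gam_s[cid][k]), str(gam_d[cid][k])))
        gsex = assign_sex(carried)
        reversed_ = rng.random() > sd_model.penetrance
        psex = ("F" if gsex == "M" else "M") if reversed_ else gsex
        truth.genotypic_sex[oid] = gsex
        truth.phenotypic_sex[oid] = psex
        truth.sex_reversed[oid] = reversed_
        truth.carried_sd_alleles[oid] = tuple(carried)
        truth.transmitted[oid] = {cid: (gam_s[cid], gam_d[cid]) for cid in locus_ids}
        offspring.append((oid, psex))

    family = Family(family_id, sire_id, dam_id, tuple(offspring))
    return matrix, family, truth


def merge_matrices(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices typed at the same marker panel into one."""
    first = matrices[0]
    ids = [m.id for m in first.markers]
    for mx in matrices[1:]:
        if [m.id for m in mx.markers] != ids:
            raise ConfigError("matrices do not share a marker panel")
    individuals = [ind for mx in matrices for ind in mx.individuals]
    out = GenotypeMatrix(first.markers, individuals)
    row = 0
    for mx in matrices:
        n = len(mx.individuals)
        out._a[row : row + n] = mx._a
        out._b[row : row + n] = mx._b
        out._depth[row : row + n] = mx._depth
        row += n
    return out


def simulate_families(
    layout: GenomeLayout,
    sd_models,
    sizes: Sequence[int],
    marker_spec: Optional[MarkerSpec] = None,
    seed=None,
) -> tuple[GenotypeMatrix, list[Family], list[SimTruth]]:
    """Several independent crosses typed at one shared marker panel.

    ``sd_models`` is either a single :class:`SexDeterminationModel` applied
    to every family or a sequence of per-family models.  Returns the merged
    genotype matrix, the families, and per-family ground truth.
    """
    rng = _rng(seed)
    spec = marker_spec or MarkerSpec()
    markers = make_markers(layout, spec, rng)
    if isinstance(sd_models, SexDeterminationModel):
        sd_models = [sd_models] * len(sizes)
    if len(sd_models) != len(sizes):
        raise ConfigError("one SD model per family required")
    matrices, families, truths = [], [], []
    for i, (model, n) in enumerate(zip(sd_models, sizes)):
        mx, fam, truth = simulate_family(
            layout, model, n, spec, seed=rng, family_id=f"fam{i+1}", markers=markers
        )
        matrices.append(mx)
        families.append(fam)
        truths.append(truth)
    return merge_matrices(matrices), families, truths


# ---------------------------------------------------------------------------
# depth noise


def simulate_depth_noise(matrix: GenotypeMatrix, mean_depth: float, seed=None) -> GenotypeMatrix:
    """Overlay Poisson read depths; zero-depth calls drop to missing.

    Emulates ddRAD-style missingness: a call's stack depth is
    Poisson(mean_depth), and a locus with no reads cannot be called.
    """
    if mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    rng = _rng(seed)
    out = matrix.copy()
    depths = rng.poisson(mean_depth, size=out._depth.shape)
    out._depth = depths.astype(np.int64)
    zero = depths == 0
    out._a[zero] = None
    out._b[zero] = None
    return out


# ---------------------------------------------------------------------------
# scaffolds and window alignments


@dataclass(frozen=True)
class SimScaffold:
    """A scaffold of the fragmented assembly, with its true placement."""

    id: str
    chrom_id: str
    chrom_start: int
    length: int
    orientation: str  # "+" or "-"


def random_scaffolds(
    layout: GenomeLayout,
    mean_length: int = 200_000,
    min_length: int = 20_000,
    seed=None,
) -> list[SimScaffold]:
    """Tile each physical chromosome with random-length scaffolds.

    Lengths are exponential around ``mean_length`` (floored at
    ``min_length``), orientations random; the final scaffold absorbs the
    chromosome remainder.  A scaffold spanning a fusion junction is produced
    whenever a cut does not fall exactly at the junction.
    """
    rng = _rng(seed)
    scaffolds = []
    i = 0
    for cid, _members in layout.chromosomes():
        L = layout.chrom_length(cid)
        start = 0
        while start < L:
            length = int(max(min_length, rng.exponential(mean_length)))
            length = min(length, L - start)
            if L - (start + length) < min_length:
                length = L - start
            scaffolds.append(
                SimScaffold(f"scaf{i}", cid, start, length, "+" if rng.random() < 0.5 else "-")
            )
            start += length
            i += 1
    return scaffolds


def simulate_alignments(
    layout: GenomeLayout,
    scaffolds: Sequence[SimScaffold],
    window: int = 5000,
    noise: float = 0.0,
    identity_range: tuple[float, float] = (0.92, 1.0),
    seed=None,
) -> list[AlignmentRecord]:
    """Window-alignment records for each scaffold against the reference LGs.

    Each scaffold is cut into non-overlapping ``window``-bp windows; a
    window's true target is its position on the reference LG implied by the
    scaffold's placement (fused chromosomes map back to their two
    constituent LGs, so junction-spanning scaffolds hit both).  A ``noise``
    fraction of windows is sent to a uniformly random LG/position instead.
    """
    rng = _rng(seed)
    if any(s.length < window for s in scaffolds):
        raise ConfigError("window larger than shortest scaffold")
    lengths = layout.lg_lengths
    lg_ids = [lg for lg, _ in layout.linkage_groups]
    # chromosome position -> (lg, pos)
    seg: dict[str, list[tuple[str, int, int]]] = {}
    for cid, members in layout.chromosomes():
        offset = 0
        seg[cid] = []
        for m in members:
            seg[cid].append((m, offset, offset + lengths[m]))
            offset += lengths[m]

    def to_lg(cid: str, cpos: int) -> tuple[str, int]:
        for lg, lo, hi in seg[cid]:
            if lo <= cpos < hi:
                return lg, cpos - lo
        raise ValidationError(f"position {cpos} outside chromosome {cid}")

    records = []
    for s in scaffolds:
        n_windows = s.length // window
        for w in range(n_windows):
            wstart, wend = w * window, (w + 1) * window
            if s.orientation == "+":
                cpos = s.chrom_start + wstart
            else:
                cpos = s.chrom_start + (s.length - wend)
            if noise > 0 and rng.random() < noise:
                lg = lg_ids[int(rng.integers(len(lg_ids)))]
                tpos = int(rng.integers(0, lengths[lg] - window + 1))
            else:
                lg, tpos = to_lg(s.chrom_id, cpos)
            records.append(
                AlignmentRecord(
                    scaffold=s.id,
                    window_start=wstart,
                    window_end=wend,
                    target_lg=lg,
                    target_pos=tpos,
                    identity=float(rng.uniform(*identity_range)),
                    n_suboptimal=0,
                    unique=True,
                    scaffold_length=s.length,
                )
            )
    return records


# ---------------------------------------------------------------------------
# scenario driver


def run_scenario(config: dict, seed: int, outdir) -> dict:
    """Simulate a whole scenario described by a plain dict (YAML-friendly).

    Config keys (all optional, with defaults):

    - ``n_lgs``, ``lg_length_bp``, ``fusion`` (pair of LG ids)
    - ``sd_loci``: list of {lg, position, allele, carrier_parent}
    - ``penetrance``
    - ``families``: list of offspring counts
    - ``markers_per_lg``, ``ssr_fraction``
    - ``mean_depth`` (omit for no depth noise)
    - ``alignments``: bool, write window-alignment PAF

    Writes ``genotypes_<fam>.tsv``, ``pedigree.tsv``, ``markers.tsv``,
    ``truth.tsv`` and optionally ``alignments.paf`` under ``outdir``;
    returns the in-memory objects.
    """
    from pathlib import Path

    from .dataio import write_genotypes, write_marker_map, write_paf, write_pedigree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    layout = default_layout(
        n_lgs=config.get("n_lgs", 3),
        lg_length=config.get("lg_length_bp", 30_000_000),
        fusion=tuple(config["fusion"]) if config.get("fusion") else None,
    )
    loci = tuple(
        SDLocus(d["lg"], int(d["position"]), d["allele"], d["carrier_parent"])
        for d in config.get("sd_loci", [])
    )
    model = SexDeterminationModel(loci, float(config.get("penetrance", 1.0)))
    spec = MarkerSpec(
        markers_per_lg=config.get("markers_per_lg", 20),
        ssr_fraction=config.get("ssr_fraction", 0.2),
    )
    fam_sizes = config.get("families", [24])
    seeds = ss.spawn(3)
    matrix, families, truths = simulate_families(
        layout, model, fam_sizes, spec, seed=np.random.default_rng(seeds[0])
    )
    if "mean_depth" in config:
        matrix = simulate_depth_noise(
            matrix, float(config["mean_depth"]), np.random.default_rng(seeds[1])
        )
    write_genotypes(matrix, outdir / "genotypes.tsv", write_depth="mean_depth" in config)
    with open(outdir / "truth.tsv", "w") as tf:
        tf.write("family_id\tindividual_id\tgenotypic_sex\tphenotypic_sex\tsex_reversed\tsd_alleles\n")
        for fam, truth in zip(families, truths):
            for oid in fam.offspring_ids:
                tf.write(
                    f"{fam.family_id}\t{oid}\t{truth.genotypic_sex[oid]}\t"
                    f"{truth.phenotypic_sex[oid]}\t{int(truth.sex_reversed[oid])}\t"
                    f"{','.join(truth.carried_sd_alleles[oid]) or '-'}\n"
                )
    write_pedigree(families, outdir / "pedigree.tsv")
    write_marker_map(matrix.markers, outdir / "markers.tsv")
    if config.get("alignments"):
        rng = np.random.default_rng(seeds[2])
        scaffolds = random_scaffolds(layout, seed=rng)
        records = simulate_alignments(layout, scaffolds, seed=rng)
        write_paf(records, outdir / "alignments.paf")
    return {"layout": layout, "families": families, "matrix": matrix, "truths": truths}
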