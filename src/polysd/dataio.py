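"""Genotype, pedigree and alignment I/O plus genotype quality control.

The pipeline works on unphased diploid genotype calls for parents and
offspring of single-pair crosses.  Markers are either biallelic SNPs from
reduced-representation (ddRAD-style) sequencing, which carry a per-call read
depth ("stack depth"), or multi-allelic microsatellites (SSRs), which do not.
Both live in one :class:`GenotypeMatrix`; downstream operations that require
biallelic markers check the marker kind and skip otherwise.

Coordinates are 0-based half-open internally; VCF positions are converted on
input.  The missing-genotype token is ``./.`` in both the TSV dialect and VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = None  #: sentinel for an uncalled allele

SNP = "SNP"
SSR = "SSR"


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


class ParameterError(ValueError):
    """An operation was called with an out-of-range parameter."""


@dataclass(frozen=True)
class Marker:
    """A genetic marker: a biallelic SNP or a multi-allelic SSR.

    ``scaffold``/``position`` locate the marker on the fragmented assembly
    (or directly on a linkage group for simulated data).  ``alleles`` is
    the known allele inventory; it may be shorter than 2 for a SNP whose
    second allele was never observed (operations that need a biallelic
    marker check for exactly 2).
    """

    id: str
    scaffold: str = "."
    position: int = 0
    kind: str = SNP
    alleles: tuple[str, ...] = ()

    def __post_init__(self):
        if self.position < 0:
            raise ValidationError(f"marker {self.id}: negative position")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"marker {self.id}: duplicate allele labels")
        if self.kind == SNP and len(self.alleles) > 2:
            raise ValidationError(
                f"marker {self.id}: SNP cannot have {len(self.alleles)} alleles"
            )


@dataclass(frozen=True)
class GenotypeCall:
    """An unphased diploid call; both alleles set or both missing."""

    allele_a: Optional[str]
    allele_b: Optional[str]
    depth: int = 0

    def __post_init__(self):
        if (self.allele_a is MISSING) != (self.allele_b is MISSING):
            raise ValidationError("half-missing genotype call")
        if self.depth < 0:
            raise ValidationError("negative depth")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is MISSING

    @property
    def is_hom(self) -> bool:
        return (not self.is_missing) and self.allele_a == self.allele_b

    @property
    def alleles(self) -> tuple[str, str]:
        if self.is_missing:
            raise ValidationError("missing call has no alleles")
        return (self.allele_a, self.allele_b)


class GenotypeMatrix:
    """Individuals x markers container of unphased genotype calls.

    Internally two object arrays (one per allele) plus an integer depth
    array; a missing call has ``None`` in both allele slots.  Depth 0 means
    "depth unknown" (the SSR convention) and is exempt from depth-based QC.
    """

    def __init__(self, markers: Sequence[Marker], individuals: Sequence[str]):
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate marker id")
        if len(set(individuals)) != len(individuals):
            raise ValidationError("duplicate individual id")
        self.markers: list[Marker] = list(markers)
        self.individuals: list[str] = list(individuals)
        self._mk_index = {m.id: j for j, m in enumerate(self.markers)}
        self._ind_index = {s: i for i, s in enumerate(self.individuals)}
        n, m = len(self.individuals), len(self.markers)
        self._a = np.full((n, m), None, dtype=object)
        self._b = np.full((n, m), None, dtype=object)
        self._depth = np.zeros((n, m), dtype=np.int64)

    # -- accessors ---------------------------------------------------------

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self._mk_index[marker_id]]

    def call(self, individual: str, marker_id: str) -> GenotypeCall:
        i, j = self._ind_index[individual], self._mk_index[marker_id]
        return GenotypeCall(self._a[i, j], self._b[i, j], int(self._depth[i, j]))

    def set_call(self, individual: str, marker_id: str, call: GenotypeCall) -> None:
        i, j = self._ind_index[individual], self._mk_index[marker_id]
        self._a[i, j] = call.allele_a
        self._b[i, j] = call.allele_b
        self._depth[i, j] = call.depth

    def n_missing(self) -> int:
        return int(np.sum(self._a == None))  # noqa: E711 -- object array scan

    def called_count(self, marker_id: str, individuals: Iterable[str]) -> int:
        j = self._mk_index[marker_id]
        rows = [self._ind_index[s] for s in individuals]
        return int(np.sum(self._a[rows, j] != None))  # noqa: E711

    def copy(self) -> "GenotypeMatrix":
        out = GenotypeMatrix(self.markers, self.individuals)
        out._a = self._a.copy()
        out._b = self._b.copy()
        out._depth = self._depth.copy()
        return out

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._mk_index[mid] for mid in marker_ids]
        out = GenotypeMatrix([self.markers[j] for j in cols], self.individuals)
        out._a = self._a[:, cols].copy()
        out._b = self._b[:, cols].copy()
        out._depth = self._depth[:, cols].copy()
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeMatrix({len(self.individuals)} individuals x "
            f"{len(self.markers)} markers, {self.n_missing()} missing)"
        )


@dataclass(frozen=True)
class Family:
    """One cross: a sire, a dam, and sexed offspring (M/F)."""

    family_id: str
    sire_id: str
    dam_id: str
    offspring: tuple[tuple[str, str], ...]  # (individual_id, sex)

    def __post_init__(self):
        if self.sire_id == self.dam_id:
            raise ValidationError(f"family {self.family_id}: sire == dam")
        ids = [o for o, _ in self.offspring]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"family {self.family_id}: duplicate offspring id")
        if {self.sire_id, self.dam_id} & set(ids):
            raise ValidationError(f"family {self.family_id}: parent listed as offspring")
        for o, sex in self.offspring:
            if sex not in ("M", "F"):
                raise ValidationError(f"family {self.family_id}: offspring {o} has sex {sex!r}")

    @property
    def offspring_ids(self) -> list[str]:
        return [o for o, _ in self.offspring]

    @property
    def n_males(self) -> int:
        return sum(1 for _, s in self.offspring if s == "M")

    @property
    def n_females(self) -> int:
        return sum(1 for _, s in self.offspring if s == "F")

    def sex_of(self, individual: str) -> str:
        for o, s in self.offspring:
            if o == individual:
                return s
        raise KeyError(individual)


@dataclass(frozen=True)
class AlignmentRecord:
    """One window-to-reference alignment (a PAF line).

    A scaffold of the fragmented assembly is cut into fixed-size windows and
    each window is aligned to an anchored reference; ``target_lg`` is the
    reference linkage group the window hit.  ``scaffold_length`` is the full
    query scaffold length (PAF column 2), needed to reflect coordinates on
    minus-orientation scaffolds.
    """

    scaffold: str
    window_start: int
    window_end: int
    target_lg: str
    target_pos: int
    identity: float
    n_suboptimal: int = 0
    unique: bool = True
    scaffold_length: int = 0

    def __post_init__(self):
        if self.window_end <= self.window_start:
            raise ValidationError("window_end must exceed window_start")
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError("identity outside [0, 1]")


# ---------------------------------------------------------------------------
# genotype TSV


def _parse_gt_token(token: str) -> Optional[tuple[str, str]]:
    """``A/C`` -> ("A", "C"); ``./.`` -> None; malformed -> raises."""
    if token == "./.":
        return None
    parts = token.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise FormatError(f"bad genotype token {token!r}")
    return (parts[0], parts[1])


def read_genotypes(path, format: str = "tsv", marker_map: Optional[dict] = None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or minimal VCF.

    TSV dialect: header ``individual<TAB>marker1<TAB>...``, cells ``A/C`` or
    ``./.``.  A parallel ``<stem>.depth.tsv`` file with the same shape, when
    present, supplies integer read depths.  Unparseable genotype cells become
    missing; the count is logged as a warning.

    ``marker_map`` optionally maps marker id -> :class:`Marker` (e.g. from
    :func:`read_marker_map`) to attach scaffold/position/kind metadata.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format != "tsv":
        raise ParameterError(f"unknown format {format!r}")

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "individual":
        raise FormatError(f"{path}: line 1: malformed header (expected 'individual<TAB>markers...')")
    marker_ids = header[1:]
    if len(set(marker_ids)) != len(marker_ids):
        raise ValidationError(f"{path}: duplicate marker id in header")

    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}")
        rows.append(cells)

    individuals = [r[0] for r in rows]
    # allele inventory per marker (observed), used when no marker map given
    observed: dict[str, set] = {mid: set() for mid in marker_ids}
    parsed: list[list[Optional[tuple[str, str]]]] = []
    n_bad = 0
    for cells in rows:
        prow = []
        for mid, token in zip(marker_ids, cells[1:]):
            try:
                gt = _parse_gt_token(token)
            except FormatError:
                n_bad += 1
                gt = None
            if gt is not None:
                observed[mid].update(gt)
            prow.append(gt)
        parsed.append(prow)
    if n_bad:
        logger.warning("%s: %d unparseable genotype cells set to missing", path, n_bad)

    markers = []
    for mid in marker_ids:
        if marker_map and mid in marker_map:
            m = marker_map[mid]
            if not m.alleles:
                alleles = tuple(sorted(observed[mid]))
                m = replace(m, alleles=alleles, kind=_infer_kind(alleles, m.kind))
            markers.append(m)
        else:
            alleles = tuple(sorted(observed[mid]))
            markers.append(Marker(mid, alleles=alleles, kind=_infer_kind(alleles, SNP)))

    matrix = GenotypeMatrix(markers, individuals)
    depth = _read_depth_sidecar(path, individuals, marker_ids)
    for i, ind in enumerate(individuals):
        for j, mid in enumerate(marker_ids):
            gt = parsed[i][j]
            d = depth[i][j] if depth is not None else 0
            if gt is None:
                matrix.set_call(ind, mid, GenotypeCall(MISSING, MISSING, d))
            else:
                matrix.set_call(ind, mid, GenotypeCall(gt[0], gt[1], d))
    return matrix


def _infer_kind(alleles: tuple, declared: str) -> str:
    if declared == SSR:
        return SSR
    return SNP if len(alleles) <= 2 else SSR


def _depth_path(path: Path) -> Path:
    return path.with_suffix(".depth.tsv") if path.suffix == ".tsv" else Path(str(path) + ".depth.tsv")


def _read_depth_sidecar(path: Path, individuals, marker_ids):
    dpath = _depth_path(path)
    if not dpath.exists():
        return None
    with open(dpath) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header[1:] != list(marker_ids):
        raise FormatError(f"{dpath}: marker columns disagree with {path}")
    out = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        out.append([int(c) for c in cells[1:]])
    if [ln.split("\t")[0] for ln in lines[1:]] != list(individuals):
        raise FormatError(f"{dpath}: individual rows disagree with {path}")
    return out


def write_genotypes(matrix: GenotypeMatrix, path, write_depth: bool = False) -> None:
    """Write the TSV dialect read by :func:`read_genotypes` (canonical form)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(matrix.marker_ids) + "\n")
        for ind in matrix.individuals:
            cells = []
            for mid in matrix.marker_ids:
                c = matrix.call(ind, mid)
                cells.append("./." if c.is_missing else f"{c.allele_a}/{c.allele_b}")
            fh.write(ind + "\t" + "\t".join(cells) + "\n")
    if write_depth:
        with open(_depth_path(path), "w") as fh:
            fh.write("individual\t" + "\t".join(matrix.marker_ids) + "\n")
            for ind in matrix.individuals:
                ds = [str(matrix.call(ind, mid).depth) for mid in matrix.marker_ids]
                fh.write(ind + "\t" + "\t".join(ds) + "\n")


# ---------------------------------------------------------------------------
# VCF


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    markers: list[Marker] = []
    records = []
    seen = set()
    for rec in vf:
        mid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        if mid in seen:
            raise ValidationError(f"{path}: duplicate marker id {mid}")
        seen.add(mid)
        alleles = tuple(rec.alleles)
        kind = SNP if len(alleles) == 2 and all(len(a) == 1 for a in alleles) else SSR
        markers.append(Marker(mid, scaffold=rec.chrom, position=rec.pos - 1, kind=kind, alleles=alleles))
        records.append(rec)
    matrix = GenotypeMatrix(markers, individuals)
    for m, rec in zip(markers, records):
        for ind in individuals:
            s = rec.samples[ind]
            gt = s.get("GT")
            dp = s.get("DP") or 0
            if gt is None or any(g is None for g in gt) or len(gt) != 2:
                matrix.set_call(ind, m.id, GenotypeCall(MISSING, MISSING, int(dp)))
            else:
                matrix.set_call(
                    ind, m.id, GenotypeCall(rec.alleles[gt[0]], rec.alleles[gt[1]], int(dp))
                )
    return matrix


# ---------------------------------------------------------------------------
# pedigree and marker map


def read_pedigree(path) -> list[Family]:
    """Read families from a TSV with columns family_id, individual_id, role, sex.

    ``role`` is sire/dam/offspring; parental sex entries are ignored (roles
    imply them).  Row order within the file is irrelevant.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    required = ["family_id", "individual_id", "role", "sex"]
    if header[: len(required)] != required:
        raise FormatError(f"{path}: line 1: expected columns {required}")
    fams: dict[str, dict] = {}
    order: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) < 4:
            raise FormatError(f"{path}: line {lineno}: expected 4 columns")
        fid, ind, role, sex = cells[:4]
        rec = fams.setdefault(fid, {"sire": None, "dam": None, "off": []})
        if fid not in order:
            order.append(fid)
        if role == "sire":
            rec["sire"] = ind
        elif role == "dam":
            rec["dam"] = ind
        elif role == "offspring":
            if sex not in ("M", "F"):
                raise ValidationError(f"{path}: line {lineno}: offspring sex must be M or F")
            rec["off"].append((ind, sex))
        else:
            raise FormatError(f"{path}: line {lineno}: unknown role {role!r}")
    out = []
    for fid in order:
        rec = fams[fid]
        if rec["sire"] is None or rec["dam"] is None:
            raise ValidationError(f"family {fid}: missing a parent")
        if not rec["off"]:
            raise ValidationError(f"family {fid}: zero offspring")
        out.append(Family(fid, rec["sire"], rec["dam"], tuple(rec["off"])))
    return out


def write_pedigree(families: Iterable[Family], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tindividual_id\trole\tsex\n")
        for fam in families:
            fh.write(f"{fam.family_id}\t{fam.sire_id}\tsire\tNA\n")
            fh.write(f"{fam.family_id}\t{fam.dam_id}\tdam\tNA\n")
            for ind, sex in fam.offspring:
                fh.write(f"{fam.family_id}\t{ind}\toffspring\t{sex}\n")


def read_marker_map(path) -> dict[str, Marker]:
    """Read ``marker, scaffold, position, kind`` TSV into a marker-id map."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header[:4] != ["marker", "scaffold", "position", "kind"]:
        raise FormatError(f"{path}: line 1: expected marker/scaffold/position/kind")
    out: dict[str, Marker] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        mid, scaf, pos, kind = ln.split("\t")[:4]
        if mid in out:
            raise ValidationError(f"{path}: line {lineno}: duplicate marker id {mid}")
        out[mid] = Marker(mid, scaffold=scaf, position=int(pos), kind=kind)
    return out


def write_marker_map(markers: Iterable[Marker], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tscaffold\tposition\tkind\n")
        for m in markers:
            fh.write(f"{m.id}\t{m.scaffold}\t{m.position}\t{m.kind}\n")


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    matrix: GenotypeMatrix,
    offspring_ids: Sequence[str],
    min_called: int,
    min_hom_depth: int,
) -> GenotypeMatrix:
    """Apply the two-stage genotype QC used on reduced-representation calls.

    Homozygous calls supported by fewer than ``min_hom_depth`` reads are set
    to missing (a single read stack cannot exclude a dropped allele);
    heterozygous calls are never depth-masked, and calls with depth 0
    ("depth unknown", e.g. SSRs) are exempt.  Markers then called in fewer
    than ``min_called`` of the listed offspring are dropped entirely.
    Idempotent, and never turns a missing call into a called one.
    """
    if min_called < 0:
        raise ParameterError("min_called must be >= 0")
    if min_called > len(offspring_ids):
        raise ParameterError("min_called exceeds number of offspring")
    out = matrix.copy()
    hom = (out._a != None) & (out._a == out._b)  # noqa: E711
    mask = hom & (out._depth > 0) & (out._depth < min_hom_depth)
    out._a[mask] = None
    out._b[mask] = None
    keep = [
        mid for mid in out.marker_ids if out.called_count(mid, offspring_ids) >= min_called
    ]
    if len(keep) != len(out.marker_ids):
        logger.info("qc_filter: dropped %d markers below call-rate threshold", len(out.marker_ids) - len(keep))
    return out.subset_markers(keep)


# ---------------------------------------------------------------------------
# PAF


def parse_alignments(path, suboptimal_tag: str = "s2") -> list[AlignmentRecord]:
    """Parse window alignments from PAF.

    Identity is ``(block_len - NM) / block_len`` when an ``NM:i`` tag is
    present, else ``matches / block_len`` from the mandatory columns.  The
    suboptimal-hit count is taken from the integer tag named by
    ``suboptimal_tag`` (default ``s2``, a common proxy; aligners differ, so
    the tag is overrideable), defaulting to 0 when absent.  A window is
    "unique" when mapping quality (column 12) is positive.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            cols = ln.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}: line {lineno}: PAF needs 12 mandatory columns")
            qname, qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            tname, tstart = cols[5], int(cols[7])
            matches, blocklen, mapq = int(cols[9]), int(cols[10]), int(cols[11])
            tags = {}
            for t in cols[12:]:
                parts = t.split(":", 2)
                if len(parts) == 3 and parts[1] == "i":
                    tags[parts[0]] = int(parts[2])
            if "NM" in tags and blocklen > 0:
                identity = max(0.0, (blocklen - tags["NM"]) / blocklen)
            else:
                identity = matches / blocklen if blocklen else 0.0
            records.append(
                AlignmentRecord(
                    scaffold=qname,
                    window_start=qstart,
                    window_end=qend,
                    target_lg=tname,
                    target_pos=tstart,
                    identity=identity,
                    n_suboptimal=tags.get(suboptimal_tag, 0),
                    unique=mapq > 0,
                    scaffold_length=qlen,
                )
            )
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    """Write records as minimal PAF (strand '+', NM from identity)."""
    with open(path, "w") as fh:
        for r in records:
            blocklen = r.window_end - r.window_start
            matches = round(r.identity * blocklen)
            mapq = 60 if r.unique else 0
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.scaffold, r.scaffold_length, r.window_start, r.window_end,
                        "+", r.target_lg, 0, r.target_pos, r.target_pos + blocklen,
                        matches, blocklen, mapq, f"s2:i:{r.n_suboptimal}",
                    )
                )
                + "\n"
            )
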