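"""Reading and writing the formats the pipeline touches.

The pipeline consumes variant tables in a minimal VCF 4.2 dialect (CHROM,
POS, REF, ALT and per-sample ``DP``/``AD`` FORMAT fields), mapped-region
intervals in BED3, gene models in GFF3 and a sample manifest in TSV, and
presents them through a uniform in-memory genotype matrix.  Only DP and AD
are interpreted; every other INFO/FORMAT key is ignored.  Multi-allelic
sites are split into biallelic records on read and merged back on write.
"""

from __future__ import annotations

import dataclasses
from bisect import insort
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

import gffutils

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "AnnotationIndex",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_annotation",
    "read_bed",
    "write_bed",
    "write_gff3",
    "read_manifest",
    "write_manifest",
]

#: key identifying one biallelic site: (chromosome, position, ref, alt)
SiteKey = tuple[str, int, str, str]

MANIFEST_ROLES = ("parentA", "parentB", "f1", "control", "mutant", "progeny")


class VcfParseError(ValueError):
    """Raised on malformed VCF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One biallelic site observed in one sample.

    ``position`` is 1-based (VCF convention).  ``allele_depths`` is the
    (ref, alt) read support; its sum may be below ``depth`` when reads
    support neither allele of this biallelic record.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    sample: str
    depth: int
    allele_depths: tuple[int, int]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")
        if self.depth < 0 or min(self.allele_depths) < 0:
            raise ValueError("read depths must be non-negative")
        if sum(self.allele_depths) > self.depth:
            raise ValueError(
                f"allele depths {self.allele_depths} exceed total depth {self.depth} "
                f"at {self.chromosome}:{self.position}"
            )

    @property
    def site(self) -> SiteKey:
        return (self.chromosome, self.position, self.ref, self.alt)

    def allele_fraction(self, allele: str) -> float:
        """Fraction of allele-supporting reads carrying ``allele``."""
        ref_d, alt_d = self.allele_depths
        total = ref_d + alt_d
        if total == 0:
            return float("nan")
        if allele == self.ref:
            return ref_d / total
        if allele == self.alt:
            return alt_d / total
        raise ValueError(
            f"allele {allele!r} is neither ref {self.ref!r} nor alt {self.alt!r}"
        )


class GenotypeMatrix:
    """Sparse site x sample matrix of :class:`VariantRecord` cells.

    Sites are kept sorted by (chromosome, position, ref, alt); a missing
    cell means the sample was not covered at that site (never a zero-depth
    record).
    """

    def __init__(self, samples: Iterable[str] = ()):
        self.samples: list[str] = list(samples)
        self._cells: dict[SiteKey, dict[str, VariantRecord]] = {}
        self._sites: list[SiteKey] = []

    @property
    def sites(self) -> list[SiteKey]:
        return self._sites

    @property
    def n_sites(self) -> int:
        return len(self._sites)

    def add(self, record: VariantRecord) -> None:
        if record.sample not in self.samples:
            self.samples.append(record.sample)
        site = record.site
        cell_row = self._cells.get(site)
        if cell_row is None:
            cell_row = self._cells[site] = {}
            insort(self._sites, site)
        cell_row[record.sample] = record

    def get(self, site: SiteKey, sample: str) -> VariantRecord | None:
        return self._cells.get(site, {}).get(sample)

    def row(self, site: SiteKey) -> dict[str, VariantRecord]:
        return self._cells.get(site, {})

    def records(self) -> Iterator[VariantRecord]:
        for site in self._sites:
            yield from self._cells[site].values()

    def __len__(self) -> int:
        return sum(len(r) for r in self._cells.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self._sites == other._sites
            and self._cells == other._cells
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_COLUMNS = [
    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF 4.2 file into a :class:`GenotypeMatrix`.

    Multi-allelic sites are split into biallelic records sharing the
    position.  A sample cell of ``.`` (or DP of ``.``) is treated as
    uncovered and produces no record.
    """
    path = Path(path)
    matrix: GenotypeMatrix | None = None
    saw_fileformat = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1:
                    if not line.startswith("##fileformat=VCF"):
                        raise VcfParseError(
                            "missing ##fileformat=VCFv4.x header", lineno
                        )
                    saw_fileformat = True
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if fields[: len(_VCF_HEADER_COLUMNS)] != _VCF_HEADER_COLUMNS:
                    raise VcfParseError(
                        f"malformed column header: {fields[:9]}", lineno
                    )
                matrix = GenotypeMatrix(fields[len(_VCF_HEADER_COLUMNS):])
                continue
            if not saw_fileformat:
                raise VcfParseError("missing ##fileformat=VCFv4.x header", 1)
            if matrix is None:
                raise VcfParseError("data line before #CHROM header", lineno)
            _parse_vcf_data_line(line, lineno, matrix)
    if matrix is None:
        raise VcfParseError("no #CHROM header found in file", None)
    return matrix


def _parse_vcf_data_line(line: str, lineno: int, matrix: GenotypeMatrix) -> None:
    fields = line.split("\t")
    if len(fields) != 9 + len(matrix.samples):
        raise VcfParseError(
            f"expected {9 + len(matrix.samples)} columns, found {len(fields)}",
            lineno,
        )
    chrom, pos_s, _id, ref, alt_s, _qual, _filt, _info, fmt = fields[:9]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfParseError(f"non-integer POS {pos_s!r}", lineno) from None
    fmt_keys = fmt.split(":")
    try:
        dp_idx = fmt_keys.index("DP")
        ad_idx = fmt_keys.index("AD")
    except ValueError:
        raise VcfParseError(f"FORMAT {fmt!r} lacks DP or AD", lineno) from None
    alts = alt_s.split(",")
    for sample, cell in zip(matrix.samples, fields[9:]):
        if cell == "." or cell.startswith("./."):
            continue
        parts = cell.split(":")
        if len(parts) != len(fmt_keys):
            raise VcfParseError(
                f"sample {sample}: cell {cell!r} does not match FORMAT {fmt!r}",
                lineno,
            )
        if parts[dp_idx] == "." or parts[ad_idx] == ".":
            continue
        try:
            depth = int(parts[dp_idx])
            ad = [int(x) for x in parts[ad_idx].split(",")]
        except ValueError:
            raise VcfParseError(
                f"sample {sample}: non-integer DP/AD in {cell!r}", lineno
            ) from None
        if len(ad) != 1 + len(alts):
            raise VcfParseError(
                f"sample {sample}: AD has {len(ad)} values for {len(alts)} ALT "
                "allele(s)",
                lineno,
            )
        if sum(ad) > depth:
            raise VcfParseError(
                f"sample {sample}: AD {ad} exceeds DP {depth}", lineno
            )
        for alt, alt_depth in zip(alts, ad[1:]):
            matrix.add(
                VariantRecord(
                    chromosome=chrom,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    sample=sample,
                    depth=depth,
                    allele_depths=(ad[0], alt_depth),
                )
            )


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as minimal VCF 4.2 (FORMAT ``DP:AD``).

    Biallelic records sharing (chromosome, position, ref) are merged back
    into one multi-allelic line, the inverse of the read-time split.
    Refuses unsorted site lists, naming the first violation.
    """
    prev: SiteKey | None = None
    for site in matrix.sites:
        if prev is not None and site < prev:
            raise ValueError(
                f"sites are not sorted: {site} follows {prev}"
            )
        prev = site

    # group consecutive sites by (chrom, pos, ref) for multi-allelic merge
    lines: list[str] = []
    groups: dict[tuple[str, int, str], list[SiteKey]] = {}
    for site in matrix.sites:
        groups.setdefault((site[0], site[1], site[2]), []).append(site)

    for (chrom, pos, ref), sites in groups.items():
        alts = [s[3] for s in sites]
        cells = []
        for sample in matrix.samples:
            recs = [matrix.get(s, sample) for s in sites]
            if all(r is None for r in recs):
                cells.append(".")
                continue
            present = [r for r in recs if r is not None]
            depth = present[0].depth
            ref_depth = present[0].allele_depths[0]
            ad = [ref_depth] + [
                (r.allele_depths[1] if r is not None else 0) for r in recs
            ]
            cells.append(f"{depth}:{','.join(str(x) for x in ad)}")
        row = [chrom, str(pos), ".", ref, ",".join(alts), ".", ".", ".", "DP:AD"]
        lines.append("\t".join(row + cells))

    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n'
        )
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele">\n'
        )
        fh.write("\t".join(_VCF_HEADER_COLUMNS + matrix.samples) + "\n")
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3 / manifest
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based, half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return intervals


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


class AnnotationIndex:
    """Classifies genomic positions as exon, intron or intergenic.

    Positions are 1-based.  A position inside any exon is ``exon``; inside
    a gene but no exon is ``intron``; anywhere else on a known chromosome
    is ``intergenic``.
    """

    def __init__(
        self,
        chromosomes: Iterable[str],
        genes: Iterable[tuple[str, int, int]],
        exons: Iterable[tuple[str, int, int]],
    ):
        self.chromosomes = set(chromosomes)
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        gene_list = list(genes)
        for chrom, start, end in gene_list:
            self.chromosomes.add(chrom)
            # 1-based inclusive -> half-open on 1-based coordinates
            self._gene_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        for chrom, start, end in exons:
            covering = self._gene_trees.get(chrom, IntervalTree())[start]
            if not covering or not any(
                iv.begin <= start and end + 1 <= iv.end for iv in covering
            ):
                raise ValueError(
                    f"exon {chrom}:{start}-{end} lies outside every gene extent"
                )
            self._exon_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    def classify(self, chromosome: str, position: int) -> str:
        if chromosome not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        if self._exon_trees.get(chromosome) and self._exon_trees[chromosome][position]:
            return "exon"
        if self._gene_trees.get(chromosome) and self._gene_trees[chromosome][position]:
            return "intron"
        return "intergenic"


def read_annotation(path: str | Path) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GFF3 file of gene/exon features."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    chromosomes: set[str] = set()
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            chromosomes.add(directive.split()[1])
    genes = [(f.seqid, f.start, f.end) for f in db.features_of_type("gene")]
    exons = [(f.seqid, f.start, f.end) for f in db.features_of_type("exon")]
    return AnnotationIndex(chromosomes, genes, exons)


def write_gff3(
    chrom_lengths: dict[str, int],
    genes: Iterable[tuple[str, int, int, list[tuple[int, int]]]],
    path: str | Path,
) -> None:
    """Write gene models (1-based inclusive, with exon sub-features) as GFF3."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for i, (chrom, start, end, exons) in enumerate(genes, start=1):
            gid = f"gene{i:05d}"
            fh.write(
                f"{chrom}\tirradgbs\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
            )
            for j, (es, ee) in enumerate(exons, start=1):
                fh.write(
                    f"{chrom}\tirradgbs\texon\t{es}\t{ee}\t.\t+\t.\t"
                    f"ID={gid}.exon{j};Parent={gid}\n"
                )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest TSV (columns: sample, role, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "role", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks column(s): {sorted(missing)}")
    bad = set(df["role"]) - set(MANIFEST_ROLES)
    if bad:
        raise ValueError(
            f"unknown role(s) {sorted(bad)}; expected one of {MANIFEST_ROLES}"
        )
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
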