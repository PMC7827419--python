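"""Recombination counting from zygosity switches in backcross progeny.

Marker selection follows the quality cascade of a pooled GBS design: a
SNP is a usable marker when both parental pools are deeply covered and
fixed for different alleles and the F1 pool shows both alleles at a
balanced fraction.  Each progeny line is then genotyped at the markers:
BC1 genotypes are recurrent-homozygous or heterozygous, so the call is
driven by the recurrent-parent allele fraction (exactly 1.0 → HOM,
within the heterozygous band → HET, anything else → MISSING).  A switch
of zygosity between adjacent informative markers evidences a crossover;
a lone marker whose two informative neighbours both disagree with it is
treated as a genotyping error and removed (one simultaneous pass) before
counting.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import pandas as pd

from .variant_io import GenotypeMatrix, VariantRecord

__all__ = [
    "HOM",
    "HET",
    "MISSING",
    "Marker",
    "MarkerSet",
    "ZygosityVector",
    "RecombinationCount",
    "select_markers",
    "call_zygosity",
    "singleton_filter",
    "count_recombination",
    "summarize_line",
    "genotype_line",
    "count_panel",
    "mean_markers_per_chromosome",
]

HOM = "HOM"
HET = "HET"
MISSING = "MISSING"


@dataclasses.dataclass(frozen=True)
class Marker:
    """One informative SNP: parents are fixed for different alleles."""

    chromosome: str
    position: int
    ref: str
    alt: str
    allele_a: str  # recurrent parent (parent A)
    allele_b: str  # donor parent (parent B)

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("parental alleles must differ at a marker")


@dataclasses.dataclass
class MarkerSet:
    """Selected markers, sorted by (chromosome, position)."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        self.markers = sorted(
            self.markers, key=lambda m: (m.chromosome, m.position)
        )

    def __len__(self) -> int:
        return len(self.markers)

    def per_chromosome(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chromosome, []).append(m)
        return out

    def counts(self) -> dict[str, int]:
        return {c: len(ms) for c, ms in self.per_chromosome().items()}


@dataclasses.dataclass
class ZygosityVector:
    """Ordered HOM/HET/MISSING calls of one line along one chromosome."""

    sample: str
    chromosome: str
    calls: list[str]
    positions: list[int] = dataclasses.field(default_factory=list)

    def informative(self) -> "ZygosityVector":
        """Drop MISSING calls; flanking informative markers become adjacent."""
        if not self.positions:
            kept = [c for c in self.calls if c != MISSING]
            return ZygosityVector(self.sample, self.chromosome, kept)
        pairs = [
            (c, p)
            for c, p in zip(self.calls, self.positions)
            if c != MISSING
        ]
        return ZygosityVector(
            self.sample,
            self.chromosome,
            [c for c, _ in pairs],
            [p for _, p in pairs],
        )


@dataclasses.dataclass
class RecombinationCount:
    sample: str
    per_chromosome: dict[str, int]
    total: int
    n_markers_used: int
    n_markers_excluded_singleton: int


def mean_markers_per_chromosome(n_markers: int, n_chromosomes: int) -> float:
    """Average marker count per chromosome (e.g. 1554 over 12 → 129.50)."""
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    return n_markers / n_chromosomes


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def _pooled_allele_depths(
    matrix: GenotypeMatrix, site, pool: Sequence[str]
) -> tuple[int, int, int]:
    """Summed (ref_depth, alt_depth, total_depth) over a sample pool."""
    ref_d = alt_d = total = 0
    for sample in pool:
        rec = matrix.get(site, sample)
        if rec is None:
            continue
        ref_d += rec.allele_depths[0]
        alt_d += rec.allele_depths[1]
        total += rec.depth
    return ref_d, alt_d, total


def select_markers(
    matrix: GenotypeMatrix,
    parent_a_pool: Sequence[str],
    parent_b_pool: Sequence[str],
    f1_pool: Sequence[str],
    min_depth: int = 10,
    f1_af_bounds: tuple[float, float] = (0.25, 0.75),
) -> MarkerSet:
    """Apply the pooled parental/F1 quality cascade.

    Keeps sites where each parental pool reaches ``min_depth`` and every
    read in it supports one allele (the pool is fixed), the parents are
    fixed for different alleles, and the F1 pool carries the donor allele
    at a fraction inside the closed interval ``f1_af_bounds``.
    """
    for name, pool in (
        ("parentA", parent_a_pool),
        ("parentB", parent_b_pool),
        ("f1", f1_pool),
    ):
        if len(pool) == 0:
            raise ValueError(f"{name} pool is empty")
    lo, hi = f1_af_bounds
    markers: list[Marker] = []
    for site in matrix.sites:
        chrom, pos, ref, alt = site
        fixed = []
        ok = True
        for pool in (parent_a_pool, parent_b_pool):
            ref_d, alt_d, total = _pooled_allele_depths(matrix, site, pool)
            if total < min_depth or (ref_d > 0 and alt_d > 0) or ref_d + alt_d == 0:
                ok = False
                break
            fixed.append(ref if ref_d > 0 else alt)
        if not ok or fixed[0] == fixed[1]:
            continue
        ref_d, alt_d, total = _pooled_allele_depths(matrix, site, f1_pool)
        if total < min_depth or ref_d + alt_d == 0:
            continue
        donor_depth = alt_d if fixed[1] == alt else ref_d
        af = donor_depth / (ref_d + alt_d)
        if lo <= af <= hi:
            markers.append(Marker(chrom, pos, ref, alt, fixed[0], fixed[1]))
    return MarkerSet(markers)


# ---------------------------------------------------------------------------
# zygosity calling
# ---------------------------------------------------------------------------

def call_zygosity(
    record: VariantRecord | None,
    recurrent_allele: str,
    min_depth: int = 5,
    het_bounds: tuple[float, float] = (0.25, 0.75),
) -> str:
    """Call one marker in one progeny line from its read support.

    The recurrent-parent allele fraction must be exactly 1.0 for HOM
    (BC1 lines cannot be donor-homozygous) or inside the closed
    heterozygous band for HET; insufficient depth or an out-of-band
    fraction yields MISSING.
    """
    if record is None or record.depth < min_depth:
        return MISSING
    if recurrent_allele not in (record.ref, record.alt):
        raise ValueError(
            f"recurrent allele {recurrent_allele!r} is neither allele of "
            f"{record.chromosome}:{record.position}"
        )
    ref_d, alt_d = record.allele_depths
    if ref_d + alt_d == 0:
        return MISSING
    frac = record.allele_fraction(recurrent_allele)
    if frac == 1.0:
        return HOM
    lo, hi = het_bounds
    if lo <= frac <= hi:
        return HET
    return MISSING


def genotype_line(
    matrix: GenotypeMatrix,
    markers: MarkerSet,
    sample: str,
    min_depth: int = 5,
    het_bounds: tuple[float, float] = (0.25, 0.75),
) -> dict[str, ZygosityVector]:
    """Zygosity vectors of one progeny line over all marker chromosomes."""
    vectors: dict[str, ZygosityVector] = {}
    for chrom, ms in markers.per_chromosome().items():
        calls, positions = [], []
        for m in ms:
            rec = matrix.get((m.chromosome, m.position, m.ref, m.alt), sample)
            calls.append(
                call_zygosity(rec, m.allele_a, min_depth=min_depth,
                              het_bounds=het_bounds)
            )
            positions.append(m.position)
        vectors[chrom] = ZygosityVector(sample, chrom, calls, positions)
    return vectors


# ---------------------------------------------------------------------------
# singleton exclusion and event counting
# ---------------------------------------------------------------------------

def singleton_filter(vector: ZygosityVector) -> tuple[ZygosityVector, int]:
    """Remove lone markers contradicted by both informative neighbours.

    Expects MISSING already dropped (adjacency is over informative calls).
    Every interior call whose two flanking calls both differ from it is
    flagged on the unmodified input and all flagged calls are removed in
    one simultaneous pass; terminal calls are never removed.  Exactly one
    pass is applied — iterating could erode genuine short double-crossover
    tracts.
    """
    calls = vector.calls
    if any(c == MISSING for c in calls):
        raise ValueError("singleton_filter expects MISSING calls to be dropped")
    keep = [True] * len(calls)
    for i in range(1, len(calls) - 1):
        if calls[i - 1] != calls[i] and calls[i + 1] != calls[i]:
            keep[i] = False
    filtered = ZygosityVector(
        vector.sample,
        vector.chromosome,
        [c for c, k in zip(calls, keep) if k],
        [p for p, k in zip(vector.positions, keep) if k]
        if vector.positions
        else [],
    )
    return filtered, keep.count(False)


def count_recombination(vector: ZygosityVector) -> int:
    """Number of adjacent informative marker pairs with unequal zygosity."""
    calls = vector.calls
    if len(calls) == 0:
        warnings.warn(
            f"empty zygosity vector for {vector.sample} {vector.chromosome}",
            stacklevel=2,
        )
        return 0
    if any(c not in (HOM, HET) for c in calls):
        raise ValueError("count_recombination expects only HOM/HET calls")
    return sum(a != b for a, b in zip(calls, calls[1:]))


def summarize_line(
    vectors: Mapping[str, ZygosityVector] | Sequence[ZygosityVector],
) -> RecombinationCount:
    """Per-chromosome counts after singleton filtering; total is their sum."""
    if not isinstance(vectors, Mapping):
        seen: dict[str, ZygosityVector] = {}
        for v in vectors:
            if v.chromosome in seen:
                raise ValueError(f"duplicate vector for chromosome {v.chromosome}")
            seen[v.chromosome] = v
        vectors = seen
    sample = next(iter(vectors.values())).sample if vectors else ""
    per_chrom: dict[str, int] = {}
    used = excluded = 0
    for chrom, vector in vectors.items():
        informative = vector.informative()
        filtered, n_removed = singleton_filter(informative)
        excluded += n_removed
        used += len(filtered.calls)
        per_chrom[chrom] = (
            count_recombination(filtered) if filtered.calls else 0
        )
    return RecombinationCount(
        sample=sample,
        per_chromosome=per_chrom,
        total=sum(per_chrom.values()),
        n_markers_used=used,
        n_markers_excluded_singleton=excluded,
    )


def count_panel(
    matrix: GenotypeMatrix,
    markers: MarkerSet,
    progeny: Sequence[str],
    min_depth: int = 5,
    het_bounds: tuple[float, float] = (0.25, 0.75),
) -> tuple[pd.DataFrame, dict[str, dict[str, ZygosityVector]]]:
    """Genotype and count every progeny line.

    Returns a tidy per-line table (one row per line with per-chromosome
    counts and the total) and the raw zygosity vectors.
    """
    chroms = sorted(markers.per_chromosome())
    rows = []
    all_vectors: dict[str, dict[str, ZygosityVector]] = {}
    for sample in progeny:
        vectors = genotype_line(
            matrix, markers, sample, min_depth=min_depth, het_bounds=het_bounds
        )
        all_vectors[sample] = vectors
        summary = summarize_line(vectors)
        row = {"sample": sample, "total": summary.total,
               "n_markers_used": summary.n_markers_used,
               "n_excluded_singleton": summary.n_markers_excluded_singleton}
        for chrom in chroms:
            row[chrom] = summary.per_chromosome.get(chrom, 0)
        rows.append(row)
    columns = ["sample", "total", "n_markers_used", "n_excluded_singleton"] + chroms
    return pd.DataFrame(rows, columns=columns), all_vectors
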