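"""Synthetic GBS panels with full ground truth.

Emulates the genotype data produced by a reduced-representation
(genotyping-by-sequencing) assay of two pepper-style study designs:

* a mutation panel — non-irradiated control plants plus mutant lines
  carrying induced heterozygous single-base substitutions (six
  strand-collapsed categories with configurable proportions) and 1-2 bp
  InDels at a configurable density per 10 Mb of mapped region;
* a backcross (BC1) panel — two fully homozygous inbred parents, their F1,
  and BC1 progeny whose gametes carry Poisson-distributed crossovers, so
  that zygosity switches along each chromosome record true recombination
  events.

The genome is reduced-representation: only short mapped regions (a
fraction of a percent of a multi-chromosome genome) are observable, and
all variants, injected mutations and markers live inside them.  Per-site
sequencing depth is negative-binomially distributed (GBS coverage is
overdispersed) and reads flip alleles with a configurable error rate.
Every stochastic draw flows from one seeded generator, so a fixed seed
reproduces the dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    AnnotationIndex,
    GenotypeMatrix,
    VariantRecord,
    write_bed,
    write_gff3,
    write_manifest,
    write_vcf,
)

__all__ = [
    "SBS_CATEGORIES",
    "SimConfig",
    "SimulatedGenome",
    "Cross",
    "Gamete",
    "InjectedMutation",
    "TruthSet",
    "SimResult",
    "build_genome",
    "simulate_cross",
    "simulate_meiosis",
    "simulate_bc1_panel",
    "inject_mutations",
    "simulate_observations",
    "simulate_dataset",
    "write_dataset",
]

#: strand-collapsed substitution categories; the first two are transitions.
SBS_CATEGORIES = (
    "A/T>G/C",
    "G/C>A/T",
    "A/T>T/A",
    "A/T>C/G",
    "G/C>T/A",
    "G/C>C/G",
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# ref base choices and the corresponding alt for each category
_CATEGORY_SUBS = {
    "A/T>G/C": {"A": "G", "T": "C"},
    "G/C>A/T": {"G": "A", "C": "T"},
    "A/T>T/A": {"A": "T", "T": "A"},
    "A/T>C/G": {"A": "C", "T": "G"},
    "G/C>T/A": {"G": "T", "C": "A"},
    "G/C>C/G": {"G": "C", "C": "G"},
}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Defaults reproduce the shape of a GBS assay of a large (12 x ~260 Mb)
    genome: ~79,000 mapped regions of ~144 bp mean length (≈11.4 Mb,
    ~0.37% of the genome), mean region depth ~35x, induced-mutation
    density of order 20 per 10 Mb with ~12% small InDels, and a
    pistil-irradiation-like substitution spectrum whose two transition
    categories carry ~69% of substitutions.
    """

    n_chromosomes: int = 12
    chrom_length: int = 260_000_000
    n_regions: int = 79_402
    region_length_mean: float = 144.0
    snp_rate: float = 3e-4
    xo_rate: float = 1.5
    mutation_density: float = 20.0
    sbs_spectrum: tuple[float, ...] = (0.31, 0.38, 0.11, 0.05, 0.11, 0.04)
    indel_fraction: float = 0.12
    depth_mean: float = 35.0
    depth_dispersion: float = 20.0
    genotype_error_rate: float = 0.002
    seed: int = 0
    # gene-model layout (annotation context of mapped regions)
    gene_probability: float = 0.6
    gene_length_mean: float = 4000.0
    exons_per_gene: int = 4
    exon_fraction: float = 0.6
    # panel sizes
    n_controls: int = 4
    n_mutants_per_group: int = 3
    mutant_groups: tuple[str, ...] = ("pistil_60Gy", "pollen_15Gy", "seed_60Gy")
    n_progeny: int = 12

    def __post_init__(self) -> None:
        if len(self.sbs_spectrum) != len(SBS_CATEGORIES):
            raise ValueError(
                f"sbs_spectrum needs {len(SBS_CATEGORIES)} entries, "
                f"got {len(self.sbs_spectrum)}"
            )
        if any(p < 0 for p in self.sbs_spectrum):
            raise ValueError("sbs_spectrum entries must be non-negative")
        if abs(sum(self.sbs_spectrum) - 1.0) > 1e-9:
            raise ValueError(
                f"sbs_spectrum must sum to 1, sums to {sum(self.sbs_spectrum)}"
            )
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must lie in [0, 1]")
        if self.xo_rate < 0 or self.mutation_density < 0:
            raise ValueError("xo_rate and mutation_density must be >= 0")
        if self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean >= 0 and depth_dispersion > 0 required")
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("genotype_error_rate must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def chromosome_names(self) -> list[str]:
        return [f"chr{i:02d}" for i in range(1, self.n_chromosomes + 1)]


@dataclasses.dataclass
class SimulatedGenome:
    """Reduced-representation genome: chromosomes, mapped regions, gene models.

    ``regions`` are 0-based half-open (BED convention), sorted and
    non-overlapping.  ``genes`` are 1-based inclusive (GFF convention),
    each with its exon sub-intervals.
    """

    chrom_lengths: dict[str, int]
    regions: list[tuple[str, int, int]]
    genes: list[tuple[str, int, int, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        prev: tuple[str, int, int] | None = None
        for chrom, start, end in self.regions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"region on unknown chromosome {chrom!r}")
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(
                    f"region {chrom}:{start}-{end} outside chromosome bounds"
                )
            if prev is not None and prev[0] == chrom and start < prev[2]:
                raise ValueError(
                    f"regions overlap or are unsorted at {chrom}:{start}"
                )
            prev = (chrom, start, end)
        self._build_offset_index()

    def _build_offset_index(self) -> None:
        lengths = np.array([e - s for _, s, e in self.regions], dtype=np.int64)
        self._region_cum = np.concatenate([[0], np.cumsum(lengths)])

    @property
    def mapped_length(self) -> int:
        return int(self._region_cum[-1])

    def offset_to_position(self, offset: int) -> tuple[str, int]:
        """Map a 0-based offset into the concatenated mapped bases to
        (chromosome, 1-based position)."""
        if not 0 <= offset < self.mapped_length:
            raise ValueError(f"offset {offset} outside mapped length")
        idx = int(np.searchsorted(self._region_cum, offset, side="right")) - 1
        chrom, start, _end = self.regions[idx]
        return chrom, start + (offset - int(self._region_cum[idx])) + 1

    def annotation_index(self) -> AnnotationIndex:
        gene_extents = [(c, s, e) for c, s, e, _ in self.genes]
        exons = [(c, es, ee) for c, _, _, ex in self.genes for es, ee in ex]
        return AnnotationIndex(self.chrom_lengths, gene_extents, exons)


@dataclasses.dataclass
class Cross:
    """Informative markers of a biparental cross.

    Per chromosome: sorted 1-based marker positions, ref/alt alleles, and
    which parent carries the alt allele.  Parent A is the recurrent parent
    of the backcross; parent B the donor.  Both parents are fully
    homozygous and the F1 is heterozygous at every marker.
    """

    positions: dict[str, np.ndarray]
    ref: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]
    parent_a_is_alt: dict[str, np.ndarray]

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def chromosomes(self) -> list[str]:
        return list(self.positions)


@dataclasses.dataclass
class Gamete:
    """One meiotic product of the F1: phase per marker and breakpoints.

    ``phase`` holds 0 where the gamete carries the parent-A (recurrent)
    allele and 1 where it carries the parent-B (donor) allele, aligned to
    the cross's marker positions.
    """

    phase: dict[str, np.ndarray]
    breakpoints: dict[str, np.ndarray]


@dataclasses.dataclass(frozen=True)
class InjectedMutation:
    sample: str
    chromosome: str
    position: int
    ref: str
    alt: str
    mtype: str  # SBS | INS | DEL
    sbs_category: str | None

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclasses.dataclass
class TruthSet:
    """Simulator ground truth for parameter-recovery checks."""

    injected_mutations: list[InjectedMutation] = dataclasses.field(
        default_factory=list
    )
    #: (sample, chromosome) -> strictly increasing crossover positions (bp)
    crossovers: dict[tuple[str, str], np.ndarray] = dataclasses.field(
        default_factory=dict
    )
    #: sample -> chromosome -> bool array (True = HET) aligned to markers
    true_zygosity: dict[str, dict[str, np.ndarray]] = dataclasses.field(
        default_factory=dict
    )

    def mutations_of(self, sample: str) -> set[tuple[str, int, str, str]]:
        return {m.site for m in self.injected_mutations if m.sample == sample}


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Lay out non-overlapping mapped regions and gene models.

    Region counts are split evenly across chromosomes; lengths are Poisson
    around ``region_length_mean`` (floor 30 bp, roughly the shortest
    alignable GBS fragment); gaps between regions follow uniform order
    statistics over the unoccupied sequence.
    """
    rng = config.rng() if rng is None else rng
    chroms = config.chromosome_names()
    per_chrom = np.full(config.n_chromosomes, config.n_regions // config.n_chromosomes)
    per_chrom[: config.n_regions % config.n_chromosomes] += 1

    regions: list[tuple[str, int, int]] = []
    genes: list[tuple[str, int, int, list[tuple[int, int]]]] = []
    for chrom, n in zip(chroms, per_chrom):
        n = int(n)
        if n == 0:
            continue
        lengths = np.maximum(rng.poisson(config.region_length_mean, n), 30)
        free = config.chrom_length - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"cannot fit {n} regions totalling {lengths.sum()} bp on "
                f"{chrom} of length {config.chrom_length}"
            )
        gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(np.int64)
        starts = np.cumsum(gaps[:-1]) + np.concatenate(
            [[0], np.cumsum(lengths[:-1])]
        )
        ends = starts + lengths
        chrom_regions = [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
        regions.extend(chrom_regions)
        genes.extend(_place_genes(chrom_regions, config, rng))

    return SimulatedGenome(
        chrom_lengths={c: config.chrom_length for c in chroms},
        regions=regions,
        genes=genes,
    )


def _place_genes(
    chrom_regions: list[tuple[str, int, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, list[tuple[int, int]]]]:
    """Place a gene model over a subset of mapped regions.

    A methylation-sensitive GBS assay is enriched near genes, so gene
    models are generated around the assayed footprint: each region is
    genic with probability ``gene_probability`` and its gene extent is
    padded around the region, clipped so neighbouring genes cannot
    overlap.  ``exons_per_gene`` equal exons covering ``exon_fraction`` of
    the gene are spread evenly through the extent.
    """
    genes = []
    chrom = chrom_regions[0][0]
    chrom_len = config.chrom_length
    genic = rng.random(len(chrom_regions)) < config.gene_probability
    pads = rng.exponential(config.gene_length_mean / 2, size=(len(chrom_regions), 2))
    for i, (region, is_genic) in enumerate(zip(chrom_regions, genic)):
        if not is_genic:
            continue
        _, rs, re = region
        left_lim = chrom_regions[i - 1][2] if i > 0 else 0
        right_lim = (
            chrom_regions[i + 1][1] if i + 1 < len(chrom_regions) else chrom_len
        )
        gs0 = max(left_lim, rs - int(pads[i, 0]))
        ge0 = min(right_lim, re + int(pads[i, 1]))
        # 1-based inclusive
        gs, ge = gs0 + 1, ge0
        if ge - gs < 2 * config.exons_per_gene:
            continue
        genes.append((chrom, gs, ge, _exon_layout(gs, ge, config)))
    return genes


def _exon_layout(gs: int, ge: int, config: SimConfig) -> list[tuple[int, int]]:
    length = ge - gs + 1
    k = config.exons_per_gene
    exon_len = max(1, int(length * config.exon_fraction / k))
    gap = (length - k * exon_len) // max(1, k - 1) if k > 1 else 0
    exons = []
    pos = gs
    for _ in range(k):
        exons.append((pos, min(pos + exon_len - 1, ge)))
        pos += exon_len + gap
        if pos > ge:
            break
    return exons


# ---------------------------------------------------------------------------
# cross, meiosis, BC1 panel
# ---------------------------------------------------------------------------

def _sample_mapped_offsets(
    genome: SimulatedGenome,
    n: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
) -> list[tuple[str, int]]:
    """Draw ``n`` distinct (chromosome, 1-based position) pairs uniformly
    over the mapped bases, avoiding ``exclude``."""
    exclude = exclude or set()
    chosen: list[tuple[str, int]] = []
    seen = set(exclude)
    guard = 0
    while len(chosen) < n:
        need = n - len(chosen)
        offsets = rng.integers(0, genome.mapped_length, size=max(need * 2, 16))
        for off in offsets:
            site = genome.offset_to_position(int(off))
            if site not in seen:
                seen.add(site)
                chosen.append(site)
                if len(chosen) == n:
                    break
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not place distinct sites in mapped regions")
    return chosen


def simulate_cross(
    genome: SimulatedGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Cross:
    """Create two homozygous parents differing at SNP sites within mapped
    regions at ``snp_rate``, and the fully heterozygous F1 they imply."""
    rng = config.rng() if rng is None else rng
    n_sites = int(rng.poisson(config.snp_rate * genome.mapped_length))
    sites = _sample_mapped_offsets(genome, n_sites, rng)

    by_chrom: dict[str, list[int]] = {c: [] for c in genome.chrom_lengths}
    for chrom, pos in sites:
        by_chrom[chrom].append(pos)

    positions, refs, alts, a_is_alt = {}, {}, {}, {}
    for chrom in genome.chrom_lengths:
        pos = np.sort(np.array(by_chrom[chrom], dtype=np.int64))
        m = len(pos)
        ref_idx = rng.integers(0, 4, m)
        alt_idx = (ref_idx + rng.integers(1, 4, m)) % 4
        positions[chrom] = pos
        refs[chrom] = _BASES[ref_idx]
        alts[chrom] = _BASES[alt_idx]
        a_is_alt[chrom] = rng.random(m) < 0.5
    return Cross(positions, refs, alts, a_is_alt)


def simulate_meiosis(
    cross: Cross,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Gamete:
    """One meiotic product of the F1.

    Per chromosome the crossover count is Poisson(``xo_rate``) with
    breakpoints uniform along the chromosome (no interference); the gamete
    alternates parental phase at each breakpoint, starting from a fair
    coin.
    """
    rng = config.rng() if rng is None else rng
    phase: dict[str, np.ndarray] = {}
    breakpoints: dict[str, np.ndarray] = {}
    for chrom, positions in cross.positions.items():
        k = int(rng.poisson(config.xo_rate))
        bp = np.sort(rng.uniform(0, config.chrom_length, k))
        start = int(rng.integers(0, 2))
        crossings = np.searchsorted(bp, positions)
        phase[chrom] = (start + crossings) % 2
        breakpoints[chrom] = bp
    return Gamete(phase=phase, breakpoints=breakpoints)


def simulate_bc1_panel(
    genome: SimulatedGenome,
    cross: Cross,
    config: SimConfig,
    n_progeny: int,
    rng: np.random.Generator | None = None,
    sample_names: Sequence[str] | None = None,
    truth: TruthSet | None = None,
) -> TruthSet:
    """Generate BC1 progeny: gamete(F1) x recurrent parent A.

    At each marker the progeny is HET when the gamete carries the donor
    (parent B) allele and recurrent-homozygous otherwise.  True zygosity
    and crossover positions are recorded in the returned truth set.
    """
    rng = config.rng() if rng is None else rng
    truth = truth or TruthSet()
    if sample_names is None:
        sample_names = [f"progeny{i:03d}" for i in range(1, n_progeny + 1)]
    for sample in sample_names:
        gamete = simulate_meiosis(cross, config, rng)
        truth.true_zygosity[sample] = {
            chrom: gamete.phase[chrom] == 1 for chrom in cross.positions
        }
        for chrom in cross.positions:
            truth.crossovers[(sample, chrom)] = gamete.breakpoints[chrom]
    return truth


# ---------------------------------------------------------------------------
# mutation injection and observation
# ---------------------------------------------------------------------------

def inject_mutations(
    genome: SimulatedGenome,
    config: SimConfig,
    samples: Iterable[str],
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
    exclude: set[tuple[str, int]] | None = None,
) -> TruthSet:
    """Inject induced heterozygous mutations into each mutant sample.

    Per sample the count is Poisson(``mutation_density`` x mapped length /
    10 Mb); positions are uniform over mapped bases; each mutation is a
    1-2 bp InDel with probability ``indel_fraction``, otherwise an SBS
    whose category is drawn from ``sbs_spectrum``.
    """
    rng = config.rng() if rng is None else rng
    truth = truth or TruthSet()
    used: set[tuple[str, int]] = set(exclude or set())
    used |= {m.site[:2] for m in truth.injected_mutations}
    expected = config.mutation_density * genome.mapped_length / 1e7
    for sample in samples:
        n = int(rng.poisson(expected))
        sites = _sample_mapped_offsets(genome, n, rng, exclude=used)
        used |= set(sites)
        for chrom, pos in sites:
            truth.injected_mutations.append(
                _draw_mutation(sample, chrom, pos, config, rng)
            )
    return truth


def _draw_mutation(
    sample: str, chrom: str, pos: int, config: SimConfig, rng: np.random.Generator
) -> InjectedMutation:
    if rng.random() < config.indel_fraction:
        length = int(rng.integers(1, 3))
        anchor = str(rng.choice(_BASES))
        extra = "".join(rng.choice(_BASES, length))
        if rng.random() < 0.5:
            return InjectedMutation(sample, chrom, pos, anchor, anchor + extra, "INS", None)
        return InjectedMutation(sample, chrom, pos, anchor + extra, anchor, "DEL", None)
    category = SBS_CATEGORIES[
        int(rng.choice(len(SBS_CATEGORIES), p=np.asarray(config.sbs_spectrum)))
    ]
    subs = _CATEGORY_SUBS[category]
    ref = str(rng.choice(list(subs)))
    return InjectedMutation(sample, chrom, pos, ref, subs[ref], "SBS", category)


def simulate_observations(
    truth: TruthSet,
    genome: SimulatedGenome,
    config: SimConfig,
    manifest: pd.DataFrame,
    cross: Cross | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Emit noisy per-sample variant records at every simulated site.

    Per site and sample the total depth is negative-binomial with mean
    ``depth_mean`` and dispersion ``depth_dispersion`` (variance = m +
    m^2/k); each read reports the true chromosome allele but flips to the
    other allele with probability ``genotype_error_rate``.  Records are
    emitted only for covered (depth > 0) sites.
    """
    rng = config.rng() if rng is None else rng

    # assemble the ordered site list: markers first, then mutation sites
    sites: list[tuple[str, int, str, str]] = []
    if cross is not None:
        for chrom in cross.positions:
            for pos, ref, alt in zip(
                cross.positions[chrom], cross.ref[chrom], cross.alt[chrom]
            ):
                sites.append((chrom, int(pos), str(ref), str(alt)))
    sites.extend(m.site for m in truth.injected_mutations)
    sites.sort()

    site_index = {s: i for i, s in enumerate(sites)}
    n_sites = len(sites)

    # alt-allele dosage per sample: 0, 0.5 or 1 copies of the alt allele
    dosages: dict[str, np.ndarray] = {}
    marker_dosage_a = np.zeros(n_sites)
    marker_dosage_b = np.zeros(n_sites)
    marker_mask = np.zeros(n_sites, dtype=bool)
    if cross is not None:
        for chrom in cross.positions:
            for pos, ref, alt, a_alt in zip(
                cross.positions[chrom],
                cross.ref[chrom],
                cross.alt[chrom],
                cross.parent_a_is_alt[chrom],
            ):
                i = site_index[(chrom, int(pos), str(ref), str(alt))]
                marker_mask[i] = True
                marker_dosage_a[i] = 1.0 if a_alt else 0.0
                marker_dosage_b[i] = 0.0 if a_alt else 1.0

    for _, row in manifest.iterrows():
        sample, role = row["sample"], row["role"]
        d = np.zeros(n_sites)
        if role == "parentA":
            d[:] = marker_dosage_a
        elif role == "parentB":
            d[:] = marker_dosage_b
        elif role == "f1":
            d[marker_mask] = 0.5
        elif role == "progeny":
            zyg = truth.true_zygosity.get(sample, {})
            if cross is not None:
                for chrom in cross.positions:
                    het = zyg[chrom]
                    for j, (pos, ref, alt, a_alt) in enumerate(
                        zip(
                            cross.positions[chrom],
                            cross.ref[chrom],
                            cross.alt[chrom],
                            cross.parent_a_is_alt[chrom],
                        )
                    ):
                        i = site_index[(chrom, int(pos), str(ref), str(alt))]
                        d[i] = 0.5 if het[j] else (1.0 if a_alt else 0.0)
        # controls and mutants are background (reference) outside their
        # own induced mutations
        dosages[sample] = d
    for m in truth.injected_mutations:
        dosages[m.sample][site_index[m.site]] = 0.5

    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)
    err = config.genotype_error_rate

    matrix = GenotypeMatrix(list(manifest["sample"]))
    for sample in manifest["sample"]:
        depths = rng.negative_binomial(k, p_nb, n_sites)
        q = dosages[sample] * (1 - err) + (1 - dosages[sample]) * err
        alt_reads = rng.binomial(depths, q)
        covered = np.nonzero(depths)[0]
        for i in covered:
            chrom, pos, ref, alt = sites[i]
            dp = int(depths[i])
            ad_alt = int(alt_reads[i])
            matrix.add(
                VariantRecord(
                    chromosome=chrom,
                    position=pos,
                    ref=ref,
                    alt=alt,
                    sample=sample,
                    depth=dp,
                    allele_depths=(dp - ad_alt, ad_alt),
                )
            )
    return matrix


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimResult:
    config: SimConfig
    genome: SimulatedGenome
    cross: Cross
    truth: TruthSet
    manifest: pd.DataFrame
    matrix: GenotypeMatrix


def default_manifest(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(1, 5):
        rows.append((f"parentA_{i}", "parentA", "parental"))
    for i in range(1, 5):
        rows.append((f"parentB_{i}", "parentB", "parental"))
    for i in range(1, 5):
        rows.append((f"f1_{i}", "f1", "parental"))
    for i in range(1, config.n_controls + 1):
        rows.append((f"control_{i}", "control", "control"))
    for group in config.mutant_groups:
        for i in range(1, config.n_mutants_per_group + 1):
            rows.append((f"{group}_rep{i}", "mutant", group))
    for i in range(1, config.n_progeny + 1):
        rows.append((f"progeny{i:03d}", "progeny", "bc1"))
    return pd.DataFrame(rows, columns=["sample", "role", "group"])


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: genome, cross, BC1 panel, mutations,
    observations — all from ``config.seed``."""
    rng = config.rng()
    genome = build_genome(config, rng)
    cross = simulate_cross(genome, config, rng)
    manifest = default_manifest(config)

    progeny = list(manifest.loc[manifest["role"] == "progeny", "sample"])
    truth = simulate_bc1_panel(
        genome, cross, config, len(progeny), rng, sample_names=progeny
    )
    marker_sites = {
        (chrom, int(pos))
        for chrom in cross.positions
        for pos in cross.positions[chrom]
    }
    mutants = list(manifest.loc[manifest["role"] == "mutant", "sample"])
    inject_mutations(genome, config, mutants, rng, truth=truth, exclude=marker_sites)

    matrix = simulate_observations(truth, genome, config, manifest, cross, rng)
    return SimResult(config, genome, cross, truth, manifest, matrix)


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write VCF / BED / GFF3 / manifest / truth TSVs plus a provenance
    record of the generating configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "bed": outdir / "regions.bed",
        "gff": outdir / "genes.gff3",
        "manifest": outdir / "samples.tsv",
        "truth_mutations": outdir / "truth_mutations.tsv",
        "truth_crossovers": outdir / "truth_crossovers.tsv",
        "provenance": outdir / "provenance.json",
    }
    write_vcf(result.matrix, paths["vcf"])
    write_bed(result.genome.regions, paths["bed"])
    write_gff3(result.genome.chrom_lengths, result.genome.genes, paths["gff"])
    write_manifest(result.manifest, paths["manifest"])

    pd.DataFrame(
        [
            (m.sample, m.chromosome, m.position, m.ref, m.alt, m.mtype)
            for m in result.truth.injected_mutations
        ],
        columns=["sample", "chromosome", "position", "ref", "alt", "mtype"],
    ).to_csv(paths["truth_mutations"], sep="\t", index=False)

    xo_rows = [
        (sample, chrom, float(pos))
        for (sample, chrom), bps in result.truth.crossovers.items()
        for pos in bps
    ]
    pd.DataFrame(
        xo_rows, columns=["sample", "chromosome", "position"]
    ).to_csv(paths["truth_crossovers"], sep="\t", index=False)

    with paths["provenance"].open("w") as fh:
        json.dump(
            {"config": dataclasses.asdict(result.config)}, fh, indent=2, default=list
        )
        fh.write("\n")
    return paths
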