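"""Screening induced mutations against non-irradiated controls.

A site is assessable when every control line is covered at or above the
depth floor and all controls agree on one clearly homozygous allele (the
control consensus).  A mutant line carries an induced mutation at an
assessable site when, at sufficient depth, it shows the other allele of
the biallelic record at an allele fraction compatible with a heterozygous
induced change.  Retained InDels change net length by 1-2 bp only;
substitutions are strand-collapsed into six categories, split into
transitions and transversions, located on exon/intron/intergenic context,
and summarised as densities per 10 Mb of mapped sequence.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import AnnotationIndex, GenotypeMatrix, SiteKey

__all__ = [
    "MutationCall",
    "DensityEstimate",
    "classify_sbs",
    "control_consensus",
    "screen_mutations",
    "mutation_density",
    "correct_generation_density",
    "spectrum_table",
    "annotate_calls",
    "screen_panel",
]

TRANSITION_CATEGORIES = frozenset({"A/T>G/C", "G/C>A/T"})

_SBS_CLASS = {
    ("A", "G"): "A/T>G/C", ("T", "C"): "A/T>G/C",
    ("G", "A"): "G/C>A/T", ("C", "T"): "G/C>A/T",
    ("A", "T"): "A/T>T/A", ("T", "A"): "A/T>T/A",
    ("A", "C"): "A/T>C/G", ("T", "G"): "A/T>C/G",
    ("G", "T"): "G/C>T/A", ("C", "A"): "G/C>T/A",
    ("G", "C"): "G/C>C/G", ("C", "G"): "G/C>C/G",
}


@dataclasses.dataclass(frozen=True)
class MutationCall:
    """A screened induced mutation in one mutant line."""

    sample: str
    chromosome: str
    position: int
    ref: str
    alt: str
    mtype: str  # SBS | INS | DEL
    indel_len: int  # 0 for SBS, 1 or 2 for InDels
    sbs_category: str | None = None
    ti_tv: str | None = None  # transition | transversion
    context: str | None = None  # exon | intron | intergenic

    def __post_init__(self) -> None:
        if self.mtype == "SBS":
            if self.indel_len != 0 or len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SBS calls must be single-base, indel_len 0")
        elif self.mtype in ("INS", "DEL"):
            if self.indel_len not in (1, 2):
                raise ValueError("InDel calls must have indel_len 1 or 2")
        else:
            raise ValueError(f"unknown mutation type {self.mtype!r}")

    @property
    def site(self) -> SiteKey:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclasses.dataclass(frozen=True)
class DensityEstimate:
    """Mutations per 10 Mb of assessable mapped sequence for one line."""

    sample: str
    n_mutations: int
    mapped_length: int
    density: float


def classify_sbs(ref: str, alt: str) -> tuple[str, str]:
    """Strand-collapsed category and transition/transversion status.

    The six categories pair each substitution with its reverse complement
    (e.g. G>A and C>T are both ``G/C>A/T``), so
    ``classify_sbs(x, y) == classify_sbs(complement(x), complement(y))``.
    """
    key = (ref.upper(), alt.upper())
    if key not in _SBS_CLASS:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    category = _SBS_CLASS[key]
    return category, (
        "transition" if category in TRANSITION_CATEGORIES else "transversion"
    )


def control_consensus(
    matrix: GenotypeMatrix,
    control_samples: Sequence[str],
    min_depth: int = 5,
    purity: float = 0.75,
) -> dict[SiteKey, str]:
    """Per-site allele common to all non-irradiated controls.

    A site is assessable only when every control has a record with depth
    >= ``min_depth`` and a clearly homozygous major allele (fraction >=
    ``purity``), and all controls agree on that allele.  Non-assessable
    sites are absent from the returned mapping and ignored downstream.
    """
    if len(control_samples) == 0:
        raise ValueError("at least one control sample is required")
    consensus: dict[SiteKey, str] = {}
    for site in matrix.sites:
        allele: str | None = None
        ok = True
        for sample in control_samples:
            rec = matrix.get(site, sample)
            if rec is None or rec.depth < min_depth:
                ok = False
                break
            ref_d, alt_d = rec.allele_depths
            total = ref_d + alt_d
            if total == 0:
                ok = False
                break
            major, frac = (
                (rec.ref, ref_d / total)
                if ref_d >= alt_d
                else (rec.alt, alt_d / total)
            )
            if frac < purity:
                ok = False
                break
            if allele is None:
                allele = major
            elif allele != major:
                ok = False
                break
        if ok and allele is not None:
            consensus[site] = allele
    return consensus


def screen_mutations(
    matrix: GenotypeMatrix,
    control_samples: Sequence[str],
    mutant_sample: str,
    min_depth: int = 5,
    min_af: float = 0.25,
    consensus: Mapping[SiteKey, str] | None = None,
) -> list[MutationCall]:
    """Extract induced mutations of one mutant line.

    At each assessable site the call requires mutant depth >=
    ``min_depth`` and the non-consensus allele at fraction >= ``min_af``
    (induced mutations are heterozygous; lower fractions are treated as
    read noise).  InDels are retained only when the net length change is
    1-2 bp.
    """
    if mutant_sample not in matrix.samples:
        raise KeyError(f"mutant sample {mutant_sample!r} not in matrix")
    if consensus is None:
        consensus = control_consensus(matrix, control_samples, min_depth=min_depth)
    calls: list[MutationCall] = []
    for site, cons_allele in consensus.items():
        rec = matrix.get(site, mutant_sample)
        if rec is None or rec.depth < min_depth:
            continue
        novel = rec.alt if cons_allele == rec.ref else rec.ref
        frac = rec.allele_fraction(novel)
        if not frac >= min_af:
            continue
        call = _build_call(mutant_sample, site, cons_allele, novel)
        if call is not None:
            calls.append(call)
    return calls


def _build_call(
    sample: str, site: SiteKey, cons_allele: str, novel: str
) -> MutationCall | None:
    chrom, pos, _ref, _alt = site
    net = len(novel) - len(cons_allele)
    if net == 0:
        if len(novel) != 1:
            return None  # multi-base substitution blocks are out of scope
        category, ti_tv = classify_sbs(cons_allele, novel)
        return MutationCall(
            sample, chrom, pos, cons_allele, novel, "SBS", 0, category, ti_tv
        )
    if abs(net) in (1, 2):
        mtype = "INS" if net > 0 else "DEL"
        return MutationCall(
            sample, chrom, pos, cons_allele, novel, mtype, abs(net)
        )
    return None  # larger InDels are invisible to this assay design


def mutation_density(n: int, mapped_length: int, sample: str = "") -> DensityEstimate:
    """Mutations per 10 Mb: ``n / mapped_length x 1e7``."""
    if mapped_length <= 0:
        raise ValueError(f"mapped_length must be positive, got {mapped_length}")
    return DensityEstimate(
        sample=sample,
        n_mutations=n,
        mapped_length=mapped_length,
        density=n / mapped_length * 1e7,
    )


def correct_generation_density(
    d_obs: float, het_fraction: float = 2 / 3, loss: float = 1 / 4
) -> float:
    """Back-correct a later-generation density for Mendelian segregation loss.

    After one selfing, carriers of an originally heterozygous mutation are
    1/3 homozygous and 2/3 heterozygous; a quarter of the heterozygous
    mutations are then lost in the next generation.  The earlier
    generation's density is ``d_obs / (1 - het_fraction x loss)`` — with
    the defaults, an observed 1.25 per 10 Mb back-corrects to 1.5.
    """
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must lie in [0, 1]")
    if not 0.0 <= loss < 1.0:
        raise ValueError("loss must lie in [0, 1)")
    denom = 1.0 - het_fraction * loss
    if denom <= 0:
        raise ValueError("correction denominator must be positive")
    return d_obs / denom


def spectrum_table(
    calls_by_group: Mapping[str, Iterable[MutationCall]],
) -> pd.DataFrame:
    """Six-category SBS counts and proportions per group.

    Returns a tidy frame with one row per (group, category); groups with
    zero substitutions are excluded (their proportions are undefined) and
    the transition share per group is the sum of the two transition
    categories.
    """
    from .synthetic_gbs import SBS_CATEGORIES

    rows = []
    for group, calls in calls_by_group.items():
        counts = {cat: 0 for cat in SBS_CATEGORIES}
        for call in calls:
            if call.mtype == "SBS":
                counts[call.sbs_category] += 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(
                f"group {group!r} has no substitutions; proportions undefined",
                stacklevel=2,
            )
            continue
        for cat in SBS_CATEGORIES:
            rows.append(
                {
                    "group": group,
                    "category": cat,
                    "count": counts[cat],
                    "proportion": counts[cat] / total,
                    "ti_tv": (
                        "transition"
                        if cat in TRANSITION_CATEGORIES
                        else "transversion"
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "category", "count", "proportion", "ti_tv"]
    )


def annotate_calls(
    calls: Iterable[MutationCall], annotation: AnnotationIndex
) -> list[MutationCall]:
    """Attach the exon/intron/intergenic context to every call."""
    out = []
    for call in calls:
        context = annotation.classify(call.chromosome, call.position)
        out.append(dataclasses.replace(call, context=context))
    return out


def screen_panel(
    matrix: GenotypeMatrix,
    manifest: pd.DataFrame,
    mapped_length: int,
    min_depth: int = 5,
    min_af: float = 0.25,
    annotation: AnnotationIndex | None = None,
) -> tuple[list[MutationCall], pd.DataFrame]:
    """Screen every mutant line of a panel against its controls.

    Returns all calls plus a per-line density table.  All lines share the
    mapped-region denominator ``mapped_length``; callers holding per-line
    assessable lengths can recompute densities with
    :func:`mutation_density`.
    """
    controls = list(manifest.loc[manifest["role"] == "control", "sample"])
    mutants = manifest.loc[manifest["role"] == "mutant", ["sample", "group"]]
    consensus = control_consensus(matrix, controls, min_depth=min_depth)
    all_calls: list[MutationCall] = []
    rows = []
    for _, (sample, group) in mutants.iterrows():
        calls = screen_mutations(
            matrix, controls, sample,
            min_depth=min_depth, min_af=min_af, consensus=consensus,
        )
        if annotation is not None:
            calls = annotate_calls(calls, annotation)
        all_calls.extend(calls)
        est = mutation_density(len(calls), mapped_length, sample=sample)
        rows.append(
            {
                "sample": sample,
                "group": group,
                "n_mutations": est.n_mutations,
                "n_sbs": sum(c.mtype == "SBS" for c in calls),
                "n_indel": sum(c.mtype != "SBS" for c in calls),
                "mapped_length": est.mapped_length,
                "density_per_10mb": est.density,
            }
        )
    return all_calls, pd.DataFrame(rows)
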