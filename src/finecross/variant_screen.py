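"""Strain-unique variant screening and insertion-allele PCR diagnostics.

A candidate variant within a queried interval must be carried (non-
reference) by every available sequence of the carrier strain and by no
sequence of any contrast strain. Positions where sequences of a single
strain disagree are reported separately as DISCORDANT, never silently
dropped. For structural insertion alleles, diagnostic PCR product sizes
are predicted from the empty-site product plus the inserted element
length, subject to a practical amplifiable-size ceiling, or from a primer
site internal to the insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations_with_replacement
from pathlib import Path

import pandas as pd

from .genome_model import ValidationError

# sentinel for a primer pair yielding no band
NO_PRODUCT = None


@dataclass(frozen=True)
class StrainVariantCall:
    strain: str
    sequence_id: str
    chromosome: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    is_alt: bool  # True when this sequence carries the non-reference state


@dataclass
class VariantCandidate:
    chromosome: str
    position: int
    ref: str
    alt: str
    status: str  # "CANDIDATE" or "DISCORDANT"
    carrier_states: dict[str, bool] = field(default_factory=dict)
    contrast_states: dict[str, dict[str, bool]] = field(default_factory=dict)
    discordant_strains: list[str] = field(default_factory=list)


@dataclass
class VariantScreenResult:
    candidates: list[VariantCandidate]
    discordant: list[VariantCandidate]


def unique_variants(
    calls: list[StrainVariantCall],
    interval: tuple[str, int, int],
    carrier_strain: str,
    contrast_strains: list[str],
) -> VariantScreenResult:
    """Variants inside ``interval`` unique to the carrier strain.

    Sequences of a strain with no call at a position are treated as
    reference-state (variant tables list non-reference observations).
    """
    strains_present = {c.strain for c in calls}
    if carrier_strain not in strains_present:
        raise ValidationError(f"carrier strain {carrier_strain!r} absent from calls")
    sequences_by_strain: dict[str, set[str]] = {}
    for c in calls:
        sequences_by_strain.setdefault(c.strain, set()).add(c.sequence_id)
    for s in contrast_strains:
        sequences_by_strain.setdefault(s, {f"{s}-1"})

    chrom, start, end = interval
    relevant_strains = [carrier_strain] + list(contrast_strains)
    sites: dict[tuple[str, int, str, str], dict[str, dict[str, bool]]] = {}
    for c in calls:
        if c.chromosome != chrom or not (start <= c.position <= end):
            continue
        if c.strain not in relevant_strains:
            continue
        key = (c.chromosome, c.position, c.ref, c.alt)
        sites.setdefault(key, {}).setdefault(c.strain, {})[c.sequence_id] = c.is_alt

    candidates: list[VariantCandidate] = []
    discordant: list[VariantCandidate] = []
    for key in sorted(sites, key=lambda k: k[1]):
        chrom_k, pos, ref, alt = key
        by_strain = sites[key]
        states: dict[str, dict[str, bool]] = {}
        for strain in relevant_strains:
            observed = by_strain.get(strain, {})
            states[strain] = {
                seq: observed.get(seq, False)
                for seq in sorted(sequences_by_strain[strain])
            }
        disagree = [
            strain
            for strain, seq_states in states.items()
            if len(set(seq_states.values())) > 1
        ]
        record = VariantCandidate(
            chromosome=chrom_k,
            position=pos,
            ref=ref,
            alt=alt,
            status="DISCORDANT" if disagree else "CANDIDATE",
            carrier_states=states[carrier_strain],
            contrast_states={s: states[s] for s in contrast_strains},
            discordant_strains=disagree,
        )
        if disagree:
            discordant.append(record)
            continue
        carrier_all_alt = all(states[carrier_strain].values())
        contrasts_all_ref = all(
            not v for s in contrast_strains for v in states[s].values()
        )
        if carrier_all_alt and contrasts_all_ref:
            candidates.append(record)
    return VariantScreenResult(candidates=candidates, discordant=discordant)


def read_vcf_calls(
    vcf_path: str | Path, samples_tsv: str | Path
) -> list[StrainVariantCall]:
    """Read per-sample calls from a VCF plus a sample->(strain, sequence) map.

    The sidecar TSV has columns ``sample``, ``strain``, ``sequence_id``.
    A sample is non-reference at a site when its genotype contains any
    alternate allele; sites are expanded per alternate allele.
    """
    from cyvcf2 import VCF

    mapping = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    required = {"sample", "strain", "sequence_id"}
    if required - set(mapping.columns):
        raise ValidationError(
            f"samples file {samples_tsv}: needs columns {sorted(required)}"
        )
    by_sample = {
        r.sample: (r.strain, r.sequence_id) for r in mapping.itertuples(index=False)
    }
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    unknown = [s for s in samples if s not in by_sample]
    if unknown:
        raise ValidationError(f"VCF samples missing from mapping: {unknown}")
    calls: list[StrainVariantCall] = []
    for variant in vcf:
        genotypes = variant.genotypes  # [[a, b, phased], ...]
        for alt_i, alt in enumerate(variant.ALT, start=1):
            for sample_i, sample in enumerate(samples):
                alleles = genotypes[sample_i][:-1]
                strain, sequence_id = by_sample[sample]
                calls.append(
                    StrainVariantCall(
                        strain=strain,
                        sequence_id=sequence_id,
                        chromosome=variant.CHROM,
                        position=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        is_alt=alt_i in alleles,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Insertion alleles and amplicon prediction

ERV_INSERTION_SITE = 34_957_384  # 1-based position of the insertion site


class InsertionAllele(Enum):
    """States of the structural insertion site: empty, solitary LTR, full ERV."""

    SELF_EMPTY = ("self", 0, False)
    IRISH_SOLITARY_LTR = ("irish", 584, False)
    HOODED_FULL_ERV = ("hooded", 7098, True)

    def __init__(
        self, short_name: str, insert_length_bp: int, contains_internal_primer_site: bool
    ):
        self.short_name = short_name
        self.insert_length_bp = insert_length_bp
        self.contains_internal_primer_site = contains_internal_primer_site

    @classmethod
    def from_name(cls, name: str) -> "InsertionAllele":
        for allele in cls:
            if name.lower() in (allele.short_name, allele.name.lower()):
                return allele
        raise ValidationError(f"unknown insertion allele {name!r}")


@dataclass(frozen=True)
class PrimerPairSpec:
    """A diagnostic primer pair, parameterized either by the empty-site
    product size (both primers flank the insertion site) or by a product
    requiring a primer site internal to the insertion."""

    name: str
    empty_site_product_bp: int | None = None
    requires_internal_site: bool = False
    internal_product_bp: int | None = None
    max_amplifiable_bp: int = 5000

    def __post_init__(self) -> None:
        flanking = self.empty_site_product_bp is not None
        internal = self.requires_internal_site
        if flanking == internal:
            raise ValidationError(
                f"primer pair {self.name}: exactly one of empty-site or "
                "internal-product parameterization must be active"
            )
        if internal and self.internal_product_bp is None:
            raise ValidationError(
                f"primer pair {self.name}: internal_product_bp required"
            )


# the two pairs used to genotype the insertion site
PAIR_AB = PrimerPairSpec(name="AB", empty_site_product_bp=1006)
PAIR_CD = PrimerPairSpec(name="CD", requires_internal_site=True, internal_product_bp=997)
DEFAULT_PAIRS = {"AB": PAIR_AB, "CD": PAIR_CD}


def predict_amplicon(pair: PrimerPairSpec, allele: InsertionAllele) -> int | None:
    """Predicted PCR product length in bp, or NO_PRODUCT (None)."""
    if pair.requires_internal_site:
        if allele.contains_internal_primer_site:
            return pair.internal_product_bp
        return NO_PRODUCT
    product = pair.empty_site_product_bp + allele.insert_length_bp
    if product > pair.max_amplifiable_bp:
        return NO_PRODUCT
    return product


def band_pattern(
    genotype: tuple[InsertionAllele, InsertionAllele],
    pairs: dict[str, PrimerPairSpec] | None = None,
) -> dict[str, frozenset[int]]:
    """Band sizes per primer pair for a (possibly heterozygous) genotype."""
    pairs = pairs or DEFAULT_PAIRS
    pattern: dict[str, frozenset[int]] = {}
    for name, pair in pairs.items():
        bands = {
            predict_amplicon(pair, allele)
            for allele in genotype
        }
        pattern[name] = frozenset(b for b in bands if b is not NO_PRODUCT)
    return pattern


@dataclass
class GenotypeInference:
    consistent_genotypes: list[tuple[InsertionAllele, InsertionAllele]]
    conflict: bool
    violations: list[str] = field(default_factory=list)


def genotype_from_products(
    observed: dict[str, int | list[int] | None],
    pairs: dict[str, PrimerPairSpec] | None = None,
) -> GenotypeInference:
    """Insertion-site genotypes consistent with observed band patterns.

    ``observed`` maps primer-pair name to the band size(s) seen (None or an
    empty list for no product). Returns every homozygous or heterozygous
    allele combination whose predicted pattern matches all observations;
    a CONFLICT result lists, per pair, the observed vs predicted bands.
    """
    if not observed:
        raise ValidationError("products from at least one primer pair required")
    pairs = pairs or DEFAULT_PAIRS
    unknown = [p for p in observed if p not in pairs]
    if unknown:
        raise ValidationError(f"unknown primer pair(s): {unknown}")
    normalized: dict[str, frozenset[int]] = {}
    for name, bands in observed.items():
        if bands is None:
            normalized[name] = frozenset()
        elif isinstance(bands, int):
            normalized[name] = frozenset({bands})
        else:
            normalized[name] = frozenset(bands)
    consistent = []
    for genotype in combinations_with_replacement(InsertionAllele, 2):
        pattern = band_pattern(genotype, pairs)
        if all(pattern[name] == normalized[name] for name in normalized):
            consistent.append(genotype)
    if consistent:
        return GenotypeInference(consistent_genotypes=consistent, conflict=False)
    violations = []
    for name, bands in sorted(normalized.items()):
        shown = sorted(bands) if bands else "no product"
        violations.append(f"pair {name}: observed {shown} matches no allele combination")
    return GenotypeInference(
        consistent_genotypes=[], conflict=True, violations=violations
    )
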