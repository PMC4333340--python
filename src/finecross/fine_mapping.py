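"""Exclusion mapping of dominant carrier alleles and inclusion mapping of
recessive alleles from genotypes of phenotype-positive animals.

The logic of dominant exclusion: a single carrier allele suffices for the
phenotype, so any phenotype-positive animal observed homozygous for the
non-carrier allele at a marker excludes that marker from the causal
interval. Candidate intervals are maximal runs of non-excluded markers,
reported with outer bounds at the nearest excluding marker on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genome_model import (
    GeneticMap,
    GenotypeCall,
    GenotypeMatrix,
    ValidationError,
)


class MarkerStatus(str, Enum):
    EXCLUDED = "EXCLUDED"
    NOT_EXCLUDED = "NOT_EXCLUDED"
    NON_INFORMATIVE = "NON_INFORMATIVE"


@dataclass
class CandidateInterval:
    """Chromosome segment with explicit flanking-bound markers.

    Bounds follow the outer-bound convention: the nearest excluding marker
    on each side defines the bound position; a side with no excluding marker
    is unbounded (``bounded_* = False``) and falls back to the outermost
    map position on that side.
    """

    chromosome: str
    left_bound_marker: str | None
    right_bound_marker: str | None
    left_mb: float
    right_mb: float
    bounded_left: bool
    bounded_right: bool
    n_supporting_animals: int = 0
    inner_marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.left_mb > self.right_mb:
            raise ValidationError("interval left bound exceeds right bound")

    @property
    def width_mb(self) -> float:
        return self.right_mb - self.left_mb

    def contains(self, position_mb: float) -> bool:
        left = self.left_mb if self.bounded_left else -np.inf
        right = self.right_mb if self.bounded_right else np.inf
        return left <= position_mb <= right


@dataclass
class ExclusionReport:
    chromosome: str
    marker_names: list[str]
    statuses: list[MarkerStatus]
    excluding_counts: list[int]
    intervals: list[CandidateInterval]
    diagnostic: str | None = None

    def status(self, marker_name: str) -> MarkerStatus:
        return self.statuses[self.marker_names.index(marker_name)]

    @property
    def best_interval(self) -> CandidateInterval | None:
        return self.intervals[0] if self.intervals else None


def _chromosome_of(genotypes: GenotypeMatrix, genetic_map: GeneticMap) -> str:
    chroms = {genetic_map.marker(n).chromosome for n in genotypes.marker_names}
    if len(chroms) != 1:
        raise ValidationError(
            f"genotype matrix spans {len(chroms)} chromosomes; expected exactly 1"
        )
    return chroms.pop()


def _build_report(
    genotypes: GenotypeMatrix,
    genetic_map: GeneticMap,
    excluding_counts: list[int],
    informative_counts: list[int],
    tolerance: int,
) -> ExclusionReport:
    chromosome = _chromosome_of(genotypes, genetic_map)
    order = {n: i for i, n in enumerate(genetic_map.marker_names())}
    names = sorted(genotypes.marker_names, key=order.__getitem__)
    if names != genotypes.marker_names:
        raise ValidationError("genotype matrix markers are not in map order")
    statuses = []
    for count, informative in zip(excluding_counts, informative_counts):
        if informative == 0:
            statuses.append(MarkerStatus.NON_INFORMATIVE)
        elif count > tolerance:
            statuses.append(MarkerStatus.EXCLUDED)
        else:
            statuses.append(MarkerStatus.NOT_EXCLUDED)

    positions = [genetic_map.marker(n).position_mb for n in names]
    span_lo, span_hi = genetic_map.span_mb(chromosome)

    intervals: list[CandidateInterval] = []
    i = 0
    while i < len(names):
        if statuses[i] is MarkerStatus.EXCLUDED:
            i += 1
            continue
        j = i
        while j + 1 < len(names) and statuses[j + 1] is not MarkerStatus.EXCLUDED:
            j += 1
        run_names = names[i : j + 1]
        bounded_left = i > 0
        bounded_right = j < len(names) - 1
        left_marker = names[i - 1] if bounded_left else None
        right_marker = names[j + 1] if bounded_right else None
        left_mb = positions[i - 1] if bounded_left else span_lo
        right_mb = positions[j + 1] if bounded_right else span_hi
        support = sum(
            1
            for row in (genotypes.row(a) for a in genotypes.animal_ids)
            if any(
                row[genotypes.marker_names.index(n)] is not GenotypeCall.MISSING
                for n in run_names
            )
        )
        intervals.append(
            CandidateInterval(
                chromosome=chromosome,
                left_bound_marker=left_marker,
                right_bound_marker=right_marker,
                left_mb=left_mb,
                right_mb=right_mb,
                bounded_left=bounded_left,
                bounded_right=bounded_right,
                n_supporting_animals=support,
                inner_marker_names=run_names,
            )
        )
        i = j + 1
    intervals.sort(key=lambda iv: -iv.n_supporting_animals)
    diagnostic = None
    if not intervals:
        diagnostic = (
            "all markers excluded: no candidate interval is consistent with "
            "every phenotype-positive animal carrying a causal allele"
        )
    return ExclusionReport(
        chromosome=chromosome,
        marker_names=names,
        statuses=statuses,
        excluding_counts=excluding_counts,
        intervals=intervals,
        diagnostic=diagnostic,
    )


def map_dominant_exclusion(
    genotypes: GenotypeMatrix,
    genetic_map: GeneticMap,
    tolerance: int = 0,
) -> ExclusionReport:
    """Exclusion mapping for a dominant carrier allele.

    ``genotypes`` must contain phenotype-positive animals only. A marker is
    EXCLUDED iff more than ``tolerance`` animals are homozygous non-carrier
    (NN) there; MISSING never excludes.
    """
    if not genotypes.animal_ids:
        raise ValidationError("no phenotype-positive animals supplied")
    excluding, informative = [], []
    for name in genotypes.marker_names:
        column = genotypes.column(name)
        excluding.append(sum(1 for c in column if c is GenotypeCall.NN))
        informative.append(sum(1 for c in column if c is not GenotypeCall.MISSING))
    return _build_report(genotypes, genetic_map, excluding, informative, tolerance)


def map_recessive_inclusion(
    genotypes: GenotypeMatrix,
    genetic_map: GeneticMap,
    recessive_code: GenotypeCall = GenotypeCall.NN,
    tolerance: int = 0,
) -> ExclusionReport:
    """Inclusion mapping for a recessive allele.

    Every phenotype-positive animal must be homozygous for the recessive
    code at the causal locus, so a marker is excluded when more than
    ``tolerance`` positive animals carry an informative call different from
    the recessive code.
    """
    if not genotypes.animal_ids:
        raise ValidationError("no phenotype-positive animals supplied")
    if recessive_code not in (GenotypeCall.CC, GenotypeCall.NN):
        raise ValidationError("recessive_code must be a homozygous code")
    excluding, informative = [], []
    for name in genotypes.marker_names:
        column = genotypes.column(name)
        excluding.append(
            sum(
                1
                for c in column
                if c is not GenotypeCall.MISSING and c is not recessive_code
            )
        )
        informative.append(sum(1 for c in column if c is not GenotypeCall.MISSING))
    return _build_report(genotypes, genetic_map, excluding, informative, tolerance)


def containment_probability(
    design,
    genetic_map: GeneticMap,
    model,
    n_replicates: int,
    seed: int,
    tolerance: int = 0,
) -> float:
    """Fraction of simulated F2 replicates whose mapped interval(s) contain
    the true causal position.

    With a phenocopy-free model (p_NN = 0), tolerance 0, and the causal
    position at a genotyped marker, this is exactly 1: no affected animal
    can be homozygous non-carrier at the causal marker, so its run is never
    excluded. When the causal position lies strictly between two markers,
    recombinant carriers can legitimately exclude both flanking markers and
    the fraction may fall (slightly) below 1 at marker resolution."""
    from dataclasses import replace

    from .cross_sim import simulate_f2

    rng = np.random.default_rng(seed)
    contained = 0
    effective = 0
    for _ in range(n_replicates):
        rep = replace(design, seed=int(rng.integers(0, 2**31 - 1)))
        result = simulate_f2(rep, genetic_map, model, return_animals=False)
        affected = [p.animal_id for p in result.phenotypes if p.affected]
        if not affected:
            continue
        effective += 1
        report = map_dominant_exclusion(
            result.genotypes.subset_animals(affected), genetic_map, tolerance
        )
        if any(
            iv.contains(design.causal_position_mb) for iv in report.intervals
        ):
            contained += 1
    if effective == 0:
        raise ValidationError("no replicate produced affected animals")
    return contained / effective
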