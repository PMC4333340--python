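"""Recombinant-chromosome classification and progeny-test interval refinement.

A recombinant animal's donor segment is only localized to marker
resolution: the inner segment spans the outermost carrier-informative
markers, the outer bounds sit at the nearest flanking non-carrier
homozygous markers (or the chromosome ends), and the gaps between them are
the breakpoint-uncertainty regions. Phenotype-conferring segments are
intersected on their outer bounds (conservative) and inner segments
(minimal) to refine the candidate interval.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import (
    GeneticMap,
    GenotypeCall,
    GenotypeMatrix,
    ValidationError,
)
from .fine_mapping import CandidateInterval

_CARRIER_CODES = (GenotypeCall.CC, GenotypeCall.CH)


@dataclass
class RecombinantSegment:
    """Donor segment of one chromosome at marker resolution."""

    animal_id: str
    chromosome: str
    inner_left_mb: float | None
    inner_right_mb: float | None
    outer_left_mb: float
    outer_right_mb: float
    outer_left_marker: str | None  # None = chromosome end
    outer_right_marker: str | None
    has_donor_segment: bool = True

    @property
    def uncertainty_gaps_mb(self) -> tuple[float, float]:
        if not self.has_donor_segment:
            raise ValidationError("animal carries no donor segment")
        return (
            self.inner_left_mb - self.outer_left_mb,
            self.outer_right_mb - self.inner_right_mb,
        )


@dataclass
class ProgenyTestResult:
    segment: RecombinantSegment
    n_progeny_tested: int
    n_affected: int

    def __post_init__(self) -> None:
        if self.n_affected > self.n_progeny_tested:
            raise ValidationError("n_affected exceeds n_progeny_tested")

    @property
    def confers(self) -> bool:
        return self.n_affected > 0


def infer_donor_segment(
    animal_id: str,
    calls: list[GenotypeCall],
    genetic_map: GeneticMap,
    chromosome: str,
    marker_names: list[str] | None = None,
) -> RecombinantSegment:
    """Locate one animal's donor segment from its ordered marker calls."""
    markers = genetic_map.chromosome_markers(chromosome)
    if marker_names is not None:
        markers = [genetic_map.marker(n) for n in marker_names]
    if len(calls) != len(markers):
        raise ValidationError("call count does not match marker count")
    span_lo, span_hi = genetic_map.span_mb(chromosome)
    carrier_idx = [i for i, c in enumerate(calls) if c in _CARRIER_CODES]
    if not carrier_idx:
        return RecombinantSegment(
            animal_id=animal_id,
            chromosome=chromosome,
            inner_left_mb=None,
            inner_right_mb=None,
            outer_left_mb=span_lo,
            outer_right_mb=span_hi,
            outer_left_marker=None,
            outer_right_marker=None,
            has_donor_segment=False,
        )
    lo, hi = carrier_idx[0], carrier_idx[-1]
    left_nn = [i for i in range(lo) if calls[i] is GenotypeCall.NN]
    right_nn = [i for i in range(hi + 1, len(calls)) if calls[i] is GenotypeCall.NN]
    outer_left_marker = markers[left_nn[-1]].name if left_nn else None
    outer_right_marker = markers[right_nn[0]].name if right_nn else None
    return RecombinantSegment(
        animal_id=animal_id,
        chromosome=chromosome,
        inner_left_mb=markers[lo].position_mb,
        inner_right_mb=markers[hi].position_mb,
        outer_left_mb=markers[left_nn[-1]].position_mb if left_nn else span_lo,
        outer_right_mb=markers[right_nn[0]].position_mb if right_nn else span_hi,
        outer_left_marker=outer_left_marker,
        outer_right_marker=outer_right_marker,
    )


def infer_donor_segment_from_matrix(
    genotypes: GenotypeMatrix,
    genetic_map: GeneticMap,
    animal_id: str,
    chromosome: str,
) -> RecombinantSegment:
    return infer_donor_segment(
        animal_id,
        genotypes.row(animal_id),
        genetic_map,
        chromosome,
        marker_names=genotypes.marker_names,
    )


@dataclass
class RefinedInterval:
    conservative: CandidateInterval
    minimal: CandidateInterval | None


def intersect_conferring_segments(
    results: list[ProgenyTestResult],
    genetic_map: GeneticMap,
    prior: CandidateInterval | None = None,
    excluded_marker_names: list[str] | None = None,
) -> RefinedInterval:
    """Intersect phenotype-conferring donor segments.

    Conservative interval: intersection of the outer bounds of every
    conferring segment, optionally clipped by a prior interval and by
    markers excluded through genotyped affected progeny (homozygous
    non-carrier there). Minimal interval: intersection of the inner
    segments; always contained in the conservative one, or None when the
    inner segments do not all overlap.
    """
    conferring = [r for r in results if r.confers]
    if not conferring:
        raise ValidationError("no conferring segment (n_affected > 0) supplied")
    chromosomes = {r.segment.chromosome for r in conferring}
    if len(chromosomes) != 1:
        raise ValidationError("conferring segments span multiple chromosomes")
    chromosome = chromosomes.pop()

    left = max(r.segment.outer_left_mb for r in conferring)
    right = min(r.segment.outer_right_mb for r in conferring)
    left_donors = [
        r.segment for r in conferring if r.segment.outer_left_mb == left
    ]
    right_donors = [
        r.segment for r in conferring if r.segment.outer_right_mb == right
    ]
    left_marker = left_donors[0].outer_left_marker
    right_marker = right_donors[0].outer_right_marker
    if prior is not None:
        if prior.bounded_left and prior.left_mb > left:
            left, left_marker = prior.left_mb, prior.left_bound_marker
        if prior.bounded_right and prior.right_mb < right:
            right, right_marker = prior.right_mb, prior.right_bound_marker
    if excluded_marker_names:
        for name in excluded_marker_names:
            pos = genetic_map.marker(name).position_mb
            # an excluded marker inside the interval clips it on the nearer side
            if left < pos < right:
                if pos - left < right - pos:
                    left, left_marker = pos, name
                else:
                    right, right_marker = pos, name
            elif pos == left or pos == right:
                continue
    if left > right:
        names = sorted({r.segment.animal_id for r in conferring})
        raise ValidationError(
            f"conferring segments have empty intersection: {', '.join(names)}"
        )
    conservative = CandidateInterval(
        chromosome=chromosome,
        left_bound_marker=left_marker,
        right_bound_marker=right_marker,
        left_mb=left,
        right_mb=right,
        bounded_left=left_marker is not None or (prior is not None and prior.bounded_left),
        bounded_right=right_marker is not None or (prior is not None and prior.bounded_right),
    )
    minimal = None
    inner_segments = [
        r.segment
        for r in conferring
        if r.segment.inner_left_mb is not None
    ]
    if inner_segments:
        min_left = max(s.inner_left_mb for s in inner_segments)
        min_right = min(s.inner_right_mb for s in inner_segments)
        if min_left <= min_right:
            minimal = CandidateInterval(
                chromosome=chromosome,
                left_bound_marker=None,
                right_bound_marker=None,
                left_mb=max(min_left, left),
                right_mb=min(min_right, right),
                bounded_left=True,
                bounded_right=True,
            )
    return RefinedInterval(conservative=conservative, minimal=minimal)


def classify_recombinants(
    genotypes: GenotypeMatrix,
    genetic_map: GeneticMap,
    region: CandidateInterval,
) -> list[str]:
    """Animals with evidence of a breakpoint inside ``region``.

    An animal is listed iff two adjacent informative markers among those
    inside the region (plus the nearest marker flanking it on each side)
    carry discordant genotype codes — a genotype change between adjacent
    markers requires at least one crossover between them.
    """
    span_lo, span_hi = genetic_map.span_mb(region.chromosome)
    if region.left_mb < span_lo or region.right_mb > span_hi:
        raise ValidationError("region extends beyond the mapped chromosome span")
    names, positions = [], []
    for n in genotypes.marker_names:
        m = genetic_map.marker(n)
        if m.chromosome == region.chromosome:
            names.append(n)
            positions.append(m.position_mb)
    inside = [
        i for i, p in enumerate(positions) if region.left_mb <= p <= region.right_mb
    ]
    if not inside:
        return []
    lo = max(inside[0] - 1, 0)
    hi = min(inside[-1] + 1, len(names) - 1)
    window = names[lo : hi + 1]
    listed: list[str] = []
    for animal_id in genotypes.animal_ids:
        row = genotypes.row(animal_id)
        calls = [
            row[genotypes.marker_names.index(n)]
            for n in window
        ]
        informative = [c for c in calls if c is not GenotypeCall.MISSING]
        if any(a is not b for a, b in zip(informative, informative[1:])):
            listed.append(animal_id)
    return listed
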