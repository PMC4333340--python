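"""Forward simulation of experimental crosses.

Meiosis uses the Haldane (no-interference) model: between each pair of
adjacent loci a recombination occurs with probability
``haldane_recomb_fraction`` of their cM distance, drawn as an independent
Bernoulli per interval. The causal position is carried as a pseudo-locus so
its genotype is simulated exactly like a marker. Ancestry is tracked at
locus resolution; segment representations place breakpoints at interval
midpoints (the true crossover point is only known to lie between the
flanking loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .genome_model import (
    Anomaly,
    GeneticMap,
    GenotypeCall,
    GenotypeMatrix,
    PhenotypeRecord,
    Side,
    ValidationError,
    haldane_recomb_fraction,
)

# Ancestry coding inside haplotype arrays: 1 = carrier/donor, 0 = non-carrier.
CARRIER = 1
NONCARRIER = 0


@dataclass
class PenetranceModel:
    """Per-genotype penetrance plus anomaly-class and laterality parameters.

    Defaults: homozygous-carrier penetrance 0.134, heterozygotes half that
    (incomplete dominance), non-carriers zero; anomaly classes mixed
    0.678/0.188/0.134 (URA/URH/HUN) given affected; URA right-sided with
    probability 0.84. URH/HUN sides are uniform; bilateral HUN has a small
    configurable probability (default 0).
    """

    p_CC: float = 0.134
    p_CH: float = 0.067
    p_NN: float = 0.0
    class_mix: tuple[float, float, float] = (0.678, 0.188, 0.134)
    q_right: float = 0.84
    p_bilateral_hun: float = 0.0

    def __post_init__(self) -> None:
        probs = [self.p_CC, self.p_CH, self.p_NN, self.q_right, self.p_bilateral_hun]
        probs += list(self.class_mix)
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("all penetrance-model probabilities must be in [0,1]")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValidationError("class_mix must sum to 1")
        if not (
            min(self.p_NN, self.p_CC) <= self.p_CH <= max(self.p_NN, self.p_CC)
        ):
            raise ValidationError("p_CH must lie between p_NN and p_CC")

    def penetrance(self, n_carrier_alleles: int) -> float:
        return (self.p_NN, self.p_CH, self.p_CC)[n_carrier_alleles]


class Design(str, Enum):
    F2_INTERCROSS = "f2"
    BACKCROSS_TO_RECIPIENT = "backcross"
    CONGENIC_PROGRAM = "congenic"


@dataclass
class CrossDesign:
    design: Design
    n_progeny: int
    causal_chromosome: str
    causal_position_mb: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_progeny <= 0:
            raise ValidationError("n_progeny must be positive")


@dataclass(frozen=True)
class ChromosomeLoci:
    """Marker loci on one chromosome, optionally with a causal pseudo-locus."""

    chromosome: str
    names: tuple[str | None, ...]
    positions_mb: np.ndarray
    positions_cm: np.ndarray
    rec_fractions: np.ndarray  # between adjacent loci, length L-1
    causal_index: int | None

    @property
    def n_loci(self) -> int:
        return len(self.names)

    @property
    def marker_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n is not None]


def build_loci(
    genetic_map: GeneticMap,
    chromosome: str,
    causal_position_mb: float | None = None,
) -> ChromosomeLoci:
    markers = genetic_map.chromosome_markers(chromosome)
    if len(markers) < 2:
        raise ValidationError(
            f"chromosome {chromosome}: at least 2 markers required for mapping"
        )
    entries: list[tuple[float, str | None]] = [(m.position_mb, m.name) for m in markers]
    causal_index = None
    if causal_position_mb is not None:
        lo, hi = markers[0].position_mb, markers[-1].position_mb
        if not (lo <= causal_position_mb <= hi):
            raise ValidationError(
                f"causal position {causal_position_mb} outside chromosome "
                f"{chromosome} span [{lo}, {hi}]"
            )
        if causal_position_mb not in [p for p, _ in entries]:
            entries.append((causal_position_mb, None))
        entries.sort(key=lambda e: e[0])
        causal_index = next(
            i
            for i, (p, n) in enumerate(entries)
            if p == causal_position_mb and (n is None or causal_position_mb == p)
        )
    positions_mb = np.array([p for p, _ in entries])
    names = tuple(n for _, n in entries)
    cm_by_name = {m.name: m.cm(genetic_map.cm_per_mb) for m in markers}
    positions_cm = np.array(
        [
            cm_by_name[n] if n is not None else p * genetic_map.cm_per_mb
            for p, n in entries
        ]
    )
    rec = np.array(
        [haldane_recomb_fraction(d) for d in np.diff(positions_cm)]
    )
    return ChromosomeLoci(
        chromosome=chromosome,
        names=names,
        positions_mb=positions_mb,
        positions_cm=positions_cm,
        rec_fractions=rec,
        causal_index=causal_index,
    )


def _gamete_choosers(
    n: int, rec_fractions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, L) array choosing which parental haplotype each locus comes from."""
    n_loci = len(rec_fractions) + 1
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if n_loci == 1:
        return start
    switches = (rng.random((n, n_loci - 1)) < rec_fractions).astype(np.int8)
    return np.concatenate([start, start ^ (np.cumsum(switches, axis=1) & 1)], axis=1)


def simulate_gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    loci: ChromosomeLoci,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product of a parent, as per-locus ancestry."""
    hap_a, hap_b = parent_haplotypes
    if len(hap_a) != loci.n_loci or len(hap_b) != loci.n_loci:
        raise ValidationError("parent haplotype length does not match loci")
    chooser = _gamete_choosers(1, loci.rec_fractions, rng)[0]
    stacked = np.stack([hap_a, hap_b])
    return stacked[chooser, np.arange(loci.n_loci)]


def simulate_gametes(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    loci: ChromosomeLoci,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, L) gametes from one parent; vectorized Haldane meiosis."""
    hap_a, hap_b = parent_haplotypes
    choosers = _gamete_choosers(n, loci.rec_fractions, rng)
    stacked = np.stack([hap_a, hap_b])
    return stacked[choosers, np.arange(loci.n_loci)]


def ancestry_segments(
    haplotype: np.ndarray, loci: ChromosomeLoci
) -> list[tuple[float, float, int]]:
    """Tile the chromosome's cM span with (start_cm, end_cm, ancestry) segments.

    Breakpoints are placed at interval midpoints; the true crossover position
    is only localized to the interval between adjacent loci.
    """
    cm = loci.positions_cm
    segments: list[tuple[float, float, int]] = []
    start = float(cm[0])
    state = int(haplotype[0])
    for i in range(1, loci.n_loci):
        if haplotype[i] != state:
            mid = float((cm[i - 1] + cm[i]) / 2.0)
            segments.append((start, mid, state))
            start = mid
            state = int(haplotype[i])
    segments.append((start, float(cm[-1]), state))
    return segments


@dataclass
class SimulatedAnimal:
    """One simulated animal: diploid locus-ancestry per chromosome plus
    derived marker genotypes and the drawn phenotype."""

    id: str
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    loci: dict[str, ChromosomeLoci]
    phenotype: PhenotypeRecord | None = None

    def genotype_counts(self, chromosome: str) -> np.ndarray:
        a, b = self.haplotypes[chromosome]
        return a + b

    def genotype_calls(self, chromosome: str) -> list[GenotypeCall]:
        counts = self.genotype_counts(chromosome)
        table = {0: GenotypeCall.NN, 1: GenotypeCall.CH, 2: GenotypeCall.CC}
        return [table[int(counts[i])] for i in self.loci[chromosome].marker_indices]

    def segments(self, chromosome: str) -> tuple[list, list]:
        loc = self.loci[chromosome]
        a, b = self.haplotypes[chromosome]
        return ancestry_segments(a, loc), ancestry_segments(b, loc)


_CALL_TABLE = np.array(
    [GenotypeCall.NN, GenotypeCall.CH, GenotypeCall.CC], dtype=object
)


def draw_phenotypes(
    animal_ids: Sequence[str],
    carrier_allele_counts: np.ndarray,
    model: PenetranceModel,
    rng: np.random.Generator,
) -> list[PhenotypeRecord]:
    """Draw anomaly class and side for each animal given its causal genotype."""
    n = len(animal_ids)
    pen = np.array([model.p_NN, model.p_CH, model.p_CC])[carrier_allele_counts]
    affected = rng.random(n) < pen
    classes = rng.choice(3, size=n, p=list(model.class_mix))
    side_draw = rng.random(n)
    bilateral_draw = rng.random(n)
    records: list[PhenotypeRecord] = []
    for i, animal_id in enumerate(animal_ids):
        if not affected[i]:
            records.append(PhenotypeRecord(animal_id, Anomaly.NONE, Side.NA))
            continue
        anomaly = (Anomaly.URA, Anomaly.URH, Anomaly.HUN)[classes[i]]
        if anomaly is Anomaly.URA:
            side = Side.RIGHT if side_draw[i] < model.q_right else Side.LEFT
        elif anomaly is Anomaly.URH:
            side = Side.RIGHT if side_draw[i] < 0.5 else Side.LEFT
        else:  # HUN
            if bilateral_draw[i] < model.p_bilateral_hun:
                side = Side.BILATERAL
            else:
                side = Side.RIGHT if side_draw[i] < 0.5 else Side.LEFT
        records.append(PhenotypeRecord(animal_id, anomaly, side))
    return records


@dataclass
class SimulationResult:
    genotypes: GenotypeMatrix
    phenotypes: list[PhenotypeRecord]
    animals: list[SimulatedAnimal] | None = None
    causal_allele_counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.genotypes, self.phenotypes))


def _founder_haplotypes(loci: ChromosomeLoci, ancestry: int) -> np.ndarray:
    return np.full(loci.n_loci, ancestry, dtype=np.int8)


def _assemble_result(
    design: CrossDesign,
    genetic_map: GeneticMap,
    model: PenetranceModel,
    loci_by_chrom: dict[str, ChromosomeLoci],
    gametes_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    id_prefix: str,
    return_animals: bool,
) -> SimulationResult:
    n = design.n_progeny
    animal_ids = [f"{id_prefix}-{i + 1}" for i in range(n)]
    columns: list[np.ndarray] = []
    marker_names: list[str] = []
    for chrom, loc in loci_by_chrom.items():
        mat, pat = gametes_by_chrom[chrom]
        counts = mat + pat  # (n, L)
        idx = loc.marker_indices
        columns.append(counts[:, idx])
        marker_names.extend(loc.names[i] for i in idx)
    all_counts = np.concatenate(columns, axis=1)
    calls = [[_CALL_TABLE[c] for c in row] for row in all_counts]
    genotypes = GenotypeMatrix(
        animal_ids=animal_ids, marker_names=marker_names, calls=calls
    )
    causal_loc = loci_by_chrom[design.causal_chromosome]
    mat, pat = gametes_by_chrom[design.causal_chromosome]
    causal_counts = (mat + pat)[:, causal_loc.causal_index]
    phenotypes = draw_phenotypes(animal_ids, causal_counts, model, rng)
    animals = None
    if return_animals:
        animals = [
            SimulatedAnimal(
                id=animal_ids[i],
                haplotypes={
                    chrom: (
                        gametes_by_chrom[chrom][0][i],
                        gametes_by_chrom[chrom][1][i],
                    )
                    for chrom in loci_by_chrom
                },
                loci=loci_by_chrom,
                phenotype=phenotypes[i],
            )
            for i in range(n)
        ]
    return SimulationResult(
        genotypes=genotypes,
        phenotypes=phenotypes,
        animals=animals,
        causal_allele_counts=causal_counts,
        metadata={
            "design": design.design.value,
            "n_progeny": n,
            "seed": design.seed,
            "causal_chromosome": design.causal_chromosome,
            "causal_position_mb": design.causal_position_mb,
        },
    )


def simulate_f2(
    design: CrossDesign,
    genetic_map: GeneticMap,
    model: PenetranceModel,
    return_animals: bool = True,
) -> SimulationResult:
    """F2 intercross: F1 x F1, each F1 carrying one carrier and one
    non-carrier chromosome; single-marker genotypes segregate 1:2:1."""
    rng = np.random.default_rng(design.seed)
    loci_by_chrom: dict[str, ChromosomeLoci] = {}
    gametes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genetic_map.chromosomes():
        causal = (
            design.causal_position_mb if chrom == design.causal_chromosome else None
        )
        loc = build_loci(genetic_map, chrom, causal)
        loci_by_chrom[chrom] = loc
        f1 = (
            _founder_haplotypes(loc, CARRIER),
            _founder_haplotypes(loc, NONCARRIER),
        )
        maternal = simulate_gametes(f1, loc, design.n_progeny, rng)
        paternal = simulate_gametes(f1, loc, design.n_progeny, rng)
        gametes[chrom] = (maternal, paternal)
    if design.causal_chromosome not in loci_by_chrom:
        raise ValidationError(
            f"causal chromosome {design.causal_chromosome!r} not in map"
        )
    return _assemble_result(
        design, genetic_map, model, loci_by_chrom, gametes, rng, "F2", return_animals
    )


def simulate_backcross(
    design: CrossDesign,
    genetic_map: GeneticMap,
    model: PenetranceModel,
    carrier_parent_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    return_animals: bool = True,
) -> SimulationResult:
    """Backcross of a (by default F1) carrier parent to the recipient strain.

    ``carrier_parent_haplotypes`` lets a recombinant animal from a previous
    cross be progeny-tested: its own mosaic haplotypes are segregated.
    """
    rng = np.random.default_rng(design.seed)
    loci_by_chrom: dict[str, ChromosomeLoci] = {}
    gametes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genetic_map.chromosomes():
        causal = (
            design.causal_position_mb if chrom == design.causal_chromosome else None
        )
        loc = build_loci(genetic_map, chrom, causal)
        loci_by_chrom[chrom] = loc
        if carrier_parent_haplotypes is None:
            parent = (
                _founder_haplotypes(loc, CARRIER),
                _founder_haplotypes(loc, NONCARRIER),
            )
        else:
            parent = carrier_parent_haplotypes[chrom]
        from_parent = simulate_gametes(parent, loc, design.n_progeny, rng)
        from_recipient = np.zeros_like(from_parent)
        gametes[chrom] = (from_parent, from_recipient)
    return _assemble_result(
        design, genetic_map, model, loci_by_chrom, gametes, rng, "BC", return_animals
    )


# ---------------------------------------------------------------------------
# Marker-assisted congenic breeding


@dataclass
class GenerationRecord:
    generation: int
    label: str
    n_candidates: int
    n_heterozygous_candidates: int
    breeder_found: bool
    background_donor_fraction: float | None
    donor_interval_retained: bool


@dataclass
class CongenicReport:
    generations: list[GenerationRecord]
    success: bool
    failure_reason: str | None = None
    final_homozygous_founder: bool = False
    final_background_donor_fraction: float | None = None


def _background_donor_fraction(
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
    loci_by_chrom: dict[str, ChromosomeLoci],
    donor_chromosome: str,
) -> float:
    """Fraction of diploid background-marker alleles of donor ancestry."""
    total = 0
    donor = 0
    for chrom, loc in loci_by_chrom.items():
        if chrom == donor_chromosome:
            continue
        a, b = haplotypes[chrom]
        idx = loc.marker_indices
        donor += int(a[idx].sum() + b[idx].sum())
        total += 2 * len(idx)
    if total == 0:
        raise ValidationError("no background markers on other chromosomes")
    return donor / total


def simulate_congenic_program(
    genetic_map: GeneticMap,
    donor_interval: tuple[str, float, float],
    n_backcross_generations: int,
    negative_selection_start: int,
    rng: np.random.Generator | int,
    n_candidates_per_generation: int = 20,
) -> CongenicReport:
    """Marker-assisted backcross program introgressing a donor interval.

    Each generation, ``n_candidates_per_generation`` progeny of the current
    breeder x recipient are genotyped; a breeder heterozygous across every
    donor-interval marker is required. From ``negative_selection_start``
    onward the qualifying candidate with the fewest donor alleles at
    background markers is chosen (before that, the first qualifying one).
    A final intercross of two heterozygous siblings seeks a founder
    homozygous for donor alleles across the interval.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    chrom, left_mb, right_mb = donor_interval
    loci_by_chrom = {c: build_loci(genetic_map, c) for c in genetic_map.chromosomes()}
    if chrom not in loci_by_chrom:
        raise ValidationError(f"donor chromosome {chrom!r} not in map")
    donor_loc = loci_by_chrom[chrom]
    interval_idx = [
        i
        for i in donor_loc.marker_indices
        if left_mb <= donor_loc.positions_mb[i] <= right_mb
    ]
    if len(interval_idx) < 2:
        raise ValidationError("donor interval must be covered by >= 2 markers")
    _background_donor_fraction(
        {c: (np.zeros(l.n_loci), np.zeros(l.n_loci)) for c, l in loci_by_chrom.items()},
        loci_by_chrom,
        chrom,
    )  # validates background marker presence

    def is_het_across_interval(haps: dict) -> bool:
        a, b = haps[chrom]
        return bool(np.all((a[interval_idx] + b[interval_idx]) == 1))

    # Generation 0: F1, heterozygous everywhere.
    breeder = {
        c: (_founder_haplotypes(l, CARRIER), _founder_haplotypes(l, NONCARRIER))
        for c, l in loci_by_chrom.items()
    }
    generations = [
        GenerationRecord(
            generation=0,
            label="F1",
            n_candidates=1,
            n_heterozygous_candidates=1,
            breeder_found=True,
            background_donor_fraction=_background_donor_fraction(
                breeder, loci_by_chrom, chrom
            ),
            donor_interval_retained=True,
        )
    ]

    def backcross_candidates(parent: dict, n: int) -> list[dict]:
        cands: list[dict] = []
        per_chrom = {
            c: simulate_gametes(parent[c], loci_by_chrom[c], n, rng)
            for c in loci_by_chrom
        }
        for i in range(n):
            cands.append(
                {
                    c: (
                        per_chrom[c][i].astype(np.int8),
                        np.zeros(loci_by_chrom[c].n_loci, dtype=np.int8),
                    )
                    for c in loci_by_chrom
                }
            )
        return cands

    for gen in range(1, n_backcross_generations + 1):
        candidates = backcross_candidates(breeder, n_candidates_per_generation)
        het = [c for c in candidates if is_het_across_interval(c)]
        if not het:
            generations.append(
                GenerationRecord(
                    generation=gen,
                    label=f"N{gen + 1}",
                    n_candidates=len(candidates),
                    n_heterozygous_candidates=0,
                    breeder_found=False,
                    background_donor_fraction=None,
                    donor_interval_retained=False,
                )
            )
            return CongenicReport(
                generations=generations,
                success=False,
                failure_reason=(
                    f"no candidate heterozygous across the donor interval at "
                    f"backcross generation {gen}"
                ),
            )
        if gen >= negative_selection_start:
            breeder = min(
                het,
                key=lambda h: _background_donor_fraction(h, loci_by_chrom, chrom),
            )
        else:
            breeder = het[0]
        generations.append(
            GenerationRecord(
                generation=gen,
                label=f"N{gen + 1}",
                n_candidates=len(candidates),
                n_heterozygous_candidates=len(het),
                breeder_found=True,
                background_donor_fraction=_background_donor_fraction(
                    breeder, loci_by_chrom, chrom
                ),
                donor_interval_retained=True,
            )
        )

    # Final intercross: two heterozygous siblings -> homozygous founder.
    sibs = backcross_candidates(breeder, n_candidates_per_generation)
    het_sibs = [c for c in sibs if is_het_across_interval(c)]
    if len(het_sibs) < 2:
        return CongenicReport(
            generations=generations,
            success=False,
            failure_reason="fewer than 2 heterozygous siblings for final intercross",
        )
    sib_a, sib_b = het_sibs[0], het_sibs[1]
    founder = None
    for _ in range(n_candidates_per_generation):
        child = {
            c: (
                simulate_gamete(sib_a[c], loci_by_chrom[c], rng).astype(np.int8),
                simulate_gamete(sib_b[c], loci_by_chrom[c], rng).astype(np.int8),
            )
            for c in loci_by_chrom
        }
        a, b = child[chrom]
        if np.all((a[interval_idx] + b[interval_idx]) == 2):
            founder = child
            break
    if founder is None:
        return CongenicReport(
            generations=generations,
            success=False,
            failure_reason="no intercross progeny homozygous across the donor interval",
        )
    return CongenicReport(
        generations=generations,
        success=True,
        final_homozygous_founder=True,
        final_background_donor_fraction=_background_donor_fraction(
            founder, loci_by_chrom, chrom
        ),
    )
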