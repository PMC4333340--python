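import math

import numpy as np
import pytest

from finecross.cross_sim import (
    CrossDesign,
    Design,
    PenetranceModel,
    simulate_backcross,
    simulate_f2,
)
from finecross.fine_mapping import CandidateInterval
from finecross.fixtures import progeny_test_fixture, rno14_map
from finecross.genome_model import (
    GeneticMap,
    GenotypeCall,
    GenotypeMatrix,
    Marker,
    ValidationError,
)
from finecross.progeny_testing import (
    ProgenyTestResult,
    RecombinantSegment,
    classify_recombinants,
    infer_donor_segment,
    intersect_conferring_segments,
)

C, H, N = GenotypeCall.CC, GenotypeCall.CH, GenotypeCall.NN


@pytest.fixture
def five_marker_map():
    return GeneticMap(
        markers=[Marker(f"m{i}", "1", float(10 * (i + 1))) for i in range(5)]
    )


class TestInferDonorSegment:
    def test_all_het_spans_whole_map(self, five_marker_map):
        seg = infer_donor_segment("a", [H] * 5, five_marker_map, "1")
        assert (seg.inner_left_mb, seg.inner_right_mb) == (10.0, 50.0)
        assert (seg.outer_left_mb, seg.outer_right_mb) == (10.0, 50.0)
        assert seg.outer_left_marker is None and seg.outer_right_marker is None

    def test_forced_bounds(self, five_marker_map):
        seg = infer_donor_segment("a", [N, N, H, H, N], five_marker_map, "1")
        assert (seg.inner_left_mb, seg.inner_right_mb) == (30.0, 40.0)
        assert (seg.outer_left_mb, seg.outer_right_mb) == (20.0, 50.0)
        assert seg.outer_left_marker == "m1"
        assert seg.outer_right_marker == "m4"
        assert seg.uncertainty_gaps_mb == (10.0, 10.0)

    def test_no_donor_segment(self, five_marker_map):
        seg = infer_donor_segment("a", [N] * 5, five_marker_map, "1")
        assert not seg.has_donor_segment

    def test_missing_ignored(self, five_marker_map):
        calls = [N, GenotypeCall.MISSING, H, GenotypeCall.MISSING, N]
        seg = infer_donor_segment("a", calls, five_marker_map, "1")
        assert (seg.inner_left_mb, seg.inner_right_mb) == (30.0, 30.0)
        assert (seg.outer_left_mb, seg.outer_right_mb) == (10.0, 50.0)

    def test_simulated_truth_contained(self, gmap):
        # 500 simulated backcross chromosomes: the true donor-ancestry loci
        # always lie within the inferred outer segment, and the inferred
        # inner segment within the true ancestry span
        design = CrossDesign(
            design=Design.BACKCROSS_TO_RECIPIENT,
            n_progeny=500,
            causal_chromosome="14",
            causal_position_mb=34.95,
            seed=31,
        )
        result = simulate_backcross(design, gmap, PenetranceModel())
        for animal in result.animals:
            loci = animal.loci["14"]
            donor_hap = animal.haplotypes["14"][0]  # the F1-derived gamete
            calls = animal.genotype_calls("14")
            seg = infer_donor_segment(animal.id, calls, gmap, "14")
            carrier_loci = np.where(donor_hap == 1)[0]
            if len(carrier_loci) == 0:
                marker_carrier = [i for i in loci.marker_indices if donor_hap[i] == 1]
                assert not marker_carrier
                continue
            if not seg.has_donor_segment:
                # donor ancestry present but not observed at any marker
                # (confined to the causal pseudo-locus between markers)
                marker_carrier = [i for i in loci.marker_indices if donor_hap[i] == 1]
                assert not marker_carrier
                continue
            true_lo = loci.positions_mb[carrier_loci[0]]
            true_hi = loci.positions_mb[carrier_loci[-1]]
            assert seg.inner_left_mb >= true_lo - 1e-12
            assert seg.inner_right_mb <= true_hi + 1e-12
            # every donor locus within the outer bounds (breakpoints inside gaps)
            marker_carrier_pos = [
                loci.positions_mb[i] for i in loci.marker_indices if donor_hap[i] == 1
            ]
            for pos in marker_carrier_pos:
                assert seg.outer_left_mb <= pos <= seg.outer_right_mb


def make_segment(animal, outer, inner=None, chrom="1"):
    return RecombinantSegment(
        animal_id=animal,
        chromosome=chrom,
        inner_left_mb=None if inner is None else inner[0],
        inner_right_mb=None if inner is None else inner[1],
        outer_left_mb=outer[0],
        outer_right_mb=outer[1],
        outer_left_marker="L",
        outer_right_marker="R",
    )


class TestIntersectConferringSegments:
    def test_worked_example_fixture_bounds(self, gmap):
        results = progeny_test_fixture(gmap)
        refined = intersect_conferring_segments(results, gmap)
        assert refined.conservative.left_bound_marker == "D14Uwm8"
        assert refined.conservative.right_bound_marker == "D14Uwm9"
        assert (refined.conservative.left_mb, refined.conservative.right_mb) == (
            34.73,
            35.11,
        )

    def test_single_segment_identity(self, five_marker_map):
        seg = make_segment("a", (20.0, 50.0), (30.0, 40.0))
        refined = intersect_conferring_segments(
            [ProgenyTestResult(seg, 10, 2)], five_marker_map
        )
        assert (refined.conservative.left_mb, refined.conservative.right_mb) == (
            20.0,
            50.0,
        )
        assert (refined.minimal.left_mb, refined.minimal.right_mb) == (30.0, 40.0)

    def test_nonconferring_segments_ignored(self, five_marker_map):
        wide = ProgenyTestResult(make_segment("a", (10.0, 50.0), (20.0, 40.0)), 10, 1)
        narrow_nonconferring = ProgenyTestResult(
            make_segment("b", (30.0, 35.0), (31.0, 33.0)), 10, 0
        )
        refined = intersect_conferring_segments(
            [wide, narrow_nonconferring], five_marker_map
        )
        assert (refined.conservative.left_mb, refined.conservative.right_mb) == (
            10.0,
            50.0,
        )

    def test_requires_a_conferring_segment(self, five_marker_map):
        seg = ProgenyTestResult(make_segment("a", (10.0, 50.0)), 10, 0)
        with pytest.raises(ValidationError):
            intersect_conferring_segments([seg], five_marker_map)

    def test_empty_intersection_names_segments(self, five_marker_map):
        a = ProgenyTestResult(make_segment("segA", (10.0, 20.0)), 5, 1)
        b = ProgenyTestResult(make_segment("segB", (40.0, 50.0)), 5, 1)
        with pytest.raises(ValidationError, match="segA.*segB"):
            intersect_conferring_segments([a, b], five_marker_map)

    def test_prior_clips(self, five_marker_map):
        seg = ProgenyTestResult(make_segment("a", (10.0, 50.0)), 5, 1)
        prior = CandidateInterval(
            chromosome="1",
            left_bound_marker="m1",
            right_bound_marker="m3",
            left_mb=20.0,
            right_mb=40.0,
            bounded_left=True,
            bounded_right=True,
        )
        refined = intersect_conferring_segments([seg], five_marker_map, prior=prior)
        assert (refined.conservative.left_mb, refined.conservative.right_mb) == (
            20.0,
            40.0,
        )

    def test_conservative_contains_minimal(self, five_marker_map, rng):
        for _ in range(200):
            results = []
            for k in range(int(rng.integers(1, 5))):
                lo, hi = np.sort(rng.uniform(10, 50, size=2))
                pad_l, pad_r = rng.uniform(0, 5, size=2)
                results.append(
                    ProgenyTestResult(
                        make_segment(f"s{k}", (lo - pad_l, hi + pad_r), (lo, hi)),
                        10,
                        int(rng.integers(1, 4)),
                    )
                )
            try:
                refined = intersect_conferring_segments(results, five_marker_map)
            except ValidationError:
                continue
            if refined.minimal is not None:
                assert refined.conservative.left_mb <= refined.minimal.left_mb
                assert refined.conservative.right_mb >= refined.minimal.right_mb

    def test_adding_segment_never_widens(self, five_marker_map, rng):
        for _ in range(100):
            segs = []
            for k in range(3):
                lo, hi = np.sort(rng.uniform(10, 50, size=2))
                segs.append(
                    ProgenyTestResult(make_segment(f"s{k}", (lo - 2, hi + 2)), 10, 1)
                )
            try:
                base = intersect_conferring_segments(segs[:2], five_marker_map)
                grown = intersect_conferring_segments(segs, five_marker_map)
            except ValidationError:
                continue
            assert grown.conservative.width_mb <= base.conservative.width_mb + 1e-12

    def test_matches_brute_force_positionwise_oracle(self, five_marker_map, rng):
        # a position is in the conservative interval iff it is inside the
        # outer bounds of every conferring segment
        grid = np.linspace(10, 50, 401)
        for _ in range(200):
            results = []
            for k in range(int(rng.integers(1, 5))):
                lo, hi = np.sort(
                    rng.choice(grid, size=2, replace=False)
                )
                results.append(
                    ProgenyTestResult(make_segment(f"s{k}", (lo, hi)), 10, 1)
                )
            inside = np.ones_like(grid, dtype=bool)
            for r in results:
                inside &= (grid >= r.segment.outer_left_mb) & (
                    grid <= r.segment.outer_right_mb
                )
            if not inside.any():
                with pytest.raises(ValidationError):
                    intersect_conferring_segments(results, five_marker_map)
                continue
            refined = intersect_conferring_segments(results, five_marker_map)
            assert refined.conservative.left_mb == pytest.approx(grid[inside][0])
            assert refined.conservative.right_mb == pytest.approx(grid[inside][-1])

    def test_phenocopy_free_containment(self, gmap):
        # conservative interval contains the causal marker position in all
        # 200 phenocopy-free replicates
        rng = np.random.default_rng(55)
        model = PenetranceModel(p_CC=0.9, p_CH=0.45, p_NN=0.0)
        hits = 0
        total = 0
        for _ in range(200):
            design = CrossDesign(
                design=Design.BACKCROSS_TO_RECIPIENT,
                n_progeny=40,
                causal_chromosome="14",
                causal_position_mb=35.11,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            result = simulate_backcross(design, gmap, model)
            results = []
            for animal in result.animals:
                calls = animal.genotype_calls("14")
                seg = infer_donor_segment(animal.id, calls, gmap, "14")
                if not seg.has_donor_segment:
                    continue
                results.append(
                    ProgenyTestResult(seg, 1, int(animal.phenotype.affected))
                )
            conferring = [r for r in results if r.confers]
            if not conferring:
                continue
            total += 1
            refined = intersect_conferring_segments(conferring, gmap)
            hits += refined.conservative.contains(35.11)
        assert total > 150
        assert hits == total


class TestClassifyRecombinants:
    REGION = CandidateInterval(
        chromosome="14",
        left_bound_marker="D14Uwm7",
        right_bound_marker="D14Rat65",
        left_mb=34.25,
        right_mb=36.41,
        bounded_left=True,
        bounded_right=True,
    )

    def test_uniform_het_not_listed(self, gmap):
        names = gmap.marker_names()
        matrix = GenotypeMatrix(
            animal_ids=["a"], marker_names=names, calls=[[H] * len(names)]
        )
        assert classify_recombinants(matrix, gmap, self.REGION) == []

    def test_discordant_adjacent_listed(self, gmap):
        names = gmap.marker_names()
        calls = [N, N, N, H, H, H, H, H, H]  # switch between 34.25 and 34.73
        matrix = GenotypeMatrix(animal_ids=["a"], marker_names=names, calls=[calls])
        assert classify_recombinants(matrix, gmap, self.REGION) == ["a"]

    def test_region_outside_map_rejected(self, gmap):
        bad = CandidateInterval(
            chromosome="14",
            left_bound_marker=None,
            right_bound_marker=None,
            left_mb=1.0,
            right_mb=99.0,
            bounded_left=True,
            bounded_right=True,
        )
        with pytest.raises(ValidationError):
            classify_recombinants(matrix := GenotypeMatrix(
                animal_ids=[], marker_names=gmap.marker_names(), calls=[]
            ), gmap, bad)

    def test_listed_fraction_matches_haldane_expectation(self, gmap):
        # fraction with a genotype change across the window approximates the
        # probability of >= 1 crossover in its cM span (double events that
        # preserve the genotype code are O(r^2) and negligible at this scale)
        n = 5000
        design = CrossDesign(
            design=Design.F2_INTERCROSS,
            n_progeny=n,
            causal_chromosome="14",
            causal_position_mb=34.95,
            seed=17,
        )
        result = simulate_f2(
            design, gmap, PenetranceModel(p_CC=0, p_CH=0), return_animals=False
        )
        listed = classify_recombinants(result.genotypes, gmap, self.REGION)
        # window spans markers 22.00 .. 42.72 Mb (nearest flanks included)
        from finecross.genome_model import haldane_recomb_fraction

        positions = [22.00, 34.25, 34.73, 34.95, 35.11, 36.25, 36.41, 42.72]
        no_rec = 1.0
        for a, b in zip(positions, positions[1:]):
            no_rec *= 1 - haldane_recomb_fraction((b - a) * 0.5)
        expected = 1 - no_rec**2
        observed = len(listed) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se
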