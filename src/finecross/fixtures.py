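"""Built-in fixtures: marker map, genotype patterns, printed counts and the
primer/allele table used by the worked examples and the test suite.

Everything here is generated programmatically; ``make_fixture_files`` writes
the same content to plain-text interchange files (TSV/VCF/JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

from .genome_model import (
    Anomaly,
    GeneticMap,
    GenotypeCall,
    GenotypeMatrix,
    Marker,
    PhenotypeRecord,
    Side,
    write_genotypes,
    write_map,
    write_phenotypes,
)
from .progeny_testing import ProgenyTestResult, RecombinantSegment
from .variant_screen import StrainVariantCall

CHROM = "14"

# RNO14 microsatellite markers with their physical positions (Mb).
RNO14_MARKERS: list[tuple[str, float]] = [
    ("D14Rat78", 17.42),
    ("D14Arb6", 22.00),
    ("D14Uwm7", 34.25),
    ("D14Uwm8", 34.73),
    ("D14Uwm9", 35.11),
    ("D14Uwm12", 36.25),
    ("D14Rat65", 36.41),
    ("D14Rat15", 42.72),
    ("D14Rat88", 65.96),
]

# Printed counts from the F2 cross and the embryo staining series.
F2_COUNTS = {
    "n_total": 4994,
    "n_affected": 351,
    "n_ura": 238,
    "n_urh": 66,
    "n_hun": 47,
    "n_ura_right": 200,
}
EMBRYO_COUNTS = {"n_abnormal": 6, "n_total": 75}

# Congenic-strain anomaly counts reconstructed from percent incidence and n.
CONGENIC_COUNTS = {
    "ACI": {"affected": round(0.134 * 216), "n": 216},
    "Con1": {"affected": round(0.206 * 238), "n": 238},
    "Con2": {"affected": round(0.117 * 298), "n": 298},
}


def rno14_map(cm_per_mb: float = 0.5) -> GeneticMap:
    return GeneticMap(
        markers=[Marker(name, CHROM, pos) for name, pos in RNO14_MARKERS],
        cm_per_mb=cm_per_mb,
    )


def _calls(pattern: str) -> list[GenotypeCall]:
    return [GenotypeCall.from_symbol(s) for s in pattern]


def exclusion_fixture() -> tuple[GenotypeMatrix, list[PhenotypeRecord]]:
    """54 affected recombinant animals whose exclusion pattern pins the
    candidate interval between the markers at 34.25 and 36.25 Mb.

    Left recombinants are homozygous non-carrier up to and including
    34.25 Mb; right recombinants from 36.25 Mb outward. The two interior
    markers are never homozygous non-carrier in an affected animal.
    """
    names = [m for m, _ in RNO14_MARKERS]
    left_pattern = _calls("NNNHHHHHH")
    right_pattern = _calls("HHHHHNNNN")
    animal_ids, rows, phenotypes = [], [], []
    for i in range(54):
        animal_id = f"F2-R{i + 1:02d}"
        animal_ids.append(animal_id)
        rows.append(list(left_pattern if i < 27 else right_pattern))
        side = Side.RIGHT if i % 5 != 0 else Side.LEFT
        phenotypes.append(PhenotypeRecord(animal_id, Anomaly.URA, side))
    return (
        GenotypeMatrix(animal_ids=animal_ids, marker_names=names, calls=rows),
        phenotypes,
    )


def hooded_inclusion_fixture() -> tuple[GenotypeMatrix, list[PhenotypeRecord]]:
    """Phenotype-positive animals homozygous for the recessive (non-carrier)
    allele only strictly inside 22.00-42.72 Mb; at each marker at or outside
    those flanks at least one positive animal is heterozygous."""
    names = [m for m, _ in RNO14_MARKERS]
    type_a = _calls("HHNNNNNNN")  # heterozygous at and left of 22.00
    type_b = _calls("NNNNNNNHH")  # heterozygous at and right of 42.72
    animal_ids, rows, phenotypes = [], [], []
    for i in range(20):
        animal_id = f"F2-H{i + 1:02d}"
        animal_ids.append(animal_id)
        rows.append(list(type_a if i < 10 else type_b))
        phenotypes.append(PhenotypeRecord(animal_id, Anomaly.URA, Side.RIGHT))
    return (
        GenotypeMatrix(animal_ids=animal_ids, marker_names=names, calls=rows),
        phenotypes,
    )


def progeny_test_fixture(genetic_map: GeneticMap) -> list[ProgenyTestResult]:
    """Six phenotype-conferring recombinant chromosomes whose outer-bound
    intersection is the 34.73-35.11 Mb interval."""
    from .progeny_testing import infer_donor_segment

    names = [m for m, _ in RNO14_MARKERS]
    patterns = {
        "BC-A": "NNNNHHHHH",  # donor right of 34.73: left outer bound there
        "BC-B": "HHHHNNNNN",  # donor left of 35.11: right outer bound there
        "BC-C": "NNNHHHHHH",
        "BC-D": "NNHHHHHHH",
        "BC-E": "HHHHHNNNN",
        "BC-F": "HHHHHHNNN",
    }
    progeny = {
        "BC-A": (24, 2),
        "BC-B": (31, 3),
        "BC-C": (18, 1),
        "BC-D": (22, 2),
        "BC-E": (27, 1),
        "BC-F": (19, 2),
    }
    results = []
    for animal_id, pattern in patterns.items():
        segment = infer_donor_segment(
            animal_id, _calls(pattern), genetic_map, CHROM, marker_names=names
        )
        tested, affected = progeny[animal_id]
        results.append(
            ProgenyTestResult(
                segment=segment, n_progeny_tested=tested, n_affected=affected
            )
        )
    return results


# ---------------------------------------------------------------------------
# Multi-strain variant calls at the five intragenic SNPs, including the two
# positions where whole-genome sequences of one strain disagree internally.

KIT_SNP_POSITIONS = [34_947_632, 34_945_425, 34_945_200, 34_904_134, 34_903_999]

STRAIN_SEQUENCES = {
    "ACI": ["ACI-1", "ACI-2"],
    "BN": ["BN-1", "BN-2"],
    "COP": ["COP-1"],
    "F344": ["F344-1"],
}


def kit_snp_calls() -> list[StrainVariantCall]:
    """Per-sequence states at the five SNPs: the shared variants are carried
    by ACI, COP and F344 alike (hence never ACI-unique), and two positions
    are internally discordant between sequences of a single strain."""
    # is_alt per sequence; BN (reference strain) is always reference.
    states: dict[int, dict[str, bool]] = {
        34_947_632: {"ACI-1": True, "ACI-2": True, "COP-1": True, "F344-1": True},
        34_945_425: {"ACI-1": True, "ACI-2": True, "COP-1": True, "F344-1": True},
        # one of two ACI sequences matches the reference here
        34_945_200: {"ACI-1": True, "ACI-2": False, "COP-1": True, "F344-1": False},
        34_904_134: {"ACI-1": True, "ACI-2": True, "COP-1": True, "F344-1": True},
        # 3' UTR variant: ACI sequences disagree; COP carries it too
        34_903_999: {"ACI-1": True, "ACI-2": False, "COP-1": True, "F344-1": False},
    }
    calls = []
    for pos in KIT_SNP_POSITIONS:
        for strain, sequences in STRAIN_SEQUENCES.items():
            for seq in sequences:
                calls.append(
                    StrainVariantCall(
                        strain=strain,
                        sequence_id=seq,
                        chromosome=CHROM,
                        position=pos,
                        ref="A",
                        alt="G",
                        is_alt=states[pos].get(seq, False),
                    )
                )
    return calls


def write_kit_snp_vcf(vcf_path: str | Path, samples_path: str | Path) -> None:
    """Write the SNP fixture as an uncompressed VCF plus sample mapping."""
    sequences = [s for seqs in STRAIN_SEQUENCES.values() for s in seqs]
    calls = kit_snp_calls()
    by_pos: dict[int, dict[str, bool]] = {}
    for c in calls:
        by_pos.setdefault(c.position, {})[c.sequence_id] = c.is_alt
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sequences),
    ]
    for pos in sorted(KIT_SNP_POSITIONS):
        gts = ["1/1" if by_pos[pos][s] else "0/0" for s in sequences]
        lines.append(
            f"{CHROM}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    sample_lines = ["sample\tstrain\tsequence_id"]
    for strain, seqs in STRAIN_SEQUENCES.items():
        for seq in seqs:
            sample_lines.append(f"{seq}\t{strain}\t{seq}")
    Path(samples_path).write_text("\n".join(sample_lines) + "\n")


def make_fixture_files(output_dir: str | Path) -> dict[str, Path]:
    """Write every built-in fixture to plain-text files; returns the paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gmap = rno14_map()

    paths["map"] = out / "rno14_map.tsv"
    write_map(gmap, paths["map"])

    genotypes, phenotypes = exclusion_fixture()
    paths["exclusion_genotypes"] = out / "exclusion_genotypes.tsv"
    paths["exclusion_phenotypes"] = out / "exclusion_phenotypes.tsv"
    write_genotypes(genotypes, paths["exclusion_genotypes"])
    write_phenotypes(phenotypes, paths["exclusion_phenotypes"])

    genotypes, phenotypes = hooded_inclusion_fixture()
    paths["hooded_genotypes"] = out / "hooded_genotypes.tsv"
    paths["hooded_phenotypes"] = out / "hooded_phenotypes.tsv"
    write_genotypes(genotypes, paths["hooded_genotypes"])
    write_phenotypes(phenotypes, paths["hooded_phenotypes"])

    results = progeny_test_fixture(gmap)
    seg_lines = [
        "animal\tchrom\tinner_left_mb\tinner_right_mb\touter_left_mb"
        "\touter_right_mb\tn_tested\tn_affected"
    ]
    for r in results:
        s = r.segment
        seg_lines.append(
            f"{s.animal_id}\t{s.chromosome}\t{s.inner_left_mb}\t{s.inner_right_mb}"
            f"\t{s.outer_left_mb}\t{s.outer_right_mb}"
            f"\t{r.n_progeny_tested}\t{r.n_affected}"
        )
    paths["progeny_segments"] = out / "progeny_segments.tsv"
    paths["progeny_segments"].write_text("\n".join(seg_lines) + "\n")

    paths["counts"] = out / "counts.json"
    paths["counts"].write_text(
        json.dumps(
            {
                "f2": F2_COUNTS,
                "embryo": EMBRYO_COUNTS,
                "congenic": CONGENIC_COUNTS,
            },
            indent=2,
        )
        + "\n"
    )

    primer_lines = [
        "pair\tempty_site_product_bp\trequires_internal_site\tinternal_product_bp",
        "AB\t1006\tfalse\t",
        "CD\t\ttrue\t997",
    ]
    paths["primer_pairs"] = out / "primer_pairs.tsv"
    paths["primer_pairs"].write_text("\n".join(primer_lines) + "\n")
    allele_lines = [
        "allele\tinsert_length_bp\tcontains_internal_primer_site",
        "self\t0\tfalse",
        "irish\t584\tfalse",
        "hooded\t7098\ttrue",
    ]
    paths["insertion_alleles"] = out / "insertion_alleles.tsv"
    paths["insertion_alleles"].write_text("\n".join(allele_lines) + "\n")

    paths["kit_vcf"] = out / "kit_snps.vcf"
    paths["kit_samples"] = out / "kit_samples.tsv"
    write_kit_snp_vcf(paths["kit_vcf"], paths["kit_samples"])
    return paths
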