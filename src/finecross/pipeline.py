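"""End-to-end composition: simulate an F2 cross, exclusion-map the affected
animals, refine by progeny testing of recombinants, and summarize incidence
and laterality. Deterministic given the seed; emits a machine-readable run
manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import finecross

from .cross_sim import (
    CrossDesign,
    Design,
    PenetranceModel,
    simulate_backcross,
    simulate_f2,
)
from .fine_mapping import CandidateInterval, map_dominant_exclusion
from .fixtures import rno14_map
from .genome_model import (
    Anomaly,
    GeneticMap,
    Side,
    read_map,
    write_genotypes,
    write_phenotypes,
)
from .incidence_stats import incidence, side_bias_test
from .progeny_testing import (
    ProgenyTestResult,
    classify_recombinants,
    infer_donor_segment,
    intersect_conferring_segments,
)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int
    n_f2: int = 2000
    map_path: str | None = None  # default: built-in RNO14 marker map
    causal_chromosome: str = "14"
    causal_position_mb: float = 34.95
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    tolerance: int = 0
    n_progeny_per_test: int = 30
    max_recombinants_tested: int = 12
    out_prefix: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        pen = data.pop("penetrance", None)
        if isinstance(pen, dict):
            if "class_mix" in pen:
                pen["class_mix"] = tuple(pen["class_mix"])
            data["penetrance"] = PenetranceModel(**pen)
        return cls(**data)


@dataclass
class PipelineResult:
    prior_interval: CandidateInterval | None
    refined_interval: CandidateInterval | None
    progeny_results: list[ProgenyTestResult]
    stats: dict
    manifest: dict


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _interval_summary(interval: CandidateInterval | None) -> dict | None:
    if interval is None:
        return None
    return {
        "chromosome": interval.chromosome,
        "left_bound_marker": interval.left_bound_marker,
        "right_bound_marker": interval.right_bound_marker,
        "left_mb": interval.left_mb,
        "right_mb": interval.right_mb,
        "width_mb": interval.width_mb,
        "bounded_left": interval.bounded_left,
        "bounded_right": interval.bounded_right,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    # --- stage: inputs
    if config.map_path is not None:
        if not Path(config.map_path).exists():
            raise PipelineError("inputs", f"map file not found: {config.map_path}")
        genetic_map: GeneticMap = read_map(config.map_path)
    else:
        genetic_map = rno14_map()

    # --- stage: simulate
    design = CrossDesign(
        design=Design.F2_INTERCROSS,
        n_progeny=config.n_f2,
        causal_chromosome=config.causal_chromosome,
        causal_position_mb=config.causal_position_mb,
        seed=config.seed,
    )
    result = simulate_f2(design, genetic_map, config.penetrance, return_animals=True)
    affected_ids = [p.animal_id for p in result.phenotypes if p.affected]
    if not affected_ids:
        raise PipelineError("mapping", "no affected animals in simulated cross")

    # --- stage: exclusion mapping
    affected_genotypes = result.genotypes.subset_animals(affected_ids)
    report = map_dominant_exclusion(affected_genotypes, genetic_map, config.tolerance)
    prior = report.best_interval
    if prior is None:
        raise PipelineError("mapping", report.diagnostic or "no candidate interval")

    # --- stage: progeny testing
    rng = np.random.default_rng(config.seed + 1)
    recombinants = classify_recombinants(affected_genotypes, genetic_map, prior)
    progeny_results: list[ProgenyTestResult] = []
    animals_by_id = {a.id: a for a in (result.animals or [])}
    for animal_id in recombinants[: config.max_recombinants_tested]:
        animal = animals_by_id[animal_id]
        bc_design = CrossDesign(
            design=Design.BACKCROSS_TO_RECIPIENT,
            n_progeny=config.n_progeny_per_test,
            causal_chromosome=config.causal_chromosome,
            causal_position_mb=config.causal_position_mb,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bc = simulate_backcross(
            bc_design,
            genetic_map,
            config.penetrance,
            carrier_parent_haplotypes=animal.haplotypes,
            return_animals=False,
        )
        n_affected = sum(1 for p in bc.phenotypes if p.affected)
        segment = infer_donor_segment(
            animal_id,
            affected_genotypes.row(animal_id),
            genetic_map,
            config.causal_chromosome,
            marker_names=affected_genotypes.marker_names,
        )
        if not segment.has_donor_segment:
            continue
        progeny_results.append(
            ProgenyTestResult(
                segment=segment,
                n_progeny_tested=config.n_progeny_per_test,
                n_affected=n_affected,
            )
        )
    refined = prior
    conferring = [r for r in progeny_results if r.confers]
    if conferring:
        refined = intersect_conferring_segments(
            conferring, genetic_map, prior=prior
        ).conservative

    # --- stage: statistics
    n = len(result.phenotypes)
    by_class = {
        cls: sum(1 for p in result.phenotypes if p.anomaly is cls)
        for cls in (Anomaly.URA, Anomaly.URH, Anomaly.HUN)
    }
    ura_unilateral = [
        p
        for p in result.phenotypes
        if p.anomaly is Anomaly.URA and p.side in (Side.LEFT, Side.RIGHT)
    ]
    stats: dict = {
        "n": n,
        "affected": incidence(len(affected_ids), n).__dict__,
        "by_class": {
            cls.value: incidence(count, n).__dict__
            for cls, count in by_class.items()
        },
    }
    if ura_unilateral:
        k_right = sum(1 for p in ura_unilateral if p.side is Side.RIGHT)
        stats["ura_side_bias"] = {
            "k_right": k_right,
            "n_unilateral": len(ura_unilateral),
            "p_value": side_bias_test(k_right, len(ura_unilateral)),
        }

    manifest = {
        "package": "finecross",
        "version": finecross.__version__,
        "seed": config.seed,
        "parameters": {
            "n_f2": config.n_f2,
            "causal_chromosome": config.causal_chromosome,
            "causal_position_mb": config.causal_position_mb,
            "tolerance": config.tolerance,
            "n_progeny_per_test": config.n_progeny_per_test,
            "max_recombinants_tested": config.max_recombinants_tested,
            "penetrance": {
                "p_CC": config.penetrance.p_CC,
                "p_CH": config.penetrance.p_CH,
                "p_NN": config.penetrance.p_NN,
                "class_mix": list(config.penetrance.class_mix),
                "q_right": config.penetrance.q_right,
                "p_bilateral_hun": config.penetrance.p_bilateral_hun,
            },
        },
        "inputs": {
            "map": (
                {"path": config.map_path, "sha256": _sha256(config.map_path)}
                if config.map_path
                else {"builtin": "rno14"}
            )
        },
        "n_affected": len(affected_ids),
        "n_recombinants": len(recombinants),
        "prior_interval": _interval_summary(prior),
        "refined_interval": _interval_summary(refined),
    }

    if config.out_prefix:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_genotypes(result.genotypes, f"{prefix}.genotypes.tsv")
        write_phenotypes(result.phenotypes, f"{prefix}.phenotypes.tsv")
        Path(f"{prefix}.stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True) + "\n"
        )
        Path(f"{prefix}.manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return PipelineResult(
        prior_interval=prior,
        refined_interval=refined,
        progeny_results=progeny_results,
        stats=stats,
        manifest=manifest,
    )
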