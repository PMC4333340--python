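"""Shared domain types: genetic maps, genotype/phenotype tables, map functions.

Coordinates are physical megabases (Mb) as printed on marker maps; genetic
positions in centimorgans (cM) are derived through a configurable linear
rate (default 0.5 cM/Mb) unless supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_CM_PER_MB = 0.5


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class GenotypeCall(str, Enum):
    """Strain-role-based genotype code at a marker.

    CC: homozygous for the carrier (donor) allele, e.g. ACI.
    CH: heterozygous.
    NN: homozygous for the non-carrier (recipient) allele, e.g. BN or COP.
    MISSING: no call; non-informative everywhere downstream.
    """

    CC = "C"
    CH = "H"
    NN = "N"
    MISSING = "-"

    @classmethod
    def from_symbol(cls, symbol: str) -> "GenotypeCall":
        try:
            return cls(symbol)
        except ValueError:
            raise ValidationError(f"unknown genotype symbol {symbol!r}") from None


class Anomaly(str, Enum):
    NONE = "NONE"
    URA = "URA"
    URH = "URH"
    HUN = "HUN"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BILATERAL = "BILATERAL"
    NA = "NA"


def mb_to_cm(position_mb: float, cm_per_mb: float = DEFAULT_CM_PER_MB) -> float:
    """Convert a physical position (Mb) to a genetic position (cM) linearly."""
    if position_mb < 0:
        raise ValidationError(f"position_mb must be non-negative, got {position_mb}")
    if cm_per_mb <= 0:
        raise ValidationError(f"cm_per_mb must be positive, got {cm_per_mb}")
    return position_mb * cm_per_mb


def haldane_recomb_fraction(distance_cm: float) -> float:
    """Recombination fraction for a genetic distance under the Haldane
    (no-interference) map function: 0.5 * (1 - exp(-2d/100))."""
    if distance_cm < 0:
        raise ValidationError(f"distance_cm must be non-negative, got {distance_cm}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cm / 100.0))


@dataclass(frozen=True)
class Marker:
    """A mapped marker with a physical and (derived or supplied) genetic position."""

    name: str
    chromosome: str
    position_mb: float
    position_cm: float | None = None

    def __post_init__(self) -> None:
        if self.position_mb < 0:
            raise ValidationError(
                f"marker {self.name}: position_mb must be non-negative"
            )

    def cm(self, cm_per_mb: float = DEFAULT_CM_PER_MB) -> float:
        if self.position_cm is not None:
            return self.position_cm
        return mb_to_cm(self.position_mb, cm_per_mb)


@dataclass
class GeneticMap:
    """Ordered markers grouped by chromosome, plus the Mb->cM conversion rate."""

    markers: list[Marker]
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValidationError("cm_per_mb must be positive")
        seen: set[str] = set()
        for m in self.markers:
            if m.name in seen:
                raise ValidationError(f"duplicate marker name {m.name!r}")
            seen.add(m.name)
        for chrom in self.chromosomes():
            positions = [m.position_mb for m in self.chromosome_markers(chrom)]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValidationError(
                    f"marker positions on chromosome {chrom} not strictly increasing"
                )

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if m.chromosome not in out:
                out.append(m.chromosome)
        return out

    def chromosome_markers(self, chromosome: str) -> list[Marker]:
        return [m for m in self.markers if m.chromosome == chromosome]

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def positions_cm(self, chromosome: str) -> list[float]:
        return [m.cm(self.cm_per_mb) for m in self.chromosome_markers(chromosome)]

    def span_mb(self, chromosome: str) -> tuple[float, float]:
        ms = self.chromosome_markers(chromosome)
        if not ms:
            raise KeyError(chromosome)
        return ms[0].position_mb, ms[-1].position_mb


@dataclass
class GenotypeMatrix:
    """Animals x markers grid of genotype calls."""

    animal_ids: list[str]
    marker_names: list[str]
    calls: list[list[GenotypeCall]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.animal_ids):
            raise ValidationError("row count does not match animal_ids")
        for row in self.calls:
            if len(row) != len(self.marker_names):
                raise ValidationError("column count does not match marker_names")

    def call(self, animal_id: str, marker_name: str) -> GenotypeCall:
        i = self.animal_ids.index(animal_id)
        j = self.marker_names.index(marker_name)
        return self.calls[i][j]

    def row(self, animal_id: str) -> list[GenotypeCall]:
        return self.calls[self.animal_ids.index(animal_id)]

    def column(self, marker_name: str) -> list[GenotypeCall]:
        j = self.marker_names.index(marker_name)
        return [row[j] for row in self.calls]

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.animal_ids.index(a) for a in animal_ids]
        return GenotypeMatrix(
            animal_ids=list(animal_ids),
            marker_names=list(self.marker_names),
            calls=[self.calls[i] for i in idx],
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """One animal's anomaly class and affected side."""

    animal_id: str
    anomaly: Anomaly
    side: Side

    def __post_init__(self) -> None:
        if (self.anomaly is Anomaly.NONE) != (self.side is Side.NA):
            raise ValidationError(
                f"animal {self.animal_id}: side must be NA iff anomaly is NONE"
            )
        if self.side is Side.BILATERAL and self.anomaly is not Anomaly.HUN:
            raise ValidationError(
                f"animal {self.animal_id}: BILATERAL permitted only for HUN"
            )

    @property
    def affected(self) -> bool:
        return self.anomaly is not Anomaly.NONE


@dataclass
class ValidationReport:
    """Accumulated table-consistency problems; empty iff all invariants hold."""

    unknown_markers: list[str] = field(default_factory=list)
    out_of_order: list[str] = field(default_factory=list)
    duplicate_animals: list[str] = field(default_factory=list)
    phenotype_inconsistencies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.unknown_markers
            or self.out_of_order
            or self.duplicate_animals
            or self.phenotype_inconsistencies
        )

    def messages(self) -> list[str]:
        out = []
        out += [f"unknown marker: {m}" for m in self.unknown_markers]
        out += [f"out of order: {m}" for m in self.out_of_order]
        out += [f"duplicate animal: {a}" for a in self.duplicate_animals]
        out += [f"phenotype inconsistency: {p}" for p in self.phenotype_inconsistencies]
        return out


def validate_tables(
    genetic_map: GeneticMap,
    genotypes: GenotypeMatrix | None = None,
    phenotypes: Iterable[dict] | Iterable[PhenotypeRecord] | None = None,
) -> ValidationReport:
    """Cross-check a map, genotype matrix and phenotype table.

    Phenotype rows may be raw dicts (``animal``/``anomaly``/``side``) so that
    files violating the PhenotypeRecord invariants can still be reported on
    rather than raising at construction.
    """
    report = ValidationReport()
    if genotypes is not None:
        known = set(genetic_map.marker_names())
        for name in genotypes.marker_names:
            if name not in known:
                report.unknown_markers.append(name)
        in_map = [n for n in genotypes.marker_names if n in known]
        order = {n: i for i, n in enumerate(genetic_map.marker_names())}
        ranked = [order[n] for n in in_map]
        if ranked != sorted(ranked):
            report.out_of_order.extend(
                n for n, r, s in zip(in_map, ranked, sorted(ranked)) if r != s
            )
        seen: set[str] = set()
        for a in genotypes.animal_ids:
            if a in seen:
                report.duplicate_animals.append(a)
            seen.add(a)
    if phenotypes is not None:
        for rec in phenotypes:
            if isinstance(rec, PhenotypeRecord):
                continue  # invariants enforced at construction
            animal = rec.get("animal", "?")
            try:
                anomaly = Anomaly(rec["anomaly"])
                side = Side(rec["side"])
            except (KeyError, ValueError) as exc:
                report.phenotype_inconsistencies.append(f"{animal}: {exc}")
                continue
            if (anomaly is Anomaly.NONE) != (side is Side.NA):
                report.phenotype_inconsistencies.append(
                    f"{animal}: anomaly {anomaly.value} with side {side.value}"
                )
            elif side is Side.BILATERAL and anomaly is not Anomaly.HUN:
                report.phenotype_inconsistencies.append(
                    f"{animal}: BILATERAL side with anomaly {anomaly.value}"
                )
    return report


# ---------------------------------------------------------------------------
# TSV interchange


def read_map(path: str | Path, cm_per_mb: float = DEFAULT_CM_PER_MB) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    required = {"marker", "chrom", "pos_mb"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"map file {path}: missing columns {sorted(missing)}")
    markers = []
    for rec in df.itertuples(index=False):
        pos_cm = getattr(rec, "pos_cm", None)
        if pos_cm is not None and pd.isna(pos_cm):
            pos_cm = None
        markers.append(
            Marker(
                name=rec.marker,
                chromosome=rec.chrom,
                position_mb=float(rec.pos_mb),
                position_cm=None if pos_cm is None else float(pos_cm),
            )
        )
    return GeneticMap(markers=markers, cm_per_mb=cm_per_mb)


def write_map(genetic_map: GeneticMap, path: str | Path) -> None:
    has_cm = any(m.position_cm is not None for m in genetic_map.markers)
    cols = {"marker": [], "chrom": [], "pos_mb": []}
    if has_cm:
        cols["pos_cm"] = []
    for m in genetic_map.markers:
        cols["marker"].append(m.name)
        cols["chrom"].append(m.chromosome)
        cols["pos_mb"].append(m.position_mb)
        if has_cm:
            cols["pos_cm"].append(m.position_cm)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "animal":
        raise ValidationError(f"genotype file {path}: first column must be 'animal'")
    marker_names = list(df.columns[1:])
    animal_ids = df["animal"].tolist()
    calls = [
        [GenotypeCall.from_symbol(df.iloc[i][name]) for name in marker_names]
        for i in range(len(df))
    ]
    return GenotypeMatrix(animal_ids=animal_ids, marker_names=marker_names, calls=calls)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    data = {"animal": matrix.animal_ids}
    for j, name in enumerate(matrix.marker_names):
        data[name] = [row[j].value for row in matrix.calls]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"animal", "anomaly", "side"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"phenotype file {path}: missing columns {sorted(missing)}"
        )
    return [
        PhenotypeRecord(
            animal_id=rec.animal, anomaly=Anomaly(rec.anomaly), side=Side(rec.side)
        )
        for rec in df.itertuples(index=False)
    ]


def write_phenotypes(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    rows = [
        {"animal": r.animal_id, "anomaly": r.anomaly.value, "side": r.side.value}
        for r in records
    ]
    pd.DataFrame(rows, columns=["animal", "anomaly", "side"]).to_csv(
        path, sep="\t", index=False
    )
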