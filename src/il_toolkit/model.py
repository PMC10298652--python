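"""Core domain types for introgression-line (IL) analysis.

An IL library is a set of lines, each carrying (ideally) a single
chromosomal segment from a donor genome in an otherwise uniform
recurrent-parent background.  Everything in this package is expressed in a
shared coordinate frame defined by a :class:`GenomeMap`.

Coordinate convention
---------------------
Internal coordinates are 1-based inclusive base pairs, so a segment
``[start, end]`` has length ``end - start + 1``.  BED export (see
:mod:`il_toolkit.io`) converts to 0-based half-open intervals by
``start - 1``, so the BED length ``end - start`` agrees with the internal
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violated a domain invariant."""


#: canonical genotype codes relative to the two parents:
#: A = recurrent-parent homozygote, B = donor homozygote, H = heterozygote.
ABH_CODES = ("A", "B", "H")

#: tokens normalised to missing on input.
MISSING_TOKENS = frozenset({"NA", "N", "-", "", "NAN", "./.", ".", "NC"})


class Zygosity(str, Enum):
    HOM_DONOR = "homozygous_donor"
    HET = "heterozygous"


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(
                f"chromosome {self.name!r}: physical length must be > 0 bp, "
                f"got {self.length_bp}"
            )
        if self.length_cm < 0:
            raise ValidationError(
                f"chromosome {self.name!r}: genetic length must be >= 0 cM, "
                f"got {self.length_cm}"
            )


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosomes with physical (bp) and genetic (cM) lengths."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        chroms = tuple(self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [c.name for c in chroms]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValidationError(f"duplicate chromosome names: {', '.join(dupes)}")
        if not chroms:
            raise ValidationError("genome map has no chromosomes")
        object.__setattr__(self, "_by_name", {c.name: c for c in chroms})

    @classmethod
    def from_lists(
        cls, rows: Iterable[tuple[str, int, float]]
    ) -> "GenomeMap":
        return cls(tuple(Chromosome(str(n), int(bp), float(cm)) for n, bp, cm in rows))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def total_length_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __len__(self) -> int:
        return len(self.chromosomes)

    def number(self, name: str) -> int:
        """1-based ordinal of a chromosome in map order (used in IL names)."""
        return self.names.index(name) + 1


@dataclass(frozen=True)
class Marker:
    """A genotyped SNP marker anchored to a physical position."""

    id: str
    chromosome: str
    position_bp: int
    position_cm: float | None = None


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker set, grouped by chromosome, positions increasing."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        if not markers:
            raise ValidationError("marker panel is empty")
        ids = [m.id for m in markers]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate marker ids: {', '.join(dupes)}")
        seen: dict[str, int] = {}
        prev_chrom = None
        prev_pos = -1
        for m in markers:
            if m.position_bp < 1:
                raise ValidationError(f"marker {m.id!r}: position must be >= 1 bp")
            if m.chromosome != prev_chrom:
                if m.chromosome in seen:
                    raise ValidationError(
                        f"markers of chromosome {m.chromosome!r} are not contiguous; "
                        "panel must be sorted by (chromosome, position)"
                    )
                seen[m.chromosome] = 1
                prev_chrom = m.chromosome
                prev_pos = -1
            if m.position_bp <= prev_pos:
                raise ValidationError(
                    f"marker {m.id!r}: positions not strictly increasing on "
                    f"{m.chromosome!r}"
                )
            prev_pos = m.position_bp

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.markers)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chromosome:
                out.append(m.chromosome)
        return tuple(out)

    def per_chromosome(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chromosome, []).append(m)
        return out

    def validate_against(self, genome: GenomeMap) -> None:
        for m in self.markers:
            if m.chromosome not in genome:
                raise ValidationError(
                    f"marker {m.id!r}: unknown chromosome {m.chromosome!r}"
                )
            if m.position_bp > genome[m.chromosome].length_bp:
                raise ValidationError(
                    f"marker {m.id!r}: position {m.position_bp} beyond end of "
                    f"{m.chromosome!r} ({genome[m.chromosome].length_bp} bp)"
                )

    def __len__(self) -> int:
        return len(self.markers)


class GenotypeMatrix:
    """Lines x markers in ABH coding relative to the two parents.

    Wraps a pandas DataFrame (index = line ids, columns = marker ids) whose
    cells are ``"A"``, ``"B"``, ``"H"`` or missing (``pd.NA``).
    """

    def __init__(self, calls: pd.DataFrame, n_unknown_tokens: int = 0):
        if calls.shape[0] == 0 or calls.shape[1] == 0:
            raise ValidationError("genotype matrix is empty")
        calls = calls.astype("string")
        bad = calls.stack().dropna()
        bad = bad[~bad.isin(ABH_CODES)]
        if len(bad):
            example = bad.iloc[0]
            raise ValidationError(
                f"genotype matrix contains {len(bad)} invalid codes "
                f"(e.g. {example!r}); allowed codes are A/B/H/NA"
            )
        if calls.index.has_duplicates:
            raise ValidationError("duplicate line ids in genotype matrix")
        if calls.columns.has_duplicates:
            raise ValidationError("duplicate marker ids in genotype matrix")
        self.calls = calls
        self.n_unknown_tokens = int(n_unknown_tokens)

    @property
    def line_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.calls.index)

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def row(self, line_id: str) -> pd.Series:
        return self.calls.loc[line_id]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.calls.equals(other.calls)


@dataclass(frozen=True)
class IntrogressionSegment:
    """A contiguous donor tract on one chromosome (1-based inclusive bp)."""

    chromosome: str
    start: int
    end: int
    zygosity: Zygosity
    n_supporting_markers: int = 1
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"segment start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.n_supporting_markers < 1:
            raise ValidationError("segment must be supported by >= 1 marker")
        if not isinstance(self.zygosity, Zygosity):
            object.__setattr__(self, "zygosity", Zygosity(self.zygosity))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "IntrogressionSegment") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ILGenotype:
    """One line's called introgressions plus its pedigree label."""

    line_id: str
    segments: tuple[IntrogressionSegment, ...]
    pedigree: str = ""

    def __post_init__(self) -> None:
        segs = tuple(
            sorted(self.segments, key=lambda s: (s.chromosome, s.start, s.end))
        )
        object.__setattr__(self, "segments", segs)
        by_chrom: dict[str, list[IntrogressionSegment]] = {}
        for s in segs:
            by_chrom.setdefault(s.chromosome, []).append(s)
        for chrom, ss in by_chrom.items():
            for a, b in zip(ss, ss[1:]):
                if a.zygosity == b.zygosity and b.start <= a.end:
                    raise ValidationError(
                        f"line {self.line_id!r}: overlapping same-zygosity "
                        f"segments on {chrom} ([{a.start},{a.end}] and "
                        f"[{b.start},{b.end}]); merge before constructing"
                    )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segments_on(self, chromosome: str) -> tuple[IntrogressionSegment, ...]:
        return tuple(s for s in self.segments if s.chromosome == chromosome)

    def validate_against(self, genome: GenomeMap) -> None:
        for s in self.segments:
            if s.chromosome not in genome:
                raise ValidationError(
                    f"line {self.line_id!r}: unknown chromosome {s.chromosome!r}"
                )
            if s.end > genome[s.chromosome].length_bp:
                raise ValidationError(
                    f"line {self.line_id!r}: segment end {s.end} beyond end of "
                    f"{s.chromosome!r} ({genome[s.chromosome].length_bp} bp)"
                )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

#: trait registry with measurement units. FS is the shape ratio FL/FD,
#: FFP a percentage of fruit section area occupied by flesh.
TRAIT_UNITS: dict[str, str] = {
    "FW": "g",
    "FP": "mm",
    "FL": "mm",
    "FD": "mm",
    "FS": "ratio",
    "FA": "cm2",
    "FFP": "%",
    "SSC": "degBrix",
    "FF": "kg/cm2",
    "RC": "categorical",
    "AL": "boolean",
}

QUANTITATIVE_TRAITS = ("FW", "FP", "FL", "FD", "FS", "FA", "FFP", "SSC", "FF")

PHENOTYPE_COLUMNS = ("location", "block", "line", "replicate", "trait", "value")


def validate_phenotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it.

    Columns: location, block, line, replicate, trait, value.  Quantitative
    values must be >= 0, FS strictly positive and FFP within [0, 100].
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    quant = df[df["trait"].isin(QUANTITATIVE_TRAITS)]
    vals = pd.to_numeric(quant["value"], errors="coerce")
    neg = quant[vals < 0]
    if len(neg):
        r = neg.iloc[0]
        raise ValidationError(
            f"negative value for quantitative trait {r['trait']!r} "
            f"(line {r['line']!r}, location {r['location']!r})"
        )
    fs = pd.to_numeric(df.loc[df["trait"] == "FS", "value"], errors="coerce")
    if (fs <= 0).any():
        raise ValidationError("FS (shape ratio) must be > 0")
    ffp = pd.to_numeric(df.loc[df["trait"] == "FFP", "value"], errors="coerce")
    if ((ffp < 0) | (ffp > 100)).any():
        raise ValidationError("FFP must lie in [0, 100] percent")
    return df
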