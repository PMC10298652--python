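"""Collection-level statistics of an IL library.

Donor-genome coverage (what fraction of the donor genome the library's
introgressions jointly represent), per-line recurrent background recovery,
segment counts and lengths, and the graphical-genotype export (one row per
IL, one column per chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .caller import CallerConfig, filter_and_classify
from .model import (
    GenomeMap,
    ILGenotype,
    IntrogressionSegment,
    MarkerPanel,
    ValidationError,
    Zygosity,
)


def union_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals by a sweep over sorted endpoints."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in union_intervals(intervals))


def complement_intervals(
    intervals: Iterable[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Complement of an interval union within [1, length]."""
    out: list[tuple[int, int]] = []
    prev_end = 0
    for s, e in union_intervals(intervals):
        if s > prev_end + 1:
            out.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < length:
        out.append((prev_end + 1, length))
    return out


@dataclass
class CoverageReport:
    """Coverage and per-IL summaries of an IL collection."""

    overall_fraction: float
    per_chromosome_fraction: dict[str, float]
    covered_bp: dict[str, int]
    count_het: bool
    introgressions_per_il: dict[str, int] | None = None
    mean_introgressions_per_il: float | None = None
    mean_target_length: float | None = None
    introgressions_per_chromosome: dict[str, int] | None = None
    mean_introgressions_per_chromosome: float | None = None
    background_per_line: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "overall_fraction": self.overall_fraction,
            "per_chromosome_fraction": self.per_chromosome_fraction,
            "covered_bp": self.covered_bp,
            "count_het": self.count_het,
            "introgressions_per_il": self.introgressions_per_il,
            "mean_introgressions_per_il": self.mean_introgressions_per_il,
            "mean_target_length": self.mean_target_length,
            "introgressions_per_chromosome": self.introgressions_per_chromosome,
            "mean_introgressions_per_chromosome":
                self.mean_introgressions_per_chromosome,
            "background_per_line": self.background_per_line,
        }


def donor_coverage(
    ils: Sequence[ILGenotype],
    genome: GenomeMap,
    count_het: bool = True,
) -> CoverageReport:
    """Donor-genome fraction covered by the union of all ILs' segments.

    Heterozygous segments count toward coverage when ``count_het`` is true
    (the default: a heterozygous introgression still represents the donor
    allele in the library).
    """
    per_chrom_iv: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    for il in ils:
        il.validate_against(genome)
        for s in il.segments:
            if s.zygosity is Zygosity.HET and not count_het:
                continue
            per_chrom_iv[s.chromosome].append((s.start, s.end))
    covered = {n: _union_length(iv) for n, iv in per_chrom_iv.items()}
    frac = {
        n: covered[n] / genome[n].length_bp for n in genome.names
    }
    overall = sum(covered.values()) / genome.total_length_bp
    return CoverageReport(overall, frac, covered, count_het)


def background_recovery(il: ILGenotype, genome: GenomeMap) -> float:
    """Recurrent-parent background fraction of one line.

    1 - donor dosage / genome length, with heterozygous segments counted
    at half weight (allele dosage).
    """
    il.validate_against(genome)
    hom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in il.segments:
        if s.zygosity is Zygosity.HOM_DONOR:
            hom_by_chrom.setdefault(s.chromosome, []).append((s.start, s.end))
    hom_len = sum(_union_length(iv) for iv in hom_by_chrom.values())
    het_len = 0
    het_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in il.segments:
        if s.zygosity is Zygosity.HET:
            het_by_chrom.setdefault(s.chromosome, []).append((s.start, s.end))
    for chrom, iv in het_by_chrom.items():
        het_u = union_intervals(iv)
        hom_u = union_intervals(hom_by_chrom.get(chrom, []))
        overlap = _intersection_length(het_u, hom_u)
        het_len += _union_length(het_u) - overlap
    donor_dosage = hom_len + 0.5 * het_len
    return 1.0 - donor_dosage / genome.total_length_bp


def _intersection_length(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                total += hi - lo + 1
    return total


def collection_summary(
    ils: Sequence[ILGenotype],
    genome: GenomeMap,
    config: CallerConfig = CallerConfig(),
    count_het: bool = True,
) -> CoverageReport:
    """Full collection report: coverage plus counts and lengths.

    Segment counts use reported segments (>= min_report_size); the mean
    target length averages target segments only (> target_size_threshold)
    and is None when the collection has no target-size segment.
    """
    if not ils:
        raise ValidationError("collection_summary needs at least one IL")
    report = donor_coverage(ils, genome, count_het=count_het)
    per_il: dict[str, int] = {}
    target_lengths: list[int] = []
    chrom_contrib: dict[str, set[str]] = {n: set() for n in genome.names}
    for il in ils:
        reported, targets = filter_and_classify(il.segments, config)
        per_il[il.line_id] = len(reported)
        target_lengths.extend(s.length for s in targets)
        for s in reported:
            chrom_contrib[s.chromosome].add(il.line_id)
    report.introgressions_per_il = per_il
    report.mean_introgressions_per_il = float(np.mean(list(per_il.values())))
    report.mean_target_length = (
        float(np.mean(target_lengths)) if target_lengths else None
    )
    report.introgressions_per_chromosome = {
        n: len(v) for n, v in chrom_contrib.items()
    }
    report.mean_introgressions_per_chromosome = float(
        np.mean([len(v) for v in chrom_contrib.values()])
    )
    report.background_per_line = {
        il.line_id: background_recovery(il, genome) for il in ils
    }
    return report


# ---------------------------------------------------------------------------
# Graphical genotype
# ---------------------------------------------------------------------------

_BAND_CHAR = {Zygosity.HOM_DONOR: "B", Zygosity.HET: "H"}


def graphical_genotype(
    ils: Sequence[ILGenotype],
    genome: GenomeMap,
    out_text: str | Path,
    out_image: str | Path | None = None,
    bins_per_chromosome: int = 60,
) -> None:
    """Export the collection's graphical genotype.

    Writes a plain-text band file: a TSV of exact segment bounds (which
    round-trips to bp) preceded by a fixed-width ASCII grid (one row per
    IL and chromosome; ``.`` recurrent background, ``B`` homozygous donor,
    ``H`` heterozygous) scaled by physical chromosome length.  Optionally
    renders the same grid with matplotlib.
    """
    max_len = max((c.length_bp for c in genome.chromosomes), default=1)
    with open(out_text, "w") as fh:
        fh.write("# graphical genotype: rows = ILs, columns = chromosomes\n")
        for il in ils:
            for chrom in genome.chromosomes:
                n_bins = max(1, round(bins_per_chromosome * chrom.length_bp / max_len))
                band = ["."] * n_bins
                for s in il.segments_on(chrom.name):
                    lo = int((s.start - 1) / chrom.length_bp * n_bins)
                    hi = int(np.ceil(s.end / chrom.length_bp * n_bins))
                    for i in range(lo, min(hi, n_bins)):
                        band[i] = _BAND_CHAR[s.zygosity]
                fh.write(f"## {il.line_id}\t{chrom.name}\t{''.join(band)}\n")
        fh.write("line\tchromosome\tstart\tend\tzygosity\n")
        for il in ils:
            for s in il.segments:
                fh.write(
                    f"{il.line_id}\t{s.chromosome}\t{s.start}\t{s.end}\t"
                    f"{s.zygosity.value}\n"
                )
    if out_image is not None:
        _render_image(ils, genome, out_image)


def read_band_file(path: str | Path) -> list[ILGenotype]:
    """Read back the exact segment bounds from a graphical-genotype band file."""
    per_line: dict[str, list[IntrogressionSegment]] = {}
    order: list[str] = []
    with open(path) as fh:
        in_table = False
        for raw in fh:
            raw = raw.rstrip("\n")
            if raw.startswith("#"):
                continue
            if raw.startswith("line\t"):
                in_table = True
                continue
            if not in_table or not raw:
                continue
            lid, chrom, start, end, zyg = raw.split("\t")
            if lid not in per_line:
                per_line[lid] = []
                order.append(lid)
            per_line[lid].append(
                IntrogressionSegment(chrom, int(start), int(end), Zygosity(zyg))
            )
    return [ILGenotype(lid, tuple(per_line[lid])) for lid in order]


def _render_image(
    ils: Sequence[ILGenotype], genome: GenomeMap, out_image: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = max(1, len(ils))
    fig, axes = plt.subplots(
        1, len(genome), figsize=(1.2 * len(genome) + 1, 0.28 * n_rows + 1),
        sharey=True, squeeze=False,
    )
    colors = {Zygosity.HOM_DONOR: "#c0392b", Zygosity.HET: "#e67e22"}
    for j, chrom in enumerate(genome.chromosomes):
        ax = axes[0][j]
        for i, il in enumerate(ils):
            ax.add_patch(
                plt.Rectangle((0, i), chrom.length_bp / 1e6, 0.8,
                              color="#d5dbdb", lw=0)
            )
            for s in il.segments_on(chrom.name):
                ax.add_patch(
                    plt.Rectangle(
                        ((s.start - 1) / 1e6, i),
                        s.length / 1e6,
                        0.8,
                        color=colors[s.zygosity],
                        lw=0,
                    )
                )
        ax.set_xlim(0, chrom.length_bp / 1e6)
        ax.set_ylim(len(ils), -0.5)
        ax.set_title(chrom.name, fontsize=8)
        ax.set_xticks([])
        if j == 0:
            ax.set_yticks([i + 0.4 for i in range(len(ils))])
            ax.set_yticklabels([il.line_id for il in ils], fontsize=7)
        else:
            ax.tick_params(left=False)
    fig.suptitle("Graphical genotype (Mbp scale)", fontsize=10)
    fig.tight_layout()
    fig.savefig(out_image)
    plt.close(fig)
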