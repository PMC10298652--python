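"""Call donor introgression segments from ABH genotype rows.

A segment is a maximal run of donor-carrying calls (B or H) along a
chromosome.  Two boundary conventions are supported:

* ``dense``  — segment bounds sit at the first and last donor-carrying SNP
  of the run (appropriate when markers are dense, so the bound
  underestimates the tract by at most one marker interval);
* ``sparse`` — each bound sits at the integer-floor midpoint between the
  outermost donor-carrying SNP and its flanking recurrent-allele (A) SNP
  (appropriate for sparse panels, splitting the uncertainty interval).

Runs touching a chromosome end, where no flanking A SNP exists, extend to
the physical chromosome end in sparse mode and stay at the terminal donor
SNP in dense mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GenomeMap,
    ILGenotype,
    IntrogressionSegment,
    MarkerPanel,
    ValidationError,
    Zygosity,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerConfig:
    """Boundary convention and size filters of the segment caller.

    ``min_report_size`` (default 0.1 Mbp) is the smallest introgression
    reported at all; ``target_size_threshold`` (default 0.55 Mbp) separates
    small residual background introgressions from target-sized ones
    (targets must be strictly larger).  Missing calls bridge runs by
    default; ``min_supporting_markers`` discards runs with fewer
    donor-carrying calls.
    """

    boundary_mode: str = "dense"
    min_report_size: int = 100_000
    target_size_threshold: int = 550_000
    min_supporting_markers: int = 1
    bridge_missing: bool = True

    def __post_init__(self) -> None:
        if self.boundary_mode not in ("dense", "sparse"):
            raise ValidationError(
                f"boundary_mode must be 'dense' or 'sparse', got "
                f"{self.boundary_mode!r}"
            )
        if not (0 < self.min_report_size <= self.target_size_threshold):
            raise ValidationError(
                "need 0 < min_report_size <= target_size_threshold"
            )
        if self.min_supporting_markers < 1:
            raise ValidationError("min_supporting_markers must be >= 1")


def call_segments(
    line_calls: pd.Series | Mapping[str, object],
    panel: MarkerPanel,
    genome: GenomeMap,
    config: CallerConfig = CallerConfig(),
) -> list[IntrogressionSegment]:
    """Call introgression segments from one line's ABH calls.

    ``line_calls`` maps marker id to A/B/H/NA and must cover exactly the
    panel's markers.  Returns unfiltered segments sorted by (chromosome in
    genome order, start); apply :func:`filter_and_classify` for the size
    filters.
    """
    if not isinstance(line_calls, pd.Series):
        line_calls = pd.Series(line_calls, dtype="string")
    if len(line_calls) != len(panel):
        raise ValidationError(
            f"calls length {len(line_calls)} does not match panel size {len(panel)}"
        )
    if set(line_calls.index) != set(panel.ids):
        missing = sorted(set(panel.ids) - set(line_calls.index))
        raise ValidationError(f"calls missing panel markers (e.g. {missing[:5]})")
    panel.validate_against(genome)
    calls = line_calls.reindex(list(panel.ids))

    segments: list[IntrogressionSegment] = []
    for chrom_name, markers in panel.per_chromosome().items():
        chrom_len = genome[chrom_name].length_bp
        pos = np.array([m.position_bp for m in markers], dtype=np.int64)
        codes = [
            None if pd.isna(calls[m.id]) else str(calls[m.id]) for m in markers
        ]
        segments.extend(
            _call_chromosome(chrom_name, pos, codes, chrom_len, config)
        )
    order = {name: i for i, name in enumerate(genome.names)}
    segments.sort(key=lambda s: (order[s.chromosome], s.start))
    return segments


def _call_chromosome(
    chrom: str,
    pos: np.ndarray,
    codes: Sequence[str | None],
    chrom_len: int,
    config: CallerConfig,
) -> list[IntrogressionSegment]:
    # indices of informative (non-missing) calls; with bridging, runs are
    # found on this compressed sequence so NA never breaks a run.
    out: list[IntrogressionSegment] = []
    n = len(codes)
    runs: list[list[int]] = []  # lists of marker indices with donor calls
    current: list[int] = []
    for i in range(n):
        c = codes[i]
        if c in ("B", "H"):
            current.append(i)
        elif c == "A":
            if current:
                runs.append(current)
                current = []
        else:  # missing
            if not config.bridge_missing and current:
                runs.append(current)
                current = []
    if current:
        runs.append(current)

    for run in runs:
        if len(run) < config.min_supporting_markers:
            continue
        first, last = run[0], run[-1]
        if config.boundary_mode == "dense":
            start = int(pos[first])
            end = int(pos[last])
        else:
            left_a = _nearest_a(codes, first, -1)
            right_a = _nearest_a(codes, last, +1)
            start = (
                (int(pos[left_a]) + int(pos[first])) // 2 if left_a is not None else 1
            )
            end = (
                (int(pos[last]) + int(pos[right_a])) // 2
                if right_a is not None
                else chrom_len
            )
        zyg = (
            Zygosity.HET
            if any(codes[i] == "H" for i in run)
            else Zygosity.HOM_DONOR
        )
        out.append(IntrogressionSegment(chrom, start, end, zyg, len(run)))
    return out


def _nearest_a(codes: Sequence[str | None], idx: int, step: int) -> int | None:
    i = idx + step
    while 0 <= i < len(codes):
        if codes[i] == "A":
            return i
        i += step
    return None


def filter_and_classify(
    segments: Sequence[IntrogressionSegment],
    config: CallerConfig = CallerConfig(),
) -> tuple[list[IntrogressionSegment], list[IntrogressionSegment]]:
    """Partition segments into (reported, target) by the size thresholds.

    Reported segments have length >= ``min_report_size``; targets are the
    strict subset with length > ``target_size_threshold``.
    """
    key = lambda s: (s.chromosome, s.start, s.end)
    reported = sorted(
        (s for s in segments if s.length >= config.min_report_size), key=key
    )
    target = [s for s in reported if s.length > config.target_size_threshold]
    return reported, target


def build_il_genotype(
    line_id: str,
    segments: Sequence[IntrogressionSegment],
    pedigree: str = "",
    genome: GenomeMap | None = None,
    donor_prefix: str = "TRI",
) -> ILGenotype:
    """Assemble an ILGenotype: merge same-zygosity overlapping or abutting
    segments and name them by chromosome and order along the chromosome
    (e.g. ``TRI05-2`` = second introgression on chromosome 5).

    Overlapping segments with conflicting zygosity are kept separate with a
    logged warning.
    """
    by_chrom: dict[str, list[IntrogressionSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)

    merged: list[IntrogressionSegment] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: (s.start, s.end))
        for s in segs:
            prev = merged[-1] if merged and merged[-1].chromosome == chrom else None
            if prev is not None and s.start <= prev.end + 1:
                if s.zygosity == prev.zygosity:
                    merged[-1] = IntrogressionSegment(
                        chrom,
                        prev.start,
                        max(prev.end, s.end),
                        prev.zygosity,
                        prev.n_supporting_markers + s.n_supporting_markers,
                    )
                    continue
                if s.start <= prev.end:
                    logger.warning(
                        "line %s: overlapping segments with conflicting zygosity "
                        "on %s kept separate ([%d,%d] %s vs [%d,%d] %s)",
                        line_id, chrom, prev.start, prev.end, prev.zygosity.value,
                        s.start, s.end, s.zygosity.value,
                    )
            merged.append(s)

    if genome is not None:
        chrom_number = {name: genome.number(name) for name in genome.names}
        chrom_order = {name: i for i, name in enumerate(genome.names)}
    else:
        names = sorted(by_chrom)
        chrom_number = {name: _parse_chrom_number(name, i) for i, name in
                        enumerate(names)}
        chrom_order = {name: i for i, name in enumerate(names)}

    merged.sort(key=lambda s: (chrom_order[s.chromosome], s.start))
    named: list[IntrogressionSegment] = []
    counter: dict[str, int] = {}
    for s in merged:
        counter[s.chromosome] = counter.get(s.chromosome, 0) + 1
        named.append(
            IntrogressionSegment(
                s.chromosome,
                s.start,
                s.end,
                s.zygosity,
                s.n_supporting_markers,
                name=f"{donor_prefix}{chrom_number[s.chromosome]:02d}-"
                     f"{counter[s.chromosome]}",
            )
        )
    return ILGenotype(line_id, tuple(named), pedigree)


def _parse_chrom_number(name: str, fallback_index: int) -> int:
    digits = "".join(ch for ch in name if ch.isdigit())
    return int(digits) if digits else fallback_index + 1
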