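"""Readers and writers for the file formats the pipeline touches.

Genome maps and marker panels are small delimited tables (CSV or TSV,
sniffed); genotype matrices are CSV with lines as rows and marker ids as
columns; called segments are exported as BED (0-based half-open, converted
from the internal 1-based inclusive coordinates); phenotypes travel as
long-format CSV.  VCF input is converted to ABH coding against the two
parents via :func:`vcf_to_abh`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    ABH_CODES,
    Chromosome,
    GenomeMap,
    GenotypeMatrix,
    ILGenotype,
    IntrogressionSegment,
    Marker,
    MarkerPanel,
    MISSING_TOKENS,
    ValidationError,
    Zygosity,
    validate_phenotype_table,
)

logger = logging.getLogger(__name__)

_BED_SCORES = {Zygosity.HOM_DONOR: 1000, Zygosity.HET: 500}


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def _pick_column(df: pd.DataFrame, names: Sequence[str], what: str, path) -> str:
    lower = {str(c).strip().lower(): c for c in df.columns}
    for n in names:
        if n in lower:
            return lower[n]
    raise ValidationError(
        f"{path}: no {what} column (expected one of {list(names)}, "
        f"found {list(df.columns)})"
    )


def read_genome_map(path: str | Path) -> GenomeMap:
    """Read a genome map table with columns (name, bp_length, cM_length)."""
    df = _read_table(path)
    name_c = _pick_column(df, ("name", "chromosome", "chrom"), "chromosome name", path)
    bp_c = _pick_column(df, ("bp_length", "length_bp", "bp", "physical_length"),
                        "physical length", path)
    cm_c = _pick_column(df, ("cm_length", "length_cm", "cm", "genetic_length"),
                        "genetic length", path)
    rows = []
    for i, r in df.iterrows():
        try:
            rows.append(Chromosome(str(r[name_c]), int(r[bp_c]), float(r[cm_c])))
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i} ({r[name_c]!r}): {exc}") from exc
    return GenomeMap(tuple(rows))


def write_genome_map(genome: GenomeMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": genome.names,
            "bp_length": [c.length_bp for c in genome.chromosomes],
            "cM_length": [c.length_cm for c in genome.chromosomes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a marker panel (id, chromosome, bp position[, cM position])."""
    df = _read_table(path)
    id_c = _pick_column(df, ("id", "marker", "marker_id", "snp"), "marker id", path)
    chrom_c = _pick_column(df, ("chromosome", "chrom"), "chromosome", path)
    pos_c = _pick_column(df, ("position", "position_bp", "bp", "pos"), "position", path)
    cm_c = None
    lower = {str(c).strip().lower(): c for c in df.columns}
    for n in ("cm", "position_cm", "cm_position"):
        if n in lower:
            cm_c = lower[n]
            break
    df = df.sort_values([chrom_c, pos_c], kind="stable")
    markers = tuple(
        Marker(
            str(r[id_c]),
            str(r[chrom_c]),
            int(r[pos_c]),
            float(r[cm_c]) if cm_c is not None and pd.notna(r[cm_c]) else None,
        )
        for _, r in df.iterrows()
    )
    return MarkerPanel(markers)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in panel.markers],
            "chromosome": [m.chromosome for m in panel.markers],
            "position": [m.position_bp for m in panel.markers],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genotypes_abh(path: str | Path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read an ABH genotype matrix (rows = lines, columns = marker ids).

    Unknown tokens are normalised to missing with a logged warning count.
    Columns must be a subset of the panel; panel markers absent from the
    file are added as all-missing columns.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty genotype matrix")
    unknown_markers = [c for c in df.columns if c not in set(panel.ids)]
    if unknown_markers:
        raise ValidationError(
            f"{path}: marker ids absent from panel: {unknown_markers[:5]}"
        )
    df = df.reindex(columns=list(panel.ids))
    norm = df.apply(lambda col: col.str.strip().str.upper())
    is_missing = norm.isna() | norm.isin(MISSING_TOKENS)
    is_code = norm.isin(ABH_CODES)
    n_unknown = int((~is_missing & ~is_code).to_numpy().sum())
    if n_unknown:
        logger.warning(
            "%s: %d unknown genotype tokens normalised to NA", path, n_unknown
        )
    cleaned = norm.where(is_code, other=pd.NA)
    return GenotypeMatrix(cleaned, n_unknown_tokens=n_unknown)


def write_genotypes_abh(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.calls.to_csv(path, na_rep="NA", index_label="line")


def vcf_to_abh(
    vcf_path: str | Path,
    recurrent_sample: str,
    donor_sample: str,
    progeny_samples: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, MarkerPanel]:
    """Convert a biparental VCF to ABH coding against the two parents.

    Only biallelic SNPs where the parents carry opposite homozygous
    genotypes are informative; all other sites are dropped and counted on
    ``matrix.n_noninformative``.  Progeny genotypes matching the recurrent
    homozygote become A, the donor homozygote B, heterozygotes H and
    anything else (including missing) NA.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in (recurrent_sample, donor_sample):
        if s not in samples:
            raise ValidationError(f"parent sample {s!r} not in VCF ({vcf_path})")
    if progeny_samples is None:
        progeny_samples = [
            s for s in samples if s not in (recurrent_sample, donor_sample)
        ]
    for s in progeny_samples:
        if s not in samples:
            raise ValidationError(f"progeny sample {s!r} not in VCF ({vcf_path})")
    ri = samples.index(recurrent_sample)
    di = samples.index(donor_sample)
    pi = [samples.index(s) for s in progeny_samples]

    markers: list[Marker] = []
    columns: list[list[object]] = []
    n_dropped = 0
    for var in vcf:
        gts = var.genotypes
        r = gts[ri][:2]
        d = gts[di][:2]
        informative = (
            len(var.ALT) == 1
            and var.is_snp
            and -1 not in r
            and -1 not in d
            and r[0] == r[1]
            and d[0] == d[1]
            and r[0] != d[0]
        )
        if not informative:
            n_dropped += 1
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(Marker(mid, var.CHROM, int(var.POS)))
        col: list[object] = []
        for j in pi:
            a = sorted(gts[j][:2])
            if -1 in a:
                col.append(pd.NA)
            elif a[0] == a[1] == r[0]:
                col.append("A")
            elif a[0] == a[1] == d[0]:
                col.append("B")
            elif set(a) == {r[0], d[0]}:
                col.append("H")
            else:
                col.append(pd.NA)
        columns.append(col)
    if not markers:
        raise ValidationError(
            f"{vcf_path}: no informative sites (parents never opposite homozygous)"
        )
    calls = pd.DataFrame(
        dict(zip((m.id for m in markers), columns)), index=list(progeny_samples)
    )
    matrix = GenotypeMatrix(calls)
    matrix.n_noninformative = n_dropped  # type: ignore[attr-defined]
    panel = MarkerPanel(tuple(markers))
    return matrix, panel


# ---------------------------------------------------------------------------
# Segment BED I/O
# ---------------------------------------------------------------------------


def write_segments_bed(ils: Iterable[ILGenotype], path: str | Path) -> None:
    """Write called segments as BED: 0-based half-open, name = line id.

    The score column encodes zygosity (1000 homozygous donor, 500
    heterozygous); two extra columns carry the zygosity word and the
    supporting-marker count so the file round-trips losslessly.
    """
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tline\tscore\tstrand\tzygosity\tn_markers\n"
        )
        for il in ils:
            for s in il.segments:
                fh.write(
                    f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{il.line_id}\t"
                    f"{_BED_SCORES[s.zygosity]}\t.\t{s.zygosity.value}\t"
                    f"{s.n_supporting_markers}\n"
                )


def read_segments_bed(path: str | Path) -> list[ILGenotype]:
    """Read a segment BED written by :func:`write_segments_bed`."""
    per_line: dict[str, list[IntrogressionSegment]] = {}
    order: list[str] = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.split("\t")
            if len(f) < 5:
                raise ValidationError(f"{path}: malformed BED line: {raw!r}")
            chrom, start0, end, line_id, score = f[:5]
            if len(f) >= 7:
                zyg = Zygosity(f[6])
            else:
                zyg = Zygosity.HOM_DONOR if int(score) >= 1000 else Zygosity.HET
            n_markers = int(f[7]) if len(f) >= 8 else 1
            seg = IntrogressionSegment(
                chrom, int(start0) + 1, int(end), zyg, n_markers
            )
            if line_id not in per_line:
                per_line[line_id] = []
                order.append(line_id)
            per_line[line_id].append(seg)
    return [ILGenotype(lid, tuple(per_line[lid])) for lid in order]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_phenotype_table(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotype_table(df).to_csv(path, index=False)
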