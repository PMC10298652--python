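"""Forward simulator of an introgression-line breeding program.

Simulates meiosis on a genetic map (Poisson crossovers, no interference,
linear cM-to-bp interpolation), backcross/selfing pedigrees, marker
genotyping with missingness and error, and multi-location randomized-block
field trials with per-segment QTL effects.

Every stochastic operation takes an explicit ``numpy.random.Generator``;
there is no hidden global state, so a fixed seed reproduces a run exactly.

Ancestry mosaics
----------------
A haplotype is a list of tracts, each either recurrent-parent (0) or donor
(1) ancestry, covering the chromosome [1, L] in 1-based inclusive bp.  The
tract representation stores only tract end positions plus ancestries, with
adjacent equal-ancestry tracts merged, so ancestry alternates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    GenomeMap,
    GenotypeMatrix,
    ILGenotype,
    IntrogressionSegment,
    MarkerPanel,
    ValidationError,
    Zygosity,
)

RECURRENT = 0
DONOR = 1

_CODE = {0: "A", 1: "H", 2: "B"}


def _require_rng(rng) -> np.random.Generator:
    if not isinstance(rng, np.random.Generator):
        raise TypeError(
            "an explicit numpy.random.Generator is required (no global state)"
        )
    return rng


def _merge_tracts(ends: list[int], anc: list[int]) -> tuple[np.ndarray, np.ndarray]:
    m_ends: list[int] = []
    m_anc: list[int] = []
    for e, a in zip(ends, anc):
        if m_anc and m_anc[-1] == a:
            m_ends[-1] = e
        else:
            m_ends.append(e)
            m_anc.append(a)
    return np.asarray(m_ends, dtype=np.int64), np.asarray(m_anc, dtype=np.int8)


@dataclass(frozen=True)
class Haplotype:
    """Ancestry mosaic of one chromosome copy.

    ``ends[i]`` is the last bp of tract i (tract i spans
    ``[ends[i-1]+1, ends[i]]``); ``ancestry[i]`` is 0 (recurrent) or 1
    (donor).  ``ends[-1]`` equals the chromosome length.
    """

    ends: np.ndarray
    ancestry: np.ndarray

    def __post_init__(self) -> None:
        ends = np.asarray(self.ends, dtype=np.int64)
        anc = np.asarray(self.ancestry, dtype=np.int8)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "ancestry", anc)

    @classmethod
    def uniform(cls, length_bp: int, ancestry: int) -> "Haplotype":
        return cls(np.array([length_bp], dtype=np.int64),
                   np.array([ancestry], dtype=np.int8))

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    def ancestry_at(self, position_bp: int) -> int:
        if position_bp < 1 or position_bp > self.length:
            raise ValidationError(
                f"position {position_bp} outside chromosome [1, {self.length}]"
            )
        return int(self.ancestry[np.searchsorted(self.ends, position_bp)])

    def donor_bp(self) -> int:
        starts = np.concatenate(([0], self.ends[:-1]))
        return int(((self.ends - starts)[self.ancestry == DONOR]).sum())

    def validate(self) -> None:
        if len(self.ends) == 0 or len(self.ends) != len(self.ancestry):
            raise ValidationError("malformed haplotype mosaic")
        if np.any(np.diff(self.ends) <= 0):
            raise ValidationError("tract breakpoints must be strictly increasing")
        if np.any(self.ancestry[1:] == self.ancestry[:-1]):
            raise ValidationError("ancestry must alternate between adjacent tracts")
        if not set(np.unique(self.ancestry)) <= {RECURRENT, DONOR}:
            raise ValidationError("ancestry codes must be 0 (recurrent) or 1 (donor)")


@dataclass(frozen=True)
class Diplotype:
    """Two haplotypes per chromosome: the full diploid ancestry mosaic."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    @classmethod
    def fully_recurrent(cls, genome: GenomeMap) -> "Diplotype":
        return cls(
            {
                c.name: (
                    Haplotype.uniform(c.length_bp, RECURRENT),
                    Haplotype.uniform(c.length_bp, RECURRENT),
                )
                for c in genome.chromosomes
            }
        )

    @classmethod
    def fully_donor(cls, genome: GenomeMap) -> "Diplotype":
        return cls(
            {
                c.name: (
                    Haplotype.uniform(c.length_bp, DONOR),
                    Haplotype.uniform(c.length_bp, DONOR),
                )
                for c in genome.chromosomes
            }
        )

    @classmethod
    def f1(cls, genome: GenomeMap) -> "Diplotype":
        """The F1 of recurrent x donor: one haplotype of each ancestry."""
        return cls(
            {
                c.name: (
                    Haplotype.uniform(c.length_bp, RECURRENT),
                    Haplotype.uniform(c.length_bp, DONOR),
                )
                for c in genome.chromosomes
            }
        )

    def validate(self, genome: GenomeMap) -> None:
        if set(self.haplotypes) != set(genome.names):
            raise ValidationError("diplotype chromosomes do not match genome map")
        for name, (h1, h2) in self.haplotypes.items():
            for h in (h1, h2):
                h.validate()
                if h.length != genome[name].length_bp:
                    raise ValidationError(
                        f"haplotype on {name} spans {h.length} bp, expected "
                        f"{genome[name].length_bp}"
                    )


def _recombine(h0: Haplotype, h1: Haplotype, xovers: Sequence[int],
               start: int) -> Haplotype:
    """Build a gamete from two parental haplotypes and crossover positions.

    A crossover at x switches source after position x (the gamete copies
    the current haplotype through x and the other from x + 1 on).
    """
    haps = (h0, h1)
    length = h0.length
    bounds = list(xovers) + [length]
    ends: list[int] = []
    anc: list[int] = []
    cur = start
    prev = 0
    for b in bounds:
        h = haps[cur]
        i = int(np.searchsorted(h.ends, prev + 1))
        while prev < b:
            e = min(int(h.ends[i]), b)
            ends.append(e)
            anc.append(int(h.ancestry[i]))
            prev = e
            i += 1
        cur ^= 1
    m_ends, m_anc = _merge_tracts(ends, anc)
    return Haplotype(m_ends, m_anc)


def simulate_gamete(
    parent: Diplotype, genome: GenomeMap, rng: np.random.Generator
) -> dict[str, Haplotype]:
    """Simulate one meiosis: per chromosome, Poisson(cM/100) crossovers.

    Crossover positions are uniform on the genetic map and mapped to bp by
    linear interpolation over the whole chromosome (single linear map); the
    starting haplotype is chosen fairly.  No interference.
    """
    _require_rng(rng)
    gamete: dict[str, Haplotype] = {}
    for chrom in genome.chromosomes:
        h0, h1 = parent.haplotypes[chrom.name]
        start = int(rng.integers(2))
        cm = chrom.length_cm
        n_co = int(rng.poisson(cm / 100.0)) if cm > 0 else 0
        if n_co == 0:
            gamete[chrom.name] = (h0, h1)[start]
            continue
        pos_cm = rng.uniform(0.0, cm, size=n_co)
        bp = np.floor(pos_cm / cm * chrom.length_bp).astype(np.int64)
        bp = np.unique(np.clip(bp, 1, chrom.length_bp - 1))
        gamete[chrom.name] = _recombine(h0, h1, [int(x) for x in bp], start)
    return gamete


def fuse_gametes(
    g1: Mapping[str, Haplotype], g2: Mapping[str, Haplotype]
) -> Diplotype:
    return Diplotype({c: (g1[c], g2[c]) for c in g1})


def advance_generation(
    population: Sequence[Diplotype],
    cross: str,
    n_offspring: int,
    genome: GenomeMap,
    rng: np.random.Generator,
) -> list[Diplotype]:
    """Produce the next generation by backcrossing to the recurrent parent
    or by self-pollination.

    Each offspring draws its (single) parent uniformly from the current
    population.  The backcross partner is the fully recurrent diplotype,
    whose gametes are deterministically all-recurrent.
    """
    _require_rng(rng)
    if len(population) == 0:
        raise ValidationError("cannot advance an empty population")
    if cross not in ("backcross_to_recurrent", "self"):
        raise ValidationError(f"unknown cross type {cross!r}")
    recurrent = {
        c.name: Haplotype.uniform(c.length_bp, RECURRENT)
        for c in genome.chromosomes
    }
    offspring: list[Diplotype] = []
    for _ in range(n_offspring):
        parent = population[int(rng.integers(len(population)))]
        g1 = simulate_gamete(parent, genome, rng)
        g2 = recurrent if cross == "backcross_to_recurrent" else simulate_gamete(
            parent, genome, rng
        )
        offspring.append(fuse_gametes(g1, g2))
    return offspring


def donor_fraction(dip: Diplotype, genome: GenomeMap) -> float:
    """Diploid donor-genome dosage fraction (heterozygous tracts count half)."""
    total = genome.total_length_bp
    donor = sum(
        h.donor_bp() for pair in dip.haplotypes.values() for h in pair
    )
    return donor / (2 * total)


def heterozygous_fraction(dip: Diplotype, genome: GenomeMap) -> float:
    """Fraction of the genome where the two haplotypes differ in ancestry."""
    het = 0
    for h1, h2 in dip.haplotypes.values():
        ends = np.union1d(h1.ends, h2.ends)
        starts = np.concatenate(([0], ends[:-1]))
        a1 = h1.ancestry[np.searchsorted(h1.ends, ends)]
        a2 = h2.ancestry[np.searchsorted(h2.ends, ends)]
        het += int(((ends - starts)[a1 != a2]).sum())
    return het / genome.total_length_bp


def true_segments(dip: Diplotype, genome: GenomeMap) -> list[IntrogressionSegment]:
    """The true donor-carrying tracts of a diplotype (the simulator oracle).

    Adjacent tracts of equal zygosity are merged; heterozygous and
    homozygous-donor tracts are reported separately.
    """
    out: list[IntrogressionSegment] = []
    for name in genome.names:
        h1, h2 = dip.haplotypes[name]
        ends = np.union1d(h1.ends, h2.ends)
        starts = np.concatenate(([0], ends[:-1])) + 1
        dosage = (
            h1.ancestry[np.searchsorted(h1.ends, ends)].astype(int)
            + h2.ancestry[np.searchsorted(h2.ends, ends)].astype(int)
        )
        run_start = None
        run_zyg = None
        prev_end = None
        for s, e, d in zip(starts, ends, dosage):
            zyg = None if d == 0 else (Zygosity.HET if d == 1 else Zygosity.HOM_DONOR)
            if zyg != run_zyg:
                if run_zyg is not None:
                    out.append(
                        IntrogressionSegment(name, int(run_start), int(prev_end),
                                             run_zyg)
                    )
                run_start, run_zyg = s, zyg
            prev_end = e
        if run_zyg is not None:
            out.append(
                IntrogressionSegment(name, int(run_start), int(prev_end), run_zyg)
            )
    return out


# ---------------------------------------------------------------------------
# Genotyping
# ---------------------------------------------------------------------------


def genotype_population(
    population: Mapping[str, Diplotype] | Sequence[Diplotype],
    panel: MarkerPanel,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Genotype a population at the panel markers with noise.

    The true ancestry dosage at each marker maps to A/H/B; each call is
    independently flipped to a uniformly chosen wrong code with probability
    ``error_rate``, then set to missing with probability ``missing_rate``
    (a call hit by both ends up missing).
    """
    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise ValidationError("missing_rate and error_rate must lie in [0, 1]")
    if (missing_rate > 0 or error_rate > 0):
        _require_rng(rng)
    if isinstance(population, Mapping):
        items = list(population.items())
    else:
        width = max(4, len(str(len(population))))
        items = [(f"L{i + 1:0{width}d}", d) for i, d in enumerate(population)]
    n_markers = len(panel)
    rows: dict[str, list[object]] = {}
    for line_id, dip in items:
        codes: list[object] = []
        for m in panel.markers:
            if m.chromosome not in dip.haplotypes:
                raise ValidationError(
                    f"marker {m.id!r}: chromosome {m.chromosome!r} not in diplotype"
                )
            h1, h2 = dip.haplotypes[m.chromosome]
            d = h1.ancestry_at(m.position_bp) + h2.ancestry_at(m.position_bp)
            codes.append(_CODE[d])
        if error_rate > 0:
            flip = rng.random(n_markers) < error_rate
            for j in np.nonzero(flip)[0]:
                wrong = [c for c in ("A", "H", "B") if c != codes[j]]
                codes[j] = wrong[int(rng.integers(2))]
        if missing_rate > 0:
            miss = rng.random(n_markers) < missing_rate
            for j in np.nonzero(miss)[0]:
                codes[j] = pd.NA
        rows[line_id] = codes
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=list(panel.ids))
    return GenotypeMatrix(calls)


# ---------------------------------------------------------------------------
# Trial design and phenotype simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeSpec:
    """How many backcross and selfing generations, and the census sizes."""

    n_backcross: int = 6
    n_self: int = 3
    plants_per_generation: int = 40
    selected_per_generation: int = 15

    def __post_init__(self) -> None:
        if self.n_backcross < 0 or self.n_self < 0:
            raise ValidationError("generation counts must be >= 0")
        if self.plants_per_generation < 1 or self.selected_per_generation < 1:
            raise ValidationError("census sizes must be >= 1")

    def label(self) -> str:
        return f"BC{self.n_backcross}S{self.n_self}"


@dataclass(frozen=True)
class TrialDesign:
    """Randomized block design of one multi-location field trial.

    Defaults mirror a typical IL evaluation: five blocks per location with
    two single-plant replicates of each IL and ten control replicates
    (two per block).
    """

    locations: tuple[str, ...] = ("Alcasser", "Meliana", "Algarrobo")
    n_blocks: int = 5
    il_reps_per_block: int = 2
    control_reps_per_block: int = 2
    control_line: str = "PS"

    def __post_init__(self) -> None:
        if (
            len(self.locations) < 1
            or self.n_blocks < 1
            or self.il_reps_per_block < 1
            or self.control_reps_per_block < 1
        ):
            raise ValidationError("all trial design counts must be >= 1")


@dataclass(frozen=True)
class TraitModel:
    """Per-location control mean and residual SD of one trait."""

    location_means: dict[str, float]
    location_sds: dict[str, float]

    def __post_init__(self) -> None:
        for loc, sd in self.location_sds.items():
            if sd < 0:
                raise ValidationError(f"residual SD for {loc!r} must be >= 0")

    @classmethod
    def from_cv(cls, location_means: dict[str, float], cv: float) -> "TraitModel":
        return cls(location_means, {k: abs(v) * cv for k, v in location_means.items()})


@dataclass(frozen=True)
class QTLEffect:
    """A percent effect of a donor interval on one trait.

    An IL expresses the effect iff one of its segments overlaps
    [start, end] on the chromosome; effects are multiplicative percent
    changes of the location mean.
    """

    trait: str
    chromosome: str
    start: int
    end: int
    percent: float

    def __post_init__(self) -> None:
        if self.percent <= -100:
            raise ValidationError("percent effect must be > -100")
        if self.start > self.end:
            raise ValidationError("QTL interval start > end")


@dataclass(frozen=True)
class TraitArchitecture:
    """The additive model field trials are simulated under.

    value = mu_location * (1 + sum expressed percent effects / 100)
            + block effect + genotype-x-location term + residual,
    with block and GxL effect SDs expressed as fractions of the location
    mean.  FS is never drawn: it is recomputed as FL/FD per fruit.
    """

    traits: dict[str, TraitModel]
    qtls: tuple[QTLEffect, ...] = ()
    block_sd_frac: float = 0.0
    gxl_sd_frac: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "qtls", tuple(self.qtls))
        if self.block_sd_frac < 0 or self.gxl_sd_frac < 0:
            raise ValidationError("effect SD fractions must be >= 0")
        if "FS" in self.traits:
            raise ValidationError(
                "FS is a derived trait (FL/FD); simulate FL and FD instead"
            )
        for t, m in self.traits.items():
            if not m.location_means:
                raise ValidationError(f"trait {t!r} has no control means")


def default_trait_architecture(
    qtls: Iterable[QTLEffect] = (),
    block_sd_frac: float = 0.02,
    gxl_sd_frac: float = 0.0,
) -> TraitArchitecture:
    """A melon-like default: 'Piel de Sapo'-scale fruit trait means/SDs.

    Means and SDs are typical of a large non-climacteric melon cultivar
    evaluated in eastern-Spain spring trials; FP, FA and FF are missing in
    one location to exercise per-trait location masks.
    """
    A, M, G = "Alcasser", "Meliana", "Algarrobo"
    traits = {
        "FW": TraitModel({A: 2514.0, M: 2637.0, G: 1753.0},
                         {A: 325.0, M: 508.0, G: 459.0}),
        "FP": TraitModel({A: 484.0, M: 474.0}, {A: 23.0, M: 31.0}),
        "FL": TraitModel({A: 215.0, M: 231.0, G: 185.0},
                         {A: 11.0, M: 20.0, G: 15.0}),
        "FD": TraitModel({A: 155.0, M: 152.0, G: 133.0},
                         {A: 7.0, M: 10.0, G: 13.0}),
        "FA": TraitModel({A: 263.0, M: 286.0}, {A: 23.0, M: 38.0}),
        "FFP": TraitModel({A: 70.3, M: 70.4, G: 70.9}, {A: 3.0, M: 3.2, G: 3.5}),
        "SSC": TraitModel({A: 12.2, M: 10.4, G: 13.9}, {A: 1.3, M: 2.7, G: 1.6}),
        "FF": TraitModel({A: 2.12, M: 2.55}, {A: 0.43, M: 0.85}),
    }
    return TraitArchitecture(traits, tuple(qtls), block_sd_frac, gxl_sd_frac)


def _expressed_percent(
    il: ILGenotype, trait: str, qtls: Sequence[QTLEffect]
) -> float:
    total = 0.0
    for q in qtls:
        if q.trait != trait:
            continue
        for s in il.segments:
            if s.chromosome == q.chromosome and s.start <= q.end and q.start <= s.end:
                total += q.percent
                break
    return total


def simulate_phenotypes(
    il_genotypes: Mapping[str, ILGenotype],
    architecture: TraitArchitecture,
    design: TrialDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a multi-location randomized-block trial in long format.

    Control plants carry no QTL effects.  FS is derived per fruit as FL/FD
    whenever both are simulated at a location.
    """
    _require_rng(rng)
    lines = [design.control_line] + sorted(il_genotypes)
    trait_names = sorted(architecture.traits)
    records: list[tuple] = []
    for loc in design.locations:
        active = [
            t for t in trait_names
            if loc in architecture.traits[t].location_means
        ]
        mus = {t: architecture.traits[t].location_means[loc] for t in active}
        sds = {t: architecture.traits[t].location_sds.get(loc, 0.0) for t in active}
        block_eff = {
            (t, b): (
                rng.normal(0.0, architecture.block_sd_frac * abs(mus[t]))
                if architecture.block_sd_frac > 0 else 0.0
            )
            for t in active
            for b in range(1, design.n_blocks + 1)
        }
        gxl_eff = {
            (t, line): (
                rng.normal(0.0, architecture.gxl_sd_frac * abs(mus[t]))
                if architecture.gxl_sd_frac > 0 and line != design.control_line
                else 0.0
            )
            for t in active
            for line in lines
        }
        for block in range(1, design.n_blocks + 1):
            for line in lines:
                is_control = line == design.control_line
                n_reps = (
                    design.control_reps_per_block
                    if is_control
                    else design.il_reps_per_block
                )
                for rep in range(1, n_reps + 1):
                    values: dict[str, float] = {}
                    for t in active:
                        pct = (
                            0.0
                            if is_control
                            else _expressed_percent(
                                il_genotypes[line], t, architecture.qtls
                            )
                        )
                        eps = rng.normal(0.0, sds[t]) if sds[t] > 0 else 0.0
                        values[t] = (
                            mus[t] * (1.0 + pct / 100.0)
                            + block_eff[(t, block)]
                            + gxl_eff[(t, line)]
                            + eps
                        )
                    if "FL" in values and "FD" in values and values["FD"] > 0:
                        values["FS"] = values["FL"] / values["FD"]
                    for t, v in values.items():
                        records.append((loc, block, line, rep, t, v))
    return pd.DataFrame(
        records,
        columns=["location", "block", "line", "replicate", "trait", "value"],
    )
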