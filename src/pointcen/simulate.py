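"""Synthetic genomes, planted point centromeres, and ChIP/input coverage.

The generator emulates a small post-WGD budding-yeast genome: ~10 chromosomes,
regularly spaced genes on alternating strands, and exactly one centromere per
chromosome placed strictly inside an intergenic interval.  Centromere windows
are drawn from a generative model of the Naumovozyma-type point centromere:
two short conserved elements (NaCDEI = SGGKTAA at window columns 20-26,
NaCDEII = ACGDDWWT at 45-52), a structured 70-bp conserved core spanning
columns 20-89 (a mixture of strict-A/T columns, G/C-rich columns, and biased
spacer columns), and AT-rich flanks.

ChIP coverage is simulated per kinetochore factor as negative-binomial counts
over fixed-width bins with Gaussian-shaped enrichment at each planted site:
every centromere, plus a per-factor number of weaker secondary sites
(emulating the one/two/six extra peaks seen for Cse4/Ndc10/Cep3 relative to
Ndc80).  All randomness flows from a single root seed through named child
streams, so adding a chromosome or a factor does not perturb other draws.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .iupac import BASES, IUPAC_SETS, encode, validate_pattern

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ElementSpec:
    """A conserved element inside the centromere window.

    ``start``/``end`` are 1-based inclusive window columns; ``pattern`` is an
    IUPAC string of matching length.
    """

    name: str
    start: int
    end: int
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_pattern(self.pattern))
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")
        if len(self.pattern) != self.end - self.start + 1:
            raise ValueError(
                f"{self.name}: pattern length {len(self.pattern)} != span "
                f"{self.end - self.start + 1}"
            )

    @property
    def columns(self) -> range:
        """0-based window column indices covered by the element."""
        return range(self.start - 1, self.end)


#: the two Naumovozyma consensus DNA elements at their window positions.
NACDEI = ElementSpec("NaCDEI", 20, 26, "SGGKTAA")
NACDEII = ElementSpec("NaCDEII", 45, 52, "ACGDDWWT")

# Structured core layout (1-based window columns) emulating the marked
# positions of the published consensus logo: strict A/T columns (the "blue"
# class), G/C columns (the asterisked class), and uniform-composition columns
# immediately flanking the elements so chance conservation cannot extend an
# element run.  Columns 87-89 anchor the right edge of the 20-89 core.
DEFAULT_AT_ONLY_COLUMNS = (29, 33, 38, 41, 56, 60, 64, 69, 73, 78, 82, 87, 88, 89)
DEFAULT_GC_RICH_COLUMNS = (31, 43, 55, 68, 80)
DEFAULT_NEUTRAL_COLUMNS = (19, 27, 44, 53)


@dataclass(frozen=True)
class CentromereModel:
    """Generative description of a point-centromere window."""

    window_length: int = 110
    elements: tuple[ElementSpec, ...] = (NACDEI, NACDEII)
    core_start: int = 20
    core_end: int = 89
    spacer_at_fraction: float = 0.7
    flank_at_fraction: float = 0.7
    at_only_columns: tuple[int, ...] = DEFAULT_AT_ONLY_COLUMNS
    gc_rich_columns: tuple[int, ...] = DEFAULT_GC_RICH_COLUMNS
    neutral_columns: tuple[int, ...] = DEFAULT_NEUTRAL_COLUMNS
    element_dominance: float = 0.995

    def __post_init__(self) -> None:
        if self.window_length < self.core_end:
            raise ValueError("window_length must cover core_end")
        if not 1 <= self.core_start <= self.core_end:
            raise ValueError("invalid core span")
        covered: set[int] = set()
        for el in self.elements:
            cols = set(range(el.start, el.end + 1))
            if cols & covered:
                raise ValueError(f"overlapping elements at {el.name}")
            if el.start < self.core_start or el.end > self.core_end:
                raise ValueError(f"{el.name} outside core span")
            covered |= cols
        for cols in (self.at_only_columns, self.gc_rich_columns, self.neutral_columns):
            for c in cols:
                if c in covered:
                    raise ValueError(f"designated column {c} overlaps an element")
                if not 1 <= c <= self.window_length:
                    raise ValueError(f"designated column {c} outside window")
        for frac in (self.spacer_at_fraction, self.flank_at_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("AT fractions must lie in [0, 1]")
        if not 0.0 < self.element_dominance <= 1.0:
            raise ValueError("element_dominance must lie in (0, 1]")

    def column_probs(self) -> np.ndarray:
        """Per-column sampling distribution over A/C/G/T, shape (window, 4)."""
        probs = np.empty((self.window_length, 4), dtype=float)
        for col in range(1, self.window_length + 1):
            at = (
                self.spacer_at_fraction
                if self.core_start <= col <= self.core_end
                else self.flank_at_fraction
            )
            probs[col - 1] = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
        for col in self.at_only_columns:
            probs[col - 1] = [0.5, 0.0, 0.0, 0.5]
        for col in self.gc_rich_columns:
            probs[col - 1] = [0.0, 0.5, 0.5, 0.0]
        for col in self.neutral_columns:
            probs[col - 1] = [0.25, 0.25, 0.25, 0.25]
        for el in self.elements:
            for j, code in enumerate(el.pattern):
                allowed = sorted(IUPAC_SETS[code])
                dominant = allowed[0]
                p = np.zeros(4)
                if len(allowed) == 1:
                    p[BASES.index(dominant)] = 1.0
                else:
                    minority = (1.0 - self.element_dominance) / (len(allowed) - 1)
                    for b in allowed:
                        p[BASES.index(b)] = minority
                    p[BASES.index(dominant)] = self.element_dominance
                probs[el.start - 1 + j] = p
        return probs


@dataclass(frozen=True)
class ConventionalCenModel:
    """Conventional CDEI-CDEII-CDEIII point centromere (the CDEII arm).

    CDEI/CDEIII consensus strings are configuration-supplied (no canonical
    strings are baked in); the CDEII spacer is 70-170 bp with AT content
    strictly above ``cdeII_min_at`` (>79% by default).
    """

    cdeI_pattern: Optional[str] = None
    cdeII_length_range: tuple[int, int] = (70, 170)
    cdeII_min_at: float = 0.79
    cdeII_at_bias: float = 0.90
    cdeIII_pattern: Optional[str] = None

    def __post_init__(self) -> None:
        lo, hi = self.cdeII_length_range
        if not 0 < lo <= hi:
            raise ValueError("empty CDEII length range")
        if not 0.0 <= self.cdeII_min_at <= 1.0:
            raise ValueError("cdeII_min_at must lie in [0, 1]")
        for pat in (self.cdeI_pattern, self.cdeIII_pattern):
            if pat is not None:
                validate_pattern(pat)


@dataclass(frozen=True)
class ChipSimParams:
    """Negative-binomial ChIP coverage simulation parameters.

    ``dispersion`` is the NB overdispersion alpha (variance = m + alpha*m^2);
    ``peak_fold`` the enrichment multiplier at a centromere summit; ``peak_sd``
    the Gaussian kernel width in bp; ``secondary_rel_amplitude`` scales the
    excess enrichment of secondary sites relative to centromeres.
    """

    bin_size: int = 50
    background_mean: float = 100.0
    dispersion: float = 0.02
    peak_fold: float = 12.0
    peak_sd: float = 150.0
    secondary_rel_amplitude: float = 0.15

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.peak_fold <= 1:
            raise ValueError("peak_fold must exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


#: per-factor extra-peak counts mirroring the Cse4/Ndc10/Cep3 observations.
DEFAULT_SECONDARY_SITES = {"Ndc80": 0, "Cse4": 1, "Ndc10": 2, "Cep3": 6}


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_chromosomes: int = 10
    chrom_length: int = 300_000
    gene_length: int = 1_500
    intergenic_length: int = 500
    seed: int = 0
    secondary_sites_per_factor: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SECONDARY_SITES)
    )
    secondary_min_cen_distance: int = 50_000
    chip: ChipSimParams = field(default_factory=ChipSimParams)

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "gene_length", "intergenic_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Gene:
    """A gene feature; coordinates are 0-based half-open."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class ElementTruth:
    window: tuple[int, int]  # 1-based inclusive window columns
    genome: tuple[int, int]  # 0-based half-open genome coords
    sequence: str


@dataclass
class CentromereTruth:
    chrom: str
    start: int  # 0-based half-open genome coords
    end: int
    core_window: tuple[int, int]  # 1-based inclusive window columns
    elements: dict[str, ElementTruth]
    sequence: str


@dataclass
class PlantedTruth:
    """Machine-readable record of everything the generator planted."""

    window_length: int
    centromeres: list[CentromereTruth]
    secondary_sites: dict[str, list[tuple[str, int]]]

    def centromere_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for cen in self.centromeres:
            out.setdefault(cen.chrom, []).append((cen.start, cen.end))
        return out

    def sites_for(self, factor: str) -> list[tuple[str, int]]:
        """All planted enrichment sites (centromere midpoints + secondary)."""
        if factor not in self.secondary_sites:
            raise KeyError(f"unknown factor {factor!r}")
        sites = [(c.chrom, (c.start + c.end) // 2) for c in self.centromeres]
        sites.extend(self.secondary_sites[factor])
        return sites

    def to_dict(self) -> dict:
        return {
            "window_length": self.window_length,
            "centromeres": [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "core_window": list(c.core_window),
                    "sequence": c.sequence,
                    "elements": {
                        name: {
                            "window": list(e.window),
                            "genome": list(e.genome),
                            "sequence": e.sequence,
                        }
                        for name, e in c.elements.items()
                    },
                }
                for c in self.centromeres
            ],
            "secondary_sites": {
                f: [[chrom, pos] for chrom, pos in sites]
                for f, sites in self.secondary_sites.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PlantedTruth":
        cens = [
            CentromereTruth(
                chrom=c["chrom"],
                start=c["start"],
                end=c["end"],
                core_window=tuple(c["core_window"]),
                sequence=c["sequence"],
                elements={
                    name: ElementTruth(
                        window=tuple(e["window"]),
                        genome=tuple(e["genome"]),
                        sequence=e["sequence"],
                    )
                    for name, e in c["elements"].items()
                },
            )
            for c in data["centromeres"]
        ]
        secondary = {
            f: [(chrom, pos) for chrom, pos in sites]
            for f, sites in data["secondary_sites"].items()
        }
        return cls(data["window_length"], cens, secondary)


@dataclass
class SampledCentromere:
    sequence: str
    elements: dict[str, tuple[int, int]]  # name -> 1-based window span


@dataclass(frozen=True)
class CoverageTrack:
    """Binned, per-chromosome read counts (uniform bin width)."""

    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, arr in self.data.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative counts on {chrom}")


# ---------------------------------------------------------------------------
# RNG plumbing


def child_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic named child stream of a root seed.

    String keys are hashed with crc32 so streams are stable across runs and
    insensitive to how many sibling streams exist.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            ints.append(zlib.crc32(key.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(key) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


# ---------------------------------------------------------------------------
# operations


def sample_centromere(
    model: CentromereModel, rng: np.random.Generator
) -> SampledCentromere:
    """Draw one centromere window from the model.

    Every element subsequence is guaranteed to match its IUPAC pattern
    because element columns sample only from the pattern's base set.
    """
    probs = model.column_probs()
    u = rng.random(model.window_length)
    cum = np.cumsum(probs, axis=1)
    idx = np.minimum((u[:, None] > cum).sum(axis=1), 3)
    seq = "".join(BASES[i] for i in idx)
    return SampledCentromere(
        sequence=seq,
        elements={el.name: (el.start, el.end) for el in model.elements},
    )


def at_content(sequence: str) -> float:
    """Fraction of A/T bases; N and any other base count as non-AT."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    return (seq.count("A") + seq.count("T")) / len(seq)


def sample_cdeii(
    model: ConventionalCenModel, rng: np.random.Generator
) -> str:
    """Sample a conventional CDEII spacer with AT content strictly > cdeII_min_at.

    Bases are drawn i.i.d. with A/T probability ``cdeII_at_bias``; rare draws
    at or below the AT bound are rejected and resampled, so the constraint
    holds by construction.
    """
    lo, hi = model.cdeII_length_range
    length = int(rng.integers(lo, hi + 1))
    at = model.cdeII_at_bias
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    while True:
        idx = rng.choice(4, size=length, p=probs)
        seq = "".join(BASES[i] for i in idx)
        if at_content(seq) > model.cdeII_min_at:
            return seq


def sample_conventional_centromere(
    model: ConventionalCenModel, rng: np.random.Generator
) -> str:
    """Sample CDEI + CDEII + CDEIII (elements only if patterns are configured)."""

    def realize(pattern: Optional[str]) -> str:
        if pattern is None:
            return ""
        return "".join(
            sorted(IUPAC_SETS[c])[int(rng.integers(len(IUPAC_SETS[c])))]
            for c in pattern
        )

    return realize(model.cdeI_pattern) + sample_cdeii(model, rng) + realize(
        model.cdeIII_pattern
    )


_BACKGROUND_PROBS = np.array([0.30, 0.20, 0.20, 0.30])  # ~60% AT, yeast-like


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=length, p=_BACKGROUND_PROBS).astype(np.uint8)


def generate_genome(
    config: SyntheticGenomeConfig,
    cen_model: Optional[CentromereModel] = None,
) -> tuple[dict[str, str], list[Gene], PlantedTruth]:
    """Generate chromosome sequences, gene annotations and planted truth.

    Chromosomes alternate intergenic and gene blocks; one centromere window is
    planted in the intergenic interval nearest the chromosome midpoint; each
    factor's secondary sites go to intergenic midpoints at least
    ``secondary_min_cen_distance`` from every centromere.
    """
    cen_model = cen_model or CentromereModel()
    if config.intergenic_length < cen_model.window_length + 2:
        raise ValueError(
            "intergenic_length must exceed the centromere window length"
        )
    unit = config.gene_length + config.intergenic_length
    n_genes = (config.chrom_length - config.intergenic_length) // unit
    if n_genes < 2:
        raise ValueError("chromosome too short to hold two genes")

    genome: dict[str, str] = {}
    genes: list[Gene] = []
    centromeres: list[CentromereTruth] = []
    intergenic_mids: list[tuple[str, int]] = []

    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1:02d}"
        rng = child_rng(config.seed, "chrom", i)
        seq = _random_sequence(config.chrom_length, rng)

        chrom_genes = []
        for j in range(n_genes):
            start = config.intergenic_length + j * unit
            chrom_genes.append(
                Gene(
                    id=f"{chrom}_g{j + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + config.gene_length,
                    strand="+" if j % 2 == 0 else "-",
                )
            )
        genes.extend(chrom_genes)

        # intergenic intervals between consecutive genes
        intervals = [
            (chrom_genes[j].end, chrom_genes[j + 1].start)
            for j in range(n_genes - 1)
        ]
        mid_target = config.chrom_length // 2
        cen_iv = min(intervals, key=lambda iv: abs((iv[0] + iv[1]) // 2 - mid_target))
        cen_start = (cen_iv[0] + cen_iv[1] - cen_model.window_length) // 2
        cen_end = cen_start + cen_model.window_length

        sample = sample_centromere(cen_model, rng)
        seq[cen_start:cen_end] = encode(sample.sequence)
        genome[chrom] = "".join(BASES[b] for b in seq)

        elements = {
            name: ElementTruth(
                window=span,
                genome=(cen_start + span[0] - 1, cen_start + span[1]),
                sequence=sample.sequence[span[0] - 1 : span[1]],
            )
            for name, span in sample.elements.items()
        }
        centromeres.append(
            CentromereTruth(
                chrom=chrom,
                start=cen_start,
                end=cen_end,
                core_window=(cen_model.core_start, cen_model.core_end),
                elements=elements,
                sequence=sample.sequence,
            )
        )
        cen_mid = (cen_start + cen_end) // 2
        for iv in intervals:
            mid = (iv[0] + iv[1]) // 2
            if abs(mid - cen_mid) >= config.secondary_min_cen_distance:
                intergenic_mids.append((chrom, mid))

    secondary: dict[str, list[tuple[str, int]]] = {}
    for factor in sorted(config.secondary_sites_per_factor):
        count = config.secondary_sites_per_factor[factor]
        if count > len(intergenic_mids):
            raise ValueError(f"not enough intergenic sites for factor {factor}")
        rng = child_rng(config.seed, "secondary", factor)
        chosen = rng.choice(len(intergenic_mids), size=count, replace=False)
        secondary[factor] = sorted(intergenic_mids[k] for k in chosen)

    truth = PlantedTruth(
        window_length=cen_model.window_length,
        centromeres=centromeres,
        secondary_sites=secondary,
    )
    return genome, genes, truth


def _nb_draw(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion*m^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_coverage(
    genome: Mapping[str, str],
    truth: PlantedTruth,
    factor: str,
    params: ChipSimParams,
    rng: np.random.Generator,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate (chip, input) coverage tracks for one factor.

    Input is flat NB noise; chip multiplies the background mean by
    ``1 + (peak_fold-1) * a * G(d)`` summed over planted sites, where G is a
    Gaussian kernel of width ``peak_sd`` and ``a`` is 1 for centromeres and
    ``secondary_rel_amplitude`` for secondary sites.
    """
    missing = {c.chrom for c in truth.centromeres} - set(genome)
    if missing:
        raise ValueError(f"truth chromosomes absent from genome: {sorted(missing)}")
    if factor not in truth.secondary_sites:
        raise KeyError(f"unknown factor {factor!r}")

    sites: dict[str, list[tuple[int, float]]] = {}
    for cen in truth.centromeres:
        sites.setdefault(cen.chrom, []).append(((cen.start + cen.end) // 2, 1.0))
    for chrom, pos in truth.secondary_sites[factor]:
        sites.setdefault(chrom, []).append((pos, params.secondary_rel_amplitude))

    chip_data: dict[str, np.ndarray] = {}
    input_data: dict[str, np.ndarray] = {}
    for chrom in sorted(genome):
        n_bins = len(genome[chrom]) // params.bin_size
        centers = np.arange(n_bins) * params.bin_size + params.bin_size / 2
        enrich = np.ones(n_bins)
        for pos, amp in sites.get(chrom, []):
            d = centers - pos
            local = np.abs(d) <= 6 * params.peak_sd
            enrich[local] += (
                (params.peak_fold - 1.0)
                * amp
                * np.exp(-(d[local] ** 2) / (2 * params.peak_sd**2))
            )
        chip_data[chrom] = _nb_draw(
            params.background_mean * enrich, params.dispersion, rng
        )
        input_data[chrom] = _nb_draw(
            np.full(n_bins, params.background_mean), params.dispersion, rng
        )
    return (
        CoverageTrack(params.bin_size, chip_data),
        CoverageTrack(params.bin_size, input_data),
    )


def generate_reference(
    truth: PlantedTruth,
    genes: Sequence[Gene],
    n_conserved: int = 1,
) -> tuple[dict[str, list[str]], dict[str, list[str]], list[tuple[str, int]]]:
    """Build a rearranged reference gene order plus ortholog map.

    The reference starts as a renamed copy of the query gene order.  For all
    but ``n_conserved`` chromosomes the two arms around the centromere-flanking
    adjacency are split and reassembled across chromosomes (arm of chromosome
    i joined to the next scrambled chromosome's arm), so the centromere
    adjacency is a synteny breakpoint there.  The conserved chromosomes keep
    their order and carry a reference centromere at the same adjacency,
    mirroring the single fully syntenic ancestral/NcCEN pair.

    Returns (reference gene order, ortholog map query->reference, reference
    centromere adjacencies as (chrom, index) pairs meaning "between order[index]
    and order[index+1]").
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    orthologs = {}
    ref_name = {}
    for g in genes:
        ref_name[g.id] = "anc_" + g.id
        orthologs[g.id] = ["anc_" + g.id]

    # index of the adjacency split by each centromere
    cen_adj: dict[str, int] = {}
    for cen in truth.centromeres:
        order = by_chrom[cen.chrom]
        left = max(
            (k for k, g in enumerate(order) if g.end <= cen.start), default=None
        )
        if left is None or left + 1 >= len(order):
            raise ValueError(f"centromere on {cen.chrom} lacks flanking genes")
        cen_adj[cen.chrom] = left

    chroms = sorted(by_chrom)
    conserved = chroms[-n_conserved:] if n_conserved > 0 else []
    scrambled = [c for c in chroms if c not in conserved]

    ref_order: dict[str, list[str]] = {}
    ref_centromeres: list[tuple[str, int]] = []
    for chrom in conserved:
        ref_order["anc_" + chrom] = [ref_name[g.id] for g in by_chrom[chrom]]
        ref_centromeres.append(("anc_" + chrom, cen_adj[chrom]))

    lefts, rights = [], []
    for chrom in scrambled:
        names = [ref_name[g.id] for g in by_chrom[chrom]]
        k = cen_adj[chrom]
        lefts.append(names[: k + 1])
        rights.append(names[k + 1 :])
    # reciprocal reshuffle: left arm of i fused to right arm of i+1
    for j, chrom in enumerate(scrambled):
        ref_order["anc_" + chrom] = lefts[j] + rights[(j + 1) % len(scrambled)]
    return ref_order, orthologs, ref_centromeres
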