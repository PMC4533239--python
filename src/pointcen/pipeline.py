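"""End-to-end orchestration: simulate -> peaks -> consensus -> scan -> synteny.

``run_all`` executes the full discovery chain from a single configuration,
persists every intermediate in a standard format, and writes a JSON run
report whose metrics are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from . import io
from .consensus import (
    ClassifyThresholds,
    anchor_align,
    annotate_consensus,
    build_pfm,
)
from .peaks import (
    PeakCallParams,
    Peak,
    call_peaks,
    classify_intergenic,
    compute_enrichment,
    peak_summary,
)
from .scan import DegenerateMotif, scan_genome, uniqueness_report
from .simulate import (
    CentromereModel,
    Gene,
    PlantedTruth,
    SyntheticGenomeConfig,
    child_rng,
    generate_genome,
    generate_reference,
    simulate_coverage,
)
from .synteny import GeneOrder, OrthologMap, locate_centromere, synteny_survey

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: Optional[SyntheticGenomeConfig] = None
    cen_model: CentromereModel = field(default_factory=CentromereModel)
    paths: Optional[Mapping[str, str]] = None  # real-data inputs
    primary_factor: str = "Ndc80"
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    include_min: float = 0.15
    extract_window: int = 400
    consensus_window: int = 110
    gap_tolerance: int = 5
    uniqueness_max_mismatch: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.simulate is None) == (self.paths is None):
            raise ConfigError(
                "exactly one of a simulate block or real-data paths is required"
            )

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        raw = io.load_yaml(path)
        kwargs: dict = {}
        if "simulate" in raw and raw.get("paths"):
            raise ConfigError("config has both a simulate block and data paths")
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            if seed is not None:
                sim["seed"] = seed
            kwargs["simulate"] = io.simulate_config_from_dict(sim)
        if raw.get("paths"):
            kwargs["paths"] = raw["paths"]
        if "cen_model" in raw:
            kwargs["cen_model"] = io.centromere_model_from_dict(raw["cen_model"])
        if "peak_params" in raw:
            kwargs["peak_params"] = PeakCallParams(**raw["peak_params"])
        if "thresholds" in raw:
            kwargs["thresholds"] = ClassifyThresholds(**raw["thresholds"])
        for key in (
            "primary_factor",
            "include_min",
            "extract_window",
            "consensus_window",
            "gap_tolerance",
            "uniqueness_max_mismatch",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        kwargs["outdir"] = Path(outdir if outdir is not None else raw.get("outdir", "."))
        kwargs["seed"] = seed if seed is not None else raw.get("seed", 0)
        return cls(**kwargs)


@dataclass
class RunReport:
    outputs: dict[str, str]
    metrics: dict
    seed: int
    version: str
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_candidates(
    genome: Mapping[str, str], peaks: list[Peak], window: int = 400
) -> list[tuple[str, str]]:
    """Window of ``window`` bp centered on each chromosome's primary summit.

    With multiple primary peaks on a chromosome the top-ranked (largest-area)
    one is used with a warning; windows are clipped at chromosome ends.
    Candidate names are the chromosome IDs.
    """
    primary = [p for p in peaks if p.tier == "primary"]
    if not primary:
        raise ValueError("no primary peaks to extract candidates from")
    by_chrom: dict[str, list[Peak]] = {}
    for p in primary:
        by_chrom.setdefault(p.chromosome, []).append(p)

    candidates = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: -p.area)
        if len(chrom_peaks) > 1:
            log.warning(
                "%d primary peaks on %s; taking the top-ranked one",
                len(chrom_peaks),
                chrom,
            )
        summit = chrom_peaks[0].summit
        seq = genome[chrom]
        start = max(0, summit - window // 2)
        end = min(len(seq), start + window)
        if end - start < window:
            start = max(0, end - window)
            log.warning("candidate window clipped at %s end", chrom)
        candidates.append((chrom, seq[start:end]))
    return candidates


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    metrics: dict = {}

    def save(key: str, filename: str) -> Path:
        path = outdir / filename
        outputs[key] = str(path)
        return path

    # --- inputs: simulate or load -----------------------------------------
    truth: Optional[PlantedTruth] = None
    ref_order = orthologs = ref_cens = None
    if config.simulate is not None:
        sim = config.simulate
        genome, genes, truth = generate_genome(sim, config.cen_model)
        io.write_fasta(genome, save("genome", "genome.fa"))
        io.write_gff3(
            genes,
            save("gff", "genes.gff3"),
            centromeres=[(c.chrom, c.start, c.end) for c in truth.centromeres],
        )
        io.write_truth(truth, save("truth", "truth.json"))
        factors = sorted(sim.secondary_sites_per_factor)
        tracks = {}
        for factor in factors:
            rng = child_rng(sim.seed, "chip", factor)
            chip, inp = simulate_coverage(genome, truth, factor, sim.chip, rng)
            io.write_bedgraph(chip, save(f"chip_{factor}", f"{factor}.chip.bedgraph"))
            io.write_bedgraph(inp, save(f"input_{factor}", f"{factor}.input.bedgraph"))
            tracks[factor] = (chip, inp)
        ref_order_raw, orthologs_raw, ref_cens = generate_reference(truth, genes)
        ref_order = GeneOrder(ref_order_raw)
        orthologs = OrthologMap.from_mapping(orthologs_raw)
    else:
        paths = config.paths
        genome = io.read_fasta(paths["genome"])
        genes = io.read_gff3_genes(paths["gff"])
        factors = sorted(paths.get("chip", {}))
        if not factors:
            raise ConfigError("real-data config lists no chip tracks")
        tracks = {
            f: (io.read_bedgraph(paths["chip"][f]), io.read_bedgraph(paths["input"][f]))
            for f in factors
        }
        if "orthologs" in paths and "ref_order" in paths:
            raise ConfigError("real-data synteny inputs not supported in this build")

    annotations: dict[str, list[Gene]] = {}
    for g in genes:
        annotations.setdefault(g.chrom, []).append(g)

    # --- peaks --------------------------------------------------------------
    peaks_by_factor: dict[str, list[Peak]] = {}
    for factor in factors:
        chip, inp = tracks[factor]
        enr = compute_enrichment(
            chip, inp, config.peak_params.pseudocount, config.peak_params.smooth_bins
        )
        called = [
            classify_intergenic(p, annotations)
            for p in call_peaks(enr, config.peak_params)
        ]
        peaks_by_factor[factor] = called
        io.write_peaks_bed(called, save(f"peaks_{factor}", f"peaks.{factor}.bed"), factor)

    summary = peak_summary(
        peaks_by_factor, chromosomes=sorted(genome), truth=truth
    )
    save("peak_summary", "peak_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )
    with open(save("peak_summary_tsv", "peak_summary.tsv"), "w") as fh:
        fh.write("factor\tn_primary\tn_secondary\tsingle_peak_chromosomes\n")
        for factor in factors:
            e = summary["factors"][factor]
            fh.write(
                f"{factor}\t{e['n_primary']}\t{e['n_secondary']}\t"
                f"{e['single_peak_chromosomes']}\n"
            )
    primary_factor = config.primary_factor
    if primary_factor not in peaks_by_factor:
        raise ConfigError(f"primary factor {primary_factor!r} has no track")
    metrics["single_peak_chromosomes"] = summary["factors"][primary_factor][
        "single_peak_chromosomes"
    ]
    metrics["secondary_peaks"] = {
        f: summary["factors"][f]["n_secondary"] for f in factors
    }

    # --- consensus ------------------------------------------------------------
    candidates = extract_candidates(
        genome, peaks_by_factor[primary_factor], config.extract_window
    )
    io.write_fasta(dict(candidates), save("candidates", "candidates.fa"))
    alignment = anchor_align(candidates, config.consensus_window)
    pfm = build_pfm(candidates, alignment)
    annotation = annotate_consensus(pfm, config.thresholds, config.include_min)
    io.write_jaspar_pfm(pfm, save("pfm", "pfm.jaspar"))
    save("consensus", "consensus.json").write_text(
        json.dumps(
            {
                "degenerate": annotation.degenerate,
                "classes": annotation.classes,
                "elements": [
                    {"start": e.start, "end": e.end, "pattern": e.pattern}
                    for e in annotation.elements
                ],
                "core": list(annotation.core) if annotation.core else None,
            },
            indent=1,
        )
    )
    with open(save("consensus_tsv", "consensus.tsv"), "w") as fh:
        fh.write("column\tclass\tcode\n")
        for j, (cls, code) in enumerate(
            zip(annotation.classes, annotation.degenerate), 1
        ):
            fh.write(f"{j}\t{cls}\t{code}\n")
    metrics["element_spans"] = [[e.start, e.end] for e in annotation.elements]
    metrics["core_span"] = list(annotation.core) if annotation.core else None
    metrics["core_length"] = annotation.core_length

    # --- uniqueness scan ------------------------------------------------------
    if annotation.core is not None:
        lo, hi = annotation.core
        core_motif = DegenerateMotif("consensus_core", annotation.degenerate[lo - 1 : hi])
        hits = scan_genome(genome, core_motif, config.uniqueness_max_mismatch)
        if truth is not None:
            intervals = truth.centromere_intervals()
        else:
            intervals = {}
            for chrom, _ in candidates:
                p = max(
                    (q for q in peaks_by_factor[primary_factor]
                     if q.chromosome == chrom and q.tier == "primary"),
                    key=lambda q: q.area,
                )
                intervals.setdefault(chrom, []).append((p.start, p.end))
        report = uniqueness_report(hits, intervals, len(core_motif))
        metrics["uniqueness"] = {
            "at_centromere": report.at_centromere,
            "elsewhere": report.elsewhere,
        }
        save("uniqueness", "uniqueness.json").write_text(
            json.dumps(metrics["uniqueness"], indent=1)
        )

    # --- synteny ---------------------------------------------------------------
    if truth is not None and ref_order is not None:
        loci = [
            locate_centromere((c.chrom, c.start, c.end), annotations[c.chrom])
            for c in truth.centromeres
        ]
        calls, syn_summary = synteny_survey(
            loci, orthologs, ref_order, ref_cens, config.gap_tolerance
        )
        metrics["synteny"] = syn_summary
        with open(save("synteny", "synteny_calls.tsv"), "w") as fh:
            fh.write("chromosome\tflank_left\tflank_right\tstatus\tgap\tpartner_has_centromere\n")
            for call in calls:
                fh.write(
                    f"{call.locus.chromosome}\t{call.locus.flank_left}\t"
                    f"{call.locus.flank_right}\t{call.status}\t"
                    f"{'' if call.gap is None else call.gap}\t"
                    f"{str(call.partner_has_centromere).lower()}\n"
                )

    from . import __version__

    report = RunReport(
        outputs=outputs,
        metrics=metrics,
        seed=config.simulate.seed if config.simulate else config.seed,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report
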