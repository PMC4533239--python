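"""Readers and writers for the standard formats the pipeline exchanges.

FASTA goes through Biopython, GFF3 parsing through gffutils; bedGraph is a
plain 4-column table handled with pandas.  Coordinates are 0-based half-open
internally and converted at the GFF3 boundary (1-based inclusive).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import PositionFrequencyMatrix
from .peaks import Peak
from .simulate import (
    CentromereModel,
    ChipSimParams,
    CoverageTrack,
    ElementSpec,
    Gene,
    PlantedTruth,
    SyntheticGenomeConfig,
)

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(
    genes: Sequence[Gene],
    path,
    centromeres: Sequence[tuple[str, int, int]] = (),
) -> None:
    """Write gene (and optional centromere) features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tpointcen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )
        for i, (chrom, start, end) in enumerate(centromeres, 1):
            fh.write(
                f"{chrom}\tpointcen\tcentromere\t{start + 1}\t{end}\t.\t.\t.\t"
                f"ID=CEN{i}\n"
            )


def read_gff3_genes(path) -> list[Gene]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            Gene(
                id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_gff3_centromeres(path) -> list[tuple[str, int, int]]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    return [
        (f.seqid, f.start - 1, f.end) for f in db.features_of_type("centromere")
    ]


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, path) -> None:
    rows = []
    for chrom in sorted(track.data):
        counts = np.asarray(track.data[chrom])
        starts = np.arange(counts.size) * track.bin_size
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + track.bin_size,
                    "value": counts,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise ValueError(f"{path}: bedGraph bins are not uniform")
    bin_size = int(widths[0])
    data = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        expected = np.arange(len(sub)) * bin_size
        if not np.array_equal(sub["start"].to_numpy(), expected):
            raise ValueError(f"{path}: non-contiguous bins on {chrom}")
        data[str(chrom)] = sub["value"].to_numpy(dtype=float)
    return CoverageTrack(bin_size, data)


# ---------------------------------------------------------------------------
# peaks and PFM


def write_peaks_bed(peaks: Sequence[Peak], path, factor: str = ".") -> None:
    """BED6+3: name=factor, score=round(100*max_enrichment), +summit,tier,intergenic."""
    with open(path, "w") as fh:
        for p in peaks:
            intergenic = "unknown" if p.intergenic is None else str(p.intergenic).lower()
            fh.write(
                f"{p.chromosome}\t{p.start}\t{p.end}\t{factor}\t"
                f"{round(100 * p.max_enrichment)}\t.\t{p.summit}\t{p.tier}\t"
                f"{intergenic}\n"
            )


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path, name: str = "consensus") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", pfm.counts):
            fh.write(f"{base}  [ " + "  ".join(str(int(v)) for v in row) + " ]\n")


def read_jaspar_pfm(path) -> PositionFrequencyMatrix:
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            base = line[0]
            inner = line[line.index("[") + 1 : line.index("]")]
            rows[base] = [int(v) for v in inner.split()]
    counts = np.array([rows[b] for b in "ACGT"])
    return PositionFrequencyMatrix(counts, int(counts.sum(axis=0)[0]))


# ---------------------------------------------------------------------------
# truth / config


def write_truth(truth: PlantedTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path) -> PlantedTruth:
    return PlantedTruth.from_dict(json.loads(Path(path).read_text()))


def centromere_model_from_dict(d: Mapping) -> CentromereModel:
    kwargs = dict(d)
    if "elements" in kwargs:
        kwargs["elements"] = tuple(
            ElementSpec(e["name"], e["start"], e["end"], e["pattern"])
            for e in kwargs["elements"]
        )
    for key in ("at_only_columns", "gc_rich_columns", "neutral_columns"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CentromereModel(**kwargs)


def simulate_config_from_dict(d: Mapping) -> SyntheticGenomeConfig:
    kwargs = dict(d)
    if "chip" in kwargs:
        kwargs["chip"] = ChipSimParams(**kwargs["chip"])
    return SyntheticGenomeConfig(**kwargs)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
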