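"""ChIP/input enrichment and single-peak calling with primary/secondary tiers.

The caller is deliberately simple: pseudocounted chip/input ratio, a short
moving average, and thresholds expressed as folds over the genome-wide median
enrichment (a robust baseline when only a tiny fraction of bins is enriched).
The claim being tested downstream is "one dominant peak per chromosome at an
intergenic position", not statistical significance, so there is no FDR
machinery here.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .simulate import CoverageTrack, Gene

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentTrack:
    """Per-bin smoothed chip/input ratio (dimensionless, > 0)."""

    bin_size: int
    data: dict[str, np.ndarray]


@dataclass(frozen=True)
class PeakCallParams:
    pseudocount: float = 1.0
    smooth_bins: int = 5
    primary_threshold: float = 4.0
    secondary_threshold: float = 1.8
    merge_gap: int = 2
    min_width: int = 3

    def __post_init__(self) -> None:
        if self.smooth_bins < 1 or self.smooth_bins % 2 == 0:
            raise ValueError("smooth_bins must be a positive odd integer")
        if not self.secondary_threshold < self.primary_threshold:
            raise ValueError("secondary_threshold must be below primary_threshold")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class Peak:
    chromosome: str
    start: int  # 0-based half-open genome coords
    end: int
    summit: int  # genome coordinate of the (leftmost) max-enrichment bin center
    max_enrichment: float
    area: float  # sum of (enrichment - 1) over the peak's bins
    tier: str  # "primary" | "secondary"
    intergenic: Optional[bool] = None


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges normalize by the in-range window size."""
    if window == 1:
        return values.astype(float)
    kernel = np.ones(window)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return num / den


def compute_enrichment(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    pseudocount: float = 1.0,
    smooth_bins: int = 5,
) -> EnrichmentTrack:
    """Per-bin (chip+pc)/(input+pc), then a centered moving average."""
    if chip.bin_size != input_track.bin_size:
        raise ValueError("chip and input tracks have different bin sizes")
    if set(chip.data) != set(input_track.data):
        raise ValueError("chip and input tracks cover different chromosomes")
    data: dict[str, np.ndarray] = {}
    for chrom in chip.data:
        c = np.asarray(chip.data[chrom], dtype=float)
        i = np.asarray(input_track.data[chrom], dtype=float)
        if c.shape != i.shape:
            raise ValueError(f"bin count mismatch on {chrom}")
        ratio = (c + pseudocount) / (i + pseudocount)
        data[chrom] = moving_average(ratio, smooth_bins)
    return EnrichmentTrack(chip.bin_size, data)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True bins."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _merge_runs(
    runs: list[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def call_peaks(
    enrichment: EnrichmentTrack, params: PeakCallParams = PeakCallParams()
) -> list[Peak]:
    """Call peaks as thresholded runs of bins; tier by max enrichment.

    Bins strictly above ``secondary_threshold`` x genome-wide median form
    candidate runs, merged across gaps of at most ``merge_gap`` bins and
    dropped when narrower than ``min_width`` bins.  A peak is primary when its
    maximum enrichment reaches ``primary_threshold`` x median.  Summit ties
    break leftmost; the returned list is sorted by area, descending.
    """
    all_bins = np.concatenate([enrichment.data[c] for c in sorted(enrichment.data)])
    if all_bins.size == 0:
        raise ValueError("empty enrichment track")
    median = float(np.median(all_bins))
    if median <= 0 or np.allclose(all_bins, all_bins[0]):
        if np.allclose(all_bins, 1.0):
            log.warning("flat enrichment track (all-zero coverage?); no peaks")
    sec_thr = params.secondary_threshold * median
    pri_thr = params.primary_threshold * median

    bs = enrichment.bin_size
    peaks: list[Peak] = []
    for chrom in sorted(enrichment.data):
        enr = enrichment.data[chrom]
        runs = _merge_runs(_runs_above(enr > sec_thr), params.merge_gap)
        for b0, b1 in runs:
            if b1 - b0 < params.min_width:
                continue
            segment = enr[b0:b1]
            k = int(np.argmax(segment))  # argmax is leftmost by numpy contract
            peaks.append(
                Peak(
                    chromosome=chrom,
                    start=b0 * bs,
                    end=b1 * bs,
                    summit=(b0 + k) * bs + bs // 2,
                    max_enrichment=float(segment[k]),
                    area=float(np.sum(segment - 1.0)),
                    tier="primary" if segment[k] >= pri_thr else "secondary",
                )
            )
    peaks.sort(key=lambda p: (-p.area, p.chromosome, p.start))
    return peaks


def classify_intergenic(
    peak: Peak, annotations: Mapping[str, Sequence[Gene]]
) -> Peak:
    """Set the intergenic flag: true iff the summit lies inside no gene.

    Gene intervals are 0-based half-open, so a summit exactly at a gene's end
    coordinate is intergenic.
    """
    if peak.chromosome not in annotations:
        log.warning("no annotations for %s; intergenic flag unknown", peak.chromosome)
        return dataclasses.replace(peak, intergenic=None)
    inside = any(
        g.start <= peak.summit < g.end for g in annotations[peak.chromosome]
    )
    return dataclasses.replace(peak, intergenic=not inside)


def peak_summary(
    peaks_by_factor: Mapping[str, Sequence[Peak]],
    chromosomes: Optional[Iterable[str]] = None,
    truth=None,
    match_distance: float = 150.0,
) -> dict:
    """Aggregate peak calls per factor; score against planted truth if given.

    A called peak matches a planted site when its summit lies within
    ``match_distance`` bp of the site.  ``single_peak_chromosomes`` counts
    chromosomes carrying exactly one primary peak.
    """
    if chromosomes is None:
        chromosomes = sorted(
            {p.chromosome for peaks in peaks_by_factor.values() for p in peaks}
        )
    chromosomes = list(chromosomes)

    summary: dict = {"factors": {}, "chromosomes": chromosomes}
    for factor, peaks in peaks_by_factor.items():
        primary = [p for p in peaks if p.tier == "primary"]
        secondary = [p for p in peaks if p.tier == "secondary"]
        per_chrom = {c: sum(p.chromosome == c for p in primary) for c in chromosomes}
        entry = {
            "n_primary": len(primary),
            "n_secondary": len(secondary),
            "primary_per_chromosome": per_chrom,
            "single_peak_chromosomes": sum(v == 1 for v in per_chrom.values()),
        }
        if truth is not None:
            sites = truth.sites_for(factor)
            matched_sites = sum(
                any(
                    p.chromosome == chrom and abs(p.summit - pos) <= match_distance
                    for p in peaks
                )
                for chrom, pos in sites
            )
            matched_peaks = sum(
                any(
                    p.chromosome == chrom and abs(p.summit - pos) <= match_distance
                    for chrom, pos in sites
                )
                for p in peaks
            )
            entry["recall"] = matched_sites / len(sites) if sites else float("nan")
            entry["precision"] = matched_peaks / len(peaks) if peaks else float("nan")
        summary["factors"][factor] = entry
    return summary
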