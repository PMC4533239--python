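"""Gene-order synteny classification of centromere loci.

A centromere locus is represented by the two genes immediately flanking its
intergenic interval.  Against a reference gene order and an ortholog map
(allowing up to two partners per gene, the post-WGD double mapping), the locus
is *syntenic* when some ortholog of the left flank and some ortholog of the
right flank lie on one reference chromosome separated by at most
``gap_tolerance`` intervening genes (existential semantics over the <=2x2
pairings, orientation-agnostic), *breakpoint* when every pairing violates
this, and *ambiguous* when a flank is absent or has no ortholog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .simulate import Gene

log = logging.getLogger(__name__)

#: reference centromere: (chromosome, adjacency index i) meaning the
#: centromere sits between order[i] and order[i+1] on that chromosome.
RefCentromere = tuple[str, int]


@dataclass(frozen=True)
class GeneOrder:
    """Ordered gene IDs per chromosome; strands carried but unused for calls."""

    order: Mapping[str, Sequence[str]]
    strands: Mapping[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, ids in self.order.items():
            for gid in ids:
                if gid in seen:
                    raise ValueError(f"duplicate gene ID {gid!r}")
                seen.add(gid)

    def index(self) -> dict[str, tuple[str, int]]:
        return {
            gid: (chrom, i)
            for chrom, ids in self.order.items()
            for i, gid in enumerate(ids)
        }

    @classmethod
    def from_genes(cls, genes: Sequence[Gene]) -> "GeneOrder":
        by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        order = {
            chrom: [g.id for g in sorted(lst, key=lambda g: g.start)]
            for chrom, lst in by_chrom.items()
        }
        strands = {g.id: g.strand for g in genes}
        return cls(order, strands)


class OrthologMap:
    """gene -> up to two reference partners (post-WGD double mapping)."""

    def __init__(self, pairs: Sequence[tuple[str, str]]):
        self._map: dict[str, list[str]] = {}
        for a, b in pairs:
            partners = self._map.setdefault(a, [])
            if b not in partners:
                partners.append(b)
            if len(partners) > 2:
                raise ValueError(f"gene {a!r} maps to more than two partners")

    def partners(self, gene: str) -> list[str]:
        return self._map.get(gene, [])

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "OrthologMap":
        return cls([(a, b) for a, bs in mapping.items() for b in bs])


@dataclass(frozen=True)
class CentromereLocus:
    genome: str
    chromosome: str
    flank_left: Optional[str]
    flank_right: Optional[str]


@dataclass
class SyntenyCall:
    locus: CentromereLocus
    status: str  # "syntenic" | "breakpoint" | "ambiguous"
    partner_interval: Optional[tuple[str, str, str]] = None  # (gene, gene, chrom)
    gap: Optional[int] = None  # intervening reference genes
    partner_has_centromere: bool = False


def locate_centromere(
    cen_interval: tuple[str, int, int],
    genes: Sequence[Gene],
    genome: str = "query",
) -> CentromereLocus:
    """Flanking genes of a centromere interval (0-based half-open coords)."""
    chrom, start, end = cen_interval
    on_chrom = [g for g in genes if g.chrom == chrom]
    lefts = [g for g in on_chrom if g.end <= start]
    rights = [g for g in on_chrom if g.start >= end]
    left = max(lefts, key=lambda g: g.end).id if lefts else None
    right = min(rights, key=lambda g: g.start).id if rights else None
    if left is None or right is None:
        log.warning("centromere at %s:%d-%d lacks a flanking gene", chrom, start, end)
    return CentromereLocus(genome, chrom, left, right)


def classify_synteny(
    locus: CentromereLocus,
    orthologs: OrthologMap,
    ref_order: GeneOrder,
    gap_tolerance: int = 5,
    ref_centromeres: Sequence[RefCentromere] = (),
) -> SyntenyCall:
    """Classify one centromere locus against the reference gene order."""
    if locus.flank_left is None or locus.flank_right is None:
        return SyntenyCall(locus, "ambiguous")
    left_orth = orthologs.partners(locus.flank_left)
    right_orth = orthologs.partners(locus.flank_right)
    if not left_orth or not right_orth:
        return SyntenyCall(locus, "ambiguous")

    index = ref_order.index()
    best: Optional[tuple[int, str, str, str]] = None  # (gap, gene_a, gene_b, chrom)
    for a in left_orth:
        for b in right_orth:
            if a not in index or b not in index:
                continue
            chrom_a, ia = index[a]
            chrom_b, ib = index[b]
            if chrom_a != chrom_b:
                continue
            gap = abs(ia - ib) - 1
            if gap <= gap_tolerance and (best is None or gap < best[0]):
                best = (gap, a, b, chrom_a)
    if best is None:
        return SyntenyCall(locus, "breakpoint")

    gap, a, b, chrom = best
    ia, ib = index[a][1], index[b][1]
    lo, hi = min(ia, ib), max(ia, ib)
    has_cen = any(
        c == chrom and lo <= adj < hi for c, adj in ref_centromeres
    )
    return SyntenyCall(
        locus,
        "syntenic",
        partner_interval=(a, b, chrom),
        gap=gap,
        partner_has_centromere=has_cen,
    )


def synteny_survey(
    loci: Sequence[CentromereLocus],
    orthologs: OrthologMap,
    ref_order: GeneOrder,
    ref_centromeres: Sequence[RefCentromere] = (),
    gap_tolerance: int = 5,
) -> tuple[list[SyntenyCall], dict[str, int]]:
    """One call per locus plus summary counts partitioning the loci."""
    calls = [
        classify_synteny(locus, orthologs, ref_order, gap_tolerance, ref_centromeres)
        for locus in loci
    ]
    summary = {
        "syntenic_with_ref_cen": 0,
        "syntenic_without_ref_cen": 0,
        "breakpoint": 0,
        "ambiguous": 0,
    }
    for call in calls:
        if call.status == "syntenic":
            key = (
                "syntenic_with_ref_cen"
                if call.partner_has_centromere
                else "syntenic_without_ref_cen"
            )
        else:
            key = call.status
        summary[key] += 1
    return calls, summary
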