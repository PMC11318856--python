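"""Low-level builders that lay annotated ORFs into genomic intervals.

Used by the synthetic-data generator and the packaged study fixture.  ORFs
are specified in *canonical* (packaging-forward) order and tiled across the
target span: the first ORF starts at the span start, the last ends at the
span end, and intergenic gaps are distributed as evenly as possible.
Reverse-packaged regions are built canonically and then mirrored in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .model import (
    Orf,
    PromoterCall,
    ProphageRegion,
    Strand,
    sort_orfs,
)


@dataclass(frozen=True)
class OrfSpec:
    """Blueprint for one ORF in canonical order.

    ``aa=None`` marks a pad ORF whose size is solved to fit the span.
    """

    id: str
    category: str = "unknown"
    strand: str = "+"
    traits: tuple = ()
    aa: Optional[int] = None
    product: str = "hypothetical protein"
    gap_after: int = 0  # extra intergenic bp reserved after this ORF


def layout_orfs(
    specs: Sequence[OrfSpec],
    start: int,
    end: int,
    default_pad_aa: int = 140,
    min_gap: int = 2,
) -> list[Orf]:
    """Tile ORFs across ``[start, end]`` with near-even intergenic gaps."""
    n = len(specs)
    if n == 0:
        return []
    span = end - start + 1
    fixed_nt = sum((s.aa * 3 + 3) for s in specs if s.aa is not None)
    reserved = sum(s.gap_after for s in specs[:-1])
    pads = [i for i, s in enumerate(specs) if s.aa is None]
    pad_aa = default_pad_aa
    if pads:
        # solve pad size so everything fits; keep a little slack for gaps
        budget = span - fixed_nt - reserved - min_gap * (n - 1)
        pad_aa = max(35, min(default_pad_aa, (budget // len(pads) - 3) // 3))
    sizes = [(s.aa if s.aa is not None else pad_aa) * 3 + 3 for s in specs]
    total_nt = sum(sizes)
    total_gap = span - total_nt - reserved
    if total_gap < (n - 1) * min_gap:
        raise ValueError(
            f"span {span} bp too small for {n} ORFs totalling {total_nt} bp"
        )
    n_gaps = n - 1
    base = total_gap // n_gaps if n_gaps else 0
    extra = total_gap - base * n_gaps
    orfs: list[Orf] = []
    pos = start
    for i, (spec, size) in enumerate(zip(specs, sizes)):
        orfs.append(
            Orf(
                id=spec.id,
                start=pos,
                end=pos + size - 1,
                strand=Strand(spec.strand),
                category=spec.category,
                traits=frozenset(spec.traits),
                product=spec.product,
                length_aa=(size - 3) // 3,
            )
        )
        if i < n_gaps:
            gap = base + (1 if i < extra else 0) + spec.gap_after
            pos += size + gap
    # pin the final ORF to the span end exactly
    last = orfs[-1]
    shift = end - last.end
    if shift:
        orfs[-1] = replace(last, start=last.start + shift, end=end)
        if len(orfs) > 1 and orfs[-1].start <= orfs[-2].end:
            raise ValueError("final ORF pinning caused an overlap; span too tight")
    return orfs


@dataclass(frozen=True)
class PromoterPlan:
    """Plant promoters in the canonical intergenic gap between two ORFs."""

    left_orf: str
    right_orf: str
    calls: tuple  # of (strand, score)


def place_promoters(
    orfs: Sequence[Orf], plans: Sequence[PromoterPlan], region_name: str
) -> list[PromoterCall]:
    by_id = {o.id: o for o in orfs}
    out: list[PromoterCall] = []
    for plan in plans:
        left, right = by_id[plan.left_orf], by_id[plan.right_orf]
        gap_lo, gap_hi = left.end + 1, right.start - 1
        width = gap_hi - gap_lo + 1
        k = len(plan.calls)
        if width < k:
            continue  # gap too narrow; promoters simply not planted
        step = max(1, width // (k + 1))
        for j, (strand, score) in enumerate(plan.calls, start=1):
            out.append(
                PromoterCall(
                    position=min(gap_lo + j * step, gap_hi),
                    strand=Strand(strand),
                    score=score,
                    region=region_name,
                )
            )
    return out


def orient_region(
    region: ProphageRegion, promoters: Sequence[PromoterCall], packaging_strand: Strand
) -> tuple[ProphageRegion, list[PromoterCall]]:
    """Mirror a canonically built region (and its promoters) onto the
    reverse packaging strand; forward regions pass through unchanged."""
    if packaging_strand is Strand.FORWARD:
        return region, list(promoters)
    lo, hi = region.start, region.end
    mirrored = [
        replace(
            o, start=lo + hi - o.end, end=lo + hi - o.start, strand=o.strand.flipped()
        )
        for o in region.orfs
    ]
    region = replace(
        region, packaging_strand=Strand.REVERSE, orfs=sort_orfs(mirrored)
    )
    proms = [
        replace(p, position=lo + hi - p.position, strand=p.strand.flipped())
        for p in promoters
    ]
    return region, proms


def build_region(
    name: str,
    chrom: str,
    start: int,
    end: int,
    specs: Sequence[OrfSpec],
    packaging_strand: Strand = Strand.FORWARD,
    promoter_plans: Sequence[PromoterPlan] = (),
    completeness: Optional[float] = None,
    default_pad_aa: int = 140,
) -> tuple[ProphageRegion, list[PromoterCall]]:
    """Lay out a region canonically, then orient it onto its packaging strand."""
    orfs = layout_orfs(specs, start, end, default_pad_aa=default_pad_aa)
    promoters = place_promoters(orfs, promoter_plans, name)
    region = ProphageRegion(
        name=name,
        chrom=chrom,
        start=start,
        end=end,
        packaging_strand=Strand.FORWARD,
        orfs=orfs,
        completeness=completeness,
    )
    return orient_region(region, promoters, packaging_strand)
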