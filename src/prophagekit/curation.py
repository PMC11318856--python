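"""Candidate-hit curation: merging, module profiling, defect detection,
completeness categorization and mosaic delineation.

The stage mirrors a manual prophage-curation workflow: raw detector hits are
unified into candidate intervals, each interval is profiled for the five
classical phage functional modules (lysogeny control, DNA replication,
packaging/capsid, tail, lysis), intervals with at least one module cluster
are confirmed as prophages or prophage remnants, structural defects are
read from the gene architecture, and a completeness score (produced
upstream, e.g. by AAI comparison) is combined with the defect flags to
categorize each region as functional, unknown or defective.  Regions whose
architecture shows several independent lysogeny/replication clusters are
mosaics of consecutive integration events and are delineated into
sub-regions using a Mu-phage boundary grammar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .model import (
    Category,
    Chromosome,
    DefectFlag,
    ModuleProfile,
    MODULE_FAMILIES,
    MODULES,
    Orf,
    ProphageRegion,
    Strand,
    canonicalize_orientation,
    region_length,
)


class ContractError(RuntimeError):
    """An operation was invoked outside its stated precondition."""


@dataclass(frozen=True)
class CandidateHit:
    """A raw detector hit: a chromosomal interval with a source label."""

    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        region_length(self.start, self.end)  # validates


@dataclass
class CurationConfig:
    """Tunable parameters of the curation stage.

    max_gap
        Maximum separation (bp) at which two candidate hits are unified.
        Defaults to 0 (overlap-only): distinct prophages can sit within a
        few bp of each other, so only genuinely overlapping duplicate hits
        are merged.
    min_cluster_orfs / max_intervening
        A module cluster needs >= ``min_cluster_orfs`` co-oriented ORFs of
        the module's category family, allowing up to ``max_intervening``
        interspersed ORFs of any other kind between members.
    integrase_truncation_aa
        Integrase products below this length are considered truncated
        (full-length phage integrases run ~300-450 aa; observed truncation
        products sit well under 200 aa).
    single_orf_modules
        Modules for which a single gene is accepted as evidence (tail and
        lysis genes occur singly in real prophages).
    opener_gap_orfs
        During mosaic delineation, a fresh opener more than this many ORFs
        past the previous opener splits a sub-region even without an
        intervening closer (the no-closer fallback for remnants that have
        lost their tail/recombinase end).  Set above the largest
        integrase-to-replication spacing seen inside a single phage.
    """

    max_gap: int = 0
    min_cluster_orfs: int = 2
    max_intervening: int = 2
    integrase_truncation_aa: int = 200
    single_orf_modules: tuple = ("tail", "lysis")
    opener_gap_orfs: int = 25


DEFAULT_CONFIG = CurationConfig()


# ---------------------------------------------------------------------------
# hit merging


def merge_hits(
    hits: Sequence[CandidateHit], max_gap: int = DEFAULT_CONFIG.max_gap
) -> list[CandidateHit]:
    """Unify hits that overlap, abut, or are separated by at most
    ``max_gap`` intervening bases (gap = next.start - prev.end - 1).

    Returns sorted, non-overlapping intervals; idempotent.  Hits must share
    one chromosome.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    if not hits:
        return []
    chroms = {h.chrom for h in hits}
    if len(chroms) > 1:
        raise ValueError(f"hits span multiple chromosomes: {sorted(chroms)}")
    merged: list[CandidateHit] = []
    for hit in sorted(hits, key=lambda h: (h.start, h.end)):
        if merged and hit.start - merged[-1].end - 1 <= max_gap:
            prev = merged[-1]
            sources = [s for s in (prev.source, hit.source) if s]
            merged[-1] = CandidateHit(
                chrom=prev.chrom,
                start=prev.start,
                end=max(prev.end, hit.end),
                source="+".join(dict.fromkeys(sources)),
            )
        else:
            merged.append(hit)
    return merged


# ---------------------------------------------------------------------------
# module profiling


def _family_clusters(
    orfs: Sequence[Orf], module: str, config: CurationConfig = DEFAULT_CONFIG
) -> list[list[int]]:
    """Indices of co-oriented category-family clusters for one module.

    Members of a cluster share a strand and are separated by at most
    ``config.max_intervening`` ORFs of any other kind.
    """
    family = MODULE_FAMILIES[module]
    clusters: list[list[int]] = []
    for strand in (Strand.FORWARD, Strand.REVERSE):
        members = [
            i
            for i, o in enumerate(orfs)
            if o.category in family and o.strand is strand
        ]
        run: list[int] = []
        for i in members:
            if run and i - run[-1] - 1 > config.max_intervening:
                if len(run) >= config.min_cluster_orfs:
                    clusters.append(run)
                run = []
            run.append(i)
        if len(run) >= config.min_cluster_orfs:
            clusters.append(run)
    clusters.sort(key=lambda c: c[0])
    return clusters


def assign_modules(
    region: ProphageRegion, config: CurationConfig = DEFAULT_CONFIG
) -> ModuleProfile:
    """Profile a region for the five canonical phage modules.

    A module is present when the region holds a cluster of co-oriented
    family ORFs; for tail and lysis a single gene suffices (single-gene
    tail/lysis modules occur in real prophages).
    """
    region = canonicalize_orientation(region)
    orfs = region.orfs
    present: dict[str, bool] = {}
    spans: dict[str, list] = {}
    for module in MODULES:
        clusters = _family_clusters(orfs, module, config)
        spans[module] = [(c[0], c[-1]) for c in clusters]
        if not clusters and module in config.single_orf_modules:
            family = MODULE_FAMILIES[module]
            singles = [i for i, o in enumerate(orfs) if o.category in family]
            spans[module] = [(i, i) for i in singles]
        present[module] = bool(spans[module])
    return ModuleProfile(present=present, spans=spans)


def confirm_phage(profile: ModuleProfile) -> bool:
    """A hit is a prophage (or remnant) iff at least one module is present."""
    return any(profile.present.values())


# ---------------------------------------------------------------------------
# defect detection


def detect_defects(
    region: ProphageRegion, config: CurationConfig = DEFAULT_CONFIG
) -> frozenset:
    """Read structural defects from a region's gene architecture.

    Returns a frozenset of :class:`DefectFlag`.  The rules formalize the
    recurring defect anatomy of curated prophages: frameshift-split or
    truncated integrases, missing packaging components, group II intron
    insertions splitting a replication gene, late-module genes flipped
    against their operon, and mosaic stacking of several phage remnants.
    """
    region = canonicalize_orientation(region)
    orfs = region.orfs
    profile = assign_modules(region, config)
    defects: set[DefectFlag] = set()
    cutoff = config.integrase_truncation_aa

    integrases = [(i, o) for i, o in enumerate(orfs) if "integrase" in o.traits]
    has_large_recombinase = any(
        "recombinase" in o.traits and o.length_aa >= cutoff for o in orfs
    )
    split_evidence: list[str] = []
    if not has_large_recombinase:
        # adjacent sub-threshold integrase ORFs read as one split gene; a
        # full-length recombinase elsewhere instead marks them as truncated
        # relics of independent machinery
        for (i, a), (j, b) in zip(integrases, integrases[1:]):
            if j == i + 1 and a.length_aa < cutoff and b.length_aa < cutoff:
                split_evidence.extend([a.id, b.id])
    if split_evidence:
        defects.add(DefectFlag("split_integrase", tuple(dict.fromkeys(split_evidence))))
    elif integrases and all(o.length_aa < cutoff for _, o in integrases):
        defects.add(
            DefectFlag("truncated_integrase", tuple(o.id for _, o in integrases))
        )

    if profile.present["packaging_capsid"]:
        if not any(o.traits & {"terminase_large", "portal"} for o in orfs):
            first, last = profile.spans["packaging_capsid"][0]
            defects.add(
                DefectFlag(
                    "missing_terminase_or_portal",
                    tuple(
                        o.id
                        for o in orfs[first : last + 1]
                        if o.category in MODULE_FAMILIES["packaging_capsid"]
                    ),
                )
            )

    for i in range(1, len(orfs) - 1):
        o = orfs[i]
        if "reverse_transcriptase_maturase" not in o.traits:
            continue
        left, right = orfs[i - 1], orfs[i + 1]
        shared = left.traits & right.traits & {"helicase", "dna_polymerase"}
        if shared and left.strand is right.strand:
            defects.add(DefectFlag("intron_split_gene", (left.id, o.id, right.id)))

    for module in ("tail", "lysis"):
        for first, last in profile.spans[module]:
            if last - first < 1:
                continue
            members = {
                k
                for k in range(first, last + 1)
                if orfs[k].category in MODULE_FAMILIES[module]
                and orfs[k].strand is orfs[first].strand
            }
            for k in range(first + 1, last):
                if k in members:
                    continue
                if orfs[k].strand is not orfs[first].strand:
                    defects.add(DefectFlag("misoriented_late_orf", (orfs[k].id,)))

    mosaic_evidence: list[str] = []
    for module in ("lysogeny_control", "dna_replication"):
        clusters = _family_clusters(orfs, module, config)
        if len(clusters) >= 2:
            mosaic_evidence.extend(orfs[c[0]].id for c in clusters)
    if mosaic_evidence:
        defects.add(DefectFlag("mosaic_region", tuple(dict.fromkeys(mosaic_evidence))))

    return frozenset(defects)


# ---------------------------------------------------------------------------
# categorization


def categorize(completeness: Optional[float], defects: Iterable = ()) -> Category:
    """Combine a completeness score with defect flags into a category.

    A score of exactly 100 with a clean architecture is functional; any
    detected defect demotes it to unknown.  Scores of 60 or below are
    defective (the band boundary resolves low), scores strictly between 60
    and 100 are unknown, and a missing score leaves the region
    unclassified.
    """
    defects = frozenset(defects)
    if completeness is None:
        return Category.UNCLASSIFIED
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if completeness == 100.0:
        return Category.FUNCTIONAL if not defects else Category.UNKNOWN
    if completeness <= 60.0:
        return Category.DEFECTIVE
    return Category.UNKNOWN


# ---------------------------------------------------------------------------
# mosaic delineation


def _is_opener(orf: Orf) -> bool:
    return bool(orf.traits & {"transposase_mu", "integrase"}) or (
        orf.category == "replication"
    )


def _is_closer(orf: Orf) -> bool:
    return orf.category == "tail" or "recombinase" in orf.traits


def delineate_mosaic(
    region: ProphageRegion, config: CurationConfig = DEFAULT_CONFIG
) -> list[ProphageRegion]:
    """Split a mosaic region into consecutive phage sub-regions.

    Boundary grammar (Mu-type): a transposase, integrase or DNA-replication
    ORF opens a phage sequence; the last tail or recombinase ORF before the
    next opener closes it.  ORFs between a closer and the next opener (for
    example the repressor/Ner switch genes preceding a Mu transposase) are
    adopted by the following sub-region, so consecutive phages tile the
    mosaic; when a new opener appears without any intervening closer the
    boundary falls immediately before the opener.  Sub-regions partition
    the ORFs they cover and are named ``<region>a``, ``<region>b``, ...
    in phage order.
    """
    defects = detect_defects(region, config)
    if not any(d.kind == "mosaic_region" for d in defects):
        raise ContractError(f"region {region.name} is not flagged as a mosaic")
    original = region
    canonical = canonicalize_orientation(region)
    orfs = canonical.orfs

    bounds: list[tuple[int, int]] = []
    cur: Optional[int] = None
    last_closer: Optional[int] = None
    last_opener: Optional[int] = None
    for i, orf in enumerate(orfs):
        if cur is None:
            if _is_opener(orf):
                cur, last_closer, last_opener = i, None, i
            continue
        if _is_opener(orf):
            if last_closer is not None:
                bounds.append((cur, last_closer))
                cur, last_closer, last_opener = last_closer + 1, None, i
            elif last_opener is not None and i - last_opener > config.opener_gap_orfs:
                bounds.append((cur, i - 1))
                cur, last_closer, last_opener = i, None, i
            else:
                last_opener = i
        elif _is_closer(orf):
            last_closer = i
    if cur is not None:
        bounds.append((cur, len(orfs) - 1))

    subs: list[ProphageRegion] = []
    for letter_idx, (first, last) in enumerate(bounds):
        ids = [o.id for o in orfs[first : last + 1]]
        members = [o for o in original.orfs if o.id in set(ids)]
        subs.append(
            ProphageRegion(
                name=f"{original.name}{chr(ord('a') + letter_idx)}",
                chrom=original.chrom,
                start=min(o.start for o in members),
                end=max(o.end for o in members),
                packaging_strand=original.packaging_strand,
                orfs=members,
            )
        )
    return subs


# ---------------------------------------------------------------------------
# stage driver


@dataclass
class CuratedRegion:
    """Result record for one merged candidate interval."""

    name: str
    region: ProphageRegion
    profile: ModuleProfile
    confirmed: bool
    defects: frozenset = frozenset()
    completeness: Optional[float] = None
    category: Category = Category.UNCLASSIFIED
    sub_regions: list = field(default_factory=list)


def curate_chromosome(
    chromosome: Chromosome,
    hits: Optional[Sequence[CandidateHit]] = None,
    completeness: Optional[dict] = None,
    config: CurationConfig = DEFAULT_CONFIG,
    delineate: bool = True,
) -> list[CuratedRegion]:
    """Run the full curation stage.

    When ``hits`` is given, hits are merged and each merged interval is
    resolved to the annotated gene neighbourhood it covers (by dominant
    region label of the ORFs inside it); otherwise every annotated region
    is treated as a candidate.  Completeness scores are joined by region
    name.  Mosaic-flagged confirmed regions are delineated into
    sub-regions, each categorized with its own completeness score.
    """
    completeness = completeness or {
        r.name: r.completeness for r in chromosome.regions
    }
    candidates: list[ProphageRegion] = []
    if hits is None:
        candidates = list(chromosome.regions)
    else:
        pairs = chromosome.all_orfs()
        for interval in merge_hits(hits, config.max_gap):
            inside = [
                (name, o)
                for name, o in pairs
                if o.start <= interval.end and o.end >= interval.start
            ]
            if not inside:
                candidates.append(
                    ProphageRegion(
                        name=f"interval_{interval.start}_{interval.end}",
                        chrom=interval.chrom,
                        start=interval.start,
                        end=interval.end,
                    )
                )
                continue
            counts: dict[str, int] = {}
            for name, _ in inside:
                counts[name] = counts.get(name, 0) + 1
            dominant = max(counts, key=lambda n: (counts[n], n))
            try:
                candidates.append(chromosome.region(dominant))
            except KeyError:
                orfs = [o for _, o in inside]
                candidates.append(
                    ProphageRegion(
                        name=dominant,
                        chrom=interval.chrom,
                        start=min(interval.start, min(o.start for o in orfs)),
                        end=max(interval.end, max(o.end for o in orfs)),
                        orfs=orfs,
                    )
                )

    results: list[CuratedRegion] = []
    for cand in candidates:
        profile = assign_modules(cand, config)
        confirmed = confirm_phage(profile)
        rec = CuratedRegion(
            name=cand.name, region=cand, profile=profile, confirmed=confirmed
        )
        if confirmed:
            rec.defects = detect_defects(cand, config)
            rec.completeness = completeness.get(cand.name, cand.completeness)
            rec.category = categorize(rec.completeness, rec.defects)
            if delineate and any(d.kind == "mosaic_region" for d in rec.defects):
                for sub in delineate_mosaic(cand, config):
                    sub_comp = completeness.get(sub.name)
                    sub_defects = detect_defects(sub, config)
                    results_sub = CuratedRegion(
                        name=sub.name,
                        region=sub,
                        profile=assign_modules(sub, config),
                        confirmed=True,
                        defects=sub_defects,
                        completeness=sub_comp,
                        category=categorize(sub_comp, sub_defects),
                    )
                    rec.sub_regions.append(results_sub)
        results.append(rec)
    return results
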