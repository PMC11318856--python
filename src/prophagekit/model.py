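"""Core data model for annotated chromosomes and prophage regions.

Coordinates are 1-based and inclusive at both ends throughout, matching the
GenBank convention; ``region_length`` is the single place where interval
arithmetic is performed.  An :class:`Orf` is an annotated coding feature with
a functional category (PHROG-style module families) and a set of trait flags
(specific gene identities such as ``terminase_large`` or ``tail_sheath``)
that downstream stages pattern-match against.  A :class:`ProphageRegion` is a
chromosomal interval owning an ordered list of ORFs plus curation state
(completeness score, defect flags, category).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence


class InvalidIntervalError(ValueError):
    """Raised for degenerate genomic intervals (start > end or non-positive)."""


class Category(str, Enum):
    """Completeness-based viability category of a prophage region."""

    FUNCTIONAL = "functional"
    UNKNOWN = "unknown"
    DEFECTIVE = "defective"
    UNCLASSIFIED = "unclassified"


class Strand(str, Enum):
    FORWARD = "+"
    REVERSE = "-"

    def flipped(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD


#: Functional categories an ORF may carry.  These follow the five classical
#: phage genome modules (lysogeny control is split into its integration and
#: transcription-regulation constituents) plus accessory/other/unknown.
CATEGORIES = (
    "integration_excision",
    "transcription_regulation",
    "replication",
    "packaging_capsid",
    "connector",
    "tail",
    "lysis",
    "moron_accessory",
    "other",
    "unknown",
)

#: Trait flags: specific gene identities used by the defect detector, the
#: morphology/lysogeny classifiers and the accessory screen.
TRAITS = (
    "integrase",
    "recombinase",
    "transposase_mu",
    "hth_regulator",
    "imma_metallopeptidase",
    "terminase_large",
    "portal",
    "major_capsid",
    "tail_tape_measure",
    "tail_sheath",
    "baseplate_or_fiber",
    "reverse_transcriptase_maturase",
    "avd_dgr",
    "anti_crispr",
    "rm_hsdR",
    "rm_hsdM",
    "rm_hsdS",
    "rm_type3",
    "ta_toxin",
    "ta_antitoxin",
    "restriction_alleviation",
    "mom_modification",
    "darB_antirestriction",
    "amidoligase",
    "haemolysin",
    "ggct",
    "paps_reductase",
    "dextransucrase",
    "cm_phosphotransferase",
    "helicase",
    "dna_polymerase",
)

#: Traits that force a particular category (a sheath gene is a tail gene).
TRAIT_FORCES_CATEGORY = {
    "tail_sheath": "tail",
    "tail_tape_measure": "tail",
    "baseplate_or_fiber": "tail",
    "terminase_large": "packaging_capsid",
    "portal": "packaging_capsid",
    "major_capsid": "packaging_capsid",
    "integrase": "integration_excision",
    "recombinase": "integration_excision",
    "transposase_mu": "integration_excision",
    "hth_regulator": "transcription_regulation",
}

#: The five canonical functional modules and the ORF-category families that
#: provide evidence for each.
MODULE_FAMILIES = {
    "lysogeny_control": ("integration_excision", "transcription_regulation"),
    "dna_replication": ("replication",),
    "packaging_capsid": ("packaging_capsid", "connector"),
    "tail": ("tail",),
    "lysis": ("lysis",),
}

MODULES = tuple(MODULE_FAMILIES)

DEFECT_KINDS = (
    "split_integrase",
    "truncated_integrase",
    "missing_terminase_or_portal",
    "intron_split_gene",
    "misoriented_late_orf",
    "mosaic_region",
)


def region_length(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval ``[start, end]``.

    >>> region_length(194517, 235362)
    40846
    """
    if start < 1 or end < 1:
        raise InvalidIntervalError(f"non-positive coordinate in ({start}, {end})")
    if start > end:
        raise InvalidIntervalError(f"start {start} > end {end}")
    return end - start + 1


@dataclass(frozen=True)
class Orf:
    """An annotated coding feature.

    ``start``/``end`` are chromosome coordinates (1-based inclusive);
    ``length_aa`` is the translated product length in amino acids.
    """

    id: str
    start: int
    end: int
    strand: Strand
    category: str = "unknown"
    traits: frozenset = frozenset()
    product: str = ""
    length_aa: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidIntervalError(
                f"ORF {self.id}: start {self.start} > end {self.end}"
            )
        if self.length_aa < 1:
            raise ValueError(f"ORF {self.id}: length_aa must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"ORF {self.id}: unknown category {self.category!r}")
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"ORF {self.id}: unknown traits {sorted(unknown)}")
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))
        if not isinstance(self.traits, frozenset):
            object.__setattr__(self, "traits", frozenset(self.traits))
        for trait, forced in TRAIT_FORCES_CATEGORY.items():
            if trait in self.traits and self.category != forced:
                raise ValueError(
                    f"ORF {self.id}: trait {trait} requires category {forced}, "
                    f"got {self.category}"
                )

    @property
    def span_nt(self) -> int:
        return region_length(self.start, self.end)


@dataclass(frozen=True)
class PromoterCall:
    """A predicted promoter: position, strand and predictor score in [0, 1]."""

    position: int
    strand: Strand
    score: float
    region: str = ""

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"promoter score {self.score} outside [0, 1]")
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))


#: Score threshold below which promoter predictions are discarded before any
#: lysogeny-switch typing.
PROMOTER_SCORE_MIN = 0.87


def filter_promoters(
    promoters: Iterable[PromoterCall], min_score: float = PROMOTER_SCORE_MIN
) -> list[PromoterCall]:
    """Retain only promoter calls with score >= ``min_score``."""
    return [p for p in promoters if p.score >= min_score]


@dataclass(frozen=True)
class DefectFlag:
    """A structural defect with the ORF ids constituting its evidence."""

    kind: str
    evidence: tuple

    def __post_init__(self):
        if self.kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if not self.evidence:
            raise ValueError(f"defect {self.kind}: evidence must be non-empty")
        object.__setattr__(self, "evidence", tuple(self.evidence))


@dataclass
class ProphageRegion:
    """A chromosomal interval owning ORFs plus curation state."""

    name: str
    chrom: str
    start: int
    end: int
    packaging_strand: Strand = Strand.FORWARD
    orfs: list = field(default_factory=list)
    completeness: Optional[float] = None
    defects: frozenset = frozenset()
    category: Category = Category.UNCLASSIFIED

    def __post_init__(self):
        region_length(self.start, self.end)  # validates
        if not isinstance(self.packaging_strand, Strand):
            self.packaging_strand = Strand(self.packaging_strand)
        if not isinstance(self.category, Category):
            self.category = Category(self.category)
        if self.completeness is not None and not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"region {self.name}: completeness {self.completeness} outside [0, 100]"
            )
        self.orfs = sort_orfs(self.orfs)
        for orf in self.orfs:
            if orf.start < self.start or orf.end > self.end:
                raise InvalidIntervalError(
                    f"ORF {orf.id} ({orf.start}-{orf.end}) outside region "
                    f"{self.name} ({self.start}-{self.end})"
                )

    @property
    def length(self) -> int:
        return region_length(self.start, self.end)

    def orf_by_id(self, orf_id: str) -> Orf:
        for orf in self.orfs:
            if orf.id == orf_id:
                return orf
        raise KeyError(orf_id)


@dataclass
class ModuleProfile:
    """Presence and ORF spans of the five canonical modules in one region.

    ``spans`` maps module name -> list of (first_orf_index, last_orf_index)
    clusters in the region's canonical ORF order.
    """

    present: dict = field(default_factory=dict)
    spans: dict = field(default_factory=dict)

    def __post_init__(self):
        for module in MODULES:
            self.present.setdefault(module, False)
            self.spans.setdefault(module, [])
        for module, flag in self.present.items():
            if flag and not self.spans[module]:
                raise ValueError(f"module {module} present without supporting span")

    @property
    def modules_present(self) -> tuple:
        return tuple(m for m in MODULES if self.present[m])


@dataclass
class Chromosome:
    """An annotated bacterial chromosome: named regions owning ORFs.

    Regions include both prophage candidates and any other annotated gene
    neighbourhoods (e.g. decoy clusters); curation decides which are phage.
    """

    name: str
    length: int
    regions: list = field(default_factory=list)

    def region(self, name: str) -> ProphageRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def all_orfs(self) -> list[tuple[str, Orf]]:
        """Flattened (region_name, orf) pairs sorted by chromosome position."""
        pairs = [(r.name, o) for r in self.regions for o in r.orfs]
        pairs.sort(key=lambda p: (p[1].start, p[1].end, p[1].id))
        return pairs


def sort_orfs(orfs: Sequence[Orf]) -> list[Orf]:
    """Canonical ORF ordering: by start, ties broken by end then id."""
    return sorted(orfs, key=lambda o: (o.start, o.end, o.id))


def canonicalize_orientation(region: ProphageRegion) -> ProphageRegion:
    """Return a copy with the packaging strand reading left to right.

    For reverse-packaged regions the ORF coordinates are mirrored within the
    region span and strands flipped, so the canonical module order (lysogeny
    control -> ... -> lysis) reads left to right; forward regions are
    returned unchanged.  Idempotent, and preserves the region span.
    """
    if region.packaging_strand is Strand.FORWARD:
        return region
    lo, hi = region.start, region.end
    mirrored = [
        replace(
            o,
            start=lo + hi - o.end,
            end=lo + hi - o.start,
            strand=o.strand.flipped(),
        )
        for o in region.orfs
    ]
    return replace(
        region,
        packaging_strand=Strand.FORWARD,
        orfs=sort_orfs(mirrored),
    )


def mirror_promoters(
    promoters: Iterable[PromoterCall], region: ProphageRegion
) -> list[PromoterCall]:
    """Mirror promoter calls into a region's canonical orientation.

    Applies the same coordinate reflection as :func:`canonicalize_orientation`
    when the region is reverse-packaged; forward regions pass through.
    """
    if region.packaging_strand is Strand.FORWARD:
        return list(promoters)
    lo, hi = region.start, region.end
    out = [
        replace(p, position=lo + hi - p.position, strand=p.strand.flipped())
        for p in promoters
    ]
    out.sort(key=lambda p: p.position)
    return out
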