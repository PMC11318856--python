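"""Virion morphology and lysogeny-switch typing from gene architecture.

Morphology is read from tail-gene content with the precedence
sheath > tape measure > baseplate: a contractile-tail sheath marks a
myovirus; a tape-measure protein without a sheath marks a (long,
non-contractile-tailed) siphovirus; a baseplate/fiber gene alone marks a
short-tailed podovirus.

The lysogeny switch is typed from repressor-gene synteny supported by
promoter orientation, against three archetypes:

* ImmR/ImmA (ICEBs1-like): a metallo-endopeptidase (ImmA) adjacent to and
  co-oriented with an HTH repressor (ImmR), with the next HTH downstream
  transcribed the opposite way.
* C/Ner (phage Mu-like): a divergently transcribed HTH pair whose
  downstream partner is a small Ner-like protein, with a Mu transposase
  shortly downstream.
* CI/Cro (lambda-like): an adjacent divergently transcribed gene pair in
  the lysogeny span, at least one an HTH regulator; a divergent promoter
  pair in the shared intergenic region lends support but does not gate
  the call.

ImmA presence is the most specific marker and is tested first; Mu
transposase adjacency separates C/Ner from generic divergent HTH pairs;
CI/Cro is the fallback for divergent-pair architectures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .curation import ContractError, CurationConfig, DEFAULT_CONFIG, assign_modules
from .model import (
    Orf,
    PromoterCall,
    ProphageRegion,
    PROMOTER_SCORE_MIN,
    Strand,
    canonicalize_orientation,
    filter_promoters,
    mirror_promoters,
)

MORPHOLOGIES = ("podovirus", "siphovirus", "myovirus", "untyped")
LYSOGENY_SYSTEMS = ("ci_cro", "immr_imma", "c_ner", "undetermined")
GEOMETRIES = ("divergent", "convergent", "tandem", "none")


@dataclass(frozen=True)
class MorphologyCall:
    morphology: str
    evidence: tuple = ()

    def __post_init__(self):
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if (self.morphology == "untyped") != (len(self.evidence) == 0):
            raise ValueError("evidence must be empty iff untyped")


@dataclass(frozen=True)
class LysogenySystemCall:
    system: str
    repressor_orf: Optional[str] = None
    partner_orf: Optional[str] = None
    promoter_geometry: str = "none"

    def __post_init__(self):
        if self.system not in LYSOGENY_SYSTEMS:
            raise ValueError(f"unknown lysogeny system {self.system!r}")
        if self.promoter_geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.promoter_geometry!r}")
        if self.system != "undetermined" and self.repressor_orf is None:
            raise ValueError("typed call requires a repressor ORF")


@dataclass
class TypingConfig:
    """Synteny windows for the lysogeny-switch grammars (in intervening ORFs)."""

    adjacency_window: int = 1  # "adjacent" = at most this many intervening ORFs
    ner_max_aa: int = 80  # Ner-like partner size bound (Mu Ner is 76 aa)
    c_ner_pair_window: int = 10  # c..ner separation (inserts tolerated)
    transposase_window: int = 10  # ner..transposase separation
    min_promoter_score: float = PROMOTER_SCORE_MIN


DEFAULT_TYPING = TypingConfig()


def call_morphology(region: ProphageRegion) -> MorphologyCall:
    """Predict virion morphology from tail-gene traits."""
    for trait, morphology in (
        ("tail_sheath", "myovirus"),
        ("tail_tape_measure", "siphovirus"),
        ("baseplate_or_fiber", "podovirus"),
    ):
        evidence = tuple(o.id for o in region.orfs if trait in o.traits)
        if evidence:
            return MorphologyCall(morphology=morphology, evidence=evidence)
    return MorphologyCall(morphology="untyped")


def promoter_pair_geometry(p1: PromoterCall, p2: PromoterCall) -> str:
    """Orientation of an ordered promoter pair: divergent, convergent or tandem."""
    if p1.position >= p2.position:
        raise ContractError("promoter pair must be ordered by position")
    if p1.score < PROMOTER_SCORE_MIN or p2.score < PROMOTER_SCORE_MIN:
        raise ContractError("promoter pair must be score-filtered before typing")
    if p1.strand is p2.strand:
        return "tandem"
    return "divergent" if p1.strand is Strand.REVERSE else "convergent"


def _intergenic_geometry(
    left: Orf, right: Orf, promoters: Sequence[PromoterCall]
) -> str:
    """Geometry of the promoter pair between two genes, or ``none``."""
    inside = [p for p in promoters if left.end < p.position < right.start]
    if len(inside) < 2:
        return "none"
    best = sorted(inside, key=lambda p: p.score, reverse=True)[:2]
    p1, p2 = sorted(best, key=lambda p: p.position)
    if p1.position == p2.position:
        return "none"
    return promoter_pair_geometry(p1, p2)


def call_lysogeny(
    region: ProphageRegion,
    promoters: Iterable[PromoterCall] = (),
    config: TypingConfig = DEFAULT_TYPING,
    curation_config: CurationConfig = DEFAULT_CONFIG,
) -> LysogenySystemCall:
    """Type the lysogeny switch of a region from synteny and promoters."""
    canonical = canonicalize_orientation(region)
    proms = filter_promoters(
        mirror_promoters(list(promoters), region), config.min_promoter_score
    )
    orfs = canonical.orfs

    # (1) ImmR/ImmA
    for a_idx, a in enumerate(orfs):
        if "imma_metallopeptidase" not in a.traits:
            continue
        partners = [
            h_idx
            for h_idx, h in enumerate(orfs)
            if "hth_regulator" in h.traits
            and h.strand is a.strand
            and 0 < abs(h_idx - a_idx) <= config.adjacency_window + 1
        ]
        for h_idx in sorted(partners, key=lambda j: abs(j - a_idx)):
            h = orfs[h_idx]
            for d in orfs[h_idx + 1 :]:
                if "hth_regulator" in d.traits:
                    if d.strand is not h.strand:
                        return LysogenySystemCall(
                            system="immr_imma",
                            repressor_orf=h.id,
                            partner_orf=a.id,
                            promoter_geometry=_intergenic_geometry(h, d, proms),
                        )
                    break

    # (2) C/Ner
    for i, c in enumerate(orfs):
        if "hth_regulator" not in c.traits or c.strand is not Strand.REVERSE:
            continue
        for j in range(i + 1, min(i + config.c_ner_pair_window + 2, len(orfs))):
            ner = orfs[j]
            if (
                "hth_regulator" in ner.traits
                and ner.strand is Strand.FORWARD
                and ner.length_aa <= config.ner_max_aa
            ):
                window = orfs[j + 1 : j + 1 + config.transposase_window]
                if any("transposase_mu" in o.traits for o in window):
                    return LysogenySystemCall(
                        system="c_ner",
                        repressor_orf=c.id,
                        partner_orf=ner.id,
                        promoter_geometry=_intergenic_geometry(c, ner, proms),
                    )

    # (3) CI/Cro — restricted to the lysogeny span (before any later module)
    profile = assign_modules(canonical, curation_config)
    limit = len(orfs)
    for module in ("dna_replication", "packaging_capsid", "tail", "lysis"):
        for first, _ in profile.spans[module]:
            limit = min(limit, first)
    for i in range(limit - 1):
        ci, cro = orfs[i], orfs[i + 1]
        if ci.strand is Strand.REVERSE and cro.strand is Strand.FORWARD:
            if "hth_regulator" in ci.traits or "hth_regulator" in cro.traits:
                return LysogenySystemCall(
                    system="ci_cro",
                    repressor_orf=ci.id,
                    partner_orf=cro.id,
                    promoter_geometry=_intergenic_geometry(ci, cro, proms),
                )

    return LysogenySystemCall(system="undetermined")
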