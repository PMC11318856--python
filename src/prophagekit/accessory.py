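"""Vocabulary-driven screen for prophage accessory genes.

Accessory genes do not run the lysogenic life cycle but can alter the
lysogen's phenotype: restriction-modification (RM) components,
toxin-antitoxin (TA) systems, diversity-generating retroelement (DGR)
parts, anti-phage-defence factors (anti-CRISPRs, restriction alleviation,
Mom/DarB-like antirestriction) and candidate host-adaptation enzymes.  The
screen is purely annotation-driven: ORF trait flags are mapped through an
editable vocabulary, so vocabulary edits never affect curation or typing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import Orf, ProphageRegion
from .vocabulary import ACCESSORY_CLASSES, ACCESSORY_VOCAB

#: Product keywords that would mark a classical moron (exotoxins, immune
#: evasion factors).  Commensal-associated prophages typically carry none.
CLASSICAL_MORON_KEYWORDS = (
    "exotoxin",
    "enterotoxin",
    "shiga",
    "superantigen",
    "immune evasion",
    "serum resistance",
    "o-antigen acetylase",
)

#: ORFs longer than this (bp) with no functional assignment resemble the
#: large polyvalent proteins of some podoviruses.
LARGE_ORF_NT = 5000


@dataclass(frozen=True)
class AccessoryRecord:
    region: str
    orf_id: str
    product: str
    accessory_class: str
    trait: str = ""
    defence_role: str = ""
    putative_function: str = ""

    def __post_init__(self):
        if self.accessory_class not in ACCESSORY_CLASSES:
            raise ValueError(f"unknown accessory class {self.accessory_class!r}")


def screen_accessory(
    region: ProphageRegion,
    vocab: Optional[dict] = None,
    large_orf_nt: int = LARGE_ORF_NT,
) -> list[AccessoryRecord]:
    """Screen one confirmed region for accessory genes.

    Each flagged trait yields one record; a solitary antitoxin (no toxin in
    the same region) is reported as anti-phage defence (or a degenerate TA
    system), while an antitoxin with a cognate toxin forms a complete TA
    system counted as phage defence.  Unassigned ORFs longer than
    ``large_orf_nt`` are reported as large-polyvalent-like.  ORFs mapping
    to no class are suppressed.
    """
    vocab = vocab or ACCESSORY_VOCAB
    region_has_toxin = any("ta_toxin" in o.traits for o in region.orfs)
    records: list[AccessoryRecord] = []
    for orf in region.orfs:
        matched = False
        for trait in sorted(orf.traits & set(vocab)):
            cls, role, fn = vocab[trait]
            if trait == "ta_antitoxin" and region_has_toxin:
                role, fn = "phage_defence", "Antitoxin component of a TA system"
            records.append(
                AccessoryRecord(
                    region=region.name,
                    orf_id=orf.id,
                    product=orf.product,
                    accessory_class=cls,
                    trait=trait,
                    defence_role=role,
                    putative_function=fn,
                )
            )
            matched = True
        if (
            not matched
            and not orf.traits
            and orf.category in ("unknown", "other")
            and orf.span_nt > large_orf_nt
        ):
            records.append(
                AccessoryRecord(
                    region=region.name,
                    orf_id=orf.id,
                    product=orf.product,
                    accessory_class="large_polyvalent_like",
                    putative_function="Hypothetical; similarity to large polyvalent protein domains",
                )
            )
    return records


@dataclass
class DefenceSummary:
    """Per-region defence/anti-defence tallies plus global flags."""

    per_region: pd.DataFrame
    no_classical_morons: bool
    records: list = field(default_factory=list)

    def regions_with_trait(self, trait: str) -> set:
        return {r.region for r in self.records if r.trait == trait}

    def regions_with_class(self, accessory_class: str) -> set:
        return {r.region for r in self.records if r.accessory_class == accessory_class}


def summarize_defence(
    records: Sequence[AccessoryRecord],
    regions: Iterable[ProphageRegion] = (),
) -> DefenceSummary:
    """Tabulate accessory classes per region and screen for classical morons.

    ``regions`` (optional) supplies the ORF products scanned for classical
    moron keywords; absent that, the records' products are scanned.
    """
    rows = [
        {
            "region": r.region,
            "accessory_class": r.accessory_class,
            "defence_role": r.defence_role or "none",
        }
        for r in records
    ]
    if rows:
        df = pd.DataFrame(rows)
        per_region = (
            df.pivot_table(
                index="region",
                columns="accessory_class",
                aggfunc="size",
                fill_value=0,
            )
            .rename_axis(columns=None)
            .reset_index()
        )
    else:
        per_region = pd.DataFrame(columns=["region"])
    products = [o.product for reg in regions for o in reg.orfs] or [
        r.product for r in records
    ]
    no_morons = not any(
        kw in p.lower() for p in products for kw in CLASSICAL_MORON_KEYWORDS
    )
    return DefenceSummary(
        per_region=per_region, no_classical_morons=no_morons, records=list(records)
    )
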