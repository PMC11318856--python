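"""Annotation vocabularies.

Two mappings live here:

* the *product vocabulary* — lower-cased substrings of product descriptions
  mapped to a functional category and trait flags, used when reading formats
  (GenBank/GFF3) that carry free-text products only.  Unmatched products
  degrade to ``category=unknown`` with no traits rather than erroring.
* the *accessory vocabulary* — trait flag mapped to an accessory class and a
  putative-function text, used by the accessory screen.  Both ship as
  editable TSV files so curation decisions can be revised without code
  changes; editing them never affects module profiling or switch typing.
"""

from __future__ import annotations

import csv
from pathlib import Path

VOCAB_VERSION = "1.0"

# (substring, category, traits) — first match wins; order from most to least
# specific.  Substrings are matched case-insensitively against the product.
PRODUCT_VOCAB: list[tuple[str, str, tuple]] = [
    ("tail sheath", "tail", ("tail_sheath",)),
    ("tape measure", "tail", ("tail_tape_measure",)),
    ("baseplate", "tail", ("baseplate_or_fiber",)),
    ("tail fiber", "tail", ("baseplate_or_fiber",)),
    ("tail spike", "tail", ("baseplate_or_fiber",)),
    ("tail", "tail", ()),
    ("large terminase", "packaging_capsid", ("terminase_large",)),
    ("terminase large", "packaging_capsid", ("terminase_large",)),
    ("portal", "packaging_capsid", ("portal",)),
    ("major capsid", "packaging_capsid", ("major_capsid",)),
    ("capsid", "packaging_capsid", ()),
    ("head", "packaging_capsid", ()),
    ("head-tail adaptor", "connector", ()),
    ("head-tail connector", "connector", ()),
    ("mu transposase", "integration_excision", ("transposase_mu",)),
    ("integrase", "integration_excision", ("integrase",)),
    ("recombinase", "integration_excision", ("recombinase",)),
    ("excisionase", "integration_excision", ()),
    ("immr", "transcription_regulation", ("hth_regulator",)),
    ("helix-turn-helix", "transcription_regulation", ("hth_regulator",)),
    ("hth", "transcription_regulation", ("hth_regulator",)),
    ("repressor", "transcription_regulation", ("hth_regulator",)),
    ("cro", "transcription_regulation", ("hth_regulator",)),
    ("transcriptional regulator", "transcription_regulation", ()),
    ("anti-repressor", "transcription_regulation", ()),
    ("imma", "other", ("imma_metallopeptidase",)),
    ("irre family metallo", "other", ("imma_metallopeptidase",)),
    ("metallo-endopeptidase", "other", ("imma_metallopeptidase",)),
    ("dna polymerase", "replication", ("dna_polymerase",)),
    ("helicase", "replication", ("helicase",)),
    ("primase", "replication", ()),
    ("single-stranded dna-binding", "replication", ()),
    ("replication", "replication", ()),
    ("dnac", "replication", ()),
    ("parb", "replication", ()),
    ("holin", "lysis", ()),
    ("endolysin", "lysis", ()),
    ("amidase", "lysis", ()),
    ("lysin", "lysis", ()),
    ("reverse transcriptase", "other", ("reverse_transcriptase_maturase",)),
    ("maturase", "other", ("reverse_transcriptase_maturase",)),
    ("avd", "moron_accessory", ("avd_dgr",)),
    ("anti-crispr", "moron_accessory", ("anti_crispr",)),
    ("hsdr", "moron_accessory", ("rm_hsdR",)),
    ("restriction subunit", "moron_accessory", ("rm_hsdR",)),
    ("hsdm", "moron_accessory", ("rm_hsdM",)),
    ("methyltransferase", "moron_accessory", ("rm_hsdM",)),
    ("hsds", "moron_accessory", ("rm_hsdS",)),
    ("specificity subunit", "moron_accessory", ("rm_hsdS",)),
    ("type iii restriction", "moron_accessory", ("rm_type3",)),
    ("antitoxin", "moron_accessory", ("ta_antitoxin",)),
    ("toxin", "moron_accessory", ("ta_toxin",)),
    ("restriction alleviation", "moron_accessory", ("restriction_alleviation",)),
    ("lar-like", "moron_accessory", ("restriction_alleviation",)),
    ("mom-like", "moron_accessory", ("mom_modification",)),
    ("dna modification", "moron_accessory", ("mom_modification",)),
    ("darb", "moron_accessory", ("darB_antirestriction",)),
    ("antirestriction", "moron_accessory", ("darB_antirestriction",)),
    ("amidoligase", "moron_accessory", ("amidoligase",)),
    ("haemolysin", "moron_accessory", ("haemolysin",)),
    ("hemolysin", "moron_accessory", ("haemolysin",)),
    ("gamma-glutamyl cyclotransferase", "moron_accessory", ("ggct",)),
    ("phosphoadenosine phosphosulfate reductase", "moron_accessory", ("paps_reductase",)),
    ("dextransucrase", "moron_accessory", ("dextransucrase",)),
    ("chloramphenicol phosphotransferase", "moron_accessory", ("cm_phosphotransferase",)),
]

#: trait -> (accessory_class, defence_role, putative function text).
#: defence_role is one of phage_defence / anti_phage_defence / "" and feeds
#: the per-region defence summary.
ACCESSORY_VOCAB: dict[str, tuple[str, str, str]] = {
    "rm_hsdR": ("rm_system", "phage_defence", "Type I RM restriction subunit (HsdR)"),
    "rm_hsdM": ("rm_system", "phage_defence", "Type I RM methyltransferase subunit (HsdM)"),
    "rm_hsdS": ("rm_system", "phage_defence", "Type I RM specificity subunit (HsdS)"),
    "rm_type3": ("rm_system", "phage_defence", "Type III restriction-modification subunit"),
    "ta_toxin": ("ta_system", "phage_defence", "Toxin component of a toxin-antitoxin system"),
    "ta_antitoxin": (
        "ta_system",
        "anti_phage_defence",
        "Solitary antitoxin (or degenerate TA system)",
    ),
    "reverse_transcriptase_maturase": (
        "diversity_generating",
        "",
        "Group II intron reverse transcriptase/maturase",
    ),
    "avd_dgr": ("diversity_generating", "", "Avd accessory protein of a DGR"),
    "anti_crispr": ("anti_phage_defence", "anti_phage_defence", "Anti-CRISPR protein"),
    "restriction_alleviation": (
        "anti_phage_defence",
        "anti_phage_defence",
        "Lar-like restriction alleviation protein",
    ),
    "mom_modification": (
        "anti_phage_defence",
        "anti_phage_defence",
        "Mom-like DNA modification protein",
    ),
    "darB_antirestriction": (
        "anti_phage_defence",
        "anti_phage_defence",
        "DarB-like antirestriction protein",
    ),
    "amidoligase": ("host_adaptation", "", "Amidoligase (cell-wall modification)"),
    "ggct": ("host_adaptation", "", "Gamma-glutamyl cyclotransferase"),
    "paps_reductase": ("host_adaptation", "", "Phosphoadenosine phosphosulfate reductase"),
    "dextransucrase": ("host_adaptation", "", "Dextransucrase activity"),
    "haemolysin": ("host_adaptation", "", "Putative haemolysin (host fitness/cell lysis)"),
    "cm_phosphotransferase": (
        "host_adaptation",
        "",
        "Chloramphenicol phosphotransferase-like protein",
    ),
}

ACCESSORY_CLASSES = (
    "rm_system",
    "ta_system",
    "diversity_generating",
    "anti_phage_defence",
    "phage_defence",
    "host_adaptation",
    "large_polyvalent_like",
    "none",
)

#: ta_system toxins count toward defence; a toxin ORF whose region also holds
#: an antitoxin forms a complete system (still phage_defence).
TOXIN_CLASSES = ("ta_system",)


def classify_product(product: str) -> tuple[str, frozenset]:
    """Map a free-text product description to (category, traits).

    Unmatched products map to ``("unknown", frozenset())``.
    """
    text = product.lower()
    for needle, category, traits in PRODUCT_VOCAB:
        if needle in text:
            return category, frozenset(traits)
    return "unknown", frozenset()


def write_accessory_vocab(path) -> None:
    """Write the accessory vocabulary as an editable TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["# accessory vocabulary", f"version={VOCAB_VERSION}", "", ""])
        w.writerow(["trait", "accessory_class", "defence_role", "putative_function"])
        for trait, (cls, role, fn) in ACCESSORY_VOCAB.items():
            w.writerow([trait, cls, role, fn])


def read_accessory_vocab(path) -> dict[str, tuple[str, str, str]]:
    """Read an accessory vocabulary TSV written by :func:`write_accessory_vocab`."""
    vocab: dict[str, tuple[str, str, str]] = {}
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "trait":
                continue
            trait, cls, role, fn = (row + ["", "", ""])[:4]
            if cls not in ACCESSORY_CLASSES:
                raise ValueError(f"unknown accessory class {cls!r} for trait {trait}")
            vocab[trait] = (cls, role, fn)
    return vocab
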