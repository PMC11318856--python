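"""The packaged LM41 study fixture.

Encodes the prophage complement of the poly-lysogenic gut commensal
*Clostridium clostridioforme* (*Enterocloster clostridioformis*) strain
LM41: 15 prophage regions (one of them, phi13, a 136-kb mosaic of five
Mu-type sub-regions), their coordinates, packaging strands, tail-gene
repertoires, lysogeny-switch architectures, structural defects, accessory
genes, completeness scores, plus 14 decoy candidate hits (8 non-phage gene
clusters and 6 duplicate/overlapping hits) so that the full 29-hit -> 15-
region curation is exercised end to end.

ORF-level architectures are reconstructions: coordinates, strands, sizes,
key ORF numbers (tail genes, switch genes, accessory genes, qPCR targets)
and completeness scores follow the study, while padding ORFs and exact
gene lengths are synthetic.  The qPCR Cq replicate values are synthetic as
well — only the treated-minus-untreated differences (delta-Cq), their
ordering, and the no-template-control relationships are anchored to the
study; raw Cq values were never published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .construct import OrfSpec, PromoterPlan, build_region
from .curation import CandidateHit
from .io import (
    write_completeness,
    write_feature_table,
    write_hits,
    write_promoters,
)
from .model import Chromosome, ProphageRegion, Strand
from .qpcr import QpcrPanel, QpcrTarget, write_cq_csv

CHROM_NAME = "LM41"
CHROM_LENGTH = 7_780_000
GENOME_SIZE_MB = 7.78

#: (name, start, end, printed_size, packaging_strand, morphology prediction)
#: Morphology "untyped" corresponds to a "-" prediction; phi13 as a whole
#: carries no prediction (None).
TABLE1 = [
    ("phi1", 194_517, 235_362, 40_846, "forward", "podovirus"),
    ("phi2", 301_574, 342_165, 40_592, "forward", "siphovirus"),
    ("phi3", 1_072_300, 1_120_599, 48_300, "forward", "myovirus"),
    ("phi4", 1_281_572, 1_323_457, 41_690, "forward", "podovirus"),
    ("phi5", 3_073_910, 3_122_116, 48_207, "reverse", "siphovirus"),
    ("phi6", 3_448_526, 3_490_199, 41_674, "reverse", "siphovirus"),
    ("phi7", 3_885_600, 3_901_899, 16_300, "reverse", "untyped"),
    ("phi8", 3_846_360, 3_885_591, 39_232, "reverse", "myovirus"),
    ("phi9", 3_997_064, 4_063_629, 66_566, "reverse", "siphovirus"),
    ("phi10", 4_120_662, 4_165_801, 45_140, "reverse", "myovirus"),
    ("phi11", 5_193_058, 5_226_919, 33_862, "reverse", "siphovirus"),
    ("phi12", 6_190_004, 6_237_536, 47_533, "forward", "siphovirus"),
    ("phi13", 6_632_999, 6_769_447, 136_449, "forward", None),
    ("phi14", 7_473_893, 7_529_677, 55_785, "forward", "myovirus"),
    ("phi15", 7_532_147, 7_579_680, 47_534, "forward", "myovirus"),
]

#: phi13 sub-regions (alpha..epsilon as a..e)
TABLE1_SUBREGIONS = [
    ("phi13a", 6_632_999, 6_684_039, 51_041, "forward", "siphovirus"),
    ("phi13b", 6_684_149, 6_706_426, 22_278, "forward", "untyped"),
    ("phi13c", 6_706_413, 6_714_990, 8_578, "forward", "untyped"),
    ("phi13d", 6_715_266, 6_749_468, 34_203, "forward", "myovirus"),
    ("phi13e", 6_750_116, 6_769_447, 19_332, "forward", "siphovirus"),
]

#: phi4's printed size disagrees with its own coordinates (which imply
#: 41,886 bp); the fixture keeps both and flags the inconsistency.
PHI4_COORDINATE_SIZE = 41_886
SIZE_DISCREPANCIES = {"phi4": (41_690, PHI4_COORDINATE_SIZE)}

#: AAI completeness scores.  phi7/phi9 (<60) and the four >60-<100 band
#: values are representative (the study reports bands, not exact figures,
#: for those); the phi13 sub-region scores are the published ones.
COMPLETENESS = {
    "phi1": 100.0,
    "phi2": 90.3,
    "phi3": 100.0,
    "phi4": 100.0,
    "phi5": 100.0,
    "phi6": 100.0,
    "phi7": 45.0,
    "phi8": 85.2,
    "phi9": 52.1,
    "phi10": 100.0,
    "phi11": 72.4,
    "phi12": 100.0,
    "phi13": 100.0,
    "phi14": 93.7,
    "phi15": 100.0,
    "phi13a": 99.65,
    "phi13b": 49.4,
    "phi13c": 18.8,
    "phi13d": 94.11,
    "phi13e": 41.2,
}

EXPECTED_CATEGORY = {
    "phi1": "functional",
    "phi2": "unknown",
    "phi3": "unknown",
    "phi4": "functional",
    "phi5": "unknown",
    "phi6": "unknown",
    "phi7": "defective",
    "phi8": "unknown",
    "phi9": "defective",
    "phi10": "functional",
    "phi11": "unknown",
    "phi12": "unknown",
    "phi13": "unknown",
    "phi14": "unknown",
    "phi15": "functional",
}

EXPECTED_DEFECTS = {
    "phi3": frozenset({"split_integrase"}),
    "phi5": frozenset({"truncated_integrase", "missing_terminase_or_portal"}),
    "phi6": frozenset({"intron_split_gene"}),
    "phi12": frozenset({"misoriented_late_orf"}),
    "phi13": frozenset({"mosaic_region"}),
}

EXPECTED_LYSOGENY = {
    "phi1": "ci_cro",
    "phi2": "immr_imma",
    "phi3": "ci_cro",
    "phi4": "ci_cro",
    "phi5": "immr_imma",
    "phi6": "ci_cro",
    "phi7": "ci_cro",
    "phi8": "undetermined",
    "phi9": "ci_cro",
    "phi10": "ci_cro",
    "phi11": "ci_cro",
    "phi12": "immr_imma",
    "phi13": "c_ner",
    "phi14": "ci_cro",
    "phi15": "ci_cro",
    "phi13a": "undetermined",
    "phi13b": "c_ner",
    "phi13c": "undetermined",
    "phi13d": "c_ner",
    "phi13e": "undetermined",
}

EXPECTED_IMMR_GEOMETRY = {"phi2": "divergent", "phi5": "convergent", "phi12": "convergent"}

#: regions carrying an anti-CRISPR gene
ANTI_CRISPR_REGIONS = {"phi1", "phi4", "phi9"}


# ---------------------------------------------------------------------------
# ORF architecture shorthands (canonical, packaging-forward order)

INT = ("integration_excision", "+", ("integrase",), 385, "tyrosine integrase")
XIS = ("integration_excision", "+", (), 72, "excisionase")
CI = ("transcription_regulation", "-", ("hth_regulator",), 225, "CI-like repressor")
CRO = ("transcription_regulation", "+", ("hth_regulator",), 71, "Cro-like regulator")

REPLICATION = {
    0: ("replication", "+", (), 180, "DNA primase"),
    1: ("replication", "+", ("helicase",), 440, "replicative DNA helicase"),
    2: ("replication", "+", ("dna_polymerase",), 560, "DNA polymerase"),
    3: ("replication", "+", (), 120, "single-stranded DNA-binding protein"),
    4: ("replication", "+", (), 200, "replication initiation protein"),
}

PACKAGING = {
    0: ("packaging_capsid", "+", ("terminase_large",), 410, "terminase large subunit"),
    1: ("packaging_capsid", "+", ("portal",), 480, "portal protein"),
    2: ("packaging_capsid", "+", (), 240, "capsid scaffolding protein"),
    3: ("packaging_capsid", "+", ("major_capsid",), 330, "major capsid protein"),
    4: ("connector", "+", (), 130, "head-tail adaptor"),
}

HOLIN = ("lysis", "+", (), 85, "holin")
ENDOLYSIN = ("lysis", "+", (), 270, "endolysin")

RT = ("other", "+", ("reverse_transcriptase_maturase",), 420,
      "group II intron reverse transcriptase/maturase")

DIV = (("-", 0.94), ("+", 0.91), ("+", 0.55))  # divergent pair plus a sub-threshold decoy
CONV = (("+", 0.92), ("-", 0.90), ("-", 0.48))  # convergent pair plus a decoy


def _tail(n: int, trait: str = "", aa: int = 150, product: str = "tail protein"):
    traits = (trait,) if trait else ()
    named = {
        "tail_sheath": "tail sheath protein",
        "tail_tape_measure": "tail tape measure protein",
        "baseplate_or_fiber": "baseplate wedge subunit",
    }
    return ("tail", "+", traits, aa, named.get(trait, product))


def _orfs(n_total: int, fixed: dict, gap_after: dict = {}) -> list[OrfSpec]:
    """Expand a sparse {orf_no: spec} dict into n_total numbered ORF specs;
    unnumbered slots become hypothetical-protein pads."""
    specs = []
    for i in range(1, n_total + 1):
        cat, strand, traits, aa, product = fixed.get(
            i, ("unknown", "+", (), None, "hypothetical protein")
        )
        specs.append(
            OrfSpec(
                f"orf{i}", cat, strand, tuple(traits), aa, product,
                gap_after=gap_after.get(i, 0),
            )
        )
    return specs


def _replication(start: int) -> dict:
    return {start + k: REPLICATION[k] for k in range(5)}


def _packaging(start: int, missing: bool = False) -> dict:
    if missing:
        return {
            start: ("packaging_capsid", "+", (), 240, "capsid scaffolding protein"),
            start + 1: ("packaging_capsid", "+", ("major_capsid",), 330,
                        "major capsid protein"),
            start + 2: ("packaging_capsid", "+", (), 110, "capsid decoration protein"),
            start + 3: ("connector", "+", (), 130, "head-tail adaptor"),
        }
    return {start + k: PACKAGING[k] for k in range(5)}


def _moron(trait: str, aa: int, product: str):
    return ("moron_accessory", "+", (trait,), aa, product)


# ---------------------------------------------------------------------------
# per-region architectures


def _phi1():
    fixed = {
        1: INT, 2: CI, 3: CRO,
        4: _moron("dextransucrase", 400, "dextransucrase"),
        **_replication(5),
        **_packaging(19),
        52: _moron("anti_crispr", 95, "anti-CRISPR protein"),
        59: HOLIN, 60: ENDOLYSIN,
        61: _tail(61, "baseplate_or_fiber", 620),
        64: ("unknown", "+", (), 2666, "hypothetical protein"),
    }
    return _orfs(64, fixed, gap_after={2: 120}), [PromoterPlan("orf2", "orf3", DIV)]


def _phi2():
    fixed = {
        1: INT, 2: XIS,
        4: ("other", "-", ("imma_metallopeptidase",), 250,
            "ImmA/IrrE family metallo-endopeptidase"),
        5: ("transcription_regulation", "-", ("hth_regulator",), 130,
            "ImmR-like repressor"),
        6: ("transcription_regulation", "+", ("hth_regulator",), 90,
            "HTH transcriptional regulator"),
        **_replication(7),
        **_packaging(31),
        51: RT,
        63: _tail(63, "", 110, "tail terminator protein"),
        64: _tail(64, "", 230, "distal tail protein"),
        65: _tail(65, "tail_tape_measure", 850),
        66: _tail(66, "tail_tape_measure", 820),
        67: _tail(67, "", 180),
        68: HOLIN, 69: ENDOLYSIN,
    }
    plans = [PromoterPlan("orf5", "orf6", DIV)]
    return _orfs(70, fixed, gap_after={5: 120}), plans


def _phi3():
    fixed = {
        1: ("integration_excision", "+", ("integrase",), 199,
            "integrase (frameshift fragment, premature stop)"),
        2: ("integration_excision", "+", ("integrase",), 150,
            "integrase (frameshift fragment)"),
        3: CI, 4: CRO,
        **_replication(5),
        13: ("other", "+", (), 310, "PFAM formylglycine-generating sulfatase enzyme"),
        16: ("replication", "+", (), 150, "VRR-NUC domain nuclease"),
        **_packaging(18),
        25: ("other", "+", (), 270, "metal-dependent phosphohydrolase"),
        55: _tail(55, "tail_sheath", 500),
        56: _tail(56, "", 120, "tail tube protein"),
        57: _tail(57, "", 150), 58: _tail(58, "", 200),
        59: _tail(59, "tail_tape_measure", 850),
        60: _tail(60, "", 140), 61: _tail(61, "", 160),
        62: _tail(62, "", 170), 63: _tail(63, "", 190),
        64: _tail(64, "baseplate_or_fiber", 600),
        65: _tail(65, "", 300),
        66: HOLIN, 67: ENDOLYSIN,
        71: ("other", "+", (), 305, "PFAM formylglycine-generating sulfatase enzyme"),
        73: _moron("avd_dgr", 130, "Avd protein of DGR"),
        76: RT,
    }
    return _orfs(78, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi4():
    fixed = {
        1: INT, 3: CI, 4: CRO,
        **_replication(5),
        **_packaging(18),
        55: _moron("anti_crispr", 95, "anti-CRISPR protein"),
        59: HOLIN, 60: ENDOLYSIN,
        63: _tail(63, "baseplate_or_fiber", 620),
        67: ("unknown", "+", (), 2666, "hypothetical protein"),
    }
    return _orfs(67, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi5():
    fixed = {
        1: _moron("amidoligase", 280, "amidoligase enzyme"),
        4: _moron("rm_hsdR", 950, "type I RM system restriction subunit HsdR"),
        5: _moron("rm_hsdS", 400, "type I RM DNA specificity domain"),
        6: ("integration_excision", "+", ("integrase",), 165, "putative integrase"),
        7: ("integration_excision", "+", ("integrase",), 167, "putative integrase"),
        8: _moron("rm_hsdS", 405, "type I RM DNA specificity domain"),
        9: _moron("rm_hsdS", 395, "type I RM DNA specificity domain"),
        10: _moron("rm_hsdS", 410, "type I RM DNA specificity domain"),
        11: _moron("rm_hsdM", 530, "type I RM system methyltransferase subunit"),
        12: ("other", "-", ("imma_metallopeptidase",), 270,
             "IrrE N-terminal-like domain protein"),
        13: ("transcription_regulation", "-", ("hth_regulator",), 130,
             "ImmR-like repressor"),
        14: ("transcription_regulation", "+", ("hth_regulator",), 90,
             "HTH transcriptional regulator"),
        **_replication(15),
        **_packaging(28, missing=True),
        52: _tail(52, "", 110, "tail terminator protein"),
        56: _tail(56, "", 230, "distal tail protein"),
        57: _tail(57, "", 180),
        58: _tail(58, "tail_tape_measure", 900),
        59: _tail(59, "", 150),
        60: _moron("cm_phosphotransferase", 180,
                   "chloramphenicol phosphotransferase-like protein"),
        61: HOLIN, 62: ENDOLYSIN,
        63: _moron("ta_toxin", 110, "toxin SymE, type I toxin-antitoxin system"),
        68: ("integration_excision", "+", ("recombinase",), 420,
             "site-specific recombinase"),
        69: ("integration_excision", "-", ("recombinase",), 282,
             "site-specific recombinase"),
    }
    plans = [PromoterPlan("orf13", "orf14", CONV)]
    return _orfs(69, fixed, gap_after={13: 120}), plans


def _phi6():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        15: ("replication", "+", (), 180, "DNA primase"),
        16: ("replication", "+", ("dna_polymerase",), 560, "DNA polymerase"),
        17: ("replication", "+", (), 120, "single-stranded DNA-binding protein"),
        18: ("replication", "+", (), 200, "replication protein"),
        19: ("replication", "+", ("helicase",), 210,
             "virulence-associated protein E-like DNA helicase (N-terminal half)"),
        20: RT,
        21: ("replication", "+", ("helicase",), 230,
             "virulence-associated protein E-like DNA helicase (C-terminal half)"),
        30: _moron("paps_reductase", 230, "phosphoadenosine phosphosulfate reductase"),
        **_packaging(33),
        50: _tail(50, "", 110, "tail terminator protein"),
        51: _tail(51, "", 230, "distal tail protein"),
        52: _tail(52, "tail_tape_measure", 900),
        53: _tail(53, "", 150),
        55: HOLIN, 56: ENDOLYSIN,
    }
    return _orfs(60, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi7():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        10: ("replication", "+", (), 180, "DNA primase"),
        11: ("replication", "+", ("helicase",), 440, "replicative DNA helicase"),
        12: ("replication", "+", ("dna_polymerase",), 560, "DNA polymerase"),
        13: ("replication", "+", (), 120, "single-stranded DNA-binding protein"),
        18: ("replication", "+", (), 250, "DnaC-like helicase loader"),
    }
    return _orfs(20, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi8():
    fixed = {
        1: INT, 2: XIS,
        3: ("transcription_regulation", "+", ("hth_regulator",), 120,
            "HTH transcriptional regulator"),
        **_replication(5),
        12: PACKAGING[0], 13: PACKAGING[1], 14: PACKAGING[2],
        15: PACKAGING[3], 16: PACKAGING[4],
        23: ("replication", "+", (), 300, "ParB N-terminal domain-containing protein"),
        36: _tail(36, "", 150), 37: _tail(37, "", 120),
        38: _tail(38, "", 120, "tail tube protein"),
        39: _tail(39, "tail_sheath", 500),
        40: _tail(40, "", 140), 41: _tail(41, "", 160),
        42: _tail(42, "", 180), 43: _tail(43, "", 200),
        44: _tail(44, "", 130), 45: _tail(45, "", 200),
        46: _tail(46, "", 180),
        47: _tail(47, "baseplate_or_fiber", 600),
        48: _tail(48, "baseplate_or_fiber", 350),
        49: _tail(49, "", 150),
        50: HOLIN, 51: ENDOLYSIN,
        57: RT,
        60: _moron("haemolysin", 320, "putative haemolysin"),
    }
    return _orfs(62, fixed), []


def _phi9():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        **_replication(5),
        27: ("other", "+", (), 220, "metal-dependent hydrolase"),
        48: _moron("paps_reductase", 230, "phosphoadenosine phosphosulfate reductase"),
        **_packaging(60),
        102: _moron("ta_toxin", 140, "endonuclease; toxin element of TA system"),
        110: _moron("mom_modification", 240, "Mom-like DNA modification protein"),
        111: _moron("darB_antirestriction", 200, "DarB-like antirestriction protein"),
        124: _moron("anti_crispr", 95, "anti-CRISPR protein"),
        130: _tail(130, "", 110, "tail terminator protein"),
        131: _tail(131, "", 230, "distal tail protein"),
        132: _tail(132, "", 200),
        133: _tail(133, "tail_tape_measure", 900),
        134: _tail(134, "", 150),
        138: HOLIN, 139: ENDOLYSIN,
        149: _moron("haemolysin", 310, "putative haemolysin (CHAP domain-containing)"),
    }
    return _orfs(149, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi10():
    fixed = {
        1: INT,
        2: _moron("ta_antitoxin", 120, "TA system HicB-like antitoxin"),
        3: _moron("ta_toxin", 80, "HicA toxin"),
        4: XIS, 5: CI, 6: CRO,
        **_replication(7),
        **_packaging(20),
        49: _moron("restriction_alleviation", 160,
                   "Lar-like restriction alleviation protein"),
        69: _tail(69, "", 120, "tail tube protein"),
        70: _tail(70, "", 150),
        71: _tail(71, "tail_sheath", 500),
        72: _tail(72, "", 130), 73: _tail(73, "", 150), 74: _tail(74, "", 170),
        75: _tail(75, "tail_tape_measure", 850),
        76: _tail(76, "", 140), 77: _tail(77, "", 160),
        78: _tail(78, "", 180), 79: _tail(79, "", 200),
        80: _tail(80, "baseplate_or_fiber", 600),
        81: _tail(81, "baseplate_or_fiber", 350),
        82: _tail(82, "", 200),
        83: HOLIN, 84: ENDOLYSIN,
    }
    return _orfs(85, fixed, gap_after={5: 120}), [PromoterPlan("orf5", "orf6", DIV)]


def _phi11():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        **_replication(5),
        17: ("transcription_regulation", "+", ("hth_regulator",), 131,
             "HTH DNA-binding protein"),
        **_packaging(20),
        48: _tail(48, "", 110, "tail terminator protein"),
        49: _tail(49, "", 230, "distal tail protein"),
        50: _tail(50, "", 200), 51: _tail(51, "", 180), 52: _tail(52, "", 150),
        53: _tail(53, "tail_tape_measure", 900),
        54: _tail(54, "", 140),
        55: HOLIN, 56: ENDOLYSIN,
    }
    return _orfs(56, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi12():
    fixed = {
        1: INT, 2: XIS,
        4: ("other", "-", ("imma_metallopeptidase",), 250,
            "IrrE family metalloendopeptidase"),
        5: ("transcription_regulation", "-", ("hth_regulator",), 130,
            "ImmR-like repressor"),
        6: ("transcription_regulation", "+", ("hth_regulator",), 90,
            "HTH transcriptional regulator"),
        **_replication(7),
        **_packaging(20),
        39: ("transcription_regulation", "+", (), 150, "transcriptional regulator"),
        58: _tail(58, "", 110, "tail terminator protein"),
        59: _tail(59, "", 230, "distal tail protein"),
        60: _tail(60, "", 180), 61: _tail(61, "", 200), 62: _tail(62, "", 150),
        63: _tail(63, "tail_tape_measure", 900),
        64: _tail(64, "", 140),
        76: HOLIN, 77: ENDOLYSIN,
        78: ("other", "-", ("reverse_transcriptase_maturase",), 420,
             "group II intron reverse transcriptase/maturase"),
        79: ("lysis", "+", (), 190, "LysB-like lysin"),
        80: ("lysis", "+", (), 140, "spanin"),
    }
    plans = [PromoterPlan("orf5", "orf6", CONV)]
    return _orfs(80, fixed, gap_after={5: 120}), plans


def _phi13():
    """The 136-kb mosaic: five consecutive Mu-type phage (sub-)regions."""
    alpha = {
        1: ("replication", "+", (), 250, "ParB-like ATP-binding protein"),
        2: ("replication", "+", (), 180, "DNA primase"),
        3: ("replication", "+", (), 120, "single-stranded DNA-binding protein"),
        5: ("other", "+", (), 160, "acetyltransferase"),
        19: ("replication", "+", ("dna_polymerase",), 560, "DNA polymerase"),
        **{21 + k: PACKAGING[k] for k in range(5)},
        28: _moron("ta_toxin", 110, "toxin SymE, type I TA system"),
        35: _moron("amidoligase", 280, "amidoligase enzyme"),
        37: _moron("amidoligase", 260, "amidoligase enzyme"),
        39: _moron("ggct", 140, "gamma-glutamyl cyclotransferase"),
        50: _moron("ta_antitoxin", 95, "addiction module antitoxin, RelB/DinJ family"),
        51: _moron("ta_toxin", 100, "ParE toxin of type II TA system"),
        60: _tail(60, "", 110, "tail terminator protein"),
        61: _tail(61, "", 230, "distal tail protein"),
        62: _tail(62, "", 200), 63: _tail(63, "", 180), 64: _tail(64, "", 150),
        65: _tail(65, "tail_tape_measure", 850),
        66: _tail(66, "", 140), 67: _tail(67, "", 160), 68: _tail(68, "", 170),
        69: _tail(69, "", 190), 70: _tail(70, "", 210),
        78: ("integration_excision", "+", ("recombinase",), 410,
             "site-specific recombinase"),
        79: ("integration_excision", "+", ("recombinase",), 380,
             "site-specific recombinase"),
    }
    beta = {
        80: ("transcription_regulation", "-", ("hth_regulator",), 168,
             "HTH transcriptional regulator (C-like repressor)"),
        82: ("transcription_regulation", "+", ("hth_regulator",), 51,
             "HTH transcriptional regulator (Ner-like)"),
        83: ("integration_excision", "+", ("transposase_mu",), 650,
             "Mu transposase C-terminal domain protein"),
        84: ("replication", "+", (), 300, "DNA transposition protein"),
        95: ("other", "+", (), 280, "transposase DDE domain protein"),
        96: ("other", "+", (), 250, "IS4 family transposase"),
        98: ("other", "+", ("reverse_transcriptase_maturase",), 420,
             "reverse transcriptase (RNA-dependent DNA polymerase)"),
        104: _moron("ta_antitoxin", 100, "antitoxin component of a TA module"),
        105: _moron("rm_hsdM", 530, "RM system HsdM methyltransferase"),
        106: _moron("rm_hsdS", 410, "RM system DNA specificity subunit"),
        107: _moron("rm_type3", 980, "type III restriction-modification subunit"),
        113: ("integration_excision", "+", ("recombinase",), 390,
              "site-specific recombinase"),
    }
    gamma = {
        114: ("replication", "+", (), 200, "replication-associated protein"),
        115: ("replication", "+", (), 230, "DNA transcription initiation protein"),
        127: ("integration_excision", "+", ("recombinase",), 370,
              "site-specific recombinase"),
    }
    delta = {
        129: ("transcription_regulation", "-", ("hth_regulator",), 197,
              "C-like repressor"),
        139: ("transcription_regulation", "+", ("hth_regulator",), 75,
              "Ner-like transcriptional regulator"),
        140: ("integration_excision", "+", ("transposase_mu",), 650,
              "Mu transposase C-terminal domain protein"),
        141: ("replication", "+", (), 300, "DNA transposition protein"),
        142: ("replication", "+", (), 180, "replication protein"),
        149: _moron("paps_reductase", 230, "phosphoadenosine phosphosulfate reductase"),
        155: _moron("ta_antitoxin", 100, "antitoxin from a TA system"),
        158: ("transcription_regulation", "+", (), 130,
              "Mor transcription activator family protein"),
        164: ("packaging_capsid", "+", ("terminase_large",), 420, "large terminase"),
        165: ("packaging_capsid", "+", ("portal",), 480, "portal protein"),
        166: ("packaging_capsid", "+", (), 260, "phage Mu protein F-like protein"),
        167: ("packaging_capsid", "+", (), 230, "Mu-like prophage I protein"),
        169: ("packaging_capsid", "+", ("major_capsid",), 310,
              "Mu-like prophage major head subunit gpT"),
        172: _tail(172, "", 150), 173: _tail(173, "", 130),
        174: _tail(174, "baseplate_or_fiber", 600),
        175: _tail(175, "", 120), 176: _tail(176, "", 140), 177: _tail(177, "", 160),
        178: _tail(178, "", 180), 179: _tail(179, "", 200),
        180: _tail(180, "tail_sheath", 500),
        181: _tail(181, "", 130), 182: _tail(182, "", 150), 183: _tail(183, "", 170),
        184: _tail(184, "tail_tape_measure", 850),
        185: _tail(185, "tail_tape_measure", 820),
        186: _tail(186, "", 210), 187: _tail(187, "", 130), 188: _tail(188, "", 140),
        189: _tail(189, "", 150), 190: _tail(190, "", 160), 191: _tail(191, "", 170),
        192: _tail(192, "", 180),
    }
    epsilon = {
        193: ("replication", "+", (), 240, "ATP-binding replication protein"),
        194: ("replication", "+", (), 200, "replication protein"),
        206: _moron("amidoligase", 280, "amidoligase enzyme"),
        208: _moron("amidoligase", 250, "amidoligase enzyme"),
        210: _moron("ggct", 140, "gamma-glutamyl cyclotransferase"),
        218: ("packaging_capsid", "+", (), 240, "capsid protein"),
        219: ("packaging_capsid", "+", ("major_capsid",), 330, "major capsid protein"),
        227: _tail(227, "tail_tape_measure", 850),
    }
    gap_after = {80: 120, 129: 120}
    plans = [
        PromoterPlan("orf80", "orf82", (("-", 0.91), ("+", 0.89))),
        PromoterPlan("orf129", "orf139", (("-", 0.90), ("+", 0.88))),
    ]
    sub_specs = []
    for (name, start, end, *_), lo, hi, fixed in [
        (TABLE1_SUBREGIONS[0], 1, 79, alpha),
        (TABLE1_SUBREGIONS[1], 80, 113, beta),
        (TABLE1_SUBREGIONS[2], 114, 127, gamma),
        (TABLE1_SUBREGIONS[3], 128, 192, delta),
        (TABLE1_SUBREGIONS[4], 193, 227, epsilon),
    ]:
        specs = []
        for i in range(lo, hi + 1):
            cat, strand, traits, aa, product = fixed.get(
                i, ("unknown", "+", (), None, "hypothetical protein")
            )
            specs.append(
                OrfSpec(f"orf{i}", cat, strand, tuple(traits), aa, product,
                        gap_after=gap_after.get(i, 0))
            )
        sub_specs.append((start, end, specs))
    return sub_specs, plans


def _phi14():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        **_replication(5),
        **{28 + k: PACKAGING[k] for k in range(5)},
        40: _moron("paps_reductase", 230, "phosphoadenosine phosphosulfate reductase"),
        42: _moron("paps_reductase", 220, "phosphoadenosine phosphosulfate reductase"),
        54: _tail(54, "", 110, "tail terminator protein"),
        55: _tail(55, "", 230, "distal tail protein"),
        56: _tail(56, "", 120, "tail tube protein"),
        57: _tail(57, "tail_sheath", 500),
        58: _tail(58, "", 140), 59: _tail(59, "", 160), 60: _tail(60, "", 180),
        61: _tail(61, "tail_tape_measure", 850),
        62: _tail(62, "", 130), 63: _tail(63, "", 150), 64: _tail(64, "", 170),
        65: _tail(65, "baseplate_or_fiber", 600),
        66: _tail(66, "", 200),
        68: HOLIN, 69: ENDOLYSIN,
        73: RT,
    }
    return _orfs(75, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


def _phi15():
    fixed = {
        1: INT, 2: XIS, 3: CI, 4: CRO,
        **_replication(5),
        **_packaging(20),
        60: _tail(60, "", 110, "tail terminator protein"),
        61: _tail(61, "", 230, "distal tail protein"),
        62: _tail(62, "", 120, "tail tube protein"),
        63: _tail(63, "tail_sheath", 500),
        64: _tail(64, "", 140), 65: _tail(65, "", 160),
        66: _tail(66, "", 180), 67: _tail(67, "", 200),
        68: _tail(68, "tail_tape_measure", 850),
        69: _tail(69, "", 130), 70: _tail(70, "", 150), 71: _tail(71, "", 170),
        72: _tail(72, "baseplate_or_fiber", 600),
        73: _tail(73, "", 190),
        74: HOLIN, 75: ENDOLYSIN,
    }
    return _orfs(75, fixed, gap_after={3: 120}), [PromoterPlan("orf3", "orf4", DIV)]


_BUILDERS = {
    "phi1": _phi1, "phi2": _phi2, "phi3": _phi3, "phi4": _phi4, "phi5": _phi5,
    "phi6": _phi6, "phi7": _phi7, "phi8": _phi8, "phi9": _phi9, "phi10": _phi10,
    "phi11": _phi11, "phi12": _phi12, "phi14": _phi14, "phi15": _phi15,
}

#: non-phage decoy gene clusters (chromosomal metabolic/regulatory loci)
DECOY_CLUSTERS = [
    ("np1", 420_001, 426_000),
    ("np2", 900_001, 906_500),
    ("np3", 1_500_001, 1_506_000),
    ("np4", 2_300_001, 2_307_000),
    ("np5", 2_800_001, 2_806_000),
    ("np6", 4_600_001, 4_606_500),
    ("np7", 5_600_001, 5_606_000),
    ("np8", 7_000_001, 7_006_000),
]

_DECOY_PRODUCTS = [
    "ABC transporter ATP-binding protein",
    "two-component sensor histidine kinase",
    "MFS family permease",
    "glycosyl hydrolase family protein",
    "acyl-CoA dehydrogenase",
    "ferredoxin oxidoreductase subunit",
]

#: duplicate/overlapping candidate hits (same-prophage secondary hits)
DUPLICATE_HITS = [
    (194_600, 215_000),
    (3_080_000, 3_100_000),
    (4_000_000, 4_030_000),
    (6_200_000, 6_220_000),
    (6_640_000, 6_700_000),
    (6_710_000, 6_760_000),
]

# ---------------------------------------------------------------------------
# qPCR panel (synthetic Cq values anchored to the published delta-Cq)

QPCR_UNTREATED = {
    "s10p": 17.0,
    "phi1": 22.4, "phi2": 23.1, "phi3": 23.8, "phi4": 22.9, "phi5": 24.0,
    "phi6": 23.5, "phi7": 24.2, "phi8": 23.3, "phi9": 23.9, "phi10": 22.7,
    "phi11": 24.1, "phi12": 23.0, "phi13a": 23.6, "phi13b": 24.3,
    "phi13c": 24.6, "phi13d": 23.7, "phi13e": 28.0, "phi14": 23.2, "phi15": 22.8,
}

#: treated-minus-untreated Cq differences; phi1/phi4/phi2/phi10 carry the
#: published values, the rest are representative low-release figures, and
#: phi13e does not amplify after treatment at all.
QPCR_DELTA = {
    "s10p": 9.8,
    "phi1": 5.11, "phi2": 8.37, "phi3": 10.4, "phi4": 8.06, "phi5": 10.9,
    "phi6": 11.3, "phi7": 12.1, "phi8": 10.1, "phi9": 10.6, "phi10": 8.69,
    "phi11": 11.6, "phi12": 12.3, "phi13a": 11.0, "phi13b": 12.6,
    "phi13c": 13.1, "phi13d": 11.9, "phi13e": None, "phi14": 10.2, "phi15": 9.95,
}

QPCR_NTC = {"s10p": 26.5, "phi13e": 38.0}
QPCR_NTC_DEFAULT = 38.2


def build_qpcr_panel() -> QpcrPanel:
    """Three mean-preserving technical replicates per target and condition."""
    targets = {}
    for name, untreated in QPCR_UNTREATED.items():
        delta = QPCR_DELTA[name]
        if delta is None:
            treated: list = [None, None, None]  # non-amplifying wells
        else:
            mean = round(untreated + delta, 3)
            treated = [round(mean - 0.15, 3), mean, round(mean + 0.15, 3)]
        targets[name] = QpcrTarget(
            name=name,
            treated_cq=treated,
            untreated_cq=[round(untreated - 0.15, 3), untreated,
                          round(untreated + 0.15, 3)],
            ntc_cq=QPCR_NTC.get(name, QPCR_NTC_DEFAULT),
        )
    return QpcrPanel(targets=targets, housekeeper="s10p")


# ---------------------------------------------------------------------------
# fixture assembly


@dataclass
class LM41Fixture:
    chromosome: Chromosome
    promoters: list
    hits: list
    completeness: dict
    qpcr_panel: QpcrPanel
    expected_category: dict = field(default_factory=lambda: dict(EXPECTED_CATEGORY))
    expected_defects: dict = field(default_factory=lambda: dict(EXPECTED_DEFECTS))
    expected_lysogeny: dict = field(default_factory=lambda: dict(EXPECTED_LYSOGENY))

    def write(self, outdir) -> dict:
        """Write the fixture bundle as plain-text tables; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "feature_table": outdir / "lm41_feature_table.tsv",
            "promoters": outdir / "lm41_promoters.tsv",
            "completeness": outdir / "lm41_completeness.tsv",
            "hits": outdir / "lm41_candidate_hits.tsv",
            "qpcr": outdir / "lm41_qpcr_cq.csv",
        }
        write_feature_table(self.chromosome, paths["feature_table"])
        write_promoters(self.promoters, paths["promoters"])
        write_completeness(self.completeness, paths["completeness"])
        write_hits(self.hits, paths["hits"])
        write_cq_csv(self.qpcr_panel, paths["qpcr"])
        return paths


def build_lm41_fixture() -> LM41Fixture:
    """Assemble the packaged LM41 fixture bundle."""
    regions: list[ProphageRegion] = []
    promoters = []
    hits: list[CandidateHit] = []

    for name, start, end, printed, strand_token, _pred in TABLE1:
        packaging = Strand.FORWARD if strand_token == "forward" else Strand.REVERSE
        if name == "phi13":
            sub_specs, plans = _phi13()
            orfs = []
            for sub_start, sub_end, specs in sub_specs:
                from .construct import layout_orfs

                orfs.extend(layout_orfs(specs, sub_start, sub_end))
            region = ProphageRegion(
                name=name, chrom=CHROM_NAME, start=start, end=end,
                packaging_strand=packaging, orfs=orfs,
                completeness=COMPLETENESS[name],
            )
            from .construct import place_promoters

            proms = place_promoters(region.orfs, plans, name)
        else:
            specs, plans = _BUILDERS[name]()
            region, proms = build_region(
                name, CHROM_NAME, start, end, specs,
                packaging_strand=packaging, promoter_plans=plans,
                completeness=COMPLETENESS[name],
            )
        regions.append(region)
        promoters.extend(proms)
        hits.append(CandidateHit(CHROM_NAME, start, end, source="detector"))

    for name, start, end in DECOY_CLUSTERS:
        n_orfs = 6
        specs = [
            OrfSpec(f"orf{k + 1}", "other", "+" if k % 3 else "-", (), 300,
                    _DECOY_PRODUCTS[k % len(_DECOY_PRODUCTS)])
            for k in range(n_orfs)
        ]
        region, _ = build_region(name, CHROM_NAME, start, end, specs)
        regions.append(region)
        hits.append(CandidateHit(CHROM_NAME, start, end, source="detector"))

    for start, end in DUPLICATE_HITS:
        hits.append(CandidateHit(CHROM_NAME, start, end, source="detector-duplicate"))

    hits.sort(key=lambda h: (h.start, h.end))
    chromosome = Chromosome(name=CHROM_NAME, length=CHROM_LENGTH, regions=regions)
    return LM41Fixture(
        chromosome=chromosome,
        promoters=promoters,
        hits=hits,
        completeness=dict(COMPLETENESS),
        qpcr_panel=build_qpcr_panel(),
    )
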