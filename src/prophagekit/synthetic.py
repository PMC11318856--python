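"""Synthetic annotated chromosomes with planted prophage architectures.

The generator is the test bed for every downstream stage: it plants
prophages with known module composition, lysogeny-switch grammar, tail-gene
repertoire, structural defects and accessory-gene inventory, together with
decoy non-phage gene clusters and duplicate/overlapping candidate hits, and
emits the ground truth for each.  Only annotations are generated — the
pipeline consumes annotated output, so nucleotide sequence carries no
information here and defects are encoded as the trait/length patterns a
real annotation of the defective locus would show (e.g. a split integrase
appears as two adjacent sub-200-aa integrase fragments).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .construct import OrfSpec, PromoterPlan, build_region
from .curation import CandidateHit
from .model import Chromosome, ProphageRegion, PromoterCall, Strand
from .vocabulary import ACCESSORY_VOCAB

LYSOGENY_TYPES = ("ci_cro", "immr_imma", "c_ner", "none")
MORPHOLOGIES = ("podovirus", "siphovirus", "myovirus", "untyped")
ALL_MODULES = ("lysogeny_control", "dna_replication", "packaging_capsid", "tail", "lysis")

#: accessory traits the generator can plant (each maps through the screen's
#: vocabulary to a class)
PLANTABLE_ACCESSORY = (
    "anti_crispr",
    "rm_hsdS",
    "rm_hsdM",
    "rm_hsdR",
    "ta_toxin",
    "ta_antitoxin",
    "restriction_alleviation",
    "mom_modification",
    "darB_antirestriction",
    "amidoligase",
    "ggct",
    "paps_reductase",
    "dextransucrase",
    "haemolysin",
    "cm_phosphotransferase",
    "avd_dgr",
)


class SpecError(ValueError):
    """An architecture specification is internally inconsistent."""


@dataclass(frozen=True)
class PhageSpec:
    """Blueprint for one planted prophage."""

    name: str
    modules: tuple = ALL_MODULES
    lysogeny_type: str = "ci_cro"
    morphology: str = "siphovirus"
    defects: frozenset = frozenset()
    completeness: Optional[float] = 100.0
    packaging_strand: Strand = Strand.FORWARD
    accessory: tuple = ()
    immr_geometry: str = "divergent"  # promoter pair planted for ImmR/ImmA

    def __post_init__(self):
        object.__setattr__(self, "defects", frozenset(self.defects))
        if not isinstance(self.packaging_strand, Strand):
            object.__setattr__(self, "packaging_strand", Strand(self.packaging_strand))
        if self.lysogeny_type not in LYSOGENY_TYPES:
            raise SpecError(f"unknown lysogeny type {self.lysogeny_type!r}")
        if self.morphology not in MORPHOLOGIES:
            raise SpecError(f"unknown morphology {self.morphology!r}")
        if "mosaic_region" in self.defects:
            # mosaic regions are realized as tandem tailed lambda-like
            # phages, so module composition and switch grammar are fixed
            if self.morphology == "untyped":
                raise SpecError(f"{self.name}: mosaic regions need a tail morphology")
            if self.lysogeny_type != "ci_cro":
                raise SpecError(
                    f"{self.name}: mosaic regions use the CI/Cro sub-phage grammar"
                )
        else:
            if self.morphology != "untyped" and "tail" not in self.modules:
                raise SpecError(f"{self.name}: morphology requires a tail module")
            if self.morphology == "untyped" and "tail" in self.modules:
                raise SpecError(f"{self.name}: untyped morphology excludes tail genes")
        if {"split_integrase", "truncated_integrase"} <= self.defects:
            raise SpecError(f"{self.name}: split and truncated integrase are exclusive")
        if self.defects & {"split_integrase", "truncated_integrase"}:
            if self.lysogeny_type == "c_ner" or "lysogeny_control" not in self.modules:
                raise SpecError(f"{self.name}: integrase defects need an integrase")
        if "missing_terminase_or_portal" in self.defects and "packaging_capsid" not in self.modules:
            raise SpecError(f"{self.name}: packaging defect needs a packaging module")
        if "intron_split_gene" in self.defects and "dna_replication" not in self.modules:
            raise SpecError(f"{self.name}: intron defect needs a replication module")
        if "misoriented_late_orf" in self.defects and "tail" not in self.modules:
            raise SpecError(f"{self.name}: misorientation defect is planted in the tail")
        if "mosaic_region" in self.defects and len(self.defects) > 1:
            raise SpecError(f"{self.name}: mosaic regions carry no other planted defects")
        bad = set(self.accessory) - set(PLANTABLE_ACCESSORY)
        if bad:
            raise SpecError(f"{self.name}: unknown accessory traits {sorted(bad)}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blueprint for a whole chromosome."""

    prophages: tuple
    n_decoys: int = 0
    n_duplicate_hits: int = 0
    intergenic_min: int = 2000
    intergenic_max: int = 40000
    chrom_name: str = "synthetic_chromosome"

    def __post_init__(self):
        object.__setattr__(self, "prophages", tuple(self.prophages))
        if self.n_duplicate_hits and not self.prophages:
            raise SpecError("duplicate hits need at least one prophage")


@dataclass
class RegionTruth:
    """Ground-truth labels for one planted region or decoy."""

    name: str
    is_phage: bool
    start: int = 0
    end: int = 0
    category: str = "unclassified"
    completeness: Optional[float] = None
    defects: tuple = ()
    morphology: str = "untyped"
    lysogeny_type: str = "undetermined"
    sub_boundaries: tuple = ()
    accessory: tuple = ()  # of (orf_id, accessory_class)


@dataclass
class SyntheticTruth:
    regions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {name: asdict(t) for name, t in self.regions.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


@dataclass
class Generated:
    chromosome: Chromosome
    promoters: list
    hits: list
    truth: SyntheticTruth


def _true_category(completeness: Optional[float], has_defects: bool) -> str:
    if completeness is None:
        return "unclassified"
    if completeness == 100.0:
        return "functional" if not has_defects else "unknown"
    if completeness <= 60.0:
        return "defective"
    return "unknown"


class _Namer:
    def __init__(self):
        self.n = 0

    def __call__(self) -> str:
        self.n += 1
        return f"orf{self.n}"


def _switch_specs(phage: PhageSpec, nxt: _Namer) -> tuple[list, list]:
    """Lysogeny-switch gene grammar plus its promoter plans."""
    specs: list[OrfSpec] = []
    plans: list[PromoterPlan] = []
    t = phage.lysogeny_type
    if t in ("ci_cro", "immr_imma", "none"):
        if "split_integrase" in phage.defects:
            specs.append(OrfSpec(nxt(), "integration_excision", "+", ("integrase",), 150,
                                 "integrase (N-terminal fragment)"))
            specs.append(OrfSpec(nxt(), "integration_excision", "+", ("integrase",), 160,
                                 "integrase (C-terminal fragment)"))
        elif "truncated_integrase" in phage.defects:
            specs.append(OrfSpec(nxt(), "integration_excision", "+", ("integrase",), 150,
                                 "truncated integrase"))
        else:
            specs.append(OrfSpec(nxt(), "integration_excision", "+", ("integrase",), 385,
                                 "tyrosine integrase"))
        specs.append(OrfSpec(nxt(), "integration_excision", "+", (), 72, "excisionase"))
    if t == "ci_cro":
        ci = OrfSpec(nxt(), "transcription_regulation", "-", ("hth_regulator",), 220,
                     "CI-like repressor")
        cro = OrfSpec(nxt(), "transcription_regulation", "+", ("hth_regulator",), 71,
                      "Cro-like regulator")
        specs += [ci, cro]
        plans.append(PromoterPlan(ci.id, cro.id, (("-", 0.94), ("+", 0.91), ("+", 0.55))))
    elif t == "immr_imma":
        imma = OrfSpec(nxt(), "other", "-", ("imma_metallopeptidase",), 250,
                       "ImmA/IrrE family metallo-endopeptidase")
        immr = OrfSpec(nxt(), "transcription_regulation", "-", ("hth_regulator",), 130,
                       "ImmR-like repressor")
        hth2 = OrfSpec(nxt(), "transcription_regulation", "+", ("hth_regulator",), 90,
                       "HTH transcriptional regulator")
        specs += [imma, immr, hth2]
        pair = (("-", 0.93), ("+", 0.9)) if phage.immr_geometry == "divergent" else (
            ("+", 0.93), ("-", 0.9))
        plans.append(PromoterPlan(immr.id, hth2.id, pair))
    elif t == "c_ner":
        c = OrfSpec(nxt(), "transcription_regulation", "-", ("hth_regulator",), 197,
                    "C-like repressor")
        pad = OrfSpec(nxt(), "unknown", "+", (), 95)
        ner = OrfSpec(nxt(), "transcription_regulation", "+", ("hth_regulator",), 76,
                      "Ner-like DNA-binding protein")
        mua = OrfSpec(nxt(), "integration_excision", "+", ("transposase_mu",), 650,
                      "Mu transposase")
        specs += [c, pad, ner, mua]
        plans.append(PromoterPlan(c.id, ner.id, (("-", 0.92), ("+", 0.9))))
    elif t == "none":
        specs.append(OrfSpec(nxt(), "transcription_regulation", "+", ("hth_regulator",),
                             120, "HTH transcriptional regulator"))
    return specs, plans


def _single_phage_specs(
    phage: PhageSpec, nxt: _Namer, accessory_out: list, n_pads: int = 4
) -> tuple[list, list]:
    specs: list[OrfSpec] = []
    plans: list[PromoterPlan] = []
    if "lysogeny_control" in phage.modules:
        s, p = _switch_specs(phage, nxt)
        specs += s
        plans += p
    for _ in range(n_pads):
        specs.append(OrfSpec(nxt(), "unknown", "+"))
    if "dna_replication" in phage.modules:
        specs.append(OrfSpec(nxt(), "replication", "+", (), 180, "DNA primase"))
        if "intron_split_gene" in phage.defects:
            specs.append(OrfSpec(nxt(), "replication", "+", ("helicase",), 210,
                                 "replicative DNA helicase (N-terminal half)"))
            rt = OrfSpec(nxt(), "other", "+", ("reverse_transcriptase_maturase",), 420,
                         "group II intron reverse transcriptase/maturase")
            specs.append(rt)
            accessory_out.append((rt.id, ACCESSORY_VOCAB["reverse_transcriptase_maturase"][0]))
            specs.append(OrfSpec(nxt(), "replication", "+", ("helicase",), 230,
                                 "replicative DNA helicase (C-terminal half)"))
        else:
            specs.append(OrfSpec(nxt(), "replication", "+", ("helicase",), 440,
                                 "replicative DNA helicase"))
        specs.append(OrfSpec(nxt(), "replication", "+", ("dna_polymerase",), 560,
                             "DNA polymerase"))
        specs.append(OrfSpec(nxt(), "replication", "+", (), 120,
                             "single-stranded DNA-binding protein"))
    if "packaging_capsid" in phage.modules:
        if "missing_terminase_or_portal" not in phage.defects:
            specs.append(OrfSpec(nxt(), "packaging_capsid", "+", ("terminase_large",),
                                 410, "terminase large subunit"))
            specs.append(OrfSpec(nxt(), "packaging_capsid", "+", ("portal",), 480,
                                 "portal protein"))
        specs.append(OrfSpec(nxt(), "packaging_capsid", "+", (), 240,
                             "capsid scaffolding protein"))
        specs.append(OrfSpec(nxt(), "packaging_capsid", "+", ("major_capsid",), 330,
                             "major capsid protein"))
        specs.append(OrfSpec(nxt(), "connector", "+", (), 130, "head-tail adaptor"))
    if "tail" in phage.modules:
        tail: list[OrfSpec] = []
        if phage.morphology == "myovirus":
            tail = [
                OrfSpec(nxt(), "tail", "+", ("tail_sheath",), 500, "tail sheath protein"),
                OrfSpec(nxt(), "tail", "+", (), 120, "tail tube protein"),
                OrfSpec(nxt(), "tail", "+", ("tail_tape_measure",), 850,
                        "tail tape measure protein"),
                OrfSpec(nxt(), "tail", "+", ("baseplate_or_fiber",), 600,
                        "baseplate wedge subunit"),
            ]
        elif phage.morphology == "siphovirus":
            tail = [
                OrfSpec(nxt(), "tail", "+", (), 110, "tail terminator protein"),
                OrfSpec(nxt(), "tail", "+", ("tail_tape_measure",), 900,
                        "tail tape measure protein"),
                OrfSpec(nxt(), "tail", "+", (), 230, "distal tail protein"),
            ]
        elif phage.morphology == "podovirus":
            tail = [
                OrfSpec(nxt(), "tail", "+", ("baseplate_or_fiber",), 620,
                        "baseplate wedge subunit / tail fiber"),
                OrfSpec(nxt(), "tail", "+", (), 150, "short tail protein"),
            ]
        if "misoriented_late_orf" in phage.defects and len(tail) >= 2:
            tail.insert(1, OrfSpec(nxt(), "other", "-", (), 90,
                                   "hypothetical protein"))
        specs += tail
    if "lysis" in phage.modules:
        specs.append(OrfSpec(nxt(), "lysis", "+", (), 85, "holin"))
        specs.append(OrfSpec(nxt(), "lysis", "+", (), 270, "endolysin"))
    for trait in phage.accessory:
        o = OrfSpec(nxt(), "moron_accessory", "+", (trait,), 150,
                    ACCESSORY_VOCAB[trait][2])
        specs.append(o)
        accessory_out.append((o.id, ACCESSORY_VOCAB[trait][0]))
    return specs, plans


def _phage_specs(phage: PhageSpec) -> tuple[list, list, list, list]:
    """ORF specs, promoter plans, accessory inventory and mosaic sub marks."""
    nxt = _Namer()
    accessory: list = []
    if "mosaic_region" in phage.defects:
        sub_marks = []
        specs: list[OrfSpec] = []
        plans: list[PromoterPlan] = []
        for _ in range(2):
            sub = PhageSpec(
                name=phage.name,
                modules=("lysogeny_control", "dna_replication", "packaging_capsid", "tail"),
                lysogeny_type="ci_cro",
                morphology=phage.morphology,
                packaging_strand=Strand.FORWARD,
            )
            s, p = _single_phage_specs(sub, nxt, accessory, n_pads=2)
            sub_marks.append((len(specs), len(specs) + len(s) - 1))
            specs += s
            plans += p
        return specs, plans, accessory, sub_marks
    specs, plans = _single_phage_specs(phage, nxt, accessory)
    return specs, plans, accessory, []


DECOY_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "two-component sensor histidine kinase",
    "MFS family permease",
    "glycosyl hydrolase family protein",
    "sigma-54-dependent transcriptional activator",
    "acyl-CoA dehydrogenase",
    "amino acid ABC transporter permease",
    "ferredoxin oxidoreductase subunit",
)


def generate_chromosome(spec: ArchitectureSpec, seed: int) -> Generated:
    """Realize an architecture spec as an annotated chromosome plus truth.

    Deterministic given ``seed``: identical inputs yield byte-identical
    serialized outputs.
    """
    rng = np.random.default_rng(seed)
    items: list[tuple[str, object]] = [("phage", p) for p in spec.prophages]
    items += [("decoy", i) for i in range(spec.n_decoys)]
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    regions: list[ProphageRegion] = []
    promoters: list[PromoterCall] = []
    hits: list[CandidateHit] = []
    truth = SyntheticTruth()
    phage_regions: list[ProphageRegion] = []

    pos = int(rng.integers(spec.intergenic_min, spec.intergenic_max))
    decoy_n = 0
    for kind, payload in items:
        if kind == "phage":
            phage: PhageSpec = payload
            specs, plans, accessory, sub_marks = _phage_specs(phage)
            span = sum((s.aa if s.aa is not None else 140) * 3 + 3 for s in specs)
            span += 60 * (len(specs) - 1)
            start, end = pos, pos + span - 1
            region, proms = build_region(
                phage.name, spec.chrom_name, start, end, specs,
                packaging_strand=phage.packaging_strand,
                promoter_plans=plans, completeness=phage.completeness,
            )
            regions.append(region)
            phage_regions.append(region)
            promoters += proms
            hits.append(CandidateHit(spec.chrom_name, start, end, source="detector"))
            sub_bounds = []
            for first, last in sub_marks:
                ids = {f"orf{k + 1}" for k in range(first, last + 1)}
                members = [o for o in region.orfs if o.id in ids]
                sub_bounds.append(
                    (min(o.start for o in members), max(o.end for o in members))
                )
            truth.regions[phage.name] = RegionTruth(
                name=phage.name,
                is_phage=True,
                start=start,
                end=end,
                category=_true_category(phage.completeness, bool(phage.defects)),
                completeness=phage.completeness,
                defects=tuple(sorted(phage.defects)),
                morphology=phage.morphology,
                lysogeny_type=(
                    "undetermined" if phage.lysogeny_type == "none"
                    else phage.lysogeny_type
                ),
                sub_boundaries=tuple(sorted(sub_bounds)),
                accessory=tuple(sorted(accessory)),
            )
        else:
            decoy_n += 1
            name = f"decoy{decoy_n:02d}"
            n_orfs = int(rng.integers(4, 9))
            prods = rng.choice(len(DECOY_PRODUCTS), size=n_orfs, replace=True)
            specs = [
                OrfSpec(f"orf{k + 1}", "other",
                        "+" if rng.random() < 0.7 else "-", (), 300,
                        DECOY_PRODUCTS[int(prods[k])])
                for k in range(n_orfs)
            ]
            span = n_orfs * (300 * 3 + 3) + 60 * (n_orfs - 1)
            start, end = pos, pos + span - 1
            region, _ = build_region(name, spec.chrom_name, start, end, specs)
            regions.append(region)
            hits.append(CandidateHit(spec.chrom_name, start, end, source="detector"))
            truth.regions[name] = RegionTruth(
                name=name, is_phage=False, start=start, end=end
            )
        pos = end + 1 + int(rng.integers(spec.intergenic_min, spec.intergenic_max))

    for _ in range(spec.n_duplicate_hits):
        target = phage_regions[int(rng.integers(len(phage_regions)))]
        width = max(1000, target.length // 3)
        off = int(rng.integers(0, max(1, target.length - width)))
        hits.append(
            CandidateHit(
                spec.chrom_name,
                target.start + off,
                min(target.end, target.start + off + width),
                source="detector-duplicate",
            )
        )

    hits.sort(key=lambda h: (h.start, h.end))
    chrom = Chromosome(
        name=spec.chrom_name,
        length=pos + int(rng.integers(spec.intergenic_min, spec.intergenic_max)),
        regions=regions,
    )
    return Generated(chromosome=chrom, promoters=promoters, hits=hits, truth=truth)


def random_architecture(
    seed: int, max_prophages: int = 10, chrom_name: str = "synthetic_chromosome"
) -> ArchitectureSpec:
    """Draw a random valid architecture (for property testing)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_prophages + 1))
    phages = []
    for i in range(n):
        lysogeny = LYSOGENY_TYPES[int(rng.integers(len(LYSOGENY_TYPES)))]
        morphology = MORPHOLOGIES[int(rng.integers(len(MORPHOLOGIES)))]
        modules = list(ALL_MODULES)
        if morphology == "untyped":
            modules.remove("tail")
        defects: set = set()
        if rng.random() < 0.45:
            options = ["missing_terminase_or_portal", "intron_split_gene", "mosaic_region"]
            if morphology != "untyped":
                options.append("misoriented_late_orf")
            if lysogeny != "c_ner":
                options += ["split_integrase", "truncated_integrase"]
            defects = {options[int(rng.integers(len(options)))]}
        if "mosaic_region" in defects:
            morphology = ("podovirus", "siphovirus", "myovirus")[int(rng.integers(3))]
            modules = list(ALL_MODULES)
            lysogeny = "ci_cro"
        band = rng.random()
        if band < 0.4:
            completeness: Optional[float] = 100.0
        elif band < 0.7:
            completeness = round(float(rng.uniform(61.0, 99.5)), 1)
        elif band < 0.95:
            completeness = round(float(rng.uniform(10.0, 60.0)), 1)
        else:
            completeness = None
        n_acc = int(rng.integers(0, 4))
        acc_idx = rng.choice(len(PLANTABLE_ACCESSORY), size=n_acc, replace=False)
        phages.append(
            PhageSpec(
                name=f"phage{i + 1:02d}",
                modules=tuple(modules),
                lysogeny_type=lysogeny,
                morphology=morphology,
                defects=frozenset(defects),
                completeness=completeness,
                packaging_strand=Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE,
                accessory=tuple(sorted(PLANTABLE_ACCESSORY[int(k)] for k in acc_idx)),
                immr_geometry="divergent" if rng.random() < 0.5 else "convergent",
            )
        )
    return ArchitectureSpec(
        prophages=tuple(phages),
        n_decoys=int(rng.integers(0, 5)),
        n_duplicate_hits=int(rng.integers(0, 3)),
        chrom_name=chrom_name,
    )
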