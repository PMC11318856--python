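"""Pipeline orchestration: curate -> type -> screen -> qpcr, plus reporting.

The pipeline is a pure function of its inputs and configuration; it never
mutates inputs, and re-running with the same config reproduces the same
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import io as pio
from .accessory import screen_accessory, summarize_defence
from .curation import (
    CurationConfig,
    CuratedRegion,
    curate_chromosome,
)
from .model import Category, filter_promoters
from .phage_typing import TypingConfig, call_lysogeny, call_morphology
from .qpcr import read_cq_csv, write_qpcr_report
from .vocabulary import read_accessory_vocab

log = logging.getLogger("prophagekit")


class ConfigurationError(ValueError):
    """A stage is enabled but a required input is missing."""


@dataclass
class PipelineConfig:
    annotations: Optional[str] = None
    annotation_format: str = "feature_table"
    hits: Optional[str] = None
    completeness: Optional[str] = None
    promoters: Optional[str] = None
    qpcr: Optional[str] = None
    vocab: Optional[str] = None
    out_dir: str = "prophagekit_out"
    run_curate: bool = True
    run_type: bool = True
    run_screen: bool = True
    run_qpcr: bool = False
    max_gap: int = 0
    housekeeper: str = "s10p"
    cq_cap: float = 40.0
    ntc_margin: float = 0.0
    render_map: bool = False

    def validate(self) -> None:
        if (self.run_curate or self.run_type or self.run_screen) and not self.annotations:
            raise ConfigurationError("annotation stages enabled but no annotations given")
        if self.run_qpcr and not self.qpcr:
            raise ConfigurationError("qpcr stage enabled but no Cq table given")
        for label in ("annotations", "hits", "completeness", "promoters", "qpcr", "vocab"):
            path = getattr(self, label)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} file not found: {path}")


@dataclass
class RegionReport:
    """One combined-summary row."""

    name: str
    start: int
    end: int
    length: int
    packaging_strand: str
    modules: tuple = ()
    completeness: Optional[float] = None
    defects: tuple = ()
    category: str = "unclassified"
    morphology: str = "untyped"
    morphology_evidence: tuple = ()
    lysogeny_system: str = "undetermined"
    lysogeny_repressor: Optional[str] = None
    promoter_geometry: str = "none"
    accessory_classes: tuple = ()
    is_sub_region: bool = False


def _report_rows(
    curated: list[CuratedRegion],
    promoters,
    vocab: Optional[dict],
    do_type: bool,
    do_screen: bool,
    typing_config: TypingConfig,
) -> tuple[list[RegionReport], list]:
    rows: list[RegionReport] = []
    accessory_records = []

    def one(rec: CuratedRegion, sub: bool) -> RegionReport:
        region = rec.region
        row = RegionReport(
            name=rec.name,
            start=region.start,
            end=region.end,
            length=region.length,
            packaging_strand=region.packaging_strand.name.lower(),
            modules=rec.profile.modules_present,
            completeness=rec.completeness,
            defects=tuple(sorted(d.kind for d in rec.defects)),
            category=rec.category.value,
            is_sub_region=sub,
        )
        if do_type:
            morph = call_morphology(region)
            row.morphology = morph.morphology
            row.morphology_evidence = morph.evidence
            region_promoters = [p for p in promoters if p.region in (rec.name, rec.name.rstrip("abcdefghij"))]
            lys = call_lysogeny(region, region_promoters, typing_config)
            row.lysogeny_system = lys.system
            row.lysogeny_repressor = lys.repressor_orf
            row.promoter_geometry = lys.promoter_geometry
        if do_screen:
            records = screen_accessory(region, vocab)
            accessory_records.extend(records)
            row.accessory_classes = tuple(
                sorted({r.accessory_class for r in records})
            )
        return row

    for rec in curated:
        if not rec.confirmed:
            continue
        rows.append(one(rec, sub=False))
        for sub in rec.sub_regions:
            rows.append(one(sub, sub=True))
    return rows, accessory_records


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; write per-stage tables plus a combined
    region summary under ``config.out_dir``; return the in-memory results."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    curation_config = CurationConfig(max_gap=config.max_gap)
    typing_config = TypingConfig()

    if config.run_curate or config.run_type or config.run_screen:
        chromosome = pio.read_chromosome(config.annotations, config.annotation_format)
        hits = pio.read_hits(config.hits) if config.hits else None
        completeness = (
            pio.read_completeness(config.completeness) if config.completeness else None
        )
        promoters = (
            filter_promoters(pio.read_promoters(config.promoters))
            if config.promoters
            else []
        )
        vocab = read_accessory_vocab(config.vocab) if config.vocab else None

        curated = curate_chromosome(
            chromosome, hits=hits, completeness=completeness, config=curation_config
        )
        results["curated"] = curated
        rows, accessory_records = _report_rows(
            curated, promoters, vocab, config.run_type, config.run_screen,
            typing_config,
        )
        results["summary"] = rows
        results["accessory"] = accessory_records
        if config.run_screen:
            confirmed_regions = [
                rec.region for rec in curated if rec.confirmed
            ]
            results["defence_summary"] = summarize_defence(
                accessory_records, confirmed_regions
            )
        _write_summary(rows, outdir / "region_summary.tsv")
        with (outdir / "region_summary.json").open("w") as fh:
            json.dump(
                [row.__dict__ for row in rows], fh, indent=1, sort_keys=True,
                default=list,
            )
        log.info("curation: %d confirmed regions", sum(1 for r in rows if not r.is_sub_region))
        if config.render_map:
            render_region_map(rows, outdir / "region_map.svg")

    if config.run_qpcr:
        panel = read_cq_csv(
            config.qpcr,
            housekeeper=config.housekeeper,
            cq_cap=config.cq_cap,
            ntc_margin=config.ntc_margin,
        )
        qpcr_results = panel.analyze()
        results["qpcr"] = qpcr_results
        results["qpcr_ranking"] = panel.release_ranking()
        write_qpcr_report(qpcr_results, outdir / "qpcr_report.tsv")
        log.info("qpcr: %d targets analyzed", len(qpcr_results))

    return results


def _write_summary(rows: list, path: Path) -> None:
    import csv

    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "region", "start", "end", "length", "packaging_strand", "modules",
                "completeness", "defects", "category", "morphology",
                "lysogeny_system", "promoter_geometry", "accessory_classes",
                "sub_region",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    r.name, str(r.start), str(r.end), str(r.length),
                    r.packaging_strand, ",".join(r.modules),
                    "" if r.completeness is None else repr(r.completeness),
                    ",".join(r.defects), r.category, r.morphology,
                    r.lysogeny_system, r.promoter_geometry,
                    ",".join(r.accessory_classes), str(r.is_sub_region),
                ]
            )


CATEGORY_COLOURS = {
    "functional": "#d62728",  # red
    "defective": "#000000",  # black
    "unknown": "#e6c300",  # yellow
    "unclassified": "#9e9e9e",
}

MORPHOLOGY_MARKS = {"podovirus": "P", "siphovirus": "S", "myovirus": "M", "untyped": ""}
LYSOGENY_MARKS = {"ci_cro": "CI/Cro", "immr_imma": "ImmR/ImmA", "c_ner": "C/Ner",
                  "undetermined": ""}


def render_region_map(rows: list, path, genome_length: Optional[int] = None):
    """Draw the chromosome with regions coloured by category and labelled
    with morphology and lysogeny-switch symbols (SVG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 2.8))
    top_rows = [r for r in rows if not r.is_sub_region]
    if not top_rows:
        log.warning("empty summary: rendering an empty genome map")
    length = genome_length or (max((r.end for r in top_rows), default=1) * 1.02)
    ax.hlines(0.5, 0, length, color="0.6", lw=2, zorder=1)
    for r in top_rows:
        ax.add_patch(
            plt.Rectangle(
                (r.start, 0.35), r.end - r.start + 1, 0.3,
                color=CATEGORY_COLOURS.get(r.category, "#9e9e9e"), zorder=2,
            )
        )
        label = r.name
        marks = " ".join(
            m for m in (MORPHOLOGY_MARKS.get(r.morphology, ""),
                        LYSOGENY_MARKS.get(r.lysogeny_system, "")) if m
        )
        if marks:
            label = f"{label}\n{marks}"
        ax.annotate(
            label, ((r.start + r.end) / 2, 0.72), ha="center", fontsize=6,
            rotation=45,
        )
    ax.set_xlim(0, length)
    ax.set_ylim(0, 1.3)
    ax.set_yticks([])
    ax.set_xlabel("chromosome position (bp)")
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=c) for c in CATEGORY_COLOURS.values()
    ]
    ax.legend(handles, list(CATEGORY_COLOURS), loc="upper right", fontsize=6,
              ncol=4, frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
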