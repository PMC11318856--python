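"""Readers and writers for annotated chromosomes and auxiliary tables.

Three chromosome formats are supported and round-trip losslessly:

* ``feature_table`` — a simple TSV dialect with columns
  ``region  orf_id  start  end  strand  length_aa  category  traits  product``
  (traits are a semicolon-joined list).  Chromosome and region metadata are
  carried on ``##``-prefixed header lines so the column contract stays flat.
* ``genbank`` — a GenBank flat file (Biopython); regions are ``misc_feature``
  records, ORFs are ``CDS`` features with category/traits in qualifiers.
* ``gff3`` — read via :mod:`gffutils`, written directly.

Auxiliary tables: promoter calls (TSV), completeness scores (TSV) and
candidate hits (TSV).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

from .model import (
    Chromosome,
    Orf,
    PromoterCall,
    ProphageRegion,
    Strand,
    sort_orfs,
)

FEATURE_COLUMNS = (
    "region",
    "orf_id",
    "start",
    "end",
    "strand",
    "length_aa",
    "category",
    "traits",
    "product",
)


class ParseError(ValueError):
    """Malformed input; message names the offending file, line and feature."""


def _strand(token: str, where: str) -> Strand:
    token = token.strip().lower()
    if token in ("+", "forward", "f", "1"):
        return Strand.FORWARD
    if token in ("-", "−", "reverse", "r", "-1"):
        return Strand.REVERSE
    raise ParseError(f"{where}: bad strand symbol {token!r}")


def _int(token: str, where: str) -> int:
    try:
        return int(token.replace(",", ""))
    except ValueError:
        raise ParseError(f"{where}: bad integer {token!r}") from None


# ---------------------------------------------------------------------------
# feature_table


def write_feature_table(chromosome: Chromosome, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["## chromosome", chromosome.name, str(chromosome.length)])
        for r in chromosome.regions:
            w.writerow(
                [
                    "## region",
                    r.name,
                    str(r.start),
                    str(r.end),
                    r.packaging_strand.name.lower(),
                    "" if r.completeness is None else repr(r.completeness),
                ]
            )
        w.writerow(FEATURE_COLUMNS)
        for r in chromosome.regions:
            for o in r.orfs:
                w.writerow(
                    [
                        r.name,
                        o.id,
                        str(o.start),
                        str(o.end),
                        o.strand.value,
                        str(o.length_aa),
                        o.category,
                        ";".join(sorted(o.traits)),
                        o.product,
                    ]
                )


def read_feature_table(path) -> Chromosome:
    path = Path(path)
    chrom_name, chrom_len = "chromosome", 0
    region_meta: dict[str, tuple] = {}
    orfs_by_region: dict[str, list[Orf]] = {}
    with path.open() as fh:
        header_seen = False
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            where = f"{path.name}:{lineno}"
            if not row or not any(row):
                continue
            if row[0] == "## chromosome":
                chrom_name, chrom_len = row[1], _int(row[2], where)
                continue
            if row[0] == "## region":
                comp = None if len(row) < 6 or row[5] == "" else float(row[5])
                region_meta[row[1]] = (
                    _int(row[2], where),
                    _int(row[3], where),
                    _strand(row[4], where),
                    comp,
                )
                orfs_by_region.setdefault(row[1], [])
                continue
            if row[0].startswith("#"):
                continue
            if not header_seen:
                if tuple(row) != FEATURE_COLUMNS:
                    raise ParseError(f"{where}: unexpected columns {row}")
                header_seen = True
                continue
            if len(row) != len(FEATURE_COLUMNS):
                raise ParseError(f"{where}: expected {len(FEATURE_COLUMNS)} columns")
            region, orf_id, start, end, strand, length_aa, category, traits, product = row
            start_i, end_i = _int(start, where), _int(end, where)
            if start_i > end_i:
                raise ParseError(f"{where}: feature {orf_id}: end < start")
            try:
                orf = Orf(
                    id=orf_id,
                    start=start_i,
                    end=end_i,
                    strand=_strand(strand, where),
                    length_aa=_int(length_aa, where),
                    category=category,
                    traits=frozenset(t for t in traits.split(";") if t),
                    product=product,
                )
            except ValueError as exc:
                raise ParseError(f"{where}: feature {orf_id}: {exc}") from None
            orfs_by_region.setdefault(region, []).append(orf)
    regions = []
    for name, orfs in orfs_by_region.items():
        if name in region_meta:
            start, end, strand, comp = region_meta[name]
        else:
            start = min(o.start for o in orfs)
            end = max(o.end for o in orfs)
            strand, comp = Strand.FORWARD, None
        regions.append(
            ProphageRegion(
                name=name,
                chrom=chrom_name,
                start=start,
                end=end,
                packaging_strand=strand,
                orfs=orfs,
                completeness=comp,
            )
        )
    if not chrom_len:
        chrom_len = max((r.end for r in regions), default=1)
    return Chromosome(name=chrom_name, length=chrom_len, regions=regions)


# ---------------------------------------------------------------------------
# GenBank


def write_genbank(chromosome: Chromosome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq("N" * chromosome.length),
        id=chromosome.name,
        name=chromosome.name[:16],
        description="annotated chromosome",
    )
    record.annotations["molecule_type"] = "DNA"
    for r in chromosome.regions:
        qualifiers = {
            "label": [r.name],
            "packaging_strand": [r.packaging_strand.name.lower()],
        }
        if r.completeness is not None:
            qualifiers["completeness"] = [repr(r.completeness)]
        record.features.append(
            SeqFeature(
                FeatureLocation(r.start - 1, r.end, strand=1),
                type="misc_feature",
                qualifiers=qualifiers,
            )
        )
        for o in r.orfs:
            record.features.append(
                SeqFeature(
                    FeatureLocation(
                        o.start - 1, o.end, strand=1 if o.strand is Strand.FORWARD else -1
                    ),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [o.id],
                        "region": [r.name],
                        "product": [o.product or "hypothetical protein"],
                        "category": [o.category],
                        "traits": [";".join(sorted(o.traits))],
                        "length_aa": [str(o.length_aa)],
                    },
                )
            )
    SeqIO.write([record], str(path), "genbank")


def read_genbank(path) -> Chromosome:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "genbank"))
    region_meta: dict[str, tuple] = {}
    orfs_by_region: dict[str, list[Orf]] = {}
    for feat in record.features:
        if feat.type == "misc_feature" and "label" in feat.qualifiers:
            name = feat.qualifiers["label"][0]
            comp = feat.qualifiers.get("completeness")
            region_meta[name] = (
                int(feat.location.start) + 1,
                int(feat.location.end),
                _strand(feat.qualifiers.get("packaging_strand", ["forward"])[0], name),
                float(comp[0]) if comp else None,
            )
            orfs_by_region.setdefault(name, [])
        elif feat.type == "CDS":
            name = feat.qualifiers.get("region", ["unassigned"])[0]
            orf_id = feat.qualifiers.get("locus_tag", ["orf"])[0]
            try:
                orf = Orf(
                    id=orf_id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand=Strand.FORWARD if feat.location.strand >= 0 else Strand.REVERSE,
                    category=feat.qualifiers.get("category", ["unknown"])[0],
                    traits=frozenset(
                        t for t in feat.qualifiers.get("traits", [""])[0].split(";") if t
                    ),
                    product=feat.qualifiers.get("product", [""])[0],
                    length_aa=int(feat.qualifiers.get("length_aa", ["1"])[0]),
                )
            except ValueError as exc:
                raise ParseError(f"{Path(path).name}: feature {orf_id}: {exc}") from None
            orfs_by_region.setdefault(name, []).append(orf)
    regions = [
        ProphageRegion(
            name=name,
            chrom=record.id,
            start=region_meta[name][0] if name in region_meta else min(o.start for o in orfs),
            end=region_meta[name][1] if name in region_meta else max(o.end for o in orfs),
            packaging_strand=region_meta.get(name, (0, 0, Strand.FORWARD, None))[2],
            orfs=orfs,
            completeness=region_meta.get(name, (0, 0, Strand.FORWARD, None))[3],
        )
        for name, orfs in orfs_by_region.items()
    ]
    return Chromosome(name=record.id, length=len(record.seq), regions=regions)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(chromosome: Chromosome, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chromosome.name} 1 {chromosome.length}\n")
        for r in chromosome.regions:
            attrs = [
                f"ID=region:{r.name}",
                f"Name={r.name}",
                f"packaging_strand={r.packaging_strand.name.lower()}",
            ]
            if r.completeness is not None:
                attrs.append(f"completeness={r.completeness!r}")
            fh.write(
                "\t".join(
                    [
                        chromosome.name,
                        "prophagekit",
                        "sequence_feature",
                        str(r.start),
                        str(r.end),
                        ".",
                        "+",
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for o in r.orfs:
                attrs = [
                    f"ID=cds:{r.name}:{o.id}",
                    f"Name={o.id}",
                    f"region={r.name}",
                    f"category={o.category}",
                    f"traits={','.join(sorted(o.traits))}",
                    f"length_aa={o.length_aa}",
                    f"product={o.product.replace(';', '%3B').replace('=', '%3D')}",
                ]
                fh.write(
                    "\t".join(
                        [
                            chromosome.name,
                            "prophagekit",
                            "CDS",
                            str(o.start),
                            str(o.end),
                            ".",
                            o.strand.value,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def _attr(attrs, key, default: str = "") -> str:
    vals = attrs.get(key, [default])
    return vals[0] if vals else default


def read_gff3(path) -> Chromosome:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_name, chrom_len = "chromosome", 0
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                chrom_name, chrom_len = parts[1], int(parts[3])
                break
    region_meta: dict[str, tuple] = {}
    orfs_by_region: dict[str, list[Orf]] = {}
    for feat in db.all_features():
        attrs = feat.attributes
        if feat.featuretype == "sequence_feature":
            name = attrs["Name"][0]
            comp = attrs.get("completeness")
            region_meta[name] = (
                feat.start,
                feat.end,
                _strand(attrs.get("packaging_strand", ["forward"])[0], name),
                float(comp[0]) if comp else None,
            )
            orfs_by_region.setdefault(name, [])
        elif feat.featuretype == "CDS":
            name = attrs["region"][0]
            orf_id = attrs["Name"][0]
            where = f"{Path(path).name}: feature {orf_id}"
            if feat.start > feat.end:
                raise ParseError(f"{where}: end < start")
            try:
                orf = Orf(
                    id=orf_id,
                    start=feat.start,
                    end=feat.end,
                    strand=_strand(feat.strand or "+", where),
                    category=_attr(attrs, "category", "unknown"),
                    traits=frozenset(
                        t for t in _attr(attrs, "traits").split(",") if t
                    ),
                    product=_attr(attrs, "product")
                    .replace("%3B", ";")
                    .replace("%3D", "="),
                    length_aa=int(_attr(attrs, "length_aa", "1")),
                )
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from None
            orfs_by_region.setdefault(name, []).append(orf)
    regions = [
        ProphageRegion(
            name=name,
            chrom=chrom_name,
            start=region_meta[name][0] if name in region_meta else min(o.start for o in orfs),
            end=region_meta[name][1] if name in region_meta else max(o.end for o in orfs),
            packaging_strand=region_meta.get(name, (0, 0, Strand.FORWARD, None))[2],
            orfs=orfs,
            completeness=region_meta.get(name, (0, 0, Strand.FORWARD, None))[3],
        )
        for name, orfs in orfs_by_region.items()
    ]
    if not chrom_len:
        chrom_len = max((r.end for r in regions), default=1)
    return Chromosome(name=chrom_name, length=chrom_len, regions=regions)


# ---------------------------------------------------------------------------
# dispatch

_READERS = {"feature_table": read_feature_table, "genbank": read_genbank, "gff3": read_gff3}
_WRITERS = {"feature_table": write_feature_table, "genbank": write_genbank, "gff3": write_gff3}


def read_chromosome(path, format: str = "feature_table") -> Chromosome:
    """Read an annotated chromosome in the named format."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_READERS)}")
    return reader(path)


def write_chromosome(chromosome: Chromosome, path, format: str = "feature_table") -> None:
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_WRITERS)}")
    writer(chromosome, path)


# ---------------------------------------------------------------------------
# auxiliary tables


def write_promoters(promoters: Iterable[PromoterCall], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["region", "position", "strand", "score"])
        for p in promoters:
            w.writerow([p.region, str(p.position), p.strand.value, repr(p.score)])


def read_promoters(path) -> list[PromoterCall]:
    out = []
    with Path(path).open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0] in ("region",) or row[0].startswith("#"):
                continue
            where = f"{Path(path).name}:{lineno}"
            try:
                out.append(
                    PromoterCall(
                        region=row[0],
                        position=_int(row[1], where),
                        strand=_strand(row[2], where),
                        score=float(row[3]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from None
    return out


def write_completeness(scores: dict[str, Optional[float]], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["region", "completeness"])
        for name, score in scores.items():
            w.writerow([name, "" if score is None else repr(score)])


def read_completeness(path) -> dict[str, Optional[float]]:
    scores: dict[str, Optional[float]] = {}
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0] in ("region",) or row[0].startswith("#"):
                continue
            scores[row[0]] = float(row[1]) if len(row) > 1 and row[1] != "" else None
    return scores


def write_hits(hits, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "source"])
        for h in hits:
            w.writerow([h.chrom, str(h.start), str(h.end), h.source])


def read_hits(path):
    from .curation import CandidateHit

    out = []
    with Path(path).open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0] in ("chrom",) or row[0].startswith("#"):
                continue
            where = f"{Path(path).name}:{lineno}"
            out.append(
                CandidateHit(
                    chrom=row[0],
                    start=_int(row[1], where),
                    end=_int(row[2], where),
                    source=row[3] if len(row) > 3 else "",
                )
            )
    return out
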