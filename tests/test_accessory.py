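"""Accessory-gene screen and defence summary."""

import pytest

from prophagekit.accessory import screen_accessory, summarize_defence
from prophagekit.curation import delineate_mosaic
from prophagekit.model import Orf, ProphageRegion, Strand
from prophagekit.vocabulary import (
    read_accessory_vocab,
    write_accessory_vocab,
)


def _records_by_class(records):
    out = {}
    for r in records:
        out.setdefault(r.accessory_class, []).append(r)
    return out


class TestScreen:
    def test_complete_type_i_rm_system(self, lm41_confirmed):
        # three specificity subunits, a methyltransferase and a restriction
        # subunit constitute a complete type I system
        records = screen_accessory(lm41_confirmed["phi5"].region)
        rm = [r for r in records if r.accessory_class == "rm_system"]
        traits = sorted(r.trait for r in rm)
        assert traits.count("rm_hsdS") == 4
        assert "rm_hsdM" in traits and "rm_hsdR" in traits
        assert all(r.defence_role == "phage_defence" for r in rm)

    def test_complete_ta_system_counts_as_defence(self, lm41_confirmed):
        records = screen_accessory(lm41_confirmed["phi10"].region)
        ta = {r.orf_id: r for r in records if r.accessory_class == "ta_system"}
        assert set(ta) == {"orf2", "orf3"}
        # the antitoxin is part of a complete system here, not a solitary one
        assert ta["orf2"].defence_role == "phage_defence"
        assert ta["orf3"].defence_role == "phage_defence"

    def test_solitary_antitoxin_reported_as_anti_defence(self, lm41_confirmed):
        subs = {s.name: s for s in delineate_mosaic(lm41_confirmed["phi13"].region)}
        records = screen_accessory(subs["phi13d"])
        anti = [r for r in records if r.trait == "ta_antitoxin"]
        assert len(anti) == 1
        assert anti[0].defence_role == "anti_phage_defence"
        assert "degenerate" in anti[0].putative_function

    def test_large_unassigned_orf_flagged_polyvalent_like(self, lm41_confirmed):
        records = screen_accessory(lm41_confirmed["phi1"].region)
        big = [r for r in records if r.accessory_class == "large_polyvalent_like"]
        assert [r.orf_id for r in big] == ["orf64"]

    def test_region_without_flagged_traits_is_empty(self):
        orfs = [Orf("o1", 1, 300, Strand.FORWARD, "unknown")]
        region = ProphageRegion(name="r", chrom="c", start=1, end=400, orfs=orfs)
        assert screen_accessory(region) == []


class TestSummary:
    def test_anti_crispr_limited_to_three_prophages(self, lm41_confirmed):
        records = []
        for rec in lm41_confirmed.values():
            records.extend(screen_accessory(rec.region))
        summary = summarize_defence(
            records, [rec.region for rec in lm41_confirmed.values()]
        )
        assert summary.regions_with_trait("anti_crispr") == {"phi1", "phi4", "phi9"}
        assert summary.no_classical_morons

    def test_empty_input_gives_empty_summary(self):
        summary = summarize_defence([])
        assert summary.per_region.empty
        assert summary.records == []

    def test_classical_moron_keyword_flips_flag(self):
        orfs = [
            Orf("o1", 1, 300, Strand.FORWARD, "moron_accessory",
                traits=frozenset({"ta_toxin"}), product="Shiga-like exotoxin"),
        ]
        region = ProphageRegion(name="r", chrom="c", start=1, end=400, orfs=orfs)
        summary = summarize_defence(screen_accessory(region), [region])
        assert not summary.no_classical_morons


def test_vocabulary_file_round_trip(tmp_path):
    path = tmp_path / "vocab.tsv"
    write_accessory_vocab(path)
    vocab = read_accessory_vocab(path)
    assert vocab["anti_crispr"][0] == "anti_phage_defence"
    assert vocab["rm_hsdS"][0] == "rm_system"
    assert len(vocab) >= 15


def test_vocabulary_edits_do_not_change_curation(lm41, lm41_confirmed):
    # the screen is a leaf stage: swapping a vocabulary class must leave
    # curation/typing results untouched (they never read the vocabulary)
    from prophagekit.curation import curate_chromosome

    again = curate_chromosome(
        lm41.chromosome, hits=lm41.hits, completeness=lm41.completeness
    )
    assert {r.name: r.category for r in again if r.confirmed} == {
        name: rec.category for name, rec in lm41_confirmed.items()
    }
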