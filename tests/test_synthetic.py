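"""Synthetic-data generator: validity, determinism, and fixture content."""

import pytest

from prophagekit.curation import curate_chromosome
from prophagekit.io import write_feature_table, write_promoters
from prophagekit.lm41 import (
    COMPLETENESS,
    PHI4_COORDINATE_SIZE,
    SIZE_DISCREPANCIES,
    TABLE1,
    TABLE1_SUBREGIONS,
)
from prophagekit.model import Strand, region_length
from prophagekit.synthetic import (
    ArchitectureSpec,
    PhageSpec,
    SpecError,
    generate_chromosome,
    random_architecture,
)


class TestSpecValidation:
    def test_morphology_needs_tail_module(self):
        with pytest.raises(SpecError, match="tail module"):
            PhageSpec(
                name="p", morphology="podovirus",
                modules=("lysogeny_control", "dna_replication"),
            )

    def test_untyped_morphology_excludes_tail_genes(self):
        with pytest.raises(SpecError, match="untyped"):
            PhageSpec(name="p", morphology="untyped")

    def test_integrase_defects_incompatible_with_mu_grammar(self):
        with pytest.raises(SpecError, match="integrase"):
            PhageSpec(
                name="p", lysogeny_type="c_ner",
                defects=frozenset({"truncated_integrase"}),
            )

    def test_split_and_truncated_are_exclusive(self):
        with pytest.raises(SpecError, match="exclusive"):
            PhageSpec(
                name="p",
                defects=frozenset({"split_integrase", "truncated_integrase"}),
            )


class TestGenerator:
    def test_zero_prophages_yields_only_decoys_and_no_confirmations(self):
        spec = ArchitectureSpec(prophages=(), n_decoys=5)
        generated = generate_chromosome(spec, seed=2)
        curated = curate_chromosome(
            generated.chromosome, hits=generated.hits
        )
        assert sum(1 for r in curated if r.confirmed) == 0
        assert len(generated.truth.regions) == 5

    def test_fifteen_phages_with_fourteen_extra_hits_confirm_fifteen(self):
        phages = tuple(
            PhageSpec(
                name=f"p{i:02d}",
                packaging_strand=Strand.FORWARD if i % 2 else Strand.REVERSE,
            )
            for i in range(1, 16)
        )
        spec = ArchitectureSpec(prophages=phages, n_decoys=8, n_duplicate_hits=6)
        generated = generate_chromosome(spec, seed=1)
        assert len(generated.hits) == 29
        curated = curate_chromosome(
            generated.chromosome,
            hits=generated.hits,
            completeness={r.name: r.completeness for r in generated.chromosome.regions},
        )
        confirmed = [r.name for r in curated if r.confirmed]
        assert sorted(confirmed) == sorted(p.name for p in phages)

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for i in (1, 2):
            spec = random_architecture(9)
            generated = generate_chromosome(spec, 9)
            write_feature_table(generated.chromosome, tmp_path / f"ft{i}.tsv")
            write_promoters(generated.promoters, tmp_path / f"pr{i}.tsv")
            generated.truth.to_json(tmp_path / f"truth{i}.json")
        for stem in ("ft", "pr", "truth"):
            ext = "json" if stem == "truth" else "tsv"
            a = (tmp_path / f"{stem}1.{ext}").read_bytes()
            b = (tmp_path / f"{stem}2.{ext}").read_bytes()
            assert a == b

    def test_generated_regions_satisfy_model_invariants(self):
        generated = generate_chromosome(random_architecture(4), 4)
        for region in generated.chromosome.regions:
            assert region.start <= region.end
            for orf in region.orfs:
                assert region.start <= orf.start <= orf.end <= region.end
        positions = sorted(
            (r.start, r.end) for r in generated.chromosome.regions
        )
        for (s1, e1), (s2, e2) in zip(positions, positions[1:]):
            assert e1 < s2  # planted regions never overlap


class TestLm41Fixture:
    def test_region_names_and_subregion_names(self, lm41):
        names = {r.name for r in lm41.chromosome.regions}
        assert {f"phi{i}" for i in range(1, 16)} <= names
        sub_names = [row[0] for row in TABLE1_SUBREGIONS]
        assert sub_names == ["phi13a", "phi13b", "phi13c", "phi13d", "phi13e"]

    def test_hit_census(self, lm41):
        # 15 prophage hits + 8 non-phage clusters + 6 duplicates
        assert len(lm41.hits) == 29
        duplicates = [h for h in lm41.hits if h.source == "detector-duplicate"]
        assert len(duplicates) == 6

    def test_phi3_tail_traits(self, lm41):
        region = lm41.chromosome.region("phi3")
        traits = set().union(*(o.traits for o in region.orfs if o.category == "tail"))
        assert {"baseplate_or_fiber", "tail_tape_measure", "tail_sheath"} <= traits

    def test_poor_completeness_regions(self):
        assert COMPLETENESS["phi7"] < 60
        assert COMPLETENESS["phi9"] < 60

    def test_phi4_size_discrepancy_is_recorded(self):
        printed, implied = SIZE_DISCREPANCIES["phi4"]
        row = next(r for r in TABLE1 if r[0] == "phi4")
        assert row[3] == printed
        assert region_length(row[1], row[2]) == implied == PHI4_COORDINATE_SIZE

    def test_fixture_bundle_writes_readable_tables(self, lm41_files):
        from prophagekit import io as pio

        chromosome = pio.read_chromosome(lm41_files["feature_table"])
        assert len(chromosome.regions) == 23  # 15 prophages + 8 decoy clusters
        assert len(pio.read_promoters(lm41_files["promoters"])) > 0
        assert pio.read_completeness(lm41_files["completeness"])["phi13b"] == 49.4
        assert len(pio.read_hits(lm41_files["hits"])) == 29
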