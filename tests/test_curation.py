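"""Curation stage: hit merging, module profiling, defect detection,
categorization and mosaic delineation."""

import pytest
from hypothesis import given, settings, strategies as st

from prophagekit.curation import (
    CandidateHit,
    ContractError,
    assign_modules,
    categorize,
    confirm_phage,
    delineate_mosaic,
    detect_defects,
    merge_hits,
)
from prophagekit.model import Category, Orf, ProphageRegion, Strand
from prophagekit.synthetic import (
    ArchitectureSpec,
    PhageSpec,
    generate_chromosome,
)


def brute_force_union(intervals, max_gap):
    """Independent O(n^2) oracle: merge any two mergeable intervals until
    a fixed point is reached."""
    work = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                if a[0] - b[1] - 1 <= max_gap and b[0] - a[1] - 1 <= max_gap:
                    work[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del work[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in work)


def _hits(pairs):
    return [CandidateHit("chr", s, e) for s, e in pairs]


class TestMergeHits:
    def test_overlap_union(self):
        merged = merge_hits(_hits([(100, 500), (450, 900)]), max_gap=0)
        assert [(h.start, h.end) for h in merged] == [(100, 900)]

    def test_gap_larger_than_max_gap_keeps_hits_apart(self):
        merged = merge_hits(_hits([(100, 500), (700, 900)]), max_gap=100)
        assert [(h.start, h.end) for h in merged] == [(100, 500), (700, 900)]

    def test_adjacent_within_gap_merges(self):
        merged = merge_hits(_hits([(100, 500), (700, 900)]), max_gap=199)
        assert [(h.start, h.end) for h in merged] == [(100, 900)]

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_hits(_hits([(1, 2)]), max_gap=-1)

    def test_idempotent(self):
        hits = _hits([(1, 50), (40, 120), (300, 400), (390, 500)])
        once = merge_hits(hits, max_gap=10)
        assert merge_hits(once, max_gap=10) == once

    @given(
        st.lists(
            st.tuples(st.integers(1, 5000), st.integers(0, 400)).map(
                lambda p: (p[0], p[0] + p[1])
            ),
            min_size=0,
            max_size=50,
        ),
        st.integers(0, 300),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_oracle(self, pairs, max_gap):
        merged = merge_hits(_hits(pairs), max_gap=max_gap)
        assert [(h.start, h.end) for h in merged] == brute_force_union(pairs, max_gap)


class TestModuleProfile:
    def test_full_prophage_has_all_five_modules(self, lm41_confirmed):
        profile = assign_modules(lm41_confirmed["phi1"].region)
        assert profile.modules_present == (
            "lysogeny_control", "dna_replication", "packaging_capsid", "tail", "lysis",
        )

    def test_remnant_retains_only_early_modules(self, lm41_confirmed):
        profile = assign_modules(lm41_confirmed["phi7"].region)
        assert profile.modules_present == ("lysogeny_control", "dna_replication")

    def test_uncharacterized_orfs_give_empty_profile(self):
        orfs = [
            Orf(f"o{i}", 1 + i * 500, 400 + i * 500, Strand.FORWARD, "unknown")
            for i in range(10)
        ]
        region = ProphageRegion(name="r", chrom="c", start=1, end=6000, orfs=orfs)
        profile = assign_modules(region)
        assert profile.modules_present == ()
        assert not confirm_phage(profile)

    def test_single_module_confirms_a_remnant(self, lm41_confirmed):
        assert confirm_phage(assign_modules(lm41_confirmed["phi7"].region))


class TestDetectDefects:
    def test_truncated_integrase_and_missing_packaging(self, lm41_confirmed):
        kinds = {d.kind for d in detect_defects(lm41_confirmed["phi5"].region)}
        assert kinds == {"truncated_integrase", "missing_terminase_or_portal"}

    def test_truncation_evidence_names_the_fragments(self, lm41_confirmed):
        defects = {d.kind: d for d in detect_defects(lm41_confirmed["phi5"].region)}
        assert set(defects["truncated_integrase"].evidence) == {"orf6", "orf7"}

    def test_split_integrase_from_adjacent_fragments(self, lm41_confirmed):
        kinds = {d.kind for d in detect_defects(lm41_confirmed["phi3"].region)}
        assert kinds == {"split_integrase"}

    def test_intron_split_replication_gene(self, lm41_confirmed):
        kinds = {d.kind for d in detect_defects(lm41_confirmed["phi6"].region)}
        assert kinds == {"intron_split_gene"}

    def test_misoriented_late_orf(self, lm41_confirmed):
        defects = {d.kind: d for d in detect_defects(lm41_confirmed["phi12"].region)}
        assert set(defects) == {"misoriented_late_orf"}
        assert defects["misoriented_late_orf"].evidence == ("orf78",)

    def test_defect_free_synthetic_region_is_clean(self):
        spec = ArchitectureSpec(prophages=(PhageSpec(name="p"),))
        generated = generate_chromosome(spec, seed=3)
        region = generated.chromosome.region("p")
        assert detect_defects(region) == frozenset()

    def test_mosaic_flag_from_repeated_clusters(self, lm41_confirmed):
        kinds = {d.kind for d in detect_defects(lm41_confirmed["phi13"].region)}
        assert kinds == {"mosaic_region"}


class TestCategorize:
    @pytest.mark.parametrize(
        "completeness,defects,expected",
        [
            (100.0, frozenset(), Category.FUNCTIONAL),
            (100.0, frozenset({"x"}), Category.UNKNOWN),
            (99.65, frozenset(), Category.UNKNOWN),
            (75.0, frozenset(), Category.UNKNOWN),
            (60.0, frozenset(), Category.DEFECTIVE),  # boundary resolves low
            (49.4, frozenset(), Category.DEFECTIVE),
            (18.8, frozenset(), Category.DEFECTIVE),
            (None, frozenset(), Category.UNCLASSIFIED),
        ],
    )
    def test_threshold_bands(self, completeness, defects, expected):
        assert categorize(completeness, defects) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            categorize(101.0)

    @given(
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
        st.booleans(),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_completeness_and_defects(self, a, b, with_defect):
        # lowering completeness never promotes a region; adding a defect
        # never yields functional
        lo, hi = sorted((a, b))
        order = {
            Category.DEFECTIVE: 0,
            Category.UNKNOWN: 1,
            Category.FUNCTIONAL: 2,
        }
        defects = frozenset({"x"}) if with_defect else frozenset()
        assert order[categorize(lo, defects)] <= order[categorize(hi, defects)]
        assert categorize(hi, frozenset({"x"})) != Category.FUNCTIONAL


class TestDelineateMosaic:
    def test_study_mosaic_splits_into_five_named_subregions(self, lm41_confirmed):
        subs = delineate_mosaic(lm41_confirmed["phi13"].region)
        assert [s.name for s in subs] == [
            "phi13a", "phi13b", "phi13c", "phi13d", "phi13e",
        ]
        assert [(s.start, s.end) for s in subs] == [
            (6632999, 6684039),
            (6684149, 6706426),
            (6706413, 6714990),
            (6715266, 6749468),
            (6750116, 6769447),
        ]

    def test_subregions_partition_their_orfs(self, lm41_confirmed):
        region = lm41_confirmed["phi13"].region
        subs = delineate_mosaic(region)
        ids = [o.id for s in subs for o in s.orfs]
        assert len(ids) == len(set(ids)) == len(region.orfs)

    def test_tandem_synthetic_mosaic_recovers_planted_boundaries(self):
        spec = ArchitectureSpec(
            prophages=(
                PhageSpec(
                    name="mosaic", defects=frozenset({"mosaic_region"}),
                    morphology="myovirus",
                ),
            )
        )
        generated = generate_chromosome(spec, seed=5)
        subs = delineate_mosaic(generated.chromosome.region("mosaic"))
        bounds = tuple(sorted((s.start, s.end) for s in subs))
        assert bounds == generated.truth.regions["mosaic"].sub_boundaries

    def test_no_closer_fallback_places_boundary_before_opener(self):
        # two replication-cluster remnants with no tail/recombinase closers:
        # the first sub-region must end on the ORF preceding the second opener
        orfs = []
        pos = 1
        for i in range(40):
            if i in (0, 1, 36, 37):
                category = "replication"
            else:
                category = "unknown"
            orfs.append(
                Orf(f"o{i}", pos, pos + 300, Strand.FORWARD, category)
            )
            pos += 400
        region = ProphageRegion(
            name="m", chrom="c", start=1, end=pos + 500, orfs=orfs
        )
        subs = delineate_mosaic(region)
        assert len(subs) == 2
        assert subs[0].orfs[-1].id == "o35"
        assert subs[1].orfs[0].id == "o36"

    def test_contract_error_on_non_mosaic_region(self, lm41_confirmed):
        with pytest.raises(ContractError):
            delineate_mosaic(lm41_confirmed["phi1"].region)
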