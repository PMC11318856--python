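"""Core data model: interval arithmetic, canonical orientation, validation."""

import pytest
from hypothesis import given, settings, strategies as st

from prophagekit.model import (
    InvalidIntervalError,
    Orf,
    PromoterCall,
    ProphageRegion,
    Strand,
    canonicalize_orientation,
    filter_promoters,
    mirror_promoters,
    region_length,
)


class TestRegionLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (194517, 235362, 40846),  # a published prophage span
            (6632999, 6769447, 136449),  # the mosaic region span
            (5, 5, 1),  # single-base interval
            (1, 10, 10),
        ],
    )
    def test_inclusive_convention(self, start, end, expected):
        assert region_length(start, end) == expected

    @pytest.mark.parametrize("start,end", [(10, 5), (0, 5), (-3, 2), (5, 0)])
    def test_degenerate_intervals_raise(self, start, end):
        with pytest.raises(InvalidIntervalError):
            region_length(start, end)

    @given(st.integers(1, 10**9), st.integers(0, 10**6))
    @settings(derandomize=True, max_examples=100)
    def test_length_matches_point_count(self, start, width):
        assert region_length(start, start + width) == width + 1


def _toy_region(strand=Strand.REVERSE):
    orfs = [
        Orf("a", 100, 400, Strand.FORWARD, "integration_excision"),
        Orf("b", 500, 700, Strand.REVERSE, "transcription_regulation"),
        Orf("c", 800, 950, Strand.FORWARD, "tail"),
    ]
    return ProphageRegion(
        name="toy", chrom="chr", start=100, end=1000,
        packaging_strand=strand, orfs=orfs,
    )


class TestCanonicalizeOrientation:
    def test_forward_region_is_identity(self):
        region = _toy_region(Strand.FORWARD)
        assert canonicalize_orientation(region) is region

    def test_reverse_region_mirrors_orfs(self):
        # brute-force mirror of the toy list: coordinates reflect within the
        # span, strands flip, order reverses
        canon = canonicalize_orientation(_toy_region())
        lo, hi = 100, 1000
        assert [o.id for o in canon.orfs] == ["c", "b", "a"]
        assert (canon.orfs[0].start, canon.orfs[0].end) == (lo + hi - 950, lo + hi - 800)
        assert canon.orfs[0].strand is Strand.REVERSE
        assert canon.orfs[2].strand is Strand.REVERSE
        assert canon.orfs[1].strand is Strand.FORWARD

    def test_idempotent_and_span_preserving(self):
        region = _toy_region()
        once = canonicalize_orientation(region)
        twice = canonicalize_orientation(once)
        assert once == twice
        assert (once.start, once.end) == (region.start, region.end)

    def test_promoters_mirror_with_region(self):
        region = _toy_region()
        proms = [PromoterCall(position=450, strand=Strand.REVERSE, score=0.9)]
        mirrored = mirror_promoters(proms, region)
        assert mirrored[0].position == 100 + 1000 - 450
        assert mirrored[0].strand is Strand.FORWARD


class TestValidation:
    def test_trait_forces_category(self):
        with pytest.raises(ValueError, match="requires category tail"):
            Orf("x", 1, 300, Strand.FORWARD, "replication",
                traits=frozenset({"tail_sheath"}))

    def test_orf_outside_region_rejected(self):
        orf = Orf("x", 1, 300, Strand.FORWARD)
        with pytest.raises(InvalidIntervalError):
            ProphageRegion(name="r", chrom="c", start=100, end=500, orfs=[orf])

    def test_promoter_score_bounds(self):
        with pytest.raises(ValueError):
            PromoterCall(position=10, strand=Strand.FORWARD, score=1.2)

    def test_promoter_score_filter(self):
        calls = [
            PromoterCall(position=10, strand=Strand.FORWARD, score=s)
            for s in (0.5, 0.86, 0.87, 0.99)
        ]
        kept = filter_promoters(calls)
        assert [p.score for p in kept] == [0.87, 0.99]

    def test_orfs_sorted_by_start_then_end_then_id(self):
        orfs = [
            Orf("b", 200, 400, Strand.FORWARD),
            Orf("a", 200, 400, Strand.FORWARD),
            Orf("c", 100, 150, Strand.FORWARD),
        ]
        region = ProphageRegion(name="r", chrom="c", start=1, end=500, orfs=orfs)
        assert [o.id for o in region.orfs] == ["c", "a", "b"]
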