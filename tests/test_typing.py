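"""Morphology and lysogeny-switch typing."""

import dataclasses

import pytest

from prophagekit.curation import ContractError, delineate_mosaic
from prophagekit.model import Orf, PromoterCall, ProphageRegion, Strand
from prophagekit.phage_typing import (
    MorphologyCall,
    call_lysogeny,
    call_morphology,
    promoter_pair_geometry,
)


class TestMorphology:
    def test_sheath_takes_precedence(self, lm41_confirmed):
        # tape measure and baseplate genes are also present; the sheath wins
        call = call_morphology(lm41_confirmed["phi3"].region)
        assert call.morphology == "myovirus"
        assert call.evidence == ("orf55",)

    def test_baseplate_only_is_podovirus(self, lm41_confirmed):
        call = call_morphology(lm41_confirmed["phi1"].region)
        assert call.morphology == "podovirus"
        assert call.evidence == ("orf61",)

    def test_tape_measure_without_sheath_is_siphovirus(self, lm41_confirmed):
        call = call_morphology(lm41_confirmed["phi2"].region)
        assert call.morphology == "siphovirus"
        assert set(call.evidence) == {"orf65", "orf66"}

    def test_no_tail_genes_is_untyped(self, lm41_confirmed):
        call = call_morphology(lm41_confirmed["phi7"].region)
        assert call.morphology == "untyped"
        assert call.evidence == ()

    def test_untyped_call_rejects_evidence(self):
        with pytest.raises(ValueError):
            MorphologyCall(morphology="untyped", evidence=("x",))


def _prom(pos, strand, score=0.9):
    return PromoterCall(position=pos, strand=Strand(strand), score=score)


class TestPromoterGeometry:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [("-", "+", "divergent"), ("+", "-", "convergent"), ("+", "+", "tandem"),
         ("-", "-", "tandem")],
    )
    def test_strand_patterns(self, s1, s2, expected):
        assert promoter_pair_geometry(_prom(100, s1), _prom(200, s2)) == expected

    def test_unordered_pair_is_contract_error(self):
        with pytest.raises(ContractError):
            promoter_pair_geometry(_prom(200, "-"), _prom(100, "+"))

    def test_unfiltered_scores_are_contract_error(self):
        with pytest.raises(ContractError):
            promoter_pair_geometry(_prom(100, "-", 0.5), _prom(200, "+"))


class TestLysogeny:
    def test_immr_imma_with_divergent_promoters(self, lm41_confirmed, lm41_promoters):
        region = lm41_confirmed["phi2"].region
        call = call_lysogeny(
            region, [p for p in lm41_promoters if p.region == "phi2"]
        )
        assert call.system == "immr_imma"
        assert call.promoter_geometry == "divergent"
        assert call.repressor_orf == "orf5"

    def test_immr_imma_with_convergent_promoters(self, lm41_confirmed, lm41_promoters):
        region = lm41_confirmed["phi12"].region
        call = call_lysogeny(
            region, [p for p in lm41_promoters if p.region == "phi12"]
        )
        assert call.system == "immr_imma"
        assert call.promoter_geometry == "convergent"

    def test_c_ner_in_mu_type_subregion(self, lm41_confirmed, lm41_promoters):
        subs = {s.name: s for s in delineate_mosaic(lm41_confirmed["phi13"].region)}
        proms = [p for p in lm41_promoters if p.region == "phi13"]
        call = subs and call_lysogeny(subs["phi13d"], proms)
        assert call.system == "c_ner"
        assert call.repressor_orf == "orf129"
        assert call.partner_orf == "orf139"

    def test_ci_cro_called_without_promoter_data(self, lm41_confirmed):
        # promoters lend support but do not gate the call
        call = call_lysogeny(lm41_confirmed["phi1"].region, [])
        assert call.system == "ci_cro"
        assert call.promoter_geometry == "none"

    def test_region_without_hth_is_undetermined(self):
        orfs = [
            Orf("o1", 100, 400, Strand.FORWARD, "integration_excision",
                traits=frozenset({"integrase"}), length_aa=385),
            Orf("o2", 500, 700, Strand.FORWARD, "replication"),
        ]
        region = ProphageRegion(name="r", chrom="c", start=1, end=1000, orfs=orfs)
        call = call_lysogeny(region, [])
        assert call.system == "undetermined"
        assert call.repressor_orf is None

    def test_unrelated_orfs_outside_lysogeny_span_do_not_change_call(
        self, lm41_confirmed, lm41_promoters
    ):
        region = lm41_confirmed["phi1"].region
        proms = [p for p in lm41_promoters if p.region == "phi1"]
        before = call_lysogeny(region, proms)
        extra = Orf(
            "extra", region.end - 400, region.end - 100, Strand.REVERSE,
            "moron_accessory", traits=frozenset({"haemolysin"}), length_aa=100,
        )
        widened = dataclasses.replace(region, orfs=list(region.orfs) + [extra])
        assert call_lysogeny(widened, proms) == before

    def test_every_region_yields_exactly_one_call(self, lm41_confirmed, lm41_promoters):
        for name, rec in lm41_confirmed.items():
            call = call_lysogeny(
                rec.region, [p for p in lm41_promoters if p.region == name]
            )
            assert call.system in ("ci_cro", "immr_imma", "c_ner", "undetermined")
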