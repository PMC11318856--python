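"""DNase-protection qPCR quantification."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from prophagekit.lm41 import build_qpcr_panel
from prophagekit.qpcr import (
    QpcrPanel,
    QpcrTarget,
    aggregate_cq,
    delta_cq,
    detection_call,
    fold_change,
    read_cq_csv,
    write_cq_csv,
)


class TestAggregate:
    @pytest.mark.parametrize(
        "replicates,expected",
        [([20, 21, 22], 21.0), ([30, None], 35.0), ([17.3], 17.3)],
    )
    def test_mean_with_cap_imputation(self, replicates, expected):
        assert aggregate_cq(replicates, cq_cap=40.0) == pytest.approx(expected)

    def test_nan_treated_as_non_amplifying(self):
        assert aggregate_cq([30.0, float("nan")], cq_cap=40.0) == pytest.approx(35.0)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cq([])


class TestDeltaAndFold:
    def test_delta_is_treated_minus_untreated(self):
        assert delta_cq(30.0, 25.0) == pytest.approx(5.0)
        assert delta_cq(12.5, 12.5) == 0.0

    @pytest.mark.parametrize(
        "target,housekeeper,expected",
        [(5.0, 5.0, 1.0), (5.0, 8.0, 8.0), (8.0, 5.0, 0.125)],
    )
    def test_fold_change_examples(self, target, housekeeper, expected):
        assert fold_change(target, housekeeper) == pytest.approx(expected)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(derandomize=True, max_examples=200)
    def test_reciprocal_symmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-12)


class TestDetection:
    def test_signal_below_ntc_floor_detected(self):
        assert detection_call(28.0, 35.0)

    def test_signal_at_or_above_ntc_not_detected(self):
        assert not detection_call(36.0, 35.0)
        assert not detection_call(35.0, 35.0)

    def test_missing_ntc_is_never_detected(self):
        assert not detection_call(20.0, None)


class TestStudyPanel:
    def test_housekeeper_fully_degraded(self):
        results = build_qpcr_panel().analyze()
        assert results["s10p"].fully_degraded
        assert not results["s10p"].detected

    def test_all_phage_targets_detected_except_the_silent_one(self):
        results = build_qpcr_panel().analyze()
        undetected = {
            name for name, r in results.items()
            if name != "s10p" and not r.detected
        }
        assert undetected == {"phi13e"}

    def test_delta_cq_ordering_of_released_phages(self):
        results = build_qpcr_panel().analyze()
        d = {n: r.delta_cq for n, r in results.items()}
        assert d["phi1"] < d["phi4"] < d["phi2"] < d["phi10"]
        assert d["phi1"] == pytest.approx(5.11, abs=1e-9)
        others = [v for n, v in d.items() if n not in
                  ("s10p", "phi1", "phi2", "phi4", "phi10")]
        assert min(others) > d["phi10"]

    def test_fold_change_ranking_puts_most_released_first(self):
        panel = build_qpcr_panel()
        ranking = panel.release_ranking()
        assert ranking[0] == "phi1"
        # ranking by fold change is the inverse of ranking by delta-Cq when
        # the housekeeper is shared
        results = panel.analyze()
        by_delta = sorted(
            (n for n in results if n != "s10p"), key=lambda n: results[n].delta_cq
        )
        assert ranking == by_delta

    def test_pipeline_scale_invariant_to_global_cq_shift(self):
        panel = build_qpcr_panel()
        shifted = QpcrPanel(
            targets={
                n: QpcrTarget(
                    name=n,
                    treated_cq=[None if c is None else c + 1.5 for c in t.treated_cq],
                    untreated_cq=[c + 1.5 for c in t.untreated_cq],
                    ntc_cq=t.ntc_cq,
                )
                for n, t in panel.targets.items()
                if n != "phi13e"  # capped wells do not shift
            },
            housekeeper="s10p",
        )
        base = panel.analyze()
        moved = shifted.analyze()
        for name, r in moved.items():
            assert r.fold_change == pytest.approx(base[name].fold_change, rel=1e-9)

    def test_replicate_csv_round_trip(self, tmp_path):
        panel = build_qpcr_panel()
        path = tmp_path / "cq.csv"
        write_cq_csv(panel, path)
        back = read_cq_csv(path)
        base, again = panel.analyze(), back.analyze()
        assert set(base) == set(again)
        for name in base:
            assert again[name].fold_change == pytest.approx(
                base[name].fold_change, rel=1e-12
            )
            assert again[name].detected == base[name].detected

    def test_out_of_range_cq_rejected(self):
        with pytest.raises(ValueError):
            QpcrPanel(
                targets={
                    "s10p": QpcrTarget("s10p", [45.0], [20.0], 35.0),
                },
                housekeeper="s10p",
            )
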