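import math

import numpy as np
import pytest

from ripdecay.decay import (
    Construct,
    ConstructPanel,
    DecaySeries,
    Edit,
    call_elements,
    element_spacing,
    fit_halflife,
    make_scanning_panel,
    normalize_series,
)
from ripdecay.simulate import simulate_decay_panel


def geometric_series(t_half, times, construct="c", pool="p1", scale=100.0):
    return DecaySeries(
        construct, pool, [(t, scale * 2 ** (-t / t_half)) for t in times]
    )


class TestNormalizeSeries:
    def test_reference_normalization_and_t0_shift(self):
        s = normalize_series("c", "p", [8, 68], target=[10, 5], reference=[1, 1])
        assert s.points == [(0.0, 100.0), (60.0, 50.0)]

    def test_constant_ratio_gives_flat_series(self):
        s = normalize_series("c", "p", [0, 60, 120], [4, 2, 1], [8, 4, 2])
        assert all(a == pytest.approx(100.0) for a in s.abundances)

    def test_reference_rescaling_cancels(self):
        a = normalize_series("c", "p", [0, 60], [10, 5], [2, 2])
        b = normalize_series("c", "p", [0, 60], [10, 5], [4, 4])
        assert a.points == b.points

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_series("c", "p", [0, 60], [10, 5], [1, 0])


class TestFitHalflife:
    def test_exact_geometric_decay(self):
        s = DecaySeries("c", "p", [(0, 100), (60, 50), (120, 25)])
        res = fit_halflife(s)
        assert res.t_half == pytest.approx(60.0, abs=1e-9)
        assert res.slope == pytest.approx(-math.log(2) / 60)
        assert res.ci95_low <= res.t_half <= res.ci95_high

    def test_rising_series_flagged_stable(self):
        s = DecaySeries("c", "p", [(0, 100), (60, 110)])
        res = fit_halflife(s)
        assert math.isinf(res.t_half) and res.stable

    def test_noise_free_recovery_is_exact(self):
        for t_half in (20.0, 60.0, 400.0):
            series = [
                geometric_series(t_half, [0, 60, 120], pool=f"p{i}") for i in range(3)
            ]
            assert fit_halflife(series).t_half == pytest.approx(t_half, abs=1e-6)

    def test_invariance_to_rescaling_and_pool_relabeling(self):
        series = [geometric_series(90, [0, 45, 90], pool="a", scale=100)]
        scaled = [geometric_series(90, [0, 45, 90], pool="zzz", scale=7.3)]
        assert fit_halflife(series).t_half == pytest.approx(fit_halflife(scaled).t_half)

    def test_pooled_equals_per_pool_on_identical_pools(self):
        series = [geometric_series(75, [0, 60, 120], pool=f"p{i}") for i in range(3)]
        pooled = fit_halflife(series, method="pooled")
        per_pool = fit_halflife(series, method="per_pool")
        assert pooled.t_half == pytest.approx(per_pool.t_half)

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_halflife(DecaySeries("c", "p", [(0, 100), (60, 0.0)]))

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            DecaySeries("c", "p", [(0, 100), (0, 90)])

    def test_ci_coverage_under_noise(self):
        panel = make_scanning_panel("utr", 100, 1, 0)
        contrib = math.log(2) / 60 - math.log(2) / 400
        covered = 0
        for seed in range(100):
            series, _ = simulate_decay_panel(
                400, [((1, 15), contrib)], panel, [0, 60, 120],
                n_pools=3, noise_cv=0.1, seed=seed,
            )
            res = fit_halflife(series)
            covered += res.ci95_low <= 60 <= res.ci95_high
        assert covered >= 85  # nominal 95%


class TestAdditiveRates:
    def test_rate_additivity_identity(self):
        # 1/t(full) - 1/t(del el1) - 1/t(del el2) + 1/t(del both) == 0
        constructs = [
            Construct("full", "utr", []),
            Construct("del1", "utr", [Edit("delete", 1, 15)]),
            Construct("del2", "utr", [Edit("delete", 16, 30)]),
            Construct("delboth", "utr", [Edit("delete", 1, 30)]),
        ]
        panel = ConstructPanel("utr", 100, constructs)
        elements = [((1, 15), 0.003), ((16, 30), 0.005)]
        _, truth = simulate_decay_panel(
            400, elements, panel, [0, 60, 120], n_pools=1, noise_cv=0.0, seed=0
        )
        inv = 1 / truth["t_half"]
        combo = inv["full"] - inv["del1"] - inv["del2"] + inv["delboth"]
        assert combo == pytest.approx(0.0, abs=1e-12)


class TestCallElements:
    @staticmethod
    def _series_by_construct(series):
        out = {}
        for s in series:
            out.setdefault(s.construct_id, []).append(s)
        return out

    def test_identical_mutant_is_no_effect(self):
        wt = [geometric_series(60, [0, 60, 120], "wt", f"p{i}") for i in range(3)]
        mut = [geometric_series(60, [0, 60, 120], "scan_1_15", f"p{i}") for i in range(3)]
        panel = make_scanning_panel("utr", 100, 1, 1)
        calls = call_elements(wt, {"scan_1_15": mut}, panel)
        assert calls[0].verdict == "no_effect"
        assert calls[0].p == pytest.approx(1.0)

    def test_planted_elements_called_and_adjacent_scans_merged(self):
        # one element spanning two adjacent 15-base scans: both significant,
        # merged into a single 30-base call
        panel = make_scanning_panel("utr", 150, 1, 6)
        elements = [((16, 45), 0.008)]  # covers scans 16-30 and 31-45
        series, _ = simulate_decay_panel(
            400, elements, panel, [0, 60, 120], n_pools=3, noise_cv=0.05, seed=4
        )
        grouped = self._series_by_construct(series)
        wt = grouped.pop("wt")
        calls = call_elements(wt, grouped, panel, alpha=0.05)
        sig = [c for c in calls if c.verdict == "instability_element"]
        assert len(sig) == 1
        assert sig[0].interval == (16, 45)
        assert sorted(sig[0].construct_ids) == ["scan_16_30", "scan_31_45"]

    def test_ci_overlap_method_calls_strong_element(self):
        panel = make_scanning_panel("utr", 150, 1, 2)
        elements = [((1, 15), 0.009)]
        series, _ = simulate_decay_panel(
            400, elements, panel, [0, 60, 120], n_pools=3, noise_cv=0.03, seed=1
        )
        grouped = self._series_by_construct(series)
        wt = grouped.pop("wt")
        calls = call_elements(wt, grouped, panel, stat_method="ci_overlap")
        by_interval = {c.interval: c.verdict for c in calls}
        assert by_interval[(1, 15)] == "instability_element"
        assert by_interval[(16, 30)] == "no_effect"

    def test_single_pool_rejected(self):
        wt = [geometric_series(60, [0, 60], "wt", "p1")]
        mut = [geometric_series(60, [0, 60], "scan_1_15", "p1")]
        panel = make_scanning_panel("utr", 100, 1, 1)
        with pytest.raises(ValueError, match="pools"):
            call_elements(wt, {"scan_1_15": mut}, panel)


class TestElementSpacing:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1584, 1613), (1644, 1658), 30),
            ((2946, 2990), (3051, 3080), 60),
            ((1, 10), (11, 20), 0),
        ],
    )
    def test_intervening_bases(self, a, b, expected):
        assert element_spacing(a, b) == expected
        assert element_spacing(b, a) == expected

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            element_spacing((1, 10), (10, 20))
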