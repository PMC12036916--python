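import numpy as np
import pytest
from scipy.optimize import brentq

from pestgame import (
    IdenticalValuesError,
    Mode,
    Player,
    comparative_statics,
    compare_modes,
    crossover_gain,
    dominance_region,
    reduce_mode,
    solve_value,
    value_table,
)


def _mode_value(player, params, mode, b, x=1.0):
    p = reduce_mode(mode, player, params)
    return solve_value(p, b, x, params).value


def _bisect_crossover(player, params, mode_x, mode_y, lo, hi, x=1.0):
    """Independent root-finder on the value difference."""
    f = lambda b: _mode_value(player, params, mode_x, b, x) - _mode_value(
        player, params, mode_y, b, x
    )
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-15)


class TestCompareModes:
    def test_high_cost_low_gain_government_prefers_resource_sharing(self, baseline_c4):
        result = compare_modes(Player.GOVERNMENT, baseline_c4, b=0.0, x=1.0)
        assert result.best_mode == Mode.S
        values = {mv.mode: mv.value for mv in result.ranking}
        assert values[Mode.S] == pytest.approx(-9.298, abs=5e-4)
        assert values[Mode.A] == pytest.approx(-9.556, abs=5e-4)
        assert values[Mode.I] == pytest.approx(-10.632, abs=5e-4)

    def test_low_cost_high_gain_government_prefers_information(self, baseline_c2):
        result = compare_modes(Player.GOVERNMENT, baseline_c2, b=5.0, x=1.0)
        assert result.best_mode == Mode.I

    def test_enterprise_zero_gain_tie_between_a_and_s(self, baseline_c2):
        result = compare_modes(Player.ENTERPRISE, baseline_c2, b=0.0, x=1.0)
        assert result.ranking[0].mode == Mode.I
        assert frozenset({Mode.A, Mode.S}) in result.ties

    def test_ranking_sorted_descending(self, baseline_c2):
        result = compare_modes(Player.GOVERNMENT, baseline_c2, b=3.0, x=1.0)
        values = [mv.value for mv in result.ranking]
        assert values == sorted(values, reverse=True)


class TestCrossoverGain:
    def test_government_low_cost_a_vs_s(self, baseline_c2):
        roots = crossover_gain(
            Player.GOVERNMENT, baseline_c2, Mode.A, Mode.S, (0.0, 10.0), x=1.0
        )
        assert len(roots) == 1
        assert roots[0].b == pytest.approx(0.0649, abs=5e-4)
        oracle = _bisect_crossover(Player.GOVERNMENT, baseline_c2, Mode.A, Mode.S, 0.01, 1.0)
        assert roots[0].b == pytest.approx(oracle, abs=1e-9)

    def test_government_high_cost_a_vs_s(self, baseline_c4):
        roots = crossover_gain(
            Player.GOVERNMENT, baseline_c4, Mode.A, Mode.S, (0.0, 10.0), x=1.0
        )
        assert len(roots) == 1
        assert roots[0].b == pytest.approx(1.717, abs=5e-4)
        oracle = _bisect_crossover(Player.GOVERNMENT, baseline_c4, Mode.A, Mode.S, 1.0, 3.0)
        assert roots[0].b == pytest.approx(oracle, abs=1e-9)

    def test_enterprise_a_vs_s_root_at_zero(self, baseline_c2):
        # (b+2)^2 = (w*b+2)^2 with w > 1 forces b = 0 on b >= 0
        roots = crossover_gain(
            Player.ENTERPRISE, baseline_c2, Mode.A, Mode.S, (0.0, 10.0), x=1.0
        )
        assert len(roots) == 1
        assert roots[0].b == pytest.approx(0.0, abs=1e-12)

    def test_identical_modes_signalled(self, baseline_c2):
        with pytest.raises(IdenticalValuesError):
            crossover_gain(Player.GOVERNMENT, baseline_c2, Mode.A, Mode.A, (0.0, 10.0))

    def test_negative_interval_rejected(self, baseline_c2):
        with pytest.raises(ValueError):
            crossover_gain(Player.GOVERNMENT, baseline_c2, Mode.A, Mode.S, (-1.0, 5.0))

    def test_roots_outside_interval_filtered(self, baseline_c2):
        roots = crossover_gain(
            Player.GOVERNMENT, baseline_c2, Mode.A, Mode.S, (1.0, 10.0), x=1.0
        )
        assert roots == []


class TestValueTable:
    def test_best_mode_changes_only_at_crossovers(self, baseline_c4):
        b_grid = np.linspace(0.0, 10.0, 201)
        table = value_table(Player.GOVERNMENT, baseline_c4, b_grid, x=1.0)
        changes = [
            (lo, hi)
            for lo, hi in zip(table.itertuples(), table.iloc[1:].itertuples())
            if lo.best_mode != hi.best_mode
        ]
        all_roots = []
        for mx, my in [(Mode.A, Mode.S), (Mode.A, Mode.I), (Mode.S, Mode.I)]:
            all_roots += [
                r.b
                for r in crossover_gain(Player.GOVERNMENT, baseline_c4, mx, my, (0, 10), x=1.0)
            ]
        for lo, hi in changes:
            assert any(lo.b - 1e-9 <= root <= hi.b + 1e-9 for root in all_roots)

    def test_values_match_direct_evaluation(self, baseline_c2):
        table = value_table(Player.ENTERPRISE, baseline_c2, [0.0, 2.5, 7.0], x=1.0)
        for row in table.itertuples():
            for mode, col in [(Mode.A, row.V_A), (Mode.S, row.V_S), (Mode.I, row.V_I)]:
                assert col == pytest.approx(
                    _mode_value(Player.ENTERPRISE, baseline_c2, mode, row.b)
                )


class TestDominanceRegion:
    def test_government_regions_match_printed_conclusions(self, baseline_c2):
        region = dominance_region(
            Player.GOVERNMENT, baseline_c2, b_grid=[0.0, 5.0], c_grid=[2.0, 4.0], x=1.0
        )
        lookup = {(row.b, row.c): row.best_mode for row in region.itertuples()}
        assert lookup[(0.0, 4.0)] == "S"
        assert lookup[(5.0, 2.0)] == "I"

    def test_enterprise_regions_match_printed_conclusions(self, baseline_c2):
        region = dominance_region(
            Player.ENTERPRISE, baseline_c2, b_grid=[0.0, 8.0], c_grid=[2.0], x=1.0
        )
        lookup = {(row.b, row.c): row.best_mode for row in region.itertuples()}
        assert lookup[(0.0, 2.0)] == "I"
        assert lookup[(8.0, 2.0)] == "S"

    def test_grid_order_invariance(self, baseline_c2):
        fwd = dominance_region(
            Player.GOVERNMENT, baseline_c2, b_grid=[0.0, 2.0, 5.0], c_grid=[2.0, 4.0]
        )
        rev = dominance_region(
            Player.GOVERNMENT, baseline_c2, b_grid=[5.0, 2.0, 0.0], c_grid=[4.0, 2.0]
        )
        key = ["b", "c"]
        fwd = fwd.sort_values(key).reset_index(drop=True)
        rev = rev.sort_values(key).reset_index(drop=True)
        assert fwd.equals(rev)


class TestComparativeStatics:
    def test_sharing_reputation_derivative(self, baseline_c2):
        res = comparative_statics(Mode.S, Player.GOVERNMENT, "aS", baseline_c2)
        assert res.depends and res.sign == 1
        assert res.derivative == pytest.approx(0.2)  # l/((c1+cS)(rho+delta))

    def test_information_gain_derivative(self, baseline_c2):
        res = comparative_statics(Mode.I, Player.GOVERNMENT, "bI", baseline_c2)
        assert res.derivative == pytest.approx(0.5)  # 1/c_eff
        res_ent = comparative_statics(Mode.I, Player.ENTERPRISE, "bI", baseline_c2)
        assert res_ent.derivative == pytest.approx(0.5)

    def test_transfer_has_no_effect_on_effort(self, baseline_c2):
        res = comparative_statics(Mode.A, Player.GOVERNMENT, "CO", baseline_c2)
        assert not res.depends
        assert res.derivative == 0.0 and res.sign == 0

    def test_resource_helpfulness_derivative(self, baseline_c2):
        import math

        res = comparative_statics(Mode.S, Player.ENTERPRISE, "betaS", baseline_c2)
        expected = baseline_c2.b2 / (baseline_c2.c2 * (math.e + baseline_c2.betaS))
        assert res.derivative == pytest.approx(expected, rel=1e-9)

    def test_unknown_parameter_rejected(self, baseline_c2):
        with pytest.raises(ValueError, match="unknown parameter"):
            comparative_statics(Mode.A, Player.GOVERNMENT, "zeta", baseline_c2)

    def test_other_players_gain_is_independent(self, baseline_c2):
        res = comparative_statics(Mode.A, Player.GOVERNMENT, "b2", baseline_c2)
        assert not res.depends


class TestDominanceIdentity:
    def test_information_minus_individual_is_affine_and_positive(self, baseline_c2):
        # V_I - V_A for the government at unit cost 2 is 1.1806 + 1.3889*b
        for b in np.linspace(0.0, 10.0, 21):
            diff = _mode_value(Player.GOVERNMENT, baseline_c2, Mode.I, b) - _mode_value(
                Player.GOVERNMENT, baseline_c2, Mode.A, b
            )
            assert diff == pytest.approx(1.18056 + 1.38889 * b, abs=5e-5)
            assert diff > 0
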