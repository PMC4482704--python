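"""Mamdani inference, membership functions and Weighted Usable Area."""

import numpy as np
import pytest

from riverscape import (FuzzySystem, HydraulicGrid, MembershipFunction, Rule,
                        infer_suitability, standardize_wua, wua)

# --- independent dense-grid Mamdani oracle ----------------------------------

def _trap(x, z1, z2, z3, z4):
    if z2 <= x <= z3:
        return 1.0
    if z1 <= x < z2:
        return (x - z1) / (z2 - z1)
    if z3 < x <= z4:
        return (z4 - x) / (z4 - z3)
    return 0.0


def oracle_mamdani(system: FuzzySystem, velocity: float, depth: float,
                   n_grid: int = 20001) -> float:
    """Brute-force Mamdani: dense discretization and direct integration."""
    xs = np.linspace(0.0, 1.0, n_grid)
    agg = np.zeros(n_grid)
    vals = {"velocity": velocity, "depth": depth}
    fired = False
    for rule in system.rules:
        act = min(_trap(vals[v], *system.variables[v][c].to_dict())
                  for v, c in rule.antecedent.items())
        if act > 0:
            fired = True
            out = np.array([_trap(x, *system.output[rule.consequent].to_dict())
                            for x in xs])
            agg = np.maximum(agg, np.minimum(out, act))
    if not fired or agg.sum() == 0:
        return 0.0
    return float(np.trapezoid(agg * xs, xs) / np.trapezoid(agg, xs))


def random_system(rng, n_out=3, n_classes=3):
    def random_classes(hi):
        classes = {}
        for i in range(n_classes):
            z = np.sort(rng.uniform(0, hi, size=4))
            classes[f"c{i}"] = MembershipFunction(*z)
        return classes

    variables = {"velocity": random_classes(2.0), "depth": random_classes(3.0)}
    output = {}
    for i in range(n_out):
        z = np.sort(rng.uniform(0, 1, size=4))
        output[f"o{i}"] = MembershipFunction(*z)
    rules = [Rule({"velocity": f"c{rng.integers(n_classes)}",
                   "depth": f"c{rng.integers(n_classes)}"},
                  f"o{rng.integers(n_out)}")
             for _ in range(int(rng.integers(3, 9)))]
    return FuzzySystem(variables, output, rules)


class TestMembership:
    def test_plateau(self):
        mf = MembershipFunction(0.1, 0.3, 0.6, 0.9)
        assert mf(0.3) == 1.0 and mf(0.45) == 1.0 and mf(0.6) == 1.0

    def test_linear_ramps(self):
        mf = MembershipFunction(0.1, 0.3, 0.6, 0.9)
        assert mf(0.2) == pytest.approx(0.5)
        assert mf(0.75) == pytest.approx(0.5)
        assert mf(0.05) == 0.0 and mf(0.95) == 0.0

    def test_crisp_shoulder_left_closed(self):
        mf = MembershipFunction(0.5, 0.5, 1.0, 1.5)
        assert mf(0.5) == 1.0
        assert mf(0.4999) == 0.0

    def test_breakpoint_ordering_enforced(self):
        with pytest.raises(ValueError):
            MembershipFunction(0.5, 0.3, 0.6, 0.9)


class TestInference:
    def test_single_rule_right_triangle_centroid(self, simple_system):
        s, undefined = infer_suitability(simple_system, 0.5, 0.5)
        assert not undefined
        assert s == pytest.approx(5.0 / 6.0, abs=1e-3)

    def test_no_rule_fires_returns_zero_with_flag(self):
        sys_ = FuzzySystem(
            variables={"velocity": {"fast": MembershipFunction(1, 2, 3, 4)},
                       "depth": {"any": MembershipFunction(0, 0, 10, 10)}},
            output={"high": MembershipFunction(0.5, 1, 1, 1)},
            rules=[Rule({"velocity": "fast", "depth": "any"}, "high")])
        s, undefined = infer_suitability(sys_, 0.1, 0.5)
        assert s == 0.0 and undefined

    def test_two_overlapping_rules_match_oracle(self):
        sys_ = FuzzySystem(
            variables={
                "velocity": {"slow": MembershipFunction(0, 0, 0.2, 0.5),
                             "fast": MembershipFunction(0.2, 0.5, 2, 2)},
                "depth": {"any": MembershipFunction(0, 0, 10, 10)}},
            output={"low": MembershipFunction(0, 0.2, 0.4, 0.6),
                    "high": MembershipFunction(0.4, 0.6, 0.8, 1.0)},
            rules=[Rule({"velocity": "slow", "depth": "any"}, "high"),
                   Rule({"velocity": "fast", "depth": "any"}, "low")])
        v = 0.38  # activations 0.4 and 0.6 on overlapping output sets
        s, _ = infer_suitability(sys_, v, 1.0)
        assert s == pytest.approx(oracle_mamdani(sys_, v, 1.0), abs=1e-3)

    def test_output_bounded_and_rule_order_invariant(self, rng):
        sys_ = random_system(rng)
        shuffled = FuzzySystem(sys_.variables, sys_.output,
                               list(reversed(sys_.rules)))
        for _ in range(20):
            v, d = rng.uniform(0, 2), rng.uniform(0, 3)
            s1, _ = infer_suitability(sys_, v, d)
            s2, _ = infer_suitability(shuffled, v, d)
            assert 0.0 <= s1 <= 1.0
            assert s1 == s2

    def test_random_systems_match_oracle(self, rng):
        for _ in range(10):
            sys_ = random_system(rng)
            v, d = rng.uniform(0, 2), rng.uniform(0, 3)
            s, undefined = infer_suitability(sys_, v, d)
            if not undefined:
                assert s == pytest.approx(oracle_mamdani(sys_, v, d), abs=1e-3)

    def test_continuity_under_velocity_sweep(self, simple_system, rng):
        sys_ = random_system(rng)
        vs = np.linspace(0, 2, 400)
        out = np.array([infer_suitability(sys_, v, 1.0)[0] for v in vs])
        fired = out > 0
        both_fired = fired[:-1] & fired[1:]
        jumps = np.abs(np.diff(out))[both_fired]
        # continuous within the sweep step + centroid resolution
        assert np.all(jumps < 0.08)


class TestWUA:
    def test_uniform_full_suitability(self, simple_system):
        # the single-rule system yields 5/6 on every wet cell
        grid = HydraulicGrid(depth=np.ones((10, 10)),
                             velocity=0.5 * np.ones((10, 10)), cell_area=0.25)
        expected = 100 * (5.0 / 6.0) * 0.25
        assert wua(grid, simple_system) == pytest.approx(expected, abs=0.05)

    def test_all_dry_gives_zero(self, simple_system):
        grid = HydraulicGrid(depth=np.zeros((4, 4)),
                             velocity=np.zeros((4, 4)), cell_area=0.25)
        assert wua(grid, simple_system) == 0.0

    def test_matches_cell_by_cell_oracle(self, rng):
        sys_ = random_system(rng)
        depth = rng.uniform(0, 2, size=(5, 6))
        depth[rng.random((5, 6)) < 0.3] = 0.0
        vel = rng.uniform(0, 1.5, size=(5, 6))
        grid = HydraulicGrid(depth=depth, velocity=vel, cell_area=0.25)
        expected = sum(
            infer_suitability(sys_, grid.velocity[r, c], grid.depth[r, c])[0] * 0.25
            for r in range(5) for c in range(6) if grid.wet[r, c])
        assert wua(grid, sys_) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_cell_area(self, simple_system, rng):
        depth = rng.uniform(0.1, 2, size=(4, 4))
        vel = rng.uniform(0, 1, size=(4, 4))
        w1 = wua(HydraulicGrid(depth, vel, 0.25), simple_system)
        w2 = wua(HydraulicGrid(depth, vel, 1.0), simple_system)
        assert w2 == pytest.approx(4 * w1, rel=1e-12)


class TestStandardizeWUA:
    def test_saturated_months(self):
        res = standardize_wua(np.full(12, 80.0), 80.0)
        assert res.median == pytest.approx(100.0)
        assert res.range_width == pytest.approx(0.0)

    def test_half_share(self):
        res = standardize_wua([50.0] * 12, 100.0)
        assert res.relative[0] == pytest.approx(50.0)

    def test_median_min_against_sorting_oracle(self, rng):
        vals = rng.uniform(5, 90, size=12)
        res = standardize_wua(vals, 100.0)
        srt = np.sort(vals)
        assert res.minimum == pytest.approx(srt[0])
        assert res.median == pytest.approx(0.5 * (srt[5] + srt[6]))

    def test_zero_bankfull_area_rejected(self):
        with pytest.raises(ValueError):
            standardize_wua([1.0] * 12, 0.0)
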