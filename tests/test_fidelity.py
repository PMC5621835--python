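"""Identity-change metric, regressions, bins, fold changes, loss accounting."""

import numpy as np
import pytest

from indeltrace.calling import INTACT
from indeltrace.fidelity import (CATEGORY_INCREASED, CATEGORY_LOST,
                                 CATEGORY_RETAINED, allele_sharing,
                                 fold_change_profile, frequency_bin,
                                 identity_change, lost_recovered_accounting,
                                 pooled_regression, unrecovered_fraction)
from indeltrace.simulate import SimulationConfig, simulate_animal, simulate_regeneration
from indeltrace.targets import synthetic_target

M = 1_000_000.0


def random_composition(rng, k):
    v = rng.dirichlet(np.full(k, 0.5)) * M
    return {f"c{i}": float(x) for i, x in enumerate(v)}


class TestIdentityChange:
    def test_identical_vectors_zero(self):
        v = {"X": 600_000.0, "Y": 400_000.0}
        assert identity_change(v, dict(v)) == 0.0

    def test_disjoint_supports_hundred(self):
        assert identity_change({"X": M}, {"Y": M}) == 100.0

    def test_worked_example(self):
        a = {"X": 600_000.0, "Y": 400_000.0}
        b = {"X": 500_000.0, "Y": 500_000.0}
        assert identity_change(a, b) == pytest.approx(10.0, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            identity_change({"X": M}, {"Y": M / 2})

    def test_metric_axioms_and_padding_on_random_compositions(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            a = random_composition(rng, k)
            b = random_composition(rng, k)
            c = random_composition(rng, k)
            dab = identity_change(a, b)
            assert 0.0 <= dab <= 100.0
            assert dab == identity_change(b, a)                       # symmetry
            assert identity_change(a, a) == 0.0
            # triangle inequality
            assert dab <= identity_change(a, c) + identity_change(c, b) + 1e-9
            # padding invariance: explicit zero classes change nothing
            a_pad = dict(a, ZPAD=0.0)
            b_pad = dict(b, ZPAD=0.0)
            assert identity_change(a_pad, b_pad) == pytest.approx(dab, abs=1e-9)

    def test_intact_exclusion_flag(self):
        a = {INTACT: 500_000.0, "X": 500_000.0}
        b = {INTACT: 400_000.0, "X": 600_000.0}
        full = identity_change(a, b)
        no_intact = identity_change(a, b, include_intact=False)
        assert full == pytest.approx(10.0)
        assert no_intact == pytest.approx(5.0)


class TestPooledRegression:
    def test_perfect_agreement(self):
        x = np.log10(np.arange(1, 30, dtype=float))
        fit = pooled_regression(x, x)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_independent_data_near_zero_r2(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 6, size=1000)
        y = rng.permutation(x)       # permutation oracle: no association
        fit = pooled_regression(x, y)
        assert fit.r2 < 0.02

    def test_both_zero_points_excluded_without_changing_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 2 * x + 1
        fit_plain = pooled_regression(x, y)
        fit_padded = pooled_regression(np.append(x, [0.0] * 5), np.append(y, [0.0] * 5))
        assert fit_padded.n == fit_plain.n == 4
        assert fit_padded.slope == pytest.approx(fit_plain.slope)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pooled_regression([1.0, 2.0], [1.0, 2.0])

    def test_r2_invariant_to_log_base(self):
        rng = np.random.default_rng(3)
        rpm = rng.uniform(0, 1e5, size=(2, 50))
        log10_pairs = np.log10(rpm + 1)
        ln_pairs = np.log(rpm + 1)
        f1 = pooled_regression(log10_pairs[0], log10_pairs[1])
        f2 = pooled_regression(ln_pairs[0], ln_pairs[1])
        assert f1.r2 == pytest.approx(f2.r2, rel=1e-9)


class TestBinsAndFoldChange:
    @pytest.mark.parametrize("rpm,expected", [
        (2_332, "low"), (16_000, "mid"), (65_000, "mid"), (70_000, "high"),
        (0, "low"), (M, "high"),
    ])
    def test_frequency_bins(self, rpm, expected):
        assert frequency_bin(rpm) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            frequency_bin(-1)

    def test_fold_change_categories(self):
        before = {"L": 1000.0, "R": 1000.0, "I": 1000.0, "pad": M - 3000.0}
        after = {"R": 600.0, "I": 3000.0, "pad": M - 3600.0}
        profile = fold_change_profile(before, after)
        cats = dict(zip(profile["allele_name"], profile["category"]))
        assert cats["L"] == CATEGORY_LOST
        assert cats["R"] == CATEGORY_RETAINED     # less than a one-fold decrease
        assert cats["I"] == CATEGORY_INCREASED
        lfc = dict(zip(profile["allele_name"], profile["log10_fold_change"]))
        assert lfc["I"] == pytest.approx(np.log10(3001 / 1001), abs=1e-12)


class TestLostRecovered:
    def test_trivial_recovery_paths(self):
        comps = {
            "primary": {INTACT: M - 300, "A": 100.0, "B": 100.0, "C": 100.0},
            "secondary": {INTACT: M - 100, "C": 100.0},
            "tertiary": {INTACT: M - 100, "A": 100.0},
        }
        acc = lost_recovered_accounting(comps)
        rows = {(r["allele_name"], r["lost_after"]): r for _, r in acc.iterrows()}
        assert rows[("A", "primary->secondary")]["recovered"]
        assert not rows[("B", "primary->secondary")]["recovered"]
        assert unrecovered_fraction(acc, "primary->secondary") == \
            pytest.approx(100.0 / M)

    def test_simulated_loss_rate_matches_generator(self):
        target = synthetic_target(seed=31, name="losstest")
        cfg = SimulationConfig(seed=31, rare_loss_probability=0.5,
                               rare_threshold=1.0, copy_regeneration=True,
                               mean_alleles_per_animal=20, sd_alleles_per_animal=0)
        n_lost = n_total = 0
        for i in range(10):
            truth = simulate_animal(cfg, target, f"a{i}", animal_index=i)
            simulate_regeneration(truth, cfg)
            comps = {c: {k: v * M for k, v in vec.items()}
                     for c, vec in truth.compartments.items()}
            acc = lost_recovered_accounting(comps)
            lost_names = set(acc["allele_name"])
            # bookkeeping: exactly the alleles whose secondary frequency is 0
            for a in truth.alleles:
                sec = truth.compartments["secondary"][a.name]
                pri = truth.compartments["primary"][a.name]
                if pri > 0:
                    n_total += 1
                    assert (sec == 0.0) == (a.name in lost_names)
            n_lost += len(lost_names)
        p_hat = n_lost / n_total
        sigma = np.sqrt(0.5 * 0.5 / n_total)
        assert abs(p_hat - cfg.rare_loss_probability) < 4 * sigma


class TestAlleleSharing:
    def test_counts_per_allele(self):
        presence = {"a1": ["X", "Y"], "a2": ["Y"], "a3": ["Y", "Z"], "a4": []}
        shared = allele_sharing(presence)
        assert shared.to_dict() == {"X": 1, "Y": 3, "Z": 1}

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            allele_sharing({"a1": ["X"]})

    def test_forced_hotspots_are_shared(self):
        target = synthetic_target(seed=32, name="sharetest")
        cfg = SimulationConfig(seed=32, hotspot_fraction=1.0, hotspot_pool_size=3,
                               mean_alleles_per_animal=3, sd_alleles_per_animal=0)
        presence = {}
        for i in range(10):
            truth = simulate_animal(cfg, target, f"a{i}", animal_index=i)
            presence[f"a{i}"] = [a.name for a in truth.alleles]
        shared = allele_sharing(presence)
        assert (shared >= 2).all()
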