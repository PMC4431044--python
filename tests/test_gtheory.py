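"""G-theory variance components and dependability coefficients.

Oracles are written from the definitions: sums of squares by explicit loops
over cells, EMS equations solved by hand, and phi assembled by enumerating
all seven components with their divisors.
"""

import itertools

import numpy as np
import pytest

from qgenie import (DesignError, GStudy, UndefinedStatisticError,
                    ValidationError, estimate_variance_components,
                    inter_user_phi, phi_coefficient, reliability_suite)
from qgenie.gtheory import (RatingArray, VarianceComponents, _anova_3way,
                            estimate_nested_components, nested_phi)


# ---------------------------------------------------------------------------
# definitional oracles
# ---------------------------------------------------------------------------

def crossed_components_oracle(y):
    """Loop-based SS/EMS solution for the crossed p x r x i design."""
    n_p, n_r, n_i = y.shape
    m = y.mean()
    ss = dict.fromkeys(["p", "r", "i", "pr", "pi", "ri", "pri"], 0.0)
    for p in range(n_p):
        ss["p"] += n_r * n_i * (y[p].mean() - m) ** 2
    for r in range(n_r):
        ss["r"] += n_p * n_i * (y[:, r].mean() - m) ** 2
    for i in range(n_i):
        ss["i"] += n_p * n_r * (y[:, :, i].mean() - m) ** 2
    for p, r in itertools.product(range(n_p), range(n_r)):
        ss["pr"] += n_i * (y[p, r].mean() - y[p].mean() - y[:, r].mean() + m) ** 2
    for p, i in itertools.product(range(n_p), range(n_i)):
        ss["pi"] += n_r * (y[p, :, i].mean() - y[p].mean() - y[:, :, i].mean() + m) ** 2
    for r, i in itertools.product(range(n_r), range(n_i)):
        ss["ri"] += n_p * (y[:, r, i].mean() - y[:, r].mean() - y[:, :, i].mean() + m) ** 2
    for p, r, i in itertools.product(range(n_p), range(n_r), range(n_i)):
        ss["pri"] += (y[p, r, i] - y[p, r].mean() - y[p, :, i].mean() - y[:, r, i].mean()
                      + y[p].mean() + y[:, r].mean() + y[:, :, i].mean() - m) ** 2
    ms = {
        "p": ss["p"] / (n_p - 1), "r": ss["r"] / (n_r - 1), "i": ss["i"] / (n_i - 1),
        "pr": ss["pr"] / ((n_p - 1) * (n_r - 1)),
        "pi": ss["pi"] / ((n_p - 1) * (n_i - 1)),
        "ri": ss["ri"] / ((n_r - 1) * (n_i - 1)),
        "pri": ss["pri"] / ((n_p - 1) * (n_r - 1) * (n_i - 1)),
    }
    return {
        "pri_e": ms["pri"],
        "pr": (ms["pr"] - ms["pri"]) / n_i,
        "pi": (ms["pi"] - ms["pri"]) / n_r,
        "ri": (ms["ri"] - ms["pri"]) / n_p,
        "p": (ms["p"] - ms["pr"] - ms["pi"] + ms["pri"]) / (n_r * n_i),
        "r": (ms["r"] - ms["pr"] - ms["ri"] + ms["pri"]) / (n_p * n_i),
        "i": (ms["i"] - ms["pi"] - ms["ri"] + ms["pri"]) / (n_p * n_r),
    }


def phi_enumeration_oracle(comp, random_facets, sizes):
    """Phi assembled by explicitly enumerating all 7 components and divisors."""
    fixed = {"r", "i"} - set(random_facets)
    tau = comp["p"] + sum(comp["p" + f] / sizes[f] for f in fixed)
    delta = 0.0
    for name in ["r", "i", "pr", "pi", "ri", "pri_e"]:
        facets = set(name.replace("_e", "")) - {"p"}
        if not facets & set(random_facets):
            continue
        div = 1.0
        for f in facets:
            div *= sizes[f]
        delta += comp[name] / div
    return tau / (tau + delta)


def nested_components_oracle(y):
    """Loop-based EMS solution for the p x (r:g) design."""
    n_p, n_g, n_r = y.shape
    m = y.mean()
    ss_p = sum(n_g * n_r * (y[p].mean() - m) ** 2 for p in range(n_p))
    ss_g = sum(n_p * n_r * (y[:, g].mean() - m) ** 2 for g in range(n_g))
    ss_pg = sum(n_r * (y[p, g].mean() - y[p].mean() - y[:, g].mean() + m) ** 2
                for p in range(n_p) for g in range(n_g))
    ss_rg = sum(n_p * (y[:, g, r].mean() - y[:, g].mean()) ** 2
                for g in range(n_g) for r in range(n_r))
    ss_res = sum((y[p, g, r] - y[p, g].mean() - y[:, g, r].mean() + y[:, g].mean()) ** 2
                 for p in range(n_p) for g in range(n_g) for r in range(n_r))
    ms_p = ss_p / (n_p - 1)
    ms_g = ss_g / (n_g - 1)
    ms_pg = ss_pg / ((n_p - 1) * (n_g - 1))
    ms_rg = ss_rg / (n_g * (n_r - 1))
    ms_res = ss_res / ((n_p - 1) * n_g * (n_r - 1))
    return {
        "pr_g_e": ms_res,
        "r_g": (ms_rg - ms_res) / n_p,
        "pg": (ms_pg - ms_res) / n_r,
        "g": (ms_g - ms_pg - ms_rg + ms_res) / (n_p * n_r),
        "p": (ms_p - ms_pg) / (n_g * n_r),
    }


def make_vc(**kw):
    base = dict(sigma2_p=0, sigma2_r=0, sigma2_i=0, sigma2_pr=0, sigma2_pi=0,
                sigma2_ri=0, sigma2_pri_e=0)
    base.update(kw)
    return VarianceComponents(**base, design_sizes={"p": 30, "r": 2, "i": 11})


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

class TestCrossedComponents:
    def test_constant_array_all_zero(self):
        vc = estimate_variance_components(np.full((4, 3, 5), 4.0))
        assert all(v == 0 for v in vc.as_dict().values())

    def test_pure_study_effect(self):
        y = np.zeros((3, 2, 2))
        y[0], y[1], y[2] = 1, 4, 7
        vc = estimate_variance_components(y)
        assert vc.sigma2_p > 0
        for name, v in vc.as_dict().items():
            if name != "p":
                assert v == pytest.approx(0, abs=1e-12)

    def test_matches_definitional_oracle(self, rng):
        y = rng.normal(4, 1, size=(5, 3, 4))
        vc = estimate_variance_components(y)
        oracle = crossed_components_oracle(y)
        for name, raw in vc.raw.items():
            assert raw == pytest.approx(oracle[name], abs=1e-10)

    def test_negative_estimates_truncated_and_flagged(self, rng):
        # small arrays routinely drive some raw estimate negative
        for seed in range(30):
            y = np.random.default_rng(seed).normal(size=(3, 2, 2))
            vc = estimate_variance_components(y)
            for name in vc.truncated:
                assert vc.raw[name] < 0
                assert vc.as_dict()[name] == 0.0
            if vc.truncated:
                return
        pytest.fail("no truncation observed across seeds")

    def test_raw_components_reproduce_observed_mean_squares(self, rng):
        """EMS algebra closes: raw components substituted back give the MS."""
        y = rng.normal(size=(6, 4, 3))
        n_p, n_r, n_i = y.shape
        ms = {k: v[0] for k, v in _anova_3way(y).items()}
        c = estimate_variance_components(y).raw
        assert ms["pri_e"] == pytest.approx(c["pri_e"], abs=1e-10)
        assert ms["pr"] == pytest.approx(c["pri_e"] + n_i * c["pr"], abs=1e-10)
        assert ms["p"] == pytest.approx(
            c["pri_e"] + n_i * c["pr"] + n_r * c["pi"] + n_r * n_i * c["p"], abs=1e-10)
        assert ms["r"] == pytest.approx(
            c["pri_e"] + n_i * c["pr"] + n_p * c["ri"] + n_p * n_i * c["r"], abs=1e-10)

    def test_rejects_missing_cells_and_thin_dims(self):
        with pytest.raises(DesignError):
            estimate_variance_components(np.ones((5, 1, 3)))
        y = np.ones((3, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(DesignError):
            RatingArray(y)

    def test_recovery_is_unbiased_over_replicates(self):
        """Mean estimate over replicates within 3 Monte-Carlo SEs of truth."""
        from qgenie.synthetic import DEFAULT_COMPONENTS, SimulationConfig, simulate_ratings

        cfg = SimulationConfig(n_studies=60, n_raters=4, n_items=6, discretize=False)
        n_rep = 120
        estimates = {k: [] for k in DEFAULT_COMPONENTS}
        for rep in range(n_rep):
            arr, truth = simulate_ratings(cfg, seed=10_000 + rep)
            vc = estimate_variance_components(truth["continuous"])
            for k, v in vc.raw.items():
                estimates[k].append(v)
        for k, vals in estimates.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - cfg.components[k]) < 3 * se + 1e-9, k


# ---------------------------------------------------------------------------
# phi coefficients
# ---------------------------------------------------------------------------

class TestPhi:
    def test_error_free_case_is_one(self):
        vc = make_vc(sigma2_p=1.0)
        for random in ({"r"}, {"i"}, {"r", "i"}):
            fixed = {"r", "i"} - random
            assert phi_coefficient(vc, random, fixed) == pytest.approx(1.0)

    def test_direct_substitution_half(self):
        vc = make_vc(sigma2_p=1.0, sigma2_pri_e=1.0)
        assert phi_coefficient(vc, {"r", "i"}, n_prime={"r": 1, "i": 1}) == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            comp = {k: rng.uniform(0, 2) for k in
                    ["p", "r", "i", "pr", "pi", "ri", "pri_e"]}
            vc = make_vc(**{f"sigma2_{k}": v for k, v in comp.items()})
            sizes = {"r": int(rng.integers(1, 6)), "i": int(rng.integers(1, 12))}
            for random in ({"r"}, {"i"}, {"r", "i"}):
                fixed = {"r", "i"} - random
                got = phi_coefficient(vc, random, fixed, sizes)
                assert got == pytest.approx(phi_enumeration_oracle(comp, random, sizes),
                                            abs=1e-12)

    def test_monotone_in_dstudy_sizes(self, rng):
        """More raters or items never reduce dependability (1000 random sets)."""
        for _ in range(1000):
            comp = {f"sigma2_{k}": rng.uniform(0, 2) for k in
                    ["p", "r", "i", "pr", "pi", "ri", "pri_e"]}
            comp["sigma2_p"] = rng.uniform(0.01, 2)
            vc = make_vc(**comp)
            n_r, n_i = rng.integers(1, 10, 2)
            base = phi_coefficient(vc, {"r", "i"}, n_prime={"r": n_r, "i": n_i})
            more_r = phi_coefficient(vc, {"r", "i"}, n_prime={"r": n_r + 3, "i": n_i})
            more_i = phi_coefficient(vc, {"r", "i"}, n_prime={"r": n_r, "i": n_i + 3})
            assert more_r >= base - 1e-12
            assert more_i >= base - 1e-12

    def test_relative_coefficient_at_least_absolute(self, rng):
        for _ in range(200):
            comp = {f"sigma2_{k}": rng.uniform(0, 2) for k in
                    ["p", "r", "i", "pr", "pi", "ri", "pri_e"]}
            comp["sigma2_p"] = rng.uniform(0.01, 2)
            vc = make_vc(**comp)
            for random in ({"r"}, {"i"}, {"r", "i"}):
                fixed = {"r", "i"} - random
                assert (phi_coefficient(vc, random, fixed, relative=True)
                        >= phi_coefficient(vc, random, fixed) - 1e-12)

    def test_zero_everything_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(make_vc(), {"r", "i"})

    def test_facet_partition_enforced(self):
        vc = make_vc(sigma2_p=1)
        with pytest.raises(ValidationError):
            phi_coefficient(vc, {"r"}, {"r"})
        with pytest.raises(ValidationError):
            phi_coefficient(vc, {"r"}, set())

    def test_analytic_phi_recovered_from_simulated_arrays(self):
        """Estimated overall phi tracks the analytic value of the generator."""
        from qgenie.synthetic import SimulationConfig, simulate_ratings

        comp = {"p": 1.0, "r": 0.1, "i": 0.15, "pr": 0.2, "pi": 0.1,
                "ri": 0.05, "pri_e": 0.6}
        cfg = SimulationConfig(n_studies=150, n_raters=4, n_items=8,
                               components=comp, discretize=False)
        truth_vc = make_vc(**{f"sigma2_{k}": v for k, v in comp.items()})
        analytic = phi_coefficient(truth_vc, {"r", "i"}, n_prime={"r": 4, "i": 8})
        errors = []
        for rep in range(40):
            arr, truth = simulate_ratings(cfg, seed=20_000 + rep)
            res = GStudy(truth["continuous"]).fit()
            errors.append(abs(res.overall() - analytic))
        assert np.mean(errors) < 0.05


# ---------------------------------------------------------------------------
# nested design / inter-user reliability
# ---------------------------------------------------------------------------

class TestNested:
    def test_matches_definitional_oracle(self, rng):
        y = rng.normal(40, 5, size=(8, 2, 3))
        vc = estimate_nested_components(y)
        oracle = nested_components_oracle(y)
        for name, raw in vc.raw.items():
            assert raw == pytest.approx(oracle[name], abs=1e-10)

    def test_zero_group_components_reduce_to_pooled_inter_rater(self):
        """With no group effects the nested phi equals the crossed one-facet phi."""
        s2_p, s2_r, s2_e = 1.3, 0.4, 0.7
        n_g, n_r = 2, 2
        from qgenie.gtheory import NestedVarianceComponents

        vc = NestedVarianceComponents(
            sigma2_p=s2_p, sigma2_g=0.0, sigma2_pg=0.0, sigma2_r_g=s2_r,
            sigma2_pr_g_e=s2_e, design_sizes={"p": 30, "g": n_g, "r": n_r})
        pooled = s2_p / (s2_p + s2_r / (n_g * n_r) + s2_e / (n_g * n_r))
        assert nested_phi(vc) == pytest.approx(pooled)

    def test_constant_ratings_undefined(self):
        arr = np.full((5, 4, 3), 4.0)
        with pytest.raises(UndefinedStatisticError):
            inter_user_phi(arr, ["a", "a", "b", "b"])

    def test_unbalanced_groups_rejected(self, rng):
        arr = rng.integers(1, 8, (5, 4, 3)).astype(float)
        with pytest.raises(DesignError):
            inter_user_phi(arr, ["a", "a", "a", "b"])

    def test_seeded_nested_simulation_matches_oracle(self, rng):
        arr = rng.integers(1, 8, (10, 6, 4)).astype(float)
        labels = ["u", "u", "u", "n", "n", "n"]
        got = inter_user_phi(arr, labels)
        totals = arr.sum(axis=2)
        nested = np.stack([totals[:, :3], totals[:, 3:]], axis=1)
        raw = nested_components_oracle(nested)
        c = {k: max(0.0, v) for k, v in raw.items()}
        expected = c["p"] / (c["p"] + c["g"] / 2 + c["pg"] / 2
                             + c["r_g"] / 6 + c["pr_g_e"] / 6)
        assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# reliability suite
# ---------------------------------------------------------------------------

class TestReliabilitySuite:
    def test_large_study_variance_gives_inter_rater_near_one(self):
        from qgenie.synthetic import SimulationConfig, simulate_ratings

        comp = {"p": 5.0, "r": 0.001, "i": 0.01, "pr": 0.001, "pi": 0.01,
                "ri": 0.001, "pri_e": 0.01}
        cfg = SimulationConfig(n_studies=80, n_raters=4, n_items=6,
                               components=comp, discretize=False)
        _, truth = simulate_ratings(cfg, seed=3)
        res = GStudy(truth["continuous"]).fit()
        assert res.inter_rater() > 0.97

    def test_group_with_better_rater_agreement_ranks_higher(self):
        """Groups tuned toward inter-rater dependability 0.74 vs 0.45 keep that order."""
        from qgenie.synthetic import SimulationConfig, simulate_ratings

        common = {"p": 1.0, "i": 0.1, "pi": 0.1, "ri": 0.02, "pri_e": 0.3}
        good = SimulationConfig(n_studies=120, n_raters=2, n_items=11, discretize=False,
                                components={**common, "r": 0.05, "pr": 0.2})
        poor = SimulationConfig(n_studies=120, n_raters=2, n_items=11, discretize=False,
                                components={**common, "r": 0.6, "pr": 1.3})
        _, t_good = simulate_ratings(good, seed=41)
        _, t_poor = simulate_ratings(poor, seed=42)
        suite = reliability_suite({"users": t_good["continuous"],
                                   "nonusers": t_poor["continuous"]})
        assert suite.inter_rater["users"] > suite.inter_rater["nonusers"]
        assert suite.overall["users"] > suite.overall["nonusers"]
        assert suite.inter_user is not None and 0 <= suite.inter_user <= 1

    def test_collapse_path_agrees_when_fixed_facet_is_inert(self):
        from qgenie.synthetic import SimulationConfig, simulate_ratings

        comp = {"p": 1.0, "r": 0.3, "i": 0.0, "pr": 0.4, "pi": 0.0,
                "ri": 0.0, "pri_e": 0.001}
        cfg = SimulationConfig(n_studies=200, n_raters=4, n_items=6,
                               components=comp, discretize=False)
        _, truth = simulate_ratings(cfg, seed=9)
        arrays = {"g": truth["continuous"]}
        mixed = reliability_suite(arrays)
        collapsed = reliability_suite(arrays, collapse=True)
        assert collapsed.inter_rater["g"] == pytest.approx(mixed.inter_rater["g"], abs=0.02)
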