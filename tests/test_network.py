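"""Eigenproteins, biweight midcorrelation, module projection, enrichment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmatmt import ConfigurationError, ModuleNetwork
from plasmatmt.network import (
    assign_modules,
    bicor,
    compute_eigenprotein,
    fet_enrichment,
    module_trait_correlation,
    overlap_summary,
)
from plasmatmt.simulate import SyntheticDesign, simulate_reference_brain


def bicor_oracle(x, y):
    """Literal transcription of the biweight midcorrelation formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def terms(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return w * (v - med)

    a, b = terms(x), terms(y)
    return float(np.sum(a * b) /
                 np.sqrt(np.sum(a ** 2) * np.sum(b ** 2)))


class TestEigenprotein:
    def test_identical_members_full_variance(self, rng):
        row = rng.normal(size=20)
        ref = pd.DataFrame([row, row, row], index=["a", "b", "c"],
                           columns=[f"s{j}" for j in range(20)])
        vec, share = compute_eigenprotein(ref, ["a", "b", "c"])
        assert share == pytest.approx(1.0)
        z = (row - row.mean()) / row.std(ddof=1)
        assert abs(np.corrcoef(vec, z)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_two_member_explained_variance_closed_form(self, rng):
        """For two standardized members the top share is (1 + |r|) / 2."""
        x = rng.normal(size=40)
        y = 0.6 * x + 0.8 * rng.normal(size=40)
        ref = pd.DataFrame([x, y], index=["a", "b"],
                           columns=[f"s{j}" for j in range(40)])
        _, share = compute_eigenprotein(ref, ["a", "b"])
        r = abs(np.corrcoef(x, y)[0, 1])
        assert share == pytest.approx((1 + r) / 2, rel=1e-10)

    def test_sign_oriented_toward_members(self, rng):
        x = rng.normal(size=30)
        ref = pd.DataFrame([x, x + 0.1 * rng.normal(size=30)],
                           index=["a", "b"],
                           columns=[f"s{j}" for j in range(30)])
        vec, _ = compute_eigenprotein(ref, ["a", "b"])
        assert np.corrcoef(vec, x)[0, 1] > 0

    def test_anticorrelated_pair_aligns_to_first_member(self, rng):
        x = rng.normal(size=30)
        ref = pd.DataFrame([x, -x], index=["a", "b"],
                           columns=[f"s{j}" for j in range(30)])
        vec, share = compute_eigenprotein(ref, ["a", "b"])
        assert share == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.corrcoef(vec, z)[0, 1] > 0

    def test_too_few_members_rejected(self, rng):
        ref = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        with pytest.raises(ConfigurationError):
            compute_eigenprotein(ref, ["a"])


class TestBicor:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=25)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_literal_formula(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 40))
            y = rng.normal(size=len(x))
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y),
                                                abs=1e-12)

    def test_outlier_resistance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pearson = np.corrcoef(x, y)[0, 1]
        robust = bicor(x, y)
        assert robust == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        assert robust > pearson

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0),
           st.floats(-100.0, 100.0))
    def test_affine_invariance_and_antisymmetry(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = bicor(x, y)
        assert bicor(a * x + b, y) == pytest.approx(base, abs=1e-9)
        assert bicor(-x, y) == pytest.approx(-base, abs=1e-9)

    def test_mad_zero_falls_back_with_warning(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])  # MAD = 0
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="zero MAD"):
            r = bicor(x, y)
        assert -1 <= r <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ConfigurationError):
            bicor([1.0, 2.0], [3.0, 4.0])


class TestAssignModules:
    def small_network(self, rng, n_samples=40):
        e1 = rng.normal(size=n_samples)
        e2 = rng.normal(size=n_samples)
        eig = pd.DataFrame([e1 / np.linalg.norm(e1), e2 / np.linalg.norm(e2)],
                           index=["M1", "M2"],
                           columns=[f"s{j}" for j in range(n_samples)])
        return ModuleNetwork(members={"M1": ["x"], "M2": ["y"]},
                             eigenproteins=eig)

    def test_exact_eigenprotein_maps_to_its_module(self, rng):
        net = self.small_network(rng)
        target = pd.DataFrame([net.eigenproteins.loc["M2"].to_numpy()],
                              index=["p"], columns=net.eigenproteins.columns)
        out = assign_modules(target, net)
        assert out.at["p", "module"] == "M2"
        assert out.at["p", "kME"] == pytest.approx(1.0)
        assert bool(out.at["p", "assigned"])

    def test_sub_threshold_goes_grey(self, rng):
        net = self.small_network(rng, n_samples=200)
        e1 = net.eigenproteins.loc["M1"].to_numpy()
        noise = rng.normal(size=200)
        # mix tuned numerically so the realized max kME is just under 0.30
        for mix in np.linspace(0.0, 1.0, 201):
            cand = mix * e1 + noise / np.linalg.norm(noise)
            r = max(bicor(cand, e1),
                    bicor(cand, net.eigenproteins.loc["M2"].to_numpy()))
            if 0.25 < r < 0.2999:
                break
        target = pd.DataFrame([cand], index=["p"],
                              columns=net.eigenproteins.columns)
        out = assign_modules(target, net, kme_min=0.30)
        assert out.at["p", "module"] == "grey"
        assert not bool(out.at["p", "assigned"])

    def test_insufficient_pairs_grey_with_reason(self, rng):
        net = self.small_network(rng)
        row = np.full(40, np.nan)
        row[:2] = 1.0
        target = pd.DataFrame([row], index=["p"],
                              columns=net.eigenproteins.columns)
        out = assign_modules(target, net)
        assert out.at["p", "module"] == "grey"
        assert out.at["p", "note"] == "insufficient pairs"

    def test_simulated_members_recovered(self):
        design = SyntheticDesign(n_proteins=300, n_modules=3, module_size=25,
                                 module_purity=0.9, n_reference_samples=60,
                                 seed=9)
        ref, net, _, labels = simulate_reference_brain(design)
        out = assign_modules(ref.values, net, kme_min=0.30)
        members = labels.index[labels != "grey"]
        agree = (out.loc[members, "module"] == labels[members]).mean()
        assert agree >= 0.90


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigenprotein(self, rng):
        design = SyntheticDesign(n_proteins=60, n_modules=2, module_size=10,
                                 n_reference_samples=30, seed=4)
        _, net, _, _ = simulate_reference_brain(design)
        traits = pd.DataFrame({
            "up": net.eigenproteins.loc["M1"],
            "down": -net.eigenproteins.loc["M1"],
        })
        tab = module_trait_correlation(net, traits).set_index(["module", "trait"])
        assert tab.loc[("M1", "up"), "bicor"] == pytest.approx(1.0)
        assert tab.loc[("M1", "down"), "bicor"] == pytest.approx(-1.0)
        assert tab.loc[("M1", "up"), "p"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_missing(self, rng):
        design = SyntheticDesign(n_proteins=60, n_modules=1, module_size=10,
                                 n_reference_samples=30, seed=4)
        _, net, _, _ = simulate_reference_brain(design)
        traits = pd.DataFrame({"flat": np.ones(30)},
                              index=net.eigenproteins.columns)
        tab = module_trait_correlation(net, traits)
        assert tab["bicor"].isna().all()


def fet_oracle(k, N, K, n):
    """Upper-tail hypergeometric mass by direct summation (exact comb)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)
               if n - j <= N - K) / total


class TestFETEnrichment:
    def test_hand_hypergeometric(self):
        background = {f"g{i}" for i in range(20)}
        cat = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}
        out = fet_enrichment(query, {"C": cat}, background, min_genes=5)
        assert out.at["C", "overlap"] == 4
        assert out.at["C", "p"] == pytest.approx(76 / 15504, rel=1e-10)
        assert out.at["C", "fold_enrichment"] == pytest.approx(4 * 20 / (5 * 5))

    def test_disjoint_query_p_one(self):
        background = {f"g{i}" for i in range(30)}
        out = fet_enrichment({"g20", "g21"}, {"C": {f"g{i}" for i in range(5)}},
                             background)
        assert out.at["C", "p"] == pytest.approx(1.0)
        assert out.at["C", "z"] < 0

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            N = int(rng.integers(8, 60))
            K = int(rng.integers(5, N + 1))
            n = int(rng.integers(1, N + 1))
            background = {f"g{i}" for i in range(N)}
            cat = {f"g{i}" for i in range(K)}
            query = set(rng.choice(sorted(background), size=n, replace=False))
            out = fet_enrichment(query, {"C": cat}, background, min_genes=5)
            k = out.at["C", "overlap"]
            assert out.at["C", "p"] == pytest.approx(
                fet_oracle(int(k), N, K, n), rel=1e-9)

    def test_z_and_p_order_consistent(self, rng):
        """For fixed margins, a larger overlap gives larger Z and smaller p."""
        background = {f"g{i}" for i in range(40)}
        cat = {f"g{i}" for i in range(10)}
        rows = []
        for k in (1, 3, 5, 7):
            query = {f"g{i}" for i in range(k)} | \
                    {f"g{i}" for i in range(10, 10 + 8 - k)}
            out = fet_enrichment(query, {"C": cat}, background)
            rows.append((out.at["C", "z"], out.at["C", "p"]))
        zs, ps = zip(*rows)
        assert list(zs) == sorted(zs)
        assert list(ps) == sorted(ps, reverse=True)

    def test_small_categories_skipped(self):
        background = {f"g{i}" for i in range(20)}
        out = fet_enrichment({"g0"}, {"tiny": {"g0", "g1"}}, background,
                             min_genes=5)
        assert len(out) == 0

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigurationError):
            fet_enrichment({"a"}, {"C": {"a"}}, set())


class TestOverlapSummary:
    def test_full_and_empty_coverage(self):
        net = ModuleNetwork(members={"M1": ["a", "b"], "M2": ["c"]},
                            eigenproteins=pd.DataFrame(
                                np.zeros((2, 3)), index=["M1", "M2"]))
        inter, cov = overlap_summary({"a", "b", "c"}, {"a", "b", "c"}, net)
        assert inter == 3 and (cov == 1.0).all()
        inter0, cov0 = overlap_summary({"x"}, {"a"}, net)
        assert inter0 == 0 and (cov0 == 0.0).all()

    def test_partial_coverage_counting(self):
        members = {"M1": [f"m{i}" for i in range(10)]}
        net = ModuleNetwork(members=members,
                            eigenproteins=pd.DataFrame(np.zeros((1, 3)),
                                                       index=["M1"]))
        plasma = {"m0", "m1", "m2", "m3", "zz"}
        _, cov = overlap_summary(plasma, set(members["M1"]), net)
        assert cov["M1"] == pytest.approx(0.4)
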