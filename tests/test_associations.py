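import numpy as np
import pandas as pd
import pytest

from helpers import (kendall_exact_p, kendall_s_bruteforce, mannwhitney_exact_p,
                     mannwhitney_u, permutation_with_inversions)
from radioprot import (OmicsMatrix, TraitSpec, TraitTable, bh_adjust,
                       consolidate_readers, kendall_tau, mann_whitney_auc,
                       run_associations)
from radioprot.associations import agreement
from radioprot.datatypes import READERS
from radioprot.errors import MergeError, ParameterError, UnresolvedConflictError


def _trait_table(values: dict, schema: dict, patients=None):
    cols = {}
    n = len(next(iter(values.values()))[0])
    patients = patients or [f"P{i}" for i in range(n)]
    for trait, (r1, r2) in values.items():
        cols[(trait, "reader1")] = r1
        cols[(trait, "reader2")] = r2
    df = pd.DataFrame(cols, index=patients)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["trait", "reader"])
    return TraitTable(df, schema)


class TestConsolidation:
    schema = {"yes_no": TraitSpec("binary"), "length": TraitSpec("quantitative", units="mm")}

    def test_concordant_categorical_kept(self):
        t = _trait_table({"yes_no": ([1, 0], [1, 0])}, {"yes_no": TraitSpec("binary")})
        arb = pd.DataFrame({"yes_no": [0, 1]}, index=t.patients)
        out = consolidate_readers(t, arb)
        assert out.reader("consolidated")["yes_no"].tolist() == [1, 0]

    def test_disagreement_goes_to_arbitrator(self):
        t = _trait_table({"yes_no": ([1, 1], [0, 1])}, {"yes_no": TraitSpec("binary")})
        arb = pd.DataFrame({"yes_no": [0, 0]}, index=t.patients)
        out = consolidate_readers(t, arb)
        # patient 0 disagrees -> arbitrator's 0; patient 1 agrees -> 1
        assert out.reader("consolidated")["yes_no"].tolist() == [0, 1]

    def test_quantitative_averaged(self):
        t = _trait_table({"length": ([60.0], [66.0])},
                         {"length": TraitSpec("quantitative", units="mm")})
        arb = pd.DataFrame(index=t.patients)
        out = consolidate_readers(t, arb)
        assert out.reader("consolidated")["length"].iloc[0] == 63.0

    def test_missing_arbitration_raises(self):
        t = _trait_table({"yes_no": ([1], [0])}, {"yes_no": TraitSpec("binary")})
        arb = pd.DataFrame(index=t.patients)  # no column
        with pytest.raises(UnresolvedConflictError, match="yes_no"):
            consolidate_readers(t, arb)


class TestAgreement:
    def test_identical_readers(self):
        t = _trait_table({"b": ([1, 0, 1, 0], [1, 0, 1, 0])}, {"b": TraitSpec("binary")})
        ag = agreement(t)
        assert ag.loc["b", "percent_agreement"] == 100.0
        assert ag.loc["b", "kappa"] == 1.0

    def test_hand_computed_two_by_two(self):
        # reader table rows (8,2 / 1,9): po=0.85, pe=0.5, kappa=0.7
        r1 = [1] * 10 + [0] * 10
        r2 = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        t = _trait_table({"b": (r1, r2)}, {"b": TraitSpec("binary")})
        ag = agreement(t)
        assert ag.loc["b", "percent_agreement"] == pytest.approx(85.0)
        assert ag.loc["b", "kappa"] == pytest.approx(0.7)

    def test_constant_reader_kappa_undefined(self):
        t = _trait_table({"b": ([1, 0, 1], [0, 0, 0])}, {"b": TraitSpec("binary")})
        ag = agreement(t)
        assert np.isnan(ag.loc["b", "kappa"])
        assert np.isfinite(ag.loc["b", "percent_agreement"])

    def test_symmetric_in_readers(self, rng):
        r1 = rng.integers(0, 3, 30)
        r2 = rng.integers(0, 3, 30)
        lv = ("a", "b", "c")
        a = agreement(_trait_table({"o": (r1, r2)}, {"o": TraitSpec("ordinal", lv)}))
        b = agreement(_trait_table({"o": (r2, r1)}, {"o": TraitSpec("ordinal", lv)}))
        assert a.loc["o", "percent_agreement"] == b.loc["o", "percent_agreement"]
        assert a.loc["o", "kappa"] == pytest.approx(b.loc["o", "kappa"])


class TestMannWhitney:
    def test_perfect_separation_small_groups(self):
        r = mann_whitney_auc([4, 5, 6], [1, 2, 3])
        assert r.auc == 1.0
        assert r.p == pytest.approx(0.1)  # 2/20, exact
        assert r.method == "exact"

    def test_all_ties_auc_half(self):
        r = mann_whitney_auc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert r.auc == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_auc([], [1, 2])

    def test_label_swap_maps_auc_and_keeps_p(self, rng):
        x = rng.normal(1, 1, 8)
        y = rng.normal(0, 1, 9)
        a = mann_whitney_auc(x, y)
        b = mann_whitney_auc(y, x)
        assert a.auc == pytest.approx(1 - b.auc)
        assert a.p == pytest.approx(b.p)

    def test_auc_u_identity(self, rng):
        x = rng.normal(0, 1, 7)
        y = rng.normal(0, 1, 5)
        r = mann_whitney_auc(x, y)
        assert r.auc == pytest.approx(r.U / (7 * 5))
        assert r.U == pytest.approx(mannwhitney_u(x, y))

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        pooled = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7 + 0.3)
        x, y = pooled[:n1], pooled[n1:]
        r = mann_whitney_auc(x, y)
        assert r.method == "exact"
        assert r.p == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        r = mann_whitney_auc([1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0])
        assert r.method == "asymptotic"


class TestKendall:
    def test_monotone_identity(self):
        x = np.arange(3, dtype=float)
        r = kendall_tau(x, x)
        assert r.tau == 1.0
        assert r.p == pytest.approx(1 / 3)  # 2 of 6 permutations as extreme
        assert r.S == 3

    def test_anti_monotone(self):
        x = np.arange(5, dtype=float)
        r = kendall_tau(x, x[::-1])
        assert r.tau == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        r = kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.method == "undefined"
        assert np.isnan(r.tau)

    def test_s_tau_identity_untied(self, rng):
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        r = kendall_tau(x, y)
        assert r.tau == pytest.approx(r.S / (10 * 9 / 2))
        assert r.S == kendall_s_bruteforce(x, y)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_permutation_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = np.arange(n, dtype=float)
        y = rng.permutation(n).astype(float)
        r = kendall_tau(x, y)
        assert r.method == "exact"
        assert r.p == pytest.approx(kendall_exact_p(x, y), abs=1e-12)

    def test_untied_n20_fixture_matches_printed_style_p(self):
        # n = 20 untied with S = 82 (tau ~ 0.432): exact p ~ 0.0073
        n = 20
        d = (n * (n - 1) // 2 - 82) // 2
        y = np.array(permutation_with_inversions(n, d), dtype=float)
        r = kendall_tau(np.arange(n, dtype=float), y)
        assert r.S == 82
        assert r.method == "exact"
        assert r.p == pytest.approx(0.00735, abs=5e-5)


class TestBHAdjust:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust([0.5, 0.9]), [0.9, 0.9])
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_permutation_invariance_and_bounds(self, rng):
        p = rng.uniform(0.001, 1.0, 25)
        adj = bh_adjust(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm])
        assert (adj >= p).all() and (adj <= 1.0).all()

    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ParameterError):
            bh_adjust([1.5])


class TestRunAssociations:
    def _grid(self, rng, n_prot=4, n_pat=20):
        prot = OmicsMatrix(pd.DataFrame(
            rng.standard_normal((n_prot, n_pat)),
            index=[f"G{i}" for i in range(n_prot)],
            columns=[f"P{i}" for i in range(n_pat)]))
        feats = pd.DataFrame({
            "bin": rng.integers(0, 2, n_pat),
            "cnt": rng.poisson(3, n_pat),
        }, index=prot.sample_ids).astype(float)
        return prot, feats

    def test_planted_shift_attains_smallest_p(self, rng):
        hits = 0
        for rep in range(20):
            prot, feats = self._grid(rng)
            # plant a strong shift of G0 with the binary feature
            shift = 3.0 * feats["bin"].to_numpy()
            prot.values.iloc[0] = rng.standard_normal(20) + shift
            res = run_associations(prot, feats, {"bin": "binary", "cnt": "count"})
            best = min(res, key=lambda r: r.p_raw)
            hits += (best.protein == "G0" and best.feature == "bin")
        assert hits >= 18

    def test_zero_proteins_empty_result(self, rng):
        prot, feats = self._grid(rng)
        empty = OmicsMatrix(prot.values.iloc[:0], kind="protein")
        assert run_associations(empty, feats, {"bin": "binary"}) == []

    def test_patient_mismatch_raises(self, rng):
        prot, feats = self._grid(rng)
        feats.index = [f"X{i}" for i in range(len(feats))]
        with pytest.raises(MergeError, match="X0"):
            run_associations(prot, feats, {"bin": "binary"})

    def test_bh_within_feature_family(self, rng):
        prot, feats = self._grid(rng, n_prot=6)
        res = run_associations(prot, feats, {"bin": "binary", "cnt": "count"},
                               bh_family="per_feature")
        for feature in ("bin", "cnt"):
            sub = [r for r in res if r.feature == feature]
            np.testing.assert_allclose([r.p_adjusted for r in sub],
                                       bh_adjust([r.p_raw for r in sub]))
        assert all(r.p_adjusted >= r.p_raw for r in res)

    def test_constant_feature_skipped(self, rng):
        prot, feats = self._grid(rng)
        feats["bin"] = 1.0  # empty absent group
        res = run_associations(prot, feats, {"bin": "binary", "cnt": "count"})
        assert all(r.feature == "cnt" for r in res)
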