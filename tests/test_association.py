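import math

import numpy as np
import pandas as pd
import pytest

from duomics.association import (
    AssociationError,
    AssociationResult,
    PairSet,
    build_pair_index,
    build_pair_set,
    cross_timepoint_association,
    fit_cca,
    mi_bins,
    mutual_information,
    pairwise_associations,
    paired_blocks,
    pearson_r,
    structure_correlations,
    threshold_associations,
    top_k_signed,
)
from duomics.data_model import Experiment
from duomics import preprocess
from duomics.synthetic import SyntheticConfig, simulate_microbiome, simulate_proteome

from .conftest import make_asv_table, make_protein_table, protein_design, asv_design


def _design(spec, timepoint=None):
    """spec: dict substrate -> count"""
    out = []
    for s, n in spec.items():
        for i in range(n):
            out.append(Experiment(f"{timepoint or 'x'}_{s}_{i}", s, timepoint, i + 1))
    return out


class TestPairing:
    def test_single_substrate_cardinality(self):
        ix = build_pair_index(_design({"dentine": 2}), _design({"dentine": 3}, "2h"))
        assert ix.n_pairs == 6

    def test_multi_substrate_cardinality(self):
        ix = build_pair_index(_design({"dentine": 2, "enamel": 3}),
                              _design({"dentine": 3, "enamel": 3}, "2h"))
        assert ix.n_pairs == 2 * 3 + 3 * 3

    def test_no_common_substrate_rejected(self):
        with pytest.raises(AssociationError, match="no substrate"):
            build_pair_index(_design({"dentine": 2}), _design({"enamel": 2}, "2h"))

    def test_matches_brute_force(self, rng):
        subs = ["dentine", "enamel", "titanium"]
        for _ in range(20):
            dx = _design({s: int(rng.integers(1, 4)) for s in
                          rng.choice(subs, size=int(rng.integers(1, 4)), replace=False)})
            dy = _design({s: int(rng.integers(1, 4)) for s in
                          rng.choice(subs, size=int(rng.integers(1, 4)), replace=False)},
                         "2h")
            common = {e.substrate for e in dx} & {e.substrate for e in dy}
            brute = sorted(
                (i, j) for i, ex in enumerate(dx) for j, ey in enumerate(dy)
                if ex.substrate == ey.substrate)
            if not common:
                with pytest.raises(AssociationError):
                    build_pair_index(dx, dy)
                continue
            ix = build_pair_index(dx, dy)
            got = sorted(zip(ix.x_indices.tolist(), ix.y_indices.tolist()))
            assert got == brute
            # both members of every pair share one substrate
            for i, j, s in zip(ix.x_indices, ix.y_indices, ix.substrates):
                assert dx[i].substrate == dy[j].substrate == s

    def test_deterministic_order(self):
        dx = _design({"titanium": 2, "dentine": 1})
        dy = _design({"dentine": 2, "titanium": 1}, "2h")
        ix = build_pair_index(dx, dy)
        assert list(ix.substrates) == ["dentine", "dentine", "titanium", "titanium"]

    def test_build_pair_set_reads_values(self):
        x = make_protein_table(np.arange(1, 10, dtype=float).reshape(1, 9))
        y = make_asv_table(np.arange(9, dtype=float).reshape(1, 9))
        ps = build_pair_set(x, "P000", y, "A000")
        assert ps.n_pairs == 27
        assert set(ps.substrates) == {"dentine", "enamel", "titanium"}


def _pairset(x, y):
    x = np.asarray(x, dtype=float)
    return PairSet("p", "q", x, np.asarray(y, dtype=float),
                   np.array(["dentine"] * len(x), dtype=object))


class TestPearson:
    def test_increasing_line(self):
        assert pearson_r(_pairset([1, 2, 3, 4], [2, 4, 6, 8])) == pytest.approx(1.0)

    def test_decreasing_line(self):
        assert pearson_r(_pairset([1, 2, 3, 4], [8, 6, 4, 2])) == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 1.0, 3.0])
        want = (((x - x.mean()) * (y - y.mean())).sum()
                / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert pearson_r(_pairset(x, y)) == pytest.approx(want, abs=1e-12)

    def test_constant_coordinate_undefined(self):
        r = pearson_r(_pairset([1, 1, 1], [1, 2, 3]))
        assert math.isnan(r)
        res = AssociationResult("p", "q", r, None, 3)
        assert not res.defined and not res.high

    def test_too_few_pairs(self):
        with pytest.raises(AssociationError):
            pearson_r(_pairset([1, 2], [3, 4]))


class TestMutualInformation:
    def test_deterministic_monotone_approaches_log_b(self, rng):
        n = 5000
        x = rng.uniform(size=n)
        y = np.exp(3 * x)  # strictly monotone
        b = mi_bins(n)
        mi = mutual_information(_pairset(x, y))
        assert abs(mi - math.log(b)) < 0.05

    def test_independent_near_zero(self, rng):
        n = 10000
        mi = mutual_information(_pairset(rng.normal(size=n), rng.normal(size=n)))
        assert mi <= 0.02

    def test_symmetry(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        assert mutual_information(_pairset(x, y)) == pytest.approx(
            mutual_information(_pairset(y, x)), abs=1e-12)

    def test_bin_rule(self):
        assert mi_bins(27) == 2
        assert mi_bins(500) == 10
        assert mi_bins(5000) == 10
        assert mi_bins(10) == 2

    def test_small_n_rejected(self):
        with pytest.raises(AssociationError):
            mutual_information(_pairset(range(5), range(5)))

    def test_small_n_warns_but_returns(self, caplog):
        with caplog.at_level("WARNING"):
            mi = mutual_information(_pairset(range(12), range(12)))
        assert mi >= 0


def brute_force_cca_2x2(Sxx, Syy, Sxy):
    """Standard CCA normal equations as a dense generalized eigenproblem."""
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    evals, evecs = np.linalg.eig(M)
    order = np.argsort(evals.real)[::-1]
    rho = np.sqrt(np.clip(evals.real[order], 0, None))
    A = evecs.real[:, order]
    for j in range(A.shape[1]):
        A[:, j] /= math.sqrt(A[:, j] @ Sxx @ A[:, j])
    return rho, A


class TestCca:
    def test_identical_single_variable(self, rng):
        x = rng.normal(size=(20, 1))
        model = fit_cca(x, x.copy(), 0.0, 0.0)
        assert model.correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_one_dim_reduces_to_pearson(self, rng):
        x = rng.normal(size=(30, 1))
        y = 0.5 * x + rng.normal(size=(30, 1))
        r = np.corrcoef(x[:, 0], y[:, 0])[0, 1]
        model = fit_cca(x, y, 0.0, 0.0)
        assert model.correlations[0] == pytest.approx(abs(r), abs=1e-10)

    def test_matches_generalized_eigen_oracle(self, rng):
        for _ in range(10):
            X = rng.normal(size=(60, 2))
            Y = X @ rng.normal(size=(2, 2)) + 0.8 * rng.normal(size=(60, 2))
            model = fit_cca(X, Y, 0.0, 0.0)
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            n = X.shape[0]
            rho, A = brute_force_cca_2x2(Xc.T @ Xc / (n - 1), Yc.T @ Yc / (n - 1),
                                         Xc.T @ Yc / (n - 1))
            np.testing.assert_allclose(model.correlations, rho, atol=1e-8)
            for j in range(2):
                got = model.x_weights.values[:, j]
                want = A[:, j]
                if np.dot(got, want) < 0:
                    want = -want
                np.testing.assert_allclose(got, want, atol=1e-8)

    def test_within_block_orthogonality(self, rng):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3)) + 0.3 * X
        model = fit_cca(X, Y, 0.0, 0.0)
        for scores in (model.x_scores.values, model.y_scores.values):
            C = np.corrcoef(scores.T)
            off = C - np.diag(np.diag(C))
            assert np.abs(off).max() <= 1e-8

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(30, 2))
        Y = rng.normal(size=(30, 2)) + 0.5 * X
        m1 = fit_cca(X, Y, 0.0, 0.0)
        X2 = X.copy()
        X2[:, 0] = 10 * X2[:, 0] + 7
        m2 = fit_cca(X2, Y, 0.0, 0.0)
        np.testing.assert_allclose(m1.correlations, m2.correlations, atol=1e-10)

    def test_rank_deficient_gets_default_ridge(self, rng):
        base = rng.normal(size=(10, 1))
        X = np.hstack([base, base])  # perfectly collinear
        Y = rng.normal(size=(10, 2))
        model = fit_cca(X, Y)
        assert model.lambda_x == pytest.approx(1e-3)
        assert model.lambda_y == 0.0

    def test_mismatched_cases_rejected(self, rng):
        with pytest.raises(AssociationError):
            fit_cca(rng.normal(size=(5, 2)), rng.normal(size=(6, 2)))

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(AssociationError):
            fit_cca(rng.normal(size=(1, 2)), rng.normal(size=(1, 2)))

    def test_correlations_sorted_descending_in_unit_interval(self, rng):
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 3))
        model = fit_cca(X, Y, 0.0, 0.0)
        rho = model.correlations
        assert np.all(rho[:-1] >= rho[1:] - 1e-12)
        assert np.all((rho >= 0) & (rho <= 1))


class TestStructureCorrelations:
    def test_interset_is_rho_times_intraset(self, rng):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 2)) + 0.4 * X[:, :2]
        model = fit_cca(X, Y, 0.0, 0.0)
        sc = structure_correlations(model, X, Y)
        np.testing.assert_allclose(
            sc.x_interset.values, sc.x_intraset.values * model.correlations,
            atol=1e-10)

    def test_single_identical_variable(self, rng):
        x = rng.normal(size=(25, 1))
        model = fit_cca(x, x.copy(), 0.0, 0.0)
        sc = structure_correlations(model, x, x.copy())
        assert sc.x_intraset.values[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert sc.x_interset.values[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_intraset_matches_direct_recomputation(self, rng):
        X = rng.normal(size=(35, 3))
        Y = rng.normal(size=(35, 3)) + 0.5 * X
        model = fit_cca(X, Y, 0.0, 0.0)
        sc = structure_correlations(model, X, Y)
        for j, dim in enumerate(sc.y_intraset.columns):
            for i in range(3):
                want = np.corrcoef(Y[:, i], model.y_scores.values[:, j])[0, 1]
                assert sc.y_intraset.values[i, j] == pytest.approx(want, abs=1e-10)


def _results(rs):
    return [AssociationResult(f"p{i}", f"q{i}", r, None, 27) for i, r in enumerate(rs)]


class TestThresholdAndTopK:
    def test_boundary_excluded(self):
        edges = threshold_associations(_results([0.7]), tau=0.7)
        assert edges.empty

    def test_strong_negative_included(self):
        edges = threshold_associations(_results([-0.85]), tau=0.7, strong_tau=0.8)
        assert len(edges) == 1
        row = edges.iloc[0]
        assert row["sign"] == -1 and bool(row["strong"])

    def test_count_matches_brute_force(self, rng):
        rs = rng.uniform(-1, 1, size=100)
        edges = threshold_associations(_results(rs), tau=0.7)
        assert len(edges) == int((np.abs(rs) > 0.7).sum())

    def test_top_k_example(self):
        neg, pos = top_k_signed(_results([0.9, 0.8, -0.95, 0.1]), k=1)
        assert pos[0].r == pytest.approx(0.9)
        assert neg[0].r == pytest.approx(-0.95)

    def test_all_positive_logs_warning(self, caplog):
        with caplog.at_level("WARNING"):
            neg, pos = top_k_signed(_results([0.5, 0.6]), k=3)
        assert neg == []
        assert len(pos) == 2

    def test_matches_sort_oracle(self, rng):
        rs = rng.uniform(-1, 1, size=50)
        neg, pos = top_k_signed(_results(rs), k=3)
        assert [r.r for r in pos] == sorted([r for r in rs if r > 0], reverse=True)[:3]
        assert [r.r for r in neg] == sorted([r for r in rs if r < 0])[:3]

    def test_tie_break_lexicographic(self):
        results = [AssociationResult("pB", "q", 0.9, None, 27),
                   AssociationResult("pA", "q", 0.9, None, 27)]
        _, pos = top_k_signed(results, k=1)
        assert pos[0].x_id == "pA"


class TestCrossTimepoint:
    def test_identical_profiles_r_one(self):
        vals = np.array([[1.0, 1.1, 0.9, 5.0, 5.2, 4.8, 9.0, 9.1, 8.9]])
        t2 = make_asv_table(vals, timepoint="2h")
        t24 = make_asv_table(vals, timepoint="24h")
        results, edges = cross_timepoint_association(t2, t24, tau=0.5)
        self_pair = [r for r in results if r.x_id == r.y_id][0]
        assert self_pair.r > 0.9

    def test_pair_count_identity(self):
        t2 = make_asv_table(np.ones((2, 9)) * np.arange(1, 10), timepoint="2h")
        d24 = asv_design("24h", 2)
        t24 = make_asv_table(np.ones((2, 6)) * np.arange(1, 7), design=d24,
                             timepoint="24h")
        results, _ = cross_timepoint_association(t2, t24)
        assert all(r.n_pairs == 3 * (3 * 2) for r in results)  # 3 subs x (3 x 2)

    def test_persistent_fixture_self_pairs_dominate(self):
        cfg = SyntheticConfig(n_proteins=40, n_asvs=20, n_discriminant_proteins=8,
                              n_discriminant_asvs=6, n_couplings=4,
                              persistence=1.0, zero_inflation=0.0, seed=5)
        _, ptruth = simulate_proteome(cfg)
        m2, m24, truth = simulate_microbiome(cfg, ptruth)
        l2 = preprocess.offset_log(m2, preprocess.offset_alpha(m2))
        l24 = preprocess.offset_log(m24, preprocess.offset_alpha(m24))
        results, edges = cross_timepoint_association(l2, l24, tau=0.5)
        # planted structured ASVs should correlate with themselves across time
        structured = set(truth.discriminant_asvs) | {c.asv_id for c in truth.couplings}
        rmap = {(r.x_id, r.y_id): r.r for r in results}
        hits = sum(abs(rmap[(a, a)]) > 0.5 for a in structured)
        assert hits / len(structured) >= 0.8


class TestPairedBlocks:
    def test_consistent_case_axis(self):
        x = make_protein_table(np.vstack([np.arange(1, 10), np.arange(2, 11)]).astype(float))
        y = make_asv_table(np.vstack([np.arange(9), np.arange(9)]).astype(float))
        Xb, Yb, ix = paired_blocks(x, y)
        assert Xb.shape == (27, 2)
        assert Yb.shape == (27, 2)
        assert list(Xb.index) == list(Yb.index)
        # values read back correctly at the pair indices
        for row in range(5):
            i, j = ix.x_indices[row], ix.y_indices[row]
            assert Xb.iloc[row, 0] == x.data.iloc[0, i]
            assert Yb.iloc[row, 0] == y.data.iloc[0, j]


class TestPairwiseAssociations:
    def test_vectorized_r_matches_scalar(self, rng):
        x = make_protein_table(rng.uniform(1, 9, size=(3, 9)))
        y = make_asv_table(rng.integers(0, 30, size=(4, 9)).astype(float))
        results = pairwise_associations(x, y, compute_mi=False)
        assert len(results) == 12
        for r in results:
            ps = build_pair_set(x, r.x_id, y, r.y_id)
            assert r.r == pytest.approx(pearson_r(ps), abs=1e-12)

    def test_mi_computed_when_requested(self, rng):
        x = make_protein_table(rng.uniform(1, 9, size=(1, 9)))
        y = make_asv_table(rng.integers(0, 30, size=(1, 9)).astype(float))
        results = pairwise_associations(x, y, compute_mi=True)
        assert results[0].mi is not None and results[0].mi >= 0
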