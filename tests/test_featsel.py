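"""Feature-selection routes against brute-force and algebraic oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tmsresp import (
    pca_reduce,
    wavelet_select,
    swlda_select,
    svm_weight_ranking,
    band_restrict,
    make_selector,
    train_svm,
    SVMParams,
    Standardizer,
)
from tmsresp.featsel import PCASelector, WaveletSelector, SWLDASelector
from tmsresp.errors import ParameterError


class TestPCA:
    def test_eigenvalues_match_dense_eigendecomposition(self, rng):
        X = rng.standard_normal((10, 6))
        sel = PCASelector(k=5).fit(X)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        ref = np.sort(np.linalg.eigvalsh(cov))[::-1][:5]
        assert np.allclose(sel.eigenvalues_, ref, atol=1e-8)

    def test_exact_rank_reconstruction(self, rng):
        basis = rng.standard_normal((3, 8))
        X = rng.standard_normal((12, 3)) @ basis  # rank 3
        sel = PCASelector(k=3).fit(X)
        Z = sel.transform(X)
        recon = Z @ sel.components_ + X.mean(axis=0)
        assert np.abs(recon - X).max() < 1e-8

    def test_default_k_columns(self, rng):
        X = rng.standard_normal((30, 100))
        _, Z = pca_reduce(X, k=20)
        assert Z.shape == (30, 20)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ParameterError):
            PCASelector(k=10).fit(rng.standard_normal((8, 50)))

    def test_explained_variance_nonincreasing_and_bounded(self, rng):
        X = rng.standard_normal((15, 10))
        sel = PCASelector(k=8).fit(X)
        ratios = np.asarray(sel.selection.fit_stats["explained_variance_ratio"])
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1 + 1e-9


class TestWavelet:
    def test_full_keep_reconstructs(self, rng):
        X = rng.standard_normal((4, 64))
        sel = WaveletSelector(keep_fraction=1.0).fit(X)
        C = sel.decompose(X)
        back = sel.inverse_transform_full(C)
        assert np.abs(back - X).max() < 1e-8

    def test_single_atom_ranked_first(self):
        import pywt

        # build a signal that is exactly one wavelet atom
        sel = WaveletSelector(keep_fraction=0.05)
        n = 64
        template = pywt.wavedec(np.zeros(n), "db4", mode="symmetric",
                                level=pywt.dwt_max_level(n, 8))
        coeffs = [np.zeros_like(c) for c in template]
        coeffs[1][2] = 5.0
        atom = pywt.waverec(coeffs, "db4", mode="symmetric")[:n]
        X = np.vstack([atom, atom])
        sel.fit(X)
        C = sel.decompose(X)
        assert sel.keep_idx_[np.argmax(np.abs(C[0, sel.keep_idx_]))] == np.argmax(np.abs(C[0]))

    def test_retained_energy_beats_sampled_subsets(self, rng):
        X = rng.standard_normal((1, 64))
        sel = WaveletSelector(keep_fraction=0.10).fit(X)
        C = sel.decompose(X)[0]
        kept_energy = np.sum(C[sel.keep_idx_] ** 2)
        k = sel.keep_idx_.size
        for _ in range(500):
            subset = rng.choice(C.size, size=k, replace=False)
            assert kept_energy >= np.sum(C[subset] ** 2) - 1e-12

    def test_retained_energy_monotone_in_keep_fraction(self, rng):
        X = rng.standard_normal((3, 64))
        energies = []
        for frac in (0.05, 0.1, 0.3, 1.0):
            sel, Z = wavelet_select(X, keep_fraction=frac)
            energies.append(np.sum(Z**2))
        assert all(a <= b + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_short_block_zero_padded_flagged(self, rng):
        X = rng.standard_normal((3, 4))  # shorter than the db4 filter support
        sel = WaveletSelector(keep_fraction=0.5).fit(X)
        assert sel.selection.fit_stats["zero_padded"]


def naive_stepwise(X, y, alpha_in=0.10, alpha_out=0.15, max_features=None):
    """Independent loop-based oracle for the stepwise rule (per-candidate OLS)."""
    n, p = X.shape
    yc = np.where(y == np.unique(y)[1], 1.0, -1.0)
    cap = n if max_features is None else min(max_features, n)
    selected = []
    changed = True
    while changed and len(selected) < cap:
        changed = False
        best_j, best_p = None, 1.0
        for j in range(p):
            if j in selected:
                continue
            D = np.column_stack([np.ones(n)] + [X[:, i] for i in selected])
            D1 = np.column_stack([D, X[:, j]])
            b0, *_ = np.linalg.lstsq(D, yc, rcond=None)
            b1, *_ = np.linalg.lstsq(D1, yc, rcond=None)
            rss0 = np.sum((yc - D @ b0) ** 2)
            rss1 = np.sum((yc - D1 @ b1) ** 2)
            dof = n - D1.shape[1]
            if dof <= 0:
                continue
            if rss1 <= 1e-12:
                pval = 0.0
            else:
                F = (rss0 - rss1) / (rss1 / dof)
                pval = stats.f.sf(max(F, 0.0), 1, dof)
            if pval < best_p:
                best_j, best_p = j, pval
        if best_j is not None and best_p < alpha_in:
            selected.append(best_j)
            changed = True
        while len(selected) > 1:
            D = np.column_stack([np.ones(n)] + [X[:, i] for i in selected])
            b, *_ = np.linalg.lstsq(D, yc, rcond=None)
            resid = yc - D @ b
            dof = n - D.shape[1]
            if dof <= 0:
                break
            sigma2 = np.sum(resid**2) / dof
            cov = sigma2 * np.linalg.pinv(D.T @ D)
            se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
            pv = 2 * stats.t.sf(np.abs(b / se), dof)[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > alpha_out:
                selected.pop(worst)
                changed = True
            else:
                break
    return selected


class TestSWLDA:
    def test_perfect_separator_selected_first(self, rng):
        n = 20
        y = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((n, 8))
        X[:, 3] = np.where(y == 1, 1.0, -1.0)
        selected, model = swlda_select(X, y)
        assert selected[0] == 3

    def test_selection_capped_at_sample_count(self, rng):
        n = 10
        y = np.array([0, 1] * 5)
        X = rng.standard_normal((n, 40)) + 0.8 * y[:, None]
        selected, _ = swlda_select(X, y, alpha_in=0.9, alpha_out=0.95, max_features=n)
        assert len(selected) <= n

    def test_matches_naive_oracle_on_noise(self):
        # pure-noise features: selection sets must match the loop-based oracle
        counts_fast, counts_naive = [], []
        for seed in range(200):
            r = np.random.default_rng(seed)
            X = r.standard_normal((16, 50))
            y = np.array([0] * 8 + [1] * 8)
            sel_fast, _ = swlda_select(X, y)
            sel_naive = naive_stepwise(X, y)
            counts_fast.append(len(sel_fast))
            counts_naive.append(len(sel_naive))
            assert sel_fast == sel_naive
        assert np.mean(counts_fast) == pytest.approx(np.mean(counts_naive))

    def test_empty_selection_warns_not_raises(self):
        X = np.zeros((10, 5))
        y = np.array([0, 1] * 5)
        selected, model = swlda_select(X, y)
        assert selected == []
        assert model.empty_
        assert set(model.predict(X)) <= {0, 1}


class TestSVMWeightRanking:
    def test_zero_feature_zero_weight(self, rng):
        X = rng.standard_normal((12, 4))
        X[:, 2] = 0.0
        y = np.array([0, 1] * 6)
        m = train_svm(X, y, SVMParams(kernel="linear"))
        prov = [("Cz", b, 0) for b in ("delta", "theta", "alpha", "beta")]
        report = svm_weight_ranking(m, prov)
        assert report.feature_weights[2] == pytest.approx(0.0, abs=1e-10)

    def test_split_column_weight_algebra(self, rng):
        # splitting a feature into two copies scaled by 1/sqrt(2) keeps the
        # kernel (hence the solution) unchanged; the copies share the weight
        # equally and their scaled sum recovers the original primal weight
        X = rng.standard_normal((20, 3))
        y = (X[:, 0] + 0.3 * rng.standard_normal(20) > 0).astype(int)
        m1 = train_svm(X, y, SVMParams(kernel="linear"))
        w1 = m1.primal_weights()
        s = 1 / np.sqrt(2)
        X2 = np.column_stack([s * X[:, 0], X[:, 1], X[:, 2], s * X[:, 0]])
        m2 = train_svm(X2, y, SVMParams(kernel="linear"))
        w2 = m2.primal_weights()
        assert abs(w2[0] - w2[3]) < 1e-6
        assert abs(s * (w2[0] + w2[3]) - w1[0]) < 1e-6
        assert np.allclose(w2[1:3], w1[1:3], atol=1e-6)

    def test_rbf_model_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([0, 1] * 5)
        m = train_svm(X, y, SVMParams(kernel="rbf"))
        with pytest.raises(ParameterError, match="linear"):
            svm_weight_ranking(m, [("Cz", "theta", i) for i in range(3)])

    def test_band_cumulative_weights_sum(self, rng):
        X = rng.standard_normal((16, 6))
        y = np.array([0, 1] * 8)
        m = train_svm(X, y, SVMParams(kernel="linear"))
        prov = [("Cz", "theta", i) for i in range(3)] + [("Cz", "alpha", i) for i in range(3)]
        report = svm_weight_ranking(m, prov)
        assert report.band_weights["theta"] == pytest.approx(report.feature_weights[:3].sum())
        assert sorted(report.feature_ranking.tolist()) == list(range(6))


class TestBandRestrict:
    def make_prov(self):
        bands = ["delta", "theta", "alpha", "beta", "gamma"]
        return [(ch, b, w) for ch in ("C3", "C4") for b in bands for w in range(2)]

    def test_restrict_keeps_exact_block(self, rng):
        prov = self.make_prov()
        X = rng.standard_normal((5, len(prov)))
        Xr, prov_r = band_restrict(X, prov, "theta")
        assert all(p[1] == "theta" for p in prov_r)
        assert Xr.shape[1] == len(prov) // 5

    def test_idempotent(self, rng):
        prov = self.make_prov()
        X = rng.standard_normal((5, len(prov)))
        X1, p1 = band_restrict(X, prov, "theta")
        X2, p2 = band_restrict(X1, p1, "theta")
        assert np.array_equal(X1, X2)
        assert p1 == p2

    def test_unknown_band_raises(self, rng):
        with pytest.raises(ParameterError):
            band_restrict(np.zeros((2, 4)), [("C3", "theta", 0)] * 4, "mu")


class TestSelectorContracts:
    def test_refit_on_same_rows_is_stable(self, rng):
        X = rng.standard_normal((12, 30))
        y = np.array([0, 1] * 6)
        for method, kw in [("pca", {"k": 5}), ("wavelet", {}), ("swlda", {})]:
            sel = make_selector(method, **kw)
            sel.fit(X, y, provenance=None)
            Z1 = sel.transform(X)
            sel2 = make_selector(method, **kw)
            sel2.fit(X, y, provenance=None)
            assert np.allclose(Z1, sel2.transform(X))

    def test_standardizer_zero_variance_guard(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Z = Standardizer().fit_transform(X)
        assert np.all(np.isfinite(Z))
        assert np.allclose(Z[:, 0], 0.0)
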