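"""Feature selection and dimension reduction routes.

Five routes over the windowed band-power features, all fit on training rows
only and then applied unchanged to validation/test rows:

* ``none``          — identity.
* ``pca``           — principal components of the training covariance.
* ``wavelet``       — per-channel Daubechies-4 decomposition; keep the
                       globally largest coefficients (by mean training
                       magnitude).
* ``swlda``         — stepwise linear discriminant analysis: forward
                       inclusion / backward elimination driven by regression
                       p-values.
* ``band_restrict`` — keep only the features of one frequency band (e.g.
                       theta), using the provenance index.

A companion utility reads per-feature weights off a linear-kernel SVM and
accumulates them per band, reproducing the weight-hierarchy analysis that
singles out theta as the most informative band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ParameterError

__all__ = [
    "FeatureSelection",
    "FeatureWeightReport",
    "Standardizer",
    "pca_reduce",
    "wavelet_select",
    "swlda_select",
    "svm_weight_ranking",
    "band_restrict",
    "PCASelector",
    "WaveletSelector",
    "SWLDASelector",
    "BandRestrictSelector",
    "IdentitySelector",
    "make_selector",
]

Provenance = Sequence[tuple[str, str, int]]


@dataclass
class FeatureSelection:
    """Audit record of a fitted selection: method, what was kept, fit statistics."""

    method: str
    selected: list
    fit_stats: dict = field(default_factory=dict)


@dataclass
class FeatureWeightReport:
    """Per-feature |weight|, per-band cumulative weight, and descending rankings."""

    feature_weights: np.ndarray
    band_weights: dict[str, float]
    feature_ranking: np.ndarray  # permutation of feature indices, largest first
    band_ranking: list[str]  # band names, largest cumulative weight first


class Standardizer:
    """Z-score by training mean and standard deviation (zero-variance guard)."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class PCASelector:
    """Project onto the top-k principal components of the training rows."""

    method = "pca"

    def __init__(self, k: int = 20):
        if k < 1:
            raise ParameterError("k must be >= 1")
        self.k = k

    def fit(self, X: np.ndarray, y=None, provenance: Provenance | None = None) -> "PCASelector":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.k > min(n - 1, p):
            raise ParameterError(
                f"k = {self.k} exceeds min(n_samples - 1, n_features) = {min(n - 1, p)}"
            )
        self._pca = PCA(n_components=self.k, svd_solver="full").fit(X)
        self.selection = FeatureSelection(
            method="pca",
            selected=[f"PC{i + 1}" for i in range(self.k)],
            fit_stats={
                "eigenvalues": self._pca.explained_variance_.tolist(),
                "explained_variance_ratio": self._pca.explained_variance_ratio_.tolist(),
            },
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float))

    @property
    def components_(self) -> np.ndarray:
        return self._pca.components_

    @property
    def eigenvalues_(self) -> np.ndarray:
        return self._pca.explained_variance_


def pca_reduce(X: np.ndarray, k: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Fit PCA on X and return (components, transformed X)."""
    sel = PCASelector(k).fit(X)
    return sel.components_, sel.transform(X)


# ---------------------------------------------------------------------------
# Wavelet coefficient selection
# ---------------------------------------------------------------------------

class WaveletSelector:
    """Keep the largest wavelet coefficients, decomposing each channel block alone.

    Each row's features are split into channel blocks (via provenance), each
    block gets a full Daubechies-4 decomposition at the maximum level its
    length permits (symmetric boundary extension), and the coefficients are
    ranked by mean |value| over the training rows.  The global top
    ``keep_fraction`` positions are retained; validation/test rows are reduced
    to the same positions.
    """

    method = "wavelet"

    def __init__(self, keep_fraction: float = 0.10, wavelet: str = "db4"):
        if not 0 < keep_fraction <= 1:
            raise ParameterError("keep_fraction must be in (0, 1]")
        self.keep_fraction = keep_fraction
        self.wavelet = wavelet

    def _blocks(self, n_features: int, provenance: Provenance | None) -> list[slice]:
        if provenance is None:
            return [slice(0, n_features)]
        if len(provenance) != n_features:
            raise ParameterError("provenance length must match feature count")
        blocks: list[slice] = []
        start = 0
        for i in range(1, n_features + 1):
            if i == n_features or provenance[i][0] != provenance[start][0]:
                blocks.append(slice(start, i))
                start = i
        return blocks

    def _decompose_row(self, row: np.ndarray) -> np.ndarray:
        parts = []
        for blk in self._block_slices:
            seg = row[blk]
            if self._pad:
                seg = np.concatenate([seg, np.zeros(self._pad_to - seg.size)])
            coeffs = pywt.wavedec(seg, self.wavelet, mode="symmetric", level=self._level)
            parts.append(np.concatenate(coeffs))
        return np.concatenate(parts)

    def fit(self, X: np.ndarray, y=None, provenance: Provenance | None = None) -> "WaveletSelector":
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        self._block_slices = self._blocks(p, provenance)
        block_len = self._block_slices[0].stop - self._block_slices[0].start
        if any(b.stop - b.start != block_len for b in self._block_slices):
            raise ParameterError("all channel blocks must have equal length")

        w = pywt.Wavelet(self.wavelet)
        self._pad = block_len < w.dec_len
        self._pad_to = w.dec_len if self._pad else block_len
        self._level = pywt.dwt_max_level(self._pad_to, w.dec_len)

        C = np.vstack([self._decompose_row(row) for row in X])
        self._n_coeffs = C.shape[1]
        magnitude = np.abs(C).mean(axis=0)
        n_keep = max(1, int(np.ceil(self.keep_fraction * self._n_coeffs)))
        order = np.argsort(-magnitude, kind="stable")
        self.keep_idx_ = np.sort(order[:n_keep])
        self.selection = FeatureSelection(
            method="wavelet",
            selected=self.keep_idx_.tolist(),
            fit_stats={
                "n_coefficients": int(self._n_coeffs),
                "level": int(self._level),
                "zero_padded": bool(self._pad),
                "retained_energy_fraction": float(
                    (magnitude[self.keep_idx_] ** 2).sum() / max((magnitude**2).sum(), 1e-300)
                ),
            },
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        C = np.vstack([self._decompose_row(row) for row in X])
        return C[:, self.keep_idx_]

    def decompose(self, X: np.ndarray) -> np.ndarray:
        """Full coefficient matrix (all positions), for inspection and tests."""
        return np.vstack([self._decompose_row(np.asarray(row, dtype=float)) for row in X])

    def inverse_transform_full(self, C: np.ndarray) -> np.ndarray:
        """Reconstruct rows from full coefficient matrices (keep_fraction = 1 path)."""
        C = np.asarray(C, dtype=float)
        out_rows = []
        # rebuild the per-block coefficient structure from a template decomposition
        template = pywt.wavedec(
            np.zeros(self._pad_to), self.wavelet, mode="symmetric", level=self._level
        )
        sizes = [c.size for c in template]
        per_block = sum(sizes)
        for row in C:
            segs = []
            for bi, blk in enumerate(self._block_slices):
                flat = row[bi * per_block : (bi + 1) * per_block]
                coeffs, pos = [], 0
                for s in sizes:
                    coeffs.append(flat[pos : pos + s])
                    pos += s
                rec = pywt.waverec(coeffs, self.wavelet, mode="symmetric")
                segs.append(rec[: blk.stop - blk.start])
            out_rows.append(np.concatenate(segs))
        return np.vstack(out_rows)


def wavelet_select(
    X: np.ndarray, provenance: Provenance | None = None, keep_fraction: float = 0.10
) -> tuple[WaveletSelector, np.ndarray]:
    """Fit the wavelet selector and return (selector, reduced X)."""
    sel = WaveletSelector(keep_fraction).fit(X, provenance=provenance)
    return sel, sel.transform(X)


# ---------------------------------------------------------------------------
# Stepwise linear discriminant analysis
# ---------------------------------------------------------------------------

def _ols_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS of y on [1, X]; returns (beta incl. intercept, p-values per column of X, RSS)."""
    n = X.shape[0]
    D = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = float(resid @ resid)
    dof = n - D.shape[1]
    if dof <= 0:
        return beta, np.zeros(X.shape[1]), rss
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(D.T @ D)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, p[1:], rss


class SWLDASelector:
    """Stepwise linear discriminant analysis: selector and linear classifier.

    Forward steps add the candidate feature whose partial F-test p-value is
    smallest and below ``alpha_in``; backward steps drop any included feature
    whose p-value rises above ``alpha_out``; iteration continues to a fixed
    point or until ``max_features`` (capped at the number of training samples
    — the discriminant cannot use more features than samples).  The final
    least-squares discriminant on the selected features doubles as a linear
    classifier: predict sign(score).

    If no feature ever passes ``alpha_in`` the selection is empty; this is a
    warning status (``empty_``), not an exception, and prediction falls back
    to the majority training class.
    """

    method = "swlda"

    def __init__(self, alpha_in: float = 0.10, alpha_out: float = 0.15,
                 max_features: int | None = None):
        if not 0 < alpha_in < 1 or not 0 < alpha_out < 1:
            raise ParameterError("alpha thresholds must be in (0, 1)")
        self.alpha_in = alpha_in
        self.alpha_out = alpha_out
        self.max_features = max_features

    def fit(self, X: np.ndarray, y: np.ndarray, provenance: Provenance | None = None) -> "SWLDASelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        classes = np.unique(y)
        if classes.size != 2:
            raise ParameterError("SWLDA requires exactly two classes")
        yc = np.where(y == classes[1], 1.0, -1.0)
        cap = n if self.max_features is None else min(self.max_features, n)

        selected: list[int] = []
        pvals_trace: list[float] = []
        changed = True
        while changed and len(selected) < cap:
            changed = False
            # forward: vectorized partial-F screen of all candidates
            j, p_j = self._best_candidate(X, yc, selected)
            if j is not None and p_j < self.alpha_in:
                selected.append(j)
                pvals_trace.append(p_j)
                changed = True
            # backward: drop anything that no longer earns its place
            while len(selected) > 1:
                _, pv, _ = _ols_pvalues(X[:, selected], yc)
                worst = int(np.argmax(pv))
                if pv[worst] > self.alpha_out:
                    selected.pop(worst)
                    changed = True
                else:
                    break

        self.classes_ = classes
        self.selected_ = list(selected)
        self.empty_ = len(selected) == 0
        self.majority_ = classes[np.argmax([np.sum(y == c) for c in classes])]
        if not self.empty_:
            beta, pv, _ = _ols_pvalues(X[:, selected], yc)
            self.coef_ = beta  # intercept first
            final_p = pv.tolist()
        else:
            self.coef_ = np.zeros(1)
            final_p = []
        self.selection = FeatureSelection(
            method="swlda",
            selected=list(selected),
            fit_stats={"inclusion_pvalues": pvals_trace, "final_pvalues": final_p,
                       "empty": self.empty_},
        )
        return self

    def _best_candidate(self, X: np.ndarray, yc: np.ndarray,
                        selected: list[int]) -> tuple[int | None, float]:
        n, p = X.shape
        # orthonormal basis of [1, X_selected]
        D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        Q, _ = np.linalg.qr(D)
        y_res = yc - Q @ (Q.T @ yc)
        rss0 = float(y_res @ y_res)
        dof = n - D.shape[1] - 1
        if dof <= 0 or rss0 <= 1e-12:
            return None, 1.0
        R = X - Q @ (Q.T @ X)  # residualized candidates
        mask = np.ones(p, dtype=bool)
        mask[selected] = False
        d = np.einsum("ij,ij->j", R, R)
        s = R.T @ y_res
        with np.errstate(divide="ignore", invalid="ignore"):
            drss = np.where(d > 1e-12, s**2 / np.where(d > 1e-12, d, 1.0), 0.0)
        rss1 = np.maximum(rss0 - drss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(rss1 > 1e-12, drss / (rss1 / dof), np.inf)
        pv = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 0.0, F), 1, dof))
        pv = np.where(mask & (d > 1e-12), pv, 1.0)
        j = int(np.argmin(pv))
        return (j, float(pv[j])) if pv[j] < 1.0 else (None, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.selected_]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        if self.empty_:
            return np.zeros(np.asarray(X).shape[0])
        Xs = self.transform(X)
        return self.coef_[0] + Xs @ self.coef_[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.empty_:
            return np.full(np.asarray(X).shape[0], self.majority_)
        scores = self.decision_scores(X)
        out = np.where(scores >= 0, self.classes_[1], self.classes_[0])
        return out


def swlda_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_in: float = 0.10,
    alpha_out: float = 0.15,
    max_features: int | None = None,
) -> tuple[list[int], SWLDASelector]:
    """Run the stepwise selection; returns (ordered selected indices, fitted model)."""
    sel = SWLDASelector(alpha_in, alpha_out, max_features).fit(X, y)
    return sel.selected_, sel


# ---------------------------------------------------------------------------
# SVM weight ranking and band restriction
# ---------------------------------------------------------------------------

def svm_weight_ranking(model, provenance: Provenance) -> FeatureWeightReport:
    """Per-feature |w| of a linear-kernel SVM, accumulated per band.

    The primal weight vector w = sum_m alpha_m y_m x_m exists only for the
    linear kernel; for an RBF model the feature map is implicit, so callers
    must refit with a linear kernel for ranking purposes.
    """
    if model.params.kernel != "linear":
        raise ParameterError(
            "feature weights are defined only for a linear kernel; refit the "
            "ranking model with kernel='linear' (the RBF model remains the classifier)"
        )
    w = np.abs(model.primal_weights())
    if len(provenance) != w.size:
        raise ParameterError("provenance length must match the model's feature count")
    band_weights: dict[str, float] = {}
    for wi, (_, band, _) in zip(w, provenance):
        band_weights[band] = band_weights.get(band, 0.0) + float(wi)
    feature_ranking = np.argsort(-w, kind="stable")
    band_ranking = sorted(band_weights, key=lambda b: -band_weights[b])
    return FeatureWeightReport(
        feature_weights=w,
        band_weights=band_weights,
        feature_ranking=feature_ranking,
        band_ranking=band_ranking,
    )


def band_restrict(
    X: np.ndarray, provenance: Provenance, band: str
) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """Keep only the columns whose provenance band matches, order preserved."""
    bands_present = {p[1] for p in provenance}
    if band not in bands_present:
        raise ParameterError(f"band {band!r} not present; have {sorted(bands_present)}")
    idx = [i for i, p in enumerate(provenance) if p[1] == band]
    return np.asarray(X, dtype=float)[:, idx], [provenance[i] for i in idx]


class BandRestrictSelector:
    """Selector wrapper around band_restrict (static column choice; no fitting)."""

    def __init__(self, band: str = "theta"):
        self.band = band

    @property
    def method(self) -> str:
        return f"band_restrict({self.band})"

    def fit(self, X: np.ndarray, y=None, provenance: Provenance | None = None) -> "BandRestrictSelector":
        if provenance is None:
            raise ParameterError("band_restrict requires a provenance index")
        bands_present = {p[1] for p in provenance}
        if self.band not in bands_present:
            raise ParameterError(
                f"band {self.band!r} not present; have {sorted(bands_present)}"
            )
        self.idx_ = np.asarray([i for i, p in enumerate(provenance) if p[1] == self.band])
        self.selection = FeatureSelection(
            method=self.method, selected=self.idx_.tolist()
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.idx_]


class IdentitySelector:
    """No feature selection."""

    method = "none"

    def fit(self, X: np.ndarray, y=None, provenance: Provenance | None = None) -> "IdentitySelector":
        self.selection = FeatureSelection(method="none", selected=[])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)


def make_selector(method: str, **params):
    """Selector factory: none | pca | wavelet | swlda | band_restrict."""
    registry = {
        "none": IdentitySelector,
        "pca": PCASelector,
        "wavelet": WaveletSelector,
        "swlda": SWLDASelector,
        "band_restrict": BandRestrictSelector,
    }
    if method not in registry:
        raise ParameterError(f"unknown selector {method!r}; choose from {sorted(registry)}")
    return registry[method](**params)
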