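"""Gaussian discriminant analysis (LDA/QDA) from first principles.

Each class n is modelled as a multivariate Gaussian with mean mu_n,
covariance Sigma_n and prior pi_n,

    f_n(x) = (2 pi)^(-k/2) |Sigma_n|^(-1/2)
             exp( -1/2 (x - mu_n)^T Sigma_n^{-1} (x - mu_n) ).

The quadratic discriminant score drops the shared (k/2) log(2 pi) term,

    delta_n(x) = -1/2 log|Sigma_n| - 1/2 (x - mu_n)^T Sigma_n^{-1} (x - mu_n)
                 + log pi_n,

and the linear score replaces every Sigma_n with the pooled covariance
Sigma, after which the terms quadratic in x cancel across classes:

    delta_n(x) = x^T Sigma^{-1} mu_n - 1/2 mu_n^T Sigma^{-1} mu_n + log pi_n.

Prediction is the argmax over classes; substituting the pooled covariance
for every class covariance makes the two rules identical.

The model object follows the statsmodels convention: build a
:class:`GaussianDiscriminant` from data, call :meth:`~GaussianDiscriminant.fit`
to obtain a :class:`GaussianDiscriminantResults` carrying estimates,
scores, posteriors, decision grids and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import SingularCovarianceError

Mode = str  # "lda" | "qda"

#: Canonical class ordering used for tie-breaking and table layout.
CANONICAL_ORDER = ("N", "M", "PM")

LOG_2PI = float(np.log(2.0 * np.pi))


def _default_class_order(labels: np.ndarray) -> Tuple[str, ...]:
    present = list(dict.fromkeys(labels.tolist()))
    if set(present) <= set(CANONICAL_ORDER):
        return tuple(c for c in CANONICAL_ORDER if c in present)
    return tuple(sorted(present))


def gaussian_density(
    x: np.ndarray, mean: np.ndarray, covariance: np.ndarray
) -> Union[float, np.ndarray]:
    """Multivariate normal density f(x; mean, covariance).

    ``x`` may be a single k-vector or an (n, k) array.  Computed in log
    space via a Cholesky factorization; the covariance must be positive
    definite.
    """
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    k = mean.size
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("covariance is not positive definite") from exc
    diff = xa - mean
    z = np.linalg.solve(chol, diff.T)  # (k, n)
    maha = np.sum(z**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    logpdf = -0.5 * (k * LOG_2PI + logdet + maha)
    out = np.exp(logpdf)
    if np.asarray(x).ndim == 1:
        return float(out[0])
    return out


class GaussianDiscriminant:
    """Gaussian classification model over a labeled feature table.

    Parameters
    ----------
    features : array-like, shape (n, k)
        Feature rows (here typically k=2: intensity and heterogeneity).
    labels : sequence of str, length n
        Class label per row.
    class_order : sequence of str, optional
        Declared class ordering; defaults to N, M, PM for lesion labels
        (the table order, also the tie-breaking order) and sorted order
        otherwise.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: Sequence[str],
        class_order: Optional[Sequence[str]] = None,
    ) -> None:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {features.shape}")
        labels = np.asarray(labels)
        if labels.shape[0] != features.shape[0]:
            raise ValueError("features and labels length mismatch")
        if class_order is None:
            class_order = _default_class_order(labels)
        else:
            class_order = tuple(class_order)
            unknown = set(labels.tolist()) - set(class_order)
            if unknown:
                raise ValueError(f"labels {unknown} not in class_order")
        if len(class_order) < 2:
            raise ValueError("need at least 2 classes")
        self.features = features
        self.labels = labels
        self.class_order = class_order
        self.k = features.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: Sequence[str] = ("intensity", "sd"),
        label_col: str = "label",
        class_order: Optional[Sequence[str]] = None,
    ) -> "GaussianDiscriminant":
        missing = [c for c in (*feature_cols, label_col) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing}")
        return cls(
            df[list(feature_cols)].to_numpy(dtype=float),
            df[label_col].to_numpy(),
            class_order=class_order,
        )

    def fit(
        self,
        regularization: float = 0.0,
        priors: Union[str, Sequence[float]] = "empirical",
    ) -> "GaussianDiscriminantResults":
        """Estimate per-class Gaussians and the pooled covariance.

        mu_n is the class sample mean; Sigma_n the class sample covariance
        (n_c - 1 denominator) plus ``regularization`` times the identity;
        the pooled Sigma is the (n_c - 1)-weighted average of the class
        covariances; pi_n defaults to the empirical class frequency.
        """
        if regularization < 0:
            raise ValueError("regularization must be nonnegative")
        K, k = len(self.class_order), self.k
        means = np.empty((K, k))
        covs = np.empty((K, k, k))
        counts = np.empty(K, dtype=int)
        for i, cls_label in enumerate(self.class_order):
            rows = self.features[self.labels == cls_label]
            if rows.shape[0] < 2:
                raise ValueError(
                    f"class {cls_label!r} has {rows.shape[0]} samples; need >= 2"
                )
            counts[i] = rows.shape[0]
            means[i] = rows.mean(axis=0)
            covs[i] = np.cov(rows, rowvar=False, ddof=1) + regularization * np.eye(k)
        weights = counts - 1
        pooled = np.tensordot(weights, covs, axes=1) / weights.sum()

        if isinstance(priors, str):
            if priors == "empirical":
                pri = counts / counts.sum()
            elif priors == "uniform":
                pri = np.full(K, 1.0 / K)
            else:
                raise ValueError(f"unknown priors mode {priors!r}")
        else:
            pri = np.asarray(priors, dtype=float)
            if pri.shape != (K,) or not np.isclose(pri.sum(), 1.0) or (pri <= 0).any():
                raise ValueError("priors must be K positive values summing to 1")

        def _chol(mat: np.ndarray, what: str) -> np.ndarray:
            try:
                return np.linalg.cholesky(mat)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    f"{what} is singular; pass regularization > 0 to ridge it"
                ) from exc

        chols = np.stack([_chol(covs[i], f"covariance of class {self.class_order[i]!r}")
                          for i in range(K)])
        pooled_chol = _chol(pooled, "pooled covariance")
        return GaussianDiscriminantResults(
            model=self,
            means=means,
            covariances=covs,
            pooled_covariance=pooled,
            priors=pri,
            counts=counts,
            regularization=regularization,
            _chols=chols,
            _pooled_chol=pooled_chol,
        )


@dataclass(frozen=True)
class DecisionGrid:
    """Class prediction at every node of a rectangular feature grid."""

    x: np.ndarray  # (nx,)
    y: np.ndarray  # (ny,)
    label_index: np.ndarray  # (ny, nx) int, indexes classes
    classes: Tuple[str, ...]
    mode: str
    class_means: np.ndarray  # (K, 2)

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        labels = np.asarray(self.classes)[self.label_index]
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "label": labels.ravel()}
        )

    def plot(self, ax=None, features=None, labels=None):
        """Render the grid (and optionally the training scatter)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.contourf(
            self.x, self.y, self.label_index,
            levels=np.arange(len(self.classes) + 1) - 0.5,
            alpha=0.25,
        )
        if features is not None and labels is not None:
            for i, cls_label in enumerate(self.classes):
                pts = np.asarray(features)[np.asarray(labels) == cls_label]
                ax.scatter(pts[:, 0], pts[:, 1], s=8, label=cls_label)
            ax.legend()
        ax.scatter(
            self.class_means[:, 0], self.class_means[:, 1],
            c="k", s=60, marker="o",
        )
        ax.set_xlabel("intensity")
        ax.set_ylabel("sd of intensity")
        ax.set_title(f"{self.mode.upper()} decision regions")
        return ax


class GaussianDiscriminantResults:
    """Fitted Gaussian discriminant model.

    Exposes the estimates (``means``, ``covariances``,
    ``pooled_covariance``, ``priors``), the LDA/QDA discriminant scores,
    posterior class probabilities, label prediction, decision-boundary
    grids, JSON round-tripping and a text ``summary()``.
    """

    def __init__(
        self,
        model: Optional[GaussianDiscriminant],
        means: np.ndarray,
        covariances: np.ndarray,
        pooled_covariance: np.ndarray,
        priors: np.ndarray,
        counts: np.ndarray,
        regularization: float,
        _chols: Optional[np.ndarray] = None,
        _pooled_chol: Optional[np.ndarray] = None,
        class_order: Optional[Tuple[str, ...]] = None,
    ) -> None:
        self.model = model
        self.classes = tuple(class_order or model.class_order)
        self.means = np.asarray(means, dtype=float)
        self.covariances = np.asarray(covariances, dtype=float)
        self.pooled_covariance = np.asarray(pooled_covariance, dtype=float)
        self.priors = np.asarray(priors, dtype=float)
        self.counts = np.asarray(counts, dtype=int)
        self.regularization = float(regularization)
        self.k = self.means.shape[1]
        if _chols is None:
            _chols = np.stack([np.linalg.cholesky(c) for c in self.covariances])
        if _pooled_chol is None:
            _pooled_chol = np.linalg.cholesky(self.pooled_covariance)
        self._chols = _chols
        self._pooled_chol = _pooled_chol
        self._logdets = 2.0 * np.log(
            np.stack([np.diag(c) for c in self._chols])
        ).sum(axis=1)
        self._pooled_logdet = 2.0 * float(np.log(np.diag(_pooled_chol)).sum())

    # -- scores -----------------------------------------------------------

    def _as_2d(self, x: np.ndarray) -> Tuple[np.ndarray, bool]:
        xa = np.asarray(x, dtype=float)
        single = xa.ndim == 1
        xa = np.atleast_2d(xa)
        if xa.shape[1] != self.k:
            raise ValueError(
                f"expected {self.k}-dimensional features, got {xa.shape[1]}"
            )
        return xa, single

    def _maha(self, x2d: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> np.ndarray:
        z = np.linalg.solve(chol, (x2d - mean).T)
        return np.sum(z**2, axis=0)

    def qda_scores(self, x: np.ndarray) -> np.ndarray:
        """Quadratic discriminant values delta_n(x), shape (n, K)."""
        x2d, single = self._as_2d(x)
        out = np.empty((x2d.shape[0], len(self.classes)))
        for i in range(len(self.classes)):
            out[:, i] = (
                -0.5 * self._logdets[i]
                - 0.5 * self._maha(x2d, self.means[i], self._chols[i])
                + np.log(self.priors[i])
            )
        return out[0] if single else out

    def lda_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant values using the pooled covariance."""
        x2d, single = self._as_2d(x)
        chol = self._pooled_chol
        # a_n = Sigma^{-1} mu_n via two triangular solves
        a = np.linalg.solve(chol.T, np.linalg.solve(chol, self.means.T))  # (k, K)
        out = x2d @ a - 0.5 * np.sum(self.means.T * a, axis=0) + np.log(self.priors)
        return out[0] if single else out

    def scores(self, x: np.ndarray, mode: Mode = "qda") -> np.ndarray:
        if mode == "qda":
            return self.qda_scores(x)
        if mode == "lda":
            return self.lda_scores(x)
        raise ValueError(f"unknown mode {mode!r}")

    def log_likelihoods(self, x: np.ndarray, mode: Mode = "qda") -> np.ndarray:
        """log f_n(x) per class (full normalized Gaussian log-density)."""
        x2d, single = self._as_2d(x)
        out = np.empty((x2d.shape[0], len(self.classes)))
        for i in range(len(self.classes)):
            if mode == "qda":
                chol, logdet = self._chols[i], self._logdets[i]
            elif mode == "lda":
                chol, logdet = self._pooled_chol, self._pooled_logdet
            else:
                raise ValueError(f"unknown mode {mode!r}")
            out[:, i] = -0.5 * (
                self.k * LOG_2PI + logdet + self._maha(x2d, self.means[i], chol)
            )
        return out[0] if single else out

    def posterior(self, x: np.ndarray, mode: Mode = "qda") -> np.ndarray:
        """Posterior class probabilities pi_n f_n(x) / sum_m pi_m f_m(x)."""
        logl = self.log_likelihoods(x, mode=mode)
        logp = logl + np.log(self.priors)
        return np.exp(logp - logsumexp(logp, axis=-1, keepdims=True))

    def predict(self, x: np.ndarray, mode: Mode = "qda") -> np.ndarray:
        """Argmax-score class label; ties go to the lowest class index."""
        sc = self.scores(x, mode=mode)
        idx = np.argmax(np.atleast_2d(sc), axis=1)
        labels = np.asarray(self.classes, dtype=object)[idx]
        if np.asarray(x).ndim == 1:
            return labels[0]
        return labels

    # -- derived artifacts ------------------------------------------------

    def with_pooled_covariances(self) -> "GaussianDiscriminantResults":
        """Copy of the fit with every class covariance replaced by the
        pooled covariance (under which QDA collapses onto LDA)."""
        K = len(self.classes)
        return GaussianDiscriminantResults(
            model=self.model,
            means=self.means,
            covariances=np.repeat(self.pooled_covariance[None], K, axis=0),
            pooled_covariance=self.pooled_covariance,
            priors=self.priors,
            counts=self.counts,
            regularization=self.regularization,
            class_order=self.classes,
        )

    def decision_grid(
        self,
        bounds: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None,
        resolution: int = 200,
        mode: Mode = "lda",
        margin: float = 0.1,
    ) -> DecisionGrid:
        """Predicted label on a rectangular grid covering the features.

        ``bounds`` is ((xmin, xmax), (ymin, ymax)); by default the
        training features' bounding box expanded by ``margin`` (fraction
        of each side).
        """
        if self.k != 2:
            raise ValueError("decision grids require a 2-D feature space")
        if bounds is None:
            if self.model is None:
                raise ValueError("no training features; pass bounds explicitly")
            feats = self.model.features
            lo, hi = feats.min(axis=0), feats.max(axis=0)
            pad = margin * (hi - lo)
            bounds = ((lo[0] - pad[0], hi[0] + pad[0]),
                      (lo[1] - pad[1], hi[1] + pad[1]))
        (x0, x1), (y0, y1) = bounds
        xs = np.linspace(x0, x1, resolution)
        ys = np.linspace(y0, y1, resolution)
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        sc = self.scores(pts, mode=mode)
        idx = np.argmax(sc, axis=1).reshape(resolution, resolution)
        return DecisionGrid(
            x=xs, y=ys, label_index=idx, classes=self.classes,
            mode=mode, class_means=self.means.copy(),
        )

    # -- reporting / persistence -----------------------------------------

    def summary(self) -> str:
        lines = [
            "Gaussian discriminant analysis",
            "=" * 46,
            f"classes:        {', '.join(self.classes)}",
            f"dimension k:    {self.k}",
            f"regularization: {self.regularization:g}",
            "",
            f"{'class':>6} {'n':>5} {'prior':>8} {'mean':>24} {'|Sigma_n|':>12}",
        ]
        for i, cls_label in enumerate(self.classes):
            mean = np.array2string(self.means[i], precision=4)
            det = float(np.linalg.det(self.covariances[i]))
            lines.append(
                f"{cls_label:>6} {self.counts[i]:>5d} {self.priors[i]:>8.4f} "
                f"{mean:>24} {det:>12.4g}"
            )
        lines.append("")
        lines.append("pooled covariance:")
        lines.append(np.array2string(self.pooled_covariance, precision=6))
        return "\n".join(lines)

    def to_dict(self) -> Dict:
        return {
            "classes": list(self.classes),
            "k": self.k,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "counts": self.counts.tolist(),
            "regularization": self.regularization,
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "GaussianDiscriminantResults":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        return cls(
            model=None,
            means=np.array(data["means"]),
            covariances=np.array(data["covariances"]),
            pooled_covariance=np.array(data["pooled_covariance"]),
            priors=np.array(data["priors"]),
            counts=np.array(data["counts"]),
            regularization=data["regularization"],
            class_order=tuple(data["classes"]),
        )


# -- functional wrappers (one fitted-results argument) -----------------------


def fit_gaussian_classes(
    data: pd.DataFrame,
    regularization: float = 0.0,
    feature_cols: Sequence[str] = ("intensity", "sd"),
    label_col: str = "label",
    class_order: Optional[Sequence[str]] = None,
    priors: Union[str, Sequence[float]] = "empirical",
) -> GaussianDiscriminantResults:
    """Fit per-class Gaussians from a labeled feature table."""
    model = GaussianDiscriminant.from_dataframe(
        data, feature_cols=feature_cols, label_col=label_col, class_order=class_order
    )
    return model.fit(regularization=regularization, priors=priors)


def qda_score(
    x: np.ndarray, results: GaussianDiscriminantResults, class_index: int
) -> Union[float, np.ndarray]:
    """Quadratic discriminant value delta_n(x) for one class."""
    sc = results.qda_scores(x)
    return sc[..., class_index] if np.ndim(sc) > 1 else float(np.atleast_1d(sc)[class_index])


def lda_score(
    x: np.ndarray, results: GaussianDiscriminantResults, class_index: int
) -> Union[float, np.ndarray]:
    """Linear discriminant value delta_n(x) for one class."""
    sc = results.lda_scores(x)
    return sc[..., class_index] if np.ndim(sc) > 1 else float(np.atleast_1d(sc)[class_index])
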