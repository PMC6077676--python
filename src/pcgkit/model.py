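"""RBF-kernel SVM models for quality estimation and diagnosis.

Two binary soft-margin SVMs drive the pipeline: a signal-quality model
(labels 1 clean / 0 noisy) and a diagnosis model (labels +1 abnormal /
-1 normal).  Both share one model class, organised like a statsmodels
model: :class:`PcgSvm` is built from a feature matrix and labels, and
``fit()`` returns a :class:`PcgSvmResults` object carrying the support
vectors, dual coefficients, preprocessing statistics and a ``summary()``
table.

The kernel is the Gaussian radial basis function

    k(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2))

with kernel width ``sigma = 14`` by default.  A non-squared variant
``exp(-||x_i - x_j|| / sigma)`` is available via ``kernel="rbf_nonsquared"``
and a linear kernel via ``kernel="linear"`` for comparison runs.  Because
the 515 features mix units (seconds, ratios, spectrum magnitudes), columns
are z-score standardized with training-split statistics before the kernel;
missing values are imputed with training-split column medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances
from sklearn.svm import SVC

from .io_prep import FeatureTable

__all__ = [
    "SvmConfig",
    "PcgSvm",
    "PcgSvmResults",
    "Decision",
    "classify_records",
    "select_top_features",
]


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters.

    sigma is the Gaussian kernel width; C the soft-margin penalty.
    """

    kernel: str = "rbf"  # rbf | rbf_nonsquared | linear
    sigma: float = 14.0
    C: float = 1.0
    class_weighting: str = "none"  # none | balanced
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.C <= 0:
            raise ValueError("sigma and C must be positive")
        if self.kernel not in ("rbf", "rbf_nonsquared", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


def _as_matrix(features, feature_names=None):
    if isinstance(features, FeatureTable):
        return features.values, list(features.feature_names)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=np.float64), list(features.columns)
    X = np.asarray(features, dtype=np.float64)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


class PcgSvm:
    """Soft-margin RBF-SVM model over a (possibly incomplete) feature matrix.

    Parameters
    ----------
    features : FeatureTable, DataFrame or ndarray
        Training design matrix; NaN marks missing values.
    labels : array-like
        Binary labels ({1, 0} for quality, {+1, -1} for diagnosis).
    config : SvmConfig, optional
    """

    def __init__(self, features, labels, config: SvmConfig | None = None, feature_names=None):
        self.X, self.feature_names = _as_matrix(features, feature_names)
        self.y = np.asarray(labels)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels and feature rows misaligned")
        self.config = config if config is not None else SvmConfig()
        self.classes = np.unique(self.y)
        if len(self.classes) < 2:
            raise ValueError("training data contains a single class")

    @classmethod
    def from_feature_table(cls, table: FeatureTable, labels, config: SvmConfig | None = None):
        return cls(table, labels, config=config)

    def fit(self) -> "PcgSvmResults":
        cfg = self.config
        X = self.X.copy()

        all_missing = np.all(np.isnan(X), axis=0)
        if np.any(all_missing):
            warnings.warn(
                f"dropping {int(np.sum(all_missing))} all-missing feature columns",
                stacklevel=2,
            )
        kept = ~all_missing
        X = X[:, kept]
        kept_names = [n for n, k in zip(self.feature_names, kept) if k]

        medians = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), medians[None, :], X)

        mean = np.mean(X, axis=0)
        sd = np.std(X, axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (X - mean) / sd_safe

        class_weight = "balanced" if cfg.class_weighting == "balanced" else None
        if cfg.kernel == "rbf":
            svc = SVC(
                C=cfg.C,
                kernel="rbf",
                gamma=1.0 / (2.0 * cfg.sigma**2),
                class_weight=class_weight,
                random_state=cfg.seed,
            )
        elif cfg.kernel == "linear":
            svc = SVC(C=cfg.C, kernel="linear", class_weight=class_weight, random_state=cfg.seed)
        else:  # non-squared exponential form

            def _kernel(A, B, sigma=cfg.sigma):
                return np.exp(-pairwise_distances(A, B) / sigma)

            svc = SVC(C=cfg.C, kernel=_kernel, class_weight=class_weight, random_state=cfg.seed)
        svc.fit(Z, self.y)

        return PcgSvmResults(
            model=self,
            svc=svc,
            kept_names=kept_names,
            kept_mask=kept,
            imputation=medians,
            standard_mean=mean,
            standard_sd=sd_safe,
        )


@dataclass
class PcgSvmResults:
    """Fitted SVM with its preprocessing statistics.

    Exposes the dual solution (support vectors, coefficients alpha_i, bias)
    and prediction on new feature matrices with the training schema.
    """

    model: PcgSvm
    svc: SVC
    kept_names: list[str]
    kept_mask: np.ndarray
    imputation: np.ndarray
    standard_mean: np.ndarray
    standard_sd: np.ndarray

    # -- dual solution ------------------------------------------------------

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_signed_alphas(self) -> np.ndarray:
        """alpha_i * y_i for each support vector (sums to ~0)."""
        return self.svc.dual_coef_.ravel()

    @property
    def alphas(self) -> np.ndarray:
        """The dual coefficients alpha_i (all in [0, C])."""
        return np.abs(self.dual_signed_alphas)

    @property
    def bias(self) -> float:
        return float(self.svc.intercept_[0])

    # -- prediction ---------------------------------------------------------

    def _transform(self, features, feature_names=None) -> np.ndarray:
        X, names = _as_matrix(features, feature_names)
        if names != self.model.feature_names:
            missing = [n for n in self.model.feature_names if n not in names]
            if missing:
                raise ValueError(f"feature schema mismatch; missing columns: {missing[:5]}...")
            idx = [names.index(n) for n in self.model.feature_names]
            X = X[:, idx]
        X = X[:, self.kept_mask]
        X = np.where(np.isnan(X), self.imputation[None, :], X)
        return (X - self.standard_mean) / self.standard_sd

    def decision_function(self, features, feature_names=None) -> np.ndarray:
        """Signed margin of each record (positive side = larger class label)."""
        return self.svc.decision_function(self._transform(features, feature_names))

    def predict(self, features, feature_names=None) -> np.ndarray:
        """Predicted labels in the training label alphabet."""
        return self.svc.predict(self._transform(features, feature_names))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "PCG SVM results",
            "=" * 46,
            f"kernel:            {cfg.kernel}",
            f"sigma:             {cfg.sigma:g}",
            f"C:                 {cfg.C:g}",
            f"classes:           {self.model.classes.tolist()}",
            f"n observations:    {len(self.model.y)}",
            f"n features (kept): {len(self.kept_names)} of {len(self.model.feature_names)}",
            f"n support vectors: {int(np.sum(self.svc.n_support_))}"
            f" {self.svc.n_support_.tolist()} per class",
            f"bias b:            {self.bias:.6g}",
            f"sum alpha_i y_i:   {float(np.sum(self.dual_signed_alphas)):.3g}",
            f"max alpha_i:       {float(np.max(self.alphas)):.6g} (C = {cfg.C:g})",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted model (schema, stats, config) to one file."""
        import joblib

        joblib.dump(
            {
                "config": self.model.config,
                "feature_names": self.model.feature_names,
                "X": self.model.X,
                "y": self.model.y,
                "svc": self.svc,
                "kept_names": self.kept_names,
                "kept_mask": self.kept_mask,
                "imputation": self.imputation,
                "standard_mean": self.standard_mean,
                "standard_sd": self.standard_sd,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PcgSvmResults":
        import joblib

        d = joblib.load(path)
        model = PcgSvm(d["X"], d["y"], config=d["config"], feature_names=d["feature_names"])
        return cls(
            model=model,
            svc=d["svc"],
            kept_names=d["kept_names"],
            kept_mask=d["kept_mask"],
            imputation=d["imputation"],
            standard_mean=d["standard_mean"],
            standard_sd=d["standard_sd"],
        )


@dataclass
class Decision:
    """Three-way decision for one record: +1 abnormal, 0 uncertain, -1 normal."""

    record_id: str
    label: int
    quality: int
    margin: float


def classify_records(
    quality_results: PcgSvmResults,
    diagnosis_results: PcgSvmResults,
    features,
    record_ids: list[str] | None = None,
    tau: float = 0.3,
) -> list[Decision]:
    """Joint quality + diagnosis decision with an uncertainty rule.

    Quality is predicted first; a record is labeled 0 (uncertain) iff its
    predicted quality is 0 (noisy) AND the absolute diagnosis margin is
    below *tau*.  ``tau=0`` disables the uncertain output entirely;
    ``tau=inf`` sends every noisy record to uncertain.
    """
    if isinstance(features, FeatureTable):
        ids = list(features.record_ids)
    elif record_ids is not None:
        ids = list(record_ids)
    else:
        ids = [str(i) for i in range(_as_matrix(features)[0].shape[0])]
    quality = quality_results.predict(features)
    margins = diagnosis_results.decision_function(features)
    diag = diagnosis_results.predict(features)
    out = []
    for rid, q, mrg, d in zip(ids, quality, margins, diag):
        label = int(d)
        if int(q) == 0 and abs(float(mrg)) < tau:
            label = 0
        out.append(Decision(record_id=rid, label=label, quality=int(q), margin=float(mrg)))
    return out


def select_top_features(features, labels, k: int) -> list[str]:
    """The k features most absolutely correlated with the label.

    Correlations are computed on the given (training) data only; ties break
    by canonical column order.
    """
    from .scoring_eval import rank_features

    X, names = _as_matrix(features)
    if not 1 <= k <= len(names):
        raise ValueError(f"k={k} out of range 1..{len(names)}")
    report = rank_features(
        FeatureTable(
            record_ids=[str(i) for i in range(X.shape[0])],
            feature_names=names,
            values=X,
            domains=[],
        ),
        labels,
    )
    return list(report.table["feature"].iloc[:k])
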