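"""Two-class quadratic discriminant "D Score" classification.

The risk-stratification score is the difference of two per-class quadratic
polynomials in the normalized expression values CtS_1..CtS_p:

    C_pos = A + sum_i x_i H_i + sum_{i<=j} x_i x_j H_{i*j}
    C_neg = B + sum_i x_i L_i + sum_{i<=j} x_i x_j L_{i*j}
    D     = C_pos - C_neg,   call positive iff D > 0 (ties -> negative)

Those polynomials are exactly the class scores of quadratic discriminant
analysis: fitting class-conditional Gaussians N(mu_k, Sigma_k) with priors
pi_k and expanding each log-density plus log-prior,

    C_k(x) = log pi_k - 1/2 log|Sigma_k| - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k)
           = const_k + linear_k' x + x' quad_k x

with quad_k = -1/2 Sigma_k^{-1}, linear_k = Sigma_k^{-1} mu_k and
const_k = log pi_k - 1/2 log|Sigma_k| - 1/2 mu_k' Sigma_k^{-1} mu_k.
``DScoreClassifier`` fits the Gaussians (optionally with shrinkage towards
the diagonal of the pooled covariance, needed when one class is small
relative to the panel size) and exposes both routes: the coefficient
polynomial (the production path) and the Gaussian log-density (used to
verify the expansion identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .panels import CANCER, HIGHER_RISK, GenePanel

__all__ = [
    "DScoreClassifier",
    "PanelModel",
    "fit_stratifier",
    "fit_diagnoser",
    "score_profiles",
]


class DScoreClassifier(ClassifierMixin, BaseEstimator):
    """Two-class quadratic discriminant with an explicit D-score polynomial.

    Parameters
    ----------
    priors : {"proportional", "equal"} or array-like of shape (2,)
        Class priors. "proportional" uses training class frequencies
        (default; matches imbalanced clinical cohorts), "equal" uses 1/2
        each. An explicit pair is taken in the order of ``classes_``.
    shrinkage : float in [0, 1]
        Blend of each class covariance towards the diagonal of the pooled
        covariance: ``(1 - s) * S_k + s * diag(S_pooled)``. At 0 this is
        plain QDA; small positive values keep covariances invertible when
        a class has few samples per feature.
    positive_class : label or None
        The class whose score enters D with a plus sign (called when
        D > 0). Defaults to ``classes_[1]`` after fitting.
    task : {"stratification", "diagnosis"}
        Metadata tag carried into reports and serialized models.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    positive_class_, negative_class_ : the resolved labels
    means_ : ndarray (2, p) — class means, row 0 = positive class
    covariances_ : ndarray (2, p, p) — shrunk class covariances
    priors_ : ndarray (2,)
    constants_, linears_, quads_ : expanded polynomial coefficients,
        row 0 = positive class; ``quads_`` are symmetric
    """

    def __init__(
        self,
        priors: str | Sequence[float] = "proportional",
        shrinkage: float = 0.1,
        positive_class=None,
        task: str = "stratification",
    ):
        self.priors = priors
        self.shrinkage = shrinkage
        self.positive_class = positive_class
        self.task = task

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if hasattr(X, "shape") and X.shape[1] < 1:
            raise ValueError("at least one feature required")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(
                f"exactly two classes required, got {classes.tolist()}"
            )
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ValueError(f"classes with fewer than 2 samples: {small}")
        self.classes_ = classes

        pos = self.positive_class if self.positive_class is not None else classes[1]
        if pos not in classes:
            raise ValueError(
                f"positive_class {pos!r} not among fitted classes {classes.tolist()}"
            )
        neg = classes[classes != pos][0]
        self.positive_class_, self.negative_class_ = pos, neg

        order = [pos, neg]  # row 0 = positive class throughout
        n, p = X.shape
        means = np.empty((2, p))
        raw_covs = np.empty((2, p, p))
        n_k = np.empty(2)
        for i, label in enumerate(order):
            Xi = X[y == label]
            n_k[i] = len(Xi)
            means[i] = Xi.mean(axis=0)
            raw_covs[i] = np.cov(Xi, rowvar=False, ddof=1)
        pooled = (
            (n_k[0] - 1) * raw_covs[0] + (n_k[1] - 1) * raw_covs[1]
        ) / (n - 2)
        target = np.diag(np.diag(pooled))
        covs = (1.0 - self.shrinkage) * raw_covs + self.shrinkage * target[None]

        if self.priors == "proportional":
            priors = n_k / n
        elif self.priors == "equal":
            priors = np.array([0.5, 0.5])
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (2,) or priors.min() <= 0:
                raise ValueError("explicit priors must be two positive numbers")
            priors = priors / priors.sum()

        constants = np.empty(2)
        linears = np.empty((2, p))
        quads = np.empty((2, p, p))
        precisions = np.empty((2, p, p))
        logdets = np.empty(2)
        for i in range(2):
            sign, logdet = np.linalg.slogdet(covs[i])
            try:
                if sign <= 0:
                    raise np.linalg.LinAlgError
                chol = np.linalg.cholesky(covs[i])
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"covariance of class {order[i]!r} is singular at "
                    f"shrinkage={self.shrinkage}; increase shrinkage"
                ) from None
            inv_chol = np.linalg.inv(chol)
            prec = inv_chol.T @ inv_chol
            prec = (prec + prec.T) / 2.0
            precisions[i] = prec
            logdets[i] = logdet
            quads[i] = -0.5 * prec
            linears[i] = prec @ means[i]
            constants[i] = (
                np.log(priors[i])
                - 0.5 * logdet
                - 0.5 * means[i] @ prec @ means[i]
            )

        self.n_features_in_ = p
        self.class_counts_ = n_k
        self.means_ = means
        self.covariances_ = covs
        self.precisions_ = precisions
        self.log_dets_ = logdets
        self.priors_ = priors
        self.constants_ = constants
        self.linears_ = linears
        self.quads_ = quads
        return self

    # ------------------------------------------------------------------
    def class_scores(self, X, method: str = "polynomial") -> np.ndarray:
        """Per-class scores C_pos, C_neg for each row of X.

        ``method="polynomial"`` evaluates the expanded coefficients;
        ``method="gaussian"`` evaluates log prior + Gaussian log-density
        (without the constant -p/2 log 2*pi, which cancels in D). The two
        agree to numerical precision — the expansion identity.
        """
        check_is_fitted(self, "constants_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out = np.empty((X.shape[0], 2))
        for i in range(2):
            if method == "polynomial":
                out[:, i] = (
                    self.constants_[i]
                    + X @ self.linears_[i]
                    + np.einsum("ni,ij,nj->n", X, self.quads_[i], X)
                )
            elif method == "gaussian":
                diff = X - self.means_[i]
                maha = np.einsum(
                    "ni,ij,nj->n", diff, self.precisions_[i], diff
                )
                out[:, i] = (
                    np.log(self.priors_[i]) - 0.5 * self.log_dets_[i] - 0.5 * maha
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        return out

    def decision_function(self, X) -> np.ndarray:
        """The D score: positive-class score minus negative-class score."""
        scores = self.class_scores(X)
        return scores[:, 0] - scores[:, 1]

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        # D > 0 calls the positive class; the boundary D == 0 is negative
        return np.where(d > 0, self.positive_class_, self.negative_class_)

    # ------------------------------------------------------------------
    def to_panel_model(self, panel: GenePanel) -> "PanelModel":
        check_is_fitted(self, "constants_")
        if len(panel) != self.n_features_in_:
            raise ValueError(
                f"panel has {len(panel)} genes but model was fitted on "
                f"{self.n_features_in_} features"
            )
        return PanelModel(
            panel=panel,
            task=self.task,
            positive_class=self.positive_class_,
            negative_class=self.negative_class_,
            constant_h=float(self.constants_[0]),
            constant_l=float(self.constants_[1]),
            linear_h=self.linears_[0].copy(),
            linear_l=self.linears_[1].copy(),
            quad_h=self.quads_[0].copy(),
            quad_l=self.quads_[1].copy(),
            class_means=self.means_.copy(),
            class_covariances=self.covariances_.copy(),
            priors=self.priors_.copy(),
        )


@dataclass
class PanelModel:
    """A fitted, portable two-class discriminant over a gene panel.

    Houses the printed polynomial quantities — the class constants, the
    per-gene linear coefficients and the symmetric per-gene-pair quadratic
    coefficient matrices — together with the Gaussian parameters they were
    expanded from. Row/entry order follows ``panel``; the ``_h`` members
    belong to the positive class (higher-risk / cancer), ``_l`` to the
    negative class.
    """

    panel: GenePanel
    task: str
    positive_class: str
    negative_class: str
    constant_h: float
    constant_l: float
    linear_h: np.ndarray
    linear_l: np.ndarray
    quad_h: np.ndarray
    quad_l: np.ndarray
    class_means: np.ndarray
    class_covariances: np.ndarray
    priors: np.ndarray

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty((X.shape[0], 2))
        for i, (c, lin, quad) in enumerate(
            (
                (self.constant_h, self.linear_h, self.quad_h),
                (self.constant_l, self.linear_l, self.quad_l),
            )
        ):
            out[:, i] = c + X @ lin + np.einsum("ni,ij,nj->n", X, quad, X)
        return out

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        scores = self.class_scores(X)
        return scores[:, 0] - scores[:, 1]

    # -- serialization: a flat, human-auditable JSON document ----------
    def to_dict(self) -> dict:
        genes = list(self.panel)

        def upper(mat):
            return [
                [genes[i], genes[j], mat[i, j]]
                for i in range(len(genes))
                for j in range(i, len(genes))
            ]

        return {
            "format": "dscore-panel-model",
            "version": 1,
            "task": self.task,
            "panel": {"name": self.panel.name, "genes": genes},
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "constant_h": self.constant_h,
            "constant_l": self.constant_l,
            "linear_h": dict(zip(genes, self.linear_h.tolist())),
            "linear_l": dict(zip(genes, self.linear_l.tolist())),
            "quad_h_upper": upper(self.quad_h),
            "quad_l_upper": upper(self.quad_l),
            "class_means": {
                self.positive_class: dict(zip(genes, self.class_means[0].tolist())),
                self.negative_class: dict(zip(genes, self.class_means[1].tolist())),
            },
            "class_covariances": {
                self.positive_class: self.class_covariances[0].tolist(),
                self.negative_class: self.class_covariances[1].tolist(),
            },
            "priors": {
                self.positive_class: float(self.priors[0]),
                self.negative_class: float(self.priors[1]),
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PanelModel":
        if doc.get("format") != "dscore-panel-model":
            raise ValueError("not a panel-model document")
        genes = list(doc["panel"]["genes"])
        panel = GenePanel(doc["panel"]["name"], tuple(genes))
        idx = {g: i for i, g in enumerate(genes)}
        p = len(genes)

        def mat(entries):
            m = np.zeros((p, p))
            for gi, gj, v in entries:
                m[idx[gi], idx[gj]] = v
                m[idx[gj], idx[gi]] = v
            return m

        pos, neg = doc["positive_class"], doc["negative_class"]
        return cls(
            panel=panel,
            task=doc["task"],
            positive_class=pos,
            negative_class=neg,
            constant_h=float(doc["constant_h"]),
            constant_l=float(doc["constant_l"]),
            linear_h=np.array([doc["linear_h"][g] for g in genes]),
            linear_l=np.array([doc["linear_l"][g] for g in genes]),
            quad_h=mat(doc["quad_h_upper"]),
            quad_l=mat(doc["quad_l_upper"]),
            class_means=np.array(
                [[doc["class_means"][c][g] for g in genes] for c in (pos, neg)]
            ),
            class_covariances=np.array(
                [doc["class_covariances"][c] for c in (pos, neg)]
            ),
            priors=np.array([doc["priors"][pos], doc["priors"][neg]]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PanelModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
def _extract_xy(profiles: pd.DataFrame, panel: GenePanel, classes: tuple[str, str]):
    missing = [g for g in panel if g not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack panel genes: {missing}")
    keep = profiles["label"].isin(classes)
    sub = profiles.loc[keep]
    return sub[list(panel)].to_numpy(dtype=float), sub["label"].to_numpy()


def fit_stratifier(
    profiles: pd.DataFrame,
    panel: GenePanel,
    prior_mode: str = "proportional",
    shrinkage: float = 0.1,
) -> DScoreClassifier:
    """Fit the higher- vs lower-risk stratification discriminant.

    ``profiles`` is a wide CtS table with a ``label`` column; rows whose
    label is neither higher_risk nor lower_risk are ignored.
    """
    from .panels import LOWER_RISK

    X, y = _extract_xy(profiles, panel, (HIGHER_RISK, LOWER_RISK))
    clf = DScoreClassifier(
        priors=prior_mode,
        shrinkage=shrinkage,
        positive_class=HIGHER_RISK,
        task="stratification",
    )
    return clf.fit(X, y)


def fit_diagnoser(
    profiles: pd.DataFrame,
    panel: GenePanel,
    prior_mode: str = "proportional",
    shrinkage: float = 0.1,
) -> DScoreClassifier:
    """Fit the cancer vs benign diagnosis discriminant (same machinery)."""
    from .panels import BENIGN

    X, y = _extract_xy(profiles, panel, (CANCER, BENIGN))
    clf = DScoreClassifier(
        priors=prior_mode,
        shrinkage=shrinkage,
        positive_class=CANCER,
        task="diagnosis",
    )
    return clf.fit(X, y)


def score_profiles(model, profiles: pd.DataFrame, panel: GenePanel | None = None):
    """Score a CtS table; returns one row per patient.

    ``model`` is a fitted ``DScoreClassifier`` (then ``panel`` is required
    to select/order columns) or a ``PanelModel``. Output columns:
    c_higher, c_lower, d_score, call.
    """
    if isinstance(model, PanelModel):
        panel = model.panel
        positive, negative = model.positive_class, model.negative_class
        scorer = model.class_scores
    else:
        check_is_fitted(model, "constants_")
        if panel is None:
            raise ValueError("panel is required when scoring with an estimator")
        positive, negative = model.positive_class_, model.negative_class_
        scorer = model.class_scores
    missing = [g for g in panel if g not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack panel genes: {missing}")
    X = profiles[list(panel)].to_numpy(dtype=float)
    scores = scorer(X)
    d = scores[:, 0] - scores[:, 1]
    return pd.DataFrame(
        {
            "c_higher": scores[:, 0],
            "c_lower": scores[:, 1],
            "d_score": d,
            "call": np.where(d > 0, positive, negative),
        },
        index=profiles.index,
    )
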