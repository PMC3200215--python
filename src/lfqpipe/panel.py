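"""Minimal biomarker panels by Fisher LDA and forward LOO selection.

The discriminant direction is ``w = (S + lambda I)^-1 (m_case - m_control)``
with S the pooled within-class covariance and a small ridge
``lambda = 1e-3 * trace(S) / p`` that keeps the solve well-posed when the
candidate count approaches the sample count (13 candidates vs 13 samples
in the study design this models).  The decision threshold sits at the
midpoint of the projected class means shifted by the log prior-odds, with
priors proportional to class sizes; a score exactly at the threshold is
assigned to the control class.

"Best discrimination with the fewest proteins" is operationalized as
greedy forward selection minimizing the leave-one-out misclassification
count, stopping as soon as LOO error reaches zero or no addition improves
it.  Among equally good additions the larger standardized projected margin
wins, then lexicographic accession order — selection is fully
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError, InferenceError

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-3


@dataclass
class PanelModel:
    proteins: list[str]
    weights: np.ndarray
    threshold: float
    scores: pd.Series  # per training sample
    loo_misclassifications: int
    margin: float
    case_label: str
    control_label: str

    @property
    def training_misclassifications(self) -> int:
        labels = self.scores.index.map(self._true_labels.get)
        pred = np.where(
            self.scores.to_numpy() > self.threshold, self.case_label,
            self.control_label
        )
        return int((pred != np.asarray(labels)).sum())

    _true_labels: dict = None  # set by fit_lda


def _validate(X: pd.DataFrame, labels: pd.Series, case_label, control_label):
    if X.isna().any().any():
        raise DataValidationError("LDA input may not contain missing cells")
    counts = labels.value_counts()
    for lab in (case_label, control_label):
        if counts.get(lab, 0) < 2:
            raise InferenceError(f"need >= 2 samples in class {lab!r}")
    if set(counts.index) - {case_label, control_label}:
        raise DataValidationError("labels contain unknown classes")


def fit_lda(
    X: pd.DataFrame,
    labels: pd.Series,
    case_label: str = "AT",
    control_label: str = "control",
    ridge: float = DEFAULT_RIDGE,
) -> PanelModel:
    """Fit a two-class Fisher discriminant on samples x proteins data."""
    labels = pd.Series(labels, index=X.index) if not isinstance(labels, pd.Series) else labels
    _validate(X, labels, case_label, control_label)
    Xc = X.loc[labels == case_label].to_numpy(dtype=float)
    X0 = X.loc[labels == control_label].to_numpy(dtype=float)
    m1, m0 = Xc.mean(axis=0), X0.mean(axis=0)
    n1, n0 = len(Xc), len(X0)
    p = X.shape[1]
    S = ((n1 - 1) * np.cov(Xc, rowvar=False).reshape(p, p)
         + (n0 - 1) * np.cov(X0, rowvar=False).reshape(p, p)) / (n1 + n0 - 2)
    lam = ridge * np.trace(S) / p if ridge > 0 else 0.0
    if lam == 0.0 and np.linalg.matrix_rank(S) < p:
        raise InferenceError(
            "pooled covariance is singular; refit with a positive ridge term"
        )
    try:
        w = np.linalg.solve(S + lam * np.eye(p), m1 - m0)
    except np.linalg.LinAlgError as exc:
        raise InferenceError(
            "pooled covariance is singular; refit with a positive ridge term"
        ) from exc
    proj1, proj0 = float(w @ m1), float(w @ m0)
    threshold = 0.5 * (proj1 + proj0) - np.log(n1 / n0)
    scores = pd.Series(X.to_numpy(dtype=float) @ w, index=X.index, name="score")
    denom = float(np.sqrt(w @ (S + lam * np.eye(p)) @ w))
    margin = (proj1 - proj0) / denom if denom > 0 else 0.0
    model = PanelModel(
        proteins=list(X.columns),
        weights=w,
        threshold=float(threshold),
        scores=scores,
        loo_misclassifications=-1,
        margin=float(margin),
        case_label=case_label,
        control_label=control_label,
    )
    model._true_labels = labels.to_dict()
    return model


def classify(model: PanelModel, x: pd.Series) -> tuple[str, float]:
    """Score one sample; ties at the threshold go to the control class."""
    missing = [pr for pr in model.proteins if pr not in x.index]
    if missing:
        raise DataValidationError(f"sample lacks panel proteins {missing}")
    score = float(x.loc[model.proteins].to_numpy(dtype=float) @ model.weights)
    label = model.case_label if score > model.threshold else model.control_label
    return label, score


def loo_misclassifications(
    X: pd.DataFrame,
    labels: pd.Series,
    case_label: str = "AT",
    control_label: str = "control",
    ridge: float = DEFAULT_RIDGE,
) -> int:
    """Leave-one-out misclassification count of the LDA on these features."""
    errors = 0
    for held in X.index:
        sub = X.drop(index=held)
        sub_labels = labels.drop(index=held)
        try:
            model = fit_lda(sub, sub_labels, case_label, control_label, ridge)
        except InferenceError:
            errors += 1
            continue
        pred, _ = classify(model, X.loc[held])
        if pred != labels.loc[held]:
            errors += 1
    return errors


def forward_select_panel(
    X: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str] | None = None,
    case_label: str = "AT",
    control_label: str = "control",
    ridge: float = DEFAULT_RIDGE,
) -> PanelModel:
    """Greedy forward selection of the smallest panel with best LOO error."""
    labels = pd.Series(labels, index=X.index) if not isinstance(labels, pd.Series) else labels
    if candidates is None:
        candidates = list(X.columns)
    if not candidates:
        raise DataValidationError("candidate set is empty")
    remaining = sorted(candidates)
    panel: list[str] = []
    best_err = None
    while remaining:
        trial = []
        for cand in remaining:
            cols = panel + [cand]
            err = loo_misclassifications(
                X[cols], labels, case_label, control_label, ridge
            )
            margin = fit_lda(X[cols], labels, case_label, control_label, ridge).margin
            trial.append((err, -margin, cand))
        trial.sort()
        err, neg_margin, cand = trial[0]
        if best_err is not None and err >= best_err:
            break
        panel.append(cand)
        remaining.remove(cand)
        best_err = err
        if best_err == 0:
            break
    model = fit_lda(X[panel], labels, case_label, control_label, ridge)
    model.loo_misclassifications = int(best_err)
    if best_err > 0:
        warnings.warn(
            f"panel {panel} leaves {best_err} leave-one-out misclassifications"
        )
    logger.info("selected panel %s (LOO errors: %d)", panel, best_err)
    return model
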