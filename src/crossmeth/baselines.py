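"""Baseline imputers: species/tissue/global means and per-probe logistic regression.

The mean baselines average the training individuals sharing the target
species (resp. tissue), or all of them.  The logistic baseline fits one
L2-penalized logistic regression per probe on the two-hot (species, tissue)
features, with each training sample contributing a positive instance weighted
by its beta value and a negative instance weighted by 1 - beta, so the
predicted class-1 probability is the predicted methylation level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data import (CombinationKey, CombinationMeanMatrix, ConditionLabels,
                   SampleMatrix, encode_condition_labels)

MEAN_KINDS = ("species", "tissue", "global")


def mean_baseline_impute(matrix: SampleMatrix, labels: ConditionLabels,
                         key: CombinationKey, kind: str) -> np.ndarray:
    """Impute one combination mean by averaging a training-sample group."""
    species, tissue = key
    if kind == "species":
        mask = np.array([s == species for s in labels.species])
        if not mask.any():
            raise ValueError(f"no training samples for species {species!r}")
    elif kind == "tissue":
        mask = np.array([t == tissue for t in labels.tissue])
        if not mask.any():
            raise ValueError(f"no training samples for tissue {tissue!r}")
    elif kind == "global":
        mask = np.ones(matrix.n_samples, dtype=bool)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return matrix.values[mask].mean(axis=0)


def mean_baseline_matrix(matrix: SampleMatrix, labels: ConditionLabels,
                         keys, kind: str) -> CombinationMeanMatrix:
    keys = [tuple(k) for k in keys]
    rows = [mean_baseline_impute(matrix, labels, k, kind) for k in keys]
    return CombinationMeanMatrix(np.vstack(rows), keys=keys,
                                 probe_ids=list(matrix.probe_ids))


@dataclass
class ProbeLogisticModel:
    """Fitted per-probe weights over the two-hot label features."""

    weights: np.ndarray
    intercept: float
    penalty: float
    probe_id: str = ""

    def predict(self, features: np.ndarray) -> np.ndarray:
        logit = features @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))


def fit_probe_logistic(matrix: SampleMatrix, labels: ConditionLabels,
                       probe: str, lam: float, max_iter: int = 1000,
                       tol: float = 1e-8) -> ProbeLogisticModel:
    """Fit min_W,c  sum_i [b_i * -log p_i + (1-b_i) * -log(1-p_i)] + lam*||W||^2.

    Implemented with the duplicated-row construction: each sample appears once
    with label 1 and weight beta, once with label 0 and weight 1 - beta.  The
    solver's regularization constant is converted (C = 1/(2*lam)) so its
    objective matches the stated one; the intercept is unpenalized.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    j = matrix.probe_ids.index(probe)
    beta = matrix.values[:, j]
    X = encode_condition_labels(labels)
    X2 = np.vstack([X, X])
    y2 = np.concatenate([np.ones(len(beta)), np.zeros(len(beta))])
    w2 = np.concatenate([beta, 1.0 - beta])
    if w2.sum() <= 0:
        raise ValueError(f"degenerate all-zero weights for probe {probe!r}")
    # C = 1/(2*lam) converts sklearn's objective to sum(logloss) + lam*||W||^2
    C = np.inf if lam == 0 else 1.0 / (2.0 * lam)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=tol)
    clf.fit(X2, y2, sample_weight=w2)
    return ProbeLogisticModel(weights=clf.coef_[0].copy(),
                              intercept=float(clf.intercept_[0]),
                              penalty=float(lam), probe_id=probe)


def fit_logistic_baseline(matrix: SampleMatrix, labels: ConditionLabels,
                          lam: float) -> list[ProbeLogisticModel]:
    return [fit_probe_logistic(matrix, labels, p, lam) for p in matrix.probe_ids]


def logistic_impute(models: list[ProbeLogisticModel], vocab: ConditionLabels,
                    key: CombinationKey) -> np.ndarray:
    """Concatenate per-probe predictions on the key's two-hot feature vector."""
    features = encode_condition_labels(vocab, [tuple(key)])[0]
    return np.array([m.predict(features[None, :])[0] for m in models])


def logistic_impute_matrix(models: list[ProbeLogisticModel], vocab: ConditionLabels,
                           keys, probe_ids) -> CombinationMeanMatrix:
    if len(models) != len(probe_ids):
        raise ValueError("need exactly one model per probe")
    keys = [tuple(k) for k in keys]
    rows = [logistic_impute(models, vocab, k) for k in keys]
    return CombinationMeanMatrix(np.vstack(rows), keys=keys, probe_ids=list(probe_ids))


def logistic_objective_gradient(model: ProbeLogisticModel, matrix: SampleMatrix,
                                labels: ConditionLabels, probe: str):
    """Gradient of the stated objective at the fitted parameters (stationarity check)."""
    j = matrix.probe_ids.index(probe)
    beta = matrix.values[:, j]
    X = encode_condition_labels(labels)
    p = model.predict(X)
    resid = p - beta
    grad_w = X.T @ resid + 2.0 * model.penalty * model.weights
    grad_c = float(resid.sum())
    return grad_w, grad_c


def lambda_sweep(train_matrix: SampleMatrix, train_labels: ConditionLabels,
                 test_means: CombinationMeanMatrix,
                 lams=(1.0, 2.0, 4.0, 8.0, 16.0)):
    """Score a grid of L2 penalties by mean sample-wise Pearson r on held-out means.

    Returns ``(best_lam, {lam: score})``; ties resolve to the first best.
    """
    scores = {}
    for lam in lams:
        models = fit_logistic_baseline(train_matrix, train_labels, lam)
        imputed = logistic_impute_matrix(models, train_labels, test_means.keys,
                                         train_matrix.probe_ids)
        rs = []
        for i in range(len(test_means.keys)):
            a, b = imputed.values[i], test_means.values[i]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
        scores[lam] = float(np.mean(rs)) if rs else float("nan")
    finite = [l for l in lams if np.isfinite(scores[l])]
    if not finite:
        raise ValueError("no penalty produced a finite score")
    best = max(finite, key=lambda l: scores[l])
    return best, scores
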