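"""Penalized multinomial classification of subjects into phenotypes.

Two model variants mirror the phenotyping workflow: Model A uses the eight
clustering variables without PC20 (methacholine challenge is unavailable in
validation cohorts and at follow-up); Model B additionally drops blood
eosinophils (measured only at screening) and serves the longitudinal
analyses.

The model is multinomial logistic regression with an elastic-net penalty
``lambda * [(1-alpha)/2 * ||beta||^2 + alpha * ||beta||_1]``; the mixing
``alpha`` and strength ``lambda`` are tuned by leave-one-out
cross-validated accuracy over a grid.  For subject ``i`` the per-class
linear predictor is ``f(k, i) = sum_{m=0..M} beta_{m,k} x_{m,i}`` with
``x_0 = 1`` the intercept, and class probabilities are the softmax
``Pr(Y_i = c) = exp(f(c,i)) / sum_k exp(f(k,i))``.

The numerical fit is delegated to scikit-learn's saga solver; everything
around it — scaling reuse, the explicit predictor/softmax path, and the
raw-scale coefficient "calculator" export — lives here.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from phenoclust.preprocess import VARIABLE_SETS, FeatureMatrix

log = logging.getLogger(__name__)

#: default tuning grids: elastic-net mixing and penalty strength
DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 1, 30))

VARIANT_VARIABLES = {"A": VARIABLE_SETS["model_a"], "B": VARIABLE_SETS["model_b"]}


@dataclass
class ClassifierModel:
    """Fitted multinomial model: coefficients plus the scaling to reuse.

    ``coef`` has shape (M+1, K); row 0 is the intercept.  Coefficients act
    on mean/MAD-scaled predictors; ``center``/``scale`` record the training
    scaling so new cohorts are projected identically.
    """

    classes: tuple[str, ...]
    coef: np.ndarray
    var_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    alpha: float
    lam: float
    variant: str
    cv_accuracy: float = float("nan")
    training_concordance: float = float("nan")

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (len(self.var_names) + 1, len(self.classes)):
            raise ValueError("coefficient matrix shape mismatch")


def softmax_probabilities(f: np.ndarray) -> np.ndarray:
    """Softmax of linear predictors, max-subtracted for overflow safety.

    Accepts a vector (one subject) or an n x K matrix.
    """
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("non-finite linear predictors")
    shifted = f - f.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def linear_predictors(model: ClassifierModel, x: np.ndarray | dict) -> np.ndarray:
    """Per-class linear predictors f(k) for one raw predictor vector."""
    if isinstance(x, dict):
        missing = [v for v in model.var_names if v not in x]
        if missing:
            raise KeyError(f"missing predictor(s) {missing}")
        x = np.array([x[v] for v in model.var_names], dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(model.var_names):
        raise ValueError("predictor vector length mismatch")
    if not np.isfinite(x).all():
        raise ValueError("missing (non-finite) predictor value")
    z = (x - model.center) / model.scale
    design = np.concatenate([np.ones(z.shape[:-1] + (1,)), z], axis=-1)
    return design @ model.coef


def _lam_to_C(lam: float, n: int) -> float:
    # glmnet-style objective averages the log-likelihood over n; sklearn does
    # not, so C = 1/(n*lambda) aligns the two parameterizations
    return 1.0 / max(n * lam, 1e-12)


def _make_estimator(alpha: float, lam: float, n: int, seed: int | None,
                    tol: float = 1e-4, warm_start: bool = False) -> LogisticRegression:
    common = dict(C=_lam_to_C(lam, n), max_iter=2000, tol=tol,
                  random_state=seed, warm_start=warm_start)
    if alpha == 0.0:
        return LogisticRegression(solver="lbfgs", **common)
    return LogisticRegression(solver="saga", l1_ratio=alpha, **common)


def _extract_rows(fm: FeatureMatrix, variables: tuple[str, ...]):
    idx = [fm.var_names.index(v) for v in variables]
    X = fm.values[:, idx]
    complete = np.isfinite(X).all(axis=1)
    return X, complete


def train_classifier(
    fm: FeatureMatrix,
    labels: np.ndarray,
    variant: str = "A",
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    cv: str | int = "loo",
    seed: int | None = 0,
    variables: tuple[str, ...] | None = None,
) -> ClassifierModel:
    """Tune (alpha, lambda) by cross-validated accuracy, refit on all rows.

    ``fm`` must be a raw-scale feature matrix whose ``center``/``scale``
    are populated (i.e. produced by ``mad_scale`` or ``apply_scaling``), or
    an unscaled matrix together with scaling is not accepted.  Rows missing
    any of the variant's variables are excluded from training, as are their
    labels.  ``cv="loo"`` is leave-one-out; an integer requests stratified
    k-fold (a cheaper surrogate for large grids).
    """
    if variant not in VARIANT_VARIABLES:
        raise ValueError(f"unknown variant {variant!r}")
    if not alpha_grid or not len(lambda_grid):
        raise ValueError("empty tuning grid")
    if fm.center is None or fm.scale is None:
        raise ValueError("feature matrix lacks stored scaling parameters")
    wanted = tuple(variables) if variables is not None else VARIANT_VARIABLES[variant]
    variables = tuple(v for v in wanted if v in fm.var_names)
    if len(variables) != len(wanted):
        missing = set(wanted) - set(fm.var_names)
        raise ValueError(f"feature matrix lacks variant {variant} variables {sorted(missing)}")

    X_all, complete = _extract_rows(fm, variables)
    labels = np.asarray(labels)
    X = X_all[complete]
    y = labels[complete]
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training subjects")
    n = X.shape[0]

    if cv == "loo":
        splitter = LeaveOneOut()
        split_args = (X,)
    else:
        splitter = StratifiedKFold(n_splits=int(cv), shuffle=True, random_state=seed)
        split_args = (X, y)
    folds = list(splitter.split(*split_args))

    best = None  # (accuracy, lam, -alpha) maximized -> prefer stronger penalty on ties
    for alpha in alpha_grid:
        for lam in lambda_grid:
            # one warm-started estimator per grid point: successive CV folds
            # differ by a single row, so each refit converges in a few passes
            est = _make_estimator(alpha, lam, n, seed, tol=1e-3, warm_start=True)
            correct = 0
            total = 0
            for tr, te in folds:
                est.fit(X[tr], y[tr])
                correct += int((est.predict(X[te]) == y[te]).sum())
                total += len(te)
            acc = correct / total
            key = (acc, lam, -alpha)
            if best is None or key > best[0]:
                best = (key, alpha, lam)
    _, alpha, lam = best
    final = _make_estimator(alpha, lam, n, seed)
    final.fit(X, y)

    # assemble (M+1) x K coefficient matrix in the declared class order;
    # sklearn collapses the binary case to one row (reference class zero)
    if len(classes) == 2 and final.coef_.shape[0] == 1:
        intercepts = np.concatenate([[0.0], final.intercept_])
        coefs = np.vstack([np.zeros_like(final.coef_[0]), final.coef_[0]])
    else:
        intercepts = final.intercept_
        coefs = final.coef_
    order = [list(final.classes_).index(c) for c in classes]
    coef = np.vstack([intercepts[order], coefs[order].T])

    idx = [fm.var_names.index(v) for v in variables]
    model = ClassifierModel(
        classes=tuple(str(c) for c in classes),
        coef=coef,
        var_names=variables,
        center=fm.center[idx].copy(),
        scale=fm.scale[idx].copy(),
        alpha=float(alpha),
        lam=float(lam),
        variant=variant,
        cv_accuracy=float(best[0][0]),
    )
    train_probs = softmax_probabilities(np.column_stack([np.ones(n), X]) @ coef)
    train_calls = np.array([model.classes[i] for i in train_probs.argmax(axis=1)])
    model.training_concordance = float((train_calls == y.astype(str)).mean())
    log.info("variant %s: alpha=%.2f lambda=%.4g cv_acc=%.3f train_concordance=%.3f",
             variant, alpha, lam, model.cv_accuracy, model.training_concordance)
    return model


@dataclass
class ClassificationResult:
    """Per-subject class probabilities and hard calls."""

    subject_ids: tuple[str, ...]
    classes: tuple[str, ...]
    probabilities: np.ndarray      # n x K, rows sum to 1
    calls: np.ndarray              # class label strings
    max_probability: np.ndarray
    concordance: float | None = None
    per_class_concordance: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities,
                          columns=[f"p_{c}" for c in self.classes])
        df.insert(0, "subject_id", list(self.subject_ids))
        df["call"] = self.calls
        df["max_probability"] = self.max_probability
        return df


def classify_cohort(
    model: ClassifierModel,
    fm: FeatureMatrix,
    reference: np.ndarray | None = None,
) -> ClassificationResult:
    """Classify every complete row of a scaled-compatible feature matrix.

    ``fm`` is on the raw scale; the model's stored training scaling is
    applied internally.  Extra columns are ignored; rows missing a variant
    variable are excluded.  When reference labels are given, overall and
    per-class concordance are reported.
    """
    try:
        idx = [fm.var_names.index(v) for v in model.var_names]
    except ValueError as exc:
        raise ValueError(f"feature matrix lacks model predictor: {exc}") from exc
    X = fm.values[:, idx]
    complete = np.isfinite(X).all(axis=1)
    Z = (X[complete] - model.center) / model.scale
    f = np.column_stack([np.ones(Z.shape[0]), Z]) @ model.coef
    probs = softmax_probabilities(f)
    calls = np.array([model.classes[i] for i in probs.argmax(axis=1)])
    ids = tuple(sid for sid, ok in zip(fm.subject_ids, complete) if ok)

    concordance = None
    per_class = None
    if reference is not None:
        ref = np.asarray(reference).astype(str)[complete]
        concordance = float((calls == ref).mean())
        per_class = {}
        for c in model.classes:
            sel = ref == c
            per_class[c] = float((calls[sel] == c).mean()) if sel.any() else float("nan")
    return ClassificationResult(
        subject_ids=ids, classes=model.classes, probabilities=probs,
        calls=calls, max_probability=probs.max(axis=1),
        concordance=concordance, per_class_concordance=per_class,
    )


# ---------------------------------------------------------------------------
# calculator export: self-contained raw-scale coefficient table

def fold_scaling(model: ClassifierModel) -> np.ndarray:
    """Coefficients re-expressed on the raw variable scale.

    ``f = b0 + sum_m b_m (x_m - c_m)/s_m`` becomes
    ``f = (b0 - sum_m b_m c_m/s_m) + sum_m (b_m/s_m) x_m``; applying the
    folded table to raw inputs reproduces the scaled-path predictors.
    """
    b0 = model.coef[0]
    B = model.coef[1:]
    raw_B = B / model.scale[:, None]
    raw_b0 = b0 - (B * (model.center / model.scale)[:, None]).sum(axis=0)
    # contiguous so downstream matmuls are bit-reproducible across copies
    return np.ascontiguousarray(np.vstack([raw_b0, raw_B]))


def export_calculator(model: ClassifierModel, path) -> None:
    """Write a self-contained CSV coefficient calculator.

    Rows: one intercept row plus one row per predictor, with raw-scale
    coefficients per class (full float precision, so a round trip through
    the file reproduces probabilities bit-identically), followed by a
    worked-example row holding sample raw inputs.
    """
    raw = fold_scaling(model)
    example_x = model.center.copy()  # training means: a plausible subject
    f = raw[0] + example_x @ raw[1:]
    probs = softmax_probabilities(f)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term"] + [f"beta_{c}" for c in model.classes])
        w.writerow(["(intercept)"] + [repr(float(v)) for v in raw[0]])
        for name, row in zip(model.var_names, raw[1:]):
            w.writerow([name] + [repr(float(v)) for v in row])
        w.writerow([])
        w.writerow(["example_input"] + [repr(float(v)) for v in example_x])
        w.writerow(["example_probability"] + [repr(float(v)) for v in probs])


def import_calculator(path) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Read a calculator CSV back: (classes, var_names, raw coef matrix)."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    header = rows[0]
    classes = tuple(h.removeprefix("beta_") for h in header[1:])
    coef_rows = []
    var_names = []
    for row in rows[1:]:
        if row[0] in ("example_input", "example_probability"):
            continue
        if row[0] != "(intercept)":
            var_names.append(row[0])
        coef_rows.append([float(v) for v in row[1:]])
    return classes, tuple(var_names), np.asarray(coef_rows)


def calculator_probabilities(coef_raw: np.ndarray, x_raw: np.ndarray) -> np.ndarray:
    """Class probabilities from a raw-scale calculator table."""
    f = coef_raw[0] + np.asarray(x_raw, dtype=float) @ coef_raw[1:]
    return softmax_probabilities(f)


# ---------------------------------------------------------------------------
# serialization

def model_to_json(model: ClassifierModel, path) -> None:
    doc = {
        "classes": list(model.classes),
        "variant": model.variant,
        "var_names": list(model.var_names),
        "coef": model.coef.tolist(),
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "alpha": model.alpha,
        "lambda": model.lam,
        "cv_accuracy": model.cv_accuracy,
        "training_concordance": model.training_concordance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def model_from_json(path) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    return ClassifierModel(
        classes=tuple(doc["classes"]),
        coef=np.asarray(doc["coef"], dtype=float),
        var_names=tuple(doc["var_names"]),
        center=np.asarray(doc["center"], dtype=float),
        scale=np.asarray(doc["scale"], dtype=float),
        alpha=float(doc["alpha"]),
        lam=float(doc["lambda"]),
        variant=doc["variant"],
        cv_accuracy=float(doc["cv_accuracy"]),
        training_concordance=float(doc["training_concordance"]),
    )
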