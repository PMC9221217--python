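"""Low-overhead RBF/linear SVM primitives for the inner cross-validation loops.

The nested leave-one-out design refits an SVM tens of thousands of times on
~40-subject folds, where :class:`sklearn.svm.SVC`'s per-call input validation
dominates the actual libsvm solve.  This module calls the same libsvm binding
that backs ``SVC`` directly, after validating inputs once per loop instead of
once per fit.  If the binding is unavailable the public estimator is used; a
unit test pins prediction equivalence between the two paths.

Everything here is internal API: inputs must already be float64 and finite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the equivalence test
    from sklearn.svm import _libsvm as _lib

    _lib.set_verbosity_wrap(0)
    _HAVE_FAST_PATH = True
except ImportError:  # pragma: no cover
    _lib = None
    _HAVE_FAST_PATH = False

from sklearn.svm import SVC

_EMPTY = np.empty(0, dtype=np.float64)


def fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    *,
    C: float,
    gamma: float,
    kernel: str = "rbf",
    tol: float = 1e-3,
) -> np.ndarray:
    """Train a C-SVC and predict labels for ``x_test``.

    ``y_train`` must be a float64 vector of 0/1 labels; the return value is a
    float64 vector of predicted 0/1 labels.
    """
    x_test = np.atleast_2d(x_test)
    if _HAVE_FAST_PATH:
        model = _lib.fit(
            np.ascontiguousarray(x_train, dtype=np.float64),
            np.ascontiguousarray(y_train, dtype=np.float64),
            svm_type=0,
            kernel=kernel,
            C=float(C),
            gamma=float(gamma),
            tol=tol,
            degree=3,
            coef0=0.0,
            nu=0.5,
            epsilon=0.1,
            class_weight=_EMPTY,
            sample_weight=_EMPTY,
            shrinking=1,
            probability=0,
            cache_size=100.0,
            max_iter=-1,
            random_seed=0,
        )
        support, sv, n_sv, sv_coef, intercept, prob_a, prob_b = model[:7]
        return _lib.predict(
            np.ascontiguousarray(x_test, dtype=np.float64),
            support,
            sv,
            n_sv,
            sv_coef,
            intercept,
            prob_a,
            prob_b,
            svm_type=0,
            kernel=kernel,
            degree=3,
            coef0=0.0,
            gamma=float(gamma),
        )
    clf = SVC(C=C, gamma=gamma, kernel=kernel, tol=tol)
    clf.fit(x_train, y_train)
    return clf.predict(x_test).astype(np.float64)


def loocv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    *,
    C: float,
    gamma: float,
    kernel: str = "rbf",
    tol: float = 1e-3,
) -> float:
    """Leave-one-out accuracy with per-fold feature standardization.

    Each fold z-scores features with the statistics of its own n-1 training
    rows, so no information from the held-out row leaks into the scaling.
    Constant features in a fold get unit scale.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    n = x.shape[0]
    if n < 3 or len(np.unique(y)) < 2:
        raise ValueError("LOOCV needs >=3 samples and both classes present")
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        xt = x[train]
        mu = xt.mean(axis=0)
        sd = xt.std(axis=0)
        sd[sd == 0] = 1.0
        yt = y[train]
        if yt.min() == yt.max():  # held-out subject removed the only member
            continue
        pred = fit_predict(
            (xt - mu) / sd,
            yt,
            ((x[i] - mu) / sd)[None, :],
            C=C,
            gamma=gamma,
            kernel=kernel,
            tol=tol,
        )
        correct += int(pred[0] == y[i])
    return correct / n
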