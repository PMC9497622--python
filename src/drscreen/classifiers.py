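"""Binary classifiers for the GLCM feature table.

Two models with one scoring contract:

* ``SvmClassifier`` — polynomial-kernel support vector machine (C = 1,
  gamma = 1, degree 3).  Its score is the signed distance-like decision
  value p = w.x + b; the sign gives the class and the magnitude the
  confidence, so the raw value is a valid ranking score for ROC/AUC.
* ``DnnClassifier`` — the NumPy deep network of :mod:`drscreen.dnn`; its
  score is the sigmoid output in [0, 1].

Both wrap a min-max scaler fitted on training rows only, mapping each
feature column to [-1, +1] (test rows may fall outside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from drscreen.dnn import DnnModel, DnnSpec, TrainConfig, build_dnn, predict_score, train_dnn

__all__ = [
    "FeatureScaler",
    "hinge_loss",
    "SvmClassifier",
    "DnnClassifier",
    "train_svm",
    "svm_decision",
    "save_model",
    "load_model",
]


class FeatureScaler:
    """Per-column linear map sending the training min to -1 and max to +1.

    Constant columns map to 0.  Transforming rows outside the training
    range extrapolates beyond [-1, 1] (no clipping): the scaler is a fixed
    affine map, not a projection.
    """

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("scaler requires a nonempty 2-D feature array")
        self.min_ = x.min(axis=0)
        self.max_ = x.max(axis=0)
        rng = self.max_ - self.min_
        self.scale_ = np.where(rng > 0, 2.0 / np.where(rng > 0, rng, 1.0), 0.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.min_) * self.scale_ - np.where(self.scale_ > 0, 1.0, 0.0)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = (z + np.where(self.scale_ > 0, 1.0, 0.0)) / self.scale_ + self.min_
        return np.where(self.scale_ > 0, x, self.min_)

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def hinge_loss(p: float, t: int) -> float:
    """Margin loss max(0, 1 - p*t) for prediction p and target t in {-1, +1}.

    A point exactly on the boundary (p = 0) costs 1 whichever side it
    belongs to; the loss vanishes once the signed margin p*t reaches 1.
    """
    return max(0.0, 1.0 - p * t)


class SvmClassifier:
    """Polynomial-kernel SVM with internal [-1, 1] feature scaling."""

    threshold = 0.0  # decision-value cut for hard labels

    def __init__(self, C: float = 1.0, gamma: float = 1.0, degree: int = 3,
                 coef0: float = 1.0):
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.scaler = FeatureScaler()
        self._svc = SVC(kernel="poly", C=C, gamma=gamma, degree=degree, coef0=coef0)

    def fit(self, x, y) -> "SvmClassifier":
        y = np.asarray(y).ravel()
        if np.unique(y).size < 2:
            raise ValueError("SVM training requires both classes present")
        z = self.scaler.fit_transform(np.asarray(x, dtype=float))
        self._svc.fit(z, y)
        return self

    def predict_scores(self, x) -> np.ndarray:
        z = self.scaler.transform(np.asarray(x, dtype=float))
        return self._svc.decision_function(z)

    def predict(self, x) -> np.ndarray:
        return (self.predict_scores(x) >= self.threshold).astype(int)


def train_svm(x, y, C: float = 1.0, gamma: float = 1.0, degree: int = 3,
              coef0: float = 1.0) -> SvmClassifier:
    """Fit the polynomial-kernel SVM on a labeled feature table."""
    return SvmClassifier(C=C, gamma=gamma, degree=degree, coef0=coef0).fit(x, y)


def svm_decision(model: SvmClassifier, x) -> np.ndarray:
    """Decision values p = w.x + b (in kernel form) for rows of x."""
    return model.predict_scores(np.atleast_2d(x))


class DnnClassifier:
    """Deep-network classifier with internal [-1, 1] feature scaling."""

    threshold = 0.5  # sigmoid-score cut for hard labels

    def __init__(self, spec: DnnSpec | None = None, config: TrainConfig | None = None):
        self.spec = spec or DnnSpec()
        self.config = config or TrainConfig()
        self.scaler = FeatureScaler()
        self.model: DnnModel | None = None

    def fit(self, x, y) -> "DnnClassifier":
        z = self.scaler.fit_transform(np.asarray(x, dtype=float))
        self.model = build_dnn(self.spec, seed=self.config.seed)
        train_dnn(self.model, z, np.asarray(y).ravel(), self.config)
        return self

    def predict_scores(self, x) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        z = self.scaler.transform(np.asarray(x, dtype=float))
        return predict_score(self.model, z, config=self.config)

    def predict(self, x) -> np.ndarray:
        return (self.predict_scores(x) >= self.threshold).astype(int)

    @property
    def history(self):
        return self.model.history if self.model is not None else {"loss": [], "accuracy": []}


# ---------------------------------------------------------------------------
# on-disk model bundles (directory with config JSON + weights), so an
# evaluation can be replayed exactly
# ---------------------------------------------------------------------------

def save_model(model, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaler = {"min": model.scaler.min_.tolist(), "max": model.scaler.max_.tolist()}
    if isinstance(model, SvmClassifier):
        import joblib

        meta = {"kind": "svm", "C": model.C, "gamma": model.gamma,
                "degree": model.degree, "coef0": model.coef0, "scaler": scaler}
        joblib.dump(model._svc, out / "svm.joblib")
    elif isinstance(model, DnnClassifier):
        from dataclasses import asdict

        meta = {"kind": "dnn", "spec": asdict(model.spec),
                "config": asdict(model.config), "scaler": scaler}
        np.savez(out / "weights.npz", **model.model.state_dict())
    else:
        raise TypeError(f"cannot save model of type {type(model).__name__}")
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    return out


def load_model(in_dir):
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "model.json").read_text())
    if meta["kind"] == "svm":
        import joblib

        model = SvmClassifier(C=meta["C"], gamma=meta["gamma"],
                              degree=meta["degree"], coef0=meta["coef0"])
        model._svc = joblib.load(in_dir / "svm.joblib")
    else:
        model = DnnClassifier(spec=DnnSpec(**meta["spec"]),
                              config=TrainConfig(**meta["config"]))
        model.model = build_dnn(model.spec, seed=model.config.seed)
        with np.load(in_dir / "weights.npz") as state:
            model.model.load_state_dict({k: state[k] for k in state.files})
    scaler = meta["scaler"]
    model.scaler.min_ = np.asarray(scaler["min"], dtype=float)
    model.scaler.max_ = np.asarray(scaler["max"], dtype=float)
    rng = model.scaler.max_ - model.scaler.min_
    model.scaler.scale_ = np.where(rng > 0, 2.0 / np.where(rng > 0, rng, 1.0), 0.0)
    return model
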