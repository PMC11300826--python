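"""Deploy/withhold decision rule on inferred latents.

Each subject contributes a single regression target -- the difference in
mean yellow-light speed with versus without the safety interface (negative
means the interface helps).  A polynomial-kernel support-vector regression
maps every snippet latent of a subject to that shared target (a many-to-one
function); deployment is decided by thresholding the predicted speed change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "DecisionHyper",
    "DecisionModel",
    "compute_speed_delta_target",
    "fit_decision_model",
    "predict_delta",
    "decide_instantaneous",
    "decide_window_averaged",
]


class NotFittedError(RuntimeError):
    pass


@dataclass(frozen=True)
class DecisionHyper:
    degree: int = 3
    C: float = 1.0
    epsilon: float = 0.1
    coef0: float = 1.0
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


def compute_speed_delta_target(trials: pd.DataFrame) -> float:
    """Per-subject speed-change target (m/s): mean yellow speed over
    interface trials minus over baseline trials.  Negative => beneficial.

    ``trials`` must contain exactly one subject's rows with columns
    ``condition``, ``had_yellow`` and ``mean_yellow_speed``.
    """
    subjects = trials["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"expected one subject, got {list(subjects)}")
    yellow = trials[trials["had_yellow"]]
    hmi = yellow[yellow["condition"] != "none"]["mean_yellow_speed"]
    base = yellow[yellow["condition"] == "none"]["mean_yellow_speed"]
    sid = subjects[0]
    if hmi.empty:
        raise ValueError(f"subject {sid}: no yellow trials in the HMI condition")
    if base.empty:
        raise ValueError(f"subject {sid}: no yellow trials in the baseline condition")
    return float(hmi.mean() - base.mean())


@dataclass
class DecisionModel:
    hyper: DecisionHyper
    _svr: Pipeline | None = None

    @property
    def fitted(self) -> bool:
        return self._svr is not None and hasattr(self._svr[-1], "support_")

    def predict(self, z: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("decision model has not been fitted")
        return self._svr.predict(np.atleast_2d(np.asarray(z, dtype=float)))


def fit_decision_model(
    latents: dict[str, np.ndarray],
    targets: dict[str, float],
    hyper: DecisionHyper = DecisionHyper(),
) -> DecisionModel:
    """Fit the SVR on (snippet latent -> subject target) pairs.

    ``latents`` maps subject id to an (n_i, d) array of that subject's
    snippet latent means; every row shares the subject's single target.
    """
    if len(latents) < 2:
        raise ValueError("need latents from at least 2 subjects")
    missing = set(latents) - set(targets)
    if missing:
        raise ValueError(f"subjects without targets: {sorted(missing)}")
    X = np.concatenate([np.atleast_2d(latents[s]) for s in sorted(latents)])
    y = np.concatenate([
        np.full(len(np.atleast_2d(latents[s])), targets[s]) for s in sorted(latents)
    ])
    # exact duplicates carry no information for a many-to-one fit but would
    # re-weight the SVR's slack penalty; drop them for duplicate-invariance
    _, keep = np.unique(np.column_stack([X, y]), axis=0, return_index=True)
    X, y = X[np.sort(keep)], y[np.sort(keep)]
    # standardize latent inputs: the polynomial kernel is scale-sensitive and
    # libsvm converges poorly on raw latent magnitudes
    svr = make_pipeline(
        StandardScaler(),
        SVR(kernel="poly", degree=hyper.degree, C=hyper.C,
            epsilon=hyper.epsilon, coef0=hyper.coef0))
    svr.fit(X, y)
    return DecisionModel(hyper=hyper, _svr=svr)


def predict_delta(model: DecisionModel, z: np.ndarray) -> float:
    """Predicted speed change (m/s) for one latent vector."""
    return float(model.predict(np.atleast_2d(z))[0])


def decide_instantaneous(model: DecisionModel, z: np.ndarray) -> bool:
    """Deploy iff the predicted speed change is below the threshold
    (ties withhold)."""
    return predict_delta(model, z) < model.hyper.decision_threshold


def decide_window_averaged(model: DecisionModel, latents: np.ndarray) -> bool:
    """Deploy iff the mean predicted speed change over the subject's recent
    snippet latents is below the threshold."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if latents.size == 0:
        raise ValueError("empty latent window")
    preds = model.predict(latents)
    return float(preds.mean()) < model.hyper.decision_threshold
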