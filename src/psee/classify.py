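"""Windowed feature assembly and the kernel disorder classifier.

Per-residue feature tables (one row per residue, a fixed set of named
columns with the PSEE column last) are expanded with a sliding window: the
feature blocks of the w residues centered on each position are concatenated,
zero-padding past the termini, so a window of 21 over 57 features yields
1197 values per residue.  An RBF-kernel support-vector classifier with
calibrated probability output predicts per-residue disorder probability;
the operating point is chosen on held-out data by maximizing Youden's J
(sensitivity + specificity - 1) over the ROC thresholds, and raw
probabilities are piecewise-linearly rescaled so the chosen threshold maps
to 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .energy import DISORDERED, ORDERED

__all__ = [
    "FeatureSchema",
    "ClassifierConfig",
    "DisorderPrediction",
    "default_schema",
    "terminal_indicator",
    "assemble_windowed_features",
    "train_disorder_classifier",
    "youden_optimal_threshold",
    "rescale_probability",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def default_schema(window: int = 21) -> "FeatureSchema":
    """The full 57-feature per-residue layout.

    One amino-acid encoding, seven physicochemical properties, twenty
    evolutionary-profile (PSSM) columns, three secondary-structure
    probabilities, one predicted relative surface area, two torsion-angle
    fluctuations, one PSSM monogram, twenty PSSM bigrams, the terminal
    indicator, and finally PSEE.  Columns other than PSEE and the terminal
    indicator are supplied from external per-residue tables.
    """
    names = (
        ["aa_code"]
        + [f"physchem_{i}" for i in range(1, 8)]
        + [f"pssm_{aa}" for aa in "ARNDCQEGHILKMFPSTWYV"]
        + ["ss_helix", "ss_beta", "ss_coil"]
        + ["rsa"]
        + ["phi_fluct", "psi_fluct"]
        + ["monogram"]
        + [f"bigram_{i}" for i in range(1, 21)]
        + ["terminal"]
        + ["psee"]
    )
    return FeatureSchema(tuple(names), window)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered per-residue feature names plus the sliding-window width."""

    feature_names: tuple[str, ...]
    window: int = 21

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.feature_names and self.feature_names[-1] != "psee":
            raise ValueError("the PSEE column must come last in the schema")

    @property
    def per_residue_width(self) -> int:
        return len(self.feature_names)

    @property
    def vector_length(self) -> int:
        return self.window * self.per_residue_width

    def without_psee(self) -> "FeatureSchema":
        """Ablated twin of the schema: identical but for the PSEE column.

        The resulting schema keeps ``terminal`` as its (new) last column and
        is exempt from the PSEE-last rule by construction.
        """
        schema = object.__new__(FeatureSchema)
        object.__setattr__(schema, "feature_names", self.feature_names[:-1])
        object.__setattr__(schema, "window", self.window)
        return schema


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM hyperparameters and the disorder decision threshold.

    cost and gamma default to the grid-search optimum of the reference
    predictor (C = 0.5, gamma = 2^-7); the decision threshold defaults to
    the Youden-optimal 0.79 found on an independent tuning set.
    """

    cost: float = 0.5
    gamma: float = 0.0078125
    decision_threshold: float = 0.79

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise ValueError("cost and gamma must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision threshold must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class DisorderPrediction:
    """Raw and rescaled disorder probability with the binary call."""

    raw_probability: float
    rescaled_probability: float
    label: str


def terminal_indicator(position: int, length: int) -> float:
    """Terminal-proximity feature: the first five positions get -1.0 to
    -0.2 in steps of 0.2, the last five +0.2 to +1.0, interior residues 0.

    For sequences shorter than 10 residues both rules can apply; the
    N-terminal value wins for the first ceil(L/2) positions.
    """
    if length < 1 or not 1 <= position <= length:
        raise ValueError(f"position {position} outside 1..{length}")
    n_value = -1.0 + 0.2 * (position - 1) if position <= 5 else None
    c_value = 0.2 * (position - (length - 5)) if position >= length - 4 else None
    if n_value is not None and c_value is not None:
        return n_value if position <= math.ceil(length / 2) else c_value
    if n_value is not None:
        return n_value
    if c_value is not None:
        return c_value
    return 0.0


def assemble_windowed_features(
    per_residue_features: np.ndarray, schema: FeatureSchema
) -> np.ndarray:
    """Concatenate the w feature blocks centered on each residue.

    Input is an L x F table aligned with ``schema.feature_names``; output is
    L x (w * F).  Positions outside the sequence contribute all-zero blocks.
    """
    table = np.asarray(per_residue_features, dtype=float)
    if table.ndim != 2 or table.shape[1] != schema.per_residue_width:
        raise ValueError(
            f"feature table width {table.shape} does not match schema width "
            f"{schema.per_residue_width}"
        )
    L, F = table.shape
    half = (schema.window - 1) // 2
    padded = np.zeros((L + 2 * half, F))
    padded[half : half + L] = table
    out = np.empty((L, schema.window * F))
    for offset in range(schema.window):
        out[:, offset * F : (offset + 1) * F] = padded[offset : offset + L]
    return out


def train_disorder_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> Pipeline:
    """Fit the RBF-kernel SVM with calibrated (sigmoid-fit) probabilities.

    Labels are {O, D} strings with disordered as the positive class.
    Features are first scaled per column into [-1, 1] (the conventional
    LIBSVM preprocessing, which keeps the RBF length scale compatible with
    the default gamma); the probability calibration uses an internal
    stratified cross-validation whose fold assignment derives from ``seed``,
    so training is reproducible for a fixed seed.
    """
    config = config or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows must match labels")
    present = set(y.tolist())
    if present != {ORDERED, DISORDERED}:
        raise ValueError(
            f"training data must contain both classes, found {sorted(present)}"
        )
    svm = SVC(C=config.cost, gamma=config.gamma, kernel="rbf")
    model = Pipeline(
        [
            ("scale", MinMaxScaler(feature_range=(-1.0, 1.0))),
            (
                "svm",
                CalibratedClassifierCV(
                    svm,
                    method="sigmoid",
                    cv=StratifiedKFold(5, shuffle=True, random_state=seed),
                    ensemble=False,
                ),
            ),
        ]
    )
    model.fit(X, (y == DISORDERED).astype(int))
    return model


def disorder_probability(model: Pipeline, features: np.ndarray) -> np.ndarray:
    """Probability of the disordered class per row."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {X.shape[1]} does not match the trained model "
            f"({model.n_features_in_})"
        )
    positive = list(model.classes_).index(1)
    return model.predict_proba(X)[:, positive]


def youden_optimal_threshold(
    probabilities: Sequence[float], labels: Sequence[str]
) -> float:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Candidates are the midpoints between consecutive distinct sorted scores,
    plus 0 and 1; a score >= threshold is called disordered.  Ties are
    broken toward higher specificity, then toward the lower threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    pos = y == DISORDERED
    neg = y == ORDERED
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to optimize the threshold")
    distinct = np.unique(p)
    candidates = [0.0, 1.0] + [
        0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])
    ]
    best = None
    for t in candidates:
        called = p >= t
        sens = np.sum(called & pos) / np.sum(pos)
        spec = np.sum(~called & neg) / np.sum(neg)
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def rescale_probability(p: float, threshold: float) -> float:
    """Map raw probability so the decision threshold lands on 0.5.

    Piecewise linear and continuous: [0, threshold) -> [0, 0.5) and
    [threshold, 1] -> [0.5, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie strictly inside (0, 1), got {threshold}")
    if p < threshold:
        return p * 0.5 / threshold
    return 0.5 + (p - threshold) * 0.5 / (1.0 - threshold)


def inverse_rescale_probability(q: float, threshold: float) -> float:
    """Inverse of :func:`rescale_probability` (used for round-trip checks)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"rescaled probability must lie in [0, 1], got {q}")
    if q < 0.5:
        return q * threshold / 0.5
    return threshold + (q - 0.5) * (1.0 - threshold) / 0.5


def predict(
    model: Pipeline, features: np.ndarray, config: ClassifierConfig | None = None
) -> list[DisorderPrediction]:
    """Per-residue disorder predictions from a trained model.

    A residue is called disordered exactly when its raw probability reaches
    the decision threshold, equivalently when its rescaled probability
    reaches 0.5.
    """
    config = config or ClassifierConfig()
    raw = disorder_probability(model, features)
    out = []
    for p in raw:
        rescaled = rescale_probability(float(p), config.decision_threshold)
        label = DISORDERED if p >= config.decision_threshold else ORDERED
        out.append(DisorderPrediction(float(p), rescaled, label))
    return out


# ---------------------------------------------------------------------------
# Model persistence


def save_model(
    path,
    model: Pipeline,
    schema: FeatureSchema,
    config: ClassifierConfig,
    seed: int,
) -> None:
    """Persist a trained model with its schema, config and seed."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": list(schema.feature_names),
            "window": schema.window,
            "config": {
                "cost": config.cost,
                "gamma": config.gamma,
                "decision_threshold": config.decision_threshold,
            },
            "seed": seed,
            "model": model,
        },
        path,
    )


def load_model(
    path, expected_schema: FeatureSchema | None = None
) -> tuple[Pipeline, FeatureSchema, ClassifierConfig, int]:
    """Load a persisted model; fails loudly on schema or version mismatch."""
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model archive version {payload.get('format_version')!r}"
        )
    schema = object.__new__(FeatureSchema)
    object.__setattr__(schema, "feature_names", tuple(payload["feature_names"]))
    object.__setattr__(schema, "window", payload["window"])
    if expected_schema is not None and schema != expected_schema:
        raise ValueError("model archive schema does not match the expected schema")
    config = ClassifierConfig(**payload["config"])
    return payload["model"], schema, config, payload["seed"]
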