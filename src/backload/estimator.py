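"""Per-sample gradient-boosted moment estimation with leave-one-subject-out CV.

The regressor is a histogram-binned gradient-boosted decision tree ensemble
(~100 trees, squared-error loss): each stage fits a shallow tree to the
residual of the running ensemble, with feature values pre-binned into
histograms for speed.  Predictions are instantaneous — the channels at one
time sample predict the moment at that same sample, with no temporal
context.

Cross-validation is leave-one-subject-out: for each participant, the
z-score normalizer and the model are fitted on the other participants and
evaluated on the held-out one, so no per-person information leaks into the
fold that predicts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingRegressor

from .features import FeatureMatrix, Normalizer, apply_normalizer, fit_normalizer

__all__ = ["GbdtConfig", "MomentEstimator", "fit", "predict", "loso_cv", "CvPrediction"]


@dataclass(frozen=True)
class GbdtConfig:
    """Gradient-boosted ensemble hyperparameters."""

    n_trees: int = 100
    learning_rate: float = 0.1
    max_bins: int = 255
    max_leaves: int = 31
    min_samples_leaf: int = 20
    loss: str = "squared_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 2 <= self.max_bins <= 255:
            raise ValueError("max_bins must lie in [2, 255]")


class MomentEstimator:
    """Stage-wise histogram GBDT with a frozen channel schema."""

    def __init__(self, config: GbdtConfig | None = None):
        self.config = config or GbdtConfig()
        self.channel_names: list[str] | None = None
        self._model = HistGradientBoostingRegressor(
            loss=self.config.loss,
            max_iter=self.config.n_trees,
            learning_rate=self.config.learning_rate,
            max_bins=self.config.max_bins,
            max_leaf_nodes=self.config.max_leaves,
            min_samples_leaf=self.config.min_samples_leaf,
            early_stopping=False,
            random_state=self.config.seed,
        )

    def fit(self, X, y, channel_names: list[str] | None = None) -> "MomentEstimator":
        if isinstance(X, FeatureMatrix):
            channel_names = X.channel_names
            X = X.values
        X = np.asarray(X)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[0] != y.shape[0]:
            raise ValueError("feature/target sample-count mismatch")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite target")
        self.channel_names = list(channel_names) if channel_names else None
        self._model.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        names = None
        if isinstance(X, FeatureMatrix):
            names = X.channel_names
            X = X.values
        X = np.asarray(X)
        if self.channel_names is not None and names is not None and names != self.channel_names:
            raise ValueError("channel schema mismatch between fit and predict")
        if X.shape[1] != self._model.n_features_in_:
            raise ValueError("channel schema mismatch between fit and predict")
        return self._model.predict(X)

    # sklearn-compatible surface for permutation importance
    def score(self, X, y) -> float:
        return self._model.score(np.asarray(X), np.asarray(y))

    def get_params(self, deep: bool = True):  # pragma: no cover - sklearn plumbing
        return {"config": self.config}

    @property
    def fingerprint(self) -> dict:
        return {"config": self.config.__dict__, "channels": self.channel_names}

    def save(self, path) -> None:
        """Serialize to a versioned artifact (pickle payload + fingerprint)."""
        import pickle
        from pathlib import Path

        artifact = {
            "format": "backload-model",
            "version": 1,
            "fingerprint": self.fingerprint,
            "model": self._model,
        }
        Path(path).write_bytes(pickle.dumps(artifact))

    @classmethod
    def load(cls, path) -> "MomentEstimator":
        import pickle
        from pathlib import Path

        artifact = pickle.loads(Path(path).read_bytes())
        if artifact.get("format") != "backload-model" or artifact.get("version") != 1:
            raise ValueError("unrecognized model artifact")
        out = cls(GbdtConfig(**artifact["fingerprint"]["config"]))
        out._model = artifact["model"]
        out.channel_names = artifact["fingerprint"]["channels"]
        return out


def fit(features, target, config: GbdtConfig | None = None) -> MomentEstimator:
    """Fit a moment estimator on (already normalized) features."""
    return MomentEstimator(config).fit(features, target)


def predict(model: MomentEstimator, features) -> np.ndarray:
    """Per-sample wearable estimate of the target moment."""
    return model.predict(features)


@dataclass
class CvPrediction:
    """Leave-one-subject-out predictions covering the full dataset."""

    participants: list[str]
    indices: dict[str, np.ndarray]  # row indices of each held-out participant
    y_true: np.ndarray
    y_pred: np.ndarray
    models: dict[str, MomentEstimator] = field(default_factory=dict)
    normalizers: dict[str, Normalizer] = field(default_factory=dict)

    def fold(self, participant: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices[participant]
        return self.y_true[idx], self.y_pred[idx]


def loso_cv(
    fm: FeatureMatrix,
    y: np.ndarray,
    config: GbdtConfig | None = None,
    keep_models: bool = True,
) -> CvPrediction:
    """Leave-one-subject-out cross-validation.

    Per fold, the z-score normalizer and the GBDT are fitted on all other
    participants and applied unchanged to the held-out one.
    """
    y = np.asarray(y)
    pids = fm.index["participant_id"].to_numpy()
    participants = sorted(set(pids))
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for LOSO CV")

    y_pred = np.empty_like(y, dtype=float)
    indices: dict[str, np.ndarray] = {}
    models: dict[str, MomentEstimator] = {}
    normalizers: dict[str, Normalizer] = {}
    for pid in participants:
        test = pids == pid
        train = ~test
        if not np.any(test):
            raise ValueError(f"participant {pid} has no samples")
        norm = fit_normalizer(fm.values[train], fm.channel_names)
        model = MomentEstimator(config).fit(
            apply_normalizer(norm, fm.values[train]), y[train], fm.channel_names)
        y_pred[test] = model.predict(apply_normalizer(norm, fm.values[test]))
        indices[pid] = np.flatnonzero(test)
        if keep_models:
            models[pid] = model
            normalizers[pid] = norm
    return CvPrediction(
        participants=participants,
        indices=indices,
        y_true=y.astype(float),
        y_pred=y_pred,
        models=models,
        normalizers=normalizers,
    )
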