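import numpy as np
import pandas as pd
import pytest

from adscreen import DecisionTable


@pytest.fixture
def t1() -> DecisionTable:
    """Six-object toy table with the unique reduct {a, b} and gamma = 4/6."""
    frame = pd.DataFrame(
        {
            "a": ["1", "1", "1", "2", "2", "1"],
            "b": ["1", "1", "2", "2", "2", "2"],
            "d": ["Normal", "Normal", "MCI", "AD", "AD", "AD"],
        }
    )
    return DecisionTable(frame, "d")


def random_table(
    rng: np.random.Generator,
    n_objects: int,
    n_attributes: int,
    cardinality: int = 3,
    n_classes: int = 2,
) -> DecisionTable:
    """Uniform random decision table (may be inconsistent)."""
    frame = pd.DataFrame(
        {
            f"a{j}": rng.integers(0, cardinality, size=n_objects).astype(str)
            for j in range(n_attributes)
        }
    )
    frame["d"] = rng.integers(0, n_classes, size=n_objects).astype(str)
    return DecisionTable(frame, "d")


class ConstantClassifier:
    """Predicts a fixed label regardless of input; sklearn-cloneable."""

    def __init__(self, label="MCI"):
        self.label = label

    def get_params(self, deep=True):
        return {"label": self.label}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=object)


class MajorityClassifier:
    """Predicts the most frequent training label."""

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y):
        vals, counts = np.unique(np.asarray(y, dtype=object), return_counts=True)
        self.majority_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=object)


class FirstItemBandClassifier:
    """Deterministic rule on the first column; zero training error on
    separable cohorts whose first item uses disjoint per-class bands."""

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, X, y):
        self.map_ = {}
        for v, lab in zip(np.asarray(X)[:, 0], y):
            self.map_.setdefault(str(v), lab)
        self.default_ = list(self.map_.values())[0]
        return self

    def predict(self, X):
        return np.asarray(
            [self.map_.get(str(v), self.default_) for v in np.asarray(X)[:, 0]],
            dtype=object,
        )
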