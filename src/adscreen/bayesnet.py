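"""Discrete Bayesian-network classifier over selected scale items.

The model is a DAG over the item nodes plus one class node, with a
conditional probability table (CPT) per node estimated by Laplace-smoothed
relative frequency.  Two structure strategies are provided:

``naive``
    class -> every item (conditional independence of items given the class);
    the simplest structure consistent with n ~ 500 training cases.
``hillclimb``
    greedy arc search (add / delete / reverse) maximising a BIC-penalised
    log-likelihood, starting from the naive structure, class node always
    present, parent count capped.

Because screening cases always observe every selected item, classification
needs no general inference machinery: the posterior over the class node is
obtained by evaluating the factorised joint once per class value and
normalising.  The predicted label is the argmax, ties broken by the first
class in the declared label order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from .table import DecisionTable

__all__ = [
    "BNError",
    "BNModel",
    "Prediction",
    "fit_bn",
    "predict",
    "save_model",
    "load_model",
    "BayesNetClassifier",
]

_HIGH_CARDINALITY_WARN = 12


class BNError(ValueError):
    pass


@dataclass
class _Node:
    states: list[str]
    parents: tuple[str, ...]
    parent_cards: tuple[int, ...]
    counts: np.ndarray  # shape (n_states, n_parent_configs), raw counts
    cpt: np.ndarray     # same shape, columns sum to 1


@dataclass
class Prediction:
    probabilities: dict[str, float]
    label: str


@dataclass
class BNModel:
    """DAG + one CPT per node; the class node carries the diagnosis."""

    class_node: str
    class_labels: tuple[str, ...]
    nodes: dict[str, _Node] = field(default_factory=dict)
    alpha: float = 1.0

    @property
    def item_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n != self.class_node)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        out = []
        for child, nd in self.nodes.items():
            for p in nd.parents:
                out.append((p, child))
        return tuple(out)

    # -- inference --------------------------------------------------------

    def _config_index(self, node: str, assignment: Mapping[str, str]) -> int | None:
        """Mixed-radix index of the parent configuration; None if any parent
        value was never seen in training."""
        nd = self.nodes[node]
        idx = 0
        stride = 1
        for p, card in zip(nd.parents, nd.parent_cards):
            try:
                k = self.nodes[p].states.index(assignment[p])
            except ValueError:
                return None
            idx += k * stride
            stride *= card
        return idx

    def _node_loglik(self, node: str, assignment: Mapping[str, str]) -> float:
        nd = self.nodes[node]
        cfg = self._config_index(node, assignment)
        k = len(nd.states)
        if cfg is None:
            # unseen parent value: uninformative uniform likelihood
            if self.alpha <= 0:
                raise BNError(
                    f"value of a parent of {node!r} unseen in training and "
                    "smoothing is 0"
                )
            return -math.log(k)
        val = assignment[node]
        try:
            vi = nd.states.index(val)
        except ValueError:
            if self.alpha <= 0:
                raise BNError(
                    f"value {val!r} of node {node!r} unseen in training and "
                    "smoothing is 0"
                )
            # pseudocount floor for a state absent from training
            n_cfg = float(nd.counts[:, cfg].sum())
            return math.log(self.alpha / (n_cfg + self.alpha * (k + 1)))
        return math.log(nd.cpt[vi, cfg])

    def posterior(self, case: Mapping[str, str]) -> Prediction:
        """Exact posterior over the class node given a fully observed case."""
        missing = [n for n in self.item_nodes if n not in case]
        if missing:
            raise BNError(f"case is missing item(s): {missing}")
        case = {k: str(v) for k, v in case.items()}
        logs = []
        for label in self.class_labels:
            assignment = dict(case)
            assignment[self.class_node] = label
            lp = 0.0
            for node in self.nodes:
                lp += self._node_loglik(node, assignment)
            logs.append(lp)
        logs = np.asarray(logs)
        logs -= logs.max()
        probs = np.exp(logs)
        probs /= probs.sum()
        probabilities = {lab: float(p) for lab, p in zip(self.class_labels, probs)}
        best = int(np.argmax(probs))  # argmax returns the first maximum: declared order
        return Prediction(probabilities=probabilities, label=self.class_labels[best])

    # -- serialization (plain JSON, bit-exact reload) ----------------------

    def to_json(self) -> dict:
        return {
            "class_node": self.class_node,
            "class_labels": list(self.class_labels),
            "alpha": self.alpha,
            "nodes": {
                name: {
                    "states": nd.states,
                    "parents": list(nd.parents),
                    "parent_cards": list(nd.parent_cards),
                    "counts": nd.counts.tolist(),
                    "cpt": nd.cpt.tolist(),
                }
                for name, nd in self.nodes.items()
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BNModel":
        model = cls(
            class_node=obj["class_node"],
            class_labels=tuple(obj["class_labels"]),
            alpha=float(obj["alpha"]),
        )
        for name, nd in obj["nodes"].items():
            model.nodes[name] = _Node(
                states=list(nd["states"]),
                parents=tuple(nd["parents"]),
                parent_cards=tuple(int(c) for c in nd["parent_cards"]),
                counts=np.asarray(nd["counts"], dtype=float),
                cpt=np.asarray(nd["cpt"], dtype=float),
            )
        return model


def save_model(model: BNModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_json(), indent=1), encoding="utf-8")


def load_model(path: str | Path) -> BNModel:
    return BNModel.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _state_lists(frame: pd.DataFrame) -> dict[str, list[str]]:
    return {c: sorted(frame[c].unique().tolist()) for c in frame.columns}


def _fit_node(
    frame: pd.DataFrame,
    node: str,
    parents: Sequence[str],
    states: Mapping[str, list[str]],
    alpha: float,
) -> _Node:
    parents = tuple(parents)
    s_node = states[node]
    k = len(s_node)
    cards = tuple(len(states[p]) for p in parents)
    n_cfg = int(np.prod(cards)) if cards else 1
    counts = np.zeros((k, n_cfg), dtype=float)
    vcodes = frame[node].map({s: i for i, s in enumerate(s_node)}).to_numpy()
    cfg = np.zeros(len(frame), dtype=np.int64)
    stride = 1
    for p, card in zip(parents, cards):
        pc = frame[p].map({s: i for i, s in enumerate(states[p])}).to_numpy()
        cfg += pc * stride
        stride *= card
    np.add.at(counts, (vcodes, cfg), 1.0)
    denom = counts.sum(axis=0) + alpha * k
    if alpha == 0 and (counts.sum(axis=0) == 0).any():
        # empty parent configurations stay NaN-free: give them uniform columns
        cpt = np.where(
            counts.sum(axis=0) > 0, counts / np.maximum(counts.sum(axis=0), 1), 1.0 / k
        )
    else:
        cpt = (counts + alpha) / denom
    return _Node(
        states=s_node, parents=parents, parent_cards=cards, counts=counts, cpt=cpt
    )


def _family_bic(
    frame: pd.DataFrame,
    node: str,
    parents: tuple[str, ...],
    states: Mapping[str, list[str]],
    cache: dict,
) -> float:
    key = (node, parents)
    if key in cache:
        return cache[key]
    nd = _fit_node(frame, node, parents, states, alpha=0.0)
    counts = nd.counts
    col_tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(col_tot > 0, counts / np.maximum(col_tot, 1), 0.0)
        ll = np.where(counts > 0, counts * np.log(np.maximum(p, 1e-300)), 0.0).sum()
    k = len(nd.states)
    n_cfg = counts.shape[1]
    n_params = (k - 1) * n_cfg
    score = ll - 0.5 * math.log(len(frame)) * n_params
    cache[key] = score
    return score


def _hillclimb_structure(
    frame: pd.DataFrame,
    class_node: str,
    states: Mapping[str, list[str]],
    max_parents: int,
    max_iter: int = 200,
) -> dict[str, tuple[str, ...]]:
    """Greedy add/delete/reverse arc search maximising total family BIC,
    starting from the naive (class -> items) structure."""
    nodes = list(frame.columns)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for item in nodes:
        if item != class_node:
            g.add_edge(class_node, item)
    cache: dict = {}

    def parents_of(n: str) -> tuple[str, ...]:
        return tuple(sorted(g.predecessors(n)))

    def family(n: str) -> float:
        return _family_bic(frame, n, parents_of(n), states, cache)

    for _ in range(max_iter):
        best_delta = 1e-9
        best_op = None
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if g.has_edge(u, v):
                    # delete u -> v
                    before = family(v)
                    g.remove_edge(u, v)
                    delta = family(v) - before
                    g.add_edge(u, v)
                    if delta > best_delta:
                        best_delta, best_op = delta, ("del", u, v)
                    # reverse u -> v
                    if (
                        not g.has_edge(v, u)
                        and g.in_degree(u) < max_parents
                    ):
                        g.remove_edge(u, v)
                        creates_cycle = nx.has_path(g, u, v)
                        if not creates_cycle:
                            before2 = before + family(u)
                            g.add_edge(v, u)
                            delta = family(v) + family(u) - before2
                            g.remove_edge(v, u)
                            if delta > best_delta:
                                best_delta, best_op = delta, ("rev", u, v)
                        g.add_edge(u, v)
                else:
                    # add u -> v
                    if g.in_degree(v) >= max_parents or g.has_edge(v, u):
                        continue
                    if nx.has_path(g, v, u):
                        continue  # would create a cycle
                    before = family(v)
                    g.add_edge(u, v)
                    delta = family(v) - before
                    g.remove_edge(u, v)
                    if delta > best_delta:
                        best_delta, best_op = delta, ("add", u, v)
        if best_op is None:
            break
        op, u, v = best_op
        if op == "add":
            g.add_edge(u, v)
        elif op == "del":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
    return {n: tuple(sorted(g.predecessors(n))) for n in nodes}


def fit_bn(
    table: DecisionTable,
    structure: str = "naive",
    smoothing: float = 1.0,
    max_parents: int = 3,
) -> BNModel:
    """Fit the classifier network on a (possibly projected) decision table.

    ``structure`` is "naive" (class -> every item) or "hillclimb" (greedy
    BIC arc search with the class node forced present).  CPTs are estimated
    by relative frequency with ``smoothing`` pseudocounts per cell.
    """
    if smoothing < 0:
        raise BNError("smoothing must be >= 0")
    class_node = table.decision_attribute
    labels = table.class_labels
    if len(labels) < 2:
        raise BNError("training table contains a single decision class")
    frame = table.data
    states = _state_lists(frame)
    for item in table.condition_attributes:
        if len(states[item]) > _HIGH_CARDINALITY_WARN:
            warnings.warn(
                f"item {item!r} has {len(states[item])} observed values; "
                "consider binning before fitting",
                stacklevel=2,
            )
    if structure == "naive":
        parent_map = {class_node: ()}
        for item in table.condition_attributes:
            parent_map[item] = (class_node,)
    elif structure == "hillclimb":
        parent_map = _hillclimb_structure(frame, class_node, states, max_parents)
    else:
        raise BNError(f"unknown structure strategy {structure!r}")

    model = BNModel(class_node=class_node, class_labels=labels, alpha=float(smoothing))
    for node in frame.columns:
        model.nodes[node] = _fit_node(
            frame, node, parent_map[node], states, alpha=float(smoothing)
        )
    return model


def predict(model: BNModel, case: Mapping[str, str]) -> Prediction:
    """Posterior class probabilities for one fully observed case."""
    return model.posterior(case)


# ---------------------------------------------------------------------------
# sklearn-style classifier
# ---------------------------------------------------------------------------

class BayesNetClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian-network classifier for categorical features.

    Parameters
    ----------
    structure : {"naive", "hillclimb"}
        Network topology strategy; see :func:`fit_bn`.
    smoothing : float
        Laplace pseudocount per CPT cell (default 1.0).
    max_parents : int
        Parent cap for the hill-climbing search.
    """

    def __init__(
        self, structure: str = "naive", smoothing: float = 1.0, max_parents: int = 3
    ):
        self.structure = structure
        self.smoothing = smoothing
        self.max_parents = max_parents

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        X = check_array(X, dtype=None, ensure_2d=True)
        y = column_or_1d(y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        names = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(X.shape[1])]
        )
        from .table import table_from_arrays

        table = table_from_arrays(X, y, feature_names=names)
        model = fit_bn(
            table,
            structure=self.structure,
            smoothing=self.smoothing,
            max_parents=self.max_parents,
        )
        # align declared label order with sklearn's sorted classes_
        model.class_labels = tuple(str(c) for c in self.classes_)
        self.model_ = model
        self._names = names
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=None, ensure_2d=True)
        out = np.empty((len(X), len(self.classes_)), dtype=float)
        for i, row in enumerate(X):
            case = {name: str(v) for name, v in zip(self._names, row)}
            pred = self.model_.posterior(case)
            out[i] = [pred.probabilities[str(c)] for c in self.classes_]
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
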