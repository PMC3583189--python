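"""Train/test classification harness and the ordering-method / r sweep.

Replicates the benchmark protocol: train a linear SVM on the IXP
features of one labeled dataset, blind-test on another, and sweep the
horizontal influence coefficient r across ordering methods.  Orderings
and gene weights are computed from the network only — never from test
data — and are reused across the whole r grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_formats import ExpressionMatrix
from .ixp import IxpParams, IXPFeatureMatrix, transform_dataset
from .network import PPINetwork, compute_gene_weights, GeneWeights
from .reorder import (AcorParams, NodeOrdering, acor_reorder, hclust_order,
                      random_order, random_walk_rank)

__all__ = ["SweepParams", "SweepResult", "train_classifier", "evaluate_accuracy",
           "run_sweep", "DEFAULT_R_GRID", "DEFAULT_METHODS"]

DEFAULT_R_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(10))
DEFAULT_METHODS: tuple[str, ...] = ("acor", "rank", "hclust", "random",
                                    "random+uniweight")


@dataclass(frozen=True)
class SweepParams:
    """Everything a sweep needs besides the data: kernel/weight settings,
    SVM regularization, ACOR parameters, and the seed for the random
    ordering baseline."""

    ixp: IxpParams = field(default_factory=IxpParams)
    acor: AcorParams = field(default_factory=AcorParams)
    normalization: str = "per_gene_z"
    c_param: float = 1.0
    damping: float = 0.85
    rank_tol: float = 1e-10
    seed: int = 0


@dataclass
class SweepResult:
    """Long-format accuracy grid: one row per (method, r) cell."""

    grid: pd.DataFrame  # columns: method, r, accuracy
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        acc = self.grid["accuracy"]
        if ((acc < 0) | (acc > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    def accuracy(self, method: str, r: float) -> float:
        sel = self.grid[(self.grid["method"] == method)
                        & np.isclose(self.grid["r"], r)]
        if sel.empty:
            raise KeyError(f"no sweep cell for ({method!r}, r={r})")
        return float(sel["accuracy"].iloc[0])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            meta = "; ".join(f"{k}={v}" for k, v in self.metadata.items())
            fh.write(f"# sweep: {meta}\n")
            self.grid.to_csv(fh, sep="\t", index=False)


def train_classifier(features: IXPFeatureMatrix, labels: pd.Series,
                     c_param: float = 1.0) -> SVC:
    """Fit a linear-kernel SVM with regularization ``c_param``."""
    if c_param <= 0:
        raise ValueError("c_param must be > 0")
    x = features.values.to_numpy()
    y = labels.loc[features.values.index].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    model = SVC(kernel="linear", C=c_param)
    model.fit(x, y)
    return model


def evaluate_accuracy(model: SVC, features: IXPFeatureMatrix,
                      labels: pd.Series) -> float:
    """Plain accuracy = (#correct) / (#samples) on a blind test set."""
    x = features.values.to_numpy()
    if x.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match the trained "
            f"model's {model.n_features_in_}"
        )
    y = labels.loc[features.values.index].to_numpy()
    return float(np.mean(model.predict(x) == y))


def _orderings_for(net: PPINetwork, methods: list[str],
                   params: SweepParams) -> dict[str, NodeOrdering]:
    out: dict[str, NodeOrdering] = {}
    base = {m.split("+")[0] for m in methods}
    if "acor" in base:
        out["acor"] = acor_reorder(net, params.acor)
    if "rank" in base:
        out["rank"] = random_walk_rank(net, params.damping, params.rank_tol)
    if "hclust" in base:
        out["hclust"] = hclust_order(net)
    if "random" in base:
        out["random"] = random_order(net, seed=params.seed)
    return out


def run_sweep(train: ExpressionMatrix, test: ExpressionMatrix, net: PPINetwork,
              r_grid=DEFAULT_R_GRID, methods=DEFAULT_METHODS,
              params: SweepParams | None = None) -> SweepResult:
    """Accuracy for every (ordering method, r) cell.

    ``random+uniweight`` reuses the random permutation but with unified
    gene weights (all equal to one); every other method uses the
    weights selected by ``params.ixp.weight_mode``.  Each ordering is
    computed once and reused across the r grid.
    """
    params = params or SweepParams()
    methods = list(methods)
    r_grid = [float(r) for r in r_grid]
    if not r_grid:
        raise ValueError("r_grid must be non-empty")
    if train.labels is None or test.labels is None:
        raise ValueError("train and test sets must both be labeled")
    shared = set(train.gene_ids) & set(net.graph.nodes)
    if not shared:
        raise ValueError("train set shares no genes with the network")

    orderings = _orderings_for(net, methods, params)
    main_weights = compute_gene_weights(net, params.ixp.weight_mode)
    uni_weights = compute_gene_weights(net, "uniform")

    rows = []
    for method in methods:
        base = method.split("+")[0]
        if base not in orderings:
            raise ValueError(f"unknown ordering method {method!r}")
        weights = uni_weights if method.endswith("+uniweight") else main_weights
        for r in r_grid:
            ixp_params = replace(params.ixp, r=r)
            try:
                fm_train = transform_dataset(train, orderings[base], weights,
                                             ixp_params, params.normalization)
                fm_test = transform_dataset(test, orderings[base], weights,
                                            ixp_params, params.normalization)
                model = train_classifier(fm_train, train.labels, params.c_param)
                acc = evaluate_accuracy(model, fm_test, test.labels)
            except Exception as exc:
                raise RuntimeError(f"sweep failed at (method={method}, r={r}): {exc}") from exc
            rows.append({"method": method, "r": r, "accuracy": acc})

    grid = pd.DataFrame(rows, columns=["method", "r", "accuracy"])
    assert len(grid) == len(methods) * len(r_grid), "incomplete sweep grid"
    return SweepResult(
        grid=grid,
        metadata={
            "n_train": train.n_samples,
            "n_test": test.n_samples,
            "n_network_genes": net.n_genes,
            "normalization": params.normalization,
            "weight_mode": params.ixp.weight_mode,
            "base_bandwidth": params.ixp.base_bandwidth,
            "c_param": params.c_param,
            "seed": params.seed,
            "acor_seed": params.acor.seed,
        },
    )
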