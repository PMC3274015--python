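"""Experiment harness: splits, level scans, wavelet scans, confusion stats.

Each experiment is a pure function of its seeds: the same (dataset seed,
split seed, init seed, configuration) always yields the same result.
Accuracy is the percentage of correctly classified patterns; confusion
matrices are row-normalized percentages (row i = true class i).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .features import (FeatureKind, Normalizer, apply_normalizer,
                       build_feature_matrix, fit_normalizer)
from .mlp import (EnlargeResult, MLPNetwork, NetworkConfig, TrainingOptions,
                  enlarge_hidden, forward, init_network, lm_train, one_hot,
                  predict)
from .synthetic import LabeledDataset
from .wavelets import FAMILY_ORDERS, WaveletSpec, get_wavelet, iter_catalogue

__all__ = [
    "DEFAULT_TRAIN_FRACTION",
    "split_indices",
    "ExperimentResult",
    "run_single",
    "level_scan",
    "wavelet_scan",
    "ConfusionStats",
    "confusion_over_runs",
    "format_level_scan",
    "format_confusion",
]

#: One third of the patterns train the network; the rest test it.
DEFAULT_TRAIN_FRACTION = 1.0 / 3.0

# Classification-accuracy stopping matches the enlarging criterion and is
# the experiments' default; plain MSE stopping remains available.
DEFAULT_OPTS = TrainingOptions(goal_accuracy=100.0)


def split_indices(labels, train_fraction: float = DEFAULT_TRAIN_FRACTION,
                  seed: int = 0, stratified: bool = True
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test split of pattern indices."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, train_size=train_fraction, random_state=int(seed),
        stratify=labels if stratified else None, shuffle=True)
    if stratified:
        missing = set(np.unique(labels)) - set(np.unique(labels[train]))
        if missing:
            raise ValueError(f"classes {sorted(missing)} absent from the "
                             "training split")
    return np.sort(train), np.sort(test)


@dataclass
class ExperimentResult:
    feature_kind: str
    wavelet: str
    level: int
    complexity: str  # n1:n2:n3
    train_accuracy: float
    test_accuracy: float
    split_seed: int
    init_seed: int
    elapsed_s: float
    confusion: np.ndarray = field(repr=False, default=None)  # row-% on test
    network: MLPNetwork = field(repr=False, default=None)
    normalizer: Normalizer = field(repr=False, default=None)
    classes: np.ndarray = field(repr=False, default=None)
    enlarge_trace: list = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "feature_kind": self.feature_kind, "wavelet": self.wavelet,
            "level": self.level, "complexity": self.complexity,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "split_seed": self.split_seed, "init_seed": self.init_seed,
            "elapsed_s": self.elapsed_s,
        }


def _accuracy(net: MLPNetwork, X: np.ndarray, y: np.ndarray,
              classes: np.ndarray) -> float:
    return 100.0 * float(np.mean(predict(net, X, classes) == y))


def run_single(dataset: LabeledDataset, kind, wavelet: WaveletSpec,
               level: int, split_seed: int = 0, init_seed: int = 0, *,
               opts: TrainingOptions = DEFAULT_OPTS,
               train_fraction: float = DEFAULT_TRAIN_FRACTION,
               stratified: bool = True,
               n_hidden: int | None = None,
               h_min: int = 2, h_step: int = 2, h_max: int = 32,
               precomputed: tuple[np.ndarray, np.ndarray] | None = None,
               ) -> ExperimentResult:
    """One full experiment: features -> split -> normalize -> train -> test.

    With ``n_hidden`` unset the hidden-layer size is found by enlarging;
    an explicit value skips the search.  ``precomputed`` may carry an
    already-built (X, y) feature matrix to avoid recomputation in scans.
    """
    kind = FeatureKind.from_code(kind)
    t0 = time.perf_counter()
    if precomputed is None:
        X, y = build_feature_matrix(dataset, kind, wavelet, level)
    else:
        X, y = precomputed
    train_idx, test_idx = split_indices(y, train_fraction, split_seed,
                                        stratified)
    norm = fit_normalizer(X[train_idx])
    X_train = apply_normalizer(norm, X[train_idx])
    X_test = apply_normalizer(norm, X[test_idx])
    T_train, classes = one_hot(y[train_idx], np.unique(y))

    trace = None
    if n_hidden is None:
        enl = enlarge_hidden(X.shape[1], len(classes), X_train, T_train, opts,
                             h_min=h_min, h_step=h_step, h_max=h_max,
                             seed=init_seed)
        net, n_hidden, trace = enl.network, enl.n_hidden, enl.trace
    else:
        cfg = NetworkConfig(X.shape[1], int(n_hidden), len(classes))
        net = lm_train(init_network(cfg, init_seed), X_train, T_train,
                       opts).network

    y_pred_test = predict(net, X_test, classes)
    conf = confusion_matrix(y[test_idx], y_pred_test, labels=classes,
                            normalize="true") * 100.0
    return ExperimentResult(
        feature_kind=kind.value,
        wavelet=wavelet.name,
        level=int(level),
        complexity=f"{X.shape[1]}:{n_hidden}:{len(classes)}",
        train_accuracy=_accuracy(net, X_train, y[train_idx], classes),
        test_accuracy=100.0 * float(np.mean(y_pred_test == y[test_idx])),
        split_seed=int(split_seed),
        init_seed=int(init_seed),
        elapsed_s=time.perf_counter() - t0,
        confusion=conf,
        network=net,
        normalizer=norm,
        classes=classes,
        enlarge_trace=trace,
    )


def level_scan(dataset: LabeledDataset, kind, wavelet: WaveletSpec,
               levels=range(1, 9), split_seed: int = 0, init_seed: int = 0,
               **kwargs) -> pd.DataFrame:
    """One experiment per decomposition level; the best test row is marked."""
    rows = [run_single(dataset, kind, wavelet, lv, split_seed, init_seed,
                       **kwargs).as_row()
            for lv in levels]
    table = pd.DataFrame(rows)
    table["best"] = table["test_accuracy"] == table["test_accuracy"].max()
    return table


def wavelet_scan(dataset: LabeledDataset, kind=FeatureKind.VARS,
                 level: int = 5, families=None, split_seed: int = 0,
                 init_seed: int = 0, **kwargs
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan the wavelet catalogue at one level and feature set.

    Returns (per-wavelet results, per-family summary with mean/min/max
    test accuracy and the orders attaining the extremes).
    """
    rows = []
    for spec in iter_catalogue(families):
        res = run_single(dataset, kind, spec, level, split_seed, init_seed,
                         **kwargs)
        row = res.as_row()
        row["family"] = spec.family
        row["order"] = spec.order
        rows.append(row)
    results = pd.DataFrame(rows)
    summaries = []
    for family, grp in results.groupby("family", sort=False):
        acc = grp["test_accuracy"]
        summaries.append({
            "family": family,
            "n_orders": len(grp),
            "mean_test_accuracy": acc.mean(),
            "min_test_accuracy": acc.min(),
            "max_test_accuracy": acc.max(),
            "argmin_order": grp.loc[acc.idxmin(), "order"],
            "argmax_order": grp.loc[acc.idxmax(), "order"],
        })
    return results, pd.DataFrame(summaries)


# --------------------------------------------------------------------------
# repeated-run confusion statistics
# --------------------------------------------------------------------------

@dataclass
class ConfusionStats:
    """Mean and standard deviation of row-% confusion matrices over runs."""

    mean: np.ndarray
    std: np.ndarray
    classes: np.ndarray
    n_iterations: int
    mode: str
    overall_mean: float  # mean overall test accuracy (%)
    overall_std: float


def confusion_over_runs(dataset: LabeledDataset, kind, wavelet: WaveletSpec,
                        level: int, n_iter: int = 10,
                        mode: str = "fixed_split", *,
                        split_seed: int = 0, init_seeds=None,
                        opts: TrainingOptions = DEFAULT_OPTS,
                        train_fraction: float = DEFAULT_TRAIN_FRACTION,
                        n_hidden: int | None = None,
                        reuse_hidden: bool = True,
                        **kwargs) -> ConfusionStats:
    """Confusion statistics over repeated trainings.

    ``fixed_split`` re-initializes the network on the same train/test split
    each iteration (isolating initialization randomness); ``resplit``
    redraws the split as well.  By default the hidden size found by
    enlarging on the first iteration is reused afterwards
    (``reuse_hidden``); set it false to re-run the search every iteration.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if mode not in ("fixed_split", "resplit"):
        raise ValueError("mode must be 'fixed_split' or 'resplit'")
    if init_seeds is None:
        init_seeds = [int(split_seed) + 1000 + i for i in range(n_iter)]
    if len(init_seeds) != n_iter:
        raise ValueError("init_seeds must have n_iter entries")

    X, y = build_feature_matrix(dataset, FeatureKind.from_code(kind),
                                wavelet, level)
    mats, overall = [], []
    hidden = n_hidden
    for it in range(n_iter):
        s_seed = split_seed if mode == "fixed_split" else int(split_seed) + it
        res = run_single(dataset, kind, wavelet, level, s_seed,
                         init_seeds[it], opts=opts,
                         train_fraction=train_fraction, n_hidden=hidden,
                         precomputed=(X, y), **kwargs)
        if reuse_hidden and hidden is None:
            hidden = int(res.complexity.split(":")[1])
        mats.append(res.confusion)
        overall.append(res.test_accuracy)
    mats = np.stack(mats)
    return ConfusionStats(
        mean=mats.mean(axis=0),
        std=mats.std(axis=0, ddof=1),
        classes=np.unique(y),
        n_iterations=n_iter,
        mode=mode,
        overall_mean=float(np.mean(overall)),
        overall_std=float(np.std(overall, ddof=1)),
    )


# --------------------------------------------------------------------------
# report formatting
# --------------------------------------------------------------------------

def format_level_scan(table: pd.DataFrame) -> str:
    """Markdown table: level, train/test accuracy, network complexity."""
    lines = ["| level | training (%) | test (%) | ANN complexity |",
             "|---|---|---|---|"]
    for _, r in table.iterrows():
        test = f"**{r.test_accuracy:.1f}**" if r.get("best", False) \
            else f"{r.test_accuracy:.1f}"
        lines.append(f"| {r.level} | {r.train_accuracy:.1f} | {test} "
                     f"| {r.complexity} |")
    return "\n".join(lines)


def format_confusion(stats: ConfusionStats) -> str:
    """Markdown confusion matrix of mean ± one standard deviation (%)."""
    names = [f"M{c}" for c in stats.classes]
    lines = ["| true \\ classified | " + " | ".join(names) + " |",
             "|" + "---|" * (len(names) + 1)]
    for i, name in enumerate(names):
        cells = [f"{stats.mean[i, j]:.1f} ± {stats.std[i, j]:.1f}"
                 for j in range(len(names))]
        lines.append(f"| {name} | " + " | ".join(cells) + " |")
    lines.append(f"\noverall: {stats.overall_mean:.1f} ± "
                 f"{stats.overall_std:.1f} % over {stats.n_iterations} "
                 f"iterations ({stats.mode})")
    return "\n".join(lines)
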