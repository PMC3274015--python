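"""The twelve wavelet-domain feature sets and train-set normalization.

Each feature set summarizes one segment's DWT decomposition per channel;
a pattern's feature vector is the above-knee channel's features followed
by the below-knee channel's, so the pattern dimension is twice the
per-channel dimension.  "Normalized" quantities are min–max scaled to
[0, 1] with statistics estimated on the training set only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import LabeledDataset
from .wavelets import (WaveletSpec, coeff_lengths, coeff_stats, dwt_decompose,
                       edr)

__all__ = [
    "FeatureKind",
    "feature_dim_per_channel",
    "feature_dim",
    "channel_features",
    "build_features",
    "build_feature_matrix",
    "Normalizer",
    "fit_normalizer",
    "apply_normalizer",
    "save_features",
    "load_features",
]


class FeatureKind(Enum):
    """The candidate feature sets, identified by their letter codes."""

    APPROX = "a"                    # normalized approximation coefficients
    APPROX_DETAIL = "b"             # normalized approximation + detail coeffs
    EDR_D = "c"                     # EDR_Dj's
    EDR_ALL = "d"                   # EDR_A and EDR_Dj's
    EDR_A_D_SUMMARY = "e"           # EDR_A + min/max/mean/var of EDR_Dj's
    D_SUMMARY = "f"                 # min/max/mean/var of EDR_Dj's
    EDR_A_D_MEANVAR = "g"           # EDR_A + mean/var of EDR_Dj's
    D_MEANVAR = "h"                 # mean/var of EDR_Dj's
    MEANS_VARS = "i"                # normalized means and variances of coeffs
    MEANS = "j"                     # normalized means of coeffs
    VARS = "k"                      # normalized variances of coeffs
    VARS_EDR = "l"                  # normalized variances + EDRs

    @classmethod
    def from_code(cls, code: "str | FeatureKind") -> "FeatureKind":
        if isinstance(code, cls):
            return code
        code = str(code).strip().lower()
        for kind in cls:
            if code in (kind.value, kind.name.lower()):
                return kind
        raise ValueError(
            f"unknown feature set {code!r}; valid codes are "
            + ", ".join(k.value for k in cls))


def feature_dim_per_channel(kind: FeatureKind, level: int, n_samples: int) -> int:
    """Per-channel feature count at a given decomposition level."""
    kind = FeatureKind.from_code(kind)
    len_a, len_d = coeff_lengths(n_samples, level)
    return {
        FeatureKind.APPROX: len_a,
        FeatureKind.APPROX_DETAIL: len_a + sum(len_d),
        FeatureKind.EDR_D: level,
        FeatureKind.EDR_ALL: level + 1,
        FeatureKind.EDR_A_D_SUMMARY: 5,
        FeatureKind.D_SUMMARY: 4,
        FeatureKind.EDR_A_D_MEANVAR: 3,
        FeatureKind.D_MEANVAR: 2,
        FeatureKind.MEANS_VARS: 2 * (level + 1),
        FeatureKind.MEANS: level + 1,
        FeatureKind.VARS: level + 1,
        FeatureKind.VARS_EDR: 2 * (level + 1),
    }[kind]


def feature_dim(kind: FeatureKind, level: int, n_samples: int,
                n_channels: int = 2) -> int:
    """Pattern feature count (all channels concatenated)."""
    return n_channels * feature_dim_per_channel(kind, level, n_samples)


def channel_features(x, kind: FeatureKind, wavelet: WaveletSpec,
                     level: int) -> np.ndarray:
    """Feature vector of one single-channel segment (un-normalized)."""
    kind = FeatureKind.from_code(kind)
    decomp = dwt_decompose(x, wavelet, level)

    if kind is FeatureKind.APPROX:
        return np.asarray(decomp.approx, dtype=float)
    if kind is FeatureKind.APPROX_DETAIL:
        return np.concatenate(decomp.coefficient_vectors())

    ratios = edr(decomp)  # [EDR_A, EDR_D1..EDR_Dlevel]
    if kind is FeatureKind.EDR_D:
        return ratios[1:]
    if kind is FeatureKind.EDR_ALL:
        return ratios

    stats = coeff_stats(decomp)
    summary = np.array([stats.edr_d_min, stats.edr_d_max,
                        stats.edr_d_mean, stats.edr_d_var])
    if kind is FeatureKind.EDR_A_D_SUMMARY:
        return np.concatenate([[ratios[0]], summary])
    if kind is FeatureKind.D_SUMMARY:
        return summary
    if kind is FeatureKind.EDR_A_D_MEANVAR:
        return np.array([ratios[0], stats.edr_d_mean, stats.edr_d_var])
    if kind is FeatureKind.D_MEANVAR:
        return np.array([stats.edr_d_mean, stats.edr_d_var])
    if kind is FeatureKind.MEANS_VARS:
        return np.concatenate([stats.means, stats.variances])
    if kind is FeatureKind.MEANS:
        return stats.means
    if kind is FeatureKind.VARS:
        return stats.variances
    if kind is FeatureKind.VARS_EDR:
        return np.concatenate([stats.variances, ratios])
    raise AssertionError(f"unhandled kind {kind}")  # pragma: no cover


def build_features(pair, kind: FeatureKind, wavelet: WaveletSpec,
                   level: int) -> np.ndarray:
    """Feature vector of one multi-channel pattern (channels concatenated)."""
    pair = np.asarray(pair, dtype=float)
    if pair.ndim != 2:
        # ragged channel lengths never form a 2-D array
        raise ValueError("expected a (n_channels, n_samples) pattern with "
                         "equal-length channels")
    return np.concatenate(
        [channel_features(pair[ch], kind, wavelet, level)
         for ch in range(pair.shape[0])])


def build_feature_matrix(dataset: LabeledDataset, kind: FeatureKind,
                         wavelet: WaveletSpec, level: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n_patterns, dim) and label vector for a dataset."""
    X = np.stack([build_features(dataset.pairs[i], kind, wavelet, level)
                  for i in range(dataset.n_patterns)])
    return X, dataset.labels.copy()


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Normalizer:
    """Per-feature min–max scaling to [0, 1] from training statistics."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def spans(self) -> np.ndarray:
        return self.maxs - self.mins


def fit_normalizer(X_train: np.ndarray) -> Normalizer:
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X_train.shape[0] == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    mins = X_train.min(axis=0)
    maxs = X_train.max(axis=0)
    if np.any(maxs == mins):
        idx = np.flatnonzero(maxs == mins)
        warnings.warn(
            f"constant feature column(s) {idx.tolist()}: mapped to 0",
            RuntimeWarning, stacklevel=2)
    return Normalizer(mins=mins, maxs=maxs)


def apply_normalizer(norm: Normalizer, X: np.ndarray) -> np.ndarray:
    """Scale with the training statistics and clip to [0, 1]."""
    X = np.asarray(X, dtype=float)
    spans = norm.spans.copy()
    constant = spans == 0
    spans[constant] = 1.0
    out = (X - norm.mins) / spans
    out[..., constant] = 0.0
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# plain-text persistence
# --------------------------------------------------------------------------

def save_features(path: str | Path, X: np.ndarray, y: np.ndarray, *,
                  kind: FeatureKind, wavelet: WaveletSpec, level: int,
                  normalizer: Normalizer | None = None) -> Path:
    """Write a feature table CSV plus a JSON sidecar describing it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"f_{i + 1}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "pattern_id", np.arange(X.shape[0]))
    frame.insert(0, "motion_id", np.asarray(y, dtype=int))
    frame.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "kind": FeatureKind.from_code(kind).value,
        "wavelet": wavelet.name,
        "level": int(level),
        "normalizer": None if normalizer is None else {
            "mins": normalizer.mins.tolist(),
            "maxs": normalizer.maxs.tolist(),
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_features(path: str | Path):
    """Inverse of :func:`save_features`; returns (X, y, sidecar dict)."""
    path = Path(path)
    frame = pd.read_csv(path)
    y = frame["motion_id"].to_numpy(dtype=int)
    X = frame[[c for c in frame.columns if c.startswith("f_")]].to_numpy()
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return X, y, sidecar
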