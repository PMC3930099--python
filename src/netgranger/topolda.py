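"""Topology classification: Fisher LDA on binarised GPDC connection matrices.

Each subject's GPDC spectrum is reduced to one scalar per ordered path
(mean over the analysis-band bins by default), thresholded into a binary
k x k adjacency matrix, and flattened to a k(k-1) feature vector (30
directed paths for k = 6).  A Fisher linear discriminant separates the two
groups; classification is validated leave-one-out, the threshold is swept
over a GPDC grid, and "discriminant accuracy" — the product of
classification accuracy and the Mahalanobis distance between group means —
scores how separable the topologies are at each threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gpdc import GPDCSpectrum

__all__ = [
    "TopologyMatrix",
    "LDAModel",
    "SweepResult",
    "binarize_topology",
    "fit_lda",
    "loo_threshold_sweep",
    "DEFAULT_THRESHOLD_GRID",
]

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.05, 0.55 + 1e-9, 0.01), 4)
LDA_RIDGE = 1e-6


@dataclass(frozen=True)
class TopologyMatrix:
    """Binary directed-connection matrix (path j -> i present iff the
    reduced GPDC exceeds the threshold); diagonal excluded."""

    adjacency: np.ndarray  # (k, k) in {0, 1}, zero diagonal
    threshold: float
    reduction: str

    @property
    def k(self) -> int:
        return self.adjacency.shape[0]

    def feature_vector(self) -> np.ndarray:
        """Off-diagonal entries in fixed row-major (target, source) order,
        length k(k-1)."""
        k = self.k
        mask = ~np.eye(k, dtype=bool)
        return self.adjacency[mask].astype(float)


@dataclass(frozen=True)
class LDAModel:
    """Fisher linear discriminant over binary path features.

    ``weights`` are proportional to pooled-covariance^{-1} (mean_A - mean_B);
    their magnitudes read as the relative contribution of each directed
    path to group separation.  The offset places the decision boundary
    midway between the projected group means.
    """

    weights: np.ndarray
    offset: float
    classes: tuple[str, str]
    projected_means: tuple[float, float]
    mahalanobis_distance: float

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return np.atleast_2d(features) @ self.weights - self.offset

    def predict(self, features: np.ndarray) -> np.ndarray:
        d = self.decision_values(features)
        return np.where(d > 0, self.classes[0], self.classes[1])


@dataclass(frozen=True)
class SweepResult:
    thresholds: np.ndarray
    loo_accuracy: np.ndarray
    mahalanobis: np.ndarray
    discriminant_accuracy: np.ndarray
    best_threshold: float
    best_predictions: np.ndarray  # per-subject labels at the best threshold

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "loo_accuracy": self.loo_accuracy,
                "mahalanobis": self.mahalanobis,
                "discriminant_accuracy": self.discriminant_accuracy,
            }
        )


def binarize_topology(
    subject_gpdc: GPDCSpectrum,
    threshold: float,
    reduction: str = "band_mean",
) -> TopologyMatrix:
    """Reduce a subject's GPDC bins to one scalar per path and threshold it.

    ``reduction`` is "band_mean" (mean over bins, default) or
    "per_bin_max".  The comparison is strict (> threshold); the diagonal
    is forced to zero.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if reduction == "band_mean":
        reduced = subject_gpdc.values.mean(axis=0)
    elif reduction == "per_bin_max":
        reduced = subject_gpdc.values.max(axis=0)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    adj = (reduced > threshold).astype(int)
    np.fill_diagonal(adj, 0)
    return TopologyMatrix(adjacency=adj, threshold=float(threshold), reduction=reduction)


def fit_lda(features: np.ndarray, labels: Sequence[str]) -> LDAModel:
    """Fisher discriminant of two groups of (binary) feature vectors.

    The pooled within-group covariance of binary topology features is
    near-singular (k(k-1) features vs ~50 subjects), so its inverse is a
    pseudo-inverse after a tiny ridge (1e-6); a group with zero within
    variance on every feature is handled the same way and flagged.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("expected exactly two group labels")
    Xa, Xb = X[labels == classes[0]], X[labels == classes[1]]
    if len(Xa) < 2 or len(Xb) < 2:
        raise ValueError("need at least 2 subjects per group")
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    na, nb = len(Xa), len(Xb)
    Sw = ((Xa - ma).T @ (Xa - ma) + (Xb - mb).T @ (Xb - mb)) / (na + nb - 2)
    if np.allclose(Sw, 0.0):
        warnings.warn(
            "zero within-group variance on all features; ridge-only covariance",
            stacklevel=2,
        )
    Sw_inv = np.linalg.pinv(Sw + LDA_RIDGE * np.eye(Sw.shape[0]))
    diff = ma - mb
    w = Sw_inv @ diff
    proj_a, proj_b = float(w @ ma), float(w @ mb)
    offset = 0.5 * (proj_a + proj_b)
    maha = float(np.sqrt(max(0.0, diff @ Sw_inv @ diff)))
    if proj_a < proj_b:  # orient so class[0] projects above the boundary
        w, offset = -w, -offset
        proj_a, proj_b = -proj_a, -proj_b
    return LDAModel(
        weights=w,
        offset=float(offset),
        classes=(str(classes[0]), str(classes[1])),
        projected_means=(proj_a, proj_b),
        mahalanobis_distance=maha,
    )


def loo_threshold_sweep(
    subject_gpdc: Sequence[GPDCSpectrum],
    labels: Sequence[str],
    thresholds: np.ndarray = DEFAULT_THRESHOLD_GRID,
    reduction: str = "band_mean",
) -> SweepResult:
    """Leave-one-out LDA classification accuracy over a GPDC-threshold grid.

    Per threshold: all subjects are binarised, then each subject in turn is
    held out, the discriminant fitted on the rest and the held-out feature
    vector classified; accuracy is the fraction classified into their true
    group.  Degenerate folds (e.g. a fold whose training groups cannot be
    fit) count as misclassifications.  Discriminant accuracy multiplies the
    LOO accuracy by the Mahalanobis distance of the full-sample fit.  The
    best threshold maximises LOO accuracy, ties broken by larger
    Mahalanobis distance then by the lower threshold.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != len(subject_gpdc):
        raise ValueError("labels and spectra must align")
    if n < 3 or np.unique(labels).size != 2:
        raise ValueError("leave-one-out needs >= 3 subjects in two groups")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise ValueError("threshold grid must lie within [0, 1]")
    loo_acc = np.zeros(thresholds.size)
    maha = np.zeros(thresholds.size)
    preds_at = []
    for ti, thr in enumerate(thresholds):
        feats = np.stack(
            [binarize_topology(g, thr, reduction).feature_vector() for g in subject_gpdc]
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = fit_lda(feats, labels)
            maha[ti] = full.mahalanobis_distance
        except ValueError:
            maha[ti] = 0.0
        preds = np.empty(n, dtype=object)
        correct = 0
        for s in range(n):
            keep = np.arange(n) != s
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fit_lda(feats[keep], labels[keep])
                pred = model.predict(feats[s])[0]
            except (ValueError, np.linalg.LinAlgError):
                pred = None  # degenerate fold counts as incorrect
            preds[s] = pred
            correct += pred == labels[s]
        loo_acc[ti] = correct / n
        preds_at.append(preds)
    disc = loo_acc * maha
    # argmax accuracy; ties -> larger Mahalanobis, then lower threshold
    order = np.lexsort((thresholds, -maha, -loo_acc))
    best = order[0]
    return SweepResult(
        thresholds=thresholds,
        loo_accuracy=loo_acc,
        mahalanobis=maha,
        discriminant_accuracy=disc,
        best_threshold=float(thresholds[best]),
        best_predictions=preds_at[best],
    )
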