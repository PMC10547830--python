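"""Penultimate-feature diagnostics: 2D embedding, LDA boundary, leakage view.

This module reproduces, on any fitted model and CV fold, the diagnostic
picture that makes cropping leakage visible: per-trial penultimate-layer
features are embedded into 2D with t-SNE (Euclidean distance), a linear
discriminant boundary is fitted on the training rows of the embedding, and
any single subject's trials can be highlighted across train/test roles.
Under subject-wise CV all of a subject's trials share one role; under
trial-wise CV they straddle the split, and because crops of one recording
cluster tightly, the boundary effectively memorises test subjects seen at
training time.

The t-SNE map is fitted on train and test rows jointly (as the diagnostic
figure of record does); this is itself a mild transductive leak, accepted
here because the embedding is a visual aid, not a performance claim — the
caveat is spelled out in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.manifold import TSNE

from .augment import TrialSet
from .cohort import CONTROL, PATIENT
from .errors import ConfigurationError
from .models import TrainedModel

TRAIN, TEST = "train", "test"


def embed_2d(features: np.ndarray, seed: int = 0,
             perplexity: Optional[float] = None) -> np.ndarray:
    """t-SNE to 2D with Euclidean distance; deterministic given ``seed``.

    Perplexity defaults to ``min(30, (n - 1) / 3)`` (t-SNE requires
    perplexity < number of samples; the divisor keeps small inputs legal).
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 5:
        raise ConfigurationError("embed_2d needs a 2-D feature matrix with >= 5 rows")
    if not np.all(np.isfinite(features)):
        raise ConfigurationError("features contain non-finite values")
    n = features.shape[0]
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, metric="euclidean", perplexity=perplexity,
                init="pca", random_state=seed)
    return tsne.fit_transform(features)


@dataclass(frozen=True)
class Boundary:
    """Linear decision boundary w·x + b = 0 (positive side = patient)."""

    weights: np.ndarray
    offset: float

    def side(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.weights + self.offset


def fit_boundary(features_train: np.ndarray, labels_train: np.ndarray,
                 ridge: float = 1e-8) -> Boundary:
    """Two-class LDA on training rows only (pooled covariance; a small
    ridge is added automatically if the covariance is singular)."""
    x = np.asarray(features_train, dtype=np.float64)
    y = np.asarray(labels_train)
    if np.unique(y).size != 2:
        raise ConfigurationError("fit_boundary needs exactly two classes in training rows")
    y01 = (y == PATIENT).astype(int)
    try:
        lda = LinearDiscriminantAnalysis(solver="lsqr")
        lda.fit(x, y01)
        w = lda.coef_[0].copy()
        b = float(lda.intercept_[0])
    except np.linalg.LinAlgError:
        w = np.zeros(x.shape[1])
        b = 0.0
    if not np.any(np.abs(w) > 0):
        # degenerate pooled covariance (e.g. zero within-class variance):
        # explicit ridge so the boundary follows the class-mean difference
        x0, x1 = x[y01 == 0], x[y01 == 1]
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        cov = (np.cov(x0.T, bias=True) * len(x0)
               + np.cov(x1.T, bias=True) * len(x1)) / len(x)
        cov = np.atleast_2d(cov)
        lam = ridge * max(float(np.trace(cov)) / x.shape[1], 1.0)
        w = np.linalg.solve(cov + lam * np.eye(x.shape[1]), mu1 - mu0)
        b = float(-w @ (mu0 + mu1) / 2 + np.log(len(x1) / len(x0)))
    return Boundary(weights=w, offset=b)


def score_boundary(boundary: Boundary, features: np.ndarray,
                   labels: np.ndarray) -> float:
    """Fraction of rows on the correct side of the boundary."""
    y01 = (np.asarray(labels) == PATIENT).astype(int)
    pred = (boundary.side(features) > 0).astype(int)
    return float((pred == y01).mean())


@dataclass
class FeatureEmbedding:
    """Per-trial features, their 2D map, roles, and the fitted boundary."""

    features: np.ndarray = field(repr=False)
    coords_2d: np.ndarray = field(repr=False)
    roles: np.ndarray  # per-trial TRAIN / TEST
    subject_ids: np.ndarray
    labels: np.ndarray
    boundary: Boundary
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.coords_2d[:, 0], "y": self.coords_2d[:, 1],
            "role": self.roles, "subject_id": self.subject_ids,
            "label": self.labels,
        })

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def make_embedding(model: TrainedModel, trialset: TrialSet,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   seed: int = 0,
                   perplexity: Optional[float] = None) -> FeatureEmbedding:
    """Embed one fold's trials and fit the boundary on training rows only.

    The boundary is fitted in the 2D plot space (where the figure draws
    it), using exclusively the rows whose role is 'train'.
    """
    idx = np.concatenate([np.asarray(train_idx), np.asarray(test_idx)])
    roles = np.array([TRAIN] * len(train_idx) + [TEST] * len(test_idx))
    feats = model.penultimate_features(trialset.trials[idx])
    coords = embed_2d(feats, seed=seed, perplexity=perplexity)
    is_train = roles == TRAIN
    boundary = fit_boundary(coords[is_train], trialset.labels[idx][is_train])
    return FeatureEmbedding(features=feats, coords_2d=coords, roles=roles,
                            subject_ids=trialset.subject_ids[idx],
                            labels=trialset.labels[idx],
                            boundary=boundary, seed=seed)


def subject_leakage_view(embedding: FeatureEmbedding, subject_id: str) -> pd.DataFrame:
    """One subject's rows with their roles — the 'highlighted subject' of
    the diagnostic figure.  Under subject-wise CV all roles agree; mixed
    roles are the signature of trial-wise leakage."""
    m = embedding.subject_ids == subject_id
    if not m.any():
        raise ConfigurationError(f"unknown subject {subject_id!r}")
    return embedding.to_frame()[m]


def within_between_dispersion(features: np.ndarray,
                              subject_ids: np.ndarray) -> tuple[float, float]:
    """Mean pairwise Euclidean distance within subjects vs between subjects."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(np.asarray(features, dtype=np.float64)))
    sid = np.asarray(subject_ids)
    same = sid[:, None] == sid[None, :]
    iu = np.triu_indices_from(d, k=1)
    same_u = same[iu]
    return float(d[iu][same_u].mean()), float(d[iu][~same_u].mean())


def plot_embedding(embedding: FeatureEmbedding, path: str | Path,
                   highlight_subject: Optional[str] = None,
                   title: str = "") -> Path:
    """Scatter the 2D map: class by marker, role by fill, boundary as a
    line, one subject optionally outlined.  Writes PNG (and a PDF next to
    it when the suffix is .png)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, marker, color in ((PATIENT, "o", "tab:red"), (CONTROL, "^", "tab:blue")):
        for role, filled in ((TRAIN, "none"), (TEST, color)):
            m = (embedding.labels == label) & (embedding.roles == role)
            if m.any():
                ax.scatter(embedding.coords_2d[m, 0], embedding.coords_2d[m, 1],
                           marker=marker, facecolors=filled, edgecolors=color,
                           s=30, label=f"{label} ({role})")
    if highlight_subject is not None:
        m = embedding.subject_ids == highlight_subject
        if not m.any():
            raise ConfigurationError(f"unknown subject {highlight_subject!r}")
        ax.scatter(embedding.coords_2d[m, 0], embedding.coords_2d[m, 1],
                   marker="s", facecolors="none", edgecolors="black", s=110,
                   linewidths=1.5, label=f"subject {highlight_subject}")
    w, b = embedding.boundary.weights, embedding.boundary.offset
    if abs(w[1]) > 1e-12:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, -(w[0] * xs + b) / w[1], "k-", lw=1, label="LDA boundary")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    if path.suffix == ".png":
        fig.savefig(path.with_suffix(".pdf"))
    plt.close(fig)
    return path
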