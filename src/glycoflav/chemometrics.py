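"""Pareto scaling, PCA and two-class OPLS-DA with VIP scores.

These are the signal-prioritization statistics of untargeted metabolomics:
intensities are Pareto-scaled (mean-centred, divided by the square root of
the standard deviation), PCA summarizes group structure, and OPLS-DA against
a two-class design yields per-feature VIP (variable importance in
projection) scores whose squares average to one; features with VIP > 1 are
prioritized for targeted MS/MS.

The estimators follow the fit/results idiom: ``PCA(k).fit(m)`` and
``OPLSDA(n_ortho).fit(m, y)`` return a :class:`LatentModel` results object
carrying scores, loadings, explained variance fractions and (for OPLS-DA)
VIP, with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityMatrix",
    "LatentModel",
    "log_transform",
    "pareto_scale",
    "PCA",
    "OPLSDA",
    "pca",
    "oplsda",
    "vip_scores",
    "vip_filter",
    "read_intensity_tsv",
    "write_intensity_tsv",
]


@dataclass(frozen=True)
class IntensityMatrix:
    """Samples x features intensity matrix with group / time annotations."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    group: tuple[str, ...]
    time_h: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n, p = v.shape
        if len(self.sample_ids) != n or len(self.group) != n:
            raise ValueError("sample_ids/group length does not match row count")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match column count")
        if self.time_h is not None and len(self.time_h) != n:
            raise ValueError("time_h length does not match row count")
        if not np.all(np.isfinite(v)):
            raise ValueError("intensity matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, keep: np.ndarray) -> "IntensityMatrix":
        return IntensityMatrix(
            values=self.values[:, keep],
            sample_ids=self.sample_ids,
            feature_ids=tuple(np.asarray(self.feature_ids)[keep]),
            group=self.group,
            time_h=self.time_h,
        )


def log_transform(m: IntensityMatrix, base: float = 2.0) -> IntensityMatrix:
    """Log-transform raw intensities (the usual step before Pareto scaling,
    since LC-MS intensities are close to log-normal); zeros are offset by
    half the smallest positive value."""
    v = m.values
    positive = v[v > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive intensities")
    eps = positive.min() / 2.0
    out = np.log(np.where(v > 0, v, eps)) / np.log(base)
    return IntensityMatrix(out, m.sample_ids, m.feature_ids, m.group, m.time_h)


def pareto_scale(m: IntensityMatrix) -> IntensityMatrix:
    """Mean-centre each feature and divide by the square root of its
    standard deviation; zero-variance features are dropped (logged).

    Pareto scaling shrinks the dominance of high-abundance metabolites while
    keeping the data closer to its original scale than unit-variance scaling.
    """
    if m.n_samples < 2:
        raise ValueError("Pareto scaling needs at least 2 samples")
    sd = m.values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("pareto_scale: dropped %d zero-variance feature(s)", dropped)
    sub = m.select_features(keep)
    centred = sub.values - sub.values.mean(axis=0)
    scaled = centred / np.sqrt(sd[keep])
    return IntensityMatrix(scaled, sub.sample_ids, sub.feature_ids, sub.group, sub.time_h)


@dataclass(frozen=True)
class LatentModel:
    """Results of a latent-variable fit (PCA or OPLS-DA)."""

    kind: str
    scores: np.ndarray  # samples x components (predictive first for oplsda)
    loadings: np.ndarray  # features x components
    explained_fraction: np.ndarray  # per component, in [0, 1]
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    vip: np.ndarray | None = None  # oplsda only
    n_ortho: int | None = None  # oplsda only
    weights: np.ndarray | None = field(default=None, repr=False)  # predictive w (oplsda)
    y_explained: np.ndarray | None = None  # fraction of y variance per component

    def summary(self) -> str:
        lines = [f"{self.kind.upper()} fit: {len(self.sample_ids)} samples x "
                 f"{len(self.feature_ids)} features"]
        for i, frac in enumerate(self.explained_fraction, start=1):
            lines.append(f"  component {i}: {100 * frac:.1f}% of X variance")
        if self.kind == "oplsda":
            lines.append(f"  orthogonal components removed: {self.n_ortho}")
            lines.append(f"  features with VIP > 1: {int((self.vip > 1).sum())}"
                         f" / {len(self.feature_ids)}")
        return "\n".join(lines)


class PCA:
    """Principal component analysis via SVD of the (already scaled) matrix.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making score plots reproducible.
    """

    def __init__(self, k: int = 2):
        self.k = k

    def fit(self, m: IntensityMatrix) -> LatentModel:
        X = m.values
        n, p = X.shape
        if not 1 <= self.k <= min(n - 1, p):
            raise ValueError(f"k={self.k} invalid for {n} samples x {p} features")
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        total = (s**2).sum()
        explained = s**2 / total if total > 0 else np.zeros_like(s)
        loadings = vt.T[:, : self.k]
        scores = u[:, : self.k] * s[: self.k]
        for j in range(self.k):
            i_max = np.argmax(np.abs(loadings[:, j]))
            if loadings[i_max, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1
        return LatentModel(
            kind="pca",
            scores=scores,
            loadings=loadings,
            explained_fraction=explained[: self.k],
            feature_ids=m.feature_ids,
            sample_ids=m.sample_ids,
        )


class OPLSDA:
    """Orthogonal projections to latent structures, discriminant variant.

    The class response is coded +/-1 and centred.  Each orthogonal round
    computes the PLS weight ``w ∝ X'y``, extracts the systematic variation in
    X orthogonal to it, and deflates X; the final predictive component is a
    one-component PLS fit on the deflated matrix.  With ``n_ortho=0`` this
    reduces exactly to single-component PLS1.
    """

    def __init__(self, n_ortho: int = 1):
        if n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.n_ortho = n_ortho

    def fit(self, m: IntensityMatrix, y: Sequence | None = None) -> LatentModel:
        X = m.values.copy()
        n, p = X.shape
        labels = np.asarray(m.group if y is None else y)
        classes = sorted(set(labels.tolist()))
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes}")
        counts = [int((labels == c).sum()) for c in classes]
        if min(counts) < 2:
            raise ValueError(f"each class needs >= 2 samples, got {dict(zip(classes, counts))}")
        if self.n_ortho >= n - 2:
            raise ValueError(f"n_ortho={self.n_ortho} too large for {n} samples")
        yv = np.where(labels == classes[1], 1.0, -1.0)
        yv = yv - yv.mean()
        Xd = X - X.mean(axis=0)
        ssx_total = (Xd**2).sum()
        ortho_scores = []
        ortho_loadings = []
        for _ in range(self.n_ortho):
            w = Xd.T @ yv
            w /= np.linalg.norm(w)
            t = Xd @ w
            p_load = Xd.T @ t / (t @ t)
            w_ortho = p_load - (w @ p_load) * w
            norm = np.linalg.norm(w_ortho)
            if norm < 1e-12:
                break  # no orthogonal variation left
            w_ortho /= norm
            t_ortho = Xd @ w_ortho
            p_ortho = Xd.T @ t_ortho / (t_ortho @ t_ortho)
            Xd = Xd - np.outer(t_ortho, p_ortho)
            ortho_scores.append(t_ortho)
            ortho_loadings.append(p_ortho)
        w = Xd.T @ yv
        w /= np.linalg.norm(w)
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        scores = np.column_stack([t] + ortho_scores) if ortho_scores else t[:, None]
        loadings = np.column_stack([p_load] + ortho_loadings) if ortho_loadings else p_load[:, None]
        explained = np.array([
            (scores[:, j] ** 2).sum() * (loadings[:, j] ** 2).sum() / ssx_total
            for j in range(scores.shape[1])
        ])
        # y-variance explained by the predictive component (orthogonal
        # components are y-orthogonal by construction)
        b = (t @ yv) / (t @ t)
        ssy = (yv**2).sum()
        y_expl = np.array([1.0 - ((yv - b * t) ** 2).sum() / ssy])
        vip = _vip_from_weights(w, y_expl)
        return LatentModel(
            kind="oplsda",
            scores=scores,
            loadings=loadings,
            explained_fraction=explained,
            feature_ids=m.feature_ids,
            sample_ids=m.sample_ids,
            vip=vip,
            n_ortho=len(ortho_scores),
            weights=w[:, None],
            y_explained=y_expl,
        )


def _vip_from_weights(w: np.ndarray, ssy_fractions: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a) over predictive
    components; with normalized w the squared VIPs average to one."""
    w = np.atleast_2d(w.T).T if w.ndim == 1 else w
    p = w.shape[0]
    w2 = (w / np.linalg.norm(w, axis=0)) ** 2
    num = (w2 * ssy_fractions).sum(axis=1)
    return np.sqrt(p * num / ssy_fractions.sum())


def pca(m: IntensityMatrix, k: int = 2) -> LatentModel:
    """Functional wrapper over :class:`PCA`."""
    return PCA(k).fit(m)


def oplsda(m: IntensityMatrix, y: Sequence | None = None, n_ortho: int = 1) -> LatentModel:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(n_ortho).fit(m, y)


def vip_scores(model: LatentModel) -> np.ndarray:
    """Per-feature VIP scores of a fitted OPLS-DA model."""
    if model.kind != "oplsda":
        raise ValueError(f"VIP is defined for oplsda models, got kind={model.kind!r}")
    return model.vip


def vip_filter(
    features: Sequence[str], vip: Sequence[float], threshold: float = 1.0
) -> list[str]:
    """Feature ids with VIP strictly above *threshold*, order preserved."""
    if len(features) != len(vip):
        raise ValueError("features and vip lengths differ")
    return [f for f, v in zip(features, vip) if v > threshold]


# -- TSV I/O -----------------------------------------------------------------


def read_intensity_tsv(path: str | Path) -> IntensityMatrix:
    """Read a matrix TSV: columns sample_id, group, [time_h], then features."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["sample_id", "group"]
    if "time_h" in df.columns:
        meta_cols.append("time_h")
    feat_cols = [c for c in df.columns if c not in meta_cols]
    return IntensityMatrix(
        values=df[feat_cols].to_numpy(float),
        sample_ids=tuple(df["sample_id"].astype(str)),
        feature_ids=tuple(feat_cols),
        group=tuple(df["group"].astype(str)),
        time_h=tuple(df["time_h"].astype(float)) if "time_h" in df.columns else None,
    )


def write_intensity_tsv(m: IntensityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, columns=list(m.feature_ids))
    df.insert(0, "sample_id", list(m.sample_ids))
    df.insert(1, "group", list(m.group))
    if m.time_h is not None:
        df.insert(2, "time_h", list(m.time_h))
    df.to_csv(path, sep="\t", index=False)
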