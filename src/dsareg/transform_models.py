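"""Nested family of planar transformations for DSA registration.

Pre/post-thrombectomy angiography series of the same view are related, to a
good approximation, by a global 2D transform induced by C-arm repositioning
and patient motion.  This module provides the nested family

    TRANSLATION (2 dof) ⊂ RIGID (3) ⊂ SIMILARITY (4) ⊂ AFFINE (6) ⊂ PROJECTIVE (8)

with closed-form / least-squares fitting to point correspondences, residual
assessment, image warping, and the transformation-type comparison experiment
(which transform family is rich enough to align a cohort of image pairs).

Conventions: points are (x, y) with x = column, y = row, origin at the
top-left pixel; the stored 3x3 homogeneous matrix maps *moving* (pre-EVT)
points onto *fixed* (post-EVT) points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class TransformType(str, Enum):
    TRANSLATION = "translation"
    RIGID = "rigid"
    SIMILARITY = "similarity"
    AFFINE = "affine"
    PROJECTIVE = "projective"


#: minimal number of point correspondences needed to determine each type
MIN_POINTS = {
    TransformType.TRANSLATION: 1,
    TransformType.RIGID: 2,
    TransformType.SIMILARITY: 2,
    TransformType.AFFINE: 3,
    TransformType.PROJECTIVE: 4,
}

#: degrees of freedom of each type
DOF = {
    TransformType.TRANSLATION: 2,
    TransformType.RIGID: 3,
    TransformType.SIMILARITY: 4,
    TransformType.AFFINE: 6,
    TransformType.PROJECTIVE: 8,
}

#: order used for nested-model comparisons (increasing dof)
TYPE_ORDER = [
    TransformType.TRANSLATION,
    TransformType.RIGID,
    TransformType.SIMILARITY,
    TransformType.AFFINE,
    TransformType.PROJECTIVE,
]


class DegeneracyError(ValueError):
    """Raised when a point configuration cannot determine the transform."""


@dataclass(frozen=True)
class Transform2D:
    """A typed 3x3 homogeneous planar transform (moving -> fixed)."""

    ttype: TransformType
    matrix: np.ndarray  # (3, 3) float64

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite entries")
        if self.ttype is TransformType.PROJECTIVE:
            if m[2, 2] != 0:
                m = m / m[2, 2]
        else:
            if not np.allclose(m[2], [0.0, 0.0, 1.0], atol=1e-12):
                raise ValueError(f"{self.ttype.value} transform must have bottom row (0,0,1)")
        object.__setattr__(self, "matrix", m)

    @property
    def dof(self) -> int:
        return DOF[self.ttype]

    @classmethod
    def identity(cls, ttype: TransformType = TransformType.SIMILARITY) -> "Transform2D":
        return cls(ttype, np.eye(3))

    @classmethod
    def from_similarity_params(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
        ttype: TransformType = TransformType.SIMILARITY,
    ) -> "Transform2D":
        """Similarity transform: rotate by ``rotation_deg`` and scale about
        ``center``, then translate.  With the default center the matrix is
        ``[[s cosθ, -s sinθ, tx], [s sinθ, s cosθ, ty], [0, 0, 1]]``."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        a = scale * np.array([[c, -s], [s, c]])
        cx, cy = center
        t = np.asarray(translation, dtype=float) + np.array([cx, cy]) - a @ [cx, cy]
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = t
        return cls(ttype, m)

    def similarity_params(self) -> tuple[float, float, float, float]:
        """Decompose into (scale, rotation_deg, tx, ty).

        Only meaningful for TRANSLATION/RIGID/SIMILARITY matrices.
        """
        a = self.matrix[:2, :2]
        scale = float(np.sqrt(np.linalg.det(a))) if np.linalg.det(a) > 0 else float(np.linalg.norm(a[:, 0]))
        rot = float(np.rad2deg(np.arctan2(a[1, 0], a[0, 0])))
        tx, ty = self.matrix[:2, 2]
        return scale, rot, float(tx), float(ty)

    def inverse(self) -> "Transform2D":
        return Transform2D(self.ttype, np.linalg.inv(self.matrix))

    def compose(self, other: "Transform2D") -> "Transform2D":
        """Return self ∘ other (apply ``other`` first).  The result carries the
        less restrictive of the two types."""
        ttype = max(self.ttype, other.ttype, key=lambda t: DOF[t])
        return Transform2D(ttype, self.matrix @ other.matrix)

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"ttype": self.ttype.value, "matrix": self.matrix.ravel().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Transform2D":
        d = json.loads(text)
        return cls(TransformType(d["ttype"]), np.asarray(d["matrix"], dtype=float).reshape(3, 3))


class CorrespondenceSource(str, Enum):
    MANUAL = "manual"
    SIFT = "sift"
    ORB = "orb"
    LANDMARK = "landmark"


@dataclass
class CorrespondenceSet:
    """Paired (moving, fixed) pixel points; the currency of fitting."""

    moving: np.ndarray  # (N, 2) float
    fixed: np.ndarray  # (N, 2) float
    labels: list[str] | None = None
    source: CorrespondenceSource | None = None
    sources: np.ndarray | None = None  # per-point source tags, set by pooling

    def __post_init__(self) -> None:
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float)).reshape(-1, 2)
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float)).reshape(-1, 2)
        if len(self.moving) != len(self.fixed):
            raise ValueError("moving and fixed must have equal length")
        if not (np.all(np.isfinite(self.moving)) and np.all(np.isfinite(self.fixed))):
            raise ValueError("correspondence coordinates must be finite")
        if self.sources is None and self.source is not None:
            self.sources = np.array([self.source.value] * len(self.moving))

    def __len__(self) -> int:
        return len(self.moving)

    def subset(self, idx) -> "CorrespondenceSet":
        labels = [self.labels[i] for i in np.arange(len(self))[idx]] if self.labels else None
        sources = self.sources[idx] if self.sources is not None else None
        return CorrespondenceSet(self.moving[idx], self.fixed[idx], labels=labels,
                                 source=self.source, sources=sources)


@dataclass
class FitResult:
    transform: Transform2D
    residuals: np.ndarray  # per-point Euclidean error, px
    n_points: int

    @property
    def mean_residual(self) -> float:
        """Arithmetic mean of the Euclidean point errors (the reported
        "average residual error")."""
        return float(np.mean(self.residuals))

    @property
    def rms_residual(self) -> float:
        """Root-mean-square point error — the square root of the objective
        the least-squares fits actually minimize, hence the statistic that is
        guaranteed non-increasing along the nested transform family."""
        return float(np.sqrt(np.mean(self.residuals ** 2)))


def apply_transform(t: Transform2D, points: np.ndarray) -> np.ndarray:
    """Map (N, 2) points through ``t`` (homogeneous multiply + perspective divide)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ph = np.column_stack([pts, np.ones(len(pts))])
    out = ph @ t.matrix.T
    w = out[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise FloatingPointError("point maps to the line at infinity (w ~ 0)")
    return out[:, :2] / w[:, None]


def _check_fit_input(corr: CorrespondenceSet, ttype: TransformType) -> None:
    n = len(corr)
    if n < MIN_POINTS[ttype]:
        raise ValueError(
            f"{ttype.value} needs >= {MIN_POINTS[ttype]} correspondences, got {n}"
        )
    if ttype in (TransformType.AFFINE, TransformType.PROJECTIVE) and n >= 3:
        # all-collinear moving points cannot determine an affine/projective map
        p = corr.moving - corr.moving.mean(axis=0)
        if np.linalg.matrix_rank(p, tol=1e-9) < 2:
            raise DegeneracyError("moving points are collinear")


def _fit_translation(m: np.ndarray, f: np.ndarray) -> np.ndarray:
    t = (f - m).mean(axis=0)
    out = np.eye(3)
    out[:2, 2] = t
    return out


def _fit_procrustes(m: np.ndarray, f: np.ndarray, with_scale: bool) -> np.ndarray:
    """Closed-form least-squares rigid/similarity alignment (Umeyama).

    Reflections are rejected: the returned rotation has determinant +1, as
    C-arm projections of one view never mirror.
    """
    mu_m, mu_f = m.mean(axis=0), f.mean(axis=0)
    mc, fc = m - mu_m, f - mu_f
    cov = fc.T @ mc / len(m)
    u, d, vt = np.linalg.svd(cov)
    s_mat = np.eye(2)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s_mat[1, 1] = -1.0
    r = u @ s_mat @ vt
    if with_scale:
        var_m = (mc ** 2).sum() / len(m)
        if var_m < 1e-30:
            raise DegeneracyError("moving points are coincident")
        scale = float((d * np.diag(s_mat)).sum() / var_m)
        if scale <= 0:
            raise DegeneracyError("non-positive optimal scale")
    else:
        scale = 1.0
    a = scale * r
    out = np.eye(3)
    out[:2, :2] = a
    out[:2, 2] = mu_f - a @ mu_m
    return out


def _fit_affine(m: np.ndarray, f: np.ndarray) -> np.ndarray:
    a = np.column_stack([m, np.ones(len(m))])
    coef, *_ = np.linalg.lstsq(a, f, rcond=None)
    out = np.eye(3)
    out[:2, :2] = coef[:2].T
    out[:2, 2] = coef[2]
    return out


def _normalize_points(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: translate to centroid, scale to mean distance √2."""
    mu = p.mean(axis=0)
    d = np.sqrt(((p - mu) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2) / max(d, 1e-12)
    t = np.array([[s, 0, -s * mu[0]], [0, s, -s * mu[1]], [0, 0, 1.0]])
    ph = np.column_stack([p, np.ones(len(p))]) @ t.T
    return ph[:, :2], t


def _fit_projective(m: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Normalized DLT followed by geometric-error refinement.

    The refinement minimizes the summed squared Euclidean transfer error with
    Levenberg–Marquardt, started from both the DLT solution and the affine
    least-squares solution; the better optimum wins.  Starting from the affine
    fit guarantees the projective residual never exceeds the affine one.
    """
    mn, tm = _normalize_points(m)
    fn, tf = _normalize_points(f)
    rows = []
    for (x, y), (u, v) in zip(mn, fn):
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        rows.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    a = np.asarray(rows)
    _, sv, vt = np.linalg.svd(a)
    if len(m) > 4 and sv[-2] < 1e-10:
        raise DegeneracyError("degenerate projective configuration")
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(tf) @ h @ tm
    candidates = [h / h[2, 2] if abs(h[2, 2]) > 1e-12 else h]
    candidates.append(_fit_affine(m, f))

    mh = np.column_stack([m, np.ones(len(m))])

    def geom_resid(params: np.ndarray) -> np.ndarray:
        hm = np.append(params, 1.0).reshape(3, 3)
        out = mh @ hm.T
        w = out[:, 2:]
        w = np.where(np.abs(w) < 1e-12, 1e-12, w)
        return ((out[:, :2] / w) - f).ravel()

    best, best_cost = None, np.inf
    for cand in candidates:
        x0 = (cand / cand[2, 2]).ravel()[:8]
        sol = least_squares(geom_resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if sol.cost < best_cost:
            best_cost, best = sol.cost, sol.x
    return np.append(best, 1.0).reshape(3, 3)


def fit_transform(corr: CorrespondenceSet, ttype: TransformType | str) -> FitResult:
    """Least-squares fit of a transform of the given type to correspondences.

    Closed forms are used where they exist (mean displacement for translation,
    Procrustes for rigid/similarity, linear least squares for affine); the
    projective fit uses normalized DLT plus geometric refinement.  Residuals
    are per-point Euclidean errors ``|T(moving_i) - fixed_i|``.
    """
    ttype = TransformType(ttype)
    _check_fit_input(corr, ttype)
    m, f = corr.moving, corr.fixed
    if ttype is TransformType.TRANSLATION:
        mat = _fit_translation(m, f)
    elif ttype is TransformType.RIGID:
        mat = _fit_procrustes(m, f, with_scale=False)
    elif ttype is TransformType.SIMILARITY:
        mat = _fit_procrustes(m, f, with_scale=True)
    elif ttype is TransformType.AFFINE:
        mat = _fit_affine(m, f)
    else:
        mat = _fit_projective(m, f)
    t = Transform2D(ttype, mat)
    resid = np.linalg.norm(apply_transform(t, m) - f, axis=1)
    return FitResult(transform=t, residuals=resid, n_points=len(corr))


def warp_image(t: Transform2D, img: np.ndarray, out_shape: tuple[int, int] | None = None,
               background: float = 1.0) -> np.ndarray:
    """Resample ``img`` under ``t`` by inverse mapping with bilinear interpolation.

    Out-of-domain pixels take the background value (1.0 = no vessel in a DSA
    minIP).  ``img`` may be a bare array or a MinIPImage-like object with a
    ``pixels`` attribute; a bare array is returned.
    """
    pixels = getattr(img, "pixels", img)
    pixels = np.asarray(pixels, dtype=float)
    h, w = out_shape if out_shape is not None else pixels.shape
    inv = np.linalg.inv(t.matrix)
    yy, xx = np.mgrid[0:h, 0:w]
    ph = np.stack([xx.ravel(), yy.ravel(), np.ones(h * w)])
    src = inv @ ph
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = src[0] / src[2]
        sy = src[1] / src[2]
    from scipy.ndimage import map_coordinates

    out = map_coordinates(pixels, [sy, sx], order=1, mode="constant", cval=background)
    bad = ~np.isfinite(sx) | ~np.isfinite(sy)
    out[bad] = background
    return out.reshape(h, w)


def assess_transform_types(
    sets: Iterable[tuple[str, CorrespondenceSet]] | dict[str, CorrespondenceSet],
    min_points: int = 6,
    types: Sequence[TransformType] = tuple(TYPE_ORDER),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every transform type to every correspondence set and tabulate residuals.

    Sets with fewer than ``min_points`` correspondences are excluded (few-point
    fits of high-dof transforms overfit and say nothing about alignment).
    Returns a long-format table ``(pair_id, ttype, dof, mean_residual, n_points)``
    and a per-type summary with median and IQR.
    """
    if isinstance(sets, dict):
        sets = sets.items()
    rows = []
    for pair_id, corr in sets:
        if len(corr) < min_points:
            continue
        for ttype in types:
            if len(corr) < MIN_POINTS[ttype]:  # only when min_points is lowered
                continue
            fit = fit_transform(corr, ttype)
            rows.append({
                "pair_id": pair_id,
                "ttype": ttype.value,
                "dof": DOF[ttype],
                "mean_residual": fit.mean_residual,
                "n_points": fit.n_points,
            })
    table = pd.DataFrame(rows, columns=["pair_id", "ttype", "dof", "mean_residual", "n_points"])
    if table.empty:
        summary = pd.DataFrame(columns=["ttype", "median", "q1", "q3", "n_sets"])
        return table, summary
    g = table.groupby("ttype", sort=False)["mean_residual"]
    summary = pd.DataFrame({
        "ttype": g.median().index,
        "median": g.median().values,
        "q1": g.quantile(0.25).values,
        "q3": g.quantile(0.75).values,
        "n_sets": g.size().values,
    })
    return table, summary
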