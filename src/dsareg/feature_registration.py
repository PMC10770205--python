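"""Automatic point correspondences and robust similarity estimation.

Candidate correspondences between the pre- and post-EVT minIPs come from
three sources: SIFT keypoints (real-valued gradient-histogram descriptors),
ORB keypoints (binary descriptors), and the two detected arterial landmarks
(ICA terminus, M1 segment).  Sources are pooled, a similarity transform is
estimated robustly with RANSAC + least-squares refit, and the solution is
classified against reference annotations:

* fewer than ``min_inliers`` (default 5) consensus points -> NO_SOLUTION;
* mean reference error > ``invalid_threshold_px`` (default 10 px) -> INVALID;
* otherwise VALID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from skimage.feature import ORB, SIFT, match_descriptors

from .transform_models import (
    CorrespondenceSet,
    CorrespondenceSource,
    DegeneracyError,
    Transform2D,
    TransformType,
    apply_transform,
    fit_transform,
)


class Detector(str, Enum):
    SIFT = "sift"
    ORB = "orb"


@dataclass
class KeypointSet:
    points: np.ndarray  # (N, 2) (x, y) px
    descriptors: np.ndarray  # (N, D); float for SIFT, bool for ORB
    detector: Detector

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DetectorConfig:
    """Keypoint-detection settings.

    ``sift_upsampling=1`` skips the initial 2x image upscaling; vessel tubes
    are several pixels wide, so the extra octave buys nothing but runtime.
    """

    sift_upsampling: int = 1
    orb_n_keypoints: int = 500
    lowe_ratio: float = 0.75


def detect_keypoints(
    img,
    detector: Detector | str,
    mask: np.ndarray | None = None,
    config: DetectorConfig | None = None,
) -> KeypointSet:
    """Detect SIFT or ORB keypoints on a minIP.

    The image is rescaled to 8-bit before detection (detector implementations
    operate on integer intensities).  An optional binary mask suppresses
    keypoints in excluded regions (image borders, burned-in text).
    """
    config = config or DetectorConfig()
    detector = Detector(detector)
    pixels = np.asarray(getattr(img, "pixels", img), dtype=float)
    if pixels.size == 0:
        raise ValueError("empty image")
    img8 = np.round(np.clip(pixels, 0, 1) * 255).astype(np.uint8)

    if detector is Detector.SIFT:
        d = SIFT(upsampling=config.sift_upsampling)
    else:
        d = ORB(n_keypoints=config.orb_n_keypoints)
    try:
        d.detect_and_extract(img8)
        keypoints = d.keypoints  # (row, col)
        descriptors = d.descriptors
    except RuntimeError:  # no features found (e.g. constant image)
        keypoints = np.empty((0, 2))
        dtype = bool if detector is Detector.ORB else float
        descriptors = np.empty((0, 0), dtype=dtype)

    points = keypoints[:, ::-1].astype(float)  # -> (x, y)
    if mask is not None and len(points):
        rows = np.clip(np.round(points[:, 1]).astype(int), 0, pixels.shape[0] - 1)
        cols = np.clip(np.round(points[:, 0]).astype(int), 0, pixels.shape[1] - 1)
        keep = np.asarray(mask, dtype=bool)[rows, cols]
        points, descriptors = points[keep], descriptors[keep]
    return KeypointSet(points=points, descriptors=descriptors, detector=detector)


def match_keypoints(
    a: KeypointSet,
    b: KeypointSet,
    lowe_ratio: float | None = 0.75,
    cross_check: bool = True,
) -> CorrespondenceSet:
    """Nearest-neighbour descriptor matching with ratio test and cross-check.

    Distances are Euclidean for real-valued descriptors and Hamming for
    binary ones.  ``lowe_ratio=None`` disables the ratio test.
    """
    if a.detector is not b.detector:
        raise ValueError(f"detector mismatch: {a.detector} vs {b.detector}")
    if len(a) == 0 or len(b) == 0:
        return CorrespondenceSet(np.empty((0, 2)), np.empty((0, 2)),
                                 source=CorrespondenceSource(a.detector.value))
    matches = match_descriptors(
        a.descriptors, b.descriptors, cross_check=cross_check, max_ratio=lowe_ratio or 1.0
    )
    return CorrespondenceSet(
        a.points[matches[:, 0]],
        b.points[matches[:, 1]],
        source=CorrespondenceSource(a.detector.value),
    )


def landmark_correspondences(pre_pred, post_pred) -> CorrespondenceSet:
    """Turn per-image landmark predictions into 2 correspondences (ICA, M1).

    Accepts LandmarkPrediction-like objects with a ``positions`` mapping, or
    bare ``{label: (x, y)}`` dicts.
    """
    pre = getattr(pre_pred, "positions", pre_pred)
    post = getattr(post_pred, "positions", post_pred)
    labels = ["ICA", "M1"]
    for lab in labels:
        if lab not in pre or lab not in post:
            raise ValueError(f"missing landmark {lab!r} in prediction")
    moving = np.array([pre[lab] for lab in labels], dtype=float)
    fixed = np.array([post[lab] for lab in labels], dtype=float)
    return CorrespondenceSet(moving, fixed, labels=labels,
                             source=CorrespondenceSource.LANDMARK)


def pool_correspondences(
    sets: list[CorrespondenceSet],
    use_sift: bool = True,
    use_orb: bool = True,
    use_lm: bool = False,
    dedup_tol_px: float = 0.5,
) -> CorrespondenceSet:
    """Concatenate correspondences from the selected sources.

    Near-duplicate pairs (same moving AND fixed point within ``dedup_tol_px``
    across sources) collapse to the first occurrence, so the same vessel
    junction found by two detectors does not vote twice in RANSAC.
    """
    if not (use_sift or use_orb or use_lm):
        raise ValueError("at least one correspondence source must be enabled")
    enabled = {
        CorrespondenceSource.SIFT: use_sift,
        CorrespondenceSource.ORB: use_orb,
        CorrespondenceSource.LANDMARK: use_lm,
    }
    moving, fixed, sources = [], [], []
    for cs in sets:
        if cs.source is not None and not enabled.get(cs.source, True):
            continue
        for i in range(len(cs)):
            m, f = cs.moving[i], cs.fixed[i]
            dup = False
            for mm, ff in zip(moving, fixed):
                if (np.linalg.norm(m - mm) <= dedup_tol_px
                        and np.linalg.norm(f - ff) <= dedup_tol_px):
                    dup = True
                    break
            if not dup:
                moving.append(m)
                fixed.append(f)
                sources.append(cs.source.value if cs.source else "unknown")
    out = CorrespondenceSet(
        np.array(moving).reshape(-1, 2), np.array(fixed).reshape(-1, 2)
    )
    out.sources = np.array(sources)
    return out


# ---------------------------------------------------------------------------
# Robust estimation
# ---------------------------------------------------------------------------

@dataclass
class RobustFit:
    transform: Transform2D
    inlier_mask: np.ndarray
    inlier_threshold_px: float
    seed: int

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())

    def to_json(self) -> str:
        import json

        return json.dumps({
            "transform": json.loads(self.transform.to_json()),
            "n_inliers": self.n_inliers,
            "n_correspondences": len(self.inlier_mask),
            "inlier_threshold_px": self.inlier_threshold_px,
            "seed": self.seed,
        })


def correspondences_to_csv(corr: CorrespondenceSet, path,
                           inlier_mask: np.ndarray | None = None) -> None:
    """Write correspondences as ``source,mx,my,fx,fy,inlier`` CSV."""
    import pandas as pd

    sources = corr.sources if corr.sources is not None else [""] * len(corr)
    inl = inlier_mask if inlier_mask is not None else np.ones(len(corr), dtype=bool)
    pd.DataFrame({
        "source": list(sources),
        "mx": corr.moving[:, 0], "my": corr.moving[:, 1],
        "fx": corr.fixed[:, 0], "fy": corr.fixed[:, 1],
        "inlier": np.asarray(inl, dtype=int),
    }).to_csv(path, index=False, float_format="%.4f")


class Status(str, Enum):
    NO_SOLUTION = "no_solution"
    VALID = "valid"
    INVALID = "invalid"
    UNVERIFIED = "unverified"


@dataclass
class SolutionStatus:
    status: Status
    mean_annotation_error_px: float | None = None


_MINIMAL_SAMPLE = {
    TransformType.TRANSLATION: 1,
    TransformType.RIGID: 2,
    TransformType.SIMILARITY: 2,
    TransformType.AFFINE: 3,
    TransformType.PROJECTIVE: 4,
}


def estimate_robust(
    corr: CorrespondenceSet,
    ttype: TransformType | str = TransformType.SIMILARITY,
    inlier_threshold_px: float = 3.0,
    min_inliers: int = 5,
    seed: int = 0,
    max_iterations: int = 2000,
    confidence: float = 0.999,
) -> RobustFit | None:
    """RANSAC + least-squares refit; ``None`` when consensus stays below
    ``min_inliers`` (no solution).

    Minimal samples of the transform type (2 points for a similarity) are
    drawn with a seeded generator; consensus is residual <= threshold;
    iteration stops early once the standard (1-w^k) confidence bound is met.
    Degenerate samples (near-coincident points) are skipped.  The final
    transform is refit by least squares on the best consensus set.
    """
    ttype = TransformType(ttype)
    n = len(corr)
    if n == 0:
        raise ValueError("empty correspondence set")
    k = _MINIMAL_SAMPLE[ttype]
    if n < max(k, min_inliers):
        return None
    rng = np.random.default_rng(seed)
    best_mask = None
    best_count = 0
    best_rss = np.inf
    n_iter = max_iterations
    it = 0
    while it < n_iter:
        it += 1
        idx = rng.choice(n, size=k, replace=False)
        sample = corr.subset(idx)
        # reject degenerate minimal samples
        if k >= 2 and np.linalg.norm(sample.moving[0] - sample.moving[1]) < 1.0:
            continue
        try:
            fit = fit_transform(sample, ttype)
        except (ValueError, DegeneracyError, FloatingPointError):
            continue
        resid = np.linalg.norm(apply_transform(fit.transform, corr.moving) - corr.fixed, axis=1)
        mask = resid <= inlier_threshold_px
        count = int(mask.sum())
        rss = float((resid[mask] ** 2).sum())
        if count > best_count or (count == best_count and rss < best_rss):
            best_count, best_mask, best_rss = count, mask, rss
            w = count / n
            if w > 0:
                denom = np.log1p(-min(w ** k, 1 - 1e-12))
                n_iter = min(max_iterations, int(np.ceil(np.log(1 - confidence) / denom)))
    if best_mask is None or best_count < min_inliers:
        return None
    refit = fit_transform(corr.subset(best_mask), ttype)
    resid = np.linalg.norm(apply_transform(refit.transform, corr.moving) - corr.fixed, axis=1)
    final_mask = resid <= inlier_threshold_px
    if final_mask.sum() < min_inliers:
        return None
    return RobustFit(
        transform=refit.transform,
        inlier_mask=final_mask,
        inlier_threshold_px=inlier_threshold_px,
        seed=seed,
    )


def classify_solution(
    fit: RobustFit | None,
    reference: CorrespondenceSet | None = None,
    invalid_threshold_px: float = 10.0,
) -> SolutionStatus:
    """Classify a registration against reference (manual) correspondences.

    Mean Euclidean error of the transform on the reference points decides
    validity; exactly at the threshold counts as valid ("greater than"
    reads strictly).  Without reference points the solution is UNVERIFIED.
    """
    if fit is None:
        return SolutionStatus(status=Status.NO_SOLUTION)
    if reference is None or len(reference) == 0:
        return SolutionStatus(status=Status.UNVERIFIED)
    err = np.linalg.norm(
        apply_transform(fit.transform, reference.moving) - reference.fixed, axis=1
    )
    mean_err = float(err.mean())
    # strict "greater than" with a 1e-9 guard so round-off cannot flip the boundary
    status = Status.INVALID if mean_err > invalid_threshold_px + 1e-9 else Status.VALID
    return SolutionStatus(status=status, mean_annotation_error_px=mean_err)
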