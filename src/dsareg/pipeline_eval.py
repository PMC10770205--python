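"""End-to-end pre/post registration and cohort evaluation.

``register_pair`` runs the full chain on one pre/post sequence pair:
minIP computation, SIFT/ORB detection and matching, optional landmark
correspondences, pooling, robust similarity estimation and validity
classification against reference annotations.  ``evaluate_cohort`` repeats
this over a cohort for each requested method combination (as in a
solutions / invalid-solutions table), reporting per-combination counts,
success rates (valid solutions / pairs) and error distributions over the
valid solutions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_registration import (
    Detector,
    DetectorConfig,
    RobustFit,
    SolutionStatus,
    Status,
    classify_solution,
    detect_keypoints,
    estimate_robust,
    landmark_correspondences,
    match_keypoints,
    pool_correspondences,
)
from .sequence_io import DSASequence, MinIPImage, compute_minip
from .transform_models import Transform2D, TransformType, warp_image


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one place.

    Defaults follow the method's stated operating points: similarity as the
    registration model, at least 5 RANSAC inliers for a solution, mean
    reference error above 10 px marks a solution invalid, and reference sets
    need at least 6 points to count toward evaluation.
    """

    use_sift: bool = True
    use_orb: bool = True
    use_lm: bool = False
    model: TransformType = TransformType.SIMILARITY
    inlier_threshold_px: float = 3.0
    min_inliers: int = 5
    invalid_threshold_px: float = 10.0
    min_reference_points: int = 6
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load thresholds/settings from a JSON config file; absent keys keep
        their defaults."""
        import json
        from pathlib import Path

        data = json.loads(Path(path).read_text())
        det = DetectorConfig(**data.pop("detector", {}))
        if "model" in data:
            data["model"] = TransformType(data["model"])
        return cls(detector=det, **data)

    def method_tag(self) -> str:
        parts = [name for name, on in
                 (("sift", self.use_sift), ("orb", self.use_orb), ("lm", self.use_lm)) if on]
        return "+".join(parts)


@dataclass
class RegistrationResult:
    pair_id: str
    methods: str
    transform: Transform2D | None
    n_inliers: int
    status: SolutionStatus
    n_correspondences: int = 0
    runtime_s: float = 0.0

    @property
    def mean_annotation_error_px(self) -> float | None:
        return self.status.mean_annotation_error_px


def register_pair(
    pre: DSASequence,
    post: DSASequence,
    config: PipelineConfig | None = None,
    reference=None,
    landmark_model=None,
    pair_id: str | None = None,
) -> RegistrationResult:
    """Register a pre-EVT sequence onto a post-EVT sequence of the same view.

    Correspondences from the enabled sources are pooled and a similarity
    transform (by default) is estimated with RANSAC + least-squares refit.
    With ``reference`` correspondences the solution is classified VALID /
    INVALID at the configured 10 px mean-error threshold; without them it is
    UNVERIFIED.  ``landmark_model`` (a trained detector) is only consulted
    when ``use_lm`` is on.
    """
    config = config or PipelineConfig()
    if pre.view != post.view:
        raise ValueError(f"view mismatch: {pre.view} vs {post.view}")
    t0 = time.perf_counter()
    pre_minip = compute_minip(pre)
    post_minip = compute_minip(post)

    sets = []
    if config.use_sift:
        a = detect_keypoints(pre_minip, Detector.SIFT, config=config.detector)
        b = detect_keypoints(post_minip, Detector.SIFT, config=config.detector)
        sets.append(match_keypoints(a, b, lowe_ratio=config.detector.lowe_ratio))
    if config.use_orb:
        a = detect_keypoints(pre_minip, Detector.ORB, config=config.detector)
        b = detect_keypoints(post_minip, Detector.ORB, config=config.detector)
        sets.append(match_keypoints(a, b, lowe_ratio=config.detector.lowe_ratio))
    if config.use_lm:
        if landmark_model is None:
            raise ValueError("use_lm requires a landmark model")
        sets.append(landmark_correspondences(
            landmark_model.predict(pre_minip), landmark_model.predict(post_minip)
        ))
    pooled = pool_correspondences(sets, use_sift=config.use_sift,
                                  use_orb=config.use_orb, use_lm=config.use_lm)
    fit = None
    if len(pooled) > 0:
        fit = estimate_robust(
            pooled,
            ttype=config.model,
            inlier_threshold_px=config.inlier_threshold_px,
            min_inliers=config.min_inliers,
            seed=config.seed,
        )
    status = classify_solution(fit, reference, config.invalid_threshold_px)
    return RegistrationResult(
        pair_id=pair_id or pre.source_id,
        methods=config.method_tag(),
        transform=fit.transform if fit is not None else None,
        n_inliers=fit.n_inliers if fit is not None else 0,
        status=status,
        n_correspondences=len(pooled),
        runtime_s=time.perf_counter() - t0,
    )


#: the method combinations of the solutions table: (sift, orb, lm)
DEFAULT_COMBINATIONS = [
    (True, False, False),
    (False, True, False),
    (True, True, False),
]


@dataclass
class CohortReport:
    results: pd.DataFrame  # long format, one row per (pair, combination)
    summary: pd.DataFrame  # one row per combination

    def to_csv(self, results_path, summary_path=None) -> None:
        self.results.to_csv(results_path, index=False, float_format="%.6f")
        if summary_path is not None:
            self.summary.to_csv(summary_path, index=False, float_format="%.6f")


def evaluate_cohort(
    pairs,
    config: PipelineConfig | None = None,
    method_combinations=None,
    landmark_model=None,
    n_reference_points: int = 8,
) -> CohortReport:
    """Register every pair under every method combination and tabulate.

    ``pairs`` are SyntheticPair objects (their ground truth supplies the
    reference correspondences) or (pre, post, reference) triples.  Pairs
    whose reference has fewer than ``config.min_reference_points`` points are
    dropped from the accounting.  Success rate is
    (n_solutions - n_invalid) / n_pairs per combination.
    """
    config = config or PipelineConfig()
    combos = method_combinations or DEFAULT_COMBINATIONS
    items = []
    for pair in pairs:
        if hasattr(pair, "pre_seq"):
            items.append((pair.pre_seq, pair.post_seq,
                          pair.reference_correspondences(n_reference_points)))
        else:
            items.append(tuple(pair))
    items = [(a, b, r) for a, b, r in items if len(r) >= config.min_reference_points]
    if not items:
        raise ValueError("empty cohort (no pair has enough reference points)")

    rows = []
    for use_sift, use_orb, use_lm in combos:
        cfg = replace(config, use_sift=use_sift, use_orb=use_orb, use_lm=use_lm)
        for pre, post, ref in items:
            res = register_pair(pre, post, cfg, reference=ref,
                                landmark_model=landmark_model)
            rows.append({
                "pair_id": res.pair_id,
                "methods": res.methods,
                "n_correspondences": res.n_correspondences,
                "n_inliers": res.n_inliers,
                "status": res.status.status.value,
                "mean_error_px": res.mean_annotation_error_px,
            })
    results = pd.DataFrame(rows)

    summ = []
    for methods, grp in results.groupby("methods", sort=False):
        n_pairs = len(grp)
        solved = grp[grp.status != Status.NO_SOLUTION.value]
        invalid = grp[grp.status == Status.INVALID.value]
        valid = grp[grp.status == Status.VALID.value]
        errs = valid.mean_error_px.astype(float)
        summ.append({
            "methods": methods,
            "n_pairs": n_pairs,
            "n_solutions": len(solved),
            "n_invalid": len(invalid),
            "success_rate": len(valid) / n_pairs,
            "median_error_px": float(errs.median()) if len(errs) else np.nan,
            "q1_error_px": float(errs.quantile(0.25)) if len(errs) else np.nan,
            "q3_error_px": float(errs.quantile(0.75)) if len(errs) else np.nan,
            "max_error_px": float(errs.max()) if len(errs) else np.nan,
        })
    return CohortReport(results=results, summary=pd.DataFrame(summ))


def make_overlay(pre_minip, post_minip, transform: Transform2D) -> np.ndarray:
    """QC overlay: warped pre vasculature in red, post in blue, on black.

    Intensities are inverted (vessels bright) before going into the colour
    channels, so vessels present in both images and correctly aligned appear
    purple, pre-only vessels red, post-only vessels blue.  Output is
    (H, W, 3) float in [0, 1] with the post image's dimensions.
    """
    post_px = np.asarray(getattr(post_minip, "pixels", post_minip), dtype=float)
    warped = warp_image(transform, pre_minip, out_shape=post_px.shape)
    rgb = np.zeros((*post_px.shape, 3))
    rgb[..., 0] = 1.0 - warped
    rgb[..., 2] = 1.0 - post_px
    return np.clip(rgb, 0, 1)
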