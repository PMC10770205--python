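"""Synthetic cerebral angiogram generator.

Clinical pre/post-thrombectomy DSA comes from registries that are not
publicly deposited, so every downstream component here is exercised on
simulated data with known ground truth.  The generator emulates the features
the registration method actually relies on:

* a branching arterial tree (dark, anti-aliased tubes on a bright
  background) whose contrast front propagates from the root over the frames
  of a sequence, as a contrast bolus does;
* two labelled landmarks — the internal carotid artery (ICA) terminus at the
  first bifurcation and the first middle-cerebral-artery (M1) node;
* pre/post pairs related by a known global similarity transform (C-arm
  repositioning + patient motion between acquisitions);
* vessel-content differences: a distal subtree missing before treatment and
  reperfused after, mimicking thrombus removal.

It does not model hemodynamics, 3D cone-beam projection geometry, or
structured DSA artifacts; see docs/methods.md for what that implies.
Every output is a pure function of its seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import DSASequence, Phase, View, save_sequence
from .transform_models import (
    CorrespondenceSet,
    CorrespondenceSource,
    Transform2D,
    TransformType,
    apply_transform,
)

ICA = "ICA"
M1 = "M1"


@dataclass
class BranchingConfig:
    """Parameters of the recursive bifurcating vessel tree.

    ``depth`` counts node levels (depth=2 is a root plus two children); radii
    and segment lengths decay geometrically with level, as arterial calibres
    do.  ``extent`` is (H, W) in pixels.
    """

    depth: int = 6
    extent: tuple[int, int] = (512, 512)
    branch_angle_deg: float = 55.0
    angle_jitter_deg: float = 12.0
    radius_decay: float = 0.8
    root_radius_px: float = 6.0
    segment_length_frac: float = 0.22  # first segment length as fraction of H
    length_decay: float = 0.72
    length_jitter: float = 0.15
    margin_frac: float = 0.06

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2 (need at least one bifurcation)")
        if not (0 < self.radius_decay < 1):
            raise ValueError("radius_decay must lie in (0, 1)")
        if self.root_radius_px <= 0 or self.segment_length_frac <= 0:
            raise ValueError("root radius and segment length must be positive")


@dataclass
class VesselTree:
    """Connected acyclic vessel graph with labelled ICA/M1 landmark nodes."""

    nodes: dict[int, tuple[float, float, float]]  # id -> (x, y, radius px)
    edges: list[tuple[int, int]]  # (parent, child)
    root: int
    landmark_ids: dict[str, int]

    def node_xy(self, node_id: int) -> np.ndarray:
        x, y, _ = self.nodes[node_id]
        return np.array([x, y])

    def children(self, node_id: int) -> list[int]:
        return [c for p, c in self.edges if p == node_id]

    def descendants(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return out

    def path_distances(self) -> dict[int, float]:
        """Euclidean path length from the root to every node."""
        dist = {self.root: 0.0}
        stack = [self.root]
        while stack:
            p = stack.pop()
            for c in self.children(p):
                dist[c] = dist[p] + float(np.linalg.norm(self.node_xy(c) - self.node_xy(p)))
                stack.append(c)
        return dist

    def without_edges(self, removed: set[tuple[int, int]]) -> "VesselTree":
        keep_edges = [e for e in self.edges if e not in removed]
        keep_ids = {self.root}
        changed = True
        children_map: dict[int, list[int]] = {}
        for p, c in keep_edges:
            children_map.setdefault(p, []).append(c)
        stack = [self.root]
        reachable = {self.root}
        while stack:
            p = stack.pop()
            for c in children_map.get(p, []):
                reachable.add(c)
                stack.append(c)
        return VesselTree(
            nodes={i: self.nodes[i] for i in reachable},
            edges=[(p, c) for p, c in keep_edges if p in reachable and c in reachable],
            root=self.root,
            landmark_ids=self.landmark_ids,
        )

    def transformed(self, t: Transform2D) -> "VesselTree":
        """Apply a global transform to node coordinates; radii scale with the
        transform's uniform scale (tube width follows image magnification)."""
        scale = float(np.sqrt(abs(np.linalg.det(t.matrix[:2, :2]))))
        ids = list(self.nodes)
        xy = np.array([self.nodes[i][:2] for i in ids])
        new_xy = apply_transform(t, xy)
        nodes = {
            i: (float(p[0]), float(p[1]), self.nodes[i][2] * scale)
            for i, p in zip(ids, new_xy)
        }
        return VesselTree(nodes=nodes, edges=list(self.edges), root=self.root,
                          landmark_ids=dict(self.landmark_ids))


def generate_tree(seed: int, params: BranchingConfig | None = None) -> VesselTree:
    """Grow a deterministic bifurcating vessel tree.

    The root (ICA terminus) sits in the upper-central region and branches
    grow downward; the first child along the main branch is labelled M1.
    Radii strictly decrease from parent to child and all nodes stay inside
    the image extent.
    """
    params = params or BranchingConfig()
    params.validate()
    rng = np.random.default_rng(seed)
    h, w = params.extent
    margin = params.margin_frac * min(h, w)

    root_xy = np.array([
        w / 2 + rng.uniform(-0.05, 0.05) * w,
        0.16 * h + rng.uniform(-0.03, 0.03) * h,
    ])
    nodes: dict[int, tuple[float, float, float]] = {
        0: (float(root_xy[0]), float(root_xy[1]), params.root_radius_px)
    }
    edges: list[tuple[int, int]] = []
    next_id = 1

    def clamp(p: np.ndarray) -> np.ndarray:
        return np.clip(p, [margin, margin], [w - 1 - margin, h - 1 - margin])

    # breadth-first growth; direction 90 deg = straight down in image coords
    frontier = [(0, 90.0, params.segment_length_frac * h, params.root_radius_px)]
    for level in range(params.depth - 1):
        new_frontier = []
        for node_id, heading, length, radius in frontier:
            split = params.branch_angle_deg / 2
            for sign in (-1.0, 1.0):
                nonlocal_id = next_id
                ang = heading + sign * split + rng.uniform(
                    -params.angle_jitter_deg, params.angle_jitter_deg
                )
                ll = length * (1 + rng.uniform(-params.length_jitter, params.length_jitter))
                # jitter kept small enough that radii stay strictly decreasing
                rr = radius * params.radius_decay * (1 + rng.uniform(-0.05, 0.05))
                p = nodes[node_id][:2] + ll * np.array(
                    [np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))]
                )
                p = clamp(p)
                nodes[nonlocal_id] = (float(p[0]), float(p[1]), float(rr))
                edges.append((node_id, nonlocal_id))
                new_frontier.append((nonlocal_id, ang, ll * params.length_decay, rr))
                next_id += 1
        frontier = new_frontier

    if not edges:
        raise ValueError("branching parameters produced zero branches")
    # first bifurcation node is the root (ICA terminus); its first child is M1
    landmark_ids = {ICA: 0, M1: edges[0][1]}
    return VesselTree(nodes=nodes, edges=edges, root=0, landmark_ids=landmark_ids)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

VESSEL_CONTRAST = 0.8  # peak darkness of a fully opacified vessel


def _edge_darkness(canvas: np.ndarray, p1, r1, p2, r2) -> None:
    """Accumulate (max) the darkness profile of one tube segment.

    The profile is flat inside the local radius and falls off as a cosine
    over one pixel, giving anti-aliased edges with stable gradients for
    keypoint detectors.
    """
    h, w = canvas.shape
    rmax = max(r1, r2) + 1.0
    x_lo = int(max(0, np.floor(min(p1[0], p2[0]) - rmax)))
    x_hi = int(min(w - 1, np.ceil(max(p1[0], p2[0]) + rmax)))
    y_lo = int(max(0, np.floor(min(p1[1], p2[1]) - rmax)))
    y_hi = int(min(h - 1, np.ceil(max(p1[1], p2[1]) + rmax)))
    if x_lo > x_hi or y_lo > y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi + 1, x_lo:x_hi + 1]
    d = np.stack([xx - p1[0], yy - p1[1]], axis=-1).astype(float)
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    vv = float(v @ v)
    if vv < 1e-12:
        t = np.zeros(d.shape[:2])
    else:
        t = np.clip((d @ v) / vv, 0.0, 1.0)
    closest = t[..., None] * v
    dist = np.sqrt(((d - closest) ** 2).sum(axis=-1))
    radius = r1 + t * (r2 - r1)
    inner = radius - 0.5
    profile = np.where(
        dist <= inner,
        1.0,
        np.where(
            dist <= inner + 1.0,
            0.5 * (1 + np.cos(np.pi * (dist - inner))),
            0.0,
        ),
    )
    region = canvas[y_lo:y_hi + 1, x_lo:x_hi + 1]
    np.maximum(region, VESSEL_CONTRAST * profile, out=region)


def render_tree(tree: VesselTree, shape: tuple[int, int],
                edges: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Static rendering of (a subset of) the tree: background 1.0, dark tubes."""
    canvas = np.zeros(shape)
    for p, c in (edges if edges is not None else tree.edges):
        x1, y1, r1 = tree.nodes[p]
        x2, y2, r2 = tree.nodes[c]
        _edge_darkness(canvas, (x1, y1), r1, (x2, y2), r2)
    return 1.0 - canvas


def render_sequence(
    tree: VesselTree,
    n_frames: int,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    view: View = View.AP,
    phase: Phase = Phase.PRE_EVT,
    source_id: str = "",
) -> DSASequence:
    """Render a temporal sequence in which contrast fills the tree root-first.

    Frame ``t`` (0-based) darkens exactly the edges whose distal node lies
    within ``(t+1)/n_frames`` of the maximum root path distance, so the final
    frame — and hence the noise-free minIP — equals the full-tree rendering.
    Gaussian noise is added per frame and clipped to [0, 1].
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dist = tree.path_distances()
    max_dist = max(dist.values()) or 1.0
    order = sorted(tree.edges, key=lambda e: (dist[e[1]], e))
    rng = np.random.default_rng(seed)

    frames = np.empty((n_frames, *shape))
    canvas = np.zeros(shape)
    cursor = 0
    for t in range(n_frames):
        reach = (t + 1) / n_frames * max_dist
        while cursor < len(order) and dist[order[cursor][1]] <= reach + 1e-9:
            p, c = order[cursor]
            x1, y1, r1 = tree.nodes[p]
            x2, y2, r2 = tree.nodes[c]
            _edge_darkness(canvas, (x1, y1), r1, (x2, y2), r2)
            cursor += 1
        frame = 1.0 - canvas
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[t] = np.clip(frame, 0.0, 1.0)
    return DSASequence(frames=frames, view=view, phase=phase, source_id=source_id)


# ---------------------------------------------------------------------------
# Pre/post pair generation
# ---------------------------------------------------------------------------

@dataclass
class TransformSpec:
    """Sampling bounds for the ground-truth pre->post similarity transform."""

    rotation_max_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_max_px: float = 50.0

    def sample(self, rng: np.random.Generator, center: tuple[float, float]
               ) -> tuple[Transform2D, dict[str, float]]:
        """Draw a similarity transform; rotation and scale act about ``center``.

        Returns the transform and the sampled parameters (the matrix
        translation additionally absorbs the rotation about the center)."""
        rot = rng.uniform(-self.rotation_max_deg, self.rotation_max_deg)
        scale = rng.uniform(*self.scale_range)
        tx = rng.uniform(-self.translation_max_px, self.translation_max_px)
        ty = rng.uniform(-self.translation_max_px, self.translation_max_px)
        t = Transform2D.from_similarity_params(
            scale=scale, rotation_deg=rot, translation=(tx, ty), center=center
        )
        return t, {"scale": scale, "rotation_deg": rot, "tx_px": tx, "ty_px": ty}

    @classmethod
    def identity(cls) -> "TransformSpec":
        return cls(rotation_max_deg=0.0, scale_range=(1.0, 1.0), translation_max_px=0.0)


@dataclass
class SyntheticPair:
    """A pre/post-EVT pair with full ground truth."""

    pre_seq: DSASequence
    post_seq: DSASequence
    true_transform: Transform2D  # moving = pre -> fixed = post
    true_landmarks_pre: dict[str, tuple[float, float]]
    true_landmarks_post: dict[str, tuple[float, float]]
    removed_subtree_fraction: float
    seed: int
    true_params: dict[str, float] = field(default_factory=dict)
    pre_tree: VesselTree = None
    post_tree: VesselTree = None

    def reference_correspondences(self, n: int = 8) -> CorrespondenceSet:
        """Ground-truth reference points standing in for manual annotations.

        ``n`` nodes of the pre tree (always including both landmarks) are
        mapped through the true transform; sampling is deterministic in the
        pair's seed.
        """
        rng = np.random.default_rng(self.seed + 977)
        lm = [self.pre_tree.landmark_ids[ICA], self.pre_tree.landmark_ids[M1]]
        others = [i for i in self.pre_tree.nodes if i not in lm]
        extra = min(max(n - len(lm), 0), len(others))
        chosen = lm + sorted(rng.choice(others, size=extra, replace=False).tolist())
        moving = np.array([self.pre_tree.nodes[i][:2] for i in chosen])
        fixed = apply_transform(self.true_transform, moving)
        return CorrespondenceSet(moving, fixed, labels=[str(i) for i in chosen],
                                 source=CorrespondenceSource.MANUAL)


@dataclass
class PairConfig:
    """Study conditions for one synthetic pre/post pair."""

    shape: tuple[int, int] = (512, 512)
    n_frames: int = 8
    noise_sd: float = 0.02
    removal_fraction: float = 0.2
    transform_spec: TransformSpec = field(default_factory=TransformSpec)
    tree: BranchingConfig = field(default_factory=BranchingConfig)


def _select_removal(tree: VesselTree, fraction: float, rng: np.random.Generator
                    ) -> set[tuple[int, int]]:
    """Pick subtrees distal to M1 covering ~``fraction`` of the edges.

    Removal is placed downstream of the M1 landmark so both landmarks stay
    visible in the pre-treatment image (the landmark detector sees pre and
    post images alike)."""
    target = int(round(fraction * len(tree.edges)))
    if target == 0:
        return set()
    m1 = tree.landmark_ids[M1]
    removed: set[tuple[int, int]] = set()

    def subtree_edges(node: int) -> set[tuple[int, int]]:
        out, stack = set(), [node]
        while stack:
            p = stack.pop()
            for c in tree.children(p):
                out.add((p, c))
                stack.append(c)
        return out

    candidates = tree.descendants(m1)
    rng.shuffle(candidates)
    remaining = target
    for cand in candidates:
        sub = subtree_edges(cand) | {e for e in tree.edges if e[1] == cand}
        sub -= removed
        if 0 < len(sub) <= remaining:
            removed |= sub
            remaining -= len(sub)
        if remaining <= 0:
            break
    return removed


def make_pair(seed: int, config: PairConfig | None = None) -> SyntheticPair:
    """Generate one pre/post pair with known transform, landmarks and removal.

    The pre sequence renders the tree minus a distal subtree (the occluded
    territory); the post sequence renders the full tree warped by a sampled
    similarity transform (reperfusion + repositioning).
    """
    config = config or PairConfig()
    if not (0 <= config.removal_fraction < 1):
        raise ValueError("removal_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tree = generate_tree(seed=int(rng.integers(2 ** 31)), params=config.tree)
    h, w = config.shape
    true_t, true_params = config.transform_spec.sample(rng, center=((w - 1) / 2, (h - 1) / 2))

    removed = _select_removal(tree, config.removal_fraction, rng)
    pre_tree = tree.without_edges(removed)
    post_tree = tree.transformed(true_t)

    noise_seeds = rng.integers(2 ** 31, size=2)
    pre_seq = render_sequence(pre_tree, config.n_frames, config.noise_sd, config.shape,
                              seed=int(noise_seeds[0]), phase=Phase.PRE_EVT,
                              source_id=f"synth{seed:05d}")
    post_seq = render_sequence(post_tree, config.n_frames, config.noise_sd, config.shape,
                               seed=int(noise_seeds[1]), phase=Phase.POST_EVT,
                               source_id=f"synth{seed:05d}")

    lm_pre = {k: tuple(tree.node_xy(i)) for k, i in tree.landmark_ids.items()}
    lm_post = {
        k: tuple(apply_transform(true_t, np.array([v]))[0]) for k, v in lm_pre.items()
    }
    return SyntheticPair(
        pre_seq=pre_seq,
        post_seq=post_seq,
        true_transform=true_t,
        true_landmarks_pre=lm_pre,
        true_landmarks_post=lm_post,
        removed_subtree_fraction=len(removed) / len(tree.edges),
        seed=seed,
        true_params=true_params,
        pre_tree=pre_tree,
        post_tree=post_tree,
    )


def generate_cohort(n: int, seed: int, config: PairConfig | None = None
                    ) -> tuple[list[SyntheticPair], pd.DataFrame]:
    """Generate ``n`` pairs (per-pair seeds ``seed + i``) plus a ground-truth
    manifest recording seeds, transform parameters, landmarks and removal."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or PairConfig()
    pairs, rows = [], []
    for i in range(n):
        pair = make_pair(seed + i, config)
        pairs.append(pair)
        rows.append({
            "pair_id": f"synth{seed + i:05d}",
            "seed": seed + i,
            **pair.true_params,
            "removed_fraction": pair.removed_subtree_fraction,
            "ica_pre_x": pair.true_landmarks_pre[ICA][0],
            "ica_pre_y": pair.true_landmarks_pre[ICA][1],
            "m1_pre_x": pair.true_landmarks_pre[M1][0],
            "m1_pre_y": pair.true_landmarks_pre[M1][1],
            "ica_post_x": pair.true_landmarks_post[ICA][0],
            "ica_post_y": pair.true_landmarks_post[ICA][1],
            "m1_post_x": pair.true_landmarks_post[M1][0],
            "m1_post_y": pair.true_landmarks_post[M1][1],
        })
    return pairs, pd.DataFrame(rows)


def landmark_training_set(
    n_pairs: int,
    seed: int,
    image_size: int = 128,
    noise_sd: float = 0.02,
) -> tuple[np.ndarray, list[dict[str, tuple[float, float]]], list[str]]:
    """Build a landmark-detection training set of minIPs with annotations.

    Each pair contributes its pre and post minIP under one shared source_id,
    so subject-level train/validation splitting is exercised for real.  Tree
    size, tube radius and transform bounds are scaled from the 512 px
    defaults to ``image_size``; pairs whose landmarks leave the field of
    view are skipped (and replaced) deterministically.
    """
    from .sequence_io import compute_minip

    f = image_size / 512.0
    config = PairConfig(
        shape=(image_size, image_size),
        n_frames=4,
        noise_sd=noise_sd,
        removal_fraction=0.2,
        transform_spec=TransformSpec(rotation_max_deg=15.0, scale_range=(0.9, 1.1),
                                     translation_max_px=50.0 * f),
        tree=BranchingConfig(depth=5, extent=(image_size, image_size),
                             root_radius_px=max(6.0 * f, 2.0)),
    )
    images, landmarks, source_ids = [], [], []
    attempt = 0
    while len(source_ids) < 2 * n_pairs:
        pair = make_pair(seed + attempt, config)
        attempt += 1
        pts = list(pair.true_landmarks_pre.values()) + list(pair.true_landmarks_post.values())
        if not all(0 <= x <= image_size - 1 and 0 <= y <= image_size - 1 for x, y in pts):
            continue
        for seq, lm in ((pair.pre_seq, pair.true_landmarks_pre),
                        (pair.post_seq, pair.true_landmarks_post)):
            images.append(compute_minip(seq).pixels)
            landmarks.append({k: tuple(v) for k, v in lm.items()})
            source_ids.append(pair.pre_seq.source_id)
    return np.asarray(images), landmarks, source_ids


def write_cohort(pairs: list[SyntheticPair], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write a cohort as image stacks + manifest.csv + annotation CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_rows = []
    for pair in pairs:
        pid = pair.pre_seq.source_id
        save_sequence(pair.pre_seq, out_dir / pid / "pre")
        save_sequence(pair.post_seq, out_dir / pid / "post")
        (out_dir / pid / "true_transform.json").write_text(pair.true_transform.to_json())
        for label, (x, y) in pair.true_landmarks_pre.items():
            ann_rows.append({"image_id": f"{pid}/pre", "label": label, "x": x, "y": y})
        for label, (x, y) in pair.true_landmarks_post.items():
            ann_rows.append({"image_id": f"{pid}/post", "label": label, "x": x, "y": y})
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(ann_rows).to_csv(out_dir / "annotations.csv", index=False)
    return out_dir
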