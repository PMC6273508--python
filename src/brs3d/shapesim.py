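"""Gaussian-overlap shape similarity and rigid/flexible superimposition.

Molecules are modeled as sums of heavy-atom Gaussians whose isolated-atom
volume equals the hard-sphere vdW volume (Grant-Pickup parametrization with
amplitude p = 2*sqrt(2)).  Similarity combines a shape Tanimoto over the
first-order (pairwise) Gaussian overlap volume with a pharmacophore
feature-point Tanimoto; both lie in [0, 1] and the combined score is their
``w_shape`` weighted mean.

Rigid alignment seeds the pose search with a centroid overlay plus the four
proper principal-axis flips and refines each start with a Nelder-Mead simplex
over 6 rigid degrees of freedom.  Flexible superimposition enumerates the
query's conformers against a rigid template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .molio import TypedMolecule

#: Gaussian amplitude so that p * (pi/alpha)^{3/2} = 4/3 pi R^3 with the
#: alpha below — each atom's Gaussian integrates to its hard-sphere volume.
AMPLITUDE = 2.0 * np.sqrt(2.0)

FEATURE_RADIUS = 1.0  # Angstrom, fixed radius of pharmacophore feature points
DEFAULT_W_SHAPE = 0.5


def gaussian_alpha(radius: float | np.ndarray) -> float | np.ndarray:
    """Exponent (1/A^2) giving an isolated-atom volume of 4/3*pi*R^3."""
    return np.pi * (3.0 * AMPLITUDE / (4.0 * np.pi)) ** (2.0 / 3.0) / np.square(radius)


@dataclass
class Pose:
    """Rigid transform: rotation (unit quaternion, scalar-last) + translation."""

    quaternion: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        norm = np.linalg.norm(self.quaternion)
        if abs(norm - 1.0) > 1e-9:
            self.quaternion = self.quaternion / norm

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, translation: np.ndarray) -> "Pose":
        return cls(Rotation.from_matrix(matrix).as_quat(), translation)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.rotation.apply(points) + self.translation

    def inverse(self) -> "Pose":
        rinv = self.rotation.inv()
        return Pose(rinv.as_quat(), -rinv.apply(self.translation))

    def compose(self, other: "Pose") -> "Pose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        rot = self.rotation * other.rotation
        return Pose(rot.as_quat(), self.rotation.apply(other.translation) + self.translation)


@dataclass
class GaussianShape:
    """Heavy-atom Gaussian density plus typed feature points."""

    centers: np.ndarray
    alphas: np.ndarray
    amplitudes: np.ndarray
    feature_points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.alphas <= 0) or np.any(self.amplitudes <= 0):
            raise ValueError("alphas and amplitudes must be positive")
        self._self_overlap: float | None = None

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    def self_overlap(self) -> float:
        if self._self_overlap is None:
            self._self_overlap = _pair_overlap(
                self.centers, self.alphas, self.amplitudes,
                self.centers, self.alphas, self.amplitudes,
            )
        return self._self_overlap

    def transformed(self, pose: Pose) -> "GaussianShape":
        return GaussianShape(
            pose.apply(self.centers),
            self.alphas.copy(),
            self.amplitudes.copy(),
            {t: pose.apply(pts) for t, pts in self.feature_points.items()},
        )


@dataclass
class AlignmentResult:
    """Best pose found for a (query conformer, template) pair with its scores."""

    pose: Pose
    shape_score: float
    feature_score: float
    combined_score: float
    conformer_index: int = 0


def make_shape(mol: TypedMolecule, conformer_index: int = 0) -> GaussianShape:
    """Build the Gaussian shape of one conformer (heavy atoms only).

    Feature points are taken from every atom carrying feature flags, at the
    conformer position, with the fixed feature radius.
    """
    if conformer_index >= len(mol.conformers):
        raise IndexError(
            f"{mol.id}: conformer {conformer_index} of {len(mol.conformers)}"
        )
    coords = mol.conformers[conformer_index]
    heavy = mol.heavy_indices
    if heavy.size == 0:
        raise ValueError(f"{mol.id}: no heavy atoms; cannot build shape")
    radii = np.array([mol.atoms[i].radius for i in heavy])
    feature_points: dict[str, list[np.ndarray]] = {}
    for i, atom in enumerate(mol.atoms):
        for feat in atom.features:
            feature_points.setdefault(feat, []).append(coords[i])
    return GaussianShape(
        centers=coords[heavy],
        alphas=gaussian_alpha(radii),
        amplitudes=np.full(heavy.size, AMPLITUDE),
        feature_points={t: np.atleast_2d(np.array(p)) for t, p in feature_points.items()},
    )


def _pair_overlap(ca, aa, pa, cb, ab, pb) -> float:
    d2 = cdist(ca, cb, "sqeuclidean")
    asum = aa[:, None] + ab[None, :]
    kappa = aa[:, None] * ab[None, :] / asum
    return float(
        np.sum(pa[:, None] * pb[None, :] * (np.pi / asum) ** 1.5 * np.exp(-kappa * d2))
    )


def overlap_volume(A: GaussianShape, B: GaussianShape, pose: Pose) -> float:
    """First-order Gaussian overlap volume (A^3) with ``pose`` applied to B."""
    moved = pose.apply(B.centers)
    return _pair_overlap(A.centers, A.alphas, A.amplitudes, moved, B.alphas, B.amplitudes)


def shape_tanimoto(A: GaussianShape, B: GaussianShape, pose: Pose) -> float:
    """V_AB / (V_AA + V_BB - V_AB); self-overlaps at identity pose."""
    vab = overlap_volume(A, B, pose)
    denom = A.self_overlap() + B.self_overlap() - vab
    if denom <= 0:
        raise ValueError("degenerate shape Tanimoto denominator")
    return vab / denom


def _feature_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = points.shape[0]
    alpha = gaussian_alpha(FEATURE_RADIUS)
    return points, np.full(n, alpha), np.full(n, AMPLITUDE)


def feature_tanimoto(A: GaussianShape, B: GaussianShape, pose: Pose) -> float:
    """Mean per-type Gaussian Tanimoto over feature types present in either
    molecule; a type present on only one side contributes 0; no features on
    either side is vacuous agreement (1.0)."""
    types = set(A.feature_points) | set(B.feature_points)
    if not types:
        return 1.0
    scores = []
    for t in sorted(types):
        pa = A.feature_points.get(t)
        pb = B.feature_points.get(t)
        if pa is None or pb is None:
            scores.append(0.0)
            continue
        ca, aa, wa = _feature_shape(pa)
        cb, ab, wb = _feature_shape(pose.apply(pb))
        vab = _pair_overlap(ca, aa, wa, cb, ab, wb)
        vaa = _pair_overlap(ca, aa, wa, ca, aa, wa)
        vbb = _pair_overlap(cb, ab, wb, cb, ab, wb)
        scores.append(vab / (vaa + vbb - vab))
    return float(np.mean(scores))


def combined_score(
    A: GaussianShape, B: GaussianShape, pose: Pose, w_shape: float = DEFAULT_W_SHAPE
) -> tuple[float, float, float]:
    """(shape, feature, combined) scores of B posed onto A."""
    s = shape_tanimoto(A, B, pose)
    f = feature_tanimoto(A, B, pose)
    return s, f, w_shape * s + (1.0 - w_shape) * f


class _PairScorer:
    """Precomputed constants for repeated scoring of one (template, query)
    pair during pose refinement; numerically identical to combined_score."""

    def __init__(self, template: GaussianShape, query: GaussianShape, w_shape: float):
        self.denom_base = template.self_overlap() + query.self_overlap()
        alpha_f = gaussian_alpha(FEATURE_RADIUS)
        kf = alpha_f / 2.0
        pf = AMPLITUDE**2 * (np.pi / (2.0 * alpha_f)) ** 1.5
        types = sorted(set(template.feature_points) | set(query.feature_points))
        self.n_types = len(types)

        # one fused kernel matrix: shape block first, then one diagonal block
        # per feature type present on both sides (off-blocks get zero weight)
        t_parts = [template.centers]
        q_parts = [query.centers]
        self.blocks: list[tuple[int, int, int, int, float]] = []  # row/col spans + self-sum
        for t in types:
            pa = template.feature_points.get(t)
            pb = query.feature_points.get(t)
            if pa is None or pb is None:
                continue  # one-sided type: constant 0 contribution
            self_sum = self._self_v(pa, kf, pf) + self._self_v(pb, kf, pf)
            r0 = sum(p.shape[0] for p in t_parts)
            c0 = sum(p.shape[0] for p in q_parts)
            t_parts.append(pa)
            q_parts.append(pb)
            self.blocks.append((r0, r0 + pa.shape[0], c0, c0 + pb.shape[0], self_sum))
        self.n_shape_t = template.centers.shape[0]
        self.n_shape_q = query.centers.shape[0]
        self.tc_all = np.vstack(t_parts)
        self.qc_all = np.vstack(q_parts)

        nt, nq = self.tc_all.shape[0], self.qc_all.shape[0]
        self.kappa = np.full((nt, nq), kf)
        self.pref = np.zeros((nt, nq))
        st, sq = self.n_shape_t, self.n_shape_q
        asum = template.alphas[:, None] + query.alphas[None, :]
        self.kappa[:st, :sq] = template.alphas[:, None] * query.alphas[None, :] / asum
        self.pref[:st, :sq] = (
            template.amplitudes[:, None]
            * query.amplitudes[None, :]
            * (np.pi / asum) ** 1.5
        )
        for r0, r1, c0, c1, _ in self.blocks:
            self.pref[r0:r1, c0:c1] = pf
        self.w = w_shape

    @staticmethod
    def _self_v(pts: np.ndarray, kf: float, pf: float) -> float:
        d2 = cdist(pts, pts, "sqeuclidean")
        return float(np.sum(pf * np.exp(-kf * d2)))

    def combined(self, rot_matrix: np.ndarray, translation: np.ndarray) -> float:
        moved = self.qc_all @ rot_matrix.T + translation
        d2 = cdist(self.tc_all, moved, "sqeuclidean")
        E = self.pref * np.exp(-self.kappa * d2)
        vab = float(E[: self.n_shape_t, : self.n_shape_q].sum())
        s = vab / (self.denom_base - vab)
        if self.n_types == 0:
            f = 1.0
        else:
            total = 0.0
            for r0, r1, c0, c1, self_sum in self.blocks:
                v = float(E[r0:r1, c0:c1].sum())
                total += v / (self_sum - v)
            f = total / self.n_types
        return self.w * s + (1.0 - self.w) * f


def _weighted_axes(shape: GaussianShape) -> tuple[np.ndarray, np.ndarray, bool]:
    """Amplitude-weighted centroid and canonical principal axes.

    Axis signs are fixed by the third moment of the mass distribution along
    each axis (falling back to the largest-magnitude component when the
    distribution is symmetric), and the third axis is the cross product of
    the first two — so the frame is intrinsic: a rigidly transformed copy of
    the shape yields the transformed frame, making downstream pose searches
    independent of the input orientation.
    """
    w = shape.amplitudes / shape.amplitudes.sum()
    centroid = w @ shape.centers
    centered = shape.centers - centroid
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = shape.n_centers < 3 or evals[0] < 1e-8
    for k in range(2):
        proj = centered @ evecs[:, k]
        m3 = float(np.sum(w * proj**3))
        if abs(m3) > 1e-6:
            sign = np.sign(m3)
        else:
            sign = np.sign(evecs[np.argmax(np.abs(evecs[:, k])), k]) or 1.0
        evecs[:, k] *= sign
    evecs[:, 2] = np.cross(evecs[:, 0], evecs[:, 1])
    return centroid, evecs, degenerate


# proper rotations flipping pairs of principal axes
_FLIPS = [
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
]


def _initial_poses(query: GaussianShape, template: GaussianShape) -> list[Pose]:
    cq, rq, dq = _weighted_axes(query)
    ct, rt, dt = _weighted_axes(template)
    if dq or dt:
        return [Pose(np.array([0.0, 0.0, 0.0, 1.0]), ct - cq)]
    poses = []
    for flip in _FLIPS:
        rot = rt @ flip @ rq.T
        poses.append(Pose.from_matrix(rot, ct - rot @ cq))
    return poses


def rigid_align(
    query: GaussianShape,
    template: GaussianShape,
    w_shape: float = DEFAULT_W_SHAPE,
    maxiter: int = 250,
    tol: float = 1e-6,
    restarts: int = 2,
) -> AlignmentResult:
    """Best rigid pose of ``query`` onto ``template`` by combined score.

    Starts from the centroid/principal-axes overlays (4 proper flips) and
    refines each with a derivative-free simplex over rotation exp-map +
    translation; each start is polished with fresh-simplex restarts until the
    score stops improving.  Deterministic; ties between starts break to the
    lowest start index, and refinement never returns a pose worse than its
    start.
    """
    scorer = _PairScorer(template, query, w_shape)
    cq, rq, dq = _weighted_axes(query)
    ct, rt, dt = _weighted_axes(template)
    if dq or dt:
        start_mats = [np.eye(3)]
        rq = rt = np.eye(3)
    else:
        start_mats = _FLIPS

    def input_frame(S: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map a canonical-frame pose (rotation S, offset u) to input frame."""
        rot = rt @ S @ rq.T
        return rot, ct + rt @ u - rot @ cq

    best_pose: Pose | None = None
    best_score = -np.inf
    for flip in start_mats:
        # the whole search happens in the intrinsic frames, so its trajectory
        # (and local optimum) does not depend on the input orientation
        def objective(x):
            S = Rotation.from_rotvec(x[:3]).as_matrix() @ flip
            return -scorer.combined(*input_frame(S, x[3:]))

        x = np.zeros(6)
        prev_fun = None
        for _ in range(restarts):
            res = minimize(
                objective,
                x,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "fatol": tol, "xatol": 1e-4},
            )
            x = res.x
            # restart with a fresh simplex; stop once it no longer helps
            if prev_fun is not None and prev_fun - res.fun < 1e-6:
                break
            prev_fun = res.fun
        S = Rotation.from_rotvec(x[:3]).as_matrix() @ flip
        rot, trans = input_frame(S, x[3:])
        s_ref = scorer.combined(rot, trans)
        rot0, trans0 = input_frame(flip, np.zeros(3))
        s_init = scorer.combined(rot0, trans0)
        if s_ref >= s_init:
            pose, score = Pose.from_matrix(rot, trans), s_ref
        else:
            pose, score = Pose.from_matrix(rot0, trans0), s_init
        if score > best_score:
            best_score, best_pose = score, pose

    s, f, c = combined_score(template, query, best_pose, w_shape)
    return AlignmentResult(pose=best_pose, shape_score=s, feature_score=f, combined_score=c)


def flexible_superimpose(
    query: TypedMolecule,
    template: GaussianShape,
    top_n: int = 10,
    w_shape: float = DEFAULT_W_SHAPE,
    **align_kwargs,
) -> list[AlignmentResult]:
    """Rigid-align every query conformer onto the rigid template; return the
    ``top_n`` results by combined score, descending."""
    if not query.conformers:
        raise ValueError(f"unprofiled molecule: {query.id} has no conformers")
    results = []
    for ci in range(len(query.conformers)):
        res = rigid_align(make_shape(query, ci), template, w_shape=w_shape, **align_kwargs)
        res.conformer_index = ci
        results.append(res)
    results.sort(key=lambda r: (-r.combined_score, r.conformer_index))
    return results[:top_n]
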