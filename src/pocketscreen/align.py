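"""Rigid superposition and similarity scoring of pocket surfaces.

The stages are

* ``superpose`` — optimal least-squares rigid superposition (Kabsch/SVD,
  reflection-corrected) of corresponding lining-atom coordinates; reports
  the coordinate RMSD (cRMSD).
* ``orientation_vectors``/``ormsd`` — per-residue CA -> side-chain-centroid
  unit vectors and their RMSD after applying the rotation (oRMSD), a
  flexibility-tolerant orientation agreement score in [0, 2].
* ``mc_significance`` — empirical p-value of the observed alignment score
  against randomly generated surface alignments (uniform random rotations
  of one pocket with the correspondence re-derived each draw).
* ``gsvot`` — global surface volume overlap Tanimoto of the superimposed
  pocket volumes on the reference grid.
* ``surfacescreen_score`` — composite similarity combining shape (KS),
  alignment significance and volume overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .signature import KSResult
from .structure import BACKBONE_ATOMS, ProteinStructure

__all__ = [
    "Correspondence",
    "AlignmentResult",
    "greedy_correspondence",
    "superpose",
    "orientation_vectors",
    "ormsd",
    "mc_significance",
    "gsvot",
    "surfacescreen_score",
]

COMPOSITE_EPS = 1e-6


@dataclass
class Correspondence:
    """Matched atom index pairs between two surfaces."""

    pairs: list[tuple[int, int]]
    method: str = "user_supplied"

    def __post_init__(self) -> None:
        if len(self.pairs) < 3:
            raise ValidationError(
                f"a correspondence needs >= 3 pairs, got {len(self.pairs)}"
            )
        for side in (0, 1):
            idx = [p[side] for p in self.pairs]
            if len(set(idx)) != len(idx):
                raise ValidationError("correspondence indices must be unique per side")


@dataclass
class AlignmentResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied as x -> R x + t
    crmsd: float
    ormsd: float | None = None
    p_empirical: float | None = None
    gsvot: float | None = None
    composite: float | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def _chemical_class(element: str) -> str:
    e = element.strip().upper()
    return e if e in {"N", "O", "S"} else "C"


def greedy_correspondence(
    coords_a: np.ndarray,
    elements_a: Sequence[str],
    coords_b: np.ndarray,
    elements_b: Sequence[str],
) -> Correspondence:
    """Greedy chemical-class matching after centroid alignment.

    Both point sets are centered on their centroids; within each chemical
    class (N / O / S / other-heavy treated as C) pairs are formed greedily
    by smallest centered distance.  Deterministic: ties resolve by lowest
    index pair.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    classes_a: dict[str, list[int]] = {}
    classes_b: dict[str, list[int]] = {}
    for i, e in enumerate(elements_a):
        classes_a.setdefault(_chemical_class(e), []).append(i)
    for j, e in enumerate(elements_b):
        classes_b.setdefault(_chemical_class(e), []).append(j)

    pairs: list[tuple[int, int]] = []
    for cls in sorted(set(classes_a) & set(classes_b)):
        ia = classes_a[cls]
        jb = classes_b[cls]
        dmat = np.linalg.norm(ca[ia][:, None, :] - cb[jb][None, :, :], axis=2)
        used_a: set[int] = set()
        used_b: set[int] = set()
        flat = [
            (dmat[r, c], ia[r], jb[c])
            for r in range(len(ia))
            for c in range(len(jb))
        ]
        flat.sort()
        for _, i, j in flat:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
    if len(pairs) < 3:
        raise DegenerateGeometryError(
            f"only {len(pairs)} chemically compatible pairs; need >= 3"
        )
    pairs.sort()
    return Correspondence(pairs=pairs, method="greedy_chemical_class")


def superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    corr: Correspondence,
) -> AlignmentResult:
    """Optimal least-squares rigid superposition of B onto A.

    Kabsch algorithm: SVD of the paired covariance with the reflection
    corrected so the returned rotation has determinant +1.  The returned
    motion maps B coordinates into A's frame; cRMSD is the RMS of the
    paired residuals after the motion.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ia = np.array([p[0] for p in corr.pairs])
    ib = np.array([p[1] for p in corr.pairs])
    pa = a[ia]
    pb = b[ib]
    # collinear paired points leave the rotation about the common axis free
    for pts, side in ((pa, "A"), (pb, "B")):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise DegenerateGeometryError(
                f"paired points on side {side} are collinear; superposition is degenerate"
            )
    mu_a = pa.mean(axis=0)
    mu_b = pb.mean(axis=0)
    h = (pb - mu_b).T @ (pa - mu_a)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = mu_a - rotation @ mu_b
    residuals = pa - (pb @ rotation.T + translation)
    crmsd = float(np.sqrt((residuals**2).sum(axis=1).mean()))
    return AlignmentResult(rotation=rotation, translation=translation, crmsd=crmsd)


def orientation_vectors(
    structure: ProteinStructure,
    residue_keys: Sequence[tuple[str, int]],
) -> tuple[list[np.ndarray], list[tuple[str, int]]]:
    """Unit CA -> side-chain-heavy-atom-centroid vectors per residue.

    Glycine has no side chain and is skipped; residues missing a CA or all
    side-chain heavy atoms are skipped too.  Returns (vectors, skipped_keys)
    so callers can report the omission count.
    """
    groups = structure.residues()
    vectors: list[np.ndarray] = []
    skipped: list[tuple[str, int]] = []
    for key in residue_keys:
        atoms = groups.get(tuple(key))
        if not atoms:
            skipped.append(tuple(key))
            continue
        resname = atoms[0].residue_name.strip().upper()
        ca = next((a for a in atoms if a.atom_name.strip() == "CA"), None)
        side = [
            a
            for a in atoms
            if a.atom_name.strip() not in BACKBONE_ATOMS and a.element.upper() != "H"
        ]
        if resname == "GLY" or ca is None or not side:
            skipped.append(tuple(key))
            continue
        centroid = np.mean([[a.x, a.y, a.z] for a in side], axis=0)
        vec = centroid - ca.coords
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            skipped.append(tuple(key))
            continue
        vectors.append(vec / norm)
    return vectors, skipped


def ormsd(
    rotation: np.ndarray,
    vecs_a: Sequence[np.ndarray],
    vecs_b: Sequence[np.ndarray],
) -> float:
    """sqrt(mean |R u_i - v_i|^2) over paired unit vectors; range [0, 2]."""
    if len(vecs_a) != len(vecs_b):
        raise ValidationError(
            f"orientation vector counts differ: {len(vecs_a)} vs {len(vecs_b)}"
        )
    if len(vecs_a) == 0:
        raise ValidationError("need at least one orientation vector pair")
    ua = np.asarray(vecs_a, float) @ np.asarray(rotation, float).T
    vb = np.asarray(vecs_b, float)
    return float(np.sqrt(((ua - vb) ** 2).sum(axis=1).mean()))


def _default_score(
    coords_a: np.ndarray,
    elements_a: Sequence[str],
    coords_b: np.ndarray,
    elements_b: Sequence[str],
) -> float:
    corr = greedy_correspondence(coords_a, elements_a, coords_b, elements_b)
    return superpose(coords_a, coords_b, corr).crmsd


def mc_significance(
    coords_a: np.ndarray,
    elements_a: Sequence[str],
    coords_b: np.ndarray,
    elements_b: Sequence[str],
    n_null: int = 99,
    seed: int = 0,
    score_fn: Callable[..., float] | None = None,
) -> float:
    """Empirical p-value of the observed alignment score.

    The null draws are uniform random rotations (quaternion sampling) of
    B's coordinates about its centroid; the correspondence is re-derived
    for every draw and each null alignment is scored identically to the
    observed one (default score: cRMSD after greedy correspondence; lower
    is better).  p = (1 + #{null <= observed}) / (1 + n_null), so the best
    attainable p is 1/(1 + n_null).  Deterministic for a fixed seed.
    """
    if n_null < 19:
        raise ValidationError(f"n_null must be >= 19, got {n_null}")
    score = score_fn or _default_score
    observed = score(coords_a, elements_a, coords_b, elements_b)
    rng = np.random.default_rng(seed)
    b = np.asarray(coords_b, float)
    centroid = b.mean(axis=0)
    hits = 0
    for _ in range(n_null):
        rot = Rotation.random(rng=rng).as_matrix()
        b_rot = (b - centroid) @ rot.T + centroid
        if score(coords_a, elements_a, b_rot, elements_b) <= observed:
            hits += 1
    return (1 + hits) / (1 + n_null)


def gsvot(
    centers_a: np.ndarray,
    centers_b: np.ndarray,
    alignment: AlignmentResult,
    spacing: float,
    origin: np.ndarray | None = None,
) -> float:
    """Volume-overlap Tanimoto of two pocket voxel sets after alignment.

    B's voxel centers are mapped through the alignment and re-rasterized
    onto A's grid (nearest voxel); the score is |A & B'| / |A | B'|.
    """
    a = np.asarray(centers_a, float)
    b = np.asarray(centers_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("gsvot needs non-empty voxel sets")
    if origin is None:
        origin = a.min(axis=0)
    b_mapped = alignment.transform(b)
    ia = np.round((a - origin) / spacing).astype(np.int64)
    ib = np.round((b_mapped - origin) / spacing).astype(np.int64)
    set_a = {tuple(v) for v in ia}
    set_b = {tuple(v) for v in ib}
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return inter / union


def surfacescreen_score(
    ks: KSResult | float,
    p_align: float,
    gsvot_score: float,
) -> float:
    """Composite similarity: geometric mean of (1-D), (1-p_align), gSVOT.

    Each component is clamped to [1e-6, 1], so the composite is monotone
    non-decreasing in every similarity component and lives in (0, 1].
    """
    d = ks.d_statistic if isinstance(ks, KSResult) else float(ks)
    for name, value in (("D", d), ("p_align", p_align), ("gsvot", gsvot_score)):
        if value is None or not np.isfinite(value):
            raise ValidationError(f"composite component {name} is missing")
    parts = np.clip(
        [1.0 - d, 1.0 - p_align, gsvot_score], COMPOSITE_EPS, 1.0
    )
    return float(np.exp(np.log(parts).mean()))
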