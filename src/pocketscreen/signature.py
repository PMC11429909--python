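"""Shape signatures: pocket distance distributions and their KS comparison.

A pocket's shape signature is the multiset of all pairwise Euclidean
distances between its lining atoms.  The multiset is invariant to rigid
motions of the pocket but sensitive to uniform scaling, so it discriminates
by size as well as shape.  Two signatures are compared by the two-sample
Kolmogorov-Smirnov statistic on the raw multisets (histograms are for
presentation only), with the p-value from the asymptotic Kolmogorov
distribution at effective sample size n1*n2/(n1+n2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import kstwobign

from .errors import ValidationError

__all__ = [
    "ShapeSignature",
    "KSResult",
    "compute_signature",
    "signature_from_coords",
    "ks_compare",
    "library_search",
    "save_signature",
    "load_signature",
    "load_library",
]

#: D below this value flags a library hit as a similarity candidate; the
#: threshold is a package default, not a measured constant.
DEFAULT_SIMILARITY_THRESHOLD = 0.25

HISTOGRAM_BIN_WIDTH = 0.5  # A


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int


@dataclass
class ShapeSignature:
    """Distance distribution of a pocket's lining atoms."""

    source_id: str
    distances: np.ndarray  # sorted ascending

    def __post_init__(self) -> None:
        d = np.sort(np.asarray(self.distances, dtype=float))
        if d.size == 0:
            raise ValidationError("a shape signature needs at least one distance")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValidationError("distances must be finite and non-negative")
        self.distances = d

    def __len__(self) -> int:
        return len(self.distances)

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, normalized masses) with fixed 0.5 A bins.

        Presentation artifact only; comparisons always use the raw multiset.
        """
        top = float(self.distances.max()) + HISTOGRAM_BIN_WIDTH
        edges = np.arange(0.0, top + HISTOGRAM_BIN_WIDTH, HISTOGRAM_BIN_WIDTH)
        masses, _ = np.histogram(self.distances, bins=edges)
        return edges, masses / masses.sum()


def signature_from_coords(coords: np.ndarray, source_id: str = "") -> ShapeSignature:
    """Signature from an (n, 3) coordinate array (n >= 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValidationError(
            f"need at least 3 points with 3 coordinates, got shape {coords.shape}"
        )
    return ShapeSignature(source_id=source_id, distances=pdist(coords))


def compute_signature(pocket) -> ShapeSignature:
    """Signature of a detected pocket's lining atoms."""
    coords = pocket.lining_coords()
    if len(coords) < 3:
        raise ValidationError(
            f"pocket {pocket.id} has {len(coords)} lining atoms; need >= 3"
        )
    return signature_from_coords(coords, source_id=f"pocket-{pocket.id}")


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """Exact sup |ECDF_a - ECDF_b| for sorted samples."""
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_compare(a: ShapeSignature, b: ShapeSignature) -> KSResult:
    """Two-sample KS comparison of raw distance multisets.

    The p-value uses the asymptotic Kolmogorov distribution and is
    approximate for effective sample sizes below ~35.
    """
    d = _ks_d(a.distances, b.distances)
    n1, n2 = len(a), len(b)
    n_eff = n1 * n2 / (n1 + n2)
    p = float(np.clip(kstwobign.sf(d * np.sqrt(n_eff)), np.finfo(float).tiny, 1.0))
    return KSResult(d_statistic=d, p_value=p, n1=n1, n2=n2)


def library_search(
    query: ShapeSignature,
    library: list[ShapeSignature],
    k: int = 10,
    *,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> list[tuple[str, KSResult, bool]]:
    """Rank a signature library against a query.

    Returns up to ``k`` tuples ``(source_id, KSResult, is_candidate)``
    ordered by ascending D, ties by descending p then lexicographic id.
    ``is_candidate`` marks hits with D below ``similarity_threshold``.
    """
    if not library:
        raise ValidationError("library is empty")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(library):
        warnings.warn(
            f"k={k} larger than library size {len(library)}; returning full ranking",
            stacklevel=2,
        )
        k = len(library)
    scored = [(member.source_id, ks_compare(query, member)) for member in library]
    scored.sort(key=lambda item: (item[1].d_statistic, -item[1].p_value, item[0]))
    return [
        (sid, res, res.d_statistic < similarity_threshold)
        for sid, res in scored[:k]
    ]


def save_signature(sig: ShapeSignature, path: str | Path) -> None:
    payload = {"source_id": sig.source_id, "distances": sig.distances.tolist()}
    Path(path).write_text(json.dumps(payload) + "\n")


def load_signature(path: str | Path) -> ShapeSignature:
    payload = json.loads(Path(path).read_text())
    return ShapeSignature(
        source_id=payload["source_id"],
        distances=np.asarray(payload["distances"], dtype=float),
    )


def load_library(directory: str | Path) -> list[ShapeSignature]:
    """Load every ``*.json`` signature in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.json"))
    if not paths:
        raise ValidationError(f"no signature files found in {directory}")
    return [load_signature(p) for p in paths]
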