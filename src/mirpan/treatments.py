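"""Treatment-string encoding: canonical bag-of-strings, edit distance,
near-duplicate merging, and 3D Cox scaling.

Free-text treatment items are rendered into a canonical string — each
(general treatment, specific method) pair becomes ``"general, specific;"``,
lowercased and whitespace-normalized, with the rendered items sorted
alphabetically and concatenated (bag semantics: input order never matters).
Character-level Levenshtein distance between canonical strings defines a
metric on treatments.  Treatments connected by chains of pairs at distance
strictly below a threshold (default 25) are merged by single linkage, and
every merged cluster is embedded at a 3D coordinate so that Euclidean
distances between coordinates track the edit distances.

Two embeddings are provided.  ``classical`` (the default) is classical
multidimensional scaling a la Torgerson — double-center -D²/2, take the top
three nonnegative eigenpairs — the procedure behind R's ``cmdscale`` and
what "Cox scaling" refers to.  ``stress`` minimizes the squared stress
Σ_{i≠j}(ldist(i,j) − ‖P_i−P_j‖)² by SMACOF majorization starting from the
classical solution.  Coordinates are fixed to a canonical orientation
(axes ordered by eigenvalue, each axis's largest-magnitude coordinate made
positive) so serialized catalogs are reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TreatmentCatalog",
    "canonicalize",
    "levenshtein",
    "merge_treatments",
    "cox_scale",
    "build_catalog",
]

_WS = re.compile(r"\s+")


def canonicalize(items: list[tuple[str, str]]) -> str:
    """Render treatment items into the canonical bag-of-strings form."""
    if not items:
        raise ValueError("treatment must contain at least one item")
    rendered = []
    for general, specific in items:
        g = _WS.sub(" ", str(general).strip().lower())
        s = _WS.sub(" ", str(specific).strip().lower())
        if not g or not s:
            raise ValueError(f"empty treatment item after trimming: {(general, specific)!r}")
        rendered.append(f"{g}, {s};")
    return "".join(sorted(rendered))


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character edits transforming a into b.

    Standard dynamic program over insertions, deletions and substitutions;
    O(len(a) * len(b)).
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def distance_matrix(strings: list[str]) -> np.ndarray:
    """Symmetric pairwise Levenshtein distances."""
    n = len(strings)
    D = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = levenshtein(strings[i], strings[j])
    return D


@dataclass
class TreatmentCatalog:
    """Canonical treatments, their distances, merged clusters, coordinates."""

    raw_items: dict[str, list[tuple[str, str]]]
    canonical: dict[str, str]
    distance: pd.DataFrame  # treatment id x treatment id
    clusters: dict[str, int] = field(default_factory=dict)  # treatment id -> cluster
    representative: dict[int, str] = field(default_factory=dict)  # cluster -> treatment id
    coordinates: dict[int, np.ndarray] = field(default_factory=dict)  # cluster -> 3-vector

    @property
    def treatment_ids(self) -> list[str]:
        return list(self.canonical)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.representative)

    def cluster_of(self, treatment_id: str) -> int:
        return self.clusters[treatment_id]

    def coordinates_of(self, treatment_id: str) -> np.ndarray:
        cluster = self.clusters[treatment_id]
        if cluster not in self.coordinates:
            raise KeyError(f"cluster {cluster} has no coordinates; run cox_scale first")
        return self.coordinates[cluster]

    def to_json(self) -> dict:
        return {
            "canonical": dict(self.canonical),
            "clusters": {k: int(v) for k, v in self.clusters.items()},
            "representative": {str(k): v for k, v in self.representative.items()},
            "coordinates": {str(k): [float(x) for x in v] for k, v in self.coordinates.items()},
        }


def merge_treatments(
    catalog: TreatmentCatalog,
    threshold: int = 25,
    counts: dict[str, int] | None = None,
) -> TreatmentCatalog:
    """Single-linkage merge of treatments at edit distance < threshold.

    Two treatments share a cluster iff they are connected by a chain of
    pairs each at distance strictly below the threshold.  The cluster
    representative is its most frequent member (``counts``, default 1
    each); ties go to the lexicographically smallest canonical string.
    Cluster ids are assigned in order of their representative's canonical
    string.
    """
    ids = catalog.treatment_ids
    D = catalog.distance.loc[ids, ids].to_numpy()
    adjacency = csr_matrix(D < threshold)
    n_comp, membership = connected_components(adjacency, directed=False)
    counts = counts or {}
    reps = {}
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(membership == comp)]
        members.sort(key=lambda t: (-counts.get(t, 1), catalog.canonical[t]))
        reps[comp] = members[0]
    # stable cluster numbering by representative canonical string
    order = sorted(range(n_comp), key=lambda c: catalog.canonical[reps[c]])
    renumber = {old: new for new, old in enumerate(order)}
    catalog.clusters = {tid: renumber[membership[i]] for i, tid in enumerate(ids)}
    catalog.representative = {renumber[c]: reps[c] for c in reps}
    return catalog


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    # sign convention: each axis's largest-magnitude coordinate is positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def classical_scaling(D: np.ndarray, dim: int = 3) -> tuple[np.ndarray, np.ndarray, int]:
    """Torgerson double-centering embedding of a distance matrix.

    Returns (coordinates, eigenvalues used, number of nonnegative
    eigenvalues among the top ``dim``).  Axes with no nonnegative
    eigenvalue left are zero-padded.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dim]
    vals = eigval[order]
    coords = np.zeros((n, dim))
    n_usable = 0
    for k, (lam, idx) in enumerate(zip(vals, order)):
        if lam > 0:
            coords[:, k] = eigvec[:, idx] * np.sqrt(lam)
            n_usable += 1
    return _canonical_orientation(coords), vals, n_usable


def stress_value(D: np.ndarray, coords: np.ndarray) -> float:
    """Squared stress Σ_{i<j} (D_ij - ||P_i - P_j||)²."""
    diff = coords[:, None, :] - coords[None, :, :]
    emb = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(D.shape[0], k=1)
    return float(((D[iu] - emb[iu]) ** 2).sum())


def smacof_refine(
    D: np.ndarray,
    init: np.ndarray,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, list[float]]:
    """Majorization (Guttman transform) descent on the squared stress.

    Stress is non-increasing across iterations by construction; iteration
    stops when the relative stress change drops below ``rtol``.  Returns
    the refined coordinates and the per-iteration stress trajectory
    (including the initial configuration's stress).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    X = init.copy()
    trajectory = [stress_value(D, X)]
    for _ in range(max_iter):
        diff = X[:, None, :] - X[None, :, :]
        emb = np.sqrt((diff**2).sum(axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(emb > 0, D / np.where(emb > 0, emb, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        s = stress_value(D, X)
        trajectory.append(s)
        prev = trajectory[-2]
        if prev > 0 and (prev - s) / prev < rtol:
            break
        if prev == 0:
            break
    return X, trajectory


def cox_scale(
    D: np.ndarray | pd.DataFrame,
    dim: int = 3,
    mode: str = "classical",
) -> tuple[np.ndarray, dict]:
    """Embed a distance matrix into ``dim`` coordinates.

    ``classical`` reproduces the cmdscale-style eigendecomposition;
    ``stress`` additionally refines it by SMACOF majorization of the
    squared stress.  Returns (coordinates, info) where info carries the
    eigenvalues, the count of usable (nonnegative) eigenvalues, the final
    stress, and — in stress mode — the per-iteration stress trajectory.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if mode not in ("classical", "stress"):
        raise ValueError("mode must be 'classical' or 'stress'")
    coords, eigvals, n_usable = classical_scaling(D, dim=dim)
    info: dict = {
        "eigenvalues": eigvals,
        "n_nonnegative": n_usable,
        "padded_axes": dim - n_usable,
    }
    if mode == "stress":
        coords, trajectory = smacof_refine(D, coords)
        coords = _canonical_orientation(coords)
        info["stress_trajectory"] = trajectory
    info["stress"] = stress_value(D, coords)
    return coords, info


def build_catalog(
    raw_items: dict[str, list[tuple[str, str]]],
    merge_threshold: int = 25,
    counts: dict[str, int] | None = None,
    mode: str = "classical",
) -> TreatmentCatalog:
    """Canonicalize, measure, merge and embed a set of treatments.

    The embedding is computed on the merged clusters' representative
    canonical strings (one point per unique treatment after merging).
    """
    canonical = {tid: canonicalize(items) for tid, items in raw_items.items()}
    ids = list(canonical)
    D = distance_matrix([canonical[t] for t in ids])
    catalog = TreatmentCatalog(
        raw_items=dict(raw_items),
        canonical=canonical,
        distance=pd.DataFrame(D, index=ids, columns=ids),
    )
    merge_treatments(catalog, threshold=merge_threshold, counts=counts)
    cluster_ids = catalog.cluster_ids
    rep_strings = [canonical[catalog.representative[c]] for c in cluster_ids]
    D_clusters = distance_matrix(rep_strings)
    coords, _ = cox_scale(D_clusters, dim=3, mode=mode)
    catalog.coordinates = {c: coords[i] for i, c in enumerate(cluster_ids)}
    return catalog
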