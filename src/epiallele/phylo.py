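"""Epigenetic disorder and phylogenetic reconstruction across samples.

Per-locus disorder is the normalised Shannon entropy of the epiallele
distribution, -(1/d) * sum_q phi_q log2 phi_q: bits of epiallele
diversity per CpG, so loci of different sizes are comparable. For the
tree, each locus contributes a pairwise Euclidean distance matrix
between the samples' (decontaminated) epiallele distributions; these are
averaged entrywise across loci and fed to a distance-based tree builder
— balanced minimum evolution with nearest-neighbour-interchange local
search (the FastME approach) by default, neighbor joining as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import bme as _bme, nj as _nj, nni as _nni

from .profiles import EpialleleProfile


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with per-pair locus counts."""

    sample_ids: list[str]
    values: np.ndarray
    n_loci_averaged: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if not np.allclose(v, v.T) or np.abs(np.diag(v)).max() > 1e-12 or v.min() < 0:
            raise ValueError("distance matrix must be symmetric, non-negative, "
                             "with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def epiallele_entropy(phi: np.ndarray, d: int) -> float:
    """Normalised Shannon entropy of an epiallele distribution.

    Returns -(1/d) sum_q phi_q log2 phi_q with 0*log(0) = 0; zero for a
    single-epiallele locus, at most log2(Q)/d.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    phi = np.asarray(phi, dtype=np.float64)
    nz = phi[phi > 0]
    return float(-(nz * np.log2(nz)).sum() / d)


def locus_distance(t_a: np.ndarray, t_b: np.ndarray) -> float:
    """Euclidean distance between two profiles on the same epiallele basis."""
    t_a = np.asarray(t_a, dtype=np.float64)
    t_b = np.asarray(t_b, dtype=np.float64)
    if t_a.shape != t_b.shape:
        raise ValueError("profiles live on different epiallele bases")
    return float(np.linalg.norm(t_a - t_b))


def per_locus_distance_matrices(
    profiles_by_locus: dict[str, dict[str, EpialleleProfile]],
) -> list[DistanceMatrix]:
    """One distance matrix per locus over the samples profiled there."""
    out = []
    for locus_id in sorted(profiles_by_locus):
        per_sample = profiles_by_locus[locus_id]
        ids = sorted(per_sample)
        if len(ids) < 2:
            continue
        k = len(ids)
        values = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                dist = locus_distance(per_sample[ids[a]].phi, per_sample[ids[b]].phi)
                values[a, b] = values[b, a] = dist
        out.append(DistanceMatrix(ids, values, np.ones((k, k), dtype=np.int64)))
    return out


def average_distance_matrix(per_locus: list[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise mean of per-locus distance matrices.

    Each sample pair is averaged over the loci at which both samples
    have a profile; a pair never observed together is an error.
    """
    if not per_locus:
        raise ValueError("no per-locus distance matrices supplied")
    ids = sorted({s for dm in per_locus for s in dm.sample_ids})
    k = len(ids)
    index = {s: i for i, s in enumerate(ids)}
    total = np.zeros((k, k))
    count = np.zeros((k, k), dtype=np.int64)
    for dm in per_locus:
        pos = [index[s] for s in dm.sample_ids]
        for a in range(len(pos)):
            for b in range(len(pos)):
                if a != b:
                    total[pos[a], pos[b]] += dm.values[a, b]
                    count[pos[a], pos[b]] += 1
    off = ~np.eye(k, dtype=bool)
    if (count[off] == 0).any():
        a, b = np.argwhere(off & (count == 0))[0]
        raise ValueError(
            f"samples {ids[a]!r} and {ids[b]!r} share no locus; "
            "cannot average a distance for this pair"
        )
    values = np.zeros((k, k))
    values[off] = total[off] / count[off]
    np.fill_diagonal(count, 0)
    return DistanceMatrix(ids, values, count)


def build_tree(dist: DistanceMatrix, method: str = "bme") -> str:
    """Build an unrooted tree from the averaged distances; returns Newick.

    ``bme`` (default) is balanced minimum evolution refined by balanced
    nearest-neighbour interchanges; ``nj`` is classical neighbor joining.
    Negative branch lengths are clamped to zero.
    """
    if len(dist.sample_ids) < 3:
        raise ValueError("tree construction requires at least 3 samples")
    dm = _SkbioDM(dist.values, ids=dist.sample_ids)
    if method == "bme":
        tree = _bme(dm, neg_as_zero=True)
        tree = _nni(tree, dm, balanced=True, neg_as_zero=True)
    elif method == "nj":
        tree = _nj(dm, neg_as_zero=True)
    else:
        raise ValueError(f"unknown tree method {method!r} (expected 'bme' or 'nj')")
    return str(tree).strip()


def tree_path_distances(newick: str, ids: list[str]) -> np.ndarray:
    """Patristic (path-length) distances between leaves of a Newick tree."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    dm = tree.cophenet()
    return np.asarray([[dm[a, b] for b in ids] for a in ids])


def entropy_table(
    profiles_by_locus: dict[str, dict[str, EpialleleProfile]],
    d_by_locus: dict[str, int],
) -> pd.DataFrame:
    """Per-locus, per-sample normalised epiallele entropies."""
    rows = []
    for locus_id in sorted(profiles_by_locus):
        d = d_by_locus[locus_id]
        for sample_id in sorted(profiles_by_locus[locus_id]):
            phi = profiles_by_locus[locus_id][sample_id].phi
            rows.append({
                "locus_id": locus_id,
                "sample_id": sample_id,
                "d": d,
                "entropy": epiallele_entropy(phi, d),
            })
    return pd.DataFrame(rows)
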