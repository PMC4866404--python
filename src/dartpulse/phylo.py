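"""Phylogenetic signal: Blomberg's K with randomization p-values.

The cross-reactivity responses are species-level traits; whether
closely-related species evoke similar responses is asked with Blomberg's K
on a rooted tree with branch lengths.  K compares the observed ratio of the
trait's raw mean-squared error to its phylogenetically corrected (GLS)
mean-squared error against the value of that ratio expected under Brownian
motion on the same tree:

    a_hat = (1' V^-1 1)^-1 1' V^-1 x
    MSE0  = (x - a_hat)' (x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' V^-1 (x - a_hat) / (n - 1)
    K     = (MSE0 / MSE) / [ (tr(V) - n / (1' V^-1 1)) / (n - 1) ]

where V[i, j] is the shared root-to-MRCA path length of tips i and j.
K = 1 matches Brownian resemblance among relatives, K < 1 weaker, K > 1
stronger; K is invariant to affine transforms of the trait and to rescaling
the tree.  Significance is assessed by shuffling trait values across tips
(the observed arrangement counted in numerator and denominator, so
p >= 1/(n_rand + 1)).

Tree I/O is delegated to dendropy (newick in and out).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

__all__ = [
    "read_newick",
    "write_newick",
    "vcv",
    "blomberg_k",
    "k_randomization_p",
    "KResult",
]


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths.

    Raises ``ValueError`` for malformed newick, unlabeled or duplicate tips,
    or negative branch lengths.
    """
    try:
        # underscores are literal label characters here, not spaces
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None or lab == "" for lab in labels):
        raise ValueError("tree has unlabeled tips")
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Canonical single-line newick string (with branch lengths)."""
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and Brownian covariance structure of a tree.

    ``V[i, j]`` is the path length from the root to the most recent common
    ancestor of tips i and j; ``V[i, i]`` is the root-to-tip distance.
    Computed from root depths and patristic distances:
    ``V[i, j] = (depth_i + depth_j - d(i, j)) / 2``.
    """
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    depth = np.array([leaf.root_distance for leaf in leaves], dtype=float)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(
                leaves[i].taxon, leaves[j].taxon
            )
    V = (depth[:, None] + depth[None, :] - dist) / 2.0
    return labels, V


def _trait_vector(labels: list[str], traits: Mapping[str, float]) -> np.ndarray:
    missing = [lab for lab in labels if lab not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing}")
    extra = set(traits) - set(labels)
    if extra:
        raise ValueError(f"traits given for unknown tips: {sorted(extra)}")
    x = np.array([float(traits[lab]) for lab in labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("traits must be finite")
    return x


def _regularized_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """vcv with zero-length terminal branches perturbed to keep V invertible.

    Tips at depth equal to their parent's depth make V singular; such
    diagonal entries are nudged up by 1e-8 of the tree height.
    """
    labels, V = vcv(tree)
    height = float(np.max(np.diag(V)))
    if height <= 0:
        raise ValueError("tree has zero total depth")
    eps = 1e-8 * height
    diag = np.diag(V).copy()
    off_max = np.where(np.eye(len(labels), dtype=bool), -np.inf, V).max(axis=1)
    bump = diag <= off_max + 0.0
    if bump.any():
        V = V + np.diag(np.where(bump, eps, 0.0))
    return labels, V


def _k_stat(V: np.ndarray, x: np.ndarray) -> float:
    return float(_k_stat_many(V, x[:, None])[0])


def _k_stat_many(V: np.ndarray, X: np.ndarray) -> np.ndarray:
    """K for each column of X on the tree with covariance V."""
    n = V.shape[0]
    if n < 3:
        raise ValueError("need at least 3 tips")
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    w = Vinv @ one
    s = one @ w  # 1' V^-1 1
    a_hat = (w @ X) / s  # per-column GLS root estimate
    R = X - a_hat[None, :]
    mse0 = np.einsum("ij,ij->j", R, R)
    mse = np.einsum("ij,ij->j", R, Vinv @ R)
    if np.any(mse <= 0):
        raise ValueError("constant trait vector: K undefined")
    # (n-1) cancels between mse0 and mse but not in the expected ratio
    expected = (np.trace(V) - n / s) / (n - 1)
    if expected <= 0:
        raise ValueError("degenerate tree: expected MSE ratio non-positive")
    return (mse0 / mse) / expected


def blomberg_k(tree: dendropy.Tree, traits: Mapping[str, float]) -> float:
    """Blomberg's K of a tip-keyed trait on a rooted tree.

    Requires n >= 3 tips, an invertible V (zero-length tip branches are
    perturbed by a documented epsilon) and a non-constant trait.
    """
    labels, V = _regularized_vcv(tree)
    x = _trait_vector(labels, traits)
    return _k_stat(V, x)


@dataclass(frozen=True)
class KResult:
    """Blomberg's K with its randomization p-value."""

    k: float
    p: float
    n_rand: int
    seed: int | None


def k_randomization_p(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    n_rand: int = 1000,
    seed: int | None = None,
) -> KResult:
    """Randomization p-value for Blomberg's K.

    ``p`` is the proportion, among ``n_rand`` tip-label permutations plus the
    observed arrangement, of K values at least as large as the observed K.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    labels, V = _regularized_vcv(tree)
    x = _trait_vector(labels, traits)
    k_obs = _k_stat(V, x)
    rng = np.random.default_rng(seed)
    perms = np.empty((len(x), n_rand))
    for b in range(n_rand):
        perms[:, b] = rng.permutation(x)
    k_null = _k_stat_many(V, perms)
    p = (1 + int(np.sum(k_null >= k_obs))) / (n_rand + 1)
    return KResult(k=k_obs, p=p, n_rand=n_rand, seed=seed)
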