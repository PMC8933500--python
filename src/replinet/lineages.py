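"""Lineage structure of consensus genotypes.

Genotypes (presence/absence vectors over the dominant-mutation panel) are
compared by Hamming distance, embedded for visualization by classical
scaling (PCoA), grouped into lineages by single-linkage threshold
components on the raw distances, and related by a neighbor-joining
phylogeny. Per-round lineage frequencies are the renormalized sums of
member-genotype frequencies.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "PCoAResult",
    "LineageAssignment",
    "NJResult",
    "hamming_matrix",
    "pcoa_embed",
    "cluster_lineages",
    "nj_tree",
    "lineage_frequencies",
]


def hamming_matrix(genotypes) -> DistanceMatrix:
    """Pairwise Hamming distances (count of differing panel positions).

    Accepts a :class:`~replinet.genotyping.GenotypeTable`, a DataFrame of
    0/1 presence vectors (rows = genotypes), or a plain array with ids.
    """
    if hasattr(genotypes, "presence_frame"):
        frame = genotypes.presence_frame()
        ids, mat = list(frame.index), frame.to_numpy()
    elif isinstance(genotypes, pd.DataFrame):
        ids, mat = list(genotypes.index.astype(str)), genotypes.to_numpy()
    else:
        mat = np.asarray(genotypes)
        ids = [f"G{i:04d}" for i in range(mat.shape[0])]
    if mat.ndim != 2:
        raise ValueError("presence data must be 2-D (genotypes x panel)")
    mat = mat.astype(bool)
    dist = (mat[:, None, :] ^ mat[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(dist, ids=ids)


@dataclass(frozen=True)
class PCoAResult:
    """Classical-scaling embedding with its full eigenvalue spectrum.

    Negative eigenvalues (possible when distances are not exactly
    Euclidean-embeddable) are reported in ``negative_eigenvalues`` rather
    than silently dropped; their axes contribute zero coordinates.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa_embed(dm: DistanceMatrix, dims: int = 2) -> PCoAResult:
    """Principal Coordinate Analysis (Torgerson classical scaling).

    Eigendecomposition of the double-centered squared-distance matrix;
    the top ``dims`` axes are returned. Axis orientation is fixed by making
    the largest-magnitude loading on each axis positive, so embeddings are
    identical run to run.
    """
    d = dm.data
    n = d.shape[0]
    if dims < 1:
        raise ValueError("dims must be >= 1")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    negative = eigvals[eigvals < -1e-9 * max(1.0, abs(eigvals[0]))]
    coords = np.zeros((n, dims))
    for axis in range(min(dims, n)):
        lam = eigvals[axis]
        if lam > 0:
            vec = eigvecs[:, axis] * np.sqrt(lam)
            i = np.argmax(np.abs(vec))
            if vec[i] < 0:
                vec = -vec
            coords[:, axis] = vec
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"axis{i+1}" for i in range(dims)]
    )
    return PCoAResult(coordinates=frame, eigenvalues=eigvals, negative_eigenvalues=negative)


@dataclass(frozen=True)
class LineageAssignment:
    """Total partition of genotypes into non-empty lineages."""

    mapping: Mapping[str, str]
    labels: tuple[str, ...]

    def members(self, label: str) -> list[str]:
        return [g for g, lab in self.mapping.items() if lab == label]


def cluster_lineages(
    dm: DistanceMatrix,
    cutoff: float,
    first_rounds: Mapping[str, int] | None = None,
    prefix: str = "L",
) -> LineageAssignment:
    """Single-linkage threshold clustering into lineages.

    Two genotypes belong to the same lineage iff they are connected through
    pairs at Hamming distance <= ``cutoff`` (connected components of the
    threshold graph). Lineage labels are ordered by the earliest round of
    appearance of any member (``first_rounds``), falling back to input
    order, and numbered ``{prefix}1``, ``{prefix}2``, ...
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    adj = csr_matrix(dm.data <= cutoff)
    n_comp, comp = connected_components(adj, directed=False)
    ids = list(dm.ids)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        groups.setdefault(int(c), []).append(i)

    def sort_key(component: int) -> tuple:
        members = groups[component]
        if first_rounds is not None:
            earliest = min(first_rounds.get(ids[i], np.inf) for i in members)
        else:
            earliest = min(members)
        return (earliest, min(members))

    ordered = sorted(groups, key=sort_key)
    labels = tuple(f"{prefix}{i+1}" for i in range(n_comp))
    mapping = {}
    for rank, component in enumerate(ordered):
        for i in groups[component]:
            mapping[ids[i]] = labels[rank]
    return LineageAssignment(mapping=mapping, labels=labels)


@dataclass(frozen=True)
class NJResult:
    """Neighbor-joining tree with its Newick serialization.

    ``clamped`` is the total branch length removed by clamping negative
    neighbor-joining estimates to zero (0 for additive inputs).
    """

    newick: str
    tree: TreeNode
    clamped: float


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(dm: DistanceMatrix) -> NJResult:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each agglomeration the pair minimizing the Q criterion is joined;
    ties pick the lexicographically smallest index pair. Negative branch
    length estimates are clamped to zero with the deficit accumulated in
    the result. The returned tree is unrooted (trifurcating root node) and
    path-length additive for additive input matrices.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [str(lab) for lab in labels]
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = np.argmin(flat)  # first occurrence = smallest (i, j) pair
        i, jdx = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * d[i, jdx] + (r[i] - r[jdx]) / (2 * (m - 2))
        lj = d[i, jdx] - li
        li, lj = clamp(li), clamp(lj)
        new_node = f"({nodes[i]}:{_fmt(li)},{nodes[jdx]}:{_fmt(lj)})"
        du = 0.5 * (d[i, :] + d[jdx, :] - d[i, jdx])
        keep = [k for k in range(m) if k not in (i, jdx)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[-1, : m - 2] = du[keep]
        new_d[: m - 2, -1] = du[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [new_node]

    # terminal trifurcation: closed-form branch lengths
    la = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    newick = (
        f"({nodes[0]}:{_fmt(la)},{nodes[1]}:{_fmt(lb)},{nodes[2]}:{_fmt(lc)});"
    )
    tree = TreeNode.read(StringIO(newick))
    return NJResult(newick=newick, tree=tree, clamped=clamped)


def lineage_frequencies(
    genotype_table,
    assignment: LineageAssignment,
    presence_threshold: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-round lineage frequencies and presence flags.

    For each round, a lineage's frequency is the sum of its member
    genotypes' frequencies renormalized over all analyzed (assigned)
    genotypes, so rounds with any reads sum to 1. The presence flag marks
    lineages strictly above ``presence_threshold`` (default 0.1%).
    """
    unassigned = [g for g in genotype_table.ids if g not in assignment.mapping]
    if unassigned:
        raise ValueError(f"genotypes without lineage assignment: {unassigned}")
    rounds = list(genotype_table.rounds)
    freq = pd.DataFrame(0.0, index=list(assignment.labels), columns=rounds)
    for gid, genotype in zip(genotype_table.ids, genotype_table.genotypes):
        lab = assignment.mapping[gid]
        for rnd in rounds:
            freq.loc[lab, rnd] += genotype.frequencies.get(rnd, 0.0)
    totals = freq.sum(axis=0)
    for rnd in rounds:
        if totals[rnd] > 0:
            freq[rnd] /= totals[rnd]
        else:
            warnings.warn(f"no analyzed genotypes in round {rnd}", stacklevel=2)
    presence = freq > presence_threshold
    return freq, presence
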