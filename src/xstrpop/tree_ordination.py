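"""UPGMA clustering and classical (metric) principal coordinate analysis.

UPGMA joins the minimum-distance pair at height d/2 and updates distances
by the size-weighted arithmetic mean over the original members, producing a
rooted ultrametric tree.  Ties are broken by the lexicographically smallest
sorted label pair, so output is bit-stable across runs and label orders.

PCoA applies Gower double-centering to -d^2/2 and eigendecomposes;
coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
eigenvalues, and explained-variance percentages are taken over the positive
eigenvalues only (non-Euclidean input can produce negative ones, which are
reported but excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DistanceMatrix, TreeNode


def upgma(d: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree; deterministic under the documented tie rule."""
    n = d.n
    if n < 2:
        raise ValueError("UPGMA needs at least two labels")
    if (d.values < 0).any():
        raise ValueError("UPGMA requires nonnegative distances")

    # active clusters: id -> (node, size, min sorted leaf-label, ...)
    nodes = {i: TreeNode(name=d.labels[i], height=0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    tag = {i: d.labels[i] for i in range(n)}  # smallest leaf label, for tie-breaking
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (get(i, j), tuple(sorted((tag[i], tag[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dmin, _), i, j = best
        height = dmin / 2.0
        if tag[j] < tag[i]:
            i, j = j, i
        a, b = nodes[i], nodes[j]
        a.length = height - a.height
        b.length = height - b.height
        parent = TreeNode(children=[a, b], height=height)
        nodes[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        tag[next_id] = min(tag[i], tag[j])
        for k in active:
            if k in (i, j):
                continue
            dik, djk = get(i, k), get(j, k)
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dnew
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1

    root = nodes[next_id - 1]
    root.length = None
    return root


def total_branch_length(tree: TreeNode) -> float:
    """Sum of branch lengths over all non-root edges."""
    return sum(child.length or 0.0 for _, child in tree.edges())


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # labels x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # over positive eigenvalues, per positive axis
    negative_mass: float  # sum of |negative eigenvalues|
    degenerate: bool = False


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical multidimensional scaling of a labelled distance matrix."""
    dm = d.values
    b = -0.5 * dm ** 2
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12
    if not pos.any():
        return PcoaResult(list(d.labels), np.zeros((n, 0)), evals,
                          np.zeros(0), float(-evals[evals < 0].sum()), degenerate=True)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        pct = pct[:n_axes]
    return PcoaResult(list(d.labels), coords, evals, pct,
                      float(-evals[evals < 0].sum()))
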