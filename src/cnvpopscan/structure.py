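"""Population structure from the CNV genotype matrix.

The genotype matrix holds alt-allele dosages (0/1/2) with an explicit
missing mask. Two views of structure are provided:

* PCA of the sample covariance after per-variant mean imputation,
  centering, and (optionally) scaling by ``sqrt(p(1-p))`` with ``p`` the
  column allele frequency — the normalization used for genotype PCA in
  EIGENSOFT-style analyses. The solver is a deterministic dense
  eigendecomposition; coordinates are reproducible bit-for-bit.
* A neighbor-joining tree (Saitou-Nei) on the allele-sharing distance
  ``d(i,j) = mean(|dosage_i - dosage_j|) / 2`` over jointly called
  variants, emitted as an unrooted Newick tree with branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CohortCallset, Genotype

__all__ = [
    "DosageMatrix",
    "PCAResult",
    "build_dosage",
    "pca",
    "distance_matrix",
    "nj_tree",
]


@dataclass
class DosageMatrix:
    """samples x variants dosage grid; missing entries are masked."""

    values: np.ndarray  # float array, samples x variants
    mask: np.ndarray    # True where missing
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("shape inconsistent with id lists")


@dataclass
class PCAResult:
    coordinates: np.ndarray          # samples x components
    explained_fraction: np.ndarray   # per component, sums to <= 1
    sample_ids: list[str] = field(default_factory=list)


def build_dosage(callset: CohortCallset) -> DosageMatrix:
    """hom_ref→0, het→1, hom_alt→2; missing entries masked, never 0."""
    callset.validate()
    n, m = len(callset.samples), len(callset.records)
    values = np.zeros((n, m), dtype=float)
    mask = np.zeros((n, m), dtype=bool)
    for j, rec in enumerate(callset.records):
        g = rec.genotypes
        miss = g == Genotype.MISSING
        values[:, j] = np.where(miss, 0.0, g)
        mask[:, j] = miss
    return DosageMatrix(values, mask, list(callset.samples), [r.record_id for r in callset.records])


def pca(matrix: DosageMatrix, scale: bool = True, n_components: int | None = None) -> PCAResult:
    """Genotype PCA with mean imputation and allele-frequency scaling.

    Missing dosages are imputed with the per-variant mean of called
    samples; columns are centered and, if ``scale``, divided by
    ``sqrt(p(1-p))`` with ``p = column mean / 2``. Monomorphic columns
    carry no variance and are dropped. Eigendecomposition of the sample
    covariance; explained fractions are eigenvalues over their sum.
    """
    n, m = matrix.values.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix.values.copy()
    called = ~matrix.mask
    n_called = called.sum(axis=0)
    keep = n_called > 0
    col_mean = np.zeros(m)
    col_mean[keep] = (X * called).sum(axis=0)[keep] / n_called[keep]
    X[matrix.mask] = np.take(col_mean, np.nonzero(matrix.mask)[1])
    X -= col_mean
    p = col_mean / 2.0
    poly = keep & (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    if not poly.any():
        raise ValueError("no variance: every variant is constant")
    X = X[:, poly]
    if scale:
        X /= np.sqrt(p[poly] * (1.0 - p[poly]))
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    # eigenvalues at numerical noise level are exact zeros of the model
    eigval[eigval < eigval.max() * 1e-12] = 0.0
    n_comp = n_components if n_components is not None else max(1, n - 1)
    n_comp = min(n_comp, n)
    # deterministic sign: largest-magnitude loading positive
    for k in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[i, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    total = eigval.sum()
    coords = eigvec[:, :n_comp] * np.sqrt(eigval[:n_comp])
    frac = eigval[:n_comp] / total if total > 0 else np.zeros(n_comp)
    return PCAResult(coordinates=coords, explained_fraction=frac, sample_ids=list(matrix.sample_ids))


def distance_matrix(matrix: DosageMatrix) -> np.ndarray:
    """Allele-sharing distance: mean |dosage_i - dosage_j| / 2 over
    jointly called variants; errors if a pair shares no called variant."""
    n = matrix.values.shape[0]
    called = ~matrix.mask
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            nb = int(both.sum())
            if nb == 0:
                raise ValueError(
                    f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
                    "share no called variant"
                )
            d[i, j] = d[j, i] = float(
                np.abs(matrix.values[i, both] - matrix.values[j, both]).sum()
            ) / (2.0 * nb)
    return d


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list | None = None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(d: np.ndarray, labels: list[str], clamp_negative: bool = True) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Ties on the Q-criterion are broken by the smallest (i, j) index pair
    in the current working matrix, which makes the output deterministic.
    Negative branch lengths are clamped to 0 with the deficit moved to
    the sister branch unless ``clamp_negative`` is False.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")

    if n == 2:
        # two leaves joined by an edge of total length d(0,1)
        return f"({labels[0]}:{d[0, 1] / 2:.10g},{labels[1]}:{d[0, 1] / 2:.10g});"

    nodes: list[_Node] = [_Node(lbl) for lbl in labels]
    D = d.copy()
    active = list(range(n))

    def _pair_lengths(li: float, lj: float) -> tuple[float, float]:
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0]:
                    best = (q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _pair_lengths(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new internal node to every other active taxon
        D = np.pad(D, ((0, 1), (0, 1)))
        k_new = D.shape[0] - 1
        for c in active:
            if c in (i, j):
                continue
            D[k_new, c] = D[c, k_new] = 0.5 * (D[i, c] + D[j, c] - dij)
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [k_new]

    # 3-taxon star resolution
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    if clamp_negative:
        li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    parts = ",".join(
        f"{nodes[c].newick()}:{bl:.10g}" for c, bl in ((i, li), (j, lj), (k, lk))
    )
    return f"({parts});"
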