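"""Simple-matching dissimilarity, neighbor-joining with locus bootstrap,
and PCA with active / supplementary individuals.

The dissimilarity between accessions i and j is

    d_ij = 1 - (1/L) * sum_l ( m_l / 2 )

with m_l the number of matching alleles (multiset intersection, 0-2) of
the two diploid genotypes at locus l, over loci typed in both
accessions (pairwise deletion).  Null homozygotes are excluded by
default; with ``null_as_state`` the ``00`` genotype is a state matching
only itself, which is how with-null-allele marker sets are compared.

Trees are classical Saitou-Nei neighbor-joining with a deterministic
lowest-index tie-break; negative branch lengths are clamped to zero
with the length transferred to the sister edge.  Bootstrap support is
the percentage of locus-resampled replicates containing each internal
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from citrus_snp.genotype_io import (
    GenotypeMatrix, AA, AB, BB, NULL2, observable_codes,
)


# ---------------------------------------------------------------------------
# Simple-matching dissimilarity

#: matching-allele counts between observable genotype states
_STATES = (AA, AB, BB, NULL2)
_MATCH = np.zeros((6, 6))
_PAIRS = {AA: (2, 0, 0), AB: (1, 1, 0), BB: (0, 2, 0), NULL2: (0, 0, 2)}
for _u, _cu in _PAIRS.items():
    for _v, _cv in _PAIRS.items():
        _MATCH[_u, _v] = sum(min(a, b) for a, b in zip(_cu, _cv))


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray           # symmetric, zero diagonal, in [0, 1]
    n_loci_used: np.ndarray      # per-pair count of loci compared

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _state_onehots(codes: np.ndarray, states) -> np.ndarray:
    """(n_states, n_acc, n_loci) boolean stack."""
    return np.stack([codes == s for s in states]).astype(np.float64)


def _match_sums(S: np.ndarray, states) -> tuple[np.ndarray, np.ndarray]:
    """Total matching alleles and typed-pair counts for every accession
    pair, via per-state inner products (16 small matmuls)."""
    n = S.shape[1]
    m = np.zeros((n, n))
    for a, u in enumerate(states):
        for b, v in enumerate(states):
            w = _MATCH[u, v]
            if w:
                m += w * (S[a] @ S[b].T)
    valid = S.sum(axis=0)                       # 1 where typed
    counts = valid @ valid.T
    return m, counts


def simple_matching(gm: GenotypeMatrix, loci: list[str] | None = None,
                    accessions: list[str] | None = None,
                    null_as_state: bool = False,
                    strict: bool = False) -> DistanceMatrix:
    """Pairwise simple-matching dissimilarity over the locus set.

    Pairs sharing no typed locus get distance NaN, or raise in
    ``strict`` mode.
    """
    sub = gm.subset(accessions=accessions, loci=loci)
    codes = observable_codes(sub.calls)
    states = _STATES if null_as_state else (AA, AB, BB)
    S = _state_onehots(codes, states)
    m, counts = _match_sums(S, states)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - (m / counts) / 2.0
    np.fill_diagonal(d, 0.0)
    empty = counts == 0
    np.fill_diagonal(empty, False)
    if empty.any():
        if strict:
            raise ValueError("accession pair with zero shared typed loci")
        d[empty] = np.nan
    return DistanceMatrix(list(sub.accession_ids), d,
                          counts.astype(int))


# ---------------------------------------------------------------------------
# Neighbor-joining

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, include_support: bool = True) -> str:
        return self._nwk(include_support) + ";"

    def _nwk(self, sup: bool) -> str:
        if self.is_leaf():
            return self.name
        parts = ",".join(f"{c._nwk(sup)}:{l:.6f}" for c, l in self.children)
        label = ""
        if sup and self.support is not None:
            label = f"{self.support:g}"
        return f"({parts}){label}"


@dataclass
class NJTree:
    root: TreeNode               # unrooted: root is an internal trifurcation
    ids: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self, include_support: bool = True) -> str:
        return self.root.newick(include_support)

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.root, set(self.ids))


def _bipartitions(root: TreeNode, all_leaves: set) -> set[frozenset]:
    """Non-trivial bipartitions, canonicalized as the side NOT holding
    an arbitrary fixed reference leaf."""
    ref = min(all_leaves)
    out: set[frozenset] = set()

    def walk(node: TreeNode):
        if node.is_leaf():
            return {node.name}
        below: set = set()
        for child, _ in node.children:
            cl = walk(child)
            if not child.is_leaf() and 1 < len(cl) < len(all_leaves) - 1:
                side = cl if ref not in cl else all_leaves - cl
                out.add(frozenset(side))
            below |= cl
        return below

    walk(root)
    return out


def nj_tree(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei agglomeration with the standard Q-criterion.

    Ties resolve to the lowest-index pair (row-major first minimum);
    a negative branch length is clamped to 0, its magnitude moved to
    the sister branch.
    """
    D = np.array(dm.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("incomplete distance matrix")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs >= 3 accessions")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        di = 0.5 * sub[i_, j_] + (r[i_] - r[j_]) / (2 * (k - 2))
        dj = sub[i_, j_] - di
        if di < 0:
            dj += di
            di = 0.0
        if dj < 0:
            di += dj
            dj = 0.0
        a, b = active[i_], active[j_]
        parent = TreeNode(children=[(nodes[a], di), (nodes[b], dj)])
        # distances from the new node
        newd = 0.5 * (D[a, :] + D[b, :] - D[a, b])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newd
        D[:-1, -1] = newd
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb),
                              (nodes[c], lc)])
    return NJTree(root=root, ids=list(dm.ids))


def bootstrap_support(gm: GenotypeMatrix, loci: list[str] | None = None,
                      accessions: list[str] | None = None,
                      n_reps: int = 1000, seed: int = 0,
                      null_as_state: bool = False) -> NJTree:
    """NJ tree on the full locus set with bootstrap supports: loci are
    resampled with replacement `n_reps` times; the support of each
    internal bipartition is the percentage of replicate trees containing
    it.  Supports are attached to internal nodes of the base tree."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sub = gm.subset(accessions=accessions, loci=loci)
    codes = observable_codes(sub.calls)
    states = _STATES if null_as_state else (AA, AB, BB)
    S = _state_onehots(codes, states)
    base_m, base_c = _match_sums(S, states)

    def to_dm(m, counts):
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - (m / counts) / 2.0
        np.fill_diagonal(d, 0.0)
        if np.isnan(d).any():
            raise ValueError("pair with zero shared typed loci")
        return DistanceMatrix(list(sub.accession_ids), d,
                              counts.astype(int))

    tree = nj_tree(to_dm(base_m, base_c))
    all_leaves = set(sub.accession_ids)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    L = sub.n_loci
    for _ in range(n_reps):
        pick = rng.integers(0, L, size=L)
        Sb = S[:, :, pick]
        m, c = _match_sums(Sb, states)
        rep = nj_tree(to_dm(m, c))
        for bp in _bipartitions(rep.root, all_leaves):
            counts[bp] = counts.get(bp, 0) + 1

    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    tree.supports = supports
    ref = min(all_leaves)

    def annotate(node: TreeNode):
        if node.is_leaf():
            return {node.name}
        below: set = set()
        for child, _ in node.children:
            cl = annotate(child)
            if not child.is_leaf() and 1 < len(cl) < len(all_leaves) - 1:
                side = cl if ref not in cl else all_leaves - cl
                child.support = supports.get(frozenset(side), 0.0)
            below |= cl
        return below

    annotate(tree.root)
    return tree


# ---------------------------------------------------------------------------
# PCA with supplementary individuals

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    coordinates: pd.DataFrame        # all individuals × axes
    active: list[str]
    supplementary: list[str]
    variable_cos2: pd.DataFrame      # per locus × axes (allele-B column)
    loci: list[str]


def pca(gm: GenotypeMatrix, loci: list[str] | None = None,
        active: list[str] | None = None,
        supplementary: list[str] | None = None,
        n_axes: int = 5) -> PCAResult:
    """PCA of the individual × within-individual-allele-frequency
    matrix (0 / 0.5 / 1 per allele per locus).

    Axes are defined by the active individuals only (columns centered on
    active means, covariance PCA); supplementary individuals are
    projected afterwards and cannot influence the axes.  ``00`` and
    missing cells are imputed with the active column mean.  The cos² of
    a locus on an axis is the squared correlation, over active
    individuals, between its allele-frequency column and the axis
    coordinates.
    """
    sub = gm.subset(loci=loci)
    if active is None:
        active = list(sub.accession_ids)
    if supplementary is None:
        supplementary = [a for a in sub.accession_ids if a not in set(active)]
    if len(active) < 3:
        raise ValueError("need >= 3 active accessions")
    order = active + [a for a in supplementary if a not in set(active)]
    sub = sub.subset(accessions=order)
    codes = observable_codes(sub.calls)
    # within-individual frequency of allele B (A column is 1 - B and
    # carries the same information; one column per locus is kept)
    freqB = np.select([codes == AA, codes == AB, codes == BB],
                      [0.0, 0.5, 1.0], default=np.nan)
    n_act = len(active)
    act = freqB[:n_act]
    col_mean = np.nanmean(np.where(np.isnan(act), np.nan, act), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(freqB), col_mean[None, :], freqB)
    X = filled - col_mean[None, :]
    Xa = X[:n_act]
    keep = Xa.std(axis=0) > 0
    if not keep.all():
        X = X[:, keep]
        Xa = Xa[:, keep]
    kept_loci = [l for l, k in zip(sub.locus_ids, keep) if k]

    U, s, Vt = np.linalg.svd(Xa, full_matrices=False)
    n_axes = min(n_axes, len(s))
    eig = (s ** 2) / max(n_act - 1, 1)
    pct = 100.0 * (s ** 2) / (s ** 2).sum()
    V = Vt.T[:, :n_axes]
    coords = X @ V
    axes = [f"PC{k + 1}" for k in range(n_axes)]
    coord_df = pd.DataFrame(coords, index=sub.accession_ids, columns=axes)

    scores_a = coords[:n_act]
    cos2 = np.zeros((Xa.shape[1], n_axes))
    col_sd = Xa.std(axis=0)
    for k in range(n_axes):
        sc = scores_a[:, k]
        sd = sc.std()
        if sd == 0:
            continue
        cov = (Xa * (sc - sc.mean())[:, None]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (col_sd * sd)
        cos2[:, k] = np.nan_to_num(r) ** 2
    cos2_df = pd.DataFrame(cos2, index=kept_loci, columns=axes)

    return PCAResult(eigenvalues=eig[:n_axes], percent_variance=pct[:n_axes],
                     coordinates=coord_df, active=list(active),
                     supplementary=list(supplementary),
                     variable_cos2=cos2_df, loci=kept_loci)
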