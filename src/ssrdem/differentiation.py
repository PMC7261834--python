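"""Between-group differentiation and its geometry.

Pairwise and global F_ST use the Weir & Cockerham (1984) theta estimator with
variance components summed over alleles and loci; significance comes from
permuting individuals among groups.  Nei's genetic distance is offered in the
1972 standard and 1978 unbiased forms.  AMOVA is distance-based
(Excoffier-style) on squared Euclidean distances between individual
allele-count vectors, with two strata (among / within groups).  Trees are
neighbor-joining (via scikit-bio) with bootstrap over loci; ordination is
classical PCoA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio.tree import TreeNode, nj as _skbio_nj

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "TreeResult",
    "pairwise_fst",
    "global_fst",
    "nei_distance",
    "amova",
    "simple_matching_dissimilarity",
    "nj_tree",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with labelled entities."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-9, equal_nan=True):
            raise ValueError("matrix not symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AmovaResult:
    table: pd.DataFrame          # df, SS, variance component, % of variation
    phi_st: float
    p_value: float


@dataclass
class TreeResult:
    newick: str
    supports: dict[frozenset, float] = field(default_factory=dict)
    tree: TreeNode | None = None


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components_locus(calls_by_pop):
    """Per-allele W&C (1984) a, b, c components for one locus.

    ``calls_by_pop``: list of (n_i, 2) non-missing call arrays, one per
    population.  Returns (sum_a, sum_b, sum_c) over alleles, or None when
    fewer than 2 populations have data or the locus is monomorphic.
    """
    pops = [c for c in calls_by_pop if c.shape[0] > 0]
    r = len(pops)
    if r < 2:
        return None
    n_i = np.array([c.shape[0] for c in pops], dtype=float)
    alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
    if alleles.size < 2:
        return None
    nbar = n_i.mean()
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    if nc <= 0 or nbar <= 1:
        return None
    sa = sb = sc = 0.0
    for a in alleles:
        p_i = np.array([np.mean(c == a) for c in pops])
        h_i = np.array([
            np.mean((c[:, 0] != c[:, 1]) & ((c[:, 0] == a) | (c[:, 1] == a)))
            for c in pops
        ])
        pbar = np.sum(n_i * p_i) / (r * nbar)
        s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n_i * h_i) / (r * nbar)
        va = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        vb = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        vc = hbar / 2
        sa, sb, sc = sa + va, sb + vb, sc + vc
    return sa, sb, sc


def _theta(g: GenotypeMatrix, groups_rows) -> float:
    """Multi-locus W&C theta over the given list of row-index arrays."""
    sa = sbc = 0.0
    any_locus = False
    for l in range(g.n_loci):
        calls_by_pop = []
        for rows in groups_rows:
            c = g.calls[rows, l, :]
            calls_by_pop.append(c[c[:, 0] != MISSING])
        comp = _wc_components_locus(calls_by_pop)
        if comp is None:
            continue
        a, b, c_ = comp
        sa += a
        sbc += a + b + c_
        any_locus = True
    if not any_locus or sbc == 0:
        return np.nan
    return sa / sbc


def global_fst(g: GenotypeMatrix, p: Partition) -> float:
    """Global multi-group Weir-Cockerham theta."""
    idx = p.group_indices(g)
    return _theta(g, list(idx.values()))


def pairwise_fst(
    g: GenotypeMatrix,
    p: Partition,
    n_perm: int = 0,
    seed: int | None = None,
):
    """Pairwise Weir-Cockerham theta with optional permutation p-values.

    P-values are one-sided (differentiation alternative): individuals are
    permuted between the two groups and theta recomputed.  Returns
    ``(DistanceMatrix(kind="fst"), p-value DataFrame, global theta)``.
    """
    idx = p.group_indices(g)
    groups = [grp for grp in p.groups if grp in idx]
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    for grp in groups:
        if idx[grp].size < 2:
            raise ValueError(f"group {grp!r} has <2 individuals")
    G = len(groups)
    vals = np.zeros((G, G))
    pvals = np.full((G, G), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(G), 2):
        rows_i, rows_j = idx[groups[i]], idx[groups[j]]
        obs = _theta(g, [rows_i, rows_j])
        vals[i, j] = vals[j, i] = obs
        if n_perm > 0 and np.isfinite(obs):
            pool = np.concatenate([rows_i, rows_j])
            ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                t = _theta(g, [perm[: rows_i.size], perm[rows_i.size:]])
                if np.isfinite(t) and t >= obs:
                    ge += 1
            pvals[i, j] = pvals[j, i] = (ge + 1) / (n_perm + 1)
    dm = DistanceMatrix(tuple(groups), vals, kind="fst")
    pdf = pd.DataFrame(pvals, index=groups, columns=groups)
    return dm, pdf, _theta(g, [idx[grp] for grp in groups])


# ---------------------------------------------------------------------------
# Nei genetic distance
# ---------------------------------------------------------------------------

def _group_freq_table(g: GenotypeMatrix, rows: np.ndarray, locus: int):
    c = g.calls[rows, locus, :]
    c = c[c[:, 0] != MISSING]
    copies = c.ravel()
    if copies.size == 0:
        return None, 0
    alleles, counts = np.unique(copies, return_counts=True)
    return dict(zip(alleles.tolist(), (counts / counts.sum()).tolist())), c.shape[0]


def nei_distance(
    g: GenotypeMatrix,
    p: Partition,
    variant: str = "standard_1972",
) -> DistanceMatrix:
    """Nei's genetic distance D = -ln(J_xy / sqrt(J_x J_y)).

    J terms are arithmetic means over loci of sum(p^2) (within) and
    sum(p_x p_y) (between).  ``variant="unbiased_1978"`` replaces the within
    terms with the small-sample-corrected (2n sum(p^2) - 1)/(2n - 1).
    Disjoint allele sets at every locus yield +inf (flagged via a warning).
    """
    if variant not in ("standard_1972", "unbiased_1978"):
        raise ValueError(f"unknown variant {variant!r}")
    idx = p.group_indices(g)
    groups = [grp for grp in p.groups if grp in idx]
    G = len(groups)
    freqs = {
        grp: [_group_freq_table(g, idx[grp], l) for l in range(g.n_loci)]
        for grp in groups
    }
    vals = np.zeros((G, G))
    for i, j in itertools.combinations(range(G), 2):
        jx = jy = jxy = 0.0
        n_loci = 0
        for l in range(g.n_loci):
            fx, nx = freqs[groups[i]][l]
            fy, ny = freqs[groups[j]][l]
            if fx is None or fy is None:
                continue
            sx = sum(v * v for v in fx.values())
            sy = sum(v * v for v in fy.values())
            if variant == "unbiased_1978":
                sx = (2 * nx * sx - 1) / (2 * nx - 1)
                sy = (2 * ny * sy - 1) / (2 * ny - 1)
            jx += sx
            jy += sy
            jxy += sum(fx[a] * fy.get(a, 0.0) for a in fx)
            n_loci += 1
        if n_loci == 0 or jxy == 0:
            warnings.warn(
                f"groups {groups[i]!r}/{groups[j]!r} share no alleles; D = +inf"
            )
            d = np.inf
        else:
            d = -np.log((jxy / n_loci) / np.sqrt((jx / n_loci) * (jy / n_loci)))
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(groups), vals, kind="nei")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_components_locus(g: GenotypeMatrix, groups_rows, locus: int):
    """One locus's AMOVA sums of squares and variance components.

    Units are gene copies; the inter-copy distance is a 0/1 allele mismatch,
    so SS reduce to allele-count expressions:
    ``SS = (C(N,2) - sum_a C(c_a,2)) / N`` within any stratum.  Returns
    ``(ss_among, ss_within, sigma_a, sigma_w)`` or None for an unusable locus
    (monomorphic or <2 groups with data).
    """
    copies_by_group = []
    for rows in groups_rows:
        c = g.calls[rows, locus, :]
        copies = c[c[:, 0] != MISSING].ravel()
        if copies.size:
            copies_by_group.append(copies)
    if len(copies_by_group) < 2:
        return None
    alleles = np.unique(np.concatenate(copies_by_group))
    if alleles.size < 2:
        return None
    G = len(copies_by_group)
    mat = np.zeros((G, alleles.size))
    for i, copies in enumerate(copies_by_group):
        mat[i] = np.bincount(
            np.searchsorted(alleles, copies), minlength=alleles.size
        )
    tot = mat.sum(axis=0)
    n_g = mat.sum(axis=1)
    N = n_g.sum()

    def ss(copy_counts, n):
        return (n * (n - 1) / 2 - np.sum(copy_counts * (copy_counts - 1) / 2)) / n

    ss_total = ss(tot, N)
    ss_within = sum(ss(mat[i], n_g[i]) for i in range(G) if n_g[i] > 0)
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, N - G
    if df_w <= 0:
        return None
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (N - np.sum(n_g**2) / N) / (G - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    return ss_among, ss_within, sigma_a, sigma_w


def _amova_over_loci(g: GenotypeMatrix, groups_rows):
    ss_a = ss_w = sig_a = sig_w = 0.0
    used = 0
    for l in range(g.n_loci):
        comp = _amova_components_locus(g, groups_rows, l)
        if comp is None:
            continue
        a, w, va, vw = comp
        ss_a += a
        ss_w += w
        sig_a += va
        sig_w += vw
        used += 1
    sig_a = max(0.0, sig_a)  # truncate negative among-group component
    phi = sig_a / (sig_a + sig_w) if (sig_a + sig_w) > 0 else 0.0
    return ss_a, ss_w, sig_a, sig_w, phi, used


def amova(
    g: GenotypeMatrix,
    p: Partition,
    n_perm: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level distance-based AMOVA (among groups / within groups).

    Computed at the gene-copy level: the inter-copy distance is a 0/1 allele
    mismatch per locus, and per-locus variance components are summed over
    loci.  Negative among-group components are truncated to 0 before
    percentages.  Phi_ST significance by permuting whole individuals among
    groups.
    """
    idx = p.group_indices(g)
    groups_rows = [rows for grp, rows in idx.items()]
    if len(groups_rows) < 2:
        raise ValueError("AMOVA needs >=2 groups")
    ss_a, ss_w, sig_a, sig_w, phi, used = _amova_over_loci(g, groups_rows)
    if used == 0:
        raise ValueError("no usable polymorphic locus")
    N2 = 2 * sum(r.size for r in groups_rows)
    G = len(groups_rows)
    df_a, df_w = G - 1, N2 - G
    ss_t = ss_a + ss_w
    total_var = sig_a + sig_w
    table = pd.DataFrame(
        {
            "df": [df_a, df_w, df_a + df_w],
            "SS": [ss_a, ss_w, ss_t],
            "variance": [sig_a, sig_w, total_var],
            "pct": [100 * sig_a / total_var, 100 * sig_w / total_var, 100.0],
        },
        index=["among_groups", "within_groups", "total"],
    )
    pval = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = [r.size for r in groups_rows]
        all_rows = np.concatenate(groups_rows)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_rows)
            splits = np.split(perm, np.cumsum(sizes)[:-1])
            *_, phi_p, _u = _amova_over_loci(g, splits)
            if phi_p >= phi:
                ge += 1
        pval = (ge + 1) / (n_perm + 1)
    return AmovaResult(table=table, phi_st=phi, p_value=pval)


# ---------------------------------------------------------------------------
# simple-matching dissimilarity
# ---------------------------------------------------------------------------

def simple_matching_dissimilarity(g: GenotypeMatrix) -> DistanceMatrix:
    """d(i,j) = 1 - mean over shared non-missing loci of (shared alleles)/2.

    Shared alleles between two diploid calls are counted as a multiset
    intersection (0, 1, or 2).  Pairs with no shared non-missing locus get a
    NaN entry (flagged with a warning).
    """
    if g.n_individuals < 2:
        raise ValueError("need >=2 individuals")
    n, L = g.n_individuals, g.n_loci
    a1 = g.calls[:, :, 0]
    a2 = g.calls[:, :, 1]
    ok = a1 != MISSING
    shared_sum = np.zeros((n, n))
    loci_count = np.zeros((n, n))
    for l in range(L):
        x1, x2, v = a1[:, l], a2[:, l], ok[:, l]
        # multiset intersection of sorted pairs = max of the two aligned matches
        m_direct = (x1[:, None] == x1[None, :]).astype(np.int8) + (
            x2[:, None] == x2[None, :]
        )
        m_cross = (x1[:, None] == x2[None, :]).astype(np.int8) + (
            x2[:, None] == x1[None, :]
        )
        s = np.maximum(m_direct, m_cross)
        both = np.outer(v, v)
        shared_sum += np.where(both, s, 0)
        loci_count += both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - (shared_sum / loci_count) / 2.0
    if np.any(loci_count[np.triu_indices(n, 1)] == 0):
        warnings.warn("some pairs share no non-missing locus; NaN entries")
        d[loci_count == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(g.individuals), d, kind="simple_matching")


# ---------------------------------------------------------------------------
# trees and ordination
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, all_leaves: frozenset) -> set[frozenset]:
    """Canonical internal bipartitions (smaller side, lexicographic tiebreak)."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            canon = min(side, other, key=lambda s: (len(s), sorted(s)))
            out.add(canon)
    return out


def nj_tree(
    d: DistanceMatrix,
    bootstrap: dict | None = None,
) -> TreeResult:
    """Neighbor-joining (Saitou-Nei) tree with optional bootstrap over loci.

    Parameters
    ----------
    d
        Finite distance matrix over >=3 entities.
    bootstrap
        Optional ``dict(distance_fn=..., genotypes=..., replicates=B,
        seed=N)``; ``distance_fn(genotypes_with_resampled_loci)`` must return
        a DistanceMatrix with the same labels.  Loci are resampled with
        replacement; supports are percentages of replicates containing each
        internal bipartition of the point-estimate tree.
    """
    if len(d.labels) < 3:
        raise ValueError("NJ needs >=3 leaves")
    bad = np.argwhere(~np.isfinite(d.values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite distance between {d.labels[i]!r} and {d.labels[j]!r}")
    tree = _skbio_nj(_SkbioDM(d.values, ids=list(d.labels)))
    supports: dict[frozenset, float] = {}
    if bootstrap:
        fn = bootstrap["distance_fn"]
        g = bootstrap["genotypes"]
        B = int(bootstrap.get("replicates", 100))
        rng = np.random.default_rng(bootstrap.get("seed"))
        leaves = frozenset(d.labels)
        target = _bipartitions(tree, leaves)
        counts = {bp: 0 for bp in target}
        for _ in range(B):
            take = rng.integers(0, g.n_loci, size=g.n_loci)
            gb = GenotypeMatrix(
                g.individuals,
                tuple(f"b{j}_{g.loci[t]}" for j, t in enumerate(take)),
                g.calls[:, take],
            )
            db = fn(gb)
            if not np.all(np.isfinite(db.values)):
                continue
            tb = _skbio_nj(_SkbioDM(db.values, ids=list(db.labels)))
            found = _bipartitions(tb, leaves)
            for bp in target:
                if bp in found:
                    counts[bp] += 1
        supports = {bp: 100.0 * c / B for bp, c in counts.items()}
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canon = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
            if canon in supports:
                node.name = f"{supports[canon]:.0f}"
    newick = str(tree).strip()
    return TreeResult(newick=newick, supports=supports, tree=tree)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical scaling (principal coordinate analysis).

    Double-centers -d^2/2 and eigendecomposes; axes are ordered by
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are retained in
    the report, not corrected.
    """
    if np.any(~np.isfinite(d.values)):
        raise ValueError("PCoA requires finite distances")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        res = _skbio_pcoa(_SkbioDM(d.values, ids=list(d.labels)), method="eigh")
    eig = res.eigvals.to_numpy()
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.index = list(d.labels)
    coords.columns = [f"axis{i + 1}" for i in range(coords.shape[1])]
    tot = eig.sum()
    ve = eig / tot if tot != 0 else np.zeros_like(eig)
    return PcoaResult(coordinates=coords, eigenvalues=eig, variance_explained=ve)
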