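"""Per-locus and per-group diversity statistics for codominant markers.

Statistics follow the standard population-genetics definitions: observed
allele number N_A; effective allele number N_E = 1/sum(p^2); Shannon index
I = -sum(p ln p); observed heterozygosity H_O; unbiased expected
heterozygosity H_E = 2n/(2n-1) * (1 - sum(p^2)); hypergeometric rarefaction
for allelic richness; Weir & Cockerham (1984) variance-component estimator
for F_IS with a one-sided permutation test toward heterozygote deficit; and
the Brookfield (1996) closed-form null-allele frequency estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "locus_summary",
    "allelic_richness",
    "group_summary",
    "null_allele_rate",
    "wc_fis_components",
]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _locus_data(g: GenotypeMatrix, locus: int, rows: np.ndarray | None = None):
    """Calls, sample size and allele bookkeeping for one locus.

    Returns ``(calls, n)`` with ``calls`` the (n, 2) non-missing diploid calls
    of the selected rows and ``n`` the number of non-missing individuals.
    """
    c = g.calls[:, locus, :] if rows is None else g.calls[rows, locus, :]
    keep = c[:, 0] != MISSING
    return c[keep], int(keep.sum())


def _freq_stats(calls: np.ndarray):
    """Allele codes, counts and frequencies from (n, 2) non-missing calls."""
    copies = calls.ravel()
    alleles, counts = np.unique(copies, return_counts=True)
    return alleles, counts, counts / counts.sum()


def wc_fis_components(calls: np.ndarray):
    """Weir & Cockerham (1984) within-population variance components.

    For a single sample the estimator reduces, per allele ``a``, to

        b_a = n/(n-1) * (p_a (1 - p_a) - (2n - 1)/(4n) * h_a)
        c_a = h_a / 2

    with ``p_a`` the allele frequency and ``h_a`` the observed frequency of
    heterozygotes carrying ``a``; f = 1 - sum(c)/sum(b + c).  Returns
    ``(sum_b, sum_c)`` over alleles (NaN, NaN when n < 2 or monomorphic).
    """
    n = calls.shape[0]
    if n < 2:
        return np.nan, np.nan
    alleles, counts, p = _freq_stats(calls)
    if alleles.size < 2:
        return np.nan, np.nan
    het = calls[:, 0] != calls[:, 1]
    # h_a: fraction of individuals heterozygous and carrying allele a
    h = np.array([
        np.mean(het & ((calls[:, 0] == a) | (calls[:, 1] == a))) for a in alleles
    ])
    b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
    c = h / 2
    return float(b.sum()), float(c.sum())


def _fis_from_components(sb: float, sc: float) -> float:
    denom = sb + sc
    return np.nan if (not np.isfinite(denom)) or denom <= 0 else 1.0 - sc / denom


def _rarefied_richness(counts: np.ndarray, g_copies: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g_copies``
    gene copies (hypergeometric rarefaction)."""
    N = counts.sum()
    if g_copies < 2:
        raise ValueError("rarefaction size must be >= 2 gene copies")
    if g_copies > N:
        raise ValueError(f"rarefaction size {g_copies} exceeds sample of {N} copies")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    with np.errstate(invalid="ignore"):
        term = np.where(
            N - counts >= g_copies,
            np.exp(log_comb(N - counts, g_copies) - log_comb(N, g_copies)),
            0.0,
        )
    return float(np.sum(1.0 - term))


def null_allele_rate(h_o: float, h_e: float) -> float:
    """Brookfield (1996) estimator 1 of the null-allele frequency.

    r = (H_E - H_O) / (1 + H_E), floored at 0: a heterozygote deficit is read
    as a hidden null allele, an excess is not a null signal.
    """
    if not (0 <= h_o <= 1 and 0 <= h_e <= 1):
        raise ValueError("heterozygosities must lie in [0, 1]")
    return max(0.0, (h_e - h_o) / (1.0 + h_e))


# ---------------------------------------------------------------------------
# per-locus summaries
# ---------------------------------------------------------------------------

def _one_locus_row(calls: np.ndarray, n: int, rarefaction_g: int | None):
    alleles, counts, p = _freq_stats(calls)
    n_a = alleles.size
    sum_p2 = float(np.sum(p**2))
    n_e = 1.0 / sum_p2
    shannon = float(-np.sum(p * np.log(p)))
    h_o = float(np.mean(calls[:, 0] != calls[:, 1]))
    h_e = (2 * n) / (2 * n - 1) * (1.0 - sum_p2) if n > 1 else np.nan
    sb, sc = wc_fis_components(calls)
    a_r = np.nan
    if rarefaction_g is not None and 2 * n >= rarefaction_g:
        a_r = _rarefied_richness(counts, rarefaction_g)
    return dict(
        n=n, N_A=n_a, N_E=n_e, A_R=a_r,
        major_allele_freq=float(p.max()), I=shannon,
        H_O=h_o, H_E=h_e,
        F_IS=_fis_from_components(sb, sc), _sb=sb, _sc=sc,
    )


def _permute_fis(calls_list, rng, n_perm, observed_pooled, observed_per_locus):
    """One-sided permutation p-values for F_IS (deficit alternative).

    Gene copies are shuffled among individuals within each locus, which makes
    H_O match H_E in expectation while preserving allele frequencies.
    Returns (per-locus p array, pooled multilocus p).
    """
    L = len(calls_list)
    exceed = np.zeros(L)
    exceed_pooled = 0
    valid = np.array([np.isfinite(observed_per_locus[l]) for l in range(L)])
    for _ in range(n_perm):
        sb_tot = sc_tot = 0.0
        for l, calls in enumerate(calls_list):
            if not valid[l]:
                continue
            copies = calls.ravel().copy()
            rng.shuffle(copies)
            perm = copies.reshape(-1, 2)
            sb, sc = wc_fis_components(perm)
            if np.isfinite(sb):
                sb_tot += sb
                sc_tot += sc
                f = _fis_from_components(sb, sc)
                if np.isfinite(f) and f >= observed_per_locus[l]:
                    exceed[l] += 1
        f_pool = _fis_from_components(sb_tot, sc_tot)
        if np.isfinite(observed_pooled) and np.isfinite(f_pool) and f_pool >= observed_pooled:
            exceed_pooled += 1
    p_loc = np.where(valid, (exceed + 1) / (n_perm + 1), np.nan)
    p_pool = (exceed_pooled + 1) / (n_perm + 1) if np.isfinite(observed_pooled) else np.nan
    return p_loc, p_pool


def locus_summary(
    g: GenotypeMatrix,
    rarefaction_g: int | str | None = "auto",
    n_perm: int = 0,
    seed: int | None = None,
    rows: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-locus diversity table plus multilocus averages.

    Frequencies use non-missing calls only; entirely missing loci are skipped
    with a warning and excluded from the averages.  The multilocus F_IS pools
    Weir-Cockerham variance components over loci (see also the per-locus mean
    in column ``F_IS`` of the returned averages via ``F_IS_mean``).

    Parameters
    ----------
    rarefaction_g
        Gene-copy rarefaction size for allelic richness; ``"auto"`` uses the
        smallest non-missing copy count over loci; ``None`` skips A_R.
    n_perm
        Permutation count for the one-sided (deficit) F_IS test; 0 disables.
    rows
        Optional row indices restricting the computation to a subsample.
    """
    rows_idx = np.arange(g.n_individuals) if rows is None else np.asarray(rows)
    per_locus_calls, kept_loci = [], []
    for l in range(g.n_loci):
        calls, n = _locus_data(g, l, rows_idx)
        if n == 0:
            warnings.warn(f"locus {g.loci[l]!r} entirely missing; skipped")
            continue
        per_locus_calls.append((l, calls, n))
        kept_loci.append(g.loci[l])
    if not per_locus_calls:
        raise ValueError("no locus with data")
    if rarefaction_g == "auto":
        rarefaction_g = min(2 * n for _, _, n in per_locus_calls)
    records = [
        _one_locus_row(calls, n, rarefaction_g) for _, calls, n in per_locus_calls
    ]
    df = pd.DataFrame(records, index=pd.Index(kept_loci, name="locus"))
    sb_tot = np.nansum([r["_sb"] for r in records])
    sc_tot = np.nansum([r["_sc"] for r in records])
    any_comp = any(np.isfinite(r["_sb"]) for r in records)
    pooled_fis = _fis_from_components(sb_tot, sc_tot) if any_comp else np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_loc, p_pool = _permute_fis(
            [c for _, c, _ in per_locus_calls], rng, n_perm,
            pooled_fis, df["F_IS"].to_numpy(),
        )
        df["F_IS_p"] = p_loc
    else:
        p_pool = np.nan
        df["F_IS_p"] = np.nan
    df = df.drop(columns=["_sb", "_sc"])
    avg = df[["N_A", "N_E", "A_R", "major_allele_freq", "I", "H_O", "H_E"]].mean()
    avg["F_IS"] = pooled_fis
    avg["F_IS_mean"] = df["F_IS"].mean(skipna=True)
    avg["F_IS_p"] = p_pool
    avg["n_loci"] = float(len(kept_loci))
    avg.name = "multilocus"
    return df, avg


def allelic_richness(
    g: GenotypeMatrix,
    p: Partition | None = None,
    rarefaction_g: int | str = "auto",
) -> pd.DataFrame:
    """Rarefied allelic richness per locus, within each partition group.

    With ``rarefaction_g="auto"`` the rarefaction size is the smallest
    non-missing gene-copy count over group x locus cells (the smallest
    partitioning level), so richness is comparable across groups of unequal
    size.  Without a partition the whole matrix forms one group.
    """
    if p is None:
        p = Partition({ind: "all" for ind in g.individuals})
    idx = p.group_indices(g)
    copy_counts = {}
    for grp, rows in idx.items():
        for l in range(g.n_loci):
            _, n = _locus_data(g, l, rows)
            copy_counts[(grp, l)] = 2 * n
    if rarefaction_g == "auto":
        positive = [v for v in copy_counts.values() if v > 0]
        rarefaction_g = min(positive)
    rarefaction_g = int(rarefaction_g)
    if rarefaction_g < 2:
        raise ValueError("rarefaction size must be >= 2 gene copies")
    out = {}
    for grp, rows in idx.items():
        col = []
        for l in range(g.n_loci):
            calls, n = _locus_data(g, l, rows)
            if 2 * n < rarefaction_g or n == 0:
                col.append(np.nan)
            else:
                _, counts, _ = _freq_stats(calls)
                col.append(_rarefied_richness(counts, rarefaction_g))
        out[grp] = col
    df = pd.DataFrame(out, index=pd.Index(g.loci, name="locus"))
    df.attrs["rarefaction_g"] = rarefaction_g
    return df


# ---------------------------------------------------------------------------
# group-level summary
# ---------------------------------------------------------------------------

def _allele_presence(g: GenotypeMatrix, idx: dict[str, np.ndarray]):
    """Which (locus, allele) classes occur in which groups / in how many
    individuals of the whole matrix."""
    group_alleles = {grp: set() for grp in idx}
    carrier_counts: dict[tuple[int, int], int] = {}
    carrier_group: dict[tuple[int, int], str] = {}
    for grp, rows in idx.items():
        for l in range(g.n_loci):
            calls, n = _locus_data(g, l, rows)
            for a in np.unique(calls):
                group_alleles[grp].add((l, int(a)))
    for l in range(g.n_loci):
        calls = g.calls[:, l, :]
        ok = calls[:, 0] != MISSING
        for i in np.flatnonzero(ok):
            for a in set(calls[i].tolist()):
                key = (l, int(a))
                carrier_counts[key] = carrier_counts.get(key, 0) + 1
    return group_alleles, carrier_counts


def group_summary(
    g: GenotypeMatrix,
    p: Partition,
    rarefaction_g: int | str = "auto",
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group diversity table (sample size, mean N_A/N_E, private and
    unique allele counts, rarefied A_R, H_O, H_E, F_IS and its permutation p).

    Private alleles occur in exactly one group; unique alleles occur in
    exactly one individual of the whole matrix and are attributed to that
    individual's group.  Groups of fewer than 2 individuals are excluded with
    a warning.
    """
    p.validate_against(g)
    idx = {grp: rows for grp, rows in p.group_indices(g).items()}
    small = [grp for grp, rows in idx.items() if rows.size < 2]
    for grp in small:
        warnings.warn(f"group {grp!r} has <2 individuals; excluded")
        del idx[grp]
    if not idx:
        raise ValueError("no group with >=2 individuals")
    ar = allelic_richness(g.subset_individuals(np.concatenate(list(idx.values()))),
                          Partition({g.individuals[i]: grp for grp, rows in idx.items() for i in rows},
                                    tuple(idx)),
                          rarefaction_g)
    group_alleles, carrier_counts = _allele_presence(g, idx)
    # private: allele seen in exactly one group
    seen_in = {}
    for grp, al in group_alleles.items():
        for key in al:
            seen_in.setdefault(key, []).append(grp)
    rows_out = []
    pos = {ind: i for i, ind in enumerate(g.individuals)}
    for grp, rows in idx.items():
        seed_g = None if seed is None else (seed + hash(grp) % 100003) % (2**31 - 1)
        df, avg = locus_summary(g, rarefaction_g=None, n_perm=n_perm,
                                seed=seed_g, rows=rows)
        private = sum(1 for key, grps in seen_in.items() if grps == [grp])
        unique = 0
        row_set = set(rows.tolist())
        for key, cnt in carrier_counts.items():
            if cnt == 1 and key in group_alleles[grp] and len(seen_in[key]) == 1 and seen_in[key][0] == grp:
                unique += 1
        rows_out.append(dict(
            group=grp, n=rows.size,
            N_A=avg["N_A"], N_E=avg["N_E"],
            private=private, unique=unique,
            A_R=float(ar[grp].mean(skipna=True)),
            H_O=avg["H_O"], H_E=avg["H_E"],
            F_IS=avg["F_IS"], F_IS_p=avg["F_IS_p"],
        ))
    out = pd.DataFrame(rows_out).set_index("group")
    out.attrs["rarefaction_g"] = ar.attrs["rarefaction_g"]
    return out
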