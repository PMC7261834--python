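"""Bayesian admixture clustering with a Gibbs sampler, K diagnostics, and
label-aligned run consensus.

The model is the classic admixture model: individual ``i`` carries a
proportion vector ``q_i`` over ``K`` clusters (Dirichlet(alpha) prior with a
single alpha shared across clusters); each allele copy independently picks a
cluster of origin ``z`` from ``q_i`` and then an allele from that cluster's
locus frequencies ``p_kl``.  The sampler alternates (i) the latent origins z
given Q and P, (ii) P given z (Dirichlet posterior; the correlated-frequency
variant shrinks each cluster toward ancestral frequencies with one drift
parameter per cluster), (iii) Q given z, and (iv) a Metropolis step on alpha
(uniform(0, 10) prior).  Missing calls contribute nothing.  Reported Q and P
are posterior means over post-burn-in thinned sweeps.

K selection diagnostics: the Evanno delta-K second-difference statistic and
the average pairwise similarity H' of label-aligned replicate runs
(CLUMPP-style); cluster assignment uses a membership threshold q* (default
0.8, inclusive), otherwise "admixed".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "AdmixtureResult",
    "RunEnsemble",
    "fit_admixture",
    "run_ensemble",
    "evanno_delta_k",
    "align_runs",
    "similarity",
    "assign_clusters",
]


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray                    # (n, K) posterior-mean memberships
    P: list[np.ndarray]              # per locus (K, m_l) posterior-mean freqs
    alpha: float
    lnL_trace: np.ndarray
    mean_lnL: float
    var_lnL: float
    seed: int | None
    mcmc: tuple[int, int, int]

    @property
    def ln_prob_data(self) -> float:
        """Model log-evidence estimate: mean(lnL) - var(lnL)/2."""
        return self.mean_lnL - self.var_lnL / 2.0


def _encode(g: GenotypeMatrix):
    """Allele-index encoding: X (n, L, 2) with missing -1, allele counts m_l."""
    n, L = g.n_individuals, g.n_loci
    X = np.full((n, L, 2), -1, dtype=np.int64)
    m = np.zeros(L, dtype=int)
    code_maps = []
    for l in range(L):
        calls = g.calls[:, l, :]
        ok = calls[:, 0] != MISSING
        alleles = np.unique(calls[ok].ravel())
        code_maps.append(alleles)
        m[l] = alleles.size
        if alleles.size:
            lut = {a: i for i, a in enumerate(alleles.tolist())}
            for c in range(2):
                X[ok, l, c] = [lut[a] for a in calls[ok, c].tolist()]
    return X, m, code_maps


def _log_alpha_density(alpha, K, sum_log_q, n):
    return n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * sum_log_q


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    mcmc: tuple[int, int, int] = (1000, 5000, 10),
    model: str = "independent",
    seed: int | None = None,
    alpha0: float = 1.0,
    lambda_prior: float = 1.0,
) -> AdmixtureResult:
    """Fit the admixture model for a fixed K.

    Parameters
    ----------
    mcmc
        ``(burn_in, iterations, thinning)``; ``iterations`` counts post
        burn-in sweeps.
    model
        ``"independent"`` (Dirichlet(lambda) frequency prior, default) or
        ``"correlated"`` (F-model prior around the empirical overall
        frequencies with a per-cluster drift parameter).
    """
    burn, iters, thin = mcmc
    if K < 1 or iters < 1 or thin < 1:
        raise ValueError("bad MCMC configuration")
    rng = np.random.default_rng(seed)
    X, m, code_maps = _encode(g)
    good = m > 0
    if not np.all(good):
        warnings.warn(f"dropping {int((~good).sum())} empty loci")
        X, m = X[:, good], m[good]
        code_maps = [cm for cm, ok in zip(code_maps, good) if ok]
    n, L, _ = X.shape
    M = int(m.max())
    valid_allele = np.arange(M)[None, :] < m[:, None]      # (L, M)
    copy_ok = X[..., 0:1] >= 0                             # (n, L, 1)
    copy_ok2 = np.repeat(copy_ok, 2, axis=2)               # (n, L, 2)
    Xs = np.where(X >= 0, X, 0)

    if K == 1:
        return _fit_k1(g, X, m, M, valid_allele, copy_ok2, Xs, rng, mcmc, seed,
                       lambda_prior, code_maps)

    # frequency prior
    if model == "correlated":
        emp = np.zeros((L, M))
        for l in range(L):
            col = X[:, l, :][X[:, l, :] >= 0]
            cnt = np.bincount(col, minlength=M).astype(float)
            emp[l] = (cnt + 0.5) / (cnt + 0.5 * valid_allele[l]).sum()
        emp *= valid_allele
        Fdrift = np.full(K, 0.1)
    elif model != "independent":
        raise ValueError(f"unknown frequency model {model!r}")

    # initial state
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.where(valid_allele[None], 1.0 / m[None, :, None], 0.0) * np.ones((K, 1, 1))
    alpha = alpha0
    l_idx = np.arange(L)

    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L, M))
    alpha_samples = []
    lnL_trace = []
    n_rec = 0
    total = burn + iters

    for it in range(total):
        # (i) origins z | Q, P
        PT = P.transpose(1, 2, 0)                    # (L, M, K)
        PX = PT[l_idx[None, :, None], Xs]            # (n, L, 2, K)
        W = Q[:, None, None, :] * PX
        Wsum = W.sum(axis=-1)
        Wsum_safe = np.where(Wsum > 0, Wsum, 1.0)
        cum = np.cumsum(W, axis=-1) / Wsum_safe[..., None]
        u = rng.random((n, L, 2, 1))
        Z = (u > cum).sum(axis=-1)                   # (n, L, 2) in [0, K)

        valid = copy_ok2 & (Wsum > 0)
        # (ii) P | z
        key = (Z * L + l_idx[None, :, None]) * M + Xs
        C = np.bincount(key[valid].ravel(), minlength=K * L * M).reshape(K, L, M)
        if model == "correlated":
            lam = emp[None] * ((1.0 - Fdrift) / Fdrift)[:, None, None]
        else:
            lam = lambda_prior
        shape = np.where(valid_allele[None], lam + C, 0.0)
        Pdraw = rng.gamma(np.maximum(shape, 1e-12))
        Pdraw *= valid_allele[None]
        tot_p = Pdraw.sum(axis=2, keepdims=True)
        P = Pdraw / np.where(tot_p > 0, tot_p, 1.0)

        if model == "correlated":
            # Metropolis on each cluster's drift parameter, uniform(0,1) prior
            for k in range(K):
                f_new = Fdrift[k] + 0.05 * rng.standard_normal()
                if not (0.001 < f_new < 0.999):
                    continue
                def logdens(f):
                    conc = emp * (1.0 - f) / f
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lp = (
                            gammaln(np.where(valid_allele, conc, 1)).sum()
                            * -1.0
                        )
                        lp += gammaln(conc.sum(axis=1)).sum()
                        logP = np.where((P[k] > 0) & valid_allele, np.log(np.where(P[k] > 0, P[k], 1.0)), 0.0)
                        lp += np.where(valid_allele, (conc - 1) * logP, 0.0).sum()
                    return lp
                if np.log(rng.random()) < logdens(f_new) - logdens(Fdrift[k]):
                    Fdrift[k] = f_new

        # (iii) Q | z
        zkey = np.arange(n)[:, None, None] * K + Z
        n_ik = np.bincount(zkey[valid].ravel(), minlength=n * K).reshape(n, K)
        Qdraw = rng.gamma(alpha + n_ik)
        Q = Qdraw / Qdraw.sum(axis=1, keepdims=True)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        # (iv) alpha Metropolis (shared across clusters)
        sum_log_q = float(np.log(Q).sum())
        a_new = alpha + 0.25 * rng.standard_normal()
        if 0 < a_new < 10:
            dlog = _log_alpha_density(a_new, K, sum_log_q, n) - _log_alpha_density(
                alpha, K, sum_log_q, n
            )
            if np.log(rng.random()) < dlog:
                alpha = a_new

        if it >= burn and (it - burn) % thin == 0:
            lnL = float(np.log(Wsum_safe[valid]).sum())
            lnL_trace.append(lnL)
            Q_sum += Q
            P_sum += P
            alpha_samples.append(alpha)
            n_rec += 1

    Qbar = Q_sum / n_rec
    Pbar = P_sum / n_rec
    Pbar /= Pbar.sum(axis=2, keepdims=True)
    P_list = [Pbar[:, l, : m[l]] for l in range(L)]
    trace = np.array(lnL_trace)
    return AdmixtureResult(
        K=K, Q=Qbar, P=P_list, alpha=float(np.mean(alpha_samples)),
        lnL_trace=trace, mean_lnL=float(trace.mean()), var_lnL=float(trace.var(ddof=1)) if trace.size > 1 else 0.0,
        seed=seed, mcmc=mcmc,
    )


def _fit_k1(g, X, m, M, valid_allele, copy_ok2, Xs, rng, mcmc, seed,
            lambda_prior, code_maps):
    burn, iters, thin = mcmc
    n, L, _ = X.shape
    l_idx = np.arange(L)
    C = np.zeros((L, M))
    for l in range(L):
        col = X[:, l, :][X[:, l, :] >= 0]
        C[l] = np.bincount(col, minlength=M)
    P_sum = np.zeros((L, M))
    trace = []
    n_rec = 0
    for it in range(burn + iters):
        draw = rng.gamma(np.where(valid_allele, lambda_prior + C, 1e-12))
        draw *= valid_allele
        P = draw / draw.sum(axis=1, keepdims=True)
        if it >= burn and (it - burn) % thin == 0:
            px = P[l_idx[None, :, None], Xs]
            lnL = float(np.log(np.where(copy_ok2, np.where(px > 0, px, 1e-300), 1.0)).sum())
            trace.append(lnL)
            P_sum += P
            n_rec += 1
    Pbar = P_sum / n_rec
    Pbar /= Pbar.sum(axis=1, keepdims=True)
    tr = np.array(trace)
    return AdmixtureResult(
        K=1, Q=np.ones((n, 1)), P=[Pbar[l, : m[l]][None, :] for l in range(L)],
        alpha=np.nan, lnL_trace=tr, mean_lnL=float(tr.mean()),
        var_lnL=float(tr.var(ddof=1)) if tr.size > 1 else 0.0,
        seed=seed, mcmc=mcmc,
    )


# ---------------------------------------------------------------------------
# run alignment (CLUMPP-style) and similarity
# ---------------------------------------------------------------------------

def _align_to(reference: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Column permutation of Q minimizing ||reference - Q P||_F (exact, via
    the Hungarian assignment on column cross-products)."""
    cost = -reference.T @ Q                 # minimize => maximize sum of dot products
    rr, cc = linear_sum_assignment(cost)
    perm = np.empty_like(cc)
    perm[rr] = cc
    return Q[:, perm]


def similarity(Q1: np.ndarray, Q2: np.ndarray) -> float:
    """S(Q, Q') = 1 - ||Q - Q'||_F / sqrt(2 n): 1 iff equal, bounded in [0,1]."""
    n = Q1.shape[0]
    return 1.0 - np.linalg.norm(Q1 - Q2) / np.sqrt(2 * n)


def align_runs(
    runs: list[np.ndarray],
    n_orders: int = 100,
    seed: int | None = None,
):
    """Align replicate Q matrices across label switching.

    Each run is aligned to a growing mean reference (exact per-pair
    permutation via the Hungarian algorithm); several random input orders are
    tried and the one with the highest total pairwise similarity is kept.

    Returns ``(aligned runs, consensus Q, H')`` where H' is the mean pairwise
    similarity after alignment.
    """
    shapes = {q.shape for q in runs}
    if len(shapes) != 1:
        raise ValueError(f"mismatched Q shapes: {shapes}")
    if len(runs) == 1:
        return [runs[0].copy()], runs[0].copy(), 1.0
    rng = np.random.default_rng(seed)
    best = None
    R = len(runs)
    orders = [np.arange(R)] + [rng.permutation(R) for _ in range(max(0, n_orders - 1))]
    for order in orders:
        aligned: list[np.ndarray | None] = [None] * R
        ref = runs[order[0]].astype(float).copy()
        aligned[order[0]] = runs[order[0]]
        count = 1
        for idx in order[1:]:
            qa = _align_to(ref / count, runs[idx])
            aligned[idx] = qa
            ref += qa
            count += 1
        hsum = sum(
            similarity(aligned[i], aligned[j])
            for i, j in itertools.combinations(range(R), 2)
        )
        if best is None or hsum > best[0]:
            best = (hsum, [a.copy() for a in aligned])
    hsum, aligned = best
    n_pairs = R * (R - 1) // 2
    hprime = hsum / n_pairs
    consensus = np.mean(aligned, axis=0)
    consensus /= consensus.sum(axis=1, keepdims=True)
    return aligned, consensus, float(hprime)


# ---------------------------------------------------------------------------
# ensembles over K and the Evanno diagnostic
# ---------------------------------------------------------------------------

@dataclass
class RunEnsemble:
    k_values: tuple[int, ...]
    runs: dict[int, list[AdmixtureResult]]
    L_mean: dict[int, float]
    L_sd: dict[int, float]
    delta_k: dict[int, float]
    h_prime: dict[int, float]
    consensus: dict[int, np.ndarray]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "L(K)": [self.L_mean[k] for k in self.k_values],
                "s(K)": [self.L_sd[k] for k in self.k_values],
                "deltaK": [self.delta_k.get(k, np.nan) for k in self.k_values],
                "H_prime": [self.h_prime.get(k, np.nan) for k in self.k_values],
            },
            index=pd.Index(self.k_values, name="K"),
        )


def evanno_delta_k(L_mean: dict[int, float], L_sd: dict[int, float]) -> dict[int, float]:
    """Evanno et al. second-difference statistic
    ``deltaK = |L(K-1) - 2 L(K) + L(K+1)| / s(K)`` for interior K."""
    ks = sorted(L_mean)
    out = {}
    for k in ks[1:-1]:
        if k - 1 not in L_mean or k + 1 not in L_mean:
            continue
        num = abs(L_mean[k - 1] - 2 * L_mean[k] + L_mean[k + 1])
        s = L_sd[k]
        if s == 0:
            warnings.warn(f"s(K={k}) = 0; deltaK reported as +inf")
            out[k] = np.inf
        else:
            out[k] = num / s
    return out


def run_ensemble(
    g: GenotypeMatrix,
    k_range,
    n_runs: int = 3,
    mcmc: tuple[int, int, int] = (500, 2000, 10),
    model: str = "independent",
    seed: int | None = None,
    align_orders: int = 20,
) -> RunEnsemble:
    """Replicate admixture runs over a K range with diagnostics.

    L(K) is the per-run log-evidence estimate (mean lnL minus half its
    variance) averaged over runs; s(K) is its standard deviation over runs.
    """
    rng = np.random.default_rng(seed)
    ks = tuple(k_range)
    runs: dict[int, list[AdmixtureResult]] = {}
    L_mean, L_sd, h_prime, consensus = {}, {}, {}, {}
    for k in ks:
        runs[k] = [
            fit_admixture(g, k, mcmc=mcmc, model=model,
                          seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_runs)
        ]
        Ls = np.array([r.ln_prob_data for r in runs[k]])
        L_mean[k] = float(Ls.mean())
        L_sd[k] = float(Ls.std(ddof=1)) if n_runs > 1 else 0.0
        if k == 1:
            h_prime[k] = 1.0
            consensus[k] = np.ones((g.n_individuals, 1))
        else:
            _, cons, hp = align_runs([r.Q for r in runs[k]],
                                     n_orders=align_orders,
                                     seed=int(rng.integers(2**31 - 1)))
            h_prime[k] = hp
            consensus[k] = cons
    dk = evanno_delta_k(L_mean, L_sd)
    return RunEnsemble(ks, runs, L_mean, L_sd, dk, h_prime, consensus)


# ---------------------------------------------------------------------------
# threshold assignment
# ---------------------------------------------------------------------------

def assign_clusters(
    qbar: np.ndarray,
    q_star: float = 0.8,
    individuals: tuple[str, ...] | None = None,
    partition: Partition | None = None,
):
    """Assign individuals to clusters by the membership threshold.

    An individual is assigned to its argmax cluster (ties to the lowest
    index) when the maximum membership is >= ``q_star`` (inclusive);
    otherwise it is labelled ``"admixed"``.

    Returns ``(labels list, tallies DataFrame)``; tallies are per partition
    group when a partition is supplied, otherwise a single overall row.
    """
    qbar = np.asarray(qbar, dtype=float)
    if np.any(np.abs(qbar.sum(axis=1) - 1) > 1e-6):
        raise ValueError("Q rows must sum to 1")
    arg = np.argmax(qbar, axis=1)
    mx = qbar[np.arange(qbar.shape[0]), arg]
    labels = [f"cluster{a + 1}" if m >= q_star else "admixed" for a, m in zip(arg, mx)]
    K = qbar.shape[1]
    cols = [f"cluster{k + 1}" for k in range(K)] + ["admixed", "assigned_pct"]
    if partition is not None and individuals is not None:
        rows = {}
        for grp in partition.groups:
            members = [i for i, ind in enumerate(individuals)
                       if partition.labels.get(ind) == grp]
            cnt = {c: 0 for c in cols[:-1]}
            for i in members:
                cnt[labels[i]] += 1
            tot = len(members)
            cnt["assigned_pct"] = 100.0 * (tot - cnt["admixed"]) / tot if tot else np.nan
            rows[grp] = cnt
        tallies = pd.DataFrame(rows).T[cols]
    else:
        cnt = {c: 0 for c in cols[:-1]}
        for lab in labels:
            cnt[lab] += 1
        cnt["assigned_pct"] = 100.0 * (len(labels) - cnt["admixed"]) / len(labels)
        tallies = pd.DataFrame({"all": cnt}).T[cols]
    return labels, tallies
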