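"""Heterozygosity-excess test for recent bottlenecks, and the allele
frequency mode-shift test.

A population that recently crashed loses rare alleles faster than gene
diversity, so its expected heterozygosity H_e exceeds the equilibrium value
H_eq that a mutation-drift-equilibrium population with the same number of
alleles and sample size would show.  H_eq is obtained by simulating a
constant-size coalescent of ``n`` gene copies with mutations placed on
branches, conditioning on the observed allele count ``k`` by rejection (the
mutation rate is first tuned so the expected allele count matches ``k``).
Three mutation models are supported: IAM (every mutation creates a new
allele), SMM (+-1 repeat steps) and TPM (single step with probability
``p_single``, otherwise a geometric multi-step whose variance is
``variance_multi``).  Departures are aggregated over polymorphic loci with a
one-tailed Wilcoxon signed-rank test toward excess.

The mode-shift test pools alleles over loci into ten frequency classes of
width 0.1; a distribution whose modal class is not the rarest class (0-0.1)
is called "shifted", the qualitative signature of a bottleneck.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "TpmParams",
    "BottleneckReport",
    "HeqSimulator",
    "simulate_heq",
    "heterozygosity_excess_test",
    "mode_shift",
    "simulate_population",
]


@dataclass(frozen=True)
class TpmParams:
    """Two-phase model mixture: fraction of single-step mutations and the
    variance of the geometric multi-step component (defaults 0.95 / 12)."""

    p_single: float = 0.95
    variance_multi: float = 12.0

    def __post_init__(self):
        if not 0 <= self.p_single <= 1:
            raise ValueError("p_single must lie in [0, 1]")
        if self.variance_multi <= 0:
            raise ValueError("variance_multi must be positive")

    @property
    def geom_q(self) -> float:
        """Geometric success parameter with step variance = variance_multi.

        For magnitude ~ Geometric(q) on {1, 2, ...}, var = (1-q)/q^2; solving
        gives q = (sqrt(1 + 4 v) - 1) / (2 v)."""
        v = self.variance_multi
        return (np.sqrt(1 + 4 * v) - 1) / (2 * v)


# ---------------------------------------------------------------------------
# coalescent machinery
# ---------------------------------------------------------------------------

def _coalescent_branches(n: int, rng: np.random.Generator, size_history=None):
    """One Kingman genealogy of ``n`` tips.

    Returns ``(parent, blen)`` arrays over 2n-1 nodes (tips 0..n-1, root
    last).  ``size_history`` is an optional list of ``(t_start, rel_size)``
    epochs (time in units of 2N_0 generations, most recent first, starting at
    t=0) scaling the coalescence rate by 1/rel_size within each epoch.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    node_time = np.zeros(total)
    active = list(range(n))
    t = 0.0
    nxt = n
    if size_history is None:
        size_history = [(0.0, 1.0)]
    starts = [s for s, _ in size_history]
    sizes = [x for _, x in size_history]
    for j in range(n, 1, -1):
        rate = j * (j - 1) / 2.0
        # draw waiting time under piecewise-constant size
        while True:
            ei = max(i for i, s in enumerate(starts) if s <= t)
            scaled_rate = rate / sizes[ei]
            w = rng.exponential(1.0 / scaled_rate)
            nxt_boundary = starts[ei + 1] if ei + 1 < len(starts) else np.inf
            if t + w <= nxt_boundary:
                t += w
                break
            t = nxt_boundary
        a = rng.integers(j)
        b = rng.integers(j - 1)
        if b >= a:
            b += 1
        na, nb = active[a], active[b]
        parent[na] = parent[nb] = nxt
        node_time[nxt] = t
        active[max(a, b)] = nxt
        del active[min(a, b)]
        nxt += 1
    blen = np.zeros(total)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, blen


def _mutate_states(parent, blen, theta, model, tpm: TpmParams, rng):
    """Leaf allele states after placing Poisson(theta/2 * len) mutations per
    branch under the given model.  Returns an integer state per tip."""
    total = parent.size
    n = (total + 1) // 2
    n_mut = rng.poisson(theta / 2.0 * blen)
    state = np.zeros(total, dtype=np.int64)
    if model == "iam":
        # label = index of the most recent mutation on the path (0 = ancestral)
        next_label = 1
        for node in range(total - 2, -1, -1):   # root has no branch
            base = state[parent[node]]
            if n_mut[node] > 0:
                state[node] = next_label
                next_label += 1
            else:
                state[node] = base
    else:
        q = tpm.geom_q
        for node in range(total - 2, -1, -1):
            k = int(n_mut[node])
            step = 0
            if k:
                signs = rng.integers(0, 2, size=k) * 2 - 1
                if model == "smm":
                    mags = np.ones(k, dtype=np.int64)
                else:  # tpm
                    single = rng.random(k) < tpm.p_single
                    mags = np.where(single, 1, rng.geometric(q, size=k))
                step = int(np.sum(signs * mags))
            state[node] = state[parent[node]] + step
    return state[:n]


def _n_alleles_one_draw(n, theta, model, tpm, rng, size_history=None):
    parent, blen = _coalescent_branches(n, rng, size_history)
    return len(np.unique(_mutate_states(parent, blen, theta, model, tpm, rng)))


def _expected_k_iam(n: int, theta: float) -> float:
    """Ewens: E[k] = sum_{i=0}^{n-1} theta / (theta + i)."""
    i = np.arange(n)
    return float(np.sum(theta / (theta + i)))


def _tune_theta(n, k, model, tpm, rng, n_probe=150):
    """Bisection on log(theta) so the expected allele count matches k."""
    if model == "iam":
        lo, hi = 1e-4, 1e5
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if _expected_k_iam(n, mid) < k:
                lo = mid
            else:
                hi = mid
        return np.sqrt(lo * hi)
    lo, hi = 1e-3, 1e5

    def mean_k(th):
        return np.mean([
            _n_alleles_one_draw(n, th, model, tpm, rng) for _ in range(n_probe)
        ])

    for _ in range(14):
        mid = np.sqrt(lo * hi)
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def _unbiased_gene_diversity(states: np.ndarray) -> float:
    n = states.size
    _, cnt = np.unique(states, return_counts=True)
    p = cnt / n
    return n / (n - 1) * (1.0 - float(np.sum(p**2)))


class HeqSimulator:
    """Conditional H_eq sampler with a cache keyed by (n, k, model, tpm).

    Re-uses draws across loci and replicate datasets that share the same
    sample size and allele count — the conditional distribution of H_eq
    depends only on that triple.
    """

    def __init__(self, n_iter: int = 1000, seed: int | None = None,
                 max_attempt_factor: int = 400):
        self.n_iter = n_iter
        self.seed = seed
        self.max_attempt_factor = max_attempt_factor
        self._cache: dict[tuple, np.ndarray] = {}

    def draws(self, n: int, k: int, model: str, tpm: TpmParams = TpmParams()) -> np.ndarray:
        model = model.lower()
        if model not in ("iam", "smm", "tpm"):
            raise ValueError(f"unknown mutation model {model!r}")
        if not 1 <= k <= n:
            raise ValueError("need 1 <= k <= n gene copies")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        key = (n, k, model, tpm.p_single, tpm.variance_multi, self.n_iter)
        if key in self._cache:
            return self._cache[key]
        if k == 1:
            out = np.zeros(self.n_iter)
            self._cache[key] = out
            return out
        if k == n:
            warnings.warn(f"k = n = {n}: every copy distinct; H_eq near its maximum")
        # deterministic per-key seed so caching does not alter results
        sub = abs(hash((self.seed, key))) % (2**31 - 1)
        rng = np.random.default_rng(sub)
        theta = _tune_theta(n, k, model, tpm, rng)
        out = np.empty(self.n_iter)
        got = 0
        attempts = 0
        max_attempts = self.n_iter * self.max_attempt_factor
        while got < self.n_iter:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"rejection acceptance below 1/{self.max_attempt_factor} for "
                    f"(n={n}, k={k}, model={model}); widen tuning bounds"
                )
            parent, blen = _coalescent_branches(n, rng)
            states = _mutate_states(parent, blen, theta, model, tpm, rng)
            attempts += 1
            if len(np.unique(states)) == k:
                out[got] = _unbiased_gene_diversity(states)
                got += 1
        self._cache[key] = out
        return out


def simulate_heq(
    n: int,
    k: int,
    model: str,
    tpm: TpmParams = TpmParams(),
    n_iter: int = 1000,
    seed: int | None = None,
    simulator: HeqSimulator | None = None,
):
    """Equilibrium gene-diversity sample conditional on (n copies, k alleles).

    Returns ``(mean, sd, draws)``.
    """
    sim = simulator or HeqSimulator(n_iter=n_iter, seed=seed)
    draws = sim.draws(n, k, model, tpm)
    return float(draws.mean()), float(draws.std(ddof=1)) if draws.size > 1 else 0.0, draws


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

@dataclass
class BottleneckReport:
    group: str
    model: str
    per_locus: pd.DataFrame        # n, k, H_e, H_eq_mean, H_eq_sd, DH, excess_prob
    wilcoxon_p: float              # one-tailed, excess alternative
    n_loci_used: int


def heterozygosity_excess_test(
    g: GenotypeMatrix,
    p: Partition,
    group: str,
    model: str = "tpm",
    tpm: TpmParams = TpmParams(),
    n_iter: int = 1000,
    seed: int | None = None,
    simulator: HeqSimulator | None = None,
) -> BottleneckReport:
    """Heterozygosity-excess bottleneck test for one partition group.

    Per polymorphic locus the observed unbiased gene diversity H_e is
    compared with simulated H_eq conditional on the locus's gene-copy count
    and allele count; the one-tailed Wilcoxon signed-rank test aggregates the
    per-locus differences toward excess.  Monomorphic loci are excluded.
    """
    idx = p.group_indices(g)
    if group not in idx:
        raise ValueError(f"unknown group {group!r}")
    rows = idx[group]
    if rows.size < 10:
        warnings.warn(f"group {group!r} has only {rows.size} individuals")
    sim = simulator or HeqSimulator(n_iter=n_iter, seed=seed)
    records = []
    for l in range(g.n_loci):
        calls = g.calls[rows, l, :]
        calls = calls[calls[:, 0] != MISSING]
        copies = calls.ravel()
        if copies.size < 4:
            continue
        alleles, cnt = np.unique(copies, return_counts=True)
        k = alleles.size
        if k < 2:
            continue
        n = copies.size
        h_e = _unbiased_gene_diversity(copies)
        draws = sim.draws(n, k, model, tpm)
        mu, sd = float(draws.mean()), float(draws.std(ddof=1))
        med = float(np.median(draws))
        dh = (h_e - mu) / sd if sd > 0 else np.nan
        records.append(dict(
            locus=g.loci[l], n=n, k=k, H_e=h_e, H_eq_mean=mu, H_eq_sd=sd,
            H_eq_median=med, DH=dh, excess_prob=float(np.mean(draws < h_e)),
        ))
    if len(records) < 4:
        raise ValueError(f"only {len(records)} usable polymorphic loci (<4)")
    if len(records) < 10:
        warnings.warn(f"only {len(records)} polymorphic loci; >=10 recommended")
    df = pd.DataFrame(records).set_index("locus")
    # centering at the conditional MEDIAN keeps the one-tailed signed-rank
    # test calibrated: H_e | k is left-skewed, so mean-centering would put
    # more than half the null mass above zero
    diffs = (df["H_e"] - df["H_eq_median"]).to_numpy()
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        p_val = 1.0
    else:
        method = "exact" if (len(diffs) <= 25 and not np.any(diffs == 0)) else "approx"
        p_val = float(wilcoxon(diffs, alternative="greater", method=method).pvalue)
    return BottleneckReport(group=group, model=model.lower(), per_locus=df,
                            wilcoxon_p=p_val, n_loci_used=len(records))


def mode_shift(g: GenotypeMatrix, p: Partition, group: str):
    """Allele-frequency class histogram (10 classes of width 0.1) and the
    qualitative mode-shift call.

    Returns ``(histogram Series of proportions, "L-shaped" | "shifted")``;
    "shifted" means the modal class is not the rarest class (0-0.1).
    """
    idx = p.group_indices(g)
    if group not in idx:
        raise ValueError(f"unknown group {group!r}")
    rows = idx[group]
    freqs = []
    for l in range(g.n_loci):
        calls = g.calls[rows, l, :]
        copies = calls[calls[:, 0] != MISSING].ravel()
        if copies.size == 0:
            continue
        _, cnt = np.unique(copies, return_counts=True)
        if cnt.size < 2:
            continue
        freqs.extend((cnt / copies.size).tolist())
    if not freqs:
        raise ValueError("no polymorphic locus in group")
    freqs = np.asarray(freqs)
    edges = np.linspace(0, 1, 11)
    binned = np.clip(np.digitize(freqs, edges[1:-1], right=False), 0, 9)
    hist = np.bincount(binned, minlength=10) / freqs.size
    labels = [f"{edges[i]:.1f}-{edges[i + 1]:.1f}" for i in range(10)]
    series = pd.Series(hist, index=labels, name=group)
    verdict = "L-shaped" if int(np.argmax(hist)) == 0 else "shifted"
    return series, verdict


# ---------------------------------------------------------------------------
# equilibrium / crash data generator (for calibration studies)
# ---------------------------------------------------------------------------

def simulate_population(
    n_individuals: int,
    n_loci: int,
    theta: float,
    model: str = "smm",
    tpm: TpmParams = TpmParams(),
    size_history=None,
    seed: int | None = None,
    base_code: int = 120,
) -> GenotypeMatrix:
    """Coalescent sample of diploid genotypes from one population.

    ``theta = 4 N_0 mu`` refers to the present (epoch-0) size; an optional
    ``size_history`` of ``(t_start, rel_size)`` epochs (time in 2N_0
    generations) models size changes — e.g. a 100-fold crash ``t`` ago is
    ``[(0, 1), (t, 100)]``.  Loci are independent; allele codes are offset
    repeat states.
    """
    rng = np.random.default_rng(seed)
    n_copies = 2 * n_individuals
    calls = np.empty((n_individuals, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        parent, blen = _coalescent_branches(n_copies, rng, size_history)
        states = _mutate_states(parent, blen, theta, model.lower(), tpm, rng)
        states = states - states.min() + base_code
        perm = rng.permutation(n_copies)
        calls[:, l, 0] = states[perm[:n_individuals]]
        calls[:, l, 1] = states[perm[n_individuals:]]
    return GenotypeMatrix(
        tuple(f"ind{i:04d}" for i in range(n_individuals)),
        tuple(f"loc{l:02d}" for l in range(n_loci)),
        calls,
    )
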