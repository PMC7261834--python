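"""Coalescent ABC estimation of present/past effective-size ratios and
admixture proportions for a multi-population microsatellite panel.

A five-population scenario (configurable) is simulated with msprime: a rooted
population tree with split times, one size change per sampled population
(``r = N_present / N_past``, the inference target on a log10 scale), optional
admixture pulses (lineage reassignment with probability ``a`` at the event
time), and a generalized stepwise mutation model for repeat numbers.
Summary statistics per population (mean allele number, gene diversity,
allele-size variance, M-index) and per pair (Weir-Cockerham F_ST, shared
allele distance) feed a rejection sampler with optional local-linear
regression adjustment (Epanechnikov weights), the standard ABC recipe.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .differentiation import _theta
from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "DemographicScenario",
    "ABCResult",
    "default_scenario",
    "simulate_scenario",
    "summary_statistics",
    "abc_fit",
    "posterior_r_report",
]


@dataclass
class DemographicScenario:
    """A rooted multi-population scenario with size changes and admixture.

    Parameters
    ----------
    populations
        Sampled population names (leaves of the tree).
    sample_sizes
        Diploid individuals sampled per population.
    splits
        ``(time, (derived...), ancestral_name)`` population-split events,
        child events before parental merges (times in generations).
    n_present, n_past, t_change
        Per sampled population: present size, past size (before ``t_change``
        looking back), and the change time.  ``r = n_present / n_past``.
    admixture
        ``(time, target, source, proportion)`` pulses: at ``time`` (backward)
        each lineage in ``target`` derives from ``source`` with probability
        ``proportion``.
    mu, p_single
        Per-locus mutation rate per generation and the GSM single-step
        fraction (multi-step geometric with mean 1/m_geom).
    """

    populations: tuple[str, ...]
    sample_sizes: dict[str, int]
    splits: list[tuple]
    n_present: dict[str, float]
    n_past: dict[str, float]
    t_change: dict[str, float]
    admixture: list[tuple] = field(default_factory=list)
    ancestral_sizes: dict[str, float] = field(default_factory=dict)
    mu: float = 5e-4
    p_single: float = 0.95
    m_geom: float = 0.25
    repeat_bounds: tuple[int, int] = (1, 80)

    def __post_init__(self):
        for pop in self.populations:
            r = self.n_present[pop] / self.n_past[pop]
            if r <= 0:
                raise ValueError(f"size ratio must be positive for {pop!r}")
            if self.t_change[pop] <= 0:
                raise ValueError(f"change time must be positive for {pop!r}")
        for t, tgt, src, a in self.admixture:
            if not 0 <= a <= 1:
                raise ValueError(f"admixture proportion {a} outside [0, 1]")
        # child splits must precede parental merges
        merged_at = {}
        for t, derived, anc in self.splits:
            for d in derived:
                merged_at[d] = t
        for t, derived, anc in self.splits:
            if anc in merged_at and merged_at[anc] < t:
                raise ValueError(
                    f"split into {anc!r} at t={t} after {anc!r} itself merged at "
                    f"t={merged_at[anc]}"
                )

    def ratios(self) -> dict[str, float]:
        return {p: self.n_present[p] / self.n_past[p] for p in self.populations}


def default_scenario(
    sample_size: int = 20,
    n_present: float = 10_000.0,
    ratios: dict[str, float] | None = None,
    admix_props: tuple[float, float, float] = (0.3, 0.3, 0.3),
) -> DemographicScenario:
    """Five-cluster template: clusters 1+2 sister, 3+5 sister, 4 basal to
    (3,5), with three admixture pulses mirroring historical contact
    (2<-ancestral via root-adjacent pulse, 3<-5, 5<-1)."""
    pops = ("C1", "C2", "C3", "C4", "C5")
    ratios = ratios or {p: 1.0 for p in pops}
    n_pres = {p: n_present for p in pops}
    n_past = {p: n_present / ratios[p] for p in pops}
    t_change = {p: 800.0 for p in pops}
    # BASAL is an unsampled ghost lineage persisting from the present to the
    # root; it stands in for ancestral/basal germplasm as an admixture source
    splits = [
        (3000.0, ("C1", "C2"), "A12"),
        (2500.0, ("C3", "C5"), "A35"),
        (3500.0, ("A35", "C4"), "A345"),
        (5000.0, ("A12", "A345", "BASAL"), "ROOT"),
    ]
    a2, a3, a5 = admix_props
    admixture = [
        (500.0, "C5", "C1", a5),
        (600.0, "C3", "C5", a3),
        (1500.0, "C2", "BASAL", a2),
    ]
    return DemographicScenario(
        populations=pops,
        sample_sizes={p: sample_size for p in pops},
        splits=splits,
        n_present=n_pres,
        n_past=n_past,
        t_change=t_change,
        admixture=admixture,
        ancestral_sizes={"A12": n_present, "A35": n_present, "A345": n_present,
                         "BASAL": n_present, "ROOT": n_present},
    )


def _build_demography(s: DemographicScenario) -> msprime.Demography:
    dem = msprime.Demography()
    for pop in s.populations:
        dem.add_population(name=pop, initial_size=s.n_present[pop])
    for t, derived, anc in s.splits:
        for name in (*derived, anc):  # ghost lineages and ancestors
            if name not in [p.name for p in dem.populations]:
                dem.add_population(
                    name=name, initial_size=s.ancestral_sizes.get(name, 10_000.0)
                )
    for pop in s.populations:
        dem.add_population_parameters_change(
            time=s.t_change[pop], population=pop, initial_size=s.n_past[pop]
        )
    for t, tgt, src, a in s.admixture:
        if a > 0:
            dem.add_mass_migration(time=t, source=tgt, dest=src, proportion=a)
    for t, derived, anc in s.splits:
        dem.add_population_split(time=t, derived=list(derived), ancestral=anc)
    dem.sort_events()
    return dem


def simulate_scenario(
    s: DemographicScenario,
    n_loci: int,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, Partition]:
    """Simulate independent microsatellite loci under the scenario.

    Each locus is an independent coalescent; repeat-number mutations follow
    msprime's two-phase microsatellite model with the scenario's single-step
    fraction.  Diploid genotypes are formed from the sampled genomes within
    each population.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    dem = _build_demography(s)
    lo, hi = s.repeat_bounds
    mid = (lo + hi) // 2
    root_dist = np.zeros(hi - lo + 1)
    root_dist[mid - lo] = 1.0
    model = msprime.TPM(p=s.p_single, m=s.m_geom, lo=lo, hi=hi,
                        root_distribution=root_dist)
    samples = {p: s.sample_sizes[p] for p in s.populations}
    anc_seed, mut_seed = (int(rng.integers(1, 2**31 - 1)) for _ in range(2))
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=1, ploidy=2,
        num_replicates=n_loci, random_seed=anc_seed,
        discrete_genome=True,
    )
    n_total = sum(samples.values())
    calls = np.empty((n_total, n_loci, 2), dtype=np.int64)
    mut_rng = np.random.default_rng(mut_seed)
    pop_of_ind: list[str] = []
    for pop in s.populations:
        pop_of_ind.extend([pop] * samples[pop])
    for l, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=s.mu, model=model,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)),
        )
        states = np.full(mts.num_samples, mid, dtype=np.int64)
        for var in mts.variants():
            alleles = np.array([int(a) for a in var.alleles if a is not None])
            states = alleles[var.genotypes]
        calls[:, l, 0] = states[0::2]
        calls[:, l, 1] = states[1::2]
    ids = tuple(f"{pop_of_ind[i]}_{i:03d}" for i in range(n_total))
    g = GenotypeMatrix(ids, tuple(f"loc{l:02d}" for l in range(n_loci)), calls)
    part = Partition({ids[i]: pop_of_ind[i] for i in range(n_total)}, s.populations)
    return g, part


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summary_statistics(g: GenotypeMatrix, p: Partition) -> pd.Series:
    """Fixed-layout summary-statistic vector.

    Per population (in partition order): mean allele number, mean unbiased
    gene diversity, mean allele-size variance, mean M-index (alleles per unit
    of allele-size range, Garza-Williamson style); per population pair: W-C
    F_ST and mean shared-allele distance.  Allele codes act as sizes.
    """
    idx = p.group_indices(g)
    pops = [grp for grp in p.groups if grp in idx]
    vals, names = [], []
    freq_tables: dict[str, list] = {}
    for pop in pops:
        rows = idx[pop]
        if rows.size < 2:
            raise ValueError(f"population {pop!r} has <2 individuals")
        ks, divs, sizevars, ms = [], [], [], []
        tables = []
        for l in range(g.n_loci):
            calls = g.calls[rows, l, :]
            copies = calls[calls[:, 0] != MISSING].ravel()
            if copies.size < 2:
                tables.append(None)
                continue
            alleles, cnt = np.unique(copies, return_counts=True)
            pr = cnt / cnt.sum()
            tables.append(dict(zip(alleles.tolist(), pr.tolist())))
            ks.append(alleles.size)
            divs.append(copies.size / (copies.size - 1) * (1 - np.sum(pr**2)))
            sizevars.append(float(np.var(copies)))
            rng_size = alleles.max() - alleles.min() + 1
            ms.append(alleles.size / rng_size)
        freq_tables[pop] = tables
        polymorphic = any(k > 1 for k in ks)
        vals += [float(np.mean(ks)), float(np.mean(divs)),
                 float(np.mean(sizevars)),
                 float(np.mean(ms)) if polymorphic else np.nan]
        names += [f"{pop}_mean_k", f"{pop}_gene_div", f"{pop}_size_var", f"{pop}_M"]
    for pa, pb in itertools.combinations(pops, 2):
        theta = _theta(g, [idx[pa], idx[pb]])
        shared = []
        for ta, tb in zip(freq_tables[pa], freq_tables[pb]):
            if ta is None or tb is None:
                continue
            shared.append(1.0 - sum(min(v, tb.get(a, 0.0)) for a, v in ta.items()))
        vals += [theta, float(np.mean(shared)) if shared else np.nan]
        names += [f"{pa}_{pb}_fst", f"{pa}_{pb}_das"]
    return pd.Series(vals, index=names)


# ---------------------------------------------------------------------------
# rejection ABC with local-linear adjustment
# ---------------------------------------------------------------------------

@dataclass
class ABCResult:
    param_names: list[str]
    prior_draws: pd.DataFrame
    accepted: pd.DataFrame
    adjusted: pd.DataFrame
    distances: np.ndarray
    threshold: float
    n_accept: int

    def posterior(self, adjusted: bool = True) -> pd.DataFrame:
        return self.adjusted if adjusted else self.accepted

    def summary(self, adjusted: bool = True) -> pd.DataFrame:
        post = self.posterior(adjusted)
        rows = {}
        for name in self.param_names:
            x = post[name].to_numpy()
            rows[name] = dict(
                mode=_kde_mode(x), mean=float(x.mean()),
                ci_low=float(np.quantile(x, 0.025)),
                ci_high=float(np.quantile(x, 0.975)),
            )
        return pd.DataFrame(rows).T


def _kde_mode(x: np.ndarray) -> float:
    if np.allclose(x, x[0]):
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _draw_params(rng, s: DemographicScenario, log10_r_bounds=(-2.0, 2.0)):
    params = {}
    for pop in s.populations:
        params[f"log10_r_{pop}"] = rng.uniform(*log10_r_bounds)
    for i, (t, tgt, src, a) in enumerate(s.admixture):
        params[f"admix_{tgt}_from_{src}"] = rng.uniform(0.0, 1.0)
    return params


def _apply_params(s: DemographicScenario, params: dict) -> DemographicScenario:
    n_past = {p: s.n_present[p] / (10.0 ** params[f"log10_r_{p}"])
              for p in s.populations}
    admixture = [
        (t, tgt, src, params[f"admix_{tgt}_from_{src}"])
        for (t, tgt, src, _a) in s.admixture
    ]
    return DemographicScenario(
        populations=s.populations, sample_sizes=s.sample_sizes, splits=s.splits,
        n_present=s.n_present, n_past=n_past, t_change=s.t_change,
        admixture=admixture, ancestral_sizes=s.ancestral_sizes, mu=s.mu,
        p_single=s.p_single, m_geom=s.m_geom, repeat_bounds=s.repeat_bounds,
    )


def abc_fit(
    observed: pd.Series,
    s_template: DemographicScenario,
    n_sims: int = 2000,
    n_loci: int = 10,
    accept_rate: float = 0.05,
    adjust: str = "loclinear",
    seed: int | None = None,
    log10_r_bounds: tuple[float, float] = (-2.0, 2.0),
) -> ABCResult:
    """Rejection ABC over size ratios and admixture proportions.

    Priors: ``log10(r) ~ Uniform(-2, 2)`` per population and
    ``a ~ Uniform(0, 1)`` per admixture pulse.  Statistics are normalized by
    their simulated standard deviation; the closest ``accept_rate`` fraction
    in Euclidean distance is accepted, optionally followed by local-linear
    regression adjustment with Epanechnikov weights.
    """
    if n_sims < 100:
        raise ValueError("n_sims too small for a rejection sampler")
    if adjust not in ("none", "loclinear"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    rng = np.random.default_rng(seed)
    params_list, stats_list = [], []
    for i in range(n_sims):
        params = _draw_params(rng, s_template, log10_r_bounds)
        scen = _apply_params(s_template, params)
        g, p = simulate_scenario(scen, n_loci, seed=int(rng.integers(1, 2**31 - 1)))
        stats_list.append(summary_statistics(g, p))
        params_list.append(params)
    stats = pd.DataFrame(stats_list)
    prior_df = pd.DataFrame(params_list)
    obs = observed.reindex(stats.columns)
    # drop unusable statistics: zero simulated variance or NaN anywhere
    sd = stats.std(ddof=1)
    usable = (sd > 0) & stats.notna().all(axis=0) & obs.notna()
    if not usable.all():
        dropped = [c for c in stats.columns if not usable[c]]
        warnings.warn(f"dropping {len(dropped)} unusable statistics: {dropped[:6]}...")
    S = stats.loc[:, usable].to_numpy()
    o = obs[usable.index[usable]].to_numpy()
    scale = sd[usable].to_numpy()
    Z = (S - o) / scale
    dist = np.sqrt(np.sum(Z**2, axis=1))
    n_acc = max(2, int(round(accept_rate * n_sims)))
    order = np.argsort(dist)
    acc_idx = order[:n_acc]
    threshold = float(dist[acc_idx[-1]])
    accepted = prior_df.iloc[acc_idx].reset_index(drop=True)
    adjusted = accepted.copy()
    if adjust == "loclinear" and threshold > 0:
        w = 1.0 - (dist[acc_idx] / threshold) ** 2          # Epanechnikov
        w = np.maximum(w, 1e-8)
        # regress on leading principal components of the normalized stats so
        # the local regression stays well-posed when the accepted count is
        # comparable to the statistic count
        n_comp = min(15, max(2, n_acc // 4), Z.shape[1])
        _, _, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
        proj = Vt[:n_comp].T
        X = np.column_stack([np.ones(n_acc), Z[acc_idx] @ proj])
        sw = np.sqrt(w)
        for name in prior_df.columns:
            y = accepted[name].to_numpy()
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            adjusted[name] = y - (X @ beta - beta[0])
        for name in adjusted.columns:
            if name.startswith("admix_"):
                adjusted[name] = adjusted[name].clip(0.0, 1.0)
            if name.startswith("log10_r_"):
                adjusted[name] = adjusted[name].clip(*log10_r_bounds)
    return ABCResult(
        param_names=list(prior_df.columns), prior_draws=prior_df,
        accepted=accepted, adjusted=adjusted, distances=dist,
        threshold=threshold, n_accept=n_acc,
    )


def posterior_r_report(
    res: ABCResult,
    dead_zone: float = 0.25,
    tv_uninformative: float = 0.1,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Classify each log10(r) posterior as bottleneck / stable / expansion.

    The call uses the posterior mode with a dead zone ``|mode| < 0.25`` for
    "stable"; parameters whose posterior is indistinguishable from the prior
    (total-variation distance below ``tv_uninformative`` on a common grid)
    are flagged uninformative.
    """
    post = res.posterior(adjusted)
    rows = {}
    for name in res.param_names:
        x = post[name].to_numpy()
        pr = res.prior_draws[name].to_numpy()
        mode = _kde_mode(x)
        lo = min(x.min(), pr.min())
        hi = max(x.max(), pr.max())
        grid = np.linspace(lo, hi, 256)
        if np.allclose(x, x[0]) or np.allclose(pr, pr[0]):
            tv = 1.0
        else:
            d_post = gaussian_kde(x)(grid)
            d_prior = gaussian_kde(pr)(grid)
            d_post /= np.trapezoid(d_post, grid)
            d_prior /= np.trapezoid(d_prior, grid)
            tv = 0.5 * float(np.trapezoid(np.abs(d_post - d_prior), grid))
        if name.startswith("log10_r_"):
            if mode < -dead_zone:
                call = "bottleneck"
            elif mode > dead_zone:
                call = "expansion"
            else:
                call = "stable"
        else:
            call = "-"
        rows[name] = dict(
            mode=mode,
            ci_low=float(np.quantile(x, 0.025)),
            ci_high=float(np.quantile(x, 0.975)),
            prior_posterior_tv=tv,
            uninformative=tv < tv_uninformative,
            classification=call,
        )
    return pd.DataFrame(rows).T
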