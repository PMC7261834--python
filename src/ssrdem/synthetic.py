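"""Forward simulation of admixed microsatellite genotype panels.

Clusters are modelled with the F-model: cluster ``k`` draws its allele
frequencies at each locus from ``Dirichlet(p_anc * (1 - F_k) / F_k)``, so the
per-cluster drift parameter ``F_k`` is on the same scale as the F_ST the
cluster accumulates away from the ancestral pool.  Individuals carry an
admixture proportion vector over clusters; every allele copy first picks its
cluster of origin from that vector, then an allele from the cluster's locus
frequencies, which makes genotype frequencies Hardy-Weinberg within a pure
cluster in expectation.

``worldwide_preset`` emulates a worldwide apricot germplasm panel: 890
accessions in 7 geographic groups, 25 loci with 18-32 ancestral alleles,
5 latent clusters with a global among-cluster F_ST around 0.17, and ~1/3 of
accessions admixed (maximum membership < 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, Partition

__all__ = [
    "GeneratorSpec",
    "sample_cluster_frequencies",
    "generate_genotypes",
    "worldwide_preset",
    "WORLDWIDE_GROUPS",
    "WORLDWIDE_GROUP_SIZES",
]


@dataclass
class GeneratorSpec:
    """Parameters of the admixed F-model generator.

    Parameters
    ----------
    K
        Number of latent clusters.
    ancestral_freqs
        Per-locus ancestral allele-frequency vectors (list of 1-D arrays that
        each sum to 1).  Allele codes are ``base_code + index`` per locus.
    F
        Per-cluster drift parameter in (0, 1), length ``K``.
    admixture
        ``(n, K)`` row-stochastic matrix of individual mixing proportions.
    missing_rate, null_allele_rate
        Per-call missing probability; per-locus probability that one allele
        is a silent (null) allele.
    seed
        Seed for all randomness in the generator.
    """

    K: int
    ancestral_freqs: list[np.ndarray]
    F: np.ndarray
    admixture: np.ndarray
    missing_rate: float = 0.0
    null_allele_rate: float = 0.0
    seed: int = 0
    base_code: int = 101

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.admixture = np.asarray(self.admixture, dtype=float)
        self.ancestral_freqs = [np.asarray(p, dtype=float) for p in self.ancestral_freqs]
        if self.K < 1 or self.F.shape != (self.K,):
            raise ValueError("F must have one entry per cluster")
        if np.any(self.F <= 0) or np.any(self.F >= 1):
            raise ValueError("F must lie in (0, 1)")
        if self.admixture.ndim != 2 or self.admixture.shape[1] != self.K:
            raise ValueError("admixture must be (n, K)")
        if np.any(np.abs(self.admixture.sum(axis=1) - 1) > 1e-9):
            raise ValueError("admixture rows must sum to 1")
        if not (0 <= self.missing_rate < 1 and 0 <= self.null_allele_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        for l, p in enumerate(self.ancestral_freqs):
            if np.any(p < 0) or abs(p.sum() - 1) > 1e-8:
                raise ValueError(f"ancestral frequencies at locus {l} not a simplex vector")

    @property
    def n(self) -> int:
        return self.admixture.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.ancestral_freqs)


def sample_cluster_frequencies(spec: GeneratorSpec, rng: np.random.Generator | None = None):
    """Draw per-cluster allele frequencies from the F-model Dirichlet.

    Returns a list over loci of ``(K, m_l)`` frequency arrays.  Ancestral
    alleles with frequency 0 are dropped (with a warning) before drawing.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    freqs = []
    for l, p_anc in enumerate(spec.ancestral_freqs):
        keep = p_anc > 0
        if not np.all(keep):
            warnings.warn(f"locus {l}: dropping {int((~keep).sum())} zero-frequency ancestral alleles")
            p_anc = p_anc[keep] / p_anc[keep].sum()
        out = np.empty((spec.K, p_anc.size))
        for k in range(spec.K):
            conc = p_anc * (1.0 - spec.F[k]) / spec.F[k]
            draw = rng.gamma(conc)
            tot = draw.sum()
            if tot == 0:  # extreme drift: all gamma mass collapsed
                draw[rng.integers(p_anc.size)] = 1.0
                tot = 1.0
            out[k] = draw / tot
        freqs.append(out)
    return freqs


def generate_genotypes(spec: GeneratorSpec, freqs=None, individual_ids=None):
    """Simulate genotypes under the admixed F-model.

    Returns
    -------
    (GenotypeMatrix, Partition, np.ndarray)
        Matrix, true-label partition (argmax of the admixture row, ties to the
        lowest cluster index), and the true ``(n, K)`` Q matrix (the design).
    """
    rng = np.random.default_rng(spec.seed)
    if freqs is None:
        freqs = sample_cluster_frequencies(spec, rng)
    n, L, K = spec.n, spec.n_loci, spec.K
    calls = np.empty((n, L, 2), dtype=np.int64)
    # cluster of origin per allele copy: (n, L, 2)
    q_cum = np.cumsum(spec.admixture, axis=1)
    u = rng.random((n, L, 2))
    origin = (u[..., None] > q_cum[:, None, None, :]).sum(axis=-1)
    for l in range(L):
        P = freqs[l]                      # (K, m)
        cum = np.cumsum(P, axis=1)
        v = rng.random((n, 2))
        idx = (v[..., None] > cum[origin[:, l], :]).sum(axis=-1)
        calls[:, l, :] = spec.base_code + idx
    # null alleles: a locus is affected with prob null_allele_rate; the
    # designated null is the allele whose cluster-mean frequency is closest
    # to 0.3 — a moderate-frequency null, detectable but not disruptive.
    for l in range(L):
        if spec.null_allele_rate > 0 and rng.random() < spec.null_allele_rate:
            mean_p = freqs[l].mean(axis=0)
            null_code = spec.base_code + int(np.argmin(np.abs(mean_p - 0.3)))
            is_null = calls[:, l, :] == null_code
            both = is_null.all(axis=1)
            one = is_null.any(axis=1) & ~both
            calls[both, l, :] = MISSING
            # heterozygote for the null appears homozygous for the visible allele
            vis = np.where(is_null[one, 0], calls[one, l, 1], calls[one, l, 0])
            calls[one, l, 0] = vis
            calls[one, l, 1] = vis
    if spec.missing_rate > 0:
        drop = rng.random((n, L)) < spec.missing_rate
        calls[drop] = MISSING
    if individual_ids is None:
        individual_ids = tuple(f"ind{i:04d}" for i in range(n))
    loci = tuple(f"loc{l:02d}" for l in range(L))
    g = GenotypeMatrix(tuple(individual_ids), loci, calls)
    true_labels = np.argmax(spec.admixture, axis=1)
    part = Partition(
        {ind: f"cluster{true_labels[i] + 1}" for i, ind in enumerate(g.individuals)},
        tuple(f"cluster{k + 1}" for k in sorted(set(true_labels.tolist()))),
    )
    return g, part, spec.admixture.copy()


# ---------------------------------------------------------------------------
# worldwide panel preset
# ---------------------------------------------------------------------------

WORLDWIDE_GROUPS = (
    "EasternAsia", "CentralAsia", "IranoCaucasian", "ContinentalEurope",
    "MediterraneanEurope", "NorthAfrica", "America",
)
# group sizes of the emulated panel (sums to 890)
WORLDWIDE_GROUP_SIZES = (67, 142, 86, 86, 250, 214, 45)

# per-cluster drift parameters; the spread mirrors the panel's diversity
# gradient (Central Asia lowest drift / highest diversity, Continental Europe
# strongest drift) and puts the realized global among-cluster F_ST near 0.17.
_WORLDWIDE_F = (0.13, 0.05, 0.15, 0.42, 0.17)

# group -> cluster composition: (cluster index, proportion of the group)
_GROUP_CLUSTERS = {
    "EasternAsia": ((0, 1.0),),
    "CentralAsia": ((1, 1.0),),
    "IranoCaucasian": ((2, 1.0),),
    "ContinentalEurope": ((3, 1.0),),
    "MediterraneanEurope": ((4, 1.0),),
    "NorthAfrica": ((2, 0.6), (4, 0.4)),
    "America": ((4, 0.6), (1, 0.4)),
}
# fraction of each group given admixed ancestry (max membership < 0.8);
# overall ~30% of the panel, America mostly admixed
_GROUP_ADMIXED = {
    "EasternAsia": 0.15,
    "CentralAsia": 0.20,
    "IranoCaucasian": 0.30,
    "ContinentalEurope": 0.15,
    "MediterraneanEurope": 0.35,
    "NorthAfrica": 0.38,
    "America": 0.60,
}
# admixture partners follow the panel's contact zones (Asian clusters mix
# with each other; the Mediterranean/Irano-Caucasian clusters mix westward;
# America mixes its two source pools)
_GROUP_PARTNERS = {
    "EasternAsia": (1,),
    "CentralAsia": (0,),
    "IranoCaucasian": (4,),
    "ContinentalEurope": (4,),
    "MediterraneanEurope": (2, 0),
    "NorthAfrica": (2, 4),
    "America": (4, 1),
}


def _admixed_row(rng, K, main, other):
    """A mixing row between two clusters with max proportion < 0.8."""
    w = rng.uniform(0.40, 0.78)
    row = np.zeros(K)
    row[main] = w
    row[other] = 1.0 - w
    return row


def worldwide_preset(seed: int = 0, missing_rate: float = 0.02):
    """Synthetic stand-in for the 890-accession worldwide apricot panel.

    Returns
    -------
    (GenotypeMatrix, Partition, np.ndarray, Partition)
        Matrix (890 x 25), geographic partition (7 groups), true Q (890 x 5),
        and the true-cluster partition (argmax labels).
    """
    rng = np.random.default_rng(seed)
    K, L = 5, 25
    n_alleles = rng.integers(18, 33, size=L)
    ancestral = [np.sort(rng.dirichlet(np.full(m, 1.0)))[::-1] for m in n_alleles]
    rows, geo_labels, ids = [], {}, []
    i = 0
    for grp, size in zip(WORLDWIDE_GROUPS, WORLDWIDE_GROUP_SIZES):
        comp = _GROUP_CLUSTERS[grp]
        clusters = [c for c, _ in comp]
        weights = np.array([w for _, w in comp])
        adm_frac = _GROUP_ADMIXED[grp]
        n_adm = int(round(adm_frac * size))
        for j in range(size):
            ind = f"{grp}_{j:03d}"
            main = clusters[int(rng.choice(len(clusters), p=weights / weights.sum()))]
            if j < n_adm:
                partners = [k for k in _GROUP_PARTNERS[grp] if k != main]
                other = int(rng.choice(partners)) if partners else (main + 1) % K
                rows.append(_admixed_row(rng, K, main, other))
            else:
                row = np.zeros(K)
                row[main] = 1.0
                rows.append(row)
            ids.append(ind)
            geo_labels[ind] = grp
            i += 1
    admixture = np.array(rows)
    spec = GeneratorSpec(
        K=K,
        ancestral_freqs=ancestral,
        F=np.array(_WORLDWIDE_F),
        admixture=admixture,
        missing_rate=missing_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    g, cluster_part, true_q = generate_genotypes(spec, individual_ids=ids)
    geo = Partition(geo_labels, WORLDWIDE_GROUPS)
    return g, geo, true_q, cluster_part
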