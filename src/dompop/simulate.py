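"""Forward simulation of dominant-marker populations with known history.

Homosporous ferns can reproduce through three sexual modes —
intragametophytic selfing (one bisexual gametophyte fertilises itself,
producing a fully homozygous sporophyte in a single step),
intergametophytic selfing (gametophytes from spores of the same parent
sporophyte; analogous to selfing in seed plants) and intergametophytic
crossing (gametophytes from different sporophytes; analogous to
outcrossing) — and also vegetatively, where a clonal lineage accumulates
heritable somatic band mutations.  This module generates band matrices
under each regime, and mixtures of the two, with the full truth (diploid
genotypes, genealogy, sexual/clonal labels) attached, so that every
analysis stage of the package can be validated against a known
generating process.  A direct sampler from the hierarchical
beta-binomial model used for Bayesian differentiation is included as
well.

Defaults mirror a typical dominant-marker population survey: 20
individuals per population, 102 loci, founder presence-allele
frequencies drawn uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .matrix import MarkerMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_sexual",
    "simulate_clonal",
    "simulate_population",
    "simulate_from_hierarchy",
]

Mode = Literal["crossing", "inter_selfing", "intra_selfing", "clonal", "mixed"]


@dataclass
class SimConfig:
    """Parameters of a band-matrix simulation.

    ``founder_beta`` are the Beta(a, b) shape parameters of the
    per-locus presence-allele frequency among founders; ``somatic_mu``
    is the per-locus probability of a band flip at each clonal birth;
    ``sexual_fraction`` applies only to ``mixed`` mode and sets the
    expected share of sexually derived (recombinant) individuals.
    """

    n_pops: int = 1
    n_individuals: int = 20
    n_loci: int = 102
    founder_beta: tuple[float, float] = (1.0, 1.0)
    mode: Mode = "crossing"
    sexual_fraction: float = 0.25
    n_generations: int = 10
    somatic_mu: float = 0.01
    infinite_sites: bool = True
    n_founder_genets: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sexual_fraction <= 1.0):
            raise ValueError("sexual_fraction must be in [0, 1]")
        if not (0.0 <= self.somatic_mu <= 1.0):
            raise ValueError("somatic_mu must be in [0, 1]")
        for name in ("n_pops", "n_individuals", "n_founder_genets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_loci < 0:
            raise ValueError("n_loci must be nonnegative")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated matrix."""

    mode: str
    seed: int | None
    #: per-population diploid genotypes (n, L, 2), sexual modes only
    diploid: dict[str, np.ndarray] = field(default_factory=dict)
    #: per individual: "sexual" or "clonal"
    labels: dict[str, str] = field(default_factory=dict)
    #: per-population genealogy: child individual -> parent individual
    genealogy: dict[str, dict[str, str | None]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _pop_names(k: int) -> list[str]:
    return [f"P{i + 1}" for i in range(k)]


def _ind_names(pop: str, n: int) -> list[str]:
    return [f"{pop}_i{j + 1:02d}" for j in range(n)]


def _gamete(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """One haploid gamete of a diploid (L, 2) individual; loci unlinked."""
    pick = rng.integers(0, 2, size=parent.shape[0])
    return parent[np.arange(parent.shape[0]), pick]


def _sexual_pop(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Diploid genotypes (n, L, 2) after ``n_generations`` of one mating mode."""
    a, b = cfg.founder_beta
    p = rng.beta(a, b, size=cfg.n_loci)
    pop = (rng.random((cfg.n_individuals, cfg.n_loci, 2)) < p[None, :, None]).astype(np.int8)
    if cfg.mode == "crossing" and cfg.n_individuals < 2:
        raise ValueError("crossing needs at least two founders")
    for _ in range(cfg.n_generations):
        nxt = np.empty_like(pop)
        for i in range(cfg.n_individuals):
            if cfg.mode == "crossing":
                m, f = rng.choice(cfg.n_individuals, size=2, replace=False)
                nxt[i, :, 0] = _gamete(rng, pop[m])
                nxt[i, :, 1] = _gamete(rng, pop[f])
            elif cfg.mode == "inter_selfing":
                m = rng.integers(cfg.n_individuals)
                nxt[i, :, 0] = _gamete(rng, pop[m])
                nxt[i, :, 1] = _gamete(rng, pop[m])
            elif cfg.mode == "intra_selfing":
                m = rng.integers(cfg.n_individuals)
                g = _gamete(rng, pop[m])
                nxt[i, :, 0] = g
                nxt[i, :, 1] = g
            else:
                raise ValueError(f"not a sexual mode: {cfg.mode}")
        pop = nxt
    return pop


def simulate_sexual(config: SimConfig) -> tuple[MarkerMatrix, SimTruth]:
    """Simulate sexually reproducing populations; dominance renders the
    band phenotype as presence of at least one presence allele."""
    if config.mode not in ("crossing", "inter_selfing", "intra_selfing"):
        raise ValueError(f"simulate_sexual cannot run mode {config.mode!r}")
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(config.mode, config.seed, params=asdict(config))
    rows, inds, pops = [], [], []
    for pop in _pop_names(config.n_pops):
        dip = _sexual_pop(rng, config)
        truth.diploid[pop] = dip
        names = _ind_names(pop, config.n_individuals)
        truth.labels.update({nm: "sexual" for nm in names})
        rows.append(dip.max(axis=2))  # dominance
        inds.extend(names)
        pops.extend([pop] * config.n_individuals)
    bands = (np.concatenate(rows, axis=0) if rows
             else np.empty((0, config.n_loci), dtype=np.int8))
    loci = [f"L{j + 1:03d}" for j in range(config.n_loci)]
    return MarkerMatrix(bands.astype(np.int8), inds, pops, loci), truth


def _founder_phenotype(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Band vector of a founder genet under Hardy-Weinberg dominance."""
    a, b = cfg.founder_beta
    p = rng.beta(a, b, size=cfg.n_loci)
    dip = (rng.random((cfg.n_loci, 2)) < p[:, None]).astype(np.int8)
    return dip.max(axis=1)


def _clonal_lineage(rng: np.random.Generator, cfg: SimConfig,
                    n_members: int) -> tuple[np.ndarray, list[int | None]]:
    """Grow a clonal lineage to *n_members* band vectors.

    Each birth copies a uniformly chosen existing ramet and applies
    somatic band flips.  Under infinite sites the number of flips per
    birth is Poisson(somatic_mu * n_loci) and every flip consumes a
    locus never mutated before anywhere in the lineage, so the lineage
    is guaranteed to fit a perfect phylogeny; otherwise each locus flips
    independently with probability somatic_mu and recurrent flips can
    occur.  Returns the vectors and the parent index of each member
    (None for founders).
    """
    founders = [
        _founder_phenotype(rng, cfg) for _ in range(min(cfg.n_founder_genets, n_members))
    ]
    members = [f.copy() for f in founders]
    parents: list[int | None] = [None] * len(members)
    unused = list(range(cfg.n_loci))
    while len(members) < n_members:
        k = int(rng.integers(len(members)))
        child = members[k].copy()
        if cfg.infinite_sites:
            n_mut = int(rng.poisson(cfg.somatic_mu * cfg.n_loci))
            if n_mut > len(unused):
                raise ValueError(
                    "infinite-sites lineage exhausted its unmutated loci; "
                    "lower somatic_mu or raise n_loci"
                )
            for _ in range(n_mut):
                j = unused.pop(int(rng.integers(len(unused))))
                child[j] ^= 1
        else:
            flips = rng.random(cfg.n_loci) < cfg.somatic_mu
            child[flips] ^= 1
        members.append(child)
        parents.append(k)
    return np.array(members, dtype=np.int8), parents


def _recombine(rng: np.random.Generator, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Free recombination of two band vectors: each locus from a random one."""
    pick = rng.random(u.shape[0]) < 0.5
    return np.where(pick, u, v).astype(np.int8)


def simulate_clonal(config: SimConfig) -> tuple[MarkerMatrix, SimTruth]:
    """Simulate clonal (and mixed clonal/sexual) populations.

    In ``clonal`` mode every individual belongs to the lineage of one or
    a few founder genets, diversified only by somatic mutation.  In
    ``mixed`` mode a fraction ``sexual_fraction`` of individuals are
    recombinants, each produced by freely recombining the band vectors
    of two distinct lineage members — the footprint sexual reproduction
    leaves on a largely clonal population.
    """
    if config.mode not in ("clonal", "mixed"):
        raise ValueError(f"simulate_clonal cannot run mode {config.mode!r}")
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(config.mode, config.seed, params=asdict(config))
    rows, inds, pops = [], [], []
    for pop in _pop_names(config.n_pops):
        n = config.n_individuals
        n_sex = round(config.sexual_fraction * n) if config.mode == "mixed" else 0
        n_clonal = n - n_sex
        if n_clonal < 1:
            raise ValueError("mixed mode needs at least one clonal individual")
        lineage, parents = _clonal_lineage(rng, config, n_clonal)
        names = _ind_names(pop, n)
        vecs = list(lineage)
        genealogy: dict[str, str | None] = {}
        for i in range(n_clonal):
            truth.labels[names[i]] = "clonal"
            genealogy[names[i]] = None if parents[i] is None else names[parents[i]]
        for i in range(n_clonal, n):
            if n_clonal >= 2:
                u, v = rng.choice(n_clonal, size=2, replace=False)
            else:
                u = v = 0
            vecs.append(_recombine(rng, lineage[u], lineage[v]))
            truth.labels[names[i]] = "sexual"
            genealogy[names[i]] = f"{names[u]}+{names[v]}"
        truth.genealogy[pop] = genealogy
        rows.append(np.array(vecs, dtype=np.int8))
        inds.extend(names)
        pops.extend([pop] * n)
    bands = np.concatenate(rows, axis=0)
    loci = [f"L{j + 1:03d}" for j in range(config.n_loci)]
    return MarkerMatrix(bands, inds, pops, loci), truth


def simulate_population(config: SimConfig) -> tuple[MarkerMatrix, SimTruth]:
    """Dispatch on ``config.mode``."""
    if config.mode in ("crossing", "inter_selfing", "intra_selfing"):
        return simulate_sexual(config)
    return simulate_clonal(config)


def simulate_from_hierarchy(K: int, L: int, n: int, theta: float, seed=None):
    """Draw band-absent counts directly from the differentiation model.

    pi_l ~ Uniform(0, 1); q_kl ~ Beta(pi_l (1-theta)/theta,
    (1-pi_l)(1-theta)/theta); x_kl ~ Binomial(n, q_kl^2).  Returns a
    :class:`~dompop.bayes.BandCounts` and a truth dict holding the
    generating ``theta``, ``pi`` and ``q``.
    """
    from .bayes import BandCounts  # local import: avoid cycle

    if not (0.0 < theta < 1.0):
        raise ValueError("theta must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pi = rng.uniform(size=L)
    scale = (1.0 - theta) / theta
    q = rng.beta(pi * scale, (1.0 - pi) * scale, size=(K, L))
    x = rng.binomial(n, q ** 2)
    counts = BandCounts(
        n=np.full((K, L), n, dtype=int),
        x=x.astype(int),
        populations=_pop_names(K),
        locus_ids=[f"L{j + 1:03d}" for j in range(L)],
    )
    return counts, {"theta": theta, "pi": pi, "q": q}
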