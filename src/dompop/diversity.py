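"""Per-population diversity statistics for dominant markers.

A dominant band reveals only two phenotypes: band present (the dominant
homozygote or heterozygote) and band absent (the recessive null
homozygote).  Assuming Hardy-Weinberg proportions within a population,
the null-allele frequency at a locus is estimated as the square root of
the band-absent phenotype frequency, q = sqrt(n_absent / n_scored),
without small-sample correction.  From p = 1 - q the usual summaries
follow: observed (na) and effective (ne = 1/(p^2+q^2)) allele numbers,
Nei's gene diversity h = 1 - p^2 - q^2, and the per-locus Shannon
information term over the two estimated allele frequencies,
S = -(p ln p + q ln q).  Population values are per-locus averages over
the retained loci; the confidence interval for mean S comes from a
percentile bootstrap over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, MarkerMatrix, filter_population_loci

__all__ = [
    "LocusDiversity",
    "PopulationDiversity",
    "locus_diversity",
    "population_diversity",
    "shannon_ci",
    "compare_populations",
]


@dataclass
class LocusDiversity:
    """Diversity summaries of a single dominant locus."""

    band_freq: float  #: fraction of scored individuals with the band
    q: float  #: null (band-absent) allele frequency, sqrt estimator
    p: float  #: presence-allele frequency, 1 - q
    na: int  #: observed number of alleles (1 or 2 phenotypes seen)
    ne: float  #: effective number of alleles, 1 / (p^2 + q^2)
    h: float  #: Nei's gene diversity, 1 - p^2 - q^2
    s: float  #: Shannon information term, -(p ln p + q ln q)


@dataclass
class PopulationDiversity:
    """Per-locus averages for one population (one row of a summary table)."""

    population: str
    n_individuals: int
    n_loci: int
    n_poly: int
    pct_poly: float
    mean_na: float
    mean_ne: float
    mean_h: float
    mean_s: float
    s_ci: tuple[float, float] | None = None


def locus_diversity(band_column) -> LocusDiversity:
    """Diversity of one band column (entries 0/1/missing) of one population."""
    col = np.asarray(band_column, dtype=np.int8)
    scored = col[col != MISSING]
    n = scored.size
    if n == 0:
        raise ValueError("locus has no scored entries; filter loci first")
    n_absent = int((scored == 0).sum())
    f = 1.0 - n_absent / n
    q = float(np.sqrt(n_absent / n))
    p = 1.0 - q
    na = 2 if 0 < n_absent < n else 1
    hom = p * p + q * q
    h = 1.0 - hom
    ne = 1.0 / hom
    s = 0.0
    if 0.0 < q < 1.0:
        s = -(p * np.log(p) + q * np.log(q))
    return LocusDiversity(f, q, p, na, ne, h, float(s))


def _per_locus(m: MarkerMatrix) -> list[LocusDiversity]:
    return [locus_diversity(m.bands[:, j]) for j in range(m.n_loci)]


def population_diversity(m: MarkerMatrix, pop: str,
                         n_boot: int | None = 1000,
                         seed=None) -> PopulationDiversity:
    """Per-locus-averaged diversity of one population.

    A locus is polymorphic when both phenotypes occur among its scored
    individuals.  When *n_boot* is given the bootstrap interval for the
    mean Shannon term is attached.
    """
    sub = filter_population_loci(m, pop)
    stats_ = _per_locus(sub)
    n_poly = sum(1 for s in stats_ if s.na == 2)
    n_loci = len(stats_)
    out = PopulationDiversity(
        population=pop,
        n_individuals=sub.n_individuals,
        n_loci=n_loci,
        n_poly=n_poly,
        pct_poly=100.0 * n_poly / n_loci if n_loci else 0.0,
        mean_na=float(np.mean([s.na for s in stats_])),
        mean_ne=float(np.mean([s.ne for s in stats_])),
        mean_h=float(np.mean([s.h for s in stats_])),
        mean_s=float(np.mean([s.s for s in stats_])),
    )
    if n_boot:
        out.s_ci = shannon_ci(m, pop, n_boot=n_boot, seed=seed)
    return out


def _mean_shannon(bands: np.ndarray) -> float:
    """Mean per-locus Shannon term of a (replicates x individuals x loci)
    or (individuals x loci) band array; loci with no scored entry in a
    replicate are skipped."""
    if bands.ndim == 2:
        bands = bands[None]
    scored = bands != MISSING
    n = scored.sum(axis=1)  # (reps, loci)
    absent = (bands == 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.sqrt(absent / n)
        p = 1.0 - q
        term = -(np.where(p > 0, p * np.log(p), 0.0)
                 + np.where(q > 0, q * np.log(q), 0.0))
    term = np.where(n > 0, term, np.nan)
    out = np.nanmean(term, axis=1)
    return float(out[0]) if out.size == 1 else out


def shannon_ci(m: MarkerMatrix, pop: str, n_boot: int = 1000,
               seed=None) -> tuple[float, float]:
    """Percentile bootstrap 95% interval for the mean Shannon term.

    Individuals of the population are resampled with replacement
    *n_boot* times and the per-locus-averaged Shannon term recomputed on
    each resample; the interval is the (2.5, 97.5) percentile pair.
    """
    sub = filter_population_loci(m, pop)
    if sub.n_individuals < 2:
        raise ValueError("bootstrap needs at least two individuals")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sub.n_individuals, size=(n_boot, sub.n_individuals))
    means = _mean_shannon(sub.bands[idx])
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def compare_populations(values_a, values_b):
    """Mann-Whitney U test between two per-locus diversity samples.

    Returns ``(U, p)`` for the first sample, two-sided.  The exact null
    distribution is used for small tie-free samples (both n <= 20);
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def diversity_table(m: MarkerMatrix, n_boot: int = 1000, seed=None) -> pd.DataFrame:
    """Summary-table of :func:`population_diversity` over all populations."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for pop, child in zip(m.population_labels, ss.spawn(len(m.population_labels))):
        d = population_diversity(m, pop, n_boot=n_boot, seed=child)
        rows.append({
            "population": d.population,
            "n_individuals": d.n_individuals,
            "n_loci": d.n_loci,
            "n_poly": d.n_poly,
            "pct_poly": round(d.pct_poly, 2),
            "mean_na": round(d.mean_na, 4),
            "mean_ne": round(d.mean_ne, 4),
            "mean_h": round(d.mean_h, 4),
            "mean_s": round(d.mean_s, 4),
            "s_ci_low": round(d.s_ci[0], 4),
            "s_ci_high": round(d.s_ci[1], 4),
        })
    return pd.DataFrame(rows)


def pairwise_mannwhitney(m: MarkerMatrix, statistic: str = "h") -> pd.DataFrame:
    """Pairwise population comparisons of per-locus diversity values.

    *statistic* selects the per-locus value compared: ``"h"`` (Nei's
    gene diversity) or ``"s"`` (Shannon term).
    """
    if statistic not in ("h", "s"):
        raise ValueError("statistic must be 'h' or 's'")
    pops = m.population_labels
    per_pop = {}
    for pop in pops:
        sub = filter_population_loci(m, pop)
        per_pop[pop] = [getattr(s, statistic) for s in _per_locus(sub)]
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            U, pval = compare_populations(per_pop[a], per_pop[b])
            rows.append({"pop_a": a, "pop_b": b, "U": U, "p_value": pval})
    return pd.DataFrame(rows)
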