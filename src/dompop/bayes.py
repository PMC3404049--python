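"""Bayesian differentiation (theta^B, an F_ST analogue) from dominant bands.

The model is the f-free hierarchical beta-binomial for dominant markers.
For population k and locus l let q_kl be the null (band-absent) allele
frequency.  Under Hardy-Weinberg proportions the band-absent phenotype
has probability q_kl^2, so the observed band-absent count is

    x_kl ~ Binomial(n_kl, q_kl^2),

and the population frequencies are tied together by a common ancestral
frequency pi_l with dispersion controlled by theta:

    q_kl ~ Beta(pi_l (1-theta)/theta, (1-pi_l)(1-theta)/theta),
    pi_l ~ Uniform(0, 1),      theta ~ Uniform(0, 1).

Var(q_kl | pi_l) = pi_l (1-pi_l) theta, which is Wright's definition of
F_ST, so the posterior of theta measures differentiation between the
populations.  "f-free" refers to the within-population inbreeding
coefficient f being fixed at zero: dominant data from the populations
alone carry essentially no information about f, so the phenotype
likelihood assumes random mating within populations.

Sampling is Metropolis-within-Gibbs in the *non-centred*
parameterisation (theta, pi_l, u_kl), where u_kl is the Beta-CDF rank
of q_kl under its prior: a Gaussian random walk on logit(theta) and on
each logit(u_kl), and a reflected random walk on (0, 1) for each pi_l,
with step sizes tuned to a 20-40% acceptance rate during burn-in and
frozen afterwards (preserving detailed balance for the sampling run).
Because the ranks are iid uniform whatever (theta, pi) is, the prior
cancels exactly from the theta and pi acceptance ratios — only the
binomial likelihood, evaluated at the materialised
q = F^{-1}(u; pi, theta), enters.  The non-centred walk remains exact
in the funnel at theta -> 1 (where q is pushed onto the boundaries and
a centred walk on q cannot follow), and with no data it reduces to a
free walk whose theta marginal is exactly the Uniform(0, 1) prior.
Deviance summaries (Dbar, pD, DIC) follow the standard definitions with
the binomial likelihood evaluated at the retained q draws and at their
posterior mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, betaincinv, expit, gammaln, logit

from .matrix import MISSING, MarkerMatrix

__all__ = [
    "BandCounts",
    "ThetaPosterior",
    "model_loglik",
    "sample_theta",
    "pairwise_theta",
    "theta_table",
]


@dataclass
class BandCounts:
    """Sufficient statistics: per population x locus, the number of
    scored individuals ``n`` and the band-absent count ``x``."""

    n: np.ndarray  # (K, L) int
    x: np.ndarray  # (K, L) int
    populations: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        if self.n.shape != self.x.shape or self.n.ndim != 2:
            raise ValueError("n and x must be 2-D arrays of equal shape")
        if ((self.x < 0) | (self.x > self.n)).any():
            raise ValueError("need 0 <= x <= n elementwise")
        if not self.populations:
            self.populations = [f"P{i + 1}" for i in range(self.n.shape[0])]

    @property
    def n_pops(self) -> int:
        return self.n.shape[0]

    @property
    def n_loci(self) -> int:
        return self.n.shape[1]

    @classmethod
    def from_matrix(cls, m: MarkerMatrix, pops: list[str] | None = None) -> "BandCounts":
        """Tally scored and band-absent individuals per population/locus."""
        pops = pops or m.population_labels
        K, L = len(pops), m.n_loci
        n = np.zeros((K, L), dtype=int)
        x = np.zeros((K, L), dtype=int)
        plist = np.asarray(m.populations)
        for k, pop in enumerate(pops):
            sub = m.bands[plist == pop]
            if sub.shape[0] == 0:
                raise ValueError(f"population {pop!r} has no individuals")
            n[k] = (sub != MISSING).sum(axis=0)
            x[k] = (sub == 0).sum(axis=0)
        return cls(n, x, list(pops), list(m.locus_ids))


@dataclass
class ThetaPosterior:
    """Posterior summary of theta^B for one population pair (or set)."""

    samples: np.ndarray  #: retained theta draws, all chains concatenated
    point: float  #: posterior mean
    ci95: tuple[float, float]  #: equal-tailed 2.5/97.5 percentiles
    dbar: float  #: posterior mean deviance
    pd: float  #: effective number of parameters, Dbar - D(posterior-mean q)
    dic: float  #: Dbar + pD
    schedule: tuple[int, int, int]  #: (burn_in, run_length, thin)
    n_chains: int = 1
    diagnostics: dict = field(default_factory=dict)


def model_loglik(q: np.ndarray, counts: BandCounts) -> float:
    """Binomial log likelihood of band-absent counts given null-allele
    frequencies ``q`` (same shape as the count arrays)."""
    q = np.asarray(q, dtype=float)
    if q.shape != counts.n.shape:
        raise ValueError("q must match the counts' shape")
    if ((q <= 0.0) | (q >= 1.0)).any():
        raise ValueError("q entries must lie strictly in (0, 1)")
    n, x = counts.n, counts.x
    coef = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return float(np.sum(coef + 2.0 * x * np.log(q) + (n - x) * np.log1p(-(q * q))))


def _deviance(q, n, x, coef) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(x > 0, 2.0 * x * np.log(q), 0.0)
        t2 = np.where(n > x, (n - x) * np.log1p(-(q * q)), 0.0)
    return -2.0 * float(np.sum(coef + t1 + t2))


def _reflect01(v: np.ndarray) -> np.ndarray:
    r = np.mod(v, 2.0)
    return np.where(r > 1.0, 2.0 - r, r)


class _Chain:
    """One Metropolis-within-Gibbs chain (internal).

    The canonical state is the *non-centred* parameterisation
    (theta, pi, u), where u_kl = F(q_kl; a_l, b_l) is the Beta-CDF rank
    of the null-allele frequency.  Under the hierarchy the ranks are
    iid Uniform(0, 1) whatever theta and pi are, so every prior term
    cancels from the theta and pi acceptance ratios: holding u fixed,
    those moves are accepted on the likelihood ratio alone, with q
    merely *materialised* through the quantile map
    q = F^{-1}(u; a, b) to evaluate the likelihood.  This keeps the
    sampler exact in the funnel (theta -> 1 forces q onto the
    boundaries, where a centred random walk on q cannot follow) and
    makes the no-data posterior of theta exactly its Uniform(0, 1)
    prior.
    """

    def __init__(self, counts: BandCounts, rng: np.random.Generator):
        self.n = counts.n.astype(float)
        self.x = counts.x.astype(float)
        self.K, self.L = counts.n.shape
        self.rng = rng
        self.coef = (gammaln(self.n + 1) - gammaln(self.x + 1)
                     - gammaln(self.n - self.x + 1))
        # moment-style initialisation, pushed off the boundaries
        q0 = np.clip(np.sqrt((self.x + 0.5) / (self.n + 1.0)), 0.05, 0.95)
        self.pi = np.clip(q0.mean(axis=0), 0.05, 0.95)
        self.theta = 0.2
        a, b = self._ab(self.pi, self.theta)
        self.u = betainc(a[None, :], b[None, :], q0)
        self.q = q0
        self.loglik = self._loglik(q0)  # cached per-cell log likelihood
        # steps: logit-u walk, pi walk, logit-theta walk
        self.steps = np.array([0.8, 0.08, 0.4])
        self.acc = np.zeros(3)
        self.prop = np.zeros(3)

    def _ab(self, pi, theta):
        s = (1.0 - theta) / theta
        return pi * s, (1.0 - pi) * s

    def _materialise(self, pi, theta) -> np.ndarray:
        a, b = self._ab(pi, theta)
        return betaincinv(a[None, :], b[None, :], self.u)

    def _loglik(self, q) -> np.ndarray:
        """Per-cell binomial log likelihood (constants dropped).

        Guarded so that cells whose term has a zero coefficient
        contribute exactly 0 even when the materialised q sits on a
        boundary (log q or log(1 - q^2) = -inf there).
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(self.x > 0, 2.0 * self.x * np.log(q), 0.0)
            t2 = np.where(self.n > self.x,
                          (self.n - self.x) * np.log1p(-(q * q)), 0.0)
        return t1 + t2

    def update_u(self):
        """Logit random walk on the ranks; q follows through the quantile."""
        z = logit(self.u) + self.rng.normal(0.0, self.steps[0], size=self.u.shape)
        up = expit(z)
        np.clip(up, 1e-15, 1.0 - 1e-15, out=up)
        a, b = self._ab(self.pi, self.theta)
        qp = betaincinv(a[None, :], b[None, :], up)
        llp = self._loglik(qp)
        jac = (np.log(up) + np.log1p(-up)
               - np.log(self.u) - np.log1p(-self.u))
        accept = np.log(self.rng.random(size=self.u.shape)) < llp - self.loglik + jac
        self.u = np.where(accept, up, self.u)
        self.q = np.where(accept, qp, self.q)
        self.loglik = np.where(accept, llp, self.loglik)
        self.acc[0] += accept.mean()
        self.prop[0] += 1.0

    def update_pi(self):
        """Reflected random walk on each pi_l, ranks held fixed."""
        pip = _reflect01(self.pi + self.rng.normal(0.0, self.steps[1], size=self.L))
        np.clip(pip, 1e-12, 1.0 - 1e-12, out=pip)
        qp = self._materialise(pip, self.theta)
        llp = self._loglik(qp)
        delta = (llp - self.loglik).sum(axis=0)
        accept = np.log(self.rng.random(size=self.L)) < delta
        self.pi = np.where(accept, pip, self.pi)
        self.q = np.where(accept[None, :], qp, self.q)
        self.loglik = np.where(accept[None, :], llp, self.loglik)
        self.acc[1] += accept.mean()
        self.prop[1] += 1.0

    def update_theta(self):
        """Logit random walk on theta, ranks held fixed."""
        zt = logit(self.theta) + self.rng.normal(0.0, self.steps[2])
        tp = float(np.clip(expit(zt), 1e-12, 1.0 - 1e-12))
        qp = self._materialise(self.pi, tp)
        llp = self._loglik(qp)
        # logit-walk Jacobian: d(theta)/d(logit theta) = theta (1 - theta)
        jac = (np.log(tp) + np.log1p(-tp)
               - np.log(self.theta) - np.log1p(-self.theta))
        delta = float((llp - self.loglik).sum()) + jac
        if np.log(self.rng.random()) < delta:
            self.theta = tp
            self.q = qp
            self.loglik = llp
            self.acc[2] += 1.0
        self.prop[2] += 1.0

    def sweep(self):
        self.update_u()
        self.update_pi()
        self.update_theta()

    def tune(self):
        """Nudge step sizes toward 20-40% acceptance; reset counters."""
        rates = self.acc / np.maximum(self.prop, 1.0)
        self.steps[rates > 0.40] *= 1.25
        self.steps[rates < 0.20] *= 0.80
        self.steps[1] = min(self.steps[1], 0.5)
        self.acc[:] = 0.0
        self.prop[:] = 0.0


def _run_chain(counts: BandCounts, burn_in: int, run_length: int, thin: int,
               rng: np.random.Generator):
    ch = _Chain(counts, rng)
    for it in range(burn_in):
        ch.sweep()
        if (it + 1) % 100 == 0:
            ch.tune()
    ch.acc[:] = 0.0
    ch.prop[:] = 0.0
    draws = []
    dev_sum = 0.0
    q_sum = np.zeros_like(ch.q)
    n_ret = 0
    nf, xf = ch.n, ch.x
    for it in range(run_length):
        ch.sweep()
        if (it + 1) % thin == 0:
            draws.append(ch.theta)
            dev_sum += _deviance(ch.q, nf, xf, ch.coef)
            q_sum += ch.q
            n_ret += 1
    rates = (ch.acc / np.maximum(ch.prop, 1.0)).tolist()
    return (np.asarray(draws), dev_sum, q_sum, n_ret,
            {"accept_u": rates[0], "accept_pi": rates[1],
             "accept_theta": rates[2], "steps": ch.steps.tolist()})


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Potential scale reduction on split chains (Gelman-Rubin)."""
    halves = []
    for c in chains:
        h = len(c) // 2
        if h >= 2:
            halves.extend([c[:h], c[h:2 * h]])
    if len(halves) < 2:
        return float("nan")
    m = len(halves)
    n = min(len(h) for h in halves)
    arr = np.stack([h[:n] for h in halves])
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W <= 0:
        return float("nan")
    return float(np.sqrt((n - 1) / n + B / (n * W)))


def sample_theta(counts: BandCounts, burn_in: int = 50_000,
                 run_length: int = 250_000, thin: int = 50,
                 seed=None, n_chains: int = 3) -> ThetaPosterior:
    """Posterior of theta^B for one set of populations.

    Runs ``n_chains`` independent replicate chains (distinct streams
    derived from *seed*), pools the retained draws, and attaches a
    split-chain potential-scale-reduction diagnostic; Rhat above 1.1
    raises a warning, not an error.  The default schedule retains 5000
    draws per chain (burn-in 50 000, run 250 000, every 50th kept).
    """
    if counts.n_pops < 2:
        raise ValueError("theta^B needs at least two populations")
    if run_length < thin:
        raise ValueError("run_length must be at least thin (no draws retained)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chains, diags = [], []
    dev_sum, n_ret = 0.0, 0
    q_sum = np.zeros(counts.n.shape)
    for child in ss.spawn(n_chains):
        draws, dsum, qsum, nr, diag = _run_chain(
            counts, burn_in, run_length, thin, np.random.default_rng(child))
        chains.append(draws)
        diags.append(diag)
        dev_sum += dsum
        q_sum += qsum
        n_ret += nr
    samples = np.concatenate(chains)
    dbar = dev_sum / n_ret
    qbar = q_sum / n_ret
    coef = (gammaln(counts.n + 1) - gammaln(counts.x + 1)
            - gammaln(counts.n - counts.x + 1))
    dhat = _deviance(np.clip(qbar, 1e-12, 1 - 1e-12),
                     counts.n.astype(float), counts.x.astype(float), coef)
    pd_ = dbar - dhat
    rhat = _split_rhat(chains)
    if np.isfinite(rhat) and rhat > 1.1:
        warnings.warn(f"theta^B chains may not have converged (split Rhat = {rhat:.3f})",
                      RuntimeWarning, stacklevel=2)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return ThetaPosterior(
        samples=samples,
        point=float(samples.mean()),
        ci95=(float(lo), float(hi)),
        dbar=float(dbar),
        pd=float(pd_),
        dic=float(dbar + pd_),
        schedule=(burn_in, run_length, thin),
        n_chains=n_chains,
        diagnostics={"split_rhat": rhat, "chains": diags},
    )


def pairwise_theta(m: MarkerMatrix, burn_in: int = 50_000,
                   run_length: int = 250_000, thin: int = 50,
                   seed=None, n_chains: int = 3) -> dict[tuple[str, str], ThetaPosterior]:
    """theta^B posterior for every unordered population pair.

    The RNG stream of each pair is derived from *seed* and the pair's
    position in the sorted pair list, so theta(A, B) == theta(B, A)
    exactly and reruns with the same seed reproduce every draw.
    """
    pops = m.population_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: dict[tuple[str, str], ThetaPosterior] = {}
    for pair, child in zip(pairs, ss.spawn(len(pairs))):
        counts = BandCounts.from_matrix(m, list(pair))
        out[pair] = sample_theta(counts, burn_in, run_length, thin,
                                 seed=child, n_chains=n_chains)
    return out


def theta_table(posteriors: dict[tuple[str, str], ThetaPosterior],
                digits: int = 4) -> pd.DataFrame:
    """Square table with point estimates above the diagonal and 95%
    intervals below it."""
    pops: list[str] = []
    for a, b in posteriors:
        for p in (a, b):
            if p not in pops:
                pops.append(p)
    df = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for (a, b), post in posteriors.items():
        i, j = pops.index(a), pops.index(b)
        hi, lo = max(i, j), min(i, j)
        df.iloc[lo, hi] = f"{post.point:.{digits}f}"
        df.iloc[hi, lo] = f"{post.ci95[0]:.{digits}f}, {post.ci95[1]:.{digits}f}"
    return df
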