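"""Selection-signature scan: pooled F_ST and a Bayesian outlier model.

Two contrasts are run per insecticide line: an F0 contrast (unexposed
founders vs LD80 survivors) and an F2 contrast (unexposed F2 vs LD25 and
LD75 survivors). Only substitutions enter the scan.

The outlier model decomposes locus-by-population differentiation
logistically, logit F_ST(i,j) = alpha_i + beta_j, where beta_j captures the
population-specific drift/selection intensity shared by all loci and
alpha_i a locus-specific departure from neutrality. Observed allele counts
are beta-binomial around an ancestral frequency p_i with overdispersion
theta_ij = exp(-(alpha_i + beta_j)) = (1 - F_ST)/F_ST. A reversible-jump
MCMC switches each alpha_i in and out of the model with prior odds for
neutrality; the per-locus posterior probability of selection is the
inclusion frequency, converted to q-values by averaging posterior error
probabilities down the ranking.

Pooled read counts stand in for allele samples of effective haploid size
min(2 x pool size, depth) — the standard pool-seq compromise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .conditions import Condition, Line, Stage
from .tables import AlleleCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """A set of member conditions compared within one line."""

    label: str  # "F0_contrast" or "F2_contrast"
    line: Line
    members: tuple[str, ...]

    @classmethod
    def f0(cls, line: Line) -> "Contrast":
        return cls(
            "F0_contrast", line, ("F0", Condition(line, Stage.F0_LD80).label)
        )

    @classmethod
    def f2(cls, line: Line) -> "Contrast":
        return cls(
            "F2_contrast",
            line,
            tuple(
                Condition(line, s).label
                for s in (Stage.F2, Stage.F2_LD25, Stage.F2_LD75)
            ),
        )


@dataclass
class ScanConfig:
    """MCMC settings; defaults follow the scan's published schedule.

    ``chain_factor`` scales every chain length; the desk preset (factor 0.1)
    is the default for tests and small synthetic runs.
    """

    prior_odds: float = 10.0
    pilot_runs: int = 20
    pilot_iters: int = 2000
    burn_in: int = 100_000
    iterations: int = 500_000
    thinning: int = 50
    chain_factor: float = 1.0
    pool_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pilot_runs", "pilot_iters", "burn_in", "iterations", "thinning"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prior_odds <= 0 or self.chain_factor <= 0:
            raise ValueError("prior_odds and chain_factor must be positive")
        if self.iterations % self.thinning:
            raise ValueError("thinning must divide iterations")

    @classmethod
    def desk(cls, **kwargs) -> "ScanConfig":
        kwargs.setdefault("chain_factor", 0.1)
        return cls(**kwargs)

    @property
    def eff_burn_in(self) -> int:
        return max(1, int(self.burn_in * self.chain_factor))

    @property
    def eff_iterations(self) -> int:
        n = max(self.thinning, int(self.iterations * self.chain_factor))
        return n - n % self.thinning

    @property
    def eff_pilot_iters(self) -> int:
        return max(1, int(self.pilot_iters * self.chain_factor))


def _is_substitution(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1


def _effective_counts(
    counts: AlleleCountTable, members: tuple[str, ...], pool_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale read counts to effective haploid samples min(2*pool, depth)."""
    alt = np.stack([counts.alt_counts(m) for m in members], axis=1).astype(float)
    dep = np.stack([counts.depth(m) for m in members], axis=1).astype(float)
    ok = (dep > 0).all(axis=1)
    n_eff = np.minimum(2 * pool_size, dep)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_eff = np.where(dep > 0, np.round(alt * n_eff / dep), 0.0)
    return a_eff, n_eff, ok


def pooled_fst(
    counts: AlleleCountTable, contrast: Contrast, config: ScanConfig | None = None
) -> np.ndarray:
    """Per-locus moment-based multi-population F_ST on pooled read counts.

    Haploid analysis-of-variance estimator with sample sizes equal to the
    effective pool haploid size; clipped to [0, 1]. Loci with zero depth in
    any member are NaN.
    """
    config = config or ScanConfig()
    a, n, ok = _effective_counts(counts, contrast.members, config.pool_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = a / n
        J = len(contrast.members)
        ntot = n.sum(axis=1)
        pbar = (n * p).sum(axis=1) / ntot
        msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (J - 1)
        msg = (n * p * (1 - p)).sum(axis=1) / (n - 1).sum(axis=1)
        nc = (ntot - (n**2).sum(axis=1) / ntot) / (J - 1)
        denom = msp + (nc - 1) * msg
        theta = np.where(denom > 0, (msp - msg) / np.where(denom > 0, denom, 1.0), 0.0)
    theta = np.clip(theta, 0.0, 1.0)
    theta[~ok] = np.nan
    return theta


def q_values(posterior_probs: np.ndarray) -> np.ndarray:
    """q-value per locus: mean posterior error probability (1 - prob) over
    all loci at least as highly ranked, monotone along the ranking."""
    p = np.asarray(posterior_probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    order = np.argsort(-p, kind="mergesort")
    pep = 1.0 - p[order]
    q_sorted = np.cumsum(pep) / np.arange(1, len(p) + 1)
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _loglik_mat(
    a: np.ndarray, n: np.ndarray, p: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Beta-binomial log-likelihood per locus and population (constants
    dropped). ``theta`` broadcasts to (L, J)."""
    tp = theta * p[:, None]
    tq = theta * (1.0 - p)[:, None]
    return (
        gammaln(a + tp)
        + gammaln(n - a + tq)
        - gammaln(n + theta)
        - gammaln(tp)
        - gammaln(tq)
        + gammaln(theta)
    )


def _col_loglik(
    a: np.ndarray, n: np.ndarray, p: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Single-population column of the log-likelihood (all 1-D arrays)."""
    tp = theta * p
    tq = theta * (1.0 - p)
    return (
        gammaln(a + tp)
        + gammaln(n - a + tq)
        - gammaln(n + theta)
        - gammaln(tp)
        - gammaln(tq)
        + gammaln(theta)
    )


_PEPS = 1e-6
_ALPHA_SD = 1.0  # prior sd of locus effects
_BETA_MEAN, _BETA_SD = -1.0, 1.8  # prior on population effects


class _ScanState:
    """Mutable MCMC state with cached per-locus log-likelihood."""

    def __init__(self, a, n, config: ScanConfig, rng: np.random.Generator):
        self.a, self.n = a, n
        self.L, self.J = a.shape
        self.rng = rng
        self.log_prior_odds = np.log(config.prior_odds)
        with np.errstate(divide="ignore"):
            init = (a.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0)
        self.p = np.clip(init, _PEPS, 1 - _PEPS)
        self.alpha = np.zeros(self.L)
        self.incl = np.zeros(self.L, dtype=bool)
        self.beta = np.full(self.J, _BETA_MEAN)
        self.w_p = np.full(self.L, 0.2)
        self.w_a = np.full(self.L, 0.5)
        self.w_b = np.full(self.J, 0.2)
        self.ll_mat = self._full_mat(self.p, self.alpha * self.incl, self.beta)
        self.ll = self.ll_mat.sum(axis=1)

    def _theta(self, eff_alpha, beta):
        # exponent clipped: F_ST pinned to (~1e-22, ~1) keeps gammaln finite
        return np.exp(np.clip(-(eff_alpha[:, None] + beta[None, :]), -50.0, 50.0))

    def _full_mat(self, p, eff_alpha, beta):
        return _loglik_mat(self.a, self.n, p, self._theta(eff_alpha, beta))

    def update_p(self) -> np.ndarray:
        prop = self.p + self.rng.uniform(-1, 1, self.L) * self.w_p
        prop = np.abs(prop)  # reflect at 0
        prop = 1 - np.abs(1 - prop)  # reflect at 1
        prop = np.clip(prop, _PEPS, 1 - _PEPS)
        mat = self._full_mat(prop, self.alpha * self.incl, self.beta)
        ll_prop = mat.sum(axis=1)
        accept = np.log(self.rng.random(self.L)) < (ll_prop - self.ll)
        self.p[accept] = prop[accept]
        self.ll_mat[accept] = mat[accept]
        self.ll[accept] = ll_prop[accept]
        return accept

    def update_alpha(self) -> np.ndarray:
        idx = np.flatnonzero(self.incl)
        accept = np.zeros(self.L, dtype=bool)
        if idx.size == 0:
            return accept
        prop = self.alpha[idx] + self.rng.normal(0, 1, idx.size) * self.w_a[idx]
        theta = np.exp(np.clip(-(prop[:, None] + self.beta[None, :]), -50.0, 50.0))
        mat = _loglik_mat(self.a[idx], self.n[idx], self.p[idx], theta)
        ll_prop = mat.sum(axis=1)
        log_prior = (self.alpha[idx] ** 2 - prop**2) / (2 * _ALPHA_SD**2)
        ok = np.log(self.rng.random(idx.size)) < (ll_prop - self.ll[idx] + log_prior)
        sel = idx[ok]
        self.alpha[sel] = prop[ok]
        self.ll_mat[sel] = mat[ok]
        self.ll[sel] = ll_prop[ok]
        accept[sel] = True
        return accept

    def jump(self) -> None:
        """Reversible-jump toggle of every locus's alpha inclusion.

        Inclusion proposals draw alpha* from its Normal prior, so the
        acceptance ratio reduces to the likelihood ratio over the prior
        odds for neutrality.
        """
        draw = self.rng.normal(0, _ALPHA_SD, self.L)
        alpha_prop = np.where(self.incl, self.alpha, draw)
        eff_prop = np.where(self.incl, 0.0, alpha_prop)
        mat = self._full_mat(self.p, eff_prop, self.beta)
        ll_prop = mat.sum(axis=1)
        penalty = np.where(self.incl, self.log_prior_odds, -self.log_prior_odds)
        accept = np.log(self.rng.random(self.L)) < (ll_prop - self.ll + penalty)
        self.incl[accept] = ~self.incl[accept]
        self.alpha[accept] = alpha_prop[accept]
        self.ll_mat[accept] = mat[accept]
        self.ll[accept] = ll_prop[accept]

    def update_beta(self) -> np.ndarray:
        eff_alpha = self.alpha * self.incl
        accepted = np.zeros(self.J, dtype=bool)
        for j in range(self.J):
            prop = self.beta[j] + self.rng.normal(0, self.w_b[j])
            th_new = np.exp(np.clip(-(eff_alpha + prop), -50.0, 50.0))
            ll_old = self.ll_mat[:, j]
            ll_new = _col_loglik(self.a[:, j], self.n[:, j], self.p, th_new)
            delta = (ll_new - ll_old).sum()
            delta += ((self.beta[j] - _BETA_MEAN) ** 2 - (prop - _BETA_MEAN) ** 2) / (
                2 * _BETA_SD**2
            )
            if np.log(self.rng.random()) < delta:
                self.beta[j] = prop
                self.ll += ll_new - ll_old
                self.ll_mat[:, j] = ll_new
                accepted[j] = True
        return accepted

    def sweep(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        acc_p = self.update_p()
        acc_a = self.update_alpha()
        self.jump()
        acc_b = self.update_beta()
        return acc_p, acc_a, acc_b


def _adapt(width: np.ndarray, rate: np.ndarray, lo=0.25, hi=0.45) -> None:
    width[rate > hi] *= 1.4
    width[rate < lo] /= 1.4
    np.clip(width, 1e-4, 10.0, out=width)


def bayes_scan(
    counts: AlleleCountTable,
    contrast: Contrast,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Run the Bayesian outlier scan for one contrast.

    Returns one row per locus: descriptive pooled F_ST, posterior
    probability of selection, posterior mean alpha, and q-value. Indels and
    loci with zero depth in a member condition are flagged ``skipped`` and
    excluded from the MCMC (their scan fields are NaN).
    """
    config = config or ScanConfig()
    subst = np.array(
        [_is_substitution(r, a) for r, a in zip(counts.df["ref"], counts.df["alt"])]
    )
    a_all, n_all, depth_ok = _effective_counts(
        counts, contrast.members, config.pool_size
    )
    usable = subst & depth_ok
    idx = np.flatnonzero(usable)
    if idx.size < 50:
        raise ValueError(
            f"scan requires >= 50 usable loci to estimate population effects; "
            f"got {idx.size}"
        )
    a, n = a_all[idx], n_all[idx]

    stream = [
        config.seed,
        {"F0_contrast": 11, "F2_contrast": 13}.get(contrast.label, 17),
        {Line.DELT: 1, Line.BEND: 2, Line.FENI: 3}.get(contrast.line, 0),
    ]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(stream)))
    state = _ScanState(a, n, config, rng)

    # pilot runs: adapt proposal widths toward acceptance in [0.25, 0.45]
    for _ in range(config.pilot_runs):
        it = config.eff_pilot_iters
        cp = np.zeros(state.L)
        ca = np.zeros(state.L)
        na = np.zeros(state.L)
        cb = np.zeros(state.J)
        for _ in range(it):
            acc_p, acc_a, acc_b = state.sweep()
            cp += acc_p
            ca += acc_a
            na += state.incl
            cb += acc_b
        _adapt(state.w_p, cp / it)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate_a = np.where(na > 0, ca / np.maximum(na, 1), 0.35)
        _adapt(state.w_a, rate_a)
        _adapt(state.w_b, cb / it)

    for _ in range(config.eff_burn_in):
        state.sweep()

    n_samples = config.eff_iterations // config.thinning
    sum_incl = np.zeros(state.L)
    sum_alpha = np.zeros(state.L)
    beta_samples = np.zeros((n_samples, state.J))
    s = 0
    for i in range(config.eff_iterations):
        state.sweep()
        if (i + 1) % config.thinning == 0:
            sum_incl += state.incl
            sum_alpha += state.alpha * state.incl
            beta_samples[s] = state.beta
            s += 1

    half = n_samples // 2
    if half > 1:
        drift = np.abs(
            beta_samples[:half].mean(axis=0) - beta_samples[half:].mean(axis=0)
        )
        if (drift > 0.5).any():
            logger.warning(
                "%s %s: split-chain beta means disagree by %.2f; "
                "consider longer chains",
                contrast.line.value,
                contrast.label,
                drift.max(),
            )

    prob = sum_incl / n_samples
    alpha_mean = sum_alpha / n_samples
    q = q_values(prob)

    out = pd.DataFrame(
        {
            "locus_id": counts.locus_ids,
            "line": contrast.line.value,
            "contrast": contrast.label,
            "fst": pooled_fst(counts, contrast, config),
            "posterior_prob": np.nan,
            "alpha": np.nan,
            "q_value": np.nan,
            "skipped": ~usable,
        }
    )
    out.loc[idx, "posterior_prob"] = prob
    out.loc[idx, "alpha"] = alpha_mean
    out.loc[idx, "q_value"] = q
    return out
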