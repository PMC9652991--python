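"""Admixture and hybrid-category inference.

``admixture_fit`` maximizes the binomial admixture likelihood
prod_i prod_l Binom(g_il | 2, sum_k q_ik f_kl) by alternating EM updates of
the ancestry proportions Q and cluster allele frequencies F (the same
optimum targeted by block-relaxation admixture programs); ``choose_k``
selects K by masked-genotype cross-validation.  ``hybrid_classify`` is a
Gibbs sampler over the six canonical two-generation hybrid categories
(P0, P1, F1, F2 and the two backcrosses), with Jeffreys Beta(1/2, 1/2)
priors on the two parental allele-frequency pools, usually run on the
highest-F_ST loci between the designated parental populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .popgen_stats import _wc_components

__all__ = [
    "AdmixtureFit",
    "HybridPosterior",
    "CATEGORY_NAMES",
    "CATEGORY_MIX",
    "admixture_fit",
    "choose_k",
    "top_fst_loci",
    "hybrid_classify",
]

EPS = 1e-6

CATEGORY_NAMES = ("P0", "P1", "F1", "F2", "BC0", "BC1")
#: ancestry-pair proportions (both copies from pool 0, one from each, both
#: from pool 1); rows sum to one.
CATEGORY_MIX = np.array([
    [1.00, 0.00, 0.00],   # P0
    [0.00, 0.00, 1.00],   # P1
    [0.00, 1.00, 0.00],   # F1
    [0.25, 0.50, 0.25],   # F2
    [0.50, 0.50, 0.00],   # BC0
    [0.00, 0.50, 0.50],   # BC1
])


@dataclass
class AdmixtureFit:
    Q: np.ndarray
    F: np.ndarray
    loglik_trace: list
    K: int
    seed: int
    converged: bool
    individual_ids: list = field(default_factory=list)

    @property
    def loglik(self):
        return self.loglik_trace[-1]


@dataclass
class HybridPosterior:
    posterior: pd.DataFrame          # individuals x categories, rows sum to 1
    diagnostics: dict

    def modal_category(self):
        return self.posterior.idxmax(axis=1)


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

def _admixture_loglik(G, ok, Q, F):
    P = np.clip(Q @ F, EPS, 1 - EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(ok, G * np.log(P) + (2 - G) * np.log1p(-P), 0.0)
    return float(ll.sum())


def admixture_fit(matrix: GenotypeMatrix, K: int, seed: int = 1,
                  max_iter: int = 500, tol: float = 1e-4,
                  n_restarts: int = 1) -> AdmixtureFit:
    """EM fit of the K-cluster admixture model; missing calls are ignored.

    The log-likelihood is asserted non-decreasing every iteration;
    convergence when the gain drops below ``tol``.  Multiple random restarts
    keep the best optimum.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_individuals:
        raise ValueError("K larger than the number of individuals")
    ok = matrix.calls != MISSING
    G = np.where(ok, matrix.calls, 0).astype(float)
    n, L = G.shape
    freqs = G.sum(axis=0) / np.maximum(2 * ok.sum(axis=0), 1)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=n)
        F = np.clip(freqs + rng.normal(0, 0.05 if K > 1 else 0.0, size=(K, L)),
                    EPS, 1 - EPS)
        trace = [_admixture_loglik(G, ok, Q, F)]
        converged = False
        for _ in range(max_iter):
            P = np.clip(Q @ F, EPS, 1 - EPS)
            A = np.where(ok, G / P, 0.0)
            B = np.where(ok, (2 - G) / (1 - P), 0.0)
            f_num = F * (Q.T @ A)
            F = np.clip(f_num / np.maximum(f_num + (1 - F) * (Q.T @ B), 1e-300),
                        EPS, 1 - EPS)
            q_factor = A @ F.T + B @ (1 - F).T
            denom = 2 * ok.sum(axis=1, keepdims=True).astype(float)
            Q = Q * q_factor / np.maximum(denom, 1)
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            ll = _admixture_loglik(G, ok, Q, F)
            if ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
                raise AssertionError(
                    f"EM log-likelihood decreased: {trace[-1]} -> {ll}")
            gain = ll - trace[-1]
            trace.append(ll)
            if gain < tol:
                converged = True
                break
        fit = AdmixtureFit(Q, F, trace, K, seed, converged,
                           list(matrix.individual_ids))
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def choose_k(matrix: GenotypeMatrix, K_range, mask_fraction: float = 0.05,
             n_folds: int = 5, seed: int = 1, **fit_kwargs) -> pd.DataFrame:
    """Cross-validated K selection by masked-genotype prediction.

    Per fold, a random ``mask_fraction`` of the non-missing genotype entries
    is hidden, the model is fitted for every K, and the predictive
    cross-entropy -log Binom(g | 2, q_i . f_.l) of the hidden entries is
    averaged.  Returns per-K mean and SD over folds (lower is better).
    """
    rng = np.random.default_rng(seed)
    ok = matrix.calls != MISSING
    nz = np.argwhere(ok)
    n_mask = max(1, int(round(mask_fraction * len(nz))))
    results = {K: [] for K in K_range}
    for fold in range(n_folds):
        for _ in range(20):
            chosen = nz[rng.choice(len(nz), size=n_mask, replace=False)]
            trial = ok.copy()
            trial[chosen[:, 0], chosen[:, 1]] = False
            if trial.any(axis=0).all() or not ok.any(axis=0).all():
                break
        else:
            raise RuntimeError("masking kept producing all-missing loci")
        masked_calls = matrix.calls.copy()
        masked_calls[chosen[:, 0], chosen[:, 1]] = MISSING
        masked = GenotypeMatrix(matrix.individual_ids, matrix.locus_ids,
                                masked_calls, matrix.population_of)
        g = matrix.calls[chosen[:, 0], chosen[:, 1]].astype(float)
        comb = np.where(g == 1, 2.0, 1.0)
        for K in K_range:
            fit = admixture_fit(masked, K,
                                seed=int(rng.integers(1, 2 ** 31 - 2)),
                                **fit_kwargs)
            p = np.clip((fit.Q @ fit.F)[chosen[:, 0], chosen[:, 1]], EPS, 1 - EPS)
            ce = -(np.log(comb) + g * np.log(p) + (2 - g) * np.log1p(-p)).mean()
            results[K].append(ce)
    return pd.DataFrame({
        "K": list(K_range),
        "cross_entropy": [float(np.mean(results[K])) for K in K_range],
        "sd": [float(np.std(results[K], ddof=1)) if n_folds > 1 else np.nan
               for K in K_range],
    }).set_index("K")


# ---------------------------------------------------------------------------
# Hybrid-category Gibbs sampler
# ---------------------------------------------------------------------------

def top_fst_loci(matrix: GenotypeMatrix, popA, popB, n: int = 300) -> list:
    """The ``n`` loci with the highest per-locus WC theta between two
    populations (descending, ties by locus order; undefined theta ranks
    last)."""
    if n > matrix.n_loci:
        raise ValueError("n exceeds the number of loci")
    calls_by_pop = [matrix.calls[matrix.pop_indices(p)] for p in (popA, popB)]
    a, b, c = _wc_components(calls_by_pop)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(a + b + c != 0, a / (a + b + c), -np.inf)
    theta[~np.isfinite(theta)] = -np.inf
    order = np.argsort(-theta, kind="stable")
    return [matrix.locus_ids[j] for j in order[:n]]


def _genotype_probs_by_origin(G, ok, p0, p1):
    """P(g | origin) arrays, shape (n, L, 3 origins); 1 where missing."""
    hw0 = np.stack([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0 ** 2])      # 3 x L
    hw1 = np.stack([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2])
    cross = np.stack([(1 - p0) * (1 - p1),
                      p0 * (1 - p1) + (1 - p0) * p1,
                      p0 * p1])
    g = np.clip(G, 0, 2).astype(int)
    P = np.stack([hw0[g, np.arange(G.shape[1])[None, :]],
                  cross[g, np.arange(G.shape[1])[None, :]],
                  hw1[g, np.arange(G.shape[1])[None, :]]], axis=-1)
    P[~ok] = 1.0
    return np.clip(P, 1e-300, None)


def hybrid_classify(matrix: GenotypeMatrix, parental_labels, sweeps: int = 20_000,
                    burnin: int = 5_000, thin: int = 10, n_chains: int = 3,
                    seed: int = 1, known_parentals: dict | None = None,
                    min_loci_warn: int = 50) -> HybridPosterior:
    """Six-category hybrid classification by Gibbs sampling.

    Individuals from the two ``parental_labels`` populations anchor the two
    allele-frequency pools (Jeffreys Beta(1/2, 1/2) priors); every individual
    in ``matrix`` receives a posterior over P0, P1, F1, F2, BC0, BC1.
    ``known_parentals`` pins listed individuals to a category (the z-option
    for samples taken far from any contact zone).  Chains disagreeing by a
    posterior SD above 0.1 for any individual set the ``mixing_flag``
    diagnostic.
    """
    if matrix.n_loci < min_loci_warn:
        import warnings
        warnings.warn(f"only {matrix.n_loci} loci; hybrid categories may be "
                      "poorly resolved")
    popA, popB = parental_labels
    for p in (popA, popB):
        if len(matrix.pop_indices(p)) == 0:
            raise ValueError(f"parental population {p!r} has no individuals")
    ok = matrix.calls != MISSING
    G = np.where(ok, matrix.calls, 0).astype(np.int16)
    n, L = G.shape
    cat_index = {c: k for k, c in enumerate(CATEGORY_NAMES)}
    fixed = np.full(n, -1, dtype=int)
    if known_parentals:
        for ind, cat in known_parentals.items():
            fixed[matrix.individual_ids.index(ind)] = cat_index[cat]

    # initial pools from the designated parental populations
    def pool_freq(pop):
        calls = matrix.calls[matrix.pop_indices(pop)]
        okp = calls != MISSING
        alt = np.where(okp, calls, 0).sum(axis=0)
        tot = 2 * okp.sum(axis=0)
        return np.clip((alt + 0.5) / np.maximum(tot + 1, 1), 1e-3, 1 - 1e-3)

    chains = []
    master = np.random.default_rng(seed)
    for _ in range(n_chains):
        rng = np.random.default_rng(int(master.integers(1, 2 ** 31 - 2)))
        p0, p1 = pool_freq(popA), pool_freq(popB)
        counts = np.zeros((n, 6))
        pi = np.full(6, 1 / 6)
        cats = np.where(fixed >= 0, fixed, rng.integers(0, 6, size=n))
        for sweep in range(sweeps):
            P = _genotype_probs_by_origin(G, ok, p0, p1)      # n x L x 3
            # category update (origins marginalized)
            mix_lik = P @ CATEGORY_MIX.T                      # n x L x 6
            cat_ll = np.log(np.clip(mix_lik, 1e-300, None)).sum(axis=1)
            cat_ll += np.log(pi)
            cat_ll -= cat_ll.max(axis=1, keepdims=True)
            w = np.exp(cat_ll)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(n)
            cats = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
            cats = np.where(fixed >= 0, fixed, np.clip(cats, 0, 5))
            # origin-pair update given category
            mix = CATEGORY_MIX[cats][:, None, :]              # n x 1 x 3
            ow = P * mix
            ow /= ow.sum(axis=2, keepdims=True)
            u = rng.random((n, L))
            origins = (ow.cumsum(axis=2) < u[:, :, None]).sum(axis=2)
            origins = np.clip(origins, 0, 2)
            # attribute allele copies to the pools
            alt0 = np.zeros(L)
            ref0 = np.zeros(L)
            alt1 = np.zeros(L)
            ref1 = np.zeros(L)
            o00 = (origins == 0) & ok
            o11 = (origins == 2) & ok
            o01 = (origins == 1) & ok
            alt0 += (G * o00).sum(axis=0)
            ref0 += ((2 - G) * o00).sum(axis=0)
            alt1 += (G * o11).sum(axis=0)
            ref1 += ((2 - G) * o11).sum(axis=0)
            # one copy from each pool: homozygotes are unambiguous
            ref0 += (o01 & (G == 0)).sum(axis=0)
            ref1 += (o01 & (G == 0)).sum(axis=0)
            alt0 += (o01 & (G == 2)).sum(axis=0)
            alt1 += (o01 & (G == 2)).sum(axis=0)
            het01 = o01 & (G == 1)
            if het01.any():
                w_alt0 = (p0 * (1 - p1)) / np.clip(p0 * (1 - p1) + (1 - p0) * p1,
                                                   1e-300, None)
                draw = rng.random((n, L)) < w_alt0[None, :]
                from0 = het01 & draw
                from1 = het01 & ~draw
                alt0 += from0.sum(axis=0)
                ref1 += from0.sum(axis=0)
                alt1 += from1.sum(axis=0)
                ref0 += from1.sum(axis=0)
            p0 = np.clip(rng.beta(0.5 + alt0, 0.5 + ref0), 1e-4, 1 - 1e-4)
            p1 = np.clip(rng.beta(0.5 + alt1, 0.5 + ref1), 1e-4, 1 - 1e-4)
            free = fixed < 0
            tally = np.bincount(cats[free], minlength=6)
            pi = rng.dirichlet(1.0 + tally)
            if sweep >= burnin and (sweep - burnin) % thin == 0:
                counts[np.arange(n), cats] += 1
        chains.append(counts / counts.sum(axis=1, keepdims=True))

    stacked = np.stack(chains)
    post = stacked.mean(axis=0)
    sd = stacked.std(axis=0).max() if n_chains > 1 else 0.0
    posterior = pd.DataFrame(post, index=matrix.individual_ids,
                             columns=list(CATEGORY_NAMES))
    diagnostics = dict(sweeps=sweeps, burnin=burnin, thin=thin,
                       n_chains=n_chains, seed=seed,
                       max_between_chain_sd=float(sd),
                       mixing_flag=bool(sd > 0.1))
    return HybridPosterior(posterior, diagnostics)
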