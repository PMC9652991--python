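"""Diversity and differentiation statistics on SNP matrices and haplotypes.

Per-population diversity: observed/expected heterozygosity (unbiased He,
2p(1-p)*2n/(2n-1)), multilocus F_IS, multilocus heterozygosity (MLH),
standardized MLH (sMLH, population mean ~1), and rarefied allelic richness.
Differentiation: the Weir & Cockerham (1984) ratio-of-averages theta for
population pairs with permutation p-values, one-level AMOVA on squared
allele-count differences, and its sequence-distance analogue Phi_ST for
haplotype alignments.  Everything is invariant to allele orientation and to
row/column order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeAlignment

__all__ = [
    "DiversityTable",
    "PairwiseFstMatrix",
    "AmovaResult",
    "diversity_table",
    "smlh",
    "allelic_richness",
    "wc_theta",
    "wc_fst_pairwise",
    "amova",
    "phi_st",
]


@dataclass
class DiversityTable:
    table: pd.DataFrame          # per-population summary
    smlh_per_individual: pd.Series


@dataclass
class PairwiseFstMatrix:
    populations: list
    fst: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    seed: int | None = None


@dataclass
class AmovaResult:
    """One-level AMOVA: variance among vs within populations.

    ``phi_st`` holds the fixation index (called F_ST for genotype distances,
    Phi_ST for sequence distances); components sum to the total variance.
    """
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float
    n_permutations: int

    @property
    def total_variance(self):
        return self.sigma2_among + self.sigma2_within


# ---------------------------------------------------------------------------
# Heterozygosity and related per-population indices
# ---------------------------------------------------------------------------

def _pop_calls(matrix, pop):
    return matrix.calls[matrix.pop_indices(pop)]


def _locus_het_stats(calls):
    """Per-locus (n non-missing, alt-allele freq, observed het fraction)."""
    ok = calls != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(ok, calls, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
        ho = np.where(n > 0, ((calls == 1) & ok).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, ho


def smlh(matrix: GenotypeMatrix) -> pd.Series:
    """Standardized multilocus heterozygosity per individual.

    sMLH_i = (het fraction of i over its typed loci) divided by the mean,
    over those same loci, of the locus heterozygosity among all individuals
    typed there (inbreedR convention).  Undefined (NaN) for individuals typed
    at no loci.
    """
    if matrix.n_individuals < 2:
        raise ValueError("sMLH needs at least two individuals")
    ok = matrix.calls != MISSING
    het = (matrix.calls == 1) & ok
    n_typed_per_locus = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        locus_het = np.where(n_typed_per_locus > 0,
                             het.sum(axis=0) / np.maximum(n_typed_per_locus, 1), np.nan)
    out = np.full(matrix.n_individuals, np.nan)
    for i in range(matrix.n_individuals):
        typed = ok[i] & (n_typed_per_locus > 0)
        if typed.sum() == 0:
            continue
        expected = locus_het[typed].mean()
        h_i = het[i, typed].mean()
        out[i] = h_i / expected if expected > 0 else np.nan
    return pd.Series(out, index=matrix.individual_ids, name="sMLH")


def allelic_richness(matrix: GenotypeMatrix, g: int | None = None):
    """Rarefied allelic richness per population.

    AR_l = sum over alleles of [1 - C(N - N_i, g) / C(N, g)] — the expected
    number of distinct alleles in a random draw of ``g`` gene copies — then
    averaged over loci.  ``g`` defaults to 2 x the smallest population size.
    Loci with fewer than ``g`` copies in a population are skipped and counted.

    Returns a DataFrame with AR mean, SD and the skipped-locus count per
    population, plus the ``g`` used (in the attribute ``g``).
    """
    pops = matrix.populations
    if g is None:
        g = 2 * min(len(matrix.pop_indices(p)) for p in pops)
    rows = {}
    for pop in pops:
        calls = _pop_calls(matrix, pop)
        ars, skipped = [], 0
        for j in range(matrix.n_loci):
            col = calls[:, j]
            col = col[col != MISSING]
            N = 2 * col.size
            if N < g or N == 0:
                skipped += 1
                continue
            n_alt = int(col.sum())
            ar = 0.0
            for n_i in (N - n_alt, n_alt):
                if n_i > 0:
                    ar += 1.0 - math.comb(N - n_i, g) / math.comb(N, g)
            ars.append(ar)
        rows[pop] = {
            "AR": float(np.mean(ars)) if ars else np.nan,
            "AR_sd": float(np.std(ars, ddof=1)) if len(ars) > 1 else np.nan,
            "loci_skipped": skipped,
        }
    out = pd.DataFrame(rows).T
    out.g = g
    return out


def diversity_table(matrix: GenotypeMatrix, rarefaction_size: int | None = None) -> DiversityTable:
    """Per-population diversity summary: N, Ho, He (+/- per-locus SD), FIS,
    MLH, sMLH mean, and rarefied allelic richness.

    He is the unbiased expected heterozygosity 2p(1-p) * 2n/(2n-1); FIS is the
    multilocus ratio estimator 1 - sum(Ho_l)/sum(He_l).  Populations of size 1
    get NaN for all frequency-based statistics.
    """
    ar = allelic_richness(matrix, rarefaction_size)
    all_smlh = []
    rows = {}
    for pop in matrix.populations:
        idx = matrix.pop_indices(pop)
        calls = matrix.calls[idx]
        n_ind = len(idx)
        if n_ind < 2:
            rows[pop] = dict(N=n_ind, Ho=np.nan, Ho_sd=np.nan, He=np.nan,
                             He_sd=np.nan, FIS=np.nan, MLH=np.nan, sMLH=np.nan,
                             AR=ar.loc[pop, "AR"], AR_sd=ar.loc[pop, "AR_sd"])
            continue
        n, p, ho = _locus_het_stats(calls)
        usable = n > 0
        with np.errstate(invalid="ignore"):
            he = 2 * p * (1 - p) * (2 * n) / np.maximum(2 * n - 1, 1)
        ho_l, he_l = ho[usable], he[usable]
        fis = 1.0 - ho_l.sum() / he_l.sum() if he_l.sum() > 0 else np.nan
        ok = calls != MISSING
        mlh = np.where(ok.sum(axis=1) > 0,
                       ((calls == 1) & ok).sum(axis=1) / np.maximum(ok.sum(axis=1), 1),
                       np.nan)
        sub = matrix.subset(individuals=idx)
        s = smlh(sub)
        all_smlh.append(s)
        rows[pop] = dict(
            N=n_ind,
            Ho=float(np.nanmean(ho_l)), Ho_sd=float(np.nanstd(ho_l, ddof=1)),
            He=float(np.nanmean(he_l)), He_sd=float(np.nanstd(he_l, ddof=1)),
            FIS=float(fis), MLH=float(np.nanmean(mlh)),
            sMLH=float(np.nanmean(s.to_numpy())),
            AR=ar.loc[pop, "AR"], AR_sd=ar.loc[pop, "AR_sd"],
        )
    per_ind = pd.concat(all_smlh) if all_smlh else pd.Series(dtype=float)
    return DiversityTable(pd.DataFrame(rows).T, per_ind)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(calls_by_pop):
    """Per-locus WC (1984) a, b, c arrays for r populations of diploids.

    ``calls_by_pop``: list of (n_ind x n_loci) arrays.  Loci where fewer than
    two populations have >=2 typed individuals contribute zeros.
    """
    r = len(calls_by_pop)
    stats = [_locus_het_stats(c) for c in calls_by_pop]
    n = np.stack([s[0] for s in stats]).astype(float)      # r x L individuals typed
    p = np.stack([np.nan_to_num(s[1]) for s in stats])
    h = np.stack([np.nan_to_num(s[2]) for s in stats])
    usable = (n >= 1).sum(axis=0) >= 2
    n = np.where(n >= 1, n, 0.0)
    r_eff = (n > 0).sum(axis=0).astype(float)

    nbar = n.sum(axis=0) / np.maximum(r_eff, 1)
    nc = np.where(
        r_eff > 1,
        (n.sum(axis=0) - (n ** 2).sum(axis=0) / np.maximum(n.sum(axis=0), 1e-12))
        / np.maximum(r_eff - 1, 1),
        np.nan,
    )
    w = n / np.maximum(n.sum(axis=0), 1e-12)
    pbar = (w * p).sum(axis=0)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / np.maximum((r_eff - 1) * nbar, 1e-12)
    hbar = (w * h).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = ~usable | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    return a, b, c


def wc_theta(matrix: GenotypeMatrix, populations=None, per_locus=False):
    """Multilocus Weir-Cockerham theta across the given populations
    (default: all).  Ratio of sums of per-locus a over (a+b+c)."""
    pops = populations or matrix.populations
    calls_by_pop = [_pop_calls(matrix, p) for p in pops]
    a, b, c = _wc_components(calls_by_pop)
    denom = (a + b + c).sum()
    theta = a.sum() / denom if denom != 0 else np.nan
    if per_locus:
        with np.errstate(invalid="ignore", divide="ignore"):
            tl = np.where(a + b + c != 0, a / (a + b + c), np.nan)
        return float(theta), tl
    return float(theta)


def wc_fst_pairwise(matrix: GenotypeMatrix, n_permutations: int = 999,
                    seed: int | None = None) -> PairwiseFstMatrix:
    """Pairwise multilocus WC theta with permutation p-values.

    p = proportion of permutations (individual labels shuffled within the
    pair) with theta >= observed, with the +1 correction.  Pairs involving a
    population of size 1 are NaN.
    """
    rng = np.random.default_rng(seed)
    pops = matrix.populations
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    for x in range(len(pops)):
        for y in range(x + 1, len(pops)):
            pa, pb = pops[x], pops[y]
            ia, ib = matrix.pop_indices(pa), matrix.pop_indices(pb)
            if len(ia) < 2 or len(ib) < 2:
                fst.loc[pa, pb] = fst.loc[pb, pa] = np.nan
                continue
            calls = matrix.calls[np.concatenate([ia, ib])]
            na = len(ia)
            obs = _theta_from_split(calls, na)
            exceed = 0
            for _ in range(n_permutations):
                perm = rng.permutation(calls.shape[0])
                if _theta_from_split(calls[perm], na) >= obs:
                    exceed += 1
            p = (exceed + 1) / (n_permutations + 1)
            fst.loc[pa, pb] = fst.loc[pb, pa] = obs
            pvals.loc[pa, pb] = pvals.loc[pb, pa] = p
    return PairwiseFstMatrix(pops, fst, pvals, n_permutations, seed)


def _theta_from_split(calls, na):
    a, b, c = _wc_components([calls[:na], calls[na:]])
    denom = (a + b + c).sum()
    return a.sum() / denom if denom != 0 else np.nan


# ---------------------------------------------------------------------------
# AMOVA and Phi_ST
# ---------------------------------------------------------------------------

def _amova_from_distances(d2, pop_of_row, n_permutations, rng):
    """One-level AMOVA from a squared-distance matrix (Excoffier et al.)."""
    n = d2.shape[0]
    pops = sorted(set(pop_of_row), key=list(pop_of_row).index)
    idx = {p: np.flatnonzero(np.asarray(pop_of_row) == p) for p in pops}
    sizes = np.array([len(idx[p]) for p in pops], dtype=float)
    r = len(pops)
    if r < 2:
        raise ValueError("AMOVA needs at least two populations")

    def components(assign):
        groups = [np.flatnonzero(assign == k) for k in range(r)]
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for g in groups:
            if len(g) > 0:
                ss_within += d2[np.ix_(g, g)].sum() / (2 * len(g))
        ss_among = ss_total - ss_within
        df_among, df_within = r - 1, n - r
        ms_within = ss_within / df_within if df_within > 0 else np.nan
        n_prime = (n - (sizes ** 2).sum() / n) / (r - 1)
        sigma_w = ms_within
        sigma_a = (ss_among / df_among - sigma_w) / n_prime
        return sigma_a, sigma_w

    assign = np.empty(n, dtype=int)
    for k, p in enumerate(pops):
        assign[idx[p]] = k
    sa, sw = components(assign)
    total = sa + sw
    phi = sa / total if total > 0 else np.nan

    exceed = 0
    for _ in range(n_permutations):
        pa, pw = components(rng.permutation(assign))
        t = pa + pw
        if t > 0 and pa / t >= phi:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(float(sa), float(sw), float(phi), float(p_value), n_permutations)


def amova(matrix: GenotypeMatrix, grouping=None, n_permutations: int = 999,
          seed: int | None = None) -> AmovaResult:
    """AMOVA at the gene-copy level: each individual contributes two allele
    copies per locus, and the squared distance between copies is the summed
    allele mismatch over loci (pairwise deletion, rescaled to the full locus
    count).  Working on gene copies rather than 0/1/2 genotype codes makes
    the fixation index commensurate with Weir-Cockerham theta (genotype-code
    distances inflate the among-population share).  Permutations shuffle
    whole individuals among populations.  ``grouping`` (population -> group
    label) collapses populations into higher-level groups before the
    one-level analysis.
    """
    if len(matrix.populations) < 2:
        raise ValueError("AMOVA needs at least two populations")
    rng = np.random.default_rng(seed)
    n, L = matrix.calls.shape
    ok = matrix.calls != MISSING
    # allele copies: individual i -> rows 2i (first copy) and 2i+1 (second);
    # an unphased heterozygote contributes one 0 and one 1
    copies = np.zeros((2 * n, L))
    copies[0::2] = (matrix.calls >= 1) & ok
    copies[1::2] = matrix.calls == 2
    cok = np.repeat(ok, 2, axis=0)
    d2 = np.zeros((2 * n, 2 * n))
    for i in range(2 * n):
        shared = cok[i] & cok
        diff = ((copies[i] != copies) & shared).sum(axis=1).astype(float)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2[i] = np.where(cnt > 0, diff * (L / np.maximum(cnt, 1)), 0.0)
    labels = [matrix.population_of[i] for i in matrix.individual_ids]
    if grouping is not None:
        labels = [grouping[p] for p in labels]
    copy_labels = np.repeat(labels, 2)
    return _amova_from_copy_distances(d2, copy_labels, labels, n_permutations, rng)


def _amova_from_copy_distances(d2, copy_labels, ind_labels, n_permutations, rng):
    """One-level AMOVA where units are gene copies but permutation keeps the
    two copies of an individual together."""
    pops = sorted(set(ind_labels), key=list(ind_labels).index)
    pop_idx = {p: k for k, p in enumerate(pops)}
    assign_ind = np.array([pop_idx[p] for p in ind_labels])

    def phi_of(assign):
        copy_assign = np.repeat(assign, 2)
        n = d2.shape[0]
        r = len(pops)
        sizes = np.array([(copy_assign == k).sum() for k in range(r)], dtype=float)
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for k in range(r):
            g = np.flatnonzero(copy_assign == k)
            ss_within += d2[np.ix_(g, g)].sum() / (2 * len(g))
        sigma_w = ss_within / (n - r)
        n_prime = (n - (sizes ** 2).sum() / n) / (r - 1)
        sigma_a = ((ss_total - ss_within) / (r - 1) - sigma_w) / n_prime
        return sigma_a, sigma_w

    sa, sw = phi_of(assign_ind)
    total = sa + sw
    phi = sa / total if total > 0 else np.nan
    exceed = 0
    for _ in range(n_permutations):
        pa, pw = phi_of(rng.permutation(assign_ind))
        t = pa + pw
        if t > 0 and pa / t >= phi:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(float(sa), float(sw), float(phi), float(p_value),
                       n_permutations)


def phi_st(alignment: HaplotypeAlignment, n_permutations: int = 999,
           seed: int | None = None) -> AmovaResult:
    """Phi_ST: AMOVA on pairwise nucleotide-difference distances.

    Positions with a gap or N in either sequence of a pair are ignored for
    that pair.  All-identical alignments have zero total variance and an
    undefined (NaN) Phi_ST.
    """
    if len(alignment.populations) < 2:
        raise ValueError("Phi_ST needs at least two populations")
    rng = np.random.default_rng(seed)
    seqs = np.array([list(s) for s in alignment.sequences])
    valid = np.isin(seqs, list("ACGT"))
    n = len(alignment.sequence_ids)
    d2 = np.zeros((n, n))
    for i in range(n):
        shared = valid[i] & valid
        # the mismatch count itself plays the role of the squared distance
        d2[i] = ((seqs[i] != seqs) & shared).sum(axis=1).astype(float)
    labels = [alignment.population_of[s] for s in alignment.sequence_ids]
    return _amova_from_distances(d2, labels, n_permutations, rng)
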