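"""Two-population demographic inference on the folded joint allele-frequency
spectrum (AFS).

The observable is a folded joint AFS built from a SNP matrix by hypergeometric
projection.  Expected spectra under a family of split/migration/size-change
models are computed by a Monte-Carlo structured-coalescent engine (msprime,
branch-length mode): the expected mass in AFS cell (i, j) is proportional to
the expected total length of branches subtending i sampled copies in
population 1 and j in population 2.  Model fit uses the Poisson composite
likelihood with the mutation scale theta profiled out analytically; model
choice uses AIC; a rejection-ABC cross-check and conversion of fitted
parameters to biological units complete the toolkit.

Units follow the diffusion-equation convention: population sizes nu are
relative to the ancestral reference size N_ref, times are in units of
2*N_ref generations, and migration rates m_ij are 2*N_ref times the fraction
of population i replaced by migrants from population j per generation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import msprime
import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = [
    "JointAFS",
    "ModelSpec",
    "MODEL_SPECS",
    "STUDY_MODELS",
    "FitResult",
    "ConversionSpec",
    "build_demography",
    "branch_joint_afs",
    "afs_from_matrix",
    "expected_afs",
    "loglik",
    "fit_model",
    "model_select",
    "residual_spectrum",
    "to_biological_units",
    "from_biological_units",
    "abc_model_choice",
    "summary_stats",
]


# ---------------------------------------------------------------------------
# Joint AFS container
# ---------------------------------------------------------------------------

@dataclass
class JointAFS:
    """(n1+1) x (n2+1) joint spectrum with mask, sample sizes in gene copies.

    ``mask`` is True for cells excluded from sums and likelihoods; the fixed
    corners (0,0) and (n1,n2) are always masked, and folded spectra also mask
    the majority-allele half-plane.
    """

    data: np.ndarray
    sample_sizes: tuple
    folded: bool = False
    mask: np.ndarray | None = None
    mc_variance: np.ndarray | None = None  # per-cell variance of a MC mean

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n1, n2 = self.sample_sizes
        if self.data.shape != (n1 + 1, n2 + 1):
            raise ValueError("AFS shape does not match sample sizes")
        if self.mask is None:
            self.mask = np.zeros_like(self.data, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
        self.mask[0, 0] = True
        self.mask[n1, n2] = True
        if self.folded:
            i = np.arange(n1 + 1)[:, None] + np.arange(n2 + 1)[None, :]
            self.mask |= i > (n1 + n2) / 2

    @property
    def unmasked(self):
        return ~self.mask

    def total(self) -> float:
        return float(self.data[self.unmasked].sum())

    def fold(self) -> "JointAFS":
        """Fold onto the minor-allele orientation, conserving total mass.

        Cell (i, j) is pooled with its mirror (n1-i, n2-j); cells on the
        half-count diagonal receive the symmetrized average.
        """
        if self.folded:
            return self
        n1, n2 = self.sample_sizes
        flip = self.data[::-1, ::-1]
        out = self.data + flip
        tot = np.arange(n1 + 1)[:, None] + np.arange(n2 + 1)[None, :]
        diag = tot * 2 == n1 + n2
        out[diag] *= 0.5
        out[tot * 2 > n1 + n2] = 0.0
        var = None
        if self.mc_variance is not None:
            var = self.mc_variance + self.mc_variance[::-1, ::-1]
            var[diag] *= 0.25
        return JointAFS(out, self.sample_sizes, folded=True, mc_variance=var)

    def project(self, sizes) -> "JointAFS":
        """Hypergeometric projection down to smaller sample sizes.

        Must be applied to an unfolded spectrum (fold afterwards); preserves
        expected totals for cells that stay polymorphic.
        """
        if self.folded:
            raise ValueError("project before folding")
        m1, m2 = sizes
        n1, n2 = self.sample_sizes
        if m1 > n1 or m2 > n2:
            raise ValueError("cannot project up")
        P1 = _projection_matrix(n1, m1)
        P2 = _projection_matrix(n2, m2)
        return JointAFS(P1.T @ self.data @ P2, (m1, m2), folded=False)

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(self.data.tobytes())
        h.update(self.mask.tobytes())
        h.update(repr((self.sample_sizes, self.folded)).encode())
        return h.hexdigest()[:12]

    # plain-text round trip -------------------------------------------------
    def to_text(self, path):
        n1, n2 = self.sample_sizes
        with open(path, "w") as fh:
            fh.write(f"# joint AFS n1={n1} n2={n2} folded={int(self.folded)}\n")
            np.savetxt(fh, self.data)
            fh.write("# mask\n")
            np.savetxt(fh, self.mask.astype(int), fmt="%d")

    @classmethod
    def from_text(cls, path):
        with open(path) as fh:
            header = fh.readline().split()
            n1 = int(header[3].split("=")[1])
            n2 = int(header[4].split("=")[1])
            folded = bool(int(header[5].split("=")[1]))
            rows = [fh.readline().split() for _ in range(n1 + 1)]
            fh.readline()
            mrows = [fh.readline().split() for _ in range(n1 + 1)]
        return cls(np.array(rows, dtype=float), (n1, n2), folded,
                   np.array(mrows, dtype=int).astype(bool))


def _projection_matrix(n, m):
    """P[i, i'] = P(i' of m copies derived | i of n copies derived)."""
    P = np.zeros((n + 1, m + 1))
    for i in range(n + 1):
        lo = max(0, m - (n - i))
        hi = min(i, m)
        ks = np.arange(lo, hi + 1)
        P[i, ks] = hypergeom.pmf(ks, n, i, m)
    return P


# ---------------------------------------------------------------------------
# Model family
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A named member of the split/migration/size-change model family."""

    name: str
    free_params: tuple
    description: str = ""

    @property
    def k(self):
        return len(self.free_params)


MODEL_SPECS = {
    "SNM_split": ModelSpec(
        "SNM_split", ("T1",),
        "split at T1, both daughters keep the ancestral size, no migration"),
    "S_nomig": ModelSpec(
        "S_nomig", ("nu1", "nu2", "T1"),
        "split at T1 into nu1, nu2; complete isolation"),
    "S_asymig": ModelSpec(
        "S_asymig", ("nu1", "nu2", "m12", "m21", "T1"),
        "split at T1 with asymmetric migration throughout"),
    "S_nomig_secont": ModelSpec(
        "S_nomig_secont", ("nu1", "nu2", "m12", "m21", "T1", "T2"),
        "split at T1, isolation until T2, then secondary-contact migration"),
    "secont_asymig_size": ModelSpec(
        "secont_asymig_size",
        ("nu1", "nu2", "nu1b", "nu2b", "m12", "m21", "T1", "T2"),
        "split at T1, isolation; at T2 sizes change to nu1b, nu2b and "
        "migration begins"),
    "S_asymig_size": ModelSpec(
        "S_asymig_size",
        ("nu1", "nu2", "nu1b", "nu2b", "m12", "m21", "T1", "T2"),
        "split at T1 with migration until T2; then isolation and size change "
        "to nu1b, nu2b"),
    "S_nomig_size": ModelSpec(
        "S_nomig_size", ("nu1", "nu2", "nu1b", "nu2b", "T1", "T2"),
        "split at T1, no migration; sizes change to nu1b, nu2b at T2"),
}

#: Fitted parameter columns for the four study population pairs (inputs for
#: simulation-based validation).  Keys are pair labels; each value carries the
#: model name and the full parameter set (theta on the composite scale).
STUDY_MODELS = {
    "C_SA": dict(model="S_nomig_secont", theta=481.0,
                 nu1=0.26, nu2=0.10, m12=2.15, m21=22.39, T1=14.91, T2=0.148),
    "C_NWIO": dict(model="secont_asymig_size", theta=293.0,
                   nu1=15.50, nu2=4.69, nu1b=0.87, nu2b=0.87,
                   m12=1.07, m21=11.90, T1=30.13, T2=0.17),
    "C_MI": dict(model="S_asymig_size", theta=479.0,
                 nu1=1.98, nu2=0.82, nu1b=2.02, nu2b=0.33,
                 m12=1.96, m21=19.98, T1=0.23, T2=0.18),
    "NWIO_SA": dict(model="S_nomig_size", theta=630.0,
                    nu1=4.42, nu2=0.99, nu1b=1.61, nu2b=0.62, T1=1.78, T2=0.25),
}


def build_demography(spec: ModelSpec | str, params: dict) -> msprime.Demography:
    """Translate a model + parameter dict into an msprime demography.

    The msprime time unit is set to 2*N_ref generations by giving the
    ancestral population size 0.5 (diploid), so diffusion-convention sizes,
    times and migration rates are used verbatim.  Direction: m12 moves
    individuals from population 2 into population 1 forwards in time, i.e.
    lineages from p1 into p2 backwards in time.
    """
    name = spec.name if isinstance(spec, ModelSpec) else spec
    if name not in MODEL_SPECS:
        raise ValueError(f"unknown model {name!r}")
    p = dict(params)
    T1 = p["T1"]
    T2 = p.get("T2")
    if T2 is not None and not (T1 > T2 > 0):
        raise ValueError(f"need T1 > T2 > 0, got T1={T1}, T2={T2}")

    nu1 = p.get("nu1", 1.0)
    nu2 = p.get("nu2", 1.0)
    has_size_change = name in ("secont_asymig_size", "S_asymig_size", "S_nomig_size")
    recent1 = p["nu1b"] if has_size_change else nu1
    recent2 = p["nu2b"] if has_size_change else nu2

    # migration per epoch (recent = (0, T2], ancient = (T2, T1])
    m12 = p.get("m12", 0.0)
    m21 = p.get("m21", 0.0)
    if name in ("S_nomig_secont", "secont_asymig_size"):
        recent_mig, ancient_mig = (m12, m21), (0.0, 0.0)
    elif name == "S_asymig_size":
        recent_mig, ancient_mig = (0.0, 0.0), (m12, m21)
    elif name == "S_asymig":
        recent_mig = ancient_mig = (m12, m21)
    else:
        recent_mig = ancient_mig = (0.0, 0.0)

    dem = msprime.Demography()
    dem.add_population(name="p1", initial_size=recent1 / 2)
    dem.add_population(name="p2", initial_size=recent2 / 2)
    dem.add_population(name="anc", initial_size=0.5)
    # backwards-in-time: lineages in p1 jump to p2 at the rate p1 receives
    # migrants from p2 forwards in time
    dem.set_migration_rate(source="p1", dest="p2", rate=recent_mig[0])
    dem.set_migration_rate(source="p2", dest="p1", rate=recent_mig[1])
    if T2 is not None:
        if has_size_change:
            dem.add_population_parameters_change(time=T2, population="p1",
                                                 initial_size=nu1 / 2)
            dem.add_population_parameters_change(time=T2, population="p2",
                                                 initial_size=nu2 / 2)
        if ancient_mig != recent_mig:
            dem.add_migration_rate_change(time=T2, source="p1", dest="p2",
                                          rate=ancient_mig[0])
            dem.add_migration_rate_change(time=T2, source="p2", dest="p1",
                                          rate=ancient_mig[1])
    dem.add_population_split(time=T1, derived=["p1", "p2"], ancestral="anc")
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# Monte-Carlo expected AFS
# ---------------------------------------------------------------------------

def branch_joint_afs(demography, sample_sizes, n_replicates, seed,
                     population_names=("p1", "p2"), return_variance=False,
                     length_budget=None, min_replicates=100):
    """Expected (relative) unfolded joint AFS by branch-length Monte Carlo.

    ``sample_sizes`` are gene-copy counts per population (must be even; the
    engine samples diploids).  The returned array has the expected branch
    length subtending each cell, averaged over replicate independent gene
    trees; multiplying by theta/2 would give expected SNP counts.  With
    ``return_variance`` the per-cell variance of the Monte-Carlo mean is
    also returned (used by :func:`loglik` to de-bias log terms).

    ``length_budget`` caps the total simulated branch length: once at least
    ``min_replicates`` trees have been accumulated and the summed tree
    length exceeds the budget, iteration stops.  Deep-tree parameter
    regions (large sizes, strong migration) cost 10-30x more per tree, and
    a fixed length budget equalizes compute across the parameter space
    while staying deterministic given the seed.
    """
    sizes = tuple(int(n) for n in sample_sizes)
    if any(n % 2 for n in sizes):
        raise ValueError("gene-copy sample sizes must be even (diploid sampling)")
    samples = {name: n // 2 for name, n in zip(population_names, sizes)}
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography, ploidy=2,
        num_replicates=n_replicates, random_seed=_msprime_seed(seed))
    total = np.zeros([n + 1 for n in sizes])
    total_sq = np.zeros_like(total) if return_variance else None
    sample_sets = None
    n_done = 0
    length_done = 0.0
    for ts in reps:
        if sample_sets is None:
            name_to_id = {p.metadata.get("name", str(p.id)): p.id
                          for p in ts.populations()}
            sample_sets = [ts.samples(population=name_to_id[n])
                           for n in population_names]
        a = ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode="branch", polarised=True,
            span_normalise=False)
        total += a
        if return_variance:
            total_sq += a * a
        n_done += 1
        if length_budget is not None:
            length_done += a.sum()
            if n_done >= min_replicates and length_done >= length_budget:
                break
    mean = total / n_done
    if not return_variance:
        return mean
    # variance of the mean across replicate gene trees
    var = (total_sq / n_done - mean ** 2) / max(n_done - 1, 1)
    return mean, np.maximum(var, 0.0)


def _msprime_seed(seed):
    return (int(seed) % (2 ** 31 - 2)) + 1


def expected_afs(spec, params, sizes, n_replicates=10_000, seed=1,
                 folded=True, length_budget=None,
                 min_replicates=100) -> JointAFS:
    """Expected joint AFS (relative scale) under a model of the family.

    Deterministic given ``seed``: a fit holds the seed fixed across parameter
    evaluations (common random numbers) so the likelihood surface is smooth
    for the simplex optimizer.  ``length_budget`` (total branch length)
    optionally caps the work spent on deep-tree parameter regions.
    """
    dem = build_demography(spec, params)
    arr, var = branch_joint_afs(dem, sizes, n_replicates, seed,
                                return_variance=True,
                                length_budget=length_budget,
                                min_replicates=min_replicates)
    afs = JointAFS(arr, tuple(sizes), folded=False, mc_variance=var)
    return afs.fold() if folded else afs


# ---------------------------------------------------------------------------
# Data spectrum
# ---------------------------------------------------------------------------

def afs_from_matrix(matrix, popA, popB, projection) -> JointAFS:
    """Folded joint AFS from a genotype matrix by hypergeometric projection.

    Each locus contributes its expected projected entry mass given the
    observed alternate-allele counts among non-missing calls; loci with fewer
    available gene copies than the projection size are dropped (the count is
    available as the ``n_dropped`` attribute).
    """
    from .genotype_io import MISSING

    m1, m2 = projection
    ia, ib = matrix.pop_indices(popA), matrix.pop_indices(popB)
    out = np.zeros((m1 + 1, m2 + 1))
    dropped = 0
    cache = {}
    for j in range(matrix.n_loci):
        colA = matrix.calls[ia, j]
        colB = matrix.calls[ib, j]
        colA, colB = colA[colA != MISSING], colB[colB != MISSING]
        nA, nB = 2 * colA.size, 2 * colB.size
        if nA < m1 or nB < m2:
            dropped += 1
            continue
        cA, cB = int(colA.sum()), int(colB.sum())
        if (nA, m1) not in cache:
            cache[(nA, m1)] = _projection_matrix(nA, m1)
        if (nB, m2) not in cache:
            cache[(nB, m2)] = _projection_matrix(nB, m2)
        out += np.outer(cache[(nA, m1)][cA], cache[(nB, m2)][cB])
    afs = JointAFS(out, (m1, m2), folded=False).fold()
    afs.n_dropped = dropped
    return afs


# ---------------------------------------------------------------------------
# Composite likelihood and fitting
# ---------------------------------------------------------------------------

def _fit_bin_edges(n, level="coarse"):
    """Allele-count bin edges for the aggregated fit statistics.

    "coarse" bands double (0, 1, 3, 7, ...) so every group keeps enough mass
    that its Monte-Carlo estimate has a small relative error — per-cell
    evaluation would systematically penalize concentrated spectra whose
    low-mass cells are driven by rare tree topologies; "fine" bands grow by
    ~1.8 for the local polish at higher replicate counts.
    """
    growth = {"coarse": lambda e: 2 * e + 1, "fine": lambda e: math.ceil(1.8 * e)}[level]
    edges = [0]
    e = 1
    while e <= (n + 1) / 2:
        edges.append(e)
        e = growth(e)
    edges.append(n + 1)
    return np.array(edges)


def _group_cells(afs: JointAFS, level="coarse"):
    """Group index per cell under the fixed coarsening (-1 for masked)."""
    n1, n2 = afs.sample_sizes
    e1, e2 = _fit_bin_edges(n1, level), _fit_bin_edges(n2, level)
    bi = np.digitize(np.arange(n1 + 1), e1) - 1
    bj = np.digitize(np.arange(n2 + 1), e2) - 1
    g = bi[:, None] * (len(e2) + 1) + bj[None, :]
    return np.where(afs.unmasked, g, -1)


def loglik(data: JointAFS, model: JointAFS, coarsen: bool = False):
    """Poisson composite log-likelihood and the profiled theta_hat.

    theta_hat = sum(data)/sum(model) over shared unmasked cells maximizes the
    Poisson likelihood analytically.  With ``coarsen`` the spectrum is first
    aggregated onto fixed geometric allele-count bins (identically for data
    and model): the statistic the optimizer sees during Monte-Carlo fitting,
    where per-cell noise in low-mass cells would otherwise bias the
    likelihood against concentrated spectra.  When the model carries
    Monte-Carlo per-cell variances, the second-order Jensen de-biasing
    d * Var(m)/(2 m^2) (capped) is added to the log terms.  Model cells that
    are zero where data is positive are floored (count in
    ``loglik.n_floored``).
    """
    if data.data.shape != model.data.shape or data.folded != model.folded:
        raise ValueError("data and model spectra are not comparable")
    um = data.unmasked & model.unmasked
    if coarsen:
        level = coarsen if isinstance(coarsen, str) else "coarse"
        gids = _group_cells(data, level)
        gids[~um] = -1
        keys = np.unique(gids[gids >= 0])
        d = np.array([data.data[gids == k].sum() for k in keys])
        m = np.array([model.data[gids == k].sum() for k in keys])
        v = None
        if model.mc_variance is not None:
            v = np.array([model.mc_variance[gids == k].sum() for k in keys])
    else:
        d = data.data[um]
        m = model.data[um].copy()
        v = model.mc_variance[um] if model.mc_variance is not None else None
    floored = int(((m <= 0) & (d > 0)).sum())
    floor = max(m.mean() * 1e-6, 1e-30)
    m = np.maximum(m, floor)
    theta_hat = d.sum() / m.sum()
    mu = theta_hat * m
    ll = float((d * np.log(mu) - mu - gammaln(d + 1)).sum())
    if v is not None:
        cv2 = v / (m * m)
        ll += float((d * np.minimum(cv2 / 2, 2.0)).sum())
    loglik.n_floored = floored
    return ll, float(theta_hat)


@dataclass
class FitResult:
    model: str
    params: dict
    loglik: float
    aic: float
    theta_hat: float
    converged: bool
    trace: list = field(default_factory=list)
    data_fingerprint: str = ""
    seed: int | None = None

    def to_dict(self):
        return dict(model=self.model, params=self.params, loglik=self.loglik,
                    aic=self.aic, theta_hat=self.theta_hat,
                    converged=self.converged, seed=self.seed)


DEFAULT_BOUNDS = {"nu": (1e-3, 30.0), "m": (1e-3, 40.0), "T": (1e-3, 40.0),
                  "T2_frac": (1e-3, 0.999)}


def _param_bounds(spec, bounds=None):
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    out = []
    for name in spec.free_params:
        if name.startswith("nu"):
            out.append(b["nu"])
        elif name.startswith("m"):
            out.append(b["m"])
        elif name == "T2":
            out.append(b["T2_frac"])
        else:
            out.append(b["T"])
    return out


def _vector_to_params(spec, x):
    """Free-parameter vector (log scale, T2 as a fraction of T1) -> dict."""
    vals = np.exp(x)
    p = dict(zip(spec.free_params, vals))
    if "T2" in p:
        p["T2"] = p["T2"] * p["T1"]  # stored as fraction: enforces T1 > T2
    return p


def _params_to_vector(spec, params):
    vals = []
    for name in spec.free_params:
        v = params[name]
        if name == "T2":
            v = v / params["T1"]
        vals.append(math.log(v))
    return np.array(vals)


def _structured_starts(spec: ModelSpec, log_b):
    """Factorial start grid over the natural scales of the model family.

    Random log-uniform draws almost never coordinate split time, sizes and
    migration, so multimodal surfaces (e.g. strong secondary contact mimicked
    by shallow splits) trap the search.  A coarse factorial over split-time
    magnitudes, size pairs, asymmetric-migration pairs and relative
    event-time fractions seeds every qualitatively distinct basin; the
    screening likelihood then ranks them.
    """
    t1_grid = (0.1, 0.5, 2.5, 8.0, 16.0, 32.0)
    nu_grid = ((0.3, 0.1), (1.0, 1.0), (3.0, 1.0), (10.0, 3.0))
    has_mig = any(p.startswith("m") for p in spec.free_params)
    mig_grid = ((0.5, 0.5), (2.0, 20.0), (20.0, 2.0)) if has_mig else ((0.0, 0.0),)
    frac_grid = (0.02, 0.35, 0.75) if "T2" in spec.free_params else (None,)
    starts = []
    for T1 in t1_grid:
        for nu1, nu2 in nu_grid:
            base = {"T1": T1, "nu1": nu1, "nu2": nu2}
            if "nu1b" in spec.free_params:
                base["nu1b"], base["nu2b"] = nu1, nu2
            for m12, m21 in mig_grid:
                for frac in frac_grid:
                    p = dict(base)
                    if has_mig:
                        p["m12"], p["m21"] = m12, m21
                    if frac is not None:
                        p["T2"] = frac * T1
                    x = _params_to_vector(spec, p)
                    starts.append(np.clip(x, log_b[:, 0], log_b[:, 1]))
    return starts


def fit_model(data: JointAFS, spec: ModelSpec | str, bounds=None,
              n_grid=96, n_starts=4, n_polish=2, maxiter=60,
              n_replicates=250, polish_replicates=1000,
              report_replicates=4000, seed=1) -> FitResult:
    """Two-stage derivative-free fit of a model to a folded joint AFS.

    Stage A (global): the coarse-binned composite likelihood (robust to
    Monte-Carlo noise, see :func:`loglik`) is screened at ``n_grid``
    log-uniform random draws over the bounds, and the best ``n_starts``
    points are polished by Nelder-Mead in log-parameter space at
    ``n_replicates`` engine replicates.  Stage A terminals are re-scored at
    ``polish_replicates`` to rank basins reliably.

    Stage B (local): from the verified best, ``n_polish`` Nelder-Mead
    restarts refine the optimum against the fine-binned statistic at
    ``polish_replicates`` replicates, where the extra resolution sharpens
    weakly identified parameters.  The engine seed is held fixed within each
    stage (common random numbers); the reported likelihood and AIC use the
    fine statistic at ``report_replicates``.  T2 is optimized as a fraction
    of T1 so T1 > T2 > 0 by construction.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(1, 2 ** 31 - 2))
    bnds = _param_bounds(spec, bounds)
    log_b = np.log(np.array(bnds))

    def objective(x, reps, level):
        x = np.clip(x, log_b[:, 0], log_b[:, 1])
        p = _vector_to_params(spec, x)
        model = expected_afs(spec, p, data.sample_sizes,
                             n_replicates=reps, seed=crn_seed,
                             folded=data.folded,
                             length_budget=40.0 * reps,
                             min_replicates=max(100, reps // 4))
        ll, _ = loglik(data, model, coarsen=level)
        return -ll

    def polish(x0, reps, level, miter, step=0.5):
        # an explicit initial simplex with ~e^0.5-fold steps: the scipy
        # default perturbs coordinates by 5%, which in log-parameter space
        # is far below the Monte-Carlo noise floor and stalls the simplex
        simplex = [np.asarray(x0, dtype=float)]
        for i in range(len(x0)):
            v = simplex[0].copy()
            delta = step if v[i] + step <= log_b[i, 1] else -step
            v[i] = np.clip(v[i] + delta, log_b[i, 0], log_b[i, 1])
            simplex.append(v)
        return minimize(lambda x: objective(x, reps, level), x0,
                        method="Nelder-Mead",
                        bounds=[tuple(lb) for lb in log_b],
                        options=dict(maxiter=miter, fatol=0.01, xatol=0.01,
                                     adaptive=True,
                                     initial_simplex=np.array(simplex)))

    # stage A: global screen (random draws + structured factorial grid),
    # then coarse Nelder-Mead polish of the best point from each split-time
    # magnitude class.  Distinct basins (e.g. recent split vs deep split
    # with ancient migration) can score within noise of one another, so the
    # polished terminals of every magnitude class are re-ranked at high
    # replicates before one is committed to.
    t1_pos = spec.free_params.index("T1")
    grid = list(rng.uniform(log_b[:, 0], log_b[:, 1], size=(n_grid, len(bnds))))
    grid += _structured_starts(spec, log_b)
    grid_f = np.array([objective(x, n_replicates, "coarse") for x in grid])
    order = np.argsort(grid_f)
    trace = [dict(stage="screen", evals=len(grid), best_negll=float(grid_f[order[0]]))]
    # best screened point per basin class, best classes first; a class is a
    # T1 decade crossed with the migration orientation (which direction
    # dominates), since the simplex rarely crosses between orientations
    mig_pos = [k for k, name in enumerate(spec.free_params)
               if name.startswith("m")]

    def basin_class(x):
        decade = int(math.floor(x[t1_pos] / math.log(10)))
        if len(mig_pos) == 2:
            ratio = x[mig_pos[0]] - x[mig_pos[1]]
            orient = 0 if abs(ratio) < math.log(3) else (1 if ratio > 0 else -1)
        else:
            orient = 0
        return decade, orient

    chosen, seen = [], set()
    for k in order:
        cls = basin_class(grid[k])
        if cls not in seen:
            seen.add(cls)
            chosen.append(k)
        if len(chosen) == n_starts:
            break
    coarse_iter = max(25, (2 * maxiter) // 3)
    terminals = []
    for k in chosen:
        res = polish(grid[k], n_replicates, "coarse", coarse_iter)
        terminals.append(res.x)
    trace.append(dict(stage="coarse", evals=len(chosen) * coarse_iter,
                      basins=len(terminals)))

    # stage B: every candidate basin gets the fine-statistic Nelder-Mead
    # polish at higher replicates; only then are the basins ranked, at high
    # precision — competing basins (e.g. a recent split vs a deep split at
    # migration-drift equilibrium) can sit within a few log-units of each
    # other, far inside coarse-stage noise
    polished = [polish(x, polish_replicates, "fine", maxiter).x
                for x in terminals]
    scores = [objective(x, max(3 * polish_replicates, report_replicates),
                        "fine") for x in polished]
    order_b = np.argsort(scores)
    best_x, best_f = polished[order_b[0]], scores[order_b[0]]
    for k in range(n_polish):
        x0 = np.clip(best_x + rng.normal(0, math.log(1.3), size=len(bnds)),
                     log_b[:, 0], log_b[:, 1])
        res = polish(x0, polish_replicates, "fine", maxiter)
        f = objective(res.x, max(3 * polish_replicates, report_replicates),
                      "fine")
        if f < best_f:
            best_f, best_x = f, res.x
    trace.append(dict(stage="fine", evals=(len(polished) + n_polish) * maxiter,
                      best_negll=float(best_f)))

    # stage C: profile refinements along the two directions Nelder-Mead
    # cannot resolve through Monte-Carlo noise, scored at high replicates
    # with common random numbers.
    #   - split-time profile: T1 varied with everything else (including the
    #     absolute T2) held fixed — the likelihood is nearly flat in T1 once
    #     isolation is old relative to the within-population coalescent
    #     scale, leaving only O(1) curvature;
    #   - scale profile: all sizes and times multiplied by s and migration
    #     divided by s — the family's near-exact scaling symmetry, broken
    #     only by the fixed ancestral size.
    t1_idx = spec.free_params.index("T1")
    frac_idx = spec.free_params.index("T2") if "T2" in spec.free_params else None
    scale_idx = [k for k, name in enumerate(spec.free_params)
                 if name.startswith("nu") or name == "T1"]
    mig_idx = [k for k, name in enumerate(spec.free_params)
               if name.startswith("m")]

    def t1_candidate(x, log_factor):
        out = x.copy()
        old_t1 = out[t1_idx]
        out[t1_idx] = np.clip(old_t1 + log_factor,
                              log_b[t1_idx, 0], log_b[t1_idx, 1])
        if frac_idx is not None:  # keep absolute T2: frac shrinks as T1 grows
            out[frac_idx] = np.clip(out[frac_idx] + old_t1 - out[t1_idx],
                                    log_b[frac_idx, 0], log_b[frac_idx, 1])
        return out

    def scale_candidate(x, log_s):
        out = x.copy()
        out[scale_idx] = np.clip(out[scale_idx] + log_s,
                                 log_b[scale_idx, 0], log_b[scale_idx, 1])
        out[mig_idx] = np.clip(out[mig_idx] - log_s,
                               log_b[mig_idx, 0], log_b[mig_idx, 1])
        return out

    profile_reps = 2 * report_replicates  # the flat directions need precision
    n_profile_evals = 0
    for factors, builder in (
            ((0.45, 0.65, 1.0, 1.5, 2.2), scale_candidate),
            ((0.4, 0.6, 0.8, 1.0, 1.3, 1.7, 2.3), t1_candidate),
            ((0.8, 1.0, 1.25), scale_candidate),
            ((0.82, 0.91, 1.0, 1.1, 1.21), t1_candidate)):
        cands = [builder(best_x, math.log(f)) for f in factors]
        scores = [objective(x, profile_reps, "fine") for x in cands]
        k = int(np.argmin(scores))
        best_x, best_f = cands[k], scores[k]
        n_profile_evals += len(cands)
    trace.append(dict(stage="profiles", evals=n_profile_evals,
                      best_negll=float(best_f)))

    params = _vector_to_params(spec, best_x)
    at_bound = bool(np.any(np.isclose(best_x, log_b[:, 0], atol=1e-6))
                    or np.any(np.isclose(best_x, log_b[:, 1], atol=1e-6)))
    model = expected_afs(spec, params, data.sample_sizes,
                         n_replicates=report_replicates, seed=crn_seed,
                         folded=data.folded,
                         length_budget=40.0 * report_replicates,
                         min_replicates=max(200, report_replicates // 8))
    ll, theta_hat = loglik(data, model, coarsen="fine")
    return FitResult(
        model=spec.name, params=params, loglik=ll,
        aic=2 * spec.k - 2 * ll, theta_hat=theta_hat,
        converged=not at_bound, trace=trace,
        data_fingerprint=data.fingerprint(), seed=seed)


def model_select(fits):
    """Rank fits of the same data by AIC; adds delta-AIC and Akaike weights."""
    if not fits:
        raise ValueError("no fits to select among")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("fits are not all on the same data spectrum")
    ranked = sorted(fits, key=lambda f: f.aic)
    amin = ranked[0].aic
    deltas = np.array([f.aic - amin for f in ranked])
    w = np.exp(-deltas / 2)
    w /= w.sum()
    return [dict(fit=f, delta_aic=float(d), akaike_weight=float(wi))
            for f, d, wi in zip(ranked, deltas, w)]


def residual_spectrum(data: JointAFS, model: JointAFS):
    """Anscombe-style Poisson residuals (data - theta*model)/sqrt(theta*model)
    for the visual model check; masked cells are NaN."""
    _, theta = loglik(data, model)
    mu = np.maximum(theta * model.data, 1e-30)
    res = (data.data - mu) / np.sqrt(mu)
    res[data.mask | model.mask] = np.nan
    return res


# ---------------------------------------------------------------------------
# Biological units
# ---------------------------------------------------------------------------

@dataclass
class ConversionSpec:
    """Mutation rate per site per generation, generation time in years, and
    effective assayed sequence length (sites)."""

    mu: float = 8e-8
    generation_time: float = 1.0
    L: float = 1.0

    def __post_init__(self):
        if min(self.mu, self.generation_time, self.L) <= 0:
            raise ValueError("all conversion quantities must be > 0")


def to_biological_units(params: dict, conv: ConversionSpec) -> dict:
    """Convert diffusion-scale parameters to demographic quantities.

    N_ref = theta/(4*mu*L); times become generations (x2*N_ref) and years;
    m_ij/(2*N_ref) is the per-generation fraction of population i replaced by
    migrants from j; m_ij*nu_i/2 is the effective number of migrants.
    """
    n_ref = params["theta"] / (4 * conv.mu * conv.L)
    out = {"N_ref": n_ref}
    for t in ("T1", "T2"):
        if t in params:
            gens = params[t] * 2 * n_ref
            out[f"{t}_generations"] = gens
            out[f"{t}_years"] = gens * conv.generation_time
    for m, nu in (("m12", "nu1"), ("m21", "nu2")):
        if m in params:
            out[f"{m}_fraction_per_generation"] = params[m] / (2 * n_ref)
            if nu in params:
                out[f"{m}_migrants_per_generation"] = params[m] * params[nu] / 2
    return out


def from_biological_units(report: dict, conv: ConversionSpec) -> dict:
    """Inverse of :func:`to_biological_units` for the convertible quantities."""
    n_ref = report["N_ref"]
    out = {"theta": n_ref * 4 * conv.mu * conv.L}
    for t in ("T1", "T2"):
        if f"{t}_generations" in report:
            out[t] = report[f"{t}_generations"] / (2 * n_ref)
    for m in ("m12", "m21"):
        if f"{m}_fraction_per_generation" in report:
            out[m] = report[f"{m}_fraction_per_generation"] * 2 * n_ref
    return out


# ---------------------------------------------------------------------------
# ABC cross-check
# ---------------------------------------------------------------------------

def summary_stats(matrix, popA, popB):
    """Summary vector for ABC: per-population expected heterozygosity,
    pairwise WC theta, private-polymorphism fractions, and quartiles of the
    folded per-locus minor-allele frequency in each population."""
    from .genotype_io import MISSING
    from .popgen_stats import wc_theta

    out = []
    mafs = {}
    poly = {}
    for pop in (popA, popB):
        calls = matrix.calls[matrix.pop_indices(pop)]
        ok = calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(ok, calls, 0).sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
        he = 2 * p * (1 - p)
        out.append(float(np.nanmean(he)))
        mafs[pop] = np.minimum(p, 1 - p)
        poly[pop] = (p > 0) & (p < 1)
    theta = wc_theta(matrix, [popA, popB])
    out.append(theta if np.isfinite(theta) else 0.0)
    n_loci = matrix.n_loci
    out.append(float((poly[popA] & ~poly[popB]).sum() / n_loci))
    out.append(float((poly[popB] & ~poly[popA]).sum() / n_loci))
    for pop in (popA, popB):
        vals = mafs[pop][np.isfinite(mafs[pop])]
        qs = np.quantile(vals, (0.25, 0.5, 0.75)) if vals.size else (0, 0, 0)
        out.extend(float(q) for q in qs)
    return np.array(out)


def abc_model_choice(data_summaries, specs, priors, n_sims_per_model=1_000_000,
                     tolerance=0.01, seed=1, n_loci=200, n_per_pop=10):
    """Rejection-ABC model choice over the demographic family.

    For each candidate model, parameters are drawn log-uniformly from
    ``priors`` (param -> (lo, hi)), a SNP matrix is simulated and reduced to
    :func:`summary_stats`.  The nearest ``tolerance`` fraction of simulations
    (normalized Euclidean distance over the pooled cloud) is accepted; the
    posterior probability of each model is its acceptance share.  Also
    returns a posterior-predictive goodness-of-fit quantile for the best
    model and the accepted parameter draws.
    """
    from .synthetic_data import simulate_genotypes

    rng = np.random.default_rng(seed)
    sims, labels, draws = [], [], []
    for spec in specs:
        if isinstance(spec, str):
            spec = MODEL_SPECS[spec]
        for _ in range(n_sims_per_model):
            p = {}
            for name in spec.free_params:
                lo, hi = priors[name if name in priors else name[:2]] \
                    if (name in priors or name[:2] in priors) else priors["nu"]
                p[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            if "T2" in p:
                p["T2"] = min(p["T2"], 0.95 * p["T1"])
            m = simulate_genotypes(spec, p, n_per_pop=n_per_pop, n_loci=n_loci,
                                   seed=int(rng.integers(1, 2 ** 31 - 2)))
            sims.append(summary_stats(m, "p1", "p2"))
            labels.append(spec.name)
            draws.append(p)
    sims = np.array(sims)
    labels = np.array(labels)
    scale = sims.std(axis=0)
    scale[scale == 0] = 1.0
    d = np.sqrt((((sims - data_summaries) / scale) ** 2).sum(axis=1))
    n_accept = max(1, int(round(tolerance * len(sims))))
    accept = np.argsort(d)[:n_accept]
    post = {str(name): float((labels[accept] == name).mean())
            for name in dict.fromkeys(labels)}
    best = max(post, key=post.get)
    cloud = sims[accept][labels[accept] == best]
    center = cloud.mean(axis=0)
    d_cloud = np.sqrt((((cloud - center) / scale) ** 2).sum(axis=1))
    d_obs = math.sqrt((((data_summaries - center) / scale) ** 2).sum())
    gof = float((d_cloud >= d_obs).mean())
    return dict(posterior=post, best_model=best, gof_quantile=gof,
                accepted_params=[draws[i] for i in accept],
                accepted_models=list(labels[accept]))
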