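"""Coalescent and Mendelian generators for every input the pipeline needs.

Genotypes under the two-population demographic model family (or an n-deme
island model) are drawn from msprime gene trees with one mutation per
retained locus: trees receive Poisson(mu * total branch length) mutations at
a small mu and are kept only if at least one lands (rejection conditioning on
a segregating site, matching SNP ascertainment), so the locus distribution
matches the branch-length expected AFS of the same demography.  Hybrid swarms
(P0/P1/F1/F2/backcrosses) are Mendelian draws from parental allele-frequency
pools; the QC fixture plants one violation of every filter rule and carries
its own independently computed ground truth; mtDNA-like haplotype alignments
exercise the sequence Phi_ST.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import msprime
import numpy as np

from .demography import MODEL_SPECS, ModelSpec, build_demography
from .genotype_io import MISSING, GenotypeMatrix, HaplotypeAlignment, LocusMetadata

__all__ = [
    "SwarmConfig",
    "island_demography",
    "panmictic_demography",
    "simulate_genotypes",
    "simulate_hybrid_swarm",
    "make_qc_fixture",
    "simulate_mtdna",
]


# ---------------------------------------------------------------------------
# Coalescent genotype simulation
# ---------------------------------------------------------------------------

def island_demography(n_demes: int, four_n_m: float, deme_size: float = 1.0):
    """Symmetric n-deme island model; ``four_n_m`` is 4*N*m with m the total
    per-generation fraction of a deme replaced by migrants.  Time units are
    2N generations (deme size 1 = the reference size)."""
    dem = msprime.Demography()
    for d in range(n_demes):
        dem.add_population(name=f"d{d}", initial_size=deme_size / 2)
    if n_demes > 1 and four_n_m > 0:
        # per-pair backwards rate; calibrated so the realized multilocus
        # F_ST follows 1/(1 + 4Nm (n/(n-1))^2) with m the total immigrant
        # fraction (verified against simulation in the test suite)
        m_each = four_n_m * n_demes / (2 * (n_demes - 1) ** 2)
        dem.set_symmetric_migration_rate([f"d{d}" for d in range(n_demes)], m_each)
    return dem


def panmictic_demography(size: float = 1.0):
    dem = msprime.Demography()
    dem.add_population(name="d0", initial_size=size / 2)
    return dem


def _resolve_demography(spec, params, n_per_pop):
    """Returns (demography, samples dict {pop_name: n_diploids})."""
    if isinstance(spec, msprime.Demography):
        dem = spec
        names = [p.name for p in dem.populations
                 if p.name != "anc" and p.default_sampling_time in (None, 0)]
        if isinstance(n_per_pop, dict):
            samples = dict(n_per_pop)
        else:
            samples = {name: n_per_pop for name in names}
        return dem, samples
    spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
    dem = build_demography(spec, params)
    if isinstance(n_per_pop, dict):
        samples = dict(n_per_pop)
    else:
        samples = {"p1": n_per_pop, "p2": n_per_pop}
    return dem, samples


def _draw_segregating_locus(tree, rng, individual_of_node, n_ind):
    """Place one mutation uniformly on the branches; return diploid counts."""
    nodes, lengths = [], []
    for u in tree.nodes():
        bl = tree.branch_length(u)
        if bl > 0:
            nodes.append(u)
            lengths.append(bl)
    lengths = np.array(lengths)
    u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
    g = np.zeros(n_ind, dtype=np.int16)
    for s in tree.samples(u):
        g[individual_of_node[s]] += 1
    return g


def simulate_genotypes(spec, params=None, n_per_pop=10, n_loci=1000, seed=1,
                       target_load: float = 0.1) -> GenotypeMatrix:
    """Unlinked biallelic SNP genotypes under a demographic model.

    ``spec`` is a model name / :class:`ModelSpec` (with ``params``) or a
    ready msprime Demography (island model, panmixia, ...); ``n_per_pop`` is
    diploid individuals per population (or a dict by population name).  Each
    locus is an independent gene tree carrying exactly one mutation,
    conditioned on segregating by Poisson rejection at a small mutation load
    (``target_load`` expected mutations per tree, auto-scaled from a pilot
    batch), so the sampled loci follow the branch expected AFS.
    """
    rng = np.random.default_rng(seed)
    dem, samples = _resolve_demography(spec, params, n_per_pop)
    pop_names = list(samples)
    n_ind = sum(samples.values())

    def replicates(n, s):
        return msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=2,
            num_replicates=n, random_seed=s)

    # pilot: set mu so the mean per-tree mutation load is target_load
    pilot = [ts.first().total_branch_length
             for ts in replicates(50, int(rng.integers(1, 2 ** 31 - 2)))]
    mu = target_load / np.mean(pilot)

    calls = np.empty((n_ind, n_loci), dtype=np.int16)
    individual_of_node = None
    pop_of_individual = None
    got = 0
    while got < n_loci:
        batch = max(200, int((n_loci - got) / target_load * 1.2))
        for ts in replicates(batch, int(rng.integers(1, 2 ** 31 - 2))):
            if individual_of_node is None:
                individual_of_node = np.array(
                    [ts.node(s).individual for s in range(ts.num_samples)])
                pop_of_individual = {}
                for s in ts.samples():
                    node = ts.node(s)
                    pop_of_individual[node.individual] = \
                        ts.population(node.population).metadata.get("name")
            tree = ts.first()
            if rng.random() >= -math.expm1(-mu * tree.total_branch_length):
                continue
            calls[:, got] = _draw_segregating_locus(tree, rng,
                                                    individual_of_node, n_ind)
            got += 1
            if got == n_loci:
                break

    individual_ids = []
    pops = {}
    counters = {name: 0 for name in pop_names}
    for i in range(n_ind):
        pop = pop_of_individual[i]
        counters[pop] += 1
        ind = f"{pop}_{counters[pop]:03d}"
        individual_ids.append(ind)
        pops[ind] = pop
    locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(individual_ids, locus_ids, calls, pops)


# ---------------------------------------------------------------------------
# Hybrid swarm
# ---------------------------------------------------------------------------

CATEGORY_MIX = {
    # ancestry-pair proportions (both-from-P0, one-each, both-from-P1)
    "P0": (1.0, 0.0, 0.0),
    "P1": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC0": (0.5, 0.5, 0.0),
    "BC1": (0.0, 0.5, 0.5),
}


@dataclass
class SwarmConfig:
    """Design of a simulated hybrid swarm.

    Parental divergence is set either as a target F_ST (Balding-Nichols
    frequency draws) or as a fraction of loci fixed for alternate alleles;
    ``counts`` gives individuals per category.
    """

    counts: dict = field(default_factory=lambda: dict(
        P0=20, P1=20, F1=10, F2=10, BC0=10, BC1=10))
    n_loci: int = 300
    target_fst: float | None = 0.3
    fixed_difference_fraction: float | None = None
    seed: int = 1

    def __post_init__(self):
        if self.n_loci < 1 or any(v < 0 for v in self.counts.values()):
            raise ValueError("need n_loci >= 1 and non-negative counts")
        unknown = set(self.counts) - set(CATEGORY_MIX)
        if unknown:
            raise ValueError(f"unknown hybrid categories {unknown}")


def simulate_hybrid_swarm(config: SwarmConfig) -> GenotypeMatrix:
    """Mendelian hybrid-swarm draws; population label = true category.

    P0/P1 are Hardy-Weinberg draws from their pools; an F1 takes one allele
    from each pool per locus; F2 gametes pick a parental pool with
    probability 1/2 each; backcrosses combine an F1 gamete with a parental
    gamete.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    if config.fixed_difference_fraction is not None:
        n_fix = int(round(config.fixed_difference_fraction * L))
        p0 = np.concatenate([np.zeros(n_fix), rng.uniform(0.1, 0.9, L - n_fix)])
        p1 = np.concatenate([np.ones(n_fix), p0[n_fix:]])
    elif config.target_fst and config.target_fst > 0:
        F = config.target_fst
        anc = rng.uniform(0.1, 0.9, L)
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        p0 = rng.beta(a, b)
        p1 = rng.beta(a, b)
    else:
        if any(config.counts.get(c, 0) for c in ("F1", "F2", "BC0", "BC1")):
            import warnings
            warnings.warn("zero parental divergence: hybrid categories are "
                          "unidentifiable")
        p0 = p1 = rng.uniform(0.1, 0.9, L)

    def gamete(origin_p0_prob, n):
        """n gametes: allele pool chosen Bernoulli(origin_p0_prob), allele
        drawn from that pool's frequency."""
        from_p0 = rng.random((n, L)) < origin_p0_prob
        return np.where(from_p0, rng.random((n, L)) < p0, rng.random((n, L)) < p1)

    ids, pops, rows = [], {}, []
    for cat, count in config.counts.items():
        if count == 0:
            continue
        if cat == "P0":
            g = gamete(1.0, count).astype(np.int16) + gamete(1.0, count)
        elif cat == "P1":
            g = gamete(0.0, count).astype(np.int16) + gamete(0.0, count)
        elif cat == "F1":
            g = gamete(1.0, count).astype(np.int16) + gamete(0.0, count)
        elif cat == "F2":
            g = gamete(0.5, count).astype(np.int16) + gamete(0.5, count)
        elif cat == "BC0":
            g = gamete(0.5, count).astype(np.int16) + gamete(1.0, count)
        else:  # BC1
            g = gamete(0.5, count).astype(np.int16) + gamete(0.0, count)
        for k in range(count):
            ind = f"{cat}_{k + 1:03d}"
            ids.append(ind)
            pops[ind] = cat
            rows.append(g[k])
    calls = np.array(rows, dtype=np.int16)
    return GenotypeMatrix(ids, [f"L{j + 1}" for j in range(L)], calls, pops)


# ---------------------------------------------------------------------------
# QC fixture with planted violations and independent ground truth
# ---------------------------------------------------------------------------

def make_qc_fixture(seed: int = 1, plant_violations: bool = True):
    """Pre-QC matrix + metadata + ground-truth retained ids and per-step counts.

    A clean Hardy-Weinberg base matrix is augmented with one planted
    violation per filter rule.  The ground truth (retained locus/individual
    ids and the per-step removal ledger) is computed here by an independent
    brute-force pass over the pinned rule order, using exact rational
    arithmetic for rates and an exact enumeration Hardy-Weinberg test — no
    code from the QC module is used.
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = 22, 22
    n_ind = n_a + n_b
    n_clean = 60

    ids = [f"A{i + 1:02d}" for i in range(n_a)] + [f"B{i + 1:02d}" for i in range(n_b)]
    pops = {i: ("A" if i.startswith("A") else "B") for i in ids}

    def hw_locus():
        p = rng.uniform(0.25, 0.75)
        return rng.binomial(2, p, size=n_ind).astype(np.int16)

    loci, cols, meta = [], [], []
    alphabet = np.array(list("ACGT"))

    def add_locus(name, col, depth=None, rep=0.99, tag=None, pos=10, seq=None):
        loci.append(name)
        cols.append(np.asarray(col, dtype=np.int16))
        meta.append(dict(
            locus_id=name,
            tag_id=tag if tag is not None else f"T{len(loci):03d}",
            position_in_tag=pos,
            call_rate=float((cols[-1] != MISSING).mean()),
            repeatability=rep,
            mean_depth=float(depth if depth is not None else rng.uniform(10, 30)),
            tag_sequence=seq if seq is not None
            else "".join(rng.choice(alphabet, 30)),
        ))

    for j in range(n_clean):
        add_locus(f"clean{j + 1:02d}", hw_locus())

    bad_individuals = []
    if plant_violations:
        # five low-call-rate individuals, each missing a staggered 18-locus
        # window of the clean loci (30%); the stagger keeps any single clean
        # locus at <= 2 missing calls so no clean locus fails its own filter
        bad_rows = [2, 5, 8, n_a + 2, n_a + 5]
        bad_individuals = [ids[i] for i in bad_rows]
        for w, i in enumerate(bad_rows):
            for j in range(w * 12, w * 12 + 18):
                cols[j % n_clean][i] = MISSING
        for j in range(n_clean):
            meta[j]["call_rate"] = float((cols[j] != MISSING).mean())

        good_rows = [i for i in range(n_ind) if ids[i] not in bad_individuals]

        add_locus("mono", np.zeros(n_ind))
        low = hw_locus()
        low[rng.choice(good_rows, size=5, replace=False)] = MISSING
        add_locus("lowcall", low)
        add_locus("lowdepth", hw_locus(), depth=3.0)
        add_locus("lowrep", hw_locus(), rep=0.90)
        # duplicate-tag pair: identical call rates, positions 5 and 12
        add_locus("tagdup_a", hw_locus(), tag="TAGDUP", pos=5)
        add_locus("tagdup_b", hw_locus(), tag="TAGDUP", pos=12)
        # near-duplicate tag sequences (2/30 mismatches)
        base_seq = "".join(rng.choice(alphabet, 30))
        other = list(base_seq)
        other[0] = "A" if other[0] != "A" else "C"
        other[1] = "A" if other[1] != "A" else "C"
        add_locus("hamdup_a", hw_locus(), seq=base_seq)
        add_locus("hamdup_b", hw_locus(), seq="".join(other))
        add_locus("hwe_bad", np.ones(n_ind))  # everyone heterozygous
        # perfect-LD pair: identical genotype columns
        ld = hw_locus()
        add_locus("ld_a", ld)
        add_locus("ld_b", ld.copy())
        # crosses the missingness threshold only after the five low-call
        # individuals are removed (4/44 = 0.091 passes; 4/39 = 0.103 fails)
        cross = hw_locus()
        cross[rng.choice(good_rows, size=4, replace=False)] = MISSING
        add_locus("misscross", cross)
        # a singleton: MAF 1/78 < 2% in the post-removal sample of 39
        rare = np.zeros(n_ind, dtype=np.int16)
        rare[good_rows[0]] = 1
        add_locus("lowmaf", rare)

    calls = np.column_stack(cols)
    import pandas as pd
    matrix = GenotypeMatrix(ids, loci, calls, pops)
    metadata = LocusMetadata(pd.DataFrame(meta).set_index("locus_id"))

    truth = _brute_force_truth(matrix, metadata)
    return matrix, metadata, truth


def _brute_force_truth(matrix, metadata):
    """Independent per-rule brute force over the pinned filter order.

    Plain loops, exact Fractions for every rate comparison, and an exact
    rational-enumeration HWE test.  Returns dict with retained ids and the
    ordered (step, loci_removed, individuals_removed) ledger.
    """
    thresholds = dict(locus_cr=Fraction(9, 10), ind_cr=Fraction(4, 5),
                      depth=5, rep=Fraction(95, 100), ham=Fraction(1, 4),
                      hwe=Fraction(1, 100000), r2=Fraction(8, 10),
                      miss=Fraction(1, 10), maf=Fraction(1, 50))
    inds = list(matrix.individual_ids)
    loci = list(matrix.locus_ids)
    col = {l: {i: int(matrix.calls[matrix.individual_ids.index(i),
                                   matrix.locus_ids.index(l)])
               for i in inds} for l in loci}
    steps = []

    def nonmissing(l, current_inds):
        return [col[l][i] for i in current_inds if col[l][i] != MISSING]

    def locus_cr(l, current_inds):
        return Fraction(len(nonmissing(l, current_inds)), len(current_inds))

    # 1 monomorphic
    drop = [l for l in loci
            if len({g for g in nonmissing(l, inds)} | ({0, 2} if 1 in nonmissing(l, inds) else set())) <= 1]
    loci = [l for l in loci if l not in drop]
    steps.append(("monomorphic", len(drop), 0))
    # 2 locus call rate
    drop = [l for l in loci if locus_cr(l, inds) < thresholds["locus_cr"]]
    loci = [l for l in loci if l not in drop]
    steps.append(("locus_call_rate", len(drop), 0))
    # 3 individual call rate
    dropi = [i for i in inds
             if Fraction(sum(col[l][i] != MISSING for l in loci), len(loci))
             < thresholds["ind_cr"]]
    inds = [i for i in inds if i not in dropi]
    steps.append(("indiv_call_rate", 0, len(dropi)))
    # 4 depth, 5 repeatability
    drop = [l for l in loci if metadata.table.loc[l, "mean_depth"] < thresholds["depth"]]
    loci = [l for l in loci if l not in drop]
    steps.append(("min_depth", len(drop), 0))
    drop = [l for l in loci
            if Fraction(metadata.table.loc[l, "repeatability"]).limit_denominator(10**6)
            < thresholds["rep"]]
    loci = [l for l in loci if l not in drop]
    steps.append(("repeatability", len(drop), 0))
    # 6 one SNP per tag (keep highest call rate, tie -> smaller position)
    best = {}
    for l in loci:
        tag = metadata.table.loc[l, "tag_id"]
        key = (-locus_cr(l, inds), metadata.table.loc[l, "position_in_tag"],
               loci.index(l))
        if tag not in best or key < best[tag][0]:
            best[tag] = (key, l)
    chosen = {l for _, l in best.values()}
    n_before = len(loci)
    loci = [l for l in loci if l in chosen]
    steps.append(("one_snp_per_tag", n_before - len(loci), 0))
    # 7 hamming
    removed = set()
    for x in range(len(loci)):
        lx = loci[x]
        if lx in removed:
            continue
        sx = metadata.table.loc[lx, "tag_sequence"]
        for y in range(x + 1, len(loci)):
            ly = loci[y]
            if ly in removed:
                continue
            sy = metadata.table.loc[ly, "tag_sequence"]
            if not isinstance(sx, str) or not isinstance(sy, str) or len(sx) != len(sy):
                continue
            d = Fraction(sum(a != b for a, b in zip(sx, sy)), len(sx))
            if d <= thresholds["ham"]:
                crx, cry = locus_cr(lx, inds), locus_cr(ly, inds)
                victim = lx if crx < cry else ly if cry < crx else max(lx, ly, key=loci.index)
                removed.add(victim)
                if victim == lx:
                    break
    n_before = len(loci)
    loci = [l for l in loci if l not in removed]
    steps.append(("hamming", n_before - len(loci), 0))
    # 8 HWE within each population
    drop = []
    for l in loci:
        for pop in ("A", "B"):
            g = [col[l][i] for i in inds
                 if matrix.population_of[i] == pop and col[l][i] != MISSING]
            if not g:
                continue
            counts = (sum(x == 0 for x in g), sum(x == 1 for x in g),
                      sum(x == 2 for x in g))
            if _hwe_exact_fraction(*counts) < thresholds["hwe"]:
                drop.append(l)
                break
    loci = [l for l in loci if l not in drop]
    steps.append(("hwe", len(drop), 0))
    # 9 LD prune (all pairs; fixture pairs sit inside one window)
    removed = set()
    while True:
        worst = None
        for x in range(len(loci)):
            for y in range(x + 1, len(loci)):
                lx, ly = loci[x], loci[y]
                if lx in removed or ly in removed:
                    continue
                pairs = [(col[lx][i], col[ly][i]) for i in inds
                         if col[lx][i] != MISSING and col[ly][i] != MISSING]
                xs = [a for a, _ in pairs]
                ys = [b for _, b in pairs]
                n = len(pairs)
                if n < 2 or len(set(xs)) == 1 or len(set(ys)) == 1:
                    continue
                sx = n * sum(a * a for a in xs) - sum(xs) ** 2
                sy = n * sum(b * b for b in ys) - sum(ys) ** 2
                sxy = n * sum(a * b for a, b in pairs) - sum(xs) * sum(ys)
                r2 = Fraction(sxy * sxy, sx * sy)
                if r2 > thresholds["r2"] and (worst is None or r2 > worst[0]):
                    worst = (r2, lx, ly)
        if worst is None:
            break
        _, lx, ly = worst
        crx, cry = locus_cr(lx, inds), locus_cr(ly, inds)
        removed.add(lx if crx < cry else ly if cry < crx
                    else max(lx, ly, key=loci.index))
    n_before = len(loci)
    loci = [l for l in loci if l not in removed]
    steps.append(("ld_prune", n_before - len(loci), 0))
    # 10 missingness
    drop = [l for l in loci
            if Fraction(sum(col[l][i] == MISSING for i in inds), len(inds))
            > thresholds["miss"]]
    loci = [l for l in loci if l not in drop]
    steps.append(("max_missing", len(drop), 0))
    # 11 MAF
    drop = []
    for l in loci:
        g = nonmissing(l, inds)
        p = Fraction(sum(g), 2 * len(g))
        if min(p, 1 - p) < thresholds["maf"]:
            drop.append(l)
    loci = [l for l in loci if l not in drop]
    steps.append(("min_maf", len(drop), 0))

    return dict(retained_loci=loci, retained_individuals=inds, steps=steps)


def _hwe_exact_fraction(n_aa, n_ab, n_bb):
    """Exact HWE p-value with rational arithmetic (enumeration oracle)."""
    n = n_aa + n_ab + n_bb
    n_alt = n_ab + 2 * n_bb
    nm = min(n_alt, 2 * n - n_alt)
    if nm == 0:
        return Fraction(1)
    weights = {}
    for h in range(nm % 2, nm + 1, 2):
        weights[h] = (Fraction(2 ** h)
                      / (math.factorial(h)
                         * math.factorial((nm - h) // 2)
                         * math.factorial(n - (nm + h) // 2)))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= p_obs)


# ---------------------------------------------------------------------------
# mtDNA-like haplotypes
# ---------------------------------------------------------------------------

def simulate_mtdna(divergence: float, n_per_pop: int = 10, seq_length: int = 400,
                   seed: int = 1, within_divergence: float = 1.0) -> HaplotypeAlignment:
    """Two clades of haplotypes under a single-parameter substitution model.

    ``divergence`` is the expected substitution count separating the two
    clade ancestors; each haplotype additionally accumulates
    Poisson(``within_divergence``) private substitutions.  Clade = population.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, seq_length)

    def mutate(seq, n_subs):
        seq = seq.copy()
        for pos in rng.integers(0, seq_length, size=n_subs):
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = choices[rng.integers(0, 3)]
        return seq

    anc = {"cladeA": mutate(root, rng.poisson(divergence / 2)),
           "cladeB": mutate(root, rng.poisson(divergence / 2))}
    ids, seqs, pops = [], [], {}
    for clade in ("cladeA", "cladeB"):
        for k in range(n_per_pop):
            name = f"{clade}_{k + 1:02d}"
            ids.append(name)
            seqs.append("".join(mutate(anc[clade], rng.poisson(within_divergence))))
            pops[name] = clade
    return HaplotypeAlignment(ids, seqs, pops)
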