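"""SNP quality-control filters applied in a fixed order with per-step attrition.

The rule set mirrors standard reduced-representation (DArTseq) practice:
monomorphic removal, locus/individual call-rate thresholds, sequencing depth
and technical repeatability floors, one SNP per sequenced tag, a normalized
Hamming-distance filter against paralogous tags, an exact Hardy-Weinberg test
within each population, windowed LD pruning, and final missingness and
minor-allele-frequency cuts.  Thresholds follow the strict inequalities of the
source protocol: call rate below 0.90 (loci) / 0.80 (individuals), depth
below 5, repeatability below 0.95, HWE P < 1e-5, r^2 > 0.80, missingness
above 10%, MAF below 2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genotype_io import MISSING, GenotypeMatrix, LocusMetadata

__all__ = [
    "FilterConfig",
    "FilterReport",
    "hwe_exact_test",
    "maf",
    "ld_r2",
    "ld_prune",
    "hamming_filter",
    "apply_filters",
]


@dataclass
class FilterConfig:
    """Thresholds for :func:`apply_filters`; defaults are the study protocol."""

    min_locus_call_rate: float = 0.90
    min_indiv_call_rate: float = 0.80
    min_depth: float = 5.0
    min_repeatability: float = 0.95
    one_snp_per_tag: bool = True
    hamming_threshold: float = 0.25
    hwe_alpha: float = 1e-5
    ld_r2_max: float = 0.80
    max_locus_missing: float = 0.10
    min_maf: float = 0.02
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self):
        for name in ("min_locus_call_rate", "min_indiv_call_rate",
                     "min_repeatability", "hamming_threshold", "ld_r2_max",
                     "max_locus_missing", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("require ld_window >= ld_step >= 1")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class FilterReport:
    """Ordered ledger of per-step attrition."""

    steps: list = field(default_factory=list)  # (name, loci_removed, ind_removed, loci_left, ind_left)

    def add(self, name, loci_removed, ind_removed, loci_left, ind_left):
        if self.steps:
            prev_loci, prev_ind = self.steps[-1][3], self.steps[-1][4]
            assert loci_left <= prev_loci and ind_left <= prev_ind
        self.steps.append((name, loci_removed, ind_removed, loci_left, ind_left))

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("step\tloci_removed\tindividuals_removed\tloci_remaining\tindividuals_remaining\n")
            for row in self.steps:
                fh.write("\t".join(str(x) for x in row) + "\n")

    def total_removed(self):
        loci = sum(s[1] for s in self.steps)
        inds = sum(s[2] for s in self.steps)
        return loci, inds


# ---------------------------------------------------------------------------
# Per-locus statistics
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test (conditional on allele counts).

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities no greater than that of the observed table
    (Wigginton-style).  Returns a p-value in (0, 1].
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("HWE test undefined for an empty genotype table")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # P(het = h | allele counts) up to a constant: n! 2^h / (h! nAA! naa!)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([
        h * math.log(2.0)
        - math.lgamma(h + 1)
        - math.lgamma((n_minor - h) // 2 + 1)
        - math.lgamma(n - (n_minor + h) // 2 + 1)
        for h in hets
    ])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def maf(matrix: GenotypeMatrix, locus) -> float:
    """Missing-aware minor-allele frequency at ``locus``."""
    j = matrix.locus_ids.index(locus) if isinstance(locus, str) else locus
    col = matrix.calls[:, j]
    col = col[col != MISSING]
    if col.size == 0:
        raise ValueError("MAF undefined: all calls missing")
    p = col.sum() / (2 * col.size)
    return float(min(p, 1 - p))


def ld_r2(matrix: GenotypeMatrix, locus_a, locus_b) -> float:
    """Squared Pearson correlation of genotype codes (composite r^2) over
    individuals non-missing at both loci.  NaN if either locus is constant on
    the shared set (treated as not prunable by callers)."""
    ja = matrix.locus_ids.index(locus_a) if isinstance(locus_a, str) else locus_a
    jb = matrix.locus_ids.index(locus_b) if isinstance(locus_b, str) else locus_b
    a, b = matrix.calls[:, ja], matrix.calls[:, jb]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _call_rates(calls):
    return (calls != MISSING).mean(axis=0)


def ld_prune(matrix: GenotypeMatrix, config: FilterConfig) -> list:
    """Plink-style sliding-window greedy LD prune.

    Within each window, while any retained pair has r^2 > ``ld_r2_max``, the
    pair member with the lower call rate is dropped (tie: the later locus);
    the window then advances by ``ld_step`` loci.  Returns retained locus ids.
    """
    n = matrix.n_loci
    call_rate = _call_rates(matrix.calls)
    removed = np.zeros(n, dtype=bool)
    starts = range(0, max(n - 1, 1), config.ld_step)
    for start in starts:
        window = [j for j in range(start, min(start + config.ld_window, n))
                  if not removed[j]]
        while True:
            worst = None  # (r2, ja, jb)
            for x in range(len(window)):
                for y in range(x + 1, len(window)):
                    ja, jb = window[x], window[y]
                    r2 = ld_r2(matrix, ja, jb)
                    if not np.isnan(r2) and r2 > config.ld_r2_max:
                        if worst is None or r2 > worst[0]:
                            worst = (r2, ja, jb)
            if worst is None:
                break
            _, ja, jb = worst
            if call_rate[ja] < call_rate[jb]:
                drop = ja
            elif call_rate[jb] < call_rate[ja]:
                drop = jb
            else:
                drop = max(ja, jb)
            removed[drop] = True
            window.remove(drop)
        if start + config.ld_window >= n:
            break
    return [matrix.locus_ids[j] for j in range(n) if not removed[j]]


def hamming_filter(metadata: LocusMetadata, threshold: float,
                   call_rate=None) -> list:
    """Drop one member of every tag-sequence pair closer than ``threshold``
    normalized Hamming distance (paralog screen).

    The lower-call-rate member of a close pair is dropped (tie: the later
    locus).  Loci without a tag sequence pass; unequal-length pairs are
    skipped (counted as warnings).  Returns retained locus ids.
    """
    ids = list(metadata.table.index)
    seqs = metadata["tag_sequence"].tolist() if "tag_sequence" in metadata.table else [None] * len(ids)
    if call_rate is None:
        call_rate = metadata["call_rate"].to_numpy(dtype=float)
    removed = set()
    n_warn = 0
    for x in range(len(ids)):
        if ids[x] in removed or not isinstance(seqs[x], str):
            continue
        for y in range(x + 1, len(ids)):
            if ids[y] in removed or not isinstance(seqs[y], str):
                continue
            if len(seqs[x]) != len(seqs[y]):
                n_warn += 1
                continue
            d = sum(a != b for a, b in zip(seqs[x], seqs[y])) / len(seqs[x])
            if d <= threshold:
                if call_rate[x] < call_rate[y]:
                    drop = x
                elif call_rate[y] < call_rate[x]:
                    drop = y
                else:
                    drop = max(x, y)
                removed.add(ids[drop])
                if drop == x:
                    break
    hamming_filter.last_warnings = n_warn
    return [i for i in ids if i not in removed]


# ---------------------------------------------------------------------------
# The ordered pipeline
# ---------------------------------------------------------------------------

def apply_filters(matrix: GenotypeMatrix, metadata: LocusMetadata | None,
                  config: FilterConfig | None = None):
    """Run the full ordered QC rule set; returns (filtered matrix, report).

    Order: monomorphic -> locus call rate -> individual call rate -> depth ->
    repeatability -> one SNP per tag -> Hamming paralog filter -> HWE (within
    each population, removed if P < alpha in any) -> LD prune -> locus
    missingness -> MAF.  Steps needing sequencing metadata are skipped (zero
    removed) when ``metadata`` is None.  All rates are recomputed on the
    progressively filtered matrix.
    """
    config = config or FilterConfig()
    report = FilterReport()
    m = matrix

    def record(name, new_m):
        nonlocal m
        report.add(name, m.n_loci - new_m.n_loci, m.n_individuals - new_m.n_individuals,
                   new_m.n_loci, new_m.n_individuals)
        m = new_m

    # 1. monomorphic loci
    keep = []
    for j in range(m.n_loci):
        col = m.calls[:, j]
        col = col[col != MISSING]
        keep.append(col.size > 0 and col.min() != col.max()
                    or (col.size > 0 and 0 < col[0] < 2))
    record("monomorphic", m.subset(loci=np.array(keep, dtype=bool)))

    # 2. locus call rate
    keep = _call_rates(m.calls) >= config.min_locus_call_rate
    record("locus_call_rate", m.subset(loci=keep))

    # 3. individual call rate
    if m.n_loci:
        rates = (m.calls != MISSING).mean(axis=1)
    else:
        rates = np.ones(m.n_individuals)
    record("indiv_call_rate", m.subset(individuals=rates >= config.min_indiv_call_rate))

    # 4. depth and 5. repeatability
    if metadata is not None:
        meta = metadata.for_loci(m.locus_ids)
        keep = meta["mean_depth"].to_numpy(dtype=float) >= config.min_depth
        record("min_depth", m.subset(loci=keep))
        meta = metadata.for_loci(m.locus_ids)
        keep = meta["repeatability"].to_numpy(dtype=float) >= config.min_repeatability
        record("repeatability", m.subset(loci=keep))
    else:
        record("min_depth", m)
        record("repeatability", m)

    # 6. one SNP per tag: keep highest call rate (tie: first by position_in_tag)
    if metadata is not None and config.one_snp_per_tag and m.n_loci:
        meta = metadata.for_loci(m.locus_ids)
        rates = _call_rates(m.calls)
        best = {}
        for j, locus in enumerate(m.locus_ids):
            tag = meta["tag_id"].iloc[j]
            pos = meta["position_in_tag"].iloc[j]
            cand = (-rates[j], pos, j)
            if tag not in best or cand < best[tag][0]:
                best[tag] = (cand, locus)
        chosen = {locus for _, locus in best.values()}
        record("one_snp_per_tag", m.subset(loci=[l in chosen for l in m.locus_ids]))
    else:
        record("one_snp_per_tag", m)

    # 7. Hamming paralog filter
    if metadata is not None and m.n_loci:
        meta = metadata.for_loci(m.locus_ids)
        kept = hamming_filter(meta, config.hamming_threshold,
                              call_rate=_call_rates(m.calls))
        record("hamming", m.subset(loci=kept))
    else:
        record("hamming", m)

    # 8. HWE within each population
    keep = np.ones(m.n_loci, dtype=bool)
    for pop in m.populations:
        rows = m.pop_indices(pop)
        if rows.size < 2:
            continue
        sub = m.calls[rows]
        for j in range(m.n_loci):
            if not keep[j]:
                continue
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            counts = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
            if hwe_exact_test(*counts) < config.hwe_alpha:
                keep[j] = False
    record("hwe", m.subset(loci=keep))

    # 9. LD prune
    if m.n_loci:
        record("ld_prune", m.subset(loci=ld_prune(m, config)))
    else:
        record("ld_prune", m)

    # 10. locus missingness (strict: more than max_locus_missing removed)
    if m.n_loci:
        missing = (m.calls == MISSING).mean(axis=0)
        record("max_missing", m.subset(loci=missing <= config.max_locus_missing))
    else:
        record("max_missing", m)

    # 11. MAF (strict: below min_maf removed)
    keep = []
    for j in range(m.n_loci):
        col = m.calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            keep.append(False)
            continue
        p = col.sum() / (2 * col.size)
        keep.append(min(p, 1 - p) >= config.min_maf)
    record("min_maf", m.subset(loci=np.array(keep, dtype=bool)) if m.n_loci else m)

    return m, report
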