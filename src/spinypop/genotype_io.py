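"""Genotype and haplotype containers plus readers/writers for the formats the
pipeline touches.

The central currency is :class:`GenotypeMatrix`: diploid biallelic genotypes
coded as counts of the alternate allele (0/1/2, missing = -9) for a set of
individuals carrying population labels.  Folding downstream statistics onto
the minor allele makes every statistic in this package orientation-free, so
which allele is "alternate" is arbitrary and recorded per locus.

Supported formats: STRUCTURE text (two-rows-per-individual or one-row
two-columns-per-locus, auto-detected), the DArT two-row scoring CSV with its
per-locus metadata columns, a minimal GT-only VCF (write), and aligned FASTA
for mitochondrial control-region haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call, matching STRUCTURE's conventional code.
MISSING = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusMetadata",
    "HaplotypeAlignment",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "read_dart_csv",
    "write_vcf",
    "read_fasta_alignment",
]


class StructureFormatError(ValueError):
    """Raised for malformed STRUCTURE input (ragged rows, >2 alleles, ...)."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele counts with population labels.

    Parameters
    ----------
    individual_ids : list of str
        Unique, ordered individual identifiers (rows of ``calls``).
    locus_ids : list of str
        Unique, ordered locus identifiers (columns of ``calls``).
    calls : ndarray of int, shape (n_individuals, n_loci)
        0, 1, 2 = number of alternate-allele copies; ``MISSING`` = no call.
    population_of : dict
        Maps every individual id to exactly one population label.
    allele_orientation : dict, optional
        Per-locus record of which source-file allele was coded as alternate.
    """

    individual_ids: list
    locus_ids: list
    calls: np.ndarray
    population_of: dict
    allele_orientation: dict = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids are not unique")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/{MISSING}")
        missing_labels = [i for i in self.individual_ids if i not in self.population_of]
        if missing_labels:
            raise ValueError(f"individuals without population label: {missing_labels[:5]}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        seen = {}
        for ind in self.individual_ids:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def pop_indices(self, population) -> np.ndarray:
        """Row indices of the individuals belonging to ``population``."""
        return np.array(
            [k for k, ind in enumerate(self.individual_ids)
             if self.population_of[ind] == population],
            dtype=int,
        )

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- subsetting ----------------------------------------------------------
    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individuals and/or loci
        (ids or boolean/int index arrays), preserving order of the arguments."""
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_loci)
        if individuals is not None:
            if all(isinstance(i, str) for i in individuals):
                lookup = {ind: k for k, ind in enumerate(self.individual_ids)}
                rows = np.array([lookup[i] for i in individuals], dtype=int)
            else:
                rows = np.asarray(individuals)
                if rows.dtype == bool:
                    rows = np.flatnonzero(rows)
        if loci is not None:
            if all(isinstance(l, str) for l in loci):
                lookup = {loc: k for k, loc in enumerate(self.locus_ids)}
                cols = np.array([lookup[l] for l in loci], dtype=int)
            else:
                cols = np.asarray(loci)
                if cols.dtype == bool:
                    cols = np.flatnonzero(cols)
        ids = [self.individual_ids[r] for r in rows]
        return GenotypeMatrix(
            individual_ids=ids,
            locus_ids=[self.locus_ids[c] for c in cols],
            calls=self.calls[np.ix_(rows, cols)],
            population_of={i: self.population_of[i] for i in ids},
            allele_orientation={
                self.locus_ids[c]: self.allele_orientation[self.locus_ids[c]]
                for c in cols if self.locus_ids[c] in self.allele_orientation
            },
        )

    def restrict_pops(self, populations) -> "GenotypeMatrix":
        keep = [i for i in self.individual_ids if self.population_of[i] in set(populations)]
        return self.subset(individuals=keep)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
            and all(self.population_of[i] == other.population_of[i]
                    for i in self.individual_ids)
        )


@dataclass
class LocusMetadata:
    """Per-locus sequencing metadata used by the QC filters (DArT fields)."""

    table: pd.DataFrame  # indexed by locus_id

    REQUIRED = ("call_rate", "repeatability", "mean_depth", "tag_id", "position_in_tag")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"locus metadata missing required column {col!r}")
        for col in ("call_rate", "repeatability"):
            vals = self.table[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        if (self.table["mean_depth"].to_numpy(dtype=float) < 0).any():
            raise ValueError("mean_depth must be >= 0")

    def for_loci(self, locus_ids) -> "LocusMetadata":
        return LocusMetadata(self.table.loc[list(locus_ids)].copy())

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class HaplotypeAlignment:
    """Equal-length aligned haplotype sequences with population labels."""

    sequence_ids: list
    sequences: list
    population_of: dict

    def __post_init__(self):
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("sequence ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        missing = [s for s in self.sequence_ids if s not in self.population_of]
        if missing:
            raise ValueError(f"sequences without population label: {missing[:5]}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def populations(self) -> list:
        seen = {}
        for s in self.sequence_ids:
            seen.setdefault(self.population_of[s], None)
        return list(seen)


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def _tokenize_structure(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if toks:
                rows.append((lineno, toks))
    return rows


def read_structure(path, missing_code: int = MISSING, two_rows=None) -> GenotypeMatrix:
    """Read a STRUCTURE genotype file into a :class:`GenotypeMatrix`.

    Both common dialects are accepted: two rows per individual (one allele per
    row, columns = loci) and one row per individual with two adjacent columns
    per locus.  When ``two_rows`` is None the dialect is auto-detected from
    whether consecutive row labels repeat, and the choice is logged.  Each row
    starts with the individual label and a population column; an optional
    leading header line of locus names is honoured.

    Genotypes are recoded to alternate-allele counts.  At each locus the
    higher-valued source allele code is taken as the alternate allele (the
    minor allele may be either); the mapping is kept in
    ``allele_orientation``.
    """
    rows = _tokenize_structure(path)
    if not rows:
        raise StructureFormatError(f"{path}: empty file")

    # optional locus-name header: shorter than data rows by the 2 id columns
    body_width = len(rows[-1][1])
    locus_names = None
    if len(rows[0][1]) == body_width - 2 and len(rows) > 1:
        locus_names = rows[0][1]
        rows = rows[1:]

    widths = {len(toks) for _, toks in rows}
    if len(widths) > 1:
        bad = next(lineno for lineno, toks in rows if len(toks) != len(rows[0][1]))
        raise StructureFormatError(f"{path}: ragged row at line {bad}")
    width = widths.pop()
    if width < 3:
        raise StructureFormatError(f"{path}: rows too short to hold genotypes")

    labels = [toks[0] for _, toks in rows]
    if two_rows is None:
        two_rows = (
            len(labels) % 2 == 0
            and all(labels[i] == labels[i + 1] for i in range(0, len(labels), 2))
            and len(set(labels[::2])) == len(labels) // 2
        )
        logger.info("read_structure: auto-detected %s dialect for %s",
                    "two-rows-per-individual" if two_rows else "one-row-per-individual",
                    path)

    if two_rows:
        if len(rows) % 2:
            raise StructureFormatError(f"{path}: odd number of rows in two-row dialect")
        n_loci = width - 2
        individual_ids, pops = [], {}
        allele_rows = []
        for i in range(0, len(rows), 2):
            (ln1, t1), (ln2, t2) = rows[i], rows[i + 1]
            if t1[0] != t2[0]:
                raise StructureFormatError(
                    f"{path}: rows {ln1} and {ln2} pair labels {t1[0]!r} != {t2[0]!r}")
            individual_ids.append(t1[0])
            pops[t1[0]] = t1[1]
            allele_rows.append((t1[2:], t2[2:]))
    else:
        if (width - 2) % 2:
            raise StructureFormatError(
                f"{path}: one-row dialect needs an even number of allele columns")
        n_loci = (width - 2) // 2
        individual_ids, pops = [], {}
        allele_rows = []
        for _, toks in rows:
            individual_ids.append(toks[0])
            pops[toks[0]] = toks[1]
            body = toks[2:]
            allele_rows.append((body[0::2], body[1::2]))

    if len(set(individual_ids)) != len(individual_ids):
        raise StructureFormatError(f"{path}: duplicate individual labels")

    a1 = np.array([r[0] for r in allele_rows])
    a2 = np.array([r[1] for r in allele_rows])
    try:
        a1 = a1.astype(int)
        a2 = a2.astype(int)
    except ValueError as exc:
        raise StructureFormatError(f"{path}: non-integer allele code ({exc})") from None

    calls = np.full((len(individual_ids), n_loci), MISSING, dtype=np.int16)
    orientation = {}
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    # files written in the canonical binary 1/2 coding keep that orientation
    # even at loci where only one allele was observed
    observed = np.unique(np.concatenate([a1.ravel(), a2.ravel()]))
    observed = set(int(v) for v in observed if v != missing_code)
    binary_coding = observed <= {1, 2}
    for j in range(n_loci):
        c1, c2 = a1[:, j], a2[:, j]
        ok = (c1 != missing_code) & (c2 != missing_code)
        alleles = np.unique(np.concatenate([c1[ok], c2[ok]]))
        if alleles.size > 2:
            raise StructureFormatError(
                f"{path}: locus {locus_names[j]} has {alleles.size} alleles; "
                "biallelic data required")
        if alleles.size == 0:
            orientation[locus_names[j]] = (None, None)
            continue
        if binary_coding:
            ref, alt = 1, 2
        else:
            ref = int(alleles[0])
            alt = int(alleles[-1])  # single observed allele: ref == alt
        orientation[locus_names[j]] = (ref, alt)
        alt_count = (c1[ok] == alt).astype(np.int16) + (c2[ok] == alt).astype(np.int16)
        if ref == alt:
            alt_count[:] = 0
        calls[ok, j] = alt_count

    return GenotypeMatrix(individual_ids, list(locus_names), calls, pops, orientation)


def write_structure(matrix: GenotypeMatrix, path, missing_code: int = MISSING) -> None:
    """Write ``matrix`` in the two-rows-per-individual STRUCTURE dialect.

    Alleles are coded 1 (reference) / 2 (alternate) so that
    ``read_structure(write_structure(m))`` reproduces ``m`` exactly.
    """
    pop_code = {p: k + 1 for k, p in enumerate(matrix.populations)}
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.locus_ids) + "\n")
        for i, ind in enumerate(matrix.individual_ids):
            pop = matrix.population_of[ind]
            for row_alleles in _diploid_rows(matrix.calls[i], missing_code):
                fh.write("\t".join([ind, str(pop_code[pop])] + row_alleles) + "\n")


def _diploid_rows(calls_row, missing_code):
    first, second = [], []
    for g in calls_row:
        if g == MISSING:
            first.append(str(missing_code))
            second.append(str(missing_code))
        else:
            first.append("2" if g >= 1 else "1")
            second.append("2" if g == 2 else "1")
    return first, second


# ---------------------------------------------------------------------------
# DArT two-row CSV
# ---------------------------------------------------------------------------

_DART_META_COLS = {
    "AlleleID": None,
    "CloneID": "tag_id",
    "SnpPosition": "position_in_tag",
    "CallRate": "call_rate",
    "RepAvg": "repeatability",
    "AvgDepth": "mean_depth",
    "TrimmedSequence": "tag_sequence",
}


def read_dart_csv(path):
    """Read a DArT two-row scoring CSV into (GenotypeMatrix, LocusMetadata).

    Each locus occupies two consecutive rows (reference-allele scores then
    SNP-allele scores, entries 1/0/"-" for present/absent/missing).  The
    genotype is 0, 1 or 2 alternate-allele copies; both scores missing gives a
    missing call.  Metadata columns CloneID, SnpPosition, CallRate, RepAvg,
    AvgDepth and TrimmedSequence populate :class:`LocusMetadata`.
    """
    df = pd.read_csv(path, dtype=str)
    for col in _DART_META_COLS:
        if col not in df.columns:
            raise ValueError(f"DArT CSV missing required metadata column {col!r}")
    sample_cols = [c for c in df.columns if c not in _DART_META_COLS]
    if len(df) % 2:
        raise ValueError("DArT two-row CSV has an odd number of data rows")

    locus_ids, meta_rows = [], []
    n_ind = len(sample_cols)
    calls = np.full((n_ind, len(df) // 2, ), MISSING, dtype=np.int16)
    for k in range(0, len(df), 2):
        ref_row, snp_row = df.iloc[k], df.iloc[k + 1]
        locus_id = snp_row["AlleleID"]
        locus_ids.append(locus_id)
        meta_rows.append({
            "locus_id": locus_id,
            "tag_id": snp_row["CloneID"],
            "position_in_tag": int(snp_row["SnpPosition"]),
            "call_rate": float(snp_row["CallRate"]),
            "repeatability": float(snp_row["RepAvg"]),
            "mean_depth": float(snp_row["AvgDepth"]),
            "tag_sequence": snp_row["TrimmedSequence"]
            if isinstance(snp_row["TrimmedSequence"], str) else None,
        })
        ref = ref_row[sample_cols].to_numpy()
        alt = snp_row[sample_cols].to_numpy()
        j = k // 2
        for i in range(n_ind):
            r, a = ref[i], alt[i]
            if r in ("-", "", None) or a in ("-", "", None):
                continue
            r, a = int(r), int(a)
            if r == 1 and a == 0:
                calls[i, j] = 0
            elif r == 1 and a == 1:
                calls[i, j] = 1
            elif r == 0 and a == 1:
                calls[i, j] = 2
            # 0/0 is an inconsistent score: leave missing

    pops = {c: "unknown" for c in sample_cols}
    matrix = GenotypeMatrix(list(sample_cols), locus_ids, calls, pops)
    meta = LocusMetadata(pd.DataFrame(meta_rows).set_index("locus_id"))
    return matrix, meta


# ---------------------------------------------------------------------------
# VCF (write-only) and FASTA
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF v4.2; DArT tags have no genomic coordinates
    so records carry a dummy contig and 1-based positions in locus order."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=tags>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individual_ids) + "\n")
        for j, locus in enumerate(matrix.locus_ids):
            ref, alt = matrix.allele_orientation.get(locus, (None, None))
            gts = "\t".join(gt_code[int(g)] for g in matrix.calls[:, j])
            fh.write(f"tags\t{j + 1}\t{locus}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def read_fasta_alignment(path, population_of: dict) -> HaplotypeAlignment:
    """Read an aligned FASTA; population labels come from ``population_of``
    (sequence id -> label).  Unequal sequence lengths raise."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return HaplotypeAlignment(ids, seqs, {i: population_of[i] for i in ids})
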