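"""SNP support thresholds, SNP filtering and per-gene allele counting.

Allele-informative reads are identified at SNP positions where the wild and
reference haplotypes differ.  Because a systematic sequencing artefact can
push every error at a site toward the same incorrect base, a called SNP must
be supported by more reads than such errors could plausibly produce: the
minor state needs at least ``min_supporting_reads(depth)`` reads, the
depth-dependent threshold that keeps the probability of that many
same-direction errors below ``alpha`` at the worst-case per-base error rate.
Further filters: total depth, biallelism, intersection with gene intervals,
and membership in an external high-quality SNP whitelist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

BASES = ("A", "C", "G", "T")

__all__ = [
    "min_supporting_reads", "GeneIntervals", "call_and_filter_snps",
    "resolve_conflicting_reads", "count_alleles_per_gene",
    "reference_bias_summary",
]


def min_supporting_reads(depth: int, error_rate: float = 0.01,
                         alpha: float = 1e-4, inclusive: bool = False) -> int:
    """Smallest m >= 1 with P(X >= m) < alpha for X ~ Binomial(depth, error_rate).

    ``inclusive=True`` uses P(X >= m) <= alpha instead (the wording
    "exceeding the threshold" does not pin the strictness; strict is the
    default).  Non-decreasing in depth; depth 0 returns 1.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0,1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    m = 1
    while True:
        tail = stats.binom.sf(m - 1, depth, error_rate)
        if (tail <= alpha) if inclusive else (tail < alpha):
            return m
        m += 1


@dataclass
class GeneIntervals:
    """Gene intervals, held 1-based inclusive internally.

    Construct via :meth:`from_bed_frame` (0-based half-open rows, the
    interval-file convention) or :meth:`from_frame` (already 1-based
    inclusive).  Strand is carried but ignored by intersection.
    """

    table: pd.DataFrame  # columns: gene, chrom, start, end, strand

    def __post_init__(self):
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValueError("interval start > end")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in t.groupby("chrom"):
            tree = IntervalTree()
            for _, r in sub.iterrows():
                tree.addi(int(r["start"]), int(r["end"]) + 1, r["gene"])
            self._trees[chrom] = tree

    @classmethod
    def from_bed_frame(cls, bed: pd.DataFrame) -> "GeneIntervals":
        t = pd.DataFrame({
            "gene": bed.iloc[:, 3] if bed.shape[1] > 3 else
            [f"iv{i}" for i in range(len(bed))],
            "chrom": bed.iloc[:, 0],
            "start": bed.iloc[:, 1].astype(int) + 1,
            "end": bed.iloc[:, 2].astype(int),
            "strand": bed.iloc[:, 5] if bed.shape[1] > 5 else "."})
        return cls(t)

    @classmethod
    def from_frame(cls, t: pd.DataFrame) -> "GeneIntervals":
        t = t.copy()
        if "strand" not in t:
            t["strand"] = "."
        return cls(t[["gene", "chrom", "start", "end", "strand"]])

    def genes_at(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(int(pos))})

    @property
    def chromosomes(self) -> set:
        return set(self._trees)


def call_and_filter_snps(pileups: pd.DataFrame, intervals: GeneIntervals,
                         whitelist: pd.DataFrame, min_depth: int = 15,
                         error_rate: float = 0.01, alpha: float = 1e-4,
                         inclusive: bool = False):
    """Apply the SNP filters; returns (retained SNP frame, removal counts).

    ``pileups``: columns chrom, pos (1-based) and per-base counts A/C/G/T.
    ``whitelist``: biallelic sites, columns chrom, pos, ref, alt (1-based).
    Retained sites satisfy, in this order (removal counted at the first
    failure): depth >= min_depth; exactly two observed states; minor-state
    support >= min_supporting_reads(depth); inside >= 1 gene interval;
    present in the whitelist with the same two alleles.
    """
    counts = pileups[list(BASES)].to_numpy(dtype=int)
    depth = counts.sum(axis=1)
    removed = {"depth": 0, "states": 0, "support": 0, "not_in_gene": 0,
               "whitelist": 0}

    wl = {(r.chrom, int(r.pos)): frozenset((r.ref, r.alt))
          for r in whitelist.itertuples()}
    missing_chroms = sorted(
        set(pileups["chrom"]) - intervals.chromosomes)

    # support threshold cached per depth
    thr_cache: dict[int, int] = {}

    def thr(d):
        if d not in thr_cache:
            thr_cache[d] = min_supporting_reads(d, error_rate, alpha,
                                                inclusive)
        return thr_cache[d]

    rows = []
    for i, r in enumerate(pileups.itertuples()):
        d = depth[i]
        if d < min_depth:
            removed["depth"] += 1
            continue
        present = np.nonzero(counts[i])[0]
        if len(present) != 2:
            removed["states"] += 1
            continue
        minor = counts[i][present].min()
        if minor < thr(int(d)):
            removed["support"] += 1
            continue
        genes = intervals.genes_at(r.chrom, int(r.pos))
        if not genes:
            removed["not_in_gene"] += 1
            continue
        alleles = frozenset(BASES[j] for j in present)
        if wl.get((r.chrom, int(r.pos))) != alleles:
            removed["whitelist"] += 1
            continue
        a, b = sorted(alleles)
        rows.append({"chrom": r.chrom, "pos": int(r.pos), "allele_a": a,
                     "allele_b": b, "depth": int(d), "genes": ",".join(genes)})
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b",
                                       "depth", "genes"])
    return snps, {"removed": removed, "missing_chromosomes": missing_chroms,
                  "retained": len(snps)}


def resolve_conflicting_reads(assignments: pd.DataFrame,
                              rule: str = "drop_read",
                              snp_conflict_threshold: float = 0.1):
    """Collapse per-(read, site) allele calls to one call per read.

    A read observed as wild at one site and reference at another is in
    conflict.  ``rule='drop_read'`` (default) removes such reads;
    ``rule='drop_snp'`` first removes sites whose fraction of conflicted
    overlapping reads exceeds ``snp_conflict_threshold``, then drops any
    still-conflicted reads.  Returns (per-read call frame, removed-SNP set).

    ``assignments`` columns: sample, read_id, chrom, pos, allele
    (allele in {'wild', 'ref'}); a (read, site) pair appears at most once.
    """
    if rule not in ("drop_read", "drop_snp"):
        raise ValueError(f"unknown conflict rule {rule!r}")
    a = assignments.copy()
    removed_snps: set = set()
    if a.empty:
        return (pd.DataFrame(columns=["sample", "read_id", "allele"]),
                removed_snps)
    if a.duplicated(["sample", "read_id", "chrom", "pos"]).any():
        raise ValueError("duplicate (read, site) assignment")

    key = ["sample", "read_id"]
    nuniq = a.groupby(key)["allele"].transform("nunique")
    conflicted = nuniq > 1

    if rule == "drop_snp" and conflicted.any():
        site = a[["chrom", "pos"]].apply(tuple, axis=1)
        rate = conflicted.groupby(site).mean()
        bad = set(rate[rate > snp_conflict_threshold].index)
        removed_snps = bad
        keep = ~site.isin(bad)
        a = a[keep]
        nuniq = a.groupby(key)["allele"].transform("nunique")
        conflicted = nuniq > 1
    a = a[~conflicted]

    calls = (a.drop_duplicates(key + ["allele"])[key + ["allele"]]
             .reset_index(drop=True))
    return calls, removed_snps


def count_alleles_per_gene(calls: pd.DataFrame, assignments: pd.DataFrame,
                           intervals: GeneIntervals,
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, sample) wild/reference read counts from resolved calls.

    Each read is mapped to a gene through the sites it covers; reads whose
    sites span more than one gene are dropped (logged implicitly by the
    count difference).  Rows appear only where at least one read remains.
    """
    sites = assignments[["sample", "read_id", "chrom", "pos"]]
    gene_of = {}
    for (chrom, pos) in sites[["chrom", "pos"]].drop_duplicates().itertuples(
            index=False):
        gene_of[(chrom, pos)] = intervals.genes_at(chrom, int(pos))

    read_gene = {}
    ambiguous = set()
    for r in sites.itertuples():
        key = (r.sample, r.read_id)
        genes = gene_of[(r.chrom, r.pos)]
        if len(genes) != 1:
            ambiguous.add(key)
            continue
        if key in read_gene and read_gene[key] != genes[0]:
            ambiguous.add(key)
        else:
            read_gene[key] = genes[0]

    known = set(metadata["sample"])
    rows: dict[tuple, list[int]] = {}
    for r in calls.itertuples():
        key = (r.sample, r.read_id)
        if key in ambiguous or key not in read_gene:
            continue
        if r.sample not in known:
            raise KeyError(f"sample {r.sample!r} absent from metadata")
        gk = (read_gene[key], r.sample)
        c = rows.setdefault(gk, [0, 0])
        c[0 if r.allele == "wild" else 1] += 1

    out = pd.DataFrame(
        [{"gene": g, "sample": s, "wild_count": w, "ref_count": f}
         for (g, s), (w, f) in sorted(rows.items())],
        columns=["gene", "sample", "wild_count", "ref_count"])
    meta_cols = [c for c in ("genotype", "replicate", "population",
                             "continent", "latitude") if c in metadata]
    return out.merge(metadata[["sample"] + meta_cols], on="sample", how="left")


def reference_bias_summary(table: pd.DataFrame, low: float = 0.45,
                           high: float = 0.55) -> dict:
    """Mean reference-allele proportions and bias strata.

    Returns per-sample and per-gene mean reference proportions (counts
    pooled within the unit before taking the proportion), the overall mean
    row-level proportion, and per-gene strata: 'toward_reference' (> high),
    'away_from_reference' (< low), else 'neutral'.
    """
    if table.empty:
        raise ValueError("empty allele count table")
    t = table.copy()
    tot = t["wild_count"] + t["ref_count"]
    t = t[tot > 0]
    t["ref_prop"] = t["ref_count"] / (t["wild_count"] + t["ref_count"])

    def pooled(g):
        return g["ref_count"].sum() / (g["wild_count"].sum()
                                       + g["ref_count"].sum())

    per_sample = t.groupby("sample").apply(pooled, include_groups=False)
    per_gene = t.groupby("gene").apply(pooled, include_groups=False)
    strata = pd.Series(
        np.where(per_gene > high, "toward_reference",
                 np.where(per_gene < low, "away_from_reference", "neutral")),
        index=per_gene.index, name="stratum")
    return {"per_sample": per_sample, "per_gene": per_gene,
            "overall": float(t["ref_prop"].mean()), "strata": strata}
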