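"""High/low-expression-allele grouping by exhaustive ordered-split likelihood.

For a gene with ASE, lines (genotypes) are sorted by their replicate-summed
log2 wild/reference read ratio and every contiguous split of that order into
a top and bottom group is scored by refitting the binomial mixed model with
a two-level Group fixed effect (genotype and replicate random effects
retained).  The maximum-likelihood split defines the high- and
low-expression-allele groups; the group whose mean log2 ratio is closer to 0
expresses its wild allele like the reference and is labelled the
reference-CRE group, which fixes whether the wild allele of the alternate
group is the high- or the low-expression allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import BinomialGLMM

__all__ = ["GroupingResult", "line_log_ratios", "best_split",
           "assign_reference_group", "group_gene", "allele_frequencies",
           "plot_log_ratios"]

_TIE_TOL = 1e-6


def line_log_ratios(gene_data: pd.DataFrame) -> pd.Series:
    """Per-line log2 wild/reference ratio on replicate-summed counts.

    A pseudocount of 0.5 is added to both alleles when either count is zero
    (display/ordering only; model fits use raw counts).  Lines with zero
    total are excluded.
    """
    s = gene_data.groupby("genotype")[["wild_count", "ref_count"]].sum()
    s = s[(s["wild_count"] + s["ref_count"]) > 0]
    w = s["wild_count"].astype(float)
    r = s["ref_count"].astype(float)
    zero = (w == 0) | (r == 0)
    w = w + np.where(zero, 0.5, 0.0)
    r = r + np.where(zero, 0.5, 0.0)
    return np.log2(w / r).rename("log2_ratio")


@dataclass
class GroupingResult:
    """Ordered-split grouping of lines into high/low expression alleles."""

    gene: str
    ratios: pd.Series                 # per-line log2 ratio, sorted descending
    split_index: int                  # size of the top (first) group
    loglik: float
    group_of: pd.Series               # per line: 'top' or 'bottom'
    group_means: dict                 # group label -> mean log2 ratio
    degenerate: bool = False
    reference_group: str | None = None
    wild_direction: str | None = None     # 'high' or 'low'
    allele_of: pd.Series | None = None    # per line: 'high' or 'low'
    all_logliks: np.ndarray | None = field(default=None, repr=False)

    @property
    def ase_magnitude(self) -> float:
        """Difference of group mean log2 ratios (high minus low group)."""
        hi = max(self.group_means.values())
        lo = min(self.group_means.values())
        return hi - lo


def best_split(gene_data: pd.DataFrame, gene: str | None = None,
               split_range: str = "all", n_quad: int = 9) -> GroupingResult:
    """Exhaustive maximum-likelihood split of the ratio-sorted lines.

    Every top-group size 1..L-1 is scored by the mixed model with a Group
    fixed effect; ties (within 1e-6 log-likelihood) go to the most balanced
    split.  ``split_range='nonreplicated'`` caps the top-group size at the
    number of non-replicated lines minus one (an alternative reading of the
    enumeration bound).
    """
    if gene is None:
        gene = str(gene_data["gene"].iloc[0]) if "gene" in gene_data else ""
    ratios = line_log_ratios(gene_data).sort_values(ascending=False,
                                                    kind="stable")
    lines = ratios.index.to_numpy()
    L = len(lines)
    if L < 2:
        raise ValueError("need at least two lines with data")
    if split_range == "all":
        sizes = range(1, L)
    elif split_range == "nonreplicated":
        reps = gene_data.groupby("genotype")["sample"].nunique() \
            if "sample" in gene_data else None
        n_nonrep = int((reps < 2).sum()) if reps is not None else L
        sizes = range(1, max(2, n_nonrep))
    else:
        raise ValueError(f"unknown split_range {split_range!r}")

    data = gene_data[gene_data["genotype"].isin(lines)].copy()
    logliks = np.full(L - 1, -np.inf)
    warm = None
    for k in sizes:
        top = set(lines[:k])
        data["group"] = np.where(data["genotype"].isin(top), "top", "bottom")
        model = BinomialGLMM.from_gene_data(data, fixed="group",
                                            n_quad=n_quad)
        fit = model.fit(start_params=warm)
        logliks[k - 1] = fit.llf
        warm = np.concatenate([fit.params, [fit.sigma_g, fit.sigma_r]])

    best = np.max(logliks)
    tied = np.nonzero(logliks >= best - _TIE_TOL)[0] + 1
    # most balanced split among ties; remaining ties to the smaller size
    k_star = int(min(tied, key=lambda k: (abs(2 * k - L), k)))
    n_sizes = len(list(sizes))
    degenerate = n_sizes > 1 and len(tied) == n_sizes
    group_of = pd.Series(np.where(np.arange(L) < k_star, "top", "bottom"),
                         index=lines, name="group")
    means = {g: float(ratios[group_of == g].mean())
             for g in ("top", "bottom")}
    return GroupingResult(gene=gene, ratios=ratios, split_index=k_star,
                          loglik=float(logliks[k_star - 1]),
                          group_of=group_of, group_means=means,
                          degenerate=degenerate, all_logliks=logliks)


def assign_reference_group(result: GroupingResult) -> GroupingResult:
    """Label the reference-CRE group and call per-line high/low alleles.

    The group with mean log2 ratio closest to 0 is the reference-CRE group;
    on an exact tie the larger group is taken (flagged degenerate).  If the
    alternate group's mean is positive the wild allele there is the
    high-expression allele, otherwise the low one.
    """
    m = result.group_means
    d_top, d_bot = abs(m["top"]), abs(m["bottom"])
    if np.isclose(d_top, d_bot, rtol=0, atol=_TIE_TOL):
        sizes = result.group_of.value_counts()
        ref = "top" if sizes.get("top", 0) >= sizes.get("bottom", 0) \
            else "bottom"
        result.degenerate = True
    else:
        ref = "top" if d_top < d_bot else "bottom"
    alt = "bottom" if ref == "top" else "top"
    result.reference_group = ref
    result.wild_direction = "high" if m[alt] > 0 else "low"
    alt_call = result.wild_direction
    ref_call = "low" if alt_call == "high" else "high"
    result.allele_of = result.group_of.map(
        {alt: alt_call, ref: ref_call}).rename("allele")
    return result


def group_gene(gene_data: pd.DataFrame, gene: str | None = None,
               split_range: str = "all", n_quad: int = 9) -> GroupingResult:
    """best_split followed by reference-group assignment."""
    return assign_reference_group(
        best_split(gene_data, gene=gene, split_range=split_range,
                   n_quad=n_quad))


def allele_frequencies(groupings: dict, metadata: pd.DataFrame):
    """High-allele frequencies per population and pooled, per gene.

    ``groupings`` maps gene -> completed GroupingResult.  Returns a frame
    with one row per gene: the per-population high-allele frequency, the
    pooled frequency, the major-allele designation ('high'/'low', ties to
    'high') and the minor-allele frequency.
    """
    pop_of = (metadata.drop_duplicates("genotype")
              .set_index("genotype")["population"])
    pops = sorted(pop_of.unique())
    rows = []
    for gene, res in groupings.items():
        if res.allele_of is None:
            raise ValueError(f"grouping for {gene} lacks allele calls")
        calls = res.allele_of
        high = calls == "high"
        row = {"gene": gene}
        for p in pops:
            mask = pop_of.reindex(calls.index) == p
            row[f"freq_high[{p}]"] = (float(high[mask].mean())
                                      if mask.any() else np.nan)
        pooled = float(high.mean())
        row["freq_high_pooled"] = pooled
        row["major_allele"] = "high" if pooled >= 0.5 else "low"
        row["maf"] = min(pooled, 1.0 - pooled)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def plot_log_ratios(result: GroupingResult, ax=None):
    """Sorted per-line log2 ratios coloured by allele group (one gene)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    colors = result.allele_of.map({"high": "#2166ac", "low": "#1b7837"}) \
        if result.allele_of is not None else "gray"
    ax.bar(range(len(result.ratios)), result.ratios.to_numpy(), color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("line (sorted by log2 wild/ref ratio)")
    ax.set_ylabel("log2 wild/ref")
    ax.set_title(f"{result.gene}: wild allele {result.wild_direction}")
    return ax
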