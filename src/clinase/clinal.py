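"""Latitude-level statistics: expression clines, ASE clines, concordance.

This module holds the population-scale analyses: cpm normalisation and
expression filtering, count down-sampling, a pluggable two-group
differential-expression test per continent, cross-continent sign
concordance with binomial confidence intervals, population-mean ASE and the
latitude likelihood-ratio test, Spearman/Fisher statistics, ASE enrichment
(with a power-matched down-sampled variant), major/minor-allele expression
effects, per-region enrichment and a PCA outlier screen.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .ase import bh_fdr
from .glmm import BinomialGLMM

__all__ = [
    "cpm", "cpm_and_filter", "downsample_counts", "latitudinal_de_test",
    "binomial_ci", "format_ci_percent", "sign_concordance",
    "population_ase_means", "ase_latitude_test", "spearman_correlation",
    "fisher_exact_2x2", "ase_enrichment", "power_matched_enrichment",
    "major_minor_expression", "region_enrichment", "ase_total_correlation",
    "qc_outliers", "latitudinal_ase_differences",
]


# --------------------------------------------------------------------- #
# expression matrix utilities
# --------------------------------------------------------------------- #

def cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; library size = column sum."""
    lib = matrix.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return matrix / lib * 1e6


def cpm_and_filter(matrix: pd.DataFrame, min_cpm: float = 1.0,
                   min_samples: int = 10):
    """Drop genes without >= min_cpm in >= min_samples samples (non-strict).

    Returns (filtered count matrix, cpm of the filtered matrix).  cpm values
    are recomputed on the original library sizes, as the filter removes
    genes, not reads.
    """
    c = cpm(matrix)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    return matrix.loc[keep], c.loc[keep]


def downsample_counts(matrix: pd.DataFrame, target_total: int,
                      seed: int = 0) -> pd.DataFrame:
    """Down-sample each library to exactly ``target_total`` reads.

    Reads are drawn without replacement across genes (multivariate
    hypergeometric), so column sums equal the target exactly and per-gene
    proportions are preserved in expectation.
    """
    lib = matrix.sum(axis=0)
    if (lib < target_total).any():
        small = lib[lib < target_total].index.tolist()
        raise ValueError(f"target exceeds library size for {small}")
    ss = np.random.SeedSequence(seed).spawn(matrix.shape[1])
    out = {}
    for j, col in enumerate(matrix.columns):
        rng = np.random.default_rng(ss[j])
        out[col] = rng.multivariate_hypergeometric(
            matrix[col].to_numpy(dtype=np.int64), int(target_total),
            method="marginals")
    return pd.DataFrame(out, index=matrix.index)


def latitudinal_de_test(matrix: pd.DataFrame, metadata: pd.DataFrame,
                        continent: str, test=None,
                        adjust: bool = True) -> pd.DataFrame:
    """Tropical-vs-temperate expression difference per gene on one continent.

    The default test is Welch's t on log2(cpm + 0.5); ``test`` may be any
    callable (tropical_values, temperate_values) -> p, so a different
    per-gene test can be plugged in.  Returns log2 fold difference
    (tropical minus temperate mean of log2 cpm), p, and BH-adjusted p.
    """
    sub = metadata[metadata["continent"] == continent]
    lats = set(sub["latitude"])
    if not {"temperate", "tropical"} <= lats:
        raise ValueError(f"both latitude classes required on {continent}")
    trop = sub.loc[sub["latitude"] == "tropical", "sample"]
    temp = sub.loc[sub["latitude"] == "temperate", "sample"]
    trop = [s for s in trop if s in matrix.columns]
    temp = [s for s in temp if s in matrix.columns]
    if len(trop) < 2 or len(temp) < 2:
        raise ValueError("need >= 2 samples per latitude class")
    logc = np.log2(cpm(matrix) + 0.5)
    a = logc[trop].to_numpy()
    b = logc[temp].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if test is None:
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    else:
        p = np.array([test(a[i], b[i]) for i in range(a.shape[0])])
    out = pd.DataFrame({"log2_fold": lfc, "p": p}, index=matrix.index)
    if adjust:
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# --------------------------------------------------------------------- #
# proportions, concordance
# --------------------------------------------------------------------- #

def binomial_ci(x: int, n: int, method: str = "wilson",
                level: float = 0.95):
    """Binomial CI: 'wilson' (score, no continuity correction) or
    'clopper_pearson' (exact beta quantiles)."""
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n, n >= 1")
    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    lo, hi = proportion_confint(x, n, alpha=1 - level, method=sm_method)
    return float(lo), float(hi)


def format_ci_percent(lo: float, hi: float) -> str:
    """Round CI bounds half-away-from-zero to whole percent, e.g. '77-88%'."""
    import decimal

    def r(v):
        return int(decimal.Decimal(v * 100).quantize(
            0, rounding=decimal.ROUND_HALF_UP))

    return f"{r(lo)}-{r(hi)}%"


def sign_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                     fdr_threshold: float = 0.20, level: float = 0.95):
    """Cross-continent direction concordance among significant genes.

    ``results_a``/``results_b``: frames indexed by gene with columns
    ``log2_fold`` and ``fdr`` (as from :func:`latitudinal_de_test`).  Genes
    significant on *either* continent at ``fdr_threshold`` and tested on
    both are counted by sign quadrant; the concordant proportion gets both
    Wilson and Clopper-Pearson intervals.
    """
    common = results_a.index.intersection(results_b.index)
    a = results_a.loc[common]
    b = results_b.loc[common]
    sig = (a["fdr"] < fdr_threshold) | (b["fdr"] < fdr_threshold)
    sa = np.sign(a.loc[sig, "log2_fold"])
    sb = np.sign(b.loc[sig, "log2_fold"])
    quadrants = {(pa, pb): int(((sa == pa) & (sb == pb)).sum())
                 for pa, pb in itertools.product((1, -1), repeat=2)}
    n = int(sig.sum())
    x = int((sa == sb).sum())
    out = {"n": n, "concordant": x, "quadrants": quadrants}
    if n == 0:
        out.update(proportion=None, wilson=None, clopper_pearson=None)
        return out
    out["proportion"] = x / n
    out["wilson"] = binomial_ci(x, n, "wilson", level)
    out["clopper_pearson"] = binomial_ci(x, n, "clopper_pearson", level)
    return out


# --------------------------------------------------------------------- #
# population-level ASE
# --------------------------------------------------------------------- #

def population_ase_means(gene_data: pd.DataFrame, n_quad: int = 9):
    """Per-population mean ASE (logit wild proportion) for one gene.

    Fits the mixed model with Population as a (cell-means) fixed effect and
    returns {'means': {population: logit}, 'latitudinal_difference':
    {continent: tropical - temperate}} (NaN when a class is missing).
    """
    model = BinomialGLMM.from_gene_data(gene_data, fixed="population",
                                        n_quad=n_quad)
    res = model.fit()
    means = {name[len("Population["):-1]: float(b)
             for name, b in zip(model.exog_names, res.params)}
    meta = gene_data.drop_duplicates("population")
    diffs = {}
    for cont, sub in meta.groupby("continent"):
        lat_of = sub.set_index("population")["latitude"]
        trop = [p for p in means if lat_of.get(p) == "tropical"]
        temp = [p for p in means if lat_of.get(p) == "temperate"]
        diffs[cont] = (means[trop[0]] - means[temp[0]]
                       if trop and temp else np.nan)
    return {"means": means, "latitudinal_difference": diffs,
            "converged": res.converged}


def latitudinal_ase_differences(table: pd.DataFrame, genes,
                                n_quad: int = 9) -> pd.DataFrame:
    """Population-mean ASE latitudinal contrasts for a set of genes."""
    rows = []
    for gene in genes:
        r = population_ase_means(table[table["gene"] == gene],
                                 n_quad=n_quad)
        row = {"gene": gene, "converged": r["converged"]}
        for cont, d in r["latitudinal_difference"].items():
            row[f"ase_diff[{cont}]"] = d
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def ase_latitude_test(gene_data: pd.DataFrame, df: int = 2,
                      n_quad: int = 9) -> dict:
    """LRT for latitude structure in one gene's ASE.

    Full model: Latitude + Continent + Latitude x Continent; reduced model
    drops the latitude main effect and the interaction jointly (2 df,
    default) or only the interaction (``df=1``).
    """
    pops = gene_data.drop_duplicates("population")
    if pops.groupby("continent")["latitude"].nunique().lt(2).any() \
            or pops["continent"].nunique() < 2:
        raise ValueError("all four continent x latitude classes required")
    model_full = BinomialGLMM.from_gene_data(gene_data, fixed="latitude",
                                             n_quad=n_quad)
    full = model_full.fit()
    if df == 2:
        conts = pd.unique(gene_data["continent"])
        X = np.column_stack([
            np.ones(len(gene_data)),
            (gene_data["continent"] == conts[1]).to_numpy(dtype=float)])
        reduced_model = BinomialGLMM(
            gene_data[["wild_count", "ref_count"]].to_numpy(dtype=float), X,
            gene_data["genotype"].to_numpy(),
            exog_names=["Intercept", f"Continent[{conts[1]}]"],
            n_quad=n_quad)
    elif df == 1:
        data = gene_data.copy()
        lat = (data["latitude"].astype(str) == "tropical").astype(float)
        conts = pd.unique(data["continent"])
        X = np.column_stack([np.ones(len(data)), lat.to_numpy(),
                             (data["continent"] == conts[1]).to_numpy(float)])
        reduced_model = BinomialGLMM(
            data[["wild_count", "ref_count"]].to_numpy(dtype=float), X,
            data["genotype"].to_numpy(),
            exog_names=["Intercept", "Latitude[tropical]",
                        f"Continent[{conts[1]}]"], n_quad=n_quad)
    else:
        raise ValueError("df must be 1 or 2")
    reduced = reduced_model.fit()
    stat, p = full.lrt_against(reduced, df=df)
    return {"lrt": stat, "p": p,
            "converged": full.converged and reduced.converged}


# --------------------------------------------------------------------- #
# rank / contingency statistics
# --------------------------------------------------------------------- #

def spearman_correlation(x, y, method: str = "auto"):
    """Tie-corrected Spearman rho with t-approximation p.

    ``method='exact'`` (automatic for n <= 8) computes the two-sided p by
    exhaustive permutation of one vector: the fraction of permutations with
    |rho| >= |observed|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    if method == "exact" or (method == "auto" and n <= 8):
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def fisher_exact_2x2(table):
    """Two-sided Fisher exact test; sample odds ratio is reported.

    The p-value sums hypergeometric probabilities of tables at most as
    probable as the observed one (scipy's convention).  Degenerate margins
    give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return np.nan, 1.0
    orat, p = stats.fisher_exact(t, alternative="two-sided")
    return float(orat), float(p)


def ase_enrichment(latitudinal_genes: set, ase_genes: set, universe: set):
    """Is ASE over-represented among latitudinally differentiated genes?

    Builds the (latitudinal x ASE) membership table over ``universe`` and
    applies the Fisher exact test.  Degenerate margins (e.g. every gene has
    ASE) are flagged rather than tested.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not (latitudinal_genes <= universe and ase_genes <= universe):
        raise ValueError("gene sets must be subsets of the universe")
    lat = latitudinal_genes
    ase = ase_genes
    a = len(lat & ase)
    b = len(lat - ase)
    c = len((universe - lat) & ase)
    d = len(universe - lat - ase)
    tab = np.array([[a, b], [c, d]])
    degenerate = (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any()
    orat, p = fisher_exact_2x2(tab) if not degenerate else (np.nan, 1.0)
    frac_lat = a / max(1, len(lat))
    frac_rest = c / max(1, len(universe) - len(lat))
    return {"table": tab, "odds_ratio": orat, "p": p,
            "degenerate": bool(degenerate),
            "ase_fraction_latitudinal": frac_lat,
            "ase_fraction_background": frac_rest}


def _thin_gene(counts: pd.DataFrame, target: int, rng) -> pd.DataFrame:
    """Hypergeometric thinning of one gene's rows to a target total."""
    tot = int(counts["wild_count"].sum() + counts["ref_count"].sum())
    if target >= tot:
        return counts
    flat = np.concatenate([counts["wild_count"].to_numpy(dtype=np.int64),
                           counts["ref_count"].to_numpy(dtype=np.int64)])
    kept = rng.multivariate_hypergeometric(flat, target, method="marginals")
    m = len(counts)
    out = counts.copy()
    out["wild_count"] = kept[:m]
    out["ref_count"] = kept[m:]
    return out


def power_matched_enrichment(table: pd.DataFrame, metadata: pd.DataFrame,
                             latitudinal_genes: set, universe: set,
                             seed: int = 0, fdr_threshold: float = 0.20,
                             min_replicated_genotypes: int | None = 12):
    """ASE enrichment after matching coverage between the two gene sets.

    The gene set with higher per-gene total allele counts is down-sampled
    (hypergeometric thinning across its rows) so that its per-gene total
    distribution matches the other set's quantile-by-quantile; ASE tests
    are re-run on the matched table and the enrichment recomputed.
    """
    from .ase import run_ase_tests

    universe = set(universe)
    in_set = sorted(universe & set(latitudinal_genes))
    out_set = sorted(universe - set(latitudinal_genes))
    if not in_set or not out_set:
        raise ValueError("both gene sets must be non-empty")
    totals = (table.assign(tot=table["wild_count"] + table["ref_count"])
              .groupby("gene")["tot"].sum())
    med_in, med_out = totals[in_set].median(), totals[out_set].median()
    hi, lo = (in_set, out_set) if med_in >= med_out else (out_set, in_set)

    ranks = totals[hi].rank(pct=True)
    lo_sorted = np.sort(totals[lo].to_numpy())
    rng = np.random.default_rng(seed)
    pieces = []
    for gene, sub in table.groupby("gene", sort=False):
        if gene in set(hi):
            q = ranks[gene]
            target = int(np.quantile(lo_sorted, q, method="nearest"))
            pieces.append(_thin_gene(sub, target, rng))
        else:
            pieces.append(sub)
    matched = pd.concat(pieces, ignore_index=True)
    res = run_ase_tests(matched, metadata,
                        min_replicated_genotypes=min_replicated_genotypes,
                        fdr_threshold=fdr_threshold)
    ase_genes = set(res.loc[res["significant"], "gene"])
    tested = set(res["gene"])
    enr = ase_enrichment(set(latitudinal_genes) & tested,
                         ase_genes, tested)
    enr["matched_table"] = matched
    return enr


def major_minor_expression(frequencies: pd.DataFrame, groupings: dict,
                           cpm_matrix: pd.DataFrame, metadata: pd.DataFrame,
                           maf_threshold: float = 0.30):
    """Does the major CRE allele have higher total expression?

    For genes with pooled minor-allele frequency below ``maf_threshold``:
    log2 ratio of mean cpm of major-allele lines over minor-allele lines,
    the fraction of positive ratios, and a one-sample t test of mean != 0.
    Genes where every line carries one allele are excluded.
    """
    sample_of = metadata.groupby("genotype")["sample"].apply(list)
    ratios = {}
    for gene, freq in frequencies.iterrows():
        if freq["maf"] >= maf_threshold or gene not in cpm_matrix.index:
            continue
        res = groupings[gene]
        major = freq["major_allele"]
        maj_lines = res.allele_of.index[res.allele_of == major]
        min_lines = res.allele_of.index[res.allele_of != major]
        if len(maj_lines) == 0 or len(min_lines) == 0:
            continue

        def mean_cpm(lines):
            cols = [s for ln in lines for s in sample_of.get(ln, [])
                    if s in cpm_matrix.columns]
            return cpm_matrix.loc[gene, cols].mean() if cols else np.nan

        a, b = mean_cpm(maj_lines), mean_cpm(min_lines)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            ratios[gene] = np.log2(a / b)
    vals = pd.Series(ratios, name="log2_major_minor")
    out = {"log2_ratios": vals, "n": len(vals)}
    if len(vals) >= 2:
        t, p = stats.ttest_1samp(vals, 0.0)
        out.update(fraction_major_higher=float((vals > 0).mean()),
                   mean_log2_ratio=float(vals.mean()),
                   t_statistic=float(t), p=float(p))
    else:
        out.update(fraction_major_higher=np.nan, mean_log2_ratio=np.nan,
                   t_statistic=np.nan, p=np.nan)
    return out


def region_enrichment(gene_set: set, gene_to_region: pd.Series,
                      universe: set | None = None):
    """Per-region Fisher tests of set membership, BH-adjusted.

    ``gene_to_region`` maps gene -> region (one region per gene).  Genes in
    the set but absent from the map are excluded.  With a single region the
    test is degenerate and flagged.
    """
    if universe is None:
        universe = set(gene_to_region.index)
    universe = set(universe) & set(gene_to_region.index)
    gene_set = set(gene_set) & universe
    regions = sorted(gene_to_region.loc[sorted(universe)].unique())
    rows = []
    for reg in regions:
        in_reg = {g for g in universe if gene_to_region[g] == reg}
        a = len(gene_set & in_reg)
        b = len(gene_set - in_reg)
        c = len(in_reg - gene_set)
        d = len(universe - in_reg - gene_set)
        orat, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"region": reg, "in_set_in_region": a, "odds_ratio": orat,
                     "p": p})
    out = pd.DataFrame(rows).set_index("region")
    out["degenerate"] = len(regions) < 2
    if len(out) and not out["degenerate"].iloc[0]:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = np.nan
    return out


def ase_total_correlation(groupings: dict, cpm_matrix: pd.DataFrame,
                          metadata: pd.DataFrame,
                          min_group_size: int = 2):
    """ASE magnitude vs high/low-group total-expression ratio across genes.

    Per gene: x = ASE magnitude (difference of group mean log2 allele
    ratios), y = log2 of mean cpm of high-allele lines over low-allele
    lines.  Returns the Spearman correlation of x and y and the fraction of
    genes with y > 0.  Genes with a group smaller than ``min_group_size``
    lines are excluded.
    """
    sample_of = metadata.groupby("genotype")["sample"].apply(list)
    xs, ys, genes = [], [], []
    for gene, res in groupings.items():
        if gene not in cpm_matrix.index or res.allele_of is None:
            continue
        hi = res.allele_of.index[res.allele_of == "high"]
        lo = res.allele_of.index[res.allele_of == "low"]
        if len(hi) < min_group_size or len(lo) < min_group_size:
            continue

        def mean_cpm(lines):
            cols = [s for ln in lines for s in sample_of.get(ln, [])
                    if s in cpm_matrix.columns]
            return cpm_matrix.loc[gene, cols].mean() if cols else np.nan

        a, b = mean_cpm(hi), mean_cpm(lo)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            continue
        xs.append(res.ase_magnitude)
        ys.append(np.log2(a / b))
        genes.append(gene)
    xs, ys = np.asarray(xs), np.asarray(ys)
    out = {"n": len(xs),
           "per_gene": pd.DataFrame({"ase_magnitude": xs,
                                     "log2_high_low_cpm": ys}, index=genes)}
    if len(xs) >= 3:
        rho, p = spearman_correlation(xs, ys, method="t")
        out.update(rho=rho, p=p,
                   fraction_high_higher=float((ys > 0).mean()))
    else:
        out.update(rho=np.nan, p=np.nan, fraction_high_higher=np.nan)
    return out


def qc_outliers(matrix: pd.DataFrame, k_sd: float = 3.0,
                n_components: int = 2):
    """Flag samples beyond k_sd standard deviations on leading PCs.

    PCA on standardised log2 cpm (genes with zero variance dropped);
    samples whose score on PC1..PCn exceeds ``k_sd`` times that PC's score
    standard deviation are flagged.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    n_components = min(n_components, matrix.shape[1] - 1)
    logc = np.log2(cpm(matrix) + 0.5)
    sd = logc.std(axis=1)
    logc = logc[sd > 0]
    z = ((logc.T - logc.mean(axis=1)) / logc.std(axis=1)).to_numpy()
    z = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    if scores.shape[0] > 1:
        ssd = scores.std(axis=0, ddof=1)
    else:
        ssd = np.ones(scores.shape[1])
    ssd[ssd == 0] = np.inf
    flagged = (np.abs(scores) > k_sd * ssd).any(axis=1)
    return pd.Series(flagged, index=matrix.columns, name="outlier")
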