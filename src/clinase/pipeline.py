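"""End-to-end pipeline: simulate -> filter -> count -> test -> group -> clinal.

The pipeline is simulation-driven: the simulate stage draws an allele-count
table with known ground truth and materialises the read-level view of it
(one SNP per gene, per-read allele assignments, pooled pileups, whitelist
and intervals), so the SNP-filter and allele-counting stages run on real
inputs and their output can be checked against the generator exactly.
Every stage writes TSV/JSON outputs and the manifest records parameters,
seeds and SHA-256 digests of all outputs, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ase import run_ase_tests
from .clinal import (ase_enrichment, cpm_and_filter, latitudinal_ase_differences,
                     latitudinal_de_test, sign_concordance, spearman_correlation)
from .counting import (GeneIntervals, call_and_filter_snps,
                       count_alleles_per_gene, reference_bias_summary,
                       resolve_conflicting_reads)
from .grouping import allele_frequencies, group_gene
from .simulate import (SimulationConfig, simulate_ase_dataset,
                       simulate_total_expression)

STAGES = ["simulate", "filter_snps", "count_alleles", "test_ase",
          "group_alleles", "clinal"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for a full pipeline run."""

    outdir: str = "clinase_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    min_depth: int = 15
    error_rate: float = 0.01
    alpha: float = 1e-4
    min_replicated_genotypes: int = 12
    min_cpm: float = 1.0
    min_cpm_samples: int = 10
    fdr_threshold: float = 0.20
    maf_threshold: float = 0.30
    bias_low: float = 0.45
    bias_high: float = 0.55
    ci_method: str = "wilson"
    lrt_reference: str = "chi2"        # or 'mixture'
    conflict_rule: str = "drop_read"   # or 'drop_snp'

    def __post_init__(self):
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate outside (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0,1)")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold outside (0,1]")
        if not 0 <= self.bias_low < self.bias_high <= 1:
            raise ValueError("bias strata bounds invalid")
        if self.ci_method not in ("wilson", "clopper_pearson"):
            raise ValueError("unknown ci_method")
        if self.lrt_reference not in ("chi2", "mixture"):
            raise ValueError("unknown lrt_reference")
        if self.conflict_rule not in ("drop_read", "drop_snp"):
            raise ValueError("unknown conflict_rule")


def _read_level_view(counts: pd.DataFrame):
    """One SNP per gene plus per-read assignments reproducing the counts."""
    genes = sorted(counts["gene"].unique())
    iv = pd.DataFrame({
        "gene": genes, "chrom": "chr2L",
        "start": [i * 1000 + 1 for i in range(len(genes))],
        "end": [i * 1000 + 1000 for i in range(len(genes))]})
    intervals = GeneIntervals.from_frame(iv)
    pos_of = {g: i * 1000 + 500 for i, g in enumerate(genes)}
    whitelist = pd.DataFrame({
        "chrom": "chr2L", "pos": [pos_of[g] for g in genes],
        "ref": "A", "alt": "C"})

    rows = []
    for r in counts.itertuples():
        pos = pos_of[r.gene]
        for j in range(int(r.wild_count)):
            rows.append((r.sample, f"{r.gene}:{r.sample}:w{j}", "chr2L",
                         pos, "wild"))
        for j in range(int(r.ref_count)):
            rows.append((r.sample, f"{r.gene}:{r.sample}:r{j}", "chr2L",
                         pos, "ref"))
    assignments = pd.DataFrame(
        rows, columns=["sample", "read_id", "chrom", "pos", "allele"])

    per_site = counts.groupby("gene")[["wild_count", "ref_count"]].sum()
    pileups = pd.DataFrame({
        "chrom": "chr2L", "pos": [pos_of[g] for g in per_site.index],
        "A": per_site["ref_count"].to_numpy(),       # ref allele is A
        "C": per_site["wild_count"].to_numpy(),      # wild allele is C
        "G": 0, "T": 0})
    return intervals, whitelist, assignments, pileups


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns {'manifest': ..., 'results': {...}}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "parameters": _config_dict(config),
                "seed": config.seed}
    results = {}

    def record(stage, outputs):
        digests = {str(p): _sha256(p) for p in outputs}
        manifest["stages"].append({"stage": stage, "outputs": digests})

    try:
        # -- simulate ------------------------------------------------- #
        sim = config.simulation
        counts, meta, truth = simulate_ase_dataset(sim, seed=config.seed)
        expr = simulate_total_expression(sim, truth, seed=config.seed + 1)
        intervals, whitelist, assignments, pileups = _read_level_view(counts)
        io.write_tsv(counts, out / "allele_counts.tsv")
        io.write_tsv(meta, out / "metadata.tsv")
        io.write_tsv(truth.to_frame(), out / "truth.tsv")
        io.write_tsv(expr, out / "expression.tsv", index=True)
        io.write_vcf_whitelist(whitelist, out / "whitelist.vcf")
        io.write_tsv(intervals.table, out / "gene_intervals.tsv")
        io.write_tsv(pileups, out / "pileups.tsv")
        io.write_config(sim, out / "simulation_config.json")
        record("simulate", [out / "allele_counts.tsv", out / "metadata.tsv",
                            out / "truth.tsv", out / "expression.tsv",
                            out / "whitelist.vcf", out / "pileups.tsv"])

        # -- filter_snps ---------------------------------------------- #
        snps, log = call_and_filter_snps(
            pileups, intervals, whitelist, min_depth=config.min_depth,
            error_rate=config.error_rate, alpha=config.alpha)
        io.write_tsv(snps, out / "snps_retained.tsv")
        io.write_json(log, out / "snp_filter_log.json")
        record("filter_snps", [out / "snps_retained.tsv",
                               out / "snp_filter_log.json"])

        # -- count_alleles -------------------------------------------- #
        kept_sites = set(zip(snps["chrom"], snps["pos"]))
        kept = assignments[[(c, p) in kept_sites for c, p in
                            zip(assignments["chrom"], assignments["pos"])]]
        calls, removed_snps = resolve_conflicting_reads(
            kept, rule=config.conflict_rule)
        counted = count_alleles_per_gene(calls, kept, intervals, meta)
        bias = reference_bias_summary(counted, low=config.bias_low,
                                      high=config.bias_high)
        io.write_tsv(counted, out / "counted_alleles.tsv")
        io.write_tsv(bias["per_gene"].rename("ref_prop").reset_index()
                     .assign(stratum=bias["strata"].to_numpy()),
                     out / "reference_bias.tsv")
        record("count_alleles", [out / "counted_alleles.tsv",
                                 out / "reference_bias.tsv"])
        results["bias"] = bias

        # -- test_ase -------------------------------------------------- #
        ase = run_ase_tests(
            counted, meta,
            min_replicated_genotypes=config.min_replicated_genotypes,
            fdr_threshold=config.fdr_threshold,
            boundary_mixture=config.lrt_reference == "mixture")
        io.write_tsv(ase, out / "ase_tests.tsv")
        record("test_ase", [out / "ase_tests.tsv"])
        results["ase"] = ase

        # -- group_alleles --------------------------------------------- #
        sig = ase.loc[ase["significant"], "gene"].tolist()
        groupings = {}
        grows = []
        for gene in sig:
            res = group_gene(counted[counted["gene"] == gene], gene=gene)
            groupings[gene] = res
            grows.append({
                "gene": gene, "split_index": res.split_index,
                "loglik": res.loglik,
                "mean_top": res.group_means["top"],
                "mean_bottom": res.group_means["bottom"],
                "reference_group": res.reference_group,
                "wild_direction": res.wild_direction,
                "ase_magnitude": res.ase_magnitude,
                "degenerate": res.degenerate})
        gdf = pd.DataFrame(grows, columns=[
            "gene", "split_index", "loglik", "mean_top", "mean_bottom",
            "reference_group", "wild_direction", "ase_magnitude",
            "degenerate"])
        io.write_tsv(gdf, out / "groupings.tsv")
        freqs = (allele_frequencies(groupings, meta) if groupings
                 else pd.DataFrame())
        io.write_tsv(freqs, out / "allele_frequencies.tsv", index=True)
        record("group_alleles", [out / "groupings.tsv",
                                 out / "allele_frequencies.tsv"])
        results["groupings"] = groupings
        results["frequencies"] = freqs

        # -- clinal ---------------------------------------------------- #
        filt, cpm_mat = cpm_and_filter(expr, config.min_cpm,
                                       config.min_cpm_samples)
        conts = sorted(meta["continent"].unique())
        de = {c: latitudinal_de_test(filt, meta, c) for c in conts}
        summary = {}
        if len(conts) == 2:
            conc = sign_concordance(de[conts[0]], de[conts[1]],
                                    fdr_threshold=config.fdr_threshold)
            conc.pop("quadrants")
            summary["concordance"] = conc
            lat_genes = set()
            a, b = de[conts[0]], de[conts[1]]
            common = a.index.intersection(b.index)
            for g in common:
                if ((a.loc[g, "p"] < 0.05 or b.loc[g, "p"] < 0.05)
                        and np.sign(a.loc[g, "log2_fold"])
                        == np.sign(b.loc[g, "log2_fold"])):
                    lat_genes.add(g)
            tested = set(ase["gene"]) & set(common)
            ase_genes = set(ase.loc[ase["significant"], "gene"]) & tested
            if tested and (lat_genes & tested) and (tested - lat_genes):
                summary["enrichment"] = {
                    k: v for k, v in ase_enrichment(
                        lat_genes & tested, ase_genes, tested).items()
                    if k != "table"}
            if sig:
                diffs = latitudinal_ase_differences(counted, sig)
                io.write_tsv(diffs, out / "ase_latitudinal_differences.tsv",
                             index=True)
                cols = [c for c in diffs.columns if c.startswith("ase_diff")]
                if len(cols) == 2:
                    ok = diffs[cols].dropna()
                    if len(ok) >= 3:
                        rho, p = spearman_correlation(ok[cols[0]],
                                                      ok[cols[1]],
                                                      method="t")
                        summary["ase_cline_correlation"] = {"rho": rho,
                                                            "p": p,
                                                            "n": len(ok)}
        for c, d in de.items():
            io.write_tsv(d, out / f"de_{c}.tsv", index=True)
        io.write_json(summary, out / "clinal_summary.json")
        record("clinal", [out / "clinal_summary.json"]
               + [out / f"de_{c}.tsv" for c in conts])
        results["clinal"] = summary
    except Exception as err:
        stage = STAGES[len(manifest["stages"])] \
            if len(manifest["stages"]) < len(STAGES) else "finalise"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["simulation"] = config.simulation.to_dict()
    return d
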