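"""Synthetic data with the statistical structure of the crossed-line ASE design.

The study design emulated here: isofemale lines from 2 continents x 2
latitude classes (temperate / tropical), each line genetically cloned for one
haploid genome and crossed to the reference strain, so every library is
heterozygous reference/wild and allele-informative reads are binomial draws.
Four lines per population carry a biological replicate.

The generator inverts the analysis model: per (gene, sample) the
wild-allele count is Binomial(depth, expit(baseline + delta*carrier +
u_genotype + v_replicate - mapping_bias)), with depth negative-binomial,
u ~ N(0, genotype_sd^2) shared across a genotype's replicates and
v ~ N(0, replicate_sd^2) drawn independently per library.  High-allele
carrier status is drawn per genotype from a per-population frequency, which
is how latitude-structured cis-regulatory clines are planted.  Full ground
truth is returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "SimulationConfig", "SimulationTruth", "simulate_ase_dataset",
    "simulate_total_expression", "simulate_pileups", "clinal_frequencies",
]

CONTINENTS = ("US", "AUS")
LATITUDES = ("temperate", "tropical")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic ASE study.

    Defaults mirror the emulated design: 2 continents x 2 latitude classes,
    13 genotypes per population of which 4 have a biological replicate.
    ``cre_freq_by_population`` maps population name -> per-gene high-allele
    frequency (scalar applied to all genes, or array of length ``n_genes``).
    ``mapping_bias_logit`` shifts the logit toward the reference allele.
    """

    n_genes: int = 100
    n_continents: int = 2
    n_latitudes_per_continent: int = 2
    genotypes_per_population: int = 13
    replicated_genotypes_per_population: int = 4
    depth_mean: float = 100.0
    depth_dispersion: float = 5.0
    baseline_logit: float = 0.0
    cre_effect_sd: float = 1.0
    cre_effect_fixed: float | None = None   # overrides the N(0, sd) draw
    cre_freq_by_population: dict | None = None
    genotype_sd: float = 0.3
    replicate_sd: float = 0.3
    mapping_bias_logit: float = 0.004
    total_expression_coupling: float = 1.0
    expression_mean: float = 200.0
    expression_dispersion: float = 10.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.genotypes_per_population <= 0:
            raise ValueError("genotypes_per_population must be positive")
        if (self.replicated_genotypes_per_population
                > self.genotypes_per_population):
            raise ValueError("replicated genotypes exceed genotypes per "
                             "population")
        if self.replicated_genotypes_per_population < 0:
            raise ValueError("replicated_genotypes_per_population negative")
        for name in ("cre_effect_sd", "genotype_sd", "replicate_sd",
                     "depth_mean", "depth_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0,1)")

    @property
    def populations(self) -> list[tuple[str, str, str]]:
        """(name, continent, latitude) for the continent x latitude cross."""
        pops = []
        for c in range(self.n_continents):
            cont = CONTINENTS[c] if c < len(CONTINENTS) else f"C{c}"
            for l in range(self.n_latitudes_per_continent):
                lat = LATITUDES[l] if l < len(LATITUDES) else f"L{l}"
                pops.append((f"{cont}_{lat}", cont, lat))
        return pops

    def frequencies(self, population: str) -> np.ndarray:
        """Per-gene high-allele frequency for one population."""
        if self.cre_freq_by_population is None:
            f = 0.5
        else:
            f = self.cre_freq_by_population[population]
        f = np.broadcast_to(np.asarray(f, dtype=float), (self.n_genes,))
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        return f

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["cre_freq_by_population"] is not None:
            d["cre_freq_by_population"] = {
                k: (list(np.atleast_1d(v).astype(float)))
                for k, v in d["cre_freq_by_population"].items()}
        return d


def clinal_frequencies(config_or_pops, tropical: float = 0.8,
                       temperate: float = 0.2,
                       continents: tuple | None = None) -> dict:
    """High-allele frequencies implementing a latitudinal cline.

    ``continents`` restricts the cline to a subset (others get 0.5),
    the negative control for the cross-continent concordance analysis.
    """
    if isinstance(config_or_pops, SimulationConfig):
        pops = config_or_pops.populations
    else:
        pops = config_or_pops
    out = {}
    for name, cont, lat in pops:
        if continents is not None and cont not in continents:
            out[name] = 0.5
        else:
            out[name] = tropical if lat == "tropical" else temperate
    return out


@dataclass
class SimulationTruth:
    """Ground truth per simulated gene, for recovery tests."""

    genes: list
    delta: np.ndarray                      # logit CRE effect per gene
    carrier: pd.DataFrame                  # gene x genotype high-allele status
    frequencies: pd.DataFrame              # gene x population drawn frequency
    genotype_sd: float
    replicate_sd: float
    config: SimulationConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = self.carrier.stack().rename("carrier").reset_index()
        rows.columns = ["gene", "genotype", "carrier"]
        d = pd.Series(self.delta, index=self.genes, name="delta")
        rows["delta"] = rows["gene"].map(d)
        return rows


def _metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for name, cont, lat in config.populations:
        for g in range(config.genotypes_per_population):
            geno = f"{name}_g{g:02d}"
            n_rep = 2 if g < config.replicated_genotypes_per_population else 1
            for r in range(n_rep):
                rows.append({"sample": f"{geno}_r{r + 1}", "genotype": geno,
                             "replicate": f"r{r + 1}", "population": name,
                             "continent": cont, "latitude": lat})
    return pd.DataFrame(rows)


def simulate_ase_dataset(config: SimulationConfig, seed: int | None = None):
    """Draw an allele-count table under the generative ASE model.

    Returns ``(counts, metadata, truth)`` where ``counts`` is the long-format
    AlleleCountTable (gene, sample, metadata columns, wild_count, ref_count).
    Per-gene random streams are spawned deterministically from the master
    seed, so identical ``(config, seed)`` give identical output.
    """
    if seed is None:
        seed = config.seed
    meta = _metadata(config)
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.spawn(config.n_genes)

    pop_of = meta.drop_duplicates("genotype").set_index("genotype")["population"]
    genotypes = pop_of.index.to_numpy()
    freqs = {p: config.frequencies(p) for p, _, _ in config.populations}

    frames = []
    carrier = np.zeros((config.n_genes, len(genotypes)), dtype=bool)
    deltas = np.zeros(config.n_genes)
    n_rows = len(meta)
    geno_idx = meta["genotype"].map(
        {g: i for i, g in enumerate(genotypes)}).to_numpy()

    for gi, gene in enumerate(genes):
        rng = np.random.default_rng(gene_seeds[gi])
        delta = rng.normal(0.0, config.cre_effect_sd)
        if config.cre_effect_fixed is not None:
            delta = float(config.cre_effect_fixed)
        deltas[gi] = delta
        f_per_geno = np.array([freqs[pop_of[g]][gi] for g in genotypes])
        carr = rng.random(len(genotypes)) < f_per_geno
        carrier[gi] = carr
        u = rng.normal(0.0, config.genotype_sd, size=len(genotypes))
        v = rng.normal(0.0, config.replicate_sd, size=n_rows)
        eta = (config.baseline_logit + delta * carr[geno_idx]
               + u[geno_idx] + v - config.mapping_bias_logit)
        if config.depth_dispersion > 0:
            k = config.depth_dispersion
            depth = rng.negative_binomial(
                k, k / (k + config.depth_mean), size=n_rows)
        else:
            depth = np.full(n_rows, int(round(config.depth_mean)))
        wild = rng.binomial(depth, special.expit(eta))
        frames.append(pd.DataFrame({
            "gene": gene, "sample": meta["sample"],
            "genotype": meta["genotype"], "replicate": meta["replicate"],
            "population": meta["population"], "continent": meta["continent"],
            "latitude": meta["latitude"],
            "wild_count": wild, "ref_count": depth - wild}))

    counts = pd.concat(frames, ignore_index=True)
    truth = SimulationTruth(
        genes=genes, delta=deltas,
        carrier=pd.DataFrame(carrier, index=genes, columns=genotypes),
        frequencies=pd.DataFrame(
            {p: freqs[p] for p, _, _ in config.populations}, index=genes),
        genotype_sd=config.genotype_sd, replicate_sd=config.replicate_sd,
        config=config)
    return counts, meta, truth


def simulate_total_expression(config: SimulationConfig, truth: SimulationTruth,
                              seed: int | None = None) -> pd.DataFrame:
    """Gene x sample total-count matrix with optional allele coupling.

    Counts are negative-binomial with gene-specific baseline means; the mean
    of libraries whose genotype carries the high-*expression* allele (the
    CRE-variant allele when delta > 0, the non-variant allele otherwise) is
    multiplied by ``total_expression_coupling``.
    """
    if seed is None:
        seed = config.seed + 1
    meta = _metadata(config)
    if truth.carrier.shape[0] != config.n_genes:
        raise ValueError("truth does not match config dimensions")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = truth.genes
    geno = meta["genotype"].to_numpy()
    base = rng.lognormal(np.log(config.expression_mean), 0.5,
                         size=len(genes))
    mat = np.zeros((len(genes), len(meta)), dtype=int)
    coup = config.total_expression_coupling
    for gi, gene in enumerate(genes):
        carr = truth.carrier.loc[gene].reindex(geno).to_numpy()
        hi_is_variant = truth.delta[gi] >= 0
        mult = np.where(carr == hi_is_variant, coup, 1.0)
        k = config.expression_dispersion
        mat[gi] = rng.negative_binomial(k, k / (k + base[gi] * mult))
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                        columns=meta["sample"].to_numpy())


def simulate_pileups(n_sites: int, depth_range: tuple[int, int],
                     true_snp_fraction: float, error_rate: float = 0.01,
                     seed: int = 0) -> pd.DataFrame:
    """Per-site base-count table under a worst-case error model.

    True SNP sites are biallelic at ~50:50; at non-SNP sites every
    sequencing error produces the *same* incorrect base (the systematic
    worst case the supporting-read threshold is designed against), so the
    alternate-base count is Binomial(depth, error_rate).
    """
    lo, hi = depth_range
    if hi < lo or lo < 1:
        raise ValueError("empty depth range")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    depth = rng.integers(lo, hi + 1, size=n_sites)
    is_snp = rng.random(n_sites) < true_snp_fraction
    alt = np.where(is_snp, rng.binomial(depth, 0.5),
                   rng.binomial(depth, error_rate))
    df = pd.DataFrame({
        "chrom": "chr2L", "pos": np.arange(1, n_sites + 1),
        "A": depth - alt, "C": alt, "G": 0, "T": 0,
        "truth_is_snp": is_snp})
    return df
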