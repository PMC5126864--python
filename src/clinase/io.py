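"""Readers and writers for the pipeline's tabular and variant formats.

All tables are tab-separated with a header row.  The SNP whitelist is a
sites-only VCF (1-based, INFO ignored); gene intervals come from BED
(0-based half-open, converted to 1-based inclusive internally) or from a
minimal gene TSV that is already 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam

from .counting import GeneIntervals
from .simulate import SimulationConfig

COUNT_COLUMNS = ["gene", "sample", "genotype", "replicate", "population",
                 "continent", "latitude", "wild_count", "ref_count"]
META_COLUMNS = ["sample", "genotype", "replicate", "population",
                "continent", "latitude"]


def _read_tsv(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_allele_counts(path) -> pd.DataFrame:
    return _read_tsv(path, required=["gene", "sample", "wild_count",
                                     "ref_count"])


def read_metadata(path) -> pd.DataFrame:
    meta = _read_tsv(path, required=META_COLUMNS)
    dup = meta.duplicated(["genotype", "replicate"])
    if dup.any():
        raise ValueError(f"duplicate (genotype, replicate) rows: "
                         f"{meta.loc[dup, 'sample'].tolist()}")
    pops = meta.groupby("population")[["latitude", "continent"]].nunique()
    if (pops > 1).any().any():
        raise ValueError("population does not determine latitude/continent")
    return meta


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_whitelist(path) -> pd.DataFrame:
    """Biallelic sites from a (sites-only) VCF; INFO/samples ignored."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if len(rec.alts or ()) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            rows.append({"chrom": rec.chrom, "pos": rec.pos,
                         "ref": rec.ref, "alt": rec.alts[0]})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def write_vcf_whitelist(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in df.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


def read_bed_intervals(path) -> GeneIntervals:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    return GeneIntervals.from_bed_frame(bed)


def read_gene_intervals_tsv(path) -> GeneIntervals:
    return GeneIntervals.from_frame(
        _read_tsv(path, required=["gene", "chrom", "start", "end"]))


def write_config(config: SimulationConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("cre_freq_by_population") is not None:
        d["cre_freq_by_population"] = {
            k: (v[0] if isinstance(v, list) and len(v) == 1 else v)
            for k, v in d["cre_freq_by_population"].items()}
    return SimulationConfig(**d)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
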