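"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCFv4.2 (GT-only FORMAT, biallelic, diploid); tables as
TSV with a header row. Metabolite tables are wide per sample × replicate:
``sample<TAB>replicate<TAB><metabolite...>`` (the replicate column may be
omitted for single-replicate data).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    MISSING,
    GeneTable,
    GenotypeMatrix,
    MetaboliteMatrix,
    PhenotypeTable,
    PopulationLabels,
    SnpRecord,
)

logger = logging.getLogger("cassava_mgwas")


class VcfFormatError(ValueError):
    pass


def read_vcf(path: str | Path, allow_multiallelic: bool = False) -> GenotypeMatrix:
    """Load a VCF into an additive-coded :class:`GenotypeMatrix`.

    Calls are coded by alt-allele count; ``./.`` becomes MISSING. Multi-allelic
    records are rejected (counted in the log) unless *allow_multiallelic*, in
    which case they are skipped too — they are never split. Non-diploid GT
    raises.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            if not allow_multiallelic:
                continue
            continue
        calls = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise VcfFormatError(
                    f"non-diploid GT at {var.CHROM}:{var.POS} sample {samples[i]}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                calls[i] = MISSING
            else:
                calls[i] = alleles[0] + alleles[1]
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(var.CHROM, var.POS, var.REF, var.ALT[0], vid))
        rows.append(calls)
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    calls = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snps, calls)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCFv4.2 with GT-only FORMAT; round-trips through read_vcf."""
    path = Path(path)
    chrom_max: dict[str, int] = {}
    for s in g.snps:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={mx + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, s in enumerate(g.snps):
            gts = "\t".join(_GT_STR[int(c)] for c in g.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_metabolite_table(path: str | Path) -> MetaboliteMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("metabolite table needs a 'sample' column")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    metabs = [c for c in df.columns if c not in ("sample", "replicate")]
    if not metabs:
        raise ValueError("metabolite table has no metabolite columns")
    for c in metabs:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"non-numeric intensity column {c!r}")
    if df.duplicated(subset=["sample", "replicate"]).any():
        raise ValueError("duplicate sample x replicate rows")
    samples = list(dict.fromkeys(df["sample"]))
    reps = sorted(df["replicate"].unique())
    values = np.full((len(samples), len(metabs), len(reps)), np.nan)
    s_idx = {s: i for i, s in enumerate(samples)}
    r_idx = {r: i for i, r in enumerate(reps)}
    for _, row in df.iterrows():
        values[s_idx[row["sample"]], :, r_idx[row["replicate"]]] = row[metabs].to_numpy(
            dtype=float
        )
    return MetaboliteMatrix(samples, metabs, values)


def write_metabolite_table(m: MetaboliteMatrix, path: str | Path) -> None:
    rows = []
    for r in range(m.n_replicates):
        for i, s in enumerate(m.samples):
            rows.append([s, r + 1] + list(m.values[i, :, r]))
    df = pd.DataFrame(rows, columns=["sample", "replicate"] + list(m.metabolites))
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("phenotype table needs a 'sample' column")
    df = df.set_index("sample")
    return PhenotypeTable(df)


def write_phenotype_table(p: PhenotypeTable, path: str | Path) -> None:
    p.data.to_csv(path, sep="\t", index_label="sample")


def read_gene_table(path: str | Path) -> GeneTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneTable(df)


def write_gene_table(g: GeneTable, path: str | Path) -> None:
    g.data.to_csv(path, sep="\t", index=False)


def read_labels(
    path: str | Path, known_samples: list[str] | None = None
) -> PopulationLabels:
    df = pd.read_csv(path, sep="\t")
    for c in ("sample", "group"):
        if c not in df.columns:
            raise ValueError(f"labels table needs a {c!r} column")
    labels = PopulationLabels(dict(zip(df["sample"], df["group"])))
    if known_samples is not None:
        labels.validate_against(known_samples)
    return labels


def write_labels(labels: PopulationLabels, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": list(labels.labels), "group": list(labels.labels.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, kind: str):
    """Dispatch by table kind ∈ {metabolite, phenotype, gene, labels}."""
    readers = {
        "metabolite": read_metabolite_table,
        "phenotype": read_phenotype_table,
        "gene": read_gene_table,
        "labels": read_labels,
    }
    if kind not in readers:
        raise ValueError(f"unknown table kind {kind!r}")
    return readers[kind](path)


DEFAULT_CONFIG: dict = {
    "maf_min": 0.05,
    "mcf_max": 0.1,
    "alpha": 0.05,
    "alpha_per_test": None,  # explicit per-test threshold (e.g. 4.43e-7) overrides alpha/m
    "clump_gap_bp": 1_000_000,
    "clump_min_snps": 5,
    "hotspot_bin_bp": 1_000_000,
    "hotspot_n_perm": 1000,
    "hotspot_alpha": 0.01,
    "coloc_window_bp": 1_000_000,
    "vip_min": 1.0,
    "fc_min": 1.5,
    "dam_n_sub": 5,
    "dam_repeats": 10,
    "pi_window_bp": 80_000,
    "pi_step_bp": 10_000,
    "structure_k": 3,
    "transform": "log2",
    "seed": 0,
}


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML config over the defaults; unknown keys rejected."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg.update(user)
    return cfg


def log_banner(params: dict) -> None:
    logger.info("run parameters: %s", " ".join(f"{k}={v}" for k, v in params.items()))
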