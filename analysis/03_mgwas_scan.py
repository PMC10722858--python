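#!/usr/bin/env python
"""Mixed-model GWAS of metabolites and phenotypes, then locus clumping.

Scans the five QTL-bearing metabolites plus SR weight and endothelium color
with the kinship + principal-component MLM, thresholds at Bonferroni
(0.05 / tested SNPs), and clumps adjacent significant SNPs (>= 5 within
< 1 Mb) into loci with lead SNPs. Full per-SNP tables go to scratch/,
the locus tables to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cassava_mgwas import io as cio
from cassava_mgwas import quantgen as qg
from cassava_mgwas import signals as sig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"
SCANS = ROOT / "scratch" / "gwas"


def main():
    RESULTS.mkdir(exist_ok=True)
    SCANS.mkdir(parents=True, exist_ok=True)
    g = cio.read_vcf(DATA / "genotypes.vcf")
    m = cio.read_metabolite_table(DATA / "metabolites.tsv")
    pheno = cio.read_phenotype_table(DATA / "phenotypes.tsv")
    truth = json.loads((DATA / "truth.json").read_text())

    gq, rep = qg.qc_filter(g)
    print(f"QC: kept {gq.n_snps}/{g.n_snps} SNPs (MAF>0.05, MCF<0.1)")
    K = qg.compute_kinship(gq)
    Q = qg.compute_structure(gq, 3)
    alpha = sig.bonferroni_threshold(gq.n_snps)
    print(f"Bonferroni per-test threshold: {alpha:.2e}")

    traits: dict[str, np.ndarray] = {}
    for q in truth["qtls"]:
        name = q["metabolite"]
        traits[name] = np.log2(m.replicate_means()[:, m.metabolites.index(name)] + 1)
    traits["sr_weight"] = pheno.trait("sr_weight").to_numpy(dtype=float)
    traits["endothelium_color"] = (
        pheno.trait("endothelium_color") == "red"
    ).to_numpy(dtype=float)

    all_loci = []
    for name, y in traits.items():
        null = qg.fit_null_mlm(y, K, Q)
        res = qg.scan_associations(gq, y, null)
        res.to_frame().to_csv(SCANS / f"{name}.tsv", sep="\t", index=False)
        snps = sig.threshold_significant(res, alpha)
        loci, _ = sig.clump_loci(snps, trait=name)
        all_loci.append(sig.loci_to_frame(loci))
        leads = ", ".join(f"{l.chrom}:{l.lead.pos} (P={l.lead.p:.1e})" for l in loci)
        print(f"{name}: {len(snps)} significant SNPs -> {len(loci)} loci {leads}")

    non_empty = [df for df in all_loci if len(df)]
    loci_df = (
        pd.concat(non_empty, ignore_index=True) if non_empty else all_loci[0]
    )
    loci_df.to_csv(RESULTS / "loci.tsv", sep="\t", index=False)
    print(f"wrote {len(loci_df)} loci to results/loci.tsv")


if __name__ == "__main__":
    main()
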