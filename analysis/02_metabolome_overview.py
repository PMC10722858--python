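#!/usr/bin/env python
"""Descriptive metabolome statistics on the simulated panel.

Computes replicate reproducibility (r > 0.25 & P < 0.01 rule), coefficients
of variation, broad-sense heritability from the two replicates, the
metabolite correlation clustering, and the accession clustering with its SR
weight contrast. Small summary tables land in results/.
"""

from pathlib import Path

import pandas as pd

from cassava_mgwas import io as cio
from cassava_mgwas import metabolome as met
from cassava_mgwas import quantgen as qg

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    m = cio.read_metabolite_table(DATA / "metabolites.tsv")
    pheno = cio.read_phenotype_table(DATA / "phenotypes.tsv")

    rep = met.replicate_reproducibility(m)
    rep.to_csv(RESULTS / "replicate_reproducibility.tsv", sep="\t", index=False)
    print(f"replicate reproducibility: {rep['pass'].mean():.1%} of "
          f"{len(rep)} metabolites pass r>0.25 & P<0.01")

    cv = met.coefficient_of_variation(m)
    cv.to_csv(RESULTS / "cv.tsv", sep="\t", index=False)
    print(f"CV > 50% for {(cv.cv_percent > 50).mean():.1%} of metabolites "
          f"(median CV {cv.cv_percent.median():.1f}%)")

    h2 = pd.DataFrame(
        [{"metabolite": e.metabolite, "h2": e.h2}
         for e in qg.estimate_heritability(m.to_log2())]
    )
    h2.to_csv(RESULTS / "heritability.tsv", sep="\t", index=False)
    print(f"H2 > 0.5 for {(h2.h2 > 0.5).mean():.1%} of metabolites "
          f"(mean {h2.h2.mean():.2f})")

    cc = met.metabolite_correlation(m)
    corr_dir = ROOT / "scratch"
    corr_dir.mkdir(exist_ok=True)
    cc.corr.stack().rename("r").reset_index().to_csv(
        corr_dir / "metabolite_correlations.tsv", sep="\t", index=False
    )
    print(f"correlation clustering over {len(cc.metabolites)} metabolites "
          f"({len(cc.excluded)} zero-variance excluded)")

    groups = met.cluster_accessions(m, k=4)
    (RESULTS / "accession_tree.nwk").write_text(groups.newick + "\n")
    summary, pairs = met.group_trait_contrast(groups, pheno, "sr_weight")
    summary.to_csv(RESULTS / "group_sr_weight.tsv", sep="\t", index=False)
    print("SR weight by accession group:")
    for row in summary.itertuples():
        print(f"  {row.group}: n={row.n} mean={row.mean:.2f} [{row.letters}]")


if __name__ == "__main__":
    main()
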