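#!/usr/bin/env python
"""Hotspot permutation test and mGWAS/pGWAS co-localization on the loci.

Pools the metabolite lead SNPs into 1-Mb bins, compares the observed bin
counts with 1000 uniform permutations (alpha = 0.01), and reports metabolite
loci whose lead SNPs fall within 1 Mb of a phenotype locus (or whose
intervals intersect).
"""

from pathlib import Path

import pandas as pd

from cassava_mgwas import signals as sig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
GENOME = {"Chr1": 5_000_000, "Chr2": 5_000_000}
PHENOTYPES = {"sr_weight", "endothelium_color"}


def to_loci(df: pd.DataFrame) -> list[sig.Locus]:
    out = []
    for row in df.itertuples():
        lead = sig.SigSnp(row.chrom, int(row.lead_pos), row.lead_id, float(row.lead_p))
        out.append(sig.Locus(row.trait, row.chrom, int(row.start), int(row.end),
                             [lead], lead))
    return out


def main():
    loci_df = pd.read_csv(RESULTS / "loci.tsv", sep="\t", dtype={"chrom": str})
    m_df = loci_df[~loci_df.trait.isin(PHENOTYPES)]
    p_df = loci_df[loci_df.trait.isin(PHENOTYPES)]

    signals = [(r.chrom, int(r.lead_pos)) for r in m_df.itertuples()]
    table = sig.detect_hotspots(signals, GENOME, bin_bp=1_000_000, n_perm=1000,
                                alpha=0.01, seed=20240915)
    table.data.to_csv(RESULTS / "hotspots.tsv", sep="\t", index=False)
    hot = table.data[table.data.flagged]
    print(f"{len(signals)} metabolite signals; permutation threshold "
          f"{table.threshold} per 1-Mb bin; {len(hot)} hotspot bins")
    for row in hot.itertuples():
        print(f"  {row.chrom}:{row.bin_start}-{row.bin_end}: {row.count} signals")

    pairs = sig.colocalize(to_loci(m_df), to_loci(p_df), window_bp=1_000_000)
    out = sig.coloc_to_frame(pairs)
    out.to_csv(RESULTS / "colocalization.tsv", sep="\t", index=False)
    print(f"{len(pairs)} metabolite/phenotype co-localizations:")
    for row in out.itertuples():
        print(f"  {row.metabolite} x {row.phenotype} on {row.m_chrom} "
              f"(lead distance {row.distance_bp} bp, {row.overlap_type})")


if __name__ == "__main__":
    main()
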