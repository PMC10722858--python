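#!/usr/bin/env python
"""Domestication analytics: the DAM resampling screen, windowed nucleotide
diversity, and allele-frequency contrasts.

Runs the 10x random 5-vs-5 cultivated-vs-wild PLS-DA/fold-change screen
(VIP >= 1, |FC| >= 1.5, all 10 repeats with one direction), computes pi in
80-kb windows with 10-kb steps per population, and contrasts allele
frequencies inside the swept window.
"""

import json
from pathlib import Path

from cassava_mgwas import domestication as dom
from cassava_mgwas import io as cio

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"
GENOME = {"Chr1": 5_000_000, "Chr2": 5_000_000}


def main():
    m = cio.read_metabolite_table(DATA / "metabolites.tsv")
    labels = cio.read_labels(DATA / "labels.tsv", known_samples=m.samples)
    g = cio.read_vcf(DATA / "genotypes.vcf")
    truth = json.loads((DATA / "truth.json").read_text())

    decision = dom.dam_classifier(m, labels, seed=20240915)
    df = decision.to_frame()
    df.to_csv(RESULTS / "dams.tsv", sep="\t", index=False)
    called = df[df.is_dam]
    planted = {d["metabolite"] for d in truth["dams"]}
    print(f"DAM screen: {len(called)}/{len(df)} metabolites called "
          f"({len(set(called.metabolite) & planted)}/{len(planted)} planted recovered)")
    for row in called.itertuples():
        print(f"  {row.metabolite}: {row.direction}")

    pi = dom.windowed_pi(g, labels, 80_000, 10_000, GENOME)
    pi.to_csv(ROOT / "scratch" / "pi_windows.tsv", sep="\t", index=False)
    sw = truth["sweep"]
    pi[pi.chrom == sw["chrom"]].to_csv(
        RESULTS / "pi_windows_sweep_chrom.tsv", sep="\t", index=False
    )
    piv = pi[pi.chrom == sw["chrom"]].pivot_table(
        index="start", columns="population", values="pi"
    )
    inside = piv.loc[(piv.index >= sw["start"]) & (piv.index + 80_000 <= sw["end"])]
    ratio = (inside["cultivated"] / inside["wild"]).mean()
    print(f"sweep {sw['chrom']}:{sw['start']}-{sw['end']}: "
          f"cultivated/wild pi ratio {ratio:.3f} inside the window")

    freqs = dom.allele_freq_contrast(g, labels)
    win = freqs[(freqs.chrom == sw["chrom"]) & (freqs.pos >= sw["start"])
                & (freqs.pos <= sw["end"])]
    win.to_csv(RESULTS / "sweep_allele_freqs.tsv", sep="\t", index=False)
    print(f"mean |allele-frequency difference| inside sweep: "
          f"{win.difference.abs().mean():.2f} over {len(win)} SNPs")


if __name__ == "__main__":
    main()
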