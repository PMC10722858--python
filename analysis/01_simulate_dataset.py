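#!/usr/bin/env python
"""Emit the study-sized synthetic dataset every later analysis step consumes.

299 cultivated + 5 wild accessions, 2 chromosomes x 5 Mb with ~6000 SNPs in
strong local LD, 60 metabolites (5 with planted QTLs, 5 with planted
domestication fold-changes), two replicates per accession, an SR-weight-like
trait, a binary endothelium color trait, and a selective sweep on Chr2.

Bulky raw files go to scratch/dataset/ (they are regenerated on demand);
the truth summary is printed here.
"""

import json
from pathlib import Path

from cassava_mgwas.simulate import default_config, emit_dataset

OUT = Path(__file__).resolve().parents[1] / "scratch" / "dataset"

def main():
    cfg = default_config(seed=20240915)
    truth = emit_dataset(cfg, OUT)
    print(f"dataset written to {OUT}")
    print(f"accessions: {cfg.n_cultivated} cultivated + {cfg.n_wild} wild; "
          f"{cfg.n_snps} SNPs on {cfg.n_chrom} chromosomes; "
          f"{cfg.n_metabolites} metabolites x {cfg.replicate_count} replicates")
    print("planted QTLs:")
    for q in truth.qtls:
        print(f"  {q['metabolite']}: {q['chrom']}:{q['pos']} "
              f"({q['fraction']:.0%} of trait variance)")
    print("planted DAMs:", ", ".join(f"{d['metabolite']}({d['log2_fc']:+.1f})"
                                     for d in truth.dams))
    sw = truth.sweep
    print(f"sweep window: {sw['chrom']}:{sw['start']}-{sw['end']}")

if __name__ == "__main__":
    main()
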