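"""End-to-end orchestration: simulate → associate → clump → hotspots →
co-localize → DAM screen → windowed π, on one config.

Used by the analysis drivers and the smoke tests; every step is the public
library call, nothing here re-implements computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import domestication, metabolome, quantgen, signals
from .simulate import SimulationConfig, SimulationTruth, simulate_genotypes, simulate_metabolome, simulate_phenotypes
from .types import GenotypeMatrix, MetaboliteMatrix, PhenotypeTable, PopulationLabels


@dataclass
class PipelineResult:
    genotypes: GenotypeMatrix  # post-QC
    labels: PopulationLabels
    metabolites: MetaboliteMatrix
    phenotypes: PhenotypeTable
    truth: SimulationTruth
    alpha_per_test: float
    scans: dict[str, quantgen.AssociationResult] = field(default_factory=dict)
    loci: dict[str, list[signals.Locus]] = field(default_factory=dict)
    pheno_loci: dict[str, list[signals.Locus]] = field(default_factory=dict)
    hotspots: signals.HotspotTable | None = None
    coloc: list[signals.ColocPair] = field(default_factory=list)
    dams: domestication.DamDecision | None = None
    pi: pd.DataFrame | None = None
    heritability: pd.DataFrame | None = None


def trait_vector(m: MetaboliteMatrix, name: str, transform: str = "log2") -> np.ndarray:
    y = m.replicate_means()[:, m.metabolites.index(name)]
    return np.log2(y + 1.0) if transform == "log2" else y


def run_pipeline(
    cfg: SimulationConfig,
    metabolites_to_scan: list[str] | None = None,
    structure_k: int = 3,
    alpha: float = 0.05,
    clump_gap_bp: int = 1_000_000,
    clump_min_snps: int = 5,
    hotspot_bin_bp: int = 1_000_000,
    coloc_window_bp: int = 1_000_000,
    seed: int | None = None,
) -> PipelineResult:
    """Simulate one dataset and run every downstream stage on it.

    By default only metabolites with planted QTLs (plus the phenotype-driving
    ones) are scanned genome-wide, keeping the run desk-scale; the DAM screen,
    heritability and π always use the full panel.
    """
    seed = cfg.seed if seed is None else seed
    g, labels = simulate_genotypes(cfg)
    m, truth = simulate_metabolome(cfg, g, labels)
    pheno = simulate_phenotypes(cfg, m)

    gq, _ = quantgen.qc_filter(g)
    K = quantgen.compute_kinship(gq)
    Q = quantgen.compute_structure(gq, structure_k)
    alpha_per_test = signals.bonferroni_threshold(gq.n_snps, alpha)

    if metabolites_to_scan is None:
        metabolites_to_scan = sorted(
            {q["metabolite"] for q in truth.qtls}
            | set(truth.pheno.get("coefficients", {}))
        )

    res = PipelineResult(gq, labels, m, pheno, truth, alpha_per_test)

    for name in metabolites_to_scan:
        y = trait_vector(m, name)
        null = quantgen.fit_null_mlm(y, K, Q)
        scan = quantgen.scan_associations(gq, y, null)
        res.scans[name] = scan
        sig = signals.threshold_significant(scan, alpha_per_test)
        res.loci[name], _ = signals.clump_loci(
            sig, clump_gap_bp, clump_min_snps, trait=name
        )

    # phenotype GWAS: quantitative SR weight + binary color coded 0/1
    for trait, values in _phenotype_vectors(pheno).items():
        null = quantgen.fit_null_mlm(values, K, Q)
        scan = quantgen.scan_associations(gq, values, null)
        sig = signals.threshold_significant(scan, alpha_per_test)
        res.pheno_loci[trait], _ = signals.clump_loci(
            sig, clump_gap_bp, clump_min_snps, trait=trait
        )

    all_m_loci = [l for ll in res.loci.values() for l in ll]
    all_p_loci = [l for ll in res.pheno_loci.values() for l in ll]
    genome = {f"Chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chrom)}
    res.hotspots = signals.detect_hotspots(
        [(l.chrom, l.lead.pos) for l in all_m_loci],
        genome,
        bin_bp=hotspot_bin_bp,
        seed=seed,
    )
    res.coloc = signals.colocalize(all_m_loci, all_p_loci, coloc_window_bp)

    if cfg.n_wild >= 1:
        res.dams = domestication.dam_classifier(m, labels, seed=seed)
        # diversity uses the unfiltered matrix: the MAF filter would strip
        # exactly the near-fixed sites a sweep produces
        res.pi = domestication.windowed_pi(g, labels, chrom_lengths=genome)
    if cfg.replicate_count >= 2:
        h = quantgen.estimate_heritability(m.to_log2())
        res.heritability = pd.DataFrame(
            [{"metabolite": x.metabolite, "var_g": x.var_g, "var_e": x.var_e, "h2": x.h2} for x in h]
        )
    return res


def _phenotype_vectors(pheno: PhenotypeTable) -> dict[str, np.ndarray]:
    out = {}
    for trait, kind in pheno.trait_types.items():
        col = pheno.trait(trait)
        if kind == "quantitative":
            out[trait] = col.to_numpy(dtype=float)
        else:
            out[trait] = (col == "red").to_numpy(dtype=float)
    return out
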