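"""Synthetic cassava-like genotype/metabolome/phenotype generator.

The generator emulates the statistical structure the downstream analyses
assume: two diverged subpopulations (cultivated vs wild) under the
Balding–Nichols model, first-order-Markov linkage disequilibrium along each
chromosome, planted metabolite QTLs with configured variance fractions,
replicate noise tuned to target broad-sense heritabilities, group mean
shifts (log2 fold-changes) for domestication-associated metabolites, a
low-diversity swept window in the cultivated group, and phenotypes driven by
designated metabolites. Every draw flows from one master seed; component
sub-streams use fixed offsets, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .types import (
    CULTIVATED,
    WILD,
    GeneTable,
    GenotypeMatrix,
    MetaboliteMatrix,
    PhenotypeTable,
    PopulationLabels,
    SnpRecord,
)

import pandas as pd

# sub-stream seed offsets (fixed so truth files are reproducible)
_OFF_GENO = 1
_OFF_METAB = 2
_OFF_PHENO = 3


@dataclass
class QtlSpec:
    metabolite: str
    chrom: str
    pos: int
    fraction: float  # fraction of replicate-mean trait variance


@dataclass
class DamSpec:
    metabolite: str
    log2_fc: float  # cultivated minus wild mean shift on the log2 scale


@dataclass
class SweepSpec:
    chrom: str
    start: int
    end: int  # 1-based inclusive


@dataclass
class PhenoSpec:
    coefficients: dict[str, float] = field(default_factory=dict)  # metabolite -> slope
    intercept: float = 20.0
    noise_sd: float = 1.0
    color_metabolite: str | None = None
    color_threshold: float = 0.0
    color_scale: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults follow the study design this pipeline targets: 299 cultivated
    and 5 wild accessions, 2 biological replicates, strong crop/wild
    divergence, and tight local LD, on a deliberately small 2-chromosome
    genome so everything runs at desk scale.
    """

    n_cultivated: int = 299
    n_wild: int = 5
    n_chrom: int = 2
    chrom_length_bp: int = 5_000_000
    n_snps: int = 6_000
    fst: float = 0.3
    ld_rho: float = 0.9
    n_metabolites: int = 60
    qtl_spec: list[QtlSpec] = field(default_factory=list)
    h2_spec: dict[str, float] | float = 0.6
    replicate_count: int = 2
    dam_spec: list[DamSpec] = field(default_factory=list)
    sweep_spec: SweepSpec | None = None
    pheno_spec: PhenoSpec = field(default_factory=PhenoSpec)
    log2_baseline: float = 10.0
    seed: int = 0

    def metabolite_names(self) -> list[str]:
        return [f"M{j + 1:04d}" for j in range(self.n_metabolites)]

    def h2_for(self, metabolite: str) -> float:
        if isinstance(self.h2_spec, dict):
            return float(self.h2_spec.get(metabolite, 0.6))
        return float(self.h2_spec)

    def validate(self) -> None:
        if self.n_snps < len(self.qtl_spec):
            raise ValueError("fewer SNPs than planted QTLs")
        if not (0.0 < self.fst < 1.0) and self.fst != 0.0:
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        names = set(self.metabolite_names())
        frac: dict[str, float] = {}
        for q in self.qtl_spec:
            if q.metabolite not in names:
                raise ValueError(f"QTL for unknown metabolite {q.metabolite}")
            if not (1 <= q.pos <= self.chrom_length_bp):
                raise ValueError("QTL position outside chromosome")
            frac[q.metabolite] = frac.get(q.metabolite, 0.0) + q.fraction
        for mname, f in frac.items():
            if f > 1.0:
                raise ValueError(f"QTL variance fractions for {mname} exceed 1")
        for mname in names:
            h2 = self.h2_for(mname)
            if not (0.0 <= h2 < 1.0):
                raise ValueError(
                    "h2 must be in [0, 1); h2 = 1 with replicate noise is infeasible"
                )
        if self.sweep_spec is not None:
            sw = self.sweep_spec
            if not (1 <= sw.start <= sw.end <= self.chrom_length_bp):
                raise ValueError("sweep window outside chromosome bounds")


def default_config(seed: int = 0) -> SimulationConfig:
    """A representative full-pipeline scenario with planted truth."""
    cfg = SimulationConfig(seed=seed)
    cfg.qtl_spec = [
        QtlSpec("M0001", "Chr1", 1_200_000, 0.20),
        QtlSpec("M0002", "Chr1", 3_500_000, 0.20),
        QtlSpec("M0003", "Chr2", 2_000_000, 0.25),
        QtlSpec("M0004", "Chr2", 4_200_000, 0.20),
        # anthocyanin-like metabolite driving the binary color trait
        QtlSpec("M0005", "Chr1", 2_400_000, 0.30),
    ]
    cfg.dam_spec = [
        DamSpec("M0010", -2.0),
        DamSpec("M0011", -2.0),
        DamSpec("M0012", 2.0),
        DamSpec("M0013", -2.5),
        DamSpec("M0014", 2.5),
    ]
    cfg.sweep_spec = SweepSpec("Chr2", 1_000_000, 1_400_000)
    cfg.pheno_spec = PhenoSpec(
        coefficients={"M0003": -1.5, "M0010": -0.8},
        intercept=20.0,
        noise_sd=1.0,
        color_metabolite="M0005",
        color_threshold=0.5,
        color_scale=1.0,
    )
    return cfg


@dataclass
class SimulationTruth:
    qtls: list[dict]
    h2_target: dict[str, float]
    h2_realized: dict[str, float]
    dams: list[dict]
    sweep: dict | None
    pheno: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


# ---------------------------------------------------------------- genotypes


def _unique_sorted_positions(rng, n: int, length: int) -> np.ndarray:
    pos: set[int] = set()
    while len(pos) < n:
        draw = rng.integers(1, length + 1, size=n - len(pos))
        pos.update(int(x) for x in draw)
    return np.array(sorted(pos), dtype=np.int64)


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, PopulationLabels]:
    """Two-population genotypes with Balding–Nichols divergence and Markov LD.

    Ancestral frequencies ~ Beta(0.5, 0.5) clipped to [0.05, 0.95]; group
    frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F). LD is a first-order Markov
    copying process on each haplotype: with probability ld_rho the haplotype
    carries its allele state forward from the previous SNP on the chromosome,
    else it draws fresh from the group frequency, giving correlation ≈
    ld_rho^k between SNPs k apart (runs of correlated markers, as clumping
    assumes). Realized per-SNP frequencies are therefore an exponential
    moving average of the drawn Balding–Nichols frequencies. Inside the sweep
    window cultivated frequencies are pushed to near-fixation toward the
    major allele. Diploid calls sum two haplotypes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _OFF_GENO)
    chrom_names = [f"Chr{i + 1}" for i in range(cfg.n_chrom)]
    per = cfg.n_snps // cfg.n_chrom
    counts = [per + (1 if i < cfg.n_snps % cfg.n_chrom else 0) for i in range(cfg.n_chrom)]

    samples = [f"C{i + 1:04d}" for i in range(cfg.n_cultivated)] + [
        f"W{i + 1:03d}" for i in range(cfg.n_wild)
    ]
    labels = PopulationLabels(
        {s: (CULTIVATED if s.startswith("C") else WILD) for s in samples}
    )
    n_ind = len(samples)

    snps: list[SnpRecord] = []
    call_blocks: list[np.ndarray] = []
    for chrom, m in zip(chrom_names, counts):
        positions = _unique_sorted_positions(rng, m, cfg.chrom_length_bp)
        p_anc = np.clip(rng.beta(0.5, 0.5, size=m), 0.05, 0.95)
        freqs = {}
        for pop in (CULTIVATED, WILD):
            if cfg.fst <= 1e-9:
                freqs[pop] = p_anc.copy()
            else:
                a = p_anc * (1 - cfg.fst) / cfg.fst
                b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
                freqs[pop] = rng.beta(a, b)
        sw = cfg.sweep_spec
        sweep_inside = None
        if sw is not None and sw.chrom == chrom:
            sweep_inside = (positions >= sw.start) & (positions <= sw.end)
            # the swept haplotype carries the major allele at every site
            sweep_allele = (freqs[CULTIVATED][sweep_inside] >= 0.5).astype(np.int8)

        calls = np.empty((n_ind, m), dtype=np.int8)
        for pop, ids in ((CULTIVATED, range(cfg.n_cultivated)),
                         (WILD, range(cfg.n_cultivated, n_ind))):
            n_hap = 2 * len(ids)
            if n_hap == 0:
                continue
            fresh = (rng.random((n_hap, m)) < freqs[pop][None, :]).astype(np.int8)
            copy = rng.random((n_hap, m - 1)) < cfg.ld_rho if m > 1 else None
            hap = np.empty((n_hap, m), dtype=np.int8)
            hap[:, 0] = fresh[:, 0]
            for j in range(1, m):
                hap[:, j] = np.where(copy[:, j - 1], hap[:, j - 1], fresh[:, j])
            if pop == CULTIVATED and sweep_inside is not None and sweep_inside.any():
                # push cultivated frequencies to near-fixation: each haplotype
                # adopts the swept (major) allele at 99% of window sites
                take = rng.random((n_hap, int(sweep_inside.sum()))) < 0.99
                block_in = hap[:, sweep_inside]
                hap[:, sweep_inside] = np.where(take, sweep_allele[None, :], block_in)
            block = hap[0::2, :] + hap[1::2, :]
            calls[list(ids), :] = block
        for pos in positions:
            snps.append(SnpRecord(chrom, int(pos), "A", "T"))
        call_blocks.append(calls)
    calls = np.concatenate(call_blocks, axis=1)
    return GenotypeMatrix(samples, snps, calls), labels


# ---------------------------------------------------------------- metabolome


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_metabolome(
    cfg: SimulationConfig,
    g: GenotypeMatrix,
    labels: PopulationLabels | None = None,
) -> tuple[MetaboliteMatrix, SimulationTruth]:
    """Metabolite intensities on the log2 scale, exponentiated to raw.

    Per metabolite the accession genetic value combines planted-QTL effects on
    standardized genotypes with a polygenic term N(0, σ² K); components are
    empirically standardized so the realized genetic variance equals h², each
    replicate adds N(0, 1−h²) noise, and DAM metabolites shift the cultivated
    mean by the configured log2 fold-change. Raw intensities are
    2^(baseline + log2 value), hence positive.
    """
    cfg.validate()
    if labels is None:
        labels = PopulationLabels(
            {s: (CULTIVATED if s.startswith("C") else WILD) for s in g.samples}
        )
    rng = np.random.default_rng(cfg.seed + _OFF_METAB)
    n = g.n_samples
    r = cfg.replicate_count
    names = cfg.metabolite_names()

    from .quantgen import compute_kinship

    K = compute_kinship(g)
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    L = U * np.sqrt(lam)[None, :]

    # snap each planted QTL to the nearest simulated SNP
    chroms = g.chroms
    positions = g.positions
    qtl_by_metab: dict[str, list[tuple[int, float]]] = {}
    qtl_truth = []
    for q in cfg.qtl_spec:
        on = np.where(chroms == q.chrom)[0]
        if on.size == 0:
            raise ValueError(f"QTL chromosome {q.chrom} not simulated")
        j = on[int(np.argmin(np.abs(positions[on] - q.pos)))]
        qtl_by_metab.setdefault(q.metabolite, []).append((int(j), q.fraction))
        qtl_truth.append(
            {
                "metabolite": q.metabolite,
                "chrom": q.chrom,
                "pos": int(positions[j]),
                "requested_pos": q.pos,
                "snp_id": g.snps[j].id,
                "fraction": q.fraction,
            }
        )

    dam_by_metab = {d.metabolite: d.log2_fc for d in cfg.dam_spec}
    cult_mask = np.array([labels.labels[s] == CULTIVATED for s in g.samples])
    dosage = g.dosage(impute=True)

    values = np.empty((n, len(names), r))
    h2_target = {}
    h2_realized = {}
    for jm, name in enumerate(names):
        h2 = cfg.h2_for(name)
        h2_target[name] = h2
        qtls = qtl_by_metab.get(name, [])
        frac_sum = sum(f for _, f in qtls)
        var_mean = h2 + (1 - h2) / r  # replicate-mean trait variance
        v_poly = h2 - frac_sum * var_mean
        if v_poly < -1e-12:
            raise ValueError(
                f"QTL fractions for {name} exceed the genetic variance budget"
            )
        v_poly = max(v_poly, 0.0)
        gvalue = np.zeros(n)
        zs = []
        for j, f in qtls:
            z = _standardize(dosage[:, j])
            zs.append(z)
            gvalue += np.sqrt(f * var_mean) * z
        if v_poly > 0:
            poly = L @ rng.standard_normal(n)
            # keep each QTL's variance share exact: make the polygenic draw
            # orthogonal (in-sample) to the planted QTL genotypes
            for z in zs:
                zz = float(z @ z)
                if zz > 0:
                    poly = poly - z * (float(z @ poly) / zz)
            gvalue += np.sqrt(v_poly) * _standardize(poly)
        sd = gvalue.std()
        if sd > 0 and h2 > 0:
            gvalue *= np.sqrt(h2) / sd
        shift = np.zeros(n)
        if name in dam_by_metab:
            shift[cult_mask] = dam_by_metab[name]
        noise_sd = np.sqrt(max(1.0 - h2, 0.0))
        noise = noise_sd * rng.standard_normal((n, r))
        log2_vals = cfg.log2_baseline + (gvalue + shift)[:, None] + noise
        values[:, jm, :] = 2.0**log2_vals
        var_g = float(np.var(gvalue))
        h2_realized[name] = var_g / (var_g + noise_sd**2) if var_g + noise_sd**2 > 0 else 0.0

    dams_truth = [
        {
            "metabolite": d.metabolite,
            "log2_fc": d.log2_fc,
            "direction": "up-in-cultivated" if d.log2_fc > 0 else "down-in-cultivated",
        }
        for d in cfg.dam_spec
    ]
    sweep_truth = (
        dataclasses.asdict(cfg.sweep_spec) if cfg.sweep_spec is not None else None
    )
    truth = SimulationTruth(
        qtls=qtl_truth,
        h2_target=h2_target,
        h2_realized=h2_realized,
        dams=dams_truth,
        sweep=sweep_truth,
        pheno=dataclasses.asdict(cfg.pheno_spec),
        seed=cfg.seed,
    )
    m = MetaboliteMatrix(list(g.samples), names, values, transform="raw")
    return m, truth


# ---------------------------------------------------------------- phenotypes


def simulate_phenotypes(cfg: SimulationConfig, m: MetaboliteMatrix) -> PhenotypeTable:
    """SR-weight-like quantitative trait plus a binary endothelium color.

    sr_weight = intercept + Σ coef × log2 replicate-mean + N(0, noise_sd²);
    endothelium_color = "red" when the liability (scaled, centered log2 level
    of the designated anthocyanin-like metabolite) exceeds the threshold.
    """
    rng = np.random.default_rng(cfg.seed + _OFF_PHENO)
    spec = cfg.pheno_spec
    log_means = np.log2(m.replicate_means() + 1.0) if m.transform == "raw" else m.replicate_means()
    midx = {name: j for j, name in enumerate(m.metabolites)}
    y = np.full(len(m.samples), spec.intercept, dtype=float)
    for name, coef in spec.coefficients.items():
        if name not in midx:
            raise ValueError(f"phenotype references unknown metabolite {name!r}")
        y += coef * log_means[:, midx[name]]
    y += spec.noise_sd * rng.standard_normal(len(m.samples))
    data = {"sr_weight": y}
    if spec.color_metabolite is not None:
        if spec.color_metabolite not in midx:
            raise ValueError(
                f"color metabolite {spec.color_metabolite!r} not simulated"
            )
        lvl = log_means[:, midx[spec.color_metabolite]]
        liability = spec.color_scale * (lvl - lvl.mean())
        data["endothelium_color"] = np.where(
            liability > spec.color_threshold, "red", "white"
        )
    df = pd.DataFrame(data, index=list(m.samples))
    return PhenotypeTable(df)


# ---------------------------------------------------------------- dataset emission


def make_gene_table(cfg: SimulationConfig, truth: SimulationTruth) -> GeneTable:
    """Toy annotation: one gene spanning each planted QTL (±1 kb)."""
    rows = []
    for i, q in enumerate(truth.qtls):
        rows.append(
            {
                "gene_id": f"gene_{q['metabolite']}_{i + 1}",
                "chrom": q["chrom"],
                "start": max(1, q["pos"] - 1000),
                "end": min(cfg.chrom_length_bp, q["pos"] + 1000),
                "strand": "+",
            }
        )
    return GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def emit_dataset(cfg: SimulationConfig, outdir: str | Path) -> SimulationTruth:
    """Run the full generator and write the standard file set.

    Writes genotypes.vcf, metabolites.tsv, phenotypes.tsv, labels.tsv,
    genes.tsv and truth.json under *outdir*.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, labels = simulate_genotypes(cfg)
    m, truth = simulate_metabolome(cfg, g, labels)
    pheno = simulate_phenotypes(cfg, m)
    genes = make_gene_table(cfg, truth)
    cio.write_vcf(g, outdir / "genotypes.vcf")
    cio.write_metabolite_table(m, outdir / "metabolites.tsv")
    cio.write_phenotype_table(pheno, outdir / "phenotypes.tsv")
    cio.write_labels(labels, outdir / "labels.tsv")
    cio.write_gene_table(genes, outdir / "genes.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
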