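"""Candidate-gene and causative-SNP mining.

SNPs inside a gene body ± 2 kb flank are tested against the target trait with
the same mixed-model engine as the genome-wide scan; gene expression is
consumed as a precomputed table and correlated with metabolite levels; allele
groups (carrier vs non-carrier, or full genotypic classes, or joint allele
combinations across a few SNPs) are contrasted on trait values with Welch
tests and compact letters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import group_contrast_table, pearson_with_p
from .quantgen import AssociationResult, NullModelFit, scan_associations
from .types import MISSING, GeneTable, GenotypeMatrix, MetaboliteMatrix

logger = logging.getLogger("cassava_mgwas")


def gene_window_snps(
    genes: GeneTable, g: GenotypeMatrix, flank_bp: int = 2000
) -> dict[str, np.ndarray]:
    """SNP indices with start − flank ≤ pos ≤ end + flank (inclusive bounds).

    The flank is strand-symmetric. Genes on chromosomes absent from the
    genotype matrix get an empty set with a warning.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    chroms = g.chroms
    positions = g.positions
    known = set(np.unique(chroms))
    out: dict[str, np.ndarray] = {}
    for gene in genes:
        if gene.chrom not in known:
            logger.warning("gene %s on unknown chromosome %s", gene.gene_id, gene.chrom)
            out[gene.gene_id] = np.array([], dtype=int)
            continue
        on = chroms == gene.chrom
        lo = gene.start - flank_bp
        hi = gene.end + flank_bp
        mask = on & (positions >= lo) & (positions <= hi)
        out[gene.gene_id] = np.where(mask)[0]
    return out


@dataclass
class GeneWindowAssoc:
    gene_id: str
    result: AssociationResult  # restricted to the window SNPs
    best_index: int | None  # index into result arrays
    causative_alpha: float
    causative: np.ndarray  # per window SNP flag

    @property
    def best_snp(self) -> str | None:
        return None if self.best_index is None else self.result.snp_ids[self.best_index]


def candidate_association(
    gene_id: str,
    snp_indices: np.ndarray,
    g: GenotypeMatrix,
    y: np.ndarray,
    null: NullModelFit,
    alpha: float | None = None,
) -> GeneWindowAssoc:
    """Mixed-model test of the window SNPs against the trait.

    Re-uses the genome-wide null fit (P3D). The best SNP is the minimum-P
    member (ties to smaller position); SNPs at or below *alpha* (default
    0.05 / window size, Bonferroni over the window) are flagged as possible
    causative SNPs.
    """
    snp_indices = np.asarray(snp_indices, dtype=int)
    if snp_indices.size == 0:
        return GeneWindowAssoc(gene_id, None, None, np.nan, np.array([], dtype=bool))
    sub = g.subset_snps(snp_indices)
    res = scan_associations(sub, y, null)
    if alpha is None:
        alpha = 0.05 / snp_indices.size
    order = np.lexsort((res.positions, res.p))
    best = int(order[0])
    return GeneWindowAssoc(gene_id, res, best, alpha, res.p <= alpha)


def expression_metabolite_correlation(
    expr: pd.DataFrame,
    m: MetaboliteMatrix,
    pairs: list[tuple[str, str]],
    log2_expr: bool = False,
) -> pd.DataFrame:
    """Pearson r / P between gene expression and metabolite level per pair.

    *expr* is samples × genes (FPKM-like, consumed as-is or log2(x+1)).
    Pairs with fewer than 3 shared samples are flagged undefined.
    """
    log_means = np.log2(m.replicate_means() + 1.0) if m.transform == "raw" else m.replicate_means()
    midx = {name: j for j, name in enumerate(m.metabolites)}
    sidx = {s: i for i, s in enumerate(m.samples)}
    rows = []
    for gene, metab in pairs:
        if gene not in expr.columns:
            raise KeyError(f"gene {gene!r} absent from expression table")
        if metab not in midx:
            raise KeyError(f"metabolite {metab!r} absent")
        shared = [s for s in expr.index if s in sidx]
        e = expr.loc[shared, gene].to_numpy(dtype=float)
        if log2_expr:
            e = np.log2(e + 1.0)
        v = log_means[[sidx[s] for s in shared], midx[metab]]
        r, p = pearson_with_p(e, v)
        rows.append(
            {
                "gene_id": gene,
                "metabolite": metab,
                "n": len(shared),
                "r": r,
                "p": p,
                "undefined": not np.isfinite(r),
            }
        )
    return pd.DataFrame(rows)


def _carrier_groups(calls: np.ndarray, snp_label: str) -> dict[str, np.ndarray]:
    ok = calls != MISSING
    return {
        f"{snp_label}:non-carrier": np.where(ok & (calls == 0))[0],
        f"{snp_label}:carrier": np.where(ok & (calls >= 1))[0],
    }


def allele_contrast(
    g: GenotypeMatrix,
    snp_id: str,
    values: np.ndarray,
    model: str = "biallelic-carrier",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait contrast between allele groups at one SNP.

    ``biallelic-carrier`` groups alt-carriers (calls ≥ 1) against
    non-carriers; ``genotypic`` keeps the three {0,1,2} classes. Welch t-tests
    with BH adjustment and compact letters; groups with n < 2 are reported
    descriptively only. A monomorphic SNP (single occupied group) raises.
    """
    ids = [s.id for s in g.snps]
    if snp_id not in ids:
        raise KeyError(f"unknown SNP {snp_id!r}")
    j = ids.index(snp_id)
    calls = g.calls[:, j]
    values = np.asarray(values, dtype=float)
    ok = (calls != MISSING) & np.isfinite(values)
    if model == "biallelic-carrier":
        members = {
            "non-carrier": np.where(ok & (calls == 0))[0],
            "carrier": np.where(ok & (calls >= 1))[0],
        }
    elif model == "genotypic":
        members = {str(c): np.where(ok & (calls == c))[0] for c in (0, 1, 2)}
    else:
        raise ValueError(f"unknown model {model!r}")
    members = {k: v for k, v in members.items() if v.size > 0}
    if len(members) < 2:
        raise ValueError(f"SNP {snp_id} is monomorphic under model {model!r}")
    groups = {k: values[v] for k, v in members.items()}
    return group_contrast_table(groups, alpha=alpha)


def allele_combination_contrast(
    g: GenotypeMatrix,
    snp_ids: list[str],
    values: np.ndarray,
    min_n: int = 2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contrast joint carrier-genotype combinations across 2–4 SNPs.

    Samples are grouped by the joint carrier string (one character per SNP:
    'C' carrier / 'N' non-carrier); combinations below *min_n* samples are
    excluded from testing. With a single SNP this reduces to allele_contrast.
    """
    if not (1 <= len(snp_ids) <= 4):
        raise ValueError("need 1-4 SNPs")
    ids = [s.id for s in g.snps]
    cols = []
    for sid in snp_ids:
        if sid not in ids:
            raise KeyError(f"unknown SNP {sid!r}")
        cols.append(g.calls[:, ids.index(sid)])
    calls = np.stack(cols, axis=1)
    values = np.asarray(values, dtype=float)
    ok = np.all(calls != MISSING, axis=1) & np.isfinite(values)
    combo = ["".join("C" if c >= 1 else "N" for c in row) for row in calls]
    groups: dict[str, np.ndarray] = {}
    for i in np.where(ok)[0]:
        groups.setdefault(combo[i], []).append(values[i])  # type: ignore[arg-type]
    groups = {k: np.asarray(v) for k, v in sorted(groups.items())}
    if all(len(v) < min_n for v in groups.values()):
        raise ValueError("every allele combination is below the minimum group size")
    return group_contrast_table(groups, alpha=alpha, min_n=min_n)
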