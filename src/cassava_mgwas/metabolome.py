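"""Descriptive metabolome statistics and structure.

Replicate reproducibility (Pearson r between the two biological replicates),
coefficients of variation, metabolite-metabolite correlation clustering,
accession clustering (neighbor-joining tree plus an average-linkage partition
on the same distance matrix), and group-vs-trait contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from ._stats import group_contrast_table, pearson_with_p
from .types import MetaboliteMatrix, PhenotypeTable


def replicate_reproducibility(
    m: MetaboliteMatrix, r_min: float = 0.25, p_max: float = 0.01
) -> pd.DataFrame:
    """Per-metabolite Pearson r between replicates 1 and 2 across accessions.

    ``pass`` requires r > r_min and P < p_max (strict, both). Metabolites with
    fewer than 3 complete pairs get NaN and fail.
    """
    if m.n_replicates < 2:
        raise ValueError("reproducibility needs 2 replicates")
    rows = []
    for j, name in enumerate(m.metabolites):
        r, p = pearson_with_p(m.values[:, j, 0], m.values[:, j, 1])
        ok = bool(np.isfinite(r) and r > r_min and p < p_max)
        rows.append({"metabolite": name, "r": r, "p": p, "pass": ok})
    return pd.DataFrame(rows)


def coefficient_of_variation(m: MetaboliteMatrix) -> pd.DataFrame:
    """CV = SD/mean of raw-scale replicate-mean intensities, in percent."""
    if m.transform != "raw":
        raise ValueError("CV is defined on raw-scale intensities")
    means = m.replicate_means()
    mu = np.nanmean(means, axis=0)
    sd = np.nanstd(means, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu != 0, 100.0 * sd / mu, np.nan)
    return pd.DataFrame(
        {
            "metabolite": m.metabolites,
            "mean": mu,
            "sd": sd,
            "cv_percent": cv,
            "undefined": mu == 0,
        }
    )


@dataclass
class CorrelationClustering:
    metabolites: list[str]  # metabolites included in the clustering
    corr: pd.DataFrame  # full symmetric matrix over included metabolites
    linkage: np.ndarray  # scipy average-linkage on distance 1 - r
    leaf_order: list[str]
    excluded: list[str]  # zero-variance metabolites


def metabolite_correlation(
    m: MetaboliteMatrix, transform: str = "log2"
) -> CorrelationClustering:
    """Pairwise Pearson on transformed replicate means + average-linkage tree.

    Zero-variance metabolites are excluded with their names recorded. Leaf
    order is deterministic (scipy optimal ordering off; ties resolved by the
    input order, which is itself sorted by metabolite id on construction).
    """
    if len(m.samples) < 3:
        raise ValueError("need >= 3 accessions")
    x = m.replicate_means()
    if transform == "log2" and m.transform == "raw":
        x = np.log2(x + 1.0)
    sd = np.nanstd(x, axis=0)
    keep = sd > 0
    excluded = [n for n, k in zip(m.metabolites, keep) if not k]
    names = [n for n, k in zip(m.metabolites, keep) if k]
    order = np.argsort(names)
    names = [names[i] for i in order]
    x = x[:, keep][:, order]
    corr = np.atleast_2d(np.corrcoef(x, rowvar=False))
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    if len(names) < 2:
        link = np.zeros((0, 4))
        leaf_order = list(names)
    else:
        dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
        link = hierarchy.average(dist)
        leaf_order = [names[i] for i in hierarchy.leaves_list(link)]
    return CorrelationClustering(
        metabolites=names,
        corr=pd.DataFrame(corr, index=names, columns=names),
        linkage=link,
        leaf_order=leaf_order,
        excluded=excluded,
    )


@dataclass
class AccessionGroups:
    assignment: dict[str, str]  # accession -> G1..Gk
    newick: str  # neighbor-joining tree
    linkage: np.ndarray  # average-linkage used for the partition
    degenerate: bool = False

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]


def cluster_accessions(m: MetaboliteMatrix, k: int) -> AccessionGroups:
    """Cluster accessions on log2 metabolite profiles into k groups.

    Distances are Euclidean between log2 replicate-mean profiles. A
    neighbor-joining tree is emitted (newick) for display; the k-group
    partition cuts an average-linkage hierarchy on the same distance matrix
    (NJ trees are unrooted and carry no canonical cut). Group labels G1..Gk
    are assigned in order of first appearance over the sorted accession list.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(m.samples) < k:
        raise ValueError("fewer accessions than groups")
    order = np.argsort(m.samples)
    samples = [m.samples[i] for i in order]
    x = m.replicate_means()
    if m.transform == "raw":
        x = np.log2(x + 1.0)
    x = x[order, :]
    dist_cond = pdist(x, metric="euclidean")
    degenerate = bool(np.all(dist_cond == 0))
    dmat = squareform(dist_cond)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    if degenerate:
        newick = "(" + ",".join(f"{s}:0.0" for s in samples) + ");"
        assignment = {s: "G1" for s in samples}
        link = hierarchy.average(dist_cond)
        return AccessionGroups(assignment, newick, link, degenerate=True)

    tree = nj(DistanceMatrix(dmat, ids=samples))
    newick = str(tree).strip()
    link = hierarchy.average(dist_cond)
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, str] = {}
    assignment = {}
    for s, c in zip(samples, raw):
        if c not in relabel:
            relabel[c] = f"G{len(relabel) + 1}"
        assignment[s] = relabel[c]
    return AccessionGroups(assignment, newick, link)


def group_trait_contrast(
    groups: AccessionGroups,
    pheno: PhenotypeTable,
    trait: str,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group trait means/SD plus pairwise Welch tests with BH letters."""
    if pheno.trait_types.get(trait) != "quantitative":
        raise ValueError(f"trait {trait!r} is not quantitative")
    y = pheno.trait(trait)
    by_group: dict[str, np.ndarray] = {}
    names = sorted(set(groups.assignment.values()))
    for gname in names:
        vals = y.reindex(groups.members(gname)).dropna().to_numpy(dtype=float)
        by_group[gname] = vals
    return group_contrast_table(by_group, alpha=alpha)
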