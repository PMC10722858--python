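"""From per-SNP association results to reporting units.

A "locus" is a maximal run of adjacent significant SNPs on one chromosome in
which every consecutive pair is closer than the clump gap (default 1 Mb) and
which contains at least the minimum number of SNPs (default 5); its lead SNP
is the most significant member. Hotspots are genomic bins whose lead-SNP
signal count exceeds a permutation-derived threshold under uniform random
assignment of all signals to bins. Co-localization pairs a metabolite locus
with a phenotype locus when their lead SNPs are close or their intervals
intersect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantgen import AssociationResult


@dataclass
class SigSnp:
    chrom: str
    pos: int
    id: str
    p: float


@dataclass
class Locus:
    trait: str
    chrom: str
    start: int
    end: int
    members: list[SigSnp]
    lead: SigSnp

    @property
    def n_snps(self) -> int:
        return len(self.members)


def threshold_significant(
    res: AssociationResult, alpha_per_test: float
) -> list[SigSnp]:
    """SNPs with P <= alpha_per_test (inclusive at the threshold)."""
    if not (0.0 < alpha_per_test < 1.0):
        raise ValueError(f"alpha_per_test must be in (0,1), got {alpha_per_test}")
    keep = res.p <= alpha_per_test
    return [
        SigSnp(str(res.chroms[i]), int(res.positions[i]), res.snp_ids[i], float(res.p[i]))
        for i in np.where(keep)[0]
    ]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


def clump_loci(
    sig: list[SigSnp],
    gap_bp: int = 1_000_000,
    min_snps: int = 5,
    trait: str = "",
) -> tuple[list[Locus], list[SigSnp]]:
    """Group adjacent significant SNPs (< gap_bp apart) into loci.

    Runs shorter than min_snps are returned in the remainder list. The lead
    SNP is the smallest-P member, ties broken by smaller position. Input must
    be position-sorted within each chromosome.
    """
    by_chrom: dict[str, list[SigSnp]] = {}
    for s in sig:
        by_chrom.setdefault(s.chrom, []).append(s)
    loci: list[Locus] = []
    remainder: list[SigSnp] = []
    for chrom in by_chrom:
        snps = by_chrom[chrom]
        pos = [s.pos for s in snps]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"significant SNPs unsorted on {chrom}; sort by position")
        run: list[SigSnp] = []
        for s in snps:
            if run and s.pos - run[-1].pos >= gap_bp:
                _close_run(run, min_snps, trait, loci, remainder)
                run = []
            run.append(s)
        _close_run(run, min_snps, trait, loci, remainder)
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci, remainder


def _close_run(run, min_snps, trait, loci, remainder):
    if not run:
        return
    if len(run) >= min_snps:
        lead = min(run, key=lambda s: (s.p, s.pos))
        loci.append(
            Locus(trait, run[0].chrom, run[0].pos, run[-1].pos, list(run), lead)
        )
    else:
        remainder.extend(run)


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": l.trait,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "n_snps": l.n_snps,
                "lead_id": l.lead.id,
                "lead_pos": l.lead.pos,
                "lead_p": l.lead.p,
            }
            for l in loci
        ],
        columns=[
            "trait", "chrom", "start", "end", "n_snps", "lead_id", "lead_pos", "lead_p",
        ],
    )


@dataclass
class ReplicateIntersection:
    matched: list[tuple[Locus, Locus]]
    only_rep1: list[Locus]
    only_rep2: list[Locus]

    @property
    def matched_metabolites(self) -> set[str]:
        return {a.trait for a, _ in self.matched}


def intersect_replicates(
    loci_rep1: list[Locus], loci_rep2: list[Locus], match_bp: int = 0
) -> ReplicateIntersection:
    """Match lead SNPs across two replicate locus lists.

    A pair matches when trait and chromosome agree and the lead positions
    differ by at most match_bp (0 = exact). Each locus matches at most once
    (greedy by position order).
    """
    used = np.zeros(len(loci_rep2), dtype=bool)
    matched = []
    only1 = []
    for a in loci_rep1:
        best = None
        for j, b in enumerate(loci_rep2):
            if used[j] or b.trait != a.trait or b.chrom != a.chrom:
                continue
            d = abs(b.lead.pos - a.lead.pos)
            if d <= match_bp and (best is None or d < best[0]):
                best = (d, j)
        if best is None:
            only1.append(a)
        else:
            used[best[1]] = True
            matched.append((a, loci_rep2[best[1]]))
    only2 = [b for j, b in enumerate(loci_rep2) if not used[j]]
    return ReplicateIntersection(matched, only1, only2)


# ---------------------------------------------------------------- hotspots


@dataclass
class HotspotTable:
    data: pd.DataFrame  # chrom, bin_start, bin_end, count, threshold, flagged
    threshold: int
    n_perm: int
    alpha: float
    bin_bp: int
    seed: int


def _genome_bins(genome: dict[str, int], bin_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.items():
        n_bins = max(1, int(np.ceil(length / bin_bp)))
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b * bin_bp + 1,
                    "bin_end": min((b + 1) * bin_bp, length),
                }
            )
    return pd.DataFrame(rows)


def detect_hotspots(
    signals: list[tuple[str, int]],
    genome: dict[str, int],
    bin_bp: int = 1_000_000,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> HotspotTable:
    """Permutation test for signal enrichment per genomic bin.

    Each permutation re-assigns all S signals independently and uniformly over
    the B equal-width bins; the null count distribution is pooled over bins and
    permutations; the threshold is the smallest c with
    Pr_null(count >= c) < alpha, and bins with observed count >= c are flagged.
    The last (partial) bin per chromosome is kept and treated as full-width.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    bins = _genome_bins(genome, bin_bp)
    n_bins = len(bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    bin_index: dict[tuple[str, int], int] = {}
    for i, row in bins.iterrows():
        bin_index[(row["chrom"], (row["bin_start"] - 1) // bin_bp)] = i
    for chrom, pos in signals:
        if chrom not in genome:
            raise ValueError(f"signal on unknown chromosome {chrom!r}")
        key = (chrom, (pos - 1) // bin_bp)
        if key not in bin_index:
            raise ValueError(f"signal at {chrom}:{pos} beyond chromosome length")
        counts[bin_index[key]] += 1
    s_total = len(signals)
    if s_total == 0:
        df = bins.assign(count=0, threshold=0, flagged=False)
        return HotspotTable(df, 0, n_perm, alpha, bin_bp, seed)

    rng = np.random.default_rng(seed)
    max_c = int(counts.max()) + 1
    # pooled null histogram of per-bin counts over permutations
    hist = np.zeros(s_total + 1, dtype=np.int64)
    for _ in range(n_perm):
        assign = rng.integers(0, n_bins, size=s_total)
        perm_counts = np.bincount(assign, minlength=n_bins)
        h = np.bincount(perm_counts, minlength=s_total + 1)
        hist += h
    total = hist.sum()
    tail = np.cumsum(hist[::-1])[::-1] / total  # Pr(count >= c)
    exceed = np.where(tail < alpha)[0]
    threshold = int(exceed[0]) if exceed.size else s_total + 1
    flagged = counts >= threshold
    df = bins.assign(count=counts, threshold=threshold, flagged=flagged)
    return HotspotTable(df, threshold, n_perm, alpha, bin_bp, seed)


# ---------------------------------------------------------------- co-localization


@dataclass
class ColocPair:
    metabolite_locus: Locus
    phenotype_locus: Locus
    distance_bp: int
    overlap_type: str  # lead-within-window | interval-intersect


def colocalize(
    m_loci: list[Locus], p_loci: list[Locus], window_bp: int = 1_000_000
) -> list[ColocPair]:
    """Report metabolite/phenotype locus pairs that co-locate.

    A pair is reported when the lead SNPs are on the same chromosome and at
    most window_bp apart, or when the locus intervals intersect.
    """
    out = []
    for ml in m_loci:
        for pl in p_loci:
            if ml.chrom != pl.chrom:
                continue
            dist = abs(ml.lead.pos - pl.lead.pos)
            intersects = ml.start <= pl.end and pl.start <= ml.end
            if dist <= window_bp:
                out.append(ColocPair(ml, pl, dist, "lead-within-window"))
            elif intersects:
                out.append(ColocPair(ml, pl, dist, "interval-intersect"))
    return out


def coloc_to_frame(pairs: list[ColocPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": c.metabolite_locus.trait,
                "m_chrom": c.metabolite_locus.chrom,
                "m_lead_pos": c.metabolite_locus.lead.pos,
                "phenotype": c.phenotype_locus.trait,
                "p_lead_pos": c.phenotype_locus.lead.pos,
                "distance_bp": c.distance_bp,
                "overlap_type": c.overlap_type,
            }
            for c in pairs
        ],
        columns=[
            "metabolite", "m_chrom", "m_lead_pos", "phenotype", "p_lead_pos",
            "distance_bp", "overlap_type",
        ],
    )
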