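"""Domestication analytics.

A metabolite is called domestication-associated (DAM) when, in every one of
R random 5-vs-5 cultivated-vs-wild comparisons, its PLS-DA variable
importance in projection is >= 1 and its raw-scale fold-change (cultivated /
wild) is >= 1.5 or <= 1/1.5 with a consistent direction. Windowed nucleotide
diversity (pi) in sliding windows contrasts cultivated against wild to expose
selective sweeps, and per-SNP group allele frequencies quantify allele
turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CULTIVATED, MISSING, WILD, GenotypeMatrix, MetaboliteMatrix, PopulationLabels

# ---------------------------------------------------------------- PLS-DA VIP


@dataclass
class VipScores:
    vip: np.ndarray
    n_components: int  # components actually fitted

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.vip, dtype=dtype)

    def __len__(self):
        return len(self.vip)


def pls_da_vip(
    X: np.ndarray, classes: np.ndarray, n_components: int = 2
) -> VipScores:
    """VIP scores from a PLS1 (NIPALS) fit of a binary class indicator.

    X (samples × variables) is centered and unit-scaled internally (constant
    columns are left centered only); y is the centered 0/1 class indicator.
    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with unit-norm
    weight vectors w_a and SSY_a the y-variance captured by component a, so
    mean(VIP^2) = 1 by construction. Components stop early if the residual X
    or y variance vanishes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(classes, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X/classes shape mismatch")
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds model rank {max_rank}"
        )
    if n_components < 1:
        raise ValueError("need at least one PLS component")

    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    E = Xc / scale
    f = y - y.mean()

    weights = []
    ssy = []
    for _ in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pload = (E.T @ t) / tt
        q = float(f @ t) / tt
        ssy_a = q * q * tt  # y-variation captured by this component
        if ssy_a < 1e-14:
            break
        E = E - np.outer(t, pload)
        f = f - q * t
        weights.append(w)
        ssy.append(ssy_a)
    if not weights:
        # no class-related variation at all: VIPs are uniformly 1
        return VipScores(np.ones(p), 0)
    W = np.stack(weights, axis=0)  # (A, p)
    ssy_arr = np.asarray(ssy)
    vip = np.sqrt(p * (ssy_arr @ (W**2)) / ssy_arr.sum())
    return VipScores(vip, len(weights))


# ---------------------------------------------------------------- fold change


def fold_change(X_raw: np.ndarray, classes: np.ndarray) -> pd.DataFrame:
    """Raw-scale fold-change per variable: mean(class 1) / mean(class 0).

    Class 1 is cultivated by convention. FC >= 1.5 or <= 1/1.5 flags the
    variable (boundary inclusive); a zero wild mean with nonzero cultivated
    mean gives FC = +inf flagged with direction up.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    cls = np.asarray(classes).astype(bool)
    if cls.all() or (~cls).all():
        raise ValueError("both classes required")
    m1 = X_raw[cls].mean(axis=0)
    m0 = X_raw[~cls].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(m0 > 0, m1 / m0, np.where(m1 > 0, np.inf, np.nan))
    flagged = (fc >= 1.5) | (fc <= 1 / 1.5)
    flagged = np.where(np.isnan(fc), False, flagged)
    direction = np.where(fc >= 1.0, "up-in-cultivated", "down-in-cultivated")
    return pd.DataFrame({"fc": fc, "flagged": flagged, "direction": direction})


# ---------------------------------------------------------------- DAM classifier


@dataclass
class DamDecision:
    metabolites: list[str]
    per_repeat_flag: np.ndarray  # (n_metabolites, repeats) bool
    per_repeat_direction: np.ndarray  # (n_metabolites, repeats) of {+1,-1}
    is_dam: np.ndarray  # bool
    direction: np.ndarray  # 'up-in-cultivated' / 'down-in-cultivated' / ''

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.metabolites,
                "n_flagged": self.per_repeat_flag.sum(axis=1),
                "is_dam": self.is_dam,
                "direction": self.direction,
            }
        )


def dam_classifier(
    m: MetaboliteMatrix,
    labels: PopulationLabels,
    n_sub: int = 5,
    repeats: int = 10,
    vip_min: float = 1.0,
    fc_min: float = 1.5,
    n_components: int = 2,
    seed: int = 0,
) -> DamDecision:
    """Repeated random 5-vs-5 PLS-DA/fold-change screen for DAMs.

    Each repeat draws n_sub cultivated accessions without replacement (fresh
    draw each repeat, seeded) against the full wild set, computes VIP on log2
    intensities and fold-change on the raw scale, and flags metabolites with
    VIP >= vip_min and FC >= fc_min or <= 1/fc_min. A metabolite is a DAM iff
    flagged in every repeat with the same direction.
    """
    cult = [s for s in m.samples if labels.labels.get(s) == CULTIVATED]
    wild = [s for s in m.samples if labels.labels.get(s) == WILD]
    if len(cult) < n_sub:
        raise ValueError(f"need >= {n_sub} cultivated accessions, have {len(cult)}")
    if not wild:
        raise ValueError("no wild accessions")
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(m.samples)}
    wild_idx = np.array([idx[s] for s in wild])
    raw_means = m.replicate_means()
    log_means = np.log2(raw_means + 1.0) if m.transform == "raw" else raw_means

    nm = len(m.metabolites)
    flags = np.zeros((nm, repeats), dtype=bool)
    dirs = np.zeros((nm, repeats), dtype=np.int8)
    for rep in range(repeats):
        pick = rng.choice(len(cult), size=n_sub, replace=False)
        cult_idx = np.array([idx[cult[i]] for i in pick])
        rows = np.concatenate([wild_idx, cult_idx])
        cls = np.concatenate([np.zeros(len(wild_idx)), np.ones(n_sub)])
        a_use = min(n_components, len(rows) - 1, nm)
        vip = pls_da_vip(log_means[rows], cls, n_components=a_use)
        fc = fold_change(raw_means[rows], cls)
        fcv = fc["fc"].to_numpy()
        flag = (np.asarray(vip) >= vip_min) & (
            (fcv >= fc_min) | (fcv <= 1.0 / fc_min)
        )
        flag &= ~np.isnan(fcv)
        flags[:, rep] = flag
        dirs[:, rep] = np.where(fcv >= 1.0, 1, -1)
    all_flagged = flags.all(axis=1)
    consistent = (dirs == dirs[:, [0]]).all(axis=1)
    is_dam = all_flagged & consistent
    direction = np.where(
        is_dam,
        np.where(dirs[:, 0] > 0, "up-in-cultivated", "down-in-cultivated"),
        "",
    )
    return DamDecision(list(m.metabolites), flags, dirs, is_dam, direction)


# ---------------------------------------------------------------- nucleotide diversity


def site_diversity(alt_count: np.ndarray, n_alleles: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity 2 c (n - c) / (n (n - 1))."""
    c = np.asarray(alt_count, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 1, 2.0 * c * (n - c) / (n * (n - 1.0)), 0.0)


def windowed_pi(
    g: GenotypeMatrix,
    labels: PopulationLabels,
    window_bp: int = 80_000,
    step_bp: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window per-bp nucleotide diversity per population.

    Window pi = (sum of per-site diversities in [start, start+window)) /
    window_bp, with every position assumed callable (no accessibility mask).
    Windows start at 1 and slide by step_bp; reported coordinates are 1-based
    inclusive. Returns long-format rows (population, chrom, start, end,
    n_sites, pi).
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    labels.validate_against(g.samples)
    pops = {
        CULTIVATED: [s for s in g.samples if labels.labels.get(s) == CULTIVATED],
        WILD: [s for s in g.samples if labels.labels.get(s) == WILD],
    }
    chroms = g.chroms
    positions = g.positions
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(positions[chroms == c].max()) for c in np.unique(chroms)
        }
    sample_idx = {s: i for i, s in enumerate(g.samples)}
    rows = []
    for pop, members in pops.items():
        if not members:
            continue
        ridx = [sample_idx[s] for s in members]
        calls = g.calls[ridx, :]
        miss = calls == MISSING
        n_alleles = 2 * (~miss).sum(axis=0)
        alt = np.where(miss, 0, calls).sum(axis=0)
        site_pi = site_diversity(alt, n_alleles)
        for chrom, length in sorted(chrom_lengths.items()):
            on = chroms == chrom
            cpos = positions[on]
            cpi = site_pi[on]
            order = np.argsort(cpos)
            cpos, cpi = cpos[order], cpi[order]
            cum = np.concatenate([[0.0], np.cumsum(cpi)])
            start = 1
            while start <= length:
                end_excl = start + window_bp  # half-open [start, end_excl)
                lo = np.searchsorted(cpos, start, side="left")
                hi = np.searchsorted(cpos, end_excl, side="left")
                rows.append(
                    {
                        "population": pop,
                        "chrom": chrom,
                        "start": start,
                        "end": min(end_excl - 1, length),
                        "n_sites": int(hi - lo),
                        "pi": (cum[hi] - cum[lo]) / window_bp,
                    }
                )
                if end_excl > length:
                    break
                start += step_bp
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- allele frequencies


def allele_freq_contrast(
    g: GenotypeMatrix, labels: PopulationLabels
) -> pd.DataFrame:
    """Per-SNP alt-allele frequency in cultivated and wild, and the difference.

    Frequencies are over non-missing calls; a group with zero non-missing
    calls at a SNP gets NaN there (flagged undefined).
    """
    labels.validate_against(g.samples)
    out = {"chrom": g.chroms, "pos": g.positions, "id": [s.id for s in g.snps]}
    freqs = {}
    for pop in (CULTIVATED, WILD):
        members = [s for s in g.samples if labels.labels.get(s) == pop]
        idx = [g.samples.index(s) for s in members]
        calls = g.calls[idx, :]
        miss = calls == MISSING
        n = (~miss).sum(axis=0) * 2
        alt = np.where(miss, 0, calls).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[pop] = np.where(n > 0, alt / n, np.nan)
    out["freq_cultivated"] = freqs[CULTIVATED]
    out["freq_wild"] = freqs[WILD]
    out["difference"] = freqs[CULTIVATED] - freqs[WILD]
    return pd.DataFrame(out)
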