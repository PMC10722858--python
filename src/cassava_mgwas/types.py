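"""Core in-memory containers shared by the whole pipeline.

Conventions: genomic positions are 1-based (VCF style); genotype calls are
additive alt-allele counts in {0, 1, 2} with ``MISSING`` (−1) for no-calls;
metabolite intensities are stored on the raw (non-negative) scale unless the
``transform`` flag says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

CULTIVATED = "cultivated"
WILD = "wild"


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "T"
    id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples × SNPs additive genotype calls.

    ``calls`` is an int8 array of shape (n_samples, n_snps) with entries in
    {0, 1, 2, MISSING}. SNPs are sorted by position within each chromosome.
    """

    samples: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        self._check_sorted()

    def _check_sorted(self):
        last: dict[str, int] = {}
        for s in self.snps:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"SNPs not strictly increasing on {s.chrom} at pos {s.pos}"
                )
            last[s.chrom] = s.pos

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Float copy of the calls with missing entries mean-imputed per SNP.

        Monomorphic all-missing columns impute to 0.
        """
        x = self.calls.astype(np.float64)
        if impute:
            miss = x == MISSING
            if miss.any():
                x[miss] = np.nan
                col_mean = np.nanmean(np.where(miss, np.nan, x), axis=0)
                col_mean = np.nan_to_num(col_mean, nan=0.0)
                idx = np.where(miss)
                x[idx] = col_mean[idx[1]]
        else:
            x[x == MISSING] = np.nan
        return x

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing calls (NaN if none)."""
        x = self.calls.astype(np.float64)
        x[x == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.snps, self.calls[idx, :])

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        snps = [self.snps[i] for i in idx]
        return GenotypeMatrix(self.samples, snps, self.calls[:, idx])


@dataclass
class MetaboliteMatrix:
    """Samples × metabolites × replicates intensity cube.

    ``values`` has shape (n_samples, n_metabolites, n_replicates); raw-scale
    intensities are non-negative. ``transform`` records whether values are on
    the raw or log2 scale so no stage double-transforms.
    """

    samples: list[str]
    metabolites: list[str]
    values: np.ndarray
    transform: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.shape[:2] != (len(self.samples), len(self.metabolites)):
            raise ValueError("values shape inconsistent with sample/metabolite lists")
        if self.transform not in ("raw", "log2"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "raw" and np.nanmin(self.values) < 0:
            raise ValueError("negative raw-scale intensities")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_means(self) -> np.ndarray:
        """(n_samples, n_metabolites) mean over replicates (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=2)

    def to_log2(self, pseudo: float = 1.0) -> "MetaboliteMatrix":
        if self.transform == "log2":
            return self
        return MetaboliteMatrix(
            self.samples, self.metabolites, np.log2(self.values + pseudo), "log2"
        )


@dataclass
class PhenotypeTable:
    """Traits per sample; each trait declared quantitative or categorical."""

    data: pd.DataFrame  # index = samples
    trait_types: dict[str, str] = field(default_factory=dict)  # name -> {quantitative, categorical}

    def __post_init__(self):
        for t in self.data.columns:
            self.trait_types.setdefault(
                t,
                "quantitative"
                if pd.api.types.is_numeric_dtype(self.data[t])
                else "categorical",
            )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown trait {name!r}")
        return self.data[name]


@dataclass
class GeneTable:
    """Minimal gene annotation: id, chrom, 1-based inclusive start/end, strand."""

    data: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if (self.data["start"] > self.data["end"]).any():
            raise ValueError("gene with start > end")
        bad = ~self.data["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be + or -")

    def __iter__(self):
        return iter(self.data.itertuples(index=False))


@dataclass
class PopulationLabels:
    """Sample → population group (cultivated vs wild)."""

    labels: dict[str, str]

    def __post_init__(self):
        bad = {g for g in self.labels.values() if g not in (CULTIVATED, WILD)}
        if bad:
            raise ValueError(f"unknown population groups {sorted(bad)}")

    def group(self, name: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == name]

    @property
    def cultivated(self) -> list[str]:
        return self.group(CULTIVATED)

    @property
    def wild(self) -> list[str]:
        return self.group(WILD)

    def validate_against(self, samples: Sequence[str]) -> None:
        known = set(samples)
        unknown = [s for s in self.labels if s not in known]
        if unknown:
            raise ValueError(f"labelled samples absent from data: {unknown[:5]}")
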