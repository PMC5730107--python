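"""Core data containers shared across the pipeline.

Two tabular panels anchor everything: :class:`FounderPanel` holds phased
homozygous founder-line genotypes, and :class:`AlleleCountPanel` holds pooled
read counts per site and sample (population x sex x generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]
SAMPLE_COLUMNS = ["population", "scheme", "replicate", "sex", "generation"]


@dataclass
class FounderPanel:
    """Biallelic genotypes of fully inbred founder lines.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom``, ``pos``, ``ref``, ``alt``
        (1-based positions, strictly increasing within a chromosome).
    genotypes : numpy.ndarray
        ``(n_lines, n_sites)`` array of 0/1 allele indicators (0 = ref,
        1 = alt).  Lines are haploid-coded because they are homozygous.
    line_names : list of str, optional
        Defaults to ``line_0 .. line_{n-1}``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    line_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (lines x sites) array")
        if self.genotypes.shape[1] != len(self.sites):
            raise ValueError(
                f"genotypes have {self.genotypes.shape[1]} sites but the site "
                f"table has {len(self.sites)}"
            )
        if not set(self.genotypes.ravel()) <= {0, 1}:
            raise ValueError("genotypes must be 0/1 allele indicators")
        if not self.line_names:
            self.line_names = [f"line_{i}" for i in range(self.n_lines)]
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def alt_frequency(self) -> np.ndarray:
        """Across-line alt-allele frequency per site."""
        return self.genotypes.mean(axis=0)

    def polymorphic_mask(self) -> np.ndarray:
        f = self.alt_frequency
        return (f > 0) & (f < 1)


@dataclass
class AlleleCountPanel:
    """Pooled ref/alt read counts per site x sample.

    ``samples`` carries one row per sequenced pool with columns
    ``population``, ``scheme`` (long/short/control), ``replicate``, ``sex``
    and ``generation``.  ``ref_count``/``alt_count`` are integer arrays of
    shape ``(n_sites, n_samples)``.  An optional boolean ``valid`` mask of
    the same shape records coverage-filter decisions; cells start valid.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    ref_count: np.ndarray
    alt_count: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        for name, arr in (("ref_count", self.ref_count), ("alt_count", self.alt_count)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative counts")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != shape:
                raise ValueError("valid mask shape mismatch")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def sample_index(self, population=None, scheme=None, replicate=None,
                     sex=None, generation=None) -> np.ndarray:
        """Positional indices of samples matching all given metadata fields."""
        mask = np.ones(self.n_samples, dtype=bool)
        for col, val in (("population", population), ("scheme", scheme),
                         ("replicate", replicate), ("sex", sex),
                         ("generation", generation)):
            if val is not None:
                mask &= (self.samples[col] == val).to_numpy()
        return np.flatnonzero(mask)

    def copy(self) -> "AlleleCountPanel":
        return AlleleCountPanel(
            sites=self.sites.copy(),
            samples=self.samples.copy(),
            ref_count=self.ref_count.copy(),
            alt_count=self.alt_count.copy(),
            valid=self.valid.copy(),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per site x sample with counts."""
        n_sites, n_samples = self.ref_count.shape
        site_rep = self.sites.loc[self.sites.index.repeat(n_samples)].reset_index(drop=True)
        samp_rep = pd.concat([self.samples] * n_sites, ignore_index=True)
        out = pd.concat([site_rep, samp_rep], axis=1)
        out["ref_count"] = self.ref_count.ravel()
        out["alt_count"] = self.alt_count.ravel()
        return out
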