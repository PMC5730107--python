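"""Founder-line panel generation.

Inbred founder lines are haploid-coded (fully homozygous).  Site
minor-allele frequencies across lines follow a configurable spectrum;
every generated site is polymorphic among the lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..panel import FounderPanel


@dataclass(frozen=True)
class MafSpectrum:
    """Distribution of across-line alt-allele frequencies.

    kinds:
      * ``point``: every site at frequency ``a`` (e.g. 0.5);
      * ``uniform``: frequency uniform on [``a``, ``b``];
      * ``beta``: Beta(``a``, ``b``) draws.

    Frequencies are converted to alt-line counts by rounding, clipped to
    [1, n_lines - 1] so all sites stay biallelic.
    """

    kind: str = "uniform"
    a: float = 0.1
    b: float = 0.9

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            if not 0 < self.a < 1:
                raise ValueError("point-mass frequency must be in (0, 1)")
            return np.full(n, self.a)
        if self.kind == "uniform":
            if not 0 <= self.a < self.b <= 1:
                raise ValueError("uniform spectrum needs 0 <= a < b <= 1")
            return rng.uniform(self.a, self.b, size=n)
        if self.kind == "beta":
            if self.a <= 0 or self.b <= 0:
                raise ValueError("beta spectrum needs positive shape parameters")
            return rng.beta(self.a, self.b, size=n)
        raise ValueError(f"unknown spectrum kind {self.kind!r}")


DEFAULT_CHROMS = ["2L", "2R", "3L", "3R", "X"]


def generate_founder_panel(n_lines: int, n_sites_per_chrom: int,
                           chrom_labels: list[str] | None = None,
                           maf_spectrum: MafSpectrum | None = None,
                           seed: int = 0,
                           chrom_length: int = 20_000_000) -> FounderPanel:
    """Random biallelic panel of homozygous founder lines.

    Positions are sorted uniform draws per chromosome; the number of
    alt-carrying lines at each site is the spectrum frequency times
    ``n_lines``, rounded and clipped to keep the site polymorphic.
    Deterministic given ``seed``.
    """
    if n_lines < 2:
        raise ValueError("need at least two founder lines")
    if n_sites_per_chrom < 1:
        raise ValueError("need at least one site per chromosome")
    chrom_labels = chrom_labels or DEFAULT_CHROMS
    maf_spectrum = maf_spectrum or MafSpectrum()
    rng = np.random.default_rng(seed)

    bases = np.array(list("ACGT"))
    frames = []
    geno_cols = []
    for chrom in chrom_labels:
        pos = np.sort(rng.choice(chrom_length, size=n_sites_per_chrom, replace=False)) + 1
        freqs = maf_spectrum.draw(n_sites_per_chrom, rng)
        n_alt = np.clip(np.rint(freqs * n_lines).astype(int), 1, n_lines - 1)
        ref = bases[rng.integers(0, 4, size=n_sites_per_chrom)]
        alt_shift = rng.integers(1, 4, size=n_sites_per_chrom)
        alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        }))
        block = np.zeros((n_lines, n_sites_per_chrom), dtype=np.uint8)
        for s in range(n_sites_per_chrom):
            carriers = rng.choice(n_lines, size=n_alt[s], replace=False)
            block[carriers, s] = 1
        geno_cols.append(block)

    sites = pd.concat(frames, ignore_index=True)
    genotypes = np.concatenate(geno_cols, axis=1)
    return FounderPanel(sites=sites, genotypes=genotypes)
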