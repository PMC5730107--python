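"""Linkage disequilibrium on phased founder lines and its persistence
under pooled data via minor-allele-frequency bounds.

r^2 is computed directly on founder haplotypes (gametic phase known for
inbred lines).  For pooled generations, where haplotypes are unknown, a
pair is called "still in high LD" when the second site's minor frequency
falls inside the closed-form admissible interval implied by the first
site's binned minor frequency and the r^2 floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import FounderPanel


def r2_phased(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared allelic correlation between two sites on phased haplotypes.

    ``hap_a``/``hap_b`` are 0/1 vectors over the same lines.  Undefined
    (raises) if either site is monomorphic.
    """
    hap_a = np.asarray(hap_a, dtype=float)
    hap_b = np.asarray(hap_b, dtype=float)
    if hap_a.shape != hap_b.shape or hap_a.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and aligned")
    if hap_a.size < 2:
        raise ValueError("need at least two lines")
    pa = hap_a.mean()
    pb = hap_b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r^2 undefined at a monomorphic site")
    pab = (hap_a * hap_b).mean()
    D = pab - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def vanliere_bounds(p_a: float, r2_min: float = 0.8) -> tuple[float, float]:
    """Admissible minor-frequency interval at the partner site.

    Given minor frequency ``p_a`` at site A, the partner frequency p_b
    compatible with r^2 >= ``r2_min`` lies in
    ``[r2*p_a / (1 + r2*p_a - p_a),  min(p_a / (r2 - r2*p_a + p_a), 0.5)]``.
    At ``r2_min = 1`` the interval degenerates to ``p_a`` itself.
    """
    if not 0 < p_a <= 0.5:
        raise ValueError("p_a must lie in (0, 0.5]")
    if not 0 < r2_min <= 1:
        raise ValueError("r2_min must lie in (0, 1]")
    lower = r2_min * p_a / (1.0 + r2_min * p_a - p_a)
    upper = min(p_a / (r2_min - r2_min * p_a + p_a), 0.5)
    return float(lower), float(upper)


def fold_minor(freq: np.ndarray) -> np.ndarray:
    """Fold frequencies above 0.5 onto the minor-allele scale."""
    freq = np.asarray(freq, dtype=float)
    return np.minimum(freq, 1.0 - freq)


def bin_frequency(freq: float) -> float:
    """Fold to minor orientation and floor to the 0.01 grid."""
    return float(np.floor(fold_minor(freq) * 100.0) / 100.0)


@dataclass
class PairSet:
    """Unordered pairs among a site sample, with founder r^2 on demand.

    ``site_idx`` are positions into the panel's site table; pairs are all
    n(n-1)/2 unordered combinations.  r^2 is computed lazily because the
    full pair table can be enormous (18,000 sites -> ~1.6e8 pairs).
    """

    panel: FounderPanel
    site_idx: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.site_idx.size

    @property
    def n_pairs(self) -> int:
        n = self.n_sites
        return n * (n - 1) // 2

    def iter_pairs(self):
        idx = self.site_idx
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                yield int(idx[i]), int(idx[j])

    def r2_table(self, max_pairs: int = 5_000_000) -> pd.DataFrame:
        """All pairs with founder r^2, as a DataFrame (site_a is the lower
        genomic position within a chromosome; cross-chromosome pairs keep
        index order).  Refuses to materialize beyond ``max_pairs``."""
        if self.n_pairs > max_pairs:
            raise ValueError(
                f"{self.n_pairs} pairs exceed max_pairs={max_pairs}; "
                "compute on a smaller sample or raise the cap"
            )
        geno = self.panel.genotypes[:, self.site_idx].astype(float)
        n = self.n_sites
        centered = geno - geno.mean(axis=0)
        denom = np.sqrt((centered ** 2).sum(axis=0))
        poly = denom > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            normed = np.where(poly, 1.0, np.nan) * centered / np.where(denom > 0, denom, 1.0)
        corr = normed.T @ normed
        iu, ju = np.triu_indices(n, k=1)
        sites = self.panel.sites
        ia = self.site_idx[iu]
        ib = self.site_idx[ju]
        # orient: site A = lower position (within-chromosome ordering)
        pos = sites["pos"].to_numpy()
        swap = pos[ia] > pos[ib]
        site_a = np.where(swap, ib, ia)
        site_b = np.where(swap, ia, ib)
        return pd.DataFrame({
            "site_a": site_a,
            "site_b": site_b,
            "chrom_a": sites["chrom"].to_numpy()[site_a],
            "chrom_b": sites["chrom"].to_numpy()[site_b],
            "pos_a": pos[site_a],
            "pos_b": pos[site_b],
            "r2": corr[iu, ju] ** 2,
        })


def sample_snp_pairs(panel: FounderPanel, n_per_chrom: int = 3600,
                     seed: int = 0) -> PairSet:
    """Randomly sample polymorphic sites per chromosome and enumerate all
    unordered pairs across the whole sample (cross-chromosome included)."""
    rng = np.random.default_rng(seed)
    poly = panel.polymorphic_mask()
    chosen = []
    for chrom in panel.sites["chrom"].unique():
        on_chrom = np.flatnonzero((panel.sites["chrom"] == chrom).to_numpy() & poly)
        if on_chrom.size < n_per_chrom:
            raise ValueError(
                f"chromosome {chrom} has {on_chrom.size} polymorphic sites, "
                f"fewer than the requested {n_per_chrom}"
            )
        chosen.append(rng.choice(on_chrom, size=n_per_chrom, replace=False))
    return PairSet(panel=panel, site_idx=np.sort(np.concatenate(chosen)))


def ld_persistence(pairs: pd.DataFrame, freqs: pd.DataFrame,
                   r2_min: float = 0.8, symmetric: bool = False) -> pd.DataFrame:
    """Count pairs still compatible with high LD per population x generation.

    ``pairs`` is an r2-table subset (founder pairs with r^2 >= ``r2_min``);
    ``freqs`` is long-format with columns ``site``, ``population``,
    ``generation``, ``freq`` (minor orientation not required; folded here).
    A pair is retained when p_b lies inside the bound interval of binned
    p_a; with ``symmetric=True`` the A<->B check is also accepted.
    Returns per population x generation: ``n_retained``, ``n_tested`` and
    the mean intra-chromosome distance among retained pairs.
    """
    if len(freqs) == 0 or len(pairs) == 0:
        return pd.DataFrame(columns=["population", "generation", "n_tested",
                                     "n_retained", "mean_distance"])
    freq_lookup = {
        (row.site, row.population, row.generation): row.freq
        for row in freqs.itertuples()
    }

    def retained(pa: float, pb: float) -> bool:
        pa_bin = bin_frequency(pa)
        if pa_bin < 0.01:
            return False
        lo, hi = vanliere_bounds(pa_bin, r2_min)
        return lo <= fold_minor(pb) <= hi

    rows = []
    groups = freqs[["population", "generation"]].drop_duplicates()
    for pop, gen in groups.itertuples(index=False):
        n_ret = n_test = 0
        dists = []
        for pr in pairs.itertuples():
            fa = freq_lookup.get((pr.site_a, pop, gen))
            fb = freq_lookup.get((pr.site_b, pop, gen))
            if fa is None or fb is None:
                continue
            n_test += 1
            keep = retained(fa, fb) or (symmetric and retained(fb, fa))
            if keep:
                n_ret += 1
                if pr.chrom_a == pr.chrom_b:
                    dists.append(abs(pr.pos_b - pr.pos_a))
        rows.append({
            "population": pop, "generation": gen,
            "n_tested": n_test, "n_retained": n_ret,
            "mean_distance": float(np.mean(dists)) if dists else np.nan,
        })
    return pd.DataFrame(rows)
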