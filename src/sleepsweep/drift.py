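"""Effective population size and drift-threshold simulation.

Variance Ne is estimated from the spread of control-population allele
frequencies around their starting values; forward binomial Wright-Fisher
simulation then yields, per starting minor-allele frequency, the 99.9%
quantile of the |mean(short pair) - mean(long pair)| statistic expected
under drift alone.  Candidates whose observed scheme divergence exceeds
the threshold at their frequency bin are flagged as beyond drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def estimate_ne(q0: float, var_qt: float, t: int) -> float:
    """Variance effective size: Ne = -t / (2 ln(1 - var/(q0(1-q0)))).

    NaN when the variance is zero (no drift signal -> infinite Ne) or at
    or beyond the binomial maximum q0(1-q0) (complete dispersal).
    """
    if not 0 < q0 < 1:
        raise ValueError("q0 must be strictly inside (0, 1)")
    if t <= 0:
        raise ValueError("t must be positive")
    vmax = q0 * (1 - q0)
    if var_qt <= 0 or var_qt >= vmax:
        return float("nan")
    return float(-t / (2.0 * np.log(1.0 - var_qt / vmax)))


@dataclass
class NeEstimate:
    per_bin: pd.DataFrame  # columns: bin_center, n_sites, var_qt, ne
    median_ne: float
    t: int


def binned_ne(q0: np.ndarray, qt: np.ndarray, t: int,
              bin_edges: np.ndarray | None = None) -> NeEstimate:
    """Bin sites by starting frequency and estimate Ne per bin.

    ``q0``/``qt`` are per-site minor-allele frequencies at generation 0
    and generation ``t``.  Default bins span 0.05-0.50 in 0.05 steps; the
    per-bin variance of ``qt`` across sites feeds :func:`estimate_ne` at
    the bin center, and the median over defined bins is reported.
    """
    q0 = np.asarray(q0, dtype=float)
    qt = np.asarray(qt, dtype=float)
    if q0.shape != qt.shape:
        raise ValueError("q0 and qt must align")
    ok = np.isfinite(q0) & np.isfinite(qt)
    q0, qt = q0[ok], qt[ok]
    if bin_edges is None:
        bin_edges = np.arange(0.05, 0.5001, 0.05)
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        inbin = (q0 >= lo) & (q0 < hi if hi < bin_edges[-1] else q0 <= hi)
        n = int(inbin.sum())
        if n < 2:
            continue
        center = (lo + hi) / 2.0
        var = float(np.var(qt[inbin], ddof=1))
        rows.append({"bin_center": center, "n_sites": n, "var_qt": var,
                     "ne": estimate_ne(center, var, t)})
    per_bin = pd.DataFrame(rows, columns=["bin_center", "n_sites", "var_qt", "ne"])
    defined = per_bin["ne"].dropna()
    median = float(defined.median()) if len(defined) else float("nan")
    return NeEstimate(per_bin=per_bin, median_ne=median, t=t)


def _copy_number(ne_diploids: int, chrom_mode: str) -> int:
    if chrom_mode == "autosome":
        return 2 * ne_diploids
    if chrom_mode == "X":
        # males carry one X: 2 copies per female + 1 per male, with an
        # equal sex ratio -> 1.5 copies per diploid, rounded to an integer
        return int(round(1.5 * ne_diploids))
    raise ValueError("chrom_mode must be 'autosome' or 'X'")


def _wright_fisher_final(q0: float, copies: int, t: int, shape: tuple,
                         rng: np.random.Generator) -> np.ndarray:
    q = np.full(shape, q0, dtype=float)
    for _ in range(t):
        q = rng.binomial(copies, q) / copies
    return q


def simulate_drift_bound(q0: float, ne_diploids: int, t: int = 12,
                         n_reps: int = 10_000, quantile: float = 0.999,
                         chrom_mode: str = "autosome",
                         seed: int | np.random.Generator = 0) -> float:
    """Drift-only upper bound on the long/short scheme divergence.

    Each rep runs four independent binomial Wright-Fisher trajectories
    (two per scheme) from ``q0`` for ``t`` generations at the chromosome's
    allele copy number; the statistic is |mean of the two short finals -
    mean of the two long finals| and the requested quantile across reps is
    returned.
    """
    if not 0 <= q0 <= 0.5:
        raise ValueError("q0 must lie in [0, 0.5] (minor orientation)")
    if ne_diploids < 1:
        raise ValueError("ne_diploids must be >= 1")
    if q0 == 0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    copies = _copy_number(ne_diploids, chrom_mode)
    finals = _wright_fisher_final(q0, copies, t, (n_reps, 4), rng)
    statistic = np.abs(finals[:, :2].mean(axis=1) - finals[:, 2:].mean(axis=1))
    return float(np.quantile(statistic, quantile))


@dataclass
class DriftThresholdTable:
    """99.9%-quantile drift bounds per 0.01 starting-frequency bin."""

    table: pd.DataFrame  # columns: q0, threshold
    ne_diploids: int
    t: int
    n_reps: int
    quantile: float
    chrom_mode: str
    seed: int

    def threshold_for(self, q0: float) -> float:
        """Threshold at the bin of ``q0`` (folded to minor orientation,
        floored to the 0.01 grid; frequencies below 0.01 get bound 0)."""
        if not np.isfinite(q0):
            return float("nan")
        q = min(q0, 1.0 - q0)
        binned = np.floor(q * 100.0) / 100.0
        if binned < 0.01:
            return 0.0
        row = self.table.loc[np.isclose(self.table["q0"], min(binned, 0.5))]
        return float(row["threshold"].iloc[0])


def drift_threshold_table(ne_diploids: int, t: int = 12, n_reps: int = 10_000,
                          quantile: float = 0.999, chrom_mode: str = "autosome",
                          seed: int = 0) -> DriftThresholdTable:
    """Thresholds for starting minor frequencies 0.01..0.50 (0.01 steps)."""
    rng = np.random.default_rng(seed)
    q0s = np.round(np.arange(0.01, 0.5001, 0.01), 2)
    thresholds = [
        simulate_drift_bound(q0, ne_diploids, t=t, n_reps=n_reps,
                             quantile=quantile, chrom_mode=chrom_mode, seed=rng)
        for q0 in q0s
    ]
    return DriftThresholdTable(
        table=pd.DataFrame({"q0": q0s, "threshold": thresholds}),
        ne_diploids=ne_diploids, t=t, n_reps=n_reps, quantile=quantile,
        chrom_mode=chrom_mode, seed=seed,
    )


def drift_verdict(candidates: pd.DataFrame,
                  tables: dict[str, DriftThresholdTable] | DriftThresholdTable,
                  x_chroms: set[str] | None = None) -> pd.DataFrame:
    """Flag candidates whose observed |short - long| divergence exceeds the
    drift bound at their starting-frequency bin.

    ``candidates`` needs columns ``q0`` (generation-0 minor frequency),
    ``divergence`` (final-generation |mean short - mean long|) and,
    when per-chromosome tables are supplied, ``chrom``.  Returns the frame
    with ``threshold`` and ``exceeds_drift`` columns appended; rows with a
    missing divergence get a missing verdict.
    """
    out = candidates.copy()
    x_chroms = x_chroms or set()

    def pick(chrom) -> DriftThresholdTable:
        if isinstance(tables, DriftThresholdTable):
            return tables
        return tables["X" if chrom in x_chroms else "autosome"]

    thresholds, exceeds = [], []
    for _, row in out.iterrows():
        tab = pick(row.get("chrom"))
        thr = tab.threshold_for(row["q0"])
        thresholds.append(thr)
        if not np.isfinite(row["divergence"]) or not np.isfinite(thr):
            exceeds.append(None)
        else:
            exceeds.append(bool(row["divergence"] > thr))
    out["threshold"] = thresholds
    out["exceeds_drift"] = exceeds
    return out
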