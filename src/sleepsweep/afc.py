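"""Allele-frequency-change detection on pooled count panels.

Stages, in pipeline order: minor/major allele calling against a reference
generation, per-cell coverage filtering, Beta-posterior HPD intervals for
read allele proportions, Cochran-Mantel-Haenszel tests per generation pair
(stratified by sex pool), Bonferroni thresholding, a control-overlap
filter, and a grouped-binomial logistic filter on candidate trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .panel import AlleleCountPanel

DEFAULT_GENERATION_PAIRS = [(0, 1), (1, 2), (2, 5), (5, 8), (8, 10), (10, 12)]
# The source study's printed genome-wide threshold; not recomputed here
# because it does not exactly equal 0.05 / any of its printed site counts.
PUBLISHED_ALPHA = 2.3e-8


# ---------------------------------------------------------------------------
# minor-allele definition
# ---------------------------------------------------------------------------

@dataclass
class MinorAssignment:
    """Which allele is minor at each site, plus minor-allele frequencies.

    ``alt_is_minor`` is per-site (ties broken toward the alt allele);
    ``deferred`` flags sites with zero total reads at the reference
    generation, whose assignment defaults to alt-as-minor but should not
    be trusted.  ``minor_freq`` is per site x sample, NaN where a sample
    has zero coverage.
    """

    alt_is_minor: np.ndarray
    deferred: np.ndarray
    minor_freq: np.ndarray
    reference_generation: int


def define_minor_allele(panel: AlleleCountPanel,
                        reference_generation: int = 0) -> MinorAssignment:
    """Call the minor allele from counts summed across all populations
    at the reference generation, then express every sample's frequency on
    the minor-allele scale."""
    ref_idx = panel.sample_index(generation=reference_generation)
    if ref_idx.size == 0:
        raise ValueError(f"no samples at generation {reference_generation}")
    ref_sum = panel.ref_count[:, ref_idx].sum(axis=1)
    alt_sum = panel.alt_count[:, ref_idx].sum(axis=1)
    alt_is_minor = alt_sum <= ref_sum  # tie -> alt
    deferred = (ref_sum + alt_sum) == 0

    minor = np.where(alt_is_minor[:, None], panel.alt_count, panel.ref_count)
    total = panel.total
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, minor / total, np.nan)
    return MinorAssignment(alt_is_minor=alt_is_minor, deferred=deferred,
                           minor_freq=freq,
                           reference_generation=reference_generation)


def minor_counts(panel: AlleleCountPanel, assignment: MinorAssignment) -> np.ndarray:
    return np.where(assignment.alt_is_minor[:, None], panel.alt_count, panel.ref_count)


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------

def coverage_filter(panel: AlleleCountPanel, min_total: int = 10,
                    max_total: int = 2000) -> AlleleCountPanel:
    """Invalidate site x sample cells with total coverage outside
    [min_total, max_total] (both bounds inclusive: totals of exactly 10
    or 2000 are retained).  Counts are kept; downstream tests skip any
    site whose required cells are invalid."""
    if min_total <= 0 or max_total <= min_total:
        raise ValueError("need 0 < min_total < max_total")
    out = panel.copy()
    total = out.total
    out.valid &= (total >= min_total) & (total <= max_total)
    return out


# ---------------------------------------------------------------------------
# HPD interval for a binomial proportion
# ---------------------------------------------------------------------------

def allele_hpd_interval(minor_count: int, total: int, mass: float = 0.95,
                        prior: tuple[float, float] = (0.5, 0.5)) -> tuple[float, float]:
    """Shortest (highest-posterior-density) credible interval for the read
    allele proportion under a Beta posterior with a Jeffreys prior.

    With a boundary posterior mode (shape parameter <= 1) the interval is
    one-sided from the corresponding boundary.
    """
    if total < 1:
        raise ValueError("total coverage must be >= 1")
    if not 0 <= minor_count <= total:
        raise ValueError("minor_count must lie in [0, total]")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    a = prior[0] + minor_count
    b = prior[1] + total - minor_count
    post = stats.beta(a, b)
    if a <= 1 and b <= 1:  # bimodal/flat posterior: fall back to central
        return float(post.ppf((1 - mass) / 2)), float(post.ppf((1 + mass) / 2))
    if a <= 1:  # mode at 0
        return 0.0, float(post.ppf(mass))
    if b <= 1:  # mode at 1
        return float(post.ppf(1 - mass)), 1.0

    def width(lower_tail: float) -> float:
        return post.ppf(lower_tail + mass) - post.ppf(lower_tail)

    res = optimize.minimize_scalar(width, bounds=(1e-12, 1 - mass - 1e-12),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    lo = float(post.ppf(res.x))
    hi = float(post.ppf(res.x + mass))
    return lo, hi


# ---------------------------------------------------------------------------
# CMH test
# ---------------------------------------------------------------------------

def cmh_test(tables) -> tuple[float, float]:
    """Mantel-Haenszel chi-square (1 df, no continuity correction) for K
    stratified 2x2 tables.

    ``tables`` is ``(K, 2, 2)``: rows = allele (minor, major), columns =
    generation (g1, g2).  All-zero strata and strata with a single
    observation are dropped.  Returns ``(statistic, p_value)``.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 2:
        tables = tables[None]
    if tables.ndim != 3 or tables.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    if (tables < 0).any():
        raise ValueError("cell counts cannot be negative")
    a = tables[:, 0, 0]
    b = tables[:, 0, 1]
    c = tables[:, 1, 0]
    d = tables[:, 1, 1]
    T = a + b + c + d
    keep = T > 1
    if not keep.any():
        raise ValueError("no usable strata")
    a, b, c, d, T = (x[keep] for x in (a, b, c, d, T))
    expect = (a + b) * (a + c) / T
    var = (a + b) * (c + d) * (a + c) * (b + d) / (T ** 2 * (T - 1))
    vsum = var.sum()
    if vsum == 0:
        return 0.0, 1.0
    stat = (a - expect).sum() ** 2 / vsum
    return float(stat), float(stats.chi2.sf(stat, 1))


def _cmh_vectorized(minor: np.ndarray, major: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CMH across sites.  ``minor``/``major`` have shape (n_sites, K, 2):
    stratum by generation-column counts.  Returns (stat, p) per site."""
    a = minor[:, :, 0]
    b = minor[:, :, 1]
    c = major[:, :, 0]
    d = major[:, :, 1]
    T = a + b + c + d
    usable = T > 1
    Tsafe = np.where(usable, T, 2).astype(float)
    expect = np.where(usable, (a + b) * (a + c) / Tsafe, 0.0)
    var = np.where(
        usable,
        (a + b) * (c + d) * (a + c) * (b + d) / (Tsafe ** 2 * (Tsafe - 1)),
        0.0,
    )
    num = (np.where(usable, a, 0) - expect).sum(axis=1) ** 2
    den = var.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    p = stats.chi2.sf(stat, 1)
    p = np.where(den > 0, p, 1.0)
    return stat, p


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-population CMH P-values for every generation pair.

    ``p_values[pop]`` is a site x pair DataFrame (NaN where a test was
    skipped for coverage); ``significant[pop]`` is the set of site indices
    with any pair below ``alpha``.
    """

    p_values: dict[str, pd.DataFrame]
    statistics: dict[str, pd.DataFrame]
    significant: dict[str, set[int]]
    alpha: float
    pairs: list[tuple[int, int]] = field(default_factory=list)


def scan(panel: AlleleCountPanel, assignment: MinorAssignment,
         generation_pairs: list[tuple[int, int]] | None = None,
         alpha: float = PUBLISHED_ALPHA) -> ScanResult:
    """CMH scan of every site in every population over generation pairs.

    Strata are the sex pools of the population.  A site enters a given
    pair's test only if all its stratum cells pass the coverage filter;
    pairs with missing generations are skipped with a warning.
    """
    if generation_pairs is None:
        generation_pairs = DEFAULT_GENERATION_PAIRS
    minor = minor_counts(panel, assignment)
    major = panel.total - minor
    sexes = sorted(panel.samples["sex"].unique())
    populations = list(panel.samples["population"].unique())

    p_values: dict[str, pd.DataFrame] = {}
    statistics: dict[str, pd.DataFrame] = {}
    significant: dict[str, set[int]] = {}
    for pop in populations:
        pcols, scols = {}, {}
        for g1, g2 in generation_pairs:
            label = f"{g1}-{g2}"
            idx = {}
            missing = False
            for sex in sexes:
                for gen in (g1, g2):
                    found = panel.sample_index(population=pop, sex=sex, generation=gen)
                    if found.size != 1:
                        missing = True
                        break
                    idx[(sex, gen)] = found[0]
                if missing:
                    break
            if missing:
                warnings.warn(
                    f"population {pop}: generation pair {label} incomplete; skipped",
                    stacklevel=2,
                )
                continue
            cols = [[idx[(sex, g1)], idx[(sex, g2)]] for sex in sexes]
            cols = np.array(cols)  # (K, 2) sample indices
            m = minor[:, cols]     # (n_sites, K, 2)
            M = major[:, cols]
            ok = panel.valid[:, cols].all(axis=(1, 2))
            stat, p = _cmh_vectorized(m, M)
            pcols[label] = np.where(ok, p, np.nan)
            scols[label] = np.where(ok, stat, np.nan)
        pdf = pd.DataFrame(pcols)
        p_values[pop] = pdf
        statistics[pop] = pd.DataFrame(scols)
        sig_mask = (pdf < alpha).any(axis=1).to_numpy() if len(pdf.columns) else \
            np.zeros(panel.n_sites, dtype=bool)
        significant[pop] = set(np.flatnonzero(sig_mask))
    return ScanResult(p_values=p_values, statistics=statistics,
                      significant=significant, alpha=alpha,
                      pairs=list(generation_pairs))


def overlap_filter(sig_long: dict[str, set[int]], sig_short: dict[str, set[int]],
                   sig_control: dict[str, set[int]],
                   within_scheme: str = "union") -> set[int]:
    """Candidate sites: significant in both selection schemes, not in any
    control.

    Default rule: (union over long replicates) intersect (union over short
    replicates) minus (union over control replicates).  Set
    ``within_scheme="intersection"`` for the stricter per-replicate rule.
    """
    combine = set.union if within_scheme == "union" else set.intersection
    if within_scheme not in ("union", "intersection"):
        raise ValueError("within_scheme must be 'union' or 'intersection'")
    long_set = combine(*sig_long.values()) if sig_long else set()
    short_set = combine(*sig_short.values()) if sig_short else set()
    control_set = set.union(*sig_control.values()) if sig_control else set()
    return (long_set & short_set) - control_set


# ---------------------------------------------------------------------------
# logistic candidate filter
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    site: int
    beta0: float
    beta1_gen: float
    beta2_sel: float
    beta3_gen_sel: float
    p_sel: float
    p_gen_sel: float
    p_lack_of_fit: float
    separation: bool
    passed: bool


def _fit_grouped_logistic(minor: np.ndarray, total: np.ndarray,
                          gen: np.ndarray, sel: np.ndarray):
    endog = np.column_stack([minor, total - minor])
    exog = np.column_stack([np.ones_like(gen, dtype=float), gen, sel, gen * sel])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200)


def _center_gen(gen: np.ndarray, sel_test_at: str) -> np.ndarray:
    if sel_test_at == "mean":
        return gen - gen.mean()
    if sel_test_at == "origin":
        return gen
    raise ValueError("sel_test_at must be 'mean' or 'origin'")


def logistic_filter(panel: AlleleCountPanel, assignment: MinorAssignment,
                    sites, alpha_effect: float = 0.05,
                    alpha_lack_of_fit: float = 0.05,
                    sel_test_at: str = "mean") -> pd.DataFrame:
    """Grouped-binomial logistic filter on candidate trajectories.

    For each candidate site, minor-allele counts from every long- and
    short-scheme sample (all replicates, sexes, generations; coverage-valid
    cells only) are modeled as
    ``logit(p) = b0 + b1*Gen + b2*Sel + b3*Gen*Sel`` with Gen the numeric
    generation and Sel an indicator for the short scheme.  A site passes
    iff the deviance lack-of-fit P >= ``alpha_lack_of_fit`` and both the
    Sel and Gen x Sel Wald P-values are <= ``alpha_effect``.  Perfect
    separation is handled by adding 0.5 to every grouped cell
    (Haldane-Anscombe) and refitting, flagged in the output.

    With the default ``sel_test_at="mean"``, Gen is centered so the Sel
    test measures the scheme level difference at the design's mean
    generation.  Both schemes share one source population, so at
    generation 0 their frequencies coincide by construction and an
    uncentered Sel test (``sel_test_at="origin"``) has essentially no
    power even for ideal selective sweeps.  Fitted probabilities and the
    Gen x Sel test are unaffected by the choice.
    """
    minor = minor_counts(panel, assignment)
    total = panel.total
    sel_mask = panel.samples["scheme"].isin(["long", "short"]).to_numpy()
    sel_idx = np.flatnonzero(sel_mask)
    gen_raw = panel.samples["generation"].to_numpy(dtype=float)[sel_idx]
    sel = (panel.samples["scheme"].to_numpy()[sel_idx] == "short").astype(float)

    rows = []
    for site in sorted(sites):
        ok = panel.valid[site, sel_idx] & (total[site, sel_idx] > 0)
        m = minor[site, sel_idx][ok].astype(float)
        t = total[site, sel_idx][ok].astype(float)
        g, s = _center_gen(gen_raw[ok], sel_test_at), sel[ok]
        for scheme_val in (0.0, 1.0):
            if len(np.unique(g[s == scheme_val])) < 2:
                break
        else:
            fit = sep = None
            try:
                res = _fit_grouped_logistic(m, t, g, s)
                bse = np.asarray(res.bse)
                sep = bool(np.any(~np.isfinite(bse)) or np.any(bse > 50)
                           or np.any(np.abs(res.params) > 25))
            except Exception:
                sep = True
            if sep:
                res = _fit_grouped_logistic(m + 0.5, t + 1.0, g, s)
            dof = len(m) - 4
            p_lof = float(stats.chi2.sf(res.deviance, dof)) if dof > 0 else np.nan
            p_sel = float(res.pvalues[2])
            p_int = float(res.pvalues[3])
            passed = (p_lof >= alpha_lack_of_fit and p_sel <= alpha_effect
                      and p_int <= alpha_effect)
            rows.append(LogisticFit(
                site=site, beta0=float(res.params[0]),
                beta1_gen=float(res.params[1]), beta2_sel=float(res.params[2]),
                beta3_gen_sel=float(res.params[3]), p_sel=p_sel,
                p_gen_sel=p_int, p_lack_of_fit=p_lof, separation=sep,
                passed=passed,
            ))
            continue
        rows.append(LogisticFit(site=site, beta0=np.nan, beta1_gen=np.nan,
                                beta2_sel=np.nan, beta3_gen_sel=np.nan,
                                p_sel=np.nan, p_gen_sel=np.nan,
                                p_lack_of_fit=np.nan, separation=False,
                                passed=False))
    columns = ["site", "beta0", "beta1_gen", "beta2_sel", "beta3_gen_sel",
               "p_sel", "p_gen_sel", "p_lack_of_fit", "separation", "passed"]
    return pd.DataFrame([r.__dict__ for r in rows], columns=columns)


def minor_freq_direction(panel: AlleleCountPanel, assignment: MinorAssignment,
                         sites, generation: int) -> pd.DataFrame:
    """Mean minor-allele frequency per scheme at one generation, and
    whether the short scheme's exceeds the long scheme's, per site."""
    rows = []
    for site in sorted(sites):
        freqs = {}
        for scheme in ("long", "short"):
            idx = panel.sample_index(scheme=scheme, generation=generation)
            idx = idx[panel.valid[site, idx]]
            f = assignment.minor_freq[site, idx]
            freqs[scheme] = float(np.nanmean(f)) if idx.size else np.nan
        rows.append({"site": site, "long_freq": freqs["long"],
                     "short_freq": freqs["short"],
                     "higher_in_short": freqs["short"] > freqs["long"]})
    return pd.DataFrame(rows)
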