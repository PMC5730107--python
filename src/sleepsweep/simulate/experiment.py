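"""Forward simulation of the truncation-selection experiment.

Six populations (two long-selected, two short-selected, two unselected
controls by default) are founded from one outbred source pool derived
from the founder panel, then propagated for a configurable number of
generations.  Each generation a fixed number of flies per sex is
phenotyped on an additive polygenic night-sleep trait; the most extreme
fraction per sex becomes the next generation's parents (random choice in
controls).  Pooled sequencing is emulated as binomial read sampling per
sex pool at the sequenced generations.

Inheritance is diploid with free recombination between sites (each site
transmitted independently); X-linked sites are hemizygous in males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..panel import AlleleCountPanel, FounderPanel

FEMALE, MALE = 0, 1
SEX_LABELS = {FEMALE: "F", MALE: "M"}


@dataclass
class ExperimentConfig:
    n_generations: int = 13
    n_measured_per_sex: int = 100
    selection_fraction: float = 0.25
    census: int = 200
    schemes: dict[str, int] = field(
        default_factory=lambda: {"long": 2, "short": 2, "control": 2})
    qtl_effects: dict[int, float] | np.ndarray | None = None
    sex_effect: float = 0.0
    baseline: float = 400.0
    env_sd: float = 100.0
    trait_bounds: tuple[float, float] | None = None
    coverage_mean: float = 100.0
    sequenced_generations: tuple[int, ...] = (0, 1, 2, 5, 8, 10, 12)
    burnin_generations: int = 21
    burnin_mode: str = "collapsed"  # or "explicit"
    burnin_pool_size: int = 1000
    x_chroms: frozenset = frozenset({"X"})
    record_phenotypes: bool = False
    seed: int = 0

    def validate(self, n_sites: int) -> None:
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must lie in (0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.census < 4:
            raise ValueError("census must be at least 4")
        half = self.census // 2
        if self.n_measured_per_sex > half:
            raise ValueError(
                f"cannot measure {self.n_measured_per_sex} flies/sex from a "
                f"census of {self.census}"
            )
        if int(self.selection_fraction * self.n_measured_per_sex) < 1:
            raise ValueError("selection fraction leaves no parents")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")
        if max(self.sequenced_generations, default=0) > self.n_generations:
            raise ValueError("sequenced generation beyond the experiment length")
        if isinstance(self.qtl_effects, dict):
            bad = [s for s in self.qtl_effects if not 0 <= s < n_sites]
            if bad:
                raise ValueError(f"qtl effects at unknown sites: {bad}")
        elif self.qtl_effects is not None and len(self.qtl_effects) != n_sites:
            raise ValueError("qtl_effects array must cover every panel site")

    def effects_array(self, n_sites: int) -> np.ndarray:
        effects = np.zeros(n_sites)
        if isinstance(self.qtl_effects, dict):
            for site, eff in self.qtl_effects.items():
                effects[site] = eff
        elif self.qtl_effects is not None:
            effects[:] = np.asarray(self.qtl_effects, dtype=float)
        return effects


def sample_pool_reads(true_freq, coverage, seed: int | np.random.Generator = 0):
    """Binomial pooled-sequencing reads: alt ~ Bin(coverage, true_freq).

    Returns ``(ref_count, alt_count)``; works elementwise on arrays.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = np.asarray(true_freq, dtype=float)
    cov = np.asarray(coverage, dtype=np.int64)
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError("true_freq must lie in [0, 1]")
    if np.any(cov < 0):
        raise ValueError("coverage cannot be negative")
    alt = rng.binomial(cov, freq)
    return cov - alt, alt


@dataclass
class ExperimentResult:
    """Ground truth plus emulated observables from one simulated run."""

    config: ExperimentConfig
    sites: pd.DataFrame
    populations: pd.DataFrame  # name, scheme, replicate
    true_freq: dict[str, np.ndarray]  # pop -> (n_generations+1, n_sites) alt freq
    summaries: pd.DataFrame
    counts: AlleleCountPanel
    phenotypes: pd.DataFrame | None = None

    def scheme_mean_freq(self, scheme: str, generation: int) -> np.ndarray:
        pops = self.populations.loc[self.populations["scheme"] == scheme, "name"]
        return np.mean([self.true_freq[p][generation] for p in pops], axis=0)

    def scheme_divergence(self, generation: int) -> np.ndarray:
        """|mean short - mean long| true alt frequency per site."""
        return np.abs(self.scheme_mean_freq("short", generation)
                      - self.scheme_mean_freq("long", generation))


class _Population:
    """Genotype state of one population; copy 0 = maternal, copy 1 = paternal.

    Male X storage keeps both copies equal to the maternal allele; dosage
    and allele counts use copy 0 only for male X sites.
    """

    def __init__(self, geno: np.ndarray, sex: np.ndarray, x_mask: np.ndarray):
        self.geno = geno
        self.sex = sex
        self.x_mask = x_mask
        self.x_idx = np.flatnonzero(x_mask)

    def dosage(self, site_idx: np.ndarray | None = None) -> np.ndarray:
        """Additive allele dosage, optionally restricted to some sites."""
        geno = self.geno if site_idx is None else self.geno[:, site_idx]
        d = geno.sum(axis=2)
        x_local = (self.x_idx if site_idx is None
                   else np.flatnonzero(self.x_mask[site_idx]))
        males = self.sex == MALE
        if x_local.size and males.any():
            d[np.ix_(males, x_local)] = geno[np.ix_(males, x_local)][:, :, 0]
        return d

    def allele_freq(self, subset: np.ndarray | slice | None = None) -> np.ndarray:
        if subset is None:
            subset = slice(None)
        geno = self.geno[subset]
        sex = self.sex[subset]
        n_ind = geno.shape[0]
        per_site = geno.sum(axis=0, dtype=np.int64)  # (n_sites, 2)
        total = per_site.sum(axis=1).astype(float)
        denom = np.full(geno.shape[1], 2.0 * n_ind)
        males = sex == MALE
        n_males = int(males.sum())
        if self.x_idx.size and n_males:
            # male X paternal slot duplicates the maternal allele: remove it
            dup = geno[males][:, self.x_idx, 1].sum(axis=0)
            total[self.x_idx] -= dup
            denom[self.x_idx] -= n_males
        return total / denom


def _found_population(p0: np.ndarray, census: int, x_mask: np.ndarray,
                      rng: np.random.Generator) -> _Population:
    n_sites = p0.size
    geno = (rng.random((census, n_sites, 2)) < p0[None, :, None]).astype(np.uint8)
    half = census // 2
    sex = np.concatenate([np.zeros(half, dtype=np.int8),
                          np.ones(census - half, dtype=np.int8)])
    x_idx = np.flatnonzero(x_mask)
    if x_idx.size:
        males = sex == MALE
        geno[np.ix_(males, x_idx, [1])] = geno[np.ix_(males, x_idx, [0])]
    return _Population(geno, sex, x_mask)


def _next_generation(pop: _Population, mothers: np.ndarray, fathers: np.ndarray,
                     census: int, rng: np.random.Generator) -> _Population:
    n_sites = pop.geno.shape[1]
    mo = mothers[rng.integers(0, mothers.size, census)]
    fa = fathers[rng.integers(0, fathers.size, census)]
    geno_m = pop.geno[mo]  # (census, n_sites, 2) row gathers
    geno_f = pop.geno[fa]
    pick_m = rng.integers(0, 2, (census, n_sites), dtype=np.uint8).astype(bool)
    pick_f = rng.integers(0, 2, (census, n_sites), dtype=np.uint8).astype(bool)
    geno = np.empty((census, n_sites, 2), dtype=np.uint8)
    np.copyto(geno[:, :, 0], np.where(pick_m, geno_m[:, :, 1], geno_m[:, :, 0]))
    np.copyto(geno[:, :, 1], np.where(pick_f, geno_f[:, :, 1], geno_f[:, :, 0]))
    x_idx = pop.x_idx
    if x_idx.size:
        # fathers pass their single X (stored in copy 0)
        geno[:, x_idx, 1] = geno_f[:, x_idx, 0]
    half = census // 2
    sex = np.concatenate([np.zeros(half, dtype=np.int8),
                          np.ones(census - half, dtype=np.int8)])
    if x_idx.size:
        # sons are hemizygous: paternal X slot mirrors the maternal allele
        sons = np.flatnonzero(sex == MALE)
        geno[np.ix_(sons, x_idx, [1])] = geno[np.ix_(sons, x_idx, [0])]
    return _Population(geno, sex, pop.x_mask)


def _source_pool_freq(panel: FounderPanel, config: ExperimentConfig,
                      x_mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Alt frequency of the outbred source pool after burn-in random mating.

    ``collapsed`` mode treats the pool as at linkage equilibrium with the
    founder-panel frequencies (large-pool limit of free-recombination
    random mating); ``explicit`` mode simulates the burn-in generations.
    """
    base = panel.alt_frequency.astype(float)
    if config.burnin_mode == "collapsed":
        return base
    if config.burnin_mode != "explicit":
        raise ValueError("burnin_mode must be 'collapsed' or 'explicit'")
    pool = _found_population(base, config.burnin_pool_size, x_mask, rng)
    everyone_f = np.flatnonzero(pool.sex == FEMALE)
    everyone_m = np.flatnonzero(pool.sex == MALE)
    for _ in range(config.burnin_generations):
        pool = _next_generation(pool, everyone_f, everyone_m,
                                config.burnin_pool_size, rng)
    return pool.allele_freq()


def simulate_experiment(panel: FounderPanel,
                        config: ExperimentConfig) -> ExperimentResult:
    """Run the full artificial-selection experiment with pooled sequencing.

    Returns ground-truth trajectories, per-generation phenotype summaries
    and an :class:`AlleleCountPanel` of pooled reads at the sequenced
    generations (one sample per population x sex x generation).
    """
    n_sites = panel.n_sites
    config.validate(n_sites)
    effects = config.effects_array(n_sites)
    x_mask = panel.sites["chrom"].isin(config.x_chroms).to_numpy()

    root = np.random.SeedSequence(config.seed)
    pop_names = []
    for scheme, n_rep in config.schemes.items():
        for rep in range(1, n_rep + 1):
            pop_names.append((f"{scheme[0].upper()}{rep}", scheme, rep))
    streams = root.spawn(len(pop_names) + 1)
    pool_rng = np.random.default_rng(streams[0])
    p0 = _source_pool_freq(panel, config, x_mask, pool_rng)

    n_par = int(config.selection_fraction * config.n_measured_per_sex)
    effect_sites = np.flatnonzero(effects)
    effect_vals = effects[effect_sites]
    gens = range(config.n_generations + 1)

    true_freq: dict[str, np.ndarray] = {}
    summary_rows = []
    pheno_rows = []
    count_samples = []
    count_ref = []
    count_alt = []

    for (name, scheme, rep), stream in zip(pop_names, streams[1:]):
        rng = np.random.default_rng(stream)
        pop = _found_population(p0, config.census, x_mask, rng)
        freqs = np.empty((config.n_generations + 1, n_sites))
        for gen in gens:
            freqs[gen] = pop.allele_freq()

            # phenotype the measured subset
            measured = []
            for sex_code in (FEMALE, MALE):
                of_sex = np.flatnonzero(pop.sex == sex_code)
                take = min(config.n_measured_per_sex, of_sex.size)
                measured.append(rng.choice(of_sex, size=take, replace=False))
            measured_idx = np.concatenate(measured)
            genetic = 0.0
            if effect_sites.size:
                genetic = pop.dosage(effect_sites)[measured_idx] @ effect_vals
            pheno = (config.baseline + genetic
                     + config.sex_effect * (pop.sex[measured_idx] == MALE)
                     + rng.normal(0.0, config.env_sd, measured_idx.size))
            if config.trait_bounds is not None:
                pheno = np.clip(pheno, *config.trait_bounds)

            # choose parents (none after the final generation)
            parent_local: np.ndarray = np.array([], dtype=int)
            if gen < config.n_generations:
                chosen = []
                offset = 0
                for block in measured:
                    sub = pheno[offset:offset + block.size]
                    if scheme == "long":
                        order = np.argsort(sub)[::-1][:n_par]
                    elif scheme == "short":
                        order = np.argsort(sub)[:n_par]
                    else:
                        order = rng.choice(block.size, size=n_par, replace=False)
                    chosen.append(offset + np.asarray(order))
                    offset += block.size
                parent_local = np.concatenate(chosen)

            is_parent = np.zeros(measured_idx.size, dtype=bool)
            is_parent[parent_local] = True
            summary_rows.append({
                "population": name, "scheme": scheme, "replicate": rep,
                "generation": gen, "mean": float(pheno.mean()),
                "sd": float(pheno.std(ddof=1)),
                "parent_mean": float(pheno[is_parent].mean()) if is_parent.any()
                else np.nan,
                "n": int(measured_idx.size), "n_parents": int(is_parent.sum()),
            })
            if config.record_phenotypes:
                for k in range(measured_idx.size):
                    pheno_rows.append({
                        "population": name, "scheme": scheme, "replicate": rep,
                        "generation": gen,
                        "sex": SEX_LABELS[int(pop.sex[measured_idx[k]])],
                        "phenotype": float(pheno[k]),
                        "is_parent": bool(is_parent[k]),
                    })

            # pooled sequencing of each sex pool (sexes are stored as
            # contiguous blocks: females first, then males)
            if gen in config.sequenced_generations:
                half = int((pop.sex == FEMALE).sum())
                for sex_code in (FEMALE, MALE):
                    block = slice(0, half) if sex_code == FEMALE \
                        else slice(half, None)
                    sex_freq = pop.allele_freq(subset=block)
                    cov = np.maximum(rng.poisson(config.coverage_mean, n_sites), 1)
                    ref_c, alt_c = sample_pool_reads(sex_freq, cov, rng)
                    count_samples.append({
                        "population": name, "scheme": scheme, "replicate": rep,
                        "sex": SEX_LABELS[sex_code], "generation": gen,
                    })
                    count_ref.append(ref_c)
                    count_alt.append(alt_c)

            if gen < config.n_generations:
                parents = measured_idx[parent_local]
                mothers = parents[pop.sex[parents] == FEMALE]
                fathers = parents[pop.sex[parents] == MALE]
                if mothers.size == 0 or fathers.size == 0:
                    raise RuntimeError("a sex lost all parents; increase census")
                pop = _next_generation(pop, mothers, fathers, config.census, rng)
        true_freq[name] = freqs

    counts = AlleleCountPanel(
        sites=panel.sites.copy(),
        samples=pd.DataFrame(count_samples),
        ref_count=np.column_stack(count_ref),
        alt_count=np.column_stack(count_alt),
    )
    return ExperimentResult(
        config=config,
        sites=panel.sites.copy(),
        populations=pd.DataFrame(
            [{"name": n, "scheme": s, "replicate": r} for n, s, r in pop_names]),
        true_freq=true_freq,
        summaries=pd.DataFrame(summary_rows),
        counts=counts,
        phenotypes=pd.DataFrame(pheno_rows) if config.record_phenotypes else None,
    )
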