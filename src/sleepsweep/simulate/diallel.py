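"""Ground-truth diallel table generator for the combining-ability
estimators: Y_ij = mean + gca_i + gca_j + sca_ij + rec_ij + noise."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..diallel import DiallelTable, gca as _gca, sca as _sca


def canonical_effects(gca_true, sca_true, rec_true):
    """Project arbitrary effects onto the identifiable parameterization.

    The combining-ability decomposition is unique only under the usual
    constraints (gca sums to zero; sca symmetric with zero row sums; rec
    antisymmetric).  This moves any additive/mean leakage in ``sca_true``
    into the gca and grand-mean components and returns
    ``(gca, sca, rec, mean_shift)``.
    """
    g = np.asarray(gca_true, dtype=float)
    s = np.asarray(sca_true, dtype=float)
    r = np.asarray(rec_true, dtype=float)
    shift = float(s.mean())
    extra_g = _gca(s)
    return g - g.mean() + extra_g, _sca(s), (r - r.T) / 2, shift


def simulate_diallel(gca_true, sca_true, rec_true, grand_mean: float = 0.0,
                     noise_sd: float = 0.0, n_per_cross: int = 1,
                     seed: int | np.random.Generator = 0,
                     parents: list | None = None) -> DiallelTable:
    """Replicate-level observations from known diallel effects.

    ``gca_true`` must sum to zero, ``sca_true`` be symmetric and
    ``rec_true`` antisymmetric (all n-parent shaped); ``n_per_cross``
    replicates are generated per ordered cross, each a single observation
    with Normal(0, noise_sd) noise.
    """
    g = np.asarray(gca_true, dtype=float)
    s = np.asarray(sca_true, dtype=float)
    r = np.asarray(rec_true, dtype=float)
    n = g.size
    if s.shape != (n, n) or r.shape != (n, n):
        raise ValueError("sca/rec matrices must be n x n for n parents")
    if not np.isclose(g.sum(), 0.0, atol=1e-8):
        raise ValueError("gca effects must sum to zero")
    if not np.allclose(s, s.T):
        raise ValueError("sca matrix must be symmetric")
    if not np.allclose(r, -r.T):
        raise ValueError("rec matrix must be antisymmetric")
    if not np.allclose(s.sum(axis=1), 0.0, atol=1e-8):
        raise ValueError("sca rows must sum to zero (identifiability); "
                         "see canonical_effects()")
    if n_per_cross < 1:
        raise ValueError("need at least one observation per cross")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parents = parents or [f"P{i + 1}" for i in range(n)]
    if len(parents) != n:
        raise ValueError("parent labels must match the number of lines")

    expected = grand_mean + g[:, None] + g[None, :] + s + r
    rows = []
    for rep in range(1, n_per_cross + 1):
        noise = rng.normal(0.0, noise_sd, size=(n, n)) if noise_sd > 0 else \
            np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                rows.append({
                    "maternal": parents[i], "paternal": parents[j],
                    "replicate": rep,
                    "value": expected[i, j] + noise[i, j],
                })
    return DiallelTable(observations=pd.DataFrame(rows), parents=parents)
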