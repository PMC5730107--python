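"""Full-diallel decomposition into general/specific combining ability and
reciprocal effects (fixed-effects analysis of a complete n x n cross table
including selfs), with the associated variance partition.

Estimators act on the table of cross means Y_ij (maternal parent i,
paternal parent j):

* ``gca_i  = (1/2n)(X_i. + X_.i) - X_../n^2``
* ``sca_ij = (Y_ij + Y_ji)/2 - (1/2n)(X_i. + X_.i + X_j. + X_.j) + X_../n^2``
* ``rec_ij = (Y_ij - Y_ji)/2``

where X_i. and X_.i are row/column sums and X_.. the grand sum.  The
decomposition is saturated and orthogonal: cell means are reconstructed
exactly as ``mu + g_i + g_j + s_ij + r_ij``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiallelTable:
    """Replicate-level phenotypes of a complete diallel cross.

    ``observations`` columns: ``maternal``, ``paternal``, ``replicate``,
    ``value`` (one or more observations per cross x replicate).  Parent
    order follows ``parents``; the table must be complete (every ordered
    maternal x paternal combination observed).
    """

    observations: pd.DataFrame
    parents: list = field(default_factory=list)

    def __post_init__(self) -> None:
        req = {"maternal", "paternal", "replicate", "value"}
        missing = req - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if not self.parents:
            self.parents = sorted(
                set(self.observations["maternal"]) | set(self.observations["paternal"])
            )
        n = len(self.parents)
        seen = set(zip(self.observations["maternal"], self.observations["paternal"]))
        expected = {(i, j) for i in self.parents for j in self.parents}
        if seen != expected:
            raise ValueError(
                f"incomplete diallel: {len(expected - seen)} of {n * n} "
                "ordered crosses missing"
            )

    @property
    def n(self) -> int:
        return len(self.parents)

    def cell_means(self, replicate=None) -> np.ndarray:
        """n x n matrix of cross means (optionally within one replicate)."""
        obs = self.observations
        if replicate is not None:
            obs = obs[obs["replicate"] == replicate]
        pivot = obs.groupby(["maternal", "paternal"])["value"].mean().unstack()
        pivot = pivot.reindex(index=self.parents, columns=self.parents)
        if pivot.isna().any().any():
            raise ValueError("incomplete cell means for the requested replicate")
        return pivot.to_numpy()


def _check_square(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
        raise ValueError("expected a square cross-mean matrix")
    return Y


def grand_mean(Y: np.ndarray) -> float:
    Y = _check_square(Y)
    return float(Y.mean())


def gca(Y: np.ndarray) -> np.ndarray:
    """General combining ability per parent; sums to zero."""
    Y = _check_square(Y)
    n = Y.shape[0]
    row = Y.sum(axis=1)
    col = Y.sum(axis=0)
    return (row + col) / (2 * n) - Y.sum() / n ** 2


def sca(Y: np.ndarray) -> np.ndarray:
    """Specific combining ability matrix; symmetric with zero row sums."""
    Y = _check_square(Y)
    n = Y.shape[0]
    row = Y.sum(axis=1)
    col = Y.sum(axis=0)
    rc = row + col
    return (Y + Y.T) / 2 - (rc[:, None] + rc[None, :]) / (2 * n) + Y.sum() / n ** 2


def rec(Y: np.ndarray) -> np.ndarray:
    """Reciprocal (parent-of-origin) effects; antisymmetric, zero diagonal."""
    Y = _check_square(Y)
    return (Y - Y.T) / 2


def reconstruct(Y: np.ndarray) -> np.ndarray:
    """mu + g_i + g_j + s_ij + r_ij — equals Y exactly (saturation)."""
    g = gca(Y)
    return grand_mean(Y) + g[:, None] + g[None, :] + sca(Y) + rec(Y)


# ---------------------------------------------------------------------------
# variance partition and effect tests
# ---------------------------------------------------------------------------

def _component_tables(Y: np.ndarray) -> dict[str, np.ndarray]:
    g = gca(Y)
    return {
        "GCA": g[:, None] + g[None, :],
        "SCA": sca(Y),
        "REC": rec(Y),
    }


def _effect_coefficient_ss(n: int, estimator, *args) -> float:
    """Sum of squared coefficients of a linear estimator of cell means,
    found by applying it to unit-indicator tables."""
    total = 0.0
    E = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            E[k, l] = 1.0
            total += float(estimator(E)[args]) ** 2
            E[k, l] = 0.0
    return total


@dataclass
class DiallelAnova:
    anova: pd.DataFrame          # Source, df, SS, MS, F, P
    effects: pd.DataFrame        # effect, parent(s), estimate, se, t, P
    gca: np.ndarray
    sca: np.ndarray
    rec: np.ndarray
    grand_mean: float
    error_ms: float
    error_df: int


def diallel_anova(table: DiallelTable) -> DiallelAnova:
    """Griffing-style fixed-effects partition with replicate interactions.

    Sums of squares: replicate, GCA, SCA, REC, each component x replicate,
    and within-cell error.  With a single observation per cross per
    replicate the within-cell error is empty, so each component is tested
    against its own replicate interaction; with a single replicate the
    interactions are inestimable and a reduced (no-interaction) model is
    fitted with a warning.  Effect standard errors use the error mean
    square through each estimator's coefficient vector.
    """
    n = table.n
    reps = sorted(table.observations["replicate"].unique())
    R = len(reps)
    obs = table.observations
    grand = obs["value"].mean()
    Y = table.cell_means()
    pooled = _component_tables(Y)
    g, s, r = gca(Y), sca(Y), rec(Y)

    # weight: observations per cell (balanced designs assumed)
    cell_counts = obs.groupby(["maternal", "paternal"])["value"].count()
    if cell_counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal observations per cross")
    w = int(cell_counts.iloc[0])
    m = w // R  # obs per cross per replicate

    ss = {name: w * float((tab ** 2).sum()) for name, tab in pooled.items()}
    df = {"GCA": n - 1, "SCA": n * (n - 1) // 2, "REC": n * (n - 1) // 2}

    rep_means = obs.groupby("replicate")["value"].mean()
    ss["Replicate"] = float(n * n * m * ((rep_means - grand) ** 2).sum())
    df["Replicate"] = R - 1

    interactions_ok = R >= 2
    if interactions_ok:
        for name in ("GCA", "SCA", "REC"):
            ss[f"{name}xR"] = 0.0
            df[f"{name}xR"] = df[name] * (R - 1)
        for rep in reps:
            Yr = table.cell_means(replicate=rep)
            per = _component_tables(Yr)
            for name in ("GCA", "SCA", "REC"):
                ss[f"{name}xR"] += m * float(((per[name] - pooled[name]) ** 2).sum())
    else:
        warnings.warn("single replicate: component x replicate interactions "
                      "are inestimable; fitting the reduced model", stacklevel=2)

    cellrep_means = obs.groupby(["maternal", "paternal", "replicate"])["value"] \
        .transform("mean")
    ss["Error"] = float(((obs["value"] - cellrep_means) ** 2).sum())
    df["Error"] = n * n * R * (m - 1)

    if df["Error"] > 0:
        error_ms = ss["Error"] / df["Error"]
        error_df = df["Error"]
        denom = {name: ("Error", error_ms, error_df) for name in ss if name != "Error"}
    elif interactions_ok:
        # RCBD-style: test each component against its replicate interaction
        denom = {}
        for name in ("GCA", "SCA", "REC"):
            ims = ss[f"{name}xR"] / df[f"{name}xR"]
            denom[name] = (f"{name}xR", ims, df[f"{name}xR"])
        pooled_int_ss = sum(ss[f"{k}xR"] for k in ("GCA", "SCA", "REC"))
        pooled_int_df = sum(df[f"{k}xR"] for k in ("GCA", "SCA", "REC"))
        error_ms = pooled_int_ss / pooled_int_df
        error_df = pooled_int_df
    else:
        error_ms = float("nan")
        error_df = 0
        denom = {}

    rows = []
    for name in [k for k in ("Replicate", "GCA", "SCA", "REC",
                             "GCAxR", "SCAxR", "RECxR", "Error") if k in ss]:
        ms = ss[name] / df[name] if df[name] > 0 else float("nan")
        F = p = float("nan")
        if name in denom and name in ("GCA", "SCA", "REC"):
            _, dms, ddf = denom[name]
            if dms > 0:
                F = ms / dms
                p = float(stats.f.sf(F, df[name], ddf))
        rows.append({"source": name, "df": df[name], "ss": ss[name],
                     "ms": ms, "F": F, "p_value": p})
    anova = pd.DataFrame(rows)

    # per-effect SEs via estimator coefficient vectors on cell means
    eff_rows = []
    var_cell = error_ms / w if w else float("nan")
    for i in range(n):
        c2 = _effect_coefficient_ss(n, gca, i)
        se = np.sqrt(var_cell * c2)
        t = g[i] / se if se > 0 else float("nan")
        eff_rows.append({"effect": "GCA", "i": table.parents[i], "j": "",
                         "estimate": g[i], "se": se, "t": t,
                         "p_value": 2 * stats.t.sf(abs(t), error_df)
                         if error_df > 0 and np.isfinite(t) else float("nan")})
    for i in range(n):
        for j in range(i, n):
            c2 = _effect_coefficient_ss(n, sca, i, j)
            se = np.sqrt(var_cell * c2)
            t = s[i, j] / se if se > 0 else float("nan")
            eff_rows.append({"effect": "SCA", "i": table.parents[i],
                             "j": table.parents[j], "estimate": s[i, j],
                             "se": se, "t": t,
                             "p_value": 2 * stats.t.sf(abs(t), error_df)
                             if error_df > 0 and np.isfinite(t) else float("nan")})
    for i in range(n):
        for j in range(i + 1, n):
            c2 = _effect_coefficient_ss(n, rec, i, j)
            se = np.sqrt(var_cell * c2)
            t = r[i, j] / se if se > 0 else float("nan")
            eff_rows.append({"effect": "REC", "i": table.parents[i],
                             "j": table.parents[j], "estimate": r[i, j],
                             "se": se, "t": t,
                             "p_value": 2 * stats.t.sf(abs(t), error_df)
                             if error_df > 0 and np.isfinite(t) else float("nan")})

    return DiallelAnova(anova=anova, effects=pd.DataFrame(eff_rows),
                        gca=g, sca=s, rec=r, grand_mean=float(grand),
                        error_ms=float(error_ms), error_df=int(error_df))
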