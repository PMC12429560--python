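"""Nonparametric inference layer: Kruskal-Wallis omnibus tests, pairwise
two-sided Mann-Whitney U tests with Bonferroni correction, Cohen's r effect
sizes, and the heatmap-style report tables.

Cohen's r is computed as |Z|/sqrt(N) where Z comes from the tie-corrected
normal approximation of U *without* continuity correction (the conventional
definition for rank-test effect sizes); p-values, by contrast, use the exact
U distribution for small tie-free samples and the continuity-corrected
normal approximation otherwise.
"""
from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import StatSummary, MOLECULES, ALL_SEGMENTS, AGES

#: Combined-sample-size cutoff below which the exact U distribution is used
#: (tie-free data only).
EXACT_N_MAX = 20


def bonferroni_alpha(family_size: int, alpha: float = 0.05) -> float:
    """Adjusted per-comparison threshold. Family sizes 10 and 3 reproduce the
    conventional figure-legend thresholds 0.005 and 0.0167."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return alpha / family_size


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square reference distribution.

    All-identical observations are a degenerate but legal input: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def _tie_sigma_u(n1: int, n2: int, pooled: np.ndarray) -> float:
    """Tie-corrected standard deviation of U under the null."""
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    if n <= 1:
        return 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    return float(np.sqrt(max(var, 0.0)))


def mann_whitney_z(u: float, n1: int, n2: int, pooled=None) -> float:
    """Z score of U under the tie-corrected normal approximation, without
    continuity correction (used for Cohen's r)."""
    mu = n1 * n2 / 2.0
    if pooled is None:
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    else:
        sigma = _tie_sigma_u(n1, n2, np.asarray(pooled, dtype=float))
    if sigma == 0:
        return 0.0
    return (u - mu) / sigma


def cohens_r(u: float, n1: int, n2: int, pooled=None) -> float:
    """Effect size r = |Z|/sqrt(n1+n2), in [0, 1]."""
    z = mann_whitney_z(u, n1, n2, pooled)
    return float(abs(z) / np.sqrt(n1 + n2))


def effect_bin(r: float) -> str:
    """Conventional bins: 0.1 small, 0.3 medium, 0.5 large (boundaries
    inclusive on the named bin)."""
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "medium"
    return "large"


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact distribution when the combined tie-free sample has n <= 20;
    otherwise the normal approximation with tie and continuity correction.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= EXACT_N_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided p by full enumeration of all C(n1+n2, n1) group assignments.

    Brute-force oracle for small samples; independent of scipy's
    implementation and of :func:`mann_whitney`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    u_obs = _u_statistic(x, y)
    mu = n1 * y.size / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    idx = range(pooled.size)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x: number of (x_i, y_j) pairs with x_i > y_j, ties counted 1/2."""
    gt = np.count_nonzero(x[:, None] > y[None, :])
    eq = np.count_nonzero(x[:, None] == y[None, :])
    return gt + 0.5 * eq


def compare_groups(
    x, y, comparison: str = "", family_size: int = 1, H: float | None = None
) -> StatSummary:
    """One pairwise WT-vs-mutant style comparison, fully summarized."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha_adj = bonferroni_alpha(family_size)
    pooled = np.concatenate([x, y])
    if x.size == 1 and y.size == 1:
        # degenerate: no permutation distribution to speak of
        u = _u_statistic(x, y)
        return StatSummary(comparison, 1, 1, u, 1.0, alpha_adj, 0.0,
                           "negligible", H=H, degenerate=True)
    u, p = mann_whitney(x, y)
    r = cohens_r(u, x.size, y.size, pooled)
    return StatSummary(comparison, int(x.size), int(y.size), u, p, alpha_adj,
                       r, effect_bin(r), H=H)


def mann_whitney_pairwise(
    groups: Mapping[str, Sequence[float]], family_size: int | None = None
) -> list[StatSummary]:
    """All pairwise two-sided comparisons among ``groups`` with a shared
    Bonferroni family. ``family_size`` defaults to the number of pairs and
    must not be smaller than it."""
    labels = list(groups)
    pairs = list(itertools.combinations(labels, 2))
    if family_size is None:
        family_size = len(pairs)
    if family_size < len(pairs):
        raise ValueError("family_size smaller than the number of comparisons")
    if len(labels) >= 2:
        H, _ = kruskal_wallis([groups[k] for k in labels])
    else:
        H = None
    return [
        compare_groups(groups[a], groups[b], comparison=f"{a} vs {b}",
                       family_size=family_size, H=H)
        for a, b in pairs
    ]


# ---------------------------------------------------------------------------
# Cohort-level analysis and report tables
# ---------------------------------------------------------------------------

def analyze_cohort(records: pd.DataFrame, family_size: int = 10) -> pd.DataFrame:
    """WT vs Q175KI Mann-Whitney comparison for every
    (molecule, age, segment, compartment) cell of a densitometry table.

    ``records`` is the tidy per-sample table produced by the densitometry
    module (one row per animal x hemisphere x segment x compartment).
    """
    rows = []
    rec = records[~records["qc_excluded"]]
    keys = ["molecule", "age", "segment", "compartment"]
    for (mol, age, seg, comp), cell in rec.groupby(keys):
        wt = cell.loc[cell["genotype"] == "WT", "mean_intensity"].to_numpy()
        ki = cell.loc[cell["genotype"] == "Q175KI", "mean_intensity"].to_numpy()
        if wt.size == 0 or ki.size == 0:
            continue
        s = compare_groups(ki, wt, comparison=f"{mol}/{age}m/{seg}/{comp}",
                           family_size=family_size)
        rows.append({
            "molecule": mol, "age": age, "segment": seg, "compartment": comp,
            "n_WT": s.n2, "n_KI": s.n1, "U": s.U, "H": s.H, "p_raw": s.p_raw,
            "alpha_adjusted": s.alpha_adjusted, "significant": s.significant,
            "r": s.r, "effect_bin": s.effect_bin,
        })
    return pd.DataFrame(rows)


def analyze_ismp(ismp: pd.DataFrame, family_size: int = 10) -> pd.DataFrame:
    """WT vs Q175KI comparison of per-sample ISMP for every
    (molecule, age, segment) cell."""
    rows = []
    for (mol, age, seg), cell in ismp.groupby(["molecule", "age", "segment"]):
        wt = cell.loc[cell["genotype"] == "WT", "ismp"].to_numpy()
        ki = cell.loc[cell["genotype"] == "Q175KI", "ismp"].to_numpy()
        if wt.size == 0 or ki.size == 0:
            continue
        s = compare_groups(ki, wt, comparison=f"ISMP {mol}/{age}m/{seg}",
                           family_size=family_size)
        rows.append({
            "molecule": mol, "age": age, "segment": seg,
            "mean_WT": wt.mean(), "sem_WT": sps.sem(wt) if wt.size > 1 else 0.0,
            "mean_KI": ki.mean(), "sem_KI": sps.sem(ki) if ki.size > 1 else 0.0,
            "n_WT": s.n2, "n_KI": s.n1, "U": s.U, "p_raw": s.p_raw,
            "alpha_adjusted": s.alpha_adjusted, "significant": s.significant,
            "r": s.r, "effect_bin": s.effect_bin,
        })
    return pd.DataFrame(rows)


def heatmap_tables(
    ri: pd.DataFrame,
    stat: pd.DataFrame,
    compartment: str = "striosome",
) -> dict[str, pd.DataFrame]:
    """Molecule x (age, segment) matrices of RI, Cohen's r and significance.

    Missing cells are explicit NaN/NA, never dropped. ``ri`` is the table
    from the densitometry module (columns molecule/age/segment/compartment/RI)
    and ``stat`` the per-cell comparison table from :func:`analyze_cohort`.
    """
    cols = pd.MultiIndex.from_product([AGES, ALL_SEGMENTS],
                                      names=["age", "segment"])
    ri_m = pd.DataFrame(np.nan, index=list(MOLECULES), columns=cols)
    eff_m = pd.DataFrame(np.nan, index=list(MOLECULES), columns=cols)
    sig_m = pd.DataFrame(pd.NA, index=list(MOLECULES), columns=cols, dtype=object)

    rsel = ri[ri["compartment"] == compartment]
    for _, row in rsel.iterrows():
        if row["molecule"] in ri_m.index:
            ri_m.loc[row["molecule"], (row["age"], row["segment"])] = row["RI"]
    ssel = stat[stat["compartment"] == compartment]
    for _, row in ssel.iterrows():
        if row["molecule"] in eff_m.index:
            key = (row["age"], row["segment"])
            eff_m.loc[row["molecule"], key] = row["r"]
            sig_m.loc[row["molecule"], key] = bool(row["significant"])
    return {"RI": ri_m, "effect": eff_m, "significant": sig_m}


def render_heatmaps(tables: dict[str, pd.DataFrame], out_prefix: str) -> list[str]:
    """Render the RI and effect-size matrices as figures (PNG).

    Significant cells (per the Bonferroni-adjusted threshold) are starred.
    Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, cmap, center in (("RI", "coolwarm", 1.0), ("effect", "viridis", None)):
        m = tables[name].astype(float)
        fig, ax = plt.subplots(figsize=(1 + 0.55 * m.shape[1], 3.2))
        data = m.to_numpy()
        if center is not None:
            span = np.nanmax(np.abs(data - center)) if np.isfinite(data).any() else 1.0
            im = ax.imshow(data, cmap=cmap, vmin=center - span, vmax=center + span)
        else:
            im = ax.imshow(data, cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks(range(m.shape[1]))
        ax.set_xticklabels([f"{a}m\n{s}" for a, s in m.columns], fontsize=6)
        ax.set_yticks(range(m.shape[0]))
        ax.set_yticklabels(m.index, fontsize=8)
        sig = tables["significant"]
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                v = data[i, j]
                if np.isfinite(v):
                    star = "*" if sig.iloc[i, j] is True else ""
                    ax.text(j, i, f"{v:.2f}{star}", ha="center", va="center",
                            fontsize=5)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(f"{name} heatmap")
        path = f"{out_prefix}_{name}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
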