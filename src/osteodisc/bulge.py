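"""Per-marker bulge computation, normalisation and regional statistics.

Bulge at a marker is the Euclidean norm of its centroid displacement in the
transverse plane between the deformed and preloaded (registered) states; the
axial component is ignored.  For cross-specimen comparisons bulge is
normalised by the applied displacement of the step.  Regional differences
between the eight marker zones are tested with a Welch-corrected one-way
ANOVA (normality and heteroscedasticity are assessed with Shapiro and Levene
tests but do not gate the Welch test), followed, when significant at
p < 0.05, by pairwise t-tests with pooled SD and Bonferroni correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from osteodisc.volume import MarkerSet

__all__ = ["compute_bulge", "normalize_bulge", "regional_comparison",
           "percentile_filter", "welch_anova", "pairwise_t_bonferroni"]


def compute_bulge(markers_step0: MarkerSet, markers_stepk: MarkerSet,
                  specimen_id: str = "S1", step: int = 1) -> pd.DataFrame:
    """Transverse-plane displacement of each marker between two states.

    Markers are paired by id (never by deformed position); ids present in
    only one set are dropped with a warning.
    """
    t0 = markers_step0.table
    tk = markers_stepk.table
    merged = t0.merge(tk, on="id", suffixes=("_0", "_k"))
    if len(merged) < max(len(t0), len(tk)):
        import warnings

        warnings.warn(f"{max(len(t0), len(tk)) - len(merged)} unmatched "
                      "marker ids dropped")
    bulge = np.hypot(merged["x_k"] - merged["x_0"], merged["y_k"] - merged["y_0"])
    return pd.DataFrame({
        "specimen_id": specimen_id,
        "marker_id": merged["id"],
        "zone": merged["zone_0"],
        "step": step,
        "bulge": bulge,
    })


def normalize_bulge(table: pd.DataFrame, applied_displacements) -> pd.DataFrame:
    """Add ``normalized_bulge`` = bulge / applied displacement of the step.

    ``applied_displacements``: mapping step -> mm (or a scalar); specimens
    have slightly different applied displacements, so normalisation makes
    zones comparable across the cohort.
    """
    out = table.copy()
    if np.isscalar(applied_displacements):
        disp = pd.Series(applied_displacements, index=out.index)
    else:
        disp = out["step"].map(applied_displacements)
    if disp.isna().any() or (disp <= 0).any():
        raise ValueError("applied displacement must be positive for every step")
    out["normalized_bulge"] = out["bulge"] / disp
    return out


def welch_anova(groups: list) -> dict:
    """Welch's heteroscedastic one-way ANOVA (k groups)."""
    k = len(groups)
    ni = np.array([len(g) for g in groups], dtype=float)
    if k < 2 or np.any(ni < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    mi = np.array([np.mean(g) for g in groups])
    vi = np.array([np.var(g, ddof=1) for g in groups])
    wi = ni / vi
    W = wi.sum()
    mstar = (wi * mi).sum() / W
    Anum = ((wi * (mi - mstar) ** 2).sum()) / (k - 1)
    tmp = ((1 - wi / W) ** 2 / (ni - 1)).sum()
    B = 1 + (2 * (k - 2) / (k ** 2 - 1)) * tmp
    F = Anum / B
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * tmp)
    return {"F": float(F), "df1": float(df1), "df2": float(df2),
            "p": float(stats.f.sf(F, df1, df2))}


def pairwise_t_bonferroni(groups: dict) -> pd.DataFrame:
    """Pairwise t-tests with pooled SD and Bonferroni correction.

    The pooled SD is computed across *all* groups (as in R's
    ``pairwise.t.test`` with ``pool.sd = TRUE``) with N - k degrees of
    freedom; the Bonferroni family is all k(k-1)/2 pairs.
    """
    names = list(groups)
    ni = {z: len(groups[z]) for z in names}
    N = sum(ni.values())
    kk = len(names)
    sp2 = sum((ni[z] - 1) * np.var(groups[z], ddof=1) for z in names) / (N - kk)
    df = N - kk
    npairs = kk * (kk - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t = (np.mean(groups[a]) - np.mean(groups[b])) / \
                np.sqrt(sp2 * (1 / ni[a] + 1 / ni[b]))
            p = 2 * stats.t.sf(abs(t), df)
            rows.append({"zone_a": a, "zone_b": b, "t": float(t),
                         "p_raw": float(p),
                         "p_adjusted": float(min(p * npairs, 1.0))})
    return pd.DataFrame(rows)


def regional_comparison(table: pd.DataFrame, step: int,
                        value: str = "normalized_bulge",
                        alpha: float = 0.05) -> dict:
    """Zone-wise comparison of (normalised) bulge at one compression step.

    Returns Shapiro p per zone, the Levene p, the Welch ANOVA result and --
    only when the ANOVA is significant at ``alpha`` -- the Bonferroni-
    adjusted pairwise matrix.
    """
    sub = table[table["step"] == step]
    if value not in sub.columns:
        raise KeyError(f"column {value!r} missing; run normalize_bulge first")
    groups = {z: g[value].to_numpy(dtype=float)
              for z, g in sub.groupby("zone", observed=True)}
    groups = {z: v for z, v in groups.items() if len(v) >= 3}
    if len(groups) < 2:
        raise ValueError("need >= 2 zones with >= 3 markers each")
    shapiro = {z: float(stats.shapiro(v).pvalue) for z, v in groups.items()}
    levene = float(stats.levene(*groups.values(), center="median").pvalue)
    anova = welch_anova(list(groups.values()))
    report = {"step": step, "n_per_zone": {z: len(v) for z, v in groups.items()},
              "shapiro_p": shapiro, "levene_p": levene, "welch_anova": anova,
              "alpha": alpha, "significant": anova["p"] < alpha,
              "pairwise": None}
    if report["significant"]:
        report["pairwise"] = pairwise_t_bonferroni(groups)
    return report


def percentile_filter(table: pd.DataFrame, column: str = "bulge",
                      q: float = 10.0) -> pd.DataFrame:
    """Drop rows whose experimental bulge lies strictly below the q-th
    percentile of the comparison set (pooled; linear-interpolation
    percentile).  The smallest displacements are the most error-prone
    relative to the image resolution, so they are excluded from agreement
    scoring."""
    if len(table) == 0:
        raise ValueError("empty bulge table")
    thr = np.percentile(table[column].to_numpy(dtype=float), q)
    return table[table[column] >= thr].copy()
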