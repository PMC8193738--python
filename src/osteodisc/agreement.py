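"""In-vitro vs in-silico agreement statistics.

Lin's concordance correlation coefficient (CCC) measures how well one method
reproduces another, combining precision (Pearson correlation) and accuracy
(bias):

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)

with population (1/n) moments, as in Lin's original definition.  The 95%
confidence interval uses the Fisher z-transform with Lin's asymptotic
variance.  Bulge agreement additionally drops markers whose experimental
displacement falls in the lowest tenth percentile, and reports the fraction
of pairs whose difference is below the image resolution (82 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from osteodisc.bulge import percentile_filter

__all__ = ["AgreementResult", "concordance", "bulge_agreement",
           "load_agreement", "RESOLUTION_MM"]

#: CT image resolution: differences below this are within measurement error
RESOLUTION_MM = 0.082


@dataclass
class AgreementResult:
    ccc: float
    ci95: tuple
    n_pairs: int
    mean_difference: pd.DataFrame | None = None   # columns: mean, difference
    resolution_band: float | None = None          # mm
    band_fraction: float | None = None            # fraction |diff| < band

    def __post_init__(self):
        if not (self.ci95[0] <= self.ccc <= self.ci95[1]):
            raise ValueError("inconsistent confidence interval")


def concordance(x, y, moment: str = "population",
                alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient with 95% CI.

    ``moment='population'`` uses 1/n denominators (Lin 1989);
    ``'sample'`` switches to 1/(n-1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    ddof = 0 if moment == "population" else 1
    sx2 = np.var(x, ddof=ddof)
    sy2 = np.var(y, ddof=ddof)
    sxy = np.mean((x - x.mean()) * (y - y.mean())) * (n / (n - ddof))
    bias2 = (x.mean() - y.mean()) ** 2
    denom = sx2 + sy2 + bias2
    if denom == 0:
        raise ValueError("zero variance and zero bias: CCC undefined")
    ccc = float(2 * sxy / denom)

    # Lin's asymptotic variance of the z-transformed CCC
    if sx2 > 0 and sy2 > 0 and abs(ccc) < 1:
        r = sxy / np.sqrt(sx2 * sy2)
        u = (x.mean() - y.mean()) / (sx2 * sy2) ** 0.25
        r = np.clip(r, -0.999999, 0.999999)
        var_z = ((1 - r ** 2) * ccc ** 2 / ((1 - ccc ** 2) * r ** 2)
                 + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - ccc ** 2) ** 2)
                 - ccc ** 4 * u ** 4 / (2 * r ** 2 * (1 - ccc ** 2) ** 2)) / (n - 2)
        var_z = max(var_z, 0.0)
        z = np.arctanh(np.clip(ccc, -0.999999, 0.999999))
        hw = stats.norm.ppf(1 - alpha / 2) * np.sqrt(var_z)
        lo, hi = float(np.tanh(z - hw)), float(np.tanh(z + hw))
    else:
        lo = hi = ccc
    lo, hi = min(lo, ccc), max(hi, ccc)
    return AgreementResult(ccc, (lo, hi), n)


def bulge_agreement(invitro: pd.DataFrame, insilico: pd.DataFrame,
                    resolution: float = RESOLUTION_MM,
                    percentile: float = 10.0) -> AgreementResult:
    """Marker-wise agreement between measured and predicted bulge.

    Tables are paired on (specimen_id, marker_id, step) where present, else
    on marker_id; the tenth-percentile filter is applied to the *in vitro*
    values before pairing.  The mean-difference rows support Bland-Altman
    style plots, and ``band_fraction`` is the share of pairs whose
    |difference| is below the image resolution.
    """
    keys = [k for k in ("specimen_id", "marker_id", "step") if
            k in invitro.columns and k in insilico.columns]
    if not keys:
        keys = ["marker_id"] if "marker_id" in invitro.columns else ["id"]
    filt = percentile_filter(invitro, "bulge", percentile)
    merged = filt.merge(insilico, on=keys, suffixes=("_vitro", "_silico"))
    if len(merged) == 0:
        raise ValueError("no surviving marker pairs after filtering")
    x = merged["bulge_vitro"].to_numpy(dtype=float)
    y = merged["bulge_silico"].to_numpy(dtype=float)
    res = concordance(x, y)
    diff = y - x
    res.mean_difference = pd.DataFrame({"mean": (x + y) / 2, "difference": diff})
    res.resolution_band = resolution
    res.band_fraction = float(np.mean(np.abs(diff) < resolution))
    return res


def load_agreement(records_invitro: pd.DataFrame,
                   records_insilico: pd.DataFrame,
                   grouping=("nucleus_model", "calibration_mode")) -> pd.DataFrame:
    """Pooled per-cell CCC of loads, one row per (model type, calibration
    mode): all specimen x step pairs within a cell are pooled.

    Both inputs need columns: specimen_id, step, peak_load_N plus the
    grouping columns on the in-silico side.
    """
    grouping = [g for g in grouping if g in records_insilico.columns]
    rows = []
    for key, g in records_insilico.groupby(list(grouping), observed=True):
        merged = g.merge(records_invitro, on=["specimen_id", "step"],
                         suffixes=("_silico", "_vitro"))
        if len(merged) < 3:
            import warnings

            warnings.warn(f"cell {key}: fewer than 3 pairs, skipped")
            continue
        res = concordance(merged["peak_load_N_vitro"],
                          merged["peak_load_N_silico"])
        row = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        row.update({"ccc": res.ccc, "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1], "n_pairs": res.n_pairs})
        rows.append(row)
    return pd.DataFrame(rows)
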