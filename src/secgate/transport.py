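"""Translocation rates from lag tables and chemo-mechanical coupling.

The split-luciferase transport assay yields, for each probe insertion
position (amino acids from the substrate N-terminus), the lag before
chemiluminescence onset.  Under a constant transport rate v the lag is
linear in position with slope 1/v, so ordinary least squares of lag on
position gives the translocation rate; its confidence interval follows
from the slope CI by first-order (delta-method) propagation.  Dividing by
the steady-state ATP turnover rate of SecA yields the coupling efficiency
in amino acids translocated per ATP hydrolysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import LagTable


@dataclass
class TransportFit:
    v_aa_per_s: float
    t0_s: float
    se_v: float
    ci95_v: tuple        # (low, high); NaN bounds when undefined (n = 2)
    residual_sd_s: float
    n_points: int
    slope_s_per_aa: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (self.ci95_v[0] <= self.v_aa_per_s
                               <= self.ci95_v[1]):
            if not np.isnan(self.ci95_v[0]):
                raise ValueError("CI does not contain the fitted rate")


@dataclass
class CouplingResult:
    aa_per_atp: float
    v_aa_per_s: float
    k_cat_per_s: float
    se_aa_per_atp: float = np.nan


def fit_transport_rate(table: LagTable) -> TransportFit:
    """OLS of lag on insertion position; v = 1/slope.

    Requires at least two distinct positions.  Two points give an exact
    line with an undefined (NaN-flagged) CI; a non-positive slope flags
    the fit invalid.
    """
    x, y = table.positions_aa, table.lags_s
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct insertion positions to fit")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    n = x.size
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt((resid ** 2).sum() / (n - 2))) if n > 2 \
        else 0.0
    if slope <= 0:
        return TransportFit(
            v_aa_per_s=np.nan, t0_s=float(intercept), se_v=np.nan,
            ci95_v=(np.nan, np.nan), residual_sd_s=residual_sd,
            n_points=n, slope_s_per_aa=float(slope), valid=False,
        )
    v = 1.0 / slope
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        se_v = res.stderr / slope ** 2  # delta method on 1/slope
        t_crit = stats.t.ppf(0.975, df=n - 2)
        ci = (v - t_crit * se_v, v + t_crit * se_v)
    else:
        se_v, ci = np.nan, (np.nan, np.nan)
    return TransportFit(
        v_aa_per_s=float(v), t0_s=float(intercept), se_v=float(se_v),
        ci95_v=ci, residual_sd_s=residual_sd, n_points=n,
        slope_s_per_aa=float(slope),
    )


def coupling_efficiency(v_aa_per_s: float, k_cat_per_s: float,
                        se_v: float = 0.0,
                        se_k_cat: float = 0.0) -> CouplingResult:
    """Amino acids translocated per ATP hydrolysed: v / k_cat.

    Uncertainty, when standard errors are given, propagates in quadrature
    on the relative scale.
    """
    if k_cat_per_s <= 0:
        raise ValueError("k_cat must be > 0")
    ratio = v_aa_per_s / k_cat_per_s
    se = np.nan
    if se_v or se_k_cat:
        rel = np.hypot(se_v / v_aa_per_s if v_aa_per_s else 0.0,
                       se_k_cat / k_cat_per_s)
        se = abs(ratio) * rel
    return CouplingResult(aa_per_atp=float(ratio),
                          v_aa_per_s=float(v_aa_per_s),
                          k_cat_per_s=float(k_cat_per_s),
                          se_aa_per_atp=float(se))


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two rates (b > 0)."""
    if b <= 0:
        raise ValueError("reference rate must be > 0")
    return float(a / b)
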