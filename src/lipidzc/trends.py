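"""Geochemical unit conversions and Z_C-versus-gradient regression.

Sample Z_C values (and their bootstrap draws) are regressed against water
temperature and the log molality of dissolved O2.  Full lipids, backbones
and alkyl chains follow near-linear trends and get ordinary least squares
with a 95% prediction band; headgroup Z_C is non-monotone along the channel
and gets a local polynomial (LOESS-style) fit: tricube weights, degree 2,
span 0.9, with the band drawn at fit +/- 1.96 x locally-smoothed residual
standard deviation.

Conductivity measured at field temperature is normalized to 25 degC by
Cond_T / (1 + alpha (T - 25)) with alpha = 0.02 for fresh water.  Dissolved
O2 in mg/L converts to log10 molality assuming 1 L of solution is 1 kg of
solvent: log10((mg/L / 1000) / 31.998 g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from importlib import resources

__all__ = [
    "normalize_conductivity",
    "o2_log_molal",
    "load_site_metadata",
    "LinearTrend",
    "LocalTrend",
    "fit_trend",
    "O2_MOLAR_MASS",
]

O2_MOLAR_MASS = 31.998  # g/mol


def normalize_conductivity(cond_t: float, temp_c: float, alpha: float = 0.02) -> float:
    """Conductivity at 25 degC from a measurement at ``temp_c``."""
    denom = 1.0 + alpha * (temp_c - 25.0)
    if denom <= 0:
        raise ValueError("temperature correction denominator is nonpositive")
    return cond_t / denom


def o2_log_molal(o2_mg_per_l) -> float:
    """log10 molality of dissolved O2 from a concentration in mg/L."""
    o2 = np.asarray(o2_mg_per_l, dtype=float)
    if np.any(o2 <= 0):
        raise ValueError("O2 concentration must be positive for log molality")
    out = np.log10((o2 / 1000.0) / O2_MOLAR_MASS)
    return float(out) if out.ndim == 0 else out


def load_site_metadata() -> pd.DataFrame:
    """Packaged hot-spring site metadata (18 samples, 4 springs).

    Below-detection entries are returned as NaN in the numeric columns with
    a companion ``<col>_bdl`` boolean; empty cells are missing data.  A
    ``log_o2_molal`` column is added where O2 is available.
    """
    path = resources.files("lipidzc.data").joinpath("site_metadata.csv")
    with path.open() as fh:
        df = pd.read_csv(fh, dtype=str)
    numeric = [
        "distance_m", "temperature_C", "pH", "conductivity_uScm",
        "o2_mgL", "no3_mgL", "no2_mgL", "so4_mgL", "nh4_mgL", "hs_ugL",
    ]
    for col in numeric:
        raw = df[col]
        df[col + "_bdl"] = raw.str.strip().eq("bdl").fillna(False)
        df[col] = pd.to_numeric(raw.where(~df[col + "_bdl"]), errors="coerce")
    df = df.drop(columns=[c for c in df.columns if c.endswith("_bdl")
                          and not df[c].any()])
    ok = df["o2_mgL"] > 0
    df["log_o2_molal"] = np.nan
    df.loc[ok, "log_o2_molal"] = o2_log_molal(df.loc[ok, "o2_mgL"].to_numpy())
    return df


@dataclass
class LinearTrend:
    """OLS line with a 95% prediction band."""

    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    nobs: int
    _res: object

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def band(self, x_grid) -> pd.DataFrame:
        x_grid = np.asarray(x_grid, dtype=float)
        X = sm.add_constant(x_grid)
        pred = self._res.get_prediction(X)
        ci = pred.conf_int(obs=True, alpha=0.05)
        return pd.DataFrame(
            {"x": x_grid, "fit": pred.predicted_mean,
             "lo": ci[:, 0], "hi": ci[:, 1]}
        )


def fit_linear(x, y) -> LinearTrend:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct predictor values")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    return LinearTrend(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        slope_ci=(float(lo), float(hi)),
        nobs=int(res.nobs),
        _res=res,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0, 1)
    return (1 - u**3) ** 3


def _local_poly(x, y, x0, span, degree):
    """Weighted polynomial fit at one point; tricube kernel over the span."""
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    d = np.abs(x - x0)
    h = np.sort(d)[min(k, n) - 1]
    if h == 0:
        h = np.max(d) or 1.0
    w = _tricube(d / h)
    mask = w > 0
    if mask.sum() <= degree:
        mask = d <= np.sort(d)[degree]
        w = np.where(mask, 1.0, 0.0)
    X = np.vander(x[mask] - x0, degree + 1, increasing=True)
    sw = np.sqrt(w[mask])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y[mask] * sw, rcond=None)
    return beta[0]


@dataclass
class LocalTrend:
    """Local-polynomial smoother with a +/- nsigma * sd(x) band."""

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    nsigma: float

    def predict(self, x_grid) -> np.ndarray:
        x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
        return np.array(
            [_local_poly(self.x, self.y, x0, self.span, self.degree)
             for x0 in x_grid]
        )

    def local_sd(self, x_grid) -> np.ndarray:
        resid2 = (self.y - self.predict(self.x)) ** 2
        x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
        smoothed = np.array(
            [_local_poly(self.x, resid2, x0, self.span, 1) for x0 in x_grid]
        )
        return np.sqrt(np.clip(smoothed, 0, None))

    def band(self, x_grid) -> pd.DataFrame:
        x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
        fit = self.predict(x_grid)
        sd = self.local_sd(x_grid)
        return pd.DataFrame(
            {"x": x_grid, "fit": fit,
             "lo": fit - self.nsigma * sd, "hi": fit + self.nsigma * sd}
        )


def fit_local(x, y, span: float = 0.9, degree: int = 2,
              nsigma: float = 1.96) -> LocalTrend:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < degree + 2:
        raise ValueError("too few distinct predictor values for a local fit")
    return LocalTrend(x=x, y=y, span=span, degree=degree, nsigma=nsigma)


def fit_trend(x, y, kind: str = "linear", **kw):
    """Fit Z_C against a gradient predictor.

    ``kind='linear'`` for full lipids, backbones and chains;
    ``kind='local'`` (span-0.9 tricube quadratic) for headgroups.
    """
    if kind == "linear":
        return fit_linear(x, y)
    if kind == "local":
        return fit_local(x, y, **kw)
    raise ValueError(f"unknown trend kind {kind!r}")
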