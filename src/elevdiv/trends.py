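"""Gradient and determinant models.

Belt-level counts (species richness) are modelled with log-link
quasi-Poisson GLMs: a Poisson likelihood fitted by iteratively reweighted
least squares, with the dispersion estimated from the Pearson chi-square
statistic and folded into the standard errors (t-tests on the slope).
Explained variance is reported as the deviance pseudo-R^2,
``1 - D_resid/D_null``; the squared Pearson correlation of fitted vs
observed values is carried alongside for comparison, since "R^2" is not
uniquely defined for GLMs.

Real-valued responses (NRI along elevation) use ordinary least squares.
The diversity "peak" of a mountain is the midpoint of its richest belt,
and peak determinants (relative elevation, longitude, temperature,
precipitation) are screened one predictor at a time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .belts import BeltMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrendFit",
    "fit_quasipoisson",
    "fit_gaussian",
    "richness_area_fit",
    "native_nonnative_correlation",
    "nri_trend",
    "peak_elevation",
    "peak_determinants",
    "trend_table",
]

PEAK_PREDICTORS = ("relative_elevation_m", "longitude_deg", "amt_c", "ap_mm")


@dataclass(frozen=True)
class TrendFit:
    response: str
    predictor: str
    family: str  # quasipoisson | gaussian
    slope: float
    intercept: float
    pseudo_r2: float
    p_value: float
    n: int
    slope_se: float = float("nan")  # dispersion-scaled standard error of the slope
    fitted_obs_r2: float = float("nan")  # squared Pearson r of fitted vs observed
    classification: str = ""


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    return x, y


def _fitted_obs_r2(fitted: np.ndarray, y: np.ndarray) -> float:
    if np.std(fitted) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(fitted, y)[0, 1] ** 2)


def fit_quasipoisson(
    x: Sequence[float],
    y: Sequence[float],
    response: str = "y",
    predictor: str = "x",
) -> TrendFit:
    """Log-link quasi-Poisson GLM of counts ``y`` on ``x``.

    Dispersion is estimated by the Pearson statistic and the slope p-value
    comes from a t-test with dispersion-scaled standard errors. Non-integer
    y is tolerated with a warning (quasi-likelihood needs only the
    mean-variance relation).
    """
    x, y = _as_xy(x, y)
    n = len(y)
    if n < 3:
        raise ValueError("quasi-Poisson fit requires n >= 3")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.all(y == 0):
        raise ValueError("all responses are zero; quasi-Poisson fit undefined")
    if not np.allclose(y, np.round(y)):
        warnings.warn("non-integer response passed to quasi-Poisson fit", stacklevel=2)
    if np.all(y == y[0]):
        # constant response: zero slope, no deviance explained; IRLS is degenerate here
        return TrendFit(
            response=response, predictor=predictor, family="quasipoisson",
            slope=0.0, intercept=float(np.log(y[0])), pseudo_r2=0.0,
            p_value=1.0, n=n,
        )

    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(scale="X2", use_t=True, maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels raises rarely here
        raise RuntimeError(f"quasi-Poisson IRLS failed: {exc}") from exc
    if not res.converged:
        raise RuntimeError(
            f"quasi-Poisson IRLS did not converge in 100 iterations "
            f"(deviance {res.deviance:.4g}, n={n})"
        )
    null_dev = res.null_deviance
    pr2 = 0.0 if null_dev == 0 else float(np.clip(1.0 - res.deviance / null_dev, 0.0, 1.0))
    return TrendFit(
        response=response,
        predictor=predictor,
        family="quasipoisson",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        pseudo_r2=pr2,
        p_value=float(res.pvalues[1]),
        n=n,
        slope_se=float(res.bse[1]),
        fitted_obs_r2=_fitted_obs_r2(np.asarray(res.fittedvalues), y),
    )


def fit_gaussian(
    x: Sequence[float],
    y: Sequence[float],
    response: str = "y",
    predictor: str = "x",
) -> TrendFit:
    """Ordinary least-squares fit of ``y`` on ``x`` (Gaussian family)."""
    x, y = _as_xy(x, y)
    n = len(y)
    if n < 3:
        raise ValueError("OLS fit requires n >= 3")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return TrendFit(
        response=response,
        predictor=predictor,
        family="gaussian",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        pseudo_r2=float(np.clip(res.rsquared, 0.0, 1.0)),
        p_value=float(res.pvalues[1]),
        n=n,
        slope_se=float(res.bse[1]),
        fitted_obs_r2=float(np.clip(res.rsquared, 0.0, 1.0)),
    )


def richness_area_fit(matrix: BeltMatrix) -> TrendFit:
    """Quasi-Poisson fit of per-belt species richness on belt area (km^2)."""
    if matrix.belt_area_km2 is None:
        raise ValueError("belt areas not attached; call attach_areas first")
    sr = matrix.richness.to_numpy()
    area = matrix.belt_area_km2.to_numpy()
    if len(sr) < 3:
        raise ValueError("richness~area fit requires >= 3 belts")
    return fit_quasipoisson(area, sr, response="SR", predictor="area_km2")


def native_nonnative_correlation(
    matrix: BeltMatrix, alien_list: set[str]
) -> dict:
    """Pearson correlation of belt-level native vs non-native richness.

    Returns ``{"r", "p", "n", "flagged"}``; ``flagged`` is True (with NaN r)
    when either richness vector has zero variance.
    """
    cols = matrix.presence.columns
    alien_cols = [c for c in cols if c in alien_list]
    native_cols = [c for c in cols if c not in alien_list]
    native_sr = matrix.presence[native_cols].sum(axis=1).to_numpy(dtype=float)
    alien_sr = matrix.presence[alien_cols].sum(axis=1).to_numpy(dtype=float)
    n = len(native_sr)
    if n < 3:
        raise ValueError("correlation requires >= 3 belts")
    if np.std(native_sr) == 0 or np.std(alien_sr) == 0:
        logger.warning("zero variance in native or non-native belt richness; r undefined")
        return {"r": float("nan"), "p": float("nan"), "n": n, "flagged": True}
    r, p = scipy.stats.pearsonr(native_sr, alien_sr)
    return {"r": float(r), "p": float(p), "n": n, "flagged": False}


def nri_trend(profile: pd.DataFrame, alpha: float = 0.05) -> TrendFit:
    """OLS fit of NRI on belt midpoint over the evaluable belts.

    Classifies the mountain as ``clustering_increasing`` (slope > 0,
    p < alpha), ``clustering_decreasing`` (slope < 0, p < alpha) or ``flat``.
    """
    ok = profile[profile["evaluable"] & profile["nri"].notna()]
    if len(ok) < 3:
        raise ValueError(f"NRI trend requires >= 3 evaluable belts, got {len(ok)}")
    fit = fit_gaussian(
        ok["midpoint"].to_numpy(), ok["nri"].to_numpy(), response="NRI", predictor="midpoint_m"
    )
    if fit.p_value < alpha:
        cls = "clustering_increasing" if fit.slope > 0 else "clustering_decreasing"
    else:
        cls = "flat"
    return TrendFit(**{**fit.__dict__, "classification": cls})


def peak_elevation(sr_by_midpoint: pd.Series) -> float:
    """Midpoint of the belt with maximal richness (ties -> lowest belt)."""
    if len(sr_by_midpoint) == 0:
        raise ValueError("empty richness profile")
    s = sr_by_midpoint.sort_index()
    return float(s.index[np.argmax(s.to_numpy())])


def peak_determinants(
    peaks: Mapping[str, float],
    attributes: pd.DataFrame,
    family: str = "quasipoisson",
) -> list[TrendFit]:
    """Single-predictor fits of diversity-peak elevation on mountain attributes.

    ``attributes`` must be indexed (or keyed by a ``mountain_id`` column) by
    the same mountains as ``peaks`` and carry the columns
    ``relative_elevation_m, longitude_deg, amt_c, ap_mm``. Requires >= 4
    mountains. No multiple-testing correction is applied across the four
    predictors; consumers see all four p-values.
    """
    if "mountain_id" in attributes.columns:
        attributes = attributes.set_index("mountain_id")
    mountains = [m for m in peaks if m in attributes.index]
    if len(mountains) < 4:
        raise ValueError(f"peak determinants require >= 4 mountains, got {len(mountains)}")
    y = np.array([peaks[m] for m in mountains], dtype=float)
    fits = []
    for pred in PEAK_PREDICTORS:
        if pred not in attributes.columns:
            raise KeyError(f"attribute table lacks column {pred!r}")
        x = attributes.loc[mountains, pred].to_numpy(dtype=float)
        if family == "quasipoisson":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # peaks are metres, not integer counts
                fit = fit_quasipoisson(x, y, response="peak_elevation_m", predictor=pred)
        elif family == "gaussian":
            fit = fit_gaussian(x, y, response="peak_elevation_m", predictor=pred)
        else:
            raise ValueError(f"unknown family {family!r}")
        fits.append(fit)
    return fits


def trend_table(fits: Sequence[TrendFit], mountain_id: str | None = None) -> pd.DataFrame:
    """Tidy table of fits: mountain, response, predictor, family, slope, r2, p, n."""
    df = pd.DataFrame(
        {
            "response": [f.response for f in fits],
            "predictor": [f.predictor for f in fits],
            "family": [f.family for f in fits],
            "slope": [f.slope for f in fits],
            "r2": [f.pseudo_r2 for f in fits],
            "fitted_obs_r2": [f.fitted_obs_r2 for f in fits],
            "p": [f.p_value for f in fits],
            "n": [f.n for f in fits],
            "classification": [f.classification for f in fits],
        }
    )
    if mountain_id is not None:
        df.insert(0, "mountain_id", mountain_id)
    return df
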