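"""Validation statistics: predicted-vs-experimental linear regression with
R², RMSE, percentage errors, and t-tests of slope against 1 and intercept
against 0.

Conventions (they change the reported slope/intercept, so they are fixed
here): y = predicted is regressed on x = experimental; RMSE uses an n
denominator; the percentage-error spread is the sample SD (n−1); two-tailed
p-values come from Student's t with n−2 degrees of freedom; significance is
declared at p = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "RegressionResult",
    "regress",
    "percent_errors",
    "compare_models",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PairedMeasurements:
    """Experimental and predicted values of one endpoint, one specimen per
    entry."""

    experimental: np.ndarray
    predicted: np.ndarray
    labels: tuple = None

    def __post_init__(self):
        self.experimental = np.asarray(self.experimental, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.experimental.shape != self.predicted.shape:
            raise ValueError("experimental and predicted lengths differ")
        if len(self.experimental) < 3:
            raise ValueError("need at least 3 specimen pairs")
        if np.any(~np.isfinite(self.experimental)) or np.any(
            ~np.isfinite(self.predicted)
        ):
            raise ValueError("missing or non-finite values are not allowed")
        if self.labels is None:
            self.labels = tuple(range(len(self.experimental)))
        else:
            self.labels = tuple(self.labels)
            if len(self.labels) != len(self.experimental):
                raise ValueError("labels length mismatch")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    percent_error_mean: float
    percent_error_sd: float
    p_slope_vs_1: float
    p_intercept_vs_0: float
    n: int

    @property
    def slope_differs_from_1(self) -> bool:
        return self.p_slope_vs_1 < SIGNIFICANCE_LEVEL

    @property
    def intercept_differs_from_0(self) -> bool:
        return self.p_intercept_vs_0 < SIGNIFICANCE_LEVEL


def regress(data: PairedMeasurements) -> RegressionResult:
    """OLS of predicted on experimental with the agreement diagnostics.

    slope/intercept by least squares; R² as the squared Pearson correlation
    of the fit; RMSE = sqrt(mean squared residual); percentage error per
    pair = |pred − exp| / exp · 100 (mean ± sample SD); t statistics
    (b−1)/SE(b) and a/SE(a) with n−2 degrees of freedom, two-tailed.
    """
    x, y = data.experimental, data.predicted
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("experimental values have zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    b = sxy / sxx
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    rmse = float(np.sqrt(sse / n))

    dof = n - 2
    s2 = sse / dof if dof > 0 else 0.0
    se_b = float(np.sqrt(s2 / sxx))
    se_a = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))

    def two_tailed(t_num, se):
        if se == 0:
            return 1.0 if t_num == 0 else 0.0
        t = t_num / se
        return float(2.0 * sps.t.sf(abs(t), dof))

    pe_mean, pe_sd = percent_errors(data)
    return RegressionResult(
        slope=float(b),
        intercept=a,
        r_squared=float(r2),
        rmse=rmse,
        percent_error_mean=pe_mean,
        percent_error_sd=pe_sd,
        p_slope_vs_1=two_tailed(b - 1.0, se_b),
        p_intercept_vs_0=two_tailed(a, se_a),
        n=n,
    )


def percent_errors(data: PairedMeasurements):
    """Mean and sample SD (n−1) of per-pair |pred − exp| / exp · 100."""
    x, y = data.experimental, data.predicted
    if np.any(x == 0):
        raise ValueError("percentage error undefined for zero experimental value")
    pe = np.abs(y - x) / np.abs(x) * 100.0
    return float(pe.mean()), float(pe.std(ddof=1))


def compare_models(tables: dict, reference: str = None) -> pd.DataFrame:
    """Per-model agreement statistics plus model-vs-model regressions.

    Parameters
    ----------
    tables : dict
        ``{model name: {endpoint name: PairedMeasurements}}``.  All tables
        must share specimen labels.
    reference : str, optional
        Model against which every other model's *predictions* are also
        regressed (typically the hexahedral homogeneous variant).

    Returns
    -------
    DataFrame with one row per (model, endpoint) regression, including the
    inter-model rows (``vs`` column names the x-side dataset), significance
    flags at p = 0.05, and a note that RMSE uses an n denominator.
    """
    rows = []
    ref_labels = None
    for model, endpoints in tables.items():
        for endpoint, pm in endpoints.items():
            if ref_labels is None:
                ref_labels = pm.labels
            elif pm.labels != ref_labels:
                raise ValueError(
                    f"specimen labels of {model}/{endpoint} do not match"
                )
            rows.append((model, endpoint, "experimental", regress(pm)))
    if reference is not None:
        if reference not in tables:
            raise ValueError(f"reference model {reference!r} not in tables")
        for model, endpoints in tables.items():
            if model == reference:
                continue
            for endpoint, pm in endpoints.items():
                ref_pm = tables[reference][endpoint]
                pair = PairedMeasurements(
                    experimental=ref_pm.predicted,
                    predicted=pm.predicted,
                    labels=pm.labels,
                )
                rows.append((model, endpoint, reference, regress(pair)))

    records = []
    for model, endpoint, vs, res in rows:
        rec = {"model": model, "endpoint": endpoint, "vs": vs}
        rec.update(asdict(res))
        rec["slope_differs_from_1"] = res.slope_differs_from_1
        rec["intercept_differs_from_0"] = res.intercept_differs_from_0
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.attrs["rmse_denominator"] = "n"
    return df
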