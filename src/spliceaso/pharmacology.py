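"""Screen pharmacology: 2^-ddCt quantification, hit calling, 4PL fits.

Expression is quantified with the comparative-Ct method: dCt = Ct_target -
Ct_housekeeping per sample (technical replicates averaged first), ddCt =
dCt - mean dCt of the calibrator condition, fold change = 2^-ddCt.

Dose-response curves use the normalized variable-slope logistic model.
Stimulation readouts arrive on the raw percent-of-mock scale; a baseline of
100 (the mock level) is subtracted before fitting

    y = top / (1 + (EC50 / x) ** h)

so the reported EC50 is the *absolute* EC50 — the dose at which the curve
crosses 50% of the normalized 0-100 span (for this model the 50-crossing of
the span coincides with the EC50 parameter). Inhibition fits the decreasing
four-parameter form on the raw scale and reports the mid-span crossing as
the IC50. Optimization is bounded least squares in log10(EC50), multi-started
over a dose-range-spanning grid, so fits are deterministic and
dose-scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


def ddct_fold_change(
    measurements: pd.DataFrame,
    calibrator_condition: str,
    sample_col: str = "sample_id",
    condition_col: str = "condition",
    target_col: str = "ct_target",
    housekeeping_col: str = "ct_housekeeping",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold change versus a calibrator condition.

    Returns one row per (condition, sample) with dct, ddct, fold and
    percent columns. Technical replicates are averaged at the Ct level
    before calibration.
    """
    df = measurements.copy()
    if df[[target_col, housekeeping_col]].isna().any().any():
        raise ValueError("missing Ct values; every row needs target and housekeeping Ct")
    grouped = (
        df.groupby([condition_col, sample_col], sort=False)[[target_col, housekeeping_col]]
        .mean()
        .reset_index()
    )
    grouped["dct"] = grouped[target_col] - grouped[housekeeping_col]
    cal = grouped[grouped[condition_col] == calibrator_condition]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator_condition!r} not present")
    cal_mean = cal["dct"].mean()
    grouped["ddct"] = grouped["dct"] - cal_mean
    grouped["fold"] = np.power(2.0, -grouped["ddct"])
    grouped["percent"] = 100.0 * grouped["fold"]
    return grouped


def serial_dilution(start: float, factor: float, points: int) -> np.ndarray:
    """Descending geometric dose series start / factor**i, i = 0..points-1."""
    if start <= 0:
        raise ValueError("start must be positive")
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if points < 1:
        raise ValueError("points must be >= 1")
    return start / factor ** np.arange(points, dtype=float)


def call_hits(
    values,
    threshold_percent: float,
    at_dose: float | None = None,
    controls: tuple = (),
) -> list[str]:
    """ASOs whose percent-of-mock readout strictly exceeds the threshold.

    ``values`` is a mapping id -> percent, or a DataFrame with columns
    (id, dose, response) when ``at_dose`` selects the dose level (replicates
    averaged). Control ids are never called.
    """
    if isinstance(values, pd.DataFrame):
        if at_dose is None:
            per_aso = values.groupby("id")["response"].mean()
        else:
            sel = values[np.isclose(values["dose"], at_dose)]
            missing = set(values["id"]) - set(sel["id"])
            if missing:
                raise ValueError(f"dose {at_dose} missing for: {sorted(missing)}")
            per_aso = sel.groupby("id")["response"].mean()
        values = per_aso.to_dict()
    return sorted(
        aso for aso, v in values.items()
        if aso not in controls and v > threshold_percent
    )


@dataclass
class DoseResponseFit:
    """Results of one curve fit: potency estimate plus diagnostics."""

    aso_id: str
    mode: str  # "stimulation" (EC50) | "inhibition" (IC50)
    ec50_or_ic50: float
    hill: float
    r_squared: float
    converged: bool
    baseline_adjusted: bool
    top: float
    bottom: float
    extrapolated: bool
    n_points: int
    residual_ss: float

    @property
    def ec50(self) -> float:
        return self.ec50_or_ic50

    ic50 = ec50

    def summary(self) -> str:
        label = "EC50" if self.mode == "stimulation" else "IC50"
        lines = [
            f"Dose-response fit: {self.aso_id} ({self.mode})",
            f"  {label}:          {self.ec50_or_ic50:.4g}",
            f"  Hill slope:    {self.hill:.4g}",
            f"  Span:          {self.bottom:.4g} .. {self.top:.4g}",
            f"  R^2:           {self.r_squared:.4f}  (n = {self.n_points})",
            f"  Converged:     {self.converged}"
            + ("  [EC50 outside dose span]" if self.extrapolated else ""),
        ]
        return "\n".join(lines)


class DoseResponseModel:
    """Normalized variable-slope logistic model for one ASO's curve.

    statsmodels-style usage::

        fit = DoseResponseModel.from_dataframe(table, mode="stimulation").fit()
        print(fit.summary())
    """

    def __init__(self, dose, response, mode: str = "stimulation",
                 aso_id: str = "ASO", baseline: float = 100.0):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.size != self.response.size:
            raise ValueError("dose and response must have equal length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")
        if np.unique(self.dose).size < 2:
            raise ValueError("need at least 2 distinct doses to fit")
        if mode not in ("stimulation", "inhibition"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.aso_id = aso_id
        self.baseline = baseline

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, mode: str = "stimulation",
                       aso_id: str | None = None, baseline: float = 100.0,
                       replicate_policy: str = "pooled") -> "DoseResponseModel":
        """Build from a (dose, response[, replicate]) table; ``replicate_policy``
        'pooled' fits all points, 'means' fits per-dose replicate means."""
        if replicate_policy not in ("pooled", "means"):
            raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
        df = table
        if replicate_policy == "means":
            df = table.groupby("dose", as_index=False)["response"].mean()
        if aso_id is None:
            aso_id = str(table["aso_id"].iloc[0]) if "aso_id" in table else "ASO"
        return cls(df["dose"], df["response"], mode=mode, aso_id=aso_id, baseline=baseline)

    # -- fitting ------------------------------------------------------------
    def fit(self) -> DoseResponseFit:
        x = self.dose
        if self.mode == "stimulation":
            # baseline subtraction: percent-of-mock -> response above mock.
            # Negative adjusted values are retained as ordinary residual mass.
            y = self.response - self.baseline
        else:
            y = self.response

        # dimensionless doses: equivariance under dose rescaling is exact
        ref = float(np.max(x))
        xs = x / ref
        log_inits = np.linspace(np.log10(xs.min()), np.log10(xs.max()), 5)
        lb_log, ub_log = np.log10(xs.min()) - 3.0, np.log10(xs.max()) + 3.0
        span_guess = float(np.max(y) - min(0.0, np.min(y))) or 1.0

        if self.mode == "stimulation":
            def model(p):
                top, logc, h = p
                return top / (1.0 + (10.0 ** logc / xs) ** h)
            p0s = [(max(span_guess, 1e-6), lc, h0) for lc in log_inits for h0 in (0.5, 1.0, 2.0)]
            lower = [0.0, lb_log, 0.05]
            upper = [np.inf, ub_log, 10.0]
        else:
            ymax, ymin = float(np.max(y)), float(np.min(y))
            def model(p):
                top, bottom, logc, h = p
                return bottom + (top - bottom) / (1.0 + (xs / 10.0 ** logc) ** h)
            p0s = [(ymax, ymin, lc, h0) for lc in log_inits for h0 in (0.5, 1.0, 2.0)]
            lower = [-np.inf, -np.inf, lb_log, 0.05]
            upper = [np.inf, np.inf, ub_log, 10.0]

        best = None
        for p0 in p0s:
            try:
                res = least_squares(
                    lambda p: model(p) - y, x0=np.array(p0, dtype=float),
                    bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # singular geometry for one start is tolerable
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            return DoseResponseFit(self.aso_id, self.mode, np.nan, np.nan, np.nan,
                                   converged=False,
                                   baseline_adjusted=self.mode == "stimulation",
                                   top=np.nan, bottom=np.nan, extrapolated=False,
                                   n_points=x.size, residual_ss=np.nan)

        if self.mode == "stimulation":
            top, logc, h = best.x
            bottom = 0.0
        else:
            top, bottom, logc, h = best.x
        c50 = float(10.0 ** logc * ref)
        fitted = model(best.x)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        converged = bool(best.success and np.isfinite(c50) and np.isfinite(h))
        return DoseResponseFit(
            aso_id=self.aso_id,
            mode=self.mode,
            ec50_or_ic50=c50,
            hill=float(h),
            r_squared=r2,
            converged=converged,
            baseline_adjusted=self.mode == "stimulation",
            top=float(top),
            bottom=float(bottom),
            extrapolated=not (x.min() <= c50 <= x.max()),
            n_points=int(x.size),
            residual_ss=ss_res,
        )


def fit_dose_response(
    table: pd.DataFrame,
    mode: str = "stimulation",
    baseline: float = 100.0,
    replicate_policy: str = "pooled",
    aso_id: str | None = None,
) -> DoseResponseFit:
    """Functional front-end to :class:`DoseResponseModel` (see its docs)."""
    import warnings

    if table["dose"].nunique() < 4:
        warnings.warn("fewer than 4 dose points; the 4PL fit may be ill-determined",
                      stacklevel=2)
    model = DoseResponseModel.from_dataframe(
        table, mode=mode, aso_id=aso_id, baseline=baseline,
        replicate_policy=replicate_policy,
    )
    return model.fit()


def fits_to_frame(fits: list[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])
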