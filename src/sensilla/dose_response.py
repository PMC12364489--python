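"""Constrained log(agonist)-vs-response fitting and ED50 estimation.

The model is the three-parameter log-logistic ("log(agonist) vs response")
family with the Hill slope fixed at 1:

    R(d) = bottom + (top - bottom) / (1 + 10^(log10 ED50 - log10 d))

fit by least squares under the constraints bottom >= 0 and top >= bottom.
ED50 is the dose (amount on filter paper, ng) producing the half-maximal
response.  A free-Hill-slope variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["DoseResponseFit", "log_logistic", "fit_log_logistic",
           "dose_response_table"]


def log_logistic(dose: np.ndarray | float, bottom: float, top: float,
                 log10_ed50: float, hill: float = 1.0) -> np.ndarray | float:
    """Three-parameter log-logistic response curve (Hill slope ``hill``).

    ``R(d) = bottom + (top - bottom) / (1 + 10^(hill * (log10 ED50 - log10 d)))``
    """
    d = np.log10(dose)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ed50 - d)))


def _model(dose: np.ndarray, bottom: float, span: float, log10_ed50: float,
           hill: float) -> np.ndarray:
    return bottom + span / (1.0 + 10.0 ** (hill * (log10_ed50 - np.log10(dose))))


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a constrained log-logistic fit."""

    bottom: float
    top: float
    log10_ed50: float
    hill: float
    residual_sum_squares: float
    n_points: int
    ed50_identifiable: bool
    doses: np.ndarray
    fitted_means: np.ndarray

    @property
    def ed50(self) -> float:
        """ED50 on the dose scale (ng)."""
        return float(10.0 ** self.log10_ed50)

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        return _model(np.asarray(dose, dtype=float), self.bottom,
                      self.top - self.bottom, self.log10_ed50, self.hill)

    def to_dict(self) -> dict:
        return {"bottom": self.bottom, "top": self.top,
                "ed50_ng": self.ed50, "log10_ed50": self.log10_ed50,
                "hill": self.hill,
                "residual_sum_squares": self.residual_sum_squares,
                "n_points": self.n_points,
                "ed50_identifiable": self.ed50_identifiable}


def fit_log_logistic(doses: np.ndarray, responses: np.ndarray,
                     free_slope: bool = False,
                     on_means: bool = False) -> DoseResponseFit:
    """Least-squares fit of the constrained log-logistic dose-response model.

    Parameters
    ----------
    doses, responses : array-like
        Paired observations; doses in ng (> 0), responses in delta spikes/s.
        Replicates are passed as repeated dose values.
    free_slope : bool
        Fit the Hill slope as a fourth parameter instead of fixing it at 1.
    on_means : bool
        Collapse replicates to per-dose means before fitting.

    The fit is deterministic: initialization uses bottom0 = max(0, min
    response), top0 = max response, and log10 ED50 started at the dose whose
    mean response is nearest to half-maximal.  ``ed50_identifiable`` is False
    for degenerate flat data (fitted span indistinguishable from the residual
    noise), in which case the ED50 value should not be interpreted.
    """
    doses = np.asarray(doses, dtype=float).ravel()
    responses = np.asarray(responses, dtype=float).ravel()
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    unique_doses = np.unique(doses)
    if len(unique_doses) < 3:
        raise ValueError("need at least 3 distinct doses")

    dose_means = np.array([responses[doses == d].mean() for d in unique_doses])
    if on_means:
        fit_d, fit_r = unique_doses, dose_means
    else:
        fit_d, fit_r = doses, responses

    bottom0 = max(0.0, float(fit_r.min()))
    top0 = float(fit_r.max())
    span0 = max(top0 - bottom0, 1e-6)
    half = bottom0 + span0 / 2.0
    log10_ed50_0 = float(np.log10(
        unique_doses[np.argmin(np.abs(dose_means - half))]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        bottom, span, log_ed50 = theta[:3]
        hill = theta[3] if free_slope else 1.0
        return _model(fit_d, bottom, span, log_ed50, hill) - fit_r

    x0 = [bottom0, span0, log10_ed50_0]
    lo = [0.0, 0.0, -12.0]
    hi = [np.inf, np.inf, 12.0]
    if free_slope:
        x0.append(1.0)
        lo.append(1e-3)
        hi.append(10.0)

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    bottom, span, log10_ed50 = sol.x[:3]
    hill = float(sol.x[3]) if free_slope else 1.0
    rss = float(np.sum(sol.fun ** 2))

    # flat-data guard: if the fitted curve barely varies across the observed
    # dose range (e.g. the optimizer pushed ED50 far outside it), the ED50 is
    # not identified by these data
    dof = max(len(fit_r) - len(sol.x), 1)
    resid_scale = np.sqrt(rss / dof)
    observed_rise = (_model(unique_doses.max(), bottom, span, log10_ed50, hill)
                     - _model(unique_doses.min(), bottom, span, log10_ed50,
                              hill))
    identifiable = bool(observed_rise > 2.0 * resid_scale
                        and observed_rise > 1e-9)

    fitted_means = _model(unique_doses, bottom, span, log10_ed50, hill)
    return DoseResponseFit(bottom=float(bottom), top=float(bottom + span),
                           log10_ed50=float(log10_ed50), hill=hill,
                           residual_sum_squares=rss, n_points=len(fit_r),
                           ed50_identifiable=identifiable,
                           doses=unique_doses, fitted_means=fitted_means)


def fit_table(table: pd.DataFrame, **kwargs) -> DoseResponseFit:
    """Fit from a tidy table with columns ``dose_ng`` and ``response``."""
    return fit_log_logistic(table["dose_ng"].to_numpy(),
                            table["response"].to_numpy(), **kwargs)


def dose_response_table(fit: DoseResponseFit, doses: np.ndarray,
                        responses: np.ndarray,
                        n_curve: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dose mean ± SEM plus a sampled fitted curve, both as tidy frames.

    Returns ``(summary, curve)``: the summary has columns dose_ng, mean, sem,
    n, fitted; the curve samples the fitted model at ``n_curve`` log-spaced
    doses spanning the observed range (for plotting).
    """
    doses = np.asarray(doses, dtype=float).ravel()
    responses = np.asarray(responses, dtype=float).ravel()
    rows = []
    for d in np.unique(doses):
        r = responses[doses == d]
        sem = r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan
        rows.append((d, r.mean(), sem, len(r), float(fit.predict(d))))
    summary = pd.DataFrame(rows,
                           columns=["dose_ng", "mean", "sem", "n", "fitted"])
    grid = np.logspace(np.log10(doses.min()), np.log10(doses.max()), n_curve)
    curve = pd.DataFrame({"dose_ng": grid, "fitted": fit.predict(grid)})
    return summary, curve
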