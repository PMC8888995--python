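"""Four-parameter-logistic dose-response fitting and hit confirmation.

The confirmation assay re-tests each primary hit over an 8-point,
3-fold dilution series from a 10 uM top concentration, in two
independent experiments on different biological material.  Responses
(% of control) are fitted with the four-parameter logistic

    y(x) = d + (a - d) / (1 + (ec50 / x)^hill)

where d is the zero-dose plateau, a the saturating-dose plateau, ec50
the midpoint concentration and hill the slope.  After fitting, hill is
canonicalized positive (the model is invariant under swapping a and d
while negating hill), so ``lower_asymptote`` is always the zero-dose
plateau and ``upper_asymptote`` the high-dose plateau; for an enhancer
the upper asymptote is the maximal effect.  The reported ECx is the
fitted midpoint (relative EC50) paired with that maximal effect; an
absolute-effect variant is available as :func:`ec_absolute` and never
silently substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Confirmation",
    "DoseSeries",
    "FourPLFit",
    "confirm_hit",
    "dilution_series",
    "ec_absolute",
    "estimate_ecx",
    "fit_4pl",
    "four_pl",
]


@dataclass(frozen=True)
class DoseSeries:
    """Geometric dilution design: c_k = top / fold^k, k = 0..n_points-1."""

    top_concentration: float = 10.0
    fold: float = 3.0
    n_points: int = 8

    def __post_init__(self) -> None:
        if not np.isfinite(self.top_concentration) or self.top_concentration <= 0:
            raise ValueError("top_concentration must be > 0")
        if not np.isfinite(self.fold) or self.fold <= 1.0:
            raise ValueError("fold must be > 1")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def dilution_series(cfg: DoseSeries = DoseSeries()) -> np.ndarray:
    """Concentrations of the dilution design, strictly decreasing, uM."""
    k = np.arange(cfg.n_points)
    return cfg.top_concentration / cfg.fold**k


def four_pl(x, d: float, a: float, ec50: float, hill: float):
    """Four-parameter logistic evaluated at concentrations x > 0."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (ec50 / x) ** hill)


@dataclass
class FourPLFit:
    """Result of one 4PL fit (all response values in % of control)."""

    lower_asymptote: float  # zero-dose plateau d
    upper_asymptote: float  # saturating-dose plateau a
    ec50: float
    hill: float
    ecx: float
    max_effect_percent_of_control: float
    converged: bool
    degenerate: bool
    rss: float
    message: str = ""

    def predict(self, x):
        return four_pl(x, self.lower_asymptote, self.upper_asymptote, self.ec50, self.hill)


def _canonicalize(params: np.ndarray) -> np.ndarray:
    """Make hill positive; (d, a, c, b) -> (a, d, c, -b) is the same curve."""
    d, a, c, b = params
    if b < 0:
        return np.array([a, d, c, -b])
    return params


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    weights: Sequence[float] | None = None,
    asymptote_zero_bounds: tuple[float, float] = (50.0, 150.0),
    asymptote_inf_bounds: tuple[float, float] = (50.0, 300.0),
    max_abs_hill: float = 10.0,
    degenerate_tol: float = 0.5,
) -> FourPLFit:
    """Least-squares 4PL fit with deterministic multi-start.

    Eight starts (two log-spaced midpoint guesses x hill in
    {0.5, 2, -0.5, -2}) are refined by trust-region least squares
    within bounds chosen for 8-point designs: zero-dose plateau in
    [50, 150] %, high-dose plateau in [50, 300] %, midpoint within
    [lowest dose / 10, highest dose x 10], |hill| <= 10.  The best
    start by residual sum of squares wins; a fit whose two plateaus
    differ by less than ``degenerate_tol`` percentage points is flagged
    degenerate (EC50 unidentifiable) rather than raising.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations for a 4PL fit")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("concentrations must be finite and > 0")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    if np.ptp(y) == 0.0:  # exactly constant responses: nothing to fit
        level = float(y[0])
        return FourPLFit(level, level, float("nan"), float("nan"), float("nan"),
                         float("nan"), False, True, 0.0, "constant responses")

    def residuals(p):
        return w * (four_pl(x, *p) - y)

    def jacobian(p):
        d, a, c, b = p
        u = (c / x) ** b
        s = 1.0 / (1.0 + u)
        s2u = s * s * u
        J = np.empty((x.size, 4))
        J[:, 0] = 1.0 - s
        J[:, 1] = s
        J[:, 2] = -(a - d) * s2u * b / c
        J[:, 3] = -(a - d) * s2u * np.log(c / x)
        return w[:, None] * J

    c_lo, c_hi = x.min() / 10.0, x.max() * 10.0
    lo = np.array([asymptote_zero_bounds[0], asymptote_inf_bounds[0], c_lo, -max_abs_hill])
    hi = np.array([asymptote_zero_bounds[1], asymptote_inf_bounds[1], c_hi, max_abs_hill])

    d0 = float(np.clip(y[np.argmin(x)], *asymptote_zero_bounds))
    a0 = float(np.clip(y[np.argmax(x)], *asymptote_inf_bounds))
    log_lo, log_hi = np.log10(x.min()), np.log10(x.max())
    c_starts = 10 ** np.array([log_lo + (log_hi - log_lo) / 3, log_lo + 2 * (log_hi - log_lo) / 3])
    b_starts = (0.5, 2.0, -0.5, -2.0)

    best = None
    for c0 in c_starts:
        for b0 in b_starts:
            p0 = np.clip(np.array([d0, a0, c0, b0]), lo + 1e-12, hi - 1e-12)
            try:
                sol = least_squares(
                    residuals, p0, jac=jacobian, bounds=(lo, hi), method="trf",
                    ftol=1e-11, xtol=1e-11, gtol=1e-11, max_nfev=150,
                    x_scale=np.array([50.0, 50.0, 1.0, 1.0]),
                )
            except Exception:  # numerical failure of one start is not fatal
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol)

    if best is None:
        nan = float("nan")
        return FourPLFit(nan, nan, nan, nan, nan, nan, False, False, float("inf"),
                         "no start converged")
    rss, sol = best
    d, a, c, b = _canonicalize(sol.x)
    degenerate = abs(a - d) < degenerate_tol
    converged = not degenerate
    ecx = c if converged else float("nan")
    max_eff = a if converged else float("nan")
    return FourPLFit(
        lower_asymptote=float(d),
        upper_asymptote=float(a),
        ec50=float(c),
        hill=float(b),
        ecx=float(ecx),
        max_effect_percent_of_control=float(max_eff),
        converged=converged,
        degenerate=degenerate,
        rss=rss,
        message=sol.message,
    )


def estimate_ecx(fit: FourPLFit) -> tuple[float, float]:
    """(ECx in uM, maximal effect in % of control) of a converged fit.

    ECx is the fitted midpoint concentration (relative EC50); the
    paired % of control is the fitted high-dose plateau — the two-column
    presentation confirmation tables use.
    """
    if not fit.converged or fit.degenerate:
        raise ValueError("no ECx estimate: fit did not converge or is degenerate")
    return fit.ec50, fit.max_effect_percent_of_control


def ec_absolute(fit: FourPLFit, target_percent_of_control: float) -> float:
    """Concentration at which the fitted curve reaches an absolute
    response level (named alternative to the relative-EC50 reading).

    Solves y(x) = target for x; raises if the target lies outside the
    open interval between the two plateaus.
    """
    if not fit.converged or fit.degenerate:
        raise ValueError("no estimate from a degenerate fit")
    d, a, c, b = fit.lower_asymptote, fit.upper_asymptote, fit.ec50, fit.hill
    t = target_percent_of_control
    lo, hi = min(d, a), max(d, a)
    if not (lo < t < hi):
        raise ValueError("target response outside the fitted response range")
    # t = d + (a-d)/(1+(c/x)^b)  =>  (c/x)^b = (a-t)/(t-d)
    ratio = (a - t) / (t - d)
    return float(c / ratio ** (1.0 / b))


@dataclass(frozen=True)
class Confirmation:
    confirmed: bool
    reason: str


def confirm_hit(
    fits: Sequence[FourPLFit],
    min_effect: float = 20.0,
    min_experiments: int = 2,
) -> Confirmation:
    """Two-independent-experiment confirmation rule.

    A compound is confirmed only if every experiment's fit converged
    and shows an enhancing plateau of at least ``100 + min_effect`` %
    of control.  Missing experiments make the compound unconfirmed with
    a reason code, not an exception.
    """
    if len(fits) < min_experiments:
        return Confirmation(False, f"missing_experiments:{len(fits)}/{min_experiments}")
    for i, fit in enumerate(fits, start=1):
        if fit is None:
            return Confirmation(False, f"missing_fit:experiment_{i}")
        if not fit.converged or fit.degenerate:
            return Confirmation(False, f"not_converged:experiment_{i}")
        if fit.max_effect_percent_of_control < 100.0 + min_effect:
            return Confirmation(False, f"effect_below_threshold:experiment_{i}")
    return Confirmation(True, "confirmed")
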