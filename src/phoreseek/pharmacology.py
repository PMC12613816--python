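"""Concentration-response analytics: 4PL fits, dose ratios, Schild analysis.

The four-parameter logistic (4PL) model

    r(c) = bottom + (top - bottom) / (1 + (c50 / c)^hill)

is fitted by least squares in log10(c50) space with analytic gradients and
multi-start initialization (the Hill sign is the classic local-minimum
trap).  Competitive antagonism is quantified through dose ratios
DR(B) = c50(B) / c50(0) and the Schild regression of log10(DR - 1) on
log10 [B]: slope 1 and a B-independent maximal response are the signatures
of simple competition, with pA2 (the x-intercept magnitude) estimating
-log10 K_B.  Both the unconstrained and the unity-slope-constrained fit
are reported, mirroring how Schild plots are customarily drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    DesignError,
    NoAntagonismError,
)


@dataclass(frozen=True)
class DoseResponse:
    """One concentration-response curve (single antagonist concentration)."""

    concentrations: np.ndarray  # molar, > 0
    responses: np.ndarray  # assay units
    antagonist_concentration: float = 0.0  # molar, 0 for control
    replicate_ids: tuple | None = None
    molecule: str = ""
    unit: str = "M"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise DesignError("concentrations and responses must be matching 1-D arrays")
        if (c <= 0).any():
            raise DesignError("concentrations must be positive")
        if not np.all(np.isfinite(r)):
            raise DesignError("responses must be finite")
        if self.antagonist_concentration < 0:
            raise DesignError("antagonist concentration must be non-negative")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    @property
    def n_distinct_concentrations(self) -> int:
        return len(np.unique(self.concentrations))


@dataclass(frozen=True)
class FourPLFit:
    """A fitted 4PL curve (canonicalized so that bottom <= top)."""

    bottom: float
    top: float
    hill: float
    half_max_conc: float  # EC50 or IC50 depending on `direction`
    log_half_max_se: float
    ci95: tuple[float, float]  # on half_max_conc, molar
    converged: bool
    residual_sd: float
    direction: str = "stimulation"
    top_ci95: tuple[float, float] = (float("nan"), float("nan"))
    hill_ci95: tuple[float, float] = (float("nan"), float("nan"))
    antagonist_concentration: float = 0.0
    n_obs: int = 0

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return _fourpl(c, self.bottom, self.top, self.hill, math.log10(self.half_max_conc))


def _fourpl(c: np.ndarray, bottom: float, top: float, hill: float, logc50: float) -> np.ndarray:
    # parameterized in log10(c50); stable form via the logistic in log space
    x = hill * (np.log10(c) - logc50)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (-x))


def _residuals(theta, c, y):
    b, t, h, l = theta
    return _fourpl(c, b, t, h, l) - y


def _jacobian(theta, c, y):
    b, t, h, l = theta
    logc = np.log10(c)
    x = h * (logc - l)
    s = 1.0 / (1.0 + 10.0 ** (-x))  # logistic in base-10 log space
    ds_dx = math.log(10.0) * s * (1.0 - s)
    J = np.empty((len(c), 4))
    J[:, 0] = 1.0 - s
    J[:, 1] = s
    J[:, 2] = (t - b) * ds_dx * (logc - l)
    J[:, 3] = (t - b) * ds_dx * (-h)
    return J


def fit_4pl(
    data: DoseResponse,
    direction: str = "stimulation",
    ci_method: str = "asymptotic",
    n_boot: int = 500,
    boot_seed: int = 0,
) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    ``direction`` only labels the half-max semantics (EC50 for
    stimulation, IC50 for inhibition); the model itself is fitted with a
    free Hill sign and canonicalized afterwards (swap asymptotes / negate
    hill leaves the curve unchanged).  95% confidence intervals on the
    log10 half-max are asymptotic (t-based) by default; pass
    ``ci_method="bootstrap"`` for a residual-bootstrap percentile interval
    (``n_boot`` refits), which is more honest at small n.
    Non-convergence is reported in-band via ``converged``.
    """
    if direction not in ("stimulation", "inhibition"):
        raise ValueError("direction must be 'stimulation' or 'inhibition'")
    if data.n_distinct_concentrations < 4:
        raise DesignError(
            f"need >=4 distinct concentrations, got {data.n_distinct_concentrations}"
        )
    c = data.concentrations
    y = data.responses
    if float(np.var(y)) == 0.0:
        raise DegenerateFitError("responses have zero variance")

    lo, hi = float(y.min()), float(y.max())
    mid = 0.5 * (lo + hi)
    logc = np.log10(c)
    # quartile-style starting half-max: concentration whose response is
    # closest to the midpoint, plus the design's log-center
    l_near = float(logc[np.argmin(np.abs(y - mid))])
    l_center = float(np.median(logc))
    starts = [
        (lo, hi, 1.0, l_near),
        (lo, hi, -1.0, l_near),
        (lo, hi, 2.0, l_center),
    ]
    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                _residuals, theta0, jac=_jacobian, args=(c, y), method="lm", max_nfev=5000
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-14:
            best = res
    if best is None:
        raise DegenerateFitError("all optimizer starts failed")

    b, t, h, l = best.x
    if h < 0:  # canonicalize: bottom <= top, hill > 0
        b, t, h = t, b, -h
    if b > t:
        b, t = t, b

    n, p = len(y), 4
    dof = max(n - p, 1)
    ssr = 2.0 * best.cost
    s2 = ssr / dof
    J = _jacobian((b, t, h, l), c, y)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    tq = stats.t.ppf(0.975, dof)
    se_l = float(se[3])
    # clip the log-scale interval before exponentiating; a CI wider than
    # 300 decades is already "unbounded" for any practical purpose
    ci_l = (max(l - tq * se_l, -300.0), min(l + tq * se_l, 300.0))
    if ci_method == "bootstrap":
        ci_l = _bootstrap_log_half_ci((b, t, h, l), c, y, n_boot, boot_seed)
    elif ci_method != "asymptotic":
        raise ValueError("ci_method must be 'asymptotic' or 'bootstrap'")
    return FourPLFit(
        bottom=float(b),
        top=float(t),
        hill=float(h),
        half_max_conc=float(10.0 ** l),
        log_half_max_se=se_l,
        ci95=(float(10.0 ** ci_l[0]), float(10.0 ** ci_l[1])),
        converged=bool(best.success),
        residual_sd=float(np.sqrt(s2)),
        direction=direction,
        top_ci95=(float(t - tq * se[1]), float(t + tq * se[1])),
        hill_ci95=(float(h - tq * se[2]), float(h + tq * se[2])),
        antagonist_concentration=float(data.antagonist_concentration),
        n_obs=n,
    )


def _bootstrap_log_half_ci(theta, c, y, n_boot, seed):
    """Residual-bootstrap percentile CI on log10(half_max)."""
    resid = _residuals(theta, c, y)
    fitted = y + resid
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = fitted - rng.choice(resid, size=len(resid), replace=True)
        try:
            res = optimize.least_squares(
                _residuals, theta, jac=_jacobian, args=(c, y_star), method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        draws.append(res.x[3])
    if len(draws) < max(20, n_boot // 10):
        return (-300.0, 300.0)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Dose ratios and Schild regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseRatio:
    antagonist_concentration: float  # B, molar
    ratio: float  # DR = c50(B) / c50(0)

    @property
    def usable(self) -> bool:
        return self.ratio > 1.0


def dose_ratios(control: FourPLFit, treated: list[FourPLFit]) -> list[DoseRatio]:
    """DR(B) = half-max with antagonist / control half-max.

    Points with DR <= 1 are flagged (``usable`` False) and excluded from
    the downstream regression.
    """
    if control is None:
        raise ValueError("control fit is required")
    for f in [control, *treated]:
        if not f.converged:
            raise DesignError("all fits must have converged")
    out = [
        DoseRatio(f.antagonist_concentration, f.half_max_conc / control.half_max_conc)
        for f in treated
    ]
    out.sort(key=lambda d: d.antagonist_concentration)
    return out


@dataclass(frozen=True)
class SchildResult:
    dose_ratios: tuple[DoseRatio, ...]
    excluded: tuple[DoseRatio, ...]
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    pA2: float
    pKB_constrained: float
    parallel_shift_ok: bool | None
    emax_unchanged_ok: bool | None

    @property
    def competitive(self) -> bool | None:
        """Simple-competition diagnostic: unit slope within CI and unchanged Emax."""
        covers_unity = self.slope_ci95[0] <= 1.0 <= self.slope_ci95[1]
        if self.emax_unchanged_ok is None:
            return covers_unity
        return covers_unity and self.emax_unchanged_ok


def _ci_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def emax_unchanged(control: FourPLFit, treated: list[FourPLFit]) -> bool:
    """Whether every treated curve's maximal response matches the control's.

    Judged by overlap of the asymptotic 95% CIs on the top parameter; an
    antagonist that suppresses the attainable maximum (non-competitive
    behavior) fails this check.
    """
    return all(_ci_overlap(f.top_ci95, control.top_ci95) for f in treated)


def parallel_shift(control: FourPLFit, treated: list[FourPLFit]) -> bool:
    """Whether Hill slopes are mutually compatible (95%-CI overlap)."""
    return all(_ci_overlap(f.hill_ci95, control.hill_ci95) for f in treated)


def schild_regression(
    ratios: list[DoseRatio],
    control: FourPLFit | None = None,
    treated: list[FourPLFit] | None = None,
) -> SchildResult:
    """Schild plot regression of log10(DR - 1) on log10 [B].

    The unconstrained ordinary least-squares line gives the Schild slope
    and pA2 (minus the x-intercept); the unity-constrained fit gives
    pK_B = mean(log10(DR - 1) - log10 B).  When the underlying 4PL fits
    are supplied, two diagnostics are evaluated by 95%-CI overlap against
    the control curve: unchanged maximal response (Emax) and parallel
    shift (Hill slopes).
    """
    usable = tuple(r for r in ratios if r.usable)
    excluded = tuple(r for r in ratios if not r.usable)
    if not usable:
        raise NoAntagonismError("no dose ratio exceeds 1; no antagonism to regress")
    if len(usable) < 2:
        raise DesignError("need >=2 usable (DR>1) points for the Schild regression")
    x = np.log10([r.antagonist_concentration for r in usable])
    yv = np.log10([r.ratio - 1.0 for r in usable])

    lr = stats.linregress(x, yv)
    dof = len(usable) - 2
    if dof > 0 and np.isfinite(lr.stderr) and lr.stderr > 0:
        tq = stats.t.ppf(0.975, dof)
        slope_ci = (lr.slope - tq * lr.stderr, lr.slope + tq * lr.stderr)
    else:
        slope_ci = (lr.slope, lr.slope)
    pA2 = lr.intercept / lr.slope if lr.slope != 0 else float("nan")
    pKB_constrained = float(np.mean(yv - x))

    emax_ok = parallel_ok = None
    if control is not None and treated:
        emax_ok = emax_unchanged(control, treated)
        parallel_ok = parallel_shift(control, treated)

    return SchildResult(
        dose_ratios=usable,
        excluded=excluded,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        slope_ci95=(float(slope_ci[0]), float(slope_ci[1])),
        pA2=float(pA2),
        pKB_constrained=pKB_constrained,
        parallel_shift_ok=parallel_ok,
        emax_unchanged_ok=emax_ok,
    )


def schild_analysis(
    curves: list[DoseResponse], direction: str = "stimulation"
) -> tuple[FourPLFit, list[FourPLFit], SchildResult]:
    """End-to-end Schild analysis from raw curves.

    ``curves`` must contain exactly one control (antagonist concentration
    0) and >= 2 antagonist curves.  Returns the control fit, treated fits
    and the Schild regression with diagnostics.
    """
    controls = [d for d in curves if d.antagonist_concentration == 0]
    treated_data = sorted(
        (d for d in curves if d.antagonist_concentration > 0),
        key=lambda d: d.antagonist_concentration,
    )
    if len(controls) != 1:
        raise DesignError(f"need exactly one control curve, got {len(controls)}")
    if len(treated_data) < 2:
        raise DesignError("need >=2 antagonist concentrations")
    control_fit = fit_4pl(controls[0], direction)
    treated_fits = [fit_4pl(d, direction) for d in treated_data]
    ratios = dose_ratios(control_fit, treated_fits)
    result = schild_regression(ratios, control=control_fit, treated=treated_fits)
    return control_fit, treated_fits, result
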