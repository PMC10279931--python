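"""Co-localisation statistics and correlation-decay fitting.

Per eye, the two binned tracer profiles are compared by Pearson correlation
(with the accompanying bin-wise linear regression).  Across eyes, the decay
of r with the inter-label interval dt is fitted to an exponential,
``r(dt) = A * exp(-lambda * dt)``, whose half-life ``tau = ln2 / lambda`` is
the headline dynamic quantity: the time for two segmental outflow patterns
to lose half their spatial correlation.  The fit is exposed statsmodels
style as :class:`ExponentialDecayModel` / :class:`ExponentialDecayResults`;
``fit_exponential_decay`` is the functional shorthand.  Group comparisons
use classical one- and two-sample t-tests on the per-eye r values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .profile import TracerProfile, scaling_factor_pixels
from .straighten import StraightenedTM

__all__ = [
    "EyeCorrelation",
    "TTestResult",
    "ExponentialDecayModel",
    "ExponentialDecayResults",
    "pearson_r",
    "pooled_r",
    "fit_exponential_decay",
    "one_sample_t",
    "two_sample_t",
    "half_life_from_single_r",
    "difference_image",
    "render_difference",
]

LN2 = float(np.log(2.0))
_TAU_BOUNDS_DAYS = (1e-3, 1e4)


@dataclass
class EyeCorrelation:
    """One eye's co-localisation summary: Pearson r and bin-wise regression."""

    eye_id: str
    r: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_valid_bins: int
    delta_t_days: Optional[float] = None
    groups: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")
        if self.n_valid_bins < 3:
            raise ValueError("a reported r needs >= 3 valid bins")


def _regress(x: np.ndarray, y: np.ndarray) -> tuple:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    res = sps.linregress(x, y)
    n = x.size
    tcrit = sps.t.ppf(0.975, n - 2) if n > 2 else np.nan
    slope_ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    icept_ci = (
        res.intercept - tcrit * res.intercept_stderr,
        res.intercept + tcrit * res.intercept_stderr,
    )
    return res, slope_ci, icept_ci


def pearson_r(
    profile: TracerProfile,
    eye_id: Optional[str] = None,
    delta_t_days: Optional[float] = None,
    groups: Optional[dict] = None,
) -> EyeCorrelation:
    """Pearson r between the two tracer profiles of one eye, over valid bins.

    The bin-wise regression (scaled blue on the x axis, red on y) supplies
    slope/intercept and their 95% confidence intervals from the t
    distribution with n - 2 degrees of freedom.
    """
    keep = profile.valid
    if keep.sum() < 3:
        raise ValueError("need >= 3 valid bins for a correlation")
    x = np.asarray(profile.blue_mean)[keep]
    y = np.asarray(profile.red_mean)[keep]
    res, slope_ci, icept_ci = _regress(x, y)
    return EyeCorrelation(
        eye_id=eye_id if eye_id is not None else profile.eye_id,
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=slope_ci,
        intercept_ci=icept_ci,
        n_valid_bins=int(keep.sum()),
        delta_t_days=delta_t_days if delta_t_days is not None else profile.delta_t_days,
        groups=groups or {},
    )


def pooled_r(profiles: Sequence[TracerProfile]) -> EyeCorrelation:
    """Correlation over the concatenated valid bins of several eyes.

    Pooling happens *before* correlating, as in a figure that scatters all
    bins of a dt group together; between-eye mean differences therefore
    contribute, so the pooled r can differ from every per-eye r.
    """
    xs, ys, n = [], [], 0
    for p in profiles:
        keep = p.valid
        xs.append(np.asarray(p.blue_mean)[keep])
        ys.append(np.asarray(p.red_mean)[keep])
        n += int(keep.sum())
    if n < 3:
        raise ValueError("need >= 3 valid bins in total")
    x, y = np.concatenate(xs), np.concatenate(ys)
    res, slope_ci, icept_ci = _regress(x, y)
    return EyeCorrelation(
        eye_id="pooled",
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=slope_ci,
        intercept_ci=icept_ci,
        n_valid_bins=n,
    )


# ---------------------------------------------------------------------------
# Exponential decay of r versus dt
# ---------------------------------------------------------------------------

def _profiled_sse(lam: float, dt: np.ndarray, r: np.ndarray, free_amplitude: bool):
    """SSE at decay rate lam; amplitude profiled out analytically if free."""
    e = np.exp(-lam * dt)
    if free_amplitude:
        denom = float(e @ e)
        amp = float(r @ e) / denom if denom > 0 else 0.0
    else:
        amp = 1.0
    resid = r - amp * e
    return float(resid @ resid), amp


def _fit_lambda(dt: np.ndarray, r: np.ndarray, free_amplitude: bool) -> tuple[float, float]:
    """Minimise the (profiled) SSE over the decay rate.

    The objective is flat to machine precision for large lambda (all
    exponentials underflow), so a bounded search over the full range can
    stall in the tail.  A coarse log-spaced scan brackets the minimum
    first; Brent then polishes it inside the bracket.
    """
    lo, hi = LN2 / _TAU_BOUNDS_DAYS[1], LN2 / _TAU_BOUNDS_DAYS[0]
    grid = np.geomspace(lo, hi, 200)
    # vectorised coarse scan
    e = np.exp(-np.outer(grid, dt))
    if free_amplitude:
        denom = np.einsum("ij,ij->i", e, e)
        amp_g = np.where(denom > 0, (e @ r) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        amp_g = np.ones(grid.size)
    resid = r[None, :] - amp_g[:, None] * e
    sse_g = np.einsum("ij,ij->i", resid, resid)
    k = int(np.argmin(sse_g))
    b_lo, b_hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda lam: _profiled_sse(lam, dt, r, free_amplitude)[0],
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-14},
    )
    lam = float(res.x)
    _, amp = _profiled_sse(lam, dt, r, free_amplitude)
    return lam, amp


class ExponentialDecayModel:
    """Exponential decay of per-eye correlation versus inter-label interval.

    Model: ``E[r_e] = A * exp(-lambda * dt_e)`` with each eye weighted
    equally.  The default form fixes ``A = 1`` (two simultaneously delivered
    tracers are perfectly correlated in expectation); ``model_form="free"``
    estimates the amplitude as well, profiled out analytically so the
    optimisation stays one-dimensional in ``lambda``.

    Parameters
    ----------
    delta_t_days, r
        Per-eye inter-label intervals and Pearson correlations.
    model_form
        ``"fixed"`` (A = 1, default) or ``"free"``.
    """

    def __init__(self, delta_t_days, r, model_form: str = "fixed"):
        self.delta_t = np.asarray(delta_t_days, dtype=float)
        self.r = np.asarray(r, dtype=float)
        if model_form not in ("fixed", "free"):
            raise ValueError("model_form must be 'fixed' or 'free'")
        self.model_form = model_form
        if self.delta_t.shape != self.r.shape or self.delta_t.ndim != 1:
            raise ValueError("delta_t_days and r must be 1-D and equal length")
        if np.any(self.delta_t < 0):
            raise ValueError("delta_t_days must be >= 0")
        if self.delta_t.size < 2:
            raise ValueError("need at least 2 observations")
        if np.unique(self.delta_t).size < 2:
            raise ValueError("need at least 2 distinct delta_t values to identify the decay rate")

    @classmethod
    def from_eyes(cls, eyes: Sequence[EyeCorrelation], model_form: str = "fixed"):
        if any(e.delta_t_days is None for e in eyes):
            raise ValueError("every eye needs a delta_t_days")
        return cls([e.delta_t_days for e in eyes], [e.r for e in eyes], model_form)

    def fit(self, n_boot: int = 2000, seed=None) -> "ExponentialDecayResults":
        """Nonlinear least squares for lambda; bootstrap-over-eyes 95% CI.

        The CI resamples eyes with replacement ``n_boot`` times and takes
        the 2.5/97.5 percentiles of the refitted half-life; degenerate
        resamples (a single distinct dt) are dropped.  ``n_boot=0`` skips
        the bootstrap.
        """
        lam, amp = _fit_lambda(self.delta_t, self.r, self.model_form == "free")
        sse, _ = _profiled_sse(lam, self.delta_t, self.r, self.model_form == "free")
        tau = LN2 / lam
        if not (_TAU_BOUNDS_DAYS[0] * 1.01 < tau < _TAU_BOUNDS_DAYS[1] * 0.99):
            converged = False
        else:
            converged = True

        ci = (np.nan, np.nan)
        n_degenerate = 0
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            n = self.delta_t.size
            taus = np.empty(n_boot)
            taus.fill(np.nan)
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                dt_b, r_b = self.delta_t[idx], self.r[idx]
                if np.unique(dt_b).size < 2:
                    n_degenerate += 1
                    continue
                lam_b, _ = _fit_lambda(dt_b, r_b, self.model_form == "free")
                taus[b] = LN2 / lam_b
            ok = np.isfinite(taus)
            if ok.sum() >= max(20, n_boot // 10):
                ci = tuple(np.percentile(taus[ok], [2.5, 97.5]))
            else:
                converged = False

        fitted = amp * np.exp(-lam * self.delta_t)
        return ExponentialDecayResults(
            model=self,
            half_life_days=tau,
            rate_per_day=lam,
            amplitude=amp,
            conf_int_days=ci,
            residuals=self.r - fitted,
            sse=sse,
            n_eyes=self.delta_t.size,
            n_boot=n_boot,
            n_degenerate_resamples=n_degenerate,
            converged=converged,
        )


@dataclass
class ExponentialDecayResults:
    """Fitted correlation half-life with bootstrap CI and diagnostics."""

    model: ExponentialDecayModel
    half_life_days: float
    rate_per_day: float
    amplitude: float
    conf_int_days: tuple[float, float]
    residuals: np.ndarray
    sse: float
    n_eyes: int
    n_boot: int
    n_degenerate_resamples: int
    converged: bool

    @property
    def model_form(self) -> str:
        return (
            "r = exp(-lambda*dt)"
            if self.model.model_form == "fixed"
            else "r = A*exp(-lambda*dt)"
        )

    def predict(self, delta_t_days) -> np.ndarray:
        dt = np.asarray(delta_t_days, dtype=float)
        return self.amplitude * np.exp(-self.rate_per_day * dt)

    def summary(self) -> str:
        lo, hi = self.conf_int_days
        lines = [
            "Exponential decay of tracer-pattern correlation",
            "=" * 47,
            f"model form        {self.model_form}",
            f"n eyes            {self.n_eyes}",
            f"half-life (days)  {self.half_life_days:.3g}",
            f"rate (1/day)      {self.rate_per_day:.4g}",
            f"95% CI (days)     [{lo:.3g}, {hi:.3g}]  (bootstrap, {self.n_boot} resamples)",
            f"amplitude         {self.amplitude:.4g}",
            f"residual SSE      {self.sse:.4g}",
            f"converged         {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-eye r versus dt with the fitted decay curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dt, r = self.model.delta_t, self.model.r
        ax.plot(dt, r, "o", color="k", alpha=0.7, label="eyes")
        grid = np.linspace(0, max(dt.max(), 1.0) * 1.05, 200)
        ax.plot(grid, self.predict(grid), "-", color="C3",
                label=f"fit: half-life {self.half_life_days:.2g} d")
        ax.set_xlabel("inter-label interval $\\Delta t$ (days)")
        ax.set_ylabel("Pearson $r$")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "half_life_days": self.half_life_days,
            "rate_per_day": self.rate_per_day,
            "amplitude": self.amplitude,
            "ci95_days": list(self.conf_int_days),
            "model_form": self.model_form,
            "sse": self.sse,
            "n_eyes": self.n_eyes,
            "n_boot": self.n_boot,
            "converged": self.converged,
        }


def fit_exponential_decay(
    eyes: Sequence[EyeCorrelation],
    model_form: str = "fixed",
    n_boot: int = 2000,
    seed=None,
) -> ExponentialDecayResults:
    """Fit r versus dt over a cohort of eyes (see ExponentialDecayModel)."""
    if len(eyes) < 4:
        raise ValueError("need at least 4 eyes for a decay fit")
    return ExponentialDecayModel.from_eyes(eyes, model_form).fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# t-tests on per-eye correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _fisher_z(values: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(values, -1 + 1e-15, 1 - 1e-15))


def one_sample_t(rs: Sequence[float], popmean: float = 0.0, fisher_z: bool = False) -> TTestResult:
    """One-sample two-tailed t-test of the per-eye values against ``popmean``.

    Operates on raw r by default; ``fisher_z=True`` applies the
    variance-stabilising arctanh transform first (sensitivity switch).
    Zero-variance samples are handled explicitly: t = 0, p = 1 when the
    common value equals ``popmean``; otherwise t diverges and p -> 0, which
    is reported with the ``zero_variance`` flag set.
    """
    x = np.asarray(rs, dtype=float)
    if fisher_z:
        x = _fisher_z(x)
        popmean = float(np.arctanh(popmean))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    if x.std(ddof=1) == 0.0:
        if mean == popmean:
            return TTestResult(t=0.0, df=n - 1, p=1.0, mean=mean, zero_variance=True)
        return TTestResult(
            t=float(np.sign(mean - popmean)) * np.inf, df=n - 1, p=0.0,
            mean=mean, zero_variance=True,
        )
    res = sps.ttest_1samp(x, popmean)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean=mean)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 fisher_z: bool = False) -> TTestResult:
    """Unpaired two-sample two-tailed Student's t-test (pooled variance)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if fisher_z:
        a, b = _fisher_z(a), _fisher_z(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean=diff, zero_variance=True)
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=df, p=0.0,
                           mean=diff, zero_variance=True)
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue), mean=diff)


def half_life_from_single_r(r: float, delta_t_days: float, cap_days: float = 1e3) -> float:
    """Invert the decay law for one (r, dt) pair: tau = -dt*ln2 / ln(r).

    Used for cohort design, e.g. choosing the generating half-life that
    reproduces an observed group-mean correlation at a given interval.
    """
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie strictly between 0 and 1")
    if delta_t_days <= 0:
        raise ValueError("delta_t_days must be positive")
    tau = -delta_t_days * LN2 / np.log(r)
    if tau > cap_days:
        raise ValueError(f"implied half-life {tau:.3g} d exceeds the cap {cap_days} d")
    return float(tau)


# ---------------------------------------------------------------------------
# Difference images
# ---------------------------------------------------------------------------

def difference_image(
    straightened: StraightenedTM,
    order: str = "blue_minus_red",
    scale_blue: bool = True,
) -> np.ndarray:
    """Signed per-pixel difference of the two straightened tracer channels.

    The blue channel is first multiplied by the pixel-wise least-squares
    scaling factor (unless ``scale_blue=False``).  Default order is scaled
    blue minus red, so regions whose filtration *increased* between the two
    label times come out positive; ``order="red_minus_blue"`` flips the sign.
    NaN propagates wherever either channel is outside the TM domain.
    """
    if order not in ("blue_minus_red", "red_minus_blue"):
        raise ValueError("order must be 'blue_minus_red' or 'red_minus_blue'")
    red = straightened.channels["red"]
    blue = straightened.channels["blue"]
    if scale_blue:
        blue = blue * scaling_factor_pixels(straightened)
    diff = blue - red
    return diff if order == "blue_minus_red" else -diff


def render_difference(diff: np.ndarray) -> np.ndarray:
    """Map a signed difference to an RGB image.

    Positive differences render green, negative red, intensity proportional
    to magnitude (normalised by the largest absolute finite difference);
    NaN pixels are black.
    """
    rgb = np.zeros(diff.shape + (3,), dtype=float)
    finite = np.isfinite(diff)
    vmax = np.abs(diff[finite]).max() if finite.any() else 1.0
    if vmax == 0:
        vmax = 1.0
    pos = finite & (diff > 0)
    neg = finite & (diff < 0)
    rgb[pos, 1] = diff[pos] / vmax
    rgb[neg, 0] = -diff[neg] / vmax
    return rgb
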