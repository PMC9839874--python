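"""Benchmark-dose (BMD) modeling with AIC model selection.

For each feature (gene), a family of dose-response models is fitted by
multi-start least squares; the optimal model is the one with the lowest AIC.
The benchmark response is BMR = BMRF * sigma with BMRF = 1.349 residual
standard deviations (about a 10% change relative to controls under constant
variance), and the BMD solves |f(BMD) - f(0)| = BMR. BMDL/BMDU are 95%
two-sided profile-likelihood bounds (a parametric bootstrap is available
behind a config switch). Features are filtered on the lack-of-fit p-value
(< 0.10 removed), on extrapolation beyond the highest tested dose, and on
the ratio limits BMD/BMDL <= 20, BMDU/BMD <= 20, BMDU/BMDL <= 40.

Model reference table (d = dose):

    linear            f(d) = a + b*d
    poly2             f(d) = a + b*d + c*d^2
    power             f(d) = a + b*d^g,                    g in [0.5, 8]
    exponential       f(d) = a + b*(exp(c*d) - 1)
    hill              f(d) = a + (b-a)*d^n / (k^n + d^n),  n in [0.5, 8]
    michaelis_menten  hill with n fixed at 1
    log_logistic      f(d) = a + (b-a) / (1 + (d/e)^(-beta)), beta in [0.2, 20]
    weibull           f(d) = a + (b-a)*(1 - exp(-(d/k)^g)), g in [0.2, 8]

The transcriptomics family is {linear, poly2, hill, power, exponential};
the qPCR family adds log_logistic, weibull and michaelis_menten.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "BmdConfig",
    "DoseResponseFit",
    "DoseResponseModel",
    "DoseResponseResults",
    "MODEL_FAMILIES",
    "fit_models",
    "estimate_bmd",
    "bmd_filter",
    "fit_dose_response_table",
]

_RSS_FLOOR = 1e-12  # keeps AIC finite on exact fits


@dataclass(frozen=True)
class BmdConfig:
    """Tuning knobs of the BMD pipeline (defaults follow the study design)."""

    bmrf: float = 1.349
    confidence: float = 0.95
    lof_threshold: float = 0.10
    ratio_bmd_bmdl: float = 20.0
    ratio_bmdu_bmd: float = 20.0
    ratio_bmdu_bmdl: float = 40.0
    dose_cap_factor: float = 10.0  # BMD search cap = factor * max dose
    bounds_method: str = "profile"  # or "bootstrap"
    n_bootstrap: int = 200
    seed: int = 0


# ---------------------------------------------------------------------------
# model definitions


def _f_linear(d, a, b):
    return a + b * d


def _f_poly2(d, a, b, c):
    return a + b * d + c * d * d


def _f_power(d, a, b, g):
    return a + b * np.power(np.maximum(d, 0.0), g)


def _f_exponential(d, a, b, c):
    return a + b * (np.exp(np.clip(c * d, -700, 700)) - 1.0)


def _f_hill(d, a, b, k, n):
    d = np.maximum(d, 0.0)
    return a + (b - a) * np.power(d, n) / (np.power(k, n) + np.power(d, n))


def _f_mm(d, a, b, k):
    return _f_hill(d, a, b, k, 1.0)


def _f_log_logistic(d, a, b, e, beta):
    d = np.asarray(d, dtype=float)
    out = np.full_like(d, a, dtype=float)
    pos = d > 0
    out[pos] = a + (b - a) / (1.0 + np.power(d[pos] / e, -beta))
    return out


def _f_weibull(d, a, b, k, g):
    d = np.maximum(d, 0.0)
    return a + (b - a) * (1.0 - np.exp(-np.power(d / k, g)))


@dataclass(frozen=True)
class _ModelDef:
    name: str
    func: object
    n_params: int
    start_fn: object
    bounds_fn: object


def _mk_models() -> dict[str, _ModelDef]:
    inf = np.inf

    def s_linear(y0, y1, yr, dmax):
        slope = (y1 - y0) / dmax if dmax > 0 else 0.0
        return [
            (y0, slope),
            (y0, 2 * slope if slope else yr / dmax),
            (y0, -slope if slope else -yr / dmax),
            (np.mean([y0, y1]), slope / 2 if slope else 0.1 * yr / dmax),
            (y0, 0.0),
        ]

    def s_poly2(y0, y1, yr, dmax):
        slope = (y1 - y0) / dmax if dmax > 0 else 0.0
        return [
            (y0, slope, 0.0),
            (y0, 0.0, slope / dmax if dmax else 0.0),
            (y0, slope / 2, slope / (2 * dmax) if dmax else 0.0),
            (y0, -slope, 2 * slope / dmax if dmax else 0.0),
            (y0, 0.0, 0.0),
        ]

    def s_power(y0, y1, yr, dmax):
        amp = (y1 - y0) / dmax if dmax > 0 else 0.0
        return [
            (y0, amp, 1.0),
            (y0, (y1 - y0) / np.sqrt(dmax) if dmax > 0 else 0.0, 0.5),
            (y0, (y1 - y0) / dmax**2 if dmax > 0 else 0.0, 2.0),
            (y0, amp, 1.5),
            (y0, -amp, 1.0),
        ]

    def s_exponential(y0, y1, yr, dmax):
        c0 = 1.0 / dmax if dmax > 0 else 1.0
        return [
            (y0, (y1 - y0) / (np.e - 1.0), c0),
            (y0, y1 - y0, 0.3 * c0),
            (y0, -(y1 - y0), -c0),
            (y0, 0.5 * (y1 - y0), 2 * c0),
            (y0, 0.1 * yr if yr else 1.0, c0),
        ]

    def s_hill(y0, y1, yr, dmax):
        return [
            (y0, y1, dmax / 2, 1.0),
            (y0, y1, dmax / 4, 2.0),
            (y0, y1, dmax, 1.0),
            (y0, y1, dmax / 10, 4.0),
            (y1, y0, dmax / 2, 1.0),
        ]

    def s_mm(y0, y1, yr, dmax):
        return [(y0, y1, k) for k in (dmax / 4, dmax / 2, dmax, dmax / 10, 2 * dmax)]

    def s_ll(y0, y1, yr, dmax):
        return [
            (y0, y1, dmax / 2, 1.0),
            (y0, y1, dmax / 4, 2.0),
            (y0, y1, dmax, 0.5),
            (y1, y0, dmax / 2, 1.0),
            (y0, y1, dmax / 10, 4.0),
        ]

    def s_weibull(y0, y1, yr, dmax):
        return [
            (y0, y1, dmax / 2, 1.0),
            (y0, y1, dmax / 4, 2.0),
            (y0, y1, dmax, 0.5),
            (y1, y0, dmax / 2, 1.0),
            (y0, y1, dmax / 10, 3.0),
        ]

    def b_free(n):
        def fn(dmax):
            return ([-inf] * n, [inf] * n)

        return fn

    def b_power(dmax):
        return ([-inf, -inf, 0.5], [inf, inf, 8.0])

    def b_exponential(dmax):
        # |c|*dmax <= 5 keeps the curvature identifiable inside the tested range
        lim = 5.0 / dmax if dmax > 0 else 5.0
        return ([-inf, -inf, -lim], [inf, inf, lim])

    def b_hill(dmax):
        return ([-inf, -inf, dmax * 1e-6, 0.5], [inf, inf, dmax * 100, 8.0])

    def b_mm(dmax):
        return ([-inf, -inf, dmax * 1e-6], [inf, inf, dmax * 100])

    def b_ll(dmax):
        return ([-inf, -inf, dmax * 1e-6, 0.2], [inf, inf, dmax * 100, 20.0])

    def b_weibull(dmax):
        return ([-inf, -inf, dmax * 1e-6, 0.2], [inf, inf, dmax * 100, 8.0])

    return {
        "linear": _ModelDef("linear", _f_linear, 2, s_linear, b_free(2)),
        "poly2": _ModelDef("poly2", _f_poly2, 3, s_poly2, b_free(3)),
        "power": _ModelDef("power", _f_power, 3, s_power, b_power),
        "exponential": _ModelDef("exponential", _f_exponential, 3, s_exponential, b_exponential),
        "hill": _ModelDef("hill", _f_hill, 4, s_hill, b_hill),
        "michaelis_menten": _ModelDef("michaelis_menten", _f_mm, 3, s_mm, b_mm),
        "log_logistic": _ModelDef("log_logistic", _f_log_logistic, 4, s_ll, b_ll),
        "weibull": _ModelDef("weibull", _f_weibull, 4, s_weibull, b_weibull),
    }


_MODELS = _mk_models()

MODEL_FAMILIES = {
    "transcriptomics": ("linear", "poly2", "hill", "power", "exponential"),
    "qpcr": (
        "linear",
        "poly2",
        "hill",
        "power",
        "exponential",
        "log_logistic",
        "weibull",
        "michaelis_menten",
    ),
}


@dataclass
class DoseResponseFit:
    """One converged model fit for one feature."""

    model: str
    params: tuple[float, ...]
    aic: float
    rss: float
    n_obs: int
    lack_of_fit_p: float
    residual_sd: float
    bmd: float | None = None
    bmdl: float | None = None
    bmdu: float | None = None

    def predict(self, d):
        return _MODELS[self.model].func(np.asarray(d, dtype=float), *self.params)


def _aic(rss: float, n: int, n_params: int) -> float:
    """AIC = n ln(RSS/n) + 2(p+1); the residual variance counts as a parameter.

    The additive constant n ln(2 pi) + n is omitted consistently across
    models, so within-feature comparisons are unaffected.
    """
    return n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * (n_params + 1)


def _lack_of_fit_p(dose, response, fitted, n_params) -> float:
    """F-test of the model against the saturated per-dose-means model.

    Returns NaN when replication is insufficient (no pure-error degrees of
    freedom or no spare dose levels beyond the parameter count).
    """
    df = pd.DataFrame({"d": dose, "y": response, "f": fitted})
    group_means = df.groupby("d")["y"].transform("mean")
    sse_pe = float(((df["y"] - group_means) ** 2).sum())
    sse_model = float(((df["y"] - df["f"]) ** 2).sum())
    n = len(df)
    n_d = df["d"].nunique()
    df_pe = n - n_d
    df_lof = n_d - n_params
    if df_pe <= 0 or df_lof <= 0:
        return float("nan")
    ss_lof = max(sse_model - sse_pe, 0.0)
    if sse_pe <= 0:
        return 0.0 if ss_lof > 0 else float("nan")
    f_stat = (ss_lof / df_lof) / (sse_pe / df_pe)
    return float(stats.f.sf(f_stat, df_lof, df_pe))


def fit_models(
    dose: np.ndarray,
    response: np.ndarray,
    family: str | tuple[str, ...] = "transcriptomics",
) -> list[DoseResponseFit]:
    """Least-squares fits of every model in the family (multi-start, 5 starts).

    Models that fail to converge from every start are excluded (logged).
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if isinstance(family, str):
        names = MODEL_FAMILIES[family]
    else:
        names = tuple(family)
    if np.unique(dose).size < 3 or 0.0 not in dose:
        raise ValueError("need >= 3 distinct doses including 0")
    dmax = float(dose.max())
    ctrl = response[dose == dose.min()]
    top = response[dose == dmax]
    y0, y1 = float(ctrl.mean()), float(top.mean())
    yr = float(response.max() - response.min())
    n = len(response)

    fits: list[DoseResponseFit] = []
    for name in names:
        mdl = _MODELS[name]
        lo, hi = mdl.bounds_fn(dmax)
        best = None
        for start in mdl.start_fn(y0, y1, yr, dmax):
            x0 = np.clip(np.asarray(start, dtype=float), lo, hi)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = optimize.least_squares(
                        lambda th: mdl.func(dose, *th) - response,
                        x0,
                        bounds=(lo, hi),
                        method="trf",
                        max_nfev=500,
                    )
            except Exception:  # noqa: BLE001 - any solver failure skips this start
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, tuple(float(v) for v in res.x))
        if best is None:
            logger.info("model %s failed to converge; excluded", name)
            continue
        rss, params = best
        fitted = mdl.func(dose, *params)
        dof = n - mdl.n_params
        residual_sd = float(np.sqrt(max(rss, 0.0) / dof)) if dof > 0 else float("nan")
        fits.append(
            DoseResponseFit(
                model=name,
                params=params,
                aic=_aic(rss, n, mdl.n_params),
                rss=rss,
                n_obs=n,
                lack_of_fit_p=_lack_of_fit_p(dose, response, fitted, mdl.n_params),
                residual_sd=residual_sd,
            )
        )
    return fits


def _bmd_of_params(
    name: str, params, f0: float, bmr: float, cap: float, refine: bool = True
) -> float | None:
    """Smallest dose in (0, cap] where |f(d) - f(0)| reaches BMR, or None.

    With refine=False the crossing is located by linear interpolation on the
    evaluation grid (cheap and smooth, used inside constrained optimization).
    """
    func = _MODELS[name].func
    grid = np.linspace(0.0, cap, 257)
    g = np.abs(func(grid, *params) - f0) - bmr
    sign = np.signbit(g)
    cross = np.nonzero(sign[:-1] != sign[1:])[0]
    if len(cross) == 0:
        return None
    i = int(cross[0])
    if not refine:
        g0, g1 = g[i], g[i + 1]
        frac = 0.5 if g1 == g0 else -g0 / (g1 - g0)
        return float(grid[i] + frac * (grid[i + 1] - grid[i]))
    try:
        root = optimize.brentq(
            lambda d: abs(float(func(np.array([d]), *params)[0]) - f0) - bmr,
            grid[i],
            grid[i + 1],
            xtol=1e-12,
            rtol=8.9e-16,
        )
    except ValueError:
        return None
    return float(root)


def estimate_bmd(
    fit: DoseResponseFit,
    config: BmdConfig,
    max_dose: float,
    dose: np.ndarray | None = None,
    response: np.ndarray | None = None,
    compute_bounds: bool = True,
) -> tuple[float | None, float | None, float | None]:
    """BMD from the fitted curve plus 95% profile-likelihood BMDL/BMDU.

    BMR = bmrf * residual_sd; the BMD search is capped at
    ``dose_cap_factor * max_dose`` (no crossing -> BMD absent). Bounds need
    the raw data; with ``compute_bounds=False`` (or no data) only the point
    estimate is returned.
    """
    if not np.isfinite(fit.residual_sd) or fit.residual_sd < 0:
        return None, None, None
    bmr = config.bmrf * fit.residual_sd
    f0 = float(fit.predict(np.array([0.0]))[0])
    cap = config.dose_cap_factor * max_dose
    if bmr <= 0:
        return None, None, None
    bmd = _bmd_of_params(fit.model, fit.params, f0, bmr, cap)
    if bmd is None or not compute_bounds or dose is None or response is None:
        return bmd, None, None
    if config.bounds_method == "bootstrap":
        bmdl, bmdu = _bootstrap_bounds(fit, config, max_dose, dose, response, bmr)
    else:
        bmdl, bmdu = _profile_bounds(fit, config, max_dose, dose, response, bmr, bmd)
    if bmdl is not None and bmdl > bmd:
        bmdl = bmd
    if bmdu is not None and bmdu < bmd:
        bmdu = bmd
    return bmd, bmdl, bmdu


def _constrained_rss(name, dose, response, lo, hi, x0, bmr, target) -> float | None:
    """min RSS subject to BMD(theta) = target (SLSQP equality constraint)."""
    func = _MODELS[name].func
    cap = target * 4.0  # grid resolution scales with the probed BMD

    def bmd_con(th):
        b = _bmd_of_params(
            name, th, float(func(np.array([0.0]), *th)[0]), bmr, cap, refine=False
        )
        if b is None:
            b = cap
        return b - target

    def rss(th):
        return float(np.sum((func(dose, *th) - response) ** 2))

    bounds = [
        (None if not np.isfinite(l) else l, None if not np.isfinite(h) else h)
        for l, h in zip(lo, hi)
    ]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                rss,
                np.asarray(x0, dtype=float),
                method="SLSQP",
                bounds=bounds,
                constraints=[{"type": "eq", "fun": bmd_con}],
                options={"maxiter": 100, "ftol": 1e-10},
            )
    except Exception:  # noqa: BLE001
        return None
    if not res.success and abs(bmd_con(res.x)) > 1e-3 * max(target, 1e-12):
        return None
    return float(rss(res.x))


def _profile_bounds(fit, config, max_dose, dose, response, bmr, bmd):
    """Likelihood-ratio profile bounds: RSS(delta)/RSS_hat <= exp(chi2_q/n)."""
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    mdl = _MODELS[fit.model]
    lo, hi = mdl.bounds_fn(float(dose.max()))
    n = len(response)
    q = stats.chi2.ppf(config.confidence, df=1)
    rss_hat = max(fit.rss, _RSS_FLOOR)
    rss_crit = rss_hat * float(np.exp(q / n))

    def profile_ok(delta: float) -> bool:
        # a failed constrained fit is treated as rejected: the constraint
        # could not be satisfied within the RSS budget
        rss = _constrained_rss(fit.model, dose, response, lo, hi, fit.params, bmr, delta)
        return rss is not None and rss <= rss_crit

    def bisect(side: str) -> float | None:
        if side == "lower":
            outer, inner = bmd * 1e-3, bmd
        else:
            outer, inner = min(config.dose_cap_factor * max_dose, bmd * 50.0), bmd
        if profile_ok(outer):
            # the profile never rejects inside the search window: the data do
            # not constrain the BMD on this side -> bound not estimable
            return None
        a, b = outer, inner  # a rejected, b accepted
        for _ in range(12):
            mid = 0.5 * (a + b)
            if profile_ok(mid):
                b = mid
            else:
                a = mid
        return b

    return bisect("lower"), bisect("upper")


def _bootstrap_bounds(fit, config, max_dose, dose, response, bmr):
    """Parametric-bootstrap percentile bounds on the BMD."""
    rng = np.random.default_rng(config.seed)
    dose = np.asarray(dose, dtype=float)
    fitted = fit.predict(dose)
    bmds = []
    for _ in range(config.n_bootstrap):
        y = fitted + rng.normal(0.0, fit.residual_sd, size=len(dose))
        try:
            fits = fit_models(dose, y, (fit.model,))
        except ValueError:
            continue
        if not fits:
            continue
        bf = fits[0]
        b, _, _ = estimate_bmd(bf, config, max_dose, compute_bounds=False)
        if b is not None:
            bmds.append(b)
    if len(bmds) < max(10, config.n_bootstrap // 10):
        return None, None
    alpha = 1.0 - config.confidence
    return (
        float(np.quantile(bmds, alpha / 2)),
        float(np.quantile(bmds, 1 - alpha / 2)),
    )


def bmd_filter(fits: pd.DataFrame, config: BmdConfig, max_dose: float) -> pd.DataFrame:
    """Pass/fail per feature with reason codes.

    Fail reasons, in the order checked: "lack_of_fit" (p < threshold),
    "no_bmd" (missing BMD/BMDL/BMDU), "extrapolated" (BMD or BMDU above the
    highest tested dose), "ratio" (BMD/BMDL, BMDU/BMD or BMDU/BMDL above the
    limits). Passing features are the dose-dependently altered set.
    """
    out = fits.copy()
    reasons = []
    for row in out.itertuples(index=False):
        lof = getattr(row, "lack_of_fit_p", float("nan"))
        bmd, bmdl, bmdu = row.bmd, row.bmdl, row.bmdu
        if np.isfinite(lof) and lof < config.lof_threshold:
            reasons.append("lack_of_fit")
        elif bmd is None or bmdl is None or bmdu is None or not np.isfinite([bmd, bmdl, bmdu]).all():
            reasons.append("no_bmd")
        elif bmd > max_dose or bmdu > max_dose:
            reasons.append("extrapolated")
        elif (
            (bmdl > 0 and bmd / bmdl > config.ratio_bmd_bmdl)
            or (bmd > 0 and bmdu / bmd > config.ratio_bmdu_bmd)
            or (bmdl > 0 and bmdu / bmdl > config.ratio_bmdu_bmdl)
        ):
            reasons.append("ratio")
        else:
            reasons.append("pass")
    out["reason"] = reasons
    out["passed"] = out["reason"] == "pass"
    return out


# ---------------------------------------------------------------------------
# model/results interface


class DoseResponseModel:
    """Dose-response model family for a single feature.

    Parameters
    ----------
    dose, response : array-like
        Paired observations; >= 3 distinct doses including 0, with replicates
        at one or more doses for the lack-of-fit test.
    family : str or tuple of str
        "transcriptomics", "qpcr", or an explicit tuple of model names.
    """

    def __init__(self, dose, response, family: str | tuple[str, ...] = "transcriptomics"):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        self.family = family
        if len(self.dose) != len(self.response):
            raise ValueError("dose and response must have equal length")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family="transcriptomics",
                       dose_col="dose", response_col="response"):
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy(), family)

    def fit(self, config: BmdConfig | None = None, compute_bounds: bool = True) -> "DoseResponseResults":
        config = config or BmdConfig()
        fits = fit_models(self.dose, self.response, self.family)
        if not fits:
            raise RuntimeError("no model converged")
        best = min(fits, key=lambda f: f.aic)
        max_dose = float(self.dose.max())
        bmd, bmdl, bmdu = estimate_bmd(
            best, config, max_dose, self.dose, self.response, compute_bounds
        )
        best.bmd, best.bmdl, best.bmdu = bmd, bmdl, bmdu
        return DoseResponseResults(self, best, fits, config, max_dose)


class DoseResponseResults:
    """Fitted dose-response results: selected model, BMD triple, diagnostics."""

    def __init__(self, model, best: DoseResponseFit, all_fits, config, max_dose):
        self.model = model
        self.best = best
        self.all_fits = all_fits
        self.config = config
        self.max_dose = max_dose

    @property
    def bmd(self):
        return self.best.bmd

    @property
    def bmdl(self):
        return self.best.bmdl

    @property
    def bmdu(self):
        return self.best.bmdu

    def predict(self, dose):
        return self.best.predict(dose)

    def passes_filters(self) -> tuple[bool, str]:
        table = pd.DataFrame(
            [
                {
                    "bmd": self.best.bmd,
                    "bmdl": self.best.bmdl,
                    "bmdu": self.best.bmdu,
                    "lack_of_fit_p": self.best.lack_of_fit_p,
                }
            ]
        )
        res = bmd_filter(table, self.config, self.max_dose)
        return bool(res["passed"].iloc[0]), str(res["reason"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Dose-response results",
            "=" * 45,
            f"selected model : {self.best.model}",
            f"parameters     : {np.round(self.best.params, 6).tolist()}",
            f"AIC            : {self.best.aic:.4f}",
            f"residual sd    : {self.best.residual_sd:.6g}",
            f"lack-of-fit p  : {self.best.lack_of_fit_p:.4g}",
            f"BMR (BMRF*sd)  : {self.config.bmrf * self.best.residual_sd:.6g}",
            f"BMD            : {self.best.bmd if self.best.bmd is not None else 'absent'}",
            f"BMDL           : {self.best.bmdl if self.best.bmdl is not None else 'absent'}",
            f"BMDU           : {self.best.bmdu if self.best.bmdu is not None else 'absent'}",
        ]
        passed, reason = self.passes_filters()
        lines.append(f"dose-dependent : {'yes' if passed else f'no ({reason})'}")
        lines.append("-" * 45)
        lines.append("candidate models (AIC):")
        for f in sorted(self.all_fits, key=lambda f: f.aic):
            lines.append(f"  {f.model:<17s} {f.aic:>10.3f}")
        return "\n".join(lines)


def fit_dose_response_table(
    data: pd.DataFrame,
    family: str | tuple[str, ...] = "transcriptomics",
    config: BmdConfig | None = None,
    max_dose: float | None = None,
    compute_bounds: bool = True,
) -> pd.DataFrame:
    """Per-feature BMD analysis of a long table (feature, dose, response).

    Returns one row per feature with the selected model, AIC, lack-of-fit p,
    BMD/BMDL/BMDU, and the pass/reason verdict of :func:`bmd_filter`.
    """
    config = config or BmdConfig()
    rows = []
    for feature, grp in data.groupby("feature", sort=True):
        dose = grp["dose"].to_numpy(dtype=float)
        try:
            res = DoseResponseModel(dose, grp["response"].to_numpy(dtype=float), family).fit(
                config, compute_bounds
            )
        except (RuntimeError, ValueError) as exc:
            logger.info("feature %s not fitted: %s", feature, exc)
            rows.append((feature, None, np.nan, np.nan, None, None, None))
            continue
        rows.append(
            (
                feature,
                res.best.model,
                res.best.aic,
                res.best.lack_of_fit_p,
                res.bmd,
                res.bmdl,
                res.bmdu,
            )
        )
    table = pd.DataFrame(
        rows, columns=["feature", "model", "aic", "lack_of_fit_p", "bmd", "bmdl", "bmdu"]
    )
    fitted = table[table["model"].notna()].copy()
    if len(fitted):
        md = max_dose if max_dose is not None else float(data["dose"].max())
        verdict = bmd_filter(fitted, config, md)
        table = table.merge(verdict[["feature", "reason", "passed"]], on="feature", how="left")
    else:
        table["reason"] = None
        table["passed"] = False
    table["passed"] = table["passed"].fillna(False).astype(bool)
    table.loc[table["model"].isna(), "reason"] = "no_fit"
    return table
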