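"""Analytical-validation statistics.

Six procedures validate the MRD assay end to end:

* **Limit of detection (LoD)** — probit regression of the detection
  proportion on log10 expected malignant cells; the LoD is the dose at which
  the fitted curve reaches the detection target (default 95%).
* **Limit of quantitation (LoQ)** — Sadler's three-parameter precision
  profile ``y = (b1 + b2*x)**J`` fitted to per-level relative total error
  (RMSE / expected cells); the LoQ is where the fitted profile crosses the
  allowable error (default 70%).
* **Limit of blank (LoB)** — nonparametric 95th percentile of MRD
  measurements across all tracked sequences in analyte-free samples.
* **Precision** — variance-component decomposition of replicate
  measurements into operator set, instrument set, reagent lot, day,
  run-within-day and residual, each reported as %CV, plus derived
  repeatability, reproducibility and lot-to-lot %CV.
* **Linearity** — the polynomial method: fit first/second/third-order
  models, test nonlinear terms at P < 0.05, accept if the best higher-order
  fit stays within +/-5% of the linear fit at every level, otherwise shrink
  the range and repeat.
* **Quantitation accuracy (bias)** — nested bootstrap (samples within
  stratum, then replicates within sample) of the mean relative bias with
  percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import least_squares
from scipy.stats import norm

from .errors import (
    ConfoundingError,
    InvalidParameterError,
    MissingDataError,
    OutOfRangeError,
)
from .synthetic import GRID_FACTORS, ValidationGrid

# ---------------------------------------------------------------------------
# limit of detection


@dataclass
class ProbitFit:
    intercept: float
    slope: float
    dose_scale: str
    detection_target: float
    lod: float
    ci: tuple[float, float] | None
    separated: bool = False


def _probit_lod(intercept, slope, target, dose_scale):
    t = (norm.ppf(target) - intercept) / slope
    return float(10**t) if dose_scale == "log10" else float(t)


def fit_probit(
    doses,
    detections,
    *,
    dose_scale: str = "log10",
    detection_target: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> ProbitFit:
    """Probit dose-response fit and LoD.

    ``doses`` are expected malignant-cell inputs, ``detections`` boolean MRD
    calls per sample. The detection proportion is modelled as
    ``Phi(a + b*log10(dose))`` (the standard LoD practice; a linear-dose mode
    is retained). LoD solves the fitted probability = ``detection_target``.
    The CI is a nonparametric bootstrap over samples (percentile, 2.5/97.5);
    ``n_boot=0`` skips it. Complete separation (all-detected or
    none-detected) returns a flagged fit rather than an estimate.
    """
    doses = np.asarray(doses, dtype=float)
    det = np.asarray(detections, dtype=float)
    if doses.shape != det.shape or doses.ndim != 1:
        raise InvalidParameterError("doses and detections must be equal-length 1-d")
    if np.unique(doses).size < 2:
        raise InvalidParameterError("need >= 2 dose levels")
    if det.min() == det.max():
        return ProbitFit(np.nan, np.nan, dose_scale, detection_target,
                         np.nan, None, separated=True)
    if dose_scale not in ("log10", "linear"):
        raise InvalidParameterError(f"unknown dose_scale {dose_scale!r}")

    x = np.log10(doses) if dose_scale == "log10" else doses
    X = sm.add_constant(x)
    fam = sm.families.Binomial(sm.families.links.Probit())
    res = sm.GLM(det, X, family=fam).fit()
    a, b = res.params
    lod = _probit_lod(a, b, detection_target, dose_scale)

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = doses.size
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            yb = det[idx]
            if yb.min() == yb.max():
                continue
            try:
                rb = sm.GLM(yb, sm.add_constant(x[idx]), family=fam).fit()
                boots.append(_probit_lod(rb.params[0], rb.params[1],
                                         detection_target, dose_scale))
            except Exception:
                continue
        if boots:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return ProbitFit(float(a), float(b), dose_scale, detection_target, lod, ci)


# ---------------------------------------------------------------------------
# relative total error and the Sadler precision profile


def relative_total_error(estimates, expected: float) -> float:
    """RMSE of cell-count estimates divided by the expected input cells.

    Equals sqrt(bias^2 + variance) / expected; for an unbiased Poisson
    estimator at rate lambda this approaches 1/sqrt(lambda).
    """
    if expected <= 0:
        raise InvalidParameterError("expected must be > 0")
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise MissingDataError("no estimates supplied")
    return float(np.sqrt(np.mean((est - expected) ** 2)) / expected)


def precision_profile(estimates_by_level: dict[float, "np.ndarray"]):
    """Per-level RTE: returns (x levels, y RTE) arrays sorted by level."""
    levels = sorted(estimates_by_level)
    x = np.array(levels, dtype=float)
    y = np.array([relative_total_error(estimates_by_level[l], l) for l in levels])
    return x, y


@dataclass
class SadlerFit:
    beta1: float
    beta2: float
    J: float
    resid_norm: float
    x_range: tuple[float, float]

    def predict(self, x):
        base = self.beta1 + self.beta2 * np.asarray(x, dtype=float)
        return np.power(np.clip(base, 1e-300, None), self.J)


_J_GRID = (-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0)


def fit_sadler(x, y) -> SadlerFit:
    """Fit Sadler's precision-profile model y = (b1 + b2*x)**J.

    Nonlinear least squares with multi-start over a grid of J values; for
    each start, b1 and b2 are initialised by linear regression of y**(1/J0)
    on x. The model requires b1 + b2*x > 0 over the data range (enforced by
    penalised residuals).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InvalidParameterError("need >= 4 levels to fit three parameters")
    if np.any(y <= 0):
        raise InvalidParameterError("precision-profile values must be > 0")

    def resid(p):
        b1, b2, J = p
        base = b1 + b2 * x
        bad = base <= 0
        base = np.where(bad, 1e-12, base)
        with np.errstate(over="ignore", invalid="ignore"):
            r = np.power(base, J) - y
        r = np.where(np.isfinite(r), r, 1e6)
        return np.where(bad, 1e6, r)

    best = None
    for J0 in _J_GRID:
        with np.errstate(over="ignore", invalid="ignore"):
            z = np.power(y, 1.0 / J0)
        if not np.all(np.isfinite(z)):
            continue
        A = np.vstack([np.ones_like(x), x]).T
        (b1_0, b2_0), *_ = np.linalg.lstsq(A, z, rcond=None)
        try:
            sol = least_squares(resid, [b1_0, b2_0, J0], method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise OutOfRangeError("Sadler fit failed from every start")
    b1, b2, J = best.x
    return SadlerFit(float(b1), float(b2), float(J),
                     float(np.sqrt(2 * best.cost)), (float(x.min()), float(x.max())))


def loq_from_profile(fit: SadlerFit, threshold: float = 0.70) -> float:
    """Solve the fitted precision profile = threshold on the data range.

    Scans for a sign change on a dense grid, then bisects (brentq). Raises
    when the profile never crosses the threshold within the fitted range.
    """
    from scipy.optimize import brentq

    lo, hi = fit.x_range
    xs = np.linspace(lo, hi, 1024)
    f = fit.predict(xs) - threshold
    sign = np.sign(f)
    idx = np.nonzero(np.diff(sign))[0]
    if idx.size == 0:
        raise OutOfRangeError(
            f"fitted profile never reaches {threshold} on [{lo}, {hi}]"
        )
    i = idx[0]
    return float(brentq(lambda v: fit.predict(v) - threshold, xs[i], xs[i + 1]))


# ---------------------------------------------------------------------------
# limit of blank


@dataclass
class LoBEstimate:
    value: float
    per_level: dict[float, float] = field(default_factory=dict)
    alpha: float = 0.05
    n: int = 0


def _nonparametric_quantile(values: np.ndarray, alpha: float) -> float:
    """CLSI-style nonparametric percentile: interpolated rank 0.5 + (1-a)n."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    rank = 0.5 + (1.0 - alpha) * n  # 1-based
    if rank <= 1:
        return float(v[0])
    if rank >= n:
        return float(v[-1])
    lo = int(np.floor(rank))
    frac = rank - lo
    return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))


def estimate_lob(
    blank_values, alpha: float = 0.05, *, levels=None
) -> LoBEstimate:
    """Limit of blank: the (1-alpha) nonparametric percentile of blanks.

    ``blank_values`` are MRD measurements (frequencies) from all tracked
    sequences in all analyte-free samples; ``levels`` optionally annotates
    each value with its DNA-input level to report per-level percentiles as
    well as the overall one.
    """
    values = np.asarray(blank_values, dtype=float)
    if values.size == 0:
        raise MissingDataError("no blank measurements")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    per_level: dict[float, float] = {}
    if levels is not None:
        levels = np.asarray(levels)
        if levels.shape != values.shape:
            raise InvalidParameterError("levels must align with blank_values")
        for lv in np.unique(levels):
            per_level[float(lv)] = _nonparametric_quantile(values[levels == lv], alpha)
    return LoBEstimate(
        value=_nonparametric_quantile(values, alpha),
        per_level=per_level,
        alpha=alpha,
        n=int(values.size),
    )


# ---------------------------------------------------------------------------
# precision: variance components


@dataclass
class VCATable:
    """Per-abundance variance components, each expressed as %CV.

    ``table`` has one row per abundance level with a %CV column per design
    factor, residual, repeatability (residual), reproducibility (all
    components summed), lot-to-lot (reagent lot) and the number of
    measurements; ``mode`` records the estimator used.
    """

    table: pd.DataFrame
    mode: str


def _moments_components(df: pd.DataFrame, factors) -> dict[str, float]:
    """ANOVA method-of-moments variance components on the raw scale.

    For each factor, a one-way decomposition gives
    sigma_f^2 = max(0, (MSB - MSW) / n0); the residual is the total variance
    minus the factor components (floored at 0), so the components sum to the
    total variance by construction.
    """
    y = df["measurement"].to_numpy(dtype=float)
    N = y.size
    total_var = float(np.var(y, ddof=1)) if N > 1 else 0.0
    comps: dict[str, float] = {}
    for f in factors:
        groups = [g.to_numpy(dtype=float) for _, g in df.groupby(f)["measurement"]]
        L = len(groups)
        if L < 2:
            comps[f] = 0.0
            continue
        sizes = np.array([g.size for g in groups])
        grand = y.mean()
        ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)))
        ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
        msb = ssb / (L - 1)
        msw = ssw / (N - L) if N > L else 0.0
        n0 = (N - (sizes**2).sum() / N) / (L - 1)
        comps[f] = max(0.0, (msb - msw) / n0) if n0 > 0 else 0.0
    comps["residual"] = max(0.0, total_var - sum(comps[f] for f in factors))
    return comps


def _reml_components(df: pd.DataFrame, factors) -> dict[str, float]:
    """REML variance components on log(measurement + 0.5) via MixedLM.

    Returned components are back-transformed to squared CVs on the raw scale
    (cv^2 = exp(sigma_log^2) - 1) times the squared mean, so the %CV
    arithmetic downstream is shared with the moments mode.
    """
    d = df.copy()
    d["_y"] = np.log(d["measurement"].to_numpy(dtype=float) + 0.5)
    d["_g"] = 1
    vcf = {f: f"0 + C({f})" for f in factors}
    model = smf.mixedlm("_y ~ 1", d, groups="_g", vc_formula=vcf, re_formula="0")
    try:
        import warnings

        with warnings.catch_warnings():
            # zero components sit on the parameter boundary by design
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, method=["lbfgs", "powell"], maxiter=500)
    except Exception as exc:  # singular designs
        raise ConfoundingError(str(exc)) from exc
    names = model.exog_vc.names
    log_vars = dict(zip(names, np.maximum(res.vcomp, 0.0)))
    log_vars["residual"] = max(float(res.scale), 0.0)
    mean = float(df["measurement"].mean())
    return {
        k: (np.expm1(v)) * mean**2  # variance on raw scale implied by log-scale vc
        for k, v in log_vars.items()
    }


def variance_components(
    grid: ValidationGrid | pd.DataFrame,
    *,
    mode: str = "reml",
    lod: float | None = None,
    factors=tuple(GRID_FACTORS),
) -> VCATable:
    """Decompose replicate variability into design-factor components.

    Performed per abundance level, pooled across DNA inputs. Each component
    is reported as %CV = 100 * sqrt(variance) / mean; repeatability is the
    residual %CV, reproducibility the %CV of the summed components, and
    lot-to-lot the reagent-lot %CV. Levels with expected cells below ``lod``
    are excluded (measurements below the detection limit carry no usable
    precision information). ``mode`` is "reml" (random-effects fit on the
    log scale, the default) or "moments" (raw-scale ANOVA estimators whose
    components sum exactly to the total variance).
    """
    df = grid.data if isinstance(grid, ValidationGrid) else grid
    if lod is not None:
        df = df[df["expected_cells"] >= lod]
    if df.empty:
        raise MissingDataError("no measurements above the LoD")
    for f in factors:
        if f not in df.columns:
            raise InvalidParameterError(f"grid lacks factor column {f!r}")
        per_stratum = df.groupby("expected_cells")[f].nunique()
        if (per_stratum < 2).any():
            raise ConfoundingError(f)

    rows = []
    for abundance, sub in df.groupby("expected_cells"):
        comps = (
            _moments_components(sub, factors)
            if mode == "moments"
            else _reml_components(sub, factors)
        )
        mean = float(sub["measurement"].mean())
        cv = {k: 100.0 * np.sqrt(v) / mean for k, v in comps.items()}
        row = {"expected_cells": float(abundance), "n": int(len(sub))}
        row.update({f"{k}_cv": cv[k] for k in [*factors, "residual"]})
        row["repeatability_cv"] = cv["residual"]
        row["reproducibility_cv"] = 100.0 * np.sqrt(sum(comps.values())) / mean
        row["lot_to_lot_cv"] = cv["reagent_lot"]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("expected_cells").reset_index(drop=True)
    return VCATable(table=table, mode=mode)


# ---------------------------------------------------------------------------
# linearity


@dataclass
class LinearityReport:
    verdict: str  # "linear", "linear-after-reduction", "nonlinear"
    order: int  # polynomial order of the best model on the accepted range
    slope: float
    intercept: float
    deviations: dict[float, float]  # level -> fractional deviation of poly vs linear
    accepted_range: tuple[float, float] | None
    dropped_levels: list[float]


def _fit_poly(logx, logy, order):
    X = np.vander(logx, order + 1, increasing=True)[:, 1:]  # drop column of ones
    return sm.OLS(logy, sm.add_constant(X)).fit()


def assess_linearity(
    observed,
    expected,
    *,
    alpha: float = 0.05,
    tolerance: float = 0.05,
    max_order: int = 3,
) -> LinearityReport:
    """Polynomial-method linearity assessment on a dilution series.

    Regression is on log10-transformed frequencies (dilution series span
    orders of magnitude); the +/-5% comparison between the best polynomial
    and the linear fit is made per level on the back-transformed scale. When
    a significant nonlinear term produces a deviation beyond tolerance, the
    extreme level on the worse-deviating end of the range is dropped and the
    procedure repeats until the remaining range is acceptably linear or
    fewer than four distinct levels remain (verdict "nonlinear").
    """
    obs = np.asarray(observed, dtype=float)
    exp_ = np.asarray(expected, dtype=float)
    if obs.shape != exp_.shape:
        raise InvalidParameterError("observed and expected must align")
    if np.any(obs <= 0) or np.any(exp_ <= 0):
        raise InvalidParameterError("frequencies must be > 0 for log-scale fitting")
    if np.unique(exp_).size < 4:
        raise InvalidParameterError("need >= 4 distinct frequencies")

    dropped: list[float] = []
    keep = np.ones_like(obs, dtype=bool)
    first_pass = True
    while True:
        levels = np.unique(exp_[keep])
        if levels.size < 4:
            return LinearityReport(
                verdict="nonlinear", order=0, slope=np.nan, intercept=np.nan,
                deviations={}, accepted_range=None, dropped_levels=dropped,
            )
        lx, ly = np.log10(exp_[keep]), np.log10(obs[keep])
        lin = _fit_poly(lx, ly, 1)
        fits = {o: _fit_poly(lx, ly, o) for o in range(2, max_order + 1)}
        significant = any(
            p < alpha for o, f in fits.items() for p in f.pvalues[2:]
        )
        if not significant:
            verdict = "linear" if first_pass else "linear-after-reduction"
            return LinearityReport(
                verdict=verdict, order=1,
                slope=float(lin.params[1]), intercept=float(lin.params[0]),
                deviations={}, accepted_range=(float(levels[0]), float(levels[-1])),
                dropped_levels=dropped,
            )
        best_order = min(fits, key=lambda o: fits[o].aic)
        best = fits[best_order]
        llev = np.log10(levels)
        pred_lin = sm.add_constant(np.vander(llev, 2, increasing=True)[:, 1:]) @ lin.params
        Xb = sm.add_constant(np.vander(llev, best_order + 1, increasing=True)[:, 1:])
        pred_best = Xb @ best.params
        dev = 10 ** (pred_best - pred_lin) - 1.0
        deviations = dict(zip(levels.tolist(), dev.tolist()))
        if np.all(np.abs(dev) <= tolerance):
            verdict = "linear" if first_pass else "linear-after-reduction"
            return LinearityReport(
                verdict=verdict, order=best_order,
                slope=float(lin.params[1]), intercept=float(lin.params[0]),
                deviations=deviations,
                accepted_range=(float(levels[0]), float(levels[-1])),
                dropped_levels=dropped,
            )
        # drop the extreme level on the worse end of the range
        drop = levels[0] if abs(dev[0]) >= abs(dev[-1]) else levels[-1]
        dropped.append(float(drop))
        keep &= exp_ != drop
        first_pass = False


# ---------------------------------------------------------------------------
# quantitation accuracy: nested bootstrap bias


@dataclass
class BiasReport:
    """Per-stratum relative bias with nested-bootstrap percentile CIs."""

    table: pd.DataFrame
    n_boot: int


def bootstrap_bias(
    data: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    *,
    stratum_col: str = "stratum",
    sample_col: str = "sample_id",
    observed_col: str = "observed",
    expected_col: str = "expected",
) -> BiasReport:
    """Nested-bootstrap relative bias of observed vs expected cell counts.

    Relative bias is (observed - expected) / expected. Within each stratum
    (disease x input-cell level), samples are resampled with replacement,
    then replicates within each chosen sample, respecting the hierarchical
    correlation structure. The stratum estimate is the mean of per-sample
    mean relative errors; the CI is the 2.5/97.5 percentile over ``n_boot``
    replicates. Strata with a single sample are flagged degenerate.
    """
    for c in (stratum_col, sample_col, observed_col, expected_col):
        if c not in data.columns:
            raise InvalidParameterError(f"data lacks column {c!r}")
    if (data[expected_col] <= 0).any():
        raise InvalidParameterError("expected counts must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, sub in data.groupby(stratum_col):
        rel = ((sub[observed_col] - sub[expected_col]) / sub[expected_col]).to_numpy()
        sample_ids = sub[sample_col].to_numpy()
        per_sample = [rel[sample_ids == s] for s in pd.unique(sample_ids)]
        n_samples = len(per_sample)
        point = float(np.mean([g.mean() for g in per_sample]))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            picks = rng.integers(0, n_samples, size=n_samples)
            means = [
                per_sample[i][rng.integers(0, per_sample[i].size, size=per_sample[i].size)].mean()
                for i in picks
            ]
            boots[b] = np.mean(means)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "stratum": stratum,
                "n_samples": n_samples,
                "n_replicates": int(len(sub)),
                "relative_bias": point,
                "ci_low": float(min(lo, point)),
                "ci_high": float(max(hi, point)),
                "degenerate": n_samples < 2,
            }
        )
    return BiasReport(table=pd.DataFrame(rows), n_boot=n_boot)
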