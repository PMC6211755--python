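"""Probit dose-mortality analysis for insect bioassays.

Mortality probability is modelled as Phi(a + b*log10(dose)) and fitted by
maximum likelihood on grouped binomial counts. LC50 = 10**(-a/b) with 95%
fiducial limits from Fieller's theorem on -a/b. Following the convention of
the classic Polo bioassay software, when the Pearson goodness-of-fit
statistic exceeds its degrees of freedom the covariance is inflated by the
heterogeneity factor chi2/df and interval critical values switch from the
normal to the t distribution with df degrees of freedom. Two LC50s are
declared significantly different when their fiducial intervals do not
overlap (touching endpoints count as overlapping).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseGroup",
    "BioassayDataset",
    "ProbitFit",
    "ComparisonVerdict",
    "FitError",
    "IntervalUndefinedError",
    "abbott_correct",
    "fit_probit",
    "lc50",
    "fiducial_limits",
    "compare_lc50",
    "mortality_summary",
    "round_sigfigs",
]


class FitError(RuntimeError):
    """Probit fit failed (separation, non-convergence or degenerate data)."""


class IntervalUndefinedError(RuntimeError):
    """Fieller g >= 1: the fiducial interval is unbounded."""


@dataclass(frozen=True)
class DoseGroup:
    dose: float  # ng/cm2
    n: int  # larvae exposed
    dead: int

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 <= self.dead <= self.n:
            raise ValueError("dead must lie in [0, n]")
        if self.n < 1:
            raise ValueError("each dose group needs at least one larva")


@dataclass
class BioassayDataset:
    """Grouped dose-mortality records for one treatment."""

    records: list[DoseGroup]
    species: str = ""
    treatment: str = ""
    control: Optional[tuple[int, int]] = None  # (n, dead) untreated control

    def __post_init__(self):
        self.records = [
            r if isinstance(r, DoseGroup) else DoseGroup(*r) for r in self.records
        ]

    @property
    def n_distinct_doses(self) -> int:
        return len({r.dose for r in self.records})

    def control_mortality(self) -> float:
        if self.control is None:
            return 0.0
        n, dead = self.control
        return dead / n if n else 0.0


@dataclass
class ProbitFit:
    """A fitted probit dose-mortality model.

    ``vcov`` is the heterogeneity-scaled covariance of (intercept, slope);
    ``crit`` the critical value used for the 95% limits (normal, or t with
    ``df`` degrees of freedom when heterogeneity > 1).
    """

    intercept: float
    slope: float
    slope_se: float
    vcov: np.ndarray
    lc50: float
    fl95: tuple[float, float]
    chisq: float
    df: int
    heterogeneity: float
    crit: float
    n_groups: int


@dataclass(frozen=True)
class ComparisonVerdict:
    pair: tuple[str, str]
    significant: bool
    basis: tuple[tuple[float, float], tuple[float, float]]


def abbott_correct(observed: float, control: float) -> float:
    """Abbott's correction for natural (control) mortality, floored at 0."""
    if not 0 <= observed <= 1:
        raise ValueError("observed mortality must be a fraction in [0, 1]")
    if not 0 <= control < 1:
        raise ValueError("control mortality must be a fraction in [0, 1)")
    return max(0.0, (observed - control) / (1.0 - control))


def _aggregate(data: BioassayDataset) -> pd.DataFrame:
    """Pool replicates at identical doses into single binomial groups."""
    df = pd.DataFrame(
        [{"dose": r.dose, "n": r.n, "dead": r.dead} for r in data.records]
    )
    return df.groupby("dose", as_index=False)[["n", "dead"]].sum().sort_values("dose")


def fit_probit(data: BioassayDataset, apply_abbott: bool = False) -> ProbitFit:
    """Maximum-likelihood probit fit of grouped dose-mortality data.

    Replicates at the same dose are pooled. With ``apply_abbott`` and a
    control group present, observed kill counts are Abbott-corrected before
    fitting (rounded back to integer counts). Fisher-scoring iterations run
    to a relative log-likelihood tolerance of 1e-10 (max 100 iterations).
    """
    groups = _aggregate(data)
    if len(groups) < 2:
        raise FitError("need at least 2 distinct doses to fit a probit line")
    if apply_abbott and data.control is not None:
        c = data.control_mortality()
        groups = groups.assign(
            dead=[
                int(round(abbott_correct(d / n, c) * n))
                for d, n in zip(groups["dead"], groups["n"])
            ]
        )
    total_n = groups["n"].sum()
    total_dead = groups["dead"].sum()
    if total_dead == 0 or total_dead == total_n:
        raise FitError("all-alive or all-dead data: mortality curve is unidentifiable")

    x = np.log10(groups["dose"].to_numpy(float))
    X = np.column_stack([np.ones_like(x), x])
    y = np.column_stack([groups["dead"].to_numpy(float),
                         (groups["n"] - groups["dead"]).to_numpy(float)])
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturated fits warn benignly at df=0
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # pragma: no cover - defensive
            raise FitError(f"probit fit failed: {exc}") from exc
    a, b = res.params
    vcov = np.asarray(res.cov_params())
    if not np.all(np.isfinite(vcov)) or not np.isfinite(a) or not np.isfinite(b):
        raise FitError("probit fit did not converge (non-finite estimates)")
    if abs(b) > 50:
        raise FitError("complete separation: slope estimate diverged")
    if b <= 0:
        raise FitError("non-positive fitted slope: dose response is not monotone increasing")

    n_groups = len(groups)
    df_resid = n_groups - 2
    chisq = float(res.pearson_chi2) if df_resid > 0 else 0.0
    heterogeneity = chisq / df_resid if df_resid > 0 else 0.0
    if heterogeneity > 1:
        vcov = vcov * heterogeneity
        crit = float(stats.t.ppf(0.975, df_resid))
    else:
        crit = float(stats.norm.ppf(0.975))
    slope_se = float(math.sqrt(vcov[1, 1]))
    lc = 10 ** (-a / b)
    fit = ProbitFit(
        intercept=float(a), slope=float(b), slope_se=slope_se, vcov=vcov,
        lc50=float(lc), fl95=(float("nan"), float("nan")),
        chisq=chisq, df=max(df_resid, 0), heterogeneity=heterogeneity,
        crit=crit, n_groups=n_groups,
    )
    try:
        fit.fl95 = fiducial_limits(fit)
    except IntervalUndefinedError:
        fit.fl95 = (float("nan"), float("nan"))
    return fit


def lc50(fit: ProbitFit) -> float:
    """Dose killing 50% of larvae: 10**(-intercept/slope)."""
    if fit.slope <= 0:
        raise ValueError("LC50 undefined for non-positive slope")
    return 10 ** (-fit.intercept / fit.slope)


def fiducial_limits(fit: ProbitFit, level: float = 0.95) -> tuple[float, float]:
    """Fieller fiducial limits for LC50.

    Solves (a + rho*b)**2 = c**2 * var(a + rho*b) for rho = log10(LC50),
    using the heterogeneity-scaled covariance and the fit's critical-value
    convention, then back-transforms. Raises
    :class:`IntervalUndefinedError` when g = c**2*var(b)/b**2 >= 1.
    """
    a, b = fit.intercept, fit.slope
    v11, v12, v22 = fit.vcov[0, 0], fit.vcov[0, 1], fit.vcov[1, 1]
    if level == 0.95:
        c = fit.crit
    elif fit.heterogeneity > 1 and fit.df > 0:
        c = float(stats.t.ppf(1 - (1 - level) / 2, fit.df))
    else:
        c = float(stats.norm.ppf(1 - (1 - level) / 2))
    g = c * c * v22 / (b * b)
    if g >= 1:
        raise IntervalUndefinedError(
            f"g = {g:.3f} >= 1: the slope is too poorly determined for a bounded interval"
        )
    A = b * b - c * c * v22
    B = 2 * (a * b - c * c * v12)
    C = a * a - c * c * v11
    disc = B * B - 4 * A * C
    if disc < 0:  # numerically tiny negative discriminants only
        disc = 0.0
    root = math.sqrt(disc)
    lo = (-B - root) / (2 * A)
    hi = (-B + root) / (2 * A)
    if lo > hi:
        lo, hi = hi, lo
    return (10 ** lo, 10 ** hi)


def _interval_of(x) -> tuple[float, float]:
    if isinstance(x, ProbitFit):
        return x.fl95
    lo, hi = x
    return float(lo), float(hi)


def _label_of(x, default: str) -> str:
    return default


def compare_lc50(
    fit_a: Union[ProbitFit, tuple[float, float]],
    fit_b: Union[ProbitFit, tuple[float, float]],
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonVerdict:
    """Significance by the fiducial-limit overlap rule.

    Two LC50s differ significantly iff their 95% fiducial intervals are
    disjoint; touching endpoints count as overlapping. Accepts fitted models
    or raw (lo, hi) intervals.
    """
    ia, ib = _interval_of(fit_a), _interval_of(fit_b)
    for interval in (ia, ib):
        if any(math.isnan(v) for v in interval):
            raise ValueError("cannot compare: fiducial interval undefined")
    disjoint = ia[1] < ib[0] or ib[1] < ia[0]
    return ComparisonVerdict(pair=labels, significant=bool(disjoint), basis=(ia, ib))


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, ties away from zero.

    90.625 -> 91; 6.25 -> 6.3; 3.125 -> 3.1; 0 -> 0.
    """
    if x == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (sig - 1 - magnitude)
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else -math.floor(-scaled + 0.5)
    return rounded / factor


def mortality_summary(data, sig: int = 2) -> pd.DataFrame:
    """Average percent mortality per treatment, replicates pooled.

    Accepts a :class:`BioassayDataset` (one treatment) or a DataFrame with
    columns ``treatment, n, dead``. Percentages are reported to ``sig``
    significant figures (29/32 dead -> 90.625 -> 91).
    """
    if isinstance(data, BioassayDataset):
        df = pd.DataFrame(
            [{"treatment": data.treatment, "n": r.n, "dead": r.dead} for r in data.records]
        )
    else:
        df = pd.DataFrame(data)
        missing = {"treatment", "n", "dead"} - set(df.columns)
        if missing:
            raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    pooled = df.groupby("treatment", as_index=False)[["n", "dead"]].sum()
    pooled["mortality_pct"] = [
        round_sigfigs(100.0 * d / n, sig) if n else 0.0
        for d, n in zip(pooled["dead"], pooled["n"])
    ]
    return pooled[["treatment", "n", "dead", "mortality_pct"]]
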