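"""Small assay statistics: growth curves, dose-response fits, group tests.

Covers the downstream validation arithmetic of a selection screen: doubling
time from exponential growth between seeding and saturation, four-parameter
log-logistic dose-response fitting for IC50 estimation (standard and
log-IC50 parametrizations), Welch two-sample comparison of IC50 groups, and
Benjamini-Hochberg control across comparison families.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import t as t_dist

from .enrichment import adjust_bh
from .errors import FitError, ValidationError

__all__ = [
    "GrowthCurve",
    "DoseResponseCurve",
    "Ll4Fit",
    "WelchResult",
    "doubling_time",
    "ll4",
    "fit_ll4",
    "compare_ic50",
    "welch_t",
    "group_test_bh",
    "load_dose_response",
    "load_growth_curves",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Replicate absorbance readouts over time (e.g. MTT assay)."""

    times: tuple[float, ...]
    absorbances: tuple[tuple[float, ...], ...]  # one replicate tuple per time

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError("times must be strictly increasing")
        if len(self.absorbances) != len(self.times):
            raise ValidationError("one absorbance replicate set per timepoint required")
        for reps in self.absorbances:
            if any(x <= 0 for x in reps):
                raise ValidationError("absorbances must be positive")

    def mean_absorbances(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.absorbances])


def doubling_time(n0: float, nt: float, t: float) -> float:
    """Doubling time ``t * ln(2) / ln(nt / n0)`` for exponential growth.

    Scale-invariant in (n0, nt).  Raises when no net growth occurred.
    """
    if n0 <= 0 or t <= 0:
        raise ValidationError("n0 and t must be positive")
    if nt <= n0:
        raise ValidationError(f"no growth: nt ({nt}) <= n0 ({n0})")
    return t * math.log(2.0) / math.log(nt / n0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Replicate-resolved viability over a concentration range.

    Concentrations may include zero-dose controls, which anchor the upper
    asymptote and are excluded from the log-dose axis.
    """

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self):
        if len(self.concentrations) != len(self.responses):
            raise ValidationError("concentrations and responses differ in length")
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("concentrations must be non-negative")
        if any(r < 0 for r in self.responses):
            raise ValidationError("responses must be non-negative")
        if len(set(self.concentrations)) < 4:
            raise ValidationError(
                "need >= 4 distinct concentrations for a four-parameter fit"
            )


def ll4(x, b: float, c: float, d: float, e: float):
    """Four-parameter log-logistic: c + (d - c) / (1 + exp(b (ln x - ln e))).

    At x = 0 the limit is d for b > 0 (upper asymptote) and c for b < 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0
    with np.errstate(over="ignore"):
        z = np.exp(np.clip(b * (np.log(np.where(zero, 1.0, x)) - math.log(e)), -700, 700))
    out = c + (d - c) / (1.0 + z)
    out[zero] = d if b > 0 else c
    return out


@dataclass
class Ll4Fit:
    """A converged four-parameter log-logistic fit."""

    lower: float
    upper: float
    hill: float
    ic50: float
    log_ic50_parametrization: bool
    residual_ss: float
    converged: bool
    ic50_se: float
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if self.converged:
            if self.ic50 <= 0:
                raise FitError(f"fitted IC50 must be positive, got {self.ic50}")
            if self.upper <= self.lower:
                raise FitError(
                    f"upper asymptote ({self.upper}) must exceed lower ({self.lower})"
                )


def _ll4_residuals(theta, x, y, log_e: bool):
    b, c, d, p = theta
    e = math.exp(p) if log_e else p
    if e <= 0:
        return np.full_like(y, 1e6)
    return ll4(x, b, c, d, e) - y


def fit_ll4(curve: DoseResponseCurve, parametrization: str = "ll4") -> Ll4Fit:
    """Least-squares four-parameter log-logistic fit with multistart.

    ``parametrization='ll4'`` fits IC50 directly; ``'ll2_4'`` fits ln(IC50).
    Raises FitError (with per-start diagnostics) if no start converges.
    """
    if parametrization not in ("ll4", "ll2_4"):
        raise ValidationError(f"unknown parametrization {parametrization!r}")
    log_e = parametrization == "ll2_4"
    x = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if np.allclose(y, y[0]):
        raise ValidationError("response is constant; dose-response fit undefined")

    pos = np.sort(np.unique(x[x > 0]))
    c0, d0 = float(y.min()), float(y.max())
    span = d0 - c0
    e_starts = [float(np.exp(np.quantile(np.log(pos), q))) for q in (0.25, 0.5, 0.75)]
    b_starts = [0.5, 1.0, 2.0, 4.0, -1.0]

    best = None
    diagnostics = {}
    for bi, b0 in enumerate(b_starts):
        for ei, e0 in enumerate(e_starts):
            theta0 = np.array(
                [b0, c0, d0, math.log(e0) if log_e else e0], dtype=float
            )
            try:
                res = optimize.least_squares(
                    _ll4_residuals, theta0, args=(x, y, log_e), method="lm",
                    max_nfev=20_000,
                )
            except Exception as exc:  # singular starts etc.
                diagnostics[(b0, e0)] = repr(exc)
                continue
            ss = float(np.sum(res.fun**2))
            diagnostics[(b0, e0)] = f"status={res.status} ss={ss:.4g}"
            if res.success and (best is None or ss < best[0]):
                best = (ss, res)
    if best is None:
        raise FitError("LL4 fit failed to converge from all starts", diagnostics)

    ss, res = best
    b, c, d, p = res.x
    e = math.exp(p) if log_e else p
    if b < 0:
        # reflect to the canonical orientation (d = response at low dose)
        b, c, d = -b, d, c
    n, k = y.size, 4
    dof = max(n - k, 1)
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (ss / dof)
        var_p = cov[3, 3]
        ic50_se = float(math.sqrt(max(var_p, 0.0)) * (e if log_e else 1.0))
    except np.linalg.LinAlgError:
        cov, ic50_se = None, float("nan")

    if e <= 0 or d <= c:
        raise FitError(
            f"LL4 fit converged to invalid parameters (ic50={e}, c={c}, d={d})",
            diagnostics,
        )
    return Ll4Fit(
        lower=float(c),
        upper=float(d),
        hill=float(b),
        ic50=float(e),
        log_ic50_parametrization=log_e,
        residual_ss=ss,
        converged=True,
        ic50_se=ic50_se,
        covariance=cov,
    )


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t test: statistic, Satterthwaite df, two-sided p."""

    t: float
    df: float
    p: float


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValidationError("both groups have zero variance; test degenerate")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * t_dist.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


def compare_ic50(fits_a: Sequence[float | Ll4Fit], fits_b: Sequence[float | Ll4Fit]) -> WelchResult:
    """Welch comparison of two groups of independent IC50 estimates."""
    def values(fits):
        return [f.ic50 if isinstance(f, Ll4Fit) else float(f) for f in fits]

    a, b = values(fits_a), values(fits_b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 IC50 estimates per group")
    return welch_t(a, b)


def group_test_bh(
    groups: Mapping[str, tuple[Sequence[float], Sequence[float]]]
) -> pd.DataFrame:
    """Welch p per two-arm comparison, BH q across the family.

    Comparisons with two degenerate (zero-variance) arms are flagged
    ``excluded`` with a warning and get no q-value; q-values for a given
    comparison are invariant to the mapping's iteration order.
    """
    names = sorted(groups)
    rows = []
    for name in names:
        a, b = groups[name]
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValidationError(f"comparison {name!r}: each arm needs >= 2 values")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            warnings.warn(f"comparison {name!r} has zero-variance arms; excluded")
            rows.append({"comparison": name, "t": np.nan, "df": np.nan,
                         "p": np.nan, "excluded": True})
            continue
        r = welch_t(a, b)
        rows.append({"comparison": name, "t": r.t, "df": r.df, "p": r.p,
                     "excluded": False})
    frame = pd.DataFrame(rows)
    frame["q"] = np.nan
    tested = ~frame["excluded"]
    if tested.any():
        frame.loc[tested, "q"] = adjust_bh(frame.loc[tested, "p"].to_numpy())
    return frame


def load_dose_response(path: str | Path) -> dict[str, DoseResponseCurve]:
    """Load long-format TSV (sample, dose, replicate, response) into curves."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "dose", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"dose-response table missing columns: {sorted(missing)}")
    out = {}
    for sample, grp in frame.groupby("sample"):
        out[str(sample)] = DoseResponseCurve(
            concentrations=tuple(float(v) for v in grp["dose"]),
            responses=tuple(float(v) for v in grp["response"]),
        )
    return out


def load_growth_curves(path: str | Path) -> dict[str, GrowthCurve]:
    """Load long-format TSV (sample, time, replicate, absorbance) into curves."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "absorbance"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)}")
    out = {}
    for sample, grp in frame.groupby("sample"):
        times = sorted(grp["time"].unique())
        reps = tuple(
            tuple(float(v) for v in grp.loc[grp["time"] == t, "absorbance"])
            for t in times
        )
        out[str(sample)] = GrowthCurve(times=tuple(float(t) for t in times),
                                       absorbances=reps)
    return out
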