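"""Statistical battery for electrode-cohort comparisons.

The experimental comparisons are nonparametric throughout: samples are
screened with Shapiro-Wilk, groups compared with Kruskal-Wallis at
alpha = 0.05, outliers flagged with asymmetric IQR fences (low fence
``Q1 - 1.5*IQR``, high fence ``Q3 + 3*IQR``), and scatter relationships
summarized with least-squares fits through the origin reported with a
centred-SST R^2.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise StatsError(f"group {self.label!r} needs a 1-D sample of n >= 1")
        if not np.isfinite(v).all():
            raise StatsError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class BoxSummary:
    """Quartile summary with the asymmetric outlier fences."""

    Q1: float
    median: float
    Q3: float
    IQR: float
    low_fence: float
    high_fence: float
    outliers: tuple[int, ...]  # indices into the input sample


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    p: float
    alpha: float = 0.05
    tie_corrected: bool = True

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha

    @property
    def stars(self) -> str:
        """Significance stars as used in the figure captions."""
        if self.p <= 0.001:
            return "***"
        if self.p <= 0.01:
            return "**"
        if self.p <= 0.05:
            return "*"
        return ""


@dataclass(frozen=True)
class OriginFit:
    """Least-squares line through the origin, y ~ k*x."""

    slope: float
    R2: float | None  # None when the centred SST vanishes
    n: int


def box_summary(
    values: Sequence[float], quantile_method: str = "linear"
) -> BoxSummary:
    """Quartiles (configurable convention) and asymmetric outlier fences.

    A point is an outlier when below ``Q1 - 1.5*IQR`` or above
    ``Q3 + 3*IQR`` — note the deliberately different multipliers for the
    two tails.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise StatsError("need n >= 3 for quartiles")
    if not np.isfinite(v).all():
        raise StatsError("values must be finite")
    q1, med, q3 = (float(np.quantile(v, q, method=quantile_method)) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    low = q1 - 1.5 * iqr
    high = q3 + 3.0 * iqr
    outliers = tuple(int(i) for i in np.flatnonzero((v < low) | (v > high)))
    return BoxSummary(
        Q1=q1, median=med, Q3=q3, IQR=iqr, low_fence=low, high_fence=high,
        outliers=outliers,
    )


def shapiro_wilk(values: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality screen (delegates to the reference
    implementation in scipy)."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise StatsError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(v)
    return TestResult(name="shapiro_wilk", statistic=float(w), df=v.size, p=float(p), alpha=alpha)


def _kw_statistic(groups: list[np.ndarray], tie_correction: bool) -> tuple[float, int]:
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # pooled mid-ranks
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean()) ** 2
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        denom = 1.0 - ((counts**3 - counts).sum()) / (n_total**3 - n_total)
        if denom > 0:
            h /= denom
    return float(h), n_total


def kruskal_wallis(
    groups: Sequence[GroupSample | Sequence[float]],
    alpha: float = 0.05,
    tie_correction: bool = True,
    method: Literal["chi2", "permutation"] = "chi2",
) -> TestResult:
    """Kruskal-Wallis rank test across two or more groups.

    ``H = 12/(N(N+1)) * sum n_i R_i^2 - 3(N+1)`` over pooled mid-ranks,
    divided by the tie correction ``1 - sum(t^3 - t)/(N^3 - N)``; the
    p-value comes from the chi-square approximation with ``k-1`` degrees
    of freedom, or from exhaustive permutation of group labels
    (small samples only).
    """
    arrs = [
        np.asarray(g.values if isinstance(g, GroupSample) else g, dtype=float)
        for g in groups
    ]
    if len(arrs) < 2:
        raise StatsError("need at least two groups")
    if any(a.size < 1 for a in arrs):
        raise StatsError("every group needs n >= 1")
    n_total = sum(a.size for a in arrs)
    if n_total < 3:
        raise StatsError("need total N >= 3")
    pooled = np.concatenate(arrs)
    df = len(arrs) - 1
    if np.ptp(pooled) == 0:
        return TestResult(
            name="kruskal_wallis", statistic=0.0, df=df, p=1.0, alpha=alpha,
            tie_corrected=tie_correction,
        )
    h, _ = _kw_statistic(arrs, tie_correction)
    if method == "chi2":
        p = float(sps.chi2.sf(h, df))
    elif method == "permutation":
        p = _kw_permutation_p(arrs, tie_correction)
    else:
        raise StatsError(f"unknown method {method!r}")
    return TestResult(
        name="kruskal_wallis", statistic=h, df=df, p=p, alpha=alpha,
        tie_corrected=tie_correction,
    )


def _kw_permutation_p(arrs: list[np.ndarray], tie_correction: bool) -> float:
    """Exact permutation p-value by enumerating all assignments of the
    pooled values to the group sizes (feasible for small N only)."""
    sizes = [a.size for a in arrs]
    n_total = sum(sizes)
    if n_total > 12:
        raise StatsError("exact permutation is limited to N <= 12")
    pooled = np.concatenate(arrs)
    h_obs, _ = _kw_statistic(arrs, tie_correction)
    idx = list(range(n_total))
    count = 0
    total = 0
    for perm in itertools.permutations(idx):
        parts = []
        start = 0
        for s in sizes:
            parts.append(pooled[list(perm[start : start + s])])
            start += s
        h, _ = _kw_statistic(parts, tie_correction)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def fit_through_origin(x: Sequence[float], y: Sequence[float]) -> OriginFit:
    """Least squares y ~ k*x with zero intercept.

    ``k = sum(xy)/sum(x^2)``; ``R2 = 1 - SSE/SST`` with the *centred*
    total sum of squares, so R2 can be negative; when SST vanishes
    (constant y) R2 is undefined and reported as None.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 2:
        raise StatsError("need matched samples of n >= 2")
    sxx = float(xv @ xv)
    if sxx == 0:
        raise StatsError("all x are zero; slope undefined")
    k = float(xv @ yv) / sxx
    sse = float(((yv - k * xv) ** 2).sum())
    sst = float(((yv - yv.mean()) ** 2).sum())
    r2 = None if sst == 0 else 1.0 - sse / sst
    return OriginFit(slope=k, R2=r2, n=int(xv.size))


# ---------------------------------------------------------------------------
# Comparison battery
# ---------------------------------------------------------------------------

_METRICS = ("G_Si", "G_CNT", "N_Si", "N_CNT")
_SCATTER_PAIRS = (
    ("G_CNT", "G_Si"),
    ("N_Si", "N_CNT"),
    ("N_CNT", "G_CNT"),
    ("G_Si", "N_CNT"),
)


@dataclass
class StatsReport:
    """All comparisons of a two-design cohort study."""

    within: dict[str, dict[str, TestResult]]
    across: dict[str, TestResult]
    fits: dict[str, dict[str, OriginFit]]
    success: dict[str, dict[str, int]]
    outliers: dict[str, dict[str, tuple[int, ...]]]
    n: dict[str, int]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def tr(t: TestResult) -> dict:
            return {
                "H": t.statistic,
                "df": t.df,
                "p": t.p,
                "significant": t.significant,
                "stars": t.stars,
            }

        return {
            "alpha": self.alpha,
            "n": self.n,
            "within": {d: {k: tr(v) for k, v in row.items()} for d, row in self.within.items()},
            "across": {k: tr(v) for k, v in self.across.items()},
            "fits": {
                d: {k: {"slope": f.slope, "R2": f.R2, "n": f.n} for k, f in row.items()}
                for d, row in self.fits.items()
            },
            "success": self.success,
            "outliers": {
                d: {k: list(v) for k, v in row.items()} for d, row in self.outliers.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for design, tests in self.within.items():
            for name, t in tests.items():
                rows.append(
                    {"comparison": f"{design}:{name}", "H": t.statistic, "df": t.df,
                     "p": t.p, "significant": t.significant, "stars": t.stars}
                )
        for name, t in self.across.items():
            rows.append(
                {"comparison": f"across:{name}", "H": t.statistic, "df": t.df,
                 "p": t.p, "significant": t.significant, "stars": t.stars}
            )
        return pd.DataFrame(rows)


def run_comparison_battery(
    designs: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    tie_correction: bool = True,
    quantile_method: str = "linear",
) -> StatsReport:
    """Run the full comparison battery on per-design metric tables.

    ``designs`` maps a design label (e.g. ``grid``/``fractal``) to a
    DataFrame with one row per electrode and columns G_Si, G_CNT, N_Si,
    N_CNT.  Within-design comparisons test surface effects (G_Si vs
    G_CNT, N_Si vs N_CNT); across-design comparisons test each metric
    between designs; through-origin fits summarize the scatter pairs;
    success counts tally electrodes satisfying ``G_Si > G_CNT`` and
    ``N_CNT > N_Si``.
    """
    if len(designs) < 2:
        raise StatsError("need at least two designs")
    for label, df in designs.items():
        missing = [m for m in _METRICS if m not in df.columns]
        if missing:
            raise StatsError(f"design {label!r} lacks metric columns {missing}")
        if len(df) < 2:
            raise StatsError(f"design {label!r} needs >= 2 electrodes")

    within: dict[str, dict[str, TestResult]] = {}
    fits: dict[str, dict[str, OriginFit]] = {}
    success: dict[str, dict[str, int]] = {}
    outliers: dict[str, dict[str, tuple[int, ...]]] = {}
    for label, df in designs.items():
        within[label] = {
            "G_Si_vs_G_CNT": kruskal_wallis(
                [df["G_Si"], df["G_CNT"]], alpha, tie_correction
            ),
            "N_Si_vs_N_CNT": kruskal_wallis(
                [df["N_Si"], df["N_CNT"]], alpha, tie_correction
            ),
        }
        fits[label] = {
            f"{y}_vs_{x}": fit_through_origin(df[x], df[y]) for x, y in _SCATTER_PAIRS
        }
        success[label] = {
            "G_Si>G_CNT": int((df["G_Si"] > df["G_CNT"]).sum()),
            "N_CNT>N_Si": int((df["N_CNT"] > df["N_Si"]).sum()),
        }
        outliers[label] = {
            m: box_summary(df[m], quantile_method).outliers if len(df) >= 3 else ()
            for m in _METRICS
        }

    labels = list(designs)
    across = {
        m: kruskal_wallis(
            [designs[lab][m] for lab in labels], alpha, tie_correction
        )
        for m in _METRICS
    }
    return StatsReport(
        within=within,
        across=across,
        fits=fits,
        success=success,
        outliers=outliers,
        n={lab: len(df) for lab, df in designs.items()},
        alpha=alpha,
    )
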