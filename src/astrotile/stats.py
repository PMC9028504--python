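"""Summary and inferential statistics for morphometric time courses.

Covers the statistics used around the morphometry: mean +/- s.e.m.
summaries, reference-timepoint normalization, pairwise Pearson
correlation of per-cell marker intensities (computed within each image,
then averaged across images), and one-way ANOVA with Tukey (equal group
sizes) / Tukey–Kramer (unequal) post-hoc comparisons.

The studentized-range CDF used for Tukey-adjusted p-values is computed
here by direct numerical integration:

    P(Q <= q; k, nu) = E_S[ k * int phi(z) (Phi(z) - Phi(z - q S))^(k-1) dz ]

with S the square root of a scaled chi-square with nu degrees of
freedom. The inner integral is evaluated with 240-point Gauss–Legendre
quadrature on z in [-10, 10 + qS] and the outer expectation with
adaptive quadrature; absolute error is well below 1e-6 over the q, k,
df ranges that occur in practice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

# ---------------------------------------------------------------------------
# simple summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: float
    n: int

    @property
    def degenerate(self) -> bool:
        """True when n == 1, where the s.e.m. is reported as 0."""
        return self.n == 1


def mean_sem(values: Sequence[float]) -> MeanSem:
    """Sample mean and standard error (sd / sqrt(n), sd with ddof=1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if x.size == 1:
        return MeanSem(float(x[0]), 0.0, 1)
    return MeanSem(float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size)), int(x.size))


def normalize_to_reference(series: Mapping, reference_label) -> dict:
    """Divide every value by the reference entry (reference maps to 1.0)."""
    if reference_label not in series:
        raise KeyError(f"reference label {reference_label!r} not present")
    ref = float(series[reference_label])
    if ref == 0.0:
        raise ValueError("reference value is zero")
    return {k: float(v) / ref for k, v in series.items()}


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

_ID_COLUMNS = ("cell_id", "image_id")


def correlation_matrix(
    table: pd.DataFrame, by: str | None = "image_id"
) -> pd.DataFrame:
    """Pairwise Pearson correlations of marker columns.

    When ``by`` names a grouping column that is present (default
    ``image_id``), correlations are computed within each group and then
    averaged unweighted across groups — the way replicate images are
    combined. Raises on constant marker columns (naming the marker) and
    on groups with fewer than 3 rows.
    """
    markers = [c for c in table.columns if c not in _ID_COLUMNS]
    if by is not None and by in table.columns:
        groups = [sub[markers] for _, sub in table.groupby(by, sort=True)]
    else:
        groups = [table[markers]]
    mats = []
    for sub in groups:
        if len(sub) < 3:
            raise ValueError("need at least 3 rows per group for correlations")
        for m in markers:
            if np.ptp(sub[m].to_numpy(dtype=float)) == 0:
                raise ValueError(f"marker {m!r} is constant; correlation undefined")
        mats.append(np.corrcoef(sub.to_numpy(dtype=float), rowvar=False))
    avg = np.mean(mats, axis=0)
    return pd.DataFrame(avg, index=markers, columns=markers)


# ---------------------------------------------------------------------------
# studentized range and Tukey / Tukey–Kramer
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(240)


def _range_cdf(r: float, k: int) -> float:
    """P(range of k iid standard normals <= r)."""
    if r <= 0.0:
        return 0.0
    lo, hi = -10.0, 10.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS
    phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    inner = special.ndtr(z) - special.ndtr(z - r)
    val = k * np.sum(w * phi * np.maximum(inner, 0.0) ** (k - 1))
    return float(min(max(val, 0.0), 1.0))


def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range Q(k, df); ``df=inf`` for the known-
    variance limit. Absolute accuracy better than 1e-6."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if q <= 0.0:
        return 0.0
    if not np.isfinite(df):
        return _range_cdf(q, k)
    nu = float(df)
    if nu <= 0:
        raise ValueError("df must be positive")
    # density of S = chi_nu / sqrt(nu)
    log_c = 0.5 * nu * math.log(nu) - special.gammaln(nu / 2.0) - (nu / 2.0 - 1.0) * math.log(2.0)

    def integrand(s: float) -> float:
        if s <= 0.0:
            return 0.0
        log_f = log_c + (nu - 1.0) * math.log(s) - 0.5 * nu * s * s
        return math.exp(log_f) * _range_cdf(q * s, k)

    center = 1.0
    spread = 8.0 / math.sqrt(max(nu, 1.0))
    pts = [max(center - spread, 1e-12), center, center + spread]
    val, _err = integrate.quad(
        integrand, 0.0, center + 12.0 * spread + 1.0, points=pts, limit=200,
        epsabs=1e-10, epsrel=1e-10,
    )
    return float(min(max(val, 0.0), 1.0))


def studentized_range_sf(q: float, k: int, df: float) -> float:
    return 1.0 - studentized_range_cdf(q, k, df)


@dataclass
class TukeyResult:
    """One-way ANOVA + Tukey / Tukey–Kramer pairwise comparisons."""

    table: pd.DataFrame
    f_stat: float
    f_pvalue: float
    df_between: int
    df_within: int
    ms_within: float
    alpha: float
    method: str

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f_stat:.4g}, p = {self.f_pvalue:.4g}",
            f"Post-hoc: {self.method} at alpha = {self.alpha}",
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)


def anova_tukey(
    groups: Mapping[object, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """One-way ANOVA with Tukey HSD (equal n) or Tukey–Kramer (unequal n).

    ``groups`` maps group labels to per-cell metric values. The pairwise
    q statistic is |mi - mj| / sqrt((MSW / 2)(1/ni + 1/nj)); adjusted
    p-values come from the studentized-range distribution with k groups
    and N - k degrees of freedom.
    """
    labels = list(groups)
    data = [np.asarray(list(groups[g]), dtype=float) for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    for lab, x in zip(labels, data):
        if x.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    k = len(labels)
    ns = np.array([x.size for x in data])
    N = int(ns.sum())
    means = np.array([x.mean() for x in data])
    sse = float(sum(((x - x.mean()) ** 2).sum() for x in data))
    df_w = N - k
    msw = sse / df_w
    f_stat, f_p = sps.f_oneway(*data)

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        se = math.sqrt((msw / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else 0.0
        p_adj = studentized_range_sf(q, k, df_w)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    method = "Tukey HSD" if len(set(ns.tolist())) == 1 else "Tukey-Kramer"
    return TukeyResult(
        table=pd.DataFrame(rows),
        f_stat=float(f_stat),
        f_pvalue=float(f_p),
        df_between=k - 1,
        df_within=df_w,
        ms_within=msw,
        alpha=alpha,
        method=method,
    )


def normality_report(groups: Mapping[object, Sequence[float]]) -> pd.DataFrame:
    """Shapiro–Wilk normality check per group; informational only — it
    never gates the analysis."""
    rows = []
    for lab, vals in groups.items():
        x = np.asarray(list(vals), dtype=float)
        if x.size >= 3:
            w, p = sps.shapiro(x)
        else:
            w, p = float("nan"), float("nan")
        rows.append({"group": lab, "n": int(x.size), "shapiro_w": w, "p": p})
    return pd.DataFrame(rows)


def paired_sign_test(
    before: Sequence[float], after: Sequence[float], alternative: str = "greater"
) -> float:
    """One-sided sign test p-value that ``after`` differs from ``before``
    in the stated direction (``greater`` means after > before), ignoring
    ties."""
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0
    wins = int((nz > 0).sum()) if alternative == "greater" else int((nz < 0).sum())
    return float(sps.binomtest(wins, nz.size, 0.5, alternative="greater").pvalue)
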