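"""Outlier detection and group tests on PC coordinates and ancestry tables.

The module operates on externally produced inputs: smartpca-style PC1/PC2
coordinates and qpAdm-style ancestry proportion tables (ANF/WHG/EHG/CHG point
estimates with standard errors).  Outliers are detected by squared
Mahalanobis distance from the group mean in the PC1-PC2 plane, with the
p-value from the chi-squared distribution with two degrees of freedom (for
which the upper tail has the closed form exp(-MD^2/2)).  Group moments use
the sample (n-1) covariance and include the tested point, mirroring the
procedure of computing group statistics first and distances afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "OutlierCall",
    "TestResult",
    "mahalanobis_outliers",
    "component_zscores",
    "variance_tests",
    "component_mean_test",
]


@dataclass(frozen=True)
class OutlierCall:
    iid: str
    group: str
    md2: float
    p: float
    flagged: bool


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_two_sided: float
    options: dict | None = None


def mahalanobis_outliers(pc: pd.DataFrame, group: str,
                         alpha: float = 0.05) -> list[OutlierCall]:
    """Flag PC1/PC2 outliers of one group by Mahalanobis distance.

    p = exp(-MD^2 / 2), the chi-squared (df = 2) upper tail; an individual is
    flagged when p < alpha.
    """
    sub = pc[pc["group"] == group]
    if len(sub) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 members")
    x = sub[["PC1", "PC2"]].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular PC covariance in group {group!r}") from exc
    d = x - mean
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    out = []
    for iid, m2 in zip(sub["iid"], md2):
        p = float(np.exp(-m2 / 2.0))
        out.append(OutlierCall(str(iid), group, float(m2), p, p < alpha))
    return out


def component_zscores(ancestry: pd.DataFrame, group: str, component: str,
                      z_threshold: float = 2.0) -> pd.DataFrame:
    """Per-individual Z of an ancestry component against its group.

    Z = (x - group mean) / group sample SD (the tested point included); rows
    are flagged at |Z| > ``z_threshold``.  Requires more than 3 group members;
    a zero SD yields missing Z values.
    """
    sub = ancestry[ancestry["group"] == group]
    if len(sub) <= 3:
        raise ValueError(f"group {group!r} needs more than 3 members for Z-scores")
    x = sub[component].to_numpy(dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        z = np.full(len(x), np.nan)
    else:
        z = (x - x.mean()) / sd
    return pd.DataFrame({
        "iid": sub["iid"].to_numpy(), "group": group, "component": component,
        "Z": z, "flagged": np.where(np.isnan(z), False, np.abs(z) > z_threshold),
    })


def variance_tests(groups: dict[str, np.ndarray]) -> dict[str, TestResult]:
    """Levene (mean-centred) and Bartlett homogeneity-of-variance tests."""
    if len(groups) < 2 or any(len(np.asarray(v)) < 2 for v in groups.values()):
        raise ValueError("need at least two groups with two values each")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    lev = sstats.levene(*samples, center="mean")
    bar = sstats.bartlett(*samples)
    return {
        "levene": TestResult("levene", float(lev.statistic), float(lev.pvalue),
                             {"center": "mean"}),
        "bartlett": TestResult("bartlett", float(bar.statistic), float(bar.pvalue)),
    }


def component_mean_test(values1, values2, kind: str = "pooled") -> TestResult:
    """Two-sample t-test on an ancestry component between groups."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if kind not in ("pooled", "welch"):
        raise ValueError("kind must be 'pooled' or 'welch'")
    res = sstats.ttest_ind(a, b, equal_var=(kind == "pooled"))
    return TestResult(f"t_{kind}", float(res.statistic), float(res.pvalue),
                      {"kind": kind})
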