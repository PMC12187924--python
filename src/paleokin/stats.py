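"""Contingency and proportion tests for the site-comparison table.

Self-contained implementations of the tests used to compare two burial
communities: Fisher's exact test (two-sided by the point-probability
criterion), the Pearson chi-square on 2x2 tables with optional Yates
continuity correction, the pooled two-proportion Z-test, and a label
permutation test.  ``site_comparison_report`` assembles the comparative
site table (outlier rates, ancestry flags, network strength ratios, clique
counts, Ne ranges, uniparental diversity, consanguinity rates), producing
every p-value with this module's own tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats

from .ancestry import TestResult

__all__ = [
    "ContingencyTable2x2",
    "SiteBundle",
    "fisher_exact_2x2",
    "chi2_2x2",
    "two_proportion_ztest",
    "permutation_test",
    "site_comparison_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are sites, columns trait yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 or int(v) != v for v in vals):
            raise ValueError("table entries must be non-negative integers")
        if sum(vals) == 0:
            raise ValueError("table must have at least one positive margin")

    @classmethod
    def from_array(cls, table) -> "ContingencyTable2x2":
        (a, b), (c, d) = np.asarray(table)
        return cls(int(a), int(b), int(c), int(d))


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    return ContingencyTable2x2.from_array(table)


def fisher_exact_2x2(table, tie_rtol: float = 1e-12) -> TestResult:
    """Two-sided Fisher's exact test by the point-probability criterion.

    With margins fixed, the two-sided p is the sum of hypergeometric
    probabilities of all tables whose point probability does not exceed the
    observed one (within a relative tie tolerance).
    """
    t = _as_table(table)
    r1, c1, n = t.a + t.b, t.a + t.c, t.a + t.b + t.c + t.d
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = sstats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(sstats.hypergeom.pmf(t.a, n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1.0 + tie_rtol)].sum())
    return TestResult("fisher_exact", p_obs, min(p, 1.0))


def chi2_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, optional Yates continuity correction."""
    t = _as_table(table)
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(exp == 0):
        raise ValueError("zero expected cell; chi-square undefined")
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev ** 2 / exp))
    return TestResult("chi2_yates" if yates else "chi2", stat,
                      float(sstats.chi2.sf(stat, df=1)), {"yates": yates})


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion Z-test, two-tailed."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n with n > 0")
    p_pool = (x1 + x2) / (n1 + n2)
    denom = np.sqrt(p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        return TestResult("two_proportion_z", 0.0, 1.0)
    z = (x2 / n2 - x1 / n1) / denom
    return TestResult("two_proportion_z", float(z),
                      float(2.0 * sstats.norm.sf(abs(z))))


def permutation_test(values: Sequence[float], labels: Sequence,
                     statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
                     n_perm: int = 10000,
                     seed: int | np.random.Generator | None = None) -> TestResult:
    """Two-group label permutation test (two-sided via |statistic|).

    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).  The default statistic
    is the difference of group means, permuted vectorised; a custom callable
    falls back to a Python loop.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("permutation test needs exactly two labels")
    mask = labels == uniq[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = int(mask.sum())
    if statistic is None:
        t_obs = values[mask].mean() - values[~mask].mean()
        perm = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
        t_perm = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
        name = "perm_mean_diff"
    else:
        t_obs = statistic(values[mask], values[~mask])
        t_perm = np.empty(n_perm)
        for i in range(n_perm):
            p = rng.permutation(values)
            t_perm[i] = statistic(p[:n1], p[n1:])
        name = "perm_custom"
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    return TestResult(name, float(t_obs), (1 + exceed) / (1 + n_perm),
                      {"n_perm": n_perm})


# ---------------------------------------------------------------------------
# Composite site comparison
# ---------------------------------------------------------------------------

@dataclass
class SiteBundle:
    """Per-site ingredients of the comparative table; unknown fields stay None."""

    name: str
    n_pca: int | None = None
    pca_outliers: int | None = None
    n_qpadm: int | None = None
    ehg_flagged: int | None = None
    k_values: Sequence[float] | None = None          # per-node k
    kw_over_k: float | None = None                   # mean within share of degree
    cliques_within: int | None = None
    cliques_between: int | None = None
    ne_range: tuple[float, float] | None = None
    n_y_males: int | None = None
    y_distinct: int | None = None
    n_mt: int | None = None
    mt_distinct: int | None = None
    n_roh: int | None = None
    consanguineous: int | None = None


def _both(a, b, *fields) -> bool:
    return all(getattr(a, f) is not None and getattr(b, f) is not None for f in fields)


def site_comparison_report(site_a: SiteBundle, site_b: SiteBundle) -> dict:
    """Comparative two-site report with the test used for every row.

    Rows (emitted when both bundles carry the inputs): PCA outlier rates
    (pooled Z-test), EHG Z-score flag rates (Yates chi-square), mean within-
    degree share kW/k (Welch t on per-node k when available), within/between
    clique counts (Pearson chi-square), Ne ranges, Y-lineage diversity (Yates
    chi-square), mtDNA subhaplogroup diversity (Fisher's exact), and
    consanguinity rates (Fisher's exact).
    """
    for bundle in (site_a, site_b):
        filled = {k: v for k, v in asdict(bundle).items() if k != "name" and v is not None}
        if not filled:
            raise ValueError(f"site bundle {bundle.name!r} carries no data")
    rows: dict[str, dict] = {}

    def row(key, xa, na, xb, nb, res: TestResult):
        rows[key] = {
            site_a.name: f"{xa}/{na}", site_b.name: f"{xb}/{nb}",
            "rate_a": xa / na if na else np.nan,
            "rate_b": xb / nb if nb else np.nan,
            "test": res.name, "statistic": res.statistic, "p": res.p_two_sided,
        }

    a, b = site_a, site_b
    if _both(a, b, "n_pca", "pca_outliers"):
        row("pca_outliers", a.pca_outliers, a.n_pca, b.pca_outliers, b.n_pca,
            two_proportion_ztest(a.pca_outliers, a.n_pca, b.pca_outliers, b.n_pca))
    if _both(a, b, "n_qpadm", "ehg_flagged"):
        row("ehg_z_flagged", a.ehg_flagged, a.n_qpadm, b.ehg_flagged, b.n_qpadm,
            chi2_2x2([[a.ehg_flagged, a.n_qpadm - a.ehg_flagged],
                      [b.ehg_flagged, b.n_qpadm - b.ehg_flagged]], yates=True))
    if a.kw_over_k is not None and b.kw_over_k is not None:
        entry = {site_a.name: a.kw_over_k, site_b.name: b.kw_over_k}
        if a.k_values is not None and b.k_values is not None:
            res = sstats.ttest_ind(np.asarray(a.k_values), np.asarray(b.k_values),
                                   equal_var=False)
            entry.update({"test": "welch_t_on_k", "statistic": float(res.statistic),
                          "p": float(res.pvalue)})
        rows["kw_over_k"] = entry
    if _both(a, b, "cliques_within", "cliques_between"):
        res = chi2_2x2([[a.cliques_within, a.cliques_between],
                        [b.cliques_within, b.cliques_between]])
        rows["cliques_within_between"] = {
            site_a.name: f"{a.cliques_within}/{a.cliques_between}",
            site_b.name: f"{b.cliques_within}/{b.cliques_between}",
            "test": res.name, "statistic": res.statistic, "p": res.p_two_sided,
        }
    if a.ne_range is not None and b.ne_range is not None:
        mid_a = float(np.sqrt(a.ne_range[0] * a.ne_range[1]))
        mid_b = float(np.sqrt(b.ne_range[0] * b.ne_range[1]))
        rows["ne_range"] = {site_a.name: list(a.ne_range), site_b.name: list(b.ne_range),
                            "fold_difference": max(mid_a, mid_b) / min(mid_a, mid_b)}
    if _both(a, b, "n_y_males", "y_distinct"):
        row("y_lineage_diversity", a.y_distinct, a.n_y_males, b.y_distinct, b.n_y_males,
            chi2_2x2([[a.y_distinct, a.n_y_males - a.y_distinct],
                      [b.y_distinct, b.n_y_males - b.y_distinct]], yates=True))
    if _both(a, b, "n_mt", "mt_distinct"):
        row("mtdna_diversity", a.mt_distinct, a.n_mt, b.mt_distinct, b.n_mt,
            fisher_exact_2x2([[a.mt_distinct, a.n_mt - a.mt_distinct],
                              [b.mt_distinct, b.n_mt - b.mt_distinct]]))
    if _both(a, b, "n_roh", "consanguineous"):
        row("inbreeding", a.consanguineous, a.n_roh, b.consanguineous, b.n_roh,
            fisher_exact_2x2([[a.consanguineous, a.n_roh - a.consanguineous],
                              [b.consanguineous, b.n_roh - b.consanguineous]]))
    if not rows:
        raise ValueError("site bundles share no comparable fields")
    return {"sites": [site_a.name, site_b.name], "rows": rows}
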