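"""Effective population size from ROH / IBD segment-length spectra.

Model: two haploid lineages in a diploid Wright-Fisher population of constant
size N coalesce g generations ago with probability
P(g) = (1/(2N)) (1 - 1/(2N))^(g-1).  Conditional on coalescence at g, the
genome (G Morgans over K chromosomes) is broken by 2g meioses into on average
2gG + K segments whose lengths are approximately Exp(2g), so the expected
number of segments with length in [u1, u2] Morgans is
(2gG + K) (exp(-2g u1) - exp(-2g u2)).  Summing over g weighted by P(g) gives
the per-lineage-pair expectation; an individual's two genomes form one such
pair (ROH mode) and a diploid pair forms four (IBD mode).  N is estimated by
maximising an independent-Poisson composite likelihood over length bins, with
the 95% CI from the chi-squared likelihood-ratio cutoff (2 dlogL <= 3.84).

An optional founder horizon ``max_gen`` truncates (without renormalising) the
coalescence pmf: lineage pairs that have not coalesced by ``max_gen``
contribute no segments.  This matches cohorts simulated from unrelated
founders a known number of generations ago; the default (None) is the open
horizon appropriate for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kinship import call_consanguinity_table, classify_degree, summarize_pairs
from .sim import GeneticMap

__all__ = [
    "SegmentSpectrum",
    "NeEstimate",
    "expected_counts",
    "build_spectrum",
    "fit_ne",
    "prefilter",
    "DEFAULT_ROH_BINS",
    "DEFAULT_IBD_BINS",
]

DEFAULT_ROH_BINS = np.array([4.0, 8.0, 12.0, 16.0, 20.0])
DEFAULT_IBD_BINS = np.geomspace(12.0, 100.0, 9)


@dataclass
class SegmentSpectrum:
    mode: str                      # "roh" | "ibd"
    bin_edges_cM: np.ndarray
    counts: np.ndarray
    n_units: int                   # individuals (roh) or diploid pairs (ibd)
    gmap: GeneticMap
    max_gen: int | None = None
    unit_bin_counts: np.ndarray | None = None  # units x bins (for dispersion)

    def __post_init__(self) -> None:
        if self.mode not in ("roh", "ibd"):
            raise ValueError("mode must be 'roh' or 'ibd'")
        edges = np.asarray(self.bin_edges_cM, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if len(counts) != len(edges) - 1:
            raise ValueError("counts/bin edges length mismatch")
        if np.any(counts < 0):
            raise ValueError("negative bin count")
        self.bin_edges_cM = edges
        self.counts = counts


@dataclass
class NeEstimate:
    N_hat: float
    ci95: tuple[float, float]
    loglik: float
    mode: str
    bins: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)
    expected: np.ndarray = field(repr=False, default=None)


_PAIRS_PER_UNIT = {"roh": 1.0, "ibd": 4.0}


def _counts_at_g(g: np.ndarray, u1: float, u2: float, gmap: GeneticMap) -> np.ndarray:
    """Expected segment count in [u1, u2] Morgans given coalescence at g."""
    G = gmap.L / 100.0
    return (2.0 * g * G + gmap.K) * (np.exp(-2.0 * g * u1) - np.exp(-2.0 * g * u2))


def expected_counts(N: float, bin_cM: tuple[float, float], gmap: GeneticMap,
                    mode: str = "roh", max_gen: int | None = None,
                    tail_tol: float = 1e-8) -> float:
    """Expected number of segments per unit in a length bin, at size N.

    ``bin_cM`` is (lower, upper) in cM.  Geometric coalescence times are
    summed in blocks until the remaining tail is below ``tail_tol`` of the
    running sum (or up to ``max_gen`` under a founder horizon).
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    u1, u2 = bin_cM[0] / 100.0, bin_cM[1] / 100.0
    if not 0 < u1 < u2:
        raise ValueError("bin must satisfy 0 < lower < upper")
    q = 1.0 - 1.0 / (2.0 * N)
    total = 0.0
    g0 = 1
    block = 512
    while True:
        g_hi = g0 + block - 1
        if max_gen is not None:
            g_hi = min(g_hi, max_gen)
        if g_hi < g0:
            break
        g = np.arange(g0, g_hi + 1, dtype=float)
        pg = (1.0 / (2.0 * N)) * q ** (g - 1.0)
        total += float(np.sum(pg * _counts_at_g(g, u1, u2, gmap)))
        if max_gen is not None and g_hi >= max_gen:
            break
        # tail bound: both the geometric pmf and exp(-2g u1) decay geometrically
        decay = q * np.exp(-2.0 * u1)
        tail = (pg[-1] * _counts_at_g(np.array([g_hi + 1.0]), u1, u2, gmap)[0]
                / max(1.0 - decay, 1e-12))
        if tail < tail_tol * max(total, 1e-300):
            break
        g0 = g_hi + 1
        if g0 > 5_000_000:          # hard stop; never reached for sane N
            break
    return _PAIRS_PER_UNIT[mode] * total


def expected_counts_fixed_g(g: int, bin_cM: tuple[float, float],
                            gmap: GeneticMap) -> float:
    """Expected per-lineage-pair count when coalescence is fixed at g."""
    u1, u2 = bin_cM[0] / 100.0, bin_cM[1] / 100.0
    if not 0 < u1 < u2:
        raise ValueError("bin must satisfy 0 < lower < upper")
    return float(_counts_at_g(np.array([float(g)]), u1, u2, gmap)[0])


def build_spectrum(segments: pd.DataFrame, mode: str, n_units: int,
                   gmap: GeneticMap, bin_edges_cM: np.ndarray | None = None,
                   max_gen: int | None = None) -> SegmentSpectrum:
    """Histogram a segment table (column length_cM) into a spectrum.

    Per-unit, per-bin counts (per individual for roh, per pair for ibd) are
    recorded when the identifying columns are present; units with no
    segments in range count as zeros.  They feed the per-bin dispersion
    estimates used to calibrate the confidence interval in :func:`fit_ne`.
    """
    edges = np.asarray(bin_edges_cM if bin_edges_cM is not None
                       else (DEFAULT_ROH_BINS if mode == "roh" else DEFAULT_IBD_BINS))
    lengths = segments["length_cM"].to_numpy(dtype=float) if len(segments) else np.empty(0)
    counts, _ = np.histogram(lengths, bins=edges)
    unit_bin = None
    key = ["iid"] if mode == "roh" else ["iid1", "iid2"]
    if len(segments) and all(c in segments.columns for c in key):
        units = segments.groupby(key, sort=True).indices
        unit_bin = np.zeros((max(n_units, len(units)), len(edges) - 1))
        for row, idx in enumerate(units.values()):
            unit_bin[row], _ = np.histogram(lengths[idx], bins=edges)
    return SegmentSpectrum(mode, edges, counts.astype(float), n_units, gmap,
                           max_gen=max_gen, unit_bin_counts=unit_bin)


def _loglik(N: float, spec: SegmentSpectrum,
            dispersion: np.ndarray | None = None) -> float:
    ll = 0.0
    for i, obs in enumerate(spec.counts):
        mu = spec.n_units * expected_counts(
            N, (spec.bin_edges_cM[i], spec.bin_edges_cM[i + 1]), spec.gmap,
            spec.mode, spec.max_gen)
        mu = max(mu, 1e-12)
        phi = 1.0 if dispersion is None else dispersion[i]
        ll += (obs * np.log(mu) - mu) / phi
    return ll


def _bin_dispersion(spec: SegmentSpectrum) -> np.ndarray | None:
    """Per-bin quasi-Poisson dispersion from unit-level counts, floored at 1.

    Segment counts cluster within a unit (one recent common ancestor leaves
    several long segments at once), most strongly in the long-length bins;
    plain Poisson information therefore overstates precision exactly where
    the data are most informative about N.
    """
    ub = spec.unit_bin_counts
    if ub is None or ub.shape[0] < 2:
        return None
    mean = ub.mean(axis=0)
    var = ub.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, var / np.maximum(mean, 1e-300), 1.0)
    return np.maximum(phi, 1.0)


def fit_ne(spectrum: SegmentSpectrum, n_min: float = 10.0,
           n_max: float = 1e6) -> NeEstimate:
    """Maximum-likelihood constant N with a likelihood-ratio 95% CI.

    The quasi-Poisson composite log-likelihood (per-bin contributions
    down-weighted by dispersion factors estimated from the unit-level
    counts, see :func:`_bin_dispersion`) is maximised over log N on
    [log n_min, log n_max]; the CI is {N : 2 (lmax - l(N)) <= 3.84},
    clipped at the search range if the bound is not bracketed.
    """
    if spectrum.counts.sum() < 1:
        raise ValueError("empty spectrum: need at least one observed segment "
                         "(more individuals/pairs or wider bins)")
    dispersion = _bin_dispersion(spectrum)
    lo, hi = np.log(n_min), np.log(n_max)
    res = optimize.minimize_scalar(
        lambda x: -_loglik(np.exp(x), spectrum, dispersion),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    n_hat = float(np.exp(res.x))
    lmax = -float(res.fun)
    cutoff = lmax - 3.84 / 2.0

    def shifted(x: float) -> float:
        return _loglik(np.exp(x), spectrum, dispersion) - cutoff

    ci_lo = n_min
    if shifted(lo) < 0:
        ci_lo = float(np.exp(optimize.brentq(shifted, lo, res.x, xtol=1e-6)))
    ci_hi = n_max
    if shifted(hi) < 0:
        ci_hi = float(np.exp(optimize.brentq(shifted, res.x, hi, xtol=1e-6)))
    expected = np.array([
        spectrum.n_units * expected_counts(
            n_hat, (spectrum.bin_edges_cM[i], spectrum.bin_edges_cM[i + 1]),
            spectrum.gmap, spectrum.mode, spectrum.max_gen)
        for i in range(len(spectrum.counts))
    ])
    return NeEstimate(n_hat, (ci_lo, ci_hi), lmax, spectrum.mode,
                      bins=spectrum.bin_edges_cM, observed=spectrum.counts,
                      expected=expected)


def prefilter(segments: pd.DataFrame, mode: str, gmap: GeneticMap,
              ibd_window_cM: tuple[float, float] = (12.0, 100.0),
              ) -> tuple[pd.DataFrame, list]:
    """Apply the pre-filters used before Ne estimation.

    roh mode: drop individuals flagged consanguineous (> 50 cM summed ROH in
    > 20 cM blocks).  ibd mode: drop pairs classified closer than 4th degree
    and keep only segments inside the 12-100 cM window.  Returns the filtered
    table and the list of removed individuals / pairs.
    """
    if mode == "roh":
        calls = call_consanguinity_table(segments, gmap.L)
        dropped = [c.iid for c in calls if c.flagged]
        return segments[~segments["iid"].isin(dropped)].reset_index(drop=True), dropped
    if mode == "ibd":
        close = {"PO", "FS", "degree2", "degree3"}
        dropped_pairs = []
        for summ in summarize_pairs(segments, gmap):
            if classify_degree(summ).category in close:
                dropped_pairs.append((summ.iid1, summ.iid2))
        if dropped_pairs:
            bad = pd.MultiIndex.from_tuples(dropped_pairs)
            idx = pd.MultiIndex.from_frame(segments[["iid1", "iid2"]])
            segments = segments[~idx.isin(bad)]
        lengths = segments["end_cM"] - segments["start_cM"]
        keep = (lengths >= ibd_window_cM[0]) & (lengths <= ibd_window_cM[1])
        return segments[keep].reset_index(drop=True), dropped_pairs
    raise ValueError("mode must be 'roh' or 'ibd'")
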