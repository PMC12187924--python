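"""Pairwise relatedness, consanguinity and pedigree validation.

Degree classification works on the merged (union) IBD share of the genome,
phi = union_cM / L, with analytic expectations 1, 3/4, 1/2, 1/4, ... for
parent-offspring, full siblings and 2nd/3rd/... degree relatives; bin edges
are the geometric midpoints between successive expectations.  Parent-offspring
and full siblings are separated on the IBD2 fraction (regions covered by two
disjoint haplotype combinations), which is ~0 for parent-offspring and ~1/4
for full siblings.  Consanguinity of an individual's parents is read from the
individual's ROH: the flag follows the rule "sum of ROH segments longer than
20 cM exceeds 50 cM", and the parental degree class from the genome-wide ROH
fraction F_hat compared with 1/4, 1/8, 1/16, ... expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sim import GeneticMap, PedigreeSpec, pedigree_degree

__all__ = [
    "PairSummary",
    "DegreeCall",
    "ConsanguinityCall",
    "merge_intervals",
    "union_length",
    "depth2_length",
    "summarize_pair",
    "summarize_pairs",
    "classify_degree",
    "call_consanguinity",
    "call_consanguinity_table",
    "infer_parental_degree",
    "validate_pedigree",
    "DEGREE_CATEGORIES",
]

DEGREE_CATEGORIES = ("PO", "FS", "degree2", "degree3", "degree4", "degree5",
                     "degree6plus", "unrelated")

# geometric midpoints between expected union-share fractions
# 1 (PO), 3/4 (FS), 1/2, 1/4, 1/8, 1/16 (degrees 2..5)
_PHI_FS_LO = math.sqrt(0.75 * 0.5)            # ~0.612, rounded to 0.60 by convention
_PHI_D2_LO = math.sqrt(0.5 * 0.25)            # 0.3536
_PHI_D3_LO = math.sqrt(0.25 * 0.125)          # 0.1768
_PHI_D4_LO = math.sqrt(0.125 * 0.0625)        # 0.0884
_PHI_D5_LO = math.sqrt(0.0625 * 0.03125)      # 0.0442

_DEGREE_RANK = {"PO": 1.0, "FS": 1.5, "degree2": 2.0, "degree3": 3.0,
                "degree4": 4.0, "degree5": 5.0, "degree6plus": 6.0,
                "unrelated": 8.0}


@dataclass(frozen=True)
class PairSummary:
    iid1: str
    iid2: str
    union_cM: float
    n_segments: int
    max_cM: float
    ibd2_cM: float
    phi: float
    n_seg_ge12: int = 0


@dataclass(frozen=True)
class DegreeCall:
    iid1: str
    iid2: str
    category: str


@dataclass(frozen=True)
class ConsanguinityCall:
    iid: str
    sum_roh_gt20_cM: float
    flagged: bool
    F_hat: float
    parental_degree_class: str


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping half-open intervals into a disjoint union."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s), np.array(out_e)


def union_length(starts, ends) -> float:
    s, e = merge_intervals(starts, ends)
    return float(np.sum(e - s))


def depth2_length(starts, ends) -> float:
    """Total length covered by at least two of the given intervals."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if len(starts) < 2:
        return 0.0
    pts = np.concatenate([starts, ends])
    wts = np.concatenate([np.ones(len(starts)), -np.ones(len(ends))])
    order = np.lexsort((wts, pts))        # closings before openings at ties
    pts, wts = pts[order], wts[order]
    depth = np.cumsum(wts)
    spans = np.diff(pts)
    return float(np.sum(spans[depth[:-1] >= 2]))


# ---------------------------------------------------------------------------
# Pair summaries
# ---------------------------------------------------------------------------

def summarize_pair(segments: pd.DataFrame, L: float,
                   iid1: str | None = None, iid2: str | None = None) -> PairSummary:
    """Summary statistics for one pair from its IBD segment list.

    ``segments`` needs columns chromosome, start_cM, end_cM (one pair only);
    rows from different haplotype combinations may overlap, in which case the
    union merges them and the doubly covered length is reported as IBD2.
    """
    if iid1 is None and len(segments):
        iid1 = str(segments["iid1"].iloc[0])
        iid2 = str(segments["iid2"].iloc[0])
    iid1 = iid1 or ""
    iid2 = iid2 or ""
    if len(segments) == 0:
        return PairSummary(iid1, iid2, 0.0, 0, 0.0, 0.0, 0.0, 0)
    lengths = (segments["end_cM"] - segments["start_cM"]).to_numpy(dtype=float)
    if np.any(lengths < 0):
        raise ValueError("segment with end < start")
    union = 0.0
    ibd2 = 0.0
    for _, chunk in segments.groupby("chromosome", sort=False):
        s = chunk["start_cM"].to_numpy(dtype=float)
        e = chunk["end_cM"].to_numpy(dtype=float)
        union += union_length(s, e)
        ibd2 += depth2_length(s, e)
    return PairSummary(
        iid1=iid1, iid2=iid2,
        union_cM=union, n_segments=int(len(segments)),
        max_cM=float(lengths.max()), ibd2_cM=ibd2,
        phi=union / L, n_seg_ge12=int(np.sum(lengths >= 12.0)),
    )


def summarize_pairs(ibd: pd.DataFrame, gmap: GeneticMap | float) -> list[PairSummary]:
    """One :class:`PairSummary` per (iid1, iid2) pair in an IBD table."""
    L = gmap.L if isinstance(gmap, GeneticMap) else float(gmap)
    out = []
    for (iid1, iid2), chunk in ibd.groupby(["iid1", "iid2"], sort=True):
        out.append(summarize_pair(chunk, L, str(iid1), str(iid2)))
    return out


# ---------------------------------------------------------------------------
# Degree classification
# ---------------------------------------------------------------------------

def classify_degree(summary: PairSummary) -> DegreeCall:
    """Bin a pair summary into a relatedness category.

    Parent-offspring requires near-complete union sharing with negligible
    IBD2; full siblings high sharing with substantial IBD2.  Deeper degrees
    use geometric-midpoint bins on phi, and pairs below the 5th-degree bin are
    called degree6plus only when they share at least two segments of >= 12 cM.
    """
    phi = summary.phi
    if phi > 1.0 + 1e-9:
        raise ValueError(f"phi = {phi} exceeds 1; union longer than the genome")
    ibd2_frac = summary.ibd2_cM / max(summary.union_cM / max(phi, 1e-300), 1e-300) \
        if phi > 0 else 0.0
    # note: union_cM / phi == L; avoids carrying L separately
    if phi >= 0.90 and ibd2_frac < 0.10:
        cat = "PO"
    elif phi > _PHI_FS_LO:
        cat = "FS"
    elif phi > _PHI_D2_LO:
        cat = "degree2"
    elif phi > _PHI_D3_LO:
        cat = "degree3"
    elif phi > _PHI_D4_LO:
        cat = "degree4"
    elif phi > _PHI_D5_LO:
        cat = "degree5"
    elif summary.n_seg_ge12 >= 2:
        cat = "degree6plus"
    else:
        cat = "unrelated"
    return DegreeCall(summary.iid1, summary.iid2, cat)


# ---------------------------------------------------------------------------
# Consanguinity from ROH
# ---------------------------------------------------------------------------

def infer_parental_degree(roh_total_cM: float, L: float) -> str:
    """Class of the parents' relatedness from the genome-wide ROH fraction.

    F_hat = roh_total / L is compared with the inbreeding coefficients of
    offspring of 1st- to 5th-degree related parents (1/4 ... 1/64) using
    geometric-midpoint bins; below the last midpoint (~0.011) the individual
    is called outbred.
    """
    if not 0.0 <= roh_total_cM <= L * (1 + 1e-9):
        raise ValueError("ROH total must lie in [0, L]")
    f = roh_total_cM / L
    edges = [math.sqrt(0.25 * 0.125), math.sqrt(0.125 * 0.0625),
             math.sqrt(0.0625 * 0.03125), math.sqrt(0.03125 * 0.015625),
             math.sqrt(0.015625 * 0.0078125)]
    names = ["parents_1st_degree", "parents_2nd_degree", "parents_3rd_degree",
             "parents_4th_degree", "parents_5th_degree"]
    for name, lo in zip(names, edges):
        if f > lo:
            return name
    return "outbred"


def call_consanguinity(roh_segments: pd.DataFrame, L: float,
                       iid: str | None = None,
                       sum_threshold_cM: float = 50.0,
                       block_threshold_cM: float = 20.0,
                       min_roh_cM: float = 4.0) -> ConsanguinityCall:
    """Consanguinity call for one individual from its ROH segment list.

    Flagged iff the summed length of ROH blocks strictly longer than
    ``block_threshold_cM`` strictly exceeds ``sum_threshold_cM`` (ties are
    conservatively not flagged).  F_hat uses all ROH >= ``min_roh_cM``.
    """
    if iid is None:
        iid = str(roh_segments["iid"].iloc[0]) if len(roh_segments) else ""
    if len(roh_segments):
        lengths = (roh_segments["end_cM"] - roh_segments["start_cM"]).to_numpy(dtype=float)
        if np.any(lengths < 0):
            raise ValueError("ROH segment with end < start")
    else:
        lengths = np.empty(0)
    long_sum = float(lengths[lengths > block_threshold_cM].sum())
    total = float(lengths[lengths >= min_roh_cM].sum())
    return ConsanguinityCall(
        iid=iid,
        sum_roh_gt20_cM=long_sum,
        flagged=long_sum > sum_threshold_cM,
        F_hat=total / L,
        parental_degree_class=infer_parental_degree(total, L),
    )


def call_consanguinity_table(roh: pd.DataFrame, L: float,
                             all_ids: list[str] | None = None,
                             **kwargs) -> list[ConsanguinityCall]:
    """Consanguinity calls for every individual in an ROH table.

    ``all_ids`` adds individuals with no ROH rows (they get empty calls).
    """
    calls = {}
    for iid, chunk in roh.groupby("iid", sort=True):
        calls[str(iid)] = call_consanguinity(chunk, L, str(iid), **kwargs)
    for iid in all_ids or []:
        if iid not in calls:
            calls[iid] = call_consanguinity(roh.iloc[0:0], L, iid, **kwargs)
    return [calls[k] for k in sorted(calls)]


# ---------------------------------------------------------------------------
# Pedigree validation
# ---------------------------------------------------------------------------

def validate_pedigree(spec: PedigreeSpec,
                      summaries: list[PairSummary] | dict[tuple[str, str], PairSummary],
                      metadata: pd.DataFrame,
                      missing: set[str] | None = None) -> list[dict]:
    """Check a proposed pedigree against IBD and uniparental evidence.

    Emits one violation record per (a) mother-child mitochondrial mismatch,
    (b) father-son Y mismatch, (c) pair whose observed degree call is at
    least one degree away from the pedigree-implied category (PO and FS count
    as the same degree).  Individuals listed in ``missing`` are skipped.
    """
    missing = missing or set()
    meta = metadata.set_index("iid")
    known = set(meta.index)
    parents = spec.parents()
    for iid in parents:
        if iid not in known and iid not in missing:
            raise KeyError(f"pedigree member {iid!r} absent from metadata and not marked missing")

    if isinstance(summaries, dict):
        sdict = {tuple(sorted(k)): v for k, v in summaries.items()}
    else:
        sdict = {tuple(sorted((s.iid1, s.iid2))): s for s in summaries}

    violations: list[dict] = []
    for iid, (mother, father) in parents.items():
        if iid in missing:
            continue
        if mother is not None and mother not in missing:
            if meta.at[iid, "mt_hg"] != meta.at[mother, "mt_hg"]:
                violations.append({"kind": "mt_mismatch", "child": iid, "mother": mother,
                                   "child_mt": meta.at[iid, "mt_hg"],
                                   "mother_mt": meta.at[mother, "mt_hg"]})
        if father is not None and father not in missing and meta.at[iid, "sex"] == "M":
            if meta.at[iid, "y_hg"] != meta.at[father, "y_hg"]:
                violations.append({"kind": "y_mismatch", "son": iid, "father": father,
                                   "son_y": meta.at[iid, "y_hg"],
                                   "father_y": meta.at[father, "y_hg"]})

    members = [i for i in parents if i not in missing]
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            implied = pedigree_degree(spec, a, b)
            key = tuple(sorted((a, b)))
            summ = sdict.get(key)
            observed = classify_degree(summ).category if summ is not None else "unrelated"
            if abs(_DEGREE_RANK[observed] - _DEGREE_RANK[implied]) >= 1.0:
                violations.append({"kind": "degree_mismatch", "iid1": key[0], "iid2": key[1],
                                   "implied": implied, "observed": observed})
    return violations
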