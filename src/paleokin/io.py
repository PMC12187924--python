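"""Readers/writers for the pipeline's TSV/JSON artifacts and the full run.

All tables are UTF-8 TSV with '.' decimals and empty strings for missing
values; coordinates are cM, half-open [start, end), 0-based per chromosome
(stated in a leading comment line of every written file).  ``run_pipeline``
ties the stages together: simulate (optional) -> kinship -> network ->
cliques -> communities -> outliers -> Ne -> site report, every output stamped
with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import demography as demog
from . import kinship as kin
from . import network as net
from . import sim
from . import stats as pstats

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_segment_table",
    "write_segment_table",
    "read_metadata",
    "write_metadata",
    "read_table",
    "run_pipeline",
]

_COORD_COMMENT = "# coordinates: cM, half-open [start_cM, end_cM), 0-based per chromosome\n"

_REQUIRED = {
    "ibd": ["iid1", "iid2", "chromosome", "start_cM", "end_cM", "length_cM"],
    "roh": ["iid", "chromosome", "start_cM", "end_cM", "length_cM"],
}


def write_segment_table(df: pd.DataFrame, path, mode: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_segment_table(path, mode: str) -> pd.DataFrame:
    """Read and validate an IBD or ROH segment TSV.

    Intervals must satisfy end > start and, when a length column is present,
    length == end - start within 1e-6 cM; offending rows are reported by
    line number.
    """
    if mode not in _REQUIRED:
        raise ValueError("mode must be 'ibd' or 'roh'")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str})
    missing = [c for c in _REQUIRED[mode] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    # line numbers: 1-based, counting the comment line(s) and header
    with open(path) as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    first_data_line = n_comment + 2
    start = df["start_cM"].to_numpy(dtype=float)
    end = df["end_cM"].to_numpy(dtype=float)
    bad = end <= start
    if "length_cM" in df.columns:
        bad |= np.abs((end - start) - df["length_cM"].to_numpy(dtype=float)) > 1e-6
    if bad.any():
        lines = [int(i) + first_data_line for i in np.flatnonzero(bad)]
        raise ValueError(f"{path}: malformed interval row(s) at line(s) {lines}")
    return df


_SEXES = {"M", "F", "U"}


def write_metadata(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path) -> pd.DataFrame:
    """Read individual metadata (iid, site, sex [, style, mt_hg, y_hg, sr_local])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in ("iid", "site", "sex") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["iid"][df["iid"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate iid(s) {sorted(set(dup))}")
    unknown = ~df["sex"].isin(_SEXES)
    if unknown.any():
        warnings.warn(f"{path}: unknown sex code(s) "
                      f"{sorted(set(df.loc[unknown, 'sex']))} coerced to 'U'")
        df.loc[unknown, "sex"] = "U"
    return df


def read_table(path) -> pd.DataFrame:
    """Generic TSV reader (ancestry / PC tables)."""
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; rule constants default to the study's values."""

    outdir: str = "paleokin_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: dict | None = None
    # ... or point at input tables
    ibd_path: str | None = None
    roh_path: str | None = None
    metadata_path: str | None = None
    ancestry_path: str | None = None
    pc_path: str | None = None
    # thresholds
    min_seg_cM: float = 12.0
    min_n_segments: int = 2
    alpha: float = 0.05
    gamma: float = 0.04
    roh_sum_cM: float = 50.0
    roh_block_cM: float = 20.0
    ne_max_gen: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_seg_cM", "min_n_segments", "alpha", "gamma",
                     "roh_sum_cM", "roh_block_cM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write its reports under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gmap = sim.make_genetic_map()
    stamp = {"config_hash": config.digest(), "seed": config.seed,
             "config": config.to_dict()}
    _dump_json(stamp, out / "run.json")

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:   # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc
        return wrap

    # -- inputs ------------------------------------------------------------
    ne_max_gen = config.ne_max_gen
    if config.simulate is not None:
        params = dict(config.simulate)
        run_sim = stage("simulate")
        cohort = run_sim(sim.simulate_community, seed=config.seed, **params)
        ibd = run_sim(sim.extract_ibd, cohort)
        roh = run_sim(sim.extract_roh, cohort)
        metadata = cohort.metadata_frame()
        sites = sorted(metadata["site"].unique())
        rng = np.random.default_rng(config.seed + 1)
        groups = {
            s: sim.GroupProfile(n=int((metadata["site"] == s).sum()),
                                pc_mean=(float(rng.normal(0, 0.01)),
                                         float(rng.normal(0, 0.01))),
                                pc_cov=((1e-4, 0.0), (0.0, 1e-4)))
            for s in sites
        }
        ancestry_df, pc_df = run_sim(sim.emulate_profiles, groups, None, config.seed + 2)
        indir = out / "inputs"
        indir.mkdir(exist_ok=True)
        write_segment_table(ibd, indir / "ibd.tsv")
        write_segment_table(roh, indir / "roh.tsv")
        write_metadata(metadata, indir / "metadata.tsv")
        ancestry_df.to_csv(indir / "ancestry.tsv", sep="\t", index=False)
        pc_df.to_csv(indir / "pc.tsv", sep="\t", index=False)
        if ne_max_gen is None:
            ne_max_gen = params.get("generations", 4)
    else:
        rd = stage("read_inputs")
        ibd = rd(read_segment_table, config.ibd_path, "ibd") if config.ibd_path else None
        roh = rd(read_segment_table, config.roh_path, "roh") if config.roh_path else None
        if config.metadata_path is None:
            raise PipelineError("read_inputs", ValueError("metadata_path is required"))
        metadata = rd(read_metadata, config.metadata_path)
        ancestry_df = rd(read_table, config.ancestry_path) if config.ancestry_path else None
        pc_df = rd(read_table, config.pc_path) if config.pc_path else None

    # -- kinship -----------------------------------------------------------
    if ibd is not None and len(ibd):
        s = stage("kinship")
        summaries = s(kin.summarize_pairs, ibd, gmap)
        pairs = pd.DataFrame([dataclasses.asdict(x) for x in summaries])
        pairs["category"] = [kin.classify_degree(x).category for x in summaries]
        pairs.to_csv(out / "pair_summaries.tsv", sep="\t", index=False)
    if roh is not None and len(roh):
        s = stage("consanguinity")
        calls = s(kin.call_consanguinity_table, roh, gmap.L,
                  all_ids=sorted(metadata["iid"]),
                  sum_threshold_cM=config.roh_sum_cM,
                  block_threshold_cM=config.roh_block_cM)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            out / "consanguinity.tsv", sep="\t", index=False)
    else:
        calls = []

    # -- network / cliques / communities ------------------------------------
    if ibd is not None and len(ibd):
        s = stage("network")
        graph = s(net.build_graph, ibd, metadata, config.min_seg_cM,
                  config.min_n_segments)
        metrics = s(net.node_metrics, graph)
        metrics.to_csv(out / "node_metrics.tsv", sep="\t")
        net.module_means(metrics).to_csv(out / "module_means.tsv", sep="\t")
        edges = pd.DataFrame(
            [{"iid1": min(u, v), "iid2": max(u, v), **d}
             for u, v, d in graph.edges(data=True)]
        ).sort_values(["iid1", "iid2"]) if graph.number_of_edges() else pd.DataFrame(
            columns=["iid1", "iid2", "n_segments", "max_cM", "total_cM"])
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        _dump_json(net.graph_summary(graph), out / "graph_summary.json")

        s = stage("cliques")
        cliques = s(net.enumerate_cliques, graph)
        _dump_json({"cliques": [{"nodes": list(c.nodes),
                                 "classification": c.classification}
                                for c in cliques],
                    "classification": s(net.classify_cliques, cliques, metadata)},
                   out / "cliques.json")

        s = stage("communities")
        part = s(net.detect_communities, graph, config.gamma, seed=config.seed)
        pd.DataFrame(sorted(part.membership.items()),
                     columns=["iid", "community"]).to_csv(
            out / "communities.tsv", sep="\t", index=False)
        _dump_json({"gamma": part.gamma, "quality": part.quality},
                   out / "communities.json")

    # -- outliers ------------------------------------------------------------
    if pc_df is not None and len(pc_df):
        s = stage("outliers")
        rows = []
        for grp, chunk in pc_df.groupby("group"):
            if len(chunk) >= 3:
                rows.extend(s(anc.mahalanobis_outliers, pc_df, str(grp), config.alpha))
        pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
            out / "pca_outliers.tsv", sep="\t", index=False)

    # -- effective population size -------------------------------------------
    if roh is not None and len(roh):
        s = stage("ne")
        filtered, dropped = s(demog.prefilter, roh, "roh", gmap)
        n_units = filtered["iid"].nunique()
        spectrum = s(demog.build_spectrum, filtered, "roh", n_units, gmap,
                     max_gen=ne_max_gen)
        if spectrum.counts.sum() >= 1:
            est = s(demog.fit_ne, spectrum)
            _dump_json({"mode": "roh", "N_hat": est.N_hat, "ci95": list(est.ci95),
                        "loglik": est.loglik, "n_units": n_units,
                        "dropped_consanguineous": dropped,
                        "bins_cM": est.bins, "observed": est.observed,
                        "expected": est.expected},
                       out / "ne_roh.json")

    # -- site comparison ------------------------------------------------------
    sites = sorted(metadata["site"].unique())
    if len(sites) >= 2:
        s = stage("site_report")
        top2 = metadata["site"].value_counts().index[:2].tolist()
        bundles = []
        flagged = {c.iid for c in calls if c.flagged}
        for name in sorted(top2):
            ids = set(metadata.loc[metadata["site"] == name, "iid"])
            males = metadata[(metadata["site"] == name) & (metadata["sex"] == "M")]
            bundles.append(pstats.SiteBundle(
                name=name,
                n_roh=len(ids), consanguineous=len(ids & flagged),
                n_y_males=len(males) or None,
                y_distinct=males["y_hg"].nunique() or None,
                n_mt=len(ids),
                mt_distinct=metadata.loc[metadata["site"] == name, "mt_hg"].nunique(),
            ))
        _dump_json(s(pstats.site_comparison_report, *bundles),
                   out / "site_report.json")
    return out
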