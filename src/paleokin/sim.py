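"""Forward simulation of burial-community cohorts as founder-segment mosaics.

Genomes are represented as mosaics of founder haplotypes on a genetic-map
coordinate system (cM).  Recombination is modelled as a Poisson process along
the map (no interference, no obligate chiasma, sex-averaged map), which is all
that matters for the segment-length spectra consumed downstream.  The module
produces truth identity-by-descent (IBD) and runs-of-homozygosity (ROH) tables
in the same tabular convention as the HMM callers whose output the analysis
modules normally ingest, plus emulated PC-coordinate and ancestry-proportion
tables, so the whole pipeline is testable without any external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "HaplotypeMosaic",
    "SimIndividual",
    "PedigreeSpec",
    "Cohort",
    "make_genetic_map",
    "meiosis",
    "simulate_pedigree",
    "simulate_population",
    "simulate_community",
    "assign_residence",
    "extract_ibd",
    "extract_roh",
    "emulate_profiles",
    "pedigree_degree",
    "HUMAN_AUTOSOME_CM",
]

# Community design used for the patrilocality demonstrations: long-established
# patrilineal sites in a wide regional marriage network whose direct exchange
# (sibship-level marriage alliances) operates in the last generation before
# observation.  See simulate_community for the parameter semantics.
PATRILOCAL_STUDY: dict = dict(
    n_sites=10, couples_per_site=8, generations=4, children_per_union=4,
    outside_spouses=6, region_exchange=0.3, exchange_generations=1,
    juvenile_fraction=0.25, rule="patrilocal",
)

# Sex-averaged genetic lengths of the 22 human autosomes in cM (deCODE-style
# pedigree map, rounded to 0.1 cM).  Total ~= 3540 cM.
HUMAN_AUTOSOME_CM: dict[str, float] = {
    "1": 286.3, "2": 268.6, "3": 223.3, "4": 214.5, "5": 204.1,
    "6": 192.0, "7": 187.2, "8": 168.0, "9": 166.4, "10": 181.1,
    "11": 158.2, "12": 174.7, "13": 125.9, "14": 120.2, "15": 141.9,
    "16": 134.0, "17": 128.5, "18": 117.5, "19": 107.0, "20": 108.3,
    "21": 62.8, "22": 74.1,
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome genetic lengths; defines the genome-wide coordinate axis.

    Chromosomes are concatenated into a single [0, L) axis; ``offsets[i]`` is
    the genome-wide start of chromosome ``i`` and ``offsets[-1] == L``.
    """

    chromosome_ids: tuple[str, ...]
    lengths_cM: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths_cM, dtype=float)
        if lengths.ndim != 1 or len(lengths) == 0:
            raise ValueError("genetic map needs at least one chromosome")
        if np.any(lengths <= 0):
            raise ValueError("all chromosome lengths must be positive")
        if len(self.chromosome_ids) != len(lengths):
            raise ValueError("chromosome_ids and lengths_cM differ in length")
        object.__setattr__(self, "lengths_cM", lengths)
        object.__setattr__(self, "_offsets",
                           np.concatenate([[0.0], np.cumsum(lengths)]))

    @property
    def K(self) -> int:
        return len(self.lengths_cM)

    @property
    def L(self) -> float:
        return float(self._offsets[-1])

    @property
    def offsets(self) -> np.ndarray:
        return self._offsets

    def chromosome_of(self, pos: np.ndarray) -> np.ndarray:
        """Index of the chromosome containing each genome-wide position."""
        return np.clip(np.searchsorted(self.offsets, pos, side="right") - 1,
                       0, self.K - 1)


def make_genetic_map(lengths_cM: Sequence[float] | None = None,
                     chromosome_ids: Sequence[str] | None = None) -> GeneticMap:
    """Build a genetic map; defaults to the packaged 22-autosome human map."""
    if lengths_cM is None:
        ids = tuple(HUMAN_AUTOSOME_CM)
        return GeneticMap(ids, np.array([HUMAN_AUTOSOME_CM[c] for c in ids]))
    lengths = np.asarray(list(lengths_cM), dtype=float)
    if chromosome_ids is None:
        chromosome_ids = tuple(str(i + 1) for i in range(len(lengths)))
    return GeneticMap(tuple(chromosome_ids), lengths)


# ---------------------------------------------------------------------------
# Haplotype mosaics and meiosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeMosaic:
    """A haplotype as a tiling of founder-allele segments on [0, L).

    ``bounds`` has ``m + 1`` ascending entries with ``bounds[0] == 0`` and
    ``bounds[-1] == L``; segment ``i`` is ``[bounds[i], bounds[i+1])`` and
    carries ``alleles[i]`` (a founder-haplotype id).  Segments are stored
    genome-wide; per-chromosome views split at chromosome offsets.
    """

    bounds: np.ndarray
    alleles: np.ndarray

    def validate(self, gmap: GeneticMap) -> None:
        b, a = self.bounds, self.alleles
        if len(b) != len(a) + 1:
            raise ValueError("bounds/alleles length mismatch")
        if b[0] != 0.0 or not np.isclose(b[-1], gmap.L):
            raise ValueError("mosaic does not span [0, L)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("mosaic bounds not strictly increasing")

    def per_chromosome(self, gmap: GeneticMap) -> dict[str, list[tuple[float, float, int]]]:
        """Segments per chromosome in chromosome-local cM coordinates."""
        out: dict[str, list[tuple[float, float, int]]] = {c: [] for c in gmap.chromosome_ids}
        offs = gmap.offsets
        cut = np.unique(np.concatenate([self.bounds, offs]))
        lefts = cut[:-1]
        seg = np.searchsorted(self.bounds, lefts, side="right") - 1
        chrom = gmap.chromosome_of(lefts)
        for s, e, i, c in zip(lefts, cut[1:], seg, chrom):
            o = offs[c]
            out[gmap.chromosome_ids[c]].append((s - o, e - o, int(self.alleles[i])))
        return out

    def founder_set(self) -> frozenset[int]:
        return frozenset(int(x) for x in np.unique(self.alleles))


def _constant_mosaic(allele: int, gmap: GeneticMap) -> HaplotypeMosaic:
    return HaplotypeMosaic(np.array([0.0, gmap.L]), np.array([allele], dtype=np.int64))


def _gamete(hap_a: HaplotypeMosaic, hap_b: HaplotypeMosaic,
            gmap: GeneticMap, rng: np.random.Generator) -> HaplotypeMosaic:
    """One recombinant gamete from a pair of parental mosaics.

    Crossovers are Poisson(L/100) genome-wide with uniform positions, which is
    equivalent to independent Poisson(length/100) per chromosome; the parental
    phase restarts with a fair coin at every chromosome start and toggles at
    every crossover.
    """
    L = gmap.L
    n_x = rng.poisson(L / 100.0)
    xpos = np.sort(rng.uniform(0.0, L, n_x))
    starts = gmap.offsets[:-1]
    coins = rng.integers(0, 2, gmap.K)

    pos = np.concatenate([starts, xpos])
    is_start = np.zeros(len(pos), dtype=bool)
    is_start[: gmap.K] = True
    order = np.argsort(pos, kind="stable")
    pos, is_start = pos[order], is_start[order]
    chrom_idx = np.cumsum(is_start) - 1
    ncross = np.cumsum(~is_start)
    toggles = ncross - ncross[np.flatnonzero(is_start)][chrom_idx]
    phase = coins[chrom_idx] ^ (toggles & 1)

    ba, aa = hap_a.bounds, hap_a.alleles
    bb, ab = hap_b.bounds, hap_b.alleles
    # duplicates in the cut grid yield zero-width pieces that the compression
    # step removes (equal position implies equal allele assignment)
    cut = np.sort(np.concatenate([pos, ba[1:-1], bb[1:-1], [L]]))
    lefts = cut[:-1]
    ia = np.searchsorted(ba, lefts, side="right") - 1
    ib = np.searchsorted(bb, lefts, side="right") - 1
    ip = np.searchsorted(pos, lefts, side="right") - 1
    allele = np.where(phase[ip] == 0, aa[ia], ab[ib])
    keep = np.empty(len(allele), dtype=bool)
    keep[0] = True
    keep[1:] = allele[1:] != allele[:-1]
    bounds = np.append(lefts[keep], L)
    return HaplotypeMosaic(bounds, allele[keep])


# ---------------------------------------------------------------------------
# Individuals, pedigrees, cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimIndividual:
    iid: str
    sex: str                       # "M" | "F"
    generation: int
    mother_id: str | None
    father_id: str | None
    maternal: HaplotypeMosaic      # haplotype inherited from the mother
    paternal: HaplotypeMosaic
    mt_lineage: str
    y_lineage: str | None          # males only
    site: str = "site0"
    natal_site: str = "site0"
    pottery_style: str = ""
    sr_local: bool = True

    def founder_set(self) -> frozenset[int]:
        return self.maternal.founder_set() | self.paternal.founder_set()


@dataclass
class PedigreeSpec:
    """Declarative pedigree: founders, unions and their offspring.

    ``unions`` are (partner, partner) id pairs of opposite sex; offspring
    reference a union by index.  ``consanguineous_unions`` is annotation only
    (union index -> relationship degree between the partners); the genetic
    consequences follow from the topology itself.
    """

    founders: Sequence[tuple[str, str]]                 # (iid, sex)
    unions: Sequence[tuple[str, str]]
    offspring: Sequence[tuple[int, str, str]]           # (union index, iid, sex)
    residence_rule: str = "none"
    sites: tuple[str, ...] = ("site0",)
    founder_sites: Mapping[str, str] = field(default_factory=dict)
    consanguineous_unions: Mapping[int, int] = field(default_factory=dict)

    def validate(self) -> None:
        sex = dict(self.founders)
        ids = set(sex)
        if len(ids) != len(list(self.founders)):
            raise ValueError("duplicate founder id")
        for u, (iid, s) in zip((o[0] for o in self.offspring), ((o[1], o[2]) for o in self.offspring)):
            if iid in ids:
                raise ValueError(f"duplicate individual id {iid!r}")
            if not 0 <= u < len(list(self.unions)):
                raise ValueError(f"offspring references unknown union {u}")
            ids.add(iid)
            sex[iid] = s
        for a, b in self.unions:
            if a not in sex or b not in sex:
                raise ValueError(f"union references unknown individual ({a}, {b})")
            if sex[a] == sex[b]:
                raise ValueError(f"union partners ({a}, {b}) are not of opposite sex")
        # acyclicity: every offspring id must be new and its union's partners
        # must be definable without it; detect cycles via iterative resolution
        defined = {f for f, _ in self.founders}
        pending = list(self.offspring)
        unions = list(self.unions)
        while pending:
            progress = []
            for u, iid, s in pending:
                a, b = unions[u]
                if a in defined and b in defined:
                    defined.add(iid)
                else:
                    progress.append((u, iid, s))
            if len(progress) == len(pending):
                raise ValueError("pedigree specification is cyclic")
            pending = progress

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        """iid -> (mother, father); founders map to (None, None)."""
        sex = dict(self.founders)
        for u, iid, s in self.offspring:
            sex[iid] = s
        out: dict[str, tuple[str | None, str | None]] = {f: (None, None) for f, _ in self.founders}
        unions = list(self.unions)
        for u, iid, _ in self.offspring:
            a, b = unions[u]
            mother, father = (a, b) if sex[a] == "F" else (b, a)
            out[iid] = (mother, father)
        return out


class Cohort:
    """A simulated set of individuals sharing one genetic map."""

    def __init__(self, individuals: Iterable[SimIndividual], gmap: GeneticMap):
        self.gmap = gmap
        self.individuals: dict[str, SimIndividual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise ValueError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, iid: str) -> SimIndividual:
        return self.individuals[iid]

    def ids(self) -> list[str]:
        return list(self.individuals)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iid": ind.iid,
                "site": ind.site,
                "sex": ind.sex,
                "style": ind.pottery_style,
                "mt_hg": ind.mt_lineage,
                "y_hg": ind.y_lineage if ind.y_lineage is not None else "",
                "sr_local": int(ind.sr_local),
            }
            for ind in self
        ]
        return pd.DataFrame(rows)


def meiosis(parent: SimIndividual, gmap: GeneticMap,
            seed: int | np.random.Generator | None = None) -> HaplotypeMosaic:
    """One gamete from ``parent`` (Poisson recombination, fair-coin start)."""
    return _gamete(parent.maternal, parent.paternal, gmap, _rng(seed))


def _make_founder(iid: str, sex: str, generation: int, allele0: int,
                  gmap: GeneticMap, site: str = "site0") -> SimIndividual:
    return SimIndividual(
        iid=iid, sex=sex, generation=generation, mother_id=None, father_id=None,
        maternal=_constant_mosaic(allele0, gmap),
        paternal=_constant_mosaic(allele0 + 1, gmap),
        mt_lineage=f"mt_{iid}",
        y_lineage=f"y_{iid}" if sex == "M" else None,
        site=site, natal_site=site,
    )


def simulate_pedigree(spec: PedigreeSpec, gmap: GeneticMap | None = None,
                      seed: int | np.random.Generator | None = None) -> Cohort:
    """Transmit founder genomes through a declared pedigree.

    Founders receive globally unique founder-haplotype ids; each offspring
    genome is one maternal plus one paternal gamete; mitochondrial labels
    follow the maternal line and Y labels the paternal line (males).
    """
    spec.validate()
    gmap = gmap or make_genetic_map()
    rng = _rng(seed)
    inds: dict[str, SimIndividual] = {}
    for i, (iid, sex) in enumerate(spec.founders):
        site = spec.founder_sites.get(iid, spec.sites[i % len(spec.sites)])
        inds[iid] = _make_founder(iid, sex, 0, 2 * i, gmap, site)

    sexes = dict(spec.founders)
    for u, iid, s in spec.offspring:
        sexes[iid] = s
    unions = list(spec.unions)
    pending = list(spec.offspring)
    while pending:
        rest = []
        for u, iid, s in pending:
            a, b = unions[u]
            if a in inds and b in inds:
                mother, father = (inds[a], inds[b]) if inds[a].sex == "F" else (inds[b], inds[a])
                child = SimIndividual(
                    iid=iid, sex=s,
                    generation=max(mother.generation, father.generation) + 1,
                    mother_id=mother.iid, father_id=father.iid,
                    maternal=_gamete(mother.maternal, mother.paternal, gmap, rng),
                    paternal=_gamete(father.maternal, father.paternal, gmap, rng),
                    mt_lineage=mother.mt_lineage,
                    y_lineage=father.y_lineage if s == "M" else None,
                )
                inds[iid] = child
            else:
                rest.append((u, iid, s))
        pending = rest

    cohort = Cohort(inds.values(), gmap)
    assign_residence(cohort, spec.residence_rule, spec.sites, rng,
                     unions=unions)
    return cohort


def pedigree_degree(spec: PedigreeSpec, a: str, b: str) -> str:
    """Pedigree-implied relatedness category for a pair of individuals.

    Categories mirror the classifier's: PO, FS, degree2 ... degree6plus,
    unrelated.  The degree is derived from the kinship coefficient
    (phi = 2^-(d+2) for degree-d relatives) with PO/FS resolved structurally.
    """
    parents = spec.parents()
    if a not in parents or b not in parents:
        raise KeyError(f"unknown individual in pedigree: {a!r} or {b!r}")
    if parents[a][0] == b or parents[a][1] == b or parents[b][0] == a or parents[b][1] == a:
        return "PO"
    if parents[a] != (None, None) and parents[a] == parents[b]:
        return "FS"
    depth: dict[str, int] = {}

    def _depth(x: str) -> int:
        if x not in depth:
            m, f = parents[x]
            depth[x] = 0 if m is None else max(_depth(m), _depth(f)) + 1
        return depth[x]

    memo: dict[tuple[str, str], float] = {}

    def phi(x: str, y: str) -> float:
        if _depth(x) < _depth(y):
            x, y = y, x
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        if x == y:
            m, f = parents[x]
            val = 0.5 * (1.0 + (phi(m, f) if m is not None else 0.0))
        else:
            m, f = parents[x]
            if m is None:          # both founders, unrelated by construction
                val = 0.0
            else:
                val = 0.5 * (phi(m, y) + phi(f, y))
        memo[key] = val
        return val

    k = phi(a, b)
    if k <= 0.0:
        return "unrelated"
    d = round(-np.log2(k) - 2)
    if d <= 1:
        return "FS"
    if d >= 6:
        return "degree6plus"
    return f"degree{d}"


# ---------------------------------------------------------------------------
# Residence rules
# ---------------------------------------------------------------------------

_RULES = ("patrilocal", "matrilocal", "neolocal", "none")


def assign_residence(cohort: Cohort, rule: str, sites: Sequence[str],
                     seed: int | np.random.Generator | None = None,
                     unions: Sequence[tuple[str, str]] | None = None) -> Cohort:
    """Assign natal and burial sites according to a post-marital residence rule.

    Under patrilocality sons stay at their natal site and daughters move (to
    the husband's site when married, otherwise to a random other site);
    matrilocality is the mirror image; neolocal couples move to a random site;
    ``none`` keeps everyone at their natal site.  A union's residence defines
    the natal site of its children.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown residence rule {rule!r}; expected one of {_RULES}")
    sites = list(sites)
    if rule != "none" and len(sites) < 2:
        raise ValueError("need at least two sites for a non-neolocal residence rule")
    rng = _rng(seed)

    if unions is None:
        unions_d: dict[tuple[str, str], None] = {}
        for ind in cohort:
            if ind.mother_id is not None:
                unions_d[(ind.mother_id, ind.father_id)] = None
        unions = list(unions_d)

    order = sorted(cohort, key=lambda i: i.generation)
    spouse: dict[str, str] = {}
    for a, b in unions:
        spouse.setdefault(a, b)
        spouse.setdefault(b, a)

    def other_site(natal: str) -> str:
        choices = [s for s in sites if s != natal] or sites
        return choices[rng.integers(0, len(choices))]

    union_res: dict[frozenset[str], str] = {}
    for ind in order:
        if ind.mother_id is not None:
            key = frozenset((ind.mother_id, ind.father_id))
            if key not in union_res:
                mother, father = cohort[ind.mother_id], cohort[ind.father_id]
                if rule == "patrilocal" or rule == "none":
                    res = father.natal_site
                elif rule == "matrilocal":
                    res = mother.natal_site
                else:  # neolocal
                    res = sites[rng.integers(0, len(sites))]
                union_res[key] = res
            ind.natal_site = union_res[key]
        # burial site: movement at adulthood
        if rule == "none":
            ind.site = ind.natal_site
        elif rule == "patrilocal":
            if ind.sex == "M":
                ind.site = ind.natal_site
            else:
                sp = spouse.get(ind.iid)
                ind.site = (union_res.get(frozenset((ind.iid, sp)))
                            or (cohort[sp].natal_site if sp else None)
                            or other_site(ind.natal_site))
        elif rule == "matrilocal":
            if ind.sex == "F":
                ind.site = ind.natal_site
            else:
                sp = spouse.get(ind.iid)
                ind.site = (union_res.get(frozenset((ind.iid, sp)))
                            or (cohort[sp].natal_site if sp else None)
                            or other_site(ind.natal_site))
        else:  # neolocal
            sp = spouse.get(ind.iid)
            res = union_res.get(frozenset((ind.iid, sp))) if sp else None
            ind.site = res if res is not None else other_site(ind.natal_site)
        ind.sr_local = ind.site == ind.natal_site
    return cohort


# ---------------------------------------------------------------------------
# Random-mating background populations
# ---------------------------------------------------------------------------

def simulate_population(N: int, generations: int, gmap: GeneticMap | None = None,
                        seed: int | np.random.Generator | None = None,
                        monogamous: bool = False) -> Cohort:
    """Discrete-generation Wright-Fisher population of ``N`` diploids.

    Each generation holds N individuals (half male, half female); every child
    draws its mother uniformly from the females and its father uniformly from
    the males of the previous generation (``monogamous``: parents are fixed
    random pairs and each child draws a pair).  The final generation is
    returned with full mosaics; two random lineages coalesce at rate 1/(2N)
    per generation, so the census size is also the effective size.
    """
    if N < 2:
        raise ValueError("population size must be at least 2")
    if generations < 1:
        raise ValueError("need at least one generation")
    gmap = gmap or make_genetic_map()
    rng = _rng(seed)

    def sexes(n: int) -> list[str]:
        return ["M" if i < n // 2 else "F" for i in range(n)]

    current = [_make_founder(f"g0_i{i}", s, 0, 2 * i, gmap)
               for i, s in enumerate(sexes(N))]
    for g in range(1, generations + 1):
        males = [i for i in current if i.sex == "M"]
        females = [i for i in current if i.sex == "F"]
        if monogamous:
            rng.shuffle(males)
            rng.shuffle(females)
            couples = list(zip(males, females))
            picks = rng.integers(0, len(couples), N)
            parent_pairs = [couples[p] for p in picks]
        else:
            fa = rng.integers(0, len(males), N)
            mo = rng.integers(0, len(females), N)
            parent_pairs = [(males[f], females[m]) for f, m in zip(fa, mo)]
        nxt = []
        for i, (s, (father, mother)) in enumerate(zip(sexes(N), parent_pairs)):
            nxt.append(SimIndividual(
                iid=f"g{g}_i{i}", sex=s, generation=g,
                mother_id=mother.iid, father_id=father.iid,
                maternal=_gamete(mother.maternal, mother.paternal, gmap, rng),
                paternal=_gamete(father.maternal, father.paternal, gmap, rng),
                mt_lineage=mother.mt_lineage,
                y_lineage=father.y_lineage if s == "M" else None,
            ))
        current = nxt
    return Cohort(current, gmap)


def simulate_community(n_sites: int = 3, couples_per_site: int = 10,
                       generations: int = 3, children_per_union: int = 3,
                       rule: str = "patrilocal", outside_spouses: int | None = None,
                       region_exchange: float = 0.35, juvenile_fraction: float = 0.2,
                       exchange_generations: int | None = None,
                       seed: int | np.random.Generator | None = None,
                       gmap: GeneticMap | None = None) -> Cohort:
    """Multi-site cohort with marriage migration governed by a residence rule.

    Founder couples are planted at each site.  Every generation, adults move
    according to ``rule`` (patrilocal: daughters marry into a random other
    site; matrilocal: mirrored; none: within-site marriage), arrived partners
    are paired with resident ones, and each union leaves
    ``children_per_union`` children of random sex.  The sampled sites are
    embedded in a larger regional marriage network: every generation each
    site also receives ``outside_spouses`` partners of the in-marrying sex
    drawn from outside the study region (fresh unrelated genomes; default
    half the founding couples), which keeps within-site relatedness at
    realistic levels instead of collapsing into one inbred kindred.  All
    generations are kept in the cohort (everyone is eventually buried), with
    ``site`` the burial site, ``sr_local`` flagging individuals buried at
    their natal site, and pottery style inherited from the natal site.

    Movement is embedded in the same regional network: a mover stays within
    the sampled sites with probability ``region_exchange`` (marrying into a
    random other site); otherwise they emigrate beyond the study region and
    leave the burial record entirely.  Direct exchange between the sampled
    sites operates only during the last ``exchange_generations`` transitions
    (default: all of them): communities are long-established lineages whose
    mutual marriage network is recent, so between-site co-ancestry reflects
    the migrants themselves rather than deep common descent.  A fraction
    ``juvenile_fraction`` of children die before adulthood and are buried at
    their natal site, as in real cemeteries.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown residence rule {rule!r}; expected one of {_RULES}")
    if n_sites < 2:
        raise ValueError("need at least two sites")
    gmap = gmap or make_genetic_map()
    rng = _rng(seed)
    if outside_spouses is None:
        outside_spouses = couples_per_site // 2
    sites = [f"site{i}" for i in range(n_sites)]
    styles = {s: f"style{chr(ord('A') + i)}" for i, s in enumerate(sites)}

    all_inds: list[SimIndividual] = []
    counter = itertools.count()
    residents: dict[str, list[SimIndividual]] = {s: [] for s in sites}
    for s in sites:
        for _ in range(couples_per_site):
            for sex in ("M", "F"):
                i = next(counter)
                ind = _make_founder(f"f{i}", sex, 0, 2 * i, gmap, site=s)
                ind.pottery_style = styles[s]
                all_inds.append(ind)
                residents[s].append(ind)

    emigrants: set[str] = set()
    for g in range(1, generations + 1):
        # movement at adulthood
        movers: dict[str, list[SimIndividual]] = {s: [] for s in sites}
        stayers: dict[str, list[SimIndividual]] = {s: [] for s in sites}
        for s in sites:
            # marriage alliances operate at the sibship level: a family either
            # marries its out-moving children into one allied site of the
            # region (all to the same destination) or beyond the region
            family_dest: dict[tuple, str | None] = {}
            dest_sites = [t for t in sites if t != s]
            exchange_on = (exchange_generations is None
                           or g > generations - exchange_generations)
            for ind in residents[s]:
                moves = (
                    (rule == "patrilocal" and ind.sex == "F")
                    or (rule == "matrilocal" and ind.sex == "M")
                    or rule == "neolocal"
                )
                if moves:
                    fam = (ind.mother_id, ind.father_id)
                    if fam not in family_dest:
                        stay = exchange_on and rng.random() < region_exchange
                        family_dest[fam] = (
                            dest_sites[rng.integers(0, len(dest_sites))]
                            if stay else None)
                    target = family_dest[fam]
                    if target is None:
                        emigrants.add(ind.iid)      # married beyond the region
                        continue
                    ind.site = target
                    ind.sr_local = False
                    movers[target].append(ind)
                else:
                    stayers[s].append(ind)
        # in-marrying partners from the wider region (fresh genomes)
        in_sex = "F" if rule in ("patrilocal", "neolocal") else "M"
        if rule != "none":
            for s in sites:
                for _ in range(outside_spouses):
                    i = next(counter)
                    ind = _make_founder(f"o{i}", in_sex, g - 1, 2 * i, gmap, site=s)
                    ind.natal_site = "outside"
                    ind.sr_local = False
                    ind.pottery_style = styles[s]
                    all_inds.append(ind)
                    movers[s].append(ind)
        next_residents: dict[str, list[SimIndividual]] = {s: [] for s in sites}
        for s in sites:
            pool = stayers[s] + movers[s]
            males = [i for i in pool if i.sex == "M"]
            females = [i for i in pool if i.sex == "F"]
            rng.shuffle(males)
            rng.shuffle(females)
            for father, mother in zip(males, females):
                for _ in range(children_per_union):
                    sex = "M" if rng.random() < 0.5 else "F"
                    i = next(counter)
                    child = SimIndividual(
                        iid=f"g{g}_i{i}", sex=sex, generation=g,
                        mother_id=mother.iid, father_id=father.iid,
                        maternal=_gamete(mother.maternal, mother.paternal, gmap, rng),
                        paternal=_gamete(father.maternal, father.paternal, gmap, rng),
                        mt_lineage=mother.mt_lineage,
                        y_lineage=father.y_lineage if sex == "M" else None,
                        site=s, natal_site=s, pottery_style=styles[s],
                    )
                    all_inds.append(child)
                    if rng.random() >= juvenile_fraction:
                        next_residents[s].append(child)
        residents = next_residents
    return Cohort((i for i in all_inds if i.iid not in emigrants), gmap)


# ---------------------------------------------------------------------------
# Truth segment extraction
# ---------------------------------------------------------------------------

def _shared_intervals(h1: HaplotypeMosaic, h2: HaplotypeMosaic) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide maximal intervals where the two mosaics are allele-identical.

    Returns (starts, ends).  Runs extend across points where both mosaics
    switch to the same new founder allele: a tract copied intact from a
    recent common ancestor carries that ancestor's internal mosaic boundaries
    in both copies, and remains one continuous identity segment.
    """
    b1, a1 = h1.bounds, h1.alleles
    b2, a2 = h2.bounds, h2.alleles
    cut = np.unique(np.concatenate([b1, b2]))
    lefts = cut[:-1]
    i1 = np.searchsorted(b1, lefts, side="right") - 1
    i2 = np.searchsorted(b2, lefts, side="right") - 1
    eq = a1[i1] == a2[i2]
    if not eq.any():
        return np.empty(0), np.empty(0)
    new_run = np.empty(len(eq), dtype=bool)
    new_run[0] = True
    new_run[1:] = eq[1:] != eq[:-1]
    run_start_idx = np.flatnonzero(new_run)
    run_end = np.append(cut[run_start_idx[1:]], cut[-1])
    good = eq[run_start_idx]
    return cut[run_start_idx][good], run_end[good]


def _segments_to_rows(starts: np.ndarray, ends: np.ndarray, gmap: GeneticMap,
                      min_cM: float) -> list[tuple[str, float, float, float]]:
    """Split genome-wide intervals at chromosome boundaries, local coords."""
    rows = []
    offs = gmap.offsets
    if min_cM > 0:      # splitting at offsets only shrinks intervals
        keep = (ends - starts) >= min_cM
        starts, ends = starts[keep], ends[keep]
    js = np.clip(np.searchsorted(offs, starts, side="right") - 1, 0, gmap.K - 1)
    je = np.clip(np.searchsorted(offs, ends, side="left") - 1, 0, gmap.K - 1)
    for s, e, a, b in zip(starts, ends, js, je):
        for c in range(a, b + 1):
            lo = max(s, offs[c]) - offs[c]
            hi = min(e, offs[c + 1]) - offs[c]
            if hi - lo >= min_cM:
                rows.append((gmap.chromosome_ids[c], lo, hi, hi - lo))
    return rows


_IBD_COLUMNS = ["iid1", "iid2", "combo", "chromosome", "start_cM", "end_cM", "length_cM"]
_ROH_COLUMNS = ["iid", "chromosome", "start_cM", "end_cM", "length_cM"]


def extract_ibd(cohort: Cohort, min_cM: float = 8.0,
                pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Truth IBD segments for every pair, per haplotype combination.

    For each ordered pair and each of the four haplotype combinations
    (maternal/paternal x maternal/paternal), maximal runs of identical
    founder alleles are reported; segments shorter than ``min_cM`` are
    dropped.  Regions of double sharing (IBD2) appear as overlapping rows of
    disjoint combinations, so pair unions and IBD2 can be recovered from the
    table alone by interval arithmetic.
    """
    gmap = cohort.gmap
    if pairs is None:
        ids = cohort.ids()
        pairs = list(itertools.combinations(ids, 2))
    fsets = {iid: cohort[iid].founder_set() for iid in cohort.individuals}
    rows = []
    for iid1, iid2 in pairs:
        if iid1 > iid2:
            iid1, iid2 = iid2, iid1
        if not (fsets[iid1] & fsets[iid2]):
            continue
        p, q = cohort[iid1], cohort[iid2]
        for combo, (h1, h2) in {
            "mm": (p.maternal, q.maternal), "mp": (p.maternal, q.paternal),
            "pm": (p.paternal, q.maternal), "pp": (p.paternal, q.paternal),
        }.items():
            s, e = _shared_intervals(h1, h2)
            for chrom, lo, hi, ln in _segments_to_rows(s, e, gmap, min_cM):
                rows.append((iid1, iid2, combo, chrom, lo, hi, ln))
    return pd.DataFrame(rows, columns=_IBD_COLUMNS)


def extract_roh(cohort: Cohort, min_cM: float = 4.0,
                ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Truth runs of homozygosity: maternal/paternal founder-allele identity."""
    gmap = cohort.gmap
    rows = []
    for iid in (ids if ids is not None else cohort.ids()):
        ind = cohort[iid]
        s, e = _shared_intervals(ind.maternal, ind.paternal)
        for chrom, lo, hi, ln in _segments_to_rows(s, e, gmap, min_cM):
            rows.append((iid, chrom, lo, hi, ln))
    return pd.DataFrame(rows, columns=_ROH_COLUMNS)


# ---------------------------------------------------------------------------
# Emulated ancestry / PC tables
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Emulation parameters for one group (site) of individuals."""

    n: int
    pc_mean: tuple[float, float] = (0.0, 0.0)
    pc_cov: Sequence[Sequence[float]] = ((1.0, 0.0), (0.0, 1.0))
    ancestry_mean: Sequence[float] = (0.88, 0.08, 0.02, 0.02)   # ANF WHG EHG CHG
    logit_sd: float = 0.3
    se: float = 0.02


_COMPONENTS = ["ANF", "WHG", "EHG", "CHG"]


def emulate_profiles(group_params: Mapping[str, GroupProfile],
                     outlier_spec: Sequence[tuple[str, float]] | None = None,
                     seed: int | np.random.Generator | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw PC coordinates and ancestry proportions per group.

    PC coordinates are bivariate Gaussian per group; ``outlier_spec`` plants
    points at a prescribed squared Mahalanobis distance from the generating
    mean (random direction).  Ancestry proportions are logistic-normal around
    the group mean, renormalised to the simplex, with fixed standard errors.
    """
    rng = _rng(seed)
    pc_rows, anc_rows = [], []
    outliers: dict[str, list[float]] = {}
    for grp, md2 in (outlier_spec or []):
        outliers.setdefault(grp, []).append(md2)
    for grp, prof in group_params.items():
        cov = np.asarray(prof.pc_cov, dtype=float)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance for group {grp!r} is not positive definite") from exc
        mean = np.asarray(prof.pc_mean, dtype=float)
        amean = np.asarray(prof.ancestry_mean, dtype=float)
        if np.any(amean < 0) or not np.isclose(amean.sum(), 1.0, atol=1e-6):
            raise ValueError(f"ancestry means for group {grp!r} must lie on the simplex")
        pts = mean + rng.standard_normal((prof.n, 2)) @ chol.T
        for j, md2 in enumerate(outliers.get(grp, [])):
            if j >= prof.n:
                break
            theta = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            pts[prof.n - 1 - j] = mean + np.sqrt(md2) * (chol @ u)
        z = np.log(np.clip(amean, 1e-9, None)) + rng.standard_normal((prof.n, 4)) * prof.logit_sd
        props = np.exp(z)
        props /= props.sum(axis=1, keepdims=True)
        for i in range(prof.n):
            iid = f"{grp}_{i}"
            pc_rows.append({"iid": iid, "group": grp, "PC1": pts[i, 0], "PC2": pts[i, 1]})
            row = {"iid": iid, "group": grp}
            row.update({c: props[i, k] for k, c in enumerate(_COMPONENTS)})
            row.update({f"se_{c}": prof.se for c in _COMPONENTS})
            row["p_model"] = rng.uniform(0.05, 1.0)
            anc_rows.append(row)
    return pd.DataFrame(anc_rows), pd.DataFrame(pc_rows)
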