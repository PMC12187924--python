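"""Simulator unit and property tests: maps, meiosis, pedigrees, extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paleokin as pk
from conftest import SPEC_OF, cousin_offspring_spec, cousins_spec, po_spec
from paleokin.kinship import summarize_pairs
from paleokin.sim import (HUMAN_AUTOSOME_CM, GroupProfile, HaplotypeMosaic,
                          _gamete, _shared_intervals)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lengths, L, K", [
    ([100.0], 100.0, 1),
    ([150.0] * 22, 3300.0, 22),
])
def test_custom_map_totals(lengths, L, K):
    g = pk.make_genetic_map(lengths)
    assert g.L == pytest.approx(L)
    assert g.K == K


def test_default_map_is_packaged_human_map():
    g = pk.make_genetic_map()
    assert g.K == 22
    assert g.L == pytest.approx(sum(HUMAN_AUTOSOME_CM.values()))
    assert 3400 < g.L < 3700


def test_non_positive_length_rejected():
    with pytest.raises(ValueError):
        pk.make_genetic_map([100.0, 0.0])


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _founder_pair(gmap, seed=0):
    spec = pk.PedigreeSpec(founders=[("m", "F"), ("f", "M")],
                           unions=[("m", "f")], offspring=[(0, "c", "M")])
    return pk.simulate_pedigree(spec, gmap, seed=seed)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_gamete_tiles_genome_exactly(seed):
    gmap = pk.make_genetic_map([100.0, 80.0])
    cohort = _founder_pair(gmap, seed=seed)
    gam = pk.meiosis(cohort["m"], gmap, seed=seed)
    gam.validate(gmap)
    assert gam.bounds[0] == 0.0
    assert gam.bounds[-1] == pytest.approx(gmap.L)
    assert np.all(np.diff(gam.bounds) > 0)


def test_zero_crossover_chromosome_copies_one_parent():
    # single 10 cM chromosome: crossovers are rare; find a seeded meiosis with
    # none and check the gamete equals one parental haplotype exactly
    gmap = pk.make_genetic_map([10.0])
    cohort = _founder_pair(gmap)
    mother = cohort["m"]
    for seed in range(50):
        gam = pk.meiosis(mother, gmap, seed=seed)
        if len(gam.alleles) == 1:
            assert gam.alleles[0] in (mother.maternal.alleles[0],
                                      mother.paternal.alleles[0])
            return
    pytest.fail("no crossover-free meiosis in 50 seeds on a 10 cM chromosome")


def test_crossover_count_is_poisson_mean_one_per_morgan():
    # founder parent: every phase switch changes the allele, so crossovers on
    # a single chromosome equal segment count - 1
    gmap = pk.make_genetic_map([100.0])
    mother = _founder_pair(gmap)["m"]
    rng = np.random.default_rng(42)
    counts = [len(_gamete(mother.maternal, mother.paternal, gmap, rng).alleles) - 1
              for _ in range(10_000)]
    se = 1.0 / np.sqrt(10_000)
    assert np.mean(counts) == pytest.approx(1.0, abs=3 * se)


# ---------------------------------------------------------------------------
# Pedigree transmission and analytic sharing
# ---------------------------------------------------------------------------

def test_parent_offspring_union_ibd_equals_genome_length(gmap):
    cohort = pk.simulate_pedigree(po_spec(), seed=11)
    ibd = pk.extract_ibd(cohort, min_cM=0, pairs=[("x", "a")])
    s = summarize_pairs(ibd, gmap)[0]
    assert s.union_cM == pytest.approx(gmap.L, rel=1e-12)
    assert s.ibd2_cM == pytest.approx(0.0)


@pytest.mark.parametrize("which, pair, expected", [
    ("FS", ("x", "y"), 0.75),
    ("degree3", ("x", "y"), 0.25),
])
def test_mean_union_sharing_matches_expectation(gmap, which, pair, expected):
    fracs = []
    for seed in range(200):
        cohort = pk.simulate_pedigree(SPEC_OF[which](), seed=seed)
        ibd = pk.extract_ibd(cohort, min_cM=0, pairs=[pair])
        ss = summarize_pairs(ibd, gmap)
        fracs.append(ss[0].phi if ss else 0.0)
    fracs = np.asarray(fracs)
    se = fracs.std(ddof=1) / np.sqrt(len(fracs))
    assert fracs.mean() == pytest.approx(expected, abs=max(3 * se, 0.01))


def test_uniparental_labels_follow_maternal_and_paternal_lines():
    cohort = pk.simulate_pedigree(cousins_spec(), seed=5)
    for ind in cohort:
        if ind.mother_id is not None:
            assert ind.mt_lineage == cohort[ind.mother_id].mt_lineage
            if ind.sex == "M":
                assert ind.y_lineage == cohort[ind.father_id].y_lineage


def test_cyclic_pedigree_rejected():
    spec = pk.PedigreeSpec(founders=[("a", "F")], unions=[("a", "x")],
                           offspring=[(0, "x", "M")])
    with pytest.raises(ValueError, match="cyclic"):
        spec.validate()


def test_same_sex_union_rejected():
    spec = pk.PedigreeSpec(founders=[("a", "F"), ("b", "F")],
                           unions=[("a", "b")], offspring=[(0, "x", "M")])
    with pytest.raises(ValueError, match="opposite sex"):
        spec.validate()


# ---------------------------------------------------------------------------
# Truth extraction against a fine-grid scan
# ---------------------------------------------------------------------------

def _grid_oracle(h1, h2, gmap, step=0.01):
    """Segment recovery by scanning allele identity on a fine position grid."""
    xs = np.arange(step / 2, gmap.L, step)
    a1 = h1.alleles[np.searchsorted(h1.bounds, xs, side="right") - 1]
    a2 = h2.alleles[np.searchsorted(h2.bounds, xs, side="right") - 1]
    eq = a1 == a2
    segs, start = [], None
    for x, e in zip(xs, eq):
        if e and start is None:
            start = x - step / 2
        elif not e and start is not None:
            segs.append((start, x - step / 2))
            start = None
    if start is not None:
        segs.append((start, gmap.L))
    return segs


def test_shared_intervals_match_grid_scan(small_map):
    h1 = HaplotypeMosaic(np.array([0.0, 30.0, 55.0, 100.0, 180.0]),
                         np.array([1, 2, 3, 2]))
    h2 = HaplotypeMosaic(np.array([0.0, 10.0, 55.0, 130.0, 180.0]),
                         np.array([4, 2, 2, 5]))
    starts, ends = _shared_intervals(h1, h2)
    oracle = _grid_oracle(h1, h2, small_map)
    assert len(starts) == len(oracle)
    for (s, e), (os_, oe) in zip(zip(starts, ends), oracle):
        assert s == pytest.approx(os_, abs=0.011)
        assert e == pytest.approx(oe, abs=0.011)


def test_random_mosaic_pairs_match_grid_scan(small_map):
    rng = np.random.default_rng(3)
    for _ in range(20):
        def mosaic():
            cuts = np.sort(rng.uniform(0, small_map.L, rng.integers(1, 8)))
            b = np.concatenate([[0.0], cuts, [small_map.L]])
            return HaplotypeMosaic(b, rng.integers(0, 4, len(b) - 1))
        h1, h2 = mosaic(), mosaic()
        starts, ends = _shared_intervals(h1, h2)
        oracle = _grid_oracle(h1, h2, small_map)
        assert len(starts) == len(oracle)
        total = np.sum(ends - starts) if len(starts) else 0.0
        assert total == pytest.approx(sum(e - s for s, e in oracle), abs=0.1)


def test_unrelated_founders_share_nothing(gmap):
    cohort = pk.simulate_pedigree(
        pk.PedigreeSpec(founders=[("a", "F"), ("b", "M")], unions=[], offspring=[]),
        seed=0)
    assert len(pk.extract_ibd(cohort)) == 0
    assert len(pk.extract_roh(cohort, min_cM=0)) == 0


def test_parent_offspring_segments_span_each_chromosome(gmap):
    cohort = pk.simulate_pedigree(po_spec(), seed=2)
    ibd = pk.extract_ibd(cohort, min_cM=0, pairs=[("x", "b")])
    merged = ibd.groupby("chromosome")["length_cM"].sum()
    for cid, length in zip(gmap.chromosome_ids, gmap.lengths_cM):
        # one full haplotype transmitted: union covers the chromosome
        chunk = ibd[ibd["chromosome"] == cid]
        s = summarize_pairs(chunk.assign(iid1="x", iid2="b"), length)[0]
        assert s.union_cM == pytest.approx(length, rel=1e-9)


@pytest.mark.parametrize("which, expected_F", [("FS", 0.25), ("degree3", 1 / 16)])
def test_offspring_roh_matches_inbreeding_coefficient(gmap, which, expected_F):
    fracs = []
    for seed in range(200):
        if which == "FS":
            spec = pk.PedigreeSpec(
                founders=[("m", "F"), ("f", "M")],
                unions=[("m", "f"), ("s", "d")],
                offspring=[(0, "s", "M"), (0, "d", "F"), (1, "x", "M")])
        else:
            spec = cousin_offspring_spec()
        cohort = pk.simulate_pedigree(spec, seed=seed)
        roh = pk.extract_roh(cohort, min_cM=0, ids=["x"])
        fracs.append(roh["length_cM"].sum() / gmap.L)
    fracs = np.asarray(fracs)
    se = fracs.std(ddof=1) / np.sqrt(len(fracs))
    assert fracs.mean() == pytest.approx(expected_F, abs=max(3 * se, 0.01))


# ---------------------------------------------------------------------------
# Wright-Fisher populations
# ---------------------------------------------------------------------------

def test_population_first_generation_has_no_roh():
    gmap = pk.make_genetic_map([100.0, 80.0])
    cohort = pk.simulate_population(20, 1, gmap, seed=0)
    assert len(pk.extract_roh(cohort, min_cM=0)) == 0


def test_tiny_population_accumulates_roh_with_time():
    gmap = pk.make_genetic_map([100.0, 80.0])
    means = []
    for gens in (2, 8, 25):
        tot = 0.0
        for seed in range(5):
            cohort = pk.simulate_population(2, gens, gmap, seed=seed)
            tot += pk.extract_roh(cohort, min_cM=0)["length_cM"].sum()
        means.append(tot)
    assert means[0] < means[1] < means[2]


def test_population_size_validation():
    with pytest.raises(ValueError):
        pk.simulate_population(1, 5)


def test_monogamous_mating_gives_full_sib_families():
    gmap = pk.make_genetic_map([100.0])
    cohort = pk.simulate_population(20, 3, gmap, seed=5, monogamous=True)
    # under fixed pairing, children sharing a mother share the father too
    by_mother = {}
    for ind in cohort:
        by_mother.setdefault(ind.mother_id, set()).add(ind.father_id)
    assert all(len(fathers) == 1 for fathers in by_mother.values())


# ---------------------------------------------------------------------------
# Residence rules
# ---------------------------------------------------------------------------

def _three_generation_spec(rule):
    return pk.PedigreeSpec(
        founders=[("m0", "F"), ("f0", "M"), ("w1", "F")],
        unions=[("m0", "f0"), ("w1", "s1")],
        offspring=[(0, "s1", "M"), (0, "d1", "F"), (1, "s2", "M"), (1, "d2", "F")],
        residence_rule=rule, sites=("alpha", "beta"))


def test_patrilocal_father_son_pairs_share_site():
    cohort = pk.simulate_pedigree(_three_generation_spec("patrilocal"), seed=1)
    for ind in cohort:
        if ind.sex == "M" and ind.father_id is not None:
            assert ind.site == cohort[ind.father_id].site


def test_rule_none_keeps_natal_sites():
    cohort = pk.simulate_pedigree(_three_generation_spec("none"), seed=1)
    for ind in cohort:
        assert ind.site == ind.natal_site


def test_unknown_residence_rule_rejected(gmap):
    cohort = pk.simulate_pedigree(_three_generation_spec("none"), seed=1)
    with pytest.raises(ValueError, match="unknown residence rule"):
        pk.assign_residence(cohort, "avunculocal", ["a", "b"], seed=0)


def test_community_patrilocal_sons_stay_daughters_move():
    cohort = pk.simulate_community(n_sites=3, couples_per_site=4, generations=2,
                                   seed=0)
    for ind in cohort:
        if ind.sex == "M":
            assert ind.site == ind.natal_site


# ---------------------------------------------------------------------------
# Emulated ancestry / PC tables
# ---------------------------------------------------------------------------

def test_emulated_ancestry_rows_sum_to_one():
    anc, pc = pk.emulate_profiles({"g1": GroupProfile(n=20)}, seed=0)
    sums = anc[["ANF", "WHG", "EHG", "CHG"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert len(pc) == 20


def test_non_positive_definite_covariance_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        pk.emulate_profiles(
            {"g1": GroupProfile(n=5, pc_cov=((1.0, 2.0), (2.0, 1.0)))}, seed=0)


def test_planted_outlier_is_flagged():
    anc, pc = pk.emulate_profiles({"g1": GroupProfile(n=50)},
                                  outlier_spec=[("g1", 25.0)], seed=1)
    calls = pk.mahalanobis_outliers(pc, "g1")
    planted = pc["iid"].iloc[-1]
    assert any(c.iid == planted and c.flagged for c in calls)
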