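"""Shared fixtures: genetic maps, standard pedigrees, cached heavy simulations."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import paleokin as pk
from paleokin.demography import build_spectrum


@pytest.fixture(scope="session")
def gmap():
    return pk.make_genetic_map()


@pytest.fixture()
def small_map():
    return pk.make_genetic_map([100.0, 80.0], ["1", "2"])


# ---------------------------------------------------------------------------
# Standard pedigrees
# ---------------------------------------------------------------------------

FOUNDERS6 = [("a", "F"), ("b", "M"), ("c", "F"), ("d", "M"), ("e", "F"), ("f", "M")]


def po_spec():
    return pk.PedigreeSpec(founders=FOUNDERS6[:2], unions=[("a", "b")],
                           offspring=[(0, "x", "M")])


def fs_spec():
    return pk.PedigreeSpec(founders=FOUNDERS6[:2], unions=[("a", "b")],
                           offspring=[(0, "x", "M"), (0, "y", "F")])


def halfsib_spec():
    return pk.PedigreeSpec(founders=FOUNDERS6[:3], unions=[("a", "b"), ("c", "b")],
                           offspring=[(0, "x", "M"), (1, "y", "F")])


def cousins_spec():
    return pk.PedigreeSpec(
        founders=FOUNDERS6,
        unions=[("a", "b"), ("c", "p1"), ("e", "p2")],
        offspring=[(0, "p1", "M"), (0, "p2", "M"), (1, "x", "M"), (2, "y", "F")])


def cousin_offspring_spec():
    """First-cousin union whose child has expected inbreeding F = 1/16."""
    return pk.PedigreeSpec(
        founders=[("gm", "F"), ("gf", "M"), ("w1", "F"), ("h2", "M")],
        unions=[("gm", "gf"), ("w1", "p1"), ("h2", "p2"), ("c2", "c1")],
        offspring=[(0, "p1", "M"), (0, "p2", "F"), (1, "c1", "M"),
                   (2, "c2", "F"), (3, "x", "M")],
        consanguineous_unions={3: 3})


PAIR_OF = {"PO": ("x", "a"), "FS": ("x", "y"), "degree2": ("x", "y"),
           "degree3": ("x", "y")}
SPEC_OF = {"PO": po_spec, "FS": fs_spec, "degree2": halfsib_spec,
           "degree3": cousins_spec}


# ---------------------------------------------------------------------------
# Cached Wright-Fisher replicates (shared by calibration and coverage tests)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def wf_roh_spectra(N: int, generations: int = 30, reps: int = 20,
                   n_sample: int = 40, seed_base: int = 100):
    """Per replicate: (full-population bin counts, sampled-cohort spectrum).

    The sampled spectrum mimics a realistic excavation (a few dozen
    individuals out of the community) and is what the likelihood CIs are
    designed for; the full-population counts serve expectation checks.
    """
    gmap = pk.make_genetic_map()
    out = []
    for r in range(reps):
        cohort = pk.simulate_population(N, generations, gmap, seed=seed_base + r)
        ids = cohort.ids()
        rng = np.random.default_rng(seed_base + 1000 + r)
        sample = [ids[i] for i in rng.choice(len(ids), min(n_sample, N), replace=False)]
        full = build_spectrum(pk.extract_roh(cohort), "roh", N, gmap,
                              max_gen=generations)
        sub = build_spectrum(pk.extract_roh(cohort, ids=sample), "roh",
                             len(sample), gmap, max_gen=generations)
        out.append((full, sub))
    return out
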