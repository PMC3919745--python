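"""Simulation-based evaluation harnesses for the streak mapping method.

These drive the gene-dropping simulator against the scan and score how often
the mapping recovers known ground truth — the package's substitute for
genome-scale data it cannot ship.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Sequence

import numpy as np

from . import simped, streak


def planted_recovery_rate(
    n_replicates: int = 200,
    penetrance: float = 1.0,
    seed: int = 0,
    relabel_antibody_positive: bool = False,
    min_carrier_set: int = 2,
    config: streak.StreakConfig | None = None,
    **sim_kwargs,
) -> float:
    """Fraction of simulated pedigrees whose planted locus falls inside a
    called IBD stretch.

    Each replicate gene-drops the study pedigree, takes the simulated
    genotyped affected members (plus, with ``relabel_antibody_positive``, the
    flagged antibody-positive unaffected carrier) as the carrier set, scans,
    and scores success when some stretch contains the planted position.
    Replicates are conditioned on the pedigree containing at least
    ``min_carrier_set`` carrier-set members — the ascertainment condition
    under which a disease family is recruited at all.
    """
    scfg = config or streak.StreakConfig()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        while True:
            rep_seed = int(rng.integers(2**31))
            sim_cfg = simped.study_sim_config(
                seed=rep_seed,
                penetrance=penetrance,
                flag_antibody_positive_carrier=relabel_antibody_positive,
                **sim_kwargs,
            )
            result = simped.gene_drop(sim_cfg)
            carrier_set = [
                iid for iid in result.genotypes.samples
                if result.phenotypes[iid] == "affected"
            ]
            if relabel_antibody_positive:
                carrier_set += [
                    iid for iid in result.genotypes.samples
                    if result.antibody.get(iid) == "positive"
                ]
            if len(carrier_set) >= min_carrier_set:
                break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stretches = streak.scan_stretches(
                result.genotypes, sim_cfg.marker_map, carrier_set, scfg
            )
        hits += any(st.contains(*sim_cfg.planted_locus) for st in stretches)
    return hits / n_replicates


def exhaustive_subset_fraction(
    matrix,
    marker_map,
    member_ids: Sequence[str],
    n_affected: int,
    threshold_k: int,
    config: streak.StreakConfig | None = None,
) -> float:
    """Exact success fraction over every C(n, n_affected) carrier subset —
    the B -> infinity limit of :func:`streak.permutation_test`."""
    cfg = config or streak.StreakConfig()
    members = list(member_ids)
    n_success = 0
    n_total = 0
    for subset in combinations(members, n_affected):
        others = [m for m in members if m not in subset]
        n_success += streak.subset_has_confined_stretch(
            matrix, marker_map, list(subset), others, threshold_k, cfg
        )
        n_total += 1
    return n_success / n_total
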