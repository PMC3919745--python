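"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's vectorised code paths:
window compatibility is re-derived marker by marker through the public
scalar rule, the mid-P test through exact rational hypergeometric masses,
and the peak-shift p through a literal per-shift loop.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from streakmap import (
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    StreakConfig,
    study_pedigree,
    marker_compatible,
)

# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def study_family():
    pedigree, groups = study_pedigree()
    return pedigree, groups


@pytest.fixture
def toy8_pedigree():
    """Small 3-generation pedigree, all 8 members genotyped."""
    inds = [
        Individual("A", None, None, "male"),
        Individual("B", None, None, "female"),
        Individual("F", None, None, "female"),
        Individual("X", None, None, "male"),
        Individual("C", "A", "B", "male"),
        Individual("D", "A", "B", "female"),
        Individual("G", "C", "F", "male"),
        Individual("H", "X", "D", "female"),
    ]
    for i in inds:
        i.genotyped = True
    return Pedigree(inds)


@pytest.fixture
def trio_ped_file(tmp_path):
    path = tmp_path / "trio.ped"
    path.write_text(
        "FAM1 dad 0 0 1 1 A A G G\n"
        "FAM1 mom 0 0 2 1 A G G G\n"
        "FAM1 kid dad mom 1 2 A G G G\n"
    )
    (tmp_path / "trio.map").write_text(
        "1\trs1\t0\t1000\tA\tG\n1\trs2\t0\t2000\tG\tA\n"
    )
    return path


def random_instance(rng, max_markers=50, max_carriers=6, with_missing=True):
    """A random small genotype matrix + map for oracle comparisons."""
    n_markers = int(rng.integers(2, max_markers + 1))
    n_carriers = int(rng.integers(2, max_carriers + 1))
    pos = np.sort(rng.choice(np.arange(1, 5_000_000, 1000), n_markers, replace=False))
    import pandas as pd

    table = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "id": [f"m{i}" for i in range(n_markers)],
            "ref": "A",
            "alt": "G",
        }
    )
    mm = MarkerMap(table)
    choices = [-1, 0, 1, 2] if with_missing else [0, 1, 2]
    values = rng.choice(choices, size=(n_carriers, n_markers)).astype(np.int8)
    samples = [f"s{i}" for i in range(n_carriers)]
    return GenotypeMatrix(samples, mm, values), mm, samples


# ----------------------------------------------------------------- oracles


def brute_force_window_calls(matrix, marker_map, carrier_ids, cfg: StreakConfig):
    """Every per-marker window placement tested marker-by-marker via the
    public scalar compatibility rule."""
    out = []
    sub = matrix.rows(carrier_ids)
    for chrom in marker_map.chroms:
        idx = marker_map.chrom_index(chrom)
        pos = [int(p) for p in marker_map.table["pos"].to_numpy()[idx]]
        for j, p in enumerate(pos):
            members = [
                k for k, q in enumerate(pos) if p <= q <= p + cfg.window_span_bp - 1
            ]
            if not members:
                continue
            n_inc = sum(
                not marker_compatible(
                    [int(g) for g in sub[:, idx[k]]], cfg.missing_policy
                )
                for k in members
            )
            out.append(
                (
                    chrom,
                    p,
                    min(members),
                    max(members),
                    n_inc,
                    n_inc <= cfg.max_exceptions_per_window,
                )
            )
    return out


def midp_oracle(a: int, b: int, c: int, d: int):
    """Exact rational two-sided mid-P and Fisher p by full enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    masses = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)
    }
    obs = masses[a]
    less = sum((m for m in masses.values() if m < obs), Fraction(0))
    equal = sum((m for m in masses.values() if m == obs), Fraction(0))
    return less + Fraction(1, 2) * equal, less + equal


def peakshift_oracle(snps, peaks, step, rng_bp, include_zero=False):
    """Literal loop over every displacement in the null population."""
    shifts = [
        s for s in range(-rng_bp, rng_bp + 1, step) if include_zero or s != 0
    ]
    n_overlap = 0
    for s in shifts:
        if any(
            pk.start_bp + s <= snp <= pk.end_bp + s for snp in snps for pk in peaks
        ):
            n_overlap += 1
    observed = any(pk.start_bp <= snp <= pk.end_bp for snp in snps for pk in peaks)
    p = n_overlap / len(shifts) if observed else 1.0
    return observed, len(shifts), n_overlap, p


# ------------------------------------------------- toy exome variant panel


def toy_variant_panel():
    """20 hand-enumerated annotated variants + known-site list.

    Expected outcome (worked out by hand against the four filter criteria,
    required carriers = the 4 sequenced cases, max frequency 0.01, +/-5 bp
    indel window, frequency-less known sites rejecting on exact match):

    retained: v1, v6, v9, v13, v15, v19
    rejected: v2,v3,v17 (consequence); v4,v5,v7,v14,v18,v20 (db_frequency);
              v8,v10 (indel_proximity); v11,v12,v16 (carrier_support)
    """
    from streakmap import CandidateVariant

    cases = ["II:12", "III:3", "III:17", "IV:9"]
    all_carry = {c: "carries_alt" for c in cases}

    def v(name, pos, kind, csq, freqs=None, calls=None):
        var = CandidateVariant(
            chrom="2", pos_bp=pos, ref="A", alt="AGG" if kind == "indel" else "G",
            kind=kind, consequence=csq, db_frequencies=freqs or {},
            carrier_calls=calls or dict(all_carry),
        )
        return name, var

    three_of_four = dict(all_carry)
    three_of_four["IV:9"] = "no_alt"
    one_missing = dict(all_carry)
    one_missing["III:3"] = "missing"
    two_of_four = dict(all_carry)
    two_of_four["II:12"] = "no_alt"
    two_of_four["III:17"] = "no_alt"

    named = dict(
        [
            v("v1", 1000, "snv", "missense"),
            v("v2", 2000, "snv", "synonymous"),
            v("v3", 3000, "snv", "other"),
            v("v4", 4000, "snv", "missense", {"1000G": 0.02}),
            v("v5", 5000, "snv", "missense", {"ESP": 0.01}),  # >= threshold
            v("v6", 6000, "snv", "missense", {"1000G": 0.005}),
            v("v7", 7000, "snv", "missense"),                 # exact known site
            v("v8", 8000, "indel", "frameshift_indel"),       # 3 bp from known
            v("v9", 9000, "indel", "frameshift_indel"),       # 6 bp from known
            v("v10", 10000, "indel", "frameshift_indel"),     # 5 bp (boundary)
            v("v11", 11000, "snv", "missense", None, three_of_four),
            v("v12", 12000, "snv", "nonsense", None, one_missing),
            v("v13", 13000, "snv", "splice_acceptor"),
            v("v14", 14000, "snv", "splice_donor", {"dbSNP": 0.5}),
            v("v15", 15000, "snv", "missense"),               # 2 bp from known, snv
            v("v16", 16000, "indel", "frameshift_indel", None, two_of_four),
            v("v17", 17000, "snv", "synonymous", {"1000G": 0.9}),
            v("v18", 18000, "snv", "missense", {"1000G": 0.009, "ESP": 0.012}),
            v("v19", 19000, "snv", "nonsense"),
            v("v20", 20000, "indel", "frameshift_indel"),     # exact known site
        ]
    )
    known_sites = {
        "dbSNP_v132": {
            ("2", 7000), ("2", 8003), ("2", 9006), ("2", 10005),
            ("2", 15002), ("2", 20000),
        }
    }
    expected_retained = ["v1", "v6", "v9", "v13", "v15", "v19"]
    expected_reasons = {
        "v2": "consequence", "v3": "consequence", "v17": "consequence",
        "v4": "db_frequency", "v5": "db_frequency", "v7": "db_frequency",
        "v14": "db_frequency", "v18": "db_frequency", "v20": "db_frequency",
        "v8": "indel_proximity", "v10": "indel_proximity",
        "v11": "carrier_support", "v12": "carrier_support",
        "v16": "carrier_support",
    }
    return named, known_sites, expected_retained, expected_reasons, cases
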