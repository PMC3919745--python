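"""SNP-streak scan, stretch calling, refinement and permutation."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_window_calls, random_instance

from streakmap import (
    GenotypeMatrix,
    MarkerMap,
    StreakConfig,
    call_stretches,
    gene_drop,
    impute_presence,
    ld_prune,
    marker_compatible,
    pairwise_r2_from_panel,
    permutation_test,
    recessive_scan,
    refine,
    scan_stretches,
    scan_windows,
)
from streakmap.simped import SimConfig, study_sim_config


def small_matrix(values, spacing_bp=100_000, chrom="1"):
    values = np.asarray(values, dtype=np.int8)
    n = values.shape[1]
    pos = np.arange(1, n + 1) * spacing_bp
    table = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"m{i}" for i in range(n)],
         "ref": "A", "alt": "G"}
    )
    mm = MarkerMap(table)
    samples = [f"s{i}" for i in range(values.shape[0])]
    return GenotypeMatrix(samples, mm, values), mm, samples


class TestMarkerCompatible:
    @pytest.mark.parametrize(
        "genotypes,policy,expected",
        [
            ([0, 1, 0], "compatible", True),     # all share the ref allele
            ([0, 2], "compatible", False),        # both homozygote classes
            ([1, 1, 1], "compatible", True),
            ([0, -1], "compatible", True),        # missing imposes no constraint
            ([0, -1], "incompatible", False),     # missing breaks the rule
            ([2, 2, 1], "compatible", True),
            ([0, 1, 2], "compatible", False),
        ],
    )
    def test_rule(self, genotypes, policy, expected):
        assert marker_compatible(genotypes, policy) is expected

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            marker_compatible([])


class TestScanWindows:
    def test_exception_budget(self):
        # 12 markers over 1.2 Mbp; carrier genotypes all-compatible except
        # a controllable number of {hom-ref, hom-alt} conflicts
        base = np.ones((2, 12), dtype=np.int8)
        gm, mm, samples = small_matrix(base)
        cfg = StreakConfig()
        calls = scan_windows(gm, mm, samples, cfg)
        assert all(c.compatible and c.n_incompatible == 0 for c in calls)

        one = base.copy()
        one[0, 5], one[1, 5] = 0, 2  # exactly 1 violating marker
        gm, mm, _ = small_matrix(one)
        first = scan_windows(gm, mm, samples, cfg)[0]
        assert first.n_incompatible == 1 and first.compatible

        two = one.copy()
        two[0, 6], two[1, 6] = 2, 0
        gm, mm, _ = small_matrix(two)
        first = scan_windows(gm, mm, samples, cfg)[0]
        assert first.n_incompatible == 2 and not first.compatible

    def test_single_carrier_warns(self):
        gm, mm, samples = small_matrix(np.zeros((1, 5), dtype=np.int8))
        with pytest.warns(UserWarning, match="size 1"):
            scan_windows(gm, mm, samples[:1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        cfg = StreakConfig(window_span_bp=700_000, min_stretch_bp=700_000)
        for _ in range(60):
            gm, mm, samples = random_instance(rng)
            calls = scan_windows(gm, mm, samples, cfg)
            got = [
                (c.chrom, c.start_bp, c.first_marker, c.last_marker,
                 c.n_incompatible, c.compatible)
                for c in calls
            ]
            assert got == brute_force_window_calls(gm, mm, samples, cfg)


class TestCallStretches:
    def test_merged_windows_form_one_stretch(self):
        # 26 compatible markers spanning 2.5 Mbp -> single stretch
        gm, mm, samples = small_matrix(np.ones((2, 26), dtype=np.int8))
        stretches = scan_stretches(gm, mm, samples)
        assert len(stretches) == 1
        st = stretches[0]
        assert (st.start_bp, st.end_bp) == (100_000, 2_600_000)
        assert st.n_markers == 26

    def test_isolated_short_window_is_no_stretch(self):
        # compatible run spans < 2 Mbp: 8 markers over 0.8 Mbp between walls
        # of incompatibility
        values = np.ones((2, 30), dtype=np.int8)
        for j in list(range(0, 10)) + list(range(19, 30)):
            values[0, j], values[1, j] = 0, 2
        gm, mm, samples = small_matrix(values)
        assert scan_stretches(gm, mm, samples) == []

    def test_planted_locus_recovered(self):
        # first seed yielding an ascertainable family (>= 2 genotyped affected)
        for seed in range(123, 200):
            cfg = study_sim_config(seed=seed, penetrance=1.0)
            result = gene_drop(cfg)
            carriers = [
                s for s in result.genotypes.samples
                if result.phenotypes[s] == "affected"
            ]
            if len(carriers) >= 2:
                break
        stretches = scan_stretches(result.genotypes, cfg.marker_map, carriers)
        assert any(st.contains(*cfg.planted_locus) for st in stretches)

    def test_monotone_in_carriers(self):
        rng = np.random.default_rng(7)
        cfg = StreakConfig(window_span_bp=500_000, min_stretch_bp=500_000)
        for _ in range(20):
            gm, mm, samples = random_instance(rng, max_markers=30, max_carriers=5)
            if len(samples) < 3:
                continue
            big = scan_stretches(gm, mm, samples, cfg)
            small = scan_stretches(gm, mm, samples[:-1], cfg)
            covered = [
                any(s2.chrom == s1.chrom and s2.start_bp <= s1.start_bp
                    and s1.end_bp <= s2.end_bp for s2 in small)
                for s1 in big
            ]
            assert all(covered)


class TestRecessiveScan:
    def test_homozygous_region_called(self):
        gm, mm, samples = small_matrix(np.full((2, 26), 2, dtype=np.int8))
        stretches = recessive_scan(gm, mm, samples)
        assert len(stretches) == 1
        assert stretches[0].mode == "recessive_homozygosity"

    def test_het_fails_recessive_passes_dominant(self):
        values = np.ones((2, 26), dtype=np.int8)  # all het
        gm, mm, samples = small_matrix(values)
        assert recessive_scan(gm, mm, samples) == []
        assert len(scan_stretches(gm, mm, samples)) == 1

    def test_recessive_subset_of_dominant(self):
        rng = np.random.default_rng(11)
        cfg = StreakConfig(window_span_bp=500_000, min_stretch_bp=500_000)
        for _ in range(30):
            gm, mm, samples = random_instance(rng, max_markers=40)
            rec = recessive_scan(gm, mm, samples, cfg)
            dom = scan_stretches(gm, mm, samples, cfg)
            for r in rec:
                assert any(
                    d.chrom == r.chrom and d.start_bp <= r.start_bp
                    and r.end_bp <= d.end_bp for d in dom
                )

    def test_heterozygous_pedigree_yields_no_recessive_stretch(self):
        # dominant-model family: carriers are heterozygous, so homozygosity
        # mapping comes back empty, unlike the streak scan
        cfg = study_sim_config(seed=5, penetrance=1.0)
        result = gene_drop(cfg)
        carriers = [
            s for s in result.genotypes.samples
            if result.phenotypes[s] == "affected"
        ]
        assert len(carriers) >= 3
        assert recessive_scan(result.genotypes, cfg.marker_map, carriers) == []


class TestImputePresence:
    def test_identical_subject_is_present(self):
        values = np.ones((3, 26), dtype=np.int8)
        gm, mm, samples = small_matrix(values)
        st = scan_stretches(gm, mm, samples[:2])[0]
        assert impute_presence(st, gm, samples[:2], samples[2]) is True

    def test_conflicting_subject_is_absent(self):
        values = np.zeros((3, 26), dtype=np.int8)
        values[2, :] = 2  # subject homozygous-opposite at every marker
        gm, mm, samples = small_matrix(values)
        st = scan_stretches(gm, mm, samples[:2])[0]
        assert impute_presence(st, gm, samples[:2], samples[2]) is False

    def test_subject_in_carrier_set_rejected(self):
        gm, mm, samples = small_matrix(np.ones((2, 26), dtype=np.int8))
        st = scan_stretches(gm, mm, samples)[0]
        with pytest.raises(ValueError, match="already"):
            impute_presence(st, gm, samples, samples[0])

    def test_matches_transmission_ground_truth(self):
        # with full penetrance every genotyped carrier is in the carrier set,
        # so all remaining subjects are true non-carriers and the strict
        # presence call should come back absent for (nearly) all of them
        agree = total = 0
        for seed in range(40):
            cfg = study_sim_config(seed=1000 + seed, penetrance=1.0)
            result = gene_drop(cfg)
            carriers = [
                s for s in result.genotypes.samples
                if result.phenotypes[s] == "affected"
            ]
            if len(carriers) < 2:
                continue
            stretches = scan_stretches(result.genotypes, cfg.marker_map, carriers)
            target = [st for st in stretches if st.contains(*cfg.planted_locus)]
            if not target:
                continue
            st = target[0]
            for subject in result.genotypes.samples:
                if subject in carriers:
                    continue
                call = impute_presence(st, result.genotypes, carriers, subject)
                truth = subject in result.true_haplotype_carriers
                total += 1
                agree += call == truth
        assert total > 50
        assert agree / total >= 0.95

    def test_weak_variant_detects_unaffected_carriers(self):
        # at half penetrance some genotyped carriers stay unaffected; the
        # >=2 Mbp sub-stretch reading imputes the haplotype present in them
        detected = total = 0
        for seed in range(40):
            cfg = study_sim_config(seed=2000 + seed, penetrance=0.5)
            result = gene_drop(cfg)
            carriers = [
                s for s in result.genotypes.samples
                if result.phenotypes[s] == "affected"
            ]
            if len(carriers) < 2:
                continue
            stretches = scan_stretches(result.genotypes, cfg.marker_map, carriers)
            target = [st for st in stretches if st.contains(*cfg.planted_locus)]
            if not target:
                continue
            for subject in result.genotypes.samples:
                if subject in carriers:
                    continue
                if subject not in result.true_haplotype_carriers:
                    continue
                total += 1
                detected += impute_presence(
                    target[0], result.genotypes, carriers, subject, strict=False
                )
        assert total > 30
        assert detected / total >= 0.95


class TestRefine:
    def test_consecutive_restriction(self):
        # stretch A harbored by 1 pool subject, stretch B by all 4:
        # walking k down isolates A
        values = np.zeros((2 + 4, 60), dtype=np.int8)  # carriers hom-ref
        # wall of carrier-incompatible markers 27..37 (wider than one window)
        # splits the chromosome into two stretches
        values[1, 27:38] = 2
        # stretch A (markers 0..27): 3 of 4 pool subjects conflict there
        for s in (3, 4, 5):
            values[s, 5], values[s, 6] = 2, 2
        gm, mm, samples = small_matrix(values)
        carriers, pool = samples[:2], samples[2:]
        stretches = scan_stretches(gm, mm, carriers)
        assert len(stretches) == 2
        trace = refine(stretches, gm, carriers, pool)
        assert trace.presence_counts == [1, 4]
        assert [st for st, c in zip(stretches, trace.presence_counts) if c <= 3] \
            == trace.survivors_at(3)
        assert len(trace.final) == 1
        assert trace.final[0] is stretches[0]

    def test_survivors_monotone_in_k(self):
        cfg = study_sim_config(seed=77, penetrance=1.0)
        result = gene_drop(cfg)
        carriers = [
            s for s in result.genotypes.samples
            if result.phenotypes[s] == "affected"
        ]
        pool = [s for s in result.genotypes.samples if s not in carriers]
        stretches = scan_stretches(result.genotypes, cfg.marker_map, carriers)
        trace = refine(stretches, result.genotypes, carriers, pool)
        sizes = [len(surv) for _, surv in trace.steps]
        assert sizes == sorted(sizes, reverse=True)

    def test_zero_count_stretches_survive_to_k0(self):
        values = np.zeros((3, 26), dtype=np.int8)  # carriers hom-ref
        values[2, 3], values[2, 4] = 2, 2  # single pool subject conflicts
        gm, mm, samples = small_matrix(values)
        stretches = scan_stretches(gm, mm, samples[:2])
        trace = refine(stretches, gm, samples[:2], samples[2:])
        assert trace.presence_counts == [0]
        assert trace.steps[-1][0] <= 1 and len(trace.final) == 1


class TestPermutation:
    def make_sim(self, toy8_pedigree, seed=11):
        mm = MarkerMap.uniform(chrom="1", length_bp=10_000_000, spacing_bp=100_000)
        cfg = SimConfig(
            pedigree=toy8_pedigree, marker_map=mm,
            planted_locus=("1", 5_000_001), ancestral_founder_id="A",
            seed=seed, penetrance=1.0,
        )
        return gene_drop(cfg), mm

    def test_deterministic_under_seed(self, toy8_pedigree):
        result, mm = self.make_sim(toy8_pedigree)
        members = list(result.genotypes.samples)
        r1 = permutation_test(result.genotypes, mm, members, 3, 1, B=200, seed=9)
        r2 = permutation_test(result.genotypes, mm, members, 3, 1, B=200, seed=9)
        assert r1.p_value == r2.p_value == r1.n_success / 200

    def test_every_subset_succeeds_gives_p_one(self):
        # uniform all-het data: every subset shares everything everywhere
        gm, mm, samples = small_matrix(np.ones((5, 26), dtype=np.int8))
        res = permutation_test(gm, mm, samples, 2, len(samples), B=50, seed=0)
        assert res.p_value == 1.0

    def test_too_large_draw_is_error(self, toy8_pedigree):
        result, mm = self.make_sim(toy8_pedigree)
        with pytest.raises(ValueError):
            permutation_test(result.genotypes, mm,
                             list(result.genotypes.samples), 8, 1, B=10, seed=0)


class TestLDPrune:
    def test_perfectly_correlated_pair_drops_second(self):
        mm = MarkerMap.uniform(chrom="1", length_bp=200_000, spacing_bp=100_000)
        ids = list(mm.table["id"])
        keep = ld_prune(mm, {(ids[0], ids[1]): 1.0}, threshold=0.9)
        assert keep == [0, 2]

    def test_below_threshold_keeps_all(self):
        mm = MarkerMap.uniform(chrom="1", length_bp=300_000, spacing_bp=100_000)
        ids = list(mm.table["id"])
        r2 = {(ids[i], ids[j]): 0.5 for i in range(4) for j in range(i + 1, 4)}
        assert ld_prune(mm, r2, threshold=0.9) == [0, 1, 2, 3]

    def test_matches_greedy_hand_oracle(self):
        # 10 markers with a hand-built r2 table; greedy left-to-right:
        # m1 dropped (pairs m0), m3 dropped (m2), m4 kept (its only strong
        # partner m3 was dropped), m7 dropped (m4), rest kept
        mm = MarkerMap.uniform(chrom="1", length_bp=900_000, spacing_bp=100_000)
        ids = list(mm.table["id"])
        r2 = {
            (ids[0], ids[1]): 0.95,
            (ids[2], ids[3]): 0.92,
            (ids[3], ids[4]): 0.99,
            (ids[4], ids[7]): 0.91,
            (ids[5], ids[6]): 0.40,
            (ids[8], ids[9]): 0.89,
        }
        assert ld_prune(mm, r2, threshold=0.9) == [0, 2, 4, 5, 6, 8, 9]

    def test_empty_source_keeps_everything(self):
        mm = MarkerMap.uniform(chrom="1", length_bp=300_000, spacing_bp=100_000)
        assert ld_prune(mm, {}, threshold=0.9) == [0, 1, 2, 3]

    def test_panel_r2_identical_markers(self):
        # duplicate marker columns have r2 = 1 and the later copy is pruned
        rng = np.random.default_rng(2)
        col = rng.choice([0, 1, 2], size=20).astype(np.int8)
        values = np.stack([col, col, rng.choice([0, 1, 2], size=20)], axis=1)
        gm, mm, _ = small_matrix(values.astype(np.int8).T.T, spacing_bp=50_000)
        r2 = pairwise_r2_from_panel(gm)
        assert r2[("m0", "m1")] == pytest.approx(1.0)
        assert 0 in ld_prune(gm, r2, 0.9) and 1 not in ld_prune(gm, r2, 0.9)
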