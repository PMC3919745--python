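"""Peak-shift enrichment of a risk-SNP set in histone-mark peaks.

Is the risk SNP inside an H3K4me3 peak more often than chance placement
allows?  The null slides all peaks jointly in 100-bp steps within +/-2 Mbp
and asks at what fraction of the 40,000 displacements the SNP set still
overlaps a peak -- a one-sided exact test on a fully enumerated null.
"""

from streakmap import Peak, ShiftTestConfig, expand_snp_set, shift_enrichment

# risk SNP plus the SNPs in absolute LD with it (r^2 = 1.00)
ld_pairs = {
    (28_848_761, 28_849_500): 1.00,
    (28_848_761, 28_851_200): 1.00,
    (28_848_761, 28_890_000): 0.45,
}
snp_set = expand_snp_set(28_848_761, ld_pairs, r2_threshold=1.0)
print(f"SNP set after LD expansion (r2 >= 1.0): {sorted(snp_set)}")

# promoter-mark peaks around the locus (one covers the index SNP)
peaks = [
    Peak("2", 28_848_000, 28_849_200, summit_bp=28_848_700),
    Peak("2", 28_950_000, 28_951_500),
    Peak("2", 29_100_000, 29_100_800),
]

res = shift_enrichment(snp_set, peaks, ShiftTestConfig(), summit_statistic=True)
print(f"observed overlap at the true peak positions: {res.observed_overlap}")
print(f"{res.n_shifts_with_overlap} of {res.n_shifts} displacements overlap")
print(f"one-sided exact P = {res.p_one_sided:.4f}")
print(f"summit-distance rank P = {res.summit_rank_p:.4f}")
# Small p: the peaks sit on the SNPs far more precisely than a random
# placement of the same peak architecture would.
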