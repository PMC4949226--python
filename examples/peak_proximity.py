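"""Do two factors bind closer together on shared promoters than chance?

On each shared target the two factors' representative binding points sit a
certain distance apart. To ask whether that proximity is real rather than a
byproduct of both factors preferring promoters, the permutation null
re-pairs each gene's factor-A peak with the factor-B peak of a different
random shared gene (on TSS-relative offsets), which preserves each factor's
positional preferences while destroying within-promoter coupling.
"""

from cotarget import (
    assign_peaks_to_genes,
    fraction_within,
    metagene_profile,
    proximity_permutation_test,
    simulate_cooccupancy,
    simulate_genome,
)

genes = simulate_genome(n_genes=300, seed=21)
peaks_a, peaks_b, truth = simulate_cooccupancy(
    genes, n_targets_a=120, n_targets_b=90, n_shared=50,
    sigma_shared_bp=50.0, seed=22,
)
assign_a = assign_peaks_to_genes(peaks_a, genes)
assign_b = assign_peaks_to_genes(peaks_b, genes)

result = proximity_permutation_test(
    assign_a, assign_b, set(truth.shared),
    statistic="median", threshold_bp=200, n_permutations=999, seed=1,
)

print(f"shared genes              : {len(truth.shared)}")
print(f"observed median distance  : {result.observed_statistic:.0f} bp")
print(f"null median (median)      : "
      f"{sorted(result.null_statistics)[len(result.null_statistics)//2]:.0f} bp")
print(f"fraction within 200 bp    : {fraction_within(result.observed, 200):.2f}")
print(f"empirical p (lower tail)  : {result.p_empirical:.4f}")

# With a planted 50 bp coupling the observed median (~34 bp) sits far below
# every re-paired null draw (~1.5 kb), so p hits the permutation floor
# 1/(999+1): the factors bind the same promoters in close proximity.

profile = metagene_profile([assign_a, assign_b], genes)
dens = profile.densities
prom = slice(0, profile.n_promoter_bins)
print(f"promoter-region density   : A {dens['A'][prom].sum():.2f}, "
      f"B {dens['B'][prom].sum():.2f} (peaks were planted in promoters)")
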