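"""Haley-Knott QTL scan of a planted fitness trait with a permutation
threshold.

Plants one additive QTL explaining ~40% of trait variance in a 180-spore F1
population, scans at pseudomarker resolution, sets the per-trait threshold
from 1,000 permutations (the LOD exceeded in only 50 of them) and prints the
calls with 1.5-LOD support intervals and variance explained.
"""

import numpy as np

import introlink as il

genome = il.default_genome()
markers = il.default_markers(genome, density_per_kb=1.0, seed=1)
f1, _ = il.generate_f1_population(genome, markers, n_tetrads=45, seed=2)

pseudo = il.collapse_pseudomarkers(f1, genome)  # one locus every 3 kb
probs = il.genotype_probabilities(pseudo, genome)

sigma = 0.1
beta = 2 * sigma * np.sqrt(0.4 / 0.6)  # beta^2/4 / (beta^2/4 + sigma^2) = 0.4
spec = il.make_qtl_spec([("growth_ratio", "E", 1_400_000, beta)])
table, _ = il.simulate_phenotypes(f1, spec, noise_sd=sigma, genome=genome, seed=4)
traits = il.segregant_trait_matrix(table)

scan = il.hk_scan(probs, traits["growth_ratio"], trait="growth_ratio")
threshold = il.permutation_threshold(probs, traits["growth_ratio"], n_perm=1000, seed=5)
print(f"permutation threshold (alpha=0.05): LOD {threshold:.2f}")

for call in il.call_qtl(scan, threshold, genome=genome):
    print(
        f"QTL on {call.chrom} at {call.peak_pos/1e6:.2f} Mb, "
        f"LOD {call.peak_lod:.1f}, support "
        f"{call.support.start/1e6:.2f}-{call.support.end/1e6:.2f} Mb, "
        f"variance explained {call.var_explained:.2f}"
    )

# Expected output: a threshold near LOD 3, and one call on chromosome E whose
# support interval contains the planted locus at 1.40 Mb with variance
# explained close to the planted 0.40.
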