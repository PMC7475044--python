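import numpy as np
import pytest

import introlink as il


@pytest.fixture(scope="session")
def small_genome() -> il.GenomeMap:
    """Three short chromosomes with a nonrecombining interval on '2' that
    carries the MAT locus; rate high enough to see events on a small map."""
    return il.GenomeMap(
        chromosomes=[("1", 500_000), ("2", 400_000), ("3", 300_000)],
        nonrecombining=[il.Interval("2", 1, 150_000)],
        mat_locus=("2", 60_000),
        crossover_rate=8.0,
    )


@pytest.fixture(scope="session")
def small_markers(small_genome) -> il.MarkerSet:
    return il.default_markers(small_genome, density_per_kb=0.5, seed=11)


@pytest.fixture(scope="session")
def f1_small(small_genome, small_markers):
    gm, truth = il.generate_f1_population(
        small_genome, small_markers, n_tetrads=30, seed=5
    )
    return gm, truth


@pytest.fixture(scope="session")
def default_cross():
    """A moderate-size cross on the default genome, shared across linkage
    tests: 180 F1 segregants at pseudomarker resolution."""
    genome = il.default_genome()
    markers = il.default_markers(genome, density_per_kb=1.0, seed=1)
    f1, truth = il.generate_f1_population(genome, markers, n_tetrads=45, seed=2)
    pseudo = il.collapse_pseudomarkers(f1, genome)
    probs = il.genotype_probabilities(pseudo, genome)
    return genome, markers, f1, truth, pseudo, probs
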