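"""Covariance PCA of individuals and of populations.

Individuals are embedded by their allele-indicator counts; populations by
their allele-frequency vectors.  With island-model structure the first axes
separate the islands.
"""

import numpy as np

import msatpipe as mp
from msatpipe import pca

config = mp.SimConfig(theta_fst=0.10, seed=21)
truth = mp.simulate_truth(config)
matrix = mp.truth_genotype_matrix(truth, islands=config.islands)

res_ind = pca.pca_individuals(matrix, permutations=199, rng=np.random.default_rng(0))
print("individual PCA, % variance per axis:",
      [f"{100 * x:.1f}" for x in res_ind.explained[:4]])
print("axis permutation p-values:", [f"{p:.3f}" for p in res_ind.p_values[:2]])

res_pop = pca.pca_populations(matrix, permutations=199, rng=np.random.default_rng(1))
print("population PCA, % variance per axis:",
      [f"{100 * x:.1f}" for x in res_pop.explained[:4]])
centroids = res_pop.scores.join(res_pop.metadata).groupby("island")[["PC1", "PC2"]].mean()
print("island centroids on PC1/PC2:")
print(centroids.round(3))
# Individual-level axes explain little variance each (many loci, much
# within-population variation); the population-level PCA concentrates the
# between-island signal on the first two axes.
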