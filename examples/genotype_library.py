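"""Genotype a simulated library end-to-end and score it against the truth.

Demultiplex by site/colony tags and primers, trim, collapse identical
inserts, filter (length, pooled depth, colony prevalence), call alleles with
the half-max-depth rule, and compare the calls with the generator's truth.
"""

import numpy as np

import msatpipe as mp

config = mp.SimConfig.noise_free(
    sites=["A", "B", "C"],
    islands={"A": "West", "B": "West", "C": "East"},
    pop_sizes=[12, 12, 12],
    loci=mp.default_loci(4),
    seed=7,
)
truth = mp.simulate_truth(config)
scheme = mp.default_barcode_scheme(config.sites)
reads = mp.simulate_read_set(truth, config, scheme)

rvs = {l.name: l.rvs_primer for l in config.loci}
assignments = []
for site, recs in reads.items():
    assigned, unassigned, _ = mp.demultiplex_reads(recs, scheme, config.loci)
    print(f"{site}: {len(assigned)} assigned, {len(unassigned)} unassigned")
    assignments.extend(mp.trim_read(a, rvs[a.locus]) for a in assigned)

tally = mp.collapse_reads(assignments)
tally, rejected_len = mp.apply_length_filter(tally, loci=config.loci)
tally, rejected_depth = mp.apply_depth_prevalence_filters(tally)
print(f"rejected: {len(rejected_len)} by length, {len(rejected_depth)} by depth/prevalence")

calls = mp.call_genotypes(tally, strategy="depth", rng=np.random.default_rng(0))
frame = truth.to_frame()
pairs = {
    (r.site, r.colony, r.locus): tuple(sorted([r.allele1_seq, r.allele2_seq]))
    for r in frame.itertuples()
}
correct = sum(tuple(sorted(c.resolved)) == pairs[k] for k, c in calls.items())
print(f"genotype recovery: {correct}/{len(pairs)} colony-loci")
# With all noise channels off (no stutter, no point error, balanced
# alleles, even depth) the pipeline is exact: recovery is 100%.
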