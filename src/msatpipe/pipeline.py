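"""Configuration and orchestration of the full genotyping + analysis run.

One master seed drives every stage through deterministic child seeds, so a
run is reproducible byte-for-byte from its serialized configuration and any
stage can be re-run on its own.  Each filter logs its removal counts; the
comparison stage rebuilds the eight dataset variants (allele-selection
strategy x prevalence filter x encoding) and tabulates their diversity and
F-statistics side by side.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bottleneck as bn
from . import pca as pca_mod
from . import popgen
from .calling import call_genotypes, encode_alleles, generate_replicate_datasets
from .demux import demultiplex_reads, trim_read
from .genotypes import GenotypeMatrix
from .io import genepop_write, write_genotype_table
from .loci import default_barcode_scheme
from .simulate import SimConfig, simulate_read_set, simulate_truth
from .tally import apply_depth_prevalence_filters, apply_length_filter, collapse_reads

__all__ = ["RunConfig", "run_pipeline"]

#: thresholds that must be present in a config file, with their defaults
THRESHOLDS = {
    "min_len": 15,
    "max_len": 190,
    "plus_repeats": 4,
    "min_depth": 10,
    "min_colonies": 2,
    "min10_colonies": 11,
    "locus_missing": 0.15,
    "individual_missing": 0.35,
    "rarefaction_colonies": 24,
    "permutations": 20000,
    "exact_steps": 100000,
    "bottleneck_iter": 10000,
    "pca_permutations": 10000,
    "replicates": 10,
}


@dataclass
class RunConfig:
    out_dir: str = "results"
    fastq_dir: str | None = None  # None -> simulate a library first
    strategy: str = "random"
    encoding: str = "length"
    seed: int = 0
    max_mismatch: int = 2
    trim_window: int = 4
    trim_quality: float = 15.0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    min_len: int = THRESHOLDS["min_len"]
    max_len: int = THRESHOLDS["max_len"]
    plus_repeats: int = THRESHOLDS["plus_repeats"]
    min_depth: int = THRESHOLDS["min_depth"]
    min_colonies: int = THRESHOLDS["min_colonies"]
    min10_colonies: int = THRESHOLDS["min10_colonies"]
    locus_missing: float = THRESHOLDS["locus_missing"]
    individual_missing: float = THRESHOLDS["individual_missing"]
    rarefaction_colonies: int = THRESHOLDS["rarefaction_colonies"]
    permutations: int = THRESHOLDS["permutations"]
    exact_steps: int = THRESHOLDS["exact_steps"]
    bottleneck_iter: int = THRESHOLDS["bottleneck_iter"]
    pca_permutations: int = THRESHOLDS["pca_permutations"]
    replicates: int = THRESHOLDS["replicates"]
    run_comparison: bool = True
    run_stats: bool = True
    run_bottleneck: bool = True
    run_pca: bool = True
    run_exact: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in ("depth", "random"):
            raise ValueError(f"strategy must be depth or random, not {self.strategy!r}")
        if self.encoding not in ("length", "unique_id"):
            raise ValueError(f"encoding must be length or unique_id, not {self.encoding!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in THRESHOLDS:
            if key not in data:
                raise ValueError(f"config is missing required threshold {key!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def child_rng(self, stage: str) -> np.random.Generator:
        tag = zlib.crc32(stage.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


def _fst_row(matrix: GenotypeMatrix, permutations: int, rng: np.random.Generator) -> dict:
    div = popgen.diversity_indices(matrix)
    fres = popgen.standardized_fst(matrix, permutations=permutations, rng=rng)
    return {
        "N": div.overall["N_alleles_mean"],
        "NE": div.overall["NE"],
        "HE": div.overall["HS"],
        "HO": div.overall["HO"],
        "HT_corrected": div.overall["HT_corrected"],
        "FST": fres.fst,
        "FprimeST": fres.fprime_st,
        "p_FST": fres.p_fst,
        "FIS": fres.fis,
        "p_FIS": fres.p_fis,
        "GprimeST": div.overall["G_ST_hedrick"],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> demux -> filter -> call -> encode -> analyse.

    Returns a results dictionary and writes the results bundle (tables,
    genepop files, JSON summary, serialized config) under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    results: dict = {"config": dataclasses.asdict(config)}

    # --- stage 1: input reads -------------------------------------------
    sim_cfg = SimConfig(**{"seed": config.seed, **config.simulate})
    loci = sim_cfg.loci
    scheme = default_barcode_scheme(sim_cfg.sites)
    islands = sim_cfg.islands
    if config.fastq_dir is None:
        truth = simulate_truth(sim_cfg)
        reads_by_site = simulate_read_set(truth, sim_cfg, scheme, out_dir=out / "reads")
        fastqs = {site: out / "reads" / f"{site}.fastq" for site in sim_cfg.sites}
        results["simulated"] = True
    else:
        fq = Path(config.fastq_dir)
        fastqs = {p.stem.replace(".fastq", ""): p for p in sorted(fq.glob("*.fastq*"))}
        if not fastqs:
            raise FileNotFoundError(f"no FASTQ files in {fq}")
        reads_by_site = None
        results["simulated"] = False

    # --- stage 2: demultiplex + trim ------------------------------------
    assignments = []
    demux_counts: dict = {}
    for site, path in sorted(fastqs.items()):
        recs, unassigned, counts = demultiplex_reads(path, scheme, loci, config.max_mismatch)
        by_locus = {l.name: l.rvs_primer for l in loci}
        for a in recs:
            assignments.append(
                trim_read(
                    a,
                    by_locus[a.locus],
                    window=config.trim_window,
                    min_quality=config.trim_quality,
                    max_mismatch=config.max_mismatch,
                )
            )
        for key, v in counts.items():
            demux_counts[f"{key[0]}:{key[1]}"] = demux_counts.get(f"{key[0]}:{key[1]}", 0) + v
    results["demux_counts"] = demux_counts

    # --- stage 3: collapse + filters ------------------------------------
    tally = collapse_reads(assignments)
    n0 = tally.total_reads
    tally, rej_len = apply_length_filter(
        tally,
        config.min_len,
        config.max_len,
        loci,
        extra_repeats=config.plus_repeats,
        rejects_path=out / "rejects_length.tsv",
    )
    tally, rej_depth = apply_depth_prevalence_filters(
        tally,
        config.min_depth,
        config.min_colonies,
        rejects_path=out / "rejects_depth.tsv",
    )
    tally.write(out / "tally.tsv")
    results["filter_counts"] = {
        "input_reads": n0,
        "rejected_length": int(rej_len["depth"].sum()) if len(rej_len) else 0,
        "rejected_depth_prevalence": int(rej_depth["depth"].sum()) if len(rej_depth) else 0,
        "surviving_reads": tally.total_reads,
    }

    # --- stage 4: call + encode -----------------------------------------
    reps = generate_replicate_datasets(tally, k=config.replicates, seed=config.seed)
    depth_calls = call_genotypes(tally, "depth", config.child_rng("call-depth"))
    canonical_calls = reps[0] if config.strategy == "random" else depth_calls
    matrix = encode_alleles(canonical_calls, config.encoding, islands=islands)
    matrix = popgen.apply_missing_filters(matrix, config.locus_missing, config.individual_missing)
    write_genotype_table(matrix, out / "genotypes.tsv")
    genepop_write(matrix, out / "genotypes.genepop", loci=loci)
    results["n_individuals"] = matrix.n_individuals
    results["n_loci"] = matrix.n_loci

    # --- stage 5: dataset comparison (Table-4-style variants) ------------
    if config.run_comparison:
        min10_tally, _ = apply_depth_prevalence_filters(tally, config.min_depth, config.min10_colonies)
        variants = {
            "random000": reps[0],
            "topdepth": depth_calls,
            "random_min10": generate_replicate_datasets(min10_tally, k=1, seed=config.seed)[0],
            "depth_min10": call_genotypes(min10_tally, "depth", config.child_rng("call-depth-min10")),
        }
        rows = {}
        rng = config.child_rng("comparison")
        for mode, tag in (("unique_id", "ID"), ("length", "len")):
            for name, calls in variants.items():
                m = encode_alleles(calls, mode, islands=islands)
                m = popgen.apply_missing_filters(m, config.locus_missing, config.individual_missing)
                rows[f"{name}_{tag}"] = _fst_row(m, config.permutations, rng)
        comparison = pd.DataFrame(rows).T
        comparison.to_csv(out / "comparison.csv")
        results["comparison"] = comparison.to_dict(orient="index")

    # --- stage 6: population statistics ---------------------------------
    if config.run_stats:
        rng = config.child_rng("stats")
        div = popgen.diversity_indices(matrix)
        div.per_locus.to_csv(out / "diversity_per_locus.csv")
        fres = popgen.standardized_fst(matrix, permutations=config.permutations, rng=rng)
        results["diversity"] = {k: float(v) for k, v in div.overall.items()}
        results["global"] = {
            "FST": fres.fst,
            "FprimeST": fres.fprime_st,
            "FIS": fres.fis,
            "p_FST": fres.p_fst,
            "p_FIS": fres.p_fis,
        }
        pw_site = popgen.pairwise_differentiation(matrix, "site", config.permutations, rng)
        pw_site.values.to_csv(out / "pairwise_sites.csv")
        if len(set(islands.values())) >= 2:
            pw_isl = popgen.pairwise_differentiation(matrix, "island", config.permutations, rng)
            pw_isl.values.to_csv(out / "pairwise_islands.csv")
            results["pairwise_islands"] = pw_isl.values.to_dict()
        if config.run_exact:
            exact = popgen.exact_test(matrix, steps=config.exact_steps, rng=rng)
            exact.to_csv(out / "exact_tests.csv", index=False)
        richness = popgen.allelic_richness(matrix, config.rarefaction_colonies)
        richness.to_csv(out / "allelic_richness.csv")

    # --- stage 7: bottleneck --------------------------------------------
    if config.run_bottleneck:
        rng = config.child_rng("bottleneck")
        brows = []
        for pop in matrix.pop_names:
            shift_counts, verdict = bn.mode_shift_test(matrix, pop)
            row = {"population": pop, "mode_shift": verdict}
            for model in (bn.IAM, bn.TPM):
                res = bn.het_excess_test(matrix, pop, model, n_iter=config.bottleneck_iter, rng=rng)
                row[f"wilcoxon_p_{model.kind}"] = res.wilcoxon_p
                res.per_locus.to_csv(out / f"bottleneck_{pop}_{model.kind}.csv", index=False)
            brows.append(row)
        bdf = pd.DataFrame(brows)
        bdf.to_csv(out / "bottleneck_summary.csv", index=False)
        results["bottleneck"] = bdf.to_dict(orient="records")

    # --- stage 8: ordination --------------------------------------------
    if config.run_pca:
        rng = config.child_rng("pca")
        pca_ind = pca_mod.pca_individuals(matrix, permutations=config.pca_permutations, rng=rng)
        pca_ind.scores.join(pca_ind.metadata).to_csv(out / "pca_individuals.csv")
        results["pca_individuals_explained"] = [float(x) for x in pca_ind.explained[:5]]
        if len(matrix.pop_names) >= 3:
            pca_pop = pca_mod.pca_populations(matrix, permutations=config.pca_permutations, rng=rng)
            pca_pop.scores.join(pca_pop.metadata).to_csv(out / "pca_populations.csv")
            results["pca_populations_explained"] = [float(x) for x in pca_pop.explained[:5]]

    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)
    return results
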