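#!/usr/bin/env python
"""Generate the synthetic patient-matched cohort all later steps analyze.

Emulates a 14-patient cohort with 24 intracranial/extracranial metastasis
pairs: per-sample methylome tables, pair difference profiles with ground-
truth HMM states, annotation tracks (genes, CpG-density context,
transposons, pathways), clinical metadata and coupled expression tables.
Everything is written as TSV/BED under results/cohort/.
"""

import argparse
from pathlib import Path

import pandas as pd

from methpair import (
    SimConfig,
    simulate_annotations,
    simulate_clinical,
    simulate_cohort,
    simulate_expression,
)
from methpair.profiles import write_methylome, write_pair_profile


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = SimConfig(n_chromosomes=2, cpgs_per_chromosome=2000, seed=args.seed)
    out = args.out
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "pairs").mkdir(exist_ok=True)

    sample_pairs, profiles, truth = simulate_cohort(cfg)
    for intra, extra in sample_pairs:
        write_methylome(intra, out / "samples" / f"{intra.sample_id}.tsv")
        write_methylome(extra, out / "samples" / f"{extra.sample_id}.tsv")
    for prof in profiles:
        write_pair_profile(prof, out / "pairs" / f"{prof.pair_id}.tsv")

    cpgs = profiles[0].records[["cpg_id", "chrom", "pos"]]
    annot, tables = simulate_annotations(cpgs, truth, cfg)
    for name, df in tables.items():
        cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        df[["chrom", "start", "end"] + cols].to_csv(
            out / f"{name}.bed", sep="\t", header=False, index=False
        )
    with open(out / "pathways.tsv", "w") as fh:
        for name, genes in annot.pathways.items():
            fh.write(f"{name}\t{','.join(sorted(genes))}\n")

    simulate_clinical(cfg).to_csv(out / "clinical.tsv", sep="\t", index=False)
    intra_e, extra_e = simulate_expression(truth, cfg)
    intra_e.to_csv(out / "expression_intra.tsv", sep="\t")
    extra_e.to_csv(out / "expression_extra.tsv", sep="\t")
    pd.concat(
        [df.assign(pair_id=pid) for pid, df in truth.states.items()],
        ignore_index=True,
    ).to_csv(out / "truth_states.tsv", sep="\t", index=False)

    n_alt = truth.recurrent.shape[0] if truth.recurrent is not None else 0
    print(
        f"cohort: {cfg.n_patients} patients, {len(profiles)} pairs, "
        f"{len(cpgs)} CpGs per sample, {n_alt} recurrently altered CpGs "
        f"planted -> {out}"
    )


if __name__ == "__main__":
    main()
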