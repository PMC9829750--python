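#!/usr/bin/env python
"""Fisher enrichment of decreased/increased CpG sets in genomic categories.

For every pair and direction, tests whether the altered CpGs are
overrepresented in gene bodies, promoters, enhancers, CpG-density contexts,
transposon classes and pathways, with BH adjustment within each pair.  The
constructed-enriched pathway should light up across pairs; the
constructed-neutral one should not.
"""

import argparse
from pathlib import Path

import pandas as pd

from methpair import annotate_cpgs, enrichment_matrix
from methpair.enrichment import load_gene_sets
from methpair.hmm import StateCalls


def load_calls(calls_dir: Path) -> dict[str, StateCalls]:
    out = {}
    for f in sorted(calls_dir.glob("*.tsv")):
        df = pd.read_csv(f, sep="\t", dtype={"cpg_id": str, "chrom": str})
        out[f.stem] = StateCalls(f.stem, f.stem.split("-")[0], df)
    return out


def load_annotations(cohort: Path):
    genes = pd.read_csv(
        cohort / "genes.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "region"],
    )
    context = pd.read_csv(
        cohort / "context.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "category"],
    )
    transposons = pd.read_csv(
        cohort / "transposons.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "category"],
    )
    pathways = load_gene_sets(cohort / "pathways.tsv")
    return genes, context, transposons, pathways


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    calls = load_calls(args.calls)
    first = next(iter(calls.values())).records
    cpgs = first[["cpg_id", "chrom", "pos"]]
    genes, context, transposons, pathways = load_annotations(args.cohort)
    annot = annotate_cpgs(cpgs, context, genes, transposons, pathways)

    em = enrichment_matrix(calls, annot)
    em.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)

    flagged = (
        em[em["significant"]]
        .groupby("category")["pair_id"]
        .nunique()
        .sort_values(ascending=False)
    )
    print("pairs with significant enrichment per category (q < 0.05):")
    for cat, n in flagged.items():
        print(f"  {cat:20s} {n}/{em['pair_id'].nunique()}")


if __name__ == "__main__":
    main()
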