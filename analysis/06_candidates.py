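#!/usr/bin/env python
"""Cross-patient CpG ranking and candidate-gene selection.

Collapses each patient's pairs by majority vote, counts per CpG how many
patients share a decreased or increased consensus, and selects genes with
at least one promoter/enhancer/gene-body CpG altered in more than 50% of
patients; finally intersects the candidates with the pathway gene sets.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

import pandas as pd

from methpair import (
    patient_consensus,
    rank_cpgs,
    select_candidate_genes,
    filter_pathway_genes,
    annotate_cpgs,
)

_here = Path(__file__).parent
spec = importlib.util.spec_from_file_location("enrich_step", _here / "05_enrichment.py")
enrich_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(enrich_step)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--min-patients", type=int, default=8)
    args = ap.parse_args()

    calls = enrich_step.load_calls(args.calls)
    genes, context, transposons, pathways = enrich_step.load_annotations(args.cohort)
    first = next(iter(calls.values())).records
    annot = annotate_cpgs(
        first[["cpg_id", "chrom", "pos"]], context, genes, transposons, pathways
    )

    by_patient = {}
    for pid, c in calls.items():
        by_patient.setdefault(pid.split("-")[0], []).append(c)
    cons = {p: patient_consensus(cs) for p, cs in by_patient.items()}
    rank = rank_cpgs(cons)
    rank.to_csv(args.out / "cpg_rank.tsv", sep="\t")

    cand = select_candidate_genes(rank, annot, args.min_patients)
    cand.to_csv(args.out / "candidate_genes.tsv", sep="\t", index=False)
    subset, pct = filter_pathway_genes(cand, pathways)
    subset.to_csv(args.out / "pathway_candidates.tsv", sep="\t", index=False)

    n_dec = cand[cand["direction"] == "decreased"]["gene"].nunique()
    n_inc = cand[cand["direction"] == "increased"]["gene"].nunique()
    print(
        f"{cand['gene'].nunique()} candidate genes at >= {args.min_patients} "
        f"of {len(cons)} patients ({n_dec} decreased, {n_inc} increased)"
    )
    for name, p in sorted(pct.items(), key=lambda kv: -kv[1]):
        print(f"  {name:20s} {p:5.1f}% of candidates")


if __name__ == "__main__":
    main()
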