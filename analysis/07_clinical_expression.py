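#!/usr/bin/env python
"""Clinical context of alteration burdens and the expression association.

Summarizes per patient how many CpGs changed and in which direction (the
balance score), joins the summaries with clinical covariates, and tests
which genes with altered body methylation shift their expression between
the intracranial and extracranial metastasis.
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from methpair import (
    clinical_scatter_tables,
    count_alterations,
    expression_log2_ratios,
)
from methpair.association import test_expression_shift

_here = Path(__file__).parent
spec = importlib.util.spec_from_file_location("enrich_step", _here / "05_enrichment.py")
enrich_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(enrich_step)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    calls = enrich_step.load_calls(args.calls)
    pair_patient = {pid: pid.split("-")[0] for pid in calls}
    summaries = count_alterations(calls, pair_patient)
    summaries.to_csv(args.out / "alteration_summaries.tsv", sep="\t", index=False)

    clinical = pd.read_csv(args.cohort / "clinical.tsv", sep="\t")
    joined = clinical_scatter_tables(summaries, clinical)
    joined["table"].to_csv(args.out / "clinical_join.tsv", sep="\t", index=False)

    intra = pd.read_csv(args.cohort / "expression_intra.tsv", sep="\t", index_col=0)
    extra = pd.read_csv(args.cohort / "expression_extra.tsv", sep="\t", index_col=0)
    ratios = expression_log2_ratios(intra, extra)
    tests = test_expression_shift(ratios, intra, extra)
    tests.to_csv(args.out / "expression_tests.tsv", sep="\t", index=False)

    mean_score = summaries["score"].mean()
    n_sig = int((tests["q_value"] < 0.05).sum())
    print(
        f"mean balance score {mean_score:+.2f} "
        f"({'losses' if mean_score < 0 else 'gains'} of methylation dominate); "
        f"Spearman n_diff vs months between: "
        f"{joined['spearman']['n_diff_vs_months_between']:+.2f}"
    )
    print(
        f"{n_sig}/{len(tests)} genes with significant expression shift "
        f"(q < 0.05) between intra- and extracranial metastases"
    )


if __name__ == "__main__":
    main()
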