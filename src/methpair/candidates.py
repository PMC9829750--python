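"""Cross-patient candidate ranking of altered CpGs and genes.

Multiple pairs of one patient are collapsed per CpG by majority vote over
the decreased/increased calls (ties count as unchanged), so each patient
contributes once to the global ranking.  CpGs are then ranked by the number
of patients with a decreased or increased consensus, and a gene becomes a
candidate for a direction when at least one of its promoter / enhancer /
gene-body CpGs reaches the patient threshold (the headline rule: altered in
more than 50% of patients).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet, GENE_REGIONS
from .hmm import StateCalls

logger = logging.getLogger(__name__)


class CandidateError(ValueError):
    pass


def patient_consensus(calls: Sequence[StateCalls]) -> pd.Series:
    """Per-CpG consensus state for one patient's pairs.

    "-" if strictly more pairs call "-" than "+", "+" for the converse,
    otherwise "=" (ties included).  CpGs missing in some pairs are voted
    over the pairs where they are present.
    """
    if len(calls) == 0:
        raise CandidateError("need at least one pair of calls")
    if len(calls) == 1:
        rec = calls[0].records
        return pd.Series(rec["state"].to_numpy(), index=rec["cpg_id"], name="state")
    frames = [c.records.set_index("cpg_id")["state"] for c in calls]
    mat = pd.concat(frames, axis=1, join="outer")
    n_dec = (mat == "-").sum(axis=1)
    n_inc = (mat == "+").sum(axis=1)
    out = np.where(n_dec > n_inc, "-", np.where(n_inc > n_dec, "+", "="))
    n_tied = int(((n_dec == n_inc) & (n_dec > 0)).sum())
    if n_tied:
        logger.info(
            "%d of %d CpGs (%.2f%%) not decidable by majority vote; "
            "counted as unchanged",
            n_tied,
            len(mat),
            100.0 * n_tied / len(mat),
        )
    return pd.Series(out, index=mat.index, name="state")


def rank_cpgs(consensus_by_patient: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-CpG counts of patients with decreased / increased consensus."""
    if len(consensus_by_patient) == 0:
        raise CandidateError("need at least one patient")
    mat = pd.concat(dict(consensus_by_patient), axis=1, join="outer")
    out = pd.DataFrame(
        {
            "n_decreased": (mat == "-").sum(axis=1).astype(int),
            "n_increased": (mat == "+").sum(axis=1).astype(int),
        }
    )
    out.index.name = "cpg_id"
    return out.sort_values(
        ["n_decreased", "n_increased"], ascending=False, kind="mergesort"
    )


def select_candidate_genes(
    rank: pd.DataFrame,
    annot: AnnotationSet,
    min_patients: int,
    regions: Sequence[str] = GENE_REGIONS,
) -> pd.DataFrame:
    """Genes with at least one linked CpG altered in >= min_patients patients.

    CpG-gene links are restricted to the given regions (promoter, enhancer,
    gene body by default); a CpG linked to several genes supports each of
    them, and a gene may appear in both direction lists if distinct CpGs
    support each direction.
    """
    regions = set(regions)
    rows = []
    skipped = 0
    for cpg_id, r in rank.iterrows():
        links = [
            (g, reg) for g, reg in annot.gene_links.get(str(cpg_id), []) if reg in regions
        ]
        if not links:
            skipped += 1
            continue
        for direction, count in (
            ("decreased", int(r["n_decreased"])),
            ("increased", int(r["n_increased"])),
        ):
            if count >= min_patients:
                for gene, region in links:
                    rows.append((gene, direction, str(cpg_id), region, count))
    if skipped:
        logger.debug("%d ranked CpGs without gene links skipped", skipped)
    if not rows:
        return pd.DataFrame(
            columns=["gene", "direction", "n_patients", "cpgs", "regions"]
        )
    long = pd.DataFrame(rows, columns=["gene", "direction", "cpg_id", "region", "n"])
    out = (
        long.groupby(["gene", "direction"])
        .agg(
            n_patients=("n", "max"),
            cpgs=("cpg_id", lambda s: ",".join(sorted(set(s)))),
            regions=("region", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return out.sort_values(
        ["direction", "n_patients", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)


def filter_pathway_genes(
    candidates: pd.DataFrame,
    pathways: Mapping[str, set[str]],
    names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Restrict candidates to pathway genes and report per-pathway overlap.

    The subset is the intersection of the candidate genes with the union of
    the named pathway gene sets; the percentage per pathway is
    100 * |candidates and pathway| / |candidates|.
    """
    if names is None:
        names = list(pathways)
    for nm in names:
        if nm not in pathways:
            raise CandidateError(f"unknown pathway {nm!r}")
    cand_genes = set(candidates["gene"]) if len(candidates) else set()
    union = set().union(*(pathways[nm] for nm in names)) if names else set()
    subset = (
        candidates[candidates["gene"].isin(union)].reset_index(drop=True)
        if len(candidates)
        else candidates
    )
    pct = {
        nm: (100.0 * len(cand_genes & pathways[nm]) / len(cand_genes))
        if cand_genes
        else 0.0
        for nm in names
    }
    return subset, pct
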