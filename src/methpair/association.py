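"""Clinical and expression associations of predicted methylation alterations.

Per pair the decreased/increased CpG calls are counted; per patient the
counts are averaged over that patient's pairs, summed into the number of
differentially methylated CpGs, and condensed into the balance score
s = (n_inc - n_dec) / (n_inc + n_dec) in [-1, 1] (negative: mostly losses of
methylation intracranially).  These summaries are joined with clinical
covariates for descriptive scatter tables, and per-gene expression log2
ratios (intra minus extra) are tested for a shift from zero with BH
adjustment across genes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_fdr
from .hmm import StateCalls

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


def count_alterations(
    calls_by_pair: Mapping[str, StateCalls],
    pair_patient: Mapping[str, str],
) -> pd.DataFrame:
    """Per-patient alteration summary averaged over the patient's pairs.

    Columns: n_dec, n_inc (mean CpG counts), n_diff = n_dec + n_inc, and the
    balance score; the score is NaN (undefined) when n_diff = 0.
    """
    rows = []
    for pair_id, calls in calls_by_pair.items():
        counts = calls.state_counts()
        rows.append(
            (pair_patient[pair_id], pair_id, counts["-"], counts["+"])
        )
    per_pair = pd.DataFrame(rows, columns=["patient_id", "pair_id", "dec", "inc"])
    per_patient = (
        per_pair.groupby("patient_id")[["dec", "inc"]].mean().rename(
            columns={"dec": "n_dec", "inc": "n_inc"}
        )
    )
    per_patient["n_diff"] = per_patient["n_dec"] + per_patient["n_inc"]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (per_patient["n_inc"] - per_patient["n_dec"]) / per_patient["n_diff"]
    per_patient["score"] = np.where(per_patient["n_diff"] > 0, score, np.nan)
    return per_patient.reset_index()


def clinical_scatter_tables(
    summaries: pd.DataFrame, clinical: pd.DataFrame
) -> dict[str, pd.DataFrame | dict[str, float]]:
    """Join alteration summaries with clinical covariates.

    Returns the joined table plus exploratory Spearman rank correlations of
    n_diff with the continuous covariates (months between metastases,
    survival); correlations are NaN when undefined (constant input).
    Patients present in only one table are dropped with a warning.
    """
    joined = summaries.merge(clinical, on="patient_id", how="inner")
    lost = set(summaries["patient_id"]) ^ set(clinical["patient_id"])
    if lost:
        warnings.warn(f"patients dropped from join: {sorted(lost)}")

    def _spearman(x: pd.Series, y: pd.Series) -> float:
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            return float("nan")
        return float(stats.spearmanr(x[ok], y[ok]).statistic)

    corr = {
        "n_diff_vs_months_between": _spearman(
            joined["n_diff"], joined["months_between"]
        ),
        "n_diff_vs_survival_months": _spearman(
            joined["n_diff"], joined["survival_months"]
        ),
    }
    return {"table": joined, "spearman": corr}


def treatment_consistency(
    rank: pd.DataFrame,
    consensus_by_patient: Mapping[str, pd.Series],
    clinical: pd.DataFrame,
    min_patients: int,
) -> pd.DataFrame:
    """Per top-ranked CpG, the fraction of patients in each treatment group
    sharing the majority alteration direction.

    Top-ranked CpGs are those with a decreased or increased consensus in at
    least ``min_patients`` patients.  Empty treatment groups are omitted
    with a warning.
    """
    groups = clinical.groupby("treatment")["patient_id"].apply(list).to_dict()
    empty = [g for g, pts in groups.items() if not pts]
    for g in empty:
        warnings.warn(f"treatment group {g!r} empty; omitted")
        groups.pop(g)

    top = rank[
        (rank["n_decreased"] >= min_patients) | (rank["n_increased"] >= min_patients)
    ]
    rows = []
    for cpg_id, r in top.iterrows():
        direction = "-" if r["n_decreased"] >= r["n_increased"] else "+"
        for grp, patients in groups.items():
            states = [
                consensus_by_patient[p].get(cpg_id, "=")
                for p in patients
                if p in consensus_by_patient
            ]
            if not states:
                continue
            frac = float(np.mean([s == direction for s in states]))
            rows.append((cpg_id, direction, grp, len(states), frac))
    return pd.DataFrame(
        rows, columns=["cpg_id", "direction", "treatment", "n_patients", "fraction"]
    )


def expression_log2_ratios(
    expr_intra: pd.DataFrame,
    expr_extra: pd.DataFrame,
    pair_patient: Mapping[str, str] | None = None,
    average_per_patient: bool = False,
) -> pd.DataFrame:
    """Per-gene expression log2-ratios: intra minus extra, per pair.

    With ``average_per_patient`` the ratios of a patient's multiple pairs
    are averaged so each patient contributes one column.  Genes missing in
    one table are dropped with a log entry.
    """
    shared_genes = expr_intra.index.intersection(expr_extra.index)
    dropped = set(expr_intra.index) ^ set(expr_extra.index)
    if dropped:
        logger.info("genes missing in one expression table dropped: %s",
                    sorted(dropped))
    shared_cols = [c for c in expr_intra.columns if c in set(expr_extra.columns)]
    ratios = (
        expr_intra.loc[shared_genes, shared_cols]
        - expr_extra.loc[shared_genes, shared_cols]
    )
    if average_per_patient:
        if pair_patient is None:
            raise AssociationError("pair_patient mapping required for averaging")
        cols = pd.Series({c: pair_patient[c] for c in ratios.columns})
        ratios = ratios.T.groupby(cols).mean().T
    return ratios


def test_expression_shift(
    ratios: pd.DataFrame,
    intra: pd.DataFrame | None = None,
    extra: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided one-sample t-test of the mean per-gene ratio against zero,
    BH-adjusted across genes.

    Genes passing q < alpha are additionally tested by a paired t-test on
    the per-column intra vs extra levels when those tables are supplied.
    Zero-variance genes are flagged with undefined p.
    """
    rows = []
    for gene, vals in ratios.iterrows():
        v = vals.dropna().to_numpy(dtype=float)
        if len(v) < 2:
            raise AssociationError(f"gene {gene!r}: need >= 2 ratios")
        mean_shift = float(v.mean())
        if np.ptp(v) == 0:
            if mean_shift == 0.0:
                t, p, flag = 0.0, 1.0, False
            else:
                t, p, flag = np.nan, np.nan, True
        else:
            res = stats.ttest_1samp(v, 0.0)
            t, p, flag = float(res.statistic), float(res.pvalue), False
        rows.append((gene, mean_shift, t, p, flag))
    out = pd.DataFrame(
        rows, columns=["gene", "mean_shift", "t", "p_value", "zero_variance"]
    )
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = adjust_fdr(out.loc[ok, "p_value"])
    out["paired_p"] = np.nan
    if intra is not None and extra is not None:
        hits = out[(out["q_value"] < alpha) & ok]["gene"]
        for gene in hits:
            a = intra.loc[gene].dropna()
            b = extra.loc[gene].dropna()
            cols = a.index.intersection(b.index)
            if len(cols) >= 2:
                out.loc[out["gene"] == gene, "paired_p"] = float(
                    stats.ttest_rel(a[cols], b[cols]).pvalue
                )
    return out


def classify_meth_expr_relation(
    methylation_direction: str, mean_expression_shift: float
) -> str:
    """Joint methylation/expression class of a gene.

    (decreased, up) -> "i"; (decreased, down) -> "ii";
    (increased, down) -> "iii"; (increased, up) -> "other"
    (a combination outside the three observed classes).  Zero shift is
    unclassifiable.
    """
    if methylation_direction not in ("-", "+", "decreased", "increased"):
        raise AssociationError(
            f"unknown methylation direction {methylation_direction!r}"
        )
    if mean_expression_shift == 0 or not np.isfinite(mean_expression_shift):
        raise AssociationError("zero or undefined expression shift: unclassified")
    dec = methylation_direction in ("-", "decreased")
    up = mean_expression_shift > 0
    if dec and up:
        return "i"
    if dec and not up:
        return "ii"
    if not dec and not up:
        return "iii"
    return "other"
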