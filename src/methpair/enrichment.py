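"""CpG annotation and Fisher enrichment of altered-CpG sets.

Each CpG is mapped to the functional categories whose genomic intervals
contain it (gene body, promoter, enhancer; CpG island / shore / shelf with
open sea as complement; transposon classes; pathways via gene links).  For
every pair and direction (decreased / increased) a one-sided Fisher exact
test asks whether the direction-altered CpGs are overrepresented in a
category against the background of all CpGs measured in that pair, with
Benjamini-Hochberg adjustment within each pair-and-panel family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTEXT_CATEGORIES = ("island", "shore", "shelf", "open_sea")
GENE_REGIONS = ("promoter", "gene_body", "enhancer")


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Many-to-many CpG -> category and CpG -> (gene, region) maps.

    Island-context categories are mutually exclusive per CpG; gene-region
    categories may co-occur.  Pathway categories are attached through gene
    links, so every pathway membership is traceable to a gene link.
    """

    categories: dict[str, set[str]]  # cpg_id -> categories
    gene_links: dict[str, list[tuple[str, str]]]  # cpg_id -> [(gene, region)]
    pathways: dict[str, set[str]]  # pathway -> genes

    def category_names(self) -> list[str]:
        names: set[str] = set()
        for cats in self.categories.values():
            names.update(cats)
        return sorted(names)

    def cpgs_in_category(self, category: str) -> set[str]:
        return {c for c, cats in self.categories.items() if category in cats}


@dataclass
class EnrichmentResult:
    pair_id: str
    direction: str  # "decreased" | "increased"
    category: str
    a: int  # altered & in category
    b: int  # altered & not in category
    c: int  # unaltered & in category
    d: int  # unaltered & not in category
    p_value: float
    q_value: float | None = None
    significant: bool | None = None


def _validate_intervals(df: pd.DataFrame, name: str) -> None:
    bad = df.index[df["end"].to_numpy() <= df["start"].to_numpy()]
    if len(bad):
        raise AnnotationError(
            f"{name}: malformed interval (end <= start) at line {int(bad[0]) + 1}"
        )


def _contained(
    pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Membership of 0-based positions in any [start, end) interval."""
    if len(starts) == 0:
        return np.zeros(len(pos0), dtype=bool)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    # running max of ends handles overlapping intervals
    run_end = np.maximum.accumulate(ends)
    j = np.searchsorted(starts, pos0, side="right") - 1
    hit = j >= 0
    hit[hit] = pos0[hit] < run_end[j[hit]]
    return hit


def load_bed(path: str | Path, value_col: str = "category") -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", value_col]
    )
    return df[[value_col, "chrom", "start", "end"]]


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """One set per line: name TAB gene,gene,..."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, genes = line.split("\t", 1)
        out[name] = set(g for g in genes.split(",") if g)
    return out


def annotate_cpgs(
    cpgs: pd.DataFrame,
    context_intervals: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    transposon_intervals: pd.DataFrame | None = None,
    pathways: Mapping[str, set[str]] | None = None,
) -> AnnotationSet:
    """Annotate CpGs (1-based positions) by interval containment.

    Interval tables are BED-like 0-based half-open with columns
    (category|gene, [region,] chrom, start, end).  A CpG overlapping several
    intervals receives every matching category; CpGs in no island / shore /
    shelf interval are "open_sea".
    """
    for name, df in (
        ("context", context_intervals),
        ("genes", gene_intervals),
    ):
        _validate_intervals(df, name)
    if transposon_intervals is not None:
        _validate_intervals(transposon_intervals, "transposons")

    cpg_ids = cpgs["cpg_id"].to_numpy()
    categories: dict[str, set[str]] = {c: set() for c in cpg_ids}
    gene_links: dict[str, list[tuple[str, str]]] = {c: [] for c in cpg_ids}
    gene_to_pathways: dict[str, list[str]] = {}
    if pathways:
        for pw, genes in pathways.items():
            for g in genes:
                gene_to_pathways.setdefault(g, []).append(pw)

    for chrom, grp in cpgs.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1  # 1-based -> 0-based
        ids = grp["cpg_id"].to_numpy()

        in_context = np.zeros(len(grp), dtype=bool)
        for cat in ("island", "shore", "shelf"):
            sub = context_intervals[
                (context_intervals["category"] == cat)
                & (context_intervals["chrom"] == chrom)
            ]
            hit = _contained(
                pos0, sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            # island-context categories are mutually exclusive: first match
            # wins in island > shore > shelf precedence
            hit = hit & ~in_context
            in_context |= hit
            for cid in ids[hit]:
                categories[cid].add(cat)
        for cid in ids[~in_context]:
            categories[cid].add("open_sea")

        if transposon_intervals is not None:
            for cat, sub in transposon_intervals[
                transposon_intervals["chrom"] == chrom
            ].groupby("category"):
                hit = _contained(
                    pos0, sub["start"].to_numpy(), sub["end"].to_numpy()
                )
                for cid in ids[hit]:
                    categories[cid].add(str(cat))

        gsub = gene_intervals[gene_intervals["chrom"] == chrom]
        for (gene, region), sub in gsub.groupby(["gene", "region"]):
            hit = _contained(
                pos0, sub["start"].to_numpy(), sub["end"].to_numpy()
            )
            for cid in ids[hit]:
                categories[cid].add(str(region))
                gene_links[cid].append((str(gene), str(region)))
                for pw in gene_to_pathways.get(str(gene), ()):
                    categories[cid].add(pw)

    return AnnotationSet(
        categories=categories,
        gene_links=gene_links,
        pathways=dict(pathways or {}),
    )


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p for a 2x2 table: the hypergeometric upper tail
    P(X >= a) with population N = a+b+c+d, K = a+c category members and
    n = a+b draws.  This is the single formula behind every enrichment test."""
    N, K, n = a + b + c + d, a + c, a + b
    p = float(stats.hypergeom.sf(a - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_enrichment(
    calls: "StateCalls",
    annot: AnnotationSet,
    direction: str,
    category: str,
    pair_id: str | None = None,
) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test for overrepresentation of
    direction-altered CpGs in a category.

    The background universe is every CpG measured in the pair.  The p-value
    is the hypergeometric upper tail P(X >= a) with population size N (all
    measured CpGs), K category CpGs and n altered draws.
    """
    if direction not in ("decreased", "increased"):
        raise AnnotationError(f"unknown direction {direction!r}")
    if category not in annot.category_names():
        raise AnnotationError(f"category {category!r} absent from annotation")
    rec = calls.records
    if len(rec) == 0:
        raise AnnotationError("no CpGs measured")
    target = "-" if direction == "decreased" else "+"
    ids = rec["cpg_id"].to_numpy()
    altered = (rec["state"] == target).to_numpy()
    in_cat = np.array([category in annot.categories.get(c, ()) for c in ids])
    a = int((altered & in_cat).sum())
    b = int((altered & ~in_cat).sum())
    c = int((~altered & in_cat).sum())
    d = int((~altered & ~in_cat).sum())
    p = hypergeom_tail(a, b, c, d)
    return EnrichmentResult(
        pair_id=pair_id or calls.pair_id,
        direction=direction,
        category=category,
        a=a,
        b=b,
        c=c,
        d=d,
        p_value=p,
    )


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.all(np.isfinite(p)):
        raise AnnotationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_matrix(
    calls_by_pair: Mapping[str, "StateCalls"],
    annot: AnnotationSet,
    categories: Sequence[str] | None = None,
    directions: Sequence[str] = ("decreased", "increased"),
    families: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per pair x category x direction enrichment with BH adjustment within
    each pair-and-panel family (all categories of one panel in one pair).

    ``families`` maps category -> panel name; by default all requested
    categories form one family per pair.  Returns a long-format table with
    counts, p, q and a significance flag at q < ``alpha``.
    """
    known = annot.category_names()
    if categories is None:
        categories = known
    else:
        absent = [c for c in categories if c not in known]
        if absent:
            raise AnnotationError(f"category {absent[0]!r} absent from annotation")
    fam = {c: (families or {}).get(c, "all") for c in categories}
    cat_sets = {c: annot.cpgs_in_category(c) for c in categories}
    rows = []
    for pair_id, calls in calls_by_pair.items():
        rec = calls.records
        ids = rec["cpg_id"].to_numpy()
        states = rec["state"].to_numpy()
        masks = {
            c: np.fromiter((i in s for i in ids), bool, len(ids))
            for c, s in ((c, cat_sets[c]) for c in categories)
        }
        for direction in directions:
            target = "-" if direction == "decreased" else "+"
            altered = states == target
            for cat in categories:
                in_cat = masks[cat]
                a = int((altered & in_cat).sum())
                b = int(altered.sum()) - a
                c = int(in_cat.sum()) - a
                d = len(ids) - a - b - c
                p = hypergeom_tail(a, b, c, d)
                rows.append(
                    {
                        "pair_id": pair_id,
                        "direction": direction,
                        "panel": fam[cat],
                        "category": cat,
                        "a": a,
                        "b": b,
                        "c": c,
                        "d": d,
                        "p_value": p,
                    }
                )
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    for _, idx in df.groupby(["pair_id", "panel"]).groups.items():
        df.loc[idx, "q_value"] = adjust_fdr(df.loc[idx, "p_value"])
    df["significant"] = df["q_value"] < alpha
    return df
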