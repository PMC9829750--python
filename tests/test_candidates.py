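import numpy as np
import pandas as pd
import pytest

from methpair import (
    filter_pathway_genes,
    patient_consensus,
    rank_cpgs,
    select_candidate_genes,
)
from methpair.candidates import CandidateError
from methpair.enrichment import AnnotationSet
from methpair.hmm import StateCalls


def _calls(states, pair_id="p1", cpg_ids=None):
    ids = cpg_ids or [f"cg{i}" for i in range(len(states))]
    df = pd.DataFrame(
        {
            "cpg_id": ids,
            "chrom": "chr1",
            "pos": np.arange(1, len(states) + 1),
            "delta": 0.0,
            "state": list(states),
            "gamma_minus": 0.0,
            "gamma_eq": 0.0,
            "gamma_plus": 0.0,
        }
    )
    return StateCalls(pair_id, "P01", df)


def _annot_from_links(links):
    """links: cpg_id -> [(gene, region)]"""
    return AnnotationSet(
        categories={c: {r for _, r in lk} for c, lk in links.items()},
        gene_links=links,
        pathways={},
    )


# ---------------------------------------------------------------------------
# majority vote


def test_majority_vote_basic():
    cons = patient_consensus([_calls("-"), _calls("-"), _calls("+")])
    assert cons.tolist() == ["-"]


def test_tie_counts_as_unchanged():
    cons = patient_consensus([_calls("-"), _calls("+")])
    assert cons.tolist() == ["="]


def test_single_pair_consensus_is_identity():
    cons = patient_consensus([_calls("-=+")])
    assert cons.tolist() == ["-", "=", "+"]


def test_vote_over_pairs_where_cpg_present():
    a = _calls("--", cpg_ids=["cg0", "cg1"])
    b = _calls("+", cpg_ids=["cg0"])
    cons = patient_consensus([a, b])
    assert cons["cg0"] == "="  # one "-" vs one "+": tie
    assert cons["cg1"] == "-"  # only pair a measured it


def test_consensus_requires_at_least_one_pair():
    with pytest.raises(CandidateError):
        patient_consensus([])


# ---------------------------------------------------------------------------
# ranking


def test_rank_counts_patients_per_direction():
    cons = {
        "P1": pd.Series(["-"], index=["cg0"]),
        "P2": pd.Series(["-"], index=["cg0"]),
        "P3": pd.Series(["="], index=["cg0"]),
    }
    rank = rank_cpgs(cons)
    assert rank.loc["cg0", "n_decreased"] == 2
    assert rank.loc["cg0", "n_increased"] == 0


def test_all_unchanged_gives_zero_counts():
    cons = {f"P{i}": pd.Series(["="], index=["cg0"]) for i in range(5)}
    rank = rank_cpgs(cons)
    assert rank.loc["cg0", "n_decreased"] == 0
    assert rank.loc["cg0", "n_increased"] == 0


def test_planted_top_cpg_heads_the_ranking():
    # one CpG altered "-" in 10 of 14 patients, background CpGs in at most 3
    rng = np.random.default_rng(0)
    cons = {}
    for p in range(14):
        states = {"cg_top": "-" if p < 10 else "="}
        for j in range(20):
            states[f"cg_bg{j}"] = "-" if rng.random() < 0.15 else "="
        cons[f"P{p}"] = pd.Series(states)
    rank = rank_cpgs(cons)
    assert rank.index[0] == "cg_top"
    assert rank.loc["cg_top", "n_decreased"] == 10
    top10 = rank[(rank["n_decreased"] >= 10) | (rank["n_increased"] >= 10)]
    assert set(top10.index) == {"cg_top"}


# ---------------------------------------------------------------------------
# gene selection


def _rank_df(counts):
    df = pd.DataFrame(counts, columns=["cpg_id", "n_decreased", "n_increased"])
    return df.set_index("cpg_id")


def test_exactly_planted_genes_selected_at_threshold():
    # 5 genes with one body CpG at n_dec >= 8 (of 14); all other genes <= 7
    rows, links = [], {}
    for g in range(10):
        cpg = f"cg{g}"
        n_dec = 8 + (g % 3) if g < 5 else 7 - (g % 4)
        rows.append((cpg, n_dec, 0))
        links[cpg] = [(f"gene{g}", "gene_body")]
    cand = select_candidate_genes(_rank_df(rows), _annot_from_links(links), 8)
    assert set(cand["gene"]) == {f"gene{g}" for g in range(5)}
    assert (cand["direction"] == "decreased").all()


def test_zero_threshold_returns_every_linked_gene():
    rows = [("cg0", 0, 0), ("cg1", 1, 0)]
    links = {"cg0": [("geneA", "promoter")], "cg1": [("geneB", "enhancer")]}
    cand = select_candidate_genes(_rank_df(rows), _annot_from_links(links), 0)
    assert set(cand["gene"]) == {"geneA", "geneB"}


def test_cpg_linked_to_two_genes_supports_both():
    rows = [("cg0", 9, 0)]
    links = {"cg0": [("geneA", "gene_body"), ("geneB", "promoter")]}
    cand = select_candidate_genes(_rank_df(rows), _annot_from_links(links), 8)
    assert set(cand["gene"]) == {"geneA", "geneB"}


def test_links_outside_allowed_regions_are_ignored():
    rows = [("cg0", 9, 0)]
    links = {"cg0": [("geneA", "intergenic")]}
    cand = select_candidate_genes(_rank_df(rows), _annot_from_links(links), 8)
    assert len(cand) == 0


def test_candidate_set_monotone_in_threshold():
    rng = np.random.default_rng(1)
    rows, links = [], {}
    for i in range(50):
        rows.append((f"cg{i}", int(rng.integers(0, 15)), int(rng.integers(0, 15))))
        links[f"cg{i}"] = [(f"gene{i % 17}", "gene_body")]
    annot = _annot_from_links(links)
    sizes = []
    for thr in range(0, 16):
        cand = select_candidate_genes(_rank_df(rows), annot, thr)
        sizes.append(len(set(zip(cand["gene"], cand["direction"]))))
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


# ---------------------------------------------------------------------------
# pathway filtering


def test_pathway_overlap_percentages():
    cand = pd.DataFrame(
        {"gene": list("ABCD"), "direction": ["decreased"] * 4,
         "n_patients": [8] * 4, "cpgs": [""] * 4, "regions": [""] * 4}
    )
    subset, pct = filter_pathway_genes(cand, {"P": {"A", "B"}})
    assert pct["P"] == 50.0
    assert set(subset["gene"]) == {"A", "B"}


def test_empty_candidates_give_zero_percentages():
    cand = pd.DataFrame(columns=["gene", "direction", "n_patients", "cpgs", "regions"])
    subset, pct = filter_pathway_genes(cand, {"P": {"A"}})
    assert len(subset) == 0
    assert pct["P"] == 0.0


def test_disjoint_pathway_yields_empty_subset():
    cand = pd.DataFrame(
        {"gene": ["A"], "direction": ["decreased"], "n_patients": [8],
         "cpgs": [""], "regions": [""]}
    )
    subset, _ = filter_pathway_genes(cand, {"P": {"Z"}}, names=["P"])
    assert len(subset) == 0


def test_recurrent_gene_recovery_from_decoded_calls():
    """Genes supported by recurrently altered body CpGs in the simulated
    truth are recovered from posterior-decoded calls with high sensitivity."""
    from methpair import (
        HMMConfig,
        SimConfig,
        init_model,
        posterior_decode,
        simulate_annotations,
        simulate_cohort,
    )
    from methpair.hmm import StateCalls

    cfg = SimConfig(
        n_patients=8,
        pairs_per_patient=[1] * 8,
        n_chromosomes=2,
        cpgs_per_chromosome=1500,
        recurrent_cpg_fraction=0.01,
        seed=33,
    )
    _, profiles, truth = simulate_cohort(cfg)
    cpgs = profiles[0].records[["cpg_id", "chrom", "pos"]]
    annot, _ = simulate_annotations(cpgs, truth, cfg)

    def consensus_from(calls_by_pair):
        return {
            truth.pair_patient[pid]: pd.Series(
                c.records["state"].to_numpy(), index=c.records["cpg_id"]
            )
            for pid, c in calls_by_pair.items()
        }

    truth_calls = {
        pid: StateCalls(pid, truth.pair_patient[pid],
                        df.assign(delta=0.0, gamma_minus=0.0, gamma_eq=0.0,
                                  gamma_plus=0.0))
        for pid, df in truth.states.items()
    }
    expected = select_candidate_genes(
        rank_cpgs(consensus_from(truth_calls)), annot, 5
    )
    params = init_model(HMMConfig())
    decoded = {p.pair_id: posterior_decode(params, p) for p in profiles}
    got = select_candidate_genes(rank_cpgs(consensus_from(decoded)), annot, 5)

    exp_set = set(zip(expected["gene"], expected["direction"]))
    got_set = set(zip(got["gene"], got["direction"]))
    assert len(exp_set) > 0
    recall = len(exp_set & got_set) / len(exp_set)
    assert recall >= 0.95


def test_unknown_pathway_name_is_an_error():
    cand = pd.DataFrame(
        {"gene": ["A"], "direction": ["decreased"], "n_patients": [8],
         "cpgs": [""], "regions": [""]}
    )
    with pytest.raises(CandidateError, match="unknown pathway"):
        filter_pathway_genes(cand, {"P": {"A"}}, names=["Q"])
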