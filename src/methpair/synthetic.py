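"""Synthetic patient-matched methylome cohorts with ground-truth states.

The generator emulates the statistical structure the downstream analyses
assume: per-chromosome ordered CpGs; pair difference profiles produced by a
three-state first-order Markov chain (decreased / unchanged / increased) with
Gaussian emissions centered near -3 / 0 / +3; a shared patient baseline plus
per-pair tissue offsets so that the two samples of a patient cluster
together; annotation tracks (genes with promoter/body/enhancer, CpG
island/shore/shelf/open-sea, transposon classes, pathway gene sets including
one constructed-enriched and one constructed-neutral pathway); clinical
metadata; and expression tables coupled to gene-body methylation direction.

A single global seed is expanded into independent per-stream sub-seeds
(states, baselines, annotations, clinical, expression) so individual pieces
can be regenerated reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import MethylomeSample, PairProfile, build_pair_profile
from .enrichment import AnnotationSet

STATES = ("-", "=", "+")


class SimulationError(ValueError):
    pass


def _default_pairs_per_patient() -> list[int]:
    # 14 patients, 24 pairs: seven singletons plus seven patients with
    # multiple pairs (four with 2, three with 3)
    return [1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3]


@dataclass
class SimConfig:
    """Cohort-level generative settings.

    ``state_means``/``state_sds`` are the emission parameters of the
    difference-profile HMM in log2-ratio units; ``altered_fraction_targets``
    is the stationary probability of the decreased and increased states
    (defaults match the cohort-average alteration rates of roughly 7.8%
    decreased and 3.4% increased).  ``self_transition`` controls run lengths
    of altered segments.  ``patient_effect_sd`` / ``tissue_effect_sd`` set
    the sample-level clustering structure: the patient baseline must
    dominate for patient-wise co-clustering.
    """

    n_patients: int = 14
    pairs_per_patient: list[int] = field(default_factory=_default_pairs_per_patient)
    n_chromosomes: int = 4
    cpgs_per_chromosome: int = 2000
    state_means: tuple[float, float, float] = (-3.0, 0.0, 3.0)
    state_sds: tuple[float, float, float] = (0.3, 0.5, 0.3)
    start_probs: tuple[float, float, float] = (0.1, 0.8, 0.1)
    self_transition: float = 0.9
    patient_effect_sd: float = 2.0
    tissue_effect_sd: float = 0.3
    altered_fraction_targets: tuple[float, float] = (0.078, 0.034)
    pair_truth_noise: float = 0.05
    # recurrent alterations shared across patients (the cohort-level signal
    # behind top-ranked CpGs and candidate genes); fraction of CpGs planted
    # and per-patient carrier probability
    recurrent_cpg_fraction: float = 0.005
    recurrent_patient_fraction: float = 0.75
    recurrent_decreased_share: float = 0.8
    # annotation geometry (CpG-index units along each chromosome)
    genes_per_chromosome: int = 40
    pathway_size: int = 12
    enriched_odds: float = 5.0
    # expression coupling
    expression_effect: float = 1.0
    expression_noise_sd: float = 0.3
    treatment_probs: tuple[float, float, float, float] = (
        8 / 14,
        2 / 14,
        3 / 14,
        1 / 14,
    )
    seed: int = 0

    def validate(self) -> None:
        start = np.asarray(self.start_probs, float)
        if (start < 0).any() or abs(float(start.sum()) - 1.0) > 1e-12:
            raise SimulationError(f"start_probs not a simplex: {self.start_probs}")
        if min(self.state_sds) <= 0:
            raise SimulationError("state SDs must be positive")
        if self.cpgs_per_chromosome < 2:
            raise SimulationError("cpgs_per_chromosome must be >= 2")
        if not 0.0 <= self.self_transition <= 1.0:
            raise SimulationError("self_transition must be in [0, 1]")
        f_dec, f_inc = self.altered_fraction_targets
        if f_dec < 0 or f_inc < 0 or f_dec + f_inc >= 1:
            raise SimulationError("altered fractions must be >= 0 and sum < 1")
        if len(self.pairs_per_patient) != self.n_patients:
            raise SimulationError("pairs_per_patient length must equal n_patients")
        if self.patient_effect_sd <= 0 or self.tissue_effect_sd <= 0:
            raise SimulationError("effect SDs must be positive")
        if not 0.0 <= self.recurrent_cpg_fraction < 1.0:
            raise SimulationError("recurrent_cpg_fraction must be in [0, 1)")

    def stationary_probs(self) -> np.ndarray:
        f_dec, f_inc = self.altered_fraction_targets
        return np.array([f_dec, 1.0 - f_dec - f_inc, f_inc])

    def transition_matrix(self) -> np.ndarray:
        """A = s*I + (1-s)*1 f^T, whose stationary distribution is exactly f."""
        f = self.stationary_probs()
        s = self.self_transition
        return s * np.eye(3) + (1.0 - s) * np.tile(f, (3, 1))

    def streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        names = ["states", "baselines", "annotations", "clinical", "expression"]
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``states``: per pair, chromosome-ordered true state per CpG.
    ``gene_direction`` / ``gene_category``: planted gene-body methylation
    direction and expression-coupling class (i: decreased body methylation,
    increased expression; ii: decreased/decreased; iii: increased/decreased).
    ``patient_baselines`` / ``pair_offsets``: latent sample-level effects.
    """

    states: dict[str, pd.DataFrame]
    pair_patient: dict[str, str]
    gene_direction: dict[str, str] = field(default_factory=dict)
    gene_category: dict[str, str] = field(default_factory=dict)
    patient_baselines: dict[str, np.ndarray] = field(default_factory=dict)
    pair_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    recurrent: pd.DataFrame | None = None  # cpg_id, state (planted direction)


def _simulate_state_path(
    rng: np.random.Generator, n: int, start: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    states = np.empty(n, dtype=np.int8)
    cum_trans = trans.cumsum(axis=1)
    u = rng.random(n)
    states[0] = np.searchsorted(start.cumsum(), u[0], side="right")
    for t in range(1, n):
        states[t] = np.searchsorted(cum_trans[states[t - 1]], u[t], side="right")
    return states


def _cpg_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        gaps = rng.integers(50, 500, size=config.cpgs_per_chromosome)
        pos = 1000 + np.cumsum(gaps)
        for p in pos:
            rows.append((f"cg{idx:08d}", chrom, int(p)))
            idx += 1
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos"])


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[tuple[MethylomeSample, MethylomeSample]], list[PairProfile], SimTruth]:
    """Generate patient-matched sample pairs, difference profiles and truth.

    For each pair a true state path is drawn per chromosome from the Markov
    chain (restarting from ``start_probs`` at each chromosome boundary) and
    the per-CpG difference value from the state's Gaussian.  Two per-sample
    methylome tables are emitted whose subtraction reproduces the pair value
    exactly: extracranial = patient baseline + pair offset, intracranial =
    extracranial + emission.  Multiple pairs of one patient share the
    patient's state path up to ``pair_truth_noise`` resampled positions.
    """
    config.validate()
    rngs = config.streams()
    rs, rb = rngs["states"], rngs["baselines"]

    cpgs = _cpg_table(config, rb)
    n_cpg = len(cpgs)
    start = np.asarray(config.start_probs, float)
    trans = config.transition_matrix()
    f = config.stationary_probs()
    chrom_slices = {
        chrom: np.flatnonzero((cpgs["chrom"] == chrom).to_numpy())
        for chrom in cpgs["chrom"].unique()
    }

    extracranial_cycle = ("lung", "lymph_node", "skin", "soft_tissue", "liver")
    sample_pairs: list[tuple[MethylomeSample, MethylomeSample]] = []
    profiles: list[PairProfile] = []
    truth = SimTruth(states={}, pair_patient={})

    # recurrent CpGs: planted alteration directions shared across patients
    n_recurrent = int(round(config.recurrent_cpg_fraction * n_cpg))
    rec_idx = (
        np.sort(rs.choice(n_cpg, size=n_recurrent, replace=False))
        if n_recurrent
        else np.empty(0, dtype=int)
    )
    rec_dir = rs.choice(
        np.array([0, 2], dtype=np.int8),
        size=n_recurrent,
        p=[config.recurrent_decreased_share, 1 - config.recurrent_decreased_share],
    )
    truth.recurrent = pd.DataFrame(
        {
            "cpg_id": cpgs["cpg_id"].to_numpy()[rec_idx],
            "state": np.array(STATES)[rec_dir],
        }
    )

    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        baseline = rb.normal(0.0, config.patient_effect_sd, size=n_cpg)
        truth.patient_baselines[patient] = baseline

        # patient-level reference state path, shared by the patient's pairs
        patient_states = np.empty(n_cpg, dtype=np.int8)
        for chrom, sl in chrom_slices.items():
            patient_states[sl] = _simulate_state_path(rs, len(sl), start, trans)
        if n_recurrent:
            carrier = rs.random(n_recurrent) < config.recurrent_patient_fraction
            patient_states[rec_idx[carrier]] = rec_dir[carrier]

        for k in range(config.pairs_per_patient[p]):
            pair_id = f"{patient}-pair{k + 1}"
            states = patient_states.copy()
            if config.pair_truth_noise > 0:
                flip = rs.random(n_cpg) < config.pair_truth_noise
                states[flip] = rs.choice(3, size=int(flip.sum()), p=f)
            means = np.asarray(config.state_means)[states]
            sds = np.asarray(config.state_sds)[states]
            emission = rs.normal(means, sds)

            offset = rb.normal(0.0, config.tissue_effect_sd, size=n_cpg)
            truth.pair_offsets[pair_id] = offset
            extra_vals = baseline + offset
            intra_vals = extra_vals + emission

            tissue = extracranial_cycle[k % len(extracranial_cycle)]
            intra = MethylomeSample(
                sample_id=f"{pair_id}-intra",
                patient_id=patient,
                tissue="brain",
                records=cpgs.assign(log2ratio=intra_vals),
            )
            extra = MethylomeSample(
                sample_id=f"{pair_id}-extra",
                patient_id=patient,
                tissue=tissue,
                records=cpgs.assign(log2ratio=extra_vals),
            )
            sample_pairs.append((intra, extra))
            profiles.append(build_pair_profile(intra, extra, pair_id=pair_id))
            truth.states[pair_id] = cpgs.assign(
                state=np.array(STATES)[states]
            )
            truth.pair_patient[pair_id] = patient

    return sample_pairs, profiles, truth


# ---------------------------------------------------------------------------
# annotations


def _consensus_alteration_fraction(
    truth: SimTruth, cpg_in_gene: np.ndarray
) -> float:
    return float(cpg_in_gene.mean())


def simulate_annotations(
    cpgs: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> tuple[AnnotationSet, dict[str, pd.DataFrame]]:
    """Tile genes, CpG-density context and transposons along each chromosome
    and build pathway gene sets.

    Genes are laid end to end with an upstream promoter, a spanning body and
    an interspersed enhancer; islands/shores/shelves tile a subset of each
    chromosome with open sea as complement; transposon intervals are drawn
    from the LTR/LINE/DNA classes.  One pathway ("pathway_enriched") is
    assembled from the genes whose body CpGs are most often truly altered
    (targeting an odds ratio of about ``config.enriched_odds`` against the
    background alteration rate) and one ("pathway_neutral") from genes whose
    alteration rate is closest to background.

    Returns the annotation set plus the interval tables (BED-like, 0-based
    half-open) for serialization.  Also assigns each altered gene a
    methylation direction and expression-coupling category on ``truth``.
    """
    if len(cpgs) == 0:
        raise SimulationError("empty cohort: no CpGs to annotate")
    rng = config.streams()["annotations"]

    # cross-pair alteration indicator per CpG (majority of pairs altered)
    state_mat = np.stack(
        [df["state"].to_numpy() for df in truth.states.values()]
    )
    altered_mat = state_mat != "="  # pairs x cpgs
    altered_frac = altered_mat.mean(axis=0)
    dec_frac = (state_mat == "-").mean(axis=0)
    inc_frac = (state_mat == "+").mean(axis=0)

    gene_rows = []  # gene, region, chrom, start, end  (0-based half-open)
    context_rows = []  # category, chrom, start, end
    transposon_rows = []
    gene_body_idx: dict[str, np.ndarray] = {}

    for chrom, grp in cpgs.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        lo, hi = int(pos.min()), int(pos.max())
        span = hi - lo + 1
        n_genes = config.genes_per_chromosome
        slot = span // n_genes
        for g in range(n_genes):
            gene = f"{chrom}_g{g + 1:03d}"
            s0 = lo + g * slot
            body_start = s0 + slot // 5
            body_end = s0 + (4 * slot) // 5
            prom_start = s0
            prom_end = body_start
            enh_start = body_end + slot // 20
            enh_end = min(s0 + slot, enh_start + slot // 10)
            gene_rows.append((gene, "promoter", chrom, prom_start - 1, prom_end - 1))
            gene_rows.append((gene, "gene_body", chrom, body_start - 1, body_end - 1))
            if enh_end > enh_start:
                gene_rows.append((gene, "enhancer", chrom, enh_start - 1, enh_end - 1))
            inside = (pos >= body_start) & (pos < body_end)
            gene_body_idx[gene] = idx[inside]

        # island / shore / shelf tiling on a coarse grid; remainder open sea
        tile = max(span // 12, 4)
        t0 = lo
        while t0 + tile <= hi:
            isl = (t0, t0 + tile // 4)
            shore = (isl[1], isl[1] + tile // 4)
            shelf = (shore[1], shore[1] + tile // 4)
            context_rows.append(("island", chrom, isl[0] - 1, isl[1] - 1))
            context_rows.append(("shore", chrom, shore[0] - 1, shore[1] - 1))
            context_rows.append(("shelf", chrom, shelf[0] - 1, shelf[1] - 1))
            t0 += tile * 2

        for cls in ("LTR", "LINE", "DNA"):
            for _ in range(6):
                s = int(rng.integers(lo, max(hi - 200, lo + 1)))
                transposon_rows.append((cls, chrom, s - 1, s - 1 + 150))

    genes_df = pd.DataFrame(
        gene_rows, columns=["gene", "region", "chrom", "start", "end"]
    )
    context_df = pd.DataFrame(
        context_rows, columns=["category", "chrom", "start", "end"]
    )
    transposon_df = pd.DataFrame(
        transposon_rows, columns=["category", "chrom", "start", "end"]
    )

    # per-gene alteration rates over body CpGs
    gene_alt: dict[str, float] = {}
    gene_dir: dict[str, str] = {}
    for gene, gidx in gene_body_idx.items():
        if len(gidx) == 0:
            continue
        gene_alt[gene] = float(altered_frac[gidx].mean())
        d, i = float(dec_frac[gidx].mean()), float(inc_frac[gidx].mean())
        gene_dir[gene] = "-" if d >= i else "+"

    background = float(altered_frac.mean())
    target_odds = config.enriched_odds * background / max(1.0 - background, 1e-9)
    target_rate = target_odds / (1.0 + target_odds)

    ranked = sorted(gene_alt, key=gene_alt.get, reverse=True)
    enriched = ranked[: config.pathway_size]
    # trim the enriched set toward the target rate: drop the hottest genes
    # while the average stays above the target
    while len(enriched) > 3:
        rate = float(np.mean([gene_alt[g] for g in enriched]))
        if rate <= target_rate:
            break
        enriched = enriched[1:]  # drop the most-altered gene

    # neutrality is enforced per pair (not just on the cross-pair average):
    # the HMM's run structure correlates neighboring body CpGs, so a gene's
    # alteration rate in a single pair fluctuates far more than independent
    # CpGs would; pick genes whose worst per-pair and per-direction deviation
    # from that pair's background rate is smallest
    pair_bg = {
        "-": (state_mat == "-").mean(axis=1),
        "+": (state_mat == "+").mean(axis=1),
    }
    dev: dict[str, float] = {}
    for gene, gidx in gene_body_idx.items():
        if len(gidx) == 0 or gene in enriched:
            continue
        worst = 0.0
        for sym in ("-", "+"):
            rates = (state_mat[:, gidx] == sym).mean(axis=1)
            worst = max(worst, float(np.abs(rates - pair_bg[sym]).max()))
        dev[gene] = worst
    neutral = sorted(dev, key=dev.get)[: config.pathway_size]

    other_genes = [g for g in gene_alt if g not in enriched and g not in neutral]
    rng.shuffle(other_genes)
    pathways = {"pathway_enriched": set(enriched), "pathway_neutral": set(neutral)}
    extra_names = ("pathway_mapk", "pathway_pi3k", "pathway_cytokine")
    for j, name in enumerate(extra_names):
        chunk = other_genes[j * config.pathway_size : (j + 1) * config.pathway_size]
        if chunk:
            pathways[name] = set(chunk)

    # expression-coupling categories for altered genes (class i/ii/iii)
    for gene in sorted(gene_alt, key=gene_alt.get, reverse=True)[
        : 3 * config.pathway_size
    ]:
        truth.gene_direction[gene] = gene_dir[gene]
        if gene_dir[gene] == "-":
            truth.gene_category[gene] = "i" if rng.random() < 8 / 11 else "ii"
        else:
            truth.gene_category[gene] = "iii"

    from .enrichment import annotate_cpgs

    annot = annotate_cpgs(
        cpgs,
        context_intervals=context_df,
        gene_intervals=genes_df,
        transposon_intervals=transposon_df,
        pathways=pathways,
    )
    tables = {
        "genes": genes_df,
        "context": context_df,
        "transposons": transposon_df,
    }
    return annot, tables


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: SimTruth,
    config: SimConfig,
    genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 expression for the intra- and extracranial sample of
    each pair, coupled to the gene's planted body-methylation direction.

    Category (i): decreased methylation, expression shifted up by
    ``expression_effect``; (ii) decreased/down; (iii) increased/down.
    Additive Gaussian noise with ``expression_noise_sd``.  Returns
    (intra_table, extra_table), each gene x pair.
    """
    if genes is None:
        genes = sorted(truth.gene_category)
    for g in genes:
        if g not in truth.gene_category:
            raise SimulationError(f"gene {g!r} has no coupling category")
    rng = config.streams()["expression"]
    pair_ids = sorted(truth.states)
    base = {g: rng.normal(5.0, 1.0) for g in genes}
    sign = {"i": +1.0, "ii": -1.0, "iii": -1.0}
    intra = pd.DataFrame(index=list(genes), columns=pair_ids, dtype=float)
    extra = pd.DataFrame(index=list(genes), columns=pair_ids, dtype=float)
    for pair in pair_ids:
        for g in genes:
            shift = sign[truth.gene_category[g]] * config.expression_effect
            e = base[g] + rng.normal(0.0, config.expression_noise_sd)
            i = base[g] + shift + rng.normal(0.0, config.expression_noise_sd)
            extra.loc[g, pair] = e
            intra.loc[g, pair] = i
    intra.index.name = "gene"
    extra.index.name = "gene"
    return intra, extra


# ---------------------------------------------------------------------------
# clinical metadata


TREATMENT_GROUPS = ("untreated", "IM-treated", "IM+EM-treated", "unknown")


def simulate_clinical(config: SimConfig) -> pd.DataFrame:
    """One row per patient: months between the two metastases, treatment
    group, survival months after the intracranial metastasis, alive flag."""
    config.validate()
    if config.n_patients < 1:
        raise SimulationError("n_patients must be >= 1")
    rng = config.streams()["clinical"]
    patients = [f"P{p + 1:02d}" for p in range(config.n_patients)]
    probs = np.asarray(config.treatment_probs, float)
    probs = probs / probs.sum()
    months = np.round(rng.normal(4.0, 4.0, size=config.n_patients), 1)
    treatment = rng.choice(TREATMENT_GROUPS, size=config.n_patients, p=probs)
    survival = np.round(rng.lognormal(2.3, 0.7, size=config.n_patients), 1)
    alive = rng.random(config.n_patients) < 1.0 / 14.0
    df = pd.DataFrame(
        {
            "patient_id": patients,
            "months_between": months,
            "treatment": treatment,
            "survival_months": np.where(alive, np.nan, survival),
            "alive_flag": alive,
        }
    )
    return df
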