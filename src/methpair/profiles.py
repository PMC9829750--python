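"""Methylome sample tables and patient-matched pair difference profiles.

A sample is the genome-ordered set of per-CpG log2-ratios (methylated vs
unmethylated hybridization signal) of one metastasis.  A pair profile holds,
for one patient, the chromosome-ordered intracranial-minus-extracranial
difference per CpG; it is the observation sequence the HMM consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TISSUES = ("brain", "lung", "lymph_node", "liver", "skin", "soft_tissue")

_CHROM_RE = re.compile(r"^chr(\d+|X|Y|M)$", re.IGNORECASE)


class ProfileError(ValueError):
    """Malformed methylome table or incompatible sample pair."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: chr1..chr22, chrX, chrY, then others."""
    m = _CHROM_RE.match(chrom)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (int(tok), "")
        return ({"X": 23, "Y": 24, "M": 25}[tok], "")
    return (100, chrom)


def _order_records(df: pd.DataFrame) -> pd.DataFrame:
    key = df["chrom"].map(lambda c: chrom_sort_key(str(c)))
    out = df.assign(_k=key).sort_values(
        ["_k", "pos", "cpg_id"], kind="mergesort"
    )
    return out.drop(columns="_k").reset_index(drop=True)


@dataclass
class MethylomeSample:
    """One metastasis sample's genome-ordered CpG log2-ratio measurements."""

    sample_id: str
    patient_id: str
    tissue: str
    records: pd.DataFrame  # columns: cpg_id, chrom, pos, log2ratio

    def __post_init__(self) -> None:
        req = ["cpg_id", "chrom", "pos", "log2ratio"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ProfileError(f"missing column(s): {', '.join(missing)}")
        if self.tissue not in TISSUES:
            raise ProfileError(
                f"unknown tissue {self.tissue!r}; expected one of {TISSUES}"
            )
        dup = self.records["cpg_id"][self.records["cpg_id"].duplicated()]
        if len(dup):
            raise ProfileError(f"duplicate cpg_id: {dup.iloc[0]}")
        vals = self.records["log2ratio"].to_numpy()
        if np.isinf(vals).any():
            raise ProfileError("non-finite log2ratio (inf) in records")
        self.records = _order_records(self.records[req])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PairProfile:
    """Chromosome-ordered intra-minus-extra difference values for one pair."""

    pair_id: str
    patient_id: str
    extracranial_tissue: str
    records: pd.DataFrame  # columns: cpg_id, chrom, pos, delta

    def __post_init__(self) -> None:
        req = ["cpg_id", "chrom", "pos", "delta"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ProfileError(f"missing column(s): {', '.join(missing)}")
        self.records = _order_records(self.records[req])
        for chrom, grp in self.records.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) >= 0).all():
                raise ProfileError(f"positions not increasing on {chrom}")

    def __len__(self) -> int:
        return len(self.records)

    def chromosomes(self) -> list[str]:
        seen = self.records["chrom"].unique().tolist()
        return sorted(seen, key=chrom_sort_key)

    def chromosome_deltas(self) -> dict[str, np.ndarray]:
        """Per-chromosome observation sequences in genomic order."""
        return {
            str(chrom): grp["delta"].to_numpy(dtype=float)
            for chrom, grp in self.records.groupby("chrom", sort=False)
        }


def load_methylome(
    path: str | Path,
    sample_id: str,
    patient_id: str,
    tissue: str,
) -> MethylomeSample:
    """Read a per-sample methylome TSV (cpg_id, chrom, pos, log2ratio).

    Input row order is irrelevant; the returned sample is sorted by
    (chromosome, position).  Duplicate CpG ids, missing columns and
    non-numeric values are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str})
    req = ["cpg_id", "chrom", "pos", "log2ratio"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ProfileError(f"{path}: missing column(s): {', '.join(missing)}")
    bad = pd.to_numeric(df["log2ratio"], errors="coerce")
    nonnum = bad.isna() & df["log2ratio"].notna()
    if nonnum.any():
        row = int(np.flatnonzero(nonnum.to_numpy())[0]) + 2  # 1-based + header
        raise ProfileError(f"{path}: non-numeric log2ratio at line {row}")
    df["log2ratio"] = bad
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    return MethylomeSample(sample_id, patient_id, tissue, df)


def write_methylome(sample: MethylomeSample, path: str | Path) -> None:
    sample.records.to_csv(path, sep="\t", index=False)


def build_pair_profile(
    intra: MethylomeSample,
    extra: MethylomeSample,
    pair_id: str | None = None,
    allow_patient_mismatch: bool = False,
) -> PairProfile:
    """Per-CpG difference profile: intracranial minus extracranial log2-ratio.

    The CpG set is the intersection of the two samples' non-missing CpGs;
    CpGs missing in either sample are dropped (the HMM has no missing-data
    emission).
    """
    if intra.patient_id != extra.patient_id and not allow_patient_mismatch:
        raise ProfileError(
            f"patient mismatch: {intra.patient_id!r} vs {extra.patient_id!r}"
        )
    a = intra.records.dropna(subset=["log2ratio"]).set_index("cpg_id")
    b = extra.records.dropna(subset=["log2ratio"]).set_index("cpg_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ProfileError("no shared CpGs between samples")
    merged = pd.DataFrame(
        {
            "cpg_id": shared,
            "chrom": a.loc[shared, "chrom"].to_numpy(),
            "pos": a.loc[shared, "pos"].to_numpy(),
            "delta": a.loc[shared, "log2ratio"].to_numpy()
            - b.loc[shared, "log2ratio"].to_numpy(),
        }
    )
    return PairProfile(
        pair_id=pair_id or f"{intra.sample_id}_vs_{extra.sample_id}",
        patient_id=intra.patient_id,
        extracranial_tissue=extra.tissue,
        records=merged,
    )


def write_pair_profile(profile: PairProfile, path: str | Path) -> None:
    profile.records.to_csv(path, sep="\t", index=False)


def load_pair_profile(
    path: str | Path,
    pair_id: str,
    patient_id: str,
    extracranial_tissue: str = "lung",
) -> PairProfile:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str})
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    df["delta"] = pd.to_numeric(df["delta"])
    return PairProfile(pair_id, patient_id, extracranial_tissue, df)
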