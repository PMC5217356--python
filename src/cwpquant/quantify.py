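"""Label-free quantification from peptide XIC tables.

The quantification chain, applied to aligned XIC observation tables:

1. **Lane normalization** — each 1D-E lane (one biological replicate at one
   stage) is rescaled by the ratio of the mean lane total to its own total,
   so that every lane carries the same summed XIC signal.
2. **Peptide aggregation** — XICs of identical peptide ions (same sequence,
   charge, and m/z within a ppm tolerance) are summed across the gel
   slices of a lane; charge states of the same sequence are then merged by
   summation into one per-peptide value.
3. **Peptide filter** — only peptides specific to one protein and observed
   in at least two biological replicates within some stage are retained.
4. **Protein quantification** — a protein's abundance in a lane is the sum
   of its specific-peptide abundances; proteins need at least two specific
   peptides and presence in at least three replicates within at least one
   stage.

Every cascade step reports its input/output sizes in a filter audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PipelineConfig

__all__ = [
    "lane_totals",
    "normalize_lanes",
    "aggregate_peptides",
    "filter_peptides",
    "quantify_proteins",
    "FilterAudit",
]

LANE_KEY = ["stage", "replicate"]


@dataclass
class FilterAudit:
    """Counts of items entering/leaving each cascade step."""

    steps: list = field(default_factory=list)

    def record(self, step: str, n_in: int, n_out: int) -> None:
        self.steps.append({"step": step, "n_in": n_in, "n_out": n_out,
                           "n_removed": n_in - n_out})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["step", "n_in", "n_out", "n_removed"])


def lane_totals(observations: pd.DataFrame) -> pd.Series:
    """Summed XIC per lane (the "XIC-lane"); empty lanes are absent."""
    return observations.groupby(LANE_KEY, sort=True)["xic"].sum()


def normalize_lanes(observations: pd.DataFrame) -> pd.DataFrame:
    """Apply the lane correction factor mean(lane totals) / lane total.

    After correction every lane total equals the pre-normalization mean.
    Lanes with zero or no total cannot be corrected and are dropped.
    """
    if observations.empty:
        return observations.copy()
    totals = lane_totals(observations)
    positive = totals[totals > 0]
    if positive.empty:
        raise ValueError("no lane with a positive XIC total")
    factors = positive.mean() / positive
    out = observations.merge(
        factors.rename("lane_factor").reset_index(), on=LANE_KEY, how="inner")
    out["xic"] = out["xic"] * out["lane_factor"]
    return out.drop(columns="lane_factor")


def _group_mz(mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Cluster sorted m/z values: a new group starts where the gap to the
    previous value exceeds the ppm tolerance."""
    order = np.argsort(mz, kind="mergesort")
    sorted_mz = mz[order]
    new_group = np.ones(len(mz), dtype=bool)
    if len(mz) > 1:
        rel = np.diff(sorted_mz) / sorted_mz[:-1]
        new_group[1:] = rel > tol_ppm * 1e-6
    labels_sorted = np.cumsum(new_group) - 1
    labels = np.empty(len(mz), dtype=int)
    labels[order] = labels_sorted
    return labels


def aggregate_peptides(
    observations: pd.DataFrame,
    config: PipelineConfig | None = None,
    audit: FilterAudit | None = None,
) -> pd.DataFrame:
    """Aggregate normalized XICs into per-lane peptide abundances.

    Identity of a peptide ion is (sequence, charge, m/z within the ppm
    tolerance); its XICs are summed over the slices of each lane. Charge
    states of one sequence are then merged by summing. Peptide ions whose
    occurrences carry conflicting protein attributions are flagged as
    inconsistent and dropped.

    Returns one row per (sequence, stage, replicate): ``abundance``,
    ``proteins`` (semicolon-sorted accession string) and ``specific``.
    """
    config = config or PipelineConfig()
    if observations.empty:
        return pd.DataFrame(columns=["peptide_sequence", "stage", "replicate",
                                     "abundance", "proteins", "specific"])
    df = observations.copy()
    df["mz_group"] = 0
    # m/z clustering only matters where one (sequence, charge) carries
    # several distinct m/z values; skip the common single-value case
    nuniq = df.groupby(["peptide_sequence", "charge"])["mz"].transform("nunique")
    multi = df.index[nuniq > 1]
    if len(multi):
        for _, idx in df.loc[multi].groupby(
                ["peptide_sequence", "charge"]).groups.items():
            df.loc[idx, "mz_group"] = _group_mz(
                df.loc[idx, "mz"].to_numpy(float), config.mz_tolerance_ppm)

    ion_key = ["peptide_sequence", "charge", "mz_group"]
    # conflicting protein attributions for one ion -> ambiguous, dropped
    nprot = df.groupby(ion_key)["protein_accessions"].nunique()
    ambiguous = set(nprot[nprot > 1].index)
    if ambiguous:
        mask = [t not in ambiguous for t in zip(*(df[c] for c in ion_key))]
        kept = df[mask]
    else:
        kept = df
    if audit is not None:
        audit.record("drop_ambiguous_ions", len(df), len(kept))

    per_ion = (kept.groupby(ion_key + LANE_KEY, sort=True)
               .agg(abundance=("xic", "sum"),
                    proteins=("protein_accessions", "first"))
               .reset_index())
    if not config.merge_charge_states:
        # keep 2+/3+ ions of one sequence as distinct peptide entities
        per_ion["peptide_sequence"] = (
            per_ion["peptide_sequence"] + "/" +
            per_ion["charge"].astype(str))
    merged = (per_ion.groupby(["peptide_sequence"] + LANE_KEY, sort=True)
              .agg(abundance=("abundance", "sum"),
                   proteins=("proteins", "first"),
                   n_prot_sets=("proteins", "nunique"))
              .reset_index())
    # same sequence attributed to different protein sets at different
    # charges: inconsistent identification, drop the peptide
    bad_seq = merged.loc[merged["n_prot_sets"] > 1, "peptide_sequence"].unique()
    merged = merged[~merged["peptide_sequence"].isin(bad_seq)]
    merged = merged.drop(columns="n_prot_sets")
    merged["specific"] = ~merged["proteins"].str.contains(";")
    return merged.reset_index(drop=True)


def filter_peptides(
    abundances: pd.DataFrame,
    config: PipelineConfig | None = None,
    audit: FilterAudit | None = None,
) -> pd.DataFrame:
    """Keep specific peptides observed in enough replicates of some stage.

    A peptide passes when it maps to exactly one protein and is observed in
    at least ``min_peptide_replicates`` biological replicates within at
    least one stage.
    """
    config = config or PipelineConfig()
    if abundances.empty:
        return abundances.copy()
    n_pep_in = abundances["peptide_sequence"].nunique()
    spec = abundances[abundances["specific"]]
    reps = (spec.groupby(["peptide_sequence", "stage"])["replicate"]
            .nunique().groupby("peptide_sequence").max())
    keep = set(reps[reps >= config.min_peptide_replicates].index)
    out = spec[spec["peptide_sequence"].isin(keep)].reset_index(drop=True)
    if audit is not None:
        audit.record("filter_peptides", n_pep_in,
                     out["peptide_sequence"].nunique())
    return out


def quantify_proteins(
    peptides: pd.DataFrame,
    config: PipelineConfig | None = None,
    audit: FilterAudit | None = None,
) -> pd.DataFrame:
    """Sum specific-peptide abundances into per-lane protein abundances.

    A protein is quantified only when it has at least
    ``min_specific_peptides`` distinct specific peptide sequences overall
    and is present in at least ``min_replicates_presence`` biological
    replicates within at least one stage.

    Returns one row per (accession, stage, replicate) with ``abundance``
    and per-protein ``n_specific_peptides``.
    """
    config = config or PipelineConfig()
    cols = ["accession", "stage", "replicate", "abundance",
            "n_specific_peptides"]
    if peptides.empty:
        return pd.DataFrame(columns=cols)
    df = peptides[peptides["specific"]].rename(
        columns={"proteins": "accession"})
    n_in = df["accession"].nunique()

    npep = df.groupby("accession")["peptide_sequence"].nunique()
    enough_pep = set(npep[npep >= config.min_specific_peptides].index)
    df = df[df["accession"].isin(enough_pep)]

    prot = (df.groupby(["accession"] + LANE_KEY, sort=True)["abundance"]
            .sum().reset_index())
    reps = (prot.groupby(["accession", "stage"])["replicate"].nunique()
            .groupby("accession").max())
    present = set(reps[reps >= config.min_replicates_presence].index)
    prot = prot[prot["accession"].isin(present)].reset_index(drop=True)
    prot["n_specific_peptides"] = prot["accession"].map(npep)
    if audit is not None:
        audit.record("quantify_proteins", n_in, prot["accession"].nunique())
    return prot[cols]
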