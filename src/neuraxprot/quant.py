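"""Peptide-to-protein rollup, replicate-wise detection, tissue proteomes.

A protein's intensity in one (tissue, condition, replicate) cell is the
arithmetic mean of its linear peptide intensities in that cell.  A protein is
*detected* in a tissue/condition when every replicate cell contains at least
one of its peptides; the tissue proteome is the set of detected proteins with
cross-replicate intensity summaries.  Single-peptide proteins are included by
design (flagged), enabling the most stringent cross-tissue comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "aggregate_protein_intensities",
    "detect_proteins",
    "build_tissue_proteome",
]


def aggregate_protein_intensities(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean linear peptide intensity per (protein, tissue, condition, replicate).

    Cells with no peptide are simply absent.  Returns columns ``protein_id,
    tissue, condition, replicate, mean_intensity, n_peptides``.
    """
    grouped = measurements.groupby(
        ["protein_id", "tissue", "condition", "replicate"],
        sort=True,
        observed=True,
    )["intensity"]
    out = grouped.agg(mean_intensity="mean", n_peptides="size").reset_index()
    return out


def _cell_presence(
    measurements: pd.DataFrame, tissue: str, condition: str
) -> pd.DataFrame:
    # tissues/conditions are extensible: accept the study panel plus whatever
    # the data carry, reject anything known to neither
    if tissue not in io.TISSUES and not (measurements["tissue"] == tissue).any():
        raise ValueError(f"unknown tissue {tissue!r}")
    if condition not in (io.CONTROL, io.CASE) and not (
        measurements["condition"] == condition
    ).any():
        raise ValueError(f"unknown condition {condition!r}")
    return measurements.loc[
        (measurements["tissue"] == tissue) & (measurements["condition"] == condition)
    ]


def detect_proteins(
    measurements: pd.DataFrame,
    tissue: str,
    condition: str,
    n_replicates: int = 3,
    same_peptide: bool = False,
) -> set[str]:
    """Proteins with at least one peptide in every replicate of the cell group.

    The default reading is protein-level: any peptide observation counts in
    each replicate.  ``same_peptide=True`` switches to the stricter rule
    requiring one specific peptide to be seen in all replicates.
    """
    sub = _cell_presence(measurements, tissue, condition)
    if sub.empty:
        return set()
    unit = ["protein_id", "peptide_id"] if same_peptide else ["protein_id"]
    counts = sub.groupby(unit, observed=True)["replicate"].nunique()
    hit = counts[counts >= n_replicates]
    if same_peptide:
        return set(hit.index.get_level_values("protein_id"))
    return set(hit.index)


def build_tissue_proteome(
    measurements: pd.DataFrame,
    tissue: str,
    condition: str,
    n_replicates: int = 3,
    same_peptide: bool = False,
    mean_over: str = "replicates",
) -> pd.DataFrame:
    """Assemble the tissue proteome: detected proteins with intensity summaries.

    Returns columns ``protein_id, mean_intensity, sd, n_peptides_total,
    single_peptide``.  ``mean_intensity`` and ``sd`` (sample sd, n-1) are
    computed across replicate-level protein means by default; with
    ``mean_over="pooled"`` they are taken over all peptide observations
    pooled across replicates instead.
    """
    if mean_over not in ("replicates", "pooled"):
        raise ValueError("mean_over must be 'replicates' or 'pooled'")
    detected = detect_proteins(
        measurements, tissue, condition, n_replicates, same_peptide
    )
    sub = _cell_presence(measurements, tissue, condition)
    sub = sub.loc[sub["protein_id"].isin(detected)]
    if sub.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "mean_intensity", "sd", "n_peptides_total",
                "single_peptide",
            ]
        )
    peptide_counts = sub.groupby("protein_id", observed=True)["peptide_id"].nunique()
    if mean_over == "replicates":
        per_rep = sub.groupby(["protein_id", "replicate"], observed=True)[
            "intensity"
        ].mean()
        stats = per_rep.groupby("protein_id", observed=True).agg(
            mean_intensity="mean", sd=lambda x: x.std(ddof=1)
        )
    else:
        stats = sub.groupby("protein_id", observed=True)["intensity"].agg(
            mean_intensity="mean", sd=lambda x: x.std(ddof=1)
        )
    out = stats.reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["n_peptides_total"] = peptide_counts.reindex(out["protein_id"]).to_numpy()
    out["single_peptide"] = out["n_peptides_total"] == 1
    return out.sort_values("protein_id", ignore_index=True)
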