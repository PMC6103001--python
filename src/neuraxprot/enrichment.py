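"""PNS- and SC-enriched proteome classification.

A protein detected in a target tissue (SN, DRG, or SC) is called enriched
relative to the brain when either

* criterion A — it is absent from every brain-region proteome (ACC, AMY,
  PFC, CER under the full replicate-wise detection rule), or
* criterion B — its target-tissue mean abundance exceeds the maximum
  brain-region mean by strictly more than the fold threshold (default 10,
  one order of magnitude) with a one-tailed Welch's t-test p below alpha.

An optional secondary filter re-screens enriched proteins against a second,
deeper reference analysis of the brain: any protein detected there (even
partially) is removed unless it again clears the fold/significance bar
against that reference.  Classification operates on linear-scale intensities;
both the fold ratio and the Welch statistic are invariant to rescaling all
intensities by a common positive constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BRAIN_TISSUES, CONTROL, AnalysisThresholds
from .quant import build_tissue_proteome

logger = logging.getLogger(__name__)

__all__ = [
    "WelchResult",
    "max_brain_abundance",
    "welch_one_tailed",
    "classify_enriched",
    "apply_secondary_filter",
    "partition_tissue_preference",
    "brain_proteomes",
]

CRITERION_A = "A_absent_in_brain"
CRITERION_B = "B_fold_enriched"
REJECTED = "rejected"
UNTESTABLE = "untestable"


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p)


def welch_one_tailed(sample_a, sample_b) -> WelchResult:
    """One-tailed Welch's t-test of mean(a) > mean(b) on unequal variances.

    Returns the Welch statistic, Welch-Satterthwaite degrees of freedom and
    the upper-tail p-value.  The result is undefined (all NaN) when either
    sample has fewer than two values or both sample variances are zero.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return WelchResult(math.nan, math.nan, math.nan)
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return WelchResult(math.nan, math.nan, math.nan)
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def max_brain_abundance(
    proteomes: dict[str, pd.DataFrame], protein_id: str
) -> tuple[str, float] | None:
    """Brain region with the highest cross-replicate mean for one protein.

    Only regions whose proteome lists the protein (i.e. where it passes the
    detection rule) contribute; returns None when it is detected in none.
    Ties break to the earliest region in the dict's iteration order, which
    :func:`brain_proteomes` fixes to ACC < AMY < PFC < CER.
    """
    best: tuple[str, float] | None = None
    for region, proteome in proteomes.items():
        hit = proteome.loc[proteome["protein_id"] == protein_id, "mean_intensity"]
        if hit.empty:
            continue
        value = float(hit.iloc[0])
        if best is None or value > best[1]:
            best = (region, value)
    return best


def brain_proteomes(
    measurements: pd.DataFrame,
    condition: str = CONTROL,
    regions: tuple[str, ...] = BRAIN_TISSUES,
    n_replicates: int = 3,
) -> dict[str, pd.DataFrame]:
    """Build the brain-region proteomes in the fixed tie-break order."""
    return {
        region: build_tissue_proteome(measurements, region, condition, n_replicates)
        for region in regions
    }


def _replicate_values(
    replicate_intensities: pd.DataFrame, protein_id: str, tissue: str
) -> np.ndarray:
    sel = replicate_intensities.loc[
        (replicate_intensities["protein_id"] == protein_id)
        & (replicate_intensities["tissue"] == tissue),
        "mean_intensity",
    ]
    return sel.to_numpy(dtype=float)


def classify_enriched(
    target_tissue: str,
    target_proteome: pd.DataFrame,
    brain: dict[str, pd.DataFrame],
    replicate_intensities: pd.DataFrame,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    log_scale: bool = False,
) -> pd.DataFrame:
    """Classify every protein of the target proteome against the brain.

    Parameters
    ----------
    target_proteome
        Output of :func:`neuraxprot.quant.build_tissue_proteome` for the
        target tissue (control condition).
    brain
        Region -> proteome mapping (see :func:`brain_proteomes`).
    replicate_intensities
        Per-replicate protein intensities (one condition), as produced by
        :func:`neuraxprot.quant.aggregate_protein_intensities`.
    log_scale
        Run the Welch test on log2 intensities instead of linear ones; the
        fold ratio is always computed on linear means.

    Returns
    -------
    DataFrame with columns ``protein_id, target_tissue, criterion,
    fold_enrichment, welch_p, secondary_filter``.  When both replicate
    variances vanish the Welch test is undefined and the decision falls back
    to the fold criterion alone (logged).
    """
    rows = []
    for protein_id, target_mean in zip(
        target_proteome["protein_id"], target_proteome["mean_intensity"]
    ):
        best = max_brain_abundance(brain, protein_id)
        if best is None:
            rows.append((protein_id, CRITERION_A, math.nan, math.nan))
            continue
        region, brain_mean = best
        fold = float(target_mean) / brain_mean
        a = _replicate_values(replicate_intensities, protein_id, target_tissue)
        b = _replicate_values(replicate_intensities, protein_id, region)
        if log_scale:
            welch = welch_one_tailed(np.log2(a), np.log2(b))
        else:
            welch = welch_one_tailed(a, b)
        if fold <= thresholds.fold_threshold:
            criterion = REJECTED
        elif welch.defined:
            criterion = CRITERION_B if welch.p < thresholds.welch_alpha else REJECTED
        elif len(a) < 2 or len(b) < 2:
            criterion = UNTESTABLE
        else:
            # zero-variance pair: fold-only decision
            logger.warning(
                "Welch undefined for %s (zero variance in both samples); "
                "falling back to fold-only decision",
                protein_id,
            )
            criterion = CRITERION_B
        rows.append((protein_id, criterion, fold, welch.p))
    out = pd.DataFrame(
        rows, columns=["protein_id", "criterion", "fold_enrichment", "welch_p"]
    )
    out.insert(1, "target_tissue", target_tissue)
    out["secondary_filter"] = "not_applied"
    return out


def apply_secondary_filter(
    decisions: pd.DataFrame,
    secondary_replicate_intensities: pd.DataFrame | None,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    brain_tissues: tuple[str, ...] = BRAIN_TISSUES,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Re-screen enriched proteins against a secondary brain reference.

    ``secondary_replicate_intensities`` carries per-replicate protein
    intensities from the secondary analysis (same schema as
    :func:`neuraxprot.quant.aggregate_protein_intensities`, one condition)
    covering the target tissue and the brain regions.  Any enriched protein
    with *any* observation in a secondary brain tissue — partial coverage
    counts as detected here — is marked ``removed`` unless it is again more
    than fold-threshold enriched (Welch p < alpha, or fold-only when the
    test is undefined) over the maximum secondary brain abundance.  With no
    secondary data the decisions pass through as ``not_applied``.
    """
    out = decisions.copy()
    if secondary_replicate_intensities is None:
        logger.warning("no secondary reference supplied; secondary filter skipped")
        out["secondary_filter"] = "not_applied"
        return out

    sec = secondary_replicate_intensities
    sec_brain = sec.loc[sec["tissue"].isin(brain_tissues)]
    # mean over fully covered regions preferred for the max; any region
    # otherwise (partial observations still count as "detected in brain")
    region_stats = (
        sec_brain.groupby(["protein_id", "tissue"], observed=True)["mean_intensity"]
        .agg(["mean", "size"])
        .reset_index()
    )

    verdicts = []
    for _, row in out.iterrows():
        if row["criterion"] not in (CRITERION_A, CRITERION_B):
            verdicts.append("not_applied")
            continue
        prot = row["protein_id"]
        regions = region_stats.loc[region_stats["protein_id"] == prot]
        if regions.empty:
            verdicts.append("passed")
            continue
        full = regions.loc[regions["size"] >= n_replicates]
        pool = full if not full.empty else regions
        best = pool.loc[pool["mean"].idxmax()]
        a = _replicate_values(sec, prot, row["target_tissue"])
        if len(a) == 0:
            verdicts.append("removed")
            continue
        fold = float(np.mean(a)) / float(best["mean"])
        if fold <= thresholds.fold_threshold:
            verdicts.append("removed")
            continue
        b = _replicate_values(sec, prot, str(best["tissue"]))
        welch = welch_one_tailed(a, b)
        if welch.defined:
            verdicts.append(
                "passed" if welch.p < thresholds.welch_alpha else "removed"
            )
        else:
            verdicts.append("passed")  # fold-only fallback, matches primary
    out["secondary_filter"] = verdicts
    return out


def enriched_set(decisions: pd.DataFrame) -> set[str]:
    """Proteins classified enriched and not removed by the secondary filter."""
    keep = decisions["criterion"].isin((CRITERION_A, CRITERION_B)) & (
        decisions["secondary_filter"] != "removed"
    )
    return set(decisions.loc[keep, "protein_id"])


def partition_tissue_preference(
    decisions_sn: pd.DataFrame,
    decisions_drg: pd.DataFrame,
    proteome_sn: pd.DataFrame,
    proteome_drg: pd.DataFrame,
) -> pd.DataFrame:
    """Label PNS-enriched proteins by tissue preference.

    A protein is tissue-specific when it is enriched in one PNS tissue and
    not even detected in the other tissue's proteome; everything else
    (enriched in both, or enriched in one and detected in the other) is
    shared.  Returns columns ``protein_id, preference`` with preference in
    {SN_specific, DRG_specific, shared}.
    """
    enriched_sn = enriched_set(decisions_sn)
    enriched_drg = enriched_set(decisions_drg)
    detected_sn = set(proteome_sn["protein_id"])
    detected_drg = set(proteome_drg["protein_id"])
    rows = []
    for prot in sorted(enriched_sn | enriched_drg):
        if prot in enriched_sn and prot not in detected_drg:
            label = "SN_specific"
        elif prot in enriched_drg and prot not in detected_sn:
            label = "DRG_specific"
        else:
            label = "shared"
        rows.append((prot, label))
    return pd.DataFrame(rows, columns=["protein_id", "preference"])
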