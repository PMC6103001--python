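"""Case-vs-control protein regulation from paired peptide-level log2 ratios.

For each peptide quantified in all control and all case replicates of a
tissue, three replicate-paired ratios log2(case_r / control_r) are formed.
A protein's regulation is summarised by the mean of its peptide-pair ratios;
a two-sided one-sample t-test against zero gives the p-value, adjusted per
tissue by the Benjamini-Hochberg step-up procedure.  A protein is *regulated*
when q < 0.05 (strict), and a *low-confidence* hit when that call rests on a
single peptide across all six samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CASE, CONTROL, AnalysisThresholds

__all__ = [
    "compute_peptide_ratios",
    "protein_regulation",
    "bh_adjust",
    "call_regulated",
    "regulate_tissue",
    "cross_model_venn",
]


def compute_peptide_ratios(
    measurements: pd.DataFrame,
    tissue: str,
    control: str = CONTROL,
    case: str = CASE,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Replicate-paired log2(case/control) ratios per fully observed peptide.

    A peptide contributes only when it is quantified in every control and
    every case replicate of the tissue (all 2*n_replicates cells); it then
    yields one ratio per replicate index.  Returns columns ``protein_id,
    peptide_id, tissue, pair_index, log2_ratio``.
    """
    sub = measurements.loc[measurements["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no measurements for tissue {tissue!r}")
    wide = sub.pivot_table(
        index=["protein_id", "peptide_id"],
        columns=["condition", "replicate"],
        values="intensity",
        aggfunc="first",
        observed=True,
    )
    needed = [(c, r) for c in (control, case) for r in range(1, n_replicates + 1)]
    missing_cols = [col for col in needed if col not in wide.columns]
    for col in missing_cols:
        wide[col] = np.nan
    wide = wide[needed]
    complete = wide.dropna()
    rows = []
    for (protein_id, peptide_id), vals in complete.iterrows():
        for r in range(1, n_replicates + 1):
            rows.append(
                (
                    protein_id,
                    peptide_id,
                    tissue,
                    r,
                    float(np.log2(vals[(case, r)] / vals[(control, r)])),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "peptide_id", "tissue", "pair_index", "log2_ratio"],
    )


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test against 0; degenerate sets handled.

    All-zero ratios give p = 1 (no evidence of change); a nonzero constant
    gives an undefined p (NaN) so the protein is excluded from the BH family
    rather than carrying a fabricated infinite t statistic.
    """
    if np.all(values == 0.0):
        return 1.0
    if np.var(values, ddof=1) == 0.0:
        return float("nan")
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def protein_regulation(
    ratios: pd.DataFrame,
    sample_unit: str = "pooled",
) -> pd.DataFrame:
    """Per-protein mean log2 fold change and one-sample t-test p-value.

    ``sample_unit="pooled"`` (default) tests all of the protein's
    peptide-pair ratios (3 x n_peptides values) against 0, which keeps
    single-peptide proteins testable; ``"pair_means"`` first averages
    peptides within each replicate pair and tests the 3 pair means.
    Returns columns ``protein_id, tissue, mean_log2fc, p_value, n_peptides,
    n_ratios, untestable`` (q and call flags are added downstream).
    """
    if sample_unit not in ("pooled", "pair_means"):
        raise ValueError("sample_unit must be 'pooled' or 'pair_means'")
    rows = []
    for (protein_id, tissue), grp in ratios.groupby(
        ["protein_id", "tissue"], sort=True, observed=True
    ):
        values = grp["log2_ratio"].to_numpy(dtype=float)
        mean_fc = float(values.mean())
        if sample_unit == "pair_means":
            test_values = (
                grp.groupby("pair_index", observed=True)["log2_ratio"]
                .mean()
                .to_numpy(dtype=float)
            )
        else:
            test_values = values
        p = _one_sample_p(test_values) if len(test_values) >= 2 else float("nan")
        rows.append(
            (
                protein_id,
                tissue,
                mean_fc,
                p,
                int(grp["peptide_id"].nunique()),
                len(values),
                bool(np.isnan(p)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "tissue", "mean_log2fc", "p_value", "n_peptides",
            "n_ratios", "untestable",
        ],
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i}( p_(j) * m / j ), capped at 1.  NaN entries are
    excluded from the family (m counts only defined p-values) and stay NaN.
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if defined.any():
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return q


def call_regulated(
    records: pd.DataFrame,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
) -> pd.DataFrame:
    """Attach BH q-values (per tissue family) and regulated/confidence flags.

    The BH family is each tissue's set of proteins with a defined p-value;
    apply this after annotation filtering so the family matches the reviewed,
    non-contaminant universe.  ``regulated`` requires q strictly below the
    threshold; ``low_confidence`` additionally flags single-peptide calls.
    """
    out = records.copy()
    out["q_value"] = np.nan
    for tissue, idx in out.groupby("tissue", observed=True).groups.items():
        out.loc[idx, "q_value"] = bh_adjust(out.loc[idx, "p_value"])
    out["regulated"] = out["q_value"] < thresholds.q_threshold
    out["regulated"] = out["regulated"].fillna(False).astype(bool)
    out["low_confidence"] = out["regulated"] & (out["n_peptides"] == 1)
    return out


def regulate_tissue(
    measurements: pd.DataFrame,
    tissue: str,
    thresholds: AnalysisThresholds = AnalysisThresholds(),
    control: str = CONTROL,
    case: str = CASE,
    sample_unit: str = "pooled",
) -> pd.DataFrame:
    """End-to-end regulation analysis for one tissue.

    Pipes peptide-pair ratios through the protein-level test and BH
    correction.  Annotation filtering (reviewed, non-contaminant) should be
    applied to ``measurements`` beforehand so the BH family is correct.
    """
    ratios = compute_peptide_ratios(
        measurements, tissue, control, case, thresholds.n_replicates
    )
    records = protein_regulation(ratios, sample_unit=sample_unit)
    return call_regulated(records, thresholds)


def cross_model_venn(model_sets: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Partition regulated proteins across pain models with direction labels.

    ``model_sets`` maps a model name (e.g. "SNI", "CFA") to a mapping of
    protein -> direction ("up"/"down", the sign of mean_log2fc).  Returns one
    row per protein in the union: ``protein_id, membership`` (sorted model
    names joined by "&") and one direction column per model (NA when the
    protein is absent from that model).
    """
    names = sorted(model_sets)
    union = sorted(set().union(*(model_sets[n] for n in names)))
    rows = []
    for prot in union:
        members = [n for n in names if prot in model_sets[n]]
        row = {
            "protein_id": prot,
            "membership": "&".join(members),
        }
        for n in names:
            row[f"direction_{n}"] = model_sets[n].get(prot, pd.NA)
        rows.append(row)
    return pd.DataFrame(rows)


def direction_map(records: pd.DataFrame) -> dict[str, str]:
    """Map each regulated protein to 'up'/'down' by the sign of mean_log2fc."""
    reg = records.loc[records["regulated"]]
    return {
        str(p): ("up" if fc >= 0 else "down")
        for p, fc in zip(reg["protein_id"], reg["mean_log2fc"])
    }
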