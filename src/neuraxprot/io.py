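"""Domain model, file I/O and annotation filtering.

Peptide-level quantification tables are held as pandas DataFrames with the
canonical columns ``protein_id, peptide_id, tissue, condition, replicate,
intensity``.  Intensities are linear-scale and strictly positive; a missing
(non-detected) peptide is simply an absent row, matching the non-detection
semantics of DIA software exports.  All log transforms are base 2 and happen
inside downstream operations, never at load time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import pandas as pd
import yaml

#: the study's tissue panel: two PNS tissues, spinal cord, four brain regions
TISSUES = ("SN", "DRG", "SC", "ACC", "AMY", "PFC", "CER")
BRAIN_TISSUES = ("ACC", "AMY", "PFC", "CER")
PNS_TISSUES = ("SN", "DRG")

#: canonical condition labels; readers can map e.g. Sham/SNI onto these
CONTROL = "control"
CASE = "case"

PEPTIDE_COLUMNS = (
    "protein_id",
    "peptide_id",
    "tissue",
    "condition",
    "replicate",
    "intensity",
)
KEY_COLUMNS = PEPTIDE_COLUMNS[:5]


@dataclass(frozen=True)
class AnalysisThresholds:
    """Analysis constants for the enrichment / regulation pipeline.

    fold_threshold
        Enrichment ratio a protein must strictly exceed over the maximum
        brain-region abundance (default 10, one order of magnitude).
    welch_alpha
        One-tailed Welch test significance level for enrichment calls.
    q_threshold
        BH-adjusted p-value cutoff defining a regulated protein (strict <).
    cluster_cut_distance
        Distance at which flat row clusters are cut in the QC dendrogram.
    n_replicates
        Replicates per tissue and condition in the design.
    pool_size
        Animals pooled per replicate (metadata only; the pipeline never sees
        animal-level data).
    """

    fold_threshold: float = 10.0
    welch_alpha: float = 0.05
    q_threshold: float = 0.05
    cluster_cut_distance: float = 3.4
    n_replicates: int = 3
    pool_size: int = 4

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        for name in ("welch_alpha", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class LoadReport:
    """Counts from loading a peptide report; rows_in = rows_loaded + rows_dropped."""

    rows_in: int = 0
    rows_loaded: int = 0
    dropped_nonpositive: int = 0
    dropped_nonnumeric: int = 0

    @property
    def rows_dropped(self) -> int:
        return self.dropped_nonpositive + self.dropped_nonnumeric


@dataclass
class FilterReport:
    """Counts of measurements removed by each annotation rule."""

    removed_unreviewed: int = 0
    removed_contaminant: int = 0
    removed_unannotated: int = 0


def _check_unique_keys(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        first = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise ValueError(
            "duplicate (protein, peptide, tissue, condition, replicate) key; "
            f"first offender: {tuple(first)}"
        )


def read_peptide_report(
    path,
    dialect: dict[str, str] | None = None,
    condition_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a long-format tab-separated peptide quantification report.

    Parameters
    ----------
    path
        TSV file with a header row naming at least the six required fields.
    dialect
        Optional map from canonical column name to the file's column name,
        e.g. ``{"protein_id": "PG.ProteinAccessions"}``.  Unmapped canonical
        names are looked up verbatim.
    condition_map
        Optional map of condition labels, e.g. ``{"Sham": "control",
        "SNI": "case"}``; labels not in the map pass through unchanged.

    Returns
    -------
    (measurements, report)
        Validated measurements and a :class:`LoadReport`.  Rows with
        non-numeric or non-positive intensity are dropped and counted.

    Raises
    ------
    ValueError
        If a required column is missing or a key occurs twice.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    dialect = dialect or {}
    colmap = {name: dialect.get(name, name) for name in PEPTIDE_COLUMNS}
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"peptide report is missing required column(s): {missing}")

    df = pd.DataFrame({name: raw[src] for name, src in colmap.items()})
    report = LoadReport(rows_in=len(df))

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    nonnumeric = intensity.isna()
    report.dropped_nonnumeric = int(nonnumeric.sum())
    nonpositive = ~nonnumeric & (intensity <= 0)
    report.dropped_nonpositive = int(nonpositive.sum())

    keep = ~(nonnumeric | nonpositive)
    df = df.loc[keep].copy()
    df["intensity"] = intensity[keep].astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    if condition_map:
        df["condition"] = df["condition"].map(lambda c: condition_map.get(c, c))
    df = df.reset_index(drop=True)
    report.rows_loaded = len(df)
    _check_unique_keys(df)
    return df, report


def write_peptide_report(measurements: pd.DataFrame, path) -> None:
    """Write measurements as a canonical TSV; round-trips with the reader."""
    measurements.to_csv(path, sep="\t", index=False, columns=list(PEPTIDE_COLUMNS))


def read_annotations(path) -> pd.DataFrame:
    """Read a protein annotation TSV: protein_id, gene, reviewed, contaminant.

    ``reviewed`` and ``contaminant`` are 0/1 flags.  When the ``contaminant``
    column is absent, keratins are flagged by the gene-symbol prefix ``Krt``
    (case-insensitive) as a convenience for reports without a flag column.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene": str})
    for col in ("protein_id", "gene", "reviewed"):
        if col not in ann.columns:
            raise ValueError(f"annotation table is missing column {col!r}")
    if ann["protein_id"].duplicated().any():
        raise ValueError("annotation table has duplicate protein_id entries")
    ann["reviewed"] = ann["reviewed"].astype(int).astype(bool)
    if "contaminant" in ann.columns:
        ann["contaminant"] = ann["contaminant"].astype(int).astype(bool)
    else:
        ann["contaminant"] = (
            ann["gene"].fillna("").str.lower().str.startswith("krt")
        )
    return ann


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out["reviewed"] = out["reviewed"].astype(int)
    out["contaminant"] = out["contaminant"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def filter_annotated(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame,
    on_missing: str = "warn",
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep only measurements of reviewed, non-contaminant proteins.

    Mirrors the redundancy filter applied before every downstream analysis:
    unreviewed identifiers and keratin contamination are removed.

    Parameters
    ----------
    on_missing
        ``"warn"`` (default) drops measurements of unannotated proteins with a
        warning; ``"error"`` raises instead.
    """
    if on_missing not in ("warn", "error"):
        raise ValueError("on_missing must be 'warn' or 'error'")
    ann = annotations.set_index("protein_id")
    known = measurements["protein_id"].isin(ann.index)
    report = FilterReport(removed_unannotated=int((~known).sum()))
    if report.removed_unannotated:
        if on_missing == "error":
            missing = measurements.loc[~known, "protein_id"].unique()[:5]
            raise ValueError(f"proteins without annotation records: {list(missing)}")
        warnings.warn(
            f"dropped {report.removed_unannotated} measurements of proteins "
            "without annotation records",
            stacklevel=2,
        )
    df = measurements.loc[known]
    reviewed = ann["reviewed"].reindex(df["protein_id"]).to_numpy(dtype=bool)
    contaminant = ann["contaminant"].reindex(df["protein_id"]).to_numpy(dtype=bool)
    report.removed_unreviewed = int((~reviewed).sum())
    report.removed_contaminant = int((reviewed & contaminant).sum())
    return df.loc[reviewed & ~contaminant].reset_index(drop=True), report


def read_protein_list(path) -> list[str]:
    """Read a plain-text protein list, one accession per line, '#' comments."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_protein_list(accessions, path) -> None:
    with open(path, "w") as fh:
        for acc in accessions:
            fh.write(f"{acc}\n")


def load_thresholds(path) -> tuple[AnalysisThresholds, dict]:
    """Load :class:`AnalysisThresholds` plus column maps from a YAML file.

    Recognised top-level keys: any AnalysisThresholds field, ``dialect``
    (column-name map) and ``condition_map``.  Returns the thresholds and a
    dict with the remaining reader options.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    names = {f.name for f in fields(AnalysisThresholds)}
    thresholds = AnalysisThresholds(**{k: v for k, v in cfg.items() if k in names})
    extras = {k: v for k, v in cfg.items() if k not in names}
    return thresholds, extras
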