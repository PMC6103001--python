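"""Synthetic peptide-level study generator with known ground truth.

Emulates the 7-tissue x 2-condition x 3-replicate DIA design so that every
downstream stage (rollup, detection, enrichment, regulation, clustering) can
be tested against planted truth.  The intensity model is multiplicative:

    I(p, j, t, c, r) = A_p * E_{p,t} * G_{p,c,t} * F_j * N

with protein base abundance A_p lognormal, tissue-enrichment factor E (planted
fold in target tissues, 1 elsewhere and always 1 in brain), condition effect
G = 2**log2_effect for planted (protein, tissue) pairs in the case condition,
a peptide response factor F_j fixed per peptide across all cells, and
independent lognormal replicate noise N with a configured coefficient of
variation.  Measurements are then thinned by random plus abundance-dependent
(logistic in log2 intensity) dropout.

Each replicate stands for a pool of animals; pooling is modelled implicitly,
its biological variance folded into the single replicate CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BRAIN_TISSUES, CASE, CONTROL, TISSUES

__all__ = [
    "DropoutConfig",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_study",
    "truth_writer",
    "truth_reader",
]


@dataclass(frozen=True)
class DropoutConfig:
    """Missingness model: p = random_rate + (1-random_rate) * logistic term.

    The abundance-dependent term rises as log2 intensity falls below
    ``midpoint_log2`` with steepness ``abundance_dependent_slope``; slope 0
    disables it.
    """

    random_rate: float = 0.0
    abundance_dependent_slope: float = 0.0
    midpoint_log2: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.random_rate < 1.0:
            raise ValueError("dropout random_rate must lie in [0, 1)")
        if self.abundance_dependent_slope < 0:
            raise ValueError("abundance_dependent_slope must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_study`.

    Defaults reproduce the study conditions: 7 tissues (4 of them brain),
    3 replicates per tissue and condition, multi-peptide proteins with
    lognormal base abundance (log2 mean 20 ~ 1e6 arbitrary units, log2 sd 2),
    peptide-specific response factors of log2 sd 1, and 10% replicate CV.
    """

    n_proteins: int = 100
    peptides_per_protein: int | tuple[int, int] = (2, 6)
    base_abundance: tuple[float, float] = (20.0, 2.0)  # log2 mean, log2 sd
    peptide_response_sd: float = 1.0  # log2 sd of per-peptide response factor
    replicate_cv: float = 0.1
    dropout: DropoutConfig = field(default_factory=DropoutConfig)
    planted_enriched: tuple[tuple[int, tuple[str, ...], float], ...] = ()
    planted_regulated: tuple[tuple[int, str, float], ...] = ()
    contaminant_fraction: float = 0.0
    unreviewed_fraction: float = 0.0
    tissues: tuple[str, ...] = TISSUES
    brain_tissues: tuple[str, ...] = BRAIN_TISSUES
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if not 0.0 <= self.unreviewed_fraction < 1.0:
            raise ValueError("unreviewed_fraction must lie in [0, 1)")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        unknown = set(self.brain_tissues) - set(self.tissues)
        if unknown:
            raise ValueError(f"brain_tissues not in tissue panel: {unknown}")
        n_flagged = self._n_contaminant + self._n_unreviewed
        for p, target_tissues, fold in self.planted_enriched:
            self._check_planted_protein(p, n_flagged)
            if fold <= 1:
                raise ValueError("planted enrichment fold must be > 1")
            bad = set(target_tissues) & set(self.brain_tissues)
            if bad:
                raise ValueError(f"cannot plant enrichment in brain tissues: {bad}")
            if not set(target_tissues) <= set(self.tissues):
                raise ValueError(f"unknown target tissue in {target_tissues}")
        for p, tissue, _effect in self.planted_regulated:
            self._check_planted_protein(p, n_flagged)
            if tissue not in self.tissues:
                raise ValueError(f"unknown tissue {tissue!r} in planted_regulated")

    # contaminant/unreviewed flags are assigned from the tail of the protein
    # index so planted (head-indexed) sets stay disjoint from them
    @property
    def _n_contaminant(self) -> int:
        return int(round(self.n_proteins * self.contaminant_fraction))

    @property
    def _n_unreviewed(self) -> int:
        return int(round(self.n_proteins * self.unreviewed_fraction))

    def _check_planted_protein(self, p: int, n_flagged: int) -> None:
        if not 0 <= p < self.n_proteins:
            raise ValueError(f"planted protein index {p} out of range")
        if p >= self.n_proteins - n_flagged:
            raise ValueError(
                f"planted protein index {p} collides with contaminant/unreviewed "
                "tail indices"
            )


@dataclass
class SimulationTruth:
    """Planted ground truth paired with a generated peptide table.

    tissue_means
        True control-condition protein mean intensity per (protein, tissue),
        linear scale, noise-free (A_p * E_{p,t}).
    enrichment
        One row per planted enrichment: protein, tissue, true fold vs the
        maximum brain tissue (equal to the planted fold, as brain E == 1).
    regulation
        One row per planted condition effect: protein, tissue, log2_effect.
    dropout
        Per pre-dropout measurement: key columns plus a ``dropped`` flag.
    """

    tissue_means: pd.DataFrame
    enrichment: pd.DataFrame
    regulation: pd.DataFrame
    dropout: pd.DataFrame


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def _peptides_range(spec) -> tuple[int, int]:
    if isinstance(spec, int):
        return spec, spec
    lo, hi = spec
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid peptides_per_protein spec {spec!r}")
    return lo, hi


def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (measurements, annotations, truth) for one synthetic study.

    Randomness is counter-based: each protein draws from its own Philox
    stream keyed by (seed, protein index) with a fixed intra-protein draw
    order, so the same (config, seed) is byte-identical and individual
    proteins can be regenerated without simulating the rest.
    """
    tissues = list(config.tissues)
    ids = _protein_ids(config.n_proteins)
    pep_lo, pep_hi = _peptides_range(config.peptides_per_protein)
    n_rep = config.n_replicates
    n_cells = len(tissues) * 2 * n_rep
    mu_log2, sd_log2 = config.base_abundance
    sigma_noise = float(np.sqrt(np.log1p(config.replicate_cv**2)))  # ln-scale sd

    enriched_by_protein: dict[int, dict[str, float]] = {}
    for p, target_tissues, fold in config.planted_enriched:
        enriched_by_protein.setdefault(p, {}).update(
            {t: float(fold) for t in target_tissues}
        )
    regulated_by_protein: dict[int, dict[str, float]] = {}
    for p, tissue, effect in config.planted_regulated:
        regulated_by_protein.setdefault(p, {})[tissue] = float(effect)

    # one (tissue, condition, replicate) grid reused for every peptide
    grid_tissue = np.repeat(tissues, 2 * n_rep)
    grid_condition = np.tile(np.repeat([CONTROL, CASE], n_rep), len(tissues))
    grid_replicate = np.tile(np.arange(1, n_rep + 1), len(tissues) * 2)

    frames: list[pd.DataFrame] = []
    mean_rows: list[tuple[str, str, float]] = []
    for p_idx, protein_id in enumerate(ids):
        rng = np.random.Generator(
            np.random.Philox(key=(np.uint64(config.seed) << np.uint64(32))
                             + np.uint64(p_idx))
        )
        # fixed draw order: n_peptides, A_p, F_j, noise, dropout uniforms
        n_pep = int(rng.integers(pep_lo, pep_hi + 1))
        abundance = float(2.0 ** rng.normal(mu_log2, sd_log2))
        response = 2.0 ** rng.normal(0.0, config.peptide_response_sd, size=n_pep)
        if sigma_noise > 0:
            noise = rng.lognormal(
                -0.5 * sigma_noise**2, sigma_noise, size=(n_pep, n_cells)
            )
        else:
            noise = np.ones((n_pep, n_cells))
        dropout_u = rng.random(size=(n_pep, n_cells))

        enrich = np.array(
            [enriched_by_protein.get(p_idx, {}).get(t, 1.0) for t in grid_tissue]
        )
        effects = regulated_by_protein.get(p_idx, {})
        condition_factor = np.array(
            [
                2.0 ** effects.get(t, 0.0) if c == CASE else 1.0
                for t, c in zip(grid_tissue, grid_condition)
            ]
        )
        cell_mean = abundance * enrich * condition_factor  # (n_cells,)
        intensity = response[:, None] * cell_mean[None, :] * noise

        dropout = config.dropout
        p_drop = np.full(intensity.shape, dropout.random_rate)
        if dropout.abundance_dependent_slope > 0:
            from scipy.special import expit

            p_abund = expit(
                -dropout.abundance_dependent_slope
                * (np.log2(intensity) - dropout.midpoint_log2)
            )
            p_drop = p_drop + (1.0 - p_drop) * p_abund
        dropped = dropout_u < p_drop

        frames.append(
            pd.DataFrame(
                {
                    "protein_id": protein_id,
                    "peptide_id": np.repeat(
                        [f"{protein_id}_pep{j}" for j in range(n_pep)], n_cells
                    ),
                    "tissue": np.tile(grid_tissue, n_pep),
                    "condition": np.tile(grid_condition, n_pep),
                    "replicate": np.tile(grid_replicate, n_pep),
                    "intensity": intensity.ravel(),
                    "dropped": dropped.ravel(),
                }
            )
        )
        for t in tissues:
            mean_rows.append(
                (protein_id, t,
                 abundance * enriched_by_protein.get(p_idx, {}).get(t, 1.0))
            )

    table = pd.concat(frames, ignore_index=True)
    dropout_table = table[list(table.columns[:5]) + ["dropped"]].copy()
    measurements = (
        table.loc[~table["dropped"]]
        .drop(columns="dropped")
        .reset_index(drop=True)
    )

    n_cont = config._n_contaminant
    n_unrev = config._n_unreviewed
    contaminant = np.zeros(config.n_proteins, dtype=bool)
    reviewed = np.ones(config.n_proteins, dtype=bool)
    if n_cont:
        contaminant[-n_cont:] = True
    if n_unrev:
        reviewed[-(n_cont + n_unrev): config.n_proteins - n_cont] = False
    genes = [
        f"Krt{i}" if contaminant[i] else f"Gene{i}"
        for i in range(config.n_proteins)
    ]
    annotations = pd.DataFrame(
        {
            "protein_id": ids,
            "gene": genes,
            "reviewed": reviewed,
            "contaminant": contaminant,
        }
    )

    truth = SimulationTruth(
        tissue_means=pd.DataFrame(
            mean_rows, columns=["protein_id", "tissue", "true_mean"]
        ),
        enrichment=pd.DataFrame(
            [
                (ids[p], t, fold)
                for p, targets, fold in config.planted_enriched
                for t in targets
            ],
            columns=["protein_id", "tissue", "fold"],
        ),
        regulation=pd.DataFrame(
            [(ids[p], t, eff) for p, t, eff in config.planted_regulated],
            columns=["protein_id", "tissue", "log2_effect"],
        ),
        dropout=dropout_table,
    )
    return measurements, annotations, truth


def truth_writer(truth: SimulationTruth, path) -> None:
    """Write a SimulationTruth as a single sectioned TSV (lossless round trip)."""
    sections = {
        "tissue_mean": truth.tissue_means.rename(columns={"true_mean": "value"}),
        "enrichment": truth.enrichment.rename(columns={"fold": "value"}),
        "regulation": truth.regulation.rename(columns={"log2_effect": "value"}),
    }
    rows = []
    for record_type, df in sections.items():
        for _, row in df.iterrows():
            rows.append(
                (record_type, row["protein_id"], row["tissue"], repr(row["value"]))
            )
    pd.DataFrame(
        rows, columns=["record_type", "protein_id", "tissue", "value"]
    ).to_csv(path, sep="\t", index=False)


def truth_reader(path) -> SimulationTruth:
    """Read a truth TSV written by :func:`truth_writer` (dropout not persisted)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"protein_id": str, "tissue": str}
    )
    df["value"] = df["value"].astype(float)

    def section(name: str, value_col: str) -> pd.DataFrame:
        sub = df.loc[df["record_type"] == name, ["protein_id", "tissue", "value"]]
        return sub.rename(columns={"value": value_col}).reset_index(drop=True)

    return SimulationTruth(
        tissue_means=section("tissue_mean", "true_mean"),
        enrichment=section("enrichment", "fold"),
        regulation=section("regulation", "log2_effect"),
        dropout=pd.DataFrame(
            columns=["protein_id", "peptide_id", "tissue", "condition",
                     "replicate", "dropped"]
        ),
    )
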