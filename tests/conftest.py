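import pandas as pd
import pytest

from neuraxprot.io import CASE, CONTROL


def make_measurements(rows):
    """Build a canonical measurement frame from (protein, peptide, tissue,
    condition, replicate, intensity) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "peptide_id", "tissue", "condition", "replicate",
            "intensity",
        ],
    )


def cell_block(protein, peptide, tissue, intensities, condition=CONTROL):
    """One peptide across replicates 1..n in a single tissue/condition."""
    return [
        (protein, peptide, tissue, condition, r, v)
        for r, v in enumerate(intensities, start=1)
    ]


@pytest.fixture
def simple_study():
    """Two proteins in two tissues, complete 3-replicate coverage."""
    rows = []
    rows += cell_block("P1", "P1_a", "DRG", [100.0, 110.0, 90.0])
    rows += cell_block("P1", "P1_b", "DRG", [300.0, 310.0, 290.0])
    rows += cell_block("P1", "P1_a", "ACC", [10.0, 11.0, 9.0])
    rows += cell_block("P1", "P1_b", "ACC", [30.0, 31.0, 29.0])
    rows += cell_block("P2", "P2_a", "DRG", [50.0, 55.0, 45.0])
    rows += cell_block("P2", "P2_a", "ACC", [48.0, 52.0, 50.0])
    rows += cell_block("P1", "P1_a", "DRG", [200.0, 220.0, 180.0], condition=CASE)
    rows += cell_block("P1", "P1_b", "DRG", [600.0, 620.0, 580.0], condition=CASE)
    rows += cell_block("P2", "P2_a", "DRG", [50.0, 55.0, 45.0], condition=CASE)
    return make_measurements(rows)


@pytest.fixture
def annotations():
    return pd.DataFrame(
        {
            "protein_id": ["P1", "P2", "P3", "P4"],
            "gene": ["Gria1", "Scn10a", "Krt5", "Alb"],
            "reviewed": [True, True, True, False],
            "contaminant": [False, False, True, False],
        }
    )
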