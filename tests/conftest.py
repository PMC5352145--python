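import numpy as np
import pandas as pd
import pytest

from panelqg import io_formats as iof
from panelqg import synthetic_data as sd


@pytest.fixture
def toy_events() -> iof.EventTable:
    """Two lines x two sexes x two replicate tubes, no censoring."""
    rows = []
    rng = np.random.default_rng(7)
    for lid, base in [("L001", 96.0), ("L002", 144.0)]:
        for sex in ("M", "F"):
            for rep in ("R1", "R2"):
                for i in range(10):
                    t = base + 12.0 * rng.integers(-2, 3)
                    rows.append((lid, sex, rep, t, "dead", "pathogen"))
    df = pd.DataFrame(rows, columns=iof.EVENT_COLUMNS)
    return iof.EventTable(df, scoring_grid_h=12.0)


@pytest.fixture
def small_panel() -> tuple:
    spec = sd.ArchitectureSpec(n_lines=20, n_markers=50, seed=11)
    return sd.simulate_panel(spec), spec


@pytest.fixture
def gene_models() -> iof.GeneModelSet:
    """One plus-strand gene with CDS/UTR/intron structure, one minus-strand
    gene overlapping it, on a 10 kb chromosome."""
    genes = pd.DataFrame([
        {"gene_id": "gA", "chrom": "2L", "strand": "+",
         "start": 1000, "end": 3000},
        {"gene_id": "gB", "chrom": "2L", "strand": "-",
         "start": 2500, "end": 4000},
        {"gene_id": "gC", "chrom": "2L", "strand": "+",
         "start": 7000, "end": 8000},
    ])
    feats = pd.DataFrame([
        {"gene_id": "gA", "chrom": "2L", "type": "utr5",
         "start": 1000, "end": 1100, "ref_codon": None, "codon_pos": None},
        {"gene_id": "gA", "chrom": "2L", "type": "exon_cds",
         "start": 1100, "end": 1400, "ref_codon": "GGA", "codon_pos": 1},
        {"gene_id": "gA", "chrom": "2L", "type": "intron",
         "start": 1400, "end": 2600, "ref_codon": None, "codon_pos": None},
        {"gene_id": "gA", "chrom": "2L", "type": "exon_cds",
         "start": 2600, "end": 2900, "ref_codon": "GGA", "codon_pos": 3},
        {"gene_id": "gA", "chrom": "2L", "type": "utr3",
         "start": 2900, "end": 3000, "ref_codon": None, "codon_pos": None},
    ])
    return iof.GeneModelSet(genes, feats)
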