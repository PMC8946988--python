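import numpy as np
import pandas as pd
import pytest

from bivalint import diffexpr, synthetic_data
from bivalint.io_formats import CountExperiment, GeneAnnotation


@pytest.fixture(scope="session")
def default_truth():
    """Default-scale planted truth shared across recovery tests."""
    return synthetic_data.generate_truth(2000, seed=7)


@pytest.fixture(scope="session")
def default_fit(default_truth):
    """Factorial NB fit on the default synthetic experiment."""
    truth, _ = default_truth
    expt = synthetic_data.generate_counts(truth, n_reps=3, seed=8)
    return diffexpr.FactorialFit(diffexpr.filter_low_counts(expt))


@pytest.fixture
def small_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "tss": [10_000, 50_000, 20_000],
            },
            index=pd.Index(["PGR", "ESR1", "AFF3"], name="gene"),
        )
    )


def make_expt(counts: np.ndarray, genes=None, n_reps: int | None = None) -> CountExperiment:
    """Tiny 2x2 experiment from a gene x sample array (samples grouped by cell)."""
    counts = np.asarray(counts, dtype=np.int64)
    n_samples = counts.shape[1]
    if n_reps is None:
        n_reps = n_samples // 4
    cells = [("ctrl", "veh"), ("ctrl", "e2"), ("kd", "veh"), ("kd", "e2")]
    rows = []
    for kd, tr in cells:
        for r in range(1, n_reps + 1):
            rows.append((f"{kd}_{tr}_{r}", kd, tr, r))
    rows = rows[:n_samples]
    design = pd.DataFrame(
        rows, columns=["sample", "knockdown", "treatment", "replicate"]
    ).set_index("sample")
    if genes is None:
        genes = [f"G{i}" for i in range(counts.shape[0])]
    return CountExperiment(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=design.index),
        design,
    )
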