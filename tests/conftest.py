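import numpy as np
import pandas as pd
import pytest

from ridgemotif import Peak, Pwm
from ridgemotif.io_formats import ExpressionTable
from ridgemotif.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    return SimulationConfig(seed=7, n_peaks=60, n_groups=4, n_genes=150,
                            n_cells=150, n_mice=2, n_clones_per_phenotype=120)


@pytest.fixture
def consensus_pwm():
    """A sharp 8-mer PWM whose consensus is ACGTACGT."""
    mat = np.full((8, 4), 0.02)
    for i, b in enumerate("ACGTACGT"):
        mat[i, "ACGT".index(b)] = 0.94
    return Pwm(name="M_test", matrix=mat, tf_gene="TfTest", family="FamT")


@pytest.fixture
def expr_three_pops():
    samples = [f"{p}_r{r}" for p in ("neg", "recent", "stable") for r in (1, 2)]
    values = pd.DataFrame(
        np.ones((3, 6)), index=["GeneHi", "GeneEdge", "GeneLo"], columns=samples
    )
    values.loc["GeneHi", ["stable_r1", "stable_r2"]] = 5.0
    values.loc["GeneLo"] = 0.2
    return ExpressionTable(values=values,
                           populations={s: s.rsplit("_", 1)[0] for s in samples})


def random_peaks(rng, n, n_chroms=2, span=5000, max_w=400):
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(50, max_w))
        summit = int(rng.integers(start, start + width))
        peaks.append(Peak(f"chr{rng.integers(1, n_chroms + 1)}", start, start + width,
                          summit, name=f"p{i}"))
    return peaks
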