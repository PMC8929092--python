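import numpy as np
import pandas as pd
import pytest

from hhmap.model import (
    Affection,
    Call,
    GenotypeMatrix,
    Individual,
    MarkerPanel,
    Pedigree,
)


def make_panel(chrom_markers, spacing_cm=1.0, build="testbuild"):
    """Panel with evenly spaced markers: {chrom: n_markers}."""
    rows = []
    for chrom, n in chrom_markers.items():
        for j in range(n):
            cm = j * spacing_cm
            rows.append((f"rs{chrom}_{j}", str(chrom), int(cm * 1e6) + j + 1, cm, "A", "G"))
    return MarkerPanel(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "bp", "cm", "a1", "a2"]),
        genome_build=build,
    )


def make_matrix(panel, calls_by_sample):
    """Matrix from {sample_id: list of Call/int}."""
    sample_ids = list(calls_by_sample)
    calls = np.array([list(map(int, calls_by_sample[s])) for s in sample_ids], dtype=np.int8)
    return GenotypeMatrix(panel, sample_ids, calls)


def flat_pedigree(sample_ids, family_id="FAM1", affected=()):
    """All-founder pedigree; ids in `affected` are affected, rest unaffected."""
    return Pedigree(
        Individual(
            s,
            family_id,
            None,
            None,
            "1",
            Affection.AFFECTED if s in affected else Affection.UNAFFECTED,
            True,
        )
        for s in sample_ids
    )


def random_matrix(rng, panel, n_samples, missing_rate=0.1):
    calls = rng.integers(0, 3, size=(n_samples, panel.n_markers), dtype=np.int8)
    calls[rng.random(calls.shape) < missing_rate] = Call.MISSING.value
    ids = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(panel, ids, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return make_panel({"1": 51})


HOM_REF = int(Call.HOM_REF)
HET = int(Call.HET)
HOM_ALT = int(Call.HOM_ALT)
MISSING = int(Call.MISSING)
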