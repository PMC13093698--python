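import numpy as np
import pandas as pd
import pytest

from nanofish.io import CountTable, SampleRecord


@pytest.fixture
def small_panel():
    from nanofish.simulate import synth_reference_panel

    return synth_reference_panel(
        n_species=5, n_identical_pairs=1, target_identity_range=(0.80, 0.92),
        amplicon_length=170, seed=11,
    )


def make_count_table(counts: dict, sample_types: dict | None = None,
                     annotations: pd.DataFrame | None = None) -> CountTable:
    """Build a CountTable from {row: {sample: count}} with default metadata."""
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    sample_types = sample_types or {}
    samples = {
        s: SampleRecord(s, f"BC{i + 1:02d}", sample_types.get(s, "environmental"))
        for i, s in enumerate(frame.columns)
    }
    if annotations is None:
        annotations = pd.DataFrame({"species": list(frame.index)}, index=frame.index)
    return CountTable(frame, annotations, samples)


@pytest.fixture
def count_table_factory():
    return make_count_table
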