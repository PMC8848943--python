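import numpy as np
import pytest

from pmdda import FeatureTable, SampleInfo, SynthConfig, simulate_dataset


def make_table(mz, rt, study, blank=None, ids=None):
    """Build a small FeatureTable from per-feature study/blank intensity rows."""
    study = np.atleast_2d(np.asarray(study, dtype=float))
    n, n_study = study.shape
    samples = [SampleInfo(f"study{i + 1}", "study") for i in range(n_study)]
    inten = study
    if blank is not None:
        blank = np.atleast_2d(np.asarray(blank, dtype=float))
        samples += [SampleInfo(f"blank{i + 1}", "blank") for i in range(blank.shape[1])]
        inten = np.hstack([study, blank])
    if ids is None:
        ids = [f"F{i + 1}" for i in range(n)]
    return FeatureTable(ids, mz, rt, inten, samples)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (300 compounds x 3 ions, 5+5 samples)."""
    return simulate_dataset(SynthConfig(seed=101))


@pytest.fixture()
def qc_toy_table():
    """Hand-enumerated 10-feature table: 2 RT-range violators, 2 blank
    fold-change violators, 2 RSD violators, 4 clean survivors (F7-F10)."""
    return make_table(
        mz=[100 + i for i in range(10)],
        rt=[25, 940, 100, 200, 300, 400, 500, 600, 700, 800],
        study=[
            [100, 100, 100],     # F1: rt 25 s, below range
            [100, 100, 100],     # F2: rt 940 s, above range
            [100, 100, 100],     # F3: fold change 2 vs blank
            [299, 299, 299],     # F4: fold change 2.99 vs blank
            [50, 100, 150],      # F5: RSD 50%
            [10, 100, 190],      # F6: RSD 90%
            [100, 101, 99],      # F7: clean
            [300, 300, 300],     # F8: fold change exactly 3 (boundary, kept)
            [1000, 1010, 990],   # F9: clean
            [500, 500, 500],     # F10: clean
        ],
        blank=[
            [0, 0], [0, 0],
            [50, 50], [100, 100],
            [0, 0], [0, 0],
            [0, 0], [100, 100], [10, 10], [0, 0],
        ],
    )
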