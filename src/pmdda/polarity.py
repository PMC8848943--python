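"""Cross-polarity feature linking.

A compound ionising in both ESI modes appears as [M+H]+ in positive and
[M-H]- in negative mode; those two features differ by two proton masses
(2 x 1.00728 = 2.0146 Da, nominally quoted as "2.02 Da") and co-elute.
Candidate same-compound pairs are therefore features whose positive-mode
m/z exceeds a negative-mode m/z by ~2.015 Da within an RT tolerance.

The default mass window [2.0046, 2.0246] Da is 0.01 Da around the
electron-corrected proton-pair difference, wide enough to cover both the
physical value (2.0146) and the nominal 2.02 convention. The linkage is
only meaningful for runs acquired on the same column and gradient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FeatureTable

#: [M+H]+ minus [M-H]-: two electron-corrected proton masses
PROTON_PAIR_DELTA = 2.01456

LINK_COLUMNS = [
    "pos_id", "neg_id", "mz_pos", "mz_neg", "delta_mz", "rt_pos", "rt_neg", "delta_rt",
]


def link_polarities(
    pos_table: FeatureTable,
    neg_table: FeatureTable,
    pmd_nominal: float = 2.02,
    pmd_window: float | None = None,
    rt_tol: float = 10.0,
) -> pd.DataFrame:
    """All (positive, negative) feature pairs consistent with one neutral.

    A pair links when ``mz_pos - mz_neg`` lies within the mass window and
    ``|rt_pos - rt_neg| <= rt_tol`` (boundary inclusive). With
    ``pmd_window=None`` the window is [2.0046, 2.0246] Da (see module
    docstring); otherwise it is ``pmd_nominal +/- pmd_window``. A feature
    may take part in several links. Result sorted by positive-mode RT.
    """
    if pmd_window is None:
        lo, hi = PROTON_PAIR_DELTA - 0.01, PROTON_PAIR_DELTA + 0.01
    else:
        lo, hi = pmd_nominal - pmd_window, pmd_nominal + pmd_window

    rows = []
    order = np.argsort(neg_table.mz, kind="stable")
    neg_mz = neg_table.mz[order]
    for i in range(pos_table.n_features):
        d = pos_table.mz[i] - neg_mz
        cand = order[(d >= lo) & (d <= hi)]
        for j in cand:
            drt = pos_table.rt[i] - neg_table.rt[j]
            if abs(drt) <= rt_tol:
                rows.append(
                    {
                        "pos_id": str(pos_table.ids[i]),
                        "neg_id": str(neg_table.ids[j]),
                        "mz_pos": pos_table.mz[i],
                        "mz_neg": neg_table.mz[j],
                        "delta_mz": pos_table.mz[i] - neg_table.mz[j],
                        "rt_pos": pos_table.rt[i],
                        "rt_neg": neg_table.rt[j],
                        "delta_rt": drt,
                    }
                )
    df = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return df.sort_values(["rt_pos", "pos_id", "neg_id"], kind="stable").reset_index(drop=True)
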