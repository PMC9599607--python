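"""Small published tables shipped for validation runs.

Currently: the TEM-1 β-lactamase single-insertion benchmark — 10 in
silico insertion mutants of PDB entry 1ZG6 with AMP-resistance fitness
values and the rigidity metric scores reported for them.

Column naming note: in the published table the headers of the TLCCS and
RDSM1 score columns are transposed relative to their contents.  The
column printed under "TLCCS" holds values of magnitude 1e-4 — RDSM-like
scores, not [0,1] cluster-overlap scores — while the column printed
under "RDSM1" holds values around 0.65–0.70, which are TLCCS-like; the
published per-metric correlation row confirms this assignment (the
1e-4-valued column reproduces R = −0.423, printed for RDSM1, and the
0.65–0.70-valued column reproduces R = 0.239, printed for TLCCS).  The
frame returned here names each column by its *content*.
"""

from __future__ import annotations

import pandas as pd

_TEM1_ROWS = [
    # position, inserted residue, fitness, tlccs, rdsm1, rdsm2, rdsm3, rdsm5
    (37, "Q", 0.164355, 0.655974, 0.00051, 0.000121, 0.000036, 2.01e-6),
    (45, "P", 0.000911, 0.662656, 0.00062, 0.000146, 0.000047, 2.72e-6),
    (89, "V", 0.022674, 0.651466, 0.00046, 0.000086, 0.000022, 1.10e-6),
    (130, "C", 0.001328, 0.672744, 0.00033, 0.000109, 0.000031, 1.67e-6),
    (148, "K", 0.237953, 0.669186, 0.00008, 0.000097, 0.000027, 1.50e-6),
    (150, "V", 0.305583, 0.697794, 0.00011, 0.000062, 0.000016, 8.42e-7),
    (172, "M", 0.435899, 0.676728, 0.00043, 0.000128, 0.000039, 2.22e-6),
    (191, "G", 0.005969, 0.676746, 0.00041, 0.000117, 0.000034, 1.89e-6),
    (210, "G", 0.028093, 0.698456, 0.00036, 0.000099, 0.000028, 1.55e-6),
    (214, "I", 0.083574, 0.673495, 0.00056, 0.000123, 0.000037, 2.08e-6),
]


def tem1_insertion_fitness() -> pd.DataFrame:
    """The TEM-1 (1ZG6) 10-insertion fitness/metric table.

    Columns: ``position``, ``inserted`` (one-letter residue),
    ``fitness`` (AMP-resistance based), and the per-mutant scores
    ``TLCCS``, ``RDSM1``, ``RDSM2``, ``RDSM3``, ``RDSM5`` — named by
    content (see the module docstring for the header-transposition
    note on TLCCS/RDSM1).
    """
    return pd.DataFrame(
        _TEM1_ROWS,
        columns=["position", "inserted", "fitness",
                 "TLCCS", "RDSM1", "RDSM2", "RDSM3", "RDSM5"],
    )
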