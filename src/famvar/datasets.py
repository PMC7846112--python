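"""Bundled reference datasets.

The plasma coagulation panel of the discovery family: measurements for the
10 members with citrated plasma available (3 affected, all on vitamin-K
antagonists at sampling, and 7 unaffected relatives).  Differences in PT,
INR, aPTT, FII and FX between groups are anticoagulant artifacts; the
biologically informative contrasts are f-TFPI (lower in carriers) and
PAI-1 (higher in carriers).
"""

from __future__ import annotations

import pandas as pd

# (parameter, units) in panel column order
_PARAMETERS = [
    ("PT", "%"),
    ("INR", "ratio"),
    ("aPTT", "sec"),
    ("fibrinogen", "g/L"),
    ("FII", "%"),
    ("FV", "%"),
    ("FX", "%"),
    ("f-TFPI", "ng/mL"),
    ("PAI-1", "IU/mL"),
]

# subject_id, status, then values in _PARAMETERS order
_ROWS = [
    ("305000", "case", 30, 2.55, 49.5, 4.16, 27, 64, 13, 7.4, 15),
    ("305001", "case", 26, 2.88, 46.7, 4.30, 18, 76, 9, 2.9, 16),
    ("305002", "case", 33, 2.29, 40.1, 3.87, 29, 96, 14, 9.5, 34),
    ("305004", "control", 98, 1.01, 32.4, 4.93, 99, 86, 105, 17.2, 1),
    ("305006", "control", 93, 1.04, 39.0, 1.97, 82, 91, 96, 17.7, 4),
    ("305007", "control", 100, 1.00, 35.4, 2.62, 107, 75, 122, 15.1, 1),
    ("305010", "control", 114, 0.93, 34.3, 3.17, 103, 117, 102, 17.1, 2),
    ("305013", "control", 104, 0.98, 35.1, 3.13, 97, 95, 90, 21.9, 4),
    ("305014", "control", 98, 1.01, 33.9, 2.66, 102, 102, 98, 20.7, 5),
    ("305015", "control", 106, 0.97, 37.8, 3.26, 95, 91, 95, 12.3, 6),
]


def family_coagulation_panel() -> pd.DataFrame:
    """Tidy plasma table: subject_id, status, parameter, value, units."""
    records = []
    for row in _ROWS:
        subject, status, *values = row
        for (param, units), value in zip(_PARAMETERS, values):
            records.append((subject, status, param, float(value), units))
    return pd.DataFrame(
        records, columns=["subject_id", "status", "parameter", "value", "units"]
    )
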