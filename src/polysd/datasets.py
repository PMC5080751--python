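"""Published per-family offspring counts for the A. burtoni cross panel.

Offspring sex counts and inferred sex-determination systems for the two
ddRAD discovery families and the 25 SSR confirmation families of the
*Astatotilapia burtoni* mapping panel.  These printed counts are inputs to
the sex-ratio statistics (pooled chi-square against 1:1 and Welch's t
between system classes); the per-family genotype data behind the p-value
columns are not part of this package.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # family, sire, dam, males, females, system
    ("RAD1", "1", "1", 12, 12, "LG13 ZW"),
    ("RAD2", "2", "2", 9, 8, "LG5-14 XY"),
    ("1", "1", "1", 10, 36, "LG13 ZW"),
    ("2", "3", "3", 8, 8, "LG13 ZW"),
    ("3", "3", "3", 9, 8, "LG13 ZW"),
    ("4", "4", "4", 6, 26, "LG13 ZW"),
    ("5", "5", "5", 4, 6, "LG13 ZW"),
    ("6", "6", "6", 4, 10, "LG13 ZW"),
    ("7", "6", "7", 10, 9, "LG13 ZW"),
    ("8", "7", "8", 2, 13, "LG13 XY"),
    ("9", "7", "9", 16, 22, "LG13 XY"),
    ("10", "8", "10", 12, 14, "LG5-14 XY"),
    ("11", "8", "11", 12, 10, "LG5-14 XY"),
    ("12", "8", "12", 15, 11, "LG5-14 XY"),
    ("13", "8", "13", 12, 7, "LG5-14 XY"),
    ("14", "8", "14", 4, 2, "LG5-14 XY"),
    ("15", "9", "15", 12, 10, "LG5-14 XY"),
    ("16", "9", "16", 13, 8, "LG5-14 XY"),
    ("17", "9", "17", 15, 8, "LG5-14 XY"),
    ("18", "10", "18", 11, 5, "LG5-14 XY"),
    ("19", "11", "19", 5, 4, "LG13 XY + LG5-14 XY"),
    ("20", "12", "20", 9, 11, "Unknown"),
    ("21", "6", "21", 12, 26, "Unknown"),
    ("22", "13", "22", 7, 9, "Unknown"),
    ("23", "13", "23", 14, 17, "Unknown"),
    ("24", "13", "24", 20, 23, "Unknown"),
    ("25", "13", "25", 22, 20, "Unknown"),
]


def burtoni_families() -> pd.DataFrame:
    """Per-family counts as a DataFrame with a derived ``ratio`` column."""
    df = pd.DataFrame(_ROWS, columns=["family", "sire", "dam", "males", "females", "system"])
    df["ratio"] = df["males"] / (df["males"] + df["females"])
    return df
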