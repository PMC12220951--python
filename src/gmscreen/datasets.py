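"""Small packaged reference tables.

The screen's consensus-hit worked example: per-gene significance calls
across the four phenotypic readouts (γH2AX and micronuclei in U2OS and
MCF10A).  The five hit genes and the 3-of-4 / 4-of-4 split are as reported
for the screen (G6PC3 and SMC4 scored in both markers in both cell lines;
CCDC108, TEX35 and URM1 in three readouts); the specific negative readout
of the 3-of-4 genes is a synthetic stand-in chosen as the MCF10A
micronuclei readout, since the published panel does not survive text
extraction.  The consensus-hit identities do not depend on that choice.
"""

from __future__ import annotations

import pandas as pd

READOUT_COLUMNS = [
    ("gH2AX", "U2OS"),
    ("gH2AX", "MCF10A"),
    ("micronuclei", "U2OS"),
    ("micronuclei", "MCF10A"),
]

_SCREEN_CALLS = {
    "G6PC3":   (True, True, True, True),
    "SMC4":    (True, True, True, True),
    "CCDC108": (True, True, True, False),
    "TEX35":   (True, True, True, False),
    "URM1":    (True, True, True, False),
    # representative sub-threshold genes from the screened library
    "BLM":     (True, True, False, False),
    "EXO5":    (True, False, False, False),
    "RECQL5":  (False, False, False, False),
}


def screen_readout_calls() -> pd.DataFrame:
    """Gene x readout significance flags for the consensus-hit worked example.

    Returns a boolean DataFrame indexed by gene with one column per
    (marker, cell line) readout.  Applying the >=3-of-4 consensus rule
    yields the screen's five hits.  Partially synthetic — see module
    docstring.
    """
    df = pd.DataFrame.from_dict(_SCREEN_CALLS, orient="index")
    df.columns = pd.MultiIndex.from_tuples(READOUT_COLUMNS, names=["marker", "cell_line"])
    df.index.name = "gene"
    return df
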