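"""Packaged published summary values used as demonstration inputs.

These are study-reported totals (family-size distribution of conserved
miRNA families; library read counts) for the Tibetan naked carp
miRNAome.  The package uses them to exercise its bookkeeping — e.g.
checking that a family-size histogram sums to the reported family total
and that the printed clean-read percentage is consistent with the printed
read counts.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    path = importlib.resources.files("mirseed.data").joinpath(name)
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def family_sizes() -> pd.Series:
    """Reported family-size distribution: size -> number of families."""
    df = _read("reported_family_sizes.tsv")
    return df.set_index("size")["n_families"]


def read_counts() -> dict[str, float]:
    """Reported library read totals keyed by quantity name."""
    df = _read("reported_read_counts.tsv")
    return dict(zip(df["quantity"], df["value"]))
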