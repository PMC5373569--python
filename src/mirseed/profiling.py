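"""Nucleotide-bias statistics and expression profiling of called miRNAs.

Composition profiles report, per 5'-anchored position, the base fractions
among miRNAs long enough to cover that position, plus a first-nucleotide
breakdown restricted to the 20-24 nt lengths where miRNAs concentrate.
Expression tables carry per-replicate counts, arithmetic means over
replicates, log-decade abundance bins and pairwise replicate correlations
of log10(count+1).
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import to_rna
from .known_annotation import MiRNARecord

#: lower-inclusive log-decade abundance bins on the mean count
BIN_EDGES = [10, 100, 1000, 10000]
BIN_LABELS = ["<10", "10-100", "100-1k", "1k-10k", ">10k"]

_BASES_RNA = ["A", "C", "G", "U"]


def composition(mirnas: Sequence[MiRNARecord]) -> dict[str, pd.DataFrame]:
    """Per-position and first-base (by length, 20-24 nt) base fractions.

    Positions are 1-based from the 5' end; a miRNA contributes to a
    position only if it is long enough to cover it, so every row of
    ``per_position`` sums to 1.
    """
    seqs = [to_rna(m.mature_seq) for m in mirnas]
    max_len = max((len(s) for s in seqs), default=0)
    rows = []
    for pos in range(1, max_len + 1):
        counts = Counter(s[pos - 1] for s in seqs if len(s) >= pos)
        n = sum(counts.values())
        rows.append(
            {"position": pos, **{b: counts.get(b, 0) / n for b in _BASES_RNA}}
        )
    per_position = pd.DataFrame(rows).set_index("position") if rows else pd.DataFrame()

    first_rows = []
    for length in range(20, 25):
        here = [s for s in seqs if len(s) == length]
        if not here:
            continue
        counts = Counter(s[0] for s in here)
        first_rows.append(
            {
                "length": length,
                "n": len(here),
                **{b: counts.get(b, 0) / len(here) for b in _BASES_RNA},
            }
        )
    first_base = (
        pd.DataFrame(first_rows).set_index("length") if first_rows else pd.DataFrame()
    )
    return {"per_position": per_position, "first_base_by_length": first_base}


def bin_label(mean_count: float) -> str:
    """Log-decade bin for a mean count.

    Edges 10/100/1000 are lower-inclusive; the top bin is strictly
    "more than 10,000" (a mean of exactly 10,000 stays in 1k-10k).
    """
    if mean_count < 10:
        return "<10"
    if mean_count < 100:
        return "10-100"
    if mean_count < 1000:
        return "100-1k"
    if mean_count <= 10000:
        return "1k-10k"
    return ">10k"


def expression_table(
    mirnas: Sequence[MiRNARecord], replicate_names: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression table plus replicate log-correlation matrix.

    Means are arithmetic over raw replicate counts; correlations are
    Pearson on log10(count+1).
    """
    if not mirnas:
        return pd.DataFrame(), pd.DataFrame()
    n_rep = len(mirnas[0].counts)
    reps = list(replicate_names or [f"rep{i + 1}" for i in range(n_rep)])
    rows = []
    for m in mirnas:
        mean = float(np.mean(m.counts))
        rows.append(
            {
                "name": m.name,
                "provenance": m.provenance,
                "family": m.family,
                **dict(zip(reps, m.counts)),
                "mean": mean,
                "bin": bin_label(mean),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["mean", "name"], ascending=[False, True], kind="stable"
    ).set_index("name")
    logs = np.log10(table[reps].to_numpy(dtype=float) + 1.0)
    corr = pd.DataFrame(np.corrcoef(logs, rowvar=False), index=reps, columns=reps)
    return table, corr


def bin_tally(table: pd.DataFrame) -> pd.Series:
    """Number of miRNAs per abundance bin (sums to the table size)."""
    return table["bin"].value_counts().reindex(BIN_LABELS, fill_value=0)


def top_families(
    table: pd.DataFrame, families: dict[str, str] | None = None, n: int = 20
) -> pd.DataFrame:
    """Family membership tally within the ``n`` highest-mean miRNAs.

    Ties in mean count are broken by name.  ``families`` may override the
    table's own family column.
    """
    ranked = table.reset_index().sort_values(
        ["mean", "name"], ascending=[False, True], kind="stable"
    ).set_index("name")
    top = ranked.head(n)
    fam_of = families or table["family"].to_dict()
    tally = Counter()
    for name in top.index:
        fam = fam_of.get(name)
        tally[fam if fam else "unassigned"] += 1
    out = pd.DataFrame(
        sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["family", "members_in_top"],
    ).set_index("family")
    return out
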