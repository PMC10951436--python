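"""TPM expression quantification and percentile ranking of a focal gene.

Operates on a per-gene count table (gene id, effective length in bases,
one nonnegative integer count column per sequencing run); read alignment
and counting happen upstream of this module.
"""

from __future__ import annotations

import math

import pandas as pd


def validate_count_table(table: pd.DataFrame) -> list[str]:
    """Return the run columns of a count table, validating invariants."""
    if "length" not in table.columns:
        raise ValueError("count table needs a 'length' column")
    runs = [c for c in table.columns if c != "length"]
    if not runs:
        raise ValueError("count table has no run columns")
    if (table["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (table[runs] < 0).any().any():
        raise ValueError("counts must be nonnegative")
    return runs


def tpm(table: pd.DataFrame) -> pd.DataFrame:
    """Transcripts per million for every run column.

    ``TPM_i = 1e6 * (c_i / L_i) / sum_j (c_j / L_j)``; every column of the
    result sums to 1e6.  The table is indexed by gene id with a ``length``
    column and one column per run.
    """
    runs = validate_count_table(table)
    rates = table[runs].div(table["length"], axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"run(s) with all-zero counts: {list(zero.index)}")
    return 1e6 * rates.div(totals, axis=1)


def percentile_rank(mean_tpm: pd.Series, focal_gene: str,
                    method: str = "strict") -> int:
    """Percentile of the focal gene's mean TPM among all genes.

    ``strict`` (default): floor(100 * #{genes strictly below focal} / (N-1)).
    ``midrank``: ties counted half, same floor.
    """
    if focal_gene not in mean_tpm.index:
        raise ValueError(f"focal gene {focal_gene} not in table")
    focal = mean_tpm[focal_gene]
    others = mean_tpm.drop(focal_gene)
    n = len(mean_tpm)
    if n < 2:
        raise ValueError("need >= 2 genes for a percentile")
    if method == "strict":
        below = int((others < focal).sum())
    elif method == "midrank":
        below = float((others < focal).sum()) + 0.5 * float((others == focal).sum())
    else:
        raise ValueError(f"unknown method {method}")
    return int(math.floor(100.0 * below / (n - 1)))


def expression_summary(table: pd.DataFrame, focal_gene: str) -> dict:
    """TPM matrix -> mean across runs -> focal gene percentile."""
    mat = tpm(table)
    mean_tpm = mat.mean(axis=1)
    return {
        "focal_gene": focal_gene,
        "mean_tpm": float(mean_tpm[focal_gene]),
        "percentile": percentile_rank(mean_tpm, focal_gene),
        "n_genes": int(len(mean_tpm)),
        "n_runs": int(mat.shape[1]),
    }
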