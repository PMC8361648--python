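"""Expression post-processing: 2^-ddCt relative quantification and DEG filtering.

Works on two small tabular inputs: a long-format qPCR Ct table
(sample, gene, ct — technical replicates averaged) and a gene × sample
abundance matrix with FPKM semantics plus a sample → group map.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _mean_ct(table: pd.DataFrame, sample: str, gene: str) -> float:
    sel = table[(table["sample"] == sample) & (table["gene"] == gene)]["ct"]
    if sel.empty:
        raise KeyError(f"no Ct value for sample {sample!r}, gene {gene!r}")
    val = float(sel.mean())
    if not math.isfinite(val) or val <= 0:
        raise ValueError(f"invalid Ct for sample {sample!r}, gene {gene!r}: {val}")
    return val


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    test_sample: str,
    calibrator_sample: str,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) − Ct(reference) within each sample; ddCt is the test
    sample's dCt minus the calibrator's; the result is 2^−ddCt (1.0 when
    test equals calibrator).  Technical replicate rows are averaged.
    """
    d_test = _mean_ct(table, test_sample, target) - _mean_ct(table, test_sample, reference)
    d_cal = _mean_ct(table, calibrator_sample, target) - _mean_ct(
        table, calibrator_sample, reference
    )
    return float(2.0 ** -(d_test - d_cal))


def group_fold_change(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    gene: str,
    test_group: str = "mutant",
    control_group: str = "wild_type",
) -> tuple[Optional[float], Optional[float]]:
    """(fold change, log2 fold change) of group means, test over control.

    Returns (None, None) when either group mean is zero — flagged rather
    than reported as infinite.
    """
    test_samples = [s for s, g in groups.items() if g == test_group]
    ctrl_samples = [s for s, g in groups.items() if g == control_group]
    if not test_samples or not ctrl_samples:
        raise ValueError("both groups must be non-empty")
    row = matrix.loc[gene]
    m_test = float(row[test_samples].mean())
    m_ctrl = float(row[ctrl_samples].mean())
    if m_test < 0 or m_ctrl < 0:
        raise ValueError("abundances must be non-negative")
    if m_test == 0 or m_ctrl == 0:
        return None, None
    fc = m_test / m_ctrl
    return fc, math.log2(fc)


def two_group_test(
    matrix: pd.DataFrame, groups: Mapping[str, str],
    test_group: str = "mutant", control_group: str = "wild_type",
) -> pd.DataFrame:
    """Per-gene log2FC and Welch-t p-value table for a small synthetic matrix.

    A convenience for testing the DEG filter; published per-gene p-values
    from a dedicated differential-expression pipeline should be supplied
    directly when available.
    """
    test_samples = [s for s, g in groups.items() if g == test_group]
    ctrl_samples = [s for s, g in groups.items() if g == control_group]
    rows = []
    for gene in matrix.index:
        fc, lfc = group_fold_change(matrix, groups, gene, test_group, control_group)
        a = matrix.loc[gene, test_samples].to_numpy(dtype=float)
        b = matrix.loc[gene, ctrl_samples].to_numpy(dtype=float)
        if len(a) > 1 and len(b) > 1 and (a.std() > 0 or b.std() > 0):
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append({"gene": gene, "fold_change": fc, "log2fc": lfc, "p_value": p})
    return pd.DataFrame(rows).set_index("gene")


def deg_filter(
    table: pd.DataFrame, lfc_min: float = 1.0, p_max: float = 0.05
) -> tuple[list[str], list[str], dict[str, int]]:
    """Split genes into up/down lists by |log2FC| >= lfc_min and p < p_max.

    The fold-change boundary is kept (>=); the p-value boundary is not (<).
    Genes with undefined log2FC or p are excluded.  Returns (up, down,
    counts).
    """
    up, down = [], []
    for gene, row in table.iterrows():
        lfc, p = row.get("log2fc"), row.get("p_value")
        if lfc is None or p is None or pd.isna(lfc) or pd.isna(p):
            continue
        if p < p_max:
            if lfc >= lfc_min:
                up.append(str(gene))
            elif lfc <= -lfc_min:
                down.append(str(gene))
    counts = {"up": len(up), "down": len(down), "total": len(up) + len(down)}
    return up, down, counts


def write_deg_lists(
    up: Sequence[str], down: Sequence[str], table: pd.DataFrame, path
) -> None:
    rows = [
        {"gene": g, "direction": d, "log2fc": table.loc[g, "log2fc"], "p_value": table.loc[g, "p_value"]}
        for d, genes in (("up", up), ("down", down))
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene", "direction", "log2fc", "p_value"]).to_csv(
        path, sep="\t", index=False
    )
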