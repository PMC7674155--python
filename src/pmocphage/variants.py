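"""SNP frequency dynamics between sample groups.

For each variant site the alternate-allele frequency in two sample groups
(e.g. the 2016 vs 2017 sampling years) is compared with a pooled
two-proportion z-test; Benjamini-Hochberg q-values control the FDR and
sites with q < 0.05 are reported as having significantly changed in
frequency. Reads may be pooled across the samples of a group (default) or
frequencies averaged per sample upstream - this module sees one alt
count and depth per group per site.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

Q_CUTOFF = 0.05


def snp_frequency_test(
    alt_a: int, depth_a: int, alt_b: int, depth_b: int
) -> tuple[float, float]:
    """Pooled two-proportion z-test for an allele-frequency change.

    z = (f_a - f_b) / sqrt(p*(1-p) * (1/n_a + 1/n_b)) with p the pooled
    frequency; two-sided p-value from the standard normal. Degenerate
    pooled frequencies (0 or 1) give z = 0, p = 1 by convention.
    """
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("zero depth in a group")
    if not (0 <= alt_a <= depth_a and 0 <= alt_b <= depth_b):
        raise ValueError("alt count outside [0, depth]")
    f_a, f_b = alt_a / depth_a, alt_b / depth_b
    pooled = (alt_a + alt_b) / (depth_a + depth_b)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / depth_a + 1.0 / depth_b))
    z = (f_a - f_b) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def bh_qvalues(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def frequency_change_test(
    table: pd.DataFrame, q_cutoff: float = Q_CUTOFF
) -> pd.DataFrame:
    """Run the z-test plus BH correction over a per-site allele-count table.

    ``table`` needs columns scaffold, pos, alt_a, depth_a, alt_b, depth_b.
    Sites with zero depth in either group are skipped with a reason code.
    Returns the table with freq_a, freq_b, z, p, q, significant, skipped.
    """
    required = {"scaffold", "pos", "alt_a", "depth_a", "alt_b", "depth_b"}
    if not required.issubset(table.columns):
        raise ValueError(f"SNP table needs columns {sorted(required)}")
    out = table.copy().reset_index(drop=True)
    usable = (out["depth_a"] > 0) & (out["depth_b"] > 0)
    out["skipped"] = np.where(usable, "", "zero-depth")
    z = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    for i in np.flatnonzero(usable.to_numpy()):
        z[i], p[i] = snp_frequency_test(
            int(out.at[i, "alt_a"]),
            int(out.at[i, "depth_a"]),
            int(out.at[i, "alt_b"]),
            int(out.at[i, "depth_b"]),
        )
    out["freq_a"] = np.where(usable, out["alt_a"] / out["depth_a"].replace(0, 1), np.nan)
    out["freq_b"] = np.where(usable, out["alt_b"] / out["depth_b"].replace(0, 1), np.nan)
    out["z"] = z
    out["p"] = p
    q = np.full(len(out), np.nan)
    mask = usable.to_numpy()
    if mask.any():
        q[mask] = bh_qvalues(p[mask])
    out["q"] = q
    out["significant"] = (out["q"] < q_cutoff).fillna(False)
    return out
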