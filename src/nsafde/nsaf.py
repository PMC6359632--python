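"""NSAF quantification and the two-sample test used on replicate NSAF values.

The normalized spectral abundance factor of protein *i* in one run is

    NSAF_i = (SC_i / L_i) / sum_j (SC_j / L_j)

where SC is the spectral count and L the protein length in residues.
Dividing by length removes the bias that longer proteins yield more tryptic
peptides and hence more spectra; the denominator makes runs of different
depth comparable.  NSAF vectors therefore sum to one per run, which also
means NSAF is compositional: a protein's NSAF can change because *other*
proteins changed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["compute_nsaf", "group_mean_nsaf", "nsaf_ratio", "ttest_independent"]


def compute_nsaf(counts_one_run: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """NSAF vector for a single run.

    Parameters
    ----------
    counts_one_run : array of non-negative reals
    lengths : array of positive integers, same shape

    Returns
    -------
    Array summing to 1; entries are zero exactly where the count is zero.
    """
    counts = np.asarray(counts_one_run, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if (counts < 0).any():
        raise ValueError("negative spectral count")
    if (lengths < 1).any():
        raise ValueError("protein length < 1")
    saf = counts / lengths
    total = saf.sum()
    if total <= 0:
        raise ValueError("all-zero run: NSAF normalization is degenerate")
    return saf / total


def group_mean_nsaf(matrix, group: str) -> "np.ndarray":
    """Arithmetic mean of the per-run NSAF vectors over one group's runs.

    NSAF is computed run-by-run first, then averaged, so each technical
    replicate contributes equally regardless of its depth.
    """
    runs = matrix.runs_for_group(group)
    lengths = matrix.lengths().to_numpy()
    per_run = [compute_nsaf(matrix.counts[r].to_numpy(), lengths) for r in runs]
    return np.mean(per_run, axis=0)


def nsaf_ratio(mean_ref: float, mean_cmp: float) -> float:
    """Comparison-over-reference abundance ratio.

    Returns 0.0 when the protein is absent from the comparison group and
    ``inf`` when absent from the reference group; both-zero is an error
    (handled upstream as absent_in_both).
    """
    if mean_ref < 0 or mean_cmp < 0:
        raise ValueError("negative group mean")
    if mean_ref == 0 and mean_cmp == 0:
        raise ValueError("ratio undefined when both group means are zero")
    if mean_ref == 0:
        return math.inf
    return mean_cmp / mean_ref


def ttest_independent(values_ref, values_cmp) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    Degenerate inputs, which arise when a table of group means is analyzed
    as single zero-variance pseudo-replicates, resolve deterministically:
    if the pooled variance is zero (or there are no residual degrees of
    freedom), equal means give p = 1 and unequal means give p = 0.
    """
    a = np.asarray(values_ref, dtype=float)
    b = np.asarray(values_cmp, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if df <= 0 or ss == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    sp2 = ss / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / se
    return float(2.0 * stats.t.sf(abs(t), df))
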