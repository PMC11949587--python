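"""Nonparametric comparison of optimal-parameter distributions.

Optimal model parameters are computed over ensembles of random initial
conditions, giving one distribution per empirical fit. Distributions from
independent ensembles (e.g. patient vs control fits with unrelated seeds)
are compared with the two-sided Wilcoxon rank-sum test; seed-paired samples
(e.g. connectotomy changes, where the patient and control arms share
simulations) with the Wilcoxon signed-rank test on the paired differences.

Exact null distributions are used where feasible (small samples, no ties);
otherwise the normal approximation with tie correction applies. p-values
are reported uncorrected, one test per comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError

logger = logging.getLogger(__name__)

_EXACT_MAX_RANKSUM = 7  # exact enumeration when min(n, m) <= 7 and no ties
_EXACT_MAX_SIGNED = 15


@dataclass(frozen=True)
class CohortComparison:
    """One row of a comparison table."""

    test: str  # "rank_sum" | "signed_rank"
    statistic: float
    p_value: float
    mean_difference: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValidationError("p-value out of [0, 1]")


def wilcoxon_rank_sum(a, b) -> CohortComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic reported is the rank sum of the first sample. The null is
    computed by exact enumeration when min(n, m) <= 7 and there are no ties,
    and by the normal approximation with tie correction otherwise. The mean
    difference is mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = min(a.size, b.size) <= _EXACT_MAX_RANKSUM and not has_ties
    res = sstats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> W
    return CohortComparison(
        test="rank_sum",
        statistic=rank_sum,
        p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def wilcoxon_signed_rank(diffs) -> CohortComparison:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (logged). Exact null for n <= 15 without
    tied magnitudes, normal approximation otherwise. The mean difference
    is the mean of the full difference sample, zeros included.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValidationError("empty difference sample")
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise ValidationError("all paired differences are zero: test degenerate")
    if nonzero.size < diffs.size:
        logger.info("dropped %d zero difference(s) of %d",
                    diffs.size - nonzero.size, diffs.size)
    mags = np.abs(nonzero)
    has_ties = len(np.unique(mags)) < len(mags)
    exact = nonzero.size <= _EXACT_MAX_SIGNED and not has_ties
    res = sstats.wilcoxon(
        nonzero, alternative="two-sided", method="exact" if exact else "approx"
    )
    return CohortComparison(
        test="signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(diffs.mean()),
        n_a=int(diffs.size),
        n_b=int(diffs.size),
    )


def pool_across_lambda(samples: dict[float, np.ndarray]) -> pd.DataFrame:
    """Concatenate per-excitability samples into one pooled distribution.

    Returns a DataFrame with columns ``lambda``, ``ic`` (index within the
    per-excitability ensemble) and ``value``, preserving provenance.
    """
    if not samples:
        raise ValidationError("nothing to pool")
    frames = [
        pd.DataFrame({
            "lambda": lam,
            "ic": np.arange(len(vals)),
            "value": np.asarray(vals, dtype=float),
        })
        for lam, vals in samples.items()
    ]
    return pd.concat(frames, ignore_index=True)


def comparison_table(rows: dict[str, CohortComparison]) -> pd.DataFrame:
    """Assemble named comparisons into a table (one row per comparison)."""
    return pd.DataFrame(
        [
            {
                "comparison": name,
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "mean_difference": c.mean_difference,
                "n_a": c.n_a,
                "n_b": c.n_b,
            }
            for name, c in rows.items()
        ]
    )
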