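"""Distributional summaries and hypothesis tests for deviation data.

Orienting deviations live on [0, 90] degrees.  The null model for "no
relation between cell shape and spindle orientation" is the uniform
distribution on that interval; alignment shows up as mass near zero and
is tested with a one-sample Kolmogorov-Smirnov test.  Group differences
use the Wilcoxon rank-sum test (with continuity correction) or an
unpaired two-tailed Student t-test.  No multiple-testing correction is
applied; p-values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

THRESHOLDS_DEG = (10.0, 20.0, 30.0)

#: sample size at or below which the exact KS null distribution is used
KS_EXACT_MAX_N = 150


def _check_range(deviations: np.ndarray) -> np.ndarray:
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("empty deviation sample")
    if (d < 0).any() or (d > 90).any():
        raise ValueError("deviations must lie in [0, 90] degrees")
    return d


def threshold_fractions(
    deviations, thresholds=THRESHOLDS_DEG
) -> np.ndarray:
    """Fraction of deviations strictly below each threshold."""
    d = _check_range(deviations)
    return np.array([float((d < t).mean()) for t in thresholds])


def random_angle_null(n: int, seed) -> np.ndarray:
    """i.i.d. uniform random angles on [0, 90] degrees (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 90.0, size=n)


def ks_uniform_test(deviations) -> tuple[float, float]:
    """One-sample two-sided KS test against Uniform(0, 90).

    Uses the exact finite-n null distribution for n <= 150 and the
    asymptotic one above; small samples (n < 5) are rejected as input.
    """
    d = _check_range(deviations)
    if d.size < 5:
        raise ValueError("KS test needs n >= 5")
    method = "exact" if d.size <= KS_EXACT_MAX_N else "asymp"
    res = sps.kstest(d, sps.uniform(loc=0.0, scale=90.0).cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def group_compare(
    group_a, group_b, test: str = "rank_sum"
) -> tuple[float, float]:
    """Two-sided comparison of two independent groups.

    ``rank_sum``: Wilcoxon rank-sum (Mann-Whitney U statistic) with
    normal approximation, tie and continuity correction — the convention
    of R's ``wilcox.test(..., correct = TRUE)``.
    ``t_two_tailed``: unpaired two-tailed Student t-test (pooled
    variance).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if test == "rank_sum":
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
        )
    elif test == "t_two_tailed":
        if a.std() == 0 and b.std() == 0:
            raise ValueError("t-test degenerate: both groups have zero variance")
        res = sps.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def half_normal_sigma(deviations) -> float:
    """Maximum-likelihood scale of a half-normal fit to deviations.

    If observed axes are the prediction plus axial Gaussian noise of
    standard deviation sigma, the deviations are |N(0, sigma)| and this
    recovers sigma (wrapping into [0, 90] is negligible for sigma well
    below 45 degrees).
    """
    d = _check_range(deviations)
    return float(math.sqrt(np.mean(d**2)))


def empirical_cdf(deviations) -> pd.DataFrame:
    """Cumulative-curve table: sorted deviation vs empirical CDF."""
    d = np.sort(_check_range(deviations))
    return pd.DataFrame(
        {"deviation_deg": d, "empirical_cdf": np.arange(1, d.size + 1) / d.size}
    )


@dataclass
class DeviationSummary:
    """Pooled summary of orienting deviations.

    ``fractions`` maps each threshold (degrees) to the proportion of
    deviations strictly below it; ``per_lineage`` carries mean +/- s.e.m.
    per lineage.
    """

    n: int
    fractions: dict[float, float]
    ks_D: float | None
    ks_p: float | None
    per_lineage: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "fractions": {str(k): v for k, v in self.fractions.items()},
            "ks": {"D": self.ks_D, "p": self.ks_p},
            "lineages": self.per_lineage.to_dict(orient="records"),
        }


def summarize_deviations(
    deviations,
    lineages=None,
    thresholds=THRESHOLDS_DEG,
) -> DeviationSummary:
    """Threshold fractions, KS-vs-uniform test and per-lineage means."""
    d = _check_range(deviations)
    fr = threshold_fractions(d, thresholds)
    ks_D = ks_p = None
    if d.size >= 5:
        ks_D, ks_p = ks_uniform_test(d)
    per_lineage = pd.DataFrame(columns=["lineage", "n", "mean_deg", "sem_deg"])
    if lineages is not None:
        df = pd.DataFrame({"lineage": list(lineages), "dev": d})
        grouped = df.groupby("lineage", sort=True)["dev"]
        per_lineage = pd.DataFrame(
            {
                "lineage": list(grouped.groups),
                "n": grouped.count().to_numpy(),
                "mean_deg": grouped.mean().to_numpy(),
                "sem_deg": grouped.sem(ddof=1).to_numpy(),
            }
        )
    return DeviationSummary(
        n=int(d.size),
        fractions={float(t): float(f) for t, f in zip(thresholds, fr)},
        ks_D=ks_D,
        ks_p=ks_p,
        per_lineage=per_lineage,
    )
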