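"""The study's statistical machinery.

Primary endpoint: three blinded evaluators each pick the registration they
would use clinically (automated, human, or "equivalent" when
indistinguishable); per case the majority label wins and a three-way split
counts as equivalent.  The automated method is declared non-inferior when the
lower limit of the exact two-sided 95% confidence interval of the proportion
"automated chosen or equivalent" strictly exceeds the 45% margin.  The
interval is Clopper-Pearson (exact binomial tail inversion via beta
quantiles) — the method that reproduces the published bounds.

Secondary machinery: a one-sided paired t-test for comparing NMI improvements,
one-way ANOVA with post-hoc Tukey HSD (gated on the overall ANOVA at p < 0.05)
for comparing Pearson correlations across the three registrations, and the
normal-approximation paired sample-size formula used at the design stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, InvalidParameterError, InvalidRecordError

__all__ = [
    "VoteRecord",
    "NonInferiorityResult",
    "aggregate_votes",
    "clopper_pearson",
    "noninferiority_test",
    "paired_t_one_sided",
    "anova_tukey",
    "sample_size_paired",
]

ARIR = "ARIR"
HRIR = "HRIR"
EQUIV = "EQUIV"
_LABELS = {ARIR, HRIR, EQUIV}

DEFAULT_MARGIN = 0.45


@dataclass(frozen=True)
class VoteRecord:
    """Labels from the three blinded evaluators for one case."""

    case_id: str
    votes: tuple[str, str, str]

    def __post_init__(self):
        if len(self.votes) != 3:
            raise InvalidRecordError(
                f"case {self.case_id}: need exactly 3 votes, got {len(self.votes)}"
            )
        bad = [v for v in self.votes if v not in _LABELS]
        if bad:
            raise InvalidRecordError(f"case {self.case_id}: unknown labels {bad}")


@dataclass(frozen=True)
class NonInferiorityResult:
    n_arir: int
    n_equiv: int
    n_hrir: int
    proportion: float
    ci_low: float
    ci_high: float
    margin: float
    non_inferior: bool

    @property
    def n(self) -> int:
        return self.n_arir + self.n_equiv + self.n_hrir


def aggregate_votes(record: VoteRecord) -> str:
    """Majority label; the three-way split counts as equivalent."""
    counts = Counter(record.votes)
    top, top_n = counts.most_common(1)[0]
    if top_n == 1:  # 1/1/1 split
        return EQUIV
    return top


def clopper_pearson(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    if n < 1 or not 0 <= successes <= n:
        raise InvalidParameterError(f"invalid counts: {successes}/{n}")
    if not 0 < confidence < 1:
        raise InvalidParameterError(f"confidence must be in (0,1): {confidence}")
    alpha = 1.0 - confidence
    low = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def noninferiority_test(
    records, margin: float = DEFAULT_MARGIN, confidence: float = 0.95
) -> NonInferiorityResult:
    """Aggregate the blinded votes and apply the non-inferiority criterion.

    Successes are cases whose aggregated label is the automated method or
    equivalent; non-inferiority requires the CI lower bound to be strictly
    greater than the margin.
    """
    labels = [aggregate_votes(r) for r in records]
    if not labels:
        raise InvalidParameterError("need at least one vote record")
    counts = Counter(labels)
    n_arir, n_equiv, n_hrir = counts[ARIR], counts[EQUIV], counts[HRIR]
    n = len(labels)
    successes = n_arir + n_equiv
    low, high = clopper_pearson(successes, n, confidence)
    return NonInferiorityResult(
        n_arir=n_arir,
        n_equiv=n_equiv,
        n_hrir=n_hrir,
        proportion=successes / n,
        ci_low=low,
        ci_high=high,
        margin=margin,
        non_inferior=bool(low > margin),
    )


def paired_t_one_sided(x, y, alternative: str = "greater") -> tuple[float, int, float]:
    """One-sided paired t-test on d = x - y; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidParameterError("need two equal-length 1-D series with n >= 2")
    if alternative not in ("greater", "less"):
        raise InvalidParameterError(f"alternative must be greater/less: {alternative}")
    d = x - y
    if np.ptp(d) == 0 and d.std() == 0:
        raise DegenerateTestError("paired differences have zero variance")
    res = sps.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_overall: float
    tukey_run: bool
    pairwise: list[dict]  # group_a, group_b, mean_diff, p_adj (when run)


def anova_tukey(groups, group_names=None, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA; Tukey HSD pairwise comparisons only when overall p < alpha."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise InvalidParameterError(f"need >= 3 groups, got {len(groups)}")
    if any(len(g) < 2 for g in groups):
        raise InvalidParameterError("each group needs >= 2 observations")
    names = list(group_names) if group_names else [f"group{i}" for i in range(len(groups))]
    if np.ptp(np.concatenate(groups)) == 0:
        # identical constant data: F is 0/0; report no effect
        return AnovaTukeyResult(0.0, 1.0, False, [])
    f_stat, p_overall = sps.f_oneway(*groups)
    if np.isnan(f_stat):  # zero within-group variance with equal means
        f_stat, p_overall = 0.0, 1.0
    result = AnovaTukeyResult(float(f_stat), float(p_overall), False, [])
    if result.p_overall < alpha:
        tk = sps.tukey_hsd(*groups)
        result.tukey_run = True
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                result.pairwise.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_diff": float(groups[i].mean() - groups[j].mean()),
                        "p_adj": float(tk.pvalue[i, j]),
                    }
                )
    return result


def sample_size_paired(
    sd: float,
    mean_diff: float,
    margin: float = 0.0,
    alpha: float = 0.05,
    power: float = 0.8,
) -> dict:
    """Paired-design sample size, normal approximation.

    Uses the shifted effect of a non-inferiority design,
    ``effect = mean_diff + margin``, in

        n = ceil( ((z_{1-alpha} + z_{power}) * sd / effect)^2 )

    with a one-sided alpha.  Returns the inputs and intermediate z values
    alongside ``n`` so the arithmetic is auditable.
    """
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    effect = mean_diff + margin
    if effect <= 0:
        raise InvalidParameterError(f"effective effect must be positive, got {effect}")
    z_alpha = float(sps.norm.ppf(1 - alpha))
    z_power = float(sps.norm.ppf(power))
    n_raw = ((z_alpha + z_power) * sd / effect) ** 2
    return {
        "n": int(ceil(n_raw)),
        "n_raw": float(n_raw),
        "effect": float(effect),
        "sd": float(sd),
        "mean_diff": float(mean_diff),
        "margin": float(margin),
        "alpha": float(alpha),
        "power": float(power),
        "z_alpha": z_alpha,
        "z_power": z_power,
    }
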