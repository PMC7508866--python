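"""Nonparametric group comparison and summary tables.

The study design compares small groups (n = 3–4) of continuous measurements,
so everything is rank-based: a Kruskal–Wallis omnibus test (tie-corrected H,
chi-square approximation with k−1 degrees of freedom) and Dunn post-hoc
pairwise z-tests on the pooled ranks with Bonferroni correction. The
significance threshold is 95% (α = 0.05). Group summaries are rendered as
"mean (SD)" with the sample (n−1) standard deviation.

The chi-square approximation is deliberate: at complete rank separation of
two groups of 3 it yields p = 0.0495, the floor attainable at this sample
size. An exact-permutation p is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "MeasurementGroup",
    "KruskalResult",
    "DunnResult",
    "ComparisonResult",
    "kruskal_wallis",
    "dunn_bonferroni",
    "compare_groups",
    "summarize",
]

ALPHA_DEFAULT = 0.05


@dataclass
class MeasurementGroup:
    """Labelled sample of real-valued measurements."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValidationError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class KruskalResult:
    H: float
    p: float
    df: int


@dataclass
class DunnResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    """Omnibus + post-hoc comparison at a given α."""

    omnibus: KruskalResult
    pairwise: list[DunnResult]
    alpha: float = ALPHA_DEFAULT

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [d.pair for d in self.pairwise if d.p_adjusted < self.alpha]


def _check_groups(groups: list[MeasurementGroup], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise ValidationError(f"need at least {min_groups} groups")
    pooled = np.concatenate([g.values for g in groups])
    if pooled.size < 3:
        raise ValidationError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        raise DegenerateDataError(
            "all observations identical: ranks are degenerate and H is undefined"
        )


def kruskal_wallis(groups: list[MeasurementGroup]) -> KruskalResult:
    """Tie-corrected Kruskal–Wallis H with the chi-square p (df = k−1)."""
    _check_groups(groups)
    H, p = sps.kruskal(*[g.values for g in groups])
    return KruskalResult(H=float(H), p=float(p), df=len(groups) - 1)


def kruskal_wallis_exact(groups: list[MeasurementGroup], n_perm: int = 10000,
                         seed: int = 0) -> KruskalResult:
    """Permutation p for the H statistic (optional alternative to chi-square)."""
    res = kruskal_wallis(groups)
    pooled = np.concatenate([g.values for g in groups])
    sizes = [g.n for g in groups]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        h, _ = sps.kruskal(*parts)
        if h >= res.H - 1e-12:
            count += 1
    return KruskalResult(H=res.H, p=(count + 1) / (n_perm + 1), df=res.df)


def dunn_bonferroni(groups: list[MeasurementGroup]) -> list[DunnResult]:
    """Dunn pairwise z-tests on pooled ranks, tie-corrected, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j)]
    with T = Σ(t³ − t) over tie groups; two-sided normal p multiplied by the
    number of pairwise comparisons, capped at 1.
    """
    _check_groups(groups)
    pooled = np.concatenate([g.values for g in groups])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    if var_base <= 0:
        raise DegenerateDataError("tie correction exhausts the rank variance")
    # mean rank per group
    offsets = np.cumsum([0] + [g.n for g in groups])
    mean_ranks = {
        g.label: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(groups)
    }
    n_by = {g.label: g.n for g in groups}
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for a, b in combinations([g.label for g in groups], 2):
        se = np.sqrt(var_base * (1.0 / n_by[a] + 1.0 / n_by[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(
            DunnResult(pair=(a, b), z=float(z), p_raw=float(p_raw),
                       p_adjusted=float(min(1.0, p_raw * m)))
        )
    return out


def compare_groups(groups: list[MeasurementGroup], alpha: float = ALPHA_DEFAULT) -> ComparisonResult:
    """Kruskal–Wallis omnibus plus Dunn/Bonferroni post-hoc in one call."""
    return ComparisonResult(
        omnibus=kruskal_wallis(groups), pairwise=dunn_bonferroni(groups), alpha=alpha
    )


def _render_cell(mean: float, sd: float | None, decimals: int) -> str:
    if sd is None:
        return f"{mean:.{decimals}f} (—)"
    return f"{mean:.{decimals}f} ({sd:.{decimals}f})"


def summarize(groups: list[MeasurementGroup], decimals: int = 2) -> pd.DataFrame:
    """Per-group mean, sample SD, n, and a rendered "mean (SD)" cell."""
    rows = []
    for g in groups:
        mean = float(g.values.mean())
        sd = float(g.values.std(ddof=1)) if g.n > 1 else None
        rows.append(
            {
                "group": g.label,
                "n": g.n,
                "mean": mean,
                "sd": sd,
                "mean_sd": _render_cell(mean, sd, decimals),
            }
        )
    return pd.DataFrame(rows)
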