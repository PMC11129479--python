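"""Statistical workflow, assay ratios and the Y-maze alternation index.

The group workflow mirrors a common immunohistology convention: screen each
metric with the D'Agostino–Pearson normality test, compare genotype groups
by one-way ANOVA and follow up pairwise with Holm–Šidák step-down adjusted
p-values; correlations are Pearson with the t-transform p-value.  All tests
are two-sided with α = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupTable",
    "AssaySample",
    "ArmSequence",
    "dagostino_pearson",
    "one_way_anova",
    "holm_sidak",
    "pearson_corr",
    "pk_remaining_percent",
    "assay_ratios",
    "alternation_index",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    adjusted_p: float | None = None
    method: str = ""
    note: str = ""


@dataclass
class GroupTable:
    """Measurements of one metric split by group."""

    name: str
    groups: dict[str, list[float]]
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {g: [float(x) for x in xs] for g, xs in self.groups.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


@dataclass
class AssaySample:
    """Biochemical assay readout of one animal's brain fraction."""

    abeta42: float
    abeta40: float
    abeta38: float = 0.0
    apoe: float = 0.0
    abeta42_post_pk: float = 0.0
    fraction: str = "insoluble"  # or "soluble"
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("abeta42", "abeta40", "abeta38", "apoe", "abeta42_post_pk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ArmSequence:
    """Ordered Y-maze arm entries over {1, 2, 3}."""

    entries: list[int]

    def __post_init__(self) -> None:
        if any(e not in (1, 2, 3) for e in self.entries):
            raise ValueError("arm entries must be 1, 2 or 3")

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def alternations(self) -> int:
        e = self.entries
        return sum(len({e[i], e[i + 1], e[i + 2]}) == 3 for i in range(len(e) - 2))

    @property
    def max_alternations(self) -> int:
        return max(self.n_entries - 2, 0)

    @property
    def alternation_index(self) -> float:
        return alternation_index(self)


# ---------------------------------------------------------------------------
# tests


def dagostino_pearson(x) -> TestResult:
    """D'Agostino–Pearson K² omnibus normality test (χ², 2 df).

    The moment approximations behind the skewness/kurtosis z-transforms need
    n ≥ 20; smaller samples raise instead of returning an unreliable p.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError(
            f"n={x.size} < 20: K-squared moment approximations unreliable; "
            "report descriptive statistics only for smaller samples"
        )
    stat, p = sps.normaltest(x)
    return TestResult(float(stat), float(p), df=2, method="dagostino_pearson")


def one_way_anova(table: GroupTable) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within, df (k−1, N−k)."""
    groups = [np.asarray(v, float) for v in table.groups.values()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    allx = np.concatenate(groups)
    if np.ptp(allx) == 0:
        raise ValueError("all observations identical: ANOVA undefined")
    k, n_total = len(groups), allx.size
    grand = allx.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        return TestResult(
            float("inf"), 0.0, df=(df1, df2), method="one_way_anova",
            note="zero within-group variance with unequal means",
        )
    f = (ssb / df1) / (ssw / df2)
    return TestResult(
        float(f), float(sps.f.sf(f, df1, df2)), df=(df1, df2), method="one_way_anova"
    )


def holm_sidak(p_values) -> list[float]:
    """Holm–Šidák step-down adjusted p-values, returned in input order.

    Sorted ascending, the i-th adjusted p is the running maximum of
    ``1 − (1 − p_(j))^(m − j + 1)`` for j ≤ i, clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = 1.0 - (1.0 - p[order]) ** (m - ranks + 1)
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return [float(a) for a in adjusted]


def pearson_corr(x, y) -> TestResult:
    """Pearson r with the two-sided p from t = r·√((n−2)/(1−r²))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), df=x.size - 2, method="pearson")


# ---------------------------------------------------------------------------
# assay ratios


def pk_remaining_percent(abeta42_pre: float, abeta42_post_pk: float) -> float:
    """Percent of insoluble Aβ₁₋₄₂ remaining after proteinase-K digestion."""
    if abeta42_pre <= 0:
        raise ValueError("pre-digestion level must be positive")
    return 100.0 * abeta42_post_pk / abeta42_pre


def assay_ratios(sample: AssaySample) -> dict[str, float]:
    """Aβ₁₋₄₂/Aβ₁₋₄₀ and ApoE/Aβ₁₋₄₂ ratios for one sample.

    When per-analyte units are recorded, numerator and denominator must
    agree; ratios with a zero denominator raise.
    """
    u = sample.units

    def check(a: str, b: str) -> None:
        if a in u and b in u and u[a] != u[b]:
            raise ValueError(f"units mismatch: {a} in {u[a]} vs {b} in {u[b]}")

    out = {}
    check("abeta42", "abeta40")
    if sample.abeta40 <= 0:
        raise ValueError("abeta40 is zero: Abeta42/40 ratio undefined")
    out["abeta42_40_ratio"] = sample.abeta42 / sample.abeta40
    check("apoe", "abeta42")
    if sample.abeta42 <= 0:
        raise ValueError("abeta42 is zero: ApoE/Abeta42 ratio undefined")
    out["apoe_per_abeta42"] = sample.apoe / sample.abeta42
    return out


# ---------------------------------------------------------------------------
# Y-maze


def alternation_index(seq: ArmSequence | list[int]) -> float:
    """Alternations over the maximum possible (entries − 2).

    An alternation is a length-3 sliding window visiting three distinct
    arms (overlapping-window convention).
    """
    if not isinstance(seq, ArmSequence):
        seq = ArmSequence(list(seq))
    if seq.n_entries < 3:
        raise ValueError("alternation index needs at least 3 entries")
    return seq.alternations / seq.max_alternations
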