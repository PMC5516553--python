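"""Normality-gated post-hoc comparisons across subgroups.

The validation machinery mirrors a common clinical-statistics workflow: a
Kolmogorov-Smirnov normality check (Lilliefors variant, since the normal
parameters are estimated from the sample) gates each variable to either a
parametric route (one-way ANOVA followed by unpaired t-tests) or a
nonparametric route (Kruskal-Wallis followed by Mann-Whitney U tests).
All tests are two-tailed at alpha = 0.05 and no multiple-testing correction
is applied; reports carry an explicit uncorrected-alpha annotation.

The Mann-Whitney implementation enumerates the exact permutation
distribution of U (midranks for ties) when the combined sample size is
small, and otherwise uses the normal approximation with tie-corrected
variance.  No continuity correction is applied by default, which makes the
two-sample Kruskal-Wallis p-value (chi-square with 1 df) coincide with the
Mann-Whitney p-value in the absence of ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .classify import round_percent  # noqa: F401  (re-exported convenience)
from .cohort import PatientRecord

ALPHA = 0.05

#: Held-out variables used to validate a cluster solution.
VALIDATION_VARIABLES: Tuple[str, ...] = (
    "age", "disease_duration", "hy_stage", "pdq39_cognition",
)

#: Combined sample size at or below which Mann-Whitney p is exact.
EXACT_MW_THRESHOLD = 12


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # "KS", "ANOVA", "Kruskal-Wallis", "t", "Mann-Whitney U"
    statistic: float
    p_value: float
    groups: Tuple[str, ...] = ()
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def ks_normality(sample: Sequence[float], variable: str = "") -> ComparisonResult:
    """Lilliefors-style KS test against a normal with estimated mean/SD.

    A constant sample is degenerate and reported non-normal (p = 0).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError(f"normality test needs n >= 5, got {x.size}")
    if np.ptp(x) == 0:
        return ComparisonResult(variable, "KS", float("nan"), 0.0)
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return ComparisonResult(variable, "KS", float(stat), float(p))


def omnibus(
    groups: Sequence[Sequence[float]], parametric: bool, variable: str = "",
    group_names: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """One-way ANOVA F or tie-corrected Kruskal-Wallis H across groups."""
    if len(groups) < 2:
        raise ValueError("omnibus test needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least two observations")
    names = tuple(group_names) if group_names else tuple(f"G{i + 1}" for i in range(len(arrays)))
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # no variation anywhere
        test = "ANOVA" if parametric else "Kruskal-Wallis"
        return ComparisonResult(variable, test, 0.0, 1.0, names)
    if parametric:
        stat, p = sps.f_oneway(*arrays)
        return ComparisonResult(variable, "ANOVA", float(stat), float(p), names)
    stat, p = sps.kruskal(*arrays)
    return ComparisonResult(variable, "Kruskal-Wallis", float(stat), float(p), names)


def _u_statistics(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """U1 (for sample a) and U2, from pooled midranks."""
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney test by enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled midranks to the
    first sample and returns ``(U, p)`` with ``U = min(U1, U2)`` and
    ``p = P(|U' - n1 n2 / 2| >= |U1_obs - n1 n2 / 2|)`` under the null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    u1_obs, u2_obs = _u_statistics(a, b)
    mu = n1 * n2 / 2.0
    ranks = sps.rankdata(np.concatenate([a, b]))
    offset = n1 * (n1 + 1) / 2.0
    dev_obs = abs(u1_obs - mu)
    hits = 0
    total = 0
    for subset in combinations(range(n1 + n2), n1):
        u1 = ranks[list(subset)].sum() - offset
        total += 1
        if abs(u1 - mu) >= dev_obs - 1e-12:
            hits += 1
    return min(u1_obs, u2_obs), hits / total


def _mann_whitney_normal(
    a: np.ndarray, b: np.ndarray, continuity: bool
) -> Tuple[float, float]:
    """Normal approximation with tie-corrected variance."""
    n1, n2 = a.size, b.size
    n = n1 + n2
    u1, u2 = _u_statistics(a, b)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return min(u1, u2), 1.0
    dev = abs(u1 - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    return min(u1, u2), float(2 * sps.norm.sf(z))


def pairwise(
    a: Sequence[float], b: Sequence[float], parametric: bool, variable: str = "",
    group_names: Tuple[str, str] = ("G1", "G2"),
    welch: bool = False, continuity: bool = False,
) -> ComparisonResult:
    """Unpaired two-sided t-test or Mann-Whitney U for two groups.

    The t-test pools variances by default (``welch=True`` switches to the
    unequal-variance form).  Mann-Whitney is exact by enumeration when the
    combined n is at most :data:`EXACT_MW_THRESHOLD`, else a tie-corrected
    normal approximation; U is reported as the smaller of U1, U2.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("every group needs at least two observations")
    if parametric:
        if np.ptp(np.concatenate([x, y])) == 0:
            return ComparisonResult(variable, "t", 0.0, 1.0, group_names)
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        return ComparisonResult(variable, "t", float(stat), float(p), group_names)
    if x.size + y.size <= EXACT_MW_THRESHOLD:
        u, p = mann_whitney_exact(x, y)
    else:
        u, p = _mann_whitney_normal(x, y, continuity)
    return ComparisonResult(variable, "Mann-Whitney U", float(u), float(p), group_names)


@dataclass
class VariableValidation:
    """Normality gate, omnibus and (on significance) pairwise results."""

    variable: str
    parametric: bool
    normality: List[ComparisonResult]
    omnibus: ComparisonResult
    pairwise: List[ComparisonResult] = field(default_factory=list)


@dataclass
class ValidationReport:
    entries: List[VariableValidation]
    alpha: float = ALPHA
    multiple_testing_correction: str = "none (uncorrected alpha)"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.entries:
            rows.append({
                "variable": entry.variable,
                "test": entry.omnibus.test,
                "comparison": "omnibus",
                "statistic": entry.omnibus.statistic,
                "p_value": entry.omnibus.p_value,
                "significant": entry.omnibus.significant,
            })
            for pw in entry.pairwise:
                rows.append({
                    "variable": entry.variable,
                    "test": pw.test,
                    "comparison": " vs ".join(pw.groups),
                    "statistic": pw.statistic,
                    "p_value": pw.p_value,
                    "significant": pw.significant,
                })
        frame = pd.DataFrame(rows)
        frame.attrs["alpha"] = self.alpha
        frame.attrs["multiple_testing_correction"] = self.multiple_testing_correction
        return frame


def _validation_value(record: PatientRecord, variable: str) -> float:
    if variable == "pdq39_cognition":
        return record.pdq39_cognition
    return float(getattr(record, variable))


def validate_solution(
    records: Sequence[PatientRecord],
    cluster_labels: Sequence[str],
    variables: Sequence[str] = VALIDATION_VARIABLES,
) -> ValidationReport:
    """Compare held-out variables across the labeled subgroups.

    Per variable: a Lilliefors normality check within every subgroup gates
    the route (parametric only if every subgroup passes at alpha = 0.05),
    then the omnibus test, then - if the omnibus is significant - all
    pairwise subgroup comparisons on the same route.
    """
    if len(records) != len(cluster_labels):
        raise ValueError("records and cluster labels differ in length")
    order: List[str] = []
    for lab in cluster_labels:
        if lab not in order:
            order.append(lab)
    if len(order) < 2:
        raise ValueError("validation needs at least two subgroups")
    grouped: Dict[str, List[PatientRecord]] = {lab: [] for lab in order}
    for record, lab in zip(records, cluster_labels):
        grouped[lab].append(record)

    entries: List[VariableValidation] = []
    for variable in variables:
        samples = {
            lab: np.array([_validation_value(r, variable) for r in grouped[lab]])
            for lab in order
        }
        normality = [
            ks_normality(samples[lab], variable=f"{variable}[{lab}]") for lab in order
        ]
        parametric = all(not res.significant for res in normality)
        omni = omnibus(
            [samples[lab] for lab in order], parametric, variable, group_names=order
        )
        pairs: List[ComparisonResult] = []
        if omni.significant:
            for lab_a, lab_b in combinations(order, 2):
                pairs.append(
                    pairwise(
                        samples[lab_a], samples[lab_b], parametric, variable,
                        group_names=(lab_a, lab_b),
                    )
                )
        entries.append(
            VariableValidation(
                variable=variable, parametric=parametric,
                normality=normality, omnibus=omni, pairwise=pairs,
            )
        )
    return ValidationReport(entries=entries)
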