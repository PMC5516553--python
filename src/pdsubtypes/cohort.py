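"""Seeded synthetic cohorts with a latent four-subgroup structure.

The generator emulates an early-stage Parkinson's disease cohort (Hoehn &
Yahr I-III, complete datasets) in which four latent subgroups coexist:

* ``YO``  - younger age of disease onset (45% of patients),
* ``TD``  - tremor dominant motor phenotype (12%),
* ``NTD`` - non-tremor dominant, cognitively worst off (23%),
* ``RDP`` - rapid disease progression at older onset (21%).

Each subgroup is parameterized by marginal means/SDs of the continuous
clinical variables and by prevalences of binary comorbid symptoms
(:class:`ClusterProfile`).  Continuous variables are drawn from truncated
normals by rejection sampling inside instrument ranges; binary symptoms are
drawn Bernoulli at the subgroup prevalence and written back into the
questionnaire scores so that the downstream cutoff classifiers recover the
drawn state exactly.  MDS-UPDRS item scores and part totals are back-filled
so that the derived motor phenotype ratio and progression rate reproduce each
record's sampled targets.

Two modes are supported: ``profile`` lets PD-MCI emerge from the sampled
neuropsychological scores, while ``prevalence`` forces the Level-1 PD-MCI
classification to a Bernoulli draw at the subgroup's MCI prevalence
(marginal means and prevalences over-determine the joint distribution, so
both views must be constructible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .features import DEFAULT_ITEM_MAP, DURATION_FLOOR_YEARS, ItemMap

CLUSTER_LABELS: Tuple[str, ...] = ("YO", "TD", "NTD", "RDP")

#: Maximum total for MDS-UPDRS parts I-III (52 + 52 + 132).
UPDRS_TOTAL_MAX = 236.0
_PART_CAPS = {"part1": 52.0, "part2": 52.0, "part3": 132.0}

#: Binary symptom names carried by :class:`ClusterProfile`.
SYMPTOM_NAMES: Tuple[str, ...] = ("fog", "hallucination", "scopa_ns", "scopa_ds", "ess", "rbdsq")

#: The eight-test Level-1 neuropsychological battery (normative z-scores).
BATTERY_TESTS: Tuple[str, ...] = (
    "mmse", "tmt_a", "tmt_b", "digit_span", "lm1", "lm2", "cowat_fas", "cowat_animals",
)

# (mean, sd, low, high) per continuous variable; means/SDs are subgroup
# specific, ranges are instrument/validity ranges shared across subgroups.
_RANGES: Dict[str, Tuple[float, float]] = {
    "age_onset": (25.0, 85.0),
    "disease_duration": (DURATION_FLOOR_YEARS, 40.0),
    "progression_rate": (0.05, 60.0),
    "motor_phenotype": (0.01, 4.0),
    "nart_iq": (70.0, 131.0),
    "mmse_raw": (10.0, 30.0),
    "lm2_z": (-4.0, 4.0),
    "tmtb_z": (-6.0, 4.0),
    "bdi_total": (0.0, 63.0),
    "ledd": (0.0, 3000.0),
    "hy_stage": (1.0, 3.0),
    "pdq39_cognition": (0.0, 100.0),
}


@dataclass(frozen=True)
class ClusterProfile:
    """Generator parameters for one latent subgroup.

    ``continuous_params`` maps a variable name to ``(mean, sd, low, high)``;
    ``binary_prevalences`` maps a symptom name to a probability.
    """

    label: str
    weight: float
    continuous_params: Dict[str, Tuple[float, float, float, float]]
    binary_prevalences: Dict[str, float]
    mci_prevalence: float

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"weight {self.weight} outside [0, 1]")
        if not 0 <= self.mci_prevalence <= 1:
            raise ValueError(f"mci_prevalence {self.mci_prevalence} outside [0, 1]")
        for name, (mean, sd, lo, hi) in self.continuous_params.items():
            if sd < 0:
                raise ValueError(f"{self.label}/{name}: sd {sd} is negative")
            if not lo < hi:
                raise ValueError(f"{self.label}/{name}: invalid range [{lo}, {hi}]")
        for name, p in self.binary_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.label}/{name}: prevalence {p} outside [0, 1]")


@dataclass
class PatientRecord:
    """One synthetic subject's complete clinical measurements."""

    id: str
    age: float
    sex: str
    age_onset: float
    disease_duration: float
    hy_stage: float
    updrs_items: Dict[str, float]
    updrs_part1: float
    updrs_part2: float
    updrs_part3: float
    updrs_1_1: int
    updrs_1_2: int
    nart_iq: float
    mmse_raw: int
    neuropsych: Dict[str, float]
    bdi_total: int
    ess_total: int
    scopa_ds: int
    scopa_ns: int
    rbdsq_total: int
    fogq_item3: int
    scopa_pc_item1: int
    pdq39_items: Dict[str, float]
    ldopa_mg_per_day: float
    da_flag: bool
    latent_cluster: Optional[str] = None

    @property
    def updrs_total_i_iii(self) -> float:
        return self.updrs_part1 + self.updrs_part2 + self.updrs_part3

    @property
    def pdq39_cognition(self) -> float:
        from .features import pdq39_dimension_score

        return pdq39_dimension_score([self.pdq39_items[k] for k in sorted(self.pdq39_items)])


@dataclass
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    n: int
    seed: int
    profiles: List[ClusterProfile] = field(default_factory=lambda: default_profiles())
    mode: str = "profile"

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not self.profiles:
            raise ValueError("at least one cluster profile is required")
        if self.mode not in ("profile", "prevalence"):
            raise ValueError(f"mode must be 'profile' or 'prevalence', got {self.mode!r}")
        total = sum(p.weight for p in self.profiles)
        if total <= 0:
            raise ValueError("profile weights must have a positive sum")


def _profile(label: str, weight: float, means: Dict[str, Tuple[float, float]],
             prevalences: Dict[str, float], mci: float) -> ClusterProfile:
    cont = {name: (m, s, *_RANGES[name]) for name, (m, s) in means.items()}
    return ClusterProfile(label, weight, cont, prevalences, mci)


def default_profiles() -> List[ClusterProfile]:
    """The four default subgroup profiles.

    Continuous means/SDs and binary prevalences follow the published
    per-subgroup summaries for a 209-patient early-PD cohort; raw mixing
    weights 45/12/23/21% are renormalized to sum to one.
    """
    raw = [
        ("YO", 0.45,
         {"age_onset": (56.63, 8.2), "disease_duration": (6.59, 4.7),
          "progression_rate": (5.29, 3.1), "motor_phenotype": (0.68, 0.6),
          "nart_iq": (112.84, 8.9), "mmse_raw": (29.06, 1.0),
          "lm2_z": (0.16, 0.9), "tmtb_z": (0.37, 0.7),
          "bdi_total": (10.47, 7.1), "ledd": (709.29, 482.7),
          "hy_stage": (1.96, 0.5), "pdq39_cognition": (22.78, 17.23)},
         {"fog": 0.41, "hallucination": 0.11, "scopa_ns": 0.19,
          "scopa_ds": 0.24, "ess": 0.22, "rbdsq": 0.41},
         0.24),
        ("TD", 0.12,
         {"age_onset": (62.28, 8.3), "disease_duration": (3.51, 2.8),
          "progression_rate": (7.49, 6.4), "motor_phenotype": (1.86, 0.7),
          "nart_iq": (104.29, 11.5), "mmse_raw": (28.21, 1.4),
          "lm2_z": (-0.63, 0.9), "tmtb_z": (-0.32, 1.4),
          "bdi_total": (6.17, 6.0), "ledd": (231.06, 258.9),
          "hy_stage": (1.54, 0.5), "pdq39_cognition": (22.57, 18.46)},
         {"fog": 0.08, "hallucination": 0.04, "scopa_ns": 0.17,
          "scopa_ds": 0.25, "ess": 0.17, "rbdsq": 0.29},
         0.42),
        ("NTD", 0.23,
         {"age_onset": (59.86, 9.3), "disease_duration": (9.07, 5.7),
          "progression_rate": (4.61, 3.4), "motor_phenotype": (0.43, 0.4),
          "nart_iq": (103.04, 8.9), "mmse_raw": (26.71, 1.4),
          "lm2_z": (-0.76, 1.0), "tmtb_z": (-1.58, 1.7),
          "bdi_total": (9.6, 5.9), "ledd": (846.14, 513.4),
          "hy_stage": (2.17, 0.6), "pdq39_cognition": (33.59, 21.21)},
         {"fog": 0.69, "hallucination": 0.23, "scopa_ns": 0.17,
          "scopa_ds": 0.40, "ess": 0.46, "rbdsq": 0.56},
         0.54),
        ("RDP", 0.21,
         {"age_onset": (69.87, 7.0), "disease_duration": (2.14, 1.1),
          "progression_rate": (17.77, 8.5), "motor_phenotype": (0.62, 0.5),
          "nart_iq": (113.41, 9.6), "mmse_raw": (29.05, 1.1),
          "lm2_z": (0.36, 0.75), "tmtb_z": (-0.49, 1.3),
          "bdi_total": (9.59, 6.5), "ledd": (309.07, 260.1),
          "hy_stage": (1.99, 0.6), "pdq39_cognition": (20.39, 15.31)},
         {"fog": 0.25, "hallucination": 0.07, "scopa_ns": 0.18,
          "scopa_ds": 0.16, "ess": 0.25, "rbdsq": 0.32},
         0.25),
    ]
    profiles = [_profile(*args) for args in raw]
    total = sum(p.weight for p in profiles)
    return [replace(p, weight=p.weight / total) for p in profiles]


def truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float,
    max_tries: int = 10_000,
) -> float:
    """One truncated-normal draw by rejection sampling (no clipping).

    Rejection keeps the density shape inside the range and creates no
    boundary atoms; an improbable window raises rather than looping forever.
    """
    if sd == 0:
        if not low <= mean <= high:
            raise ValueError(f"degenerate distribution at {mean} outside [{low}, {high}]")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise RuntimeError(
        f"rejection sampling failed for N({mean}, {sd}) within [{low}, {high}]"
    )


def spread_mean(target_mean: float, k: int, high: float = 4.0) -> List[float]:
    """Split a target mean over ``k`` item scores in [0, high].

    All but one score sit on the integer grid; a single correction score
    absorbs the rounding remainder so the mean equals ``target_mean``
    exactly.
    """
    if not 0 <= target_mean <= high:
        raise ValueError(f"target mean {target_mean} outside [0, {high}]")
    if k == 1:
        return [float(target_mean)]
    base = math.floor(target_mean)
    if base >= high:  # target equals the scale maximum
        return [float(high)] * k
    frac = target_mean - base
    # c items at base+1, k-1-c at base, one correction item.
    c_ideal = round(frac * (k - 1))
    c_lo = max(0, math.ceil(base + k * frac - high))
    c_hi = min(k - 1, math.floor(base + k * frac))
    c = int(min(max(c_ideal, c_lo), c_hi))
    correction = base + k * frac - c
    values = [float(base + 1)] * c + [float(base)] * (k - 1 - c) + [float(correction)]
    return values


def _draw(rng: np.random.Generator, profile: ClusterProfile, name: str) -> float:
    return truncated_normal(rng, *profile.continuous_params[name])


def _bernoulli(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _positive_score(rng: np.random.Generator, cutoff: int, maximum: int) -> int:
    """Integer score at or above ``cutoff`` with mass concentrated near it."""
    span = maximum - cutoff
    return cutoff + int(min(span, rng.geometric(0.45) - 1))


def _negative_score(rng: np.random.Generator, cutoff: int) -> int:
    """Integer score strictly below ``cutoff``, concentrated near zero."""
    return int(min(cutoff - 1, rng.geometric(0.5) - 1))


def _backfill_updrs(
    items_map: ItemMap,
    motor_phenotype: float,
    total_target: float,
    s1: float,
) -> Tuple[Dict[str, float], float, float, float]:
    """Construct item scores and part totals hitting the sampled targets.

    Tremor items share a common mean ``t`` and non-tremor items a common mean
    ``n`` with ``t/n`` equal to the motor phenotype target; part totals sum
    exactly to ``total_target`` so the derived progression rate reproduces
    its target.  When the natural item scores would exceed the total budget,
    the items are scaled down by a ratio-preserving factor.
    """
    m = motor_phenotype
    n_mean = min(1.3, 3.8 / max(m, 1e-9)) if m > 0 else 1.3
    t_mean = m * n_mean

    n_tremor = len(items_map.tremor_items)
    n_nontremor = len(items_map.nontremor_items)
    tremor_vals = spread_mean(t_mean, n_tremor)
    nontremor_vals = spread_mean(n_mean, n_nontremor)

    items: Dict[str, float] = {}

    def assign(name: str, value: float) -> None:
        if name in items_map.lateralized_pairs:
            left, right = items_map.lateralized_pairs[name]
            items[left] = value
            items[right] = value
        else:
            items[name] = value

    for name, value in zip(items_map.tremor_items, tremor_vals):
        assign(name, value)
    for name, value in zip(items_map.nontremor_items, nontremor_vals):
        assign(name, value)

    # Part membership in the default flattened dialect: item23 belongs to
    # part II, everything else stored here to part III.
    part2_keys = {"item23"} & set(items)
    s2 = sum(items[k] for k in part2_keys)
    s3 = sum(v for k, v in items.items() if k not in part2_keys)
    s_motor = s2 + s3

    if s_motor > 0 and s1 + s_motor > total_target:
        lam = max(0.02, (total_target - s1) / s_motor)
        lam = min(lam, 1.0)
        items = {k: v * lam for k, v in items.items()}
        s2 *= lam
        s3 *= lam

    stored = s1 + s2 + s3
    remainder = total_target - stored
    if remainder >= 0:
        f3 = min(remainder, _PART_CAPS["part3"] - s3)
        remainder -= f3
        f2 = min(remainder, _PART_CAPS["part2"] - s2)
        remainder -= f2
        f1 = min(remainder, _PART_CAPS["part1"] - s1)
        part1, part2, part3 = s1 + f1, s2 + f2, s3 + f3
    else:
        # Tiny total budget: keep the exact total (rate target) and distribute
        # it proportionally; item/total coherence is sacrificed for these
        # rare records.
        scale = total_target / stored if stored > 0 else 0.0
        part1, part2, part3 = s1 * scale, s2 * scale, s3 * scale
    return items, part1, part2, part3


def _make_record(
    rng: np.random.Generator,
    profile: ClusterProfile,
    record_id: str,
    mode: str,
    items_map: ItemMap,
    forced: Optional[Mapping[str, bool]] = None,
) -> PatientRecord:
    forced = dict(forced or {})

    age_onset = _draw(rng, profile, "age_onset")
    duration = _draw(rng, profile, "disease_duration")
    # Joint guard: the implied UPDRS I-III total r*d must fit the instrument.
    mean, sd, lo, hi = profile.continuous_params["progression_rate"]
    rate = truncated_normal(rng, mean, sd, lo, min(hi, UPDRS_TOTAL_MAX / duration))
    motor = _draw(rng, profile, "motor_phenotype")
    nart_iq = _draw(rng, profile, "nart_iq")
    mmse_raw = int(round(_draw(rng, profile, "mmse_raw")))
    lm2_z = _draw(rng, profile, "lm2_z")
    tmtb_z = _draw(rng, profile, "tmtb_z")
    bdi = int(math.floor(_draw(rng, profile, "bdi_total")))
    ledd = _draw(rng, profile, "ledd")
    hy = min(3.0, max(1.0, round(_draw(rng, profile, "hy_stage") * 2) / 2))
    pdq_scaled = _draw(rng, profile, "pdq39_cognition")
    sex = "M" if rng.random() < 144 / 209 else "F"
    da_flag = _bernoulli(rng, 0.29)

    # Binary comorbid symptoms: Bernoulli draws written back into scores so
    # the cutoff classifiers recover the drawn state exactly.
    flags = {
        name: forced.get(name, _bernoulli(rng, profile.binary_prevalences[name]))
        for name in SYMPTOM_NAMES
    }
    fog = _positive_score(rng, 1, 4) if flags["fog"] else 0
    ess = _positive_score(rng, 10, 24) if flags["ess"] else _negative_score(rng, 10)
    scopa_ds = _positive_score(rng, 5, 18) if flags["scopa_ds"] else _negative_score(rng, 5)
    scopa_ns = _positive_score(rng, 7, 15) if flags["scopa_ns"] else _negative_score(rng, 7)
    rbdsq = _positive_score(rng, 5, 13) if flags["rbdsq"] else _negative_score(rng, 5)
    if flags["hallucination"]:
        pc1 = _positive_score(rng, 1, 3)
        updrs_1_2 = _positive_score(rng, 1, 4)
    elif rng.random() < 0.9:
        pc1, updrs_1_2 = 0, int(rng.integers(0, 2))
    else:  # screening positive but unconfirmed
        pc1, updrs_1_2 = _positive_score(rng, 1, 3), 0

    # Neuropsychological battery (normative z-scores).
    premorbid_z = (nart_iq - 100.0) / 15.0
    threshold = premorbid_z - 1.5
    lm2_mean = profile.continuous_params["lm2_z"][0]
    tmtb_mean = profile.continuous_params["tmtb_z"][0]
    aux_mean = (lm2_mean + tmtb_mean) / 2.0
    neuropsych = {"lm2": lm2_z, "tmt_b": tmtb_z}
    for test in ("mmse", "tmt_a", "digit_span", "lm1", "cowat_fas", "cowat_animals"):
        neuropsych[test] = truncated_normal(rng, aux_mean, 1.0, -5.0, 4.0)

    if mode == "prevalence" or "mci" in forced:
        mci = forced.get("mci", _bernoulli(rng, profile.mci_prevalence))
        if mci:
            n_impaired = 2 if rng.random() < 0.7 else 3
            updrs_1_1 = 1 if rng.random() < 0.7 else 2
        else:
            n_impaired = 0 if rng.random() < 0.75 else 1
            updrs_1_1 = 1 if rng.random() < 0.3 else 0
        order = ("tmt_b", "lm2", "tmt_a", "mmse", "digit_span", "lm1",
                 "cowat_fas", "cowat_animals")
        for i, test in enumerate(order):
            if i < n_impaired:
                neuropsych[test] = max(-6.0, threshold - rng.uniform(0.1, 1.0))
            else:
                neuropsych[test] = min(4.0, threshold + rng.uniform(0.3, 2.0))
    else:
        p_subjective = min(1.0, profile.mci_prevalence + 0.2)
        updrs_1_1 = (1 if rng.random() < 0.7 else 2) if _bernoulli(rng, p_subjective) else 0

    s1 = float(updrs_1_1 + updrs_1_2)
    total_target = rate * duration
    items, part1, part2, part3 = _backfill_updrs(items_map, motor, total_target, s1)

    pdq_sum = pdq_scaled * 16.0 / 100.0
    pdq_vals = spread_mean(pdq_sum / 4.0, 4)
    pdq_items = {f"q{30 + i}": v for i, v in enumerate(pdq_vals)}

    record = PatientRecord(
        id=record_id,
        age=age_onset + duration,
        sex=sex,
        age_onset=age_onset,
        disease_duration=duration,
        hy_stage=hy,
        updrs_items=items,
        updrs_part1=part1,
        updrs_part2=part2,
        updrs_part3=part3,
        updrs_1_1=updrs_1_1,
        updrs_1_2=updrs_1_2,
        nart_iq=nart_iq,
        mmse_raw=mmse_raw,
        neuropsych=neuropsych,
        bdi_total=bdi,
        ess_total=ess,
        scopa_ds=scopa_ds,
        scopa_ns=scopa_ns,
        rbdsq_total=rbdsq,
        fogq_item3=fog,
        scopa_pc_item1=pc1,
        pdq39_items=pdq_items,
        ldopa_mg_per_day=ledd,
        da_flag=da_flag,
        latent_cluster=profile.label,
    )
    # Non-field bookkeeping: the sampled targets the back-fill must reproduce
    # (not part of equality or CSV round-trips).
    record.sampled_targets = {"motor_phenotype": motor, "progression_rate": rate}
    return record


def generate_cohort(spec: CohortSpec, items_map: ItemMap = DEFAULT_ITEM_MAP) -> List[PatientRecord]:
    """Generate ``spec.n`` patient records; identical spec -> identical cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.n == 0:
        return []
    weights = np.array([p.weight for p in spec.profiles], dtype=float)
    weights = weights / weights.sum()
    assignments = rng.choice(len(spec.profiles), size=spec.n, p=weights)
    width = len(str(spec.n))
    return [
        _make_record(rng, spec.profiles[c], f"P{i + 1:0{width}d}", spec.mode, items_map)
        for i, c in enumerate(assignments)
    ]


def make_count_fixture(
    subgroup_sizes: Mapping[str, int],
    positive_counts: Mapping[str, int],
    feature: str,
    seed: int = 0,
    profiles: Optional[Sequence[ClusterProfile]] = None,
    items_map: ItemMap = DEFAULT_ITEM_MAP,
) -> List[PatientRecord]:
    """Deterministic cohort with exact per-subgroup positive counts.

    ``feature`` is ``"mci"`` or one of :data:`SYMPTOM_NAMES`; exactly
    ``positive_counts[g]`` records in subgroup ``g`` classify positive for it
    and the rest negative.
    """
    if feature != "mci" and feature not in SYMPTOM_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    profiles = list(profiles) if profiles is not None else default_profiles()
    by_label = {p.label: p for p in profiles}
    rng = np.random.default_rng(seed)
    records: List[PatientRecord] = []
    total = sum(subgroup_sizes.values())
    width = len(str(max(total, 1)))
    i = 0
    for label, size in subgroup_sizes.items():
        if label not in by_label:
            raise ValueError(f"no profile for subgroup {label!r}")
        positives = positive_counts.get(label, 0)
        if not 0 <= positives <= size:
            raise ValueError(
                f"{label}: positive count {positives} outside [0, {size}]"
            )
        for j in range(size):
            forced = {feature: j < positives}
            records.append(
                _make_record(
                    rng, by_label[label], f"P{i + 1:0{width}d}", "prevalence",
                    items_map, forced=forced,
                )
            )
            i += 1
    return records
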