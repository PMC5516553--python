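"""MDS Level-1 PD-MCI diagnosis and questionnaire cutoff classifiers.

PD-MCI (Level 1) requires (1) impairment on two or more neuropsychological
tests, where impairment means a normative z-score at least 1.5 SD below the
premorbid level of functioning estimated from the NART-R IQ
(premorbid z = (IQ - 100) / 15), and (2) subjective cognitive complaints,
operationalized as a score of 1 or more on MDS-UPDRS part I item 1.1.
Level-2 subtyping (amnestic vs non-amnestic) is out of scope.

All questionnaire cutoffs follow the published conventions: BDI-II 13/14
(>= 14 positive) for at least moderate depressive symptoms, ESS >= 10 for
excessive daytime sleepiness, SCOPA-S 4/5 (daytime) and 6/7 (night-time),
RBDSQ >= 5, any positive FOG-Q item 3, and SCOPA-PC item 1 >= 1 confirmed by
MDS-UPDRS item 1.2 >= 1 for hallucinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .cohort import BATTERY_TESTS, PatientRecord

#: Default Level-1 battery: the eight non-NART tests (normative z-scores).
DEFAULT_BATTERY: Tuple[str, ...] = BATTERY_TESTS

#: How far below the premorbid estimate a test must fall to count impaired.
IMPAIRMENT_SD = 1.5


@dataclass(frozen=True)
class MCIStatus:
    impaired_test_count: int
    impaired_test_names: Tuple[str, ...]
    subjective_flag: bool
    diagnosis: bool


@dataclass(frozen=True)
class SymptomFlags:
    depression: bool
    fog: bool
    hallucination: bool
    scopa_ns: bool
    scopa_ds: bool
    ess: bool
    rbdsq: bool


@dataclass(frozen=True)
class SymptomCutoffs:
    """First abnormal value per instrument (inclusive thresholds)."""

    bdi: int = 14
    ess: int = 10
    scopa_ds: int = 5
    scopa_ns: int = 7
    rbdsq: int = 5
    fog: int = 1
    hallucination_screen: int = 1
    hallucination_confirm: int = 1


DEFAULT_CUTOFFS = SymptomCutoffs()


def _check_range(name: str, value: float, low: float, high: float) -> None:
    if not low <= value <= high:
        raise ValueError(f"{name} score {value} outside [{low}, {high}]")


def diagnose_pdmci(
    record: PatientRecord, battery: Sequence[str] = DEFAULT_BATTERY
) -> MCIStatus:
    """Apply the Level-1 PD-MCI rule to one record.

    A test is impaired iff its normative z-score is at or below
    ``(NART-R IQ - 100)/15 - 1.5``; the diagnosis additionally requires
    MDS-UPDRS item 1.1 >= 1 (subjective complaint).
    """
    premorbid_z = (record.nart_iq - 100.0) / 15.0
    threshold = premorbid_z - IMPAIRMENT_SD
    impaired: List[str] = []
    for test in battery:
        if test not in record.neuropsych:
            raise KeyError(
                f"record {record.id!r} has no normative z-score for test {test!r}"
            )
        if record.neuropsych[test] <= threshold:
            impaired.append(test)
    subjective = record.updrs_1_1 >= 1
    return MCIStatus(
        impaired_test_count=len(impaired),
        impaired_test_names=tuple(impaired),
        subjective_flag=subjective,
        diagnosis=len(impaired) >= 2 and subjective,
    )


def classify_depression(bdi: float, cutoff: int = DEFAULT_CUTOFFS.bdi) -> bool:
    """BDI-II 13/14 cutoff for at least moderate depressive symptomatology."""
    _check_range("BDI-II", bdi, 0, 63)
    return bdi >= cutoff


def classify_ess(ess: float, cutoff: int = DEFAULT_CUTOFFS.ess) -> bool:
    """ESS >= 10 flags excessive daytime sleepiness."""
    _check_range("ESS", ess, 0, 24)
    return ess >= cutoff


def classify_scopa_sleep(
    ds: float, ns: float,
    ds_cutoff: int = DEFAULT_CUTOFFS.scopa_ds,
    ns_cutoff: int = DEFAULT_CUTOFFS.scopa_ns,
) -> Tuple[bool, bool]:
    """SCOPA-S daytime (4/5) and night-time (6/7) disturbance flags."""
    _check_range("SCOPA-S (DS)", ds, 0, 18)
    _check_range("SCOPA-S (NS)", ns, 0, 15)
    return ds >= ds_cutoff, ns >= ns_cutoff


def classify_rbd(rbdsq: float, cutoff: int = DEFAULT_CUTOFFS.rbdsq) -> bool:
    """RBDSQ >= 5 screens positive for REM sleep behavior disorder."""
    _check_range("RBDSQ", rbdsq, 0, 13)
    return rbdsq >= cutoff


def classify_fog(fogq_item3: float, cutoff: int = DEFAULT_CUTOFFS.fog) -> bool:
    """Any positive FOG-Q item 3 response defines a freezer."""
    _check_range("FOG-Q item 3", fogq_item3, 0, 4)
    return fogq_item3 >= cutoff


def classify_hallucination(
    scopa_pc_item1: float, updrs_1_2: float,
    screen_cutoff: int = DEFAULT_CUTOFFS.hallucination_screen,
    confirm_cutoff: int = DEFAULT_CUTOFFS.hallucination_confirm,
) -> bool:
    """SCOPA-PC item 1 screening confirmed by MDS-UPDRS item 1.2."""
    _check_range("SCOPA-PC item 1", scopa_pc_item1, 0, 3)
    _check_range("MDS-UPDRS item 1.2", updrs_1_2, 0, 4)
    return scopa_pc_item1 >= screen_cutoff and updrs_1_2 >= confirm_cutoff


def classify_symptoms(
    record: PatientRecord, cutoffs: SymptomCutoffs = DEFAULT_CUTOFFS
) -> SymptomFlags:
    """All binary symptom flags for one record."""
    ds, ns = classify_scopa_sleep(
        record.scopa_ds, record.scopa_ns, cutoffs.scopa_ds, cutoffs.scopa_ns
    )
    return SymptomFlags(
        depression=classify_depression(record.bdi_total, cutoffs.bdi),
        fog=classify_fog(record.fogq_item3, cutoffs.fog),
        hallucination=classify_hallucination(
            record.scopa_pc_item1, record.updrs_1_2,
            cutoffs.hallucination_screen, cutoffs.hallucination_confirm,
        ),
        scopa_ns=ns,
        scopa_ds=ds,
        ess=classify_ess(record.ess_total, cutoffs.ess),
        rbdsq=classify_rbd(record.rbdsq_total, cutoffs.rbdsq),
    )


def round_percent(x: float) -> int:
    """Percentage rounding used in all printed tables.

    Two-stage: round to one decimal place, then to the nearest integer, half
    away from zero at both stages.  This is the convention that reproduces
    the reported cohort composition (e.g. 93/209 -> 44.5 -> 45).
    """
    if x < 0:
        return -round_percent(-x)
    one_decimal = math.floor(x * 10 + 0.5) / 10
    return int(math.floor(one_decimal + 0.5))


#: Display order of the frequency-table rows.
FREQUENCY_ROWS: Tuple[Tuple[str, str], ...] = (
    ("PD-MCI", "mci"),
    ("FOG-Q item 3", "fog"),
    ("SCOPA-PC item 1 + MDS-UPDRS 1.2", "hallucination"),
    ("SCOPA-S (NS)", "scopa_ns"),
    ("SCOPA-S (DS)", "scopa_ds"),
    ("ESS", "ess"),
    ("RBDSQ", "rbdsq"),
)


@dataclass
class FrequencyTable:
    """Per-subgroup percentages with the counts they were computed from."""

    percents: pd.DataFrame  # rows: features, columns: cluster labels (int %)
    counts: pd.DataFrame
    sizes: pd.Series

    def recount_percent(self, feature: str, cluster: str) -> Optional[int]:
        n = int(self.sizes[cluster])
        if n == 0:
            return None
        return round_percent(100.0 * int(self.counts.loc[feature, cluster]) / n)


def frequency_table(
    records: Sequence[PatientRecord],
    cluster_labels: Sequence[str],
    battery: Sequence[str] = DEFAULT_BATTERY,
    cutoffs: SymptomCutoffs = DEFAULT_CUTOFFS,
    cluster_order: Optional[Sequence[str]] = None,
) -> FrequencyTable:
    """Per-cluster percentage of PD-MCI and each comorbid symptom.

    ``cluster_labels`` assigns every record to a subgroup.  Percentages are
    ``100 * positives / cluster size`` rounded by :func:`round_percent`;
    empty clusters report missing values.
    """
    if len(records) != len(cluster_labels):
        raise ValueError("records and cluster labels differ in length")
    if cluster_order is None:
        seen: List[str] = []
        for lab in cluster_labels:
            if lab not in seen:
                seen.append(lab)
        cluster_order = seen
    flags_per_record: List[Dict[str, bool]] = []
    for record in records:
        status = diagnose_pdmci(record, battery)
        flags = classify_symptoms(record, cutoffs)
        flags_per_record.append({
            "mci": status.diagnosis,
            "fog": flags.fog,
            "hallucination": flags.hallucination,
            "scopa_ns": flags.scopa_ns,
            "scopa_ds": flags.scopa_ds,
            "ess": flags.ess,
            "rbdsq": flags.rbdsq,
        })
    row_names = [name for name, _ in FREQUENCY_ROWS]
    counts = pd.DataFrame(0, index=row_names, columns=list(cluster_order), dtype=int)
    sizes = pd.Series(0, index=list(cluster_order), dtype=int)
    for lab, flags in zip(cluster_labels, flags_per_record):
        sizes[lab] += 1
        for name, key in FREQUENCY_ROWS:
            counts.loc[name, lab] += int(flags[key])
    percents = pd.DataFrame(index=row_names, columns=list(cluster_order), dtype=object)
    for lab in cluster_order:
        for name, _ in FREQUENCY_ROWS:
            if sizes[lab] == 0:
                percents.loc[name, lab] = pd.NA
            else:
                percents.loc[name, lab] = round_percent(
                    100.0 * counts.loc[name, lab] / sizes[lab]
                )
    return FrequencyTable(percents=percents, counts=counts, sizes=sizes)
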