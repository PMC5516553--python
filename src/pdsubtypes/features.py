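"""Derivation of the nine clustering variables.

The cluster analysis operates on standardized values of: motor phenotype
score, age of disease onset, rate of disease progression, NART-R estimated
IQ, MMSE raw score, Logical Memory II z, Trail Making Test B z, BDI-II raw
score, and a 0-2 dopaminergic-therapy ordinal.

The motor phenotype score is the ratio of mean tremor-item severity to mean
non-tremor-item severity on the MDS-UPDRS, where lateralized items contribute
only their higher (left vs right) score.  The rate of disease progression is
the total MDS-UPDRS I-III score divided by disease duration in years, which
puts patients assessed at a single time point on a common scale.

MDS-UPDRS item numbering dialects differ between sites; the mapping from
score names to tremor/non-tremor sets and to lateralized left/right pairs is
therefore configuration (:class:`ItemMap`), not code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Sequence, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientRecord

logger = logging.getLogger(__name__)

#: Ordered names of the nine clustering variables.
FEATURE_COLUMNS: Tuple[str, ...] = (
    "motor_phenotype",
    "age_onset",
    "progression_rate",
    "nart_iq",
    "mmse_raw",
    "lm2_z",
    "tmtb_z",
    "bdi_total",
    "dopa_ordinal",
)

#: Floor on disease duration (years) in the progression-rate quotient;
#: guards degenerate synthetic durations against explosive rates.
DURATION_FLOOR_YEARS = 0.25

#: Value assigned to the tremor/non-tremor ratio when the non-tremor mean is
#: exactly zero but tremor severity is present (keeps the column finite).
MOTOR_PHENOTYPE_CAP = 5.0


@dataclass(frozen=True)
class ItemMap:
    """Configuration of MDS-UPDRS item sets used by the motor phenotype score.

    ``tremor_items`` and ``nontremor_items`` list *resolved* item names.  A
    resolved name that appears in ``lateralized_pairs`` is scored as the
    higher of its left/right raw scores; any other name is looked up directly
    in the record's raw item map.
    """

    tremor_items: Tuple[str, ...]
    nontremor_items: Tuple[str, ...]
    lateralized_pairs: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.tremor_items) & set(self.nontremor_items)
        if overlap:
            raise ValueError(f"tremor and non-tremor item sets overlap: {sorted(overlap)}")
        for key, pair in self.lateralized_pairs.items():
            if len(pair) != 2:
                raise ValueError(f"lateralized pair for {key!r} must have exactly two sides")

    def raw_keys(self) -> List[str]:
        """All raw item keys this map reads from a record."""
        keys: List[str] = []
        for name in (*self.tremor_items, *self.nontremor_items):
            if name in self.lateralized_pairs:
                keys.extend(self.lateralized_pairs[name])
            else:
                keys.append(name)
        return keys


def _default_item_map() -> ItemMap:
    """Default flattened-numbering dialect.

    Tremor: item 23 (part II tremor), the 54/55 lateralized tremor pair and
    item 59.  Non-tremor: items 28-44 (speech, facial expression, rigidity,
    gait/posture, spontaneity of movement), of which 33-37 (rigidity of neck
    and limbs in this dialect) are stored as left/right pairs.
    """
    pairs = {"item54_55": ("item54", "item55")}
    for i in range(33, 38):
        pairs[f"item{i}"] = (f"item{i}_left", f"item{i}_right")
    return ItemMap(
        tremor_items=("item23", "item54_55", "item59"),
        nontremor_items=tuple(f"item{i}" for i in range(28, 45)),
        lateralized_pairs=pairs,
    )


DEFAULT_ITEM_MAP = _default_item_map()


@dataclass(frozen=True)
class DerivedFeatures:
    """The nine clustering variables for one patient, with intermediates."""

    tremor_score: float
    nontremor_score: float
    motor_phenotype: float
    age_onset: float
    progression_rate: float
    nart_iq: float
    mmse_raw: float
    lm2_z: float
    tmtb_z: float
    bdi_total: float
    dopa_ordinal: int

    def as_row(self) -> Tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_COLUMNS)


@dataclass
class FeatureMatrix:
    """An n x 9 feature grid, optionally column-wise z-standardized.

    ``values`` holds the matrix handed to the clustering engine; ``raw``
    always keeps the pre-standardization values (needed to profile clusters
    on the original scales).
    """

    ids: List[str]
    columns: Tuple[str, ...]
    values: np.ndarray
    raw: np.ndarray
    standardized: bool
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("feature matrix shape does not match ids/columns")

    @property
    def n(self) -> int:
        return len(self.ids)


def compute_progression_rate(updrs_total_i_iii: float, duration_years: float) -> float:
    """Total MDS-UPDRS I-III divided by disease duration (years).

    Durations below :data:`DURATION_FLOOR_YEARS` are floored so that very
    recently diagnosed (synthetic) patients cannot produce unbounded rates.
    """
    if updrs_total_i_iii < 0:
        raise ValueError(f"UPDRS total must be non-negative, got {updrs_total_i_iii}")
    if duration_years <= 0:
        raise ValueError(f"disease duration must be positive, got {duration_years}")
    return updrs_total_i_iii / max(duration_years, DURATION_FLOOR_YEARS)


def lateralized_max(left: float, right: float) -> float:
    """Higher of the left/right scores of a lateralized MDS-UPDRS item."""
    for side, score in (("left", left), ("right", right)):
        if not 0 <= score <= 4:
            raise ValueError(f"{side} score {score} outside the 0-4 item range")
    return max(left, right)


def _resolve_item(record: "PatientRecord", name: str, items: ItemMap) -> float:
    try:
        if name in items.lateralized_pairs:
            lkey, rkey = items.lateralized_pairs[name]
            return lateralized_max(record.updrs_items[lkey], record.updrs_items[rkey])
        return record.updrs_items[name]
    except KeyError as exc:
        raise KeyError(f"record {record.id!r} is missing MDS-UPDRS item {exc.args[0]!r}") from None


def compute_motor_phenotype(
    record: "PatientRecord", items: ItemMap = DEFAULT_ITEM_MAP
) -> Tuple[float, float, float]:
    """Tremor score, non-tremor score and their ratio for one record.

    Returns ``(tremor_score, nontremor_score, motor_phenotype)``.  A zero
    non-tremor denominator with non-zero tremor maps to
    :data:`MOTOR_PHENOTYPE_CAP`; 0/0 maps to 0.
    """
    tremor = [_resolve_item(record, n, items) for n in items.tremor_items]
    nontremor = [_resolve_item(record, n, items) for n in items.nontremor_items]
    t = float(np.mean(tremor))
    nt = float(np.mean(nontremor))
    if nt > 0:
        ratio = t / nt
    elif t > 0:
        ratio = MOTOR_PHENOTYPE_CAP
    else:
        ratio = 0.0
    return t, nt, ratio


def compute_dopa_ordinal(ldopa_mg_per_day: float, da_flag: bool) -> int:
    """Collapse dopaminergic therapy to the 0-2 ordinal.

    0: no L-dopa and no dopamine agonist; 1: L-dopa below 1,000 mg/day
    (with or without an agonist) or agonist monotherapy; 2: L-dopa at or
    above 1,000 mg/day.  The boundary dose of exactly 1,000 mg/day is
    assigned to the higher-exposure class.
    """
    if ldopa_mg_per_day < 0:
        raise ValueError(f"L-dopa dose must be non-negative, got {ldopa_mg_per_day}")
    if ldopa_mg_per_day >= 1000:
        return 2
    if ldopa_mg_per_day > 0 or da_flag:
        return 1
    return 0


def derive_features(record: "PatientRecord", items: ItemMap = DEFAULT_ITEM_MAP) -> DerivedFeatures:
    """Compute all nine clustering variables for one patient record."""
    t, nt, ratio = compute_motor_phenotype(record, items)
    rate = compute_progression_rate(record.updrs_total_i_iii, record.disease_duration)
    return DerivedFeatures(
        tremor_score=t,
        nontremor_score=nt,
        motor_phenotype=ratio,
        age_onset=record.age_onset,
        progression_rate=rate,
        nart_iq=record.nart_iq,
        mmse_raw=record.mmse_raw,
        lm2_z=record.neuropsych["lm2"],
        tmtb_z=record.neuropsych["tmt_b"],
        bdi_total=record.bdi_total,
        dopa_ordinal=compute_dopa_ordinal(record.ldopa_mg_per_day, record.da_flag),
    )


def standardize(values: np.ndarray) -> np.ndarray:
    """Column-wise z-standardization with sample SD (n-1 denominator).

    Constant columns map to all zeros (with a logged warning) rather than
    erroring, so degenerate inputs do not abort a run.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    out = np.zeros_like(values)
    for j in range(values.shape[1]):
        if sd[j] > 0 and math.isfinite(sd[j]):
            out[:, j] = (values[:, j] - mean[j]) / sd[j]
        else:
            logger.warning("constant column %d standardized to zeros", j)
    return out


def build_feature_matrix(
    cohort: Sequence["PatientRecord"],
    items: ItemMap = DEFAULT_ITEM_MAP,
    standardize_columns: bool = True,
) -> FeatureMatrix:
    """Derive the n x 9 feature matrix for a cohort and z-standardize it.

    Records missing any constituent (an MDS-UPDRS item, a neuropsychological
    score) are dropped and counted in ``n_dropped``; an all-incomplete cohort
    is an error.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    ids: List[str] = []
    rows: List[Tuple[float, ...]] = []
    dropped = 0
    for record in cohort:
        try:
            rows.append(derive_features(record, items).as_row())
        except KeyError as exc:
            logger.info("dropping incomplete record: %s", exc)
            dropped += 1
            continue
        ids.append(record.id)
    if not rows:
        raise ValueError("no complete records: every record is missing a clustering constituent")
    if dropped:
        logger.info("dropped %d incomplete record(s) from the feature matrix", dropped)
    raw = np.asarray(rows, dtype=float)
    values = standardize(raw) if standardize_columns else raw.copy()
    return FeatureMatrix(
        ids=ids,
        columns=FEATURE_COLUMNS,
        values=values,
        raw=raw,
        standardized=standardize_columns,
        n_dropped=dropped,
    )


def pdq39_dimension_score(item_scores: Sequence[float]) -> float:
    """Scale a PDQ-39 dimension to 0-100: ``100 * sum / (4 * n_items)``."""
    if len(item_scores) == 0:
        raise ValueError("PDQ-39 dimension needs at least one item")
    for score in item_scores:
        if not 0 <= score <= 4:
            raise ValueError(f"PDQ-39 item score {score} outside the 0-4 range")
    return 100.0 * float(sum(item_scores)) / (4.0 * len(item_scores))
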