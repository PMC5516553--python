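"""End-to-end orchestration, CSV I/O and report rendering.

``run_pipeline`` chains the full analysis: load or generate a cohort, derive
and standardize the nine clustering variables, scan k = 2..5 with the cubic
clustering criterion, name the subgroups, classify PD-MCI and comorbid
symptoms, tabulate per-subgroup frequencies, and compare the held-out
validation variables.  Every run is deterministic given its seed, and the
written manifest records everything needed to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .classify import (
    DEFAULT_BATTERY,
    DEFAULT_CUTOFFS,
    FrequencyTable,
    SymptomCutoffs,
    classify_symptoms,
    diagnose_pdmci,
    frequency_table,
)
from .cluster import CCCProfile, ClusterSolution, label_clusters, run_cluster_scan
from .cohort import (
    BATTERY_TESTS,
    ClusterProfile,
    CohortSpec,
    PatientRecord,
    default_profiles,
    generate_cohort,
)
from .features import DEFAULT_ITEM_MAP, FeatureMatrix, ItemMap, build_feature_matrix
from .stats import ValidationReport, ks_normality, omnibus, validate_solution

logger = logging.getLogger(__name__)

_SCALAR_COLUMNS: Tuple[Tuple[str, type], ...] = (
    ("age", float), ("sex", str), ("age_onset", float),
    ("disease_duration", float), ("hy_stage", float),
    ("updrs_part1", float), ("updrs_part2", float), ("updrs_part3", float),
    ("updrs_1_1", int), ("updrs_1_2", int),
    ("nart_iq", float), ("mmse_raw", int),
    ("bdi_total", int), ("ess_total", int), ("scopa_ds", int),
    ("scopa_ns", int), ("rbdsq_total", int), ("fogq_item3", int),
    ("scopa_pc_item1", int), ("ldopa_mg_per_day", float), ("da_flag", bool),
)

_RANGE_CHECKS: Dict[str, Tuple[float, float]] = {
    "bdi_total": (0, 63), "ess_total": (0, 24), "scopa_ds": (0, 18),
    "scopa_ns": (0, 15), "rbdsq_total": (0, 13), "fogq_item3": (0, 4),
    "scopa_pc_item1": (0, 3), "updrs_1_1": (0, 4), "updrs_1_2": (0, 4),
    "hy_stage": (1, 3), "mmse_raw": (0, 30),
}

_PDQ_KEYS = ("q30", "q31", "q32", "q33")


def _item_columns(item_map: ItemMap) -> List[str]:
    return sorted(item_map.raw_keys())


def write_cohort_csv(
    records: Sequence[PatientRecord],
    path: str | Path,
    spec: Optional[CohortSpec] = None,
) -> None:
    """Write a cohort as one-row-per-patient CSV (UTF-8, '.' decimal).

    A sidecar ``<path>.meta.json`` records the generating spec and seed when
    one is supplied.
    """
    path = Path(path)
    rows = []
    for record in records:
        row: Dict[str, object] = {"id": record.id}
        for name, _ in _SCALAR_COLUMNS:
            row[name] = getattr(record, name)
        for key in sorted(record.updrs_items):
            row[key] = record.updrs_items[key]
        for test in BATTERY_TESTS:
            row[f"z_{test}"] = record.neuropsych[test]
        for key in _PDQ_KEYS:
            row[f"pdq39_{key}"] = record.pdq39_items[key]
        row["latent_cluster"] = record.latent_cluster if record.latent_cluster else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
    if spec is not None:
        meta = {
            "n": spec.n, "seed": spec.seed, "mode": spec.mode,
            "profiles": [profile_to_dict(p) for p in spec.profiles],
            "package_version": _version,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort_csv(path: str | Path, item_map: ItemMap = DEFAULT_ITEM_MAP) -> List[PatientRecord]:
    """Read a cohort CSV back into records; lossless round-trip of all fields."""
    frame = pd.read_csv(path, encoding="utf-8", keep_default_na=True,
                        float_precision="round_trip")
    mandatory = (
        ["id"] + [name for name, _ in _SCALAR_COLUMNS]
        + _item_columns(item_map)
        + [f"z_{t}" for t in BATTERY_TESTS]
        + [f"pdq39_{k}" for k in _PDQ_KEYS]
    )
    for column in mandatory:
        if column not in frame.columns:
            raise ValueError(f"cohort file {path} is missing mandatory column {column!r}")
    item_cols = [c for c in frame.columns if c.startswith("item")]
    records: List[PatientRecord] = []
    for idx, row in frame.iterrows():
        for column, (lo, hi) in _RANGE_CHECKS.items():
            value = row[column]
            if not lo <= value <= hi:
                raise ValueError(
                    f"{path} row {idx + 2}: column {column!r} value {value} "
                    f"outside [{lo}, {hi}]"
                )
        latent = row.get("latent_cluster")
        if pd.isna(latent) or latent == "":
            latent = None
        records.append(PatientRecord(
            id=str(row["id"]),
            age=float(row["age"]), sex=str(row["sex"]),
            age_onset=float(row["age_onset"]),
            disease_duration=float(row["disease_duration"]),
            hy_stage=float(row["hy_stage"]),
            updrs_items={c: float(row[c]) for c in item_cols},
            updrs_part1=float(row["updrs_part1"]),
            updrs_part2=float(row["updrs_part2"]),
            updrs_part3=float(row["updrs_part3"]),
            updrs_1_1=int(row["updrs_1_1"]), updrs_1_2=int(row["updrs_1_2"]),
            nart_iq=float(row["nart_iq"]), mmse_raw=int(row["mmse_raw"]),
            neuropsych={t: float(row[f"z_{t}"]) for t in BATTERY_TESTS},
            bdi_total=int(row["bdi_total"]), ess_total=int(row["ess_total"]),
            scopa_ds=int(row["scopa_ds"]), scopa_ns=int(row["scopa_ns"]),
            rbdsq_total=int(row["rbdsq_total"]),
            fogq_item3=int(row["fogq_item3"]),
            scopa_pc_item1=int(row["scopa_pc_item1"]),
            pdq39_items={k: float(row[f"pdq39_{k}"]) for k in _PDQ_KEYS},
            ldopa_mg_per_day=float(row["ldopa_mg_per_day"]),
            da_flag=bool(row["da_flag"]),
            latent_cluster=str(latent) if latent is not None else None,
        ))
    return records


def profile_to_dict(profile: ClusterProfile) -> Dict:
    return dataclasses.asdict(profile)


def profile_from_dict(data: Dict) -> ClusterProfile:
    cont = {k: tuple(v) for k, v in data["continuous_params"].items()}
    return ClusterProfile(
        label=data["label"], weight=data["weight"], continuous_params=cont,
        binary_prevalences=dict(data["binary_prevalences"]),
        mci_prevalence=data["mci_prevalence"],
    )


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    seed: int = 0
    n: int = 209
    mode: str = "profile"
    cohort_path: Optional[str] = None
    profiles: List[ClusterProfile] = field(default_factory=default_profiles)
    item_map: ItemMap = field(default_factory=lambda: DEFAULT_ITEM_MAP)
    battery: Tuple[str, ...] = DEFAULT_BATTERY
    cutoffs: SymptomCutoffs = DEFAULT_CUTOFFS
    k_range: Tuple[int, ...] = (2, 3, 4, 5)
    restarts: int = 50
    outdir: Optional[str] = None

    def validate(self, n_available: int) -> None:
        for k in self.k_range:
            if not 2 <= k <= max(2, n_available - 1):
                raise ValueError(f"k={k} outside [2, n-1] for n={n_available}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    config: RunConfig
    n_total: int
    n_dropped: int
    features: FeatureMatrix
    solutions: List[ClusterSolution]
    ccc_profile: CCCProfile
    selected: ClusterSolution
    cluster_names: Dict[int, str]
    label_evidence: pd.DataFrame
    characteristics: pd.DataFrame     # per-subgroup mean (SD) of the 9 variables
    validation: ValidationReport
    frequencies: FrequencyTable
    flags: pd.DataFrame               # per-patient classifications
    assignments: pd.DataFrame         # patient id, cluster index, subgroup name

    def manifest(self) -> Dict:
        return {
            "package_version": _version,
            "seed": self.config.seed,
            "n_total": self.n_total,
            "n_dropped": self.n_dropped,
            "mode": self.config.mode,
            "cohort_path": self.config.cohort_path,
            "k_range": list(self.config.k_range),
            "restarts": self.config.restarts,
            "selected_k": self.ccc_profile.selected_k,
            "selection_kind": self.ccc_profile.selection_kind,
            "ccc": dict(zip(
                map(str, self.ccc_profile.k_values), self.ccc_profile.ccc_values
            )),
            "cutoffs": dataclasses.asdict(self.config.cutoffs),
            "profiles": [profile_to_dict(p) for p in self.config.profiles],
        }


def _characteristics_table(
    features: FeatureMatrix, labels_by_row: Sequence[str], order: Sequence[str]
) -> pd.DataFrame:
    """Per-subgroup mean/SD of each raw clustering variable plus an omnibus test."""
    frame = pd.DataFrame(features.raw, columns=list(features.columns))
    frame["subgroup"] = list(labels_by_row)
    rows = []
    for variable in features.columns:
        samples = [frame.loc[frame["subgroup"] == lab, variable].to_numpy() for lab in order]
        row: Dict[str, object] = {"variable": variable}
        for lab, sample in zip(order, samples):
            row[f"{lab}_mean"] = float(np.mean(sample)) if sample.size else float("nan")
            row[f"{lab}_sd"] = float(np.std(sample, ddof=1)) if sample.size > 1 else float("nan")
        usable = [s for s in samples if s.size >= 2]
        if len(usable) >= 2:
            parametric = all(
                not ks_normality(s).significant for s in usable if s.size >= 5
            )
            result = omnibus(usable, parametric, variable)
            row["test"] = result.test
            row["statistic"] = result.statistic
            row["p_value"] = result.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full subtyping analysis; deterministic given the seed."""
    if config.cohort_path:
        records = read_cohort_csv(config.cohort_path, config.item_map)
        spec = None
    else:
        spec = CohortSpec(n=config.n, seed=config.seed, profiles=config.profiles,
                          mode=config.mode)
        records = generate_cohort(spec, config.item_map)
    n_total = len(records)
    logger.info("cohort loaded: %d records", n_total)

    features = build_feature_matrix(records, config.item_map)
    config.validate(features.n)
    by_id = {r.id: r for r in records}
    clustered_records = [by_id[i] for i in features.ids]

    solutions, profile = run_cluster_scan(
        features, k_range=config.k_range, restarts=config.restarts, seed=config.seed
    )
    selected = next(s for s in solutions if s.k == profile.selected_k)
    names, evidence = label_clusters(selected, features)
    logger.info("selected k=%d (%s)", profile.selected_k, profile.selection_kind)

    row_labels = [names[int(c)] for c in selected.labels]
    order = [names[j] for j in range(selected.k)]

    characteristics = _characteristics_table(features, row_labels, order)
    validation = validate_solution(clustered_records, row_labels)
    frequencies = frequency_table(
        clustered_records, row_labels, battery=config.battery,
        cutoffs=config.cutoffs, cluster_order=order,
    )

    flag_rows = []
    for record, lab in zip(clustered_records, row_labels):
        status = diagnose_pdmci(record, config.battery)
        flags = classify_symptoms(record, config.cutoffs)
        flag_rows.append({
            "id": record.id, "subgroup": lab,
            "latent_cluster": record.latent_cluster,
            "pd_mci": status.diagnosis,
            "impaired_tests": status.impaired_test_count,
            "subjective_complaint": status.subjective_flag,
            "depression": flags.depression, "fog": flags.fog,
            "hallucination": flags.hallucination, "scopa_ns": flags.scopa_ns,
            "scopa_ds": flags.scopa_ds, "ess": flags.ess, "rbdsq": flags.rbdsq,
        })
    flags_frame = pd.DataFrame(flag_rows)

    assignments = pd.DataFrame({
        "id": features.ids,
        "cluster": [int(c) for c in selected.labels],
        "subgroup": row_labels,
    })

    report = RunReport(
        config=config, n_total=n_total, n_dropped=features.n_dropped,
        features=features, solutions=solutions, ccc_profile=profile,
        selected=selected, cluster_names=names, label_evidence=evidence,
        characteristics=characteristics, validation=validation,
        frequencies=frequencies, flags=flags_frame, assignments=assignments,
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(records, outdir / "cohort.csv", spec)
        pd.DataFrame(features.values, columns=list(features.columns)).assign(
            id=features.ids
        ).to_csv(outdir / "features.csv", index=False)
        assignments.to_csv(outdir / "assignments.csv", index=False)
        profile.to_frame().to_csv(outdir / "ccc_profile.csv", index=False)
        characteristics.to_csv(outdir / "table1_characteristics.csv", index=False)
        validation.to_frame().to_csv(outdir / "table2_validation.csv", index=False)
        frequencies.percents.to_csv(outdir / "table3_frequencies.csv")
        frequencies.counts.to_csv(outdir / "table3_counts.csv")
        flags_frame.to_csv(outdir / "flags.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(report.manifest(), indent=2))
        logger.info("artifacts written to %s", outdir)

    return report
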