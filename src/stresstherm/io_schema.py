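"""Observation data model, CSV/Newick input, and inclusion rules.

One :class:`ObservationRecord` is one study-group observation of a
stress-induced body-temperature change, with the covariates the
meta-regression needs (air temperature, body mass, latency, technique,
age class) and their dispersions.  A :class:`Dataset` is an ordered
collection of records plus a filter log that accounts for every record
removed by an inclusion rule, so that `filter_log + retained = input`
always holds.

Inclusion rules implemented here:

* latency longer than 8 h (28 800 s) excludes the record;
* pharmacological manipulation (other than saline) excludes the record;
* effect-size outliers: records whose log response ratio lies more than
  3.5 sample s.d. from the sample mean AND whose implied absolute
  body-temperature change exceeds 10 deg C are excluded (iterated to a
  fixed point so that filtering is idempotent).

Imputation rules:

* a reported mass range is replaced by its midpoint, with s.d. = range/4;
* missing air-temperature s.d. is set to the mean of the observed ones;
* missing mass s.d. is set to (mean observed CV of mass) x record mass.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Tuple

import dendropy
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ObservationRecord",
    "Dataset",
    "SchemaError",
    "ValidationFailure",
    "LATENCY_CUTOFF_S",
    "read_observations",
    "write_observations",
    "impute_mass_from_range",
    "impute_missing_sds",
    "apply_inclusion_filters",
    "read_tree",
    "normalize_species_name",
]

#: Latency exclusion threshold: 8 hours in seconds (strictly greater excludes).
LATENCY_CUTOFF_S = 28_800.0

#: Outlier screen constants: z-score multiplier and absolute-change cutoff.
OUTLIER_SD_MULTIPLIER = 3.5
OUTLIER_DELTA_T_C = 10.0


class SchemaError(ValueError):
    """Input file violates the observation-table contract."""


class ValidationFailure(ValueError):
    """A record or record collection violates a schema invariant."""


class ObservationRecord(BaseModel):
    """One study-group observation of a stress-induced thermal response.

    ``tb_baseline`` is the pre-stress body temperature for a pre/post
    design, or the control-arm temperature for a stressed-vs-control
    design; ``tb_response`` is the extreme (min or max) post-stress body
    temperature, or the stressed-arm temperature.
    """

    model_config = ConfigDict(validate_assignment=True)

    study_id: str
    group_id: str
    species: str
    family: str = ""
    taxon_class: Literal["bird", "mammal"]
    n_individuals: int = Field(ge=1)
    tb_baseline: float = Field(gt=0.0, lt=50.0)
    tb_baseline_sd: Optional[float] = Field(default=None, ge=0.0)
    tb_response: float = Field(gt=0.0, lt=50.0)
    tb_response_sd: Optional[float] = Field(default=None, ge=0.0)
    design: Literal["pre_post", "stressed_vs_control"]
    pooled_se_reported: Optional[float] = Field(default=None, ge=0.0)
    air_temp: float
    air_temp_sd: Optional[float] = Field(default=None, ge=0.0)
    mass: Optional[float] = Field(default=None, gt=0.0)
    mass_sd: Optional[float] = Field(default=None, ge=0.0)
    mass_range: Optional[Tuple[float, float]] = None
    latency: float = Field(ge=0.0)
    technique: Literal["telemetry", "thermocouple"]
    age_class: Literal[-1, 0, 1] = 1  # missing age class defaults to adult
    sex: Literal["female", "male", "mixed"] = "mixed"
    season: Literal["spring", "summer", "autumn", "winter", "NA"] = "NA"
    pharma_flag: bool = False

    @model_validator(mode="after")
    def _check_mass_source(self) -> "ObservationRecord":
        if self.mass is None and self.mass_range is None:
            raise ValueError("record needs either mass or mass_range")
        if self.mass_range is not None:
            lo, hi = self.mass_range
            if hi < lo:
                raise ValueError(f"inverted mass_range ({lo}, {hi})")
            if lo <= 0:
                raise ValueError("mass_range bounds must be positive")
        return self

    @property
    def record_id(self) -> str:
        return f"{self.study_id}/{self.group_id}"


@dataclass
class FilterEvent:
    """One exclusion: which record, which rule, and the offending value."""

    record: str
    rule: str
    value: float | bool | str

    def to_json(self) -> str:
        return json.dumps(
            {"record": self.record, "rule": self.rule, "value": self.value}
        )


@dataclass
class Dataset:
    """Ordered observation records plus an exclusion audit trail."""

    records: list[ObservationRecord]
    provenance: str = ""
    filter_log: list[FilterEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.study_id, rec.group_id)
            if key in seen:
                raise ValidationFailure(
                    f"duplicated (study_id, group_id) pair: {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = rec.model_dump()
            rng = row.pop("mass_range")
            row["mass_range_lo"] = rng[0] if rng else None
            row["mass_range_hi"] = rng[1] if rng else None
            rows.append(row)
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def species_set(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return out

    def write_filter_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self.filter_log:
                fh.write(ev.to_json() + "\n")


_MANDATORY_COLUMNS = [
    "study_id", "group_id", "species", "taxon_class", "n_individuals",
    "tb_baseline", "tb_response", "design", "air_temp", "latency",
    "technique",
]
_CSV_COLUMNS = [
    "study_id", "group_id", "species", "family", "taxon_class",
    "n_individuals", "tb_baseline", "tb_baseline_sd", "tb_response",
    "tb_response_sd", "design", "pooled_se_reported", "air_temp",
    "air_temp_sd", "mass", "mass_sd", "mass_range_lo", "mass_range_hi",
    "latency", "technique", "age_class", "sex", "season", "pharma_flag",
]
_OPTIONAL_DEFAULTS = {"family": "", "age_class": 1, "sex": "mixed",
                      "season": "NA", "pharma_flag": False}


def _parse_row(row: pd.Series) -> ObservationRecord:
    kw: dict = {}
    for col in _CSV_COLUMNS:
        if col in ("mass_range_lo", "mass_range_hi"):
            continue
        if col not in row.index:
            if col in _OPTIONAL_DEFAULTS:
                kw[col] = _OPTIONAL_DEFAULTS[col]
            continue
        val = row[col]
        if pd.isna(val) or (isinstance(val, str) and val == ""):
            if col in _OPTIONAL_DEFAULTS:
                kw[col] = _OPTIONAL_DEFAULTS[col]
            continue
        kw[col] = val
    lo = row.get("mass_range_lo")
    hi = row.get("mass_range_hi")
    if lo is not None and hi is not None and not (pd.isna(lo) or pd.isna(hi)):
        kw["mass_range"] = (float(lo), float(hi))
    if "n_individuals" in kw:
        kw["n_individuals"] = int(kw["n_individuals"])
    if "age_class" in kw:
        kw["age_class"] = int(kw["age_class"])
    if "pharma_flag" in kw and isinstance(kw["pharma_flag"], str):
        kw["pharma_flag"] = kw["pharma_flag"].strip().lower() in ("true", "1", "yes")
    if "season" in kw and isinstance(kw["season"], str):
        kw["season"] = kw["season"].strip()
    return ObservationRecord(**kw)


def read_observations(
    path: str | Path, *, strict: bool = False
) -> tuple[Dataset, list[str]]:
    """Read the observation table; returns (dataset, row-error messages).

    Mandatory columns missing from the header raise :class:`SchemaError`.
    Rows that fail to parse are skipped and described in the returned
    error list (``strict=True`` raises on the first bad row instead).
    Extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"observation file not found: {path}")
    df = pd.read_csv(path, dtype={"study_id": str, "group_id": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    records: list[ObservationRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(row))
        except Exception as exc:  # row-level: report and continue
            msg = f"row {i} ({row.get('study_id')}/{row.get('group_id')}): {exc}"
            if strict:
                raise ValidationFailure(msg) from exc
            errors.append(msg)
    return Dataset(records=records, provenance=str(path)), errors


def write_observations(ds: Dataset, path: str | Path) -> None:
    """Write the dataset back to CSV (round-trips clean files)."""
    ds.to_dataframe().to_csv(path, index=False)


def impute_mass_from_range(rec: ObservationRecord) -> ObservationRecord:
    """Replace a reported mass range with its midpoint; s.d. = width / 4."""
    if rec.mass_range is None:
        raise ValidationFailure(f"{rec.record_id}: no mass_range to impute from")
    if rec.mass is not None:
        raise ValidationFailure(f"{rec.record_id}: mass already present")
    lo, hi = rec.mass_range
    return rec.model_copy(
        update={"mass": (lo + hi) / 2.0, "mass_sd": (hi - lo) / 4.0}
    )


def impute_missing_sds(ds: Dataset) -> tuple[Dataset, list[str]]:
    """Fill missing air-temperature and mass dispersions across the table.

    Missing ``air_temp_sd`` is set to the mean of the observed air-temp
    s.d. values; missing ``mass_sd`` to the mean observed coefficient of
    variation of mass times the record's mass.  Records carrying a mass
    range (and no mass) are first resolved by :func:`impute_mass_from_range`.
    Returns the new dataset and a log of imputations performed.
    """
    log: list[str] = []
    records = list(ds.records)
    for i, rec in enumerate(records):
        if rec.mass is None and rec.mass_range is not None:
            records[i] = impute_mass_from_range(rec)
            log.append(f"{rec.record_id}: mass from range -> {records[i].mass}")

    air_sds = [r.air_temp_sd for r in records if r.air_temp_sd is not None]
    needs_air = [r for r in records if r.air_temp_sd is None]
    if needs_air and not air_sds:
        raise ValidationFailure("no observed air_temp_sd to impute from")
    mean_air_sd = sum(air_sds) / len(air_sds) if air_sds else None

    cvs = [r.mass_sd / r.mass for r in records
           if r.mass_sd is not None and r.mass is not None and r.mass > 0]
    needs_mass = [r for r in records if r.mass_sd is None]
    if needs_mass and not cvs:
        raise ValidationFailure("no observed mass_sd to impute a mass CV from")
    mean_cv = sum(cvs) / len(cvs) if cvs else None

    for i, rec in enumerate(records):
        update: dict = {}
        if rec.air_temp_sd is None:
            update["air_temp_sd"] = mean_air_sd
            log.append(f"{rec.record_id}: air_temp_sd <- {mean_air_sd:.6g}")
        if rec.mass_sd is None:
            update["mass_sd"] = mean_cv * rec.mass
            log.append(f"{rec.record_id}: mass_sd <- {update['mass_sd']:.6g}")
        if update:
            records[i] = rec.model_copy(update=update)
    return Dataset(records, ds.provenance, list(ds.filter_log)), log


def _record_lrr(rec: ObservationRecord) -> float:
    # local import: effect_size depends on this module's types
    from stresstherm.effect_size import response_ratio

    return response_ratio(rec).lrr


def apply_inclusion_filters(
    ds: Dataset,
    tb0_default: Optional[float] = None,
    *,
    outlier_rule: Literal["and", "or"] = "and",
) -> Dataset:
    """Apply the latency, pharmacology, and effect-size outlier screens.

    ``tb0_default`` sets the baseline used to convert a log response
    ratio into an absolute temperature change for the 10 deg C arm of the
    outlier screen; by default each record's own denominator temperature
    is used.  The outlier screen conjoins its two descriptors
    (``outlier_rule="and"``); the either-or reading is available as a
    sensitivity switch.  The screen is iterated to a fixed point, so
    applying this function twice equals applying it once.
    """
    kept: list[ObservationRecord] = []
    log = list(ds.filter_log)
    for rec in ds.records:
        if rec.latency > LATENCY_CUTOFF_S:
            log.append(FilterEvent(rec.record_id, "latency_8h", rec.latency))
        elif rec.pharma_flag:
            log.append(FilterEvent(rec.record_id, "pharma", True))
        else:
            kept.append(rec)

    # effect-size outlier screen, iterated to a fixed point
    while len(kept) >= 2:
        lrrs = [_record_lrr(r) for r in kept]
        mean = sum(lrrs) / len(lrrs)
        sd = math.sqrt(sum((x - mean) ** 2 for x in lrrs) / (len(lrrs) - 1))
        removed_any = False
        next_kept: list[ObservationRecord] = []
        for rec, lrr in zip(kept, lrrs):
            extreme = sd > 0 and abs(lrr - mean) > OUTLIER_SD_MULTIPLIER * sd
            tb0 = tb0_default if tb0_default is not None else rec.tb_baseline
            delta_t = tb0 * (math.exp(lrr) - 1.0)
            big_shift = abs(delta_t) > OUTLIER_DELTA_T_C
            hit = (extreme and big_shift) if outlier_rule == "and" else (
                extreme or big_shift
            )
            if hit:
                log.append(FilterEvent(rec.record_id, "outlier_3.5sd_10C", lrr))
                removed_any = True
            else:
                next_kept.append(rec)
        kept = next_kept
        if not removed_any:
            break
    return Dataset(kept, ds.provenance, log)


def normalize_species_name(name: str) -> str:
    """Canonical species label: lower case, underscores as spaces, squeezed."""
    return re.sub(r"\s+", " ", name.replace("_", " ").strip()).lower()


def read_tree(
    path: str | Path,
    taxon_class: str = "",
    *,
    required_species: Optional[Sequence[str]] = None,
) -> dendropy.Tree:
    """Read a rooted Newick tree with strictly positive branch lengths.

    ``required_species`` (dataset species labels) are matched to tips
    after whitespace/underscore/case normalization; any absent species
    raises an error listing them.  Fuzzy matching is deliberately not
    attempted.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"tree file not found: {path}")
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationFailure(
                f"{path}: edge above {edge.head_node} lacks a branch length"
            )
        if edge.length <= 0:
            raise ValidationFailure(
                f"{path}: non-positive branch length {edge.length}"
            )
    if required_species is not None:
        tips = {normalize_species_name(t.label) for t in tree.taxon_namespace}
        missing = [
            s for s in required_species if normalize_species_name(s) not in tips
        ]
        if missing:
            raise ValidationFailure(
                f"species absent from {taxon_class or 'tree'} tips: {missing}"
            )
    return tree


def dataset_from_records(
    records: Iterable[ObservationRecord], provenance: str = ""
) -> Dataset:
    return Dataset(list(records), provenance)
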