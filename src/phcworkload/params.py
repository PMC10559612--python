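"""Region parameter sets: domain types, CSV/YAML readers/writers, validation.

A *region parameter workbook* is a directory of plain-text files describing
everything the workload model needs for one catchment region:

    tasks.csv        one row per clinical task (service catalog)
    fertility.csv    age-banded annual fertility rates with year-over-year trend
    mortality.csv    age-banded annual mortality rates with year-over-year trend
    seasonality.csv  curve_id, m1..m12 monthly weights; each row sums to 1
    population.csv   age, female, male baseline counts (single-year ages 0-100)
    region.yaml      region_name, start_year, end_year

Conventions: all rates are annual proportions of the relevant population;
an *annual change* is a multiplicative year-over-year ratio (1.0 = no change,
0.98 = 2% annual decline); task age bounds are in whole years, inclusive
(so a service for children aged 0-59 months spans years 0-4).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SERVICE_CATEGORIES",
    "FERTILITY_BANDS",
    "MAX_AGE",
    "ParameterError",
    "Violation",
    "RelevantPopulationSpec",
    "ClinicalTask",
    "RateSchedule",
    "SeasonalityCurve",
    "PopulationPyramid",
    "RegionParameters",
    "parse_band",
    "band_label",
    "load_region_parameters",
    "write_region_parameters",
    "validate",
]

MAX_AGE = 100

#: The twelve service categories of the primary-care package.
SERVICE_CATEGORIES = (
    "family_planning",
    "nutrition",
    "pregnancy",
    "sick_child",
    "ncds",
    "malaria",
    "ntds",
    "sexual_health",
    "first_aid",
    "tb",
    "hiv",
    "mental_health",
)

#: Reproductive-age bands a fertility schedule must cover (5-year bands).
FERTILITY_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(15, 50, 5))


class ParameterError(ValueError):
    """Raised when a parameter workbook cannot be parsed.

    The message carries file and row context so broken inputs can be fixed
    without reading a stack trace.
    """


def parse_band(label: str) -> tuple[int, int]:
    """Parse an age-band label like ``"15-19"`` into inclusive bounds."""
    try:
        lo_s, hi_s = str(label).split("-")
        lo, hi = int(lo_s), int(hi_s)
    except Exception as exc:  # noqa: BLE001 - rewrap with context
        raise ParameterError(f"malformed age band label {label!r}") from exc
    if lo > hi:
        raise ParameterError(f"age band {label!r} has low > high")
    return lo, hi


def band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelevantPopulationSpec:
    """Who a clinical task applies to.

    ``state="general"`` selects a standing cohort by sex and inclusive age
    bounds; ``state="birth_linked"`` selects the year's expected births
    (pregnancy, delivery, postnatal and newborn services), in which case the
    age bounds are ignored.
    """

    sex: str = "both"  # female | male | both
    age_low: int = 0
    age_high: int = MAX_AGE
    state: str = "general"  # general | birth_linked

    @property
    def birth_linked(self) -> bool:
        return self.state == "birth_linked"


@dataclass(frozen=True)
class ClinicalTask:
    """One service task in the catalog.

    ``rate`` is the annual proportion of the relevant population needing the
    service (incidence or prevalence, used identically; ``rate_kind`` is
    metadata). ``annual_change`` is the multiplicative year-over-year trend in
    the rate. ``contact_offsets`` shifts each contact along the task's
    seasonality curve in whole months (e.g. antenatal visits sit at negative
    offsets relative to the birth curve).
    """

    task_name: str
    service_category: str
    relevant_population: RelevantPopulationSpec
    rate: float
    num_contacts: int
    minutes_per_contact: float
    rate_kind: str = "incidence"  # incidence | prevalence
    rate_spread: float = 0.0
    annual_change: float = 1.0
    annual_change_spread: float = 0.0
    seasonality_curve_id: str | None = None
    contact_offsets: tuple[int, ...] = ()

    def offsets_or_default(self) -> tuple[int, ...]:
        """Contact offsets, defaulting to all-zero when none were supplied."""
        if self.contact_offsets:
            return self.contact_offsets
        return (0,) * self.num_contacts


@dataclass(frozen=True)
class RateSchedule:
    """Age-banded annual fertility or mortality rates with trend and spread.

    ``bands`` maps an age-band label ("15-19") to the baseline annual rate per
    person; ``annual_change`` to its year-over-year ratio; ``rate_spread`` and
    ``change_spread`` to the half-widths used for Monte Carlo sampling.
    """

    kind: str  # fertility | mortality
    bands: Mapping[str, float]
    annual_change: Mapping[str, float]
    rate_spread: Mapping[str, float] = field(default_factory=dict)
    change_spread: Mapping[str, float] = field(default_factory=dict)

    def spread_for(self, band: str) -> float:
        return float(self.rate_spread.get(band, 0.0))

    def change_spread_for(self, band: str) -> float:
        return float(self.change_spread.get(band, 0.0))

    def age_rate_array(self) -> np.ndarray:
        """Per-single-year-age rate array (length MAX_AGE+1), 0 where uncovered."""
        rates = np.zeros(MAX_AGE + 1)
        for label, rate in self.bands.items():
            lo, hi = parse_band(label)
            rates[lo : min(hi, MAX_AGE) + 1] = rate
        return rates


@dataclass(frozen=True)
class SeasonalityCurve:
    """Twelve monthly weights giving a condition's within-year frequency.

    Weights are non-negative and sum to 1 (tolerance 1e-9 at validation).
    """

    curve_id: str
    weights: tuple[float, ...]

    def weights_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass
class PopulationPyramid:
    """Single-year age x sex population counts for one calendar year.

    Counts are real-valued persons (cohort-component arithmetic produces
    fractional people); arrays span ages 0..100 inclusive.
    """

    year: int
    female: np.ndarray
    male: np.ndarray

    def __post_init__(self) -> None:
        self.female = np.asarray(self.female, dtype=float)
        self.male = np.asarray(self.male, dtype=float)
        if self.female.shape != (MAX_AGE + 1,) or self.male.shape != (MAX_AGE + 1,):
            raise ValueError(
                f"pyramid arrays must have length {MAX_AGE + 1} (ages 0..{MAX_AGE})"
            )

    def total(self) -> float:
        return float(self.female.sum() + self.male.sum())

    def count(self, sex: str, age_low: int = 0, age_high: int = MAX_AGE) -> float:
        """Sum of counts for a sex ('female'|'male'|'both') and inclusive age range."""
        sl = slice(age_low, age_high + 1)
        if sex == "female":
            return float(self.female[sl].sum())
        if sex == "male":
            return float(self.male[sl].sum())
        if sex == "both":
            return float(self.female[sl].sum() + self.male[sl].sum())
        raise ValueError(f"unknown sex {sex!r}")

    def scaled_to(self, target_total: float) -> "PopulationPyramid":
        """Rescale all counts so the pyramid totals ``target_total`` exactly,
        preserving the age/sex shape."""
        total = self.total()
        if total <= 0:
            raise ValueError("cannot rescale an empty pyramid")
        f = target_total / total
        return PopulationPyramid(self.year, self.female * f, self.male * f)

    def copy(self) -> "PopulationPyramid":
        return PopulationPyramid(self.year, self.female.copy(), self.male.copy())

    def to_frame(self) -> pd.DataFrame:
        """Tidy (year, age, sex, count) representation."""
        ages = np.arange(MAX_AGE + 1)
        return pd.DataFrame(
            {
                "year": self.year,
                "age": np.concatenate([ages, ages]),
                "sex": ["female"] * (MAX_AGE + 1) + ["male"] * (MAX_AGE + 1),
                "count": np.concatenate([self.female, self.male]),
            }
        )


@dataclass
class RegionParameters:
    """A complete, self-contained input set for one region."""

    region_name: str
    baseline_pyramid: PopulationPyramid
    fertility: RateSchedule
    mortality: RateSchedule
    tasks: list[ClinicalTask]
    curves: list[SeasonalityCurve]
    start_year: int
    end_year: int

    def curve_map(self) -> dict[str, SeasonalityCurve]:
        return {c.curve_id: c for c in self.curves}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One broken invariant: which entity, which rule, and a readable message."""

    entity: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: [{self.rule}] {self.message}"


def _check(cond: bool, out: list[Violation], entity: str, rule: str, msg: str) -> None:
    if not cond:
        out.append(Violation(entity, rule, msg))


def validate(params: RegionParameters) -> list[Violation]:
    """Check every type invariant; return violations instead of raising.

    An empty list means the parameter set is safe to simulate.
    """
    v: list[Violation] = []
    curve_ids = {c.curve_id for c in params.curves}

    # pyramid
    pyr = params.baseline_pyramid
    _check(
        bool(np.all(pyr.female >= 0)) and bool(np.all(pyr.male >= 0)),
        v, "baseline_pyramid", "nonnegative_counts", "population counts must be >= 0",
    )
    _check(pyr.total() > 0, v, "baseline_pyramid", "positive_total",
           "total population must be > 0")

    _check(params.start_year < params.end_year, v, params.region_name,
           "year_order", "start_year must precede end_year")

    # seasonality curves
    for curve in params.curves:
        w = curve.weights_array()
        ent = f"curve:{curve.curve_id}"
        _check(w.shape == (12,), v, ent, "twelve_months", "curve needs 12 weights")
        _check(bool(np.all(w >= 0)), v, ent, "nonnegative_weights",
               "monthly weights must be >= 0")
        if w.shape == (12,):
            s = float(w.sum())
            _check(abs(s - 1.0) <= 1e-9, v, ent, "weights_sum_to_one",
                   f"weights sum to {s:.12g}, expected 1 within 1e-9")

    # rate schedules
    for sched in (params.fertility, params.mortality):
        ent = f"schedule:{sched.kind}"
        for band, rate in sched.bands.items():
            _check(rate >= 0, v, f"{ent}:{band}", "nonnegative_rate",
                   f"rate {rate} must be >= 0")
        for band, ratio in sched.annual_change.items():
            _check(ratio > 0, v, f"{ent}:{band}", "positive_change_ratio",
                   f"annual change ratio {ratio} must be > 0")
        for band, s in list(sched.rate_spread.items()) + list(sched.change_spread.items()):
            _check(s >= 0, v, f"{ent}:{band}", "nonnegative_spread",
                   f"spread {s} must be >= 0")
    covered = set(params.fertility.bands)
    _check(set(FERTILITY_BANDS) <= covered, v, "schedule:fertility",
           "covers_reproductive_ages",
           f"fertility bands must cover female ages 15-49 in 5-year bands; "
           f"missing {sorted(set(FERTILITY_BANDS) - covered)}")
    for band, rate in params.mortality.bands.items():
        _check(rate <= 1, v, f"schedule:mortality:{band}", "mortality_at_most_one",
               f"annual mortality {rate} cannot exceed 1")

    # tasks
    for task in params.tasks:
        ent = f"task:{task.task_name}"
        _check(task.service_category in SERVICE_CATEGORIES, v, ent,
               "known_category",
               f"category {task.service_category!r} is not one of the 12 service categories")
        _check(0.0 <= task.rate <= 1.0, v, ent, "rate_in_unit_interval",
               f"rate {task.rate} must be within [0, 1]")
        _check(task.rate_kind in ("incidence", "prevalence"), v, ent,
               "rate_kind", f"rate_kind {task.rate_kind!r} unknown")
        _check(task.rate_spread >= 0, v, ent, "nonnegative_spread",
               f"rate_spread {task.rate_spread} must be >= 0")
        _check(task.annual_change > 0, v, ent, "positive_change_ratio",
               f"annual_change {task.annual_change} must be > 0")
        _check(task.annual_change_spread >= 0, v, ent, "nonnegative_spread",
               f"annual_change_spread {task.annual_change_spread} must be >= 0")
        _check(isinstance(task.num_contacts, int) and task.num_contacts >= 0, v, ent,
               "contacts_nonnegative_integer",
               f"num_contacts {task.num_contacts!r} must be an integer >= 0")
        _check(task.minutes_per_contact > 0, v, ent, "positive_minutes",
               f"minutes_per_contact {task.minutes_per_contact} must be > 0")
        spec = task.relevant_population
        _check(spec.sex in ("female", "male", "both"), v, ent, "known_sex",
               f"sex {spec.sex!r} unknown")
        _check(spec.state in ("general", "birth_linked"), v, ent, "known_state",
               f"state {spec.state!r} unknown")
        if not spec.birth_linked:
            _check(0 <= spec.age_low <= spec.age_high <= MAX_AGE, v, ent,
                   "age_bounds",
                   f"need 0 <= age_low <= age_high <= {MAX_AGE}, "
                   f"got [{spec.age_low}, {spec.age_high}]")
        if task.seasonality_curve_id is not None:
            _check(task.seasonality_curve_id in curve_ids, v, ent,
                   "curve_exists",
                   f"references missing seasonality curve {task.seasonality_curve_id!r}")
            _check(len(task.offsets_or_default()) == task.num_contacts, v, ent,
                   "one_offset_per_contact",
                   f"{len(task.contact_offsets)} offsets for {task.num_contacts} contacts")
    return v


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TASK_COLUMNS = [
    "task_name", "service_category", "sex", "age_low", "age_high", "state",
    "rate", "rate_kind", "rate_spread", "num_contacts", "minutes_per_contact",
    "annual_change", "annual_change_spread", "seasonality_curve_id",
    "contact_offsets",
]
_SCHEDULE_COLUMNS = ["band", "rate", "annual_change", "rate_spread", "change_spread"]


def _read_csv(path: Path, required: Iterable[str]) -> pd.DataFrame:
    if not path.is_file():
        raise ParameterError(f"missing parameter file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"{path.name}: missing columns {missing}")
    return df


def _num(raw: str, *, file: str, row: int, col: str, kind=float):
    try:
        return kind(raw)
    except (TypeError, ValueError) as exc:
        raise ParameterError(
            f"{file}, row {row}: non-numeric value {raw!r} in column {col!r}"
        ) from exc


def _parse_offsets(raw: str, *, file: str, row: int) -> tuple[int, ...]:
    raw = raw.strip()
    if not raw:
        return ()
    try:
        return tuple(int(tok) for tok in raw.split("|"))
    except ValueError as exc:
        raise ParameterError(
            f"{file}, row {row}: malformed contact_offsets {raw!r} "
            "(expected '|'-separated integers)"
        ) from exc


def _load_tasks(path: Path) -> list[ClinicalTask]:
    df = _read_csv(path, _TASK_COLUMNS)
    tasks = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # header is row 1
        curve = rec["seasonality_curve_id"].strip() or None
        spec = RelevantPopulationSpec(
            sex=rec["sex"].strip(),
            age_low=_num(rec["age_low"], file=path.name, row=row, col="age_low", kind=int),
            age_high=_num(rec["age_high"], file=path.name, row=row, col="age_high", kind=int),
            state=rec["state"].strip() or "general",
        )
        tasks.append(
            ClinicalTask(
                task_name=rec["task_name"].strip(),
                service_category=rec["service_category"].strip(),
                relevant_population=spec,
                rate=_num(rec["rate"], file=path.name, row=row, col="rate"),
                rate_kind=rec["rate_kind"].strip() or "incidence",
                rate_spread=_num(rec["rate_spread"] or "0", file=path.name, row=row,
                                 col="rate_spread"),
                num_contacts=_num(rec["num_contacts"], file=path.name, row=row,
                                  col="num_contacts", kind=int),
                minutes_per_contact=_num(rec["minutes_per_contact"], file=path.name,
                                         row=row, col="minutes_per_contact"),
                annual_change=_num(rec["annual_change"] or "1", file=path.name, row=row,
                                   col="annual_change"),
                annual_change_spread=_num(rec["annual_change_spread"] or "0",
                                          file=path.name, row=row,
                                          col="annual_change_spread"),
                seasonality_curve_id=curve,
                contact_offsets=_parse_offsets(rec["contact_offsets"],
                                               file=path.name, row=row),
            )
        )
    return tasks


def _load_schedule(path: Path, kind: str) -> RateSchedule:
    df = _read_csv(path, _SCHEDULE_COLUMNS)
    bands, change, rspread, cspread = {}, {}, {}, {}
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2
        band = rec["band"].strip()
        parse_band(band)  # fail fast on malformed labels
        bands[band] = _num(rec["rate"], file=path.name, row=row, col="rate")
        change[band] = _num(rec["annual_change"] or "1", file=path.name, row=row,
                            col="annual_change")
        rspread[band] = _num(rec["rate_spread"] or "0", file=path.name, row=row,
                             col="rate_spread")
        cspread[band] = _num(rec["change_spread"] or "0", file=path.name, row=row,
                             col="change_spread")
    return RateSchedule(kind=kind, bands=bands, annual_change=change,
                        rate_spread=rspread, change_spread=cspread)


def _load_curves(path: Path) -> list[SeasonalityCurve]:
    cols = ["curve_id"] + [f"m{i}" for i in range(1, 13)]
    df = _read_csv(path, cols)
    curves = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2
        weights = tuple(
            _num(rec[f"m{m}"], file=path.name, row=row, col=f"m{m}")
            for m in range(1, 13)
        )
        curves.append(SeasonalityCurve(curve_id=rec["curve_id"].strip(), weights=weights))
    return curves


def _load_population(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ["age", "female", "male"])
    female = np.zeros(MAX_AGE + 1)
    male = np.zeros(MAX_AGE + 1)
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2
        age = _num(rec["age"], file=path.name, row=row, col="age", kind=int)
        if not 0 <= age <= MAX_AGE:
            raise ParameterError(f"{path.name}, row {row}: age {age} outside 0..{MAX_AGE}")
        female[age] = _num(rec["female"], file=path.name, row=row, col="female")
        male[age] = _num(rec["male"], file=path.name, row=row, col="male")
    return female, male


def load_region_parameters(path: str | Path) -> RegionParameters:
    """Load and structurally check a region parameter workbook directory.

    Raises :class:`ParameterError` (with file and row context) on missing
    files, non-numeric fields, or a task referencing a seasonality curve that
    does not exist. Soft invariants (rate ranges, curve normalization, ...)
    are reported by :func:`validate` instead.
    """
    path = Path(path)
    if not path.is_dir():
        raise ParameterError(f"parameter workbook directory not found: {path}")

    meta_path = path / "region.yaml"
    if not meta_path.is_file():
        raise ParameterError(f"missing parameter file: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text()) or {}
    for key in ("region_name", "start_year", "end_year"):
        if key not in meta:
            raise ParameterError(f"region.yaml: missing key {key!r}")

    tasks = _load_tasks(path / "tasks.csv")
    fertility = _load_schedule(path / "fertility.csv", "fertility")
    mortality = _load_schedule(path / "mortality.csv", "mortality")
    curves = _load_curves(path / "seasonality.csv")
    female, male = _load_population(path / "population.csv")

    curve_ids = {c.curve_id for c in curves}
    for task in tasks:
        cid = task.seasonality_curve_id
        if cid is not None and cid not in curve_ids:
            raise ParameterError(
                f"tasks.csv: task {task.task_name!r} references seasonality curve "
                f"{cid!r} which is not defined in seasonality.csv"
            )

    start_year = int(meta["start_year"])
    return RegionParameters(
        region_name=str(meta["region_name"]),
        baseline_pyramid=PopulationPyramid(start_year, female, male),
        fertility=fertility,
        mortality=mortality,
        tasks=tasks,
        curves=curves,
        start_year=start_year,
        end_year=int(meta["end_year"]),
    )


def write_region_parameters(params: RegionParameters, path: str | Path) -> None:
    """Write a workbook directory that :func:`load_region_parameters` reads back
    with all numeric fields at full precision."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in params.tasks:
        s = t.relevant_population
        rows.append({
            "task_name": t.task_name,
            "service_category": t.service_category,
            "sex": s.sex, "age_low": s.age_low, "age_high": s.age_high,
            "state": s.state,
            "rate": repr(t.rate), "rate_kind": t.rate_kind,
            "rate_spread": repr(t.rate_spread),
            "num_contacts": t.num_contacts,
            "minutes_per_contact": repr(t.minutes_per_contact),
            "annual_change": repr(t.annual_change),
            "annual_change_spread": repr(t.annual_change_spread),
            "seasonality_curve_id": t.seasonality_curve_id or "",
            "contact_offsets": "|".join(str(o) for o in t.contact_offsets),
        })
    pd.DataFrame(rows, columns=_TASK_COLUMNS).to_csv(path / "tasks.csv", index=False)

    for sched, name in ((params.fertility, "fertility.csv"),
                        (params.mortality, "mortality.csv")):
        recs = [{
            "band": band,
            "rate": repr(float(sched.bands[band])),
            "annual_change": repr(float(sched.annual_change.get(band, 1.0))),
            "rate_spread": repr(sched.spread_for(band)),
            "change_spread": repr(sched.change_spread_for(band)),
        } for band in sched.bands]
        pd.DataFrame(recs, columns=_SCHEDULE_COLUMNS).to_csv(path / name, index=False)

    curve_rows = [
        {"curve_id": c.curve_id,
         **{f"m{i + 1}": repr(float(w)) for i, w in enumerate(c.weights)}}
        for c in params.curves
    ]
    pd.DataFrame(curve_rows, columns=["curve_id"] + [f"m{i}" for i in range(1, 13)]) \
        .to_csv(path / "seasonality.csv", index=False)

    pyr = params.baseline_pyramid
    pd.DataFrame({
        "age": np.arange(MAX_AGE + 1),
        "female": [repr(float(x)) for x in pyr.female],
        "male": [repr(float(x)) for x in pyr.male],
    }).to_csv(path / "population.csv", index=False)

    (path / "region.yaml").write_text(yaml.safe_dump({
        "region_name": params.region_name,
        "start_year": params.start_year,
        "end_year": params.end_year,
    }, sort_keys=False))


def region_equal(a: RegionParameters, b: RegionParameters) -> bool:
    """Field-for-field equality of two parameter sets (exact numerics)."""
    if (a.region_name, a.start_year, a.end_year) != (b.region_name, b.start_year, b.end_year):
        return False
    if a.baseline_pyramid.year != b.baseline_pyramid.year:
        return False
    if not (np.array_equal(a.baseline_pyramid.female, b.baseline_pyramid.female)
            and np.array_equal(a.baseline_pyramid.male, b.baseline_pyramid.male)):
        return False
    for sa, sb in ((a.fertility, b.fertility), (a.mortality, b.mortality)):
        if (dict(sa.bands), dict(sa.annual_change), dict(sa.rate_spread),
                dict(sa.change_spread)) != (dict(sb.bands), dict(sb.annual_change),
                                            dict(sb.rate_spread), dict(sb.change_spread)):
            return False
    return a.tasks == b.tasks and a.curves == b.curves
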