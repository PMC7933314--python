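"""Planning-cohort tables for radioembolization target-volume analysis.

A cohort table holds, for each treated patient, the target volume (TgV, the
liver volume perfused by the injected artery) measured with each work-up
imaging modality — contrast-enhanced CT (CECT), C-arm cone-beam CT (CBCT)
and 99mTc-MAA SPECT/CT — together with the post-therapy 90Y PET/CT TgV used
as the reference, the arteries injected with their MAA split fractions, the
prescribed 90Y activities per artery, and two treatment flags:

``lobar_or_total``
    the administration was a pure lobar or whole-liver treatment (as opposed
    to a selective segmental/subsegmental one);
``changed_administration``
    the injection site differed between the MAA work-up and the
    90Y-microsphere administration (patient motion, vasospasm, or deliberate
    repositioning).

The built-in fixture (``load_cohort("builtin")``) is a 24-patient planning
cohort with exactly this structure: 5 patients lack an evaluable CBCT
volume, 7 were lobar/total treatments and 4 had changed administrations.

CSV dialect: comma-separated, UTF-8, one header row, one row per patient.
Injections and prescriptions are semicolon-joined ``artery:value`` pairs
(fractions 0-1 for MAA, GBq for prescriptions). An empty ``tgv_cbct_ml``
cell means the CBCT volume is not available.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "MODALITIES",
    "Injection",
    "PatientRecord",
    "CohortTable",
    "Subgroup",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "select_subgroup",
]

#: TgV columns available per modality, keyed by short modality name.
MODALITIES = ("cect", "cbct", "maa", "pet")

_FIXTURE_NAME = "planning_cohort.csv"
_MAA_FRACTION_TOL = 0.01 + 1e-9  # printed percentages: 33+33+33 must pass


class CohortValidationError(ValueError):
    """A cohort row violates an invariant; the message names the row."""


@dataclass(frozen=True)
class Injection:
    """One artery entry: an MAA split fraction or a prescribed activity."""

    artery: str
    value: float


@dataclass(frozen=True)
class PatientRecord:
    """One patient of a planning cohort.

    Volumes are in ml, activities in GBq, fractions in [0, 1].
    ``tgv_cbct_ml`` is ``None`` when the CBCT study was missing or not
    evaluable for volumetry.
    """

    patient_id: int
    injections: tuple[Injection, ...]
    tgv_cect_ml: float
    tgv_cbct_ml: Optional[float]
    tgv_maa_ml: float
    tgv_pet_ml: float
    prescribed_gbq: tuple[Injection, ...]
    lobar_or_total: bool = False
    changed_administration: bool = False

    def tgv_ml(self, modality: str) -> Optional[float]:
        """TgV for ``modality`` (one of MODALITIES), or None if absent."""
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return getattr(self, f"tgv_{modality}_ml")

    def validate(self) -> None:
        pid = self.patient_id
        if not isinstance(pid, int) or pid <= 0:
            raise CohortValidationError(f"row {pid!r}: patient_id must be a positive integer")
        for name in ("tgv_cect_ml", "tgv_maa_ml", "tgv_pet_ml"):
            v = getattr(self, name)
            if not (v > 0):
                raise CohortValidationError(f"row {pid}: {name}={v!r} must be > 0")
        if self.tgv_cbct_ml is not None and not (self.tgv_cbct_ml > 0):
            raise CohortValidationError(
                f"row {pid}: tgv_cbct_ml={self.tgv_cbct_ml!r} must be > 0 or absent"
            )
        if not self.injections:
            raise CohortValidationError(f"row {pid}: no MAA injections")
        total = sum(i.value for i in self.injections)
        if abs(total - 1.0) > _MAA_FRACTION_TOL:
            raise CohortValidationError(
                f"row {pid}: MAA fractions sum to {total:.3f}, expected 1 within 0.01"
            )
        for inj in self.injections:
            if not (0.0 <= inj.value <= 1.0):
                raise CohortValidationError(
                    f"row {pid}: MAA fraction {inj.value!r} outside [0, 1]"
                )
        for rx in self.prescribed_gbq:
            if rx.value < 0:
                raise CohortValidationError(f"row {pid}: negative prescribed activity")


@dataclass
class CohortTable:
    """An ordered, validated collection of :class:`PatientRecord`."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        self.validate()

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        seen: set[int] = set()
        for i in ids:
            if i in seen:
                raise CohortValidationError(f"row {i}: duplicate patient_id")
            seen.add(i)
        if ids != sorted(ids):
            raise CohortValidationError("patient_ids must be sorted ascending")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> list[int]:
        return [r.patient_id for r in self.records]

    def tgv_column(self, modality: str, *, drop_absent: bool = True) -> "pd.Series":
        """The TgV column (ml) for one modality, indexed by patient id."""
        data = {r.patient_id: r.tgv_ml(modality) for r in self.records}
        s = pd.Series(data, name=f"tgv_{modality}_ml", dtype=float)
        return s.dropna() if drop_absent else s

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "injections": _join(r.injections),
                    "tgv_cect_ml": r.tgv_cect_ml,
                    "tgv_cbct_ml": r.tgv_cbct_ml,
                    "tgv_maa_ml": r.tgv_maa_ml,
                    "tgv_pet_ml": r.tgv_pet_ml,
                    "prescribed_gbq": _join(r.prescribed_gbq),
                    "lobar_or_total": int(r.lobar_or_total),
                    "changed_administration": int(r.changed_administration),
                }
            )
        return pd.DataFrame(rows)


class Subgroup(str, enum.Enum):
    """Named patient subsets used throughout the concordance analysis."""

    ALL = "all"
    SELECTIVE_ONLY = "selective_only"
    EXCLUDE_CHANGED = "exclude_changed"
    SELECTIVE_EXCLUDE_CHANGED = "selective_exclude_changed"
    CBCT_AVAILABLE = "cbct_available"


def _join(entries: Sequence[Injection]) -> str:
    return ";".join(f"{e.artery}:{e.value:g}" for e in entries)


def _split(cell: str, pid: object) -> tuple[Injection, ...]:
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            artery, value = part.rsplit(":", 1)
            out.append(Injection(artery.strip(), float(value)))
        except ValueError as exc:
            raise CohortValidationError(f"row {pid}: malformed injection field {part!r}") from exc
    return tuple(out)


def load_cohort(path: Union[str, Path] = "builtin") -> CohortTable:
    """Load a cohort CSV, or the packaged 24-patient fixture.

    Parameters
    ----------
    path
        A CSV file in the documented dialect, or the literal string
        ``"builtin"`` for the packaged planning cohort.
    """
    if str(path) == "builtin":
        src = resources.files("rembody").joinpath("data", _FIXTURE_NAME)
        with resources.as_file(src) as p:
            return _read_csv(p, provenance="builtin")
    return _read_csv(Path(path), provenance=str(path))


def _read_csv(path: Path, provenance: str) -> CohortTable:
    df = pd.read_csv(path, dtype={"injections": str, "prescribed_gbq": str})
    required = {
        "patient_id", "injections", "tgv_cect_ml", "tgv_cbct_ml",
        "tgv_maa_ml", "tgv_pet_ml", "prescribed_gbq",
        "lobar_or_total", "changed_administration",
    }
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        try:
            pid_int = int(pid)
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"row {pid!r}: non-integer patient_id") from exc
        cbct = row["tgv_cbct_ml"]
        records.append(
            PatientRecord(
                patient_id=pid_int,
                injections=_split(row["injections"], pid_int),
                tgv_cect_ml=float(row["tgv_cect_ml"]),
                tgv_cbct_ml=None if pd.isna(cbct) else float(cbct),
                tgv_maa_ml=float(row["tgv_maa_ml"]),
                tgv_pet_ml=float(row["tgv_pet_ml"]),
                prescribed_gbq=_split(row["prescribed_gbq"], pid_int),
                lobar_or_total=bool(int(row["lobar_or_total"])),
                changed_administration=bool(int(row["changed_administration"])),
            )
        )
    return CohortTable(records=tuple(records), provenance=provenance)


def write_cohort(cohort: CohortTable, path: Union[str, Path]) -> None:
    """Write a cohort to CSV; ``load_cohort`` of the result is an identity."""
    cohort.to_dataframe().to_csv(path, index=False)


def select_subgroup(
    cohort: CohortTable, selector: Union[str, Subgroup]
) -> CohortTable:
    """Restrict a cohort to one of the named analysis subsets.

    ``selective_only`` keeps segmental/subsegmental administrations (drops
    the lobar/total flag), ``exclude_changed`` drops patients whose injection
    site changed between MAA and microsphere administration,
    ``selective_exclude_changed`` applies both filters, and
    ``cbct_available`` keeps patients with an evaluable CBCT volume.
    """
    sel = Subgroup(selector)
    if sel is Subgroup.ALL:
        keep = list(cohort.records)
    elif sel is Subgroup.SELECTIVE_ONLY:
        keep = [r for r in cohort if not r.lobar_or_total]
    elif sel is Subgroup.EXCLUDE_CHANGED:
        keep = [r for r in cohort if not r.changed_administration]
    elif sel is Subgroup.SELECTIVE_EXCLUDE_CHANGED:
        keep = [r for r in cohort if not (r.lobar_or_total or r.changed_administration)]
    elif sel is Subgroup.CBCT_AVAILABLE:
        keep = [r for r in cohort if r.tgv_cbct_ml is not None]
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown selector {selector!r}")
    return CohortTable(records=tuple(keep), provenance=f"{cohort.provenance}[{sel.value}]")
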