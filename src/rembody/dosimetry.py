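"""Partition-model absorbed-dose engine for 90Y microsphere therapy.

The partition (MIRD three-compartment) model distributes the administered
activity A among lung, tumor, and non-tumoral liver. A fraction HPS (the
hepatopulmonary shunt) reaches the lungs; the remainder A·(1−HPS) splits
between tumor and normal parenchyma in proportion to mass weighted by the
tumor-to-normal uptake ratio TNR:

    A_t = A·(1−HPS) · TNR·M_t / (TNR·M_t + M_n),     A_n = A·(1−HPS) − A_t.

For a permanently implanted pure beta emitter the absorbed dose in a
compartment of mass M (kg) receiving activity A (GBq) is

    D [Gy] = 49.67 · A / M,

with 49.67 Gy·kg/GBq the 90Y equilibrium dose constant, tissue density
1.03 g/ml to convert ml to kg, and a fixed 1.0 kg lung mass. These
constants are exposed as parameters of :class:`DoseConstants`.

The single-compartment (uniform) model is the TNR = 1 limit: activity is
assumed uniform over the whole target volume, D = 49.67·A·(1−HPS)/M_tgv.

Prescription follows the clinical two-rule scheme: in cirrhotic patients
with a small predicted spared volume the activity is capped so the normal
compartment stays at or below 40 Gy; in non-cirrhotic patients with a
small target volume the activity is raised until the tumor dose exceeds
the 100 Gy tumoricidal floor; otherwise the safe cap binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DoseConstants",
    "DosimetryInput",
    "DoseReport",
    "PrescriptionPolicy",
    "Prescription",
    "partition_dose",
    "uniform_dose",
    "prescribe_activity",
    "split_activity",
    "percent_change",
    "modality_dose_table",
    "DEFAULT_CONSTANTS",
]

_ACTIVITY_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class DoseConstants:
    """Physical constants of the dose calculation, overridable per run."""

    dose_factor_gy_kg_per_gbq: float = 49.67
    tissue_density_g_ml: float = 1.03
    lung_mass_kg: float = 1.0

    def mass_kg(self, volume_ml: float) -> float:
        return volume_ml * self.tissue_density_g_ml / 1000.0


DEFAULT_CONSTANTS = DoseConstants()


@dataclass(frozen=True)
class DosimetryInput:
    """Inputs of one partition-model evaluation.

    activity_gbq : administered activity A (GBq)
    tumor_ml, normal_ml : tumor and non-tumoral compartment volumes (ml)
    tnr : tumor-to-normal activity-concentration ratio
    hps : hepatopulmonary shunt fraction in [0, 1)
    """

    activity_gbq: float
    tumor_ml: float
    normal_ml: float
    tnr: float
    hps: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_gbq < 0:
            raise ValueError("activity_gbq must be >= 0")
        if self.tumor_ml < 0:
            raise ValueError("tumor_ml must be >= 0")
        if not (self.normal_ml > 0):
            raise ValueError("normal_ml must be > 0")
        if not (self.tnr > 0):
            raise ValueError("tnr must be > 0")
        if not (0.0 <= self.hps < 1.0):
            raise ValueError("hps must be in [0, 1)")


@dataclass(frozen=True)
class DoseReport:
    """Per-compartment activities (GBq) and absorbed doses (Gy)."""

    dose_tumor_gy: float
    dose_normal_gy: float
    dose_lung_gy: float
    activity_tumor_gbq: float
    activity_normal_gbq: float
    activity_lung_gbq: float

    @property
    def total_activity_gbq(self) -> float:
        return self.activity_tumor_gbq + self.activity_normal_gbq + self.activity_lung_gbq


def partition_dose(
    inp: DosimetryInput, constants: DoseConstants = DEFAULT_CONSTANTS
) -> DoseReport:
    """Evaluate the three-compartment partition model.

    Activity is conserved: lung + tumor + normal activities equal the
    administered activity to 1e-9 GBq.
    """
    m_t = constants.mass_kg(inp.tumor_ml)
    m_n = constants.mass_kg(inp.normal_ml)
    if m_n <= 0 or constants.lung_mass_kg <= 0:
        raise ValueError("compartment masses must be positive")

    a_lung = inp.activity_gbq * inp.hps
    a_hep = inp.activity_gbq - a_lung
    w_t = inp.tnr * m_t
    a_t = a_hep * w_t / (w_t + m_n)
    a_n = a_hep - a_t

    k = constants.dose_factor_gy_kg_per_gbq
    d_t = k * a_t / m_t if m_t > 0 else 0.0
    d_n = k * a_n / m_n
    d_lung = k * a_lung / constants.lung_mass_kg

    report = DoseReport(d_t, d_n, d_lung, a_t, a_n, a_lung)
    assert abs(report.total_activity_gbq - inp.activity_gbq) <= _ACTIVITY_BALANCE_TOL
    return report


def uniform_dose(
    activity_gbq: float,
    tgv_ml: float,
    hps: float = 0.0,
    constants: DoseConstants = DEFAULT_CONSTANTS,
) -> float:
    """Single-compartment dose: uniform activity over the whole TgV (Gy)."""
    if not (tgv_ml > 0):
        raise ValueError("tgv_ml must be > 0")
    if not (0.0 <= hps <= 1.0):
        raise ValueError("hps must be in [0, 1]")
    return constants.dose_factor_gy_kg_per_gbq * activity_gbq * (1.0 - hps) / constants.mass_kg(tgv_ml)


@dataclass(frozen=True)
class PrescriptionPolicy:
    """Clinical thresholds governing activity prescription.

    ``spared_volume_fraction`` is the predicted fraction of whole liver
    outside the target volume; if None it is computed from the volumes.
    """

    cirrhotic: bool = False
    spared_volume_fraction: Optional[float] = None
    normal_cap_gy: float = 40.0
    tumoricidal_floor_gy: float = 100.0
    small_tgv_fraction: float = 0.60
    spared_fraction_cut: float = 0.40
    floor_epsilon_gy: float = 1e-6  # strict "> 100 Gy" floor

    def __post_init__(self) -> None:
        for name in ("normal_cap_gy", "tumoricidal_floor_gy", "small_tgv_fraction", "spared_fraction_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Prescription:
    activity_gbq: float
    rationale: str
    report: DoseReport


def prescribe_activity(
    policy: PrescriptionPolicy,
    tumor_ml: float,
    normal_ml: float,
    whole_liver_ml: float,
    tnr: float,
    hps: float = 0.0,
    constants: DoseConstants = DEFAULT_CONSTANTS,
) -> Prescription:
    """Prescribe the 90Y activity under the safety/efficacy rules.

    Both compartment doses are linear in A, so each rule solves exactly:
    the safe cap is the largest A with normal-liver dose <= 40 Gy, the
    tumoricidal floor the smallest A with tumor dose > 100 Gy.
    """
    if tumor_ml <= 0 or normal_ml <= 0 or whole_liver_ml <= 0:
        raise ValueError("volumes must be positive")
    tgv_ml = tumor_ml + normal_ml
    if tgv_ml > whole_liver_ml * (1 + 1e-12):
        raise ValueError(f"TgV {tgv_ml} ml exceeds whole liver {whole_liver_ml} ml")

    spared = policy.spared_volume_fraction
    if spared is None:
        spared = 1.0 - tgv_ml / whole_liver_ml

    unit = partition_dose(DosimetryInput(1.0, tumor_ml, normal_ml, tnr, hps), constants)
    if unit.dose_normal_gy <= 0 or unit.dose_tumor_gy <= 0:
        raise ValueError("degenerate unit doses; cannot prescribe")
    a_cap = policy.normal_cap_gy / unit.dose_normal_gy
    a_floor = (policy.tumoricidal_floor_gy + policy.floor_epsilon_gy) / unit.dose_tumor_gy

    if policy.cirrhotic and spared < policy.spared_fraction_cut:
        a, why = a_cap, (
            f"cirrhotic with spared volume {spared:.0%} < {policy.spared_fraction_cut:.0%}: "
            f"largest activity with normal-liver dose <= {policy.normal_cap_gy:g} Gy"
        )
    elif not policy.cirrhotic and tgv_ml / whole_liver_ml < policy.small_tgv_fraction:
        a, why = a_floor, (
            f"non-cirrhotic with TgV {tgv_ml / whole_liver_ml:.0%} < {policy.small_tgv_fraction:.0%} "
            f"of liver: smallest activity with tumor dose > {policy.tumoricidal_floor_gy:g} Gy"
        )
    else:
        a = min(a_cap, a_floor)
        which = "safe cap" if a_cap <= a_floor else "tumoricidal floor"
        why = f"intermediate case: min(safe cap, tumoricidal) = {which} binds"

    report = partition_dose(DosimetryInput(a, tumor_ml, normal_ml, tnr, hps), constants)
    return Prescription(a, why, report)


def split_activity(
    per_artery_tumor_ml: Sequence[float], total_activity_gbq: float
) -> list[float]:
    """Split a total activity across feeding arteries by perfused tumor volume."""
    v = np.asarray(list(per_artery_tumor_ml), dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("per-artery volumes must be non-negative and non-empty")
    total_v = v.sum()
    if total_v <= 0:
        raise ValueError("at least one per-artery volume must be positive")
    return list(total_activity_gbq * v / total_v)


def percent_change(dose_pet_gy: float, dose_modality_gy: float) -> float:
    """Percent change of the reference (PET) dose against a modality dose.

    Positive means the dose computed from the final PET-based TgV is higher
    than predicted by the work-up modality (underestimated volume leads to
    overestimated dose and a negative change).
    """
    if dose_modality_gy <= 0:
        raise ValueError("modality dose must be > 0")
    return 100.0 * (dose_pet_gy - dose_modality_gy) / dose_modality_gy


def modality_dose_table(
    table,
    activity_gbq: float = 1.0,
    modalities: Sequence[str] = ("cect", "cbct", "maa"),
    reference: str = "pet",
    constants: DoseConstants = DEFAULT_CONSTANTS,
    deduct_shunt: bool = True,
):
    """Per-patient partition doses for each modality TgV at a fixed activity.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per patient with columns ``patient_id``, ``tumor_ml``,
        ``tnr``, ``hps`` and ``tgv_<modality>_ml`` for each modality and
        the reference. The TNR is the one measured on MAA SPECT/CT and is
        shared across modalities; only the TgV changes.
    activity_gbq
        The fixed (fictitious) activity applied to every patient, 1 GBq by
        default so doses are directly comparable across modalities.
    deduct_shunt
        Deduct the lung shunt before distributing activity (the default);
        set False to assign the full activity to the liver compartments.

    Returns
    -------
    pandas.DataFrame
        Long format: one row per (patient, modality) with tumor/normal
        doses and percent changes of the reference dose against that
        modality. Rows whose TgV is absent or not larger than the tumor
        volume are excluded and listed in the ``excluded`` attribute
        (``result.attrs["excluded"]``).
    """
    import pandas as pd

    rows, excluded = [], []
    for _, patient in table.iterrows():
        pid = patient["patient_id"]
        v_t = float(patient["tumor_ml"])
        tnr = float(patient["tnr"])
        hps = float(patient["hps"]) if deduct_shunt else 0.0

        ref_tgv = float(patient[f"tgv_{reference}_ml"])
        if ref_tgv <= v_t:
            excluded.append((pid, reference, ref_tgv))
            continue
        ref = partition_dose(
            DosimetryInput(activity_gbq, v_t, ref_tgv - v_t, tnr, hps), constants
        )
        for mod in modalities:
            raw = patient.get(f"tgv_{mod}_ml")
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                excluded.append((pid, mod, None))
                continue
            tgv = float(raw)
            if tgv <= v_t:
                excluded.append((pid, mod, tgv))
                continue
            rep = partition_dose(
                DosimetryInput(activity_gbq, v_t, tgv - v_t, tnr, hps), constants
            )
            rows.append(
                {
                    "patient_id": pid,
                    "modality": mod,
                    "dose_tumor_gy": rep.dose_tumor_gy,
                    "dose_normal_gy": rep.dose_normal_gy,
                    "ref_dose_tumor_gy": ref.dose_tumor_gy,
                    "ref_dose_normal_gy": ref.dose_normal_gy,
                    "pct_change_tumor": percent_change(ref.dose_tumor_gy, rep.dose_tumor_gy),
                    "pct_change_normal": percent_change(ref.dose_normal_gy, rep.dose_normal_gy),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out
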