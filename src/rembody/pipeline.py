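"""Orchestration: rebuild the published concordance analysis end to end.

``reproduce_paper`` loads the packaged 24-patient planning cohort, computes
the per-modality TgV medians and the Lin CCC / R² agreement analyses on all
named subgroups, runs the fictitious 1-GBq dose comparison (with synthetic
per-patient TNR, tumor volume and shunt, since those are not part of the
printed table), and checks the computed values against the reference
results of the source study. Each reference value is classified up front:

* ``reproducible`` — expected to match after rounding to the printed
  precision (1 decimal for ml medians, 2 for CCC);
* ``discrepancy`` — a printed value the packaged table demonstrably cannot
  reproduce (the CECT selective-subgroup CCC and the regression R² values,
  whose exact subset is ambiguous in the source); reported with the
  computed value;
* ``not_reproducible`` — requires unprinted per-patient inputs (the dose
  medians); reported from synthetic inputs for illustration only.

The run passes (exit code 0 in the CLI) iff every ``reproducible`` check
matches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from . import cohort_data as cd
from . import dosimetry as dm
from .phantom import CohortSimSpec, _truncnorm

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

#: Agreement comparisons of the study: key -> (modality, subgroup).
COMPARISONS: dict[str, tuple[str, cd.Subgroup]] = {
    "ccc_cect_all": ("cect", cd.Subgroup.ALL),
    "ccc_cbct_all": ("cbct", cd.Subgroup.ALL),
    "ccc_maa_all": ("maa", cd.Subgroup.ALL),
    "ccc_maa_exclude_changed": ("maa", cd.Subgroup.EXCLUDE_CHANGED),
    "ccc_cect_selective": ("cect", cd.Subgroup.SELECTIVE_ONLY),
    "ccc_cbct_selective": ("cbct", cd.Subgroup.SELECTIVE_ONLY),
    "ccc_maa_selective_exclude_changed": ("maa", cd.Subgroup.SELECTIVE_EXCLUDE_CHANGED),
}

#: Reference (printed) values with their reproducibility class.
REFERENCE_MEDIANS = {  # modality -> (median, min, max), ml
    "cect": (558.5, 25.0, 2260.0),
    "cbct": (626.0, 25.0, 2305.0),
    "maa": (798.5, 83.0, 2279.0),
    "pet": (957.0, 181.0, 2420.0),
}
REFERENCE_CCC = {
    "ccc_cect_all": (0.72, "reproducible"),
    "ccc_cbct_all": (0.71, "reproducible"),
    "ccc_maa_all": (0.85, "reproducible"),
    "ccc_maa_exclude_changed": (0.97, "reproducible"),
    "ccc_cect_selective": (0.50, "discrepancy"),
    "ccc_cbct_selective": (0.67, "reproducible"),
    "ccc_maa_selective_exclude_changed": (0.95, "reproducible"),
}
REFERENCE_R2 = {  # regression subset ambiguous in the source; informational
    "r2_cect_all": (0.68, "discrepancy"),
    "r2_cbct_all": (0.66, "discrepancy"),
    "r2_maa_all": (0.96, "discrepancy"),
}
REFERENCE_DOSE_MEDIANS_GY = {  # tumor dose at 1 GBq; needs unprinted inputs
    "cect": 152.0,
    "cbct": 125.0,
    "maa": 116.0,
    "pet": 102.0,
}
DISCREPANCY_REASONS = {
    "ccc_cect_selective": (
        "computed CCC on the 17 selective patients is ~0.66 under both 1/n "
        "and 1/(n-1) estimators; the printed 0.5 is not attainable from the "
        "published table"
    ),
    "r2_cect_all": "printed R² matches no documented patient subset exactly",
    "r2_cbct_all": "printed R² matches no documented patient subset exactly",
    "r2_maa_all": (
        "printed 0.96 matches the selective-excluding-changed subset "
        "(R²=0.957), not the full cohort (R²=0.80)"
    ),
}


@dataclass
class RunConfig:
    """Inputs and knobs of a reproduction run."""

    cohort_path: str = "builtin"
    output_dir: Optional[Path] = None
    seed: int = 0
    constants: dm.DoseConstants = field(default_factory=dm.DoseConstants)
    subgroups: tuple[str, ...] = tuple(COMPARISONS)
    log_level: str = "INFO"


def modality_pairs(cohort: cd.CohortTable, modality: str) -> ag.PairedSample:
    """Paired (modality TgV, PET TgV); patients without the modality dropped."""
    xs = [r.tgv_ml(modality) for r in cohort]
    ys = [r.tgv_pet_ml for r in cohort]
    sample = ag.PairedSample.from_pairs(xs, ys, labels=cohort.patient_ids)
    if sample.n_dropped:
        logger.info(
            "%s vs pet: dropped %d patients without %s volume (n=%d)",
            modality, sample.n_dropped, modality, sample.n,
        )
    return sample


def agreement_table(cohort: cd.CohortTable) -> dict[str, ag.AgreementResult]:
    """All named modality/subgroup agreement analyses on one cohort."""
    out = {}
    for key, (modality, subgroup) in COMPARISONS.items():
        sub = cd.select_subgroup(cohort, subgroup)
        out[key] = ag.lin_ccc(modality_pairs(sub, modality))
    return out


def synthetic_dose_inputs(cohort: cd.CohortTable, seed: int) -> pd.DataFrame:
    """Per-patient TNR / tumor volume / HPS draws for the 1-GBq comparison.

    The printed table carries no per-patient TNR or tumor volume, so the
    dose comparison uses the cohort's TgVs with synthetic draws from the
    cohort-scale distributions (TNR 2.6 +/- 1.5, HPS 6.9 +/- 3.4%).
    """
    spec = CohortSimSpec(seed=seed)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    tnr = _truncnorm(rng, spec.tnr_mean, spec.tnr_sd, spec.tnr_min, np.inf, n)
    hps = _truncnorm(rng, spec.hps_mean, spec.hps_sd, *spec.hps_range, n)
    frac = rng.uniform(*spec.tumor_fraction_range, n)
    rows = []
    for r, t, h, f in zip(cohort, tnr, hps, frac):
        tgvs = [r.tgv_cect_ml, r.tgv_maa_ml, r.tgv_pet_ml] + (
            [r.tgv_cbct_ml] if r.tgv_cbct_ml is not None else []
        )
        rows.append(
            {
                "patient_id": r.patient_id,
                "tumor_ml": f * min(tgvs),
                "tnr": t,
                "hps": h,
                "tgv_cect_ml": r.tgv_cect_ml,
                "tgv_cbct_ml": np.nan if r.tgv_cbct_ml is None else r.tgv_cbct_ml,
                "tgv_maa_ml": r.tgv_maa_ml,
                "tgv_pet_ml": r.tgv_pet_ml,
                "lobar_or_total": r.lobar_or_total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReproduceReport:
    checks: list[dict]
    agreement: dict[str, ag.AgreementResult]
    medians: dict[str, ag.MedianSummary]
    dose_summary: dict
    seed: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": self.seed,
            "passed": self.passed,
            "checks": self.checks,
            "agreement": {
                k: {
                    "ccc": v.ccc, "ci_low": v.ci_low, "ci_high": v.ci_high,
                    "r2": v.r2, "n": v.n,
                }
                for k, v in self.agreement.items()
            },
            "median_tgv_ml": {
                k: {"median": m.median, "min": m.min, "max": m.max, "iqr": m.iqr}
                for k, m in self.medians.items()
            },
            "dose_comparison_synthetic": self.dose_summary,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        lines = [
            "# Reproduction report",
            "",
            f"Schema {REPORT_SCHEMA_VERSION}, seed {self.seed}, "
            f"overall: {'PASS' if self.passed else 'FAIL'}",
            "",
            "## Target volume medians (ml)",
            "",
            "| modality | median | min | max | IQR |",
            "|---|---|---|---|---|",
        ]
        for k, m in self.medians.items():
            lines.append(f"| {k} | {m.median:g} | {m.min:g} | {m.max:g} | {m.iqr:g} |")
        lines += [
            "",
            "## Agreement with the final PET/CT TgV",
            "",
            "| comparison | n | CCC | 95% CI | R² |",
            "|---|---|---|---|---|",
        ]
        for k, v in self.agreement.items():
            lines.append(
                f"| {k} | {v.n} | {v.ccc:.3f} | {v.ci_low:.2f}-{v.ci_high:.2f} | {v.r2:.3f} |"
            )
        lines += [
            "",
            "## Reference checks",
            "",
            "| check | class | reference | computed | match |",
            "|---|---|---|---|---|",
        ]
        for c in self.checks:
            mark = {True: "yes", False: "NO", None: "n/a"}[c["match"]]
            lines.append(
                f"| {c['name']} | {c['class']} | {c['reference']} | {c['computed']} | {mark} |"
            )
        lines += [
            "",
            "Synthetic-input dose comparison (fictitious 1 GBq, synthetic TNR/tumor/HPS):",
            "",
            "```json",
            json.dumps(self.dose_summary, indent=2),
            "```",
            "",
        ]
        return "\n".join(lines)


def reproduce_paper(config: RunConfig = RunConfig()) -> ReproduceReport:
    """Run the full reproduction and classify every reference check."""
    logging.basicConfig(level=config.log_level)
    cohort = cd.load_cohort(config.cohort_path)

    medians = {
        m: ag.median_summary(cohort.tgv_column(m).tolist()) for m in cd.MODALITIES
    }
    agreement = agreement_table(cohort)

    checks: list[dict] = []
    for mod, (med, lo, hi) in REFERENCE_MEDIANS.items():
        got = medians[mod]
        match = (round(got.median, 1), round(got.min, 1), round(got.max, 1)) == (med, lo, hi)
        checks.append(
            {
                "name": f"median_tgv_{mod}",
                "class": "reproducible",
                "reference": f"{med:g} ({lo:g}-{hi:g})",
                "computed": f"{got.median:g} ({got.min:g}-{got.max:g})",
                "match": bool(match),
            }
        )
    for key, (ref, klass) in REFERENCE_CCC.items():
        got = agreement[key].ccc
        entry = {
            "name": key,
            "class": klass,
            "reference": ref,
            "computed": round(got, 3),
            "match": bool(round(got, 2) == ref) if klass == "reproducible" else None,
        }
        if klass != "reproducible":
            entry["reason"] = DISCREPANCY_REASONS.get(key, "")
            logger.warning("discrepancy %s: reference %s, computed %.3f", key, ref, got)
        checks.append(entry)
    for key, (ref, klass) in REFERENCE_R2.items():
        mod = key.split("_")[1]
        got = agreement[f"ccc_{mod}_all"].r2
        checks.append(
            {
                "name": key,
                "class": klass,
                "reference": ref,
                "computed": round(got, 3),
                "match": None,
                "reason": DISCREPANCY_REASONS.get(key, ""),
            }
        )

    # fictitious 1-GBq dose comparison on synthetic per-patient inputs
    inputs = synthetic_dose_inputs(cohort, config.seed)
    table = dm.modality_dose_table(inputs, activity_gbq=1.0, constants=config.constants)
    dose_summary = _summarize_doses(table, inputs)
    for mod, ref in REFERENCE_DOSE_MEDIANS_GY.items():
        checks.append(
            {
                "name": f"median_tumor_dose_{mod}",
                "class": "not_reproducible",
                "reference": ref,
                "computed": dose_summary["median_dose_tumor_gy"].get(mod),
                "match": None,
                "reason": "per-patient TNR and tumor volumes are not printed; "
                "computed from synthetic draws",
            }
        )

    passed = all(c["match"] for c in checks if c["class"] == "reproducible")
    report = ReproduceReport(checks, agreement, medians, dose_summary, config.seed, passed)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.to_markdown())
    return report


def _summarize_doses(table: pd.DataFrame, inputs: pd.DataFrame) -> dict:
    ref_med = float(table.groupby("patient_id")["ref_dose_tumor_gy"].first().median())
    med_t = {"pet": round(ref_med, 1)}
    med_pct = {}
    for mod, grp in table.groupby("modality"):
        med_t[mod] = round(float(grp["dose_tumor_gy"].median()), 1)
        med_pct[mod] = round(float(grp["pct_change_tumor"].median()), 1)
    flags = dict(zip(inputs["patient_id"], inputs["lobar_or_total"]))
    approach = {}
    for mod, grp in table.groupby("modality"):
        f = grp["patient_id"].map(flags).astype(bool)
        if f.sum() >= 2 and (~f).sum() >= 2:
            t = ag.approach_comparison(grp["pct_change_tumor"].tolist(), f.tolist())
            approach[mod] = {"t": round(t.statistic, 3), "p": round(t.p_value, 4)}
    return {
        "median_dose_tumor_gy": med_t,
        "median_pct_change_tumor": med_pct,
        "approach_t_test": approach,
        "n_excluded_rows": len(table.attrs.get("excluded", [])),
    }
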