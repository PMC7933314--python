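"""Partition-model dose engine: oracles, conservation, prescription rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rembody.dosimetry import (
    DEFAULT_CONSTANTS,
    DoseConstants,
    DosimetryInput,
    PrescriptionPolicy,
    modality_dose_table,
    partition_dose,
    percent_change,
    prescribe_activity,
    split_activity,
    uniform_dose,
)


def oracle_partition(a, v_t, v_n, tnr, hps, k=49.67, rho=1.03, lung_kg=1.0):
    """Independent hand evaluation of the partition-model formula chain."""
    m_t, m_n = v_t * rho / 1000.0, v_n * rho / 1000.0
    a_lung = a * hps
    a_hep = a - a_lung
    a_t = a_hep * (tnr * m_t) / (tnr * m_t + m_n)
    a_n = a_hep - a_t
    d_t = k * a_t / m_t if m_t else 0.0
    return d_t, k * a_n / m_n, k * a_lung / lung_kg


class TestPartitionDose:
    def test_uniform_distribution_limit(self):
        rep = partition_dose(DosimetryInput(1.0, 100.0, 900.0, 1.0, 0.0))
        expected = 49.67 / 1.03
        assert rep.dose_tumor_gy == pytest.approx(expected, abs=1e-9)
        assert rep.dose_normal_gy == pytest.approx(expected, abs=1e-9)

    def test_zero_activity_gives_zero_doses(self):
        rep = partition_dose(DosimetryInput(0.0, 100.0, 900.0, 2.0, 0.1))
        assert rep.dose_tumor_gy == rep.dose_normal_gy == rep.dose_lung_gy == 0.0

    def test_cohort_scale_example_against_hand_chain(self):
        # TNR 2.6 / HPS 6.9% are the cohort-scale means; tumoricidal tumor
        # dose and a near-cap normal dose emerge at 1 GBq in a 1 L liver
        inp = DosimetryInput(1.0, 100.0, 900.0, 2.6, 0.069)
        rep = partition_dose(inp)
        d_t, d_n, d_l = oracle_partition(1.0, 100.0, 900.0, 2.6, 0.069)
        assert rep.dose_tumor_gy == pytest.approx(d_t, abs=1e-12)
        assert rep.dose_normal_gy == pytest.approx(d_n, abs=1e-12)
        assert rep.dose_lung_gy == pytest.approx(d_l, abs=1e-12)
        assert rep.dose_tumor_gy == pytest.approx(100.6, abs=0.05)
        assert rep.dose_normal_gy == pytest.approx(38.7, abs=0.05)

    @given(
        a=st.floats(0.0, 10.0),
        v_t=st.floats(1.0, 2000.0),
        v_n=st.floats(1.0, 2500.0),
        tnr=st.floats(0.1, 20.0),
        hps=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_activity_conservation(self, a, v_t, v_n, tnr, hps):
        rep = partition_dose(DosimetryInput(a, v_t, v_n, tnr, hps))
        assert abs(rep.total_activity_gbq - a) <= 1e-9

    @given(
        a=st.floats(0.1, 5.0),
        tgv=st.floats(10.0, 3000.0),
        split=st.floats(0.05, 0.95),
        hps=st.floats(0.0, 0.3),
    )
    @settings(max_examples=200, deadline=None)
    def test_tnr_one_equals_uniform_model(self, a, tgv, split, hps):
        v_t = tgv * split
        rep = partition_dose(DosimetryInput(a, v_t, tgv - v_t, 1.0, hps))
        d = uniform_dose(a, tgv, hps)
        assert rep.dose_tumor_gy == pytest.approx(d, abs=1e-9)
        assert rep.dose_normal_gy == pytest.approx(d, abs=1e-9)

    def test_monotonic_in_tnr_and_tumor_volume(self, rng):
        for _ in range(1000):
            a = rng.uniform(0.1, 5)
            v_t = rng.uniform(10, 500)
            v_n = rng.uniform(100, 2000)
            tnr = rng.uniform(0.5, 8)
            hps = rng.uniform(0, 0.3)
            base = partition_dose(DosimetryInput(a, v_t, v_n, tnr, hps))
            up_tnr = partition_dose(DosimetryInput(a, v_t, v_n, tnr * 1.5, hps))
            assert up_tnr.dose_tumor_gy > base.dose_tumor_gy
            assert up_tnr.dose_normal_gy < base.dose_normal_gy
            up_vt = partition_dose(DosimetryInput(a, v_t * 1.5, v_n, tnr, hps))
            assert up_vt.dose_tumor_gy < base.dose_tumor_gy

    def test_custom_constants_propagate(self):
        const = DoseConstants(dose_factor_gy_kg_per_gbq=50.0, tissue_density_g_ml=1.0)
        rep = partition_dose(DosimetryInput(1.0, 100.0, 900.0, 1.0, 0.0), const)
        assert rep.dose_tumor_gy == pytest.approx(50.0, abs=1e-9)


class TestUniformDose:
    def test_cohort_median_volume(self):
        # 1 GBq uniformly in the 957 ml median target volume
        assert uniform_dose(1.0, 957.0, 0.0) == pytest.approx(49.67 / (1.03 * 0.957), abs=1e-12)
        assert uniform_dose(1.0, 957.0, 0.0) == pytest.approx(50.4, abs=0.05)

    def test_liter_reference_and_full_shunt(self):
        assert uniform_dose(1.0, 1000.0, 0.0) == pytest.approx(48.22, abs=0.005)
        assert uniform_dose(1.0, 1000.0, 1.0) == 0.0

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            uniform_dose(1.0, 0.0)


class TestPrescription:
    def test_cirrhotic_cap_is_exact_at_40(self):
        policy = PrescriptionPolicy(cirrhotic=True, spared_volume_fraction=0.30)
        rx = prescribe_activity(policy, 200.0, 800.0, 1500.0, 3.0, 0.05)
        assert rx.report.dose_normal_gy == pytest.approx(40.0, abs=1e-6)
        assert "cirrhotic" in rx.rationale

    def test_tumoricidal_floor_just_above_100(self):
        policy = PrescriptionPolicy(cirrhotic=False)
        rx = prescribe_activity(policy, 100.0, 350.0, 1500.0, 2.0, 0.0)
        assert rx.report.dose_tumor_gy > 100.0
        assert rx.report.dose_tumor_gy == pytest.approx(100.0, abs=1e-5)

    def test_higher_tnr_lowers_tumoricidal_activity(self):
        policy = PrescriptionPolicy(cirrhotic=False)
        a1 = prescribe_activity(policy, 100.0, 350.0, 1500.0, 2.0, 0.0).activity_gbq
        a2 = prescribe_activity(policy, 100.0, 350.0, 1500.0, 4.0, 0.0).activity_gbq
        assert a2 < a1
        # grid-search oracle: smallest activity on a fine grid reaching >100 Gy
        grid = np.linspace(0.001, 5.0, 50000)
        doses = [
            partition_dose(DosimetryInput(a, 100.0, 350.0, 4.0, 0.0)).dose_tumor_gy for a in grid
        ]
        first = grid[next(i for i, d in enumerate(doses) if d > 100.0)]
        assert a2 == pytest.approx(first, abs=grid[1] - grid[0])

    def test_intermediate_case_safe_cap_binds(self):
        policy = PrescriptionPolicy(cirrhotic=False)
        # TgV = 80% of liver: neither special rule; min(cap, floor)
        rx = prescribe_activity(policy, 300.0, 900.0, 1500.0, 2.0, 0.0)
        assert rx.report.dose_normal_gy <= 40.0 + 1e-6 or rx.report.dose_tumor_gy <= 100.0 + 1e-3
        assert "intermediate" in rx.rationale

    def test_tgv_exceeding_liver_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            prescribe_activity(PrescriptionPolicy(), 600.0, 1000.0, 1500.0, 2.0)


class TestSplitActivity:
    def test_two_arteries_by_perfused_volume(self):
        assert split_activity([32.0, 68.0], 1.0) == pytest.approx([0.32, 0.68])

    def test_symmetry_and_single_artery(self):
        assert split_activity([50.0, 50.0], 1.0) == pytest.approx([0.5, 0.5])
        assert split_activity([120.0], 2.5) == pytest.approx([2.5])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            split_activity([0.0, 0.0], 1.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "pet, mod, expected", [(50, 50, 0.0), (50, 100, -50.0), (82, 100, -18.0)]
    )
    def test_formula(self, pet, mod, expected):
        assert percent_change(pet, mod) == pytest.approx(expected)

    def test_zero_modality_dose_rejected(self):
        with pytest.raises(ValueError):
            percent_change(50.0, 0.0)


class TestModalityDoseTable:
    def _table(self, **overrides):
        import pandas as pd

        base = {
            "patient_id": [1],
            "tumor_ml": [50.0],
            "tnr": [2.0],
            "hps": [0.0],
            "tgv_cect_ml": [800.0],
            "tgv_cbct_ml": [800.0],
            "tgv_maa_ml": [800.0],
            "tgv_pet_ml": [800.0],
        }
        base.update(overrides)
        return pd.DataFrame(base)

    def test_identical_tgvs_give_zero_change(self):
        out = modality_dose_table(self._table())
        assert np.allclose(out["pct_change_tumor"], 0.0)
        assert np.allclose(out["pct_change_normal"], 0.0)

    def test_single_patient_against_two_dose_evaluations(self):
        out = modality_dose_table(self._table(tgv_maa_ml=[800.0], tgv_pet_ml=[957.0]))
        d_mod = oracle_partition(1.0, 50.0, 750.0, 2.0, 0.0)[0]
        d_pet = oracle_partition(1.0, 50.0, 907.0, 2.0, 0.0)[0]
        row = out[out.modality == "maa"].iloc[0]
        assert row["pct_change_tumor"] == pytest.approx(100.0 * (d_pet - d_mod) / d_mod, abs=1e-9)

    def test_pet_larger_than_modality_means_negative_change(self):
        out = modality_dose_table(self._table(tgv_pet_ml=[1200.0]))
        assert (out["pct_change_tumor"] < 0).all()

    def test_tgv_not_above_tumor_volume_excluded(self):
        out = modality_dose_table(self._table(tgv_cbct_ml=[40.0]))
        assert "cbct" not in set(out["modality"])
        assert (1, "cbct", 40.0) in out.attrs["excluded"]
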