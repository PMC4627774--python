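"""Mixed-factorial ANOVA, eta-squared, casewise deletion, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from conftest import anova_ss_oracle, random_balanced_table
from stridelab.demographics import demographic_summary, he_sample, pd_sample
from stridelab.stats import (
    BalanceError,
    DesignInfeasibleError,
    casewise_delete,
    classify_effect_size,
    descriptive_table,
    eta_squared,
    mixed_anova,
    read_subject_level_xlsx,
)


class TestCasewiseDelete:
    def _table(self):
        return random_balanced_table(np.random.default_rng(0), n_per_group=4)

    def test_complete_table_unchanged(self):
        t = self._table()
        kept, removed = casewise_delete(t, "group_rac_device")
        assert removed == []
        assert len(kept) == len(t)

    def test_one_missing_cell_removes_whole_subject(self):
        t = self._table()
        drop = (t.subject == "PD00") & (t.condition == "110") & (t.device == "reference")
        kept, removed = casewise_delete(t[~drop], "group_rac_device")
        assert removed == ["PD00"]
        assert "PD00" not in set(kept.subject)

    def test_everyone_missing_a_cell_is_infeasible(self):
        t = self._table()
        # every PD subject lacks condition "110", every HE subject lacks "100":
        # no subject covers the full condition x device cross
        broken = t[~(((t.group == "PD") & (t.condition == "110"))
                     | ((t.group == "HE") & (t.condition == "100")))]
        with pytest.raises(DesignInfeasibleError):
            casewise_delete(broken, "group_rac_device")


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_three_way_partition_matches_brute_force(self, seed):
        t = random_balanced_table(np.random.default_rng(seed), n_per_group=5)
        at = mixed_anova(t, "group_rac_device")
        oracle = anova_ss_oracle(t, between="group", within=["condition", "device"])
        got = dict(zip(at.table.Effect, at.table.SS))
        rename = {"RAC": "condition", "Device": "device",
                  "Group × RAC": "Group x condition", "Group × Device": "Group x device",
                  "RAC × Device": "condition x device",
                  "Group × RAC × Device": "Group x condition x device",
                  "Error (RAC)": "Error (condition)", "Error (Device)": "Error (device)",
                  "Error (RAC × Device)": "Error (condition x device)"}
        for eff, ss in got.items():
            key = rename.get(eff, eff)
            assert ss == pytest.approx(oracle[key], rel=1e-9, abs=1e-12), eff
        assert at.ss_total == pytest.approx(oracle["total"], rel=1e-9)

    def test_unequal_group_sizes_still_partition(self):
        t = random_balanced_table(np.random.default_rng(7), n_per_group=6)
        t = t[~((t.group == "HE") & (t.subject.isin(["HE04", "HE05"])))]
        at = mixed_anova(t, "group_rac_device")
        oracle = anova_ss_oracle(t, between="group", within=["condition", "device"])
        assert at.ss_total == pytest.approx(oracle["total"], rel=1e-9)
        assert at.effect("Group").SS == pytest.approx(oracle["Group"], rel=1e-9)

    def test_zero_noise_additive_effects_flagged(self):
        # constructed cell means, no residual variance within strata
        rows = []
        for gi, g in enumerate(["PD", "HE"]):
            for s in range(4):
                for ci, c in enumerate(["self", "100", "110"]):
                    for di, d in enumerate(["smartmove", "reference"]):
                        rows.append({"subject": f"{g}{s}", "group": g, "condition": c,
                                     "device": d,
                                     "value": 1.0 + 0.5 * gi + 0.2 * ci + 0.1 * di})
        at = mixed_anova(pd.DataFrame(rows), "group_rac_device")
        dev = at.effect("Device")
        assert np.isinf(dev.F)
        # additive construction: interaction SS vanish
        assert at.effect("Group × Device").SS == pytest.approx(0.0, abs=1e-12)
        # Group SS from constructed magnitudes: ab * sum n_g (m_g - GM)^2
        # m_g differ by 0.5 -> each deviates 0.25; 6 cells * 4 subj * 2 * 0.0625
        assert at.effect("Group").SS == pytest.approx(6 * 4 * 2 * 0.25**2)


class TestAgainstIndependentPackages:
    def test_group_device_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        t = random_balanced_table(np.random.default_rng(21), n_per_group=6,
                                  conditions=("self",))
        at = mixed_anova(t, "group_device")
        aov = pg.mixed_anova(data=t, dv="value", within="device",
                             subject="subject", between="group")
        ref = aov.set_index("Source")
        assert at.effect("Group").F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert at.effect("Device").F == pytest.approx(ref.loc["device", "F"], rel=1e-9)
        assert at.effect("Group × Device").F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_rac_device_matches_anova_rm(self):
        sm = pytest.importorskip("statsmodels.stats.anova")
        t = random_balanced_table(np.random.default_rng(22), n_per_group=8,
                                  groups=("PD",))
        at = mixed_anova(t, "rac_device")
        res = sm.AnovaRM(t, "value", "subject", within=["condition", "device"]).fit()
        ref = res.anova_table
        assert at.effect("RAC").F == pytest.approx(ref.loc["condition", "F Value"], rel=1e-9)
        assert at.effect("Device").F == pytest.approx(ref.loc["device", "F Value"], rel=1e-9)
        assert at.effect("RAC × Device").F == pytest.approx(
            ref.loc["condition:device", "F Value"], rel=1e-9)

    def test_single_within_factor_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(23)
        t = random_balanced_table(rng, n_per_group=10, groups=("PD",),
                                  conditions=("self",))
        at = mixed_anova(t, "rac_device")
        wide = t.pivot_table(index="subject", columns="device", values="value")
        tstat, _ = sp_stats.ttest_rel(wide["smartmove"], wide["reference"])
        assert at.effect("Device").F == pytest.approx(tstat**2, rel=1e-9)


class TestAnovaApi:
    def test_unbalanced_table_names_offenders(self):
        t = random_balanced_table(np.random.default_rng(5), n_per_group=3)
        t = t[~((t.subject == "HE01") & (t.device == "reference") & (t.condition == "self"))]
        with pytest.raises(BalanceError, match="HE01"):
            mixed_anova(t, "group_rac_device")

    def test_rac_device_rejects_multiple_groups(self):
        t = random_balanced_table(np.random.default_rng(6), n_per_group=3)
        with pytest.raises(ValueError, match="single group"):
            mixed_anova(t, "rac_device")

    def test_eta2_denominator_constancy(self):
        t = random_balanced_table(np.random.default_rng(8), n_per_group=5)
        at = mixed_anova(t, "group_rac_device")
        eff = at.table.dropna(subset=["eta2"])
        denoms = eff.SS / eff.eta2
        np.testing.assert_allclose(denoms, at.ss_total, rtol=1e-9)

    def test_csv_output_has_table_columns(self, tmp_path):
        t = random_balanced_table(np.random.default_rng(9), n_per_group=4)
        at = mixed_anova(t, "group_rac_device")
        dest = tmp_path / "anova.csv"
        at.to_csv(dest)
        back = pd.read_csv(dest)
        assert {"Effect", "SS", "F", "p", "eta2"} <= set(back.columns)


class TestEtaSquared:
    def test_ratio(self):
        assert eta_squared(2.0, 8.0) == pytest.approx(0.25)
        assert eta_squared(0.0, 5.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            eta_squared(2.0, 1.0)
        with pytest.raises(ValueError):
            eta_squared(1.0, 0.0)

    @pytest.mark.parametrize(
        "value,label",
        [(0.0, "negligible"), (0.019, "negligible"), (0.02, "small"),
         (0.129, "small"), (0.13, "medium"), (0.259, "medium"),
         (0.26, "large"), (1.0, "large")],
    )
    def test_classification_boundaries(self, value, label):
        assert classify_effect_size(value) == label

    def test_classification_domain(self):
        with pytest.raises(ValueError):
            classify_effect_size(1.5)


class TestDescriptives:
    def test_cohort_means_and_sds(self):
        summary = demographic_summary().set_index(["group", "variable"])
        assert summary.loc[("PD", "age"), "mean"] == pytest.approx(64.96, abs=0.005)
        assert summary.loc[("PD", "updrs3"), "mean"] == pytest.approx(24.75, abs=0.005)
        assert summary.loc[("PD", "updrs3"), "sd"] == pytest.approx(9.76, abs=0.005)
        assert summary.loc[("HE", "mmse"), "mean"] == pytest.approx(29.25, abs=0.005)

    def test_group_age_welch_p(self):
        t = descriptive_table({"PD": pd_sample().age.to_numpy(),
                               "HE": he_sample().age.to_numpy()})
        assert t.attrs["p"] == pytest.approx(0.577, abs=0.001)

    def test_constant_groups_flag_undefined_t(self):
        t = descriptive_table({"A": np.full(5, 2.0), "B": np.full(5, 2.0)})
        assert np.isnan(t.attrs["t"])
        assert (t.sd == 0).all()

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            descriptive_table({"A": np.array([1.0]), "B": np.array([1.0, 2.0])})


class TestSubjectLevelXlsx:
    def _write_wide(self, path, header_style="tokens"):
        rng = np.random.default_rng(3)
        subjects = [f"PD{i:02d}" for i in range(3)] + [f"HE{i:02d}" for i in range(3)]
        cols = {}
        for cond in ("Self", "100", "110"):
            for dev in ("SmartMOVE", "Footswitch"):
                key = (f"{cond}_{dev}_M" if header_style == "tokens"
                       else f"colA_{cond}{dev}")
                cols[key] = rng.normal(0.6, 0.05, len(subjects))
        wide = pd.DataFrame({"Subject": subjects,
                             "Group": [s[:2] for s in subjects], **cols})
        wide.to_excel(path, index=False)

    def test_autodetects_wide_layout(self, tmp_path):
        p = tmp_path / "s1_synthetic.xlsx"
        self._write_wide(p)
        long = read_subject_level_xlsx(p)
        assert set(long.condition) == {"self", "100", "110"}
        assert set(long.device) == {"smartmove", "reference"}
        assert len(long) == 6 * 6
        # feeds straight into the ANOVA
        at = mixed_anova(long.assign(measure="delta_M"), "group_rac_device")
        assert at.ss_total > 0

    def test_unrecognizable_headers_fail_loudly(self, tmp_path):
        p = tmp_path / "bad.xlsx"
        pd.DataFrame({"Subject": ["PD01"], "foo": [1.0], "bar": [2.0]}).to_excel(
            p, index=False)
        with pytest.raises(ValueError, match="auto-detect"):
            read_subject_level_xlsx(p)
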