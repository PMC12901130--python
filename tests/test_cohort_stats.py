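"""Normality, device ANOVA/Tukey and R^2 tables, with simulation-based
calibration checks and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flairqc.cohort_stats import (
    QC_PARAMS,
    anova_by_device,
    build_report,
    build_table,
    r2_table,
    shapiro_per_device,
    tukey_hsd,
    write_report,
)


def make_table(p_by_device: dict[str, np.ndarray], **params) -> pd.DataFrame:
    rows = []
    k = 0
    for dev, ps in p_by_device.items():
        for p in ps:
            row = {"study_id": f"{dev}-S{k:03d}", "device_id": dev, "p": p, "sd": 0.1}
            for name, vals in params.items():
                row[name] = vals[k]
            rows.append(row)
            k += 1
    return pd.DataFrame(rows)


class TestShapiro:
    def test_constant_device_sample_is_flagged_degenerate(self):
        t = make_table({"A": np.full(10, 0.5), "B": np.linspace(0.2, 0.8, 10)})
        res = shapiro_per_device(t).set_index("device_id")
        assert res.loc["A", "flag"] == "zero variance"
        assert np.isnan(res.loc["A", "p_value"])
        assert res.loc["B", "flag"] == ""

    def test_two_point_mixture_rejected_most_of_the_time(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sample = rng.choice([0.0, 1.0], size=10)
            while np.ptp(sample) == 0:
                sample = rng.choice([0.0, 1.0], size=10)
            t = make_table({"A": sample})
            p = shapiro_per_device(t)["p_value"].iloc[0]
            rejections += p < 0.05
        assert rejections >= 160  # >= 80% of 200 seeds

    def test_gaussian_type_I_error_near_nominal(self):
        rejections = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t = make_table({"A": rng.normal(0.5, 0.1, 10)})
            rejections += shapiro_per_device(t)["p_value"].iloc[0] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rejections / n_seeds - 0.05) < 3 * se


class TestAnova:
    def test_equal_group_means_give_small_f(self):
        base = np.array([0.3, 0.4, 0.5, 0.6, 0.7])
        t = make_table({d: base for d in ("A", "B", "C")})
        f, p = anova_by_device(t)
        assert f < 0.2
        assert p > 0.5

    def test_null_type_I_error_near_nominal(self):
        n_seeds = 1000
        rejections = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            t = make_table({f"D{i}": rng.normal(0.5, 0.1, 10) for i in range(15)})
            _, p = anova_by_device(t)
            rejections += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rejections / n_seeds - 0.05) < 3 * se

    def test_power_against_a_three_sigma_shifted_group(self):
        n_seeds = 200
        hits = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            groups = {f"D{i}": rng.normal(0.5, 0.1, 10) for i in range(14)}
            groups["DS"] = rng.normal(0.8, 0.1, 10)  # +3 within-group SDs
            _, p = anova_by_device(make_table(groups))
            hits += p < 0.05
        assert hits >= 0.95 * n_seeds

    def test_single_device_is_an_error(self):
        t = make_table({"A": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError):
            anova_by_device(t)


class TestTukey:
    def test_identical_pair_among_many_rarely_significant(self):
        n_seeds = 200
        false_hits = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            groups = {
                "A": rng.normal(0.5, 0.1, 10),
                "B": rng.normal(0.5, 0.1, 10),  # identical distribution to A
                "C": rng.normal(0.9, 0.1, 10),
                "D": rng.normal(0.1, 0.1, 10),
            }
            mat = tukey_hsd(make_table(groups))
            false_hits += mat.loc["A", "B"] <= 0.05
        assert false_hits <= 0.05 * n_seeds

    def test_adjusted_p_not_below_unadjusted_pairwise_p(self):
        """Multiplicity adjustment can only raise the p of the underlying
        pooled-variance pairwise comparison."""
        rng = np.random.default_rng(42)
        groups = {f"D{i}": rng.normal(0.5 + 0.05 * i, 0.1, 10) for i in range(6)}
        t = make_table(groups)
        mat = tukey_hsd(t)
        all_x = np.concatenate(list(groups.values()))
        k, n = len(groups), 10
        df_err = all_x.size - k
        s2p = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups.values()) / df_err
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                t_stat = abs(np.mean(groups[a]) - np.mean(groups[b])) / np.sqrt(s2p * 2 / n)
                p_raw = 2 * stats.t.sf(t_stat, df_err)
                assert mat.loc[a, b] >= p_raw - 1e-12

    def test_matrix_is_symmetric_with_ignored_diagonal(self):
        rng = np.random.default_rng(7)
        t = make_table({f"D{i}": rng.normal(0.5, 0.1, 10) for i in range(5)})
        mat = tukey_hsd(t)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(mat.values)))

    def test_agrees_with_statsmodels_reference(self):
        """Independent cross-check of the adjusted p-values."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        t = make_table({f"D{i}": rng.normal(0.5 + 0.07 * i, 0.1, 10) for i in range(4)})
        mat = tukey_hsd(t)
        ref = pairwise_tukeyhsd(t["p"], t["device_id"])
        for (a, b), p_ref in zip(ref._multicomp.pairindices and
                                 [(ref.groupsunique[i], ref.groupsunique[j])
                                  for i, j in zip(*np.triu_indices(4, 1))],
                                 ref.pvalues):
            assert mat.loc[a, b] == pytest.approx(p_ref, abs=1e-3)


class TestR2:
    def test_exact_linear_relation_gives_r2_one(self):
        p = np.linspace(0.1, 0.9, 20)
        t = make_table({"A": p[:10], "B": p[10:]}, cnr=3.0 * p + 1.0)
        assert r2_table(t, "study")["cnr"] == pytest.approx(1.0)

    def test_independent_parameter_gives_small_r2(self):
        small = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0, 1, 150)
            t = make_table({"A": p}, qi=rng.uniform(0, 1, 150))
            small += r2_table(t, "study")["qi"] < 0.05
        assert small >= 0.90 * n_seeds

    def test_device_median_level_matches_by_hand_computation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 45)
        noise = rng.uniform(0, 5, 45)
        t = make_table({f"D{i:02d}": p[3 * i: 3 * i + 3] for i in range(15)}, noise_sd=noise)
        got = r2_table(t, "device_median")["noise_sd"]
        # independent brute-force oracle on the same 15-device fixture
        med_p, med_x = [], []
        for i in range(15):
            med_p.append(np.median(p[3 * i: 3 * i + 3]))
            med_x.append(np.median(noise[3 * i: 3 * i + 3]))
        mx, my = np.mean(med_x), np.mean(med_p)
        num = np.sum((np.array(med_x) - mx) * (np.array(med_p) - my))
        expected = num**2 / (np.sum((np.array(med_x) - mx) ** 2) * np.sum((np.array(med_p) - my) ** 2))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("scale, offset", [(3.0, 0.0), (-2.0, 5.0), (0.01, -1.0)])
    def test_r2_invariant_to_affine_rescaling(self, scale, offset):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 60)
        x = 2.0 * p + rng.normal(0, 0.2, 60)
        t1 = make_table({"A": p[:30], "B": p[30:]}, contrast=x)
        t2 = make_table({"A": p[:30], "B": p[30:]}, contrast=scale * x + offset)
        assert r2_table(t1, "study")["contrast"] == pytest.approx(
            r2_table(t2, "study")["contrast"], rel=1e-9
        )

    def test_constant_parameter_is_flagged_undefined(self):
        t = make_table({"A": np.linspace(0.1, 0.9, 10)}, qi=np.ones(10))
        assert np.isnan(r2_table(t, "study")["qi"])

    def test_infinite_sentinels_are_excluded_pairwise(self):
        p = np.linspace(0.1, 0.9, 10)
        x = 3 * p.copy()
        x[3] = np.inf
        t = make_table({"A": p}, mtf50_fh=x)
        assert r2_table(t, "study")["mtf50_fh"] == pytest.approx(1.0)


class TestBuildReport:
    def test_single_device_report_has_no_anova_or_device_median_sections(self):
        t = make_table({"A": np.linspace(0.2, 0.8, 10)}, cnr=np.linspace(1, 5, 10))
        rep = build_report(t)
        assert rep.anova_f is None
        assert rep.tukey is None
        assert "r2_by_device_median" not in rep.r2.columns
        assert "r2_by_study" in rep.r2.columns
        assert len(rep.device_summary) == 1

    def test_rendered_csvs_match_report_fields(self, tmp_path):
        rng = np.random.default_rng(1)
        t = make_table(
            {f"D{i}": rng.uniform(0.2, 0.8, 10) for i in range(5)},
            cnr=rng.uniform(1, 10, 50),
            contrast=rng.uniform(0.1, 0.3, 50),
        )
        rep = build_report(t)
        write_report(rep, tmp_path)
        r2_disk = pd.read_csv(tmp_path / "r2_table.csv", index_col=0)
        for param in ("cnr", "contrast"):
            assert r2_disk.loc[param, "r2_by_study"] == pytest.approx(
                rep.r2.loc[param, "r2_by_study"], rel=1e-6
            )
        anova_disk = pd.read_csv(tmp_path / "anova_by_device.csv")
        assert anova_disk["f_statistic"].iloc[0] == pytest.approx(rep.anova_f, rel=1e-6)

    def test_rerun_produces_identical_bytes(self, tmp_path):
        rng = np.random.default_rng(2)
        t = make_table({f"D{i}": rng.uniform(0, 1, 5) for i in range(4)},
                       qi=rng.uniform(0.8, 1.0, 20))
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_report(build_report(t), d1, header="# h=x\n")
        write_report(build_report(t), d2, header="# h=x\n")
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_build_table_joins_on_study_id(self):
        ratings = pd.DataFrame(
            {"study_id": ["a", "b"], "device_id": ["D", "D"], "p": [0.4, 0.6], "sd": [0.1, 0.1]}
        )
        qc = pd.DataFrame({"study_id": ["b", "a"], "cnr": [2.0, 1.0]})
        t = build_table(ratings, qc)
        assert t.set_index("study_id").loc["a", "cnr"] == 1.0
        with pytest.raises(ValueError):
            build_table(ratings, qc.assign(study_id=["x", "y"]))
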