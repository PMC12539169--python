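"""Metric suite: closed forms, brute-force oracle equivalence, exclusion rule."""

import numpy as np
import pytest

from cephalo3d.catalog import builtin_catalog, dental_names, phantom_catalog
from cephalo3d.metrics import (
    axis_decomposition,
    icc31,
    manifest_rollup,
    mre_summary,
    paired_errors,
    presence_confusion,
    radial_error,
    report,
    sample_size_one_sample_t,
    sdr,
    wovi_hd95,
)
from cephalo3d.volume_io import LandmarkSet


class TestRadialError:
    def test_pythagorean_triple(self):
        assert radial_error((0, 0, 0), (1, 2, 2)) == pytest.approx(3.0)

    def test_identity_and_translation_invariance(self, rng):
        p = rng.normal(size=3)
        assert radial_error(p, p) == 0.0
        t = rng.normal(size=3)
        assert radial_error(p + t, p + t + [1, 2, 2]) == pytest.approx(3.0)

    def test_absent_operand_rejected(self):
        with pytest.raises(ValueError):
            radial_error((np.nan, 0, 0), (0, 0, 0))


class TestMRESummary:
    def test_degenerate_spread(self):
        s = mre_summary([1.0, 1.0, 1.0])
        assert s["mean"] == 1.0 and s["sd"] == 0.0
        assert s["ci95"] == (1.0, 1.0)

    def test_two_point_formula(self):
        s = mre_summary([0.0, 2.0])
        assert s["mean"] == pytest.approx(1.0)
        assert s["sd"] == pytest.approx(np.sqrt(2.0))

    def test_ci_midpoint_is_mean(self, rng):
        e = rng.exponential(size=50)
        s = mre_summary(e)
        assert 0.5 * (s["ci95"][0] + s["ci95"][1]) == pytest.approx(s["mean"])

    def test_single_error_no_sd(self):
        s = mre_summary([1.5])
        assert np.isnan(s["sd"])


class TestSDR:
    def test_direct_count(self):
        out = sdr([1.0, 2.5, 3.5])
        assert out[2.0] == pytest.approx(100 / 3)
        assert out[3.0] == pytest.approx(200 / 3)
        assert out[4.0] == pytest.approx(100.0)

    def test_all_under_two(self):
        assert list(sdr([0.5, 1.0, 1.9]).values()) == [100.0, 100.0, 100.0]

    def test_monotone_in_threshold_property(self, rng):
        for _ in range(20):
            e = rng.exponential(2.0, size=rng.integers(1, 40))
            v = list(sdr(e).values())
            assert v == sorted(v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sdr([])

    def test_oracle_equivalence(self, rng):
        for _ in range(100):
            e = rng.exponential(2.0, size=rng.integers(1, 30))
            ours = sdr(e)
            for t in (2.0, 3.0, 4.0):
                brute = 100.0 * sum(1 for x in e if x < t) / len(e)
                assert ours[t] == pytest.approx(brute)


def _mk_records(offsets, names=None):
    names = names or [f"lm{i}" for i in range(len(offsets))]
    return [{"name": n, "radial": float(np.linalg.norm(o)),
             "dx": abs(o[0]), "dy": abs(o[1]), "dz": abs(o[2])}
            for n, o in zip(names, offsets)]


class TestAxisDecomposition:
    def test_all_z_dominant(self):
        recs = _mk_records([(0, 0, 1.0)] * 5)
        out = axis_decomposition(recs)
        assert out["dominant_fractions"]["z"] == 100.0

    def test_fractions_partition(self, rng):
        recs = _mk_records(rng.normal(size=(30, 3)))
        out = axis_decomposition(recs)
        assert sum(out["dominant_fractions"].values()) == pytest.approx(100.0)

    def test_41_landmark_constructed_fractions(self):
        # 26 z-dominant, 7 x-dominant, 8 y-dominant -> 63.4 / 17.1 / 19.5 %
        offsets = ([(0.1, 0.1, 1.0)] * 26 + [(1.0, 0.1, 0.1)] * 7 + [(0.1, 1.0, 0.1)] * 8)
        out = axis_decomposition(_mk_records(offsets))
        assert out["n_landmarks"] == 41
        assert out["dominant_fractions"]["z"] == pytest.approx(63.4, abs=0.05)
        assert out["dominant_fractions"]["x"] == pytest.approx(17.1, abs=0.05)
        assert out["dominant_fractions"]["y"] == pytest.approx(19.5, abs=0.05)

    def test_tie_breaks_to_earlier_axis(self):
        out = axis_decomposition(_mk_records([(1.0, 1.0, 0.5)]))
        assert out["dominant_axis"]["lm0"] == "x"

    def test_inequality_chain_on_random_records(self, rng):
        for _ in range(100):
            o = rng.normal(size=3)
            r = float(np.linalg.norm(o))
            assert max(abs(o)) <= r + 1e-12
            assert r <= np.sum(np.abs(o)) + 1e-12


def _sets(pairs, dental=("UI",)):
    preds, truths = [], []
    for i, (p_present, t_present) in enumerate(pairs):
        pred = LandmarkSet(case_id=f"c{i}", source="prediction")
        truth = LandmarkSet(case_id=f"c{i}")
        pred.add("UI", [0, 0, 0] if p_present else None, present=p_present)
        truth.add("UI", [0, 0, 0] if t_present else None, present=t_present)
        preds.append(pred)
        truths.append(truth)
    return preds, truths


class TestPresenceConfusion:
    def test_direct_formulas(self):
        pairs = [(True, True)] * 8 + [(False, False)] + [(True, False)]
        preds, truths = _sets(pairs)
        out = presence_confusion(preds, truths, ["UI"])
        assert (out["TP"], out["TN"], out["FP"], out["FN"]) == (8, 1, 1, 0)
        assert out["dl_acc"] == pytest.approx(90.0)
        assert out["dl_pre"] == pytest.approx(100 * 8 / 9, abs=0.05)

    def test_perfect_agreement(self):
        preds, truths = _sets([(True, True)] * 5 + [(False, False)] * 2)
        out = presence_confusion(preds, truths, ["UI"])
        assert out["dl_acc"] == 100.0 and out["dl_pre"] == 100.0

    def test_always_present_with_missing_teeth(self):
        preds, truths = _sets([(True, True)] * 4 + [(True, False)] * 2)
        out = presence_confusion(preds, truths, ["UI"])
        assert out["dl_acc"] < 100.0

    def test_no_positive_predictions_flagged(self):
        preds, truths = _sets([(False, False)] * 3)
        assert np.isnan(presence_confusion(preds, truths, ["UI"])["dl_pre"])

    def test_positional_tp_variant(self):
        pred = LandmarkSet(case_id="c0", source="prediction")
        truth = LandmarkSet(case_id="c0")
        pred.add("UI", [5.0, 0, 0])
        truth.add("UI", [0.0, 0, 0])
        strict = presence_confusion([pred], [truth], ["UI"], positional_tp_mm=2.0)
        assert strict["TP"] == 0 and strict["FP"] == 1


class TestICC:
    def test_identical_columns(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc31(m) == pytest.approx(1.0)

    def test_rater_offset_ignored(self):
        m = np.column_stack([np.arange(5.0), np.arange(5.0) + 3.7])
        assert icc31(m) == pytest.approx(1.0)

    def test_against_full_anova_oracle(self):
        m = np.array([[1, 2], [2, 3], [4, 4], [6, 7.0]])

        def oracle(mat):
            n, k = mat.shape
            rows = mat.mean(1)
            cols = mat.mean(0)
            g = mat.mean()
            ssr = k * ((rows - g) ** 2).sum()
            ssc = n * ((cols - g) ** 2).sum()
            sse = sum((mat[i, j] - rows[i] - cols[j] + g) ** 2
                      for i in range(n) for j in range(k))
            msr, mse = ssr / (n - 1), sse / ((n - 1) * (k - 1))
            return (msr - mse) / (msr + (k - 1) * mse)

        assert icc31(m) == pytest.approx(oracle(m), rel=1e-12)

    def test_against_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        for _ in range(5):
            m = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(8), 3),
                "raters": np.tile(np.arange(3), 8),
                "score": m.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="score")
            # consistency, single rater: pingouin's ICC(C,1) == ICC(3,1)
            ref_val = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
            assert icc31(m) == pytest.approx(ref_val, abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            icc31(np.ones((5, 2)))


class TestWOVI:
    def test_identical_sessions_zero(self, rng):
        pts = rng.normal(size=(20, 3))
        out = wovi_hd95([pts], [pts.copy()])
        assert out["mean"] == 0.0

    def test_single_displacement_oracle(self):
        a = np.zeros((20, 3))
        a[:, 0] = np.arange(20) * 10  # well-separated points
        b = a.copy()
        b[7, 1] += 5.0

        def oracle_hd95(x, y):
            d = np.sqrt(((x[:, None, :] - y[None, :, :]) ** 2).sum(-1))
            directed = np.concatenate([d.min(1), d.min(0)])
            return np.percentile(directed, 95)

        out = wovi_hd95([a], [b])
        assert out["mean"] == pytest.approx(oracle_hd95(a, b))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(15, 3)), rng.normal(size=(12, 3))
        assert wovi_hd95([a], [b])["mean"] == pytest.approx(wovi_hd95([b], [a])["mean"])

    def test_empty_excluded(self, rng):
        a = rng.normal(size=(5, 3))
        out = wovi_hd95([a, np.empty((0, 3))], [a.copy(), a])
        assert out["excluded_cases"] == 1


class TestSampleSize:
    def test_published_configuration(self):
        assert sample_size_one_sample_t(0.4, 1.0, 0.05, 0.90) == 68

    def test_quadratic_scaling_vs_normal_oracle(self):
        from scipy import stats
        def normal_approx(delta, sd, alpha=0.05, power=0.9):
            za = stats.norm.ppf(1 - alpha / 2)
            zb = stats.norm.ppf(power)
            return ((za + zb) * sd / delta) ** 2
        n1 = sample_size_one_sample_t(0.4, 1.0)
        n2 = sample_size_one_sample_t(0.8, 1.0)
        assert n1 / n2 == pytest.approx(normal_approx(0.4, 1) / normal_approx(0.8, 1), rel=0.15)
        assert n1 / n2 == pytest.approx(4.0, rel=0.25)

    def test_against_statsmodels_oracle(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        ref = smp.TTestPower().solve_power(effect_size=0.4, alpha=0.05, power=0.9)
        assert sample_size_one_sample_t(0.4, 1.0) == int(np.ceil(ref))

    def test_boundary_sanity(self):
        assert sample_size_one_sample_t(5.0, 0.1, alpha=0.5, power=0.5) == 2

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            sample_size_one_sample_t(-1, 1)


class TestOracleEquivalence:
    """MRE and axis metrics agree with plain-loop implementations."""

    def test_mre_loop_oracle(self, rng):
        for _ in range(100):
            e = rng.exponential(size=rng.integers(2, 20))
            s = mre_summary(e)
            mean = sum(e) / len(e)
            var = sum((x - mean) ** 2 for x in e) / (len(e) - 1)
            assert s["mean"] == pytest.approx(mean)
            assert s["sd"] == pytest.approx(np.sqrt(var))

    def test_radial_loop_oracle(self, rng):
        for _ in range(100):
            p, t = rng.normal(size=3), rng.normal(size=3)
            brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, t)))
            assert radial_error(p, t) == pytest.approx(brute)


class TestReport:
    def _phantom_sets(self, rng, n_cases=4):
        catalog = phantom_catalog()
        preds, truths, scen = [], [], []
        for i in range(n_cases):
            truth = LandmarkSet(case_id=f"c{i}")
            pred = LandmarkSet(case_id=f"c{i}", source="prediction")
            for d in catalog:
                t = rng.uniform(10, 30, size=3)
                absent = (i == 2 and d.name == "L6L")
                truth.add(d.name, None if absent else t, present=not absent)
                pred.add(d.name, None if absent else t + rng.normal(0, 0.5, 3),
                         present=not absent)
            preds.append(pred)
            truths.append(truth)
            scen.append(["Normal", "M", "MDL", "MA"][i % 4])
        return preds, truths, scen

    def test_exclusion_rule_leaves_errors_bit_identical(self, rng):
        preds, truths, scen = self._phantom_sets(rng)
        rep = report(preds, truths, phantom_catalog(), scenarios=scen)
        # adding a truth-absent landmark changes confusion, not MRE/SDR
        extra_p, extra_t = [], []
        for p, t in zip(preds, truths):
            p2 = LandmarkSet(case_id=p.case_id, source="prediction")
            t2 = LandmarkSet(case_id=t.case_id)
            for n, lm in p.entries.items():
                p2.add(n, lm.coord if lm.present else None, lm.present)
            for n, lm in t.entries.items():
                if n == "U6R":
                    t2.add(n, None, present=False)  # flip truth to absent
                else:
                    t2.add(n, lm.coord if lm.present else None, lm.present)
            extra_p.append(p2)
            extra_t.append(t2)
        rep2 = report(extra_p, extra_t, phantom_catalog(), scenarios=scen)
        assert rep2.presence["FP"] > rep.presence["FP"]
        # errors for remaining landmarks unchanged
        kept = rep.per_case[rep.per_case.name != "U6R"]["radial"].to_numpy()
        assert np.array_equal(np.sort(rep2.per_case["radial"].to_numpy()), np.sort(kept))

    def test_case_mismatch_lists_ids(self, rng):
        preds, truths, _ = self._phantom_sets(rng)
        preds[0].case_id = "other"
        with pytest.raises(ValueError, match="other"):
            report(preds, truths, phantom_catalog())

    def test_strata_and_frame(self, rng):
        preds, truths, scen = self._phantom_sets(rng)
        rep = report(preds, truths, phantom_catalog(), scenarios=scen)
        assert set(rep.by_scenario) == {"Normal", "M", "MDL", "MA"}
        assert set(rep.by_tissue) <= {"bone", "dental"}
        frame = rep.to_frame()
        assert {"stratum", "MRE", "SDR_2mm"} <= set(frame.columns)


class TestManifestRollup:
    MANIFEST = {
        "center1-sct": {"n": 480, "male": 265, "mean_age": 28.03, "M": 216, "MDL": 148, "MA": 78},
        "center1-cbct": {"n": 240, "male": 117, "mean_age": 33.20, "M": 102, "MDL": 48, "MA": 27},
        "center2-sct": {"n": 320, "male": 172, "mean_age": 34.57, "M": 104, "MDL": 64, "MA": 28},
        "center3-cbct": {"n": 150, "male": 67, "mean_age": 24.65, "M": 36, "MDL": 54, "MA": 53},
    }

    def test_totals(self):
        out = manifest_rollup(self.MANIFEST)
        assert out["total_cases"] == 1190
        assert out["total_M"] == 458

    def test_pooled_demographics(self):
        out = manifest_rollup(self.MANIFEST)
        assert out["pct_male"] == pytest.approx(52.2, abs=0.05)
        assert out["pooled_mean_age"] == pytest.approx(30.41, abs=0.005)
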