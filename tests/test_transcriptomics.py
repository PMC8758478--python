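"""TMM normalisation, ComBat adjustment, NB differential expression."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from lfapp.transcriptomics import (
    CountMatrix, NormFactors, SampleMetadata, bh_adjust, build_design,
    combat_adjust, filter_zero_counts, log_cpm, nb_dea, overlap_percentage,
    percent_increase, tmm_factors,
)


def _cm(mat, genes=None, samples=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))


class TestTMM:
    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, 200)
        cm = _cm(np.stack([a, 2 * a], axis=1))
        f = tmm_factors(cm).factor.to_numpy()
        np.testing.assert_allclose(f, [1.0, 1.0], rtol=1e-9)

    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(30, 100) + 1
        cm = _cm(np.stack([a, a, a], axis=1))
        np.testing.assert_allclose(tmm_factors(cm).factor.to_numpy(), 1.0)

    def test_toy_matches_hand_computation(self):
        """A 20-gene toy with a 5-gene 8-fold-up sample reproduces a direct
        computation of the trimmed weighted mean of M-values."""
        rng = np.random.default_rng(2)
        base = rng.integers(20, 200, 20)
        b = base.copy()
        b[:5] *= 8  # 25% of genes strongly up in sample B
        cm = _cm(np.stack([base, b], axis=1))
        factors = tmm_factors(cm).factor.to_numpy()

        # independent hand computation (same definition, written straight)
        y_a, y_b = base.astype(float), b.astype(float)
        n_a, n_b = y_a.sum(), y_b.sum()
        # reference: sample with f75 closest to mean
        f75 = [np.quantile(y_a / n_a, 0.75), np.quantile(y_b / n_b, 0.75)]
        ref = int(np.argmin(np.abs(np.array(f75) - np.mean(f75))))
        y_r, n_r = (y_a, n_a) if ref == 0 else (y_b, n_b)
        y_o, n_o = (y_b, n_b) if ref == 0 else (y_a, n_a)
        m = np.log2((y_o / n_o) / (y_r / n_r))
        a_val = 0.5 * np.log2((y_o / n_o) * (y_r / n_r))
        m_lo, m_hi = np.quantile(m, [0.3, 0.7])
        a_lo, a_hi = np.quantile(a_val, [0.05, 0.95])
        keep = (m >= m_lo) & (m <= m_hi) & (a_val >= a_lo) & (a_val <= a_hi)
        w = 1.0 / ((n_o - y_o) / (n_o * y_o) + (n_r - y_r) / (n_r * y_r))
        f_other = 2.0 ** (np.sum((w * m)[keep]) / np.sum(w[keep]))
        expected = np.ones(2)
        expected[1 - ref] = f_other
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(factors, expected, rtol=1e-12)
        # the sample with extra expression is down-weighted relative to the other
        assert factors[1] < factors[0]

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(40, size=(150, 4)) + 1
        f1 = tmm_factors(_cm(counts)).factor.to_numpy()
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 3.0
        f2 = tmm_factors(_cm(scaled.astype(int))).factor.to_numpy()
        np.testing.assert_allclose(f1, f2, atol=0.02)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_against_edger_reference(self, tmp_path):
        """Factors agree with edgeR::calcNormFactors on a mixed fixture."""
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(10, 10 / (10 + 100.0), size=(400, 6))
        counts[:40, :3] *= 4  # composition bias in half the samples
        cm = _cm(counts)
        ours = tmm_factors(cm).factor.to_numpy()
        csv = tmp_path / "c.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = tmp_path / "t.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.csv("{csv}"));'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=0.02)

    def test_disjoint_sample_rejected(self):
        cm = _cm([[5, 0], [7, 0], [0, 3]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(cm, ref_sample="s0")


class TestLogCpm:
    def test_zero_count_arithmetic(self):
        cm = _cm([[0], [10 ** 6 - 0]])  # library size 1e6
        vals = log_cpm(cm, prior=0.5)
        assert vals.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-6)

    def test_doubling_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(500, size=(50, 3)) + 100
        v1 = log_cpm(_cm(counts)).to_numpy()
        v2 = log_cpm(_cm(2 * counts)).to_numpy()
        assert np.max(np.abs(v1 - v2)) < 0.01

    def test_three_by_three_hand_computation(self):
        counts = np.array([[10, 0, 4], [90, 50, 6], [0, 50, 0]])
        cm = _cm(counts)
        vals = log_cpm(cm, prior=0.5).to_numpy()
        lib = counts.sum(axis=0)
        expected = np.log2((counts + 0.5) / lib * 1e6)
        np.testing.assert_allclose(vals, expected, rtol=1e-12)


class TestComBat:
    def _paired_shift_fixture(self, rng, g=150, n1=10, n2=10, delta=1.7):
        """Two batches differing by a constant shift, noise standardised per
        gene so the shift is the only batch difference in standardised units."""
        e = rng.normal(0, 1, (g, n1))
        e = (e - e.mean(1, keepdims=True)) / e.std(1, keepdims=True)
        x = np.hstack([e, e + delta])
        cols = [f"s{j}" for j in range(n1 + n2)]
        return pd.DataFrame(x, columns=cols), ["b1"] * n1 + ["b2"] * n2

    def test_single_batch_identity(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(50, 12)))
        out = combat_adjust(df, ["b1"] * 12)
        np.testing.assert_array_equal(out.to_numpy(), df.to_numpy())

    def test_constant_shift_removed_exactly(self):
        """Empirical-Bayes adjustment equalises batch means to 1e-6 on a
        shift-only fixture."""
        rng = np.random.default_rng(7)
        df, batch = self._paired_shift_fixture(rng)
        adj = combat_adjust(df, batch, shrink=True)
        m1 = adj.iloc[:, :10].mean(axis=1)
        m2 = adj.iloc[:, 10:].mean(axis=1)
        assert np.max(np.abs(m1 - m2)) < 1e-6

    def test_null_data_f_statistics_near_one(self):
        """Random batch labels on i.i.d. data: per-gene batch F-statistics
        stay near 1 after adjustment (no signal is invented)."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(200, 24))
        df = pd.DataFrame(x)
        batch = list(rng.permutation(["b1"] * 12 + ["b2"] * 12))
        adj = combat_adjust(df, batch, shrink=True).to_numpy()
        b1 = np.array(batch) == "b1"

        def fstats(m):
            a, b = m[:, b1], m[:, ~b1]
            num = (12 * (a.mean(1) - m.mean(1)) ** 2
                   + 12 * (b.mean(1) - m.mean(1)) ** 2)
            den = (a.var(1, ddof=1) * 11 + b.var(1, ddof=1) * 11) / 22
            return num / den

        assert 0.3 < fstats(adj).mean() < 1.3

    def test_idempotent_in_exact_mode(self):
        rng = np.random.default_rng(9)
        x = np.hstack([rng.normal(0, 1, (80, 8)),
                       rng.normal(0, 1, (80, 8)) + rng.normal(0, 1, (80, 1))])
        df = pd.DataFrame(x)
        batch = ["b1"] * 8 + ["b2"] * 8
        once = combat_adjust(df, batch, shrink=False)
        twice = combat_adjust(once, batch, shrink=False)
        assert np.max(np.abs(twice.to_numpy() - once.to_numpy())) < 1e-6

    def test_group_effect_preserved(self):
        """Preserving the design keeps a true group difference intact."""
        rng = np.random.default_rng(10)
        g, n = 100, 24
        group = np.array([1.0] * 12 + [0.0] * 12)
        batch = ["b1", "b2"] * 12  # balanced, not confounded
        x = rng.normal(size=(g, n)) + 2.0 * group[None, :]
        x[:, np.array(batch) == "b2"] += 1.0
        df = pd.DataFrame(x)
        adj = combat_adjust(df, batch, preserve=group[:, None])
        diff = (adj.to_numpy()[:, group == 1].mean(1)
                - adj.to_numpy()[:, group == 0].mean(1))
        assert diff.mean() == pytest.approx(2.0, abs=0.1)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(20, 8)))
        batch = ["b1"] * 4 + ["b2"] * 4
        group = np.array([1.0] * 4 + [0.0] * 4)  # identical to batch
        with pytest.raises(ValueError, match="confounded"):
            combat_adjust(df, batch, preserve=group[:, None])

    def test_small_batch_rejected(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            combat_adjust(df, ["b1", "b1", "b2"])

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_against_sva_combat(self, tmp_path):
        """Adjusted values agree with sva::ComBat on a batch-shift fixture."""
        rng = np.random.default_rng(12)
        g, n1, n2 = 120, 8, 8
        x = np.hstack([rng.normal(0, 1, (g, n1)),
                       rng.normal(0.8, 1.3, (g, n2))])
        df = pd.DataFrame(x, columns=[f"s{j}" for j in range(n1 + n2)])
        ours = combat_adjust(df, ["b1"] * n1 + ["b2"] * n2, shrink=True)
        csv = tmp_path / "x.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "c.R"
        script.write_text(
            'suppressMessages(library(sva));'
            f'x <- as.matrix(read.csv("{csv}"));'
            f'b <- c(rep(1,{n1}), rep(2,{n2}));'
            'out <- ComBat(x, batch=b);'
            f'write.csv(out, "{tmp_path}/out.csv", row.names=FALSE)')
        subprocess.run(["Rscript", str(script)], capture_output=True,
                       text=True, check=True)
        theirs = pd.read_csv(tmp_path / "out.csv").to_numpy()
        # same EB model; residual discrepancy is the pooled-variance dof
        # convention (sva divides by n, this package by n - rank)
        assert np.corrcoef(ours.to_numpy().ravel(), theirs.ravel())[0, 1] > 0.9995
        assert np.max(np.abs(ours.to_numpy() - theirs)) < 0.35
        # batch means agree closely in both adjustments
        np.testing.assert_allclose(ours.to_numpy().mean(axis=1),
                                   theirs.mean(axis=1), atol=0.02)


class TestNbDea:
    def test_identical_groups_zero_log2fc(self):
        rng = np.random.default_rng(13)
        half = rng.poisson(100, size=(40, 10))
        counts = np.hstack([half, half])  # cases duplicate controls exactly
        cm = _cm(counts)
        n = 20
        # identical groups carry identical covariates so the group
        # coefficient is exactly zero
        half = pd.DataFrame({
            "batch": rng.choice(["b1", "b2"], 10),
            "age": rng.normal(85, 6, 10),
            "sex": rng.choice(["m", "f"], 10),
            "rin": rng.normal(7, 1, 10),
            "study": rng.choice(["ROS", "MAP"], 10),
        })
        t = pd.concat([half, half], ignore_index=True)
        t.insert(0, "sample_id", [f"s{j}" for j in range(n)])
        t.insert(1, "group", ["case"] * 10 + ["control"] * 10)
        res = nb_dea(cm, SampleMetadata(t), None)
        assert np.max(np.abs(res.table["log2fc"])) < 1e-6

    def test_type_one_error_on_null(self, small_cohort):
        cm, meta = small_cohort
        res = nb_dea(cm, meta, tmm_factors(cm))
        frac = float((res.table["pvalue"] < 0.05).mean())
        assert 0.01 < frac < 0.10  # desk-scale version of the calibration check

    def test_log2fc_recovery(self):
        """Genes planted at log2FC = 1 (mean 200, dispersion 0.05, 50/50)
        are recovered within [0.8, 1.2] in >=90% of replicates."""
        rng = np.random.default_rng(14)
        g0, g1, n = 1000, 50, 100
        base = np.concatenate([np.exp(rng.normal(5, 1.5, g0)), np.full(g1, 200.0)])
        lfc = np.concatenate([np.zeros(g0), np.ones(g1)])
        disp = np.concatenate([np.full(g0, 0.1), np.full(g1, 0.05)])
        group = np.array([1] * 50 + [0] * 50)
        mu = base[:, None] * 2.0 ** (lfc[:, None] * group[None, :])
        r = 1 / disp
        counts = rng.negative_binomial(r[:, None], r[:, None] / (r[:, None] + mu))
        cm = _cm(counts)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "group": np.where(group == 1, "case", "control"),
            "batch": ["b1", "b2"] * 50,
            "age": rng.normal(85, 6, n), "sex": rng.choice(["m", "f"], n),
            "rin": rng.normal(7, 1, n), "study": rng.choice(["ROS", "MAP"], n)}))
        res = nb_dea(cm, meta, tmm_factors(cm))
        est = res.table.set_index("gene_id").loc[
            [f"g{i}" for i in range(g0, g0 + g1)], "log2fc"].to_numpy()
        assert np.mean((est > 0.8) & (est < 1.2)) >= 0.9

    def test_rank_follows_fdr(self, small_cohort):
        cm, meta = small_cohort
        res = nb_dea(cm, meta, None)
        t = res.table.sort_values("rank")
        assert np.all(np.diff(t["fdr"].to_numpy()) >= -1e-15)
        assert np.all(t["fdr"].to_numpy() >= t["pvalue"].to_numpy() - 1e-12)

    def test_non_full_rank_design_rejected(self, small_cohort):
        cm, meta = small_cohort
        t = meta.table.copy()
        t["study"] = t["batch"]  # alias study with batch
        with pytest.raises(ValueError, match="aliased"):
            build_design(SampleMetadata(t))


class TestBhAdjust:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_step_up_definition_on_permutations(self):
        """Agrees with the literal step-up definition on every ordering of
        five p-values."""
        base = [0.011, 0.04, 0.04, 0.33, 0.9]

        def reference(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            prev = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                prev = min(prev, p[i] * m / (rank_idx + 1))
                q[i] = prev
            return q

        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_adjust(list(perm)), reference(perm))


class TestFoldChangeArithmetic:
    def test_printed_percent_increase(self):
        """A 0.5338 log2 fold change is a 44.8% increase."""
        assert percent_increase(0.5338) == pytest.approx(44.8, abs=0.05)

    def test_identity_points(self):
        assert percent_increase(0.0) == 0.0
        assert percent_increase(1.0) == pytest.approx(100.0)

    def test_overlap_percentage(self):
        assert overlap_percentage(3778, 3980) == pytest.approx(94.92, abs=0.01)


def test_filter_zero_counts():
    cm = _cm([[0, 0], [1, 2], [0, 5]])
    kept = filter_zero_counts(cm)
    assert kept.gene_ids == ["g1", "g2"]


class TestQcAndIO:
    def test_qc_report_flags_planted_outlier(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(200, 15))
        x[:, 0] += 6.0  # one sample far from the rest
        df = pd.DataFrame(x, columns=[f"s{j}" for j in range(15)])
        from lfapp.transcriptomics import qc_outlier_report
        rep = qc_outlier_report(df)
        assert rep["centroid_distance_z"].idxmax() == "s0"
        assert rep.shape[0] == 15  # nothing dropped, report only

    def test_mtx_round_trip(self, tmp_path):
        from lfapp.transcriptomics import read_counts_mtx, write_counts_mtx
        rng = np.random.default_rng(22)
        cm = _cm(rng.poisson(5, size=(30, 6)))
        write_counts_mtx(cm, tmp_path / "counts")
        back = read_counts_mtx(tmp_path / "counts")
        pd.testing.assert_frame_equal(back.counts, cm.counts)
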