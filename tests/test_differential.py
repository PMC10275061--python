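"""Case-control differential correlation: Steiger chi-square, shifted
rank-sum, Bonferroni both-tests rule, list collapsing."""

import itertools

import numpy as np
import pytest
from scipy import stats

import cmuscan as cs
from cmuscan.differential import PairedMatrices


def _bm(values):
    return cs.BetaMatrix(
        [f"s{i}" for i in range(values.shape[0])], values, transformed=True
    )


def toy_cmu(probes, chrom="chr1"):
    probes = np.asarray(probes)
    return cs.CMU(
        id="u", chrom=chrom, start=0, end=100, probe_indices=probes, mean_abs_r=0.8
    )


class TestPairedMatrices:
    def test_identical_groups_identical_matrices(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((50, 6))
        pm = cs.paired_correlation_matrices(_bm(v), _bm(v.copy()), toy_cmu(range(6)))
        assert np.allclose(pm.R1, pm.R2)
        assert (np.diag(pm.R1) == 1.0).all() and (np.diag(pm.R2) == 1.0).all()

    def test_matches_direct_pairwise_computation(self):
        rng = np.random.default_rng(1)
        v1, v2 = rng.standard_normal((40, 5)), rng.standard_normal((30, 5))
        pm = cs.paired_correlation_matrices(_bm(v1), _bm(v2), toy_cmu(range(5)))
        for i, j in itertools.combinations(range(5), 2):
            assert pm.R1[i, j] == pytest.approx(stats.pearsonr(v1[:, i], v1[:, j])[0])
            assert pm.R2[i, j] == pytest.approx(stats.pearsonr(v2[:, i], v2[:, j])[0])

    def test_missing_probe_coverage_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="cover"):
            cs.paired_correlation_matrices(
                _bm(rng.standard_normal((20, 3))),
                _bm(rng.standard_normal((20, 8))),
                toy_cmu(range(5)),
            )


class TestSteiger:
    def test_equal_matrices_null_exact(self):
        R = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        pm = PairedMatrices(None, R, R.copy(), 50, 60)
        chi2, df, p = cs.steiger_matrix_test(pm)
        assert chi2 == 0.0 and df == 3 and p == 1.0

    def test_p2_matches_closed_form_fisher_z(self):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal((80, 2))
        x2 = rng.standard_normal((120, 2))
        R1 = np.corrcoef(x1, rowvar=False)
        R2 = np.corrcoef(x2, rowvar=False)
        pm = PairedMatrices(None, R1, R2, 80, 120)
        chi2, df, p = cs.steiger_matrix_test(pm)
        z = (np.arctanh(R1[0, 1]) - np.arctanh(R2[0, 1])) / np.sqrt(
            1 / 77 + 1 / 117
        )
        assert df == 1
        assert chi2 == pytest.approx(z**2, abs=1e-10)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-10)

    def test_probe_relabeling_invariance_and_group_swap(self):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal((60, 5))
        x2 = rng.standard_normal((70, 5))
        R1, R2 = np.corrcoef(x1, rowvar=False), np.corrcoef(x2, rowvar=False)
        chi2, _, _ = cs.steiger_matrix_test(PairedMatrices(None, R1, R2, 60, 70))
        perm = rng.permutation(5)
        chi2_perm, _, _ = cs.steiger_matrix_test(
            PairedMatrices(None, R1[np.ix_(perm, perm)], R2[np.ix_(perm, perm)], 60, 70)
        )
        chi2_swap, _, _ = cs.steiger_matrix_test(PairedMatrices(None, R2, R1, 70, 60))
        assert chi2_perm == pytest.approx(chi2, abs=1e-10)
        assert chi2_swap == pytest.approx(chi2, abs=1e-10)

    def test_tiny_groups_rejected(self):
        R = np.eye(3)
        with pytest.raises(ValueError, match="3 samples"):
            cs.steiger_matrix_test(PairedMatrices(None, R, R, 3, 50))

    def test_null_rejection_rate_calibrated(self):
        # both groups from one population of independent probes
        rng = np.random.default_rng(5)
        rej = 0
        n_reps = 300
        for _ in range(n_reps):
            R1 = np.corrcoef(rng.standard_normal((100, 6)), rowvar=False)
            R2 = np.corrcoef(rng.standard_normal((100, 6)), rowvar=False)
            _, _, p = cs.steiger_matrix_test(PairedMatrices(None, R1, R2, 100, 100))
            rej += p < 0.05
        assert 0.02 <= rej / n_reps <= 0.09


class TestWilcoxonShift:
    def _pm(self, offd1, offd2, p=4):
        R1, R2 = np.eye(p), np.eye(p)
        iu = np.triu_indices(p, 1)
        R1[iu] = offd1
        R2[iu] = offd2
        R1 += np.triu(R1, 1).T
        R2 += np.triu(R2, 1).T
        return PairedMatrices(None, R1, R2, 50, 50)

    def test_identical_offdiagonals_not_significant(self):
        vals = np.array([0.5, 0.6, 0.7, 0.55, 0.65, 0.45])
        effect, p, _ = cs.wilcoxon_shift_test(self._pm(vals, vals.copy()), mu=0.1)
        assert p > 0.5
        assert effect == pytest.approx(0.0)

    def test_separated_groups_significant_with_negative_effect(self):
        p = 6
        n_off = p * (p - 1) // 2
        rng = np.random.default_rng(6)
        hi = 0.9 + rng.uniform(-0.01, 0.01, n_off)
        lo = 0.5 + rng.uniform(-0.01, 0.01, n_off)
        effect, pval, _ = cs.wilcoxon_shift_test(self._pm(hi, lo, p=p), mu=0.1)
        assert pval < 0.01
        assert effect == pytest.approx(-0.4, abs=0.05)

    def test_mu_zero_reduces_to_standard_ranksum(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0.3, 0.9, 6)
        b = rng.uniform(0.3, 0.9, 6)
        _, p0, _ = cs.wilcoxon_shift_test(self._pm(a, b), mu=0.0)
        want = stats.mannwhitneyu(a, b, alternative="greater").pvalue
        assert p0 == pytest.approx(want, abs=1e-12)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="4 probes"):
            cs.wilcoxon_shift_test(self._pm([0.5, 0.5, 0.5], [0.5, 0.5, 0.5], p=3))


class TestCollapse:
    def _cmus(self, ids):
        return [toy_cmu(range(4)) for _ in ids], ids

    def test_members_removed_noncontiguous_kept(self):
        a, b, c = (
            cs.CMU(i, "chr1", 0, 10, np.arange(4), 0.8) for i in ("A", "B", "C")
        )
        nc = cs.NonContiguousCMU("AB", [a, b], np.zeros((2, 2), np.int8))
        out = cs.collapse_cmu_lists([a, b, c], [nc])
        assert out == [nc, c]

    def test_no_noncontiguous_identity(self):
        a, b = (cs.CMU(i, "chr1", 0, 10, np.arange(4), 0.8) for i in ("A", "B"))
        assert cs.collapse_cmu_lists([a, b], []) == [a, b]

    def test_all_absorbed(self):
        a, b = (cs.CMU(i, "chr1", 0, 10, np.arange(4), 0.8) for i in ("A", "B"))
        nc = cs.NonContiguousCMU("AB", [a, b], np.zeros((2, 2), np.int8))
        assert cs.collapse_cmu_lists([a, b], [nc]) == [nc]


class TestEndToEnd:
    def test_attenuated_block_detected_with_correct_sign(self):
        spec = cs.simulate.casecontrol_spec(seed=42)
        m, ctrl, case, truth, _ = cs.simulate.generate_case_control(spec)
        res = cs.differential_cmus(
            cs.inverse_normal_transform(ctrl),
            cs.inverse_normal_transform(case),
            m,
            labels=("controls", "cases"),
        )
        blk = truth["blocks"].iloc[0]  # the attenuated block
        hits = [
            r
            for r in res
            if r.significant
            and r.defining_group == "controls"
            and getattr(r.cmu, "start", None) is not None
            and r.cmu.start < blk.end_bp
            and r.cmu.end > blk.start_bp
        ]
        assert hits, "attenuated block not flagged"
        assert all(r.effect_size < 0 for r in hits)  # defining (controls) stronger

    def test_null_split_yields_no_hits(self):
        # identical population in both groups
        spec = cs.simulate.casecontrol_spec(seed=7, attenuated_r=0.8)
        m, ctrl, case, _, _ = cs.simulate.generate_case_control(spec)
        res = cs.differential_cmus(
            cs.inverse_normal_transform(ctrl),
            cs.inverse_normal_transform(case),
            m,
        )
        assert sum(r.significant for r in res) == 0

    def test_raising_mu_never_increases_hits(self):
        spec = cs.simulate.casecontrol_spec(seed=9)
        m, ctrl, case, _, _ = cs.simulate.generate_case_control(spec)
        tc, ta = cs.inverse_normal_transform(ctrl), cs.inverse_normal_transform(case)
        hits = {
            mu: sum(r.significant for r in cs.differential_cmus(tc, ta, m, mu=mu))
            for mu in (0.1, 0.5)
        }
        assert hits[0.5] <= hits[0.1]

    def test_covariate_effect_removed_by_residualization(self):
        from dataclasses import replace

        spec = replace(cs.simulate.casecontrol_spec(seed=3), covariate_effect_sd=1.0)
        m, ctrl, case, truth, cov = cs.simulate.generate_case_control(spec)
        assert cov is not None
        t_raw = cs.inverse_normal_transform(ctrl)
        t_res = cs.residualize(t_raw, cov)
        base_spec = cs.simulate.casecontrol_spec(seed=3)
        m0, ctrl0, _, _, _ = cs.simulate.generate_case_control(base_spec)
        clean = cs.scan_dataset(cs.inverse_normal_transform(ctrl0), m0)
        resid = cs.scan_dataset(t_res, m)
        clean_probes = {frozenset(c.probe_indices) for c in clean.contiguous}
        resid_probes = {frozenset(c.probe_indices) for c in resid.contiguous}
        # residualized calls match the covariate-free run closely
        jacc = []
        for rp in resid_probes:
            jacc.append(max((len(rp & cp) / len(rp | cp) for cp in clean_probes), default=0))
        assert clean_probes and resid_probes
        assert np.mean(jacc) >= 0.9
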