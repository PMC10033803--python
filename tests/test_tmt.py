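import numpy as np
import pandas as pd
import pytest

from ffevomics import (
    PSMTable,
    call_deps,
    gen_psm_table,
    protein_ratios_from_psms,
    protein_significance,
    robust_cutoffs,
)


def make_psms(rows, pairing=None):
    pairing = pairing or [("case_1", "ctrl_1")]
    cols = ["psm_id", "peptide", "protein"] + [c for pair in pairing for c in pair]
    return PSMTable(pd.DataFrame(rows, columns=cols), pairing)


class TestMedianCascade:
    def test_odd_count_peptide_median(self):
        rows = [
            ["p1", "PEPA", "PROT1", 10.0, 10.0],
            ["p2", "PEPB", "PROT1", 20.0, 10.0],
            ["p3", "PEPC", "PROT1", 40.0, 10.0],
        ]
        q = protein_ratios_from_psms(make_psms(rows))
        assert q.loc["PROT1", "combined_ratio"] == pytest.approx(2.0)
        assert q.loc["PROT1", "n_peptides"] == 3
        assert q.loc["PROT1", "n_psms"] == 3

    def test_equal_channels_give_unity(self):
        psms, _ = gen_psm_table(n_proteins=8, frac_de=0.0, noise_sd=0.0, seed=1)
        q = protein_ratios_from_psms(psms)
        np.testing.assert_allclose(q["combined_ratio"], 1.0)

    def test_order_and_odd_duplication_invariance(self):
        psms, _ = gen_psm_table(n_proteins=6, frac_de=0.5, noise_sd=0.4, seed=2)
        q1 = protein_ratios_from_psms(psms)
        shuffled = PSMTable(
            psms.frame.sample(frac=1.0, random_state=0).reset_index(drop=True),
            psms.pairing,
        )
        q2 = protein_ratios_from_psms(shuffled)
        pd.testing.assert_frame_equal(
            q1.drop(columns=["n_psms"]), q2.drop(columns=["n_psms"])
        )
        # duplicating one peptide's PSM block an odd number of times keeps medians
        pep = psms.frame["peptide"].iloc[0]
        block = psms.frame[psms.frame["peptide"] == pep]
        tripled = pd.concat([psms.frame, block, block], ignore_index=True)
        tripled["psm_id"] = [f"q{i}" for i in range(len(tripled))]
        q3 = protein_ratios_from_psms(PSMTable(tripled, psms.pairing))
        np.testing.assert_allclose(q1["combined_ratio"], q3["combined_ratio"])

    def test_case_channel_scaling_is_exact(self):
        psms, _ = gen_psm_table(n_proteins=5, frac_de=0.5, noise_sd=0.3, seed=3)
        q1 = protein_ratios_from_psms(psms)
        scaled = psms.frame.copy()
        for case_ch, _ in psms.pairing:
            scaled[case_ch] = scaled[case_ch] * 3.0
        q2 = protein_ratios_from_psms(PSMTable(scaled, psms.pairing))
        np.testing.assert_allclose(q2["combined_ratio"], 3.0 * q1["combined_ratio"])

    def test_zero_intensity_psm_dropped_per_pair(self):
        rows = [
            ["p1", "PEPA", "PROT1", 20.0, 10.0],
            ["p2", "PEPA", "PROT1", 0.0, 10.0],  # dropped: zero case intensity
        ]
        q = protein_ratios_from_psms(make_psms(rows))
        assert q.loc["PROT1", "combined_ratio"] == pytest.approx(2.0)

    def test_protein_missing_in_pair_gets_nan_replicate(self):
        pairing = [("case_1", "ctrl_1"), ("case_2", "ctrl_2")]
        rows = [["p1", "PEPA", "PROT1", 20.0, 10.0, 0.0, 10.0]]
        q = protein_ratios_from_psms(make_psms(rows, pairing))
        assert q.loc["PROT1", "ratio_1"] == pytest.approx(2.0)
        assert np.isnan(q.loc["PROT1", "ratio_2"])
        assert q.loc["PROT1", "combined_ratio"] == pytest.approx(2.0)

    def test_razor_assignment_most_peptides_then_lexicographic(self):
        pairing = [("case_1", "ctrl_1")]
        rows = [
            ["p1", "PEPA", "PROT2", 10.0, 10.0],
            ["p2", "PEPB", "PROT2", 10.0, 10.0],
            ["p3", "PEPC", "PROT3", 10.0, 10.0],
            ["p4", "PEPD", "PROT2;PROT3", 40.0, 10.0],  # -> PROT2 (more peptides)
            ["p5", "PEPE", "PROT5;PROT4", 40.0, 10.0],  # tie -> PROT4 (lexicographic)
        ]
        q = protein_ratios_from_psms(make_psms(rows, pairing))
        assert "PROT4" in q.index and "PROT5" not in q.index
        assert q.loc["PROT2", "n_psms"] == 3

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PSMTable(pd.DataFrame(columns=["psm_id", "peptide", "protein", "a", "b"]),
                     [("a", "b")])

    def test_absent_channel_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            PSMTable(
                pd.DataFrame([["p1", "PEPA", "PROT1", 1.0]],
                             columns=["psm_id", "peptide", "protein", "ctrl_1"]),
                [("case_1", "ctrl_1")],
            )


class TestSignificance:
    @staticmethod
    def quants_from_log2(rows):
        arr = 2.0 ** np.asarray(rows, dtype=float)
        q = pd.DataFrame(
            arr, columns=[f"ratio_{k + 1}" for k in range(arr.shape[1])],
            index=[f"PROT{i}" for i in range(arr.shape[0])],
        )
        q["combined_ratio"] = np.median(arr, axis=1)
        q["n_peptides"] = 1
        q["n_psms"] = 1
        return q

    def test_closed_form_t(self):
        # log2 ratios (0.9, 1.0, 1.1): t = 1.0 / (0.1/sqrt(3)) = 17.32, df 2
        sig = protein_significance(self.quants_from_log2([[0.9, 1.0, 1.1]]))
        assert sig["p_value"].iloc[0] == pytest.approx(0.003317, abs=2e-5)

    def test_symmetric_ratios_give_p_one(self):
        sig = protein_significance(self.quants_from_log2([[-0.2, 0.0, 0.2]]))
        assert sig["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_flagged_missing(self):
        sig = protein_significance(self.quants_from_log2([[1.0, 1.0, 1.0]]))
        assert np.isnan(sig["p_value"].iloc[0])
        assert bool(sig["degenerate"].iloc[0])

    def test_single_replicate_excluded(self):
        q = self.quants_from_log2([[0.5]])
        sig = protein_significance(q)
        assert np.isnan(sig["p_value"].iloc[0])
        assert not bool(sig["degenerate"].iloc[0])


class TestRobustCutoffs:
    def test_direct_formula(self):
        thr = robust_cutoffs([-2, -1, 0, 1, 2])
        assert thr.center == pytest.approx(0.0)
        assert thr.s_iqr == pytest.approx(2 / 1.34898, rel=1e-9)
        assert thr.upper_cut == pytest.approx(2.9652, abs=2e-4)
        assert thr.lower_cut == pytest.approx(-2.9652, abs=2e-4)

    def test_constant_input_zero_width(self):
        thr = robust_cutoffs([0.3] * 10)
        assert thr.s_iqr == 0.0
        assert thr.upper_cut == thr.lower_cut == pytest.approx(0.3)

    def test_consistent_sigma_estimate_on_normal_draws(self):
        x = np.random.default_rng(123).normal(size=10_000)
        thr = robust_cutoffs(x)
        assert 1.90 <= thr.upper_cut <= 2.10

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            robust_cutoffs([0.1, 0.2, 0.3])


class TestCallDeps:
    def test_boundary_fold_change_is_ns(self):
        # 4 background proteins at exact log2 ratios (-2, -1, 1, 2) plus a
        # probe that is the largest of the five, so the quartiles of the call
        # set are -1 and 2 and its upper cut is u = 1 + 2 * (3 / 1.34898).
        # The probe's combined ratio r is chosen so log2(r) equals u to the
        # last bit: at exactly the cut, the strict ">" rule must say ns.
        u = 1.0 + 2.0 * (3.0 / 1.34898)
        r = 2.0 ** u
        while np.log2(r) > u:
            r = np.nextafter(r, 0.0)
        while np.log2(r) < u:
            r = np.nextafter(r, np.inf)
        assert np.log2(r) == u

        def replicates(ratio):
            return [ratio / 1.001, ratio, ratio * 1.001]

        rows = [replicates(2.0 ** v) for v in (-2, -1, 1, 2)] + [replicates(r)]
        q = pd.DataFrame(rows, columns=["ratio_1", "ratio_2", "ratio_3"],
                         index=["A", "B", "C", "D", "PROBE"])
        q["combined_ratio"] = q["ratio_2"]  # median of the three replicates
        q["n_peptides"] = 1
        q["n_psms"] = 1
        deps, thr = call_deps(q)
        assert thr.upper_cut == u
        assert deps.loc["PROBE", "p_value"] < 0.05
        assert deps.loc["PROBE", "direction"] == "ns"  # strict inequality

    def test_spiked_proteins_called_with_correct_direction(self):
        true = {f"PROT{i:04d}": 0.0 for i in range(1, 101)}
        spikes = {"PROT0001": 2.0, "PROT0002": 2.0, "PROT0003": -2.0,
                  "PROT0004": -2.0, "PROT0005": 2.0}
        true.update(spikes)
        psms, truth = gen_psm_table(
            n_proteins=100, n_peptides=3, psms_per_peptide=2, noise_sd=0.1,
            n_replicate_pairs=3, seed=9,
            gene_ids=list(true), true_ratios=true,
        )
        q = protein_ratios_from_psms(psms)
        deps, thr = call_deps(q)
        for prot, lfc in spikes.items():
            assert deps.loc[prot, "direction"] == ("up" if lfc > 0 else "down")
        nulls = [p for p in true if p not in spikes]
        assert (deps.loc[nulls, "direction"] == "ns").mean() > 0.9

    def test_identical_ratios_make_no_calls(self):
        psms, _ = gen_psm_table(n_proteins=10, frac_de=0.0, noise_sd=0.0, seed=4)
        q = protein_ratios_from_psms(psms)
        deps, _ = call_deps(q)
        assert (deps["direction"] == "ns").all()

    def test_sorted_by_foldchange_descending(self):
        psms, _ = gen_psm_table(n_proteins=20, frac_de=0.5, noise_sd=0.3, seed=5)
        deps, _ = call_deps(protein_ratios_from_psms(psms))
        assert (np.diff(deps["foldchange"]) <= 0).all()

    def test_agrees_with_independent_rederivation(self):
        """Brute-force re-derivation with its own quantile code matches."""
        psms, _ = gen_psm_table(n_proteins=60, frac_de=0.3, noise_sd=0.25, seed=6)
        q = protein_ratios_from_psms(psms)
        deps, thr = call_deps(q)

        logs = np.log2(np.sort(q["combined_ratio"].to_numpy()))
        n = logs.size

        def quantile(arr, frac):  # position 1 + (n-1) q, linear interpolation
            pos = (len(arr) - 1) * frac
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return arr[lo] + (pos - lo) * (arr[hi] - arr[lo])

        center = quantile(logs, 0.5)
        s_iqr = (quantile(logs, 0.75) - quantile(logs, 0.25)) / 1.34898
        assert thr.center == pytest.approx(center, rel=1e-12)
        assert thr.s_iqr == pytest.approx(s_iqr, rel=1e-12)
        sig = protein_significance(q)
        for prot in q.index:
            lfc = np.log2(q.loc[prot, "combined_ratio"])
            p = sig.loc[prot, "p_value"]
            expect = "ns"
            if np.isfinite(p) and p < 0.05:
                if lfc > center + 2 * s_iqr:
                    expect = "up"
                elif lfc < center - 2 * s_iqr:
                    expect = "down"
            assert deps.loc[prot, "direction"] == expect

    def test_estimator_recovery_over_replicate_simulations(self):
        """Mean log2 ratio error across 200 seeded runs stays within 0.05."""
        errs = []
        for seed in range(200):
            psms, truth = gen_psm_table(
                n_proteins=2, n_peptides=5, psms_per_peptide=3, frac_de=1.0,
                effect_log2_ratio=1.0, noise_sd=0.3, n_replicate_pairs=3, seed=seed,
            )
            q = protein_ratios_from_psms(psms)
            errs.extend(
                np.log2(q["combined_ratio"])
                - truth["true_log2_ratio"].reindex(q.index)
            )
        assert abs(np.mean(errs)) <= 0.05
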