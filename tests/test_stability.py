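"""Unit and property tests for the four per-gene stability algorithms."""

import numpy as np
import pandas as pd
import pytest

from refstab import (
    CtMatrix,
    QpcrValidationError,
    SampleSheet,
    bestkeeper,
    delta_ct_msd,
    genorm,
    genorm_v_curve,
    normfinder,
    relative_quantities,
)

from conftest import random_ct

SD_0111 = np.std([0.0, -1.0, 1.0, -1.0], ddof=1)  # 0.9574, the toy's wobble SD


class TestDeltaCt:
    def test_toy_hand_computed(self, toy_ct):
        r = delta_ct_msd(toy_ct)
        assert r.scores["A"] == pytest.approx(SD_0111 / 2, abs=1e-4)  # 0.4787
        assert r.scores["B"] == pytest.approx(SD_0111 / 2, abs=1e-4)
        assert r.scores["C"] == pytest.approx(SD_0111, abs=1e-4)  # 0.9574
        assert r.ranking[-1] == "C"
        assert r.orientation == "lower_is_stabler"

    def test_offset_constant_pair_has_zero_pairwise_sd(self):
        ct = CtMatrix(
            pd.DataFrame({"a": [20.0, 25.0], "b": [21.0, 26.0]}, index=["A", "B"])
        )
        r = delta_ct_msd(ct)
        assert r.scores["A"] == 0.0 and r.scores["B"] == 0.0

    def test_duplicating_samples_keeps_pairwise_structure(self, toy_ct):
        doubled = CtMatrix(
            pd.concat(
                [toy_ct.ct, toy_ct.ct.add_suffix("_dup")], axis=1
            )
        )
        r0 = delta_ct_msd(toy_ct)
        r1 = delta_ct_msd(doubled)
        # identical duplicates rescale every pair SD by the same ddof factor
        # sqrt(2(n-1)/(2n-1)), so ordering and score ratios are preserved
        assert r1.ranking == r0.ranking
        ratio = r1.scores / r0.scores
        np.testing.assert_allclose(ratio.to_numpy(), np.sqrt(6 / 7), atol=1e-9)

    def test_requires_two_genes_and_samples(self):
        with pytest.raises(QpcrValidationError):
            delta_ct_msd(CtMatrix(pd.DataFrame({"a": [20.0], "b": [21.0]}, index=["A"])))


class TestBestKeeper:
    def test_toy_descriptives(self):
        ct = CtMatrix(
            pd.DataFrame(
                {"a": [20.0, 20.0], "b": [22.0, 22.0], "c": [24.0, 24.0], "d": [26.0, 26.0]},
                index=["A", "B"],
            )
        )
        res = bestkeeper(ct)
        assert res.stats.loc["A", "AM"] == 23.0
        assert res.stats.loc["A", "SD"] == pytest.approx(2.0)  # (3+1+1+3)/4
        assert res.stats.loc["A", "CV"] == pytest.approx(100 * 2 / 23, abs=1e-3)
        # identical genes: index equals their common Ct, r = 1
        np.testing.assert_allclose(res.index.to_numpy(), ct.values[0], atol=1e-9)
        assert res.stats["r"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_classic_sd_mode(self):
        ct = CtMatrix(
            pd.DataFrame(
                {"a": [20.0, 21.0], "b": [22.0, 20.0], "c": [24.0, 22.0], "d": [26.0, 19.0]},
                index=["A", "B"],
            )
        )
        res = bestkeeper(ct, sd_mode="classic")
        assert res.stats.loc["A", "SD"] == pytest.approx(np.std([20, 22, 24, 26], ddof=1))

    def test_constant_gene_r_undefined_ranks_last(self):
        ct = CtMatrix(
            pd.DataFrame(
                {"a": [25.0, 20.0, 19.0], "b": [25.0, 21.0, 20.5], "c": [25.0, 22.0, 21.0], "d": [25.0, 23.0, 23.0]},
                index=["FLAT", "X", "Y"],
            )
        )
        with pytest.warns(UserWarning, match="FLAT"):
            res = bestkeeper(ct)
        assert np.isnan(res.stats.loc["FLAT", "r"])
        assert res.ranking.ranking[-1] == "FLAT"
        assert res.stats.loc["FLAT", "SD"] == 0.0 and res.stats.loc["FLAT", "CV"] == 0.0

    def test_ranking_by_cv(self, rng):
        res = bestkeeper(random_ct(rng, 5, 8))
        by_cv = res.ranking_by("cv")
        assert by_cv.orientation == "lower_is_stabler"
        assert by_cv.ranking == list(res.stats["CV"].sort_values(kind="stable").index)


class TestGenorm:
    def test_toy_exclusion(self, toy_ct):
        q = relative_quantities(toy_ct)  # E = 2
        res = genorm(q)
        # C is removed first with M ~ 0.9574; A and B end tied with V_AB = 0
        assert res.trace["removed_gene"].tolist() == ["C"]
        assert res.trace["m_at_removal"].iloc[0] == pytest.approx(SD_0111, abs=1e-4)
        assert set(res.ranking.ranking[:2]) == {"A", "B"}
        assert res.ranking.scores["A"] == pytest.approx(0.0, abs=1e-12)
        assert ("A", "B") in res.ranking.ties

    def test_scalar_multiples_all_tie_at_zero(self):
        # genes proportional on the quantity scale: constant log ratios
        base = np.array([20.0, 21.0, 23.0, 19.5])
        ct = CtMatrix(
            pd.DataFrame(
                [base, base + 2.0, base + 5.0], index=["A", "B", "C"],
                columns=["a", "b", "c", "d"],
            )
        )
        res = genorm(relative_quantities(ct))
        np.testing.assert_allclose(res.ranking.scores.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.initial_m.to_numpy(), 0.0, atol=1e-12)

    def test_full_panel_m_equals_delta_ct_msd_at_e2(self, rng):
        ct = random_ct(rng, 7, 10)
        msd = delta_ct_msd(ct).scores
        m0 = genorm(relative_quantities(ct)).initial_m
        np.testing.assert_allclose(m0.to_numpy(), msd.to_numpy(), atol=1e-9)

    def test_ranking_is_reverse_removal_order(self, rng):
        res = genorm(relative_quantities(random_ct(rng, 8, 6)))
        removed = res.trace["removed_gene"].tolist()
        assert res.ranking.ranking[2:] == list(reversed(removed))

    def test_m_cutoff_flag(self):
        base = np.array([20.0, 21.0, 23.0, 19.5, 22.0])
        noisy = base + np.array([3.0, -2.5, 2.0, -3.0, 2.5])
        ct = CtMatrix(
            pd.DataFrame(
                [base, base + 1, noisy], index=["A", "B", "NOISY"],
                columns=list("abcde"),
            )
        )
        res = genorm(relative_quantities(ct))
        assert res.unstable == ["NOISY"]

    def test_needs_three_genes(self, toy_ct):
        with pytest.raises(QpcrValidationError):
            genorm(relative_quantities(toy_ct.subset_genes(["A", "B"])))


class TestVCurve:
    def test_redundant_gene_gives_zero_v(self):
        # gene C's quantity equals the geometric mean of A and B in every
        # sample -> NF_2 == NF_3 up to a constant -> V_{2/3} = 0
        a = np.array([20.0, 21.0, 22.5, 19.0])
        b = np.array([25.0, 26.5, 27.0, 24.0])
        c = (a + b) / 2
        d = a + np.array([0.5, -0.6, 0.7, -0.4])
        ct = CtMatrix(
            pd.DataFrame([a, b, c, d], index=["A", "B", "C", "D"], columns=list("wxyz"))
        )
        q = relative_quantities(ct)
        ranking = genorm(q).ranking
        # force the ordering A, B, C, D for the check
        order = ["A", "B", "C", "D"]
        ranking = type(ranking)(
            algorithm="genorm",
            scores=ranking.scores,
            orientation="lower_is_stabler",
            ranking=order,
            score_label="M",
        )
        curve = genorm_v_curve(q, ranking, threshold=0.15)
        assert curve.v[2] == pytest.approx(0.0, abs=1e-12)
        assert curve.recommended_n == 2

    def test_recommended_n_is_first_below_threshold(self, rng):
        from refstab import SyntheticSpec, generate_dataset

        ds = generate_dataset(SyntheticSpec(seed=5, sigma_stable=0.05))
        q = relative_quantities(ds.ct, ds.efficiencies).subset_genes(
            ds.reference_genes
        )
        res = genorm(q)
        curve = genorm_v_curve(q, res.ranking)
        assert curve.v[2] < 0.15
        assert curve.recommended_n == 2
        assert not curve.none_below_threshold


class TestNormFinder:
    def test_identical_profiles_score_zero(self):
        base = np.array([20.0, 21.0, 23.0, 19.5, 22.0, 20.5])
        ct = CtMatrix(
            pd.DataFrame(
                [base, base + 1, base + 2], index=["A", "B", "C"],
                columns=list("abcdef"),
            )
        )
        r = normfinder(relative_quantities(ct))
        np.testing.assert_allclose(r.scores.to_numpy(), 0.0, atol=1e-12)

    def test_pure_between_group_shift_gives_sv_half(self):
        """±0.5 log2 shift, zero intra-group noise -> grouped SV exactly 0.5."""
        genes = ["A", "B", "C", "SHIFT"]
        samples = [f"g1_{i}" for i in range(3)] + [f"g2_{i}" for i in range(3)]
        vals = np.full((4, 6), 25.0)
        vals[3, :3] -= 0.5  # +0.5 log2 expression in group 1 (E=2: 0.5 cycles)
        vals[3, 3:] += 0.5
        ct = CtMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "group": ["g1"] * 3 + ["g2"] * 3,
                    "is_control": [True] * 3 + [False] * 3,
                }
            )
        )
        r = normfinder(relative_quantities(ct), sheet)
        assert r.scores["SHIFT"] == pytest.approx(0.5, abs=1e-12)
        assert r.ranking[-1] == "SHIFT"

    def test_noisy_gene_ranks_last(self, rng):
        """Noise added to one gene of an identical panel raises its SV above all."""
        n_last = 0
        for trial in range(100):
            trial_rng = np.random.default_rng(1000 + trial)
            base = trial_rng.uniform(19, 27, size=8)
            vals = np.tile(base, (5, 1))
            vals[2] = vals[2] + trial_rng.normal(0, 0.8, size=8)
            ct = CtMatrix(pd.DataFrame(vals, index=list("ABCDE"), columns=[f"s{i}" for i in range(8)]))
            r = normfinder(relative_quantities(ct))
            n_last += r.ranking[-1] == "C"
        assert n_last >= 99

    def test_small_group_rejected(self):
        samples = ["a1", "a2", "b1", "b2", "b3"]
        ct = CtMatrix(
            pd.DataFrame(
                np.full((3, 5), 25.0) + np.arange(15).reshape(3, 5) * 0.01,
                index=["A", "B", "C"],
                columns=samples,
            )
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "group": ["a", "a", "b", "b", "b"],
                    "is_control": [True, True, False, False, False],
                }
            )
        )
        with pytest.raises(QpcrValidationError, match="more than two samples"):
            normfinder(relative_quantities(ct), sheet)


class TestSharedInvariances:
    """Invariances that hold across algorithms (documented exceptions aside)."""

    def test_gene_and_sample_permutation(self, rng):
        ct = random_ct(rng, 6, 9)
        q = relative_quantities(ct)
        perm_g = rng.permutation(ct.gene_ids).tolist()
        perm_s = rng.permutation(ct.sample_ids).tolist()
        ct_p = CtMatrix(ct.ct.loc[perm_g, perm_s])
        q_p = relative_quantities(ct_p)
        for fn, data, data_p in [
            (delta_ct_msd, ct, ct_p),
            (lambda x: bestkeeper(x).ranking, ct, ct_p),
            (normfinder, q, q_p),
            (lambda x: genorm(x).ranking, q, q_p),
        ]:
            s0 = fn(data).scores.sort_index()
            s1 = fn(data_p).scores.sort_index()
            np.testing.assert_allclose(s0.to_numpy(), s1.to_numpy(), atol=1e-9)

    def test_per_sample_offset_invariance(self, rng):
        """A loading offset per sample cancels for ΔCt, geNorm, NormFinder —
        but not for BestKeeper's raw-Ct descriptives (documented exception)."""
        ct = random_ct(rng, 5, 8)
        offsets = rng.normal(0, 1.0, size=8)
        ct_off = CtMatrix(ct.ct + offsets[None, :])
        q, q_off = relative_quantities(ct), relative_quantities(ct_off)
        np.testing.assert_allclose(
            delta_ct_msd(ct).scores.to_numpy(),
            delta_ct_msd(ct_off).scores.to_numpy(),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            genorm(q).ranking.scores.to_numpy(),
            genorm(q_off).ranking.scores.to_numpy(),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            normfinder(q).scores.to_numpy(),
            normfinder(q_off).scores.to_numpy(),
            atol=1e-9,
        )
        bk0 = bestkeeper(ct).stats["SD"]
        bk1 = bestkeeper(ct_off).stats["SD"]
        assert not np.allclose(bk0.to_numpy(), bk1.to_numpy(), atol=1e-6)

    def test_per_gene_offset_invariance(self, rng):
        """A constant per gene cancels in ΔCt/geNorm/NormFinder; BestKeeper's
        CV shifts because the mean Ct moves (documented exception)."""
        ct = random_ct(rng, 5, 8)
        shifted = ct.ct.copy()
        shifted.iloc[1] += 3.0
        ct_s = CtMatrix(shifted)
        np.testing.assert_allclose(
            delta_ct_msd(ct).scores.to_numpy(),
            delta_ct_msd(ct_s).scores.to_numpy(),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            normfinder(relative_quantities(ct)).scores.to_numpy(),
            normfinder(relative_quantities(ct_s)).scores.to_numpy(),
            atol=1e-9,
        )
        cv0 = bestkeeper(ct).stats["CV"].iloc[1]
        cv1 = bestkeeper(ct_s).stats["CV"].iloc[1]
        assert cv0 != pytest.approx(cv1, abs=1e-6)
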