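"""Normalization: geometric means, the factor formula, and the two-step run.

The independent oracle is a pure-Python transcription of the factor formula
(mean of per-sample control geomeans divided by this sample's geomean),
applied step by step with loops and math.* only.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ifnsig import (
    GenePanel,
    NormalizationError,
    PipelineConfig,
    control_geomeans,
    factors_frame,
    geometric_mean,
    normalization_factor,
    normalize,
)

from conftest import build_matrix

POS = GenePanel("pos", tuple(f"POS_{c}" for c in "ABCDEF"), "positive_control")
HK = GenePanel("hk", ("NRDC", "OTUD5", "TUBB"), "housekeeping")


def brute_force_two_step(counts, pos_genes, hk_genes, pseudocount=1.0):
    """Loop-and-math.* transcription of the two-step normalization."""
    samples = list(counts)

    def gm(sample_counts, genes):
        return math.exp(
            sum(math.log(max(sample_counts[g], pseudocount)) for g in genes) / len(genes)
        )

    pos_gm = {s: gm(counts[s], pos_genes) for s in samples}
    pos_mean = sum(pos_gm.values()) / len(samples)
    pos_f = {s: pos_mean / pos_gm[s] for s in samples}
    step1 = {s: {g: c * pos_f[s] for g, c in counts[s].items()} for s in samples}
    hk_gm = {s: gm(step1[s], hk_genes) for s in samples}
    hk_mean = sum(hk_gm.values()) / len(samples)
    hk_f = {s: hk_mean / hk_gm[s] for s in samples}
    final = {s: {g: counts[s][g] * pos_f[s] * hk_f[s] for g in counts[s]} for s in samples}
    return pos_f, hk_f, final


class TestGeometricMean:
    def test_constant_identity(self):
        assert geometric_mean([7.0] * 6) == pytest.approx(7.0)

    def test_two_point(self):
        assert geometric_mean([4, 9]) == pytest.approx(6.0)

    def test_twofold_ladder(self):
        # 1..32 in 2-fold steps: geomean is 2^2.5
        assert geometric_mean([1, 2, 4, 8, 16, 32]) == pytest.approx(2 ** 2.5)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(NormalizationError):
            geometric_mean([])
        with pytest.raises(NormalizationError, match="pseudocount"):
            geometric_mean([1.0, 0.0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=20), st.permutations(range(5)))
    def test_permutation_invariant(self, values, _perm):
        shuffled = [values[i] for i in np.random.default_rng(0).permutation(len(values))]
        assert geometric_mean(shuffled) == pytest.approx(geometric_mean(values))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=20),
           st.floats(0.01, 100))
    def test_scale_equivariant(self, values, c):
        assert geometric_mean([c * v for v in values]) == pytest.approx(
            c * geometric_mean(values), rel=1e-9
        )


class TestControlGeomeans:
    def _matrix(self, hk_counts):
        classes = {g: "housekeeping" for g in HK.genes}
        counts = {"s1": dict(zip(HK.genes, hk_counts))}
        return build_matrix(counts, classes)

    def test_constant_controls(self):
        m = self._matrix([100, 100, 100])
        assert control_geomeans(m.counts, HK)["s1"] == pytest.approx(100.0)

    def test_hand_value(self):
        m = self._matrix([50, 200, 800])
        assert control_geomeans(m.counts, HK)["s1"] == pytest.approx(200.0)

    def test_zero_floored_by_pseudocount(self):
        m = self._matrix([0, 200, 800])
        expected = (1 * 200 * 800) ** (1 / 3)
        assert control_geomeans(m.counts, HK, pseudocount=1)["s1"] == pytest.approx(expected)

    def test_missing_gene_named(self):
        m = self._matrix([1, 1, 1])
        bad = GenePanel("hk", ("NRDC", "ABSENT"), "housekeeping")
        with pytest.raises(NormalizationError, match="ABSENT"):
            control_geomeans(m.counts, bad)


class TestNormalizationFactor:
    def test_equal_geomeans_give_unit_factors(self):
        f = normalization_factor(pd.Series([3.5, 3.5, 3.5]))
        assert (f == 1.0).all()

    def test_single_sample_scope(self):
        assert normalization_factor(pd.Series([42.0])).iloc[0] == pytest.approx(1.0)

    def test_hand_values(self):
        f = normalization_factor(pd.Series([100.0, 200.0, 400.0], index=list("abc")))
        assert f["a"] == pytest.approx(7 / 3, abs=1e-12)
        assert f["b"] == pytest.approx(7 / 6, abs=1e-12)
        assert f["c"] == pytest.approx(7 / 12, abs=1e-12)

    def test_empty_scope_rejected(self):
        with pytest.raises(NormalizationError, match="empty"):
            normalization_factor(pd.Series(dtype=float))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e5), min_size=1, max_size=30))
    def test_conservation_of_scope_mean(self, geomeans):
        g = pd.Series(geomeans)
        f = normalization_factor(g)
        assert (g * f).mean() == pytest.approx(g.mean(), rel=1e-9)


def _two_panel_config(**kw):
    return PipelineConfig(panels={"pos": POS, "hk": HK}, **kw)


class TestNormalize:
    def test_identical_geomeans_is_identity(self, toy_three_sample):
        m = toy_three_sample
        equal = m.counts.copy()
        equal.loc[:, :] = equal[["s1"]].to_numpy()  # all samples identical
        m2 = build_matrix(
            {s: equal[s].to_dict() for s in equal.columns},
            m.gene_info["code_class"].to_dict(),
            m.batch_of,
        )
        norm, factors = normalize(m2, _two_panel_config())
        assert all(f.pos_factor == pytest.approx(1.0) for f in factors)
        assert all(f.hk_factor == pytest.approx(1.0) for f in factors)
        pd.testing.assert_frame_equal(norm.values, m2.counts.astype(float))

    def test_toy_matches_hand_factors_exactly(self, toy_three_sample):
        norm, factors = normalize(toy_three_sample, _two_panel_config())
        by_id = {f.sample_id: f for f in factors}
        for s, expected in (("s1", 7 / 3), ("s2", 7 / 6), ("s3", 7 / 12)):
            assert by_id[s].pos_factor == pytest.approx(expected, abs=1e-12)
            assert by_id[s].hk_factor == pytest.approx(1.0, abs=1e-12)
        # counts scaled by exactly the positive-control factor
        assert norm.values.loc["G1", "s3"] == pytest.approx(4000 * 7 / 12, rel=1e-12)

    def test_equalization_invariants(self):
        rng = np.random.default_rng(5)
        classes = {g: "positive_control" for g in POS.genes}
        classes.update({g: "housekeeping" for g in HK.genes})
        classes["G1"] = "endogenous"
        counts = {
            f"s{i}": {g: int(rng.integers(10, 5000)) for g in classes}
            for i in range(8)
        }
        m = build_matrix(counts, classes, {f"s{i}": f"B{i % 2}" for i in range(8)})
        cfg = _two_panel_config()
        norm, factors = normalize(m, cfg)
        fdf = factors_frame(factors).set_index("sample_id")
        step1 = m.counts.astype(float).mul(fdf["pos_factor"], axis=1)
        for _, idx in fdf.groupby("batch").groups.items():
            pos_gm = control_geomeans(step1[list(idx)], POS)
            assert pos_gm.std() / pos_gm.mean() <= 1e-9
            hk_gm = control_geomeans(norm.values[list(idx)], HK)
            assert hk_gm.std() / hk_gm.mean() <= 1e-9
            # conservation: scope mean of raw pos geomeans unchanged by step 1
            raw_gm = control_geomeans(m.counts.astype(float)[list(idx)], POS)
            assert pos_gm.mean() == pytest.approx(raw_gm.mean(), rel=1e-12)

    def test_idempotence(self, toy_three_sample):
        cfg = _two_panel_config()
        norm, _ = normalize(toy_three_sample, cfg)
        renorm_input = build_matrix(
            {s: norm.values[s].round().astype(int).to_dict() for s in norm.samples},
            toy_three_sample.gene_info["code_class"].to_dict(),
            toy_three_sample.batch_of,
        )
        # rounding to ints perturbs slightly; compare at matching tolerance
        _, factors = normalize(renorm_input, cfg)
        for f in factors:
            assert f.pos_factor == pytest.approx(1.0, rel=1e-2)
            assert f.hk_factor == pytest.approx(1.0, rel=1e-2)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(0, 2))
    def test_matches_brute_force_oracle(self, seed, n_samples, n_extra):
        rng = np.random.default_rng(seed)
        classes = {g: "positive_control" for g in POS.genes}
        classes.update({g: "housekeeping" for g in HK.genes})
        classes.update({f"G{k}": "endogenous" for k in range(n_extra)})
        counts = {
            f"s{i}": {g: int(rng.integers(0, 3000)) for g in classes}
            for i in range(n_samples)
        }
        m = build_matrix(counts, classes, {s: "B1" for s in counts})
        norm, factors = normalize(m, _two_panel_config())
        pos_f, hk_f, final = brute_force_two_step(counts, POS.genes, HK.genes)
        for f in factors:
            assert f.pos_factor == pytest.approx(pos_f[f.sample_id], abs=1e-12, rel=1e-12)
            assert f.hk_factor == pytest.approx(hk_f[f.sample_id], abs=1e-12, rel=1e-12)
        for s in counts:
            for g in classes:
                assert norm.values.loc[g, s] == pytest.approx(final[s][g], rel=1e-12, abs=1e-9)

    def test_hk_on_raw_switch(self, toy_three_sample):
        cfg = _two_panel_config(hk_factor_on_raw=True)
        _, factors = normalize(toy_three_sample, cfg)
        by_id = {f.sample_id: f for f in factors}
        # raw hk geomeans are 150/300/600 -> mean 350
        assert by_id["s1"].hk_factor == pytest.approx(350 / 150, abs=1e-12)
        assert by_id["s3"].hk_factor == pytest.approx(350 / 600, abs=1e-12)

    def test_per_batch_scope_is_default(self, toy_three_sample):
        m = toy_three_sample
        m.batch_of.update({"s1": "B1", "s2": "B1", "s3": "B2"})
        _, factors = normalize(m, _two_panel_config())
        by_id = {f.sample_id: f for f in factors}
        assert by_id["s3"].pos_factor == pytest.approx(1.0)  # alone in its batch
        assert by_id["s1"].n_samples_in_scope == 2
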