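import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from imgtx.expression import (
    ProbeMatrix,
    assign_samples,
    build_dataset,
    differential_stability,
    intensity_filter,
    select_probes,
    srs_normalize,
)


def make_pm(expr, probe2gene, pacall=None, samples=None):
    if pacall is None:
        pacall = pd.DataFrame(True, index=expr.index, columns=expr.columns)
    if samples is None:
        n = expr.shape[1]
        samples = pd.DataFrame(
            {
                "donor": ["D1"] * n,
                "region": ["R1"] * n,
                "x": np.arange(n, dtype=float),
                "y": 0.0,
                "z": 0.0,
            },
            index=expr.columns,
        )
    return ProbeMatrix(expr, probe2gene, pacall, samples)


class TestIntensityFilter:
    def _pm(self, fracs, n_samples=200):
        probes = [f"p{i}" for i in range(len(fracs))]
        cols = [f"s{i}" for i in range(n_samples)]
        pac = pd.DataFrame(
            [
                [j < int(round(f * n_samples)) for j in range(n_samples)]
                for f in fracs
            ],
            index=probes, columns=cols,
        )
        expr = pd.DataFrame(0.0, index=probes, columns=cols)
        genes = pd.Series([f"g{i}" for i in range(len(fracs))], index=probes)
        return make_pm(expr, genes, pac)

    def test_boundary_49_percent_dropped(self):
        pm = self._pm([0.49])
        assert len(intensity_filter(pm)) == 0

    def test_boundary_50_percent_retained(self):
        pm = self._pm([0.50])
        assert list(intensity_filter(pm)) == ["p0"]

    def test_random_flags_match_count_oracle(self, rng):
        n, n_samples = 50, 200
        flags = rng.random((n, n_samples)) < 0.7
        probes = [f"p{i}" for i in range(n)]
        cols = [f"s{i}" for i in range(n_samples)]
        pm = make_pm(
            pd.DataFrame(0.0, index=probes, columns=cols),
            pd.Series([f"g{i}" for i in range(n)], index=probes),
            pd.DataFrame(flags, index=probes, columns=cols),
        )
        kept = set(intensity_filter(pm))
        for i, p in enumerate(probes):
            expected = sum(flags[i]) >= 100
            assert (p in kept) == expected


def orthonormal_pair(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / np.linalg.norm(a - a.mean())
    b = b - b.mean()
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


class TestSelectProbes:
    def _single_probe_pm(self, r, n=60, seed=0):
        ref, noise = orthonormal_pair(n, seed)
        probe = r * ref + np.sqrt(1 - r**2) * noise
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame([probe], index=["p1"], columns=cols)
        rnaseq = pd.DataFrame([ref], index=["g1"], columns=cols)
        pm = make_pm(expr, pd.Series(["g1"], index=["p1"]))
        return pm, rnaseq

    def test_boundary_r_above_threshold_selected(self):
        pm, rnaseq = self._single_probe_pm(0.21)
        out = select_probes(pm, rnaseq)
        assert list(out.index) == ["g1"]

    def test_boundary_r_below_threshold_dropped(self):
        pm, rnaseq = self._single_probe_pm(0.19)
        with pytest.warns(RuntimeWarning, match="dropped"):
            out = select_probes(pm, rnaseq)
        assert out.empty

    def test_planted_anticorrelated_probe_never_selected(self, small_bundle):
        pm = ProbeMatrix(
            small_bundle.probes, small_bundle.probe2gene,
            small_bundle.pacall, small_bundle.samples,
        )
        out = select_probes(pm, small_bundle.rnaseq)
        # the last probe of each gene is planted anti-correlated
        shared = pm.expr.columns.intersection(small_bundle.rnaseq.columns)
        for gene in out.index:
            bad = pm.expr.loc[f"{gene}_p3", shared]
            ref = small_bundle.rnaseq.loc[gene, shared]
            assert np.corrcoef(bad, ref)[0, 1] < 0
            chosen = out.loc[gene]
            assert not np.allclose(chosen[shared].to_numpy(), bad.to_numpy())

    def test_matches_enumeration_oracle(self, rng):
        n = 40
        cols = [f"s{i}" for i in range(n)]
        genes = ["gA", "gA", "gA", "gB", "gB", "gB"]
        probes = [f"p{i}" for i in range(6)]
        expr = pd.DataFrame(rng.normal(size=(6, n)), index=probes, columns=cols)
        rnaseq = pd.DataFrame(rng.normal(size=(2, n)), index=["gA", "gB"],
                              columns=cols)
        pm = make_pm(expr, pd.Series(genes, index=probes))
        out = select_probes(pm, rnaseq, r_thresh=-2.0)
        for gene in ("gA", "gB"):
            rs = {
                p: np.corrcoef(expr.loc[p], rnaseq.loc[gene])[0, 1]
                for p, g in zip(probes, genes) if g == gene
            }
            best = max(rs, key=rs.get)
            assert np.allclose(out.loc[gene].to_numpy(),
                               expr.loc[best].to_numpy())

    def test_gene_missing_from_rnaseq_dropped(self):
        pm, rnaseq = self._single_probe_pm(0.9)
        rnaseq.index = ["other_gene"]
        with pytest.warns(RuntimeWarning):
            out = select_probes(pm, rnaseq)
        assert out.empty


class TestAssignSamples:
    def _frames(self, s_xyz, c_xyz):
        s = pd.DataFrame(s_xyz, columns=["x", "y", "z"],
                         index=[f"s{i}" for i in range(len(s_xyz))])
        c = pd.DataFrame(c_xyz, columns=["x", "y", "z"],
                         index=[f"r{i}" for i in range(len(c_xyz))])
        return s, c

    def test_exact_centroid_assigned(self):
        s, c = self._frames([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        out = assign_samples(s, c)
        assert out.loc["s0"] == "r0"

    def test_beyond_2mm_excluded(self):
        s, c = self._frames([[2.01, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
        assert assign_samples(s, c).empty

    def test_matches_bruteforce_scan(self, rng):
        s_xyz = rng.uniform(0, 10, size=(100, 3))
        c_xyz = rng.uniform(0, 10, size=(10, 3))
        s, c = self._frames(s_xyz, c_xyz)
        out = assign_samples(s, c, max_dist=2.0)
        for i in range(100):
            d = np.linalg.norm(c_xyz - s_xyz[i], axis=1)
            j = int(d.argmin())
            if d[j] <= 2.0:
                assert out.loc[f"s{i}"] == f"r{j}"
            else:
                assert f"s{i}" not in out.index


class TestSrsNormalize:
    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        df = pd.DataFrame([x], index=["g"], columns=list("abcde"))
        out = srs_normalize(df).to_numpy().ravel()
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        s = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        expected = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(out, expected)
        assert out.max() == 1.0 and out.min() == 0.0

    def test_median_maps_to_half_before_rescale(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        med, iqr = 3.0, 2.0
        s_med = 1 / (1 + np.exp(-(x[2] - med) / (iqr / 1.35)))
        assert s_med == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(-1e4, 1e4, allow_nan=False), min_size=4, max_size=30,
            unique=True,
        )
    )
    def test_monotone(self, values):
        x = np.sort(np.asarray(values))
        df = pd.DataFrame([x], index=["g"],
                          columns=[f"s{i}" for i in range(len(x))])
        out = srs_normalize(df).to_numpy().ravel()
        assert np.all(np.diff(out) >= 0)

    def test_iqr_zero_falls_back_to_ranks(self):
        x = np.array([5.0, 5.0, 5.0, 5.0, 9.0])
        df = pd.DataFrame([x], index=["g"], columns=list("abcde"))
        with pytest.warns(RuntimeWarning, match="IQR"):
            out = srs_normalize(df).to_numpy().ravel()
        assert np.isfinite(out).all()
        assert out[-1] == out.max()

    def test_too_few_values_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            srs_normalize(df)


class TestDifferentialStability:
    def test_identical_profiles_give_one(self):
        prof = pd.DataFrame(
            np.arange(15.0).reshape(3, 5),
            index=["g1", "g2", "g3"],
            columns=[f"R{i}" for i in range(5)],
        )
        ds = differential_stability({"D1": prof, "D2": prof.copy(),
                                     "D3": prof.copy()})
        assert np.allclose(ds.to_numpy(), 1.0)

    def test_rank_reversed_profiles_give_minus_one(self):
        cols = [f"R{i}" for i in range(5)]
        a = pd.DataFrame([np.arange(5.0)], index=["g"], columns=cols)
        b = pd.DataFrame([np.arange(5.0)[::-1]], index=["g"], columns=cols)
        ds = differential_stability({"D1": a, "D2": b})
        assert ds.loc["g"] == pytest.approx(-1.0)

    def test_matches_pairwise_spearman_oracle(self, rng):
        cols = [f"R{i}" for i in range(5)]
        genes = [f"g{i}" for i in range(4)]
        profs = {
            d: pd.DataFrame(rng.normal(size=(4, 5)), index=genes, columns=cols)
            for d in ("D1", "D2", "D3")
        }
        ds = differential_stability(profs)
        for g in genes:
            vals = []
            for a, b in (("D1", "D2"), ("D1", "D3"), ("D2", "D3")):
                vals.append(
                    stats.spearmanr(profs[a].loc[g], profs[b].loc[g]).statistic
                )
            assert ds.loc[g] == pytest.approx(np.mean(vals), rel=1e-10)

    def test_single_donor_rejected(self):
        prof = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"],
                            columns=list("ABCD"))
        with pytest.raises(ValueError):
            differential_stability({"D1": prof})


class TestBuildDataset:
    def test_output_contracts(self, small_dataset):
        ds = small_dataset
        vals = ds.expr.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert not ds.expr.isna().any().any()
        assert ds.ds.between(-1.0, 1.0).all()
        assert set(ds.ds.index) == set(ds.expr.index)

    def test_normalization_idempotent_bounds(self, small_dataset):
        renorm = srs_normalize(small_dataset.expr, axis=1)
        assert renorm.to_numpy().min() >= 0.0
        assert renorm.to_numpy().max() <= 1.0
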