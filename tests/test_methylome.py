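"""Methylome operations: detection filter, quantile normalization, FC, MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from globalmeth import MethylomeConfig
from globalmeth import methylome as meth
from globalmeth import synthetic_data as synth
from globalmeth.exceptions import ConfigurationError, PairingError

from conftest import make_beta_matrix

# global_shift for which the generator's true mean fold-change is 3.0
# (root-found against a direct Monte Carlo of the generative model at 4e6 CpGs)
SHIFT_FOR_FC3 = 0.2805


def _detp_like(bm, value=0.001):
    return pd.DataFrame(value, index=bm.betas.index, columns=bm.betas.columns)


class TestDetectionFilter:
    def test_all_good_probes_kept(self):
        bm = make_beta_matrix(np.full((4, 2), 0.5), ["active", "inactive"])
        out = meth.filter_detection(bm, _detp_like(bm, 0.001))
        assert out.n_probes == 4

    def test_single_failure_drops_probe_everywhere(self):
        bm = make_beta_matrix(np.full((4, 2), 0.5), ["active", "inactive"])
        detp = _detp_like(bm, 0.001)
        detp.iloc[2, 1] = 0.02
        out = meth.filter_detection(bm, detp)
        assert out.n_probes == 3
        assert "cg00002" not in out.betas.index

    def test_boundary_p_is_retained(self):
        """p exactly at the threshold passes the strict > comparison."""
        bm = make_beta_matrix(np.full((2, 2), 0.5), ["active", "inactive"])
        out = meth.filter_detection(bm, _detp_like(bm, 0.01))
        assert out.n_probes == 2


class TestQuantileNormalize:
    def test_two_column_closed_form(self):
        bm = make_beta_matrix(
            np.array([[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]]), ["active", "inactive"]
        )
        out = meth.quantile_normalize(bm).betas.to_numpy()
        expected = np.array([[0.25, 0.25], [0.35, 0.35], [0.45, 0.45]])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_identical_columns_are_fixed_point(self):
        col = np.array([0.3, 0.1, 0.8, 0.5])
        bm = make_beta_matrix(np.column_stack([col, col]), ["active", "inactive"])
        out = meth.quantile_normalize(bm).betas.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col, col]), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            float, (50, 4),
            elements=st.floats(0.0, 1.0, allow_nan=False, width=32),
            unique=True,
        )
    )
    def test_columns_share_distribution_and_idempotence(self, values):
        bm = make_beta_matrix(values, ["active", "active", "inactive", "inactive"],
                              replicates=[1, 2, 1, 2])
        out = meth.quantile_normalize(bm)
        x = out.betas.to_numpy()
        ref = np.sort(x[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(x[:, j]), ref, atol=1e-12)
        again = meth.quantile_normalize(out).betas.to_numpy()
        np.testing.assert_allclose(again, x, atol=1e-12)


class TestFoldChange:
    @pytest.mark.parametrize(
        "active,inactive,expected",
        [(0.6, 0.2, 3.0), (0.5, 0.5, 1.0), (0.5, 0.0, 50.0)],
    )
    def test_single_replicate_arithmetic(self, active, inactive, expected):
        bm = make_beta_matrix(np.array([[active, inactive]]), ["active", "inactive"])
        fc = meth.fold_change(bm)
        assert fc.fc.iloc[0] == pytest.approx(expected)

    def test_antisymmetric_under_arm_swap(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.05, 0.95, size=(30, 2))  # above the floor
        bm = make_beta_matrix(vals, ["active", "inactive"])
        fwd = meth.fold_change(bm, "active", "inactive").fc
        rev = meth.fold_change(bm, "inactive", "active").fc
        np.testing.assert_allclose(fwd * rev, 1.0, atol=1e-12)

    def test_unpaired_replicates_rejected(self):
        bm = make_beta_matrix(
            np.full((2, 3), 0.5), ["active", "active", "inactive"], replicates=[1, 2, 1]
        )
        with pytest.raises(PairingError):
            meth.fold_change(bm)

    def test_missing_arm_rejected(self):
        bm = make_beta_matrix(np.full((2, 2), 0.5), ["active", "active"], replicates=[1, 2])
        with pytest.raises(PairingError):
            meth.fold_change(bm)


class TestMeanGlobalFoldChange:
    def test_examples(self):
        tbl = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3], "fc": [1.0, 2.0, 3.0]})
        assert meth.mean_global_fold_change(meth.FoldChangeTable(tbl)) == 2.0
        tbl2 = pd.DataFrame({"chrom": "chr1", "pos": [1], "fc": [1.0]})
        assert meth.mean_global_fold_change(meth.FoldChangeTable(tbl2)) == 1.0

    def test_empty_table_rejected(self):
        tbl = pd.DataFrame({"chrom": [], "pos": [], "fc": []})
        with pytest.raises(ConfigurationError):
            meth.mean_global_fold_change(meth.FoldChangeTable(tbl))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_null_methylome_fc_near_unity(self, seed):
        """Without a shift the genome-wide mean FC stays in [0.95, 1.05]."""
        cfg = MethylomeConfig(n_cpg=20_000, global_shift=0.0, seed=seed)
        bm, _, detp = synth.make_methylome(cfg)
        bm = meth.filter_detection(bm, detp)
        est = meth.mean_global_fold_change(meth.fold_change(bm))
        assert 0.95 <= est <= 1.05

    def test_generator_round_trip_recovers_threefold(self):
        """The calibrated global shift yields a mean FC of 3 on raw betas."""
        cfg = MethylomeConfig(
            n_cpg=50_000, global_shift=SHIFT_FOR_FC3, shift_probability=1.0, seed=3
        )
        bm, _, detp = synth.make_methylome(cfg)
        bm = meth.filter_detection(bm, detp)
        est = meth.mean_global_fold_change(meth.fold_change(bm))
        assert est == pytest.approx(3.0, abs=0.1)


class TestClassicalMDS:
    def test_equilateral_distances_reproduced(self):
        a = 0.6
        vals = np.array([[a, 0, 0], [0, a, 0], [0, 0, a]], dtype=float).T
        bm = make_beta_matrix(vals, ["mock", "inactive", "active"])
        coords = meth.classical_mds(bm, k=2).coordinates.to_numpy()
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        expected = a * np.sqrt(2)
        off = d[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, expected, atol=1e-9)

    def test_collinear_samples_have_flat_second_axis(self):
        base = np.full(5, 0.2)
        vals = np.column_stack([base, base + 0.1, base + 0.25, base + 0.4])
        bm = make_beta_matrix(vals, ["mock", "inactive", "active", "active"],
                              replicates=[1, 1, 1, 2])
        coords = meth.classical_mds(bm, k=2).coordinates.to_numpy()
        assert np.abs(coords[:, 1]).max() < 1e-6

    def test_matches_pcoa_oracle(self):
        """Embedded distances agree with scikit-bio's principal coordinates."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, size=(40, 5))
        bm = make_beta_matrix(vals, ["mock", "inactive", "inactive", "active", "active"],
                              replicates=[1, 1, 2, 1, 2])
        ours = meth.classical_mds(bm, k=3).coordinates.to_numpy()
        dm = squareform(pdist(vals.T))
        ref = pcoa(dm, number_of_dimensions=3).samples.to_numpy()
        d_ours = squareform(pdist(ours))
        d_ref = squareform(pdist(ref))
        np.testing.assert_allclose(d_ours, d_ref, atol=1e-8)

    def test_k_bounds_enforced(self):
        bm = make_beta_matrix(np.random.default_rng(0).uniform(size=(5, 3)),
                              ["mock", "inactive", "active"])
        with pytest.raises(ConfigurationError):
            meth.classical_mds(bm, k=3)

    def test_active_arm_separates_in_mds(self):
        """Active-arm replicates cluster away from inactive and mock arms."""
        ok = 0
        for seed in range(20):
            bm, _, detp = synth.make_methylome(MethylomeConfig(n_cpg=5_000, seed=seed))
            bm = meth.quantile_normalize(meth.filter_detection(bm, detp))
            co = meth.classical_mds(bm).coordinates
            cent = {
                arm: co.loc[bm.samples.index[bm.samples.arm == arm]].mean()
                for arm in ("mock", "inactive", "active")
            }
            d_ai = np.linalg.norm(cent["active"] - cent["inactive"])
            d_im = np.linalg.norm(cent["inactive"] - cent["mock"])
            ok += d_ai > d_im
        assert ok >= 19


class TestManhattanExport:
    def test_bedgraph_convention(self, tmp_path):
        tbl = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "fc": [2.0]},
                           index=pd.Index(["cg0"], name="probe"))
        path = tmp_path / "out.bedGraph"
        meth.manhattan_export(meth.FoldChangeTable(tbl), path)
        lines = path.read_text().splitlines()
        assert lines[1] == "chr1\t99\t100\t1.000000"

    def test_empty_table_writes_header_only(self, tmp_path):
        tbl = pd.DataFrame({"chrom": [], "pos": [], "fc": []})
        path = tmp_path / "empty.bedGraph"
        meth.manhattan_export(meth.FoldChangeTable(tbl), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_round_trip(self, tmp_path, small_methylome):
        bm, _, _ = small_methylome
        fc = meth.fold_change(bm)
        path = tmp_path / "fc.bedGraph"
        meth.manhattan_export(fc, path)
        back = meth.read_bedgraph(path)
        merged = fc.table.copy()
        merged["start"] = merged["pos"] - 1
        merged = merged.merge(back, on=["chrom", "start"])
        assert len(merged) == len(fc.table)
        np.testing.assert_allclose(np.log2(merged["fc"]), merged["value"], atol=1e-6)
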