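import numpy as np
import pandas as pd
import pytest

from sctme.cnv import CNVMatrix
from sctme.cohort import (
    cell_type_proportions,
    cnv_immune_correlation,
    immune_fractions,
    proportion_tests,
)
from conftest import make_dataset


def proportions_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "cell_type",
                                       "fraction"])


class TestProportions:
    def test_single_type_sample(self):
        ds = make_dataset(np.ones((10, 3), dtype=int),
                          major_types=["T"] * 10)
        props = cell_type_proportions(ds)
        assert len(props) == 1
        assert props.iloc[0]["fraction"] == 1.0

    def test_sums_to_one_per_sample(self, tiny_cohort):
        ds, _ = tiny_cohort
        props = cell_type_proportions(ds)
        sums = props.groupby("sample_id")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_cell_order_invariance(self, tiny_cohort):
        ds, _ = tiny_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_cells)
        from sctme.io import Dataset
        ds2 = Dataset(counts=ds.counts[perm], cells=ds.cells.iloc[perm],
                      genes=ds.genes)
        a = cell_type_proportions(ds).sort_values(
            ["sample_id", "cell_type"]).reset_index(drop=True)
        b = cell_type_proportions(ds2).sort_values(
            ["sample_id", "cell_type"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_immune_fraction_sums_immune_types(self):
        props = proportions_frame([
            ("s1", "TNBC", "T", 0.2), ("s1", "TNBC", "B", 0.1),
            ("s1", "TNBC", "Myeloid", 0.15), ("s1", "TNBC", "Epithelial", 0.55),
        ])
        imm = immune_fractions(props)
        assert imm.iloc[0]["immune_fraction"] == pytest.approx(0.45)


class TestProportionTests:
    def make_props(self, fractions_by_condition):
        rows = []
        for cond, fracs in fractions_by_condition.items():
            for i, f in enumerate(fracs):
                rows.append((f"{cond}_{i}", cond, "T", f))
                rows.append((f"{cond}_{i}", cond, "Epithelial", 1 - f))
        return proportions_frame(rows)

    def test_identical_groups_p_one(self):
        props = self.make_props({"TNBC": [0.3, 0.3], "HRpos": [0.3, 0.3]})
        out = proportion_tests(props)
        assert out.iloc[0]["adj_p"] == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        props = self.make_props({
            "TNBC": rng.uniform(0.1, 0.9, 5),
            "HRpos": rng.uniform(0.1, 0.9, 5),
            "Normal": rng.uniform(0.1, 0.9, 5),
        })
        out = proportion_tests(props)
        assert (out["adj_p"] >= out["p_value"] - 1e-15).all()

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(2)
        props = self.make_props({
            "TNBC": np.clip(rng.normal(0.6, 0.01, 8), 0, 1),
            "HRpos": np.clip(rng.normal(0.2, 0.01, 8), 0, 1),
        })
        out = proportion_tests(props)
        assert out.iloc[0]["adj_p"] < 0.01

    def test_small_group_skipped_with_warning(self):
        props = self.make_props({"TNBC": [0.3], "HRpos": [0.2, 0.4]})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = proportion_tests(props)
        assert out.empty

    def test_matches_textbook_welch(self):
        """Welch t against an explicit textbook implementation on 100
        random fraction tables."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            na, nb = rng.integers(3, 10, size=2)
            a = rng.uniform(0, 1, na)
            b = rng.uniform(0, 1, nb)
            props = self.make_props({"TNBC": a, "HRpos": b})
            out = proportion_tests(props)
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            from scipy.stats import t as tdist
            p = 2 * tdist.sf(abs(t), df)
            # groups sort alphabetically: HRpos first, so sign may flip
            assert abs(out.iloc[0]["t"]) == pytest.approx(abs(t), rel=1e-10)
            assert out.iloc[0]["p_value"] == pytest.approx(p, rel=1e-10)


def build_cnv(values, sample_of_cell):
    n_cells, n_windows = values.shape
    wm = pd.DataFrame({
        "chromosome": ["chr1"] * n_windows,
        "gene_start": np.arange(n_windows) * 10,
        "gene_end": np.arange(n_windows) * 10 + 10,
    })
    cell_ids = pd.Index([f"c{i}" for i in range(n_cells)])
    cells = pd.DataFrame({
        "sample_id": sample_of_cell,
        "condition": "TNBC",
        "major_type": "Epithelial",
        "minor_type": "Epithelial",
    }, index=cell_ids)
    calls = pd.DataFrame({"is_tumor": True}, index=cell_ids)
    return CNVMatrix(values=values, window_map=wm, cell_ids=cell_ids), cells, calls


class TestCnvImmuneCorrelation:
    def constructed(self, noise=0.05, n_samples=8, seed=0):
        """One window's per-sample CNV is proportional to the immune
        fraction; the remaining windows are noise."""
        rng = np.random.default_rng(seed)
        imm = np.linspace(0.1, 0.8, n_samples)
        n_windows = 10
        values, samples, prop_rows = [], [], []
        for i in range(n_samples):
            per_cell = rng.normal(0, noise, size=(20, n_windows))
            per_cell[:, 4] += imm[i]  # window 4 tracks immune fraction
            values.append(per_cell)
            samples += [f"s{i}"] * 20
            prop_rows += [(f"s{i}", "TNBC", "T", imm[i]),
                          (f"s{i}", "TNBC", "Epithelial", 1 - imm[i])]
        cnv, cells, calls = build_cnv(np.vstack(values), samples)
        return cnv, cells, calls, proportions_frame(prop_rows)

    def test_constructed_signal_found(self):
        cnv, cells, calls, props = self.constructed()
        spots = cnv_immune_correlation(cnv, calls, props, "TNBC", cells,
                                       r_threshold=None)
        assert spots.iloc[0]["window"] == 4
        assert spots.iloc[0]["pcc"] > 0.9
        assert (spots["n_samples"] == 8).all()

    def test_window_permutation_invariance(self):
        cnv, cells, calls, props = self.constructed()
        rng = np.random.default_rng(1)
        perm = rng.permutation(cnv.values.shape[1])
        cnv2 = CNVMatrix(values=cnv.values[:, perm],
                         window_map=cnv.window_map.iloc[perm].reset_index(
                             drop=True),
                         cell_ids=cnv.cell_ids)
        a = cnv_immune_correlation(cnv, calls, props, "TNBC", cells,
                                   r_threshold=None)
        b = cnv_immune_correlation(cnv2, calls, props, "TNBC", cells,
                                   r_threshold=None)
        key = ["chromosome", "gene_start", "gene_end"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[key + ["pcc"]],
            b.sort_values(key).reset_index(drop=True)[key + ["pcc"]],
        )

    def test_constant_immune_fraction_no_spots(self):
        cnv, cells, calls, props = self.constructed()
        props["fraction"] = np.where(props["cell_type"] == "T", 0.3, 0.7)
        spots = cnv_immune_correlation(cnv, calls, props, "TNBC", cells,
                                       r_threshold=None)
        assert spots.empty

    def test_too_few_samples_rejected(self):
        cnv, cells, calls, props = self.constructed(n_samples=2)
        with pytest.raises(ValueError, match="3"):
            cnv_immune_correlation(cnv, calls, props, "TNBC", cells)

    def test_report_threshold_filters(self):
        cnv, cells, calls, props = self.constructed()
        spots = cnv_immune_correlation(cnv, calls, props, "TNBC", cells,
                                       r_threshold=0.6)
        assert (spots["pcc"].abs() >= 0.6).all()
        assert 4 in set(spots["window"])
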