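import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from permscreen.data_model import (
    CollinearityError,
    FormatError,
    QCThresholds,
    apply_dataset_qc,
    build_covariate_matrix,
    read_dataset,
    write_dataset,
)

from conftest import make_dataset


def write_tsv_fixture(tmp_path, counts, assignment, grna_table, covariates):
    cdir = tmp_path / "data"
    cdir.mkdir(exist_ok=True)
    counts.to_csv(cdir / "counts.tsv", sep="\t", index_label="response_id")
    assignment.to_csv(cdir / "grna_assignment.tsv", sep="\t", index=False)
    grna_table.to_csv(cdir / "grna_table.tsv", sep="\t", index=False)
    covariates.to_csv(cdir / "covariates.tsv", sep="\t", index=False)
    return cdir


@pytest.fixture
def tsv_fixture(tmp_path):
    counts = pd.DataFrame(
        [[1, 0, 2, 0], [0, 3, 0, 1], [5, 0, 0, 0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    assignment = pd.DataFrame(
        {"cell_id": ["c1", "c2", "c3", "c4"], "grna_id": ["u1", "u1", "u2", "u2"]}
    )
    grna_table = pd.DataFrame(
        {
            "grna_id": ["u1", "u2"],
            "target": ["non-targeting", "gA"],
            "targeting": [False, True],
            "grna_group": ["u1", "u2"],
        }
    )
    covariates = pd.DataFrame({"cell_id": ["c1", "c2", "c3", "c4"], "batch": list("xxyy")})
    return write_tsv_fixture(tmp_path, counts, assignment, grna_table, covariates)


class TestReadDataset:
    def test_tsv_roundtrip_shapes(self, tsv_fixture):
        ds = read_dataset(
            str(tsv_fixture / "counts.tsv"),
            str(tsv_fixture / "grna_assignment.tsv"),
            str(tsv_fixture / "grna_table.tsv"),
            str(tsv_fixture / "covariates.tsv"),
        )
        assert ds.counts.shape == (3, 4)
        assert ds.response_ids == ["gA", "gB", "gC"]
        assert ds.cell_ids == ["c1", "c2", "c3", "c4"]
        assert list(ds.covariates["batch"]) == list("xxyy")

    def test_negative_entry_rejected(self, tsv_fixture):
        path = tsv_fixture / "counts.tsv"
        txt = path.read_text().replace("5", "-5")
        path.write_text(txt)
        with pytest.raises(FormatError):
            read_dataset(
                str(path),
                str(tsv_fixture / "grna_assignment.tsv"),
                str(tsv_fixture / "grna_table.tsv"),
                str(tsv_fixture / "covariates.tsv"),
            )

    def test_negative_mtx_entry_rejected(self, tmp_path, small_screen):
        write_dataset(small_screen, str(tmp_path), fmt="mtx")
        path = tmp_path / "counts.mtx"
        lines = path.read_text().splitlines()
        # flip the first data entry negative
        for i, line in enumerate(lines):
            if not line.startswith("%") and len(line.split()) == 3 and i > 0:
                r, c, v = line.split()
                lines[i] = f"{r} {c} -{v}"
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError):
            read_dataset(
                str(path),
                str(tmp_path / "grna_assignment.tsv"),
                str(tmp_path / "grna_table.tsv"),
                str(tmp_path / "covariates.tsv"),
            )

    def test_unassigned_cells_dropped(self, tsv_fixture):
        path = tsv_fixture / "grna_assignment.tsv"
        tbl = pd.read_csv(path, sep="\t")
        tbl[tbl["cell_id"] != "c3"].to_csv(path, sep="\t", index=False)
        ds = read_dataset(
            str(tsv_fixture / "counts.tsv"),
            str(path),
            str(tsv_fixture / "grna_table.tsv"),
            str(tsv_fixture / "covariates.tsv"),
        )
        assert ds.cell_ids == ["c1", "c2", "c4"]
        assert ds.filter_report["cells_without_assignment"] == 1


@pytest.mark.parametrize("fmt", ["mtx", "tsv"])
def test_write_read_roundtrip(tmp_path, small_screen, fmt):
    write_dataset(small_screen, str(tmp_path), fmt=fmt)
    counts_file = tmp_path / ("counts.mtx" if fmt == "mtx" else "counts.tsv")
    ds2 = read_dataset(
        str(counts_file),
        str(tmp_path / "grna_assignment.tsv"),
        str(tmp_path / "grna_table.tsv"),
        str(tmp_path / "covariates.tsv"),
    )
    a = small_screen.counts
    b = ds2.counts.toarray() if sp.issparse(ds2.counts) else ds2.counts
    np.testing.assert_array_equal(np.asarray(a), np.asarray(b))
    assert ds2.response_ids == small_screen.response_ids
    assert ds2.cell_ids == small_screen.cell_ids
    pd.testing.assert_frame_equal(
        ds2.grna_assignment, small_screen.grna_assignment, check_dtype=False
    )
    assert list(ds2.grna_table["grna_group"]) == list(small_screen.grna_table["grna_group"])


class TestQC:
    def test_paper_default_thresholds(self):
        thr = QCThresholds()
        assert thr.min_gene_frac == 0.005
        assert thr.min_cells_per_grna == 10
        assert thr.require_single_grna

    def test_multi_grna_cell_removed(self, small_screen):
        ds = small_screen
        extra = pd.DataFrame({"cell_id": ["c0"], "grna_id": ["nt_b"]})
        ds.grna_assignment = pd.concat([ds.grna_assignment, extra], ignore_index=True)
        out = apply_dataset_qc(ds, QCThresholds(min_gene_frac=0, min_cells_per_grna=0))
        assert "c0" not in out.cell_ids
        assert out.filter_report["cells_multi_grna"] == 1

    def test_gene_filter_matches_bruteforce(self, rng):
        counts = (rng.random((200, 80)) < 0.05 * rng.random((200, 1)) * 10).astype(int) * rng.poisson(
            3, size=(200, 80)
        )
        ds = make_dataset(counts, ["nt_0"] * 40 + ["nt_1"] * 40, {"nt_0": False, "nt_1": False})
        thr = QCThresholds(min_gene_frac=0.05, min_cells_per_grna=0)
        out = apply_dataset_qc(ds, thr)
        # independent loop-based oracle (no gRNA/cell removal happens here)
        survivors = []
        for g in range(200):
            nonzero = sum(1 for c in range(80) if counts[g, c] > 0)
            if nonzero / 80 >= 0.05:
                survivors.append(f"g{g}")
        assert out.response_ids == survivors

    def test_idempotent_and_shrinking(self, rng):
        counts = rng.poisson(0.3, size=(50, 120))
        grnas = [f"nt_{i % 7}" for i in range(120)]
        ds = make_dataset(counts, grnas, {f"nt_{i}": False for i in range(7)})
        thr = QCThresholds(min_gene_frac=0.1, min_cells_per_grna=15)
        once = apply_dataset_qc(ds, thr)
        twice = apply_dataset_qc(once, thr)
        assert once.n_responses <= ds.n_responses
        assert once.n_cells <= ds.n_cells
        assert twice.response_ids == once.response_ids
        assert twice.cell_ids == once.cell_ids
        assert list(twice.grna_table.index) == list(once.grna_table.index)

    def test_grna_filter_drops_cells(self, small_screen):
        thr = QCThresholds(min_gene_frac=0.0, min_cells_per_grna=11)
        out = apply_dataset_qc(small_screen, thr)
        # nt_c has 10 cells -> dropped along with its cells
        assert "nt_c" not in out.grna_table.index
        assert out.n_cells == 50


class TestCovariateMatrix:
    def test_intercept_only(self, small_screen):
        Z = build_covariate_matrix(small_screen, [])
        assert Z.shape == (60, 1)
        np.testing.assert_array_equal(Z.to_numpy(), np.ones((60, 1)))

    def test_three_level_batch(self, rng):
        counts = rng.poisson(2, size=(4, 30))
        cov = pd.DataFrame({"batch": ["a", "b", "c"] * 10})
        ds = make_dataset(counts, ["nt_0"] * 30, {"nt_0": False}, covariates=cov)
        Z = build_covariate_matrix(ds, ["batch"])
        assert Z.shape == (30, 3)  # intercept + 2 indicators
        assert list(Z.columns) == ["intercept", "batch[b]", "batch[c]"]

    def test_rank_equals_columns(self, rng):
        counts = rng.poisson(2, size=(4, 50))
        cov = pd.DataFrame(
            {"x1": rng.standard_normal(50), "batch": rng.choice(list("pq"), 50)}
        )
        ds = make_dataset(counts, ["nt_0"] * 50, {"nt_0": False}, covariates=cov)
        Z = build_covariate_matrix(ds, ["x1", "batch", "library_size"]).to_numpy()
        # independent decomposition oracle
        assert np.linalg.matrix_rank(Z) == Z.shape[1]

    def test_constant_covariate_rejected(self, rng):
        counts = rng.poisson(2, size=(4, 20))
        cov = pd.DataFrame({"flat": np.ones(20)})
        ds = make_dataset(counts, ["nt_0"] * 20, {"nt_0": False}, covariates=cov)
        with pytest.raises(CollinearityError):
            build_covariate_matrix(ds, ["flat"])

    def test_positive_numeric_logged(self, rng):
        counts = rng.poisson(5, size=(4, 20)) + 1
        cov = pd.DataFrame({"depth": np.arange(1.0, 21.0)})
        ds = make_dataset(counts, ["nt_0"] * 20, {"nt_0": False}, covariates=cov)
        Z = build_covariate_matrix(ds, ["depth"])
        np.testing.assert_allclose(Z["depth"], np.log(np.arange(1.0, 21.0)))
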