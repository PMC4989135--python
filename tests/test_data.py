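import numpy as np
import pandas as pd
import pytest

from hicats import (
    HicatsConfig,
    SyntheticSpec,
    cv_accuracy,
    make_synthetic,
    read_expression_table,
    run_hicats,
    write_result,
)


class TestReadExpressionTable:
    @pytest.fixture
    def csv_with_labels(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text(
            "sample,class,gA,gB,gC,gD\n"
            "s1,tumor,1.0,2.0,3.0,4.0\n"
            "s2,normal,5.0,6.0,7.0,8.0\n"
            "s3,tumor,9.0,10.0,11.0,12.0\n"
        )
        return path

    def test_label_column(self, csv_with_labels):
        ds = read_expression_table(csv_with_labels, label_source="class")
        assert ds.matrix.shape == (3, 4)
        assert ds.labels.tolist() == ["tumor", "normal", "tumor"]
        assert ds.gene_names == ["gA", "gB", "gC", "gD"]

    def test_genes_in_rows_round_trip(self, csv_with_labels, tmp_path):
        ds = read_expression_table(csv_with_labels, label_source="class")
        tpath = tmp_path / "transposed.tsv"
        pd.DataFrame(
            ds.matrix.T,
            index=ds.gene_names,
            columns=["s1", "s2", "s3"],
        ).to_csv(tpath, sep="\t")
        lpath = tmp_path / "labels.txt"
        lpath.write_text("tumor\nnormal\ntumor\n")
        ds2 = read_expression_table(tpath, orientation="genes-in-rows", labels_path=lpath)
        assert np.array_equal(ds.matrix, ds2.matrix)
        assert ds.gene_names == ds2.gene_names
        assert ds.labels.tolist() == ds2.labels.tolist()

    def test_label_count_mismatch(self, tmp_path):
        path = tmp_path / "plain.csv"
        path.write_text("sample,gA,gB\ns1,1.0,2.0\ns2,3.0,4.0\ns3,5.0,6.0\n")
        lpath = tmp_path / "labels.txt"
        lpath.write_text("tumor\nnormal\n")
        with pytest.raises(ValueError, match="labels"):
            read_expression_table(path, labels_path=lpath)

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,class,gA\ns1,a,1.0\ns2,b,oops\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_table(path, label_source="class")

    def test_missing_label_column(self, csv_with_labels):
        with pytest.raises(ValueError, match="nope"):
            read_expression_table(csv_with_labels, label_source="nope")


class TestMakeSynthetic:
    def test_even_class_split_and_planted_positions(self):
        ds, planted = make_synthetic(SyntheticSpec(40, 200, 5, 3, 3.0, 1.0, seed=1))
        _, counts = np.unique(ds.labels, return_counts=True)
        assert counts.tolist() == [14, 13, 13]
        assert len(planted) == 5 == len(set(planted))
        assert planted == sorted(planted)
        assert all(1 <= p <= 200 for p in planted)

    def test_pure_function_of_spec(self):
        spec = SyntheticSpec(seed=9)
        (a, pa), (b, pb) = make_synthetic(spec), make_synthetic(spec)
        assert np.array_equal(a.matrix, b.matrix)
        assert pa == pb

    def test_zero_effect_leaves_no_class_signal(self):
        ds, planted = make_synthetic(SyntheticSpec(60, 50, 5, 2, 0.0, 1.0, seed=3))
        cols = np.array(planted) - 1
        grand = ds.matrix[:, cols]
        # planted columns are plain noise: class means differ only by noise
        by_class = [grand[ds.labels == c].mean() for c in np.unique(ds.labels)]
        assert abs(by_class[0] - by_class[1]) < 0.5

    def test_no_informative_genes_gives_chance_accuracy(self):
        # LOOCV on label-independent data sits at (slightly below) chance
        accs = []
        for seed in range(15):
            ds, _ = make_synthetic(SyntheticSpec(30, 50, 0, 2, 3.0, 1.0, seed=seed))
            accs.append(cv_accuracy(ds, [1, 2, 3, 4, 5], "centroid", "loocv"))
        assert 0.3 < np.mean(accs) < 0.65

    def test_planted_subset_beats_random_subsets(self):
        # the planted genes must out-score 95% of random same-size subsets
        ds, planted = make_synthetic(SyntheticSpec(40, 200, 5, 3, 3.0, 1.0, seed=2))
        target = cv_accuracy(ds, planted, "centroid", 5)
        rng = np.random.default_rng(0)
        random_accs = [
            cv_accuracy(ds, sorted(rng.choice(200, 5, replace=False) + 1), "centroid", 5)
            for _ in range(200)
        ]
        assert target > np.quantile(random_accs, 0.95)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_informative=300, n_genes=200),
            dict(n_classes=0),
            dict(n_samples=2, n_classes=3),
            dict(noise_sd=0.0),
            dict(effect_size=-1.0),
        ],
    )
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)


@pytest.fixture(scope="module")
def result():
    ds, _ = make_synthetic(SyntheticSpec(20, 25, 3, 2, 4.0, 1.0, seed=4))
    cfg = HicatsConfig(
        n_pop=6, n_imp=2, generations=3, ts_iters=1, ts_neighbors=4,
        classifier="centroid", cv=3, seed=1,
    )
    return run_hicats(ds, cfg)


class TestWriteResult:

    def test_summary_contents(self, result, tmp_path):
        paths = write_result(result, tmp_path / "run1")
        text = paths["summary"].read_text()
        assert f"{result.best_accuracy * 100:.2f}" in text
        assert str(result.best_n_selected) in text
        for name in result.selected_gene_names:
            assert name in text

    def test_log_round_trip(self, result, tmp_path):
        paths = write_result(result, tmp_path / "run2")
        df = pd.read_csv(paths["log"], sep="\t")
        assert len(df) == len(result.log)
        assert np.allclose(df["best_fitness"], [r.best_fitness for r in result.log])
        assert df["generation"].tolist() == [r.generation for r in result.log]

    def test_manifest_holds_config_and_genes(self, result, tmp_path):
        import json

        paths = write_result(result, tmp_path / "run3")
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["config"]["seed"] == 1
        assert manifest["selected_genes"] == result.selected_genes
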