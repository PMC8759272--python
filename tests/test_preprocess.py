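"""Filter chain and TMM normalization, cross-checked against edgeR."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from stagewire.preprocess import (
    clean_genes,
    connectivity,
    connectivity_filter,
    cpm_filter,
    cv_filter,
    preprocess_counts,
    tmm_factors,
    tmm_normalize,
)


def frame(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples:
        df.columns = samples
    df.index.name = "gene"
    return df


class TestCleanGenes:
    def test_na_and_zero_rows_removed_others_kept(self):
        counts = frame({"na": [1, np.nan, 2], "zero": [0, 0, 0], "ok": [3, 0, 7]})
        out = clean_genes(counts)
        assert list(out.index) == ["ok"]
        assert list(out.columns) == list(counts.columns)

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="all genes removed"):
            clean_genes(frame({"zero": [0, 0]}))


class TestCpmFilter:
    def test_threshold_is_strict_less_than(self):
        libs = 1_000_000
        counts = frame(
            {
                "low": [0, 0, 1, 0],  # mean CPM 0.25 -> removed
                "edge": [1, 0, 1, 0],  # mean CPM exactly 0.5 -> kept
                "big": [libs // 10] * 4,
            }
        )
        # make library sizes exactly 1e6 per sample via a filler gene
        filler = libs - counts.sum(axis=0)
        counts.loc["filler"] = filler
        out = cpm_filter(counts)
        assert "low" not in out.index
        assert "edge" in out.index

    def test_unit_count_at_million_library_is_cpm_one(self):
        counts = frame({"g": [1, 1], "filler": [999_999, 999_999]})
        assert "g" in cpm_filter(counts).index


class TestCvFilter:
    def test_lowest_quartile_removed(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 200, size=(100, 6))
        scale = np.linspace(1.0, 8.0, 100)[:, None]  # increasing variability
        counts = pd.DataFrame(
            (base * rng.normal(1, 0.02 + 0.1 * scale, base.shape)).clip(1).astype(int),
            index=[f"g{i:03d}" for i in range(100)],
        )
        out = cv_filter(counts)
        assert out.shape[0] == 75

    def test_four_genes_lowest_cv_removed(self):
        rng = np.random.default_rng(1)
        rows = {}
        for name, cv in zip("abcd", [0.1, 0.2, 0.3, 0.4]):
            rows[name] = (1000 * rng.normal(1, cv, 50)).clip(1)
        counts = frame(rows).astype(int)
        out = cv_filter(counts)
        assert "a" not in out.index and out.shape[0] == 3

    def test_identical_cv_tie_broken_by_gene_id(self):
        counts = frame({f"g{i}": [10, 20, 30] for i in range(8)})
        out = cv_filter(counts)  # all CVs equal; keep ceil(6)=6, drop last two ids
        assert list(out.index) == [f"g{i}" for i in range(6)]


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = frame({"a": [10, 10, 10], "b": [20, 20, 20], "c": [5, 5, 5]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_gives_equal_factors(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(4, 1.5, 80)
        counts = pd.DataFrame(
            {
                "A": rng.poisson(base / base.sum() * 1e6),
                "B": rng.poisson(2 * base / base.sum() * 1e6),
                "C": rng.poisson(base / base.sum() * 1e6),
            },
            index=[f"g{i}" for i in range(80)],
        )
        f = tmm_factors(clean_genes(counts))
        assert abs(f["B"] / f["A"] - 1.0) < 0.02

    def test_factor_product_is_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(100, (60, 5)), index=[f"g{i}" for i in range(60)]
        )
        f = tmm_factors(counts)
        assert np.isclose(np.prod(f), 1.0)

    def test_factors_match_edger_reference(self, tmp_path):
        rng = np.random.default_rng(7)
        base = rng.lognormal(4, 1.5, 60)
        counts = np.zeros((60, 8), int)
        for s in range(8):
            f = base.copy()
            if s >= 4:
                f[:10] *= 6  # composition shift for half the samples
            counts[:, s] = rng.poisson(f / f.sum() * rng.integers(5e5, 1.5e6))
        df = clean_genes(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(60)],
                         columns=[f"s{i}" for i in range(8)])
        )
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t")
        r_code = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.delim("{path}", row.names=1));'
            'cat(paste(calcNormFactors(x, method="TMM"), collapse=","))'
        )
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split(",")])
        mine = tmm_factors(df).to_numpy()
        assert np.abs(mine - ref).max() < 0.02

    def test_permuting_samples_permutes_factors(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(rng.lognormal(3, 1, (50, 6)) * 20),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        counts = clean_genes(counts)
        f1 = tmm_factors(counts)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        f2 = tmm_factors(counts[perm])
        assert np.allclose(f1[perm].to_numpy(), f2.to_numpy())

    def test_normalized_output_is_log_scale_and_finite(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson(50, (30, 4)), index=[f"g{i}" for i in range(30)]
        )
        expr = tmm_normalize(clean_genes(counts))
        assert np.isfinite(expr.to_numpy()).all()
        assert (expr.to_numpy() >= 0).all()


class TestConnectivity:
    def test_direct_sum_then_scale(self):
        adj = pd.DataFrame(
            [
                [1.0, 0.2, 0.3, 0.5],
                [0.2, 1.0, 0.1, 0.4],
                [0.3, 0.1, 1.0, 0.6],
                [0.5, 0.4, 0.6, 1.0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        assert np.isclose(connectivity(adj, "a"), 1.0 / 3)

    def test_isolated_and_saturated_genes(self):
        adj = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        assert connectivity(adj, "a") == 0.0
        full = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
        assert connectivity(full, "a") == 1.0

    def test_absent_gene_raises(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(KeyError):
            connectivity(adj, "z")


class TestConnectivityFilter:
    def test_weakly_connected_genes_removed(self, rewired_dataset):
        expr = rewired_dataset["expr"]
        out = connectivity_filter(expr, threshold=0.1)
        kept_planted = sum(1 for g in out.index if g.startswith("M"))
        kept_noise = sum(1 for g in out.index if g.startswith("BG"))
        assert kept_planted >= 150  # tight modules survive
        assert kept_noise <= 20  # unstructured genes are pruned

    def test_zero_threshold_keeps_everything(self, rewired_dataset):
        expr = rewired_dataset["expr"].iloc[:50]
        assert connectivity_filter(expr, threshold=0.0).shape[0] == 50


class TestChain:
    def test_gene_count_monotone_and_samples_preserved(self, rewired_dataset):
        counts = rewired_dataset["counts"]
        expr, report = preprocess_counts(counts)
        assert expr.shape[0] <= counts.shape[0]
        assert list(expr.columns) == list(counts.columns)
        removed = (
            report["removed_clean"] + report["removed_cpm"]
            + report["removed_cv"] + report["removed_connectivity"]
        )
        assert report["input_genes"] - removed == report["output_genes"] == expr.shape[0]
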