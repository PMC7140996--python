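import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from taxonet import (
    GeneratorConfig,
    NetworkError,
    PipelineConfig,
    anova_levels,
    build_index_table,
    build_zscore_table,
    compare_levels,
    generate_study,
    posthoc_paired,
    run_pipeline,
    spearman_levels,
)
from taxonet import connectance, nodf, binarize, wnodf


def _long(values_by_level):
    rows = []
    for level, vals in values_by_level.items():
        for i, v in enumerate(vals):
            rows.append({"network": f"n{i}", "level": level, "value": v})
    return pd.DataFrame(rows)


class TestAnova:
    def test_df_structure(self):
        rng = np.random.default_rng(0)
        tbl = _long({lvl: rng.normal(size=41) for lvl in ("species", "genus", "family")})
        f, df1, df2, p = anova_levels(tbl)
        assert (df1, df2) == (2, 120)

    def test_identical_groups_give_zero_f(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        tbl = _long({lvl: vals for lvl in ("species", "genus", "family")})
        f, *_ = anova_levels(tbl)
        assert f == pytest.approx(0.0)

    def test_matches_sum_of_squares_by_hand(self):
        groups = {
            "species": [1.0, 2.0, 3.0],
            "genus": [2.0, 3.0, 4.0],
            "family": [3.0, 4.0, 5.0],
        }
        f, df1, df2, p = anova_levels(_long(groups))
        # hand ANOVA: grand mean 3; SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6
        # SSW = 3 groups * 2 each = 6; F = (6/2)/(6/6) = 3
        assert (f, df1, df2) == (pytest.approx(3.0), 2, 6)
        assert p == pytest.approx(1 - sps.f.cdf(3.0, 2, 6))

    def test_missing_level_errors(self):
        tbl = _long({"species": [1.0, 2.0], "genus": [1.0, 2.0]})
        with pytest.raises(NetworkError, match="missing levels"):
            anova_levels(tbl)

    def test_f_invariant_under_shift_and_scale(self):
        rng = np.random.default_rng(1)
        groups = {lvl: rng.normal(size=10) for lvl in ("species", "genus", "family")}
        f0, *_ = anova_levels(_long(groups))
        shifted = {k: [x * 3.0 + 7.0 for x in v] for k, v in groups.items()}
        f1, *_ = anova_levels(_long(shifted))
        assert f1 == pytest.approx(f0)


class TestPosthoc:
    def test_constant_difference_is_degenerate(self):
        base = [1.0, 2.0, 3.0, 4.0]
        tbl = _long(
            {
                "species": base,
                "genus": [x + 1 for x in base],
                "family": [x + 1.5 for x in base],
            }
        )
        res = posthoc_paired(tbl)
        sg = res[(res.level_a == "species") & (res.level_b == "genus")].iloc[0]
        assert sg.degenerate and np.isnan(sg.t)

    def test_bonferroni_triples_raw_p(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=12)
        tbl = _long(
            {
                "species": base,
                "genus": base + rng.normal(scale=0.5, size=12),
                "family": base + rng.normal(scale=0.5, size=12),
            }
        )
        res = posthoc_paired(tbl)
        for _, row in res.iterrows():
            assert row.p_bonferroni == pytest.approx(min(1.0, 3 * row.p_raw))

    def test_t_statistic_matches_hand_computation(self):
        s = np.array([1.0, 3.0, 2.0, 5.0])
        g = np.array([2.0, 2.5, 4.0, 4.5])
        tbl = _long({"species": s, "genus": g, "family": g + 0.1 * s})
        res = posthoc_paired(tbl)
        d = s - g
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        sg = res[(res.level_a == "species") & (res.level_b == "genus")].iloc[0]
        assert sg.t == pytest.approx(t_hand)


class TestSpearman:
    def test_identical_vectors(self):
        rho, p = spearman_levels([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        rho, _ = spearman_levels([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_pearson_on_average_ranks(self):
        a = [1.0, 2.0, 2.0, 4.0, 5.0]
        b = [3.0, 1.0, 4.0, 4.0, 6.0]
        rho, _ = spearman_levels(a, b)
        ra = sps.rankdata(a)
        rb = sps.rankdata(b)
        assert rho == pytest.approx(np.corrcoef(ra, rb)[0, 1])

    def test_constant_vector_errors(self):
        with pytest.raises(NetworkError):
            spearman_levels([1, 1, 1], [1, 2, 3])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=15)
        b = a + rng.normal(scale=0.4, size=15)
        rho0, _ = spearman_levels(a, b)
        rho1, _ = spearman_levels(np.exp(a), b**3 + 5 * b)
        assert rho1 == pytest.approx(rho0)

    def test_rho_recovers_as_noise_vanishes(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        rhos = []
        for noise in (2.0, 0.5, 0.0):
            b = a + rng.normal(scale=noise, size=30) if noise else a
            rhos.append(spearman_levels(a, b)[0])
        assert rhos[0] < rhos[2] and rhos[1] < rhos[2] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_study():
    cfg = GeneratorConfig(
        n_networks=4,
        plants_range=(6, 12),
        pollinators_range=(8, 14),
        fraction_binary=0.5,
        seed=21,
    )
    return generate_study(cfg)


class TestIndexTable:
    def test_cardinality_per_index(self, small_study):
        tbl = build_index_table(small_study, PipelineConfig(seed=21))
        conn = tbl[tbl["index"] == "connectance"]
        assert len(conn) == 4 * 3  # networks x levels

    def test_binary_networks_skip_weighted_indices(self, small_study):
        tbl = build_index_table(small_study, PipelineConfig(seed=21))
        binary_names = {n.name for n, _ in small_study if not n.weighted}
        weighted_rows = tbl[tbl["index"].isin(["WNODF", "SR_Qua", "modularity"])]
        assert binary_names.isdisjoint(set(weighted_rows.network))

    def test_values_match_direct_module_calls(self, small_study):
        tbl = build_index_table(small_study, PipelineConfig(seed=21))
        net, _ = small_study[0]
        row = tbl[
            (tbl.network == net.name)
            & (tbl.level == "species")
            & (tbl["index"] == "connectance")
        ].iloc[0]
        assert row.value == pytest.approx(connectance(binarize(net)))
        row = tbl[
            (tbl.network == net.name)
            & (tbl.level == "species")
            & (tbl["index"] == "NODF")
        ].iloc[0]
        assert row.value == pytest.approx(nodf(binarize(net)))
        if net.weighted:
            row = tbl[
                (tbl.network == net.name)
                & (tbl.level == "species")
                & (tbl["index"] == "WNODF")
            ].iloc[0]
            assert row.value == pytest.approx(wnodf(net))

    def test_zscore_table_pairings(self, small_study):
        ztbl = build_zscore_table(small_study, PipelineConfig(n_null=15, seed=21))
        pairs = set(map(tuple, ztbl[["index", "null_model"]].drop_duplicates().values))
        assert ("NODF", "DD") in pairs
        assert not any(idx == "NODF" and nm != "DD" for idx, nm in pairs)
        weighted_any = any(n.weighted for n, _ in small_study)
        if weighted_any:
            assert ("WNODF", "RTCA") in pairs and ("WNODF", "r2dtable") in pairs


class TestPipeline:
    def test_rerun_same_seed_is_byte_identical(self, tmp_path):
        config = {
            "synthetic": {
                "n_networks": 3,
                "plants_range": [6, 10],
                "pollinators_range": [8, 12],
                "seed": 5,
            },
            "n_null": 10,
            "robustness_sequences": 20,
            "modularity_restarts": 3,
            "seed": 5,
        }
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_pipeline(config, out_dir=out1)
        run_pipeline(config, out_dir=out2)
        for name in ("indices.csv", "zscores.csv", "anova.csv", "posthoc.csv",
                     "spearman.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_invalid_config_errors(self):
        with pytest.raises(NetworkError, match="config"):
            run_pipeline({"n_null": 10})

    def test_compare_levels_report_shape(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=8)
        tbl = pd.concat(
            [
                _long(
                    {
                        "species": base,
                        "genus": base + rng.normal(scale=0.2, size=8),
                        "family": base + rng.normal(scale=0.4, size=8),
                    }
                ).assign(index=name)
                for name in ("idxA", "idxB")
            ]
        )
        report = compare_levels(tbl)
        assert set(report.anova["index"]) == {"idxA", "idxB"}
        assert len(report.posthoc) == 6  # 2 indices x 3 level pairs
        assert len(report.spearman) == 6
        assert ((report.spearman.rho >= -1) & (report.spearman.rho <= 1)).all()
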