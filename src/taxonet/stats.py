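"""Cross-resolution comparison of network indices.

Assembles the per-network x per-level index table, standardizes the
nestedness indices against their null models, and asks the study's two
questions: do absolute index values differ across species / genus / family
resolution (one-way ANOVA with Bonferroni-corrected paired post hoc
t-tests), and are index *ranks* conserved across resolutions (Spearman's
rho between levels)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import binary_indices as bi
from . import weighted_indices as wi
from .motifs import build_catalogue, motif_census
from .network import (
    BipartiteNetwork,
    NetworkError,
    TaxonomyTable,
    aggregate,
    binarize,
    check_multifamily,
    filter_species_resolved,
)
from .nulls import INDEX_NULL_PAIRING, nodf_c, null_ensemble
from .synthetic import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)

LEVEL_PAIRS = (("species", "genus"), ("genus", "family"), ("species", "family"))

BINARY_INDICES = (
    "NODF", "BR", "SR_Bin", "connectance", "robustness",
    "ND_Q1", "ND_median", "ND_Q3",
)
WEIGHTED_INDICES = ("WNODF", "SR_Qua", "modularity")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full comparison pipeline."""

    n_null: int = 500
    robustness_sequences: int = 100
    modularity_restarts: int = 10
    min_families: int = 2
    include_motifs: bool = False
    include_nodf_c: bool = False
    include_zscores: bool = True
    seed: int = 0


def _levels_of(net: BipartiteNetwork, tax: TaxonomyTable):
    by_level = {"species": net}
    by_level["genus"] = aggregate(net, tax, "genus")
    by_level["family"] = aggregate(net, tax, "family")
    return by_level


def _binary_values(net: BipartiteNetwork, cfg: PipelineConfig, rng) -> dict[str, float]:
    b = binarize(net)
    q1, med, q3 = bi.normalized_degree_quartiles(b)
    return {
        "connectance": bi.connectance(b),
        "NODF": bi.nodf(b),
        "BR": float(bi.discrepancy(b)),
        "SR_Bin": bi.spectral_radius(b),
        "robustness": bi.robustness(b, n_sequences=cfg.robustness_sequences, seed=rng),
        "ND_Q1": q1,
        "ND_median": med,
        "ND_Q3": q3,
    }


def _weighted_values(net: BipartiteNetwork, cfg: PipelineConfig, rng) -> dict[str, float]:
    return {
        "WNODF": wi.wnodf(net),
        "SR_Qua": bi.spectral_radius(net),
        "modularity": wi.modularity_dirtlpawb(
            net, n_restarts=cfg.modularity_restarts, seed=rng
        ).Q,
    }


def build_index_table(
    networks: list[tuple[BipartiteNetwork, TaxonomyTable]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Long-form (network, level, index, value) table across all resolutions.

    Binary indices are computed for every network (weighted ones are
    binarized first); WNODF, SR_Qua and modularity only for weighted
    networks.  A failing index yields a logged NaN instead of aborting.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for net_idx, (net, tax) in enumerate(networks):
        for level_idx, (level, lnet) in enumerate(_levels_of(net, tax).items()):
            values: dict[str, float] = {}
            rng = np.random.default_rng([cfg.seed, net_idx, level_idx, 1])
            try:
                values.update(_binary_values(lnet, cfg, rng))
            except NetworkError as exc:
                logger.warning("%s/%s binary indices failed: %s", net.name, level, exc)
            if net.weighted:
                try:
                    values.update(_weighted_values(lnet, cfg, rng))
                except NetworkError as exc:
                    logger.warning(
                        "%s/%s weighted indices failed: %s", net.name, level, exc
                    )
            if cfg.include_nodf_c:
                try:
                    values["NODF_c"] = nodf_c(lnet).nodf_c
                except NetworkError as exc:
                    logger.warning("%s/%s NODF_c failed: %s", net.name, level, exc)
            if cfg.include_motifs:
                census = motif_census(binarize(lnet))
                for m in build_catalogue():
                    values[f"motif_f{m.motif_id}"] = census.frequencies[m.motif_id]
            for index_name, value in values.items():
                rows.append(
                    {
                        "network": net.name,
                        "level": level,
                        "index": index_name,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["network", "level", "index", "value"])


def build_zscore_table(
    networks: list[tuple[BipartiteNetwork, TaxonomyTable]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Z-scores of the nestedness indices under their paired null models.

    NODF, BR and SR_Bin are standardized under the binary DD model for all
    networks; WNODF and SR_Qua under both RTCA and r2dtable for weighted
    networks.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for net_idx, (net, tax) in enumerate(networks):
        for level_idx, (level, lnet) in enumerate(_levels_of(net, tax).items()):
            plans = [("NODF", "DD"), ("BR", "DD"), ("SR_Bin", "DD")]
            if net.weighted:
                plans += [
                    (idx, nm)
                    for idx in ("WNODF", "SR_Qua")
                    for nm in INDEX_NULL_PAIRING[idx]
                ]
            for plan_idx, (index_name, null_model) in enumerate(plans):
                target = binarize(lnet) if null_model == "DD" else lnet
                rng = np.random.default_rng(
                    [cfg.seed, net_idx, level_idx, 2, plan_idx]
                )
                try:
                    ens = null_ensemble(
                        target, index_name, null_model, n_null=cfg.n_null, seed=rng
                    )
                except NetworkError as exc:
                    logger.warning(
                        "%s/%s %s (%s) z-score failed: %s",
                        net.name, level, index_name, null_model, exc,
                    )
                    continue
                nulls = np.asarray(ens.null_values)
                rows.append(
                    {
                        "network": net.name,
                        "level": level,
                        "index": index_name,
                        "null_model": null_model,
                        "observed": ens.observed_value,
                        "null_mean": float(nulls.mean()),
                        "null_sd": float(nulls.std(ddof=1)),
                        "z": ens.z_score,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "network", "level", "index", "null_model",
            "observed", "null_mean", "null_sd", "z",
        ],
    )


# ---------------------------------------------------------------------------
# statistics


def anova_levels(values: pd.DataFrame) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of a value across the three levels.

    ``values`` must hold columns ``network``, ``level``, ``value`` with the
    same networks at every level.  Returns (F, df1, df2, p) with df1 = 2
    and df2 = 3n - 3.
    """
    groups = _paired_level_matrix(values)
    n = groups.shape[0]
    if n < 2:
        raise NetworkError("ANOVA needs at least 2 networks")
    f, p = sps.f_oneway(*(groups[:, i] for i in range(3)))
    return float(f), 2, 3 * n - 3, float(p)


def _paired_level_matrix(values: pd.DataFrame) -> np.ndarray:
    wide = values.pivot(index="network", columns="level", values="value")
    missing = [lvl for lvl in ("species", "genus", "family") if lvl not in wide]
    if missing:
        raise NetworkError(f"missing levels: {missing}")
    wide = wide[["species", "genus", "family"]].dropna()
    if wide.empty:
        raise NetworkError("no network has values at all three levels")
    return wide.to_numpy()


def posthoc_paired(values: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between levels with Bonferroni correction (m = 3).

    Comparisons with zero-variance differences are flagged degenerate and
    carry NaN statistics instead of raising.
    """
    groups = _paired_level_matrix(values)
    cols = {"species": 0, "genus": 1, "family": 2}
    rows = []
    for a, b in LEVEL_PAIRS:
        diff = groups[:, cols[a]] - groups[:, cols[b]]
        degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
        if degenerate:
            t = p_raw = p_adj = float("nan")
        else:
            t, p_raw = sps.ttest_rel(groups[:, cols[a]], groups[:, cols[b]])
            p_adj = min(1.0, 3.0 * float(p_raw))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": float(p_adj),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def spearman_levels(values_a, values_b) -> tuple[float, float]:
    """Spearman rank correlation with ties averaged; asymptotic p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise NetworkError("spearman needs two equal-length vectors")
    if a.size < 3:
        raise NetworkError("spearman needs at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise NetworkError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


@dataclass
class ComparisonReport:
    """ANOVA, post hoc, and rank-correlation results per index."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame
    spearman: pd.DataFrame
    index_table: pd.DataFrame = field(repr=False, default=None)
    zscore_table: pd.DataFrame = field(repr=False, default=None)


def _compare(values: pd.DataFrame, measure: str, index_name: str,
             null_model: str, anova_rows, posthoc_rows, spearman_rows) -> None:
    base = {"measure": measure, "index": index_name, "null_model": null_model}
    try:
        f, df1, df2, p = anova_levels(values)
    except NetworkError as exc:
        logger.warning("ANOVA skipped for %s %s: %s", measure, index_name, exc)
        return
    n_used = (df2 + 3) // 3
    anova_rows.append({**base, "F": f, "df1": df1, "df2": df2, "p": p,
                       "n_networks": n_used})
    ph = posthoc_paired(values)
    for _, row in ph.iterrows():
        posthoc_rows.append({**base, **row.to_dict()})
    wide = values.pivot(index="network", columns="level", values="value").dropna()
    for a, b in LEVEL_PAIRS:
        try:
            rho, p_rho = spearman_levels(wide[a], wide[b])
        except NetworkError as exc:
            logger.warning("Spearman skipped for %s %s-%s: %s",
                           index_name, a, b, exc)
            continue
        spearman_rows.append(
            {**base, "level_a": a, "level_b": b, "rho": rho, "p": p_rho}
        )


def compare_levels(
    index_table: pd.DataFrame, zscore_table: pd.DataFrame | None = None
) -> ComparisonReport:
    """Run ANOVA, post hoc and Spearman analyses over an index table."""
    anova_rows: list[dict] = []
    posthoc_rows: list[dict] = []
    spearman_rows: list[dict] = []
    for index_name, sub in index_table.groupby("index", sort=True):
        _compare(sub, "value", index_name, "", anova_rows, posthoc_rows,
                 spearman_rows)
    if zscore_table is not None and not zscore_table.empty:
        for (index_name, null_model), sub in zscore_table.groupby(
            ["index", "null_model"], sort=True
        ):
            zvals = sub.rename(columns={"z": "value"})[
                ["network", "level", "value"]
            ]
            _compare(zvals, "zscore", index_name, null_model, anova_rows,
                     posthoc_rows, spearman_rows)
    return ComparisonReport(
        anova=pd.DataFrame(anova_rows),
        posthoc=pd.DataFrame(posthoc_rows),
        spearman=pd.DataFrame(spearman_rows),
        index_table=index_table,
        zscore_table=zscore_table,
    )


# ---------------------------------------------------------------------------
# orchestration


def prepare_networks(
    raw: list[tuple[BipartiteNetwork, TaxonomyTable]], min_families: int = 2
) -> list[tuple[BipartiteNetwork, TaxonomyTable]]:
    """Apply the study's resolution filters to species-level networks."""
    kept = []
    for net, tax in raw:
        try:
            filtered = filter_species_resolved(net, tax)
        except NetworkError as exc:
            logger.warning("dropping %s: %s", net.name, exc)
            continue
        if not check_multifamily(filtered, tax, min_families=min_families):
            logger.warning("dropping %s: fewer than %d families in a guild",
                           net.name, min_families)
            continue
        kept.append((filtered, tax))
    return kept


def run_pipeline(
    config: dict, out_dir: str | Path | None = None
) -> ComparisonReport:
    """Execute the full comparison study from a config mapping.

    The config either carries a ``synthetic`` block (GeneratorConfig
    fields) or ``matrices``/``taxonomy`` file paths, plus any
    PipelineConfig field at the top level.  When ``out_dir`` is given the
    long-form CSV outputs and a run log are written there.  Identical
    config and seed give byte-identical outputs.
    """
    from .network import read_matrix, read_taxonomy

    pipe_fields = PipelineConfig.__dataclass_fields__
    cfg = PipelineConfig(**{k: v for k, v in config.items() if k in pipe_fields})

    if "synthetic" in config:
        gen_cfg = GeneratorConfig(**config["synthetic"])
        raw = generate_study(gen_cfg)
    elif "matrices" in config:
        tax = read_taxonomy(config["taxonomy"])
        raw = [
            (read_matrix(path, name=Path(path).stem), tax)
            for path in config["matrices"]
        ]
    else:
        raise NetworkError("config needs a 'synthetic' block or 'matrices' list")

    networks = prepare_networks(raw, min_families=cfg.min_families)
    index_table = build_index_table(networks, cfg)
    zscore_table = (
        build_zscore_table(networks, cfg) if cfg.include_zscores else pd.DataFrame()
    )
    report = compare_levels(index_table, zscore_table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index_table.to_csv(out / "indices.csv", index=False)
        zscore_table.to_csv(out / "zscores.csv", index=False)
        report.anova.to_csv(out / "anova.csv", index=False)
        report.posthoc.to_csv(out / "posthoc.csv", index=False)
        report.spearman.to_csv(out / "spearman.csv", index=False)
        with open(out / "run.log", "w") as fh:
            fh.write(
                f"networks analyzed: {len(networks)}\n"
                f"weighted: {sum(1 for n, _ in networks if n.weighted)}\n"
                f"pipeline config: {cfg}\n"
            )
    return report
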