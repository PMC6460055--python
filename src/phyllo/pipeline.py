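"""End-to-end orchestration of the community + black-carbon analysis.

The pipeline mirrors the study's analysis order: rarefy to the minimum
depth → check Good's coverage → alpha diversity with Kruskal–Wallis /
pairwise Wilcoxon comparisons between sites per year → remove singletons →
collapse to genus and extract the persistent core → Bray-Curtis → PCoA →
PERMANOVA (year omnibus, year-blocked site test, per-year pairwise with
FDR) → LDA effect-size screen (urban vs rural, years as subclasses) → and,
when stacks are given, black-carbon quantification with the Kruskal–Wallis
/ Wilcoxon group comparison.

Every stage seed derives from the single config seed and is recorded in
the run manifest, making reruns byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bc import compare_bc_groups, quantify_stack
from .containers import URBAN_SITES, ASVTable, ValidationError
from .core import PersistenceRule, collapse_to_genus, persistent_genera, shared_core
from .diversity import (
    alpha_table,
    bh_adjust,
    bray_curtis,
    goods_coverage,
    kruskal_wallis,
    pairwise_permanova,
    pcoa,
    permanova,
    rarefy,
    remove_singletons,
    wilcoxon_rank_sum,
)
from .lefse import build_clade_table, lefse_screen

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "land_use_of"]


def land_use_of(site: str) -> str:
    """Collapse the three sites into the urban/rural class contrast."""
    return "urban" if site in URBAN_SITES else "rural"


@dataclass
class PipelineConfig:
    """Paths, per-stage parameters, and the global seed."""

    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    stack_paths: list[str] = field(default_factory=list)
    stack_locations: list[str] = field(default_factory=list)
    output_dir: str = "phyllo_out"

    rarefaction_depth: int | str = "min"
    threshold_frac: float = 0.0128
    connectivity: int = 8
    pixel_xy_um: float = 1.8
    z_step_um: float = 6.6
    bit_depth: int = 8
    n_permutations: int = 999
    min_occupancy_frac: float = 0.75
    alpha: float = 0.05
    lda_min: float = 2.0
    n_boot: int = 30
    seed: int = 0


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's outputs."""

    rarefied: ASVTable
    coverage: pd.Series
    alpha: pd.DataFrame
    alpha_tests: pd.DataFrame
    filtered: ASVTable
    core: object
    distance: object
    ordination: object
    permanova_report: pd.DataFrame
    pairwise_report: pd.DataFrame
    enrichment: list
    bc_metrics: pd.DataFrame | None
    bc_comparison: dict | None
    manifest: dict


def _alpha_site_tests(alpha_df: pd.DataFrame, alpha_level: float) -> pd.DataFrame:
    """Kruskal–Wallis across sites per (year, metric), then pairwise Wilcoxon."""
    rows = []
    metrics = [c for c in ("observed", "shannon", "simpson", "faith_pd") if c in alpha_df]
    for year in sorted(alpha_df["year"].unique()):
        sub = alpha_df[alpha_df["year"] == year]
        sites = sorted(sub["site"].unique())
        for metric in metrics:
            groups = [sub.loc[sub["site"] == s, metric].to_numpy() for s in sites]
            H, p = kruskal_wallis(groups)
            rows.append(
                {"year": year, "metric": metric, "test": "kruskal-wallis",
                 "group_a": "all", "group_b": "all", "statistic": H, "p_value": p,
                 "p_adjusted": np.nan}
            )
            raw, pairs = [], []
            for i in range(len(sites)):
                for j in range(i + 1, len(sites)):
                    _, pw = wilcoxon_rank_sum(groups[i], groups[j])
                    raw.append(pw)
                    pairs.append((sites[i], sites[j]))
            for (a, b), pr, pa in zip(pairs, raw, bh_adjust(raw)):
                rows.append(
                    {"year": year, "metric": metric, "test": "wilcoxon",
                     "group_a": a, "group_b": b, "statistic": np.nan,
                     "p_value": pr, "p_adjusted": pa}
                )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: PipelineConfig,
    table: ASVTable | None = None,
    taxonomy: pd.Series | None = None,
    tree=None,
    stacks=None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage; inputs come from ``cfg`` paths unless given in memory."""
    if table is None:
        if cfg.table_path is None or cfg.metadata_path is None:
            raise ValidationError("need a count table and metadata (paths or objects)")
        table = pio.load_asv_table(cfg.table_path, cfg.metadata_path)
    if taxonomy is None and cfg.taxonomy_path:
        taxonomy = pio.read_taxonomy(cfg.taxonomy_path)
    if taxonomy is None:
        raise ValidationError("a taxonomy map is required")
    if tree is None and cfg.tree_path:
        tree = pio.read_newick(cfg.tree_path)
    if stacks is None and cfg.stack_paths:
        stacks = [
            pio.read_stack(p, cfg.pixel_xy_um, cfg.z_step_um, cfg.bit_depth)
            for p in cfg.stack_paths
        ]

    seeds = {
        "rarefaction": cfg.seed,
        "permanova_year": cfg.seed + 1,
        "permanova_site_blocked": cfg.seed + 2,
        "pairwise": cfg.seed + 3,
        "lefse": cfg.seed + 4,
    }

    # 1. rarefy + coverage
    rarefied = rarefy(table, cfg.rarefaction_depth, seed=seeds["rarefaction"])
    coverage = pd.Series(
        {s: goods_coverage(rarefied.counts.loc[s].to_numpy()) for s in rarefied.sample_ids},
        name="goods_coverage",
    )

    # 2. alpha diversity on the rarefied table, compared between sites
    alpha_df = alpha_table(rarefied, tree=tree)
    alpha_tests = _alpha_site_tests(alpha_df, cfg.alpha)

    # 3. singleton removal for all following analysis
    filtered = remove_singletons(rarefied)

    # 4. genus collapse + persistent core
    genus_table, genus_map = collapse_to_genus(filtered, taxonomy)
    rule = PersistenceRule(min_occupancy_frac=cfg.min_occupancy_frac)
    sites = list(pd.unique(genus_table.metadata["site"]))
    per_site = {s: persistent_genera(genus_table, s, rule) for s in sites}
    core = shared_core(per_site, genus_table, genus_map)

    # 5. beta diversity, ordination, PERMANOVA
    dm = bray_curtis(filtered)
    ordination = pcoa(dm)
    meta = filtered.metadata
    perm_rows = []
    res_year = permanova(
        dm, meta["year"].astype(str), cfg.n_permutations, seed=seeds["permanova_year"]
    )
    perm_rows.append({"effect": "year", "scope": "all", **asdict(res_year)})
    res_site = permanova(
        dm, meta["site"], cfg.n_permutations,
        seed=seeds["permanova_site_blocked"], strata=meta["year"].astype(str),
    )
    perm_rows.append({"effect": "site (year-blocked)", "scope": "all", **asdict(res_site)})

    pairwise_frames = []
    for k, year in enumerate(sorted(meta["year"].unique())):
        ids = meta.index[meta["year"] == year]
        sub = dm.filter(list(ids))
        pw = pairwise_permanova(
            sub, meta.loc[ids, "site"], cfg.n_permutations, seed=seeds["pairwise"] + k
        )
        pw.insert(0, "year", year)
        pairwise_frames.append(pw)
        res_y = permanova(
            sub, meta.loc[ids, "site"], cfg.n_permutations, seed=seeds["pairwise"] + 50 + k
        )
        perm_rows.append({"effect": "site", "scope": f"year {year}", **asdict(res_y)})
    permanova_report = pd.DataFrame(perm_rows)
    pairwise_report = pd.concat(pairwise_frames, ignore_index=True)

    # 6. enrichment screen: urban vs rural with years as subclasses
    classes = meta["site"].map(land_use_of)
    cft = build_clade_table(filtered, taxonomy, classes, meta["year"])
    enrichment = lefse_screen(
        cft, alpha=cfg.alpha, lda_min=cfg.lda_min, n_boot=cfg.n_boot, seed=seeds["lefse"]
    )

    # 7. black-carbon quantification, if stacks provided
    bc_df = None
    bc_cmp = None
    if stacks:
        locations = cfg.stack_locations or [f"stack{i}" for i in range(len(stacks))]
        recs = []
        for i, (st, loc) in enumerate(zip(stacks, locations)):
            m = quantify_stack(st, cfg.threshold_frac, cfg.connectivity)
            recs.append(
                {"stack_id": f"stack{i:03d}", "location": loc,
                 "n_particles": m.n_particles,
                 "particles_per_mm2": m.particles_per_mm2,
                 "area_covered_percent": m.area_covered_percent}
            )
        bc_df = pd.DataFrame(recs)
        by_loc = {}
        for loc in bc_df["location"].unique():
            sel = bc_df[bc_df["location"] == loc]
            from .bc import BCMetrics

            by_loc[loc] = [
                BCMetrics(int(r.n_particles), r.particles_per_mm2, r.area_covered_percent)
                for r in sel.itertuples()
            ]
        if len(by_loc) >= 2 and all(len(v) >= 2 for v in by_loc.values()):
            bc_cmp = compare_bc_groups(by_loc)

    manifest = {
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            # input/output locations are run-specific, not analysis parameters
            if "path" not in k and k not in ("output_dir", "stack_locations")
        },
        "seeds": seeds,
        "n_samples": table.n_samples,
        "rarefaction_depth": int(rarefied.sample_sums().iloc[0]),
        "n_asvs_after_singleton_removal": len(filtered.asv_ids),
    }

    result = PipelineResult(
        rarefied=rarefied, coverage=coverage, alpha=alpha_df,
        alpha_tests=alpha_tests, filtered=filtered, core=core, distance=dm,
        ordination=ordination, permanova_report=permanova_report,
        pairwise_report=pairwise_report, enrichment=enrichment,
        bc_metrics=bc_df, bc_comparison=bc_cmp, manifest=manifest,
    )
    if write:
        _write_outputs(result, cfg)
    return result


def _alpha_summary(alpha_df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± standard error per site × year for each alpha metric."""
    metrics = [c for c in ("observed", "shannon", "simpson", "faith_pd") if c in alpha_df]
    grouped = alpha_df.groupby(["site", "year"])
    rows = []
    for (site, year), sub in grouped:
        row = {"site": site, "year": year}
        for m in metrics:
            v = sub[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = v.mean()
            row[f"{m}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.coverage.to_frame().round(6).to_csv(out / "coverage.tsv", sep="\t")
    result.alpha.round(6).to_csv(out / "alpha.tsv", sep="\t")
    _alpha_summary(result.alpha).round(6).to_csv(
        out / "alpha_summary.tsv", sep="\t", index=False
    )
    result.alpha_tests.round(4).to_csv(out / "alpha_tests.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.distance.data,
        index=list(result.distance.ids),
        columns=list(result.distance.ids),
    ).round(6).to_csv(out / "bray_curtis.tsv", sep="\t")
    result.ordination.coordinates.round(6).to_csv(out / "pcoa.tsv", sep="\t")
    result.permanova_report.round(4).to_csv(out / "permanova.tsv", sep="\t", index=False)
    result.pairwise_report.round(4).to_csv(
        out / "pairwise_permanova.tsv", sep="\t", index=False
    )
    core = result.core
    with open(out / "core.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "per_site": {s: sorted(v) for s, v in core.per_site.items()},
                "shared": sorted(core.shared),
                "genus_read_fraction": core.genus_read_fraction,
                "shared_read_fraction": core.shared_read_fraction,
                "shared_asv_fraction": core.shared_asv_fraction,
                "pair_exclusive": {
                    f"{a}|{b}": sorted(v) for (a, b), v in core.pair_exclusive.items()
                },
            },
            fh,
            indent=1,
        )
    pd.DataFrame(
        [
            {"feature": r.feature, "enriched_class": r.enriched_class,
             "kw_p": round(r.kw_p, 4), "lda_score": r.lda_score, "kept": r.kept}
            for r in result.enrichment
        ]
    ).to_csv(out / "lefse.tsv", sep="\t", index=False)
    if result.bc_metrics is not None:
        result.bc_metrics.round(6).to_csv(out / "bc_metrics.tsv", sep="\t", index=False)
    if result.bc_comparison is not None:
        with open(out / "bc_comparison.json", "w", encoding="utf-8") as fh:
            json.dump(result.bc_comparison, fh, indent=1)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
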