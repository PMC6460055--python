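"""Persistent core microbiome: occupancy-based genus persistence per site.

A genus belongs to a tree's persistent microbiome when it is observed in at
least 75% of the replicate samples at that site in *every* sampling year —
presence across non-consecutive years is the persistence signal. The core
shared across all sites is the intersection of the per-site persistent
sets, reported together with the fraction of total reads and of ASVs it
accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import ASVTable, ValidationError

__all__ = [
    "PersistenceRule",
    "PersistentCore",
    "split_lineage",
    "genus_of",
    "collapse_to_genus",
    "persistent_genera",
    "shared_core",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def split_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-joined 7-rank lineage into rank → name (no prefix)."""
    parts = [p.strip() for p in lineage.split(";")]
    parts += [""] * (len(RANKS) - len(parts))
    out = {}
    for rank, part in zip(RANKS, parts):
        name = part.split("__", 1)[1] if "__" in part else part
        out[rank] = name
    return out


def genus_of(lineage: str) -> str:
    """Genus bin for a lineage; unassigned genera are binned per family."""
    ranks = split_lineage(lineage)
    if ranks["genus"]:
        return ranks["genus"]
    family = ranks["family"] or "unknown_family"
    return f"unclassified_{family}"


@dataclass
class PersistenceRule:
    """Occupancy rule defining persistence at a site.

    A genus is persistent iff, for every year, it is present (count ≥
    ``presence_threshold``) in at least ``min_occupancy_frac`` of that
    year's replicates. The 75% default is inclusive: 3 of 4 replicates
    qualifies.
    """

    min_occupancy_frac: float = 0.75
    presence_threshold: int = 1
    require_every_year: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_occupancy_frac <= 1.0):
            raise ValidationError("min_occupancy_frac must be in (0, 1]")
        if self.presence_threshold < 1:
            raise ValidationError("presence_threshold must be >= 1")


@dataclass
class PersistentCore:
    """Per-site persistent genus sets, their intersection, and attribution."""

    per_site: dict[str, set[str]]
    shared: set[str]
    genus_read_fraction: dict[str, float]
    shared_read_fraction: float
    shared_asv_fraction: float
    pair_exclusive: dict[tuple[str, str], set[str]] = field(default_factory=dict)


def collapse_to_genus(table: ASVTable, taxonomy: pd.Series):
    """Sum ASV counts into genus bins.

    Returns the genus-level table (same samples/metadata) and the genus →
    member-ASV map. Total reads are conserved exactly.
    """
    missing = [a for a in table.asv_ids if a not in taxonomy.index]
    if missing:
        raise ValidationError("ASVs missing from taxonomy: " + ", ".join(missing))
    genus_map: dict[str, list[str]] = {}
    for asv in table.asv_ids:
        genus_map.setdefault(genus_of(taxonomy.loc[asv]), []).append(asv)
    genus_counts = pd.DataFrame(
        {g: table.counts[asvs].sum(axis=1) for g, asvs in genus_map.items()},
        index=table.counts.index,
    )
    return table.with_counts(genus_counts), genus_map


def persistent_genera(
    genus_table: ASVTable,
    site: str,
    rule: PersistenceRule | None = None,
) -> set[str]:
    """Genera meeting the occupancy rule at ``site`` in every year."""
    rule = rule or PersistenceRule()
    meta = genus_table.metadata
    if site not in set(meta["site"]):
        raise ValidationError(f"unknown site: {site!r}")
    site_meta = meta[meta["site"] == site]
    years = sorted(site_meta["year"].unique())
    persistent: set[str] = set()
    for genus in genus_table.counts.columns:
        ok = True
        for year in years:
            sids = site_meta.index[site_meta["year"] == year]
            present = (
                genus_table.counts.loc[sids, genus] >= rule.presence_threshold
            ).sum()
            frac = present / len(sids)
            if frac < rule.min_occupancy_frac:
                ok = False
                if rule.require_every_year:
                    break
        if ok:
            persistent.add(genus)
    return persistent


def shared_core(
    per_site_sets: dict[str, set[str]],
    genus_table: ASVTable,
    genus_map: dict[str, list[str]],
) -> PersistentCore:
    """Intersect per-site persistent sets and attribute reads and ASVs.

    Read fractions are taken over the same analysis-ready table used for
    the persistence calls; the ASV fraction counts member ASVs of shared
    genera over all ASVs in the genus map. Site-pair exclusive persistents
    (genera shared by exactly one pair of sites beyond the full core) are
    reported as well.
    """
    if len(per_site_sets) < 2:
        raise ValidationError("need at least two sites")
    sites = list(per_site_sets)
    shared = set.intersection(*per_site_sets.values())

    grand_total = float(genus_table.counts.to_numpy().sum())
    genus_reads = genus_table.counts.sum(axis=0)
    genus_read_fraction = {
        g: (float(genus_reads.get(g, 0)) / grand_total if grand_total else 0.0)
        for g in sorted(shared)
    }
    shared_read_fraction = sum(genus_read_fraction.values())

    n_asvs_total = sum(len(v) for v in genus_map.values())
    n_asvs_shared = sum(len(genus_map.get(g, [])) for g in shared)
    shared_asv_fraction = n_asvs_shared / n_asvs_total if n_asvs_total else 0.0

    pair_exclusive: dict[tuple[str, str], set[str]] = {}
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            both = per_site_sets[a] & per_site_sets[b]
            pair_exclusive[(a, b)] = both - shared
    return PersistentCore(
        per_site={s: set(v) for s, v in per_site_sets.items()},
        shared=shared,
        genus_read_fraction=genus_read_fraction,
        shared_read_fraction=shared_read_fraction,
        shared_asv_fraction=shared_asv_fraction,
        pair_exclusive=pair_exclusive,
    )
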