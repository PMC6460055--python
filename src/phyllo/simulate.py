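"""Synthetic data generators for the full pipeline.

Two generators mirror the study design end to end so that every analysis
stage can be exercised and verified without external downloads:

* :func:`gen_zstack` plants spherical, supra-threshold particles into a
  confocal z-stack with the instrument's pixel geometry (1.8 µm in-plane,
  6.6 µm z step, ~25 slices covering a 900 × 900 µm field).
* :func:`gen_asv_table` draws Dirichlet-multinomial 16S count tables over a
  3-site × 2-year × 4-replicate design, with genus-structured taxonomy and
  optional planted site/year log2 fold changes; library depths are drawn
  log-uniformly across the observed 2,907–34,895 read spread.
* :func:`gen_tree` supplies a rooted phylogeny over the ASVs (star or
  random coalescent) for phylogenetic diversity.

Every generator is deterministic given its config seed and returns the
planted truth alongside the data, so recovery tests are exact.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .containers import SITES, URBAN_SITES, ASVTable, GroundTruth, ValidationError

__all__ = [
    "StackConfig",
    "CommunityConfig",
    "PackingError",
    "gen_zstack",
    "gen_asv_table",
    "gen_tree",
    "gen_bc_replicates",
    "urban_site_effects",
]


class PackingError(ValueError):
    """Too many particles requested for the frame: placement is impossible."""


@dataclass
class StackConfig:
    """Geometry and planting parameters for a synthetic z-stack.

    ``particle_intensity_frac`` and ``background_intensity_frac`` are
    fractions of full-scale intensity (``2**bit_depth - 1``). For particle
    recovery to be meaningful the particle fraction must exceed the
    detection threshold (default 1.28% of full scale) and the background
    fraction must stay below it.
    """

    width_px: int = 500
    height_px: int = 500
    n_slices: int = 25
    pixel_xy_um: float = 1.8
    z_step_um: float = 6.6
    bit_depth: int = 8
    n_particles: int = 10
    particle_radius_px: int = 2
    particle_intensity_frac: float = 0.8
    background_intensity_frac: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_slices) < 1:
            raise ValidationError("stack dimensions must be positive")
        if self.n_particles < 0:
            raise ValidationError("n_particles must be non-negative")
        if self.particle_radius_px < 1:
            raise ValidationError("particle radius must be a positive pixel count")
        if not (0.0 < self.particle_intensity_frac <= 1.0):
            raise ValidationError("particle_intensity_frac must be in (0, 1]")
        if not (0.0 <= self.background_intensity_frac < 1.0):
            raise ValidationError("background_intensity_frac must be in [0, 1)")
        if self.background_intensity_frac >= self.particle_intensity_frac:
            raise ValidationError("background must be dimmer than particles")
        if self.pixel_xy_um <= 0 or self.z_step_um <= 0:
            raise ValidationError("pixel geometry must be positive")


def _place_centers(cfg: StackConfig, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Rejection-sample (row, col) centres keeping discs ≥2 px apart."""
    r = cfg.particle_radius_px
    margin = r + 1
    if cfg.height_px - 2 * margin < 0 or cfg.width_px - 2 * margin < 0:
        raise PackingError("frame too small for even one particle at this radius")
    # centre separation 2r+3 guarantees at least 2 background px between discs
    min_d2 = (2 * r + 3) ** 2
    centers: list[tuple[int, int]] = []
    max_tries = 200 * max(cfg.n_particles, 1)
    tries = 0
    while len(centers) < cfg.n_particles:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {cfg.n_particles} particles of radius {r} px "
                f"in a {cfg.height_px}x{cfg.width_px} frame"
            )
        tries += 1
        y = int(rng.integers(margin, cfg.height_px - margin))
        x = int(rng.integers(margin, cfg.width_px - margin))
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_d2 for cy, cx in centers):
            centers.append((y, x))
    return centers


def gen_zstack(cfg: StackConfig):
    """Generate a z-stack with ``cfg.n_particles`` planted spherical particles.

    Particles are spheres in physical coordinates: in slice ``s`` a particle
    centred at slice ``zc`` appears as a disc of radius
    ``sqrt(r^2 - ((s - zc) * z_step/pixel_xy)^2)`` pixels, so with the
    default anisotropic geometry a small particle intersects a single slice
    — the maximum projection must still pick it up. Background voxels are
    uniform noise strictly below ``background_intensity_frac`` of full scale.

    Returns
    -------
    (ZStack, GroundTruth)
        The stack and the planted particle centres (slice, row, col).
    """
    from .containers import ZStack  # local import to avoid cycle in type tools

    rng = np.random.default_rng(cfg.seed)
    full_scale = 2**cfg.bit_depth - 1
    bg_max = int(np.floor(cfg.background_intensity_frac * full_scale))
    fg_val = int(round(cfg.particle_intensity_frac * full_scale))

    vol = rng.integers(
        0, bg_max + 1, size=(cfg.n_slices, cfg.height_px, cfg.width_px)
    ).astype(np.uint16 if cfg.bit_depth > 8 else np.uint8)

    centers_yx = _place_centers(cfg, rng)
    r = cfg.particle_radius_px
    z_aspect = cfg.z_step_um / cfg.pixel_xy_um
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    centers: list[tuple[int, int, int]] = []
    for cy, cx in centers_yx:
        zc = int(rng.integers(0, cfg.n_slices))
        centers.append((zc, cy, cx))
        for s in range(cfg.n_slices):
            dz_px = (s - zc) * z_aspect
            r2 = r * r - dz_px * dz_px
            if r2 < 0:
                continue
            disc = (yy * yy + xx * xx) <= r2
            sl = vol[s, cy - r : cy + r + 1, cx - r : cx + r + 1]
            sl[disc] = fg_val

    stack = ZStack(
        intensities=vol,
        pixel_xy_um=cfg.pixel_xy_um,
        z_step_um=cfg.z_step_um,
        bit_depth=cfg.bit_depth,
    )
    truth = GroundTruth(
        particle_centers=centers,
        particle_radius_px=r,
        particle_intensity=fg_val,
    )
    return stack, truth


def gen_bc_replicates(
    mean_particles_by_location: dict[str, float],
    stacks_per_biopsy: int = 3,
    biopsies_per_leaf: int = 3,
    leaves_per_location: int = 2,
    template: StackConfig | None = None,
    seed: int = 0,
):
    """Generate the leaf-sampling design of z-stacks per location.

    Three stacks per tissue biopsy, three biopsies per leaf and two leaves
    per location give 18 technical replicates per location by default.
    Per-stack particle counts are Poisson around the location mean, so
    locations with dirtier air carry proportionally more particles.

    Returns
    -------
    dict mapping location → list of (ZStack, GroundTruth).
    """
    template = template or StackConfig()
    n_per_loc = stacks_per_biopsy * biopsies_per_leaf * leaves_per_location
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for loc, mean in mean_particles_by_location.items():
        stacks = []
        for k in range(n_per_loc):
            n = int(rng.poisson(mean))
            cfg = StackConfig(
                width_px=template.width_px,
                height_px=template.height_px,
                n_slices=template.n_slices,
                pixel_xy_um=template.pixel_xy_um,
                z_step_um=template.z_step_um,
                bit_depth=template.bit_depth,
                n_particles=n,
                particle_radius_px=template.particle_radius_px,
                particle_intensity_frac=template.particle_intensity_frac,
                background_intensity_frac=template.background_intensity_frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            stacks.append(gen_zstack(cfg))
        out[loc] = stacks
    return out


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

_PHYLA = (
    "Proteobacteria",
    "Deinococcus-Thermus",
    "Actinobacteria",
    "Firmicutes",
    "Bacteroidetes",
)


@dataclass
class CommunityConfig:
    """Design and noise parameters for the synthetic 16S count table.

    Genus base abundances are lognormal with shape ``abundance_sigma``
    (default 2.0): a handful of dominant genera plus a long tail of rare
    ones, so occupancy-based persistence is a real filter rather than a
    tautology. ``base_concentration`` is the Dirichlet prior: a scalar broadcasts to a
    mean per-taxon prior count (so the total concentration is 50 × S by
    default), while a vector of length n_genera × asvs_per_genus is used as
    the per-ASV prior directly (its normalisation then defines the base
    proportions). Per-sample compositions are drawn
    ``Dirichlet(alpha * exp2(effects))`` and counts
    ``Multinomial(depth, composition)`` — overdispersed relative to a plain
    multinomial, as amplicon replicates are. Depths are log-uniform over
    ``depth_range`` to emulate the heavy right skew of real libraries.
    """

    n_sites: int = 3
    n_years: int = 2
    n_replicates: int = 4
    n_genera: int = 60
    asvs_per_genus: int = 5
    abundance_sigma: float = 2.0
    base_concentration: float = 50.0
    site_effect_log2: dict[str, dict[str, float]] = field(default_factory=dict)
    year_effect_log2: dict[str, dict[int, float]] = field(default_factory=dict)
    depth_range: tuple[int, int] = (2907, 34895)
    seed: int = 0

    sites: tuple[str, ...] = SITES
    years: tuple[int, ...] = (2014, 2016)

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_years < 1 or self.n_replicates < 1:
            raise ValidationError("design dimensions must be positive")
        if self.n_genera < 1 or self.asvs_per_genus < 1:
            raise ValidationError("taxon counts must be positive")
        if np.any(np.asarray(self.base_concentration) <= 0):
            raise ValidationError("Dirichlet concentration must be positive")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValidationError("depth_range must satisfy 1 <= min <= max")
        self.sites = tuple(self.sites[: self.n_sites])
        self.years = tuple(self.years[: self.n_years])

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.n_years * self.n_replicates

    def genus_ids(self) -> list[str]:
        width = len(str(self.n_genera))
        return [f"Genus{g + 1:0{width}d}" for g in range(self.n_genera)]


def urban_site_effects(
    genera: list[str],
    magnitude: float = 1.5,
    n_up: int = 5,
    n_down: int = 5,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Plant ±``magnitude`` log2 fold changes at both urban sites.

    ``n_up`` genera are enriched and ``n_down`` depleted at the Inner-city
    and Intersection sites relative to Rural; the affected genera are drawn
    at random from ``genera`` with the given seed.
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genera), size=n_up + n_down, replace=False)
    effects: dict[str, dict[str, float]] = {}
    for k, idx in enumerate(chosen):
        sign = 1.0 if k < n_up else -1.0
        effects[genera[idx]] = {site: sign * magnitude for site in URBAN_SITES}
    return effects


def _lineage(genus: str, phylum: str) -> str:
    stem = phylum.replace("-", "")
    return (
        f"d__Bacteria;p__{phylum};c__{stem}ia;o__{stem}ales;"
        f"f__{stem}aceae_{genus[-2:]};g__{genus};s__"
    )


def gen_asv_table(cfg: CommunityConfig):
    """Draw a synthetic ASV count table over the full sampling design.

    Returns
    -------
    (ASVTable, pandas.Series, GroundTruth)
        The count table with attached metadata, the ASV → 7-rank lineage
        taxonomy map, and the ground truth (true per-sample proportions,
        planted effects, drawn depths).
    """
    rng = np.random.default_rng(cfg.seed)
    genera = cfg.genus_ids()
    n_asvs = cfg.n_genera * cfg.asvs_per_genus
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n_asvs)]
    asv_genus = np.repeat(np.arange(cfg.n_genera), cfg.asvs_per_genus)

    # genus-level base proportions: lognormal abundances give the realistic
    # few-dominant / long-tail shape; ASV shares within a genus likewise
    genus_base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_genera)
    genus_base /= genus_base.sum()
    asv_share = rng.lognormal(mean=0.0, sigma=0.7, size=n_asvs)
    for g in range(cfg.n_genera):
        sel = asv_genus == g
        asv_share[sel] /= asv_share[sel].sum()

    conc = np.asarray(cfg.base_concentration, dtype=float)
    if conc.ndim == 0:
        # scalar: mean per-ASV prior count, i.e. total concentration conc * S
        total_concentration = float(conc) * n_asvs
        base_alpha = None
    else:
        if conc.shape != (n_asvs,):
            raise ValidationError(
                f"base_concentration vector must have length {n_asvs}"
            )
        base_alpha = conc
        total_concentration = float(conc.sum())

    taxonomy = pd.Series(
        {
            asv: _lineage(genera[g], _PHYLA[g % len(_PHYLA)])
            for asv, g in zip(asv_ids, asv_genus)
        },
        name="lineage",
    )
    taxonomy.index.name = "asv_id"

    lo, hi = cfg.depth_range
    rows, meta_rows, props = [], [], []
    sample_ids = []
    for site in cfg.sites:
        for year in cfg.years:
            for rep in range(1, cfg.n_replicates + 1):
                lfc = np.zeros(cfg.n_genera)
                for gi, genus in enumerate(genera):
                    lfc[gi] += cfg.site_effect_log2.get(genus, {}).get(site, 0.0)
                    lfc[gi] += cfg.year_effect_log2.get(genus, {}).get(year, 0.0)
                if base_alpha is None:
                    genus_p = genus_base * np.exp2(lfc)
                    genus_p /= genus_p.sum()
                    p = genus_p[asv_genus] * asv_share
                else:
                    p = base_alpha / base_alpha.sum() * np.exp2(lfc[asv_genus])
                p /= p.sum()

                depth = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
                depth = min(max(depth, lo), hi)
                comp = rng.dirichlet(total_concentration * p)
                counts = rng.multinomial(depth, comp)

                sid = f"{site}_{year}_{rep}"
                sample_ids.append(sid)
                rows.append(counts)
                props.append(p)
                meta_rows.append((site, year, rep))

    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=sample_ids, columns=asv_ids
    )
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(
        meta_rows, index=sample_ids, columns=["site", "year", "replicate"]
    )
    metadata.index.name = "sample_id"
    table = ASVTable(counts=counts, metadata=metadata)
    truth = GroundTruth(
        true_proportions=pd.DataFrame(props, index=sample_ids, columns=asv_ids),
        site_effect_log2=cfg.site_effect_log2,
        year_effect_log2=cfg.year_effect_log2,
        depths=counts.sum(axis=1),
    )
    return table, taxonomy, truth


def gen_tree(taxa: list[str], mode: str = "star", seed: int = 0) -> TreeNode:
    """Build a rooted tree with positive branch lengths over ``taxa``.

    ``star`` attaches every tip to the root with unit branches (Faith's PD
    of k observed tips is then exactly k). ``random-coalescent`` simulates a
    Kingman coalescent genealogy, giving a realistic ultrametric tree.
    """
    if not taxa:
        raise ValidationError("taxa must be non-empty")
    if len(set(taxa)) != len(taxa):
        raise ValidationError("duplicate taxa in tree request")
    if mode == "star":
        newick = "(" + ",".join(f"{t}:1.0" for t in taxa) + ");"
        return TreeNode.read(io.StringIO(newick))
    if mode == "random-coalescent":
        tns = dendropy.TaxonNamespace(list(taxa))
        dtree = treesim.pure_kingman_tree(
            taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
        )
        newick = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        tree = TreeNode.read(io.StringIO(newick))
        # guard against zero-length edges from the simulator's float output
        for node in tree.traverse(include_self=False):
            if node.length is None or node.length <= 0:
                node.length = 1e-9
        return tree
    raise ValueError(f"unknown tree mode: {mode!r}")
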