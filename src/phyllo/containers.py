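"""Core in-memory containers shared across the pipeline.

The community-analysis substrate is :class:`ASVTable` — a samples × ASVs
count matrix with aligned per-sample metadata (site, year, replicate).
Imaging data travels as :class:`ZStack`, a 3-D intensity volume plus the
physical pixel geometry needed to convert pixel counts into leaf area.
Dissimilarities use :class:`skbio.DistanceMatrix` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITES = ("Rural", "Inner-city", "Intersection")
URBAN_SITES = ("Inner-city", "Intersection")

#: metadata columns every ASVTable must carry
METADATA_COLUMNS = ("site", "year", "replicate")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class ZStack:
    """A confocal z-stack: intensities indexed (slice, row, col).

    Parameters
    ----------
    intensities
        3-D array of non-negative integers, one 2-D image per z slice.
    pixel_xy_um
        In-plane pixel edge length in micrometres.
    z_step_um
        Distance between consecutive slices in micrometres.
    bit_depth
        Detector bit depth; intensities must fit in ``2**bit_depth - 1``.
    """

    intensities: np.ndarray
    pixel_xy_um: float = 1.8
    z_step_um: float = 6.6
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise ValidationError("z-stack must be 3-D with at least one slice")
        if self.pixel_xy_um <= 0 or self.z_step_um <= 0:
            raise ValidationError("pixel geometry must be positive")
        if self.intensities.size and (
            self.intensities.min() < 0
            or self.intensities.max() > 2**self.bit_depth - 1
        ):
            raise ValidationError(
                f"intensities must lie in [0, 2^{self.bit_depth} - 1]"
            )

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ASVTable:
    """Samples × ASVs count matrix with per-sample metadata.

    ``counts`` is a DataFrame indexed by sample id with ASV ids as columns;
    ``metadata`` is indexed by the same sample ids and carries at least the
    ``site``, ``year`` and ``replicate`` design columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate ASV ids in count table")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(
                "metadata missing for samples: " + ", ".join(map(str, missing))
            )
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValidationError("negative counts")
        # keep metadata aligned to the count-table row order
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def with_counts(self, counts: pd.DataFrame) -> "ASVTable":
        """Return a new table with the same metadata and new counts."""
        return ASVTable(counts=counts, metadata=self.metadata.copy())

    def subset(self, sample_ids) -> "ASVTable":
        ids = list(sample_ids)
        return ASVTable(
            counts=self.counts.loc[ids].copy(),
            metadata=self.metadata.loc[ids].copy(),
        )


@dataclass
class GroundTruth:
    """Planted parameters emitted by the synthetic generators.

    Image case: particle centres/radius/intensity. Community case: the true
    per-sample relative-abundance vectors, the planted effect maps and drawn
    depths. Sufficient to recompute every planted quantity from config+seed.
    """

    particle_centers: list[tuple[int, int, int]] = field(default_factory=list)
    particle_radius_px: int = 0
    particle_intensity: int = 0
    true_proportions: pd.DataFrame | None = None
    site_effect_log2: dict | None = None
    year_effect_log2: dict | None = None
    depths: pd.Series | None = None

    def to_jsonable(self) -> dict:
        out: dict = {}
        if self.particle_centers:
            out["particle_centers"] = [list(map(int, c)) for c in self.particle_centers]
            out["particle_radius_px"] = int(self.particle_radius_px)
            out["particle_intensity"] = int(self.particle_intensity)
        if self.true_proportions is not None:
            out["true_proportions"] = {
                s: self.true_proportions.loc[s].tolist()
                for s in self.true_proportions.index
            }
            out["asv_ids"] = list(self.true_proportions.columns)
        if self.site_effect_log2 is not None:
            out["site_effect_log2"] = self.site_effect_log2
        if self.year_effect_log2 is not None:
            out["year_effect_log2"] = self.year_effect_log2
        if self.depths is not None:
            out["depths"] = {s: int(d) for s, d in self.depths.items()}
        return out
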