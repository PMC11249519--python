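"""Core domain types shared by every pipeline stage.

All genomic intervals are 0-based half-open internally (BED convention on
disk).  A *region* is the unit of methylation analysis: the interval between
two adjacent MspI (CCGG) cut points.  A *fragment* is one sequenced DNA
molecule summarised by its CpG count and methylated-CpG count; its alpha
value is the fraction of methylated CpGs on the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABELS = ("LUAD", "LUSC", "noncancer")
MATERIALS = ("tissue", "plasma")
DIRECTIONS = ("hypo", "hyper")
TARGET_CLASSES = ("LUAD", "LUSC")

#: Columns of the per-fragment table held by :class:`SampleFragments`.
FRAGMENT_COLUMNS = ("region_id", "n_cpgs", "n_methylated")


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class Region:
    """A genomic interval delimited by two adjacent MspI cut points."""

    chrom: str
    start: int
    end: int
    region_id: str
    n_cpgs: int | None = None
    contains_n: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.region_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.n_cpgs is not None and self.n_cpgs < 0:
            raise ValidationError(f"region {self.region_id!r}: n_cpgs < 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    """One sequenced molecule: CpG count and methylated-CpG count."""

    region_id: str
    n_cpgs: int
    n_methylated: int

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValidationError("fragment must carry at least one CpG")
        if not 0 <= self.n_methylated <= self.n_cpgs:
            raise ValidationError(
                f"n_methylated ({self.n_methylated}) outside "
                f"[0, n_cpgs={self.n_cpgs}]"
            )

    @property
    def alpha(self) -> float:
        return self.n_methylated / self.n_cpgs


@dataclass
class SampleFragments:
    """One donor's fragment collection plus its normalisation denominator.

    ``total_fragments`` is the genome-wide deduplicated mapped-fragment
    count; it can exceed the number of stored (region-mapped) fragments and
    is kept explicit because it is the depth-normalisation denominator.
    """

    sample_id: str
    label: str
    material: str
    total_fragments: int
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.material not in MATERIALS:
            raise ValidationError(f"unknown material {self.material!r}")
        if self.total_fragments <= 0:
            raise ValidationError("total_fragments must be positive")
        missing = set(FRAGMENT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"fragment frame missing columns {missing}")
        if self.total_fragments < len(self.frame):
            raise ValidationError(
                "total_fragments smaller than stored fragment count"
            )
        n_cpgs = self.frame["n_cpgs"].to_numpy()
        n_meth = self.frame["n_methylated"].to_numpy()
        if len(self.frame):
            if (n_cpgs < 1).any():
                raise ValidationError("fragment with n_cpgs < 1")
            if ((n_meth < 0) | (n_meth > n_cpgs)).any():
                raise ValidationError("fragment with n_methylated outside [0, n_cpgs]")

    @property
    def n_fragments(self) -> int:
        return len(self.frame)

    def alpha(self, min_cpgs: int = 1) -> np.ndarray:
        """Alpha values of stored fragments with at least ``min_cpgs`` CpGs."""
        f = self.frame
        if min_cpgs > 1:
            f = f[f["n_cpgs"] >= min_cpgs]
        return f["n_methylated"].to_numpy(float) / f["n_cpgs"].to_numpy(float)

    def region_alphas(self, region_id: str, min_cpgs: int = 1) -> np.ndarray:
        f = self.frame
        mask = (f["region_id"] == region_id).to_numpy()
        if min_cpgs > 1:
            mask &= f["n_cpgs"].to_numpy() >= min_cpgs
        sub = f[mask]
        return sub["n_methylated"].to_numpy(float) / sub["n_cpgs"].to_numpy(float)


@dataclass
class Marker:
    """A subtype-specific methylation marker: region, direction, threshold.

    ``n_target`` / ``n_other`` count samples of the target / other subtype
    containing qualifying fragments at ``alpha_threshold``; ``bg_fraction``
    is the share of noncancer plasma samples containing such fragments.
    """

    region_id: str
    target_class: str
    direction: str
    alpha_threshold: float
    n_target: int
    n_other: int
    bg_fraction: float = float("nan")
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(f"unknown target class {self.target_class!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not 0.0 <= self.alpha_threshold <= 1.0:
            raise ValidationError("alpha threshold outside [0, 1]")

    @property
    def marker_id(self) -> str:
        return f"{self.target_class}:{self.direction}:{self.region_id}"

    def check_invariants(self, max_bg_fraction: float = 0.2,
                         max_n_other: int = 2) -> None:
        if self.n_other >= max_n_other:
            raise ValidationError(
                f"marker {self.marker_id}: n_other={self.n_other} >= {max_n_other}"
            )
        if np.isfinite(self.bg_fraction) and self.bg_fraction > max_bg_fraction:
            raise ValidationError(
                f"marker {self.marker_id}: bg_fraction={self.bg_fraction:.3f} "
                f"> {max_bg_fraction}"
            )


@dataclass
class MergedMarker:
    """A size-bounded cluster of markers of one class+direction cell."""

    merged_id: str
    target_class: str
    direction: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)

    def check_invariants(self, min_size: int = 45, max_size: int = 55) -> None:
        if not min_size <= self.size <= max_size:
            raise ValidationError(
                f"merged marker {self.merged_id}: size {self.size} outside "
                f"[{min_size}, {max_size}]"
            )


@dataclass
class BetaMatrix:
    """Array-style methylation: probe x sample beta values in [0, 1]."""

    values: pd.DataFrame
    probes: pd.DataFrame | None = None  # index probe_id; columns chrom, pos
    labels: pd.Series | None = None  # sample -> class label

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValidationError("beta values outside [0, 1]")
        if self.probes is not None:
            unknown = set(self.values.index) - set(self.probes.index)
            if unknown:
                raise ValidationError(f"probes without coordinates: {sorted(unknown)[:3]}")


@dataclass
class TpmMatrix:
    """Gene x sample expression matrix in transcripts-per-million."""

    values: pd.DataFrame
    promoters: pd.DataFrame | None = None  # index gene_id; chrom, start, end
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(float)
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("negative TPM values")
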