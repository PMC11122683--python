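"""Domain types shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) everywhere: an interval
``[start, end)`` covers ``end - start`` base pairs and two intervals overlap
iff ``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "ConfigError",
    "NormalizationError",
    "GenerationError",
    "MissingDataError",
    "GenomeSpec",
    "GenomicInterval",
    "StrandedPeak",
    "LibraryInfo",
    "CountMatrix",
    "ThresholdConfig",
    "FORWARD",
    "REVERSE",
]

FORWARD = "+"
REVERSE = "-"


class ValidationError(ValueError):
    """A record violates an invariant (coordinates, genome membership, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(ValueError):
    """A configuration value is outside its legal range."""


class NormalizationError(ValueError):
    """Spike-in or library-size normalization cannot be computed."""


class GenerationError(RuntimeError):
    """The synthetic dataset cannot be generated under the given config."""


class MissingDataError(ValueError):
    """A required input (condition, library, metadata column) is absent."""


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths, the coordinate frame of a study.

    Stands in for the genome dictionaries (chromosome sizes files) that real
    pipelines carry alongside hg19/mm10 alignments.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in GenomeSpec")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))
        object.__setattr__(self, "_order", {n: i for i, n in enumerate(names)})

    @classmethod
    def from_lengths(cls, lengths: dict[str, int] | Iterable[tuple[str, int]]) -> "GenomeSpec":
        items = lengths.items() if isinstance(lengths, dict) else lengths
        return cls(tuple((str(n), int(l)) for n, l in items))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths  # type: ignore[attr-defined]

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def order_of(self, chrom: str) -> int:
        try:
            return self._order[chrom]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``chrom:[start, end)`` with optional name/score."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValidationError(
                f"start >= end ({self.start} >= {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, genome: GenomeSpec) -> None:
        if self.end > genome.length_of(self.chrom):
            raise ValidationError(
                f"{self.chrom}:[{self.start},{self.end}) exceeds chromosome length "
                f"{genome.length_of(self.chrom)}"
            )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


@dataclass(frozen=True)
class StrandedPeak:
    """A strand-specific peak.

    Forward (+) peaks are built from right-side (F1R2) read stacks, reverse (-)
    peaks from left-side (F2R1) stacks; a blunt double-strand break therefore
    sits between a reverse peak and the forward peak just downstream of it.
    """

    interval: GenomicInterval
    strand: str
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class LibraryInfo:
    """Per-library sequencing metadata driving normalization.

    ``total_reads`` is the quality-filtered read count (RQC).  END-seq
    libraries carry ``spike_on_target_reads`` (reads at the spike genome's
    on-target cut locus, RiP); DRIP libraries carry ``spike_fraction`` (the
    proportion of reads mapping to the exogenous spike genome).
    """

    library_id: str
    assay: str  # "ENDseq" | "DRIP"
    condition: str  # e.g. NT / T10 / T20 (END-seq) or NT / T5 / T60 (DRIP)
    replicate: int
    role: str = "IP"  # IP | RNaseH | input | control
    total_reads: int = 0
    spike_on_target_reads: Optional[int] = None
    spike_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.total_reads <= 0:
            raise ValidationError(
                f"library {self.library_id!r}: total_reads must be > 0"
            )
        if self.spike_on_target_reads is not None and self.spike_on_target_reads < 0:
            raise ValidationError(
                f"library {self.library_id!r}: spike_on_target_reads must be >= 0"
            )
        if self.spike_fraction is not None and not (0.0 < self.spike_fraction < 1.0):
            raise ValidationError(
                f"library {self.library_id!r}: spike_fraction must lie in (0,1)"
            )


@dataclass
class CountMatrix:
    """Integer read counts indexed (region, library)."""

    regions: list[GenomicInterval]
    libraries: list[LibraryInfo]
    counts: np.ndarray  # shape (n_regions, n_libraries)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.libraries)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.regions)}, {len(self.libraries)})"
            )
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValidationError("counts must be non-negative integers")

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    def columns_for(self, **query) -> list[int]:
        """Indices of libraries matching every given attribute (condition=..., role=...)."""
        out = []
        for j, lib in enumerate(self.libraries):
            if all(getattr(lib, k) == v for k, v in query.items()):
                out.append(j)
        return out

    def subset_libraries(self, indices: Sequence[int]) -> "CountMatrix":
        return CountMatrix(
            regions=self.regions,
            libraries=[self.libraries[j] for j in indices],
            counts=self.counts[:, list(indices)],
        )

    def subset_regions(self, indices: Sequence[int]) -> "CountMatrix":
        return CountMatrix(
            regions=[self.regions[i] for i in indices],
            libraries=self.libraries,
            counts=self.counts[list(indices), :],
        )


@dataclass
class ThresholdConfig:
    """All statistical gates and structural thresholds in one place.

    max_pair_gap     bp   reverse-to-forward gap at or beyond which a peak pair
                          is not a double-ended break (paired gate: 0 <= d < gap)
    dsb_log2fc            absolute log2 fold-change gate for END-seq differential calls
    dsb_p                 two-sided p gate for END-seq differential calls
    rloop_p               two-sided p gate for DRIP differential calls (no fold gate)
    n_shuffles            randomizations for overlap enrichment
    pseudocount           added to normalized counts before log2
    moderation_df         prior degrees of freedom d0 for variance moderation
    """

    max_pair_gap: int = 150
    dsb_log2fc: float = 1.0
    dsb_p: float = 0.05
    rloop_p: float = 0.01
    n_shuffles: int = 100
    pseudocount: float = 0.5
    moderation_df: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "max_pair_gap",
            "dsb_log2fc",
            "dsb_p",
            "rloop_p",
            "pseudocount",
            "moderation_df",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown threshold keys: {sorted(bad)}")
        return cls(**d)
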