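"""Readers and writers for the text formats the pipeline touches.

BED3/BED6 for intervals and strand-specific peaks, bedGraph for signal
tracks, TSV with header for count matrices, library metadata and results
tables, YAML for threshold configuration.  Coordinates on disk follow the
same 0-based half-open convention as in memory, so write-then-read is the
identity on validated records.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    FORWARD,
    REVERSE,
    CountMatrix,
    GenomeSpec,
    GenomicInterval,
    LibraryInfo,
    ParseError,
    StrandedPeak,
    ThresholdConfig,
    ValidationError,
)
from .interval_ops import sort_intervals

__all__ = [
    "read_intervals",
    "write_intervals",
    "SignalTrack",
    "read_signal_track",
    "write_signal_track",
    "read_genome",
    "write_genome",
    "read_library_table",
    "write_library_table",
    "read_count_matrix",
    "write_count_matrix",
    "load_thresholds",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: Union[str, Path]):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_intervals(
    path: Union[str, Path],
    expect_strand: bool = False,
    replicate: Optional[int] = None,
) -> list:
    """Read BED3+ records; with ``expect_strand`` return :class:`StrandedPeak`.

    Malformed lines raise :class:`ParseError` naming the line number;
    coordinate violations raise :class:`ValidationError`.
    """
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        name = None
        score = None
        if len(fields) >= 4 and fields[3] != ".":
            name = fields[3]
        if len(fields) >= 5 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from None
        try:
            interval = GenomicInterval(chrom, start, end, name=name, score=score)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
        if expect_strand:
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 with strand column required")
            strand = fields[5]
            if strand not in (FORWARD, REVERSE):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            records.append(StrandedPeak(interval, strand, replicate=replicate))
        else:
            records.append(interval)
    return records


def write_intervals(
    records: Sequence[Union[GenomicInterval, StrandedPeak]],
    path: Union[str, Path],
    genome: Optional[GenomeSpec] = None,
    extra_columns: Optional[Sequence[Sequence]] = None,
) -> None:
    """Write BED, deterministically ordered (genome chromosome order, then start).

    ``extra_columns``: one row of extra fields per record, appended after the
    standard columns (reordered together with the records).
    """
    rows = list(records)
    extras = list(extra_columns) if extra_columns is not None else [()] * len(rows)
    if len(extras) != len(rows):
        raise ValidationError("extra_columns length does not match records")

    def iv(rec):
        return rec.interval if isinstance(rec, StrandedPeak) else rec

    if genome is not None:
        for rec in rows:
            iv(rec).validate_against(genome)
        order_key = lambda pair: (genome.order_of(iv(pair[0]).chrom), iv(pair[0]).start, iv(pair[0]).end)
    else:
        order_key = lambda pair: (iv(pair[0]).chrom, iv(pair[0]).start, iv(pair[0]).end)
    paired = sorted(zip(rows, extras), key=order_key)

    stranded = any(isinstance(r, StrandedPeak) for r in rows)
    named = stranded or any(iv(r).name is not None or iv(r).score is not None for r in rows)
    with open(path, "w") as fh:
        for rec, extra in paired:
            i = iv(rec)
            fields = [i.chrom, str(i.start), str(i.end)]
            if named:
                fields.append(i.name if i.name is not None else ".")
                fields.append(_fmt_score(i.score))
            if stranded:
                fields.append(rec.strand if isinstance(rec, StrandedPeak) else ".")
            fields.extend(str(x) for x in extra)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(score: Optional[float]) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


class SignalTrack:
    """Piecewise-constant per-chromosome signal (bedGraph semantics).

    Value is 0 anywhere not covered by a block.  Blocks within a chromosome
    must be non-overlapping.
    """

    def __init__(self, blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._blocks = {}
        for chrom, (starts, ends, values) in blocks.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts >= ends):
                raise ValidationError(f"{chrom}: block with start >= end")
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"{chrom}: overlapping bedGraph blocks")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._blocks[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        per: dict[str, list] = {}
        for chrom, start, end, value in intervals:
            per.setdefault(chrom, []).append((start, end, value))
        return cls(
            {
                chrom: tuple(np.array(col) for col in zip(*rows))
                for chrom, rows in per.items()
            }
        )

    @property
    def chromosomes(self) -> list[str]:
        return list(self._blocks)

    def value(self, chrom: str, pos: int) -> float:
        if chrom not in self._blocks:
            return 0.0
        starts, ends, values, _ = self._blocks[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            return float(values[j])
        return 0.0

    def integral(self, chrom: str, start, end) -> np.ndarray:
        """Integral of the signal over [start, end); vectorized over arrays."""
        a = np.atleast_1d(np.asarray(start, dtype=float))
        b = np.atleast_1d(np.asarray(end, dtype=float))
        if chrom not in self._blocks:
            return np.zeros(a.shape, dtype=float)
        starts, ends, values, cum = self._blocks[chrom]
        i0 = np.searchsorted(ends, a, side="right")
        i1 = np.searchsorted(starts, b, side="left")
        i0c = np.minimum(i0, i1)
        total = cum[i1] - cum[i0c]
        has = i1 > i0c
        left_trim = np.where(
            has, values[np.minimum(i0c, len(values) - 1)] * np.maximum(0, a - starts[np.minimum(i0c, len(starts) - 1)]), 0.0
        )
        right_trim = np.where(
            has, values[np.maximum(i1 - 1, 0)] * np.maximum(0, ends[np.maximum(i1 - 1, 0)] - b), 0.0
        )
        return total - left_trim - right_trim

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValidationError("mean requires start < end")
        return float(self.integral(chrom, start, end)[0]) / (end - start)

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {
                chrom: (starts, ends, values * factor)
                for chrom, (starts, ends, values, _) in self._blocks.items()
            }
        )

    def iter_blocks(self):
        for chrom, (starts, ends, values, _) in self._blocks.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


def read_signal_track(path: Union[str, Path]) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from None
    return SignalTrack.from_intervals(rows)


def write_signal_track(
    track: SignalTrack, path: Union[str, Path], genome: Optional[GenomeSpec] = None
) -> None:
    blocks = sorted(
        track.iter_blocks(),
        key=(lambda b: (genome.order_of(b[0]), b[1])) if genome else (lambda b: (b[0], b[1])),
    )
    with open(path, "w") as fh:
        for chrom, s, e, v in blocks:
            fh.write(f"{chrom}\t{s}\t{e}\t{_fmt_score(v)}\n")


def read_genome(path: Union[str, Path]) -> GenomeSpec:
    """Two-column chrom-sizes file -> GenomeSpec."""
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
        pairs.append((fields[0], int(fields[1])))
    return GenomeSpec.from_lengths(pairs)


def write_genome(genome: GenomeSpec, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


_LIB_COLUMNS = [
    "library_id",
    "assay",
    "condition",
    "replicate",
    "role",
    "total_reads",
    "spike_on_target_reads",
    "spike_fraction",
]


def write_library_table(libraries: Sequence[LibraryInfo], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "library_id": lib.library_id,
                "assay": lib.assay,
                "condition": lib.condition,
                "replicate": lib.replicate,
                "role": lib.role,
                "total_reads": lib.total_reads,
                "spike_on_target_reads": "" if lib.spike_on_target_reads is None else lib.spike_on_target_reads,
                "spike_fraction": "" if lib.spike_fraction is None else repr(lib.spike_fraction),
            }
            for lib in libraries
        ],
        columns=_LIB_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_library_table(path: Union[str, Path]) -> list[LibraryInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    libs = []
    for _, row in df.iterrows():
        spike_reads = row.get("spike_on_target_reads")
        spike_frac = row.get("spike_fraction")
        libs.append(
            LibraryInfo(
                library_id=str(row["library_id"]),
                assay=str(row["assay"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                role=str(row["role"]),
                total_reads=int(row["total_reads"]),
                spike_on_target_reads=None if pd.isna(spike_reads) else int(spike_reads),
                spike_fraction=None if pd.isna(spike_frac) else float(spike_frac),
            )
        )
    return libs


def write_count_matrix(matrix: CountMatrix, path: Union[str, Path]) -> None:
    data = {
        "chrom": [r.chrom for r in matrix.regions],
        "start": [r.start for r in matrix.regions],
        "end": [r.end for r in matrix.regions],
        "name": [r.name if r.name is not None else "." for r in matrix.regions],
    }
    for j, lib in enumerate(matrix.libraries):
        data[lib.library_id] = matrix.counts[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_count_matrix(
    path: Union[str, Path], libraries: Sequence[LibraryInfo]
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    regions = [
        GenomicInterval(
            str(row.chrom), int(row.start), int(row.end),
            name=None if str(row.name_col) == "." else str(row.name_col),
        )
        for row in df.rename(columns={"name": "name_col"}).itertuples(index=False)
    ]
    by_id = {lib.library_id: lib for lib in libraries}
    lib_cols = [c for c in df.columns if c in by_id]
    counts = df[lib_cols].to_numpy(dtype=np.int64)
    return CountMatrix(regions=regions, libraries=[by_id[c] for c in lib_cols], counts=counts)


def load_thresholds(path: Union[str, Path]) -> ThresholdConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: threshold config must be a mapping")
    return ThresholdConfig.from_dict(data)
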