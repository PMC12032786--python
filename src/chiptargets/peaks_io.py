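"""Reading and writing MACS2 narrowPeak (BED6+4) peak calls.

narrowPeak coordinates are already 0-based half-open and are taken verbatim.
The strand column is carried through but ignored by all downstream logic:
transcription-factor binding events have no meaningful strand.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable

from .genome_model import GenomicInterval

__all__ = ["Peak", "NarrowPeakParseError", "read_narrowpeak", "write_narrowpeak"]

_NCOLS = 10


class NarrowPeakParseError(ValueError):
    """Raised on malformed narrowPeak lines; names the line number."""


@dataclass(frozen=True)
class Peak:
    """One called peak with its narrowPeak metadata and provenance labels.

    ``summit_offset`` is the offset of the point source from ``interval.start``
    or -1 when absent; ``pvalue_neglog10``/``qvalue_neglog10`` are -log10
    transformed significance values, -1 when missing.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    pvalue_neglog10: float = -1.0
    qvalue_neglog10: float = -1.0
    summit_offset: int = -1
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"width {self.interval.width}"
            )
        for label, v in (
            ("pvalue", self.pvalue_neglog10),
            ("qvalue", self.qvalue_neglog10),
        ):
            if v < 0 and v != -1:
                raise ValueError(f"peak {self.name}: {label} must be >= 0 or -1")

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when the file carried none."""
        if self.summit_offset == -1:
            return None
        return self.interval.start + self.summit_offset

    @property
    def anchor(self) -> int:
        """Summit if present, else the interval midpoint (floor)."""
        s = self.summit
        if s is not None:
            return s
        return self.interval.start + self.interval.width // 2

    def relabel(self, replicate_id: str | None = None, condition: str | None = None) -> "Peak":
        kwargs = {}
        if replicate_id is not None:
            kwargs["replicate_id"] = replicate_id
        if condition is not None:
            kwargs["condition"] = condition
        return replace(self, **kwargs)


def _open_text(source: IO[str] | str | Path) -> tuple[Iterable[str], bool]:
    """Return (line iterable, needs_close). Accepts paths, text and streams."""
    if isinstance(source, Path) or (
        isinstance(source, str) and source and "\n" not in source
        and "\t" not in source and Path(source).is_file()
    ):
        p = Path(source)
        if p.suffix == ".gz":
            return gzip.open(p, "rt"), True
        return open(p, "rt"), True
    if isinstance(source, str):
        return io.StringIO(source), False
    return source, False


def read_narrowpeak(
    stream: IO[str] | str | Path,
    replicate_id: str = "",
    condition: str = "",
) -> list[Peak]:
    """Parse a narrowPeak stream (path, text, or file object) into peaks.

    Track and comment lines are skipped; input order is preserved.  Raises
    :class:`NarrowPeakParseError` on a wrong column count or invalid
    coordinates, naming the offending line number.
    """
    lines, needs_close = _open_text(stream)
    peaks: list[Peak] = []
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != _NCOLS:
                raise NarrowPeakParseError(
                    f"line {lineno}: expected {_NCOLS} tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = int(fields[4])
                strand = fields[5]
                signal = float(fields[6])
                pval = float(fields[7])
                qval = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise NarrowPeakParseError(
                    f"line {lineno}: unparseable field ({exc})"
                ) from exc
            if end <= start:
                raise NarrowPeakParseError(
                    f"line {lineno}: end {end} <= start {start}"
                )
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    name=name,
                    score=score,
                    strand=strand,
                    signal_value=signal,
                    pvalue_neglog10=pval,
                    qvalue_neglog10=qval,
                    summit_offset=summit,
                    replicate_id=replicate_id,
                    condition=condition,
                )
            )
    finally:
        if needs_close:
            lines.close()  # type: ignore[union-attr]
    return peaks


def _fmt_float(x: float) -> str:
    # shortest decimal that round-trips; integers print without exponent
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def write_narrowpeak(peaks: Iterable[Peak], stream: IO[str]) -> None:
    """Write peaks as canonical 10-column narrowPeak; round-trips all fields."""
    for p in peaks:
        stream.write(
            "\t".join(
                (
                    p.interval.chrom,
                    str(p.interval.start),
                    str(p.interval.end),
                    p.name,
                    str(p.score),
                    p.strand,
                    _fmt_float(p.signal_value),
                    _fmt_float(p.pvalue_neglog10),
                    _fmt_float(p.qvalue_neglog10),
                    str(p.summit_offset),
                )
            )
            + "\n"
        )
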