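"""Candidate marker regions: propose from classified windows, extract sub-alignments.

Auto-proposed regions are maximal runs of variable windows (class at or
above a threshold), optionally bridging short runs of cold windows, the way
named plastid spacers (trnC-rps16, trnE-trnM, psbM-trnD, ...) span several
800 bp bins. Gene-anchored names come only from a user-supplied region
table; annotation lift-over is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import CoordinateError, FormatError
from .msa_io import Alignment
from .snpscan import CLASS_ORDER, WindowDensity

__all__ = [
    "MarkerRegion",
    "propose_regions",
    "extract_region",
    "read_regions",
    "write_regions",
]


@dataclass(frozen=True)
class MarkerRegion:
    """A named 1-based inclusive column range, auto-proposed or user-supplied."""

    name: str
    start: int
    end: int
    source: str = "user"  # {"auto", "user"}

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"region {self.name!r}: invalid range ({self.start},{self.end})"
            )


def propose_regions(
    wd: WindowDensity, min_class: str = "moderate", merge_gap: int = 1
) -> list[MarkerRegion]:
    """Merge runs of variable windows into candidate marker regions.

    A window qualifies when its class is >= ``min_class`` in the order
    low < moderate < high. Up to ``merge_gap`` consecutive non-qualifying
    windows are allowed inside a run. Regions are ordered by total SNP
    count (including bridged windows) descending, then by start.
    """
    if min_class not in CLASS_ORDER:
        raise ValueError(f"unknown class {min_class!r}")
    threshold = CLASS_ORDER.index(min_class)
    qualifying = [
        w.cls is not None and CLASS_ORDER.index(w.cls) >= threshold
        for w in wd.windows
    ]
    regions: list[tuple[int, int, int]] = []  # (first_idx, last_idx, snp_total)
    i = 0
    n = len(wd.windows)
    while i < n:
        if not qualifying[i]:
            i += 1
            continue
        first = last = i
        j = i + 1
        gap = 0
        while j < n:
            if qualifying[j]:
                last = j
                gap = 0
            else:
                gap += 1
                if gap > merge_gap:
                    break
            j += 1
        total = sum(w.snp_count for w in wd.windows[first : last + 1])
        regions.append((first, last, total))
        i = last + 1
    regions.sort(key=lambda r: (-r[2], r[0]))
    out = []
    for first, last, _ in regions:
        start = wd.windows[first].start
        end = wd.windows[last].end
        out.append(MarkerRegion(f"R{start}-{end}", start, end, source="auto"))
    return out


def extract_region(aln: Alignment, region: MarkerRegion) -> Alignment:
    """Sub-alignment of the region's columns; all taxa retained."""
    if region.end > aln.length:
        raise CoordinateError(
            f"region {region.name!r} end {region.end} exceeds alignment "
            f"length {aln.length}"
        )
    return aln.columns(region.start, region.end)


def read_regions(path: str | Path) -> list[MarkerRegion]:
    """Read a TSV region table ``name<TAB>start<TAB>end`` (header required)."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"empty region table: {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            out.append(MarkerRegion(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_regions(regions: Iterable[MarkerRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.start}\t{r.end}\n")
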