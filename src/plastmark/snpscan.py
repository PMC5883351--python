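"""SNP extraction and windowed SNP-density classification.

A column is a SNP iff at least two distinct unambiguous nucleotides
(A/C/G/T) occur in it; gaps, N and IUPAC ambiguity codes are not states.
Window counts are classified by the z-score of each window's SNP count
against the mean and sample standard deviation of all window counts:
``low`` (z < 1, including negative z), ``moderate`` (1 <= z < 2) and
``high`` (z >= 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import CoordinateError, InsufficientDataError
from .msa_io import Alignment

__all__ = [
    "SnpTable",
    "Window",
    "WindowDensity",
    "extract_snps",
    "bin_density",
    "classify_windows",
    "percent_variable_sites",
    "write_window_report",
    "write_snp_bed",
    "write_windows_bed",
]

_BASES = b"ACGT"

CLASS_ORDER = ("low", "moderate", "high")


@dataclass(frozen=True)
class SnpTable:
    """Variant columns of an alignment.

    positions are sorted 1-based column indices; ``states[i]`` is the
    multiset of unambiguous nucleotides observed in column ``positions[i]``.
    """

    positions: tuple[int, ...]
    states: tuple[Counter, ...]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class Window:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    snp_count: int
    z_score: float | None = None
    cls: str | None = None


@dataclass(frozen=True)
class WindowDensity:
    window_size: int
    length: int
    windows: tuple[Window, ...]


def _matrix(aln: Alignment) -> np.ndarray:
    """Alignment as a (n_taxa, L) uint8 byte matrix."""
    return np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_taxa, aln.length)


def extract_snps(aln: Alignment) -> SnpTable:
    """Columns with >=2 distinct A/C/G/T states, ignoring gaps/ambiguity."""
    if aln.n_taxa == 0 or aln.length == 0:
        return SnpTable((), ())
    mat = _matrix(aln)
    present = np.zeros((4, aln.length), dtype=bool)
    for k, base in enumerate(_BASES):
        present[k] = (mat == base).any(axis=0)
    snp_mask = present.sum(axis=0) >= 2
    positions = np.flatnonzero(snp_mask)
    states = []
    for col in positions:
        column = mat[:, col]
        states.append(
            Counter(chr(c) for c in column.tolist() if c in _BASES)
        )
    return SnpTable(tuple(int(p) + 1 for p in positions), tuple(states))


def bin_density(
    snps: SnpTable, length: int, window_size: int = 800
) -> WindowDensity:
    """Tile [1, L] into fixed windows (final window may be partial)."""
    if window_size < 1:
        raise CoordinateError(f"window_size must be >=1, got {window_size}")
    if snps.positions and max(snps.positions) > length:
        raise CoordinateError(
            f"SNP position {max(snps.positions)} exceeds alignment length {length}"
        )
    edges = list(range(0, length, window_size)) + [length]
    counts = np.histogram(
        np.asarray(snps.positions, dtype=float), bins=np.asarray(edges) + 0.5
    )[0] if snps.positions else np.zeros(len(edges) - 1, dtype=int)
    windows = tuple(
        Window(start=edges[i] + 1, end=edges[i + 1], snp_count=int(counts[i]))
        for i in range(len(edges) - 1)
    )
    return WindowDensity(window_size, length, windows)


def classify_windows(wd: WindowDensity) -> WindowDensity:
    """Assign z-scores and low/moderate/high classes to each window.

    Uses the sample (n-1) standard deviation of window counts; if it is
    zero every window is class ``low``.
    """
    if len(wd.windows) < 2:
        raise InsufficientDataError(
            f"window classification needs >=2 windows, got {len(wd.windows)}"
        )
    counts = np.array([w.snp_count for w in wd.windows], dtype=float)
    sd = counts.std(ddof=1)
    mean = counts.mean()
    if sd == 0:
        zs = np.zeros_like(counts)
    else:
        zs = (counts - mean) / sd
    classified = []
    for w, z in zip(wd.windows, zs):
        cls = "low" if z < 1 else ("moderate" if z < 2 else "high")
        classified.append(replace(w, z_score=float(z), cls=cls))
    return WindowDensity(wd.window_size, wd.length, tuple(classified))


def percent_variable_sites(aln: Alignment) -> float:
    """Fraction of SNP columns, as a percentage of alignment length."""
    if aln.length == 0:
        return 0.0
    return 100.0 * len(extract_snps(aln)) / aln.length


def write_window_report(wd: WindowDensity, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\twindow_end\tsnp_count\tz\tclass\n")
        for w in wd.windows:
            z = "" if w.z_score is None else f"{w.z_score:.4f}"
            fh.write(f"{w.start}\t{w.end}\t{w.snp_count}\t{z}\t{w.cls or ''}\n")


def write_snp_bed(snps: SnpTable, path: str | Path, chrom: str = "alignment") -> None:
    """BED (0-based half-open) of SNP positions."""
    with open(path, "w") as fh:
        for pos in snps.positions:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")


def write_windows_bed(
    wd: WindowDensity,
    path: str | Path,
    classes: Sequence[str] = ("high",),
    chrom: str = "alignment",
) -> None:
    """BED of windows whose class is in ``classes``."""
    keep = set(classes)
    with open(path, "w") as fh:
        for w in wd.windows:
            if w.cls in keep:
                fh.write(f"{chrom}\t{w.start - 1}\t{w.end}\t{w.cls}\t{w.snp_count}\n")
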