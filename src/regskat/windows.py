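"""Sliding-window tiling of variants along each chromosome.

Rare variants are grouped for testing by overlapping fixed-length
windows (default 4 kb long, advancing 2 kb per step, so each interior
position is covered by exactly two windows).  Tiling is anchored at
coordinate 1 of every chromosome, which makes the window grid
deterministic and independent of the variant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindowingConfig", "Window", "tile_windows", "window_category_profile",
           "write_windows_bed"]


@dataclass(frozen=True)
class WindowingConfig:
    window_length: int = 4000
    step: int = 2000

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.step <= 0:
            raise ValueError("window length and step must be positive")
        if self.step > self.window_length:
            raise ValueError("step must not exceed window length")


@dataclass(frozen=True)
class Window:
    """A genomic interval (1-based, inclusive ends) and its member variants.

    ``variant_indices`` index into the cohort-wide variant arrays and
    are sorted by position.  The label names the window by its midpoint.
    """

    chromosome: str
    start: int
    end: int
    variant_indices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def label(self) -> str:
        return f"{self.chromosome}:{(self.start + self.end) // 2}"

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


def tile_windows(chroms, positions, config: WindowingConfig | None = None) -> list[Window]:
    """Tile chromosomes with sliding windows and keep those holding >= 1 variant.

    Parameters
    ----------
    chroms, positions
        Parallel arrays over the cohort's variants; positions must be
        sorted ascending within each chromosome.
    """
    config = config or WindowingConfig()
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    if chroms.shape != positions.shape:
        raise ValueError("chroms and positions must be parallel arrays")

    length, step = config.window_length, config.step
    out: list[Window] = []
    # preserve first-appearance chromosome order
    seen: dict = {}
    for c in chroms:
        seen.setdefault(str(c), None)
    for chrom in seen:
        mask = chroms == chrom
        idx = np.flatnonzero(mask)
        pos = positions[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
        if pos.size == 0:
            continue
        lo, hi = int(pos[0]), int(pos[-1])
        # window k covers [1 + k*step, k*step + length]
        k_min = max(0, -(-(lo - length) // step))  # ceil((lo - length)/step)
        k_max = (hi - 1) // step
        for k in range(k_min, k_max + 1):
            start = 1 + k * step
            end = start + length - 1
            a, b = np.searchsorted(pos, [start, end + 1])
            if b > a:
                out.append(Window(chrom, start, end, tuple(int(i) for i in idx[a:b])))
    return out


def window_category_profile(window: Window, categories) -> np.ndarray:
    """Count member variants per functional category 1..6."""
    from .annotate import category_values

    counts = np.zeros(6, dtype=int)
    if window.n_variants:
        vals = category_values([categories[i] for i in window.variant_indices])
        for v in vals:
            counts[v - 1] += 1
    return counts


def write_windows_bed(windows, path) -> None:
    """Export windows as BED (0-based half-open, converted at this boundary)."""
    with open(path, "w") as fh:
        fh.write("# sliding windows; coordinates converted to 0-based half-open\n")
        for w in windows:
            fh.write(f"{w.chromosome}\t{w.start - 1}\t{w.end}\t{w.label}\t{w.n_variants}\n")
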