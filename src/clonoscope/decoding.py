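"""Cell-code decoding and clone partitioning.

Each cell's mean fluorescence intensity per channel (0–255) is quantized
into one of five levels of 51 intensity points each; the ordered tuple of
levels across channels is the cell's *code* (the clonal barcode).  Cells
sharing a code within one tissue section are grouped into a clone.  The
all-zero code is reserved for unlabeled cells (no fluorophore) and never
forms a clone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "LEVEL_WIDTH",
    "N_LEVELS",
    "bin_center",
    "quantize",
    "encode_cell",
    "encode_table",
    "code_to_str",
    "parse_code",
    "CloneGroup",
    "group_clones",
    "CloneSizeHistogram",
    "clone_size_histogram",
]

#: Width of one quantization level on the 8-bit scale: 5 levels × 51 = 255.
LEVEL_WIDTH = 51
#: Number of intensity levels per channel.
N_LEVELS = 5

_COORD_COLS = ("x_um", "y_um", "z_um")


def bin_center(level: int | np.ndarray) -> int | np.ndarray:
    """Center intensity of quantization level ``level``: ``51·level + 25``.

    Centers (25, 76, 127, 178, 229) maximize the margin to the quantizer
    boundaries.
    """
    lvl = np.asarray(level)
    if np.any((lvl < 0) | (lvl >= N_LEVELS)):
        raise ValueError(f"level must be in [0, {N_LEVELS - 1}]")
    out = LEVEL_WIDTH * lvl + LEVEL_WIDTH // 2
    return int(out) if np.isscalar(level) else out


def quantize(intensity: float | np.ndarray) -> int | np.ndarray:
    """Quantize an 8-bit intensity into a level in ``{0..4}``.

    ``level = floor(intensity / 51)``; intensity 255 (the one gray value the
    5 × 51 arithmetic leaves over) is clamped into the top level.  Monotone
    non-decreasing in intensity.
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(x < 0) or np.any(x > 255):
        raise ValueError("intensity outside [0, 255]")
    lvl = np.minimum(np.floor(x / LEVEL_WIDTH).astype(int), N_LEVELS - 1)
    return int(lvl) if np.isscalar(intensity) else lvl


def channel_columns(df: pd.DataFrame) -> list[str]:
    """The ``ch1..chK`` intensity columns of a cell table, in channel order."""
    cols = sorted(
        (c for c in df.columns if c.startswith("ch") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    return cols


def encode_cell(intensities: Sequence[float]) -> tuple[int, ...]:
    """Quantize one cell's per-channel intensities into its cell code."""
    if len(intensities) == 0:
        raise ValueError("cell has no channel intensities")
    vals = np.asarray(intensities, dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("missing channel intensity")
    return tuple(int(v) for v in quantize(vals))

def code_to_str(code: Iterable[int]) -> str:
    return "-".join(str(int(c)) for c in code)


def parse_code(s: str) -> tuple[int, ...]:
    return tuple(int(part) for part in s.split("-"))


def encode_table(df: pd.DataFrame, channel_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Add ``code`` (string ``"l1-l2-..."``) and ``labeled`` columns to a cell table.

    Cells whose code is all-zero are flagged ``labeled=False`` and take no
    part in clone grouping or clone statistics.
    """
    cols = list(channel_cols) if channel_cols is not None else channel_columns(df)
    if not cols:
        raise ValueError("no channel intensity columns (ch1..chK) found")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing channel column(s): {missing}")
    out = df.copy()
    if len(out) == 0:
        out["code"] = pd.Series(dtype=str)
        out["labeled"] = pd.Series(dtype=bool)
        return out
    levels = quantize(out[cols].to_numpy(dtype=float))
    out["code"] = ["-".join(map(str, row)) for row in levels]
    out["labeled"] = levels.any(axis=1)
    return out


@dataclass(frozen=True)
class CloneGroup:
    """A set of cells sharing one cell code within one tissue section."""

    clone_id: str
    code: tuple[int, ...]
    cell_ids: tuple[int, ...]
    section: str | int | None = None
    extent_um: float = 0.0

    @property
    def size(self) -> int:
        return len(self.cell_ids)


def _spatial_extent(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    return float(pdist(coords).max())


def _coords(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in _COORD_COLS if c in df.columns]
    if not cols:
        return np.zeros((len(df), 1))
    return df[cols].to_numpy(dtype=float)


def group_clones(
    cells: pd.DataFrame,
    max_link_distance: float | None = None,
    section_col: str = "section",
) -> list[CloneGroup]:
    """Partition labeled cells into clones by code identity.

    By default all same-code cells within one tissue section form one clone
    (code reiteration across sections is never merged).  If
    ``max_link_distance`` is given, same-code cells are further split by
    single-linkage clustering at that distance — a sensitivity analysis for
    accidental code collisions between spatially implausible cells.

    Returns a list of :class:`CloneGroup` forming a partition of the labeled
    cells, ordered deterministically by (section, code, first cell id).
    """
    df = cells if "code" in cells.columns else encode_table(cells)
    if "labeled" in df.columns:
        df = df[df["labeled"]]
    else:
        df = df[df["code"].map(lambda s: any(int(x) for x in s.split("-")))]
    groups: list[CloneGroup] = []
    if len(df) == 0:
        return groups
    if section_col in df.columns:
        section_key = df[section_col].to_numpy(dtype=object)
    else:
        section_key = np.full(len(df), "", dtype=object)
    counter = itertools.count(1)
    keys = sorted(
        {(s, c) for s, c in zip(section_key, df["code"])},
        key=lambda k: (str(k[0]), k[1]),
    )
    for sec, code in keys:
        sub = df[(df["code"] == code).to_numpy() & (section_key == sec)]
        sub = sub.sort_values("cell_id")
        coords = _coords(sub)
        if max_link_distance is not None and len(sub) > 1:
            labels = fcluster(
                linkage(coords, method="single"), t=max_link_distance,
                criterion="distance",
            )
        else:
            labels = np.ones(len(sub), dtype=int)
        for lab in np.unique(labels):
            mask = labels == lab
            groups.append(
                CloneGroup(
                    clone_id=f"C{next(counter):04d}",
                    code=parse_code(code),
                    cell_ids=tuple(int(i) for i in sub["cell_id"][mask]),
                    section=sec,
                    extent_um=_spatial_extent(coords[mask]),
                )
            )
    return groups


#: Clone-size bins used in the source study's frequency analysis: sizes 1–8,
#: 8–16, and 16–32 (half-open on the right; the last bin absorbs larger clones).
DEFAULT_SIZE_BINS: tuple[tuple[int, int], ...] = ((1, 8), (8, 16), (16, 33))


@dataclass(frozen=True)
class CloneSizeHistogram:
    """Clone-size frequency table over configurable bins."""

    bins: tuple[tuple[int, int], ...]
    counts: tuple[int, ...]
    missing_sizes: tuple[int, ...] = field(default=())

    @property
    def n_clones(self) -> int:
        return int(sum(self.counts))


def clone_size_histogram(
    groups: Iterable[CloneGroup] | Sequence[int],
    bins: Sequence[tuple[int, int]] = DEFAULT_SIZE_BINS,
) -> CloneSizeHistogram:
    """Bin clone sizes into half-open ``[lo, hi)`` size bins.

    Also reports which integer clone sizes between 1 and the largest observed
    size are unrepresented (useful for spotting gaps in the size spectrum).
    """
    bins = tuple((int(lo), int(hi)) for lo, hi in bins)
    for lo, hi in bins:
        if hi <= lo:
            raise ValueError(f"empty bin [{lo}, {hi})")
    for (_, hi_prev), (lo, _) in zip(bins, bins[1:]):
        if lo < hi_prev:
            raise ValueError("overlapping clone-size bins")
    sizes = [g.size if isinstance(g, CloneGroup) else int(g) for g in groups]
    if any(s < 1 for s in sizes):
        raise ValueError("clone sizes must be >= 1")
    counts = [0] * len(bins)
    for s in sizes:
        for i, (lo, hi) in enumerate(bins):
            if lo <= s < hi:
                counts[i] += 1
                break
        else:
            raise ValueError(f"clone size {s} falls outside all bins {bins}")
    present = set(sizes)
    upper = max(sizes) if sizes else 0
    missing = tuple(s for s in range(1, upper + 1) if s not in present)
    return CloneSizeHistogram(bins=bins, counts=tuple(counts), missing_sizes=missing)
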