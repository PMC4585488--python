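"""Ground-truthed synthetic clonal labeling in a laminated cortical slab.

Emulates combinatorial-fluorophore (CLoNe-style) clonal labeling: each clone
is assigned one non-zero cell code (a tuple of quantization levels across up
to 4 channels); its member cells are placed in the slab with controllable
same-layer and cross-layer separations; per-channel intensities are drawn
around the quantization-bin centers with additive Gaussian noise and clipped
to the 8-bit range.

Placement law (the source measurements give only summary distances): the
clone anchor is uniform in the slab; every other member sits at an exact
separation ``r`` from the anchor, where ``r`` is drawn from a zero-truncated
normal whose location is solved so the *truncated* mean equals the configured
category mean.  Same-layer mates are displaced tangentially with a small
depth jitter; cross-layer mates land in a different layer chosen among those
reachable at separation ``r``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .cortex import ConfigurationError, CorticalModel
from .decoding import LEVEL_WIDTH, N_LEVELS, bin_center, code_to_str

__all__ = [
    "SimulationParams",
    "CloneTruth",
    "simulate_clones",
    "default_clone_size_pmf",
    "truncated_normal_location",
    "expected_unrelated_different_layer_mean",
    "scaled_model_for_unrelated_mean",
]


def default_clone_size_pmf() -> dict[int, float]:
    """Default clone-size distribution over sizes 1–32.

    Encodes the observed ordering of clone-size frequencies in lineage-traced
    cortex: sizes 8–16 roughly twice as frequent as 1–8, and sizes >16 the
    most frequent.  Bin probabilities 0.25 / 0.35 / 0.40 for 1–8 / 9–16 /
    17–32, uniform within each bin.
    """
    bins = {(1, 8): 0.25, (9, 16): 0.35, (17, 32): 0.40}
    pmf: dict[int, float] = {}
    for (lo, hi), p in bins.items():
        for s in range(lo, hi + 1):
            pmf[s] = p / (hi - lo + 1)
    return pmf


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic clonal-labeling generator.

    Separation means/SDs default to the measured dispersion of clonally
    related cortical cells: same-layer pairs 36.8 ± 20.5 μm, different-layer
    pairs 142.1 ± 76.8 μm.  ``cross_layer_fraction`` defaults to 19/42, the
    observed share of different-layer pairs among related pairs.
    """

    n_clones: int = 50
    clone_size_distribution: dict[int, float] | int | None = None
    n_channels: int = 4
    n_levels: int = N_LEVELS
    noise_sd: float = 5.0
    same_layer_sep_mean: float = 36.8
    same_layer_sep_sd: float = 20.5
    cross_layer_sep_mean: float = 142.1
    cross_layer_sep_sd: float = 76.8
    cross_layer_fraction: float = 19.0 / 42.0
    depth_jitter_sd: float = 5.0
    labeled_fraction_per_layer: dict[str, float] | float = 1.0
    min_cell_separation: float = 0.0
    allow_code_collisions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 0:
            raise ConfigurationError("n_clones must be >= 0")
        if not (1 <= self.n_channels <= 4):
            raise ConfigurationError("n_channels must be in 1..4")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.cross_layer_fraction <= 1.0):
            raise ConfigurationError("cross_layer_fraction must be in [0, 1]")
        fr = self.labeled_fraction_per_layer
        vals = fr.values() if isinstance(fr, dict) else [fr]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ConfigurationError("labeled fractions must be in [0, 1]")
        if isinstance(self.clone_size_distribution, int):
            if self.clone_size_distribution < 1:
                raise ConfigurationError("clone sizes must be >= 1")
        elif isinstance(self.clone_size_distribution, dict):
            if any(s < 1 for s in self.clone_size_distribution):
                raise ConfigurationError("clone sizes must be >= 1")


@dataclass(frozen=True)
class CloneTruth:
    """Ground-truth clone membership: cell id → (clone id, cell code)."""

    table: pd.DataFrame  # columns: cell_id, clone_id, code

    def partition(self) -> dict[int, frozenset[int]]:
        """True clone partition as ``{clone_id: {cell ids}}``."""
        return {
            int(cid): frozenset(int(c) for c in sub["cell_id"])
            for cid, sub in self.table.groupby("clone_id")
        }

    def code_of(self, cell_id: int) -> tuple[int, ...]:
        row = self.table.loc[self.table["cell_id"] == cell_id]
        if len(row) != 1:
            raise KeyError(f"cell {cell_id} not in truth table")
        return tuple(int(x) for x in row["code"].iloc[0].split("-"))


def truncated_normal_location(target_mean: float, sd: float) -> float:
    """Location μ0 such that a normal(μ0, sd) truncated at 0 has the target mean.

    The truncated mean exceeds the location, so μ0 is solved below the target
    with Brent's method; the correction matters once the target is within a
    couple of SDs of zero.
    """
    if sd <= 0:
        return target_mean
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")

    def trunc_mean(loc: float) -> float:
        a = -loc / sd
        # mean of N(loc, sd) conditioned on > 0
        return loc + sd * norm.pdf(a) / norm.sf(a)

    lo, hi = target_mean - 6 * sd, target_mean
    if trunc_mean(hi) < target_mean:  # numerically flat; no correction needed
        return target_mean
    return float(brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-10))


def _sample_separation(rng: np.random.Generator, loc: float, sd: float) -> float:
    """One draw from the zero-truncated normal (rejection; acceptance ≈ Φ(loc/sd))."""
    if sd == 0:
        return max(loc, 1e-9)
    for _ in range(1000):
        r = rng.normal(loc, sd)
        if r > 0:
            return r
    return max(loc, 1e-9)


def _abs_depth_difference_pmf(
    model: CorticalModel, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of |Δdepth| for two uniform depths in *different* layers."""
    t = model.cortical_thickness
    grid = np.arange(step / 2, t, step)
    layer_idx = np.searchsorted(np.asarray(model.boundaries), grid, side="right") - 1
    nbins = int(np.ceil(t / step)) + 1
    pmf = np.zeros(nbins)
    # O(G^2) accumulation over the depth grid; G ~ 800 for a 780 μm slab.
    for i in range(len(grid)):
        dd = np.abs(grid - grid[i])
        diff = layer_idx != layer_idx[i]
        idx = np.round(dd[diff] / step).astype(int)
        np.add.at(pmf, idx, 1.0)
    total = pmf.sum()
    if total == 0:
        raise ConfigurationError("model has a single layer; no different-layer pairs")
    return np.arange(nbins) * step, pmf / total


def _mean_pair_distance(width: float, dd_vals: np.ndarray, dd_pmf: np.ndarray) -> float:
    """E[distance] for Δx triangular on [0, width], |Δdepth| per the given pmf."""
    nx = 400
    x = np.linspace(0, width, nx + 1)[1:] - width / (2 * nx)
    fx = 2 * (width - x) / width**2
    fx /= fx.sum()
    d = np.sqrt(x[None, :] ** 2 + dd_vals[:, None] ** 2)
    return float((dd_pmf[:, None] * fx[None, :] * d).sum())


def expected_unrelated_different_layer_mean(model: CorticalModel) -> float:
    """Expected distance between two uniformly placed cells in *different*
    layers of the slab, by deterministic quadrature (no sampling)."""
    dd_vals, dd_pmf = _abs_depth_difference_pmf(model)
    return _mean_pair_distance(model.slab_width, dd_vals, dd_pmf)


def scaled_model_for_unrelated_mean(
    model: CorticalModel, target_mean: float
) -> CorticalModel:
    """Rescale the slab so unrelated different-layer pairs average ``target_mean`` μm.

    The expected distance between two independent uniform positions scales
    linearly with the slab geometry, so scaling every boundary and the width
    by ``target / current`` calibrates the unrelated-pair dispersion exactly
    while preserving layer proportions.
    """
    if target_mean <= 0:
        raise ConfigurationError("target_mean must be positive")
    current = expected_unrelated_different_layer_mean(model)
    s = target_mean / current
    return CorticalModel(
        layer_names=model.layer_names,
        boundaries=tuple(float(b * s) for b in model.boundaries),
        slab_width=model.slab_width * s,
        thickness_z=model.thickness_z,
    )


def _draw_codes(
    rng: np.random.Generator, params: SimulationParams
) -> list[tuple[int, ...]]:
    space = params.n_levels**params.n_channels - 1  # excludes the all-zero code
    n = params.n_clones
    if n > space and not params.allow_code_collisions:
        warnings.warn(
            f"{n} clones exceed the {space}-code space; drawing with collisions",
            stacklevel=3,
        )
    def decode(k: int) -> tuple[int, ...]:
        # k in [1, space]; mixed-radix expansion, never all-zero
        out = []
        for _ in range(params.n_channels):
            out.append(k % params.n_levels)
            k //= params.n_levels
        return tuple(out)

    if params.allow_code_collisions or n > space:
        ks = rng.integers(1, space + 1, size=n)
    else:
        ks = rng.choice(np.arange(1, space + 1), size=n, replace=False)
    return [decode(int(k)) for k in ks]


def _clone_sizes(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    dist = params.clone_size_distribution
    if isinstance(dist, int):
        return np.full(params.n_clones, dist, dtype=int)
    pmf = default_clone_size_pmf() if dist is None else dist
    sizes = np.array(sorted(pmf), dtype=int)
    probs = np.array([pmf[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=params.n_clones, p=probs)


def _min_sep_ok(pos: tuple[float, float], placed: list[tuple[float, float]],
                min_sep: float) -> bool:
    if min_sep <= 0 or not placed:
        return True
    arr = np.asarray(placed)
    d2 = (arr[:, 0] - pos[0]) ** 2 + (arr[:, 1] - pos[1]) ** 2
    return bool(d2.min() >= min_sep**2)


def _place_same_layer_mate(
    rng: np.random.Generator,
    anchor: tuple[float, float],
    r: float,
    model: CorticalModel,
    jitter_sd: float,
) -> tuple[float, float]:
    ax, ad = anchor
    lo, hi = model.layer_span(model.layer_of(ad))
    delta = 0.0
    for _ in range(50):
        d = rng.normal(0.0, jitter_sd)
        if abs(d) < r and lo <= ad + d < hi:
            delta = d
            break
    dx = np.sqrt(max(r**2 - delta**2, 0.0))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    x = ax + sign * dx
    if not (0.0 <= x <= model.slab_width):
        x = ax - sign * dx
    x = float(np.clip(x, 0.0, model.slab_width))
    return x, ad + delta


def _cross_feasible_ranges(
    model: CorticalModel, anchor_depth: float, r: float
) -> list[tuple[str, float, float]]:
    """Depth ranges in layers other than the anchor's reachable at separation r."""
    anchor_layer = model.layer_of(anchor_depth)
    feasible = []
    for name in model.layer_names:
        if name == anchor_layer:
            continue
        lo, hi = model.layer_span(name)
        fl, fh = max(lo, anchor_depth - r), min(hi, anchor_depth + r)
        if fh > fl:
            feasible.append((name, fl, fh))
    return feasible


def _place_cross_layer_mate(
    rng: np.random.Generator,
    anchor: tuple[float, float],
    r: float,
    model: CorticalModel,
) -> tuple[float, float]:
    """Mate at exact separation r from the anchor, landing in another layer.

    The anchor is pre-conditioned so at least one other layer is reachable;
    the separation r itself is never resampled here, keeping the configured
    cross-layer distance distribution exact.
    """
    ax, ad = anchor
    feasible = _cross_feasible_ranges(model, ad, r)
    if not feasible:  # callers precondition the anchor; fall back gracefully
        spans = [model.layer_span(n) for n in model.layer_names
                 if n != model.layer_of(ad)]
        gaps = [min(abs(ad - lo), abs(ad - hi)) for lo, hi in spans]
        lo, hi = spans[int(np.argmin(gaps))]
        depth = lo + 0.5 if abs(ad - lo) < abs(ad - hi) else hi - 0.5
        return ax, float(depth)
    name, fl, fh = feasible[rng.integers(len(feasible))]
    depth = rng.uniform(fl, fh)
    delta = depth - ad
    dx = np.sqrt(max(r**2 - delta**2, 0.0))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    x = ax + sign * dx
    if not (0.0 <= x <= model.slab_width):
        x = ax - sign * dx
    return float(np.clip(x, 0.0, model.slab_width)), depth


def simulate_clones(
    model: CorticalModel, params: SimulationParams
) -> tuple[pd.DataFrame, CloneTruth]:
    """Simulate a labeled cell table plus its ground-truth clone partition.

    Returns a cell table with columns
    ``cell_id, x_um, y_um, z_um, layer, clone_id, ch1..chK`` (``y_um`` is
    cortical depth; ``clone_id`` is nullable — NA marks unlabeled background
    cells) and a :class:`CloneTruth` mapping for labeled cells.  Fully
    reproducible from ``params.seed``.
    """
    if model.n_layers == 0:
        raise ConfigurationError("empty cortical model")
    ss = np.random.SeedSequence(params.seed)
    rng_codes, rng_place, rng_noise, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    chan_cols = [f"ch{i + 1}" for i in range(params.n_channels)]
    columns = ["cell_id", "x_um", "y_um", "z_um", "layer", "clone_id"] + chan_cols
    if params.n_clones == 0:
        empty = pd.DataFrame(columns=columns)
        empty["clone_id"] = empty["clone_id"].astype("Int64")
        truth = CloneTruth(pd.DataFrame(columns=["cell_id", "clone_id", "code"]))
        return empty, truth

    codes = _draw_codes(rng_codes, params)
    sizes = _clone_sizes(rng_place, params)
    loc_same = truncated_normal_location(
        params.same_layer_sep_mean, params.same_layer_sep_sd
    )
    loc_cross = truncated_normal_location(
        params.cross_layer_sep_mean, params.cross_layer_sep_sd
    )

    multi_layer = model.n_layers > 1
    rows: list[dict] = []
    placed: list[tuple[float, float]] = []
    cell_counter = itertools.count(0)
    truth_rows: list[dict] = []
    W, T = model.slab_width, model.cortical_thickness

    for clone_id, (code, size) in enumerate(zip(codes, sizes)):
        # designations and separations are drawn before the anchor so the
        # anchor can be conditioned on cross-layer feasibility without ever
        # resampling a separation (keeps the configured means exact)
        is_cross = [
            multi_layer and rng_place.random() < params.cross_layer_fraction
            for _ in range(size - 1)
        ]
        seps = [
            _sample_separation(
                rng_place,
                loc_cross if cross else loc_same,
                params.cross_layer_sep_sd if cross else params.same_layer_sep_sd,
            )
            for cross in is_cross
        ]
        r_cross_min = min(
            (r for r, c in zip(seps, is_cross) if c), default=None
        )
        anchor = (rng_place.uniform(0, W), rng_place.uniform(0, T))
        for attempt in range(500):
            anchor = (rng_place.uniform(0, W), rng_place.uniform(0, T))
            if not _min_sep_ok(anchor, placed, params.min_cell_separation):
                continue
            if r_cross_min is not None and not _cross_feasible_ranges(
                model, anchor[1], r_cross_min
            ):
                continue
            break
        members = [anchor]
        for cross, r in zip(is_cross, seps):
            # a mate sits exactly r from the anchor, so a requested minimum
            # cell separation truncates the separation distribution below
            tries = 0
            while r < params.min_cell_separation and tries < 100:
                r = _sample_separation(
                    rng_place,
                    loc_cross if cross else loc_same,
                    params.cross_layer_sep_sd if cross else params.same_layer_sep_sd,
                )
                tries += 1
            for attempt in range(100):
                if cross:
                    pos = _place_cross_layer_mate(rng_place, anchor, r, model)
                else:
                    pos = _place_same_layer_mate(
                        rng_place, anchor, r, model, params.depth_jitter_sd
                    )
                if _min_sep_ok(pos, placed + members, params.min_cell_separation):
                    break
            members.append(pos)
        for x, depth in members:
            cid = next(cell_counter)
            depth = float(np.clip(depth, 0.0, T))
            row = {
                "cell_id": cid,
                "x_um": float(x),
                "y_um": depth,
                "z_um": 0.0 if model.thickness_z == 0
                else float(rng_place.uniform(0, model.thickness_z)),
                "layer": model.layer_of(depth),
                "clone_id": clone_id,
            }
            for ch, lvl in zip(chan_cols, code):
                noisy = bin_center(lvl) + rng_noise.normal(0.0, params.noise_sd)
                row[ch] = float(np.clip(noisy, 0.0, 255.0))
            rows.append(row)
            placed.append((x, depth))
            truth_rows.append(
                {"cell_id": cid, "clone_id": clone_id, "code": code_to_str(code)}
            )

    # unlabeled background cells to realize the requested labeled fraction
    fr = params.labeled_fraction_per_layer
    fractions = (
        {name: fr for name in model.layer_names} if not isinstance(fr, dict) else fr
    )
    labeled_per_layer = pd.Series([r["layer"] for r in rows]).value_counts()
    for name in model.layer_names:
        f = fractions.get(name, 1.0)
        n_lab = int(labeled_per_layer.get(name, 0))
        if f >= 1.0 or n_lab == 0:
            continue
        if f <= 0.0:
            warnings.warn(
                f"layer {name!r} has labeled cells but labeled fraction 0; "
                "no background cells added",
                stacklevel=2,
            )
            continue
        n_unlab = int(round(n_lab * (1.0 - f) / f))
        lo, hi = model.layer_span(name)
        for _ in range(n_unlab):
            cid = next(cell_counter)
            depth = float(rng_bg.uniform(lo, hi))
            row = {
                "cell_id": cid,
                "x_um": float(rng_bg.uniform(0, W)),
                "y_um": depth,
                "z_um": 0.0 if model.thickness_z == 0
                else float(rng_bg.uniform(0, model.thickness_z)),
                "layer": name,
                "clone_id": pd.NA,
            }
            for ch in chan_cols:
                noisy = bin_center(0) + rng_bg.normal(0.0, params.noise_sd)
                row[ch] = float(np.clip(noisy, 0.0, 255.0))
            rows.append(row)

    table = pd.DataFrame(rows, columns=columns)
    table["clone_id"] = table["clone_id"].astype("Int64")
    truth = CloneTruth(pd.DataFrame(truth_rows, columns=["cell_id", "clone_id", "code"]))
    return table, truth
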