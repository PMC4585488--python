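"""Dispersion and laminar statistics for clonally labeled cells.

Builds the table of cell pairs (clonally related vs unrelated, same vs
different cortical layer, Euclidean distance in μm), summarizes category
dispersion as mean ± SD with Mann–Whitney comparisons, Sidak-adjusts
multiple per-layer tests, and carries the bookkeeping arithmetic for
laminar contribution fractions and the excitatory-neuron fraction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "pair_distances",
    "subsample_pairs",
    "DispersionSummary",
    "summarize_dispersion",
    "mann_whitney",
    "sidak_adjust",
    "compare_layer_counts",
    "laminar_contribution",
    "excitatory_fraction",
]

_COORD_COLS = ("x_um", "y_um", "z_um")


def _coordinates(cells: pd.DataFrame) -> np.ndarray:
    cols = [c for c in _COORD_COLS if c in cells.columns]
    if "x_um" not in cols or "y_um" not in cols:
        raise ValueError("cell table must have x_um and y_um columns")
    return cells[cols].to_numpy(dtype=float)


def pair_distances(
    cells: pd.DataFrame,
    clone_col: str = "clone_id",
    layer_col: str = "layer",
    section_col: str = "section",
    sampling_policy: str = "all",
    seed: int | None = None,
) -> pd.DataFrame:
    """All analyzed cell pairs with relatedness, layer class, and distance.

    Related pairs are all within-clone pairs; unrelated pairs are cross-clone
    pairs within the same section (``sampling_policy="all"``) or a random
    subsample of them matching the related-pair count
    (``sampling_policy="match-related"``).  Unlabeled cells (missing clone
    id) are excluded.  Distances use every coordinate column present
    (``x_um, y_um[, z_um]``).  Fewer than two labeled cells yield an empty
    table.
    """
    if sampling_policy not in ("all", "match-related"):
        raise ValueError(f"unknown sampling_policy {sampling_policy!r}")
    df = cells[cells[clone_col].notna()].reset_index(drop=True)
    cols = ["cell_id_a", "cell_id_b", "relatedness", "layer_class", "distance_um"]
    if len(df) < 2:
        return pd.DataFrame(columns=cols)
    coords = _coordinates(df)
    dmat = squareform(pdist(coords))
    clone = df[clone_col].to_numpy()
    layer = df[layer_col].to_numpy()
    ids = df["cell_id"].to_numpy()
    section = (
        df[section_col].to_numpy()
        if section_col in df.columns
        else np.zeros(len(df), dtype=int)
    )
    ia, ib = np.triu_indices(len(df), k=1)
    same_section = section[ia] == section[ib]
    ia, ib = ia[same_section], ib[same_section]
    related = clone[ia] == clone[ib]
    out = pd.DataFrame(
        {
            "cell_id_a": ids[ia],
            "cell_id_b": ids[ib],
            "relatedness": np.where(related, "related", "unrelated"),
            "layer_class": np.where(
                layer[ia] == layer[ib], "same", "different"
            ),
            "distance_um": dmat[ia, ib],
        }
    )
    if sampling_policy == "match-related":
        n_rel = int((out["relatedness"] == "related").sum())
        unrel = out[out["relatedness"] == "unrelated"]
        if len(unrel) > n_rel:
            rng = np.random.default_rng(seed)
            keep = rng.choice(unrel.index.to_numpy(), size=n_rel, replace=False)
            out = pd.concat(
                [out[out["relatedness"] == "related"], out.loc[np.sort(keep)]]
            ).reset_index(drop=True)
    return out


def subsample_pairs(
    pairs: pd.DataFrame, n_per_category: int, seed: int | None = None
) -> pd.DataFrame:
    """Subsample at most ``n_per_category`` pairs per (relatedness, layer_class)."""
    rng = np.random.default_rng(seed)
    parts = []
    for _, sub in pairs.groupby(["relatedness", "layer_class"], sort=True):
        if len(sub) > n_per_category:
            keep = rng.choice(sub.index.to_numpy(), size=n_per_category, replace=False)
            sub = sub.loc[np.sort(keep)]
        parts.append(sub)
    return pd.concat(parts).reset_index(drop=True)


@dataclass(frozen=True)
class DispersionSummary:
    """Per-category dispersion (mean ± SD) and related-vs-unrelated tests.

    ``table`` rows are indexed by (relatedness, layer_class) with the pooled
    ``"total"`` layer class included; ``tests`` holds the Mann–Whitney
    comparison of related vs unrelated distances within each layer class.
    """

    table: pd.DataFrame
    tests: pd.DataFrame


def summarize_dispersion(pairs: pd.DataFrame) -> DispersionSummary:
    """Mean ± SD of pair distances per (relatedness × layer class) category.

    Categories with no pairs are reported with ``n = 0`` and empty
    statistics.  For each layer class (and pooled) a two-sided Mann–Whitney
    test compares related vs unrelated distances when both samples are
    non-empty.
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    rows = []
    for rel in ("related", "unrelated"):
        for lc in ("same", "different", "total"):
            sub = pairs[pairs["relatedness"] == rel]
            if lc != "total":
                sub = sub[sub["layer_class"] == lc]
            d = sub["distance_um"].to_numpy()
            rows.append(
                {
                    "relatedness": rel,
                    "layer_class": lc,
                    "n": len(d),
                    "mean_um": float(d.mean()) if len(d) else None,
                    "sd_um": float(d.std(ddof=1)) if len(d) > 1 else
                    (0.0 if len(d) == 1 else None),
                }
            )
    table = pd.DataFrame(rows).set_index(["relatedness", "layer_class"])
    trows = []
    for lc in ("same", "different", "total"):
        sel = pairs if lc == "total" else pairs[pairs["layer_class"] == lc]
        a = sel.loc[sel["relatedness"] == "related", "distance_um"].to_numpy()
        b = sel.loc[sel["relatedness"] == "unrelated", "distance_um"].to_numpy()
        if len(a) and len(b):
            u, p = mann_whitney(a, b)
            trows.append({"layer_class": lc, "U": u, "p": p,
                          "n_related": len(a), "n_unrelated": len(b)})
        else:
            trows.append({"layer_class": lc, "U": None, "p": None,
                          "n_related": len(a), "n_unrelated": len(b)})
    return DispersionSummary(table=table, tests=pd.DataFrame(trows))


def _u_statistic_x2(a: np.ndarray, b: np.ndarray) -> int:
    """2·U of sample a (doubled so midrank ties stay integral)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return int(2 * gt + eq)


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann–Whitney U test; returns (U of sample_a, p).

    ``method="exact"`` enumerates every assignment of the pooled values to
    the two groups (ties handled by midrank counting); the two-sided p is
    the probability of a U at least as far from its null mean
    ``n_a·n_b / 2`` as observed.  ``method="auto"`` uses the exact test for
    joint sample sizes ≤ 12 and otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if a.size + b.size <= 12 else "asymptotic"

    if method == "asymptotic":
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        return float(res.statistic), float(res.pvalue)

    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs2 = _u_statistic_x2(a, b)
    mean2 = na * (n - na)  # 2·(na·nb/2)
    total = 0
    extreme = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u2 = _u_statistic_x2(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "two-sided":
            extreme += abs(u2 - mean2) >= abs(u_obs2 - mean2)
        elif alternative == "less":
            extreme += u2 <= u_obs2
        else:
            extreme += u2 >= u_obs2
    return u_obs2 / 2.0, extreme / total


def sidak_adjust(
    p_values: Sequence[float] | float, m: int | None = None
) -> np.ndarray | float:
    """Sidak multiple-comparison adjustment: ``p_adj = 1 − (1 − p)^m``.

    ``m`` defaults to the number of p values supplied.  Adjusted values are
    clipped into [0, 1] and are never smaller than the raw p.
    """
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    adj = np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)
    return float(adj[0]) if scalar else adj


def compare_layer_counts(
    counts_group1: Mapping[str, Sequence[float]],
    counts_group2: Mapping[str, Sequence[float]],
    layers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-layer Welch t-tests between two groups of replicate counts.

    Inputs map layer → replicate counts (≥ 2 replicates each, e.g. one count
    per brain).  Reports per layer the group means, the percent change
    ``(mean2 − mean1)/mean1 × 100``, the Welch t statistic and raw p, and
    the Sidak-adjusted p across the layers tested.
    """
    if layers is None:
        layers = [l for l in counts_group1 if l in counts_group2]
    if not layers:
        raise ValueError("no common layers to compare")
    rows = []
    for layer in layers:
        g1 = np.asarray(counts_group1[layer], dtype=float)
        g2 = np.asarray(counts_group2[layer], dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise ValueError(
                f"layer {layer!r} needs >= 2 replicates per group "
                f"(got {g1.size} and {g2.size})"
            )
        t, p = sps.ttest_ind(g2, g1, equal_var=False)
        m1, m2 = g1.mean(), g2.mean()
        rows.append(
            {
                "layer": layer,
                "mean_group1": m1,
                "mean_group2": m2,
                "percent_change": (m2 - m1) / m1 * 100.0 if m1 != 0 else np.nan,
                "t": float(t),
                "p_raw": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_sidak"] = sidak_adjust(out["p_raw"].to_numpy(), m=len(out))
    return out


#: Default grouping of cortical layers above/below the granular layer.
DEFAULT_LAYER_GROUPS: dict[str, tuple[str, ...]] = {
    "supragranular": ("L2/3", "L4"),
    "infragranular": ("L5", "L6", "SP"),
}


def laminar_contribution(
    labeled_counts: Mapping[str, float],
    total_counts: Mapping[str, float],
    layer_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fraction of labeled cells per layer, plus grouped and total aggregates.

    Aggregate fractions are count-weighted: Σ labeled / Σ total over the
    member layers.  Raises if any layer has more labeled than total cells.
    """
    groups = DEFAULT_LAYER_GROUPS if layer_groups is None else layer_groups
    rows = []
    for layer, lab in labeled_counts.items():
        tot = total_counts[layer]
        if lab > tot:
            raise ValueError(f"layer {layer!r}: labeled {lab} exceeds total {tot}")
        rows.append(
            {"layer": layer, "labeled": lab, "total": tot,
             "fraction": lab / tot if tot else np.nan}
        )
    for gname, members in groups.items():
        present = [m for m in members if m in labeled_counts]
        if not present:
            continue
        lab = sum(labeled_counts[m] for m in present)
        tot = sum(total_counts[m] for m in present)
        rows.append(
            {"layer": gname, "labeled": lab, "total": tot,
             "fraction": lab / tot if tot else np.nan}
        )
    lab = sum(labeled_counts.values())
    tot = sum(total_counts[l] for l in labeled_counts)
    rows.append(
        {"layer": "total", "labeled": lab, "total": tot,
         "fraction": lab / tot if tot else np.nan}
    )
    return pd.DataFrame(rows)


def excitatory_fraction(
    f_all: float, p_neuron: float, p_interneuron: float
) -> float:
    """Fraction of *excitatory neurons* carrying the lineage label.

    Converts a label fraction measured against all cortical cells into a
    fraction of excitatory neurons:
    ``f_all / (p_neuron · (1 − p_interneuron))``, where ``p_neuron`` is the
    neuronal share of all cells and ``p_interneuron`` the interneuron share
    of neurons.  E.g. with 30% of all cells labeled, 64% of cells neuronal
    and 25% of neurons inhibitory, 30/48 = 62.5% of excitatory neurons carry
    the label.
    """
    for name, v in (("f_all", f_all), ("p_neuron", p_neuron),
                    ("p_interneuron", p_interneuron)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = p_neuron * (1.0 - p_interneuron)
    if denom == 0.0:
        raise ZeroDivisionError("excitatory denominator is zero")
    frac = f_all / denom
    if frac > 1.0:
        warnings.warn(
            f"excitatory fraction {frac:.3f} exceeds 1; inputs are inconsistent",
            stacklevel=2,
        )
    return frac
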