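"""Laminated cortical geometry.

A :class:`CorticalModel` describes a flattened cortical slab as a stack of
named layers along the depth axis (origin at the pial surface, depth
increasing toward the white matter).  Layer intervals are half-open
``[a, b)`` so every depth in ``[0, thickness]`` maps to exactly one layer
(the white-matter boundary itself is clamped into the deepest layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "CorticalModel",
    "build_layer_model",
    "mouse_s1_model",
    "S1_LAMINAR_FRACTIONS",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent layer geometry or simulation configuration."""


@dataclass(frozen=True)
class CorticalModel:
    """Layer geometry of a cortical slab.

    Parameters
    ----------
    layer_names
        Ordered layer names from the pia downward, e.g.
        ``("L1", "L2/3", "L4", "L5", "L6", "SP")``.
    boundaries
        ``len(layer_names) + 1`` strictly increasing depths in μm; layer *i*
        occupies ``[boundaries[i], boundaries[i + 1])``.
    slab_width
        Tangential extent of the slab in μm.
    thickness_z
        Section thickness in μm; 0 selects a planar (2-D) slab.
    """

    layer_names: tuple[str, ...]
    boundaries: tuple[float, ...]
    slab_width: float = 600.0
    thickness_z: float = 0.0
    _edges: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.layer_names) == 0:
            raise ConfigurationError("at least one layer is required")
        if len(self.boundaries) != len(self.layer_names) + 1:
            raise ConfigurationError(
                f"{len(self.layer_names)} layers require "
                f"{len(self.layer_names) + 1} boundaries, "
                f"got {len(self.boundaries)}"
            )
        edges = np.asarray(self.boundaries, dtype=float)
        if edges[0] < 0:
            raise ConfigurationError("boundaries must be non-negative")
        if np.any(np.diff(edges) <= 0):
            raise ConfigurationError(
                f"boundaries must be strictly increasing, got {self.boundaries}"
            )
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ConfigurationError("layer names must be unique")
        if self.slab_width <= 0:
            raise ConfigurationError("slab_width must be positive")
        if self.thickness_z < 0:
            raise ConfigurationError("thickness_z must be non-negative")
        object.__setattr__(self, "_edges", edges)

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def cortical_thickness(self) -> float:
        """Total depth of the modeled slab (pia to the deepest boundary), μm."""
        return float(self._edges[-1])

    def layer_of(self, depth: float | np.ndarray) -> str | np.ndarray:
        """Layer name at ``depth`` (μm); half-open ``[a, b)`` intervals.

        A depth exactly on an interior boundary belongs to the deeper layer;
        ``depth == cortical_thickness`` is clamped into the deepest layer.
        """
        d = np.asarray(depth, dtype=float)
        if np.any(d < self._edges[0]) or np.any(d > self._edges[-1]):
            raise ValueError(
                f"depth outside [{self._edges[0]}, {self._edges[-1]}] μm"
            )
        idx = np.searchsorted(self._edges, d, side="right") - 1
        idx = np.clip(idx, 0, self.n_layers - 1)
        names = np.asarray(self.layer_names, dtype=object)
        out = names[idx]
        return str(out) if np.isscalar(depth) else out

    def layer_index(self, name: str) -> int:
        try:
            return self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"unknown layer {name!r}") from None

    def layer_span(self, name: str) -> tuple[float, float]:
        """``(top, bottom)`` depth interval of a layer in μm."""
        i = self.layer_index(name)
        return float(self._edges[i]), float(self._edges[i + 1])


def build_layer_model(
    layer_spec: dict[str, tuple[float, float]],
    slab_width: float = 600.0,
    thickness_z: float = 0.0,
) -> CorticalModel:
    """Build a :class:`CorticalModel` from ``{name: (top, bottom)}`` intervals.

    Intervals must be contiguous and ordered from the pia downward.
    """
    names = tuple(layer_spec)
    edges: list[float] = []
    for i, (name, (lo, hi)) in enumerate(layer_spec.items()):
        if hi <= lo:
            raise ConfigurationError(f"layer {name!r} interval {lo}–{hi} is empty")
        if i == 0:
            edges.append(float(lo))
        elif lo != edges[-1]:
            raise ConfigurationError(
                f"layer {name!r} starts at {lo} but previous layer ends at "
                f"{edges[-1]}; layers must be contiguous"
            )
        edges.append(float(hi))
    return CorticalModel(names, tuple(edges), slab_width, thickness_z)


def mouse_s1_model(slab_width: float = 600.0, thickness_z: float = 0.0) -> CorticalModel:
    """Six-layer mouse somatosensory (S1) slab with typical proportions.

    Depths are representative of early-postnatal S1 (total ≈ 780 μm).
    """
    return build_layer_model(
        {
            "L1": (0.0, 100.0),
            "L2/3": (100.0, 320.0),
            "L4": (320.0, 420.0),
            "L5": (420.0, 560.0),
            "L6": (560.0, 720.0),
            "SP": (720.0, 780.0),
        },
        slab_width=slab_width,
        thickness_z=thickness_z,
    )


#: Measured fraction of lineage-labeled cells among all cells per S1 layer
#: (mean values; usable as a labeled_fraction_per_layer preset).  L1 is set to
#: 0 — it is essentially devoid of excitatory somata in these counts.
S1_LAMINAR_FRACTIONS: dict[str, float] = {
    "L1": 0.0,
    "L2/3": 0.402,
    "L4": 0.313,
    "L5": 0.198,
    "L6": 0.290,
    "SP": 0.272,
}
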