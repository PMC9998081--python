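"""Grammar-of-graphics scene construction for protein structures.

A :class:`Layout` binds a structure to a grid of panels; geoms (ribbon,
sphere, surface) are layered onto panels, each colored either by a fixed
color or by a feature track through a named palette.  ``render()``
compiles the scene to a deterministic, viewer-neutral JSON document with
the structure embedded as PDB text and every layer fully resolved
(concrete atom serials and per-residue hex colors).  Actual display is
delegated to external viewers; :func:`write_attributes` emits ChimeraX
defattr files for the same purpose.

Typical use::

    ly = Layout(model, panel_size=(200, 200), grid=(1, 3), linked=True)
    mask = ly.select(residues=positive, elements=["CA"], chain="A")
    ly.geom_ribbon(color="#ffffff")
    ly.geom_sphere(selection=mask, color="black")
    ly.geom_surface("hotspots", palette="binary", panel=(0, 1))
    ly.geom_surface("clusters", palette="Set2_r", panel=(0, 2))
    doc = ly.render()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structure import Fold, write_pdb

__all__ = ["Selection", "Layout", "SceneDocument", "layout", "write_attributes",
           "PALETTES"]

# ColorBrewer Set2; "binary" maps low -> white, high -> black.
_SET2 = ["#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3",
         "#a6d854", "#ffd92f", "#e5c494", "#b3b3b3"]
PALETTES: dict[str, list[str]] = {
    "binary": ["#ffffff", "#000000"],
    "greys": ["#f7f7f7", "#636363"],
    "Set2": _SET2,
    "Set2_r": _SET2[::-1],
    "viridis": ["#440154", "#3b528b", "#21918c", "#5ec962", "#fde725"],
}

_NAMED_COLORS = {
    "black": "#000000", "white": "#ffffff", "red": "#ff0000",
    "green": "#008000", "blue": "#0000ff", "grey": "#808080",
    "gray": "#808080", "orange": "#ffa500", "yellow": "#ffff00",
}


def _as_hex(color: str) -> str:
    c = color.lower()
    if c in _NAMED_COLORS:
        return _NAMED_COLORS[c]
    if c.startswith("#") and len(c) == 7:
        return c
    raise ValueError(f"unknown color {color!r} (use a name or #rrggbb)")


def _interp_hex(palette: list[str], t: float) -> str:
    """Linear interpolation along an ordered hex color list, t in [0, 1]."""
    rgb = np.array([[int(h[i:i + 2], 16) for i in (1, 3, 5)] for h in palette], float)
    pos = t * (len(palette) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(palette) - 1)
    frac = pos - lo
    mix = rgb[lo] * (1 - frac) + rgb[hi] * frac
    return "#" + "".join(f"{int(round(v)):02x}" for v in mix)


def track_colors(values: np.ndarray, palette: str) -> list[str]:
    """Per-residue colors: min-max normalize, then interpolate the palette."""
    if palette not in PALETTES:
        raise ValueError(f"unknown palette {palette!r} (have {sorted(PALETTES)})")
    v = np.asarray(values, dtype=float)
    span = np.ptp(v)
    t = np.zeros_like(v) if span == 0 else (v - v.min()) / span
    return [_interp_hex(PALETTES[palette], ti) for ti in t]


@dataclass
class Selection:
    """A (residues, atom elements, chain) filter resolved against a Fold."""

    residues: list[int] | None = None  # None = all
    elements: list[str] | None = None  # atom-name filter, None = all
    chain: str | None = None

    def resolve(self, fold: Fold) -> list[tuple[int, int]]:
        """Concrete (residue_index, atom_serial) pairs for this fold."""
        if self.chain is not None and self.chain not in fold.chains:
            raise KeyError(f"chain {self.chain!r} not present (have {fold.chains})")
        wanted = None if self.residues is None else set(self.residues)
        out = []
        for r in fold.residues:
            if self.chain is not None and r.chain_id != self.chain:
                continue
            if wanted is not None and r.index not in wanted:
                continue
            for a in r.atoms:
                if self.elements is not None and a.name not in self.elements:
                    continue
                out.append((r.index, a.serial))
        return out


def _normalize_residues(fold: Fold, residues) -> list[int] | None:
    """Accept an index list or a 0/1 (boolean) mask of length n."""
    if residues is None:
        return None
    arr = np.asarray(residues)
    n = len(fold)
    if arr.dtype == bool or (len(arr) == n and set(np.unique(arr)) <= {0, 1}):
        return [int(i) for i in np.flatnonzero(arr)]
    return [int(i) for i in arr]


@dataclass
class _Layer:
    kind: str
    panel: tuple[int, int]
    selection: Selection | None
    color: str | None
    track: str | None
    palette: str | None


class Layout:
    """A scene: a structure bound to a grid of panels plus ordered layers."""

    def __init__(self, fold: Fold, panel_size: tuple[int, int] = (200, 200),
                 grid: tuple[int, int] = (1, 1), linked: bool = False):
        rows, cols = grid
        w, h = panel_size
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if w <= 0 or h <= 0:
            raise ValueError("panel_size must be positive")
        self.fold = fold
        self.grid = (int(rows), int(cols))
        self.panel_size = (int(w), int(h))
        self.linked = bool(linked)
        self.layers: list[_Layer] = []

    def select(self, residues=None, elements=None, chain=None) -> Selection:
        """Build a selection against this layout's structure.

        ``residues`` may be an index list or a 0/1 mask of length n.
        """
        sel = Selection(_normalize_residues(self.fold, residues), elements, chain)
        sel.resolve(self.fold)  # validate eagerly (unknown chain, etc.)
        return sel

    def _add(self, kind, selection, color, track, palette, panel):
        if color is not None and track is not None:
            raise ValueError("a layer takes either a color or a track+palette, not both")
        if track is not None:
            if track not in self.fold.tracks:
                raise ValueError(
                    f"unknown track {track!r} (have {sorted(self.fold.tracks)})"
                )
            if palette is None:
                palette = "viridis"
            if palette not in PALETTES:
                raise ValueError(f"unknown palette {palette!r}")
        else:
            color = _as_hex(color) if color is not None else "#808080"
            palette = None
        r, c = panel
        if not (0 <= r < self.grid[0] and 0 <= c < self.grid[1]):
            raise ValueError(f"panel {panel} outside grid {self.grid} (0-based)")
        self.layers.append(_Layer(kind, (int(r), int(c)), selection, color, track, palette))
        return self

    def geom_ribbon(self, selection=None, color=None, track=None,
                    palette=None, panel=(0, 0)):
        return self._add("ribbon", selection, color, track, palette, panel)

    def geom_sphere(self, selection=None, color=None, track=None,
                    palette=None, panel=(0, 0)):
        return self._add("sphere", selection, color, track, palette, panel)

    def geom_surface(self, track=None, selection=None, color=None,
                     palette=None, panel=(0, 0)):
        return self._add("surface", selection, color, track, palette, panel)

    def render(self) -> "SceneDocument":
        """Compile to a deterministic scene document (JSON-serializable)."""
        if not self.layers:
            raise ValueError("cannot render an empty scene (add a geom first)")
        fold = self.fold
        layers = []
        for ly in self.layers:
            pairs = (ly.selection or Selection()).resolve(fold)
            entry = {
                "kind": ly.kind,
                "panel": list(ly.panel),
                "atom_serials": [serial for _, serial in pairs],
            }
            if ly.track is not None:
                colors = track_colors(fold.tracks[ly.track], ly.palette)
                entry["track"] = ly.track
                entry["palette"] = ly.palette
                entry["residue_colors"] = {
                    str(i): colors[i] for i in sorted({ri for ri, _ in pairs})
                }
            else:
                entry["color"] = ly.color
            layers.append(entry)
        doc = {
            "scene_version": 1,
            "grid": list(self.grid),
            "panel_size": list(self.panel_size),
            "linked": self.linked,
            "n_panels": self.grid[0] * self.grid[1],
            "structure_pdb": write_pdb(fold),
            "layers": layers,
        }
        return SceneDocument(doc)


def layout(fold: Fold, panel_size=(200, 200), grid=(1, 1), linked=False) -> Layout:
    """Functional alias for :class:`Layout`."""
    return Layout(fold, panel_size=panel_size, grid=grid, linked=linked)


@dataclass
class SceneDocument:
    """A resolved scene; serializes byte-identically for identical input."""

    document: dict

    def to_json(self) -> str:
        return json.dumps(self.document, sort_keys=True, separators=(",", ":"))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    def show(self) -> "SceneDocument":
        """Display is delegated to external viewers; summarize instead."""
        n_layers = len(self.document["layers"])
        print(f"Scene: {self.document['n_panels']} panel(s), {n_layers} layer(s)")
        return self

    @property
    def n_panels(self) -> int:
        return self.document["n_panels"]

    @property
    def layers(self) -> list[dict]:
        return self.document["layers"]


def write_attributes(fold: Fold, track: str, path) -> None:
    """Write one track as a ChimeraX defattr-format attribute file.

    Header line ``attribute: <name>``, then one record per residue:
    ``\\t/<chain>:<author_number><icode>\\t<value>`` at full precision.
    """
    if track not in fold.tracks:
        raise ValueError(f"unknown track {track!r} (have {sorted(fold.tracks)})")
    values = fold.tracks[track]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"attribute: {track}\n")
        for r in fold.residues:
            spec = f"/{r.chain_id}:{r.author_number}{r.insertion_code}"
            fh.write(f"\t{spec}\t{float(values[r.index])!r}\n")
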