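"""Deterministic synthetic structures and feature patterns.

Every generator is reproducible (pure geometry or seeded RNG) so the
whole toolkit is testable without downloading structures.  Fixtures are
CA-only (geometrically idealized, not physically realistic backbones);
the two-chain variant adds CB atoms so heavy-atom distance modes have
more than one atom per residue.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Fold, Complex, Residue

__all__ = ["make_helix", "make_two_blob", "make_two_chain", "plant_feature"]


def _ca_fold(coords: np.ndarray, chain: str = "A", res_name: str = "GLY",
             cls=Fold, start_serial: int = 1, start_number: int = 1):
    residues = [
        Residue(
            chain,
            start_number + i,
            res_name,
            [Atom(start_serial + i, "CA", "C", xyz)],
        )
        for i, xyz in enumerate(np.asarray(coords, dtype=float))
    ]
    return cls(residues)


def make_helix(n: int, rise: float = 1.5, twist: float = 100.0,
               radius: float = 2.3) -> Fold:
    """CA-only ideal helix, alpha-helix-like by default.

    Residue i sits at (radius*cos(i*twist), radius*sin(i*twist), i*rise)
    with twist in degrees; chain A, GLY residues.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    t = np.deg2rad(twist) * i
    coords = np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * i])
    fold = _ca_fold(coords)
    fold.source = f"<helix n={n}>"
    return fold


def make_two_blob(n1: int = 20, n2: int = 20, separation: float = 50.0,
                  seed: int = 0, sd: float = 2.0) -> Fold:
    """Two Gaussian CA point clouds (s.d. ``sd`` Angstrom) centered at the
    origin and at (separation, 0, 0); deterministic under ``seed``."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n1, 3))
    b = rng.normal(0.0, sd, size=(n2, 3)) + np.array([separation, 0.0, 0.0])
    fold = _ca_fold(np.vstack([a, b]))
    fold.source = f"<two_blob {n1}+{n2} sep={separation:g} seed={seed}>"
    return fold


def make_two_chain(n: int = 10, spacing: float = 3.8,
                   separation: float = 4.0) -> Complex:
    """Two parallel n-residue strands (chains A and B) ``separation``
    Angstrom apart along y; each residue carries CA plus a CB offset
    1.5 Angstrom in z, for heavy-atom distance tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    residues = []
    serial = 1
    for chain, y in (("A", 0.0), ("B", separation)):
        for i in range(n):
            x = i * spacing
            ca = Atom(serial, "CA", "C", (x, y, 0.0))
            cb = Atom(serial + 1, "CB", "C", (x, y, 1.5))
            serial += 2
            residues.append(Residue(chain, i + 1, "ALA", [ca, cb]))
    cx = Complex(residues)
    cx.source = f"<two_chain n={n} sep={separation:g}>"
    return cx


def plant_feature(fold: Fold, center_index: int, radius: float):
    """Binary track: 1 for residues whose CA lies within ``radius`` of the
    center residue's CA, else 0 (emulates a spatially clustered signal
    such as sites under positive selection)."""
    from .spatial import FeatureTrack
    from .structure import ca_coords

    n = len(fold)
    if not 0 <= center_index < n:
        raise ValueError(f"center_index {center_index} out of range 0..{n - 1}")
    coords = ca_coords(fold)
    d = np.linalg.norm(coords - coords[center_index], axis=1)
    return FeatureTrack(f"planted_r{radius:g}", (d <= radius).astype(float))
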