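"""Attach named feature tracks to structures and export them as tidy tables.

A track is any per-residue vector: a plain list, a hotspot result
(contributing its hot flags as 0/1) or cluster labels (contributing the
integer assignment).  The export is one row per residue with fixed
columns ``chain, residue_index, author_number, res_name`` followed by
the tracks in insertion order — a tidy frame usable without modification
by downstream tools.
"""

from __future__ import annotations

import pandas as pd

from .structure import Fold

__all__ = ["annotate", "annotate_many", "to_table", "write_table", "read_table"]

FIXED_COLUMNS = ["chain", "residue_index", "author_number", "res_name"]


def annotate(fold: Fold, name: str, values) -> Fold:
    """Attach (or overwrite) one named per-residue track; returns the fold."""
    return fold.annotate_(name, values)


def annotate_many(fold: Fold, named_values: dict) -> Fold:
    """Attach several tracks at once, preserving insertion order."""
    return fold.annotate_many_(named_values)


def to_table(fold: Fold) -> pd.DataFrame:
    """Export all annotations as a data frame, one row per residue.

    Row i corresponds to residue index i; column order is the fixed
    columns followed by tracks in insertion order.
    """
    data = {
        "chain": [r.chain_id for r in fold.residues],
        "residue_index": [r.index for r in fold.residues],
        "author_number": [r.author_number for r in fold.residues],
        "res_name": [r.res_name for r in fold.residues],
    }
    for name, values in fold.tracks.items():
        data[name] = values
    return pd.DataFrame(data)


def write_table(fold: Fold, path, sep: str = "\t", comments: list[str] | None = None) -> None:
    """Write the annotation table as TSV (default) or CSV, UTF-8.

    Optional ``comments`` are emitted first as ``# key=value`` lines.
    """
    table = to_table(fold)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a table written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep=sep, comment="#")
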