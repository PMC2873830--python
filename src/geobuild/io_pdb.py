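"""File I/O: PDB coordinate files, xyz output, and the distance-list
format.

PDB files are read with :mod:`gemmi`, which parses the fixed-column
format strictly and preserves file order.  The distance-list format is
one line per unordered pair — ``i<TAB>j<TAB>distance`` with 1-based
indices and ≥15 significant digits — preceded by a ``#n=<atom count>``
header, so exact instances round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .core import ReconstructionResult, SparseDistanceSet, Structure
from .errors import EmptySelection, IndexOutOfRange, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "PdbSelection",
    "read_pdb",
    "write_structure",
    "read_distance_list",
    "write_distance_list",
    "read_xyz",
]


@dataclass
class PdbSelection:
    """Which atoms of a PDB entry to keep.

    Defaults: first model, ATOM records only, hydrogens included,
    altloc blank or 'A'.
    """

    model_index: int = 1  # 1-based
    include_hetatm: bool = False
    include_hydrogens: bool = True
    altlocs: tuple[str, ...] = ("", "A")

    def __post_init__(self) -> None:
        if self.model_index < 1:
            raise ValueError("model_index is 1-based")


def read_pdb(path: str | Path, sel: PdbSelection | None = None) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Atoms appear in file order; coordinates are taken from the
    fixed-column fields in Å.  Raises :class:`ParseError` on malformed
    files and :class:`EmptySelection` when no atom survives the
    selection.
    """
    sel = sel or PdbSelection()
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) < sel.model_index:
        raise EmptySelection(
            f"{path} has {len(st)} model(s); model {sel.model_index} requested"
        )
    model = st[sel.model_index - 1]

    allowed_altlocs = {a for a in sel.altlocs if a}
    if "" in sel.altlocs:
        allowed_altlocs.add("\0")  # gemmi stores a blank altloc as '\0'

    coords: list[list[float]] = []
    labels: list[tuple] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H" and not sel.include_hetatm:
                continue
            for atom in residue:
                if atom.altloc not in allowed_altlocs:
                    continue
                if not sel.include_hydrogens and atom.is_hydrogen():
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                labels.append(
                    (atom.name, residue.name, residue.seqid.num, chain.name)
                )
    if not coords:
        raise EmptySelection(f"no atoms match the selection in {path}")
    return Structure(coords=np.asarray(coords), labels=labels)


def write_structure(
    result: ReconstructionResult, path: str | Path, format: str = "xyz"
) -> None:
    """Write the positioned atoms of a reconstruction.

    ``xyz`` keeps full precision; ``pdb`` uses the fixed 8.3f coordinate
    columns.  Unpositioned atoms are omitted with a warning.
    """
    if result.status == "failed":
        raise ValueError("nothing to write for a failed reconstruction")
    ids = result.positioned_ids()
    n_skip = result.structure.n_atoms - len(ids)
    if n_skip:
        logger.warning("omitting %d unpositioned atom(s) from %s", n_skip, path)
    coords = result.structure.coords
    labels = result.structure.labels
    path = Path(path)
    if format == "xyz":
        lines = [str(len(ids)), f"geobuild {result.algorithm} reconstruction"]
        for i in ids:
            name = labels[i][0] if labels else "C"
            element = name.strip()[:1] or "C"
            x, y, z = coords[i]
            lines.append(f"{element} {x:.10f} {y:.10f} {z:.10f}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "pdb":
        lines = []
        for serial, i in enumerate(ids, start=1):
            if labels:
                name, resname, resseq, chain = labels[i]
            else:
                name, resname, resseq, chain = "CA", "GLY", serial, "A"
            x, y, z = coords[i]
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s}{resname:>4.3s} {str(chain)[:1]}"
                f"{int(resseq):4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("format must be 'xyz' or 'pdb'")


def read_xyz(path: str | Path) -> Structure:
    """Read an xyz file written by :func:`write_structure`."""
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0])
        rows = [line.split() for line in lines[2 : 2 + n]]
        coords = np.array([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"malformed xyz file {path}: {exc}") from exc
    if len(coords) != n:
        raise ParseError(f"{path}: expected {n} atoms, found {len(coords)}")
    return Structure(coords=coords)


def write_distance_list(dset: SparseDistanceSet, path: str | Path) -> None:
    """TSV distance list, 1-based indices, 17 significant digits."""
    lines = [f"#n={dset.n}"]
    for (i, j), d in sorted(dset.entries.items()):
        lines.append(f"{i + 1}\t{j + 1}\t{d:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_distance_list(path: str | Path) -> SparseDistanceSet:
    """Read the TSV distance-list format back into a
    :class:`SparseDistanceSet` (exact round-trip)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#n="):
        raise ParseError(f"{path}: missing '#n=' header")
    try:
        n = int(lines[0][3:])
    except ValueError as exc:
        raise ParseError(f"{path}: bad atom count header") from exc
    dset = SparseDistanceSet(n=n)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'i<TAB>j<TAB>distance'")
        try:
            i, j, d = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if i == j:
            raise ParseError(f"{path}:{lineno}: self-pair {i}")
        if not (1 <= i <= n and 1 <= j <= n):
            raise IndexOutOfRange(f"{path}:{lineno}: index outside 1..{n}")
        try:
            dset.add(i - 1, j - 1, d)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return dset
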