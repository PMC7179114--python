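"""Structure and ensemble I/O.

Two on-disk representations are supported for decoy ensembles of a single
target protein:

* multi-model PDB (``MODEL``/``ENDMDL`` records, CA atoms only), readable by
  any molecular viewer;
* a flat coordinate table — one row per decoy, ``3n`` whitespace-separated
  coordinates (plus an optional trailing lRMSD label column) and a ``#``
  header line carrying the target id — stored either as plain text or as
  HDF5.

PDB reading goes through Biopython's :class:`Bio.PDB.PDBParser` and follows
the common CA-trace dialect: first model only, altloc blank or ``'A'`` only,
insertion codes honored in residue order, HETATM ignored.  All coordinates
are in Å; internal indexing is 0-based.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import EmptySelectionError, PDBParseError, ShapeError

__all__ = [
    "Conformation",
    "DecoyEnsemble",
    "read_ca_trace",
    "read_ensemble",
    "write_ensemble",
]

DIFFICULTIES = ("easy", "medium", "hard")


@dataclass
class Conformation:
    """One structure's CA trace: an ``n x 3`` array of Å positions.

    ``label`` is the structure's lRMSD from the native structure (Å), when
    known; ``id`` is a free-form identifier.
    """

    coords: np.ndarray
    label: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(
                f"conformation coordinates must be n x 3, got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ShapeError("conformation must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("conformation coordinates must be finite")
        if self.label is not None and self.label < 0:
            raise ShapeError("lRMSD label must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Flattened 3n coordinate vector (x1, y1, z1, x2, ...)."""
        return self.coords.reshape(-1)


@dataclass
class DecoyEnsemble:
    """An ordered set of conformations of one target protein.

    All members share the same atom count.  ``native`` optionally holds the
    experimentally determined structure used for lRMSD labeling, and
    ``difficulty`` tags the target by the quality of its decoy set.
    """

    conformations: list[Conformation]
    target_id: str = ""
    difficulty: str | None = None
    native: Conformation | None = None

    def __post_init__(self) -> None:
        if not self.conformations:
            raise ShapeError("ensemble must contain at least one conformation")
        n = self.conformations[0].n_atoms
        for i, c in enumerate(self.conformations):
            if c.n_atoms != n:
                raise ShapeError(
                    f"member {i} has {c.n_atoms} atoms, expected {n}"
                )
        if self.difficulty is not None and self.difficulty not in DIFFICULTIES:
            raise ShapeError(
                f"difficulty must be one of {DIFFICULTIES}, got {self.difficulty!r}"
            )
        if self.native is not None and self.native.n_atoms != n:
            raise ShapeError("native structure atom count differs from ensemble")

    def __len__(self) -> int:
        return len(self.conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self.conformations[i]

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    @property
    def n_residues(self) -> int:
        return self.conformations[0].n_atoms

    def coords_matrix(self) -> np.ndarray:
        """Stack all members into an ``m x 3n`` matrix of flattened coordinates."""
        return np.stack([c.flat for c in self.conformations])

    def labels(self) -> np.ndarray | None:
        """lRMSD labels as an m-vector, or None if any member is unlabeled."""
        vals = [c.label for c in self.conformations]
        if any(v is None for v in vals):
            return None
        return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _pdb_handle(pdb_source) -> io.TextIOBase:
    """Accept a path, raw PDB text, or an open text handle."""
    if hasattr(pdb_source, "read"):
        return pdb_source
    if isinstance(pdb_source, Path):
        return open(pdb_source)
    if isinstance(pdb_source, str):
        # Raw PDB text contains newlines or record names; a path does not.
        if "\n" in pdb_source:
            return io.StringIO(pdb_source)
        if os.path.exists(pdb_source):
            return open(pdb_source)
        return io.StringIO(pdb_source)
    raise TypeError(f"cannot read PDB from {type(pdb_source)!r}")


def _ca_coords_of_model(model, chain_id: str | None) -> np.ndarray:
    coords = []
    chains = list(model)
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
    elif chains:
        chains = chains[:1]  # default: first chain encountered
    for ch in chains:
        for res in ch:
            if res.id[0] != " ":  # HETATM / water
                continue
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                children = {a.get_altloc(): a for a in atom.disordered_get_list()}
                atom = children.get(" ") or children.get("A")
                if atom is None:
                    continue
            coords.append(atom.get_coord())
    if not coords:
        where = f"chain {chain_id!r}" if chain_id else "first chain"
        raise EmptySelectionError(f"no CA atoms found for {where}")
    # PDB fixed columns carry exactly 3 decimals; rounding restores the
    # printed decimal values lost to the parser's float32 storage
    return np.round(np.asarray(coords, dtype=float), 3)


def read_ca_trace(pdb_source, chain: str | None = None, id: str = "") -> Conformation:
    """Extract the CA trace of the first model of a PDB file or text.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, raw PDB text, or an open text handle.
    chain
        Single-character chain id; defaults to the first chain encountered.

    Raises
    ------
    EmptySelectionError
        If no CA atoms match the requested chain.
    PDBParseError
        If an ATOM record is malformed; the message names the line.
    """
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure(id or "structure", _pdb_handle(pdb_source))
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    models = list(structure)
    if not models:
        raise EmptySelectionError("PDB source contains no models")
    coords = _ca_coords_of_model(models[0], chain)
    return Conformation(coords=coords, id=id)


def _write_model_records(handle, coords: np.ndarray, serial_start: int = 1) -> None:
    for i, (x, y, z) in enumerate(coords):
        handle.write(
            "ATOM  {serial:5d}  CA  ALA A{resseq:4d}    "
            "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n".format(
                serial=serial_start + i, resseq=i + 1, x=x, y=y, z=z
            )
        )


def write_multimodel_pdb(ensemble: DecoyEnsemble, path) -> None:
    """Write an ensemble as a CA-only multi-model PDB (MODEL/ENDMDL)."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   6 decoyfeat ensemble target_id={ensemble.target_id}\n")
        for k, conf in enumerate(ensemble, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            _write_model_records(fh, conf.coords)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path, target_id: str | None = None) -> DecoyEnsemble:
    """Read every model's CA trace from a multi-model PDB."""
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure("ensemble", _pdb_handle(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"malformed PDB record: {exc}") from exc
    confs = []
    for k, model in enumerate(structure):
        coords = _ca_coords_of_model(model, None)
        confs.append(Conformation(coords=coords, id=f"model_{k}"))
    if not confs:
        raise EmptySelectionError("no models in PDB source")
    return DecoyEnsemble(conformations=confs, target_id=target_id or "")


# ---------------------------------------------------------------------------
# Coordinate-table reading / writing (text and HDF5)
# ---------------------------------------------------------------------------


def _header_line(ensemble: DecoyEnsemble, labeled: bool) -> str:
    diff = ensemble.difficulty or "none"
    return (
        f"# decoyfeat target_id={ensemble.target_id or 'unknown'} "
        f"n_residues={ensemble.n_residues} difficulty={diff} "
        f"labeled={int(labeled)}\n"
    )


def _write_coords_text(ensemble: DecoyEnsemble, path) -> None:
    labels = ensemble.labels()
    with open(path, "w") as fh:
        fh.write(_header_line(ensemble, labels is not None))
        for i, conf in enumerate(ensemble):
            row = " ".join(format(v, ".17g") for v in conf.flat)
            if labels is not None:
                row += " " + format(labels[i], ".17g")
            fh.write(row + "\n")


def _read_coords_text(path) -> DecoyEnsemble:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
        )
        n_res = int(meta["n_residues"])
        labeled = bool(int(meta.get("labeled", "0")))
        expected = 3 * n_res + (1 if labeled else 0)
        confs = []
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            vals = [float(v) for v in line.split()]
            if len(vals) != expected:
                raise ShapeError(
                    f"member {i}: expected {expected} values per row, got {len(vals)}"
                )
            label = vals.pop() if labeled else None
            confs.append(
                Conformation(
                    coords=np.asarray(vals).reshape(n_res, 3),
                    label=label,
                    id=f"{meta.get('target_id', '')}_{i}",
                )
            )
    diff = meta.get("difficulty")
    return DecoyEnsemble(
        conformations=confs,
        target_id=meta.get("target_id", ""),
        difficulty=None if diff in (None, "none") else diff,
    )


def _write_coords_hdf5(ensemble: DecoyEnsemble, path) -> None:
    import h5py

    labels = ensemble.labels()
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=ensemble.coords_matrix())
        if labels is not None:
            f.create_dataset("labels", data=labels)
        f.attrs["target_id"] = ensemble.target_id or ""
        f.attrs["n_residues"] = ensemble.n_residues
        f.attrs["difficulty"] = ensemble.difficulty or "none"


def _read_coords_hdf5(path) -> DecoyEnsemble:
    import h5py

    with h5py.File(path, "r") as f:
        coords = np.asarray(f["coords"])
        labels = np.asarray(f["labels"]) if "labels" in f else None
        target_id = str(f.attrs.get("target_id", ""))
        n_res = int(f.attrs["n_residues"])
        diff = str(f.attrs.get("difficulty", "none"))
    if coords.ndim != 2 or coords.shape[1] != 3 * n_res:
        raise ShapeError(
            f"coordinate matrix has shape {coords.shape}, expected (m, {3 * n_res})"
        )
    confs = [
        Conformation(
            coords=row.reshape(n_res, 3),
            label=None if labels is None else float(labels[i]),
            id=f"{target_id}_{i}",
        )
        for i, row in enumerate(coords)
    ]
    return DecoyEnsemble(
        conformations=confs,
        target_id=target_id,
        difficulty=None if diff == "none" else diff,
    )


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "multi-model-pdb"
    if suffix in (".h5", ".hdf5"):
        return "coords-hdf5"
    return "coords-table"


def write_ensemble(ensemble: DecoyEnsemble, path, format: str | None = None) -> None:
    """Write an ensemble; format inferred from the extension unless given.

    ``multi-model-pdb`` keeps 3 decimals (PDB fixed columns); the text
    ``coords-table`` round-trips coordinates bit-comparably; ``coords-hdf5``
    stores them exactly in binary.
    """
    fmt = _infer_format(path, format)
    if fmt == "multi-model-pdb":
        write_multimodel_pdb(ensemble, path)
    elif fmt == "coords-table":
        _write_coords_text(ensemble, path)
    elif fmt == "coords-hdf5":
        _write_coords_hdf5(ensemble, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_ensemble(path, format: str | None = None) -> DecoyEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    fmt = _infer_format(path, format)
    if fmt == "multi-model-pdb":
        return read_multimodel_pdb(path)
    if fmt == "coords-table":
        return _read_coords_text(path)
    if fmt == "coords-hdf5":
        return _read_coords_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")
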