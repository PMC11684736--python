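"""Reading molecular geometries and writing screening matrices.

Supported coordinate formats: xyz, pdb (ATOM/HETATM records, MODEL 1 only)
and mol2 (@<TRIPOS>ATOM section). One molecule or conformation per file; the
hard-sphere model is purely the printed coordinates plus a van der Waals
radius looked up per element — no protonation, bond perception or
sanitization. All coordinates are interpreted in angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SphereSet

__all__ = [
    "RadiiTable",
    "AtomRecord",
    "MoleculeFile",
    "MolFileError",
    "load_radii_table",
    "read_geometry",
    "read_geometry_set",
    "write_screen_matrix",
]

_FORMATS = ("xyz", "pdb", "mol2")


class MolFileError(ValueError):
    """Malformed molecule file, unknown element, or invalid radii table."""


def normalize_symbol(sym: str) -> str:
    """Case-normalize an element symbol: 'CL' -> 'Cl', 'br' -> 'Br'."""
    sym = sym.strip()
    return sym[:1].upper() + sym[1:].lower()


@dataclass(frozen=True)
class AtomRecord:
    """A parsed atom: element, position (angstrom), and source line number
    (1-based, for error reporting)."""

    element: str
    position: tuple[float, float, float]
    line: int


@dataclass(frozen=True)
class MoleculeFile:
    """A coordinate file plus its format tag and molecule label."""

    path: Path
    fmt: str
    label: str

    @classmethod
    def from_path(cls, path: str | Path, fmt: str | None = None, label: str | None = None) -> "MoleculeFile":
        path = Path(path)
        if fmt is None:
            fmt = path.suffix.lstrip(".").lower()
        if fmt not in _FORMATS:
            raise MolFileError(
                f"{path}: unrecognized format {fmt!r} (expected one of {', '.join(_FORMATS)})"
            )
        return cls(path=path, fmt=fmt, label=label or path.stem)


class RadiiTable:
    """Mapping from case-normalized element symbol to a positive van der
    Waals radius (angstrom)."""

    _REQUIRED = ("H", "C", "N", "O", "F", "S", "Cl", "Br", "I")

    def __init__(self, radii: dict[str, float]):
        table: dict[str, float] = {}
        for sym, r in radii.items():
            sym = normalize_symbol(sym)
            r = float(r)
            if r <= 0:
                raise MolFileError(f"radius for element {sym!r} must be positive, got {r:g}")
            table[sym] = r
        self._radii = table

    def __contains__(self, sym: str) -> bool:
        return normalize_symbol(sym) in self._radii

    def __getitem__(self, sym: str) -> float:
        key = normalize_symbol(sym)
        try:
            return self._radii[key]
        except KeyError:
            raise MolFileError(f"no van der Waals radius known for element {sym!r}") from None

    def items(self):
        return self._radii.items()

    def updated(self, other: "RadiiTable") -> "RadiiTable":
        merged = dict(self._radii)
        merged.update(other._radii)
        return RadiiTable(merged)

    def validate(self) -> None:
        missing = [s for s in self._REQUIRED if s not in self._radii]
        if missing:
            raise MolFileError(f"radii table is missing required elements: {', '.join(missing)}")


def _parse_radii_lines(lines, source: str) -> dict[str, float]:
    radii: dict[str, float] = {}
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MolFileError(f"{source}, line {i}: expected 'element radius', got {raw.strip()!r}")
        sym, val = parts
        try:
            r = float(val)
        except ValueError:
            raise MolFileError(f"{source}, line {i}: radius {val!r} is not a number") from None
        if r <= 0:
            raise MolFileError(f"{source}, line {i}: radius for element {sym!r} must be positive, got {r:g}")
        radii[normalize_symbol(sym)] = r
    return radii


def load_radii_table(path: str | Path | None = None) -> RadiiTable:
    """Load the packaged default radii table, element-wise overridden by the
    optional user table (two-column element/radius text)."""
    default_text = resources.files("molcage.data").joinpath("vdw_radii.txt").read_text()
    table = RadiiTable(_parse_radii_lines(default_text.splitlines(), "packaged radii table"))
    table.validate()
    if path is not None:
        path = Path(path)
        user = RadiiTable(_parse_radii_lines(path.read_text().splitlines(), str(path)))
        table = table.updated(user)
    return table


# ---------------------------------------------------------------------------
# coordinate-file parsers


def _parse_xyz(lines: list[str], source: str) -> list[AtomRecord]:
    # standard xyz: atom count, comment line, then one atom per line; parsed
    # tolerantly (a file without the two header lines is accepted too)
    start = 0
    if lines and lines[0].split() and lines[0].split()[0].lstrip("+-").isdigit():
        start = 2
    records = []
    for i in range(start, len(lines)):
        line = lines[i].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise MolFileError(f"{source}, line {i + 1}: expected 'element x y z', got {line!r}")
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise MolFileError(f"{source}, line {i + 1}: non-numeric coordinate in {line!r}") from None
        records.append(AtomRecord(parts[0], (x, y, z), i + 1))
    return records


def _pdb_element(line: str, lineno: int, source: str) -> str:
    # columns 77-78 when present, else inferred from the atom-name field
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if not elem:
        name = line[12:16]
        letters = "".join(ch for ch in name.strip() if ch.isalpha())
        if not letters:
            raise MolFileError(f"{source}, line {lineno}: cannot infer element from atom name {name!r}")
        # a name starting in column 13 carries a two-letter symbol (CL, BR, FE...);
        # names starting in column 14 are one-letter elements (CA = alpha carbon)
        two_letter = len(name) >= 1 and name[0] != " " and len(letters) >= 2
        elem = letters[:2] if two_letter else letters[:1]
    return elem


def _parse_pdb(lines: list[str], source: str) -> list[AtomRecord]:
    records = []
    in_model = 0
    for i, line in enumerate(lines, start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            in_model += 1
            if in_model > 1:  # only MODEL 1 is read
                break
            continue
        if tag == "ENDMDL":
            break
        if tag not in ("ATOM", "HETATM"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError):
            raise MolFileError(f"{source}, line {i}: malformed coordinate fields in {line.rstrip()!r}") from None
        records.append(AtomRecord(_pdb_element(line, i, source), (x, y, z), i))
    return records


def _parse_mol2(lines: list[str], source: str) -> list[AtomRecord]:
    records = []
    in_atoms = False
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            in_atoms = stripped.upper() == "@<TRIPOS>ATOM"
            continue
        if not in_atoms or not stripped:
            continue
        parts = stripped.split()
        if len(parts) < 6:
            raise MolFileError(f"{source}, line {i}: malformed mol2 atom record {stripped!r}")
        try:
            x, y, z = (float(v) for v in parts[2:5])
        except ValueError:
            raise MolFileError(f"{source}, line {i}: non-numeric coordinate in {stripped!r}") from None
        element = parts[5].split(".", 1)[0]  # SYBYL type truncated at first dot
        records.append(AtomRecord(element, (x, y, z), i))
    return records


_PARSERS = {"xyz": _parse_xyz, "pdb": _parse_pdb, "mol2": _parse_mol2}


def read_geometry(file: MoleculeFile | str | Path, radii: RadiiTable) -> SphereSet:
    """Parse a coordinate file into a SphereSet, one sphere per atom record
    in file order, with radius looked up per element."""
    if not isinstance(file, MoleculeFile):
        file = MoleculeFile.from_path(file)
    source = str(file.path)
    lines = file.path.read_text().splitlines()
    records = _PARSERS[file.fmt](lines, source)
    if not records:
        raise MolFileError(f"{source}: no atom records parsed (format {file.fmt})")
    for rec in records:
        if rec.element not in radii:
            raise MolFileError(
                f"{source}, line {rec.line}: element {rec.element!r} has no entry in the radii table"
            )
        if not all(np.isfinite(rec.position)):
            raise MolFileError(f"{source}, line {rec.line}: non-finite coordinate")
    centers = np.array([r.position for r in records], dtype=float)
    rads = np.array([radii[r.element] for r in records], dtype=float)
    elements = tuple(normalize_symbol(r.element) for r in records)
    return SphereSet(centers, rads, elements)


def read_geometry_set(
    source: str | Path | list[str | Path],
    radii: RadiiTable,
) -> list[tuple[str, SphereSet]]:
    """Read a directory or explicit list of coordinate files.

    Returns (label, SphereSet) pairs ordered lexicographically by label;
    duplicate labels are disambiguated with numeric suffixes. All failing
    files are reported together.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(
            p for p in Path(source).iterdir()
            if p.suffix.lstrip(".").lower() in _FORMATS
        )
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise MolFileError(f"no coordinate files found in {source}")
    entries = sorted(
        (MoleculeFile.from_path(p) for p in paths), key=lambda f: (f.label, str(f.path))
    )
    out: list[tuple[str, SphereSet]] = []
    failures: list[str] = []
    seen: dict[str, int] = {}
    for mf in entries:
        label = mf.label
        n = seen.get(label, 0)
        seen[label] = n + 1
        if n:
            label = f"{label}-{n + 1}"
        try:
            out.append((label, read_geometry(mf, radii)))
        except MolFileError as exc:
            failures.append(str(exc))
    if failures:
        raise MolFileError("failed to read geometry file(s):\n  " + "\n  ".join(failures))
    return out


# ---------------------------------------------------------------------------
# screening-matrix output


def write_screen_matrix(result, path: str | Path, fmt: str = "csv") -> Path:
    """Write a screening result's strong/weak/not matrix.

    csv/tsv: first column host labels, header row guest labels. json
    additionally carries run parameters and per-offset verdict details.
    Round-trips through :func:`molcage.screen.read_screen_matrix`.
    """
    path = Path(path)
    frame = pd.DataFrame(result.classes, index=result.host_labels, columns=result.guest_labels)
    frame.index.name = "host"
    if fmt in ("csv", "tsv"):
        frame.to_csv(path, sep="," if fmt == "csv" else "\t", lineterminator="\n")
    elif fmt == "json":
        payload = {
            "hosts": list(result.host_labels),
            "guests": list(result.guest_labels),
            "matrix": [list(row) for row in result.classes],
            "params": result.metadata,
            "details": result.details_payload(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise MolFileError(f"unknown matrix format {fmt!r} (expected csv, tsv or json)")
    return path
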