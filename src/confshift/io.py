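"""Readers and writers for conformer ensembles and experimental tables.

Supported inputs
----------------
* multi-structure XYZ files (concatenated blocks; the comment line may
  carry ``id=<label>`` and ``energy=<Hartree>`` tokens),
* Gaussian-style quantum-chemistry text logs (``SCF Done`` energies,
  ``Standard/Input orientation`` geometries, GIAO ``Isotropic =``
  shieldings; last occurrence wins, matching an optimization followed by
  an NMR single point in one file),
* delimited text tables for experimental shifts, couplings and
  externally computed shieldings.

Energies are converted from Hartree to kJ/mol at this boundary
(x 2625.4996); everything downstream works in kJ/mol.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    HARTREE_TO_KJ_PER_MOL,
    ConformerRecord,
    CouplingTable,
    ShiftAssignmentTable,
    ValidationError,
)


class ParseError(ValueError):
    """Raised for malformed structure or log files, naming block and line."""


# --------------------------------------------------------------------------
# XYZ ensembles
# --------------------------------------------------------------------------

_COMMENT_TOKEN = re.compile(r"(\w+)=([^\s]+)")


def read_xyz_ensemble(path: str | Path) -> list[ConformerRecord]:
    """Read a file of concatenated XYZ blocks into conformer records.

    The comment line of each block may carry ``id=<label>`` and
    ``energy=<Hartree>``; ids default to ``conf-<k>`` (1-based block
    order). Blank lines between blocks and trailing whitespace are
    ignored.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    records: list[ConformerRecord] = []
    i, block = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        block += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"block {block} (line {i + 1}): expected atom count, got {lines[i]!r}"
            )
        if n_atoms <= 0:
            raise ParseError(f"block {block} (line {i + 1}): non-positive atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        atom_lines = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise ParseError(
                f"block {block} (line {i + 1}): declares {n_atoms} atoms but block is truncated"
            )
        elements, coords = [], []
        for k, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(
                    f"block {block} (line {i + 3 + k}): expected 'El x y z', got {ln!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"block {block} (line {i + 3 + k}): non-numeric coordinate in {ln!r}"
                )
            elements.append(parts[0])
            coords.append(xyz)
        tokens = dict(_COMMENT_TOKEN.findall(comment))
        cid = tokens.get("id", f"conf-{block}")
        energy = None
        if "energy" in tokens:
            try:
                energy = float(tokens["energy"]) * HARTREE_TO_KJ_PER_MOL
            except ValueError:
                raise ParseError(
                    f"block {block}: non-numeric energy token {tokens['energy']!r}"
                )
        records.append(
            ConformerRecord(id=cid, elements=tuple(elements), coords=np.array(coords), energy=energy)
        )
        i += 2 + n_atoms
    return records


def write_xyz_ensemble(
    records: Iterable[ConformerRecord], path: str | Path, precision: int = 8
) -> None:
    """Write conformers as concatenated XYZ blocks (id/energy in comment)."""
    out = []
    for rec in records:
        comment = f"id={rec.id}"
        if rec.energy is not None:
            comment += f" energy={rec.energy / HARTREE_TO_KJ_PER_MOL:.10f}"
        out.append(f"{rec.n_atoms}\n{comment}")
        for el, (x, y, z) in zip(rec.elements, rec.coords):
            out.append(f"{el} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Quantum-chemistry logs (Gaussian-style text markers)
# --------------------------------------------------------------------------

_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_ISO_RE = re.compile(r"^\s*(\d+)\s+(\w+)\s+Isotropic\s*=\s*(-?\d+\.\d+)")
_ORIENT_RE = re.compile(r"(Standard|Input) orientation")

_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 35: "Br", 53: "I",
}


def parse_qm_log(path: str | Path, conformer_id: str | None = None) -> ConformerRecord:
    """Parse one Gaussian-style log: last geometry, last SCF energy and
    (when present) GIAO isotropic shieldings.

    Last-value-wins throughout, so a single file holding an optimization
    followed by an NMR single point yields the NMR-step quantities.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()

    energies = _SCF_RE.findall(text)
    if not energies:
        raise ParseError(f"{path}: no 'SCF Done' energy found")
    energy = float(energies[-1]) * HARTREE_TO_KJ_PER_MOL

    geometry = _last_orientation(lines)
    if geometry is None:
        raise ParseError(f"{path}: no orientation (geometry) block found")
    elements, coords = geometry

    shieldings = None
    iso = [(int(m.group(1)), m.group(2), float(m.group(3)))
           for m in (_ISO_RE.match(ln) for ln in lines) if m]
    if iso:
        # keep only the last GIAO block if the job printed several
        starts = [k for k, (idx, _, _) in enumerate(iso) if idx == 1]
        iso = iso[starts[-1]:] if starts else iso
        if len(iso) != len(elements):
            raise ParseError(
                f"{path}: {len(iso)} isotropic shieldings for {len(elements)} atoms"
            )
        shieldings = np.array([v for (_, _, v) in iso])

    cid = conformer_id if conformer_id is not None else Path(path).stem
    return ConformerRecord(
        id=cid, elements=tuple(elements), coords=np.array(coords),
        energy=energy, shieldings=shieldings,
    )


def _last_orientation(lines: Sequence[str]) -> tuple[list[str], list[list[float]]] | None:
    start = None
    for k, ln in enumerate(lines):
        if _ORIENT_RE.search(ln):
            start = k
    if start is None:
        return None
    elements, coords = [], []
    k = start + 5  # header: title, two rules, column names, rule
    while k < len(lines):
        ln = lines[k]
        if ln.strip().startswith("---"):
            break
        parts = ln.split()
        if len(parts) < 6:
            break
        z = int(parts[1])
        elements.append(_SYMBOLS.get(z, f"Z{z}"))
        coords.append([float(parts[-3]), float(parts[-2]), float(parts[-1])])
        k += 1
    if not elements:
        raise ParseError("orientation block present but empty")
    return elements, coords


# --------------------------------------------------------------------------
# Delimited tables
# --------------------------------------------------------------------------

def read_shift_table(path: str | Path, sep: str = ",") -> ShiftAssignmentTable:
    """Read an experimental shift table.

    Columns: ``site_label``, ``nucleus`` (H1 or C13), ``delta_exp`` (ppm)
    and ``atom_indices`` — semicolon-separated 1-based atom indices that
    are isochronous at the site (e.g. ``40;41;42`` for a methyl).
    """
    df = pd.read_csv(path, sep=sep, dtype={"site_label": str, "nucleus": str})
    problems = []
    parsed = []
    for label, raw in zip(df.get("site_label", []), df.get("atom_indices", [])):
        try:
            parsed.append(tuple(int(tok) for tok in str(raw).split(";") if tok.strip()))
        except ValueError:
            problems.append(f"site {label!r}: unparseable atom_indices {raw!r}")
            parsed.append(())
    if problems:
        raise ValidationError("; ".join(problems))
    df = df.assign(atom_indices=parsed)
    return ShiftAssignmentTable(df)


def write_shift_table(table: ShiftAssignmentTable, path: str | Path) -> None:
    df = table.rows.copy()
    df["atom_indices"] = [";".join(str(i) for i in idx) for idx in df["atom_indices"]]
    df.to_csv(path, index=False)


def read_coupling_table(path: str | Path, sep: str = ",") -> CouplingTable:
    """Read couplings: columns ``pair_label``, ``j_exp`` and one column of
    calculated 3J(H,H) values (Hz) per conformer id."""
    return CouplingTable(pd.read_csv(path, sep=sep, dtype={"pair_label": str}))


def read_shielding_csv(path: str | Path, sep: str = ",") -> dict[str, np.ndarray]:
    """Read per-atom shieldings from a plain CSV with columns
    ``conformer_id``, ``atom_index`` (1-based), ``shielding`` (ppm).

    Returns a mapping conformer id -> dense shielding vector; use
    :func:`attach_shieldings` to join onto an ensemble. This is the
    engine-agnostic path for users of non-Gaussian codes.
    """
    df = pd.read_csv(path, sep=sep, dtype={"conformer_id": str})
    out: dict[str, np.ndarray] = {}
    for cid, grp in df.groupby("conformer_id", sort=False):
        idx = grp["atom_index"].to_numpy(dtype=int)
        if idx.min() < 1:
            raise ValidationError(f"conformer {cid!r}: atom index < 1")
        vec = np.full(idx.max(), np.nan)
        vec[idx - 1] = grp["shielding"].to_numpy(dtype=float)
        out[cid] = vec
    return out


def attach_shieldings(
    ensemble: Sequence[ConformerRecord], shieldings: dict[str, np.ndarray]
) -> list[ConformerRecord]:
    """Return a new ensemble with shieldings joined by conformer id."""
    out = []
    for rec in ensemble:
        if rec.id not in shieldings:
            raise ValidationError(f"no shieldings supplied for conformer {rec.id!r}")
        vec = np.asarray(shieldings[rec.id], dtype=float)
        if vec.size < rec.n_atoms:
            vec = np.concatenate([vec, np.full(rec.n_atoms - vec.size, np.nan)])
        elif vec.size > rec.n_atoms:
            raise ValidationError(
                f"conformer {rec.id!r}: {vec.size} shieldings for {rec.n_atoms} atoms"
            )
        out.append(rec.with_(shieldings=vec))
    return out
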