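"""Core domain types shared across the package.

Atom indices are 1-based in every file format and user-facing table
(chemistry convention: C1, H3, ...) and converted to 0-based numpy
indexing exactly once, at the accessors defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

HARTREE_TO_KJ_PER_MOL = 2625.4996
R_GAS = 8.314462618e-3  # kJ mol^-1 K^-1

#: nucleus codes accepted in shift tables
NUCLEI = ("H1", "C13")

#: element symbol expected for each nucleus code
NUCLEUS_ELEMENT = {"H1": "H", "C13": "C"}


class ValidationError(ValueError):
    """Raised when an input table or record violates its invariants."""


@dataclass
class ConformerRecord:
    """One conformer: identity, geometry, energy and per-atom shieldings.

    Parameters
    ----------
    id : str
        Conformer label, e.g. ``"conf-3"`` or ``"5-1"``.
    elements : sequence of str
        Element symbols in atom order.
    coords : (N, 3) array
        Cartesian coordinates in angstrom.
    energy : float, optional
        Electronic energy in kJ/mol (relative or absolute; only
        differences matter downstream).
    shieldings : (N,) array, optional
        GIAO isotropic shieldings in ppm, aligned with atom order.
    """

    id: str
    elements: tuple[str, ...]
    coords: np.ndarray
    energy: float | None = None
    shieldings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValidationError(
                f"conformer {self.id!r}: coords shape {self.coords.shape} "
                f"does not match {len(self.elements)} atoms"
            )
        if self.shieldings is not None:
            self.shieldings = np.asarray(self.shieldings, dtype=float)
            if self.shieldings.shape != (len(self.elements),):
                raise ValidationError(
                    f"conformer {self.id!r}: {self.shieldings.size} shieldings "
                    f"for {len(self.elements)} atoms"
                )
        if self.energy is not None and not math.isfinite(self.energy):
            raise ValidationError(f"conformer {self.id!r}: non-finite energy")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_atom_indices(self) -> np.ndarray:
        """0-based indices of non-hydrogen atoms."""
        return np.array([i for i, e in enumerate(self.elements) if e != "H"], dtype=int)

    def shielding_at(self, atom_index_1based: int) -> float:
        """Shielding of a single atom, addressed 1-based."""
        if self.shieldings is None:
            raise ValidationError(f"conformer {self.id!r} has no shieldings")
        i = int(atom_index_1based)
        if not 1 <= i <= self.n_atoms:
            raise ValidationError(
                f"conformer {self.id!r}: atom index {i} out of range 1..{self.n_atoms}"
            )
        return float(self.shieldings[i - 1])

    def with_(self, **changes) -> "ConformerRecord":
        return replace(self, **changes)


@dataclass
class ShiftAssignmentTable:
    """Experimental shift sites mapped to (isochronous) conformer atoms.

    Each row is one experimentally resolved site: a label, its nucleus,
    the experimental shift in ppm, and the 1-based atom indices that are
    equivalent (isochronous) at this site — e.g. the three protons of a
    methyl group.
    """

    rows: pd.DataFrame  # columns: site_label, nucleus, delta_exp, atom_indices

    REQUIRED = ("site_label", "nucleus", "delta_exp", "atom_indices")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"shift table missing columns: {missing}")
        problems: list[str] = []
        dup = df["site_label"][df["site_label"].duplicated()].tolist()
        if dup:
            problems.append(f"duplicate site labels: {sorted(set(dup))}")
        bad_nuc = df.loc[~df["nucleus"].isin(NUCLEI), "site_label"].tolist()
        if bad_nuc:
            problems.append(f"unknown nucleus code at sites: {bad_nuc}")
        norm_idx = []
        for label, idx in zip(df["site_label"], df["atom_indices"]):
            idx = tuple(int(i) for i in idx)
            if len(idx) == 0:
                problems.append(f"site {label!r}: empty atom index list")
            if len(set(idx)) != len(idx):
                problems.append(f"site {label!r}: repeated atom index")
            if any(i <= 0 for i in idx):
                problems.append(f"site {label!r}: non-positive atom index")
            norm_idx.append(idx)
        if problems:
            raise ValidationError("; ".join(problems))
        df["atom_indices"] = norm_idx
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    def for_nucleus(self, nucleus: str) -> pd.DataFrame:
        return self.rows[self.rows["nucleus"] == nucleus]

    @property
    def nuclei(self) -> tuple[str, ...]:
        return tuple(n for n in NUCLEI if (self.rows["nucleus"] == n).any())

    def delta_exp(self, nucleus: str) -> np.ndarray:
        return self.for_nucleus(nucleus)["delta_exp"].to_numpy(dtype=float)

    def check_against(self, conformer: ConformerRecord) -> None:
        """Verify each referenced atom exists and matches the row's element."""
        problems = []
        for _, row in self.rows.iterrows():
            want = NUCLEUS_ELEMENT[row["nucleus"]]
            for i in row["atom_indices"]:
                if not 1 <= i <= conformer.n_atoms:
                    problems.append(
                        f"site {row['site_label']!r}: atom {i} absent from "
                        f"conformer {conformer.id!r}"
                    )
                elif conformer.elements[i - 1] != want:
                    problems.append(
                        f"site {row['site_label']!r}: atom {i} is "
                        f"{conformer.elements[i - 1]}, expected {want}"
                    )
        if problems:
            raise ValidationError("; ".join(problems))

    def drop_missing(self) -> "ShiftAssignmentTable":
        """Drop rows whose experimental shift is NaN (paired comparison)."""
        kept = self.rows[np.isfinite(self.rows["delta_exp"].to_numpy(dtype=float))]
        return ShiftAssignmentTable(kept)


@dataclass
class CouplingTable:
    """Experimental 3J(H,H) couplings with per-conformer calculated values.

    ``rows`` has columns ``pair_label``, ``j_exp`` and one column per
    conformer id holding that conformer's calculated coupling in Hz.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows).reset_index(drop=True)
        for col in ("pair_label", "j_exp"):
            if col not in df.columns:
                raise ValidationError(f"coupling table missing column {col!r}")
        values = df.drop(columns=["pair_label"]).to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("coupling table contains non-finite Hz values")
        self.rows = df

    @property
    def conformer_ids(self) -> tuple[str, ...]:
        return tuple(c for c in self.rows.columns if c not in ("pair_label", "j_exp"))

    def j_exp(self) -> np.ndarray:
        return self.rows["j_exp"].to_numpy(dtype=float)

    def j_calc(self, conformer_ids: Sequence[str]) -> np.ndarray:
        """(n_pairs, n_conformers) matrix of calculated couplings."""
        missing = [c for c in conformer_ids if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"coupling table lacks conformers: {missing}")
        return self.rows[list(conformer_ids)].to_numpy(dtype=float)


@dataclass(frozen=True)
class TDistribution:
    """Location-scale Student-t error model for one nucleus/error kind."""

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.nu > 0):
            raise ValidationError(
                f"t-distribution requires sigma > 0 and nu > 0, got "
                f"sigma={self.sigma}, nu={self.nu}"
            )


@dataclass
class DP4Parameters:
    """DP4+ error-model parameters: t-distributions per nucleus and error
    kind, plus the reference (TMS) shieldings used to convert isotropic
    shieldings to chemical shifts.

    These are configuration, not constants: they depend on the level of
    theory of the GIAO calculation and should be loaded from a YAML file
    (see :meth:`from_yaml`; packaged defaults live in
    ``confshift/params/``).
    """

    distributions: Mapping[tuple[str, str], TDistribution]
    sigma_ref: Mapping[str, float]

    KINDS = ("scaled", "unscaled")

    def __post_init__(self) -> None:
        self.distributions = dict(self.distributions)
        self.sigma_ref = {k: float(v) for k, v in self.sigma_ref.items()}
        for nuc in NUCLEI:
            for kind in self.KINDS:
                if (nuc, kind) not in self.distributions:
                    raise ValidationError(f"missing t-parameters for {nuc}/{kind}")
            if nuc not in self.sigma_ref:
                raise ValidationError(f"missing reference shielding for {nuc}")

    def dist(self, nucleus: str, kind: str) -> TDistribution:
        return self.distributions[(nucleus, kind)]

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DP4Parameters":
        dists = {}
        sigma_ref = {}
        for nuc in NUCLEI:
            block = doc[nuc]
            for kind in cls.KINDS:
                cell = block[kind]
                dists[(nuc, kind)] = TDistribution(
                    mu=float(cell["mu"]), sigma=float(cell["sigma"]), nu=float(cell["nu"])
                )
            sigma_ref[nuc] = float(block["sigma_ref"])
        return cls(distributions=dists, sigma_ref=sigma_ref)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DP4Parameters":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def default(cls, solvation: str = "pcm") -> "DP4Parameters":
        """Packaged parameter set for mPW1PW91/6-31+G**//B3LYP/6-31G*.

        ``solvation`` selects ``"pcm"`` or ``"gas"``. Verify these
        defaults against the DP4+ parametrization for your level of
        theory before production use; see the packaged YAML headers.
        """
        from importlib.resources import files

        name = {"pcm": "mpw1pw91_631pgdp_pcm.yaml", "gas": "mpw1pw91_631pgdp_gas.yaml"}
        try:
            resource = files("confshift.params").joinpath(name[solvation])
        except KeyError:
            raise ValidationError(f"unknown solvation {solvation!r}; use 'pcm' or 'gas'")
        return cls.from_dict(yaml.safe_load(resource.read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        doc: dict = {}
        for nuc in NUCLEI:
            doc[nuc] = {
                kind: {
                    "mu": self.dist(nuc, kind).mu,
                    "sigma": self.dist(nuc, kind).sigma,
                    "nu": self.dist(nuc, kind).nu,
                }
                for kind in self.KINDS
            }
            doc[nuc]["sigma_ref"] = self.sigma_ref[nuc]
        return doc


@dataclass(frozen=True)
class Composition:
    """Molar fractions of an ensemble's representatives (a simplex point)."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = tuple(float(x) for x in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(x < -1e-12 or x > 1 + 1e-12 for x in fr):
            raise ValidationError(f"fractions outside [0, 1]: {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {sum(fr)}, not 1")

    def __len__(self) -> int:
        return len(self.fractions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def __str__(self) -> str:
        return ":".join(f"{x:g}" for x in self.fractions)


def ensemble_by_id(ensemble: Iterable[ConformerRecord]) -> dict[str, ConformerRecord]:
    out: dict[str, ConformerRecord] = {}
    for rec in ensemble:
        if rec.id in out:
            raise ValidationError(f"duplicate conformer id {rec.id!r}")
        out[rec.id] = rec
    return out
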