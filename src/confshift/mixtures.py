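"""Boltzmann populations, simplex mixture grids and the mixture DP4+ scan.

A conformational equilibrium faster than the NMR timescale produces
population-weighted average observables. This module treats every
molar-fraction composition on a simplex grid (step 0.1 by default) as
one DP4+ candidate: shieldings are averaged in shielding space (all
downstream maps — referencing and linear scaling — are affine, so the
order of averaging is immaterial), converted to shifts, scaled per
composition, and scored with the same t-likelihoods as single
conformers. Probabilities are normalized over the whole grid with a
uniform prior, so they sum to 1 across compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dp4 import (
    ALL_CHANNELS,
    DP4Result,
    ErrorSummary,
    dp4_probabilities,
    error_summary,
    shieldings_to_site_values,
)
from .records import (
    R_GAS,
    Composition,
    ConformerRecord,
    DP4Parameters,
    ShiftAssignmentTable,
    ValidationError,
)


def boltzmann_weights(
    energies: Sequence[float], temperature: float = 298.15
) -> np.ndarray:
    """Equilibrium populations from energies in kJ/mol.

    w_k = exp(-(E_k - E_min)/RT) / sum_j exp(-(E_j - E_min)/RT),
    R = 8.314462618 J mol^-1 K^-1. Invariant under a uniform energy
    shift; the minimum is subtracted for numerical safety.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValidationError("no energies supplied")
    if not np.all(np.isfinite(e)):
        raise ValidationError("non-finite energy")
    if not temperature > 0:
        raise ValidationError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (R_GAS * temperature))
    return w / w.sum()


def boltzmann_table(
    ensemble: Sequence[ConformerRecord], temperature: float = 298.15
) -> pd.DataFrame:
    """Per-conformer relative energies (kJ/mol) and populations."""
    missing = [r.id for r in ensemble if r.energy is None]
    if missing:
        raise ValidationError(f"conformers without energies: {missing}")
    e = np.array([r.energy for r in ensemble], dtype=float)
    w = boltzmann_weights(e, temperature)
    return pd.DataFrame(
        {
            "conformer": [r.id for r in ensemble],
            "rel_energy_kj_mol": e - e.min(),
            "population": w,
        }
    )


# --------------------------------------------------------------------------
# simplex grid
# --------------------------------------------------------------------------

def simplex_grid(k: int, step: float) -> list[Composition]:
    """All k-part molar-fraction tuples on the step grid, lexicographic.

    Fractions are integer multiples of ``step`` summing to 1, vertices
    (pure conformers) included; the count is the stars-and-bars number
    C(1/step + k - 1, k - 1).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = round(1.0 / step)
    if n <= 0 or abs(n * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} does not divide 1")

    def parts(total: int, slots: int):
        if slots == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in parts(total - first, slots - 1):
                yield (first,) + rest

    return [Composition(tuple(i / n for i in tup)) for tup in sorted(parts(n, k))]


def mixture_shifts(
    site_shieldings: np.ndarray, x: Composition | Sequence[float]
) -> np.ndarray:
    """Population-weighted average of per-representative site shieldings.

    ``site_shieldings`` is (n_representatives, n_sites); returns the
    per-site mixture shieldings sum_k x_k * sigma_ik.
    """
    s = np.asarray(site_shieldings, dtype=float)
    xa = x.as_array() if isinstance(x, Composition) else np.asarray(x, dtype=float)
    if s.ndim != 2 or s.shape[0] != xa.size:
        raise ValidationError(
            f"shielding matrix {s.shape} incompatible with {xa.size} fractions"
        )
    if np.any(np.isnan(s)):
        raise ValidationError("representative shieldings do not cover all sites")
    return xa @ s


def _representative_site_shieldings(
    representatives: Sequence[ConformerRecord],
    table: ShiftAssignmentTable,
) -> dict[str, np.ndarray]:
    """nucleus -> (n_reps, n_sites) matrix of site-averaged shieldings."""
    out = {}
    for nuc in table.nuclei:
        rows = []
        for rec in representatives:
            if rec.shieldings is None:
                raise ValidationError(f"representative {rec.id!r} has no shieldings")
            rows.append(shieldings_to_site_values(rec.shieldings, table, nuc, rec.id))
        out[nuc] = np.vstack(rows)
    return out


# --------------------------------------------------------------------------
# grid scans
# --------------------------------------------------------------------------

@dataclass
class MixtureGridResult:
    """DP4+ scan over every composition of the simplex grid."""

    step: float
    representative_ids: tuple[str, ...]
    compositions: list[Composition]
    dp4: DP4Result

    @property
    def log_likelihoods(self) -> np.ndarray:
        return self.dp4.log_likelihoods["combined"].to_numpy()

    @property
    def probabilities(self) -> np.ndarray:
        return self.dp4.probabilities["combined"].to_numpy()

    def argmax(self) -> Composition:
        return self.compositions[int(np.argmax(self.probabilities))]

    def as_frame(self) -> pd.DataFrame:
        frac = np.array([c.fractions for c in self.compositions])
        df = pd.DataFrame(frac, columns=[f"x_{cid}" for cid in self.representative_ids])
        df["log_likelihood"] = self.log_likelihoods
        df["probability"] = self.probabilities
        return df

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def mixture_dp4_scan(
    representatives: Sequence[ConformerRecord],
    table: ShiftAssignmentTable,
    params: DP4Parameters,
    step: float = 0.1,
    channels: Sequence[tuple[str, str]] = ALL_CHANNELS,
    outlier_correction: bool = False,
) -> MixtureGridResult:
    """Score every molar-fraction grid composition as a DP4+ candidate."""
    if len(representatives) < 2:
        raise ValidationError("mixture scan needs >= 2 representatives")
    table = table.drop_missing()
    grid = simplex_grid(len(representatives), step)
    shield = _representative_site_shieldings(representatives, table)
    candidates = {}
    for comp in grid:
        candidates[str(comp)] = {
            nuc: params.sigma_ref[nuc] - mixture_shifts(shield[nuc], comp)
            for nuc in table.nuclei
        }
    result = dp4_probabilities(
        candidates, table, params, channels, outlier_correction=outlier_correction
    )
    return MixtureGridResult(
        step=step,
        representative_ids=tuple(r.id for r in representatives),
        compositions=grid,
        dp4=result,
    )


def mixture_error_scan(
    representatives: Sequence[ConformerRecord],
    table: ShiftAssignmentTable,
    params: DP4Parameters,
    step: float = 0.1,
) -> pd.DataFrame:
    """CMAE and CMaxErr per nucleus for every grid composition
    (per-composition scaling, as for any DP4+ candidate)."""
    if len(representatives) < 1:
        raise ValidationError("need representatives")
    table = table.drop_missing()
    grid = simplex_grid(len(representatives), step)
    shield = _representative_site_shieldings(representatives, table)
    rows = []
    for comp in grid:
        shifts = {
            nuc: params.sigma_ref[nuc] - mixture_shifts(shield[nuc], comp)
            for nuc in table.nuclei
        }
        summ = error_summary(shifts, table)
        row: dict = {
            f"x_{cid}": x for cid, x in zip((r.id for r in representatives), comp.fractions)
        }
        for nuc, (c, m, n) in summ.per_nucleus.items():
            row[f"cmae_{nuc}"] = c
            row[f"cmaxerr_{nuc}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def band_probability(
    grid: MixtureGridResult, predicate: Callable[[Composition], bool]
) -> float:
    """Total probability of the grid compositions satisfying ``predicate``."""
    p = grid.probabilities
    return float(sum(pi for pi, comp in zip(p, grid.compositions) if predicate(comp)))


# --------------------------------------------------------------------------
# ternary aggregation
# --------------------------------------------------------------------------

@dataclass
class TernaryGrid:
    """Grid probabilities aggregated onto three (possibly merged) axes."""

    axis_labels: tuple[str, str, str]
    points: pd.DataFrame  # columns a, b, c, probability

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def aggregate_ternary(
    grid: MixtureGridResult, merged_axes: Sequence[Sequence[int]]
) -> TernaryGrid:
    """Collapse the composition space onto three axes by summing the
    fractions inside each group (0-based component indices) and the
    probabilities of compositions that map to the same triple.

    Minor components are typically merged onto one axis so a
    higher-dimensional scan can be drawn as a ternary diagram; total
    probability is preserved.
    """
    k = len(grid.representative_ids)
    groups = [tuple(g) for g in merged_axes]
    flat = [i for g in groups for i in g]
    if len(groups) != 3 or sorted(flat) != list(range(k)):
        raise ValidationError(
            f"merged_axes must partition components 0..{k - 1} into 3 groups"
        )
    labels = tuple(
        "+".join(grid.representative_ids[i] for i in g) for g in groups
    )
    acc: dict[tuple[float, float, float], float] = {}
    for comp, p in zip(grid.compositions, grid.probabilities):
        triple = tuple(
            round(sum(comp.fractions[i] for i in g), 9) for g in groups
        )
        acc[triple] = acc.get(triple, 0.0) + float(p)
    pts = pd.DataFrame(
        [(a, b, c, p) for (a, b, c), p in sorted(acc.items())],
        columns=["a", "b", "c", "probability"],
    )
    return TernaryGrid(axis_labels=labels, points=pts)  # type: ignore[arg-type]


# --------------------------------------------------------------------------
# model / results interface
# --------------------------------------------------------------------------

class MixtureDP4Model:
    """Mixture-ensemble DP4+ analysis as a fit/results pair.

    Given cluster representatives (conformers with shieldings), an
    experimental shift table and DP4+ parameters, ``fit()`` runs the
    molar-fraction grid scan and returns :class:`MixtureResults`.
    """

    def __init__(
        self,
        representatives: Sequence[ConformerRecord],
        table: ShiftAssignmentTable,
        params: DP4Parameters | None = None,
        step: float = 0.1,
        outlier_correction: bool = False,
    ):
        self.representatives = list(representatives)
        self.table = table.drop_missing()
        self.params = params if params is not None else DP4Parameters.default()
        self.step = step
        self.outlier_correction = outlier_correction

    def fit(self, channels: Sequence[tuple[str, str]] = ALL_CHANNELS) -> "MixtureResults":
        grid = mixture_dp4_scan(
            self.representatives, self.table, self.params, self.step, channels,
            outlier_correction=self.outlier_correction,
        )
        errors = mixture_error_scan(
            self.representatives, self.table, self.params, self.step
        )
        return MixtureResults(model=self, grid=grid, errors=errors)


@dataclass
class MixtureResults:
    """Fitted mixture scan: grid probabilities and per-composition errors."""

    model: MixtureDP4Model
    grid: MixtureGridResult
    errors: pd.DataFrame

    def argmax(self) -> Composition:
        return self.grid.argmax()

    def band_probability(self, predicate: Callable[[Composition], bool]) -> float:
        return band_probability(self.grid, predicate)

    def to_ternary(self, merged_axes: Sequence[Sequence[int]]) -> TernaryGrid:
        return aggregate_ternary(self.grid, merged_axes)

    def best_errors(self) -> dict[str, tuple[Composition, float]]:
        """Per nucleus, the composition minimizing CMAE and its value."""
        out = {}
        for nuc in self.model.table.nuclei:
            col = f"cmae_{nuc}"
            j = int(self.errors[col].idxmin())
            out[nuc] = (self.grid.compositions[j], float(self.errors[col][j]))
        return out

    def summary(self, top_n: int = 5) -> str:
        ids = self.grid.representative_ids
        lines = ["Mixture DP4+ scan", "=" * 60]
        lines.append(
            f"representatives: {', '.join(ids)}   step: {self.model.step:g}   "
            f"grid points: {len(self.grid.compositions)}"
        )
        order = np.argsort(self.grid.probabilities)[::-1][:top_n]
        lines.append("")
        lines.append(f"{'composition (' + ':'.join(ids) + ')':<36}{'probability':>12}")
        for j in order:
            comp = self.grid.compositions[int(j)]
            lines.append(f"{str(comp):<36}{100 * self.grid.probabilities[j]:>11.2f}%")
        lines.append("")
        for nuc, (comp, val) in self.best_errors().items():
            lines.append(f"best {nuc} CMAE: {val:.3f} ppm at {comp}")
        return "\n".join(lines)
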