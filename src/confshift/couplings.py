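"""Ensemble-averaged 3J(H,H) comparison against experiment.

Calculated couplings are consumed as input (computed externally at the
DFT level, one column per conformer); under fast exchange the observed
coupling is the population-weighted average, so each grid composition
yields one predicted coupling set whose root-mean-square deviation from
experiment ranks the mixtures independently of the chemical shifts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mixtures import simplex_grid
from .records import Composition, CouplingTable, ValidationError


def mixture_couplings(
    table: CouplingTable, x: Composition, conformer_ids=None
) -> np.ndarray:
    """Population-weighted couplings J_mix = sum_k x_k J_k per pair (Hz)."""
    ids = tuple(conformer_ids) if conformer_ids is not None else table.conformer_ids
    if len(ids) != len(x):
        raise ValidationError(
            f"{len(x)} fractions for {len(ids)} conformers in the coupling table"
        )
    return table.j_calc(ids) @ x.as_array()


def j_rmsd(j_mix, j_exp) -> float:
    """Root-mean-square deviation between predicted and experimental J (Hz)."""
    a = np.asarray(j_mix, dtype=float)
    b = np.asarray(j_exp, dtype=float)
    if a.size == 0:
        raise ValidationError("empty coupling comparison")
    if a.shape != b.shape:
        raise ValidationError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def j_rmsd_scan(
    table: CouplingTable, step: float = 0.1, conformer_ids=None
) -> pd.DataFrame:
    """J-RMSD over every simplex-grid composition.

    Returns a frame with one fraction column per conformer plus
    ``j_rmsd``; the first row of ``frame.nsmallest(1, "j_rmsd")`` is the
    best-fitting mixture.
    """
    ids = tuple(conformer_ids) if conformer_ids is not None else table.conformer_ids
    if not ids:
        raise ValidationError("coupling table has no conformer columns")
    jexp = table.j_exp()
    jcalc = table.j_calc(ids)
    rows = []
    for comp in simplex_grid(len(ids), step):
        rows.append(
            {**{f"x_{cid}": xi for cid, xi in zip(ids, comp.fractions)},
             "j_rmsd": j_rmsd(jcalc @ comp.as_array(), jexp)}
        )
    return pd.DataFrame(rows)


def best_j_mixture(scan: pd.DataFrame) -> tuple[Composition, float]:
    """Argmin composition of a :func:`j_rmsd_scan` frame and its RMSD."""
    j = int(scan["j_rmsd"].idxmin())
    frac = tuple(
        float(scan.loc[j, c]) for c in scan.columns if c.startswith("x_")
    )
    return Composition(frac), float(scan.loc[j, "j_rmsd"])
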