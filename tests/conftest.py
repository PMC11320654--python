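import numpy as np
import pandas as pd
import pytest

from confshift.records import (
    ConformerRecord,
    DP4Parameters,
    ShiftAssignmentTable,
    TDistribution,
)


@pytest.fixture(scope="session")
def params() -> DP4Parameters:
    """Compact error-model parameters for numeric tests (not the packaged
    defaults, so tests do not depend on configuration files)."""
    return DP4Parameters(
        distributions={
            ("H1", "scaled"): TDistribution(0.0, 0.15, 8.0),
            ("H1", "unscaled"): TDistribution(-0.05, 0.25, 5.0),
            ("C13", "scaled"): TDistribution(0.0, 2.0, 8.0),
            ("C13", "unscaled"): TDistribution(-1.0, 3.0, 5.0),
        },
        sigma_ref={"H1": 31.8, "C13": 186.5},
    )


def make_table(delta_h=(), delta_c=(), atoms_h=None, atoms_c=None) -> ShiftAssignmentTable:
    """Assignment table with one atom per site: carbons first, then protons."""
    rows = []
    n_c = len(delta_c)
    for k, d in enumerate(delta_c, start=1):
        idx = atoms_c[k - 1] if atoms_c else (k,)
        rows.append({"site_label": f"C{k}", "nucleus": "C13", "delta_exp": d,
                     "atom_indices": idx})
    for k, d in enumerate(delta_h, start=1):
        idx = atoms_h[k - 1] if atoms_h else (n_c + k,)
        rows.append({"site_label": f"H{k}", "nucleus": "H1", "delta_exp": d,
                     "atom_indices": idx})
    return ShiftAssignmentTable(pd.DataFrame(rows))


def make_conformer(cid, shieldings_c=(), shieldings_h=(), energy=None,
                   coords=None) -> ConformerRecord:
    """One-atom-per-site conformer matching :func:`make_table` ordering."""
    elements = ("C",) * len(shieldings_c) + ("H",) * len(shieldings_h)
    n = len(elements)
    if coords is None:
        coords = np.arange(3 * n, dtype=float).reshape(n, 3) ** 1.1  # non-degenerate
    return ConformerRecord(
        id=cid,
        elements=elements,
        coords=coords,
        energy=energy,
        shieldings=np.concatenate(
            [np.asarray(shieldings_c, float), np.asarray(shieldings_h, float)]
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240618)
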