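"""DP4+ probabilities and shift-agreement statistics.

The DP4+ metric compares candidate structures (here: conformers or
conformer mixtures) by the likelihood of their calculated-shift errors
under location-scale Student-t distributions fitted once per level of
theory. Two error kinds enter per nucleus:

* *unscaled* errors, ``delta_calc - delta_exp``, where
  ``delta_calc = sigma_ref - sigma_calc`` (TMS-referenced);
* *scaled* ("corrected") errors, ``delta_scaled - delta_exp``, where
  ``delta_scaled`` removes the systematic slope/offset of the calculation
  through an ordinary least-squares fit of ``delta_calc`` against
  ``delta_exp`` — per candidate and per nucleus.

The candidate probability is the normalized product of the per-site
t-likelihoods over the selected (nucleus, kind) cells, with a uniform
prior. Accumulation is done in log space with max-subtraction before
exponentiation: a product over ~50 sites would otherwise underflow.

:class:`DP4Model` / :class:`DP4Results` wrap this machinery in a
fit/results interface; the module-level functions are the functional
core they delegate to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    NUCLEI,
    Composition,
    ConformerRecord,
    DP4Parameters,
    ShiftAssignmentTable,
    ValidationError,
)

#: all (nucleus, kind) likelihood cells of the full DP4+ model
ALL_CHANNELS: tuple[tuple[str, str], ...] = (
    ("H1", "scaled"), ("H1", "unscaled"), ("C13", "scaled"), ("C13", "unscaled"),
)


class DegenerateRegressionError(ValidationError):
    """OLS scaling impossible: fewer than two sites or zero experimental
    variance. Use the unscaled channel only for such nuclei."""


# --------------------------------------------------------------------------
# shift construction and scaling
# --------------------------------------------------------------------------

def shieldings_to_site_values(
    shieldings: np.ndarray, table: ShiftAssignmentTable, nucleus: str, label: str = "?"
) -> np.ndarray:
    """Average a per-atom shielding vector over each site's isochronous
    atom group (1-based indices); returns per-site shieldings in table order."""
    sub = table.for_nucleus(nucleus)
    out = np.empty(len(sub))
    for k, (site, idx) in enumerate(zip(sub["site_label"], sub["atom_indices"])):
        ii = np.asarray(idx, dtype=int) - 1
        if ii.max(initial=-1) >= shieldings.size or np.any(np.isnan(shieldings[ii])):
            raise ValidationError(
                f"candidate {label!r}: missing shielding for site {site!r}"
            )
        out[k] = shieldings[ii].mean()
    return out


def candidate_site_shifts(
    conformer: ConformerRecord, table: ShiftAssignmentTable, params: DP4Parameters
) -> dict[str, np.ndarray]:
    """Per-site calculated shifts for one conformer, keyed by nucleus.

    delta_calc = mean over the site's equivalent atoms of
    (sigma_ref - shielding); output ordered as the table.
    """
    if conformer.shieldings is None:
        raise ValidationError(f"conformer {conformer.id!r} has no shieldings")
    out = {}
    for nuc in table.nuclei:
        sigma_site = shieldings_to_site_values(
            conformer.shieldings, table, nuc, label=conformer.id
        )
        out[nuc] = params.sigma_ref[nuc] - sigma_site
    return out


@dataclass(frozen=True)
class ScalingFit:
    """Per-candidate, per-nucleus OLS correction of systematic shift error."""

    slope: float
    intercept: float
    delta_scaled: np.ndarray

    def __post_init__(self):
        if self.slope == 0:
            raise DegenerateRegressionError("zero slope in scaling fit")


def fit_scaling(delta_calc: np.ndarray, delta_exp: np.ndarray) -> ScalingFit:
    """OLS of delta_calc against delta_exp (delta_calc = m*delta_exp + b);
    scaled shifts are (delta_calc - b)/m."""
    x = np.asarray(delta_exp, dtype=float)
    y = np.asarray(delta_calc, dtype=float)
    if x.size != y.size:
        raise ValidationError("length mismatch between calculated and experimental shifts")
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateRegressionError(
            "scaling needs >= 2 sites with non-identical experimental shifts; "
            "use the unscaled channel only"
        )
    m, b = np.polyfit(x, y, 1)
    if m == 0:
        raise DegenerateRegressionError("zero slope in scaling fit")
    return ScalingFit(slope=float(m), intercept=float(b), delta_scaled=(y - b) / m)


def cmae(delta_scaled: np.ndarray, delta_exp: np.ndarray) -> float:
    """Corrected mean absolute error, sum(|delta_scaled - delta_exp|)/n (ppm)."""
    a, b = _paired(delta_scaled, delta_exp)
    return float(np.mean(np.abs(a - b)))


def cmaxerr(delta_scaled: np.ndarray, delta_exp: np.ndarray) -> float:
    """Corrected maximum absolute error, max(|delta_scaled - delta_exp|) (ppm)."""
    a, b = _paired(delta_scaled, delta_exp)
    return float(np.max(np.abs(a - b)))


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0:
        raise ValidationError("empty input")
    if a.shape != b.shape:
        raise ValidationError("length mismatch")
    return a, b


@dataclass(frozen=True)
class ErrorSummary:
    """CMAE/CMaxErr per nucleus for one candidate."""

    per_nucleus: Mapping[str, tuple[float, float, int]]  # nucleus -> (cmae, cmaxerr, n)

    def as_frame(self, candidate: str = "") -> pd.DataFrame:
        rows = [
            {"candidate": candidate, "nucleus": nuc, "cmae": v[0], "cmaxerr": v[1],
             "n_sites": v[2]}
            for nuc, v in self.per_nucleus.items()
        ]
        return pd.DataFrame(rows)


def error_summary(
    site_shifts: Mapping[str, np.ndarray], table: ShiftAssignmentTable
) -> ErrorSummary:
    """Scaled-error statistics (CMAE, CMaxErr) per nucleus for one candidate."""
    per = {}
    for nuc, dcalc in site_shifts.items():
        dexp = table.delta_exp(nuc)
        try:
            ds = fit_scaling(dcalc, dexp).delta_scaled
        except DegenerateRegressionError:
            ds = np.asarray(dcalc, dtype=float)
        per[nuc] = (cmae(ds, dexp), cmaxerr(ds, dexp), dexp.size)
    return ErrorSummary(per)


# --------------------------------------------------------------------------
# t-likelihoods
# --------------------------------------------------------------------------

def t_density(error, mu: float, sigma: float, nu: float):
    """Location-scale Student-t density of a shift error (1/ppm)."""
    if not (sigma > 0 and nu > 0):
        raise ValidationError("t_density requires sigma > 0 and nu > 0")
    return stats.t.pdf(error, df=nu, loc=mu, scale=sigma)


def t_log_density(error, mu: float, sigma: float, nu: float):
    if not (sigma > 0 and nu > 0):
        raise ValidationError("t_density requires sigma > 0 and nu > 0")
    return stats.t.logpdf(error, df=nu, loc=mu, scale=sigma)


def _downweight(errors: np.ndarray, cutoff: float) -> np.ndarray:
    """Halve absolute errors above ``cutoff`` (optional 13C robustness
    heuristic mirroring the DP4+ spreadsheet treatment of outliers)."""
    out = errors.copy()
    big = np.abs(out) > cutoff
    out[big] *= 0.5
    return out


# --------------------------------------------------------------------------
# DP4+ probabilities over candidates
# --------------------------------------------------------------------------

@dataclass
class DP4Result:
    """Per-candidate channel log-likelihoods and normalized probabilities.

    ``log_likelihoods``/``probabilities`` are DataFrames indexed by
    candidate with columns H1, C13, scaled, unscaled, combined. Channel
    columns multiply the relevant cells: the H1 channel is
    H-scaled x H-unscaled, the scaled channel is H-scaled x C-scaled,
    and combined is the product of all active cells (equivalently of the
    H and C channels).
    """

    cell_log_likelihoods: pd.DataFrame  # columns = "H1/scaled" etc.
    log_likelihoods: pd.DataFrame
    probabilities: pd.DataFrame
    channels: tuple[tuple[str, str], ...]
    notices: tuple[str, ...] = ()

    @property
    def candidates(self) -> list[str]:
        return list(self.probabilities.index)

    def top(self, channel: str = "combined", atol: float = 1e-12) -> list[str]:
        """Highest-probability candidate(s); ties reported as a set."""
        p = self.probabilities[channel]
        return sorted(p.index[p >= p.max() - atol].tolist())

    def to_csv(self, path) -> None:
        long = self.probabilities.stack().rename("probability").reset_index()
        long.columns = ["candidate", "channel", "probability"]
        ll = self.log_likelihoods.stack().rename("log_likelihood").reset_index()
        long["log_likelihood"] = ll["log_likelihood"]
        long.to_csv(path, index=False)


def softmax(log_l: np.ndarray) -> np.ndarray:
    z = log_l - np.max(log_l)
    w = np.exp(z)
    return w / w.sum()


def dp4_probabilities(
    candidates: Mapping[str, Mapping[str, np.ndarray]],
    table: ShiftAssignmentTable,
    params: DP4Parameters,
    channels: Sequence[tuple[str, str]] = ALL_CHANNELS,
    outlier_correction: bool = False,
    outlier_cutoff: float = 10.0,
) -> DP4Result:
    """DP4+ probabilities over candidate shift sets.

    Parameters
    ----------
    candidates : mapping
        candidate id -> {nucleus: per-site calculated shifts (ppm),
        ordered as the table}.
    table : ShiftAssignmentTable
        Sites with experimental shifts; rows with missing (NaN)
        experimental shifts are dropped from all candidates symmetrically.
    params : DP4Parameters
        t-distribution parameters and reference shieldings.
    channels : sequence of (nucleus, kind)
        Likelihood cells to include (default: all four).
    outlier_correction : bool
        Halve absolute 13C scaled errors above ``outlier_cutoff`` ppm
        before evaluating likelihoods (off by default).
    """
    if not candidates:
        raise ValidationError("no candidates supplied")
    table = table.drop_missing()
    channels = tuple(channels)
    for nuc, kind in channels:
        if nuc not in NUCLEI or kind not in ("scaled", "unscaled"):
            raise ValidationError(f"unknown channel {(nuc, kind)!r}")
    active_nuclei = [n for n in NUCLEI if any(c[0] == n for c in channels)]

    notices = []
    ids = list(candidates)
    if len(ids) == 1:
        notices.append(
            f"single candidate {ids[0]!r}: probability 1 by construction"
        )

    # the experimental vector is shared by all candidates, so the
    # per-candidate OLS scaling has a closed vector form; likelihoods are
    # then one t.logpdf call per (nucleus, kind) cell over all candidates
    cell_ll: dict[str, np.ndarray] = {}
    for nuc in active_nuclei:
        dexp = table.delta_exp(nuc)
        rows = []
        for cid in ids:
            shifts = candidates[cid]
            if nuc not in shifts:
                raise ValidationError(f"candidate {cid!r} lacks {nuc} shifts")
            dcalc = np.asarray(shifts[nuc], dtype=float)
            if dcalc.size != dexp.size:
                raise ValidationError(
                    f"candidate {cid!r}: {dcalc.size} {nuc} shifts for "
                    f"{dexp.size} sites"
                )
            rows.append(dcalc)
        y = np.vstack(rows)  # (n_candidates, n_sites)
        for kind in ("scaled", "unscaled"):
            if (nuc, kind) not in channels:
                continue
            if kind == "scaled":
                if dexp.size < 2 or np.ptp(dexp) == 0:
                    raise DegenerateRegressionError(
                        f"{nuc}: scaling needs >= 2 sites with non-identical "
                        "experimental shifts; use the unscaled channel only"
                    )
                xc = dexp - dexp.mean()
                m = (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
                if np.any(m == 0):
                    raise DegenerateRegressionError(f"{nuc}: zero slope in scaling fit")
                b = y.mean(axis=1) - m * dexp.mean()
                errors = (y - b[:, None]) / m[:, None] - dexp
                if outlier_correction and nuc == "C13":
                    errors = _downweight(errors, outlier_cutoff)
            else:
                errors = y - dexp
            d = params.dist(nuc, kind)
            cell_ll[f"{nuc}/{kind}"] = t_log_density(errors, d.mu, d.sigma, d.nu).sum(axis=1)

    cells = pd.DataFrame(cell_ll, index=pd.Index(ids, name="candidate"))

    def channel_sum(pred) -> np.ndarray:
        cols = [f"{n}/{k}" for n, k in channels if pred(n, k)]
        return cells[cols].sum(axis=1).to_numpy() if cols else np.zeros(len(ids))

    ll = pd.DataFrame(
        {
            "H1": channel_sum(lambda n, k: n == "H1"),
            "C13": channel_sum(lambda n, k: n == "C13"),
            "scaled": channel_sum(lambda n, k: k == "scaled"),
            "unscaled": channel_sum(lambda n, k: k == "unscaled"),
            "combined": channel_sum(lambda n, k: True),
        },
        index=cells.index,
    )
    probs = ll.apply(lambda col: softmax(col.to_numpy()), axis=0)
    return DP4Result(
        cell_log_likelihoods=cells,
        log_likelihoods=ll,
        probabilities=probs,
        channels=channels,
        notices=tuple(notices),
    )


# --------------------------------------------------------------------------
# model / results interface
# --------------------------------------------------------------------------

class DP4Model:
    """DP4+ candidate comparison as a fit/results pair.

    Built from an ensemble of conformers (with shieldings), an
    experimental :class:`ShiftAssignmentTable` and :class:`DP4Parameters`;
    ``fit()`` evaluates the Bayesian model comparison and returns a
    :class:`DP4Results` with probabilities, error statistics and a
    ``summary()`` table.

    Examples
    --------
    >>> model = DP4Model(ensemble, table, params)       # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(
        self,
        ensemble: Sequence[ConformerRecord],
        table: ShiftAssignmentTable,
        params: DP4Parameters | None = None,
        outlier_correction: bool = False,
    ):
        self.ensemble = list(ensemble)
        if not self.ensemble:
            raise ValidationError("empty ensemble")
        self.table = table.drop_missing()
        self.params = params if params is not None else DP4Parameters.default()
        self.outlier_correction = outlier_correction
        self.table.check_against(self.ensemble[0])

    @classmethod
    def from_files(
        cls, ensemble_path, shifts_path, params_path=None, shieldings_path=None, **kw
    ) -> "DP4Model":
        from . import io

        ensemble = io.read_xyz_ensemble(ensemble_path)
        if shieldings_path is not None:
            ensemble = io.attach_shieldings(ensemble, io.read_shielding_csv(shieldings_path))
        table = io.read_shift_table(shifts_path)
        params = (
            DP4Parameters.from_yaml(params_path) if params_path else DP4Parameters.default()
        )
        return cls(ensemble, table, params, **kw)

    def candidate_shifts(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            rec.id: candidate_site_shifts(rec, self.table, self.params)
            for rec in self.ensemble
        }

    def fit(self, channels: Sequence[tuple[str, str]] = ALL_CHANNELS) -> "DP4Results":
        shifts = self.candidate_shifts()
        result = dp4_probabilities(
            shifts, self.table, self.params, channels,
            outlier_correction=self.outlier_correction,
        )
        errors = {cid: error_summary(s, self.table) for cid, s in shifts.items()}
        return DP4Results(model=self, dp4=result, errors=errors)


@dataclass
class DP4Results:
    """Fitted DP4+ comparison: probabilities, error statistics, summary."""

    model: DP4Model
    dp4: DP4Result
    errors: Mapping[str, ErrorSummary]

    @property
    def probabilities(self) -> pd.DataFrame:
        return self.dp4.probabilities

    def top(self, channel: str = "combined") -> list[str]:
        return self.dp4.top(channel)

    def error_table(self) -> pd.DataFrame:
        return pd.concat(
            [summ.as_frame(cid) for cid, summ in self.errors.items()],
            ignore_index=True,
        )

    def summary(self) -> str:
        lines = ["DP4+ conformer comparison", "=" * 60]
        lines.append(f"candidates: {len(self.dp4.candidates)}   "
                     f"sites: {len(self.model.table)}")
        probs = self.dp4.probabilities
        lines.append("")
        lines.append(f"{'candidate':<14}" + "".join(f"{c:>10}" for c in probs.columns))
        for cid, row in probs.iterrows():
            lines.append(f"{cid:<14}" + "".join(f"{100 * v:>9.2f}%" for v in row))
        top = self.top()
        lines.append("")
        lines.append(
            "best candidate (combined): " + (top[0] if len(top) == 1 else f"tie {top}")
        )
        for note in self.dp4.notices:
            lines.append(f"note: {note}")
        return "\n".join(lines)
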