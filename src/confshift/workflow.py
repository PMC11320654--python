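"""End-to-end analyses: single-conformation selection and mixture scans.

Two pipelines mirror the two ways a conformational problem presents:

* :func:`run_conformer_analysis` — prefilter an ensemble, score every
  conformer as a DP4+ candidate, and report probabilities, CMAE/CMaxErr
  and Boltzmann populations (molecules expected to adopt one dominant
  conformation);
* :func:`run_mixture_analysis` — cluster the ensemble, take one
  representative per cluster, and scan molar-fraction mixtures of the
  representatives on a simplex grid, optionally cross-checked against
  ensemble-averaged 3J(H,H) couplings (molecules in fast exchange).

Every report carries a provenance block (config echo, package version,
timestamp) from which the tables are re-derivable.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, couplings as cp, io
from .dp4 import ALL_CHANNELS, DP4Model
from .geometry import ClusterResult, cluster_conformers, prefilter_conformers
from .mixtures import MixtureDP4Model, boltzmann_table
from .records import DP4Parameters, ValidationError

log = logging.getLogger("confshift")


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


@dataclass
class AnalysisConfig:
    """Paths and knobs for one analysis run."""

    ensemble_path: str
    shifts_path: str | None = None
    shieldings_path: str | None = None
    params_path: str | None = None
    couplings_path: str | None = None
    outdir: str = "confshift-report"
    channels: tuple[str, ...] = ("H1", "C13")  # nuclei to use
    solvation: str = "pcm"
    step: float = 0.1
    merge_distance: float = 0.25
    energy_window: float = 12.0
    rmsd_cutoff: float = 1.0
    temperature: float = 298.15
    prefilter: bool = True
    outlier_correction: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self, need_shifts: bool = True) -> None:
        problems = []
        for name in ("ensemble_path", "shifts_path", "shieldings_path",
                     "params_path", "couplings_path"):
            p = getattr(self, name)
            if p is None:
                if name == "shifts_path" and need_shifts:
                    problems.append("shifts_path is required")
                continue
            if not Path(p).exists():
                problems.append(f"{name}: {p} does not exist")
        n = round(1.0 / self.step) if self.step > 0 else 0
        if n <= 0 or abs(n * self.step - 1.0) > 1e-9:
            problems.append(f"step {self.step} does not divide 1")
        bad = [c for c in self.channels if c not in ("H1", "C13")]
        if bad:
            problems.append(f"unknown nuclei in channels: {bad}")
        if problems:
            raise ConfigError("; ".join(problems))

    def dp4_channels(self) -> tuple[tuple[str, str], ...]:
        return tuple(c for c in ALL_CHANNELS if c[0] in self.channels)

    def load_params(self) -> DP4Parameters:
        if self.params_path:
            return DP4Parameters.from_yaml(self.params_path)
        return DP4Parameters.default(self.solvation)


@dataclass
class AnalysisReport:
    """Result tables of one pipeline run plus provenance."""

    tables: Mapping[str, pd.DataFrame]
    summary_text: str
    provenance: dict
    cluster: ClusterResult | None = None
    notices: tuple[str, ...] = ()

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name, df in self.tables.items():
                path = out / f"{name}.csv"
                df.to_csv(path, index=False)
                written.append(path)
            (out / "summary.txt").write_text(self.summary_text + "\n", encoding="utf-8")
            written.append(out / "summary.txt")
            (out / "provenance.json").write_text(
                json.dumps(self.provenance, indent=2, default=str) + "\n",
                encoding="utf-8",
            )
            written.append(out / "provenance.json")
        except Exception:
            for p in written:  # no partial reports
                p.unlink(missing_ok=True)
            raise
        return out


def _provenance(config: AnalysisConfig, **extra) -> dict:
    return {
        "package": "confshift",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        **extra,
    }


def _load_ensemble(config: AnalysisConfig):
    ensemble = io.read_xyz_ensemble(config.ensemble_path)
    if config.shieldings_path:
        ensemble = io.attach_shieldings(
            ensemble, io.read_shielding_csv(config.shieldings_path)
        )
    return ensemble


def run_conformer_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Prefilter + per-conformer DP4+ + error statistics + Boltzmann."""
    config.validate()
    stage = "input"
    try:
        ensemble = _load_ensemble(config)
        params = config.load_params()
        table = io.read_shift_table(config.shifts_path)
        log.info("input: %d conformers, %d sites", len(ensemble), len(table))

        stage = "prefilter"
        have_energies = all(r.energy is not None for r in ensemble)
        if config.prefilter and have_energies and len(ensemble) > 1:
            kept = prefilter_conformers(
                ensemble, config.energy_window, config.rmsd_cutoff
            )
            log.info("prefilter: kept %d of %d conformers", len(kept), len(ensemble))
        else:
            kept = list(ensemble)

        stage = "dp4"
        model = DP4Model(
            kept, table, params, outlier_correction=config.outlier_correction
        )
        res = model.fit(config.dp4_channels())

        stage = "boltzmann"
        tables = {
            "dp4_probabilities": res.probabilities.reset_index(),
            "error_summary": res.error_table(),
        }
        if have_energies:
            tables["boltzmann"] = boltzmann_table(kept, config.temperature)

        top = res.top()
        summary = res.summary()
        if have_energies:
            bt = tables["boltzmann"]
            best = bt.loc[bt["population"].idxmax()]
            summary += (
                f"\nBoltzmann: top population {100 * best['population']:.2f}% "
                f"for {best['conformer']} at {config.temperature:g} K"
            )
        report = AnalysisReport(
            tables=tables,
            summary_text=summary,
            provenance=_provenance(
                config, n_conformers_in=len(ensemble), n_conformers_kept=len(kept),
                top_candidates=top,
            ),
            notices=res.dp4.notices,
        )
        return report
    except (ValidationError, io.ParseError) as exc:
        raise ValidationError(f"stage {stage!r}: {exc}") from exc


def run_mixture_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Cluster + representatives + mixture DP4+/error scans (+ J-RMSD)."""
    config.validate()
    stage = "input"
    try:
        ensemble = _load_ensemble(config)
        params = config.load_params()
        table = io.read_shift_table(config.shifts_path)

        stage = "cluster"
        clusters = cluster_conformers(ensemble, config.merge_distance)
        by_id = {r.id: r for r in ensemble}
        reps = [by_id[cid] for cid in clusters.representatives.values()]
        log.info(
            "cluster: %d conformers -> %d clusters (merge %.3g A)",
            len(ensemble), clusters.n_clusters, config.merge_distance,
        )
        notices = []
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                si, sj = reps[i].shieldings, reps[j].shieldings
                if si is not None and sj is not None and np.allclose(si, sj, atol=1e-12):
                    notices.append(
                        f"degenerate: representatives {reps[i].id!r} and "
                        f"{reps[j].id!r} have identical shieldings — probability "
                        "is flat along their shared axis"
                    )

        stage = "mixture-scan"
        if len(reps) < 2:
            raise ValidationError(
                "only one cluster representative; run the conformer analysis instead"
            )
        model = MixtureDP4Model(
            reps, table, params, step=config.step,
            outlier_correction=config.outlier_correction,
        )
        res = model.fit(config.dp4_channels())
        log.info("mixture-scan: %d grid compositions", len(res.grid.compositions))

        tables = {
            "mixture_grid": res.grid.as_frame(),
            "mixture_errors": res.errors,
            "clusters": clusters.as_frame(),
        }

        stage = "ternary"
        if len(reps) >= 3:
            # merge all but the two largest-probability-vertex axes
            groups = [[0], [1], list(range(2, len(reps)))]
            tern = res.to_ternary(groups)
            tables["ternary"] = tern.points.assign(
                axis_a=tern.axis_labels[0], axis_b=tern.axis_labels[1],
                axis_c=tern.axis_labels[2],
            )

        stage = "couplings"
        summary = res.summary()
        if config.couplings_path:
            jt = io.read_coupling_table(config.couplings_path)
            scan = cp.j_rmsd_scan(
                jt, config.step, conformer_ids=[r.id for r in reps]
            )
            tables["j_rmsd"] = scan
            best, val = cp.best_j_mixture(scan)
            summary += f"\nbest J-RMSD: {val:.3f} Hz at {best}"

        for note in notices:
            summary += f"\nnote: {note}"
        return AnalysisReport(
            tables=tables,
            summary_text=summary,
            provenance=_provenance(
                config,
                n_conformers_in=len(ensemble),
                n_clusters=clusters.n_clusters,
                representatives=[r.id for r in reps],
                argmax=list(res.argmax().fractions),
            ),
            cluster=clusters,
            notices=tuple(notices),
        )
    except (ValidationError, io.ParseError) as exc:
        raise ValidationError(f"stage {stage!r}: {exc}") from exc
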