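"""Configuration-driven campaign orchestration and machine-readable reports.

A :class:`RunConfig` (YAML/JSON or constructed in Python) names the
scenarios to run and the model parameters; :func:`run` executes them and
writes a reproducible report bundle:

* per-scenario JSON report, per-angle elongation-profile CSV, optional
  polar plot of e_tot(theta) and VTK exports of the solved fields;
* a consolidated orientation table over the requested scenarios;
* the nine-case strain-transmission table (optional);
* a contraction-sensitivity sweep for the oblique 3D case (optional);
* the echoed configuration and a provenance record (config hash, package
  and library versions, seed).

Reports contain no timestamps: rerunning an identical configuration
reproduces byte-identical CSV/JSON output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .orientation import CombinationParams
from .scenarios import (
    CANONICAL_SCENARIOS,
    DEFAULT_APPLIED_STRAIN,
    DEFAULT_SPRING_FRACTION,
    ScenarioResult,
    contraction_sweep,
    run_scenario,
    strain_transmission_campaign,
)

__all__ = ["RunConfig", "ReportBundle", "run", "expected_elongation", "polar_plot"]

_FLOAT_FMT = "%.6g"


def expected_elongation(roi_length: float, intended_strain: float) -> float:
    """Anticipated elongation (mm) of a region of interest under a stretch.

    The product of the gauge length and the intended engineering strain:
    e.g. a 15 mm region at 5% intended strain should elongate by 0.75 mm.
    Raises for negative inputs.
    """
    if roi_length < 0 or intended_strain < 0:
        raise ValueError("roi_length and intended_strain must be non-negative")
    return roi_length * intended_strain


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one reporting run."""

    scenarios: tuple[str, ...] = ("2d_parallel", "2d_perpendicular", "3d_parallel", "3d_perpendicular")
    applied_strain: float = DEFAULT_APPLIED_STRAIN
    transmission_strain: float = 0.36
    n: float = 4.0
    angle_grid: float = 0.5
    spring_fraction: float = DEFAULT_SPRING_FRACTION
    contraction_scale: float = 1.0
    include_transmission: bool = True
    include_sweep: bool = False
    make_plots: bool = True
    export_fields: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if not self.scenarios:
            raise ValueError("scenario list must not be empty")
        unknown = [s for s in self.scenarios if s not in CANONICAL_SCENARIOS]
        if unknown:
            raise ValueError(
                f"unknown scenarios {unknown}; canonical names: {', '.join(CANONICAL_SCENARIOS)}"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "scenarios" in data:
            data["scenarios"] = tuple(data["scenarios"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenarios"] = list(self.scenarios)
        return d

    def params(self) -> CombinationParams:
        return CombinationParams(n=self.n, angle_grid=self.angle_grid)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    """In-memory results of a run, mirroring what was written to disk."""

    config: RunConfig
    results: dict[str, ScenarioResult]
    orientation_table: pd.DataFrame
    transmission_table: pd.DataFrame | None = None
    sweep_table: pd.DataFrame | None = None
    output_dir: Path | None = None


def _scenario_record(res: ScenarioResult) -> dict:
    rec = {
        "scenario": res.scenario,
        "angle_deg": None if np.isnan(res.angle) else round(float(res.angle), 6),
        "degenerate": res.prediction.degenerate,
        "tie": res.prediction.tie,
        "applied_strain": res.applied_strain,
        "contraction_magnitude": res.contraction_magnitude,
        "spring_stiffness_pa_per_m": res.spring_stiffness,
    }
    if res.eps_cyclic is not None:
        rec["eps_cyclic_lab"] = np.round(res.eps_cyclic, 9).tolist()
    if res.eps_self is not None:
        rec["eps_self_lab"] = np.round(res.eps_self, 9).tolist()
    return rec


def polar_plot(res: ScenarioResult, path) -> None:
    """Polar rendering of the combined elongation profile e_tot(theta)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = res.prediction.profile
    theta = np.deg2rad(np.concatenate([prof.angles, prof.angles + 180.0, prof.angles[:1]]))
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4.5, 4.5))
    for name, vals, style in (
        ("e_cyclic", prof.e_cyclic, ":"),
        ("e_self", prof.e_self, "--"),
        ("e_tot", prof.e_tot, "-"),
    ):
        r = np.concatenate([vals, vals, vals[:1]])
        ax.plot(theta, r, style, label=name)
    if not res.prediction.degenerate:
        ang = np.deg2rad(res.angle)
        ax.plot([ang, ang + np.pi], [prof.e_tot.max()] * 2, "r.", ms=8)
    ax.set_title(f"{res.scenario}: {res.angle:.1f} deg" if not res.prediction.degenerate
                 else f"{res.scenario}: no preferred direction")
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=8)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def run(config: RunConfig, output_dir=None) -> ReportBundle:
    """Execute the configured campaigns; write the report bundle if a
    directory is given. Deterministic: identical configs yield byte-identical
    CSV/JSON reports."""
    out = Path(output_dir) if output_dir is not None else None
    params = config.params()
    results: dict[str, ScenarioResult] = {}
    rows = []
    for name in config.scenarios:
        res = run_scenario(
            name,
            params=params,
            applied_strain=config.applied_strain,
            spring_fraction=config.spring_fraction,
            contraction_scale=config.contraction_scale,
            keep_fields=config.export_fields,
        )
        results[name] = res
        rows.append(_scenario_record(res))
        if config.verbosity:
            angle = "n/a" if np.isnan(res.angle) else f"{res.angle:.1f} deg"
            print(f"[strainavoid] {name}: {angle}")
    table = pd.DataFrame(
        [{k: r.get(k) for k in ("scenario", "angle_deg", "degenerate", "tie")} for r in rows]
    )

    trans = None
    if config.include_transmission:
        cases = strain_transmission_campaign(config.transmission_strain)
        trans = pd.DataFrame(
            [
                {
                    "topography": c.topography,
                    "seeding": c.seeding,
                    "axial_strain_pct": c.axial_strain_pct,
                }
                for c in cases
            ]
        )

    sweep = None
    if config.include_sweep:
        pts = contraction_sweep(
            (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0),
            params=params,
            applied_strain=config.applied_strain,
        )
        sweep = pd.DataFrame(pts, columns=["contraction_multiplier", "angle_deg"])

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            sdir = out / "scenarios" / name
            sdir.mkdir(parents=True, exist_ok=True)
            (sdir / "report.json").write_text(
                json.dumps(_scenario_record(res), indent=2, sort_keys=True) + "\n"
            )
            res.prediction.profile.to_frame().to_csv(
                sdir / "profile.csv", index=False, float_format=_FLOAT_FMT
            )
            if config.make_plots:
                polar_plot(res, sdir / "polar.png")
            for label, fld in res.fields.items():
                fld.export_vtk(sdir / f"field_{label}.vtk")
        table.to_csv(out / "orientation_table.csv", index=False, float_format=_FLOAT_FMT)
        if trans is not None:
            trans.to_csv(out / "transmission_table.csv", index=False, float_format=_FLOAT_FMT)
        if sweep is not None:
            sweep.to_csv(out / "contraction_sweep.csv", index=False, float_format=_FLOAT_FMT)
        (out / "config_echo.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        import scipy

        from . import __version__

        provenance = {
            "config_sha256": config.digest(),
            "strainavoid": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "seed": config.seed,
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )

    return ReportBundle(
        config=config,
        results=results,
        orientation_table=table,
        transmission_table=trans,
        sweep_table=sweep,
        output_dir=out,
    )
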