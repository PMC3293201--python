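"""Simulation campaign orchestration.

Two campaign designs are built in:

* campaign 1 — movement-model comparison: prey density fixed at 0.16 km⁻²,
  all three movement models across a sweep of line densities;
* campaign 2 — the factorial used for encounter-rate regression: six prey
  densities {0.5 … 3} × four line densities {0, 2.23, 4.46, 8.91} × 10
  replicates under the anisotropic-diffusion model = 240 solutions.

Seeding is hierarchical and fully deterministic: each run derives child seeds
from the base seed and its factor indices, landscapes are shared across
movement models (and prey placements shared across line densities) within a
replicate so comparisons are paired.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coeffs import MODELS, build_field
from .movestats import MovementParams, reference_params
from .solver import average_mfpt, encounter_rate, solve_mfpt
from .synthetic import Domain, generate_landscape, place_prey

__all__ = ["DesignSpec", "Run", "enumerate_runs", "run_campaign"]

log = logging.getLogger(__name__)

#: factorial line densities (km km⁻²): none, half baseline, the 4.46 baseline,
#: and double baseline — spanning the ≈2–9 km km⁻² study range
DEFAULT_SEISMIC_DENSITIES = (0.0, 2.23, 4.46, 8.91)
DEFAULT_PREY_DENSITIES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design: movement models × line densities × prey densities ×
    replicates, plus the numerical configuration shared by every run."""

    seismic_densities: tuple = DEFAULT_SEISMIC_DENSITIES
    prey_densities: tuple = DEFAULT_PREY_DENSITIES
    replicates: int = 10
    models: tuple = ("aniso",)
    base_seed: int = 0
    h: float = 0.05  # km; 50 m cells so the 100 m prey radius spans ≥ 2 cells
    domain_km: float = 25.0
    radius_r: float = 0.1
    params: MovementParams = field(default_factory=reference_params)

    def __post_init__(self) -> None:
        if not self.seismic_densities or not self.prey_densities or not self.models:
            raise ValueError("every design factor must be non-empty")
        if any(s < 0 for s in self.seismic_densities) or any(
            n < 0 for n in self.prey_densities
        ):
            raise ValueError("densities must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        for mdl in self.models:
            if mdl not in MODELS:
                raise ValueError(f"unknown movement model {mdl!r}")

    @property
    def n_runs(self) -> int:
        return (
            len(self.models)
            * len(self.seismic_densities)
            * len(self.prey_densities)
            * self.replicates
        )

    @property
    def domain(self) -> Domain:
        return Domain.square(self.domain_km)

    @classmethod
    def campaign1(cls, **overrides) -> "DesignSpec":
        """Model comparison at fixed prey density 0.16 km⁻²."""
        base = cls(
            prey_densities=(0.16,),
            models=("no_response", "aniso", "aniso_bias"),
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def campaign2(cls, **overrides) -> "DesignSpec":
        """The 6 × 10 × 4 = 240-solution factorial (anisotropic model)."""
        base = cls()
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class Run:
    index: int
    model: str
    S: float
    N: float
    replicate: int
    landscape_seed: int
    prey_seed: int


def _child_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def enumerate_runs(spec: DesignSpec) -> list[Run]:
    """Deterministic, ordered run list with derived child seeds.

    Landscape seeds depend on (line-density index, replicate) only, so the
    same landscape realisation is shared across movement models and prey
    densities; prey seeds depend on (prey-density index, replicate) only, so
    prey placements are shared across line densities. Each replicate gets a
    fresh prey placement.
    """
    runs = []
    index = 0
    for im, model in enumerate(spec.models):
        for is_, S in enumerate(spec.seismic_densities):
            for in_, N in enumerate(spec.prey_densities):
                for rep in range(spec.replicates):
                    runs.append(
                        Run(
                            index=index,
                            model=model,
                            S=float(S),
                            N=float(N),
                            replicate=rep,
                            landscape_seed=_child_seed(spec.base_seed, 1, is_, rep),
                            prey_seed=_child_seed(spec.base_seed, 2, in_, rep),
                        )
                    )
                    index += 1
    return runs


def run_campaign(
    spec: DesignSpec,
    out_csv=None,
    resume: bool = True,
) -> pd.DataFrame:
    """Execute every run: landscape → coefficients → MFPT solve → T̄ → E.

    Landscapes and coefficient fields are cached across runs that share them.
    Solver failures mark the run ``failed`` and the campaign continues. When
    ``out_csv`` exists and ``resume`` is true, completed run indices are
    skipped and results appended.
    """
    runs = enumerate_runs(spec)
    done: set[int] = set()
    prior = None
    if out_csv is not None and resume:
        try:
            prior = pd.read_csv(out_csv)
            done = set(prior["run"].astype(int))
        except (FileNotFoundError, pd.errors.EmptyDataError):
            prior = None

    landscapes: dict[int, object] = {}
    fields: dict[tuple, object] = {}
    rows = []
    n_failed = 0
    for run in runs:
        if run.index in done:
            continue
        if run.landscape_seed not in landscapes or landscapes[run.landscape_seed][0] != run.S:
            landscapes[run.landscape_seed] = (
                run.S,
                generate_landscape(run.S, spec.domain, seed=run.landscape_seed),
            )
        landscape = landscapes[run.landscape_seed][1]
        fkey = (run.model, run.S, run.landscape_seed)
        if fkey not in fields:
            fields[fkey] = build_field(run.model, spec.params, landscape, spec.h)
        fld = fields[fkey]
        prey = place_prey(run.N, spec.domain, spec.radius_r, seed=run.prey_seed)
        t0 = time.perf_counter()
        try:
            surface = solve_mfpt(fld, prey)
            tbar = average_mfpt(surface)
            rows.append(
                {
                    "run": run.index,
                    "model": run.model,
                    "S": run.S,
                    "N": run.N,
                    "replicate": run.replicate,
                    "tbar_h": tbar,
                    "E_per_h": encounter_rate(tbar),
                    "residual": surface.residual,
                    "status": "ok",
                    "wall_s": time.perf_counter() - t0,
                }
            )
        except Exception as exc:  # noqa: BLE001 - campaign must continue
            n_failed += 1
            log.warning("run %d failed: %s", run.index, exc)
            rows.append(
                {
                    "run": run.index,
                    "model": run.model,
                    "S": run.S,
                    "N": run.N,
                    "replicate": run.replicate,
                    "tbar_h": np.nan,
                    "E_per_h": np.nan,
                    "residual": np.nan,
                    "status": f"failed: {exc}",
                    "wall_s": time.perf_counter() - t0,
                }
            )
        log.info("run %d/%d done", run.index + 1, len(runs))

    out = pd.DataFrame(rows)
    if prior is not None:
        out = pd.concat([prior, out], ignore_index=True).sort_values("run")
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    if n_failed:
        log.warning("%d of %d runs failed", n_failed, len(runs))
    out.attrs["n_failed"] = n_failed
    return out
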