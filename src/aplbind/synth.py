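"""Synthetic-data generators emulating the study's measurement structure.

No raw reporter or gel quantifications are deposited for this system, so the
pipeline is exercised on synthetic data drawn from the model itself: reporter
assays with 8-12 biological replicates renormalised to 1 at zero inducer,
gel-shift free-DNA fractions with an unannealed-DNA plateau, and noise-free
footprint occupancy matrices.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import STANDARD_CONSTRUCTS, ReporterConstruct, ReporterDataset, predict_dataset
from .invitro import (
    FOOTPRINT_GRID_NM,
    GELSHIFT_GRID_NM,
    GelShiftDataset,
    simulate_footprint,
)
from .lattice import PAPER_PARAMS_EU, BindingParameters, convert_scale, fraction_free, parse_config

__all__ = ["SyntheticSpec", "REPORTER_GRID_EU", "gen_reporter_data",
           "gen_gelshift_data", "gen_footprint_truth"]

#: 12 Apl concentrations (expression units) spanning the in vivo induction
#: range 0-1500 EU: zero plus roughly log-spaced levels.
REPORTER_GRID_EU = (0.0, 25.0, 50.0, 100.0, 150.0, 250.0, 400.0, 600.0,
                    800.0, 1000.0, 1250.0, 1500.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic experiments.

    ``noise_sd`` is the sigma of multiplicative log-normal measurement noise
    (expression data are positive and ratio-valued); ``plateau_fraction`` is
    the fraction of gel DNA that is mis-annealed and cannot bind.
    """

    seed: int
    true_params: BindingParameters = PAPER_PARAMS_EU
    constructs: tuple[ReporterConstruct, ...] = STANDARD_CONSTRUCTS
    c_grid_reporter: tuple[float, ...] = REPORTER_GRID_EU
    c_grid_gel: tuple[float, ...] = GELSHIFT_GRID_NM
    n_replicates: int = 10
    noise_sd: float = 0.05
    plateau_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.plateau_fraction < 0.5:
            raise ValueError("plateau_fraction must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_reporter_data(spec: SyntheticSpec) -> list[ReporterDataset]:
    """Synthetic relative-expression datasets for every construct.

    Model curve x multiplicative log-normal noise, then renormalised within
    each replicate by its own zero-Apl value (so c = 0 rows are exactly 1, as
    in the per-replicate normalisation of the LacZ assays).
    """
    c_grid = np.asarray(spec.c_grid_reporter, dtype=float)
    if not np.any(c_grid == 0):
        raise ValueError("reporter c grid must include 0 (normalisation anchor)")
    rng = np.random.default_rng(spec.seed)
    i0 = int(np.flatnonzero(c_grid == 0)[0])
    out = []
    for con in spec.constructs:
        template = ReporterDataset(con, c_grid, np.ones_like(c_grid),
                                   np.zeros_like(c_grid))
        model = predict_dataset(spec.true_params, template)
        cs, vals, reps = [], [], []
        for rep in range(spec.n_replicates):
            noise = rng.lognormal(mean=0.0, sigma=spec.noise_sd,
                                  size=c_grid.size) if spec.noise_sd > 0 else 1.0
            y = model * noise
            y = y / y[i0]
            cs.append(c_grid)
            vals.append(y)
            reps.append(np.full(c_grid.size, rep))
        out.append(ReporterDataset(con, np.concatenate(cs),
                                   np.concatenate(vals), np.concatenate(reps)))
    return out


def _per_nM(params: BindingParameters) -> BindingParameters:
    if params.scale == "per_nM":
        return params
    return convert_scale(params, direction="to_nM")


def gen_gelshift_data(spec: SyntheticSpec, fragment: str) -> GelShiftDataset:
    """Raw (un-normalised) synthetic gel-shift free-DNA fractions.

    raw(c) = plateau + (1 - plateau) * fraction_free(c) * noise, clipped to
    [0, 1]; the zero-Apl point is left noise-free so the normalisation anchor
    is exact, mirroring its role as the within-gel reference lane.
    """
    c_grid = np.asarray(spec.c_grid_gel, dtype=float)
    if not np.any(c_grid == 0):
        raise ValueError("gel c grid must include 0 (normalisation anchor)")
    rng = np.random.default_rng(spec.seed + 1)   # decouple from reporter draws
    params = _per_nM(spec.true_params)
    lat = parse_config(fragment)
    model = np.array([fraction_free(lat, params, c) for c in c_grid])
    noise = (rng.lognormal(0.0, spec.noise_sd, size=c_grid.size)
             if spec.noise_sd > 0 else np.ones(c_grid.size))
    noise[c_grid == 0] = 1.0
    raw = spec.plateau_fraction + (1 - spec.plateau_fraction) * model * noise
    return GelShiftDataset(fragment=fragment, c=c_grid,
                           fraction_free=np.clip(raw, 0.0, 1.0),
                           normalized=False)


def gen_footprint_truth(spec: SyntheticSpec, n_specific: int,
                        flanks_per_side: int = 2,
                        c_list=FOOTPRINT_GRID_NM) -> pd.DataFrame:
    """Noise-free footprint occupancy matrix at the spec's true parameters.

    Delegates to the forward simulator; exists so tests can diff a generated
    artifact against the pipeline output.
    """
    return simulate_footprint(n_specific, _per_nM(spec.true_params),
                              flanks_per_side=flanks_per_side, c_list=c_list)
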