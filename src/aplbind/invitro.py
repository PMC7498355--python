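"""Forward prediction of in vitro observables: gel-shift free-DNA curves,
binding-stoichiometry distributions, and DNase-footprint-style occupancy maps.

All fragments are modelled in "in vitro mode" (no RNAP species) with
parameters on the nM scale, obtained from the in vivo fit via the calibration
factor d.  Gel-shift fragments are taken literally as their config strings
(no flanking non-specific sites); footprint fragments carry non-specific
flanks on each side, matching the embedding of operators in vector DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .lattice import (
    BindingParameters,
    fraction_free,
    occupancy_profile,
    parse_config,
)

__all__ = [
    "GelShiftDataset",
    "GELSHIFT_GRID_NM",
    "FOOTPRINT_GRID_NM",
    "normalize_gel_fractions",
    "predict_curves",
    "stoichiometry_table",
    "simulate_footprint",
]

#: Apl concentration grid (nM) used in the gel-shift titrations.
GELSHIFT_GRID_NM = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)

#: Apl concentration grid (nM) used in the DNase footprints.
FOOTPRINT_GRID_NM = (3000.0, 2000.0, 1000.0, 794.0, 631.0, 500.0, 400.0, 319.0,
                     100.0, 10.0)


@dataclass
class GelShiftDataset:
    """Free-DNA fractions from a gel-shift titration of one fragment."""

    fragment: str                 # config string, e.g. "1111111"
    c: np.ndarray                 # Apl concentration, nM
    fraction_free: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.fraction_free = np.asarray(self.fraction_free, dtype=float)
        if self.c.shape != self.fraction_free.shape:
            raise ValueError("c and fraction_free must have equal length")
        if np.any(self.c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.c).size != self.c.size:
            raise ValueError("concentrations must be unique")
        if self.normalized and (np.any(self.fraction_free < 0)
                                or np.any(self.fraction_free > 1)):
            raise ValueError("normalized fractions must lie in [0, 1]")


def normalize_gel_fractions(raw: GelShiftDataset,
                            n_plateau: int = 1) -> GelShiftDataset:
    """Affine renormalisation of raw free-DNA fractions.

    Maps the zero-Apl value to 1 and the high-concentration plateau (mean of
    the ``n_plateau`` largest-concentration values, default the single top
    point) to 0, then clips to [0, 1].  The plateau corresponds to a small
    fraction of DNA that is not annealed correctly and cannot be bound.
    """
    if raw.normalized:
        raise ValueError("dataset is already normalized")
    order = np.argsort(raw.c)
    c, y = raw.c[order], raw.fraction_free[order]
    if c[0] != 0:
        raise ValueError("normalisation needs a c = 0 observation")
    if not 1 <= n_plateau < c.size:
        raise ValueError("n_plateau must be in [1, n_points)")
    y0 = y[0]
    plateau = float(np.mean(y[-n_plateau:]))
    if plateau >= y0:
        raise ValueError(
            f"degenerate normalisation: plateau ({plateau:.4g}) >= "
            f"zero-Apl value ({y0:.4g})"
        )
    norm = np.clip((y - plateau) / (y0 - plateau), 0.0, 1.0)
    return GelShiftDataset(fragment=raw.fragment, c=c, fraction_free=norm,
                           normalized=True)


def predict_curves(configs: list[str], params: BindingParameters,
                   c_grid=GELSHIFT_GRID_NM) -> pd.DataFrame:
    """Model fraction of free DNA for each fragment config over a grid.

    Returns a tidy table with columns (config, c, fraction_free).
    """
    rows = []
    for cfg in configs:
        lat = parse_config(cfg)
        for c in c_grid:
            rows.append({"config": cfg, "c": float(c),
                         "fraction_free": fraction_free(lat, params, float(c))})
    return pd.DataFrame(rows)


def stoichiometry_table(config: str, params: BindingParameters,
                        c_grid) -> pd.DataFrame:
    """P(k monomers bound) for one fragment over a concentration grid."""
    lat = parse_config(config)
    rows = []
    for c in c_grid:
        prof = occupancy_profile(lat, params, float(c))
        for k, p in enumerate(prof.stoichiometry):
            rows.append({"config": config, "c": float(c), "k": k,
                         "probability": float(p)})
    return pd.DataFrame(rows)


def simulate_footprint(n_specific: int, params: BindingParameters,
                       flanks_per_side: int = 2,
                       c_list=FOOTPRINT_GRID_NM) -> pd.DataFrame:
    """Per-site occupancy matrix (site x concentration) for a footprint fragment.

    ``n_specific`` adjacent operators embedded between ``flanks_per_side``
    non-specific sites on each side — the in silico counterpart of a DNase
    footprint titration.  Rows are labelled N (flank) or O1..On (operator);
    columns are the concentrations of ``c_list`` in nM.
    """
    if n_specific < 1:
        raise ValueError("need at least one specific site")
    if flanks_per_side < 0:
        raise ValueError("flanks_per_side must be >= 0")
    cfg = "0" * flanks_per_side + "1" * n_specific + "0" * flanks_per_side
    lat = parse_config(cfg)
    labels = ([f"N{-i}" for i in range(flanks_per_side - 1, -1, -1)]
              + [f"O{i + 1}" for i in range(n_specific)]
              + [f"N{n_specific + 1 + i}" for i in range(flanks_per_side)])
    cols = {}
    for c in c_list:
        prof = occupancy_profile(lat, params, float(c))
        cols[float(c)] = prof.site_occupancy
    df = pd.DataFrame(cols, index=labels)
    df.index.name = "site"
    return df
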