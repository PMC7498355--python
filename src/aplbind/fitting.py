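"""Global fitting of the lattice model to promoter-repression reporter data.

The in vivo dataset consists of relative LacZ expression curves for four
reporter constructs (wild-type pR, two operator-scrambled pR variants, and
wild-type pL with pR inactivated), each normalised to 1 at zero Apl.  All
four are fit simultaneously with a shared parameter vector (B, U, F, R, L).

The optimiser mirrors a combined Monte-Carlo / local-search protocol: many
log-uniform random starts ranked by the objective, bounded least-squares
refinement of the best starts, an optional second round with bounds shrunk
around the best runs, and a mean +/- SD summary over the k best refined runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .lattice import (
    BindingParameters,
    SiteLattice,
    convert_scale,
    fraction_free,
    parse_config,
    promoter_occupancy,
)

__all__ = [
    "ReporterConstruct",
    "ReporterDataset",
    "FitRun",
    "FitResult",
    "STANDARD_CONSTRUCTS",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
    "dataset_error",
    "predict_dataset",
    "global_objective",
    "multistart_fit",
    "fit_calibration_d",
]

PARAM_NAMES = ("B", "U", "F", "R", "L")

#: Default log-uniform search bounds; B and U span orders of magnitude.
DEFAULT_BOUNDS = {
    "B": (1e-8, 1e-2),
    "U": (1e-8, 1e-2),
    "F": (1.0, 1e4),
    "R": (1e-3, 1e2),
    "L": (1e-3, 1e2),
}


@dataclass(frozen=True)
class ReporterConstruct:
    """A reporter fusion: lattice config, which promoter drives LacZ, and
    which promoters are present (the pL reporter carries an inactivated pR)."""

    config: str
    readout: str                  # "pR" or "pL"
    pR_active: bool = True
    pL_active: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.readout not in ("pR", "pL"):
            raise ValueError(f"readout must be 'pR' or 'pL', got {self.readout!r}")
        active = self.pR_active if self.readout == "pR" else self.pL_active
        if not active:
            raise ValueError(f"readout promoter {self.readout} is inactive")

    def lattice(self) -> SiteLattice:
        return parse_config(self.config, pR_active=self.pR_active,
                            pL_active=self.pL_active,
                            label=self.label or self.config)


#: The four in vivo constructs fit globally: WT pR, operators 3+5 scrambled,
#: operators 3-5 scrambled, and WT pL with pR inactivated.
STANDARD_CONSTRUCTS = (
    ReporterConstruct("00111111100", "pR", label="WT-pR"),
    ReporterConstruct("00110101100", "pR", label="1101011-pR"),
    ReporterConstruct("00110001100", "pR", label="1100011-pR"),
    ReporterConstruct("00111111100", "pL", pR_active=False, label="WT-pL(pR-)"),
)


@dataclass
class ReporterDataset:
    """Observed (or synthetic) relative-expression measurements for one construct."""

    construct: ReporterConstruct
    c: np.ndarray            # Apl concentration, expression units
    value: np.ndarray        # relative expression, 1 at c = 0 per replicate
    replicate: np.ndarray    # replicate id per row

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (self.c.shape == self.value.shape == self.replicate.shape):
            raise ValueError("c, value and replicate must have equal length")
        if np.any(self.c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(self.value <= 0):
            raise ValueError("relative expression must be > 0")
        for rep in np.unique(self.replicate):
            sel = self.replicate == rep
            if not np.any(self.c[sel] == 0):
                raise ValueError(
                    f"replicate {rep!r} lacks a c = 0 observation "
                    "(normalisation anchor)"
                )

    @property
    def n_points(self) -> int:
        return self.c.size


def _params_from_vector(x: np.ndarray,
                        template: BindingParameters | None = None) -> BindingParameters:
    tpl = template or BindingParameters(B=1e-5, U=1e-5, F=1.0)
    return replace(tpl, B=float(x[0]), U=float(x[1]), F=float(x[2]),
                   R=float(x[3]), L=float(x[4]))


def predict_dataset(params: BindingParameters,
                    dataset: ReporterDataset) -> np.ndarray:
    """Model relative expression at every observation of a dataset."""
    lat = dataset.construct.lattice()
    readout = dataset.construct.readout
    # observations share few distinct concentrations; evaluate each once and
    # normalise by the zero-Apl occupancy (computed once, not per point)
    uniq, inv = np.unique(dataset.c, return_inverse=True)
    p0 = promoter_occupancy(lat, params, 0.0, readout)
    vals = np.array([promoter_occupancy(lat, params, c, readout) for c in uniq]) / p0
    return vals[inv]


def dataset_error(predictions: np.ndarray, dataset: ReporterDataset,
                  kind: str = "squared") -> float:
    """Per-dataset error: mean squared (default) or mean absolute residual."""
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != dataset.value.shape:
        raise ValueError("predictions and observations differ in length")
    r = pred - dataset.value
    if kind == "squared":
        return float(np.mean(r ** 2))
    if kind == "absolute":
        return float(np.mean(np.abs(r)))
    raise ValueError(f"unknown error kind {kind!r}")


def global_objective(params: BindingParameters | np.ndarray,
                     datasets: list[ReporterDataset],
                     kind: str = "squared") -> float:
    """Sum over datasets of the per-dataset (point-normalised) error."""
    if not datasets:
        raise ValueError("need at least one dataset")
    if not isinstance(params, BindingParameters):
        params = _params_from_vector(np.asarray(params, dtype=float))
    return sum(dataset_error(predict_dataset(params, ds), ds, kind=kind)
               for ds in datasets)


def _residual_vector(x_log10: np.ndarray,
                     datasets: list[ReporterDataset]) -> np.ndarray:
    """Residuals scaled so that sum of squares equals the global objective."""
    params = _params_from_vector(10.0 ** x_log10)
    out = []
    for ds in datasets:
        r = predict_dataset(params, ds) - ds.value
        out.append(r / math.sqrt(ds.n_points))
    return np.concatenate(out)


@dataclass
class FitRun:
    params: dict
    objective: float
    start: dict
    converged: bool
    round: int


@dataclass
class FitResult:
    """All refined runs plus a mean +/- SD summary over the k best."""

    runs: list[FitRun]
    k_best: int
    bounds: dict
    seed: int

    @property
    def sorted_runs(self) -> list[FitRun]:
        return sorted(self.runs, key=lambda r: r.objective)

    @property
    def best(self) -> FitRun:
        return self.sorted_runs[0]

    def best_params(self, template: BindingParameters | None = None) -> BindingParameters:
        b = self.best.params
        return _params_from_vector([b[n] for n in PARAM_NAMES], template)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each parameter over the k best-by-objective runs."""
        top = self.sorted_runs[: self.k_best]
        rows = []
        for name in PARAM_NAMES:
            vals = np.array([r.params[name] for r in top])
            rows.append({"parameter": name, "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0})
        rows.append({"parameter": "objective",
                     "mean": np.mean([r.objective for r in top]),
                     "sd": (np.std([r.objective for r in top], ddof=1)
                            if len(top) > 1 else 0.0)})
        return pd.DataFrame(rows)

    def runs_table(self) -> pd.DataFrame:
        """Pooled runs (one row per refined start) for convergence inspection:
        plotting each parameter column against ``objective`` reproduces the
        error-vs-parameter profiles."""
        recs = []
        for r in self.sorted_runs:
            rec = dict(r.params)
            rec.update({f"start_{k}": v for k, v in r.start.items()})
            rec["objective"] = r.objective
            rec["converged"] = r.converged
            rec["round"] = r.round
            recs.append(rec)
        return pd.DataFrame(recs)


def _bounds_arrays(bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([bounds[n][0] for n in PARAM_NAMES], dtype=float)
    hi = np.array([bounds[n][1] for n in PARAM_NAMES], dtype=float)
    if np.any(lo <= 0) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite, positive and ordered")
    return lo, hi


def multistart_fit(datasets: list[ReporterDataset],
                   bounds: dict | None = None,
                   n_random: int = 1000,
                   n_polish: int = 100,
                   k_best: int = 20,
                   seed: int = 0,
                   rounds: int = 2,
                   round2_polish: int | None = None) -> FitResult:
    """Multistart random search with bounded local least-squares refinement.

    Round 1 draws ``n_random`` log-uniform start points inside ``bounds``,
    refines the ``n_polish`` best; round 2 (if ``rounds >= 2``) shrinks the
    bounds to the 2x-padded hull of the best decile of round-1 runs, redraws,
    and refines ``round2_polish`` (default ``2 * n_polish``) starts.  All
    refined runs are pooled; the summary averages the ``k_best`` lowest-error
    runs.  Deterministic for a fixed seed.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    bounds = dict(bounds or DEFAULT_BOUNDS)
    rng = np.random.default_rng(seed)
    runs: list[FitRun] = []
    round_bounds = bounds
    polish_counts = [n_polish] + [round2_polish or 2 * n_polish] * max(0, rounds - 1)

    for rnd in range(1, rounds + 1):
        lo, hi = _bounds_arrays(round_bounds)
        starts = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi),
                                     size=(n_random, len(PARAM_NAMES)))
        objs = np.array([global_objective(s, datasets) for s in starts])
        order = np.argsort(objs)
        n_pol = min(polish_counts[rnd - 1], n_random)
        for idx in order[:n_pol]:
            runs.append(_polish(starts[idx], objs[idx], lo, hi, datasets, rnd))
        if rnd < rounds:
            round_bounds = _shrink_bounds(runs, bounds)

    if not any(r.converged for r in runs):
        objs = [r.objective for r in runs]
        raise RuntimeError(
            "no multistart run converged; best objective was "
            f"{min(objs) if objs else math.nan}"
        )
    return FitResult(runs=runs, k_best=min(k_best, len(runs)),
                     bounds=bounds, seed=seed)


def _polish(start: np.ndarray, start_obj: float, lo: np.ndarray, hi: np.ndarray,
            datasets: list[ReporterDataset], rnd: int) -> FitRun:
    x0 = np.log10(start)
    try:
        res = least_squares(_residual_vector, x0, args=(datasets,),
                            bounds=(np.log10(lo), np.log10(hi)),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        x_fit = 10.0 ** res.x
        obj = float(2 * res.cost)      # cost = 0.5 * sum of squares
        converged = bool(res.success)
    except Exception:
        x_fit, obj, converged = start, start_obj, False
    if obj > start_obj:                # refinement must never worsen the start
        x_fit, obj = start, start_obj
    return FitRun(params=dict(zip(PARAM_NAMES, map(float, x_fit))),
                  objective=obj,
                  start=dict(zip(PARAM_NAMES, map(float, start))),
                  converged=converged, round=rnd)


def _shrink_bounds(runs: list[FitRun], outer: dict) -> dict:
    """Hull of the best decile of runs, padded 2x, clipped to the outer bounds."""
    ranked = sorted(runs, key=lambda r: r.objective)
    top = ranked[: max(1, len(ranked) // 10)]
    new = {}
    for name in PARAM_NAMES:
        vals = np.array([r.params[name] for r in top])
        lo = max(vals.min() / 2.0, outer[name][0])
        hi = min(vals.max() * 2.0, outer[name][1])
        if hi <= lo:                  # degenerate hull: keep outer bounds
            lo, hi = outer[name]
        new[name] = (lo, hi)
    return new


def fit_calibration_d(gel_c_nM: np.ndarray, gel_fraction_free: np.ndarray,
                      params_in_vivo: BindingParameters,
                      config: str = "1111111",
                      d_bounds: tuple[float, float] = (1e-3, 1e3)) -> float:
    """Fit the expression-unit -> nM calibration factor d on gel-shift data.

    B/U and F are held at their in vivo values; only the concentration axis is
    rescaled (``B_nM = B_EU * d``).  Minimises the squared error between the
    model fraction of free DNA and the normalised gel data over log d.
    """
    c = np.asarray(gel_c_nM, dtype=float)
    y = np.asarray(gel_fraction_free, dtype=float)
    if c.size == 0 or c.size != y.size:
        raise ValueError("gel data must be non-empty and aligned")
    if c.size >= 2:
        order = np.argsort(c)
        if np.all(np.diff(y[order]) >= 0) and y[order][0] != y[order][-1]:
            raise ValueError("gel free-DNA fractions increase with concentration; "
                             "check normalisation")
    lat = parse_config(config)

    def sse(log_d: float) -> float:
        p = convert_scale(params_in_vivo, d=float(np.exp(log_d)),
                          direction="to_nM")
        pred = np.array([fraction_free(lat, p, ci) for ci in c])
        return float(np.sum((pred - y) ** 2))

    res = minimize_scalar(sse, bounds=(math.log(d_bounds[0]), math.log(d_bounds[1])),
                          method="bounded", options={"xatol": 1e-12})
    return float(math.exp(res.x))
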