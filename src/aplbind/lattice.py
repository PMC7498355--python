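"""Statistical-thermodynamic model of cooperative monomer binding on a 1-D site lattice.

The phage 186 excisionase/repressor Apl binds the pR-pL regulatory region as a
row of monomers: seven specific operators (S) flanked by non-specific DNA (N),
with nearest-neighbour cooperativity letting bound monomers "spread" into
non-specific sites.  Every occupancy state of the lattice is assigned a
statistical weight

    w(state) = prod_{occupied S} c*w_S  *  prod_{occupied N} c*U
               *  F^{#adjacent occupied pairs}  *  R^{RNAP at pR}  *  L^{RNAP at pL}

where ``c`` is the free Apl concentration, ``w_S`` is ``B+U`` (a specific site
can also be bound non-specifically) or plain ``B`` depending on
``specific_weight_mode``, ``F`` is the dimensionless pairwise cooperativity,
and ``R``/``L`` are composite weights for RNA polymerase occupying the pR/pL
promoters.  RNAP at a promoter requires its footprint sites to be free of Apl.
Observable quantities (promoter occupancy, repression curves, fraction of free
DNA in a gel shift, per-site footprint occupancies, binding stoichiometry) are
ratios of sums of these weights.

Two independent routes to the partition function are provided: exhaustive
enumeration (:func:`partition_function`, vectorised over all ``2^n`` occupancy
states) and a 2x2 transfer matrix (:func:`transfer_matrix_Z`) used as an O(n)
cross-check and as the only route for lattices beyond the enumeration cap.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import xlogy

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "ENUMERATION_CAP",
    "SiteLattice",
    "BindingParameters",
    "LatticeState",
    "StateEnsemble",
    "OccupancyProfile",
    "PAPER_PARAMS_EU",
    "parse_config",
    "enumerate_states",
    "state_weight",
    "partition_function",
    "transfer_matrix_Z",
    "promoter_occupancy",
    "relative_expression",
    "fraction_free",
    "occupancy_profile",
    "apparent_kd",
    "derived_constants",
    "convert_scale",
]

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.987e-3

#: Default temperature for free-energy conversions (37 C growth conditions).
DEFAULT_TEMPERATURE_K = 310.0

#: Largest lattice enumerated exhaustively (2^n states); beyond this the
#: transfer matrix must be used.
ENUMERATION_CAP = 20

_DEFAULT_PR_FOOTPRINT = frozenset({1, 2, 3, 4})
_DEFAULT_PL_FOOTPRINT = frozenset({9, 10, 11})


@dataclass(frozen=True)
class SiteLattice:
    """An ordered row of binding sites with optional promoter footprints.

    Parameters
    ----------
    sites
        Sequence over ``{'S', 'N'}``: specific operator or non-specific DNA,
        numbered 1..n from the pR-proximal end.
    pR_footprint, pL_footprint
        1-based site indices whose Apl occupancy excludes RNAP from pR / pL.
        Empty sets together with inactive promoters give "in vitro mode".
    pR_active, pL_active
        Whether RNAP-bound states at each promoter are part of the state space.
    label
        Free-text name ("WT", "1101011", "attP5", ...).
    """

    sites: tuple[str, ...]
    pR_footprint: frozenset[int] = frozenset()
    pL_footprint: frozenset[int] = frozenset()
    pR_active: bool = False
    pL_active: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("lattice needs at least one site")
        bad = [s for s in self.sites if s not in ("S", "N")]
        if bad:
            raise ValueError(f"site classes must be 'S' or 'N', got {bad!r}")
        n = len(self.sites)
        for name, fp in (("pR", self.pR_footprint), ("pL", self.pL_footprint)):
            if not all(1 <= i <= n for i in fp):
                raise ValueError(f"{name} footprint {sorted(fp)} outside 1..{n}")
        if self.pR_active and not self.pR_footprint:
            raise ValueError("active pR promoter requires a pR footprint")
        if self.pL_active and not self.pL_footprint:
            raise ValueError("active pL promoter requires a pL footprint")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def in_vitro(self) -> bool:
        """True when no promoter is active (no RNAP species in the model)."""
        return not (self.pR_active or self.pL_active)

    @property
    def specific_indices(self) -> tuple[int, ...]:
        """1-based positions of specific operators."""
        return tuple(i + 1 for i, s in enumerate(self.sites) if s == "S")

    def config_string(self) -> str:
        return "".join("1" if s == "S" else "0" for s in self.sites)


@dataclass(frozen=True)
class BindingParameters:
    """Association parameters of the lattice model.

    ``B`` and ``U`` are specific and non-specific association parameters per
    concentration unit (``scale`` tags the unit system: in vivo "expression
    units" or in vitro nM).  ``F`` is the nearest-neighbour cooperativity,
    ``R``/``L`` the composite RNAP weights at pR/pL, and ``d`` the calibration
    factor linking the two concentration scales (expression units per nM).
    """

    B: float
    U: float
    F: float
    R: float = 0.0
    L: float = 0.0
    scale: str = "expression_units"
    d: float = 1.75
    specific_weight_mode: str = "B_plus_U"

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("B must be > 0")
        if self.U < 0:
            raise ValueError("U must be >= 0")
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if self.R < 0 or self.L < 0:
            raise ValueError("R and L must be >= 0")
        if self.d <= 0:
            raise ValueError("calibration factor d must be > 0")
        if self.scale not in ("expression_units", "per_nM"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.specific_weight_mode not in ("B_plus_U", "B_only"):
            raise ValueError(
                f"unknown specific_weight_mode {self.specific_weight_mode!r}"
            )

    @property
    def specific_site_weight(self) -> float:
        """Per-concentration weight of an occupied specific site."""
        if self.specific_weight_mode == "B_plus_U":
            return self.B + self.U
        return self.B


#: Mean fitted in vivo parameter set (top-20 fits), on the expression-unit scale.
PAPER_PARAMS_EU = BindingParameters(
    B=4.55e-5, U=0.99e-5, F=50.7, R=6.88, L=0.29,
    scale="expression_units", d=1.75,
)


@dataclass(frozen=True)
class LatticeState:
    """One microstate: per-site Apl occupancy plus RNAP flags."""

    occupancy: tuple[int, ...]
    rnap_pR: bool = False
    rnap_pL: bool = False

    @property
    def n_bound(self) -> int:
        return sum(self.occupancy)


@dataclass(frozen=True)
class OccupancyProfile:
    """Marginal per-site occupancies and stoichiometry distribution at one c."""

    c: float
    site_occupancy: np.ndarray   # shape (n,), P(site i bound)
    stoichiometry: np.ndarray    # shape (n+1,), P(k monomers bound)


class StateEnsemble:
    """Enumerated states with weights, partition function and probabilities.

    Weights are held in log space so that large lattices / strong binding do
    not overflow; ``weights`` and ``Z`` exponentiate on access.
    """

    def __init__(self, lattice: SiteLattice, params: BindingParameters,
                 c: float, log_weights: np.ndarray):
        self.lattice = lattice
        self.params = params
        self.c = float(c)
        self.log_weights = log_weights
        self._log_Z = _logsumexp(log_weights)
        if not np.isfinite(self._log_Z):
            raise FloatingPointError(
                f"partition function non-finite (log Z = {self._log_Z})"
            )

    @property
    def log_Z(self) -> float:
        return self._log_Z

    @property
    def Z(self) -> float:
        return math.exp(self._log_Z)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights - self._log_Z)

    @property
    def states(self) -> list[LatticeState]:
        return enumerate_states(self.lattice)

    def __len__(self) -> int:
        return self.log_weights.size


# ---------------------------------------------------------------------------
# construction

def parse_config(config_string: str, *, pR_active: bool = False,
                 pL_active: bool = False,
                 pR_footprint: Iterable[int] | None = None,
                 pL_footprint: Iterable[int] | None = None,
                 label: str | None = None) -> SiteLattice:
    """Build a lattice from a binary config string like ``"00111111100"``.

    ``'1'`` marks a specific operator, ``'0'`` a non-specific site.  When a
    promoter is active and no footprint is given, the wild-type defaults are
    attached: sites 1-4 exclude RNAP at pR and sites 9-11 exclude it at pL.
    """
    if not config_string:
        raise ValueError("config string must be non-empty")
    for pos, ch in enumerate(config_string, start=1):
        if ch not in "01":
            raise ValueError(
                f"config string has non-binary character {ch!r} at position {pos}"
            )
    n = len(config_string)
    sites = tuple("S" if ch == "1" else "N" for ch in config_string)

    def _resolve(fp, default, active, name):
        if fp is not None:
            return frozenset(int(i) for i in fp)
        if not active:
            return frozenset()
        if max(default) > n:
            raise ValueError(
                f"default {name} footprint {sorted(default)} does not fit a "
                f"{n}-site lattice; pass {name}_footprint explicitly"
            )
        return default

    return SiteLattice(
        sites=sites,
        pR_footprint=_resolve(pR_footprint, _DEFAULT_PR_FOOTPRINT, pR_active, "pR"),
        pL_footprint=_resolve(pL_footprint, _DEFAULT_PL_FOOTPRINT, pL_active, "pL"),
        pR_active=pR_active,
        pL_active=pL_active,
        label=label if label is not None else config_string,
    )


# ---------------------------------------------------------------------------
# enumeration internals (cached per lattice)

def _logsumexp(logw: np.ndarray) -> float:
    m = np.max(logw)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(logw - m))))


@functools.lru_cache(maxsize=64)
def _occupancy_arrays(lattice: SiteLattice):
    """Per-occupancy-state count arrays for all 2^n Apl configurations.

    Returns (occ, nS, nN, pairs, pR_free, pL_free); state ``i`` is the n-digit
    binary expansion of ``i`` with site 1 as the most significant digit, so the
    enumeration order matches the integer order of the config strings.
    """
    n = lattice.n_sites
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"lattice of {n} sites exceeds the enumeration cap "
            f"({ENUMERATION_CAP}); use transfer_matrix_Z instead"
        )
    idx = np.arange(2 ** n, dtype=np.int64)
    occ = np.empty((2 ** n, n), dtype=np.uint8)
    for j in range(n):
        occ[:, j] = (idx >> (n - 1 - j)) & 1
    s_mask = np.array([s == "S" for s in lattice.sites])
    nS = occ[:, s_mask].sum(axis=1).astype(np.int64)
    nN = occ[:, ~s_mask].sum(axis=1).astype(np.int64)
    if n > 1:
        pairs = (occ[:, :-1] & occ[:, 1:]).sum(axis=1).astype(np.int64)
    else:
        pairs = np.zeros(2 ** n, dtype=np.int64)
    pR_free = _footprint_free(occ, lattice.pR_footprint)
    pL_free = _footprint_free(occ, lattice.pL_footprint)
    return occ, nS, nN, pairs, pR_free, pL_free


def _footprint_free(occ: np.ndarray, footprint: frozenset[int]) -> np.ndarray:
    if not footprint:
        return np.ones(occ.shape[0], dtype=bool)
    cols = np.array(sorted(i - 1 for i in footprint))
    return occ[:, cols].sum(axis=1) == 0


@functools.lru_cache(maxsize=64)
def _full_state_table(lattice: SiteLattice):
    """Row indices into the 2^n occupancy table plus RNAP flags for every state.

    Order: all Apl-only states, then RNAP@pR states, RNAP@pL states, and
    states with RNAP at both promoters simultaneously.
    """
    occ, nS, nN, pairs, pR_free, pL_free = _occupancy_arrays(lattice)
    nstates = occ.shape[0]
    blocks = [(np.arange(nstates), False, False)]
    if lattice.pR_active:
        blocks.append((np.flatnonzero(pR_free), True, False))
    if lattice.pL_active:
        blocks.append((np.flatnonzero(pL_free), False, True))
    if lattice.pR_active and lattice.pL_active:
        blocks.append((np.flatnonzero(pR_free & pL_free), True, True))
    rows = np.concatenate([b[0] for b in blocks])
    fR = np.concatenate([np.full(b[0].size, b[1]) for b in blocks])
    fL = np.concatenate([np.full(b[0].size, b[2]) for b in blocks])
    return rows, fR, fL


def enumerate_states(lattice: SiteLattice) -> list[LatticeState]:
    """All model states: Apl occupancies plus compatible RNAP placements."""
    occ = _occupancy_arrays(lattice)[0]
    rows, fR, fL = _full_state_table(lattice)
    return [
        LatticeState(tuple(int(x) for x in occ[r]), bool(a), bool(b))
        for r, a, b in zip(rows, fR, fL)
    ]


def _occupancy_log_weights(lattice: SiteLattice, params: BindingParameters,
                           c: float) -> np.ndarray:
    """Log weights of the 2^n Apl-only occupancy states at concentration c."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    _, nS, nN, pairs, _, _ = _occupancy_arrays(lattice)
    wS = c * params.specific_site_weight
    wN = c * params.U
    # xlogy(0, 0) = 0: unoccupied sites contribute nothing even at c = 0.
    return xlogy(nS, wS) + xlogy(nN, wN) + xlogy(pairs, params.F)


def state_weight(state: LatticeState, lattice: SiteLattice,
                 params: BindingParameters, c: float) -> float:
    """Statistical weight of a single state (scalar, direct product form)."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if len(state.occupancy) != lattice.n_sites:
        raise ValueError("state does not match lattice length")
    if state.rnap_pR and any(state.occupancy[i - 1] for i in lattice.pR_footprint):
        raise ValueError("RNAP at pR requires its footprint sites to be empty")
    if state.rnap_pL and any(state.occupancy[i - 1] for i in lattice.pL_footprint):
        raise ValueError("RNAP at pL requires its footprint sites to be empty")
    if (state.rnap_pR or state.rnap_pL) and lattice.in_vitro:
        raise ValueError("RNAP flags are not allowed in in vitro mode")
    w = 1.0
    for site_class, bit in zip(lattice.sites, state.occupancy):
        if bit:
            w *= c * (params.specific_site_weight if site_class == "S" else params.U)
    for a, b in zip(state.occupancy[:-1], state.occupancy[1:]):
        if a and b:
            w *= params.F
    if state.rnap_pR:
        w *= params.R
    if state.rnap_pL:
        w *= params.L
    return w


def partition_function(lattice: SiteLattice, params: BindingParameters,
                       c: float) -> StateEnsemble:
    """Enumerate all states and return the ensemble with Z and probabilities."""
    logw_occ = _occupancy_log_weights(lattice, params, c)
    rows, fR, fL = _full_state_table(lattice)
    logw = logw_occ[rows].astype(float, copy=True)
    if lattice.pR_active:
        logw[fR] += xlogy(1.0, params.R)
    if lattice.pL_active:
        logw[fL] += xlogy(1.0, params.L)
    return StateEnsemble(lattice, params, c, logw)


# ---------------------------------------------------------------------------
# transfer matrix (independent O(n) oracle)

def transfer_matrix_Z(lattice: SiteLattice, params: BindingParameters,
                      c: float) -> float:
    """Partition function via a 2-state transfer matrix along the lattice.

    In vivo mode sums the four RNAP sectors (none / pR / pL / both), clamping
    the footprint sites of each occupied promoter to the empty state.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    w = np.array([
        c * (params.specific_site_weight if s == "S" else params.U)
        for s in lattice.sites
    ])
    Z = _tm_chain(w, params.F)
    if lattice.pR_active:
        Z += params.R * _tm_chain(_clamped(w, lattice.pR_footprint), params.F)
    if lattice.pL_active:
        Z += params.L * _tm_chain(_clamped(w, lattice.pL_footprint), params.F)
    if lattice.pR_active and lattice.pL_active:
        Z += (params.R * params.L
              * _tm_chain(_clamped(w, lattice.pR_footprint | lattice.pL_footprint),
                          params.F))
    return Z


def _clamped(w: np.ndarray, footprint: frozenset[int]) -> np.ndarray:
    out = w.copy()
    for i in footprint:
        out[i - 1] = 0.0
    return out


def _tm_chain(w: np.ndarray, F: float) -> float:
    # z[s] = partial sum over prefixes ending with site state s
    z0, z1 = 1.0, w[0]
    log_scale = 0.0
    for wi in w[1:]:
        z0, z1 = z0 + z1, wi * (z0 + F * z1)
        total = z0 + z1
        if total > 1e250:          # rescale to avoid overflow on long chains
            z0 /= total
            z1 /= total
            log_scale += math.log(total)
    return (z0 + z1) * math.exp(log_scale)


# ---------------------------------------------------------------------------
# observables

def _sector_sums(lattice: SiteLattice, params: BindingParameters, c: float):
    """Scaled sums (Zf, ZpR, ZpL, Zboth, log_scale) over the occupancy sectors.

    All four sums share one log-scale offset so their ratios are exact.
    """
    logw = _occupancy_log_weights(lattice, params, c)
    _, _, _, _, pR_free, pL_free = _occupancy_arrays(lattice)
    m = float(np.max(logw))
    w = np.exp(logw - m)
    Zf = float(w.sum())
    ZpR = float(w[pR_free].sum())
    ZpL = float(w[pL_free].sum())
    Zb = float(w[pR_free & pL_free].sum())
    return Zf, ZpR, ZpL, Zb, m


def promoter_occupancy(lattice: SiteLattice, params: BindingParameters,
                       c: float, promoter: str) -> float:
    """Probability that RNAP occupies the given promoter ("pR" or "pL")."""
    if promoter not in ("pR", "pL"):
        raise ValueError(f"unknown promoter {promoter!r}")
    active = lattice.pR_active if promoter == "pR" else lattice.pL_active
    if not active:
        raise ValueError(f"promoter {promoter} is not active in this lattice")
    Zf, ZpR, ZpL, Zb, _ = _sector_sums(lattice, params, c)
    R = params.R if lattice.pR_active else 0.0
    L = params.L if lattice.pL_active else 0.0
    denom = Zf + R * ZpR + L * ZpL + R * L * Zb
    if promoter == "pR":
        num = R * (ZpR + L * Zb)
    else:
        num = L * (ZpL + R * Zb)
    return num / denom


def relative_expression(lattice: SiteLattice, params: BindingParameters,
                        c: float, promoter: str) -> float:
    """Promoter occupancy normalised to 1 at zero Apl concentration."""
    return (promoter_occupancy(lattice, params, c, promoter)
            / promoter_occupancy(lattice, params, 0.0, promoter))


def fraction_free(lattice: SiteLattice, params: BindingParameters,
                  c: float) -> float:
    """Probability of the completely unoccupied lattice (unshifted gel band).

    Defined for in vitro mode only; RNAP is absent from gel-shift assays.
    """
    if not lattice.in_vitro:
        raise ValueError("fraction_free is defined for in vitro lattices "
                         "(no active promoters)")
    logw = _occupancy_log_weights(lattice, params, c)
    m = float(np.max(logw))
    Z_scaled = float(np.sum(np.exp(logw - m)))
    # empty state has log weight 0
    return math.exp(-m) / Z_scaled


def occupancy_profile(lattice: SiteLattice, params: BindingParameters,
                      c: float) -> OccupancyProfile:
    """Per-site marginal occupancy and P(k monomers bound) at concentration c."""
    ens = partition_function(lattice, params, c)
    occ = _occupancy_arrays(lattice)[0]
    rows, _, _ = _full_state_table(lattice)
    p = ens.probabilities
    occ_full = occ[rows]
    site_occ = occ_full.T.astype(float) @ p
    k = occ_full.sum(axis=1).astype(np.int64)
    stoich = np.bincount(k, weights=p, minlength=lattice.n_sites + 1)
    return OccupancyProfile(c=float(c), site_occupancy=site_occ,
                            stoichiometry=stoich)


def apparent_kd(lattice: SiteLattice, params: BindingParameters,
                criterion: str = "fraction_free_half",
                rtol: float = 1e-8, max_widen: int = 60) -> float:
    """Apparent dissociation constant of the whole fragment.

    ``fraction_free_half``: concentration at which half the DNA molecules
    carry no Apl (the gel-shift definition).  ``half_occupancy``: concentration
    at which the mean occupancy of the specific sites reaches 50%.
    """
    if criterion == "fraction_free_half":
        def f(c):
            return fraction_free(lattice, params, c) - 0.5
    elif criterion == "half_occupancy":
        s_idx = np.array([i - 1 for i in lattice.specific_indices])
        if s_idx.size == 0:
            raise ValueError("half_occupancy criterion needs specific sites")

        def f(c):
            prof = occupancy_profile(lattice, params, c)
            return 0.5 - float(prof.site_occupancy[s_idx].mean())
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    scale = 1.0 / params.specific_site_weight
    lo, hi = scale * 1e-6, scale
    widened = 0
    while f(hi) > 0 and widened < max_widen:
        hi *= 4.0
        widened += 1
    while f(lo) < 0 and widened < max_widen:
        lo /= 4.0
        widened += 1
    if f(lo) < 0 or f(hi) > 0:
        raise RuntimeError("could not bracket the apparent K_D")
    return brentq(f, lo, hi, rtol=rtol)


def derived_constants(params: BindingParameters,
                      temperature: float = DEFAULT_TEMPERATURE_K) -> dict:
    """Dissociation constants and free energies implied by the parameters.

    ``kd_*`` values are on the parameter scale (1/B etc.).  Molar association
    constants and binding free energies are reported when the parameters are
    on the nM scale (``per_nM``), where 1 nM^-1 = 1e9 M^-1; the cooperativity
    free energy ``dG_coop = -RT ln F`` is scale-free.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    RT = GAS_CONSTANT_KCAL * temperature
    out = {
        "kd_specific": 1.0 / params.B,
        "kd_combined": 1.0 / params.specific_site_weight,
        "dG_coop_kcal_mol": -RT * math.log(params.F),
        "temperature_K": temperature,
        "scale": params.scale,
    }
    if params.U > 0:
        out["kd_nonspecific"] = 1.0 / params.U
    if params.scale == "per_nM":
        B_M = params.B * 1e9
        out["B_per_M"] = B_M
        out["kd_specific_M"] = 1.0 / B_M
        out["dG_specific_kcal_mol"] = -RT * math.log(B_M)
        if params.U > 0:
            U_M = params.U * 1e9
            out["U_per_M"] = U_M
            out["kd_nonspecific_M"] = 1.0 / U_M
            out["dG_nonspecific_kcal_mol"] = -RT * math.log(U_M)
    return out


def convert_scale(params: BindingParameters, d: float | None = None,
                  direction: str = "to_nM") -> BindingParameters:
    """Convert B and U between expression units and nM using calibration d.

    ``d`` is in expression units per nM, so ``c_EU = d * c_nM`` and weights
    ``c*B`` are invariant when ``B_nM = B_EU * d``.
    """
    d = params.d if d is None else d
    if d <= 0:
        raise ValueError("calibration factor d must be > 0")
    if direction == "to_nM":
        if params.scale == "per_nM":
            raise ValueError("parameters already on the nM scale")
        return replace(params, B=params.B * d, U=params.U * d,
                       scale="per_nM", d=d)
    if direction == "to_expression_units":
        if params.scale == "expression_units":
            raise ValueError("parameters already on the expression-unit scale")
        return replace(params, B=params.B / d, U=params.U / d,
                       scale="expression_units", d=d)
    raise ValueError(f"unknown direction {direction!r}")
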