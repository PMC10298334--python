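"""Nearest-neighbor duplex thermodynamics and amplicon melt simulation.

Duplex helix-formation enthalpy and entropy are summed from a unified
nearest-neighbor stack table (versioned in ``data/nn_unified.json``) with
initiation terms carrying the terminal A·T penalty.  Entropy is corrected
for monovalent salt with 0.368·(N−1)·ln[Na⁺] cal/(mol·K).

Oligo melting temperature (bimolecular, non-self-complementary):

    Tm = ΔH·1000 / (ΔS + R·ln(C_T/4)) − 273.15

Long amplicons use a unimolecular two-state approximation (no concentration
term): helicity θ(T) = 1 / (1 + exp[(ΔH_melt/R)(1/T_m − 1/T)]) with
T_m = ΔH/ΔS, which is what HRM curve shape and relative ΔTm clustering
consume.  A windowed variant averages θ over overlapping sub-windows to
produce compound transitions for multi-domain amplicons.

No Tm formula is attached to the bundled primer panel's reported values, so
one global (Na⁺, total strand concentration) convention is calibrated by
least mean-absolute-error against those reported values and frozen as the
defaults below; :func:`calibrate_convention` re-runs that fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize

from .seqio import Primer, expand_degenerate, is_concrete

__all__ = ["ThermoProfile", "MeltCurve", "duplex_params", "primer_tm",
           "simulate_melt_curve", "melt_grid", "calibrate_convention",
           "DEFAULT_NA_MM", "DEFAULT_STRAND_CONC_M", "DEFAULT_GRID"]

# Convention frozen from the one-time calibration against the bundled
# 22-primer panel (MAE ~0.95 degC, max |err| ~2.2 degC).
DEFAULT_NA_MM = 91.4
DEFAULT_STRAND_CONC_M = 8.34e-7

#: HRM dissociation grid: 0.2 degC increments from 65 to 95 degC.
DEFAULT_GRID = (65.0, 95.0, 0.2)

_MIN_OLIGO_LEN = 8
_MIN_AMPLICON_LEN = 20


def _load_nn():
    with resources.files("meltmark.data").joinpath("nn_unified.json").open() as fh:
        raw = json.load(fh)
    return raw


_NN = _load_nn()
_STACKS = {k: tuple(v) for k, v in _NN["stacks"].items()}
_INIT_GC = tuple(_NN["initiation_terminal_GC"])
_INIT_AT = tuple(_NN["initiation_terminal_AT"])
R_CAL = float(_NN["gas_constant_cal"])
_SALT_COEFF = float(_NN["salt_entropy_coefficient"])


@dataclass(frozen=True)
class ThermoProfile:
    """Helix-formation thermodynamics of one duplex.

    dH in kcal/mol and dS in cal/(mol·K) are negative for any stable duplex;
    dS is salt-corrected.  ``tm`` is in °C under the convention used.
    """

    dH: float
    dS: float
    tm: float


@dataclass
class MeltCurve:
    """Fluorescence over a strictly increasing, constant-step temperature grid."""

    sample_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperatures and fluorescence must be 1-D arrays of equal length")
        if len(self.temperatures) < 2:
            raise ValueError("a melt curve needs at least two grid points")
        steps = np.diff(self.temperatures)
        if np.any(steps <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise ValueError("temperature grid step must be constant")
        if np.any(self.fluorescence < -1e-9):
            raise ValueError("fluorescence must be non-negative")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])

    def __len__(self) -> int:
        return len(self.temperatures)


def _nn_sums(seq: str) -> tuple[float, float]:
    """Raw (1 M Na+) stack + initiation sums for a concrete sequence."""
    dh = ds = 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _STACKS[a + b]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    return dh, ds


def _salt_ds(ds: float, n: int, na_mM: float) -> float:
    return ds + _SALT_COEFF * (n - 1) * math.log(na_mM / 1000.0)


def _oligo_tm(dh: float, ds_salt: float, strand_conc_M: float) -> float:
    return dh * 1000.0 / (ds_salt + R_CAL * math.log(strand_conc_M / 4.0)) - 273.15


def duplex_params(
    seq: str,
    na_mM: float = DEFAULT_NA_MM,
    strand_conc_M: float = DEFAULT_STRAND_CONC_M,
) -> ThermoProfile:
    """Nearest-neighbor ΔH, salt-corrected ΔS and oligo Tm of a duplex.

    Degenerate sequences are averaged over all concrete expansions (at most
    64); dH/dS are expansion means and tm is the mean of per-expansion Tm.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < _MIN_OLIGO_LEN:
        raise ValueError(f"too short for NN model: {len(seq)} < {_MIN_OLIGO_LEN}")
    if na_mM <= 0 or strand_conc_M <= 0:
        raise ValueError("na_mM and strand_conc_M must be positive")
    variants = [seq] if is_concrete(seq) else expand_degenerate(seq, max_expansions=64)
    dh_sum = ds_sum = tm_sum = 0.0
    for v in variants:
        dh, ds = _nn_sums(v)
        ds = _salt_ds(ds, len(v), na_mM)
        dh_sum += dh
        ds_sum += ds
        tm_sum += _oligo_tm(dh, ds, strand_conc_M)
    k = len(variants)
    return ThermoProfile(dH=dh_sum / k, dS=ds_sum / k, tm=tm_sum / k)


def primer_tm(
    primer: Primer | str,
    na_mM: float = DEFAULT_NA_MM,
    strand_conc_M: float = DEFAULT_STRAND_CONC_M,
) -> float:
    """Predicted Tm (°C) of a primer under the given convention."""
    seq = primer.sequence if isinstance(primer, Primer) else primer
    return duplex_params(seq, na_mM, strand_conc_M).tm


def melt_grid(grid: tuple[float, float, float] = DEFAULT_GRID) -> np.ndarray:
    """Temperature grid for a (start, stop, step) specification, inclusive."""
    start, stop, step = grid
    if step <= 0 or stop <= start:
        raise ValueError(f"invalid grid {grid}")
    n = int(round((stop - start) / step)) + 1
    return np.linspace(start, stop, n)


def _two_state_theta(seq: str, temps_K: np.ndarray, na_mM: float) -> tuple[np.ndarray, float]:
    dh, ds = _nn_sums(seq)
    ds = _salt_ds(ds, len(seq), na_mM)
    tm_K = dh * 1000.0 / ds  # both negative -> positive kelvin
    dh_melt = -dh * 1000.0   # cal/mol, positive
    exponent = (dh_melt / R_CAL) * (1.0 / tm_K - 1.0 / temps_K)
    # clip to keep exp() finite on wide grids
    theta = 1.0 / (1.0 + np.exp(np.clip(exponent, -500, 500)))
    return theta, tm_K - 273.15


def simulate_melt_curve(
    amplicon_seq: str,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    model: str = "two_state",
    window_len: int = 50,
    window_step: int = 10,
    na_mM: float = DEFAULT_NA_MM,
    sample_id: str = "simulated",
) -> MeltCurve:
    """Simulated HRM dissociation curve of an amplicon, as 100·θ(T).

    ``two_state`` melts the amplicon as one cooperative unit; ``windowed``
    averages per-window helicity (length-weighted) over overlapping windows
    of ``window_len`` stepped by ``window_step``, yielding compound curves
    for amplicons with domains of different stability.
    """
    seq = amplicon_seq.upper().replace("U", "T")
    if len(seq) < _MIN_AMPLICON_LEN:
        raise ValueError(f"amplicon too short for melt simulation: {len(seq)} < {_MIN_AMPLICON_LEN}")
    if not is_concrete(seq):
        raise ValueError("melt simulation needs a concrete amplicon sequence")
    temps_C = melt_grid(grid)
    temps_K = temps_C + 273.15

    if model == "two_state":
        theta, _ = _two_state_theta(seq, temps_K, na_mM)
    elif model == "windowed":
        if window_len > len(seq):
            raise ValueError("window_len exceeds amplicon length")
        if window_step <= 0:
            raise ValueError("window_step must be positive")
        starts = list(range(0, len(seq) - window_len + 1, window_step))
        if starts[-1] != len(seq) - window_len:
            starts.append(len(seq) - window_len)  # cover the 3' tail
        thetas = []
        weights = []
        for s in starts:
            sub = seq[s:s + window_len]
            th, _ = _two_state_theta(sub, temps_K, na_mM)
            thetas.append(th)
            weights.append(len(sub))
        weights = np.asarray(weights, dtype=float)
        theta = np.average(np.vstack(thetas), axis=0, weights=weights)
    else:
        raise ValueError(f"unknown melt model {model!r}")

    return MeltCurve(sample_id=sample_id, temperatures=temps_C,
                     fluorescence=100.0 * theta)


def calibrate_convention(
    primers: list[Primer],
    na_grid_mM: tuple[float, ...] = (10, 25, 50, 75, 100, 150, 200, 300, 500, 1000),
    conc_grid_M: tuple[float, ...] = (1e-8, 5e-8, 1e-7, 2.5e-7, 5e-7, 1e-6, 5e-6, 1e-5),
) -> dict:
    """Fit one global (Na⁺, strand concentration) pair to reported primer Tms.

    Coarse grid search followed by Nelder–Mead refinement in log space,
    minimizing the mean absolute error between :func:`primer_tm` and each
    primer's reported Tm.  Deterministic.  Returns a dict with the fitted
    convention, the MAE, the maximum absolute error and per-primer errors.
    """
    cal = [p for p in primers if p.reported_tm is not None]
    if not cal:
        raise ValueError("no primers with reported_tm to calibrate against")

    def mae(x):
        na, conc = math.exp(x[0]), math.exp(x[1])
        return sum(abs(primer_tm(p, na, conc) - p.reported_tm) for p in cal) / len(cal)

    best = min(
        ((math.log(na), math.log(c)) for na in na_grid_mM for c in conc_grid_M),
        key=mae,
    )
    res = minimize(mae, best, method="Nelder-Mead",
                   options=dict(xatol=1e-5, fatol=1e-6, maxiter=500))
    na_mM, conc_M = math.exp(res.x[0]), math.exp(res.x[1])
    errors = {p.name: primer_tm(p, na_mM, conc_M) - p.reported_tm for p in cal}
    return {
        "na_mM": na_mM,
        "strand_conc_M": conc_M,
        "mae": float(res.fun),
        "max_abs_error": max(abs(e) for e in errors.values()),
        "errors": errors,
        "n_primers": len(cal),
    }
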