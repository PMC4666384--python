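"""Estimate a TF's chemical potential from ChIP peak sequences and signals.

Given a motif and a set of bound sequences (e.g. 200 bp windows around
ChIP-seq peak summits) with per-peak enrichment signals, the chemical
potential mu of the Fermi-Dirac occupancy model is recovered by profiled
least squares: for each candidate mu the model

    signal_k ~ scale * occupancy(S_k; mu) + offset,   scale >= 0

has a closed-form optimal (scale, offset), leaving a one-dimensional
residual-sum-of-squares profile over mu. The profile is evaluated on a
grid (step 0.25 over [-30, 0] by default) and the minimum is refined by
bounded scalar minimisation to a 0.01 tolerance. mu is identifiable
because the shape of the occupancy-vs-energy response changes with mu:
sites near saturation flatten out, sites far below stay proportional to
exp(mu), and real peak sets contain sites across that range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .motifs import EnergyMatrix, batch_window_energies, binding_probability, encode_sequence

__all__ = ["PeakDataset", "MuFit", "estimate_mu"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakDataset:
    """Bound sequences paired with non-negative enrichment signals."""

    sequences: tuple
    signals: np.ndarray

    def __post_init__(self) -> None:
        signals = np.asarray(self.signals, dtype=float)
        if len(self.sequences) != signals.size:
            raise ValueError(
                f"{len(self.sequences)} sequences but {signals.size} signals"
            )
        if not np.isfinite(signals).all():
            raise ValueError("signals must be finite")
        object.__setattr__(self, "sequences", tuple(self.sequences))
        object.__setattr__(self, "signals", signals)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class MuFit:
    """Result of a chemical-potential fit."""

    motif_id: str
    mu_hat: float
    scale: float
    offset: float
    rss: float
    grid: np.ndarray  # (n, 2) array of evaluated (mu, rss) pairs
    n_peaks: int
    degenerate: bool = False  # flat signals: scale pinned near 0


def _occupancies(ew_rows, mu: float) -> np.ndarray:
    if isinstance(ew_rows, np.ndarray):  # equal-length peaks: one vectorised pass
        return binding_probability(ew_rows, mu).sum(axis=1)
    return np.array([binding_probability(ew, mu).sum() for ew in ew_rows])


def _fit_linear(occ: np.ndarray, signals: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (scale >= 0, offset) of signals on occupancies; returns rss too."""
    # ptp (not var) detects constant occupancies exactly: var of a constant
    # vector carries O(eps^2) dust from the mean division
    if np.ptp(occ) == 0.0 or np.ptp(signals) == 0.0:
        scale = 0.0
    else:
        scale = max(float(np.cov(occ, signals, bias=True)[0, 1] / occ.var()), 0.0)
    offset = float(signals.mean() - scale * occ.mean())
    resid = signals - scale * occ - offset
    return scale, offset, float(resid @ resid)


def estimate_mu(
    energy: EnergyMatrix,
    data: PeakDataset,
    mu_bounds: tuple = (-30.0, 0.0),
    grid_step: float = 0.25,
    refine_tol: float = 0.01,
) -> MuFit:
    """Fit the Fermi-Dirac occupancy model to peak signals and estimate mu.

    Raises ``ValueError("uninformative motif")`` when occupancies have zero
    variance across the peaks at every candidate mu (e.g. a flat motif).
    Flat signals fit with scale ~ 0; the result is flagged degenerate and a
    warning is logged.
    """
    if len(data) < 10:
        raise ValueError(f"need at least 10 peaks, got {len(data)}")
    lo, hi = float(mu_bounds[0]), float(mu_bounds[1])
    if not lo < hi:
        raise ValueError(f"invalid mu bounds {mu_bounds}")
    for i, seq in enumerate(data.sequences):
        if len(seq) <= energy.m:
            raise ValueError(
                f"peak sequence {i} (length {len(seq)}) is not longer than "
                f"motif {energy.motif_id!r} (width {energy.m})"
            )
    # window energies per peak, computed once; peaks may differ in length
    ew_rows = [
        batch_window_energies(energy, encode_sequence(seq))[0] for seq in data.sequences
    ]
    if len({len(s) for s in data.sequences}) == 1:
        ew_rows = np.array(ew_rows)
    signals = data.signals

    def rss_at(mu: float) -> tuple[float, float, float, float]:
        occ = _occupancies(ew_rows, mu)
        scale, offset, rss = _fit_linear(occ, signals)
        return rss, scale, offset, float(np.ptp(occ))

    grid_mu = np.arange(lo, hi + grid_step / 2, grid_step)
    evals = [rss_at(mu) for mu in grid_mu]
    grid = np.column_stack([grid_mu, [e[0] for e in evals]])
    if max(e[3] for e in evals) == 0.0:
        raise ValueError(f"uninformative motif {energy.motif_id!r}: occupancies have zero variance")
    best = int(np.argmin(grid[:, 1]))

    span = (max(grid_mu[best] - grid_step, lo), min(grid_mu[best] + grid_step, hi))
    res = minimize_scalar(
        lambda mu: rss_at(mu)[0], bounds=span, method="bounded",
        options={"xatol": refine_tol},
    )
    mu_hat = float(res.x)
    rss, scale, offset, _ = rss_at(mu_hat)
    if rss > grid[best, 1]:  # keep the grid point if refinement did not help
        mu_hat = float(grid_mu[best])
        rss, scale, offset, _ = rss_at(mu_hat)

    degenerate = np.ptp(signals) == 0.0 or scale == 0.0
    if degenerate:
        log.warning(
            "motif %s: flat response (scale = %.3g); mu estimate is weakly constrained",
            energy.motif_id, scale,
        )
    return MuFit(
        motif_id=energy.motif_id,
        mu_hat=mu_hat,
        scale=scale,
        offset=offset,
        rss=rss,
        grid=grid,
        n_peaks=len(data),
        degenerate=degenerate,
    )
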