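"""Odds-ratio contrasts, exposure-response curves and interaction surfaces.

Every reported quantity is a log-odds contrast c'beta between a target and
a reference exposure configuration, with the delta-method standard error
sqrt(c' V c) and a normal 95% interval. Reference conventions follow the
analysis design: 5 ug/m3 for PM2.5 and the median heat-index percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSpec, CrossbasisSpec, contrast_vector, crossbasis_row
from .condlogit import FitResult

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class ORContrast:
    """A target-vs-reference odds ratio with its uncertainty."""

    target: object
    reference: object
    log_or: float
    se: float
    method: str = "delta"
    ci95: tuple[float, float] | None = None  # set explicitly for MC intervals

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci(self) -> tuple[float, float]:
        if self.ci95 is not None:
            return self.ci95
        return (float(np.exp(self.log_or - Z95 * self.se)),
                float(np.exp(self.log_or + Z95 * self.se)))


def or_contrast(fit: FitResult, cvec: np.ndarray,
                target=None, reference=None) -> ORContrast:
    """Delta-method OR for a contrast vector: log OR = c'beta, se = sqrt(c'Vc)."""
    cvec = np.asarray(cvec, dtype=float)
    if cvec.shape != fit.beta.shape:
        raise ValueError(
            f"contrast length {cvec.shape} != coefficient length {fit.beta.shape}")
    log_or = float(cvec @ fit.beta)
    var = float(cvec @ fit.vcov @ cvec)
    return ORContrast(target=target, reference=reference, log_or=log_or,
                      se=float(np.sqrt(max(var, 0.0))))


def curve(fit: FitResult, spec: BasisSpec, grid, reference: float | None = None,
          ) -> pd.DataFrame:
    """Exposure-response curve: one OR per grid value vs the reference level.

    Grid values beyond the basis boundary are clamped and flagged.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty exposure grid")
    ref = spec.reference if reference is None else float(reference)
    lo, hi = spec.boundary
    rows = []
    for x in grid:
        c = or_contrast(fit, contrast_vector(x, ref, spec), target=x, reference=ref)
        lo_ci, hi_ci = c.ci
        rows.append({"exposure": x, "or": c.odds_ratio, "lo": lo_ci,
                     "hi": hi_ci, "clamped": bool(x < lo or x > hi)})
    return pd.DataFrame(rows)


def surface(fit: FitResult, cb_spec: CrossbasisSpec, grid1, grid2,
            reference: tuple[float, float] | None = None,
            observed_pairs: pd.DataFrame | None = None,
            sparse_min_count: int = 0) -> pd.DataFrame:
    """OR over a (heat, PM2.5) grid vs a fixed reference pair, tidy format.

    Cells supported by fewer than ``sparse_min_count`` observed exposure
    pairs (nearest-cell binning of ``observed_pairs`` columns x1, x2) are
    flagged ``sparse``: ORs there reflect spline extrapolation more than
    data.
    """
    ref = cb_spec.reference if reference is None else reference
    g1 = np.atleast_1d(np.asarray(grid1, dtype=float))
    g2 = np.atleast_1d(np.asarray(grid2, dtype=float))
    if g1.size == 0 or g2.size == 0:
        raise ValueError("empty exposure grid")
    counts = None
    if observed_pairs is not None and sparse_min_count > 0:
        i1 = np.argmin(np.abs(observed_pairs["x1"].to_numpy()[:, None] - g1), axis=1)
        i2 = np.argmin(np.abs(observed_pairs["x2"].to_numpy()[:, None] - g2), axis=1)
        counts = np.zeros((g1.size, g2.size), dtype=int)
        np.add.at(counts, (i1, i2), 1)
    rows = []
    for i, h in enumerate(g1):
        for j, p in enumerate(g2):
            c = or_contrast(fit, contrast_vector((h, p), ref, cb_spec),
                            target=(h, p), reference=ref)
            lo_ci, hi_ci = c.ci
            rows.append({"heat": h, "pm25": p, "or": c.odds_ratio,
                         "lo": lo_ci, "hi": hi_ci,
                         "sparse": bool(counts is not None
                                        and counts[i, j] < sparse_min_count)})
    return pd.DataFrame(rows)


def marginal_linear_or(fit: FitResult, change: float, at: float,
                       which: str = "first") -> ORContrast:
    """Marginal OR from the linear interaction model b1*H + b2*P + b3*H*P.

    The OR for a ``change`` in one exposure depends on the level of the
    other; it is evaluated holding the co-exposure at ``at`` (the observed
    median by convention, configurable). ``which`` selects the changed
    exposure: "first" gives contrast (dH, 0, dH*P), "second" (0, dP, dP*H).
    """
    if fit.beta.shape != (3,):
        raise ValueError("marginal_linear_or requires the 3-coefficient "
                         "linear interaction model")
    if which == "first":
        cvec = np.array([change, 0.0, change * at])
        target, reference = (change, at), (0.0, at)
    elif which == "second":
        cvec = np.array([0.0, change, change * at])
        target, reference = (at, change), (at, 0.0)
    else:
        raise ValueError("which must be 'first' or 'second'")
    c = or_contrast(fit, cvec, target=target, reference=reference)
    return c


def crossbasis_or(fit: FitResult, cb_spec: CrossbasisSpec,
                  target: tuple[float, float],
                  reference: tuple[float, float] | None = None) -> ORContrast:
    """Convenience: delta-method OR between two (heat, PM2.5) points."""
    ref = cb_spec.reference if reference is None else reference
    return or_contrast(fit, contrast_vector(target, ref, cb_spec),
                       target=target, reference=ref)
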