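"""B-spline bases, tensor-product crossbases, and contrast vectors.

A ``BasisSpec`` describes how one exposure enters a model: either linearly
(one column, the raw value) or through a cubic B-spline basis without an
intercept column (df columns, the convention of R's ``splines::bs``).  A
``CrossbasisSpec`` pairs two such specs and adds the flattened tensor
product of their columns, giving df1 + df2 + df1*df2 design columns that
encode main effects plus the exposure-exposure interaction.

Evaluation outside the boundary knots is clamped to the nearest boundary,
so contrasts never extrapolate a polynomial tail. Knot placement, when
derived from data, uses equally spaced quantiles of the pooled exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class BasisSpec:
    """One exposure's transform: kind, df, knots, boundary and reference level."""

    kind: str  # "linear" or "bspline"
    df: int = 1
    degree: int = 3
    internal_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)
    reference: float = 0.0

    def __post_init__(self):
        if self.kind not in ("linear", "bspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "linear":
            object.__setattr__(self, "df", 1)
        else:
            if self.df < self.degree:
                raise ValueError("bspline df must be >= degree")
            if len(self.internal_knots) != self.df - self.degree:
                raise ValueError(
                    f"bspline with df={self.df}, degree={self.degree} needs "
                    f"{self.df - self.degree} internal knots, got "
                    f"{len(self.internal_knots)}")
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary must satisfy min < max")
        if not (lo <= self.reference <= hi):
            raise ValueError("reference must lie within the boundary")

    @classmethod
    def from_data(cls, x, kind: str = "bspline", df: int = 4, degree: int = 3,
                  reference: float | None = None,
                  boundary_quantiles: tuple[float, float] = (0.0, 1.0),
                  ) -> "BasisSpec":
        """Data-adaptive spec: boundary at observed quantiles (min/max by
        default; heavy-tailed exposures are better served by e.g. (0, 0.99)
        since evaluation clamps beyond the boundary), internal knots at
        equally spaced quantiles inside it, reference defaulting to the
        median."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        lo, hi = (float(q) for q in np.quantile(x, boundary_quantiles))
        x = np.clip(x, lo, hi)
        ref = float(np.median(x)) if reference is None else float(reference)
        if kind == "linear":
            return cls(kind="linear", boundary=(lo, hi), reference=ref)
        n_int = df - degree
        probs = np.linspace(0, 1, n_int + 2)[1:-1]
        knots = tuple(float(k) for k in np.quantile(x, probs))
        return cls(kind="bspline", df=df, degree=degree, internal_knots=knots,
                   boundary=(lo, hi), reference=ref)


def basis_matrix(x, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis at x (scalar or 1-D) -> (n, df) design block.

    For the bspline kind this is the full degree-``degree`` B-spline basis on
    [boundary] with the first basis function dropped (no intercept; the
    stratified conditional likelihood absorbs it). x is clamped to the
    boundary before evaluation.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("basis input must be finite")
    lo, hi = spec.boundary
    xc = np.clip(x, lo, hi)
    if spec.kind == "linear":
        return xc[:, None]
    t = np.concatenate([
        np.repeat(lo, spec.degree + 1),
        np.asarray(spec.internal_knots, dtype=float),
        np.repeat(hi, spec.degree + 1),
    ])
    full = BSpline.design_matrix(xc, t, spec.degree, extrapolate=False).toarray()
    return full[:, 1:]  # drop intercept column


def bspline_row(x: float, spec: BasisSpec) -> np.ndarray:
    """Single basis row (length df) at exposure value x."""
    return basis_matrix(np.asarray([x]), spec)[0]


@dataclass(frozen=True)
class CrossbasisSpec:
    """Two exposures' bases plus their tensor interaction.

    Column order is fixed: the df1 columns of basis 1, the df2 columns of
    basis 2, then the interaction block flattened row-major as
    b1[i]*b2[j] for i in 0..df1-1, j in 0..df2-1.
    """

    spec1: BasisSpec
    spec2: BasisSpec

    @property
    def n_columns(self) -> int:
        d1, d2 = self.spec1.df, self.spec2.df
        return d1 + d2 + d1 * d2

    @property
    def reference(self) -> tuple[float, float]:
        return (self.spec1.reference, self.spec2.reference)


def crossbasis_matrix(x1, x2, spec: CrossbasisSpec) -> np.ndarray:
    """(n, df1+df2+df1*df2) design block for paired exposure values."""
    b1 = basis_matrix(x1, spec.spec1)
    b2 = basis_matrix(x2, spec.spec2)
    if b1.shape[0] != b2.shape[0]:
        raise ValueError("x1 and x2 must have equal length")
    inter = (b1[:, :, None] * b2[:, None, :]).reshape(b1.shape[0], -1)
    return np.hstack([b1, b2, inter])


def crossbasis_row(x1: float, x2: float, spec: CrossbasisSpec) -> np.ndarray:
    return crossbasis_matrix(np.asarray([x1]), np.asarray([x2]), spec)[0]


def contrast_vector(target, reference, spec) -> np.ndarray:
    """Design-row difference target - reference.

    ``spec`` may be a BasisSpec (scalar target/reference) or a CrossbasisSpec
    (pair target/reference).  The log odds ratio of the contrast is the dot
    product of this vector with the fitted coefficients.
    """
    if isinstance(spec, CrossbasisSpec):
        t = crossbasis_row(target[0], target[1], spec)
        r = crossbasis_row(reference[0], reference[1], spec)
    else:
        t = bspline_row(float(target), spec)
        r = bspline_row(float(reference), spec)
    return t - r


# -- serialization ----------------------------------------------------------

def _basis_dict(spec: BasisSpec) -> dict:
    d = asdict(spec)
    d["internal_knots"] = list(d["internal_knots"])
    d["boundary"] = list(d["boundary"])
    return d


def spec_to_dict(spec) -> dict:
    if isinstance(spec, CrossbasisSpec):
        return {"crossbasis": {"spec1": _basis_dict(spec.spec1),
                               "spec2": _basis_dict(spec.spec2)}}
    return {"basis": _basis_dict(spec)}


def spec_from_dict(d: dict):
    if "crossbasis" in d:
        c = d["crossbasis"]
        return CrossbasisSpec(spec1=_basis_from(c["spec1"]),
                              spec2=_basis_from(c["spec2"]))
    return _basis_from(d["basis"])


def _basis_from(d: dict) -> BasisSpec:
    return BasisSpec(kind=d["kind"], df=int(d["df"]), degree=int(d["degree"]),
                     internal_knots=tuple(d["internal_knots"]),
                     boundary=tuple(d["boundary"]),
                     reference=float(d["reference"]))


def spec_to_yaml(spec, path):
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def spec_from_yaml(path):
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
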