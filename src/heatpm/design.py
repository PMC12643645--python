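"""Assemble conditional-logit design matrices from long stratum tables.

A model is a list of terms; each term is either
``(column, BasisSpec)`` for an additive exposure term, or
``((column1, column2), CrossbasisSpec)`` for a tensor-product interaction
block. Columns refer to the long-format stratum table produced by
:func:`heatpm.cohort.build_strata` (one row per stratum-day).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import BasisSpec, CrossbasisSpec, basis_matrix, crossbasis_matrix
from .condlogit import StratumData

Term = tuple  # (col, BasisSpec) | ((col1, col2), CrossbasisSpec)


def design_matrix(frame: pd.DataFrame, terms: list[Term]) -> np.ndarray:
    """Stack per-term basis blocks into one (n_rows, p) design."""
    blocks = []
    for cols, spec in terms:
        if isinstance(spec, CrossbasisSpec):
            c1, c2 = cols
            blocks.append(crossbasis_matrix(frame[c1].to_numpy(),
                                            frame[c2].to_numpy(), spec))
        else:
            blocks.append(basis_matrix(frame[cols].to_numpy(), spec))
    return np.hstack(blocks)


def stratum_data(frame: pd.DataFrame, terms: list[Term]) -> StratumData:
    """Long stratum table -> :class:`StratumData` ready for fitting.

    Rows are sorted by stratum_id (then date when present) so each stratum
    forms a contiguous block.
    """
    sort_cols = ["stratum_id"] + (["date"] if "date" in frame.columns else [])
    f = frame.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    X = design_matrix(f, terms)
    return StratumData(X=X, case=f["case_flag"].to_numpy(dtype=bool),
                       stratum=f["stratum_id"].to_numpy())
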