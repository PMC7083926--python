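"""Design-matrix construction for hierarchical models.

Categorical factors are coded with sum-to-zero (deviation) contrasts so that a
single inclusion indicator can gate a whole factor or interaction block: the
block's columns jointly represent departures of factor levels from the grand
mean, and switching the block off removes the factor as a unit.

Terms are written as in model formulas: ``"1"`` is the intercept, ``"group"``
a factor or covariate, ``"group:condition"`` an interaction (column-wise
products of the component codings).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["term_matrix", "build_design", "Design"]


def _component_matrix(data: pd.DataFrame, name: str,
                      levels: dict[str, list] | None = None):
    col = data[name]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype):
        return col.to_numpy(dtype=float)[:, None], [name]
    lv = (levels or {}).get(name)
    if lv is None:
        lv = sorted(pd.unique(col.astype(str)))
    else:
        lv = [str(x) for x in lv]
    if len(lv) < 2:
        raise ValueError(f"factor {name!r} has fewer than 2 levels")
    codes = pd.Categorical(col.astype(str), categories=lv).codes
    if (codes < 0).any():
        bad = sorted(set(col.astype(str)) - set(lv))
        raise ValueError(f"factor {name!r} has unknown levels {bad}")
    k = len(lv)
    # sum-to-zero: column j is +1 for level j, -1 for the last level
    X = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
        X[codes == k - 1, j] = -1.0
    names = [f"{name}[{lv[j]}]" for j in range(k - 1)]
    return X, names


def term_matrix(data: pd.DataFrame, term: str,
                levels: dict[str, list] | None = None):
    """Design block for a single term.

    Returns ``(X, colnames)`` where ``X`` is ``n x p_term``.
    """
    term = term.strip()
    if term in ("1", "Intercept", "(Intercept)"):
        return np.ones((len(data), 1)), ["(Intercept)"]
    parts = [p.strip() for p in term.split(":")]
    X, names = _component_matrix(data, parts[0], levels)
    for p in parts[1:]:
        Xp, np_ = _component_matrix(data, p, levels)
        X = np.einsum("ni,nj->nij", X, Xp).reshape(len(data), -1)
        names = [f"{a}:{b}" for a in names for b in np_]
    return X, names


class Design:
    """Concatenated design blocks with per-term column slices."""

    def __init__(self, X: np.ndarray, colnames: list[str],
                 slices: dict[str, slice], terms: list[str]):
        self.X = X
        self.colnames = colnames
        self.slices = slices
        self.terms = terms

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def cols(self, term: str) -> slice:
        return self.slices[term]


def build_design(data: pd.DataFrame, terms: list[str],
                 levels: dict[str, list] | None = None) -> Design:
    blocks, names, slices = [], [], {}
    start = 0
    for t in terms:
        X, cn = term_matrix(data, t, levels)
        blocks.append(X)
        names.extend(cn)
        slices[t] = slice(start, start + X.shape[1])
        start += X.shape[1]
    X = np.hstack(blocks) if blocks else np.empty((len(data), 0))
    return Design(X, names, slices, list(terms))
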