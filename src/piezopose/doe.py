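"""Design-of-experiments composition screening for the nanocomposite gauge.

A single-sample block DOE sweeps nickel-nanostrand (NiNs) and
nickel-coated-carbon-fiber (NCCF) volume fractions.  Each cell is either
conductive (with a measured average gauge factor and critical strain),
not conductive (NC), or failed mechanically before reaching its critical
strain (MF).  The composition optimizer picks the conductive cell that
maximizes the gauge factor and minimizes the critical strain; a quadratic
response surface relates fitted sensor parameters to the two volume
fractions and reports coefficient p-values from ordinary least squares.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sensor import PiezoParams

__all__ = [
    "DoeCell",
    "ResponseSurface",
    "DoeError",
    "EmptySelectionError",
    "RankDeficiencyError",
    "load_doe_table",
    "packaged_doe_table",
    "select_composition",
    "fit_response_surface",
]

STATUSES = ("C", "NC", "MF")


class DoeError(ValueError):
    """Invalid DOE table input."""


class EmptySelectionError(DoeError):
    """No conductive cell available to select."""


class RankDeficiencyError(DoeError):
    """The DOE design does not support the requested surface."""


@dataclass(frozen=True)
class DoeCell:
    """One composition of the block DOE.

    ``status`` is ``"C"`` (conductive), ``"NC"`` (not conductive) or ``"MF"``
    (material failure before the critical strain).  Gauge factor and critical
    strain are present exactly when the cell is conductive.
    """

    nins_vf: float
    nccf_vf: float
    status: str
    gauge_factor: float | None = None
    critical_strain: float | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise DoeError(f"status must be one of {STATUSES}, got {self.status!r}")
        if not (self.nins_vf > 0 and self.nccf_vf > 0):
            raise DoeError("volume fractions must be positive")
        have_metrics = self.gauge_factor is not None and self.critical_strain is not None
        if (self.status == "C") != have_metrics:
            raise DoeError(
                "gauge_factor and critical_strain must be present iff status == 'C'"
            )

    @property
    def is_conductive(self) -> bool:
        return self.status == "C"


def load_doe_table(path) -> list[DoeCell]:
    """Read a DOE table CSV (``nins_vf,nccf_vf,status,gauge_factor,critical_strain``)."""
    df = pd.read_csv(path)
    required = {"nins_vf", "nccf_vf", "status", "gauge_factor", "critical_strain"}
    missing = required - set(df.columns)
    if missing:
        raise DoeError(f"DOE CSV missing columns: {sorted(missing)}")
    cells = []
    for row in df.itertuples(index=False):
        gf = None if pd.isna(row.gauge_factor) else float(row.gauge_factor)
        cs = None if pd.isna(row.critical_strain) else float(row.critical_strain)
        cells.append(DoeCell(float(row.nins_vf), float(row.nccf_vf), str(row.status), gf, cs))
    return cells


def packaged_doe_table() -> list[DoeCell]:
    """The packaged block-DOE screening table (NiNs 3-11%, NCCF 0.5-2.0%)."""
    ref = importlib.resources.files("piezopose") / "data" / "doe_block_table.csv"
    with importlib.resources.as_file(ref) as path:
        return load_doe_table(path)


def select_composition(table: Iterable[DoeCell]) -> DoeCell:
    """Pick the best conductive composition.

    Lexicographic objectives: maximum gauge factor; ties broken by minimum
    critical strain; remaining ties by lowest total filler fraction
    (easier manufacturing, lower stiffness).  Order of the input table does
    not matter.
    """
    conductive = [c for c in table if c.is_conductive]
    if not conductive:
        raise EmptySelectionError("no conductive cells in the DOE table")
    return min(
        conductive,
        key=lambda c: (-c.gauge_factor, c.critical_strain, c.nins_vf + c.nccf_vf),
    )


_SURFACE_TERMS = ("const", "nins", "nccf", "nins^2", "nccf^2", "nins*nccf")


def _design_matrix(nins: np.ndarray, nccf: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(nins), nins, nccf, nins ** 2, nccf ** 2, nins * nccf]
    )


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic surfaces mapping (nins_vf, nccf_vf) to each sensor parameter.

    ``coef[p]`` holds the six coefficients of parameter ``p`` in the term
    order ``const, nins, nccf, nins^2, nccf^2, nins*nccf``; ``pvalues[p]``
    the matching OLS coefficient p-values (NaN when the fit leaves no
    residual degrees of freedom).
    """

    coef: dict
    pvalues: dict
    terms: tuple = _SURFACE_TERMS

    def predict(self, nins_vf: float, nccf_vf: float) -> PiezoParams:
        x = _design_matrix(np.atleast_1d(float(nins_vf)),
                           np.atleast_1d(float(nccf_vf)))[0]
        vals = {p: float(x @ self.coef[p]) for p in ("a", "c", "d")}
        return PiezoParams(**vals)


def fit_response_surface(
    fits: Sequence[tuple[float, float, PiezoParams]]
) -> ResponseSurface:
    """Fit per-parameter quadratic response surfaces over the DOE design.

    ``fits`` is a sequence of ``(nins_vf, nccf_vf, PiezoParams)`` for the
    conductive compositions.  At least six design points are required (a full
    quadratic in two factors has six coefficients) and the design matrix must
    have full rank.
    """
    if len(fits) < 6:
        raise RankDeficiencyError(
            f"quadratic surface needs >= 6 design points, got {len(fits)}"
        )
    nins = np.array([f[0] for f in fits], dtype=float)
    nccf = np.array([f[1] for f in fits], dtype=float)
    X = _design_matrix(nins, nccf)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design with {len(fits)} points at rank {rank} cannot identify "
            f"all {X.shape[1]} quadratic terms; add off-axis compositions"
        )
    coef, pvalues = {}, {}
    for pname in ("a", "c", "d"):
        y = np.array([getattr(f[2], pname) for f in fits], dtype=float)
        model = sm.OLS(y, X).fit()
        coef[pname] = np.asarray(model.params, dtype=float)
        pvalues[pname] = np.asarray(model.pvalues, dtype=float)
    return ResponseSurface(coef=coef, pvalues=pvalues)
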