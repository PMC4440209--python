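"""Build correlation-thresholded weighted networks from a cohort slice.

For one effort intensity, every pair of measured variables is correlated
across participants (Pearson). Coefficient magnitudes below 0.3 are
"weak" and yield no link; [0.3, 0.7) is "moderate" and [0.7, 1] "high",
both of which become bidirectional links. A link carries the correlation
magnitude as its weight ("raw" mode: r = 0.75 means 75% influence), or
the magnitude divided by the largest magnitude over all links
("max_normalized" mode). The result is a symmetric, zero-diagonal
connection matrix C over the variable nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variables import ALL_VARIABLES

__all__ = [
    "CorrelationRecord",
    "ConnectionMatrix",
    "pearson_r",
    "classify_correlation",
    "link_weight",
    "build_network",
    "DEFAULT_THRESHOLDS",
]

#: (weak/moderate, moderate/high) magnitude cut points. Boundaries belong
#: to the stronger class.
DEFAULT_THRESHOLDS = (0.3, 0.7)

WEIGHT_MODES = ("raw", "max_normalized")


class ConstantVariableError(ValueError):
    """Pearson correlation is undefined for a zero-variance sample."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One variable pair: coefficient, sample size and strength class."""

    variable_a: str
    variable_b: str
    r: float
    n: int
    class_label: str  # weak | moderate | high


@dataclass(frozen=True)
class ConnectionMatrix:
    """Symmetric weighted adjacency matrix over named variable nodes."""

    node_names: tuple[str, ...]
    weights: np.ndarray
    weight_mode: str = "raw"
    intensity: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_names", tuple(self.node_names))
        w = np.asarray(self.weights, dtype=float)
        k = len(self.node_names)
        if w.shape != (k, k):
            raise ValueError(f"weights must be {k}x{k}, got {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("connection matrix must be symmetric")
        if not np.allclose(np.diag(w), 0.0, atol=1e-12):
            raise ValueError("connection matrix must have a zero diagonal")
        if (w < 0).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
        w = (w + w.T) / 2.0
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return len(self.node_names)

    def index(self, node: str) -> int:
        try:
            return self.node_names.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    @property
    def n_links(self) -> int:
        """Number of undirected links (positive off-diagonal pairs)."""
        return int(np.count_nonzero(np.triu(self.weights, k=1) > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_names, columns=self.node_names)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("samples must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ConstantVariableError(
                f"sample {name} is constant; correlation undefined"
            )
    return float(sps.pearsonr(x, y).statistic)


def classify_correlation(
    r: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify |r| as ``weak`` (< 0.3), ``moderate`` ([0.3, 0.7)) or ``high``.

    Boundary magnitudes are assigned to the stronger class.
    """
    moderate, high = thresholds
    if not 0 < moderate < high <= 1:
        raise ValueError("thresholds must satisfy 0 < moderate < high <= 1")
    mag = abs(r)
    if mag > 1:
        raise ValueError(f"|r| = {mag:g} exceeds 1")
    if mag < moderate:
        return "weak"
    if mag < high:
        return "moderate"
    return "high"


def link_weight(
    r: float,
    mode: str = "raw",
    max_abs_r: float | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> float:
    """Influence weight in [0, 1] carried by the link for coefficient ``r``.

    Raw mode returns |r| (a 0.75 correlation is a 75%-influence link);
    max-normalised mode returns |r| / max|r| over all links. Weak-class
    coefficients carry no link and raise.
    """
    if classify_correlation(r, thresholds) == "weak":
        raise ValueError(f"r = {r:g} is weak-class: no link exists")
    if mode == "raw":
        return abs(r)
    if mode == "max_normalized":
        if max_abs_r is None or max_abs_r <= 0:
            raise ValueError("max_normalized mode requires max_abs_r > 0")
        return abs(r) / max_abs_r
    raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")


def build_network(
    dataset: pd.DataFrame,
    mode: str = "raw",
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    variables: tuple[str, ...] | None = None,
    intensity: object = None,
) -> tuple[ConnectionMatrix, list[CorrelationRecord]]:
    """Correlate all variable pairs of one intensity slice and threshold.

    ``dataset`` holds one row per participant and one column per variable
    (defaults to the canonical 13). Constant variables are kept as
    isolated nodes with a warning; moderate/high pairs become weighted
    bidirectional links, weak pairs give zero entries.
    """
    if mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    names = tuple(variables) if variables is not None else tuple(
        v for v in ALL_VARIABLES if v in dataset.columns
    )
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    missing = [v for v in names if v not in dataset.columns]
    if missing:
        raise KeyError(f"variables not in dataset: {missing}")
    data = dataset.loc[:, list(names)].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")

    constant = [names[j] for j in range(len(names)) if np.ptp(data[:, j]) == 0]
    if constant:
        warnings.warn(
            f"constant variable(s) {constant} retained as isolated nodes",
            stacklevel=2,
        )

    k = len(names)
    records: list[CorrelationRecord] = []
    rmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if names[i] in constant or names[j] in constant:
                continue
            r = pearson_r(data[:, i], data[:, j])
            label = classify_correlation(r, thresholds)
            records.append(CorrelationRecord(names[i], names[j], r, n, label))
            if label != "weak":
                rmat[i, j] = rmat[j, i] = abs(r)

    weights = rmat.copy()
    if mode == "max_normalized":
        max_abs = rmat.max()
        if max_abs > 0:
            weights = rmat / max_abs
    matrix = ConnectionMatrix(names, weights, weight_mode=mode, intensity=intensity)
    return matrix, records


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Link/correlation list as a DataFrame (one row per variable pair)."""
    return pd.DataFrame(
        [
            {
                "variable_a": rec.variable_a,
                "variable_b": rec.variable_b,
                "r": rec.r,
                "n": rec.n,
                "class": rec.class_label,
            }
            for rec in records
        ]
    )
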