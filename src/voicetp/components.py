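"""Correlation-matrix PCA of transitional-probability distributions.

Each (aggregation unit, voice) pair is one variable; the observations are the
transition types (context -> target patterns) of one model order.  Variables
are standardized, so the decomposition is of the variable correlation matrix
and the eigenvalues sum to the number of variables.  Components with
eigenvalue > 1 are adopted (Kaiser criterion).  Loadings are reported on the
correlation scale (eigenvector scaled by the square root of its eigenvalue),
so every loading lies in [-1, 1] and a component's loading on a variable is
the correlation between the two.

A component on which every variable loads positively is read as structure
shared across the whole corpus; a component whose loadings separate by voice
(or by tonal mode) is read as melody/bass-specific (or major/minor-specific)
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .encoding import pattern_text
from .exceptions import FeatureMatrixError
from .markov import TPDistribution, information_content
from .score_io import BASS, MELODY

log = logging.getLogger(__name__)

TP = "tp"
IC = "ic"

ColumnKey = tuple[str, str]  # (unit_id, voice)


@dataclass
class FeatureMatrix:
    """Transition-type x (unit, voice) value matrix for one model order.

    ``values`` has transition-type rows (pattern text, lexicographic order)
    and a (unit_id, voice) MultiIndex on columns.  Under ``value_kind="tp"``
    the rows are the union of observed types with 0 where a column never saw
    the type — absence is informative — and each column sums to its number of
    observed contexts.  Under ``"ic"`` rows are restricted to types observed
    in every column, because unobserved transitions have no information
    content.
    """

    order: int
    value_kind: str
    values: pd.DataFrame
    modes: dict[ColumnKey, str]


def build_feature_matrix(
    dists: Mapping[ColumnKey, TPDistribution],
    value_kind: str = TP,
    modes: Mapping[ColumnKey, str] | None = None,
) -> FeatureMatrix:
    """Assemble the PCA input matrix from per-(unit, voice) TP distributions."""
    if value_kind not in (TP, IC):
        raise ValueError(f"value_kind must be '{TP}' or '{IC}', got {value_kind!r}")
    if not dists:
        raise FeatureMatrixError("no distributions supplied")
    orders = {d.order for d in dists.values()}
    if len(orders) != 1:
        raise FeatureMatrixError(f"distributions mix orders {sorted(orders)}")
    order = orders.pop()

    per_col: dict[ColumnKey, dict[str, float]] = {}
    for key, d in dists.items():
        col = {pattern_text(a, b): p for a, b, p in d.items()}
        if not col:
            raise FeatureMatrixError(f"column {key} has no observed transitions")
        per_col[key] = col

    keys = list(per_col)
    if value_kind == TP:
        row_set: set[str] = set()
        for col in per_col.values():
            row_set.update(col)
        if not row_set:
            raise FeatureMatrixError("empty union of transition types")
        rows = sorted(row_set)
        data = {key: [col.get(r, 0.0) for r in rows] for key, col in per_col.items()}
    else:
        common = set.intersection(*(set(c) for c in per_col.values()))
        if not common:
            raise FeatureMatrixError(
                "no transition type observed in every column; information-content "
                "values cannot represent absence — use value_kind='tp'")
        rows = sorted(common)
        data = {key: [information_content(col[r]) for r in rows]
                for key, col in per_col.items()}

    values = pd.DataFrame(data, index=rows,
                          columns=pd.MultiIndex.from_tuples(keys, names=["unit_id", "voice"]))
    mode_map = {k: (modes.get(k, "unknown") if modes else "unknown") for k in keys}
    return FeatureMatrix(order=order, value_kind=value_kind, values=values, modes=mode_map)


@dataclass
class PCAResult:
    """Eigenvalues, variance shares and loadings of a correlation-matrix PCA.

    ``loadings`` holds every component (columns ``PC1..PCk``) indexed by the
    (unit_id, voice) variables; each component's sign is fixed so its mean
    loading is nonnegative.  ``n_adopted`` counts eigenvalues > 1.
    """

    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame
    n_adopted: int

    @property
    def n_columns(self) -> int:
        return len(self.loadings)


def pca_correlation(m: FeatureMatrix | pd.DataFrame) -> PCAResult:
    """PCA of the column correlation matrix of a feature matrix.

    Variance percentages are ``eigenvalue / n_columns * 100`` since the trace
    of a correlation matrix equals the number of variables.
    """
    values = m.values if isinstance(m, FeatureMatrix) else m
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 2:
        raise FeatureMatrixError("PCA needs at least 2 columns")
    if X.shape[0] < 2:
        raise FeatureMatrixError("PCA needs at least 2 transition-type rows")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [values.columns[i] for i in zero]
        raise FeatureMatrixError(f"zero-variance column(s): {names}")

    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    idx = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[idx], 0.0, None)
    eigvecs = eigvecs[:, idx]

    n_cols = X.shape[1]
    loadings = eigvecs * np.sqrt(eigvals)[np.newaxis, :]
    # eigenvector sign is arbitrary; fix each component to mean-positive
    flip = loadings.mean(axis=0) < 0
    loadings[:, flip] *= -1.0

    variance_pct = eigvals / n_cols * 100.0
    return PCAResult(
        eigenvalues=eigvals,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        loadings=pd.DataFrame(
            loadings, index=values.columns,
            columns=[f"PC{k + 1}" for k in range(n_cols)]),
        n_adopted=int(np.sum(eigvals > 1.0)),
    )


def interpret_components(
    result: PCAResult,
    modes: Mapping[ColumnKey, str] | None = None,
    n_components: int | None = None,
    shared_floor: float = 0.0,
    contrast_margin: float = 0.2,
) -> list[dict[str, object]]:
    """Classify adopted components as shared vs voice-/mode-contrast structure.

    A component is ``shared`` when every loading exceeds ``shared_floor``;
    otherwise it is a ``voice-contrast`` (``mode-contrast``) when the group
    mean loadings differ in sign or by more than ``contrast_margin``, taking
    the larger of the two separations; else ``mixed``.
    """
    k = n_components if n_components is not None else max(result.n_adopted, 1)
    k = min(k, result.loadings.shape[1])
    voices = [key[1] for key in result.loadings.index]
    mode_list = [modes.get(tuple(key), "unknown") if modes else "unknown"
                 for key in result.loadings.index]

    reports: list[dict[str, object]] = []
    for c in range(k):
        load = result.loadings.iloc[:, c].to_numpy()
        by_voice = {v: float(np.mean(load[[w == v for w in voices]]))
                    for v in (MELODY, BASS) if v in voices}
        known = [m for m in mode_list if m in ("major", "minor")]
        by_mode = {m: float(np.mean(load[[w == m for w in mode_list]]))
                   for m in ("major", "minor") if m in known}

        def _gap(groups: dict[str, float]) -> tuple[float, bool]:
            if len(groups) < 2:
                return 0.0, False
            vals = list(groups.values())
            gap = abs(vals[0] - vals[1])
            sign_split = (vals[0] > 0) != (vals[1] > 0)
            return gap, (sign_split or gap > contrast_margin)

        voice_gap, voice_contrast = _gap(by_voice)
        mode_gap, mode_contrast = _gap(by_mode)
        if np.all(load > shared_floor):
            label = "shared"
        elif voice_contrast and (voice_gap >= mode_gap or not mode_contrast):
            label = "voice-contrast"
        elif mode_contrast:
            label = "mode-contrast"
        else:
            label = "mixed"
        reports.append({
            "component": f"PC{c + 1}",
            "eigenvalue": float(result.eigenvalues[c]),
            "variance_pct": float(result.variance_pct[c]),
            "mean_loading_by_voice": by_voice,
            "mean_loading_by_mode": by_mode,
            "classification": label,
        })
    return reports
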