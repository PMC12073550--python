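"""Multi-trait genotype-ideotype distance index (MGIDI).

Within a trial the index works on a genotype x trait matrix of means
(BLUP-adjusted by default).  Each trait is linearly rescaled to 0-100 so
that 100 is the desired direction; the rescaled traits are grouped by an
exploratory factor analysis of their correlation matrix (Kaiser criterion,
varimax rotation, regression scores); the ideotype is the virtual genotype
scoring 100 on every trait; and the index is the Euclidean distance between
each genotype and the ideotype in factor-score space,

    MGIDI_i = sqrt( sum_j (y_ij - y_j)^2 ),

where y_ij is genotype i's score on factor j and y_j the ideotype's score.
Genotypes with the smallest index are selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateTraitError, ParameterError

logger = logging.getLogger(__name__)

VARIMAX_TOL = 1e-5
VARIMAX_MAX_SWEEPS = 1000
RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------

def rescale_traits(
    means: pd.DataFrame, orientation: Mapping[str, bool]
) -> pd.DataFrame:
    """Rescale each trait to 0-100 in its desirable direction.

    For a higher-is-better trait the maximum maps to 100 and the minimum to
    0; a lower-is-better trait is reflected.  A constant trait cannot be
    oriented and raises :class:`DegenerateTraitError`.
    """
    if means.isna().any().any():
        raise ParameterError("trait-means matrix contains missing cells")
    out = pd.DataFrame(index=means.index, dtype=float)
    for trait in means.columns:
        x = means[trait].to_numpy(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateTraitError(
                f"trait {trait!r} is constant across genotypes"
            )
        higher_better = orientation.get(trait, True)
        if higher_better:
            out[trait] = (x - lo) / (hi - lo) * 100.0
        else:
            out[trait] = (hi - x) / (hi - lo) * 100.0
    return out


# ---------------------------------------------------------------------------
# Factor analysis
# ---------------------------------------------------------------------------

def _varimax(loadings: np.ndarray) -> np.ndarray:
    """Varimax rotation with Kaiser normalisation (orthogonal)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    h = np.sqrt((loadings ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = loadings / h[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(VARIMAX_MAX_SWEEPS):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < VARIMAX_TOL * max(var_new, 1e-12):
            break
        var_old = var_new
    return (A @ R) * h[:, None]


def _flip_signs(L: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each loading column positive."""
    out = L.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class FactorModel:
    """Eigenstructure and factor scores of a rescaled genotype x trait matrix."""

    rescaled: pd.DataFrame
    correlation: pd.DataFrame
    eigenvalues: np.ndarray          # descending, sums to n_traits
    n_retained: int
    loadings: pd.DataFrame           # traits x retained factors, varimax-rotated
    communalities: pd.Series
    scores: pd.DataFrame             # genotypes x retained factors
    ideotype_scores: np.ndarray      # the all-100 genotype's scores
    explained: np.ndarray            # variance proportion per retained factor


def factor_analysis(rescaled: pd.DataFrame) -> FactorModel:
    """Exploratory factor analysis of the trait correlation matrix.

    Factors with eigenvalue >= 1 are retained (never fewer than one);
    loadings are the eigenvectors scaled by the square roots of their
    eigenvalues, varimax-rotated.  Factor scores use the regression method,
    ``Z R^{-1} L``, and the ideotype (100 on every trait) is pushed through
    the same standardisation and scoring transform as the genotypes.
    """
    G, T = rescaled.shape
    if G < 3:
        raise ParameterError("factor analysis needs at least 3 genotypes")
    Xr = rescaled.to_numpy(float)
    mu = Xr.mean(axis=0)
    sd = Xr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = rescaled.columns[sd == 0].tolist()
        raise DegenerateTraitError(f"constant rescaled traits: {bad}")
    Z = (Xr - mu) / sd
    if T == 1:
        R = np.array([[1.0]])
    else:
        R = np.corrcoef(Xr, rowvar=False)
        R = (R + R.T) / 2.0

    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    k = max(1, int(np.sum(evals >= 1.0)))
    L = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    L = _flip_signs(_varimax(L))

    try:
        Rinv = np.linalg.inv(R)
        if np.linalg.cond(R) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular trait correlation matrix; ridge-regularising",
            RuntimeWarning, stacklevel=2,
        )
        Rinv = np.linalg.inv(R + RIDGE * np.eye(T))
    B = Rinv @ L
    scores = Z @ B
    z_ideo = (100.0 - mu) / sd
    ideo_scores = z_ideo @ B

    return FactorModel(
        rescaled=rescaled,
        correlation=pd.DataFrame(R, index=rescaled.columns,
                                 columns=rescaled.columns),
        eigenvalues=evals,
        n_retained=k,
        loadings=pd.DataFrame(
            L, index=rescaled.columns,
            columns=[f"FA{j + 1}" for j in range(k)],
        ),
        communalities=pd.Series((L ** 2).sum(axis=1), index=rescaled.columns),
        scores=pd.DataFrame(
            scores, index=rescaled.index,
            columns=[f"FA{j + 1}" for j in range(k)],
        ),
        ideotype_scores=ideo_scores,
        explained=evals[:k] / T,
    )


# ---------------------------------------------------------------------------
# Index and selection
# ---------------------------------------------------------------------------

def compute_mgidi(model: FactorModel) -> pd.Series:
    """Euclidean genotype-ideotype distance over the retained factors."""
    d = model.scores.to_numpy(float) - model.ideotype_scores[None, :]
    return pd.Series(
        np.sqrt((d ** 2).sum(axis=1)), index=model.scores.index, name="MGIDI"
    )


def n_to_select(n: int, intensity: float) -> int:
    """Selected-set size: round-half-to-even of n * intensity / 100, min 1."""
    if not (0.0 < intensity <= 100.0):
        raise ParameterError("selection intensity must be in (0, 100]")
    if n < 1:
        raise ParameterError("need at least one genotype")
    exact = Fraction(n) * Fraction(str(intensity)) / 100
    return max(1, round(exact))


@dataclass
class SelectionResult:
    """Ranking and selected set for a distance-type index (smaller = better)."""

    index: pd.Series                 # per-genotype index values
    ranking: pd.Series               # 1 = best (smallest index)
    selected: tuple[str, ...]
    intensity: float
    differentials: pd.DataFrame | None = None


def select_genotypes(index: pd.Series, intensity: float) -> SelectionResult:
    """Select the genotypes with the smallest index values.

    Ties at the selection boundary are all included and a warning notes that
    the realised intensity exceeds the nominal one.
    """
    n = len(index)
    n_sel = n_to_select(n, intensity)
    order = index.sort_values(kind="mergesort")
    ranking = pd.Series(
        np.arange(1, n + 1), index=order.index, name="rank"
    ).reindex(index.index)
    cutoff = order.iloc[n_sel - 1]
    selected = order.index[order <= cutoff].tolist()
    if len(selected) > n_sel:
        logger.warning(
            "select_genotypes: %d genotypes tied at the boundary; realised "
            "intensity %.1f%% exceeds nominal %.1f%%",
            len(selected), 100.0 * len(selected) / n, intensity,
        )
    return SelectionResult(
        index=index,
        ranking=ranking,
        selected=tuple(selected),
        intensity=intensity,
    )


def selection_differential(site_mean: float, selected_mean: float) -> float:
    """Percent change of the selected mean over the site mean (1 decimal)."""
    if site_mean <= 0:
        raise ParameterError("site mean must be positive")
    return round(100.0 * (selected_mean - site_mean) / site_mean, 1)


def differential_table(
    means: pd.DataFrame, selected: Sequence[str]
) -> pd.DataFrame:
    """Per-trait overall mean, selected mean and selection differential.

    ``means`` is a genotype x trait matrix; both means weight each genotype
    equally.
    """
    sel = [g for g in means.index if g in set(selected)]
    if not sel:
        raise ParameterError("selected set is empty or disjoint from means")
    rows = []
    for trait in means.columns:
        m_all = float(means[trait].mean())
        m_sel = float(means.loc[sel, trait].mean())
        rows.append(
            (trait, m_all, m_sel, selection_differential(m_all, m_sel))
        )
    return pd.DataFrame(
        rows,
        columns=["trait", "site_mean", "selected_mean", "differential_pct"],
    ).set_index("trait")


def run_mgidi(
    means: pd.DataFrame,
    orientation: Mapping[str, bool],
    intensity: float = 15.0,
) -> tuple[FactorModel, SelectionResult]:
    """Full within-site MGIDI pipeline on a genotype x trait means matrix."""
    rescaled = rescale_traits(means, orientation)
    model = factor_analysis(rescaled)
    index = compute_mgidi(model)
    result = select_genotypes(index, intensity)
    result.differentials = differential_table(means, result.selected)
    return model, result
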