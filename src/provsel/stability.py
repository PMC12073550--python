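"""Across-site stability indices: WAASB, WAASBY and the MTSI.

WAASB summarises a genotype's instability as the weighted average of the
absolute scores of the singular-value decomposition of the BLUP matrix of
genotype-by-environment interaction effects: with theta (g x e) = U D V',
the interaction principal-component axis (IPCA) scores are
theta_ik = U_ik d_k, each axis explains EP_k = d_k^2 / sum(d^2) of the
interaction, and

    WAASB_i = sum_k |theta_ik| EP_k / sum_k EP_k .

Lower WAASB means a more stable genotype.  WAASBY blends rescaled mean
performance (rY, 100 = best mean) with rescaled stability (rW, 100 = most
stable) using user weights.  The MTSI then applies the same
rescale / factor-analysis / ideotype-distance construction as the MGIDI to
the genotype x trait matrix of WAASBY values, with the ideotype at 100
everywhere; lower MTSI identifies genotypes that combine performance and
stability across all traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .mgidi import (
    FactorModel,
    SelectionResult,
    compute_mgidi,
    factor_analysis,
    rescale_traits,
    select_genotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class WaasbResult:
    """SVD stability summary of one trait's interaction-BLUP matrix."""

    scores: pd.DataFrame       # genotype x IPCA axis, theta_ik = U_ik d_k
    explained: np.ndarray      # EP_k per axis, non-increasing, sums to 1
    waasb: pd.Series           # per-genotype weighted absolute score
    performance: pd.Series | None = None
    r_y: pd.Series | None = None
    r_w: pd.Series | None = None
    weights: tuple[float, float] | None = None
    waasby: pd.Series | None = None


def waasb(theta: pd.DataFrame) -> WaasbResult:
    """WAASB from a genotype x environment interaction-BLUP matrix.

    All ``min(g - 1, e - 1)`` axes (at least one) enter the weighted
    average; no axis truncation is applied.
    """
    g, e = theta.shape
    if e < 2:
        raise DesignError("stability is undefined with a single environment")
    if g < 2:
        raise DesignError("need at least 2 genotypes")
    if theta.isna().any().any():
        raise ParameterError("interaction matrix has missing cells")
    M = theta.to_numpy(float)
    U, d, Vt = np.linalg.svd(M, full_matrices=False)
    p = max(1, min(g - 1, e - 1))
    d2 = d ** 2
    total = d2.sum()
    scores = U[:, :p] * d[:p]
    if total > 0:
        ep = d2[:p] / d2[:p].sum()
        w = (np.abs(scores) * ep).sum(axis=1) / ep.sum()
    else:
        ep = np.zeros(p)
        ep[0] = 1.0
        w = np.zeros(g)
    return WaasbResult(
        scores=pd.DataFrame(
            scores, index=theta.index,
            columns=[f"IPCA{k + 1}" for k in range(p)],
        ),
        explained=ep,
        waasb=pd.Series(w, index=theta.index, name="WAASB"),
    )


def _rescale_vector(x: pd.Series, higher_better: bool) -> pd.Series:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return pd.Series(100.0, index=x.index)
    if higher_better:
        return (x - lo) / (hi - lo) * 100.0
    return (hi - x) / (hi - lo) * 100.0


def waasby(
    performance: pd.Series,
    waasb_values: pd.Series,
    w_y: float = 50.0,
    w_s: float = 50.0,
) -> pd.Series:
    """Blend of rescaled mean performance and rescaled stability (0-100).

    The best-performing genotype gets rY = 100 and the most stable (lowest
    WAASB) gets rW = 100; the blend is the weighted mean with weights
    ``w_y`` (performance) and ``w_s`` (stability).  If performance or WAASB
    is constant across genotypes that component is 100 for everyone (all
    genotypes equally optimal); both constant is degenerate and an error.
    """
    if w_y < 0 or w_s < 0 or (w_y + w_s) <= 0:
        raise ParameterError("weights must be non-negative and not both zero")
    if not performance.index.equals(waasb_values.index):
        waasb_values = waasb_values.reindex(performance.index)
        if waasb_values.isna().any():
            raise ParameterError("performance and WAASB indices do not match")
    const_y = performance.max() == performance.min()
    const_w = waasb_values.max() == waasb_values.min()
    if const_y and const_w:
        raise ParameterError(
            "both performance and WAASB are constant; WAASBY is undefined"
        )
    if const_y or const_w:
        warnings.warn(
            "constant performance or WAASB; that component is 100 for all "
            "genotypes", RuntimeWarning, stacklevel=2,
        )
    r_y = _rescale_vector(performance, higher_better=True)
    r_w = _rescale_vector(waasb_values, higher_better=False)
    out = (r_y * w_y + r_w * w_s) / (w_y + w_s)
    out.name = "WAASBY"
    return out


@dataclass
class MtsiResult:
    """Factor model and index values for the multi-trait stability index."""

    waasby_matrix: pd.DataFrame      # genotype x trait WAASBY values
    factor_model: FactorModel
    mtsi: pd.Series
    selection: SelectionResult | None = None


def mtsi(waasby_matrix: pd.DataFrame) -> MtsiResult:
    """MTSI from a genotype x trait matrix of WAASBY values.

    Reuses the MGIDI pipeline verbatim: rescale to 0-100 (WAASBY is always
    higher-is-better), factor analysis, ideotype at 100 on every trait,
    Euclidean distance in factor-score space.
    """
    if waasby_matrix.shape[0] < 3:
        raise ParameterError("MTSI needs at least 3 genotypes")
    if waasby_matrix.shape[1] < 2:
        raise ParameterError("MTSI needs at least 2 traits")
    orientation = {t: True for t in waasby_matrix.columns}
    rescaled = rescale_traits(waasby_matrix, orientation)
    model = factor_analysis(rescaled)
    index = compute_mgidi(model)
    index.name = "MTSI"
    return MtsiResult(
        waasby_matrix=waasby_matrix, factor_model=model, mtsi=index
    )


def select_across_sites(result: MtsiResult, intensity: float = 20.0) -> MtsiResult:
    """Select the lowest-MTSI genotypes at the given intensity (percent)."""
    result.selection = select_genotypes(result.mtsi, intensity)
    return result
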