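"""Synthetic multi-environment provenance trials.

Generates individual-tree data for a set of common-garden experiments under
the linear mixed model used by the analysis:

    Y_ijkl = mu + S_i + P_j + B_k(i) + (SxP)_ij + (PxB)_jk(i) + e_ijkl

with the provenance effect P_j, the provenance-by-site interaction (SxP)_ij,
the provenance-by-block interaction (PxB)_jk(i) and the residual e_ijkl drawn
as independent Gaussians, and the site and block effects treated as fixed
offsets.  A provenance shared by several sites reuses the same P_j draw at
every site, which is what makes the across-site model identifiable.

The default design reproduces the structure of a three-site Douglas fir
provenance test: 61 provenances of which 55/49/48 are planted per site with 38
common to all sites, three blocks per site and 25 trees per plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError, ParseError

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["site", "provenance", "block", "tree"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Layout of a multi-site provenance trial.

    Parameters
    ----------
    site_ids : sequence of str
        Labels of the trial sites.
    provenance_sets : mapping site -> sequence of provenance labels
        Which provenances are planted at each site.
    n_blocks : int
        Number of complete blocks per site (>= 2).
    n_trees_per_plot : int
        Trees per provenance-by-block plot (>= 1).
    traits : mapping trait label -> bool
        Measured traits; the flag is True when larger values are desirable.
    """

    site_ids: tuple[str, ...]
    provenance_sets: Mapping[str, tuple[str, ...]]
    n_blocks: int
    n_trees_per_plot: int
    traits: Mapping[str, bool]

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise DesignError("n_blocks must be >= 2")
        if self.n_trees_per_plot < 1:
            raise DesignError("n_trees_per_plot must be >= 1")
        if not self.site_ids:
            raise DesignError("at least one site is required")
        for site in self.site_ids:
            provs = self.provenance_sets.get(site, ())
            if len(provs) == 0:
                raise DesignError(f"provenance set for site {site!r} is empty")
            if len(set(provs)) != len(provs):
                raise DesignError(f"duplicate provenances at site {site!r}")
        if not self.traits:
            raise DesignError("at least one trait is required")

    @property
    def common_provenances(self) -> tuple[str, ...]:
        """Provenances present at every site, in label order."""
        sets = [set(self.provenance_sets[s]) for s in self.site_ids]
        common = set.intersection(*sets)
        return tuple(sorted(common))

    @property
    def all_provenances(self) -> tuple[str, ...]:
        every: set[str] = set()
        for s in self.site_ids:
            every.update(self.provenance_sets[s])
        return tuple(sorted(every))


@dataclass(frozen=True)
class TraitParams:
    """Generative parameters for a single trait (trait units / squared units)."""

    grand_mean: float
    site_effects: Mapping[str, float] = field(default_factory=dict)
    block_effects: tuple[float, ...] | None = None  # fixed offsets per block
    block_effects_sd: float = 0.0  # random draw when block_effects is None
    v_p: float = 0.0
    v_ge: float = 0.0
    v_pb: float = 0.0
    v_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_p", "v_ge", "v_pb", "v_r"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.block_effects_sd < 0:
            raise ParameterError("block_effects_sd must be non-negative")


@dataclass(frozen=True)
class VarianceParams:
    """Per-trait generative parameters plus trial-level settings."""

    traits: Mapping[str, TraitParams]
    survival_rate: float = 1.0
    trait_correlation: np.ndarray | None = None  # applied to all random terms

    def __post_init__(self) -> None:
        if not (0.0 < self.survival_rate <= 1.0):
            raise ParameterError("survival_rate must be in (0, 1]")
        if self.trait_correlation is not None:
            c = np.asarray(self.trait_correlation, dtype=float)
            t = len(self.traits)
            if c.shape != (t, t):
                raise ParameterError(
                    f"trait_correlation must be {t}x{t}, got {c.shape}"
                )
            if not np.allclose(c, c.T):
                raise ParameterError("trait_correlation must be symmetric")


@dataclass
class TrialDataset:
    """Long-format individual-tree measurements.

    ``data`` holds one row per tree with columns ``site, provenance, block,
    tree`` followed by one column per trait.  ``truth`` optionally records the
    simulated random effects (provenance main effects and provenance-by-site
    interactions) for parameter-recovery checks.
    """

    data: pd.DataFrame
    traits: tuple[str, ...]
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"dataset is missing key columns: {missing}")
        for t in self.traits:
            if t not in self.data.columns:
                raise ParseError(f"dataset is missing trait column {t!r}")
        dup = self.data.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ParseError(
                f"duplicate (site, provenance, block, tree) key at row {row}"
            )
        vals = self.data[list(self.traits)].to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ParseError("trait values must be finite")

    def __len__(self) -> int:
        return len(self.data)

    def sites(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.data["site"]))

    def restrict_to_site(self, site: str) -> "TrialDataset":
        sub = self.data[self.data["site"] == site].reset_index(drop=True)
        return TrialDataset(sub, self.traits, truth=self.truth)

    def restrict_to_provenances(self, provenances: Sequence[str]) -> "TrialDataset":
        keep = self.data["provenance"].isin(set(provenances))
        return TrialDataset(
            self.data[keep].reset_index(drop=True), self.traits, truth=self.truth
        )

    def equals(self, other: "TrialDataset") -> bool:
        if self.traits != other.traits:
            return False
        a = self.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not a[KEY_COLUMNS].equals(b[KEY_COLUMNS]):
            return False
        return np.allclose(
            a[list(self.traits)].to_numpy(float),
            b[list(self.traits)].to_numpy(float),
            rtol=0.0, atol=1e-12, equal_nan=True,
        )


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------

DEFAULT_SITES = ("Alesd", "Faget", "Pades")
DEFAULT_TRAITS = {"DBH": True, "TH": True, "PH": True}


def default_design() -> TrialDesign:
    """Three-site design: 55/49/48 provenances per site, 38 common, 61 total.

    Provenances P01..P38 are planted everywhere.  The remaining 23 labels are
    distributed so that each appears at one or two sites, giving per-site
    totals of 55, 49 and 48.
    """
    common = [f"P{i:02d}" for i in range(1, 39)]
    extra = [f"P{i:02d}" for i in range(39, 62)]  # 23 site-specific labels
    # pairwise-shared: 8 at sites 1+2, 6 at sites 1+3, 1 at sites 2+3;
    # singletons: 3 / 2 / 3.  Totals: 38+8+6+3 = 55, 38+8+1+2 = 49,
    # 38+6+1+3 = 48.
    ab, ac, bc = extra[:8], extra[8:14], extra[14:15]
    only_a, only_b, only_c = extra[15:18], extra[18:20], extra[20:23]
    sets = {
        DEFAULT_SITES[0]: tuple(sorted(common + ab + ac + only_a)),
        DEFAULT_SITES[1]: tuple(sorted(common + ab + bc + only_b)),
        DEFAULT_SITES[2]: tuple(sorted(common + ac + bc + only_c)),
    }
    return TrialDesign(
        site_ids=DEFAULT_SITES,
        provenance_sets=sets,
        n_blocks=3,
        n_trees_per_plot=25,
        traits=dict(DEFAULT_TRAITS),
    )


def default_params() -> VarianceParams:
    """Generative parameters emulating a mature three-site Douglas fir trial.

    Grand means are across-site trait means; per-site offsets reproduce the
    observed site means.  Provenance and residual variances are site averages
    of the per-site REML components, the interaction variance comes from the
    across-site fit.  Units: cm for DBH, m for TH and PH.

    The traits carry a realistic cross-trait correlation (diameter and height
    growth are strongly correlated in mature conifers, natural pruning more
    loosely so); the factor-analytic selection indices presuppose such
    structure, and uncorrelated traits would make factor retention
    degenerate.
    """
    corr = np.array([
        [1.0, 0.7, 0.4],   # DBH
        [0.7, 1.0, 0.5],   # TH
        [0.4, 0.5, 1.0],   # PH
    ])
    return VarianceParams(
        traits={
            "DBH": TraitParams(
                grand_mean=33.03,
                site_effects={"Alesd": 3.02, "Faget": -4.21, "Pades": 1.68},
                block_effects=(-1.0, 0.0, 1.0),
                v_p=4.01, v_ge=3.91, v_pb=0.0, v_r=55.94,
            ),
            "TH": TraitParams(
                grand_mean=29.50,
                site_effects={"Alesd": 0.86, "Faget": 0.11, "Pades": -0.73},
                block_effects=(-0.5, 0.0, 0.5),
                v_p=2.32, v_ge=1.75, v_pb=0.0, v_r=19.90,
            ),
            "PH": TraitParams(
                grand_mean=17.47,
                site_effects={"Alesd": 0.01, "Faget": -0.15, "Pades": 0.21},
                block_effects=(-0.3, 0.0, 0.3),
                v_p=1.03, v_ge=0.92, v_pb=0.0, v_r=8.71,
            ),
        },
        survival_rate=1.0,
        trait_correlation=corr,
    )


def scenario_from_toml(path: str | Path):
    """Load a simulation scenario (design + parameters + seed) from TOML.

    Layout::

        seed = 1
        [design]
        sites = ["A", "B"]
        n_blocks = 3
        n_trees_per_plot = 25
        [design.provenances]      # per-site provenance lists
        A = ["P1", "P2"]
        B = ["P1", "P2"]
        [traits.DBH]              # one table per trait
        higher_is_better = true
        grand_mean = 33.0
        v_p = 4.0
        v_ge = 3.9
        v_r = 56.0
        site_effects = { A = 3.0, B = -4.2 }
        block_effects = [-1.0, 0.0, 1.0]

    Returns ``(design, params, seed)`` ready for :func:`simulate_met`.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        d = raw["design"]
        traits_raw = raw["traits"]
    except KeyError as exc:
        raise ParseError(f"{path}: missing section {exc}") from exc
    design = TrialDesign(
        site_ids=tuple(d["sites"]),
        provenance_sets={s: tuple(p) for s, p in d["provenances"].items()},
        n_blocks=int(d["n_blocks"]),
        n_trees_per_plot=int(d["n_trees_per_plot"]),
        traits={t: bool(v.get("higher_is_better", True))
                for t, v in traits_raw.items()},
    )
    params = VarianceParams(
        traits={
            t: TraitParams(
                grand_mean=float(v["grand_mean"]),
                site_effects=dict(v.get("site_effects", {})),
                block_effects=(tuple(v["block_effects"])
                               if "block_effects" in v else None),
                block_effects_sd=float(v.get("block_effects_sd", 0.0)),
                v_p=float(v.get("v_p", 0.0)),
                v_ge=float(v.get("v_ge", 0.0)),
                v_pb=float(v.get("v_pb", 0.0)),
                v_r=float(v.get("v_r", 0.0)),
            )
            for t, v in traits_raw.items()
        },
        survival_rate=float(raw.get("survival_rate", 1.0)),
    )
    return design, params, int(raw.get("seed", 0))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _correlated_normals(
    rng: np.random.Generator, n: int, n_traits: int, chol: np.ndarray | None
) -> np.ndarray:
    """n x n_traits standard normals with optional cross-trait correlation."""
    z = rng.standard_normal((n, n_traits))
    if chol is not None:
        z = z @ chol.T
    return z


def simulate_met(
    design: TrialDesign, params: VarianceParams, seed: int
) -> TrialDataset:
    """Simulate a complete multi-environment trial.

    One master ``seed`` drives deterministic per-stage substreams (provenance
    effects, interaction effects, provenance-by-block effects, residuals), so
    the output is bit-reproducible and common provenances share identical
    provenance-effect draws across sites.
    """
    trait_names = [t for t in design.traits]
    for t in trait_names:
        if t not in params.traits:
            raise ParameterError(f"no generative parameters for trait {t!r}")
    n_traits = len(trait_names)

    chol = None
    if params.trait_correlation is not None:
        chol = np.linalg.cholesky(np.asarray(params.trait_correlation, float))

    ss = np.random.SeedSequence(seed)
    rng_p, rng_ge, rng_pb, rng_b, rng_e = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    all_provs = design.all_provenances
    sites = design.site_ids
    prov_index = {p: i for i, p in enumerate(all_provs)}

    sd_p = np.array([np.sqrt(params.traits[t].v_p) for t in trait_names])
    sd_ge = np.array([np.sqrt(params.traits[t].v_ge) for t in trait_names])
    sd_pb = np.array([np.sqrt(params.traits[t].v_pb) for t in trait_names])
    sd_r = np.array([np.sqrt(params.traits[t].v_r) for t in trait_names])

    # One provenance-effect draw per provenance, shared across sites.
    p_eff = _correlated_normals(rng_p, len(all_provs), n_traits, chol) * sd_p
    ge_eff = {
        s: _correlated_normals(rng_ge, len(all_provs), n_traits, chol) * sd_ge
        for s in sites
    }

    # Fixed or random block offsets per site, per trait.
    block_offsets = np.zeros((len(sites), design.n_blocks, n_traits))
    for j, t in enumerate(trait_names):
        tp = params.traits[t]
        if tp.block_effects is not None:
            be = np.asarray(tp.block_effects, float)
            if be.shape != (design.n_blocks,):
                raise ParameterError(
                    f"block_effects for {t!r} must have length {design.n_blocks}"
                )
            block_offsets[:, :, j] = be[None, :]
        elif tp.block_effects_sd > 0:
            block_offsets[:, :, j] = rng_b.normal(
                0.0, tp.block_effects_sd, size=(len(sites), design.n_blocks)
            )

    rows: list[dict] = []
    values: list[np.ndarray] = []
    truth_ge: dict[str, pd.DataFrame] = {}
    for si, site in enumerate(sites):
        provs = design.provenance_sets[site]
        pb_eff = (
            _correlated_normals(
                rng_pb, len(provs) * design.n_blocks, n_traits, chol
            ).reshape(len(provs), design.n_blocks, n_traits)
            * sd_pb
        )
        for pi, prov in enumerate(provs):
            g = prov_index[prov]
            for b in range(design.n_blocks):
                base = (
                    np.array(
                        [
                            params.traits[t].grand_mean
                            + params.traits[t].site_effects.get(site, 0.0)
                            for t in trait_names
                        ]
                    )
                    + block_offsets[si, b]
                    + p_eff[g]
                    + ge_eff[site][g]
                    + pb_eff[pi, b]
                )
                e = _correlated_normals(
                    rng_e, design.n_trees_per_plot, n_traits, chol
                ) * sd_r
                for k in range(design.n_trees_per_plot):
                    rows.append(
                        {
                            "site": site,
                            "provenance": prov,
                            "block": f"B{b + 1}",
                            "tree": f"T{k + 1:03d}",
                        }
                    )
                    values.append(base + e[k])

    df = pd.DataFrame(rows)
    vals = np.asarray(values)
    for j, t in enumerate(trait_names):
        df[t] = vals[:, j]

    for si, site in enumerate(sites):
        truth_ge[site] = ge_eff[site]
    truth = {
        "provenance_effects": pd.DataFrame(
            p_eff, index=list(all_provs), columns=trait_names
        ),
        "interaction_effects": {
            t: pd.DataFrame(
                {s: truth_ge[s][:, j] for s in sites}, index=list(all_provs)
            )
            for j, t in enumerate(trait_names)
        },
        "params": params,
        "seed": seed,
    }
    data = TrialDataset(df, tuple(trait_names), truth=truth)
    if params.survival_rate < 1.0:
        data = apply_mortality(data, params.survival_rate, seed=seed + 1)
    return data


def apply_mortality(
    data: TrialDataset, survival_rate: float, seed: int, max_attempts: int = 100
) -> TrialDataset:
    """Thin a dataset by independent Bernoulli survival per tree.

    Plots (site x provenance x block) must not end up empty while their
    provenance remains in the dataset: the draw is repeated up to
    ``max_attempts`` times and, failing that, the offending provenance is
    dropped from that site (logged).
    """
    if not (0.0 < survival_rate <= 1.0):
        raise ParameterError("survival_rate must be in (0, 1]")
    if survival_rate == 1.0:
        return data

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    df = data.data
    for _ in range(max_attempts):
        keep = rng.random(len(df)) < survival_rate
        kept = df[keep]
        plot_counts = kept.groupby(["site", "provenance"])["block"].nunique()
        full = df.groupby(["site", "provenance"])["block"].nunique()
        ok = plot_counts.reindex(full.index, fill_value=0) == full
        if ok.all():
            return TrialDataset(
                kept.reset_index(drop=True), data.traits, truth=data.truth
            )
    bad = ok[~ok].index.tolist()
    logger.warning(
        "apply_mortality: dropping %d provenance-site pairs with emptied plots: %s",
        len(bad), bad,
    )
    mask = ~pd.MultiIndex.from_frame(kept[["site", "provenance"]]).isin(bad)
    return TrialDataset(
        kept[mask].reset_index(drop=True), data.traits, truth=data.truth
    )


# ---------------------------------------------------------------------------
# I/O: long-format delimited text
# ---------------------------------------------------------------------------

def write_dataset(data: TrialDataset, path: str | Path) -> None:
    """Write a dataset as comma-separated UTF-8 text with a header row."""
    out = data.data[KEY_COLUMNS + list(data.traits)]
    out.to_csv(path, index=False, encoding="utf-8")


def read_dataset(path: str | Path) -> TrialDataset:
    """Read a long-format CSV back into a :class:`TrialDataset`.

    The header must start with ``site, provenance, block, tree``; every later
    column is a trait.  Empty cells encode missing trait values.  Malformed
    input raises :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if list(df.columns[: len(KEY_COLUMNS)]) != KEY_COLUMNS:
        raise ParseError(
            f"{path}: header must start with {KEY_COLUMNS}, got "
            f"{list(df.columns[:len(KEY_COLUMNS)])}"
        )
    traits = [c for c in df.columns if c not in KEY_COLUMNS]
    if not traits:
        raise ParseError(f"{path}: no trait columns found")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    for t in traits:
        col = df[t].str.strip()
        blank = col == ""
        converted = pd.to_numeric(col.where(~blank, None), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[t].iloc[row]!r} for trait "
                f"{t!r} at data row {row}"
            )
        df[t] = converted
    return TrialDataset(df, tuple(traits))
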