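"""End-to-end pipeline: data in, variance/selection tables out.

Composes the full analysis: per-site REML fits with likelihood-ratio tests
for the provenance effect, the across-site fit with the interaction-BLUP
matrix, within-site MGIDI selection, and across-site WAASB/WAASBY/MTSI
selection.  Outputs are a pure function of (input data, configuration,
seed); every written table is stamped with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import mgidi as mgidi_mod
from . import mixed_models as mm
from . import stability as stab
from .exceptions import ParameterError, ProvselError
from .simulate import (
    TrialDataset,
    default_design,
    default_params,
    read_dataset,
    simulate_met,
)

logger = logging.getLogger(__name__)


class PipelineError(ProvselError):
    """A pipeline stage failed; the message carries stage and trait labels."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str | None = None
    scenario: str | None = None          # "default" simulates the built-in trial
    traits: Mapping[str, bool] | None = None  # trait -> higher-is-better
    mgidi_intensity: float = 15.0
    mtsi_intensity: float = 20.0
    waasby_weights: tuple[float, float] = (50.0, 50.0)
    analysis_set_mode: str = "common"    # "common" | "all"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ParameterError(
                "exactly one of input_path / scenario must be given"
            )
        for name in ("mgidi_intensity", "mtsi_intensity"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ParameterError(f"{name} must be in (0, 100]")
        if self.analysis_set_mode not in ("common", "all"):
            raise ParameterError("analysis_set_mode must be 'common' or 'all'")
        w_y, w_s = self.waasby_weights
        if w_y < 0 or w_s < 0 or (w_y + w_s) <= 0:
            raise ParameterError("waasby_weights must be non-negative, not both 0")

    def config_hash(self) -> str:
        payload = {
            "input_path": self.input_path,
            "scenario": self.scenario,
            "traits": dict(self.traits) if self.traits else None,
            "mgidi_intensity": self.mgidi_intensity,
            "mtsi_intensity": self.mtsi_intensity,
            "waasby_weights": list(self.waasby_weights),
            "analysis_set_mode": self.analysis_set_mode,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        traits = raw.get("traits")
        if traits is not None:
            traits = {
                t: (v if isinstance(v, bool) else str(v).lower() == "higher")
                for t, v in traits.items()
            }
        kwargs = dict(
            input_path=raw.get("input_path"),
            scenario=raw.get("scenario"),
            traits=traits,
            mgidi_intensity=float(raw.get("mgidi_intensity", 15.0)),
            mtsi_intensity=float(raw.get("mtsi_intensity", 20.0)),
            waasby_weights=tuple(raw.get("waasby_weights", (50.0, 50.0))),
            analysis_set_mode=raw.get("analysis_set_mode", "common"),
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def summarize_dataset(data: TrialDataset) -> pd.DataFrame:
    """Per-site, per-trait mean, sample SD, tree and provenance counts."""
    if len(data) == 0:
        raise ParameterError("dataset is empty")
    rows = []
    for site, grp in data.data.groupby("site", sort=True):
        n_prov = grp["provenance"].nunique()
        for trait in data.traits:
            vals = grp[trait].dropna()
            if vals.empty:
                warnings.warn(
                    f"site {site!r} has no observations for trait {trait!r}; "
                    "omitted from the summary", RuntimeWarning, stacklevel=2,
                )
                continue
            rows.append(
                (site, trait, len(vals), float(vals.mean()),
                 float(vals.std(ddof=1)), n_prov)
            )
    return pd.DataFrame(
        rows, columns=["site", "trait", "n", "mean", "sd", "n_provenances"]
    )


def _load_data(config: PipelineConfig) -> TrialDataset:
    if config.input_path is not None:
        return read_dataset(config.input_path)
    if config.scenario != "default":
        raise ParameterError(f"unknown scenario {config.scenario!r}")
    return simulate_met(default_design(), default_params(), seed=config.seed)


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    config: PipelineConfig
    summary: pd.DataFrame
    variance_components: pd.DataFrame      # per-site fits (Table-2 layout)
    gxe: pd.DataFrame                      # across-site fit (Table-3 layout)
    mgidi_ranking: pd.DataFrame
    mgidi_differentials: pd.DataFrame      # Table-4 layout
    mtsi_ranking: pd.DataFrame
    mtsi_differentials: pd.DataFrame       # Table-5 layout
    site_fits: dict = field(default_factory=dict)
    met_fits: dict = field(default_factory=dict)
    mtsi_result: stab.MtsiResult | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "summary": self.summary,
            "variance_components": self.variance_components,
            "gxe": self.gxe,
            "mgidi_ranking": self.mgidi_ranking,
            "mgidi_differentials": self.mgidi_differentials,
            "mtsi_ranking": self.mtsi_ranking,
            "mtsi_differentials": self.mtsi_differentials,
        }


def _stage(name: str, trait: str | None = None):
    label = f"stage={name}" + (f" trait={trait}" if trait else "")
    return label


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Any stage failure is re-raised as :class:`PipelineError` carrying the
    stage name and trait label.
    """
    t0 = time.perf_counter()
    try:
        data = _load_data(config)
    except ProvselError as exc:
        raise PipelineError(f"{_stage('load')}: {exc}") from exc

    traits = dict(config.traits) if config.traits else {
        t: True for t in data.traits
    }
    unknown = [t for t in traits if t not in data.traits]
    if unknown:
        raise PipelineError(
            f"{_stage('validate')}: unknown traits {unknown}; dataset has "
            f"{list(data.traits)}"
        )

    summary = summarize_dataset(data)
    sites = sorted(data.data["site"].unique())

    # --- per-site fits, LRT for provenance, fixed-effect ANOVA -------------
    site_fits: dict[tuple[str, str], mm.SiteFit] = {}
    vc_rows = []
    for site in sites:
        sub = data.restrict_to_site(site)
        for trait in traits:
            label = _stage("site_fit", f"{site}/{trait}")
            try:
                t_start = time.perf_counter()
                fit = mm.fit_site_model(sub, trait)
                red = mm.fit_site_model(sub, trait, exclude=("provenance",))
                lrt = mm.lrt_random_effect(
                    fit.loglik, red.loglik, df=1, term="provenance"
                )
                anova = mm.anova_fixed(fit)
                logger.info(
                    "%s n=%d elapsed=%.2fs", label, fit.n_obs,
                    time.perf_counter() - t_start,
                )
            except ProvselError as exc:
                raise PipelineError(f"{label}: {exc}") from exc
            site_fits[(site, trait)] = fit
            vals = sub.data[trait].dropna()
            ms_b = anova.table.loc["block"]
            vc_rows.append(
                (site, trait, lrt.statistic, lrt.stars(), fit.v_p, fit.v_pb,
                 fit.v_r, ms_b["ms"], ms_b["stars"],
                 float(vals.mean()), float(vals.std(ddof=1)))
            )
    variance_components = pd.DataFrame(
        vc_rows,
        columns=["site", "trait", "lrt_p", "lrt_p_sig", "v_p", "v_pb", "v_r",
                 "ms_block", "ms_block_sig", "mean", "sd"],
    )

    # --- across-site fits ---------------------------------------------------
    if config.analysis_set_mode == "common":
        by_site = data.data.groupby("site")["provenance"].agg(set)
        analysis_set = sorted(set.intersection(*by_site.tolist()))
    else:
        analysis_set = sorted(data.data["provenance"].unique())

    met_fits: dict[str, mm.MetFit] = {}
    gxe_rows = []
    for trait in traits:
        label = _stage("met_fit", trait)
        try:
            fit = mm.fit_met_model(data, trait, analysis_set=analysis_set)
            red_g = mm.fit_met_model(
                data, trait, analysis_set=analysis_set, exclude=("provenance",)
            )
            red_ge = mm.fit_met_model(
                data, trait, analysis_set=analysis_set,
                exclude=("provenance:site",),
            )
            lrt_g = mm.lrt_random_effect(
                fit.loglik, red_g.loglik, df=1, term="provenance"
            )
            lrt_ge = mm.lrt_random_effect(
                fit.loglik, red_ge.loglik, df=1, term="provenance:site"
            )
            props = mm.variance_proportions(fit)
            anova = mm.anova_fixed(fit)
        except ProvselError as exc:
            raise PipelineError(f"{label}: {exc}") from exc
        met_fits[trait] = fit
        sub = data.data[data.data["provenance"].isin(set(analysis_set))]
        vals = sub[trait].dropna()
        gxe_rows.append(
            (trait, lrt_g.statistic, lrt_g.stars(),
             lrt_ge.statistic, lrt_ge.stars(),
             fit.v_p, 100.0 * props["provenance"],
             fit.v_ge, 100.0 * props["provenance:site"],
             fit.v_r, 100.0 * props["residual"],
             anova.table.loc["site", "ms"], anova.table.loc["site", "stars"],
             anova.table.loc["block(site)", "ms"],
             anova.table.loc["block(site)", "stars"],
             float(vals.mean()), float(vals.std(ddof=1)))
        )
    gxe = pd.DataFrame(
        gxe_rows,
        columns=["trait", "lrt_g", "lrt_g_sig", "lrt_ge", "lrt_ge_sig",
                 "v_p", "v_p_pct", "v_ge", "v_ge_pct", "v_r", "v_r_pct",
                 "ms_env", "ms_env_sig", "ms_block_env", "ms_block_env_sig",
                 "mean", "sd"],
    )

    # --- within-site MGIDI ---------------------------------------------------
    mgidi_rank_rows = []
    mgidi_diff_rows = []
    site_mean_tables: dict[str, pd.DataFrame] = {}
    for site in sites:
        label = _stage("mgidi", site)
        means = pd.DataFrame(
            {t: site_fits[(site, t)].predicted_means for t in traits}
        )
        site_mean_tables[site] = means
        try:
            model, sel = mgidi_mod.run_mgidi(
                means, traits, intensity=config.mgidi_intensity
            )
        except ProvselError as exc:
            raise PipelineError(f"{label}: {exc}") from exc
        for prov in sel.index.index:
            mgidi_rank_rows.append(
                (site, prov, float(sel.index[prov]), int(sel.ranking[prov]),
                 prov in sel.selected)
            )
        for trait, row in sel.differentials.iterrows():
            mgidi_diff_rows.append(
                (trait, site, row["site_mean"], row["selected_mean"],
                 row["differential_pct"])
            )
    mgidi_ranking = pd.DataFrame(
        mgidi_rank_rows,
        columns=["site", "provenance", "mgidi", "rank", "selected"],
    )
    mgidi_differentials = pd.DataFrame(
        mgidi_diff_rows,
        columns=["trait", "site", "site_mean", "selected_mean",
                 "differential_pct"],
    )

    # --- across-site WAASB / WAASBY / MTSI -----------------------------------
    label = _stage("mtsi")
    try:
        waasby_cols = {}
        for trait in traits:
            fit = met_fits[trait]
            wres = stab.waasb(fit.interaction_blups)
            waasby_cols[trait] = stab.waasby(
                fit.predicted_means, wres.waasb,
                w_y=config.waasby_weights[0], w_s=config.waasby_weights[1],
            )
        waasby_matrix = pd.DataFrame(waasby_cols)
        mtsi_res = stab.mtsi(waasby_matrix)
        mtsi_res = stab.select_across_sites(
            mtsi_res, intensity=config.mtsi_intensity
        )
    except ProvselError as exc:
        raise PipelineError(f"{label}: {exc}") from exc
    sel = mtsi_res.selection
    mtsi_ranking = pd.DataFrame(
        {
            "provenance": sel.index.index,
            "mtsi": sel.index.to_numpy(float),
            "rank": sel.ranking.reindex(sel.index.index).to_numpy(int),
            "selected": [p in sel.selected for p in sel.index.index],
        }
    ).sort_values("rank").reset_index(drop=True)

    mtsi_diff_rows = []
    for site in sites:
        means = site_mean_tables[site]
        present = [p for p in sel.selected if p in means.index]
        if not present:
            warnings.warn(
                f"no MTSI-selected provenances present at site {site!r}",
                RuntimeWarning, stacklevel=2,
            )
            continue
        diffs = mgidi_mod.differential_table(means, present)
        for trait, row in diffs.iterrows():
            mtsi_diff_rows.append(
                (trait, site, row["site_mean"], row["selected_mean"],
                 row["differential_pct"])
            )
    mtsi_differentials = pd.DataFrame(
        mtsi_diff_rows,
        columns=["trait", "site", "site_mean", "selected_mean",
                 "differential_pct"],
    )

    result = PipelineResult(
        config=config,
        summary=summary,
        variance_components=variance_components,
        gxe=gxe,
        mgidi_ranking=mgidi_ranking,
        mgidi_differentials=mgidi_differentials,
        mtsi_ranking=mtsi_ranking,
        mtsi_differentials=mtsi_differentials,
        site_fits=site_fits,
        met_fits=met_fits,
        mtsi_result=mtsi_res,
    )
    if config.output_dir is not None:
        write_tables(result, config.output_dir)
    logger.info("pipeline complete elapsed=%.2fs", time.perf_counter() - t0)
    return result


def write_tables(result: PipelineResult, output_dir: str | Path) -> list[Path]:
    """Write every table as CSV stamped with the config hash and seed."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = (
        f"# provsel config_hash={result.config.config_hash()} "
        f"seed={result.config.seed}\n"
    )
    written = []
    for name, table in result.tables().items():
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(stamp)
            table.to_csv(fh, index=False, float_format="%.6g")
        written.append(path)
    return written
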