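"""End-to-end orchestration of the plankton time-series analysis.

One config drives the whole chain: simulate (or ingest) -> validate ->
normalize/convert -> hydrography -> climatology -> complete-case carbon
budget -> time-lag similarity -> co-occurrence.  Every output CSV carries
a provenance header (package version, seed, config hash), intermediates
are plain files so stages can be re-run, and a rerun with an identical
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon import (
    BUDGET_POOLS,
    ConversionConstants,
    bacterial_carbon,
    complete_case_filter,
    phytoplankton_carbon,
    seasonal_carbon_budget,
    zooplankton_carbon,
)
from .community import (
    CommunityTable,
    aggregate_groups,
    copy_number_normalize,
    exclude_taxa,
    read_community_csv,
    time_lag_similarity,
    to_relative,
)
from .cooccurrence import correlation_matrix, predator_prey_links
from .hydrography import mixed_layer_depth, nutrient_availability, read_ctd_csv
from .synthetic import Campaign, CampaignConfig, default_config, simulate_campaign
from .timeseries import (
    HELCOM_SEASONS,
    SampleSeries,
    read_series_csv,
    rolling_climatology,
    seasonal_mean,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything a full run needs, with the standard constants as defaults."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    seed: int = 0
    out_dir: str = "plankton_run"
    input_dir: str | None = None  # files mode: directory in the campaign layout
    climatology_window: int = 15
    mld_threshold: float = 0.125
    alpha: float = 0.05
    noise_factor: float = 1.0
    campaign: CampaignConfig | None = None
    constants: ConversionConstants = field(default_factory=ConversionConstants)

    def __post_init__(self) -> None:
        if self.climatology_window % 2 == 0:
            raise ValueError("climatology window must be odd")
        if self.mld_threshold <= 0:
            raise ValueError("MLD threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded, so the
        same analysis written to two directories shares one hash)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("input_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_inputs(tables: Mapping[str, CommunityTable],
                    series: Mapping[str, SampleSeries]) -> list[str]:
    """Invariant checks over all inputs; reports violations, mutates nothing."""
    violations: list[str] = []
    for name, s in series.items():
        if not s.units:
            violations.append(f"series {name}: empty units")
        if s.variable != "temperature" and (s.data.to_numpy() < 0).any():
            idx = list(np.flatnonzero(s.data.to_numpy() < 0)[:3])
            violations.append(f"series {name}: negative values at rows {idx}")
        if s.data.index.has_duplicates:
            violations.append(f"series {name}: duplicate dates (collapse first)")
    for name, t in tables.items():
        vals = t.data.to_numpy()
        if (vals < 0).any():
            rows, cols = np.nonzero(vals < 0)
            violations.append(
                f"table {name}: negative value at ({t.data.index[rows[0]]}, "
                f"{t.data.columns[cols[0]]})"
            )
    # the cyanobacteria rule: no taxon may sit in both the bacterio- and
    # phytoplankton tables once the amplicon taxonomy has been cleaned
    if "bacterioplankton" in tables and "phytoplankton" in tables:
        overlap = set(tables["bacterioplankton"].taxa) & set(tables["phytoplankton"].taxa)
        for taxon in sorted(overlap):
            violations.append(f"taxon {taxon!r} present in both bacterio- and phytoplankton tables")
    return violations


def _provenance(config: PipelineConfig) -> str:
    return f"planktonts={__version__} seed={config.seed} config={config.config_hash()}"


def _load_campaign_from_files(input_dir: Path) -> dict:
    """Read a campaign directory (the layout write_campaign produces)."""
    required = {
        "abiotic": input_dir / "abiotic",
        "communities": input_dir / "communities",
        "ctd": input_dir / "ctd",
    }
    for label, p in required.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {label} inputs: {p}")
    abiotic = {}
    for f in sorted(required["abiotic"].glob("*.csv")):
        abiotic[f.stem] = read_series_csv(f)
    casts = [read_ctd_csv(f) for f in sorted(required["ctd"].glob("ctd_*.csv"))]
    communities = {}
    for level in ("bacterioplankton", "phytoplankton", "mesozooplankton"):
        table_path = required["communities"] / f"{level}.csv"
        tax_path = required["communities"] / f"{level}_taxonomy.csv"
        if not table_path.exists():
            raise FileNotFoundError(f"missing community table: {table_path}")
        bundle = {"table": read_community_csv(table_path, tax_path)}
        biomass = required["communities"] / f"{level}_biomass.csv"
        if biomass.exists():
            bundle["total_biomass"] = read_series_csv(biomass)
        communities[level] = bundle
    counts = required["communities"] / "bacterial_abundance.csv"
    if counts.exists():
        communities["bacterioplankton"]["cell_counts"] = read_series_csv(counts)
    return {"abiotic": abiotic, "casts": casts, "communities": communities}


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in fixed order and write all outputs under out_dir.

    Returns the run report (stage summaries, output paths).  Any stage
    error removes this run's partial outputs and re-raises as
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "inputs"
        campaign: Campaign | None = None
        if config.mode == "synthetic":
            camp_cfg = config.campaign or default_config(seed=config.seed)
            camp_cfg = dataclasses.replace(camp_cfg, seed=config.seed)
            if config.noise_factor != 1.0:
                camp_cfg = camp_cfg.scale_noise(config.noise_factor)
            campaign = simulate_campaign(camp_cfg)
            from .synthetic import write_campaign
            write_campaign(campaign, out / "data", provenance=prov)
            abiotic = campaign.abiotic
            casts = campaign.casts
            communities = campaign.communities
        else:
            if not config.input_dir:
                raise FileNotFoundError("files mode requires input_dir")
            loaded = _load_campaign_from_files(Path(config.input_dir))
            abiotic = loaded["abiotic"]
            casts = loaded["casts"]
            communities = loaded["communities"]

        # ------------------------------------------------ transforms
        stage = "normalization"
        bact_raw = communities["bacterioplankton"]["table"]
        bact_clean = exclude_taxa(bact_raw, lambda t, row: row["group"] == "Cyanobacteria")
        bact_rel = copy_number_normalize(bact_clean)
        phyto_table = communities["phytoplankton"]["table"]
        # microscopy biovolumes are converted to carbon before closing so
        # relative shares are on the biomass scale
        phyto_carbon_taxa = phytoplankton_carbon(
            phyto_table.data, phyto_table.taxonomy["group"], config.constants)
        phyto_rel = to_relative(
            phyto_table.copy_with(phyto_carbon_taxa, value_kind="biomass",
                                  note="biovolume converted to carbon"))
        zoo_table = communities["mesozooplankton"]["table"]
        zoo_rel = to_relative(zoo_table)

        stage = "validation"
        violations = validate_inputs(
            {"bacterioplankton": bact_rel, "phytoplankton": phyto_rel,
             "mesozooplankton": zoo_rel},
            abiotic,
        )
        if violations:
            raise ValueError("; ".join(violations))

        bact_groups, _ = aggregate_groups(bact_rel)
        phyto_groups, _ = aggregate_groups(phyto_rel)
        zoo_groups, _ = aggregate_groups(zoo_rel)

        # ------------------------------------------------ hydrography
        stage = "hydrography"
        mld_rows = []
        for cast in casts:
            res = mixed_layer_depth(cast, threshold=config.mld_threshold)
            mld_rows.append({"date": cast.cast_date, "mld_m": res.mld,
                             "crossed": res.crossed,
                             "reference_sigma_theta": res.reference_density})
        mld_df = pd.DataFrame(mld_rows).set_index("date").sort_index()
        nut_index = pd.Series(
            nutrient_availability(
                abiotic["no3no2"].data.to_numpy(),
                abiotic["po4"].data.to_numpy(),
                abiotic["sio4"].data.to_numpy(),
            ),
            index=abiotic["no3no2"].data.index,
        )
        mld_series = SampleSeries("pipeline", "mld", "m",
                                  pd.Series(mld_df["mld_m"].to_numpy(), index=mld_df.index))
        nut_series = SampleSeries("pipeline", "nutrient_availability", "uM", nut_index)

        # ------------------------------------------------ climatology
        stage = "climatology"
        clim_dir = out / "climatology"
        clim_dir.mkdir(exist_ok=True)
        seasonal_means: dict[str, dict[str, float]] = {}
        clim_vars = dict(abiotic)
        clim_vars["nutrient_availability"] = nut_series
        clim_vars["mld"] = mld_series
        for var, s in clim_vars.items():
            clim = rolling_climatology(s, window_days=config.climatology_window)
            _write_frame(clim, clim_dir / f"{var}.csv", prov)
            seasonal_means[var] = seasonal_mean(s)

        # ------------------------------------------------ carbon budget
        stage = "carbon_budget"
        constants = config.constants
        if "cell_counts" in communities["bacterioplankton"]:
            cells = communities["bacterioplankton"]["cell_counts"].data
            bact_carbon = pd.Series(bacterial_carbon(cells.to_numpy(), constants),
                                    index=cells.index)
        else:
            bact_carbon = communities["bacterioplankton"]["total_biomass"].data
        lito_taxa = [t for t in phyto_table.taxa
                     if phyto_table.taxonomy.loc[t, "group"] == "Litostomatea"]
        lito_carbon = phyto_carbon_taxa[lito_taxa].sum(axis=1)
        phyto_carbon = phyto_carbon_taxa.drop(columns=lito_taxa).sum(axis=1)
        zoo_carbon = pd.Series(
            zooplankton_carbon(zoo_table.data.sum(axis=1).to_numpy(), constants),
            index=zoo_table.dates,
        )
        cc_dates = complete_case_filter(
            [bact_carbon.index, phyto_carbon.index, zoo_carbon.index])
        pools = pd.DataFrame({
            "bacterioplankton": bact_carbon.loc[cc_dates].to_numpy(),
            "phytoplankton": phyto_carbon.loc[cc_dates].to_numpy(),
            "litostomatea": lito_carbon.loc[cc_dates].to_numpy(),
            "mesozooplankton": zoo_carbon.loc[cc_dates].to_numpy(),
        }, index=pd.DatetimeIndex(cc_dates))
        budget = seasonal_carbon_budget(pools)
        _write_frame(budget, out / "carbon_budget.csv", prov)

        # ------------------------------------------------ lag similarity
        stage = "lag_similarity"
        lag_dir = out / "lag_similarity"
        lag_dir.mkdir(exist_ok=True)
        lag_curves = {}
        for level, table in (("bacterioplankton", bact_rel),
                             ("phytoplankton", phyto_rel),
                             ("mesozooplankton", zoo_rel)):
            curve, pairs = time_lag_similarity(table, return_pairs=True)
            lag_curves[level] = curve
            _write_frame(curve, lag_dir / f"{level}.csv", prov)
            pairs = pairs.copy()
            pairs["sample_a"] = pairs["sample_a"].dt.date
            pairs["sample_b"] = pairs["sample_b"].dt.date
            _write_frame(pairs, lag_dir / f"{level}_pairs.csv", prov)

        # ------------------------------------------------ co-occurrence
        stage = "cooccurrence"
        biotic = {
            "bacterioplankton_biomass": bact_carbon,
            "phytoplankton_biomass": phyto_carbon + lito_carbon,
            "mesozooplankton_biomass": zoo_carbon,
        }
        frame_vars = {}
        for var in ("temperature", "salinity", "chla", "doc", "cdom"):
            frame_vars[var] = abiotic[var].data
        frame_vars["nutrient_availability"] = nut_series.data
        frame_vars["mld"] = mld_series.data
        frame_vars.update(biotic)
        aligned = pd.DataFrame(frame_vars)
        corr = correlation_matrix(aligned, alpha=config.alpha)
        corr_dir = out / "correlations"
        corr_dir.mkdir(exist_ok=True)
        _write_frame(corr.rho.reset_index(names="variable"), corr_dir / "rho.csv", prov)
        _write_frame(corr.p_value.reset_index(names="variable"), corr_dir / "p_value.csv", prov)
        _write_frame(corr.n_pairs.reset_index(names="variable"), corr_dir / "n_pairs.csv", prov)

        predators = zoo_groups.data.join(phyto_groups.data[["Litostomatea"]], how="outer") \
            if "Litostomatea" in phyto_groups.data.columns else zoo_groups.data
        prey = phyto_groups.data.drop(
            columns=[c for c in ("Litostomatea",) if c in phyto_groups.data.columns]
        ).join(bact_groups.data, how="outer", lsuffix="", rsuffix="_bact")
        links = predator_prey_links(predators, prey, alpha=config.alpha)
        _write_frame(links, corr_dir / "predator_prey_links.csv", prov)

        # ------------------------------------------------ report
        stage = "report"
        report = {
            "provenance": prov,
            "n_sampling_dates": int(len(abiotic["temperature"].data)),
            "n_casts": int(len(casts)),
            "n_complete_case": int(len(cc_dates)),
            "n_climatology_variables": len(clim_vars),
            "n_budget_rows": int(len(budget)),
            "n_lag_curves": len(lag_curves),
            "n_correlation_variables": len(corr.variables),
            "n_predator_prey_links": int(len(links)),
            "seasonal_means": seasonal_means,
            "violations": violations,
        }
        with (out / "report.json").open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        report["budget"] = budget
        report["lag_curves"] = lag_curves
        report["correlations"] = corr
        report["links"] = links
        report["mld"] = mld_df
        report["pools"] = pools
        if campaign is not None:
            report["campaign"] = campaign
        return report
    except PipelineError:
        raise
    except Exception as exc:  # halt with stage name; drop partial outputs
        if created and out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(stage, str(exc)) from exc


def _write_frame(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
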