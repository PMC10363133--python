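"""Synthetic multi-year Baltic plankton campaign generator.

Emulates an offshore Baltic Proper monitoring station: irregular sampling
(twice-weekly to monthly), sinusoidal abiotic seasonality with a spring
bloom and summer stratification, seasonally modulated compositional
communities at three trophic levels (bacterio-, phyto- and large
mesozooplankton), and two-layer CTD density profiles.  Every campaign is
emitted together with its ground truth (seasonal parameters, per-cast
mixed-layer depth, analytic seasonal group shares and carbon-pool means),
so downstream estimators can be validated by parameter recovery.

The seasonal model for every scalar is one or two cosine harmonics,

    x(d) = mean + a1 cos(2 pi (d - p1)/365) + a2 cos(4 pi (d - p2)/365) + noise,

with additive Gaussian noise and truncation at zero for concentrations.
Compositions are Dirichlet draws centred on seasonally interpolated mean
shares; a very large concentration parameter makes the draw degenerate at
the mean, which the recovery tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .hydrography import CtdProfile, write_ctd_csv
from .timeseries import SampleSeries, assign_season, julian_day, write_series_csv
from .community import CommunityTable, write_community_csv

__all__ = [
    "SeasonalParam",
    "LevelConfig",
    "ProfileParams",
    "CampaignConfig",
    "Campaign",
    "default_config",
    "generate_sampling_dates",
    "simulate_abiotic",
    "simulate_ctd_profiles",
    "simulate_communities",
    "simulate_campaign",
    "write_campaign",
]

YEAR_DAYS = 365.0


@dataclass(frozen=True)
class SeasonalParam:
    """One- or two-harmonic seasonal cycle of a scalar variable.

    ``mean`` carries the variable's units; ``amplitude`` and ``peak_day``
    set the annual harmonic, ``amplitude2``/``peak_day2`` an optional
    semi-annual harmonic (used for variables with a single summer pulse on
    an otherwise flat background, like DOC).  ``noise_sd`` is the SD of
    additive Gaussian noise.
    """

    mean: float
    amplitude: float = 0.0
    peak_day: int = 1
    noise_sd: float = 0.0
    amplitude2: float = 0.0
    peak_day2: int = 1

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.amplitude2 < 0:
            raise ValueError("amplitude must be >= 0")
        if not (1 <= self.peak_day <= 365 and 1 <= self.peak_day2 <= 365):
            raise ValueError("peak_day must lie in 1..365")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def value(self, day):
        """Noise-free seasonal value at julian day(s) ``day``."""
        d = np.asarray(day, dtype=float)
        out = (self.mean
               + self.amplitude * np.cos(2 * np.pi * (d - self.peak_day) / YEAR_DAYS)
               + self.amplitude2 * np.cos(4 * np.pi * (d - self.peak_day2) / YEAR_DAYS))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProfileParams:
    """Seasonal two-layer CTD structure.

    The thermo-/halocline depth follows a SeasonalParam (shallow in
    summer, deep in winter).  The upper layer takes the campaign's surface
    temperature and salinity; the lower layer is cold bottom water with a
    fixed salinity excess so a density jump exists year-round.
    """

    thermocline_depth: SeasonalParam = field(
        default_factory=lambda: SeasonalParam(mean=16.5, amplitude=6.5, peak_day=15, noise_sd=1.5)
    )
    deep_temperature: float = 4.0
    deep_salinity_offset: float = 0.5
    grid_step_m: float = 0.5
    max_depth_m: float = 40.0
    level_noise_sd_t: float = 0.02
    level_noise_sd_s: float = 0.005


@dataclass(frozen=True)
class LevelConfig:
    """One trophic level: total biomass cycle plus per-group share cycles.

    ``group_shares`` are unnormalized seasonal weights on the share scale
    (renormalized to sum to one at every date).  ``genera`` maps each
    group to its member genera and their fixed within-group split.
    ``concentration`` is the Dirichlet precision; None means degenerate
    (no compositional noise).  ``monthly`` restricts sampling of this
    level to the first campaign date of each calendar month (the
    mesozooplankton net-haul cadence).
    """

    total_biomass: SeasonalParam
    group_shares: dict[str, SeasonalParam]
    genera: dict[str, dict[str, float]]
    value_kind: str
    concentration: float | None = 200.0
    monthly: bool = False
    #: lower clamp on total biomass (mg C m-3); keeps every sample's
    #: composition defined when noise would push the total to zero
    biomass_floor: float = 0.5

    def __post_init__(self) -> None:
        for g, p in self.group_shares.items():
            if p.mean < 0:
                raise ValueError(f"group {g}: mean share must be >= 0")
        for g, split in self.genera.items():
            if g not in self.group_shares:
                raise ValueError(f"genera given for unknown group {g}")
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValueError(f"genus split for group {g} must sum to 1")


@dataclass(frozen=True)
class CampaignConfig:
    """Full specification of a synthetic campaign."""

    start_date: str = "2011-03-01"
    end_date: str = "2018-11-30"
    cadence_days_by_season: Mapping[str, float] = field(
        default_factory=lambda: {"winter": 14.0, "spring": 7.0, "summer": 7.0, "autumn": 10.0}
    )
    seed: int = 0
    abiotic_params: Mapping[str, SeasonalParam] = field(default_factory=dict)
    community_params: Mapping[str, LevelConfig] = field(default_factory=dict)
    profile_params: ProfileParams = field(default_factory=ProfileParams)
    station_id: str = "synthetic-baltic-station"

    def __post_init__(self) -> None:
        if pd.Timestamp(self.start_date) >= pd.Timestamp(self.end_date):
            raise ValueError("start_date must precede end_date (degenerate campaign)")
        for season, c in self.cadence_days_by_season.items():
            if c < 1:
                raise ValueError(f"cadence for {season} must be >= 1 day")

    def scale_noise(self, factor: float) -> "CampaignConfig":
        """Campaign with all noise SDs scaled and Dirichlet noise removed
        when ``factor`` is 0 (the noise-reduced recovery regime)."""
        abi = {k: replace(p, noise_sd=p.noise_sd * factor) for k, p in self.abiotic_params.items()}
        comm = {}
        for lvl, cfg in self.community_params.items():
            conc = None if factor == 0 else (
                None if cfg.concentration is None else cfg.concentration / max(factor, 1e-12))
            comm[lvl] = replace(
                cfg,
                total_biomass=replace(cfg.total_biomass, noise_sd=cfg.total_biomass.noise_sd * factor),
                concentration=conc,
            )
        prof = replace(
            self.profile_params,
            thermocline_depth=replace(self.profile_params.thermocline_depth,
                                      noise_sd=self.profile_params.thermocline_depth.noise_sd * factor),
            level_noise_sd_t=self.profile_params.level_noise_sd_t * factor,
            level_noise_sd_s=self.profile_params.level_noise_sd_s * factor,
        )
        return replace(self, abiotic_params=abi, community_params=comm, profile_params=prof)


# ---------------------------------------------------------------------------
# Default study conditions: a Baltic Proper surface station, 2011-2018.
# Values are chosen so the noise-free seasonal curves land on the station's
# observed winter/summer levels (temperature 4 -> 18 degC, nitrate 2.5 -> 0.2
# uM, phosphate 0.8 -> 0.1, silicate 16 -> 8, Chl a spring peak ~ 4.5 with a
# winter floor near 0.3, DOC ~ 360 with a mid-summer pulse to 410, cDOM 0.25
# -> 0.33), and the community percentages approximate the observed seasonal
# relative biomass of the dominant groups.
# ---------------------------------------------------------------------------

DEFAULT_ABIOTIC: dict[str, SeasonalParam] = {
    "temperature": SeasonalParam(mean=11.0, amplitude=7.0, peak_day=205, noise_sd=0.8),
    "salinity": SeasonalParam(mean=7.2, amplitude=0.25, peak_day=60, noise_sd=0.05),
    "no3no2": SeasonalParam(mean=1.35, amplitude=1.15, peak_day=20, noise_sd=0.25),
    "nh4": SeasonalParam(mean=0.8, amplitude=0.0, peak_day=1, noise_sd=0.2),
    "po4": SeasonalParam(mean=0.45, amplitude=0.35, peak_day=20, noise_sd=0.08),
    "sio4": SeasonalParam(mean=12.0, amplitude=4.0, peak_day=15, noise_sd=1.0),
    "chla": SeasonalParam(mean=2.4, amplitude=1.7, peak_day=165, noise_sd=0.5,
                          amplitude2=1.2, peak_day2=105),
    "doc": SeasonalParam(mean=375.0, amplitude=17.5, peak_day=205, noise_sd=8.0,
                         amplitude2=17.5, peak_day2=205),
    "cdom": SeasonalParam(mean=0.29, amplitude=0.04, peak_day=190, noise_sd=0.015),
}

#: variables truncated at zero (concentrations and optical absorption)
NON_NEGATIVE_VARS = ("no3no2", "nh4", "po4", "sio4", "chla", "doc", "cdom")

ABIOTIC_UNITS: dict[str, str] = {
    "temperature": "degC",
    "salinity": "psu",
    "no3no2": "uM",
    "nh4": "uM",
    "po4": "uM",
    "sio4": "uM",
    "chla": "ug/L",
    "doc": "uM",
    "cdom": "1/m",
}


def _default_bacterio() -> LevelConfig:
    return LevelConfig(
        total_biomass=SeasonalParam(mean=55.0, amplitude=35.0, peak_day=215, noise_sd=6.0),
        group_shares={
            "Proteobacteria": SeasonalParam(mean=0.33, amplitude=0.03, peak_day=150),
            "Actinobacteria": SeasonalParam(mean=0.20, amplitude=0.06, peak_day=290),
            "Bacteroidetes": SeasonalParam(mean=0.18, amplitude=0.06, peak_day=120),
            "Verrucomicrobia": SeasonalParam(mean=0.08, amplitude=0.06, peak_day=205),
            "Planctomycetes": SeasonalParam(mean=0.07, amplitude=0.03, peak_day=250),
            "Cyanobacteria": SeasonalParam(mean=0.10, amplitude=0.08, peak_day=210),
            "Minor phyla": SeasonalParam(mean=0.04, amplitude=0.01, peak_day=30),
        },
        genera={
            "Proteobacteria": {"Pelagibacter": 0.6, "Rheinheimera": 0.4},
            "Actinobacteria": {"Nanopelagicus": 0.65, "Ilumatobacter": 0.35},
            "Bacteroidetes": {"Flavobacterium": 0.6, "Polaribacter": 0.4},
            "Verrucomicrobia": {"Luteolibacter": 1.0},
            "Planctomycetes": {"Planctomyces": 1.0},
            "Cyanobacteria": {"Synechococcus": 0.7, "Aphanizomenon": 0.3},
            "Minor phyla": {"Nitrospina": 1.0},
        },
        value_kind="counts",
        concentration=200.0,
    )


def _default_phyto() -> LevelConfig:
    return LevelConfig(
        total_biomass=SeasonalParam(mean=115.0, amplitude=90.0, peak_day=145, noise_sd=12.0,
                                    amplitude2=50.0, peak_day2=105),
        group_shares={
            # spring-dominant dinoflagellate bloom, summer cyanobacteria,
            # a persistent mixotrophic ciliate (Litostomatea) background
            "Dinophyceae": SeasonalParam(mean=0.22, amplitude=0.20, peak_day=105),
            "Litostomatea": SeasonalParam(mean=0.38, amplitude=0.10, peak_day=300),
            "Bacillariophyceae": SeasonalParam(mean=0.10, amplitude=0.05, peak_day=290),
            "Flagellates": SeasonalParam(mean=0.15, amplitude=0.05, peak_day=200),
            "Cyanophyceae": SeasonalParam(mean=0.15, amplitude=0.14, peak_day=205),
            "Cryptophyceae": SeasonalParam(mean=0.03, amplitude=0.01, peak_day=150),
            "Other phytoplankton": SeasonalParam(mean=0.03, amplitude=0.01, peak_day=250),
        },
        genera={
            "Dinophyceae": {"Peridiniella": 0.6, "Gymnodinium": 0.4},
            "Litostomatea": {"Mesodinium": 1.0},
            "Bacillariophyceae": {"Skeletonema": 0.55, "Chaetoceros": 0.45},
            "Flagellates": {"Chrysochromulina": 0.6, "Pyramimonas": 0.4},
            "Cyanophyceae": {"Aphanizomenon": 0.6, "Nodularia": 0.4},
            "Cryptophyceae": {"Teleaulax": 1.0},
            "Other phytoplankton": {"Ebria": 1.0},
        },
        value_kind="biovolume",
        concentration=200.0,
    )


def _default_zoo() -> LevelConfig:
    return LevelConfig(
        total_biomass=SeasonalParam(mean=5.5, amplitude=4.5, peak_day=170, noise_sd=0.6),
        group_shares={
            "Copepoda": SeasonalParam(mean=0.66, amplitude=0.08, peak_day=20),
            "Cladocera": SeasonalParam(mean=0.22, amplitude=0.19, peak_day=200),
            "Appendicularia": SeasonalParam(mean=0.15, amplitude=0.10, peak_day=20),
            "Rotifera": SeasonalParam(mean=0.05, amplitude=0.04, peak_day=190),
            "Other zooplankton": SeasonalParam(mean=0.05, amplitude=0.02, peak_day=30),
        },
        genera={
            "Copepoda": {"Acartia": 0.6, "Temora": 0.4},
            "Cladocera": {"Bosmina": 0.7, "Evadne": 0.3},
            "Appendicularia": {"Fritillaria": 1.0},
            "Rotifera": {"Synchaeta": 1.0},
            "Other zooplankton": {"Bivalvia_larvae": 1.0},
        },
        value_kind="wet_weight",
        concentration=200.0,
        monthly=True,
    )


#: 16S copies per genome per bacterial genus (plausible reference values)
GENOME_COPY_NUMBERS: dict[str, float] = {
    "Pelagibacter": 1, "Rheinheimera": 6, "Nanopelagicus": 1, "Ilumatobacter": 2,
    "Flavobacterium": 4, "Polaribacter": 2, "Luteolibacter": 2, "Planctomyces": 1,
    "Synechococcus": 2, "Aphanizomenon": 3, "Nitrospina": 1,
}

#: conversion of bacterial carbon (mg C m-3) to cell counts (cells mL-1)
#: at 20 fg C per cell: cells mL-1 = mg C m-3 / (20 fg * 1e-6)
_CELLS_PER_MGC = 1.0 / (20.0 * 1e-6)

#: nominal amplicon library size per sample
READ_DEPTH = 100_000

ZOO_CARBON_FRACTION = 0.05


def default_config(seed: int = 0, **overrides) -> CampaignConfig:
    """The default 8-year study conditions with a given seed."""
    return CampaignConfig(
        seed=seed,
        abiotic_params=dict(DEFAULT_ABIOTIC),
        community_params={
            "bacterioplankton": _default_bacterio(),
            "phytoplankton": _default_phyto(),
            "mesozooplankton": _default_zoo(),
        },
        **overrides,
    )


def _rngs(config: CampaignConfig) -> dict[str, np.random.Generator]:
    """Independent, reproducible substreams per simulation stage."""
    names = ("dates", "abiotic", "profiles", "communities")
    seqs = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def generate_sampling_dates(config: CampaignConfig,
                            rng: np.random.Generator | None = None) -> pd.DatetimeIndex:
    """Irregular sampling dates with season-dependent mean cadence.

    Inter-arrival times are exponential with the current season's mean
    cadence, rounded to whole days and clipped to >= 1, which mimics an
    opportunistic field schedule without calendar bookkeeping.
    """
    rng = rng or _rngs(config)["dates"]
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    dates = []
    t = start
    while t <= end:
        dates.append(t)
        season = assign_season(t)
        gap = max(1, int(round(rng.exponential(config.cadence_days_by_season[season]))))
        t = t + pd.Timedelta(days=gap)
    return pd.DatetimeIndex(dates)


def simulate_abiotic(dates, config: CampaignConfig,
                     rng: np.random.Generator | None = None) -> dict[str, SampleSeries]:
    """Seasonal-cosine scalar series with Gaussian noise at the given dates."""
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("dates must be nonempty")
    rng = rng or _rngs(config)["abiotic"]
    days = np.array([julian_day(d) for d in dates], dtype=float)
    out = {}
    for var in sorted(config.abiotic_params):
        p = config.abiotic_params[var]
        vals = p.value(days)
        if p.noise_sd > 0:
            vals = vals + rng.normal(0.0, p.noise_sd, size=len(days))
        else:
            vals = np.array(vals, dtype=float)
        if var in NON_NEGATIVE_VARS:
            vals = np.maximum(vals, 0.0)
        out[var] = SampleSeries(
            station_id=config.station_id,
            variable=var,
            units=ABIOTIC_UNITS.get(var, "unknown"),
            data=pd.Series(vals, index=dates),
        )
    return out


def simulate_ctd_profiles(dates, config: CampaignConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[CtdProfile], pd.Series]:
    """Two-layer CTD casts with a seasonally varying pycnocline.

    The upper layer carries the seasonal surface temperature/salinity; the
    lower layer is cold and slightly saltier, so the surface-referenced
    density jump always exceeds the standard 0.125 kg m-3 threshold at the
    (stored) true cline depth.  Returns the casts and the per-date ground
    truth mixed-layer depth.
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("dates must be nonempty")
    rng = rng or _rngs(config)["profiles"]
    pp = config.profile_params
    grid = np.arange(0.0, pp.max_depth_m + pp.grid_step_m / 2, pp.grid_step_m)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("depth grid must be strictly increasing")
    t_param = config.abiotic_params.get("temperature", DEFAULT_ABIOTIC["temperature"])
    s_param = config.abiotic_params.get("salinity", DEFAULT_ABIOTIC["salinity"])
    casts = []
    truths = []
    for d in dates:
        jd = julian_day(d)
        h = pp.thermocline_depth.value(jd)
        if pp.thermocline_depth.noise_sd > 0:
            h += rng.normal(0.0, pp.thermocline_depth.noise_sd)
        h = float(np.clip(h, 2.0, pp.max_depth_m - 2.0))
        t_surf = t_param.value(jd)
        s_surf = s_param.value(jd)
        upper = grid < h
        temp = np.where(upper, t_surf, pp.deep_temperature)
        sal = np.where(upper, s_surf, s_surf + pp.deep_salinity_offset)
        if pp.level_noise_sd_t > 0:
            temp = temp + rng.normal(0.0, pp.level_noise_sd_t, size=grid.size)
        if pp.level_noise_sd_s > 0:
            sal = sal + rng.normal(0.0, pp.level_noise_sd_s, size=grid.size)
        casts.append(CtdProfile(
            cast_date=d,
            depth_m=grid.copy(),
            pressure_dbar=grid.copy(),  # ~1 dbar per metre at these depths
            temperature_c=np.clip(temp, -1.9, 34.9),
            salinity_psu=np.clip(sal, 0.0, 41.9),
            station_depth_m=pp.max_depth_m,
        ))
        truths.append(h)
    return casts, pd.Series(truths, index=dates, name="true_mld_m")


def _group_share_matrix(cfg: LevelConfig, days: np.ndarray) -> pd.DataFrame:
    """Normalized seasonal mean group shares, one row per day."""
    groups = sorted(cfg.group_shares)
    raw = np.column_stack([np.maximum(cfg.group_shares[g].value(days), 0.0) for g in groups])
    totals = raw.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("all group weights vanish on some date")
    return pd.DataFrame(raw / totals, columns=groups)


def _genus_shares(cfg: LevelConfig, group_shares: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for g in group_shares.columns:
        for genus, frac in cfg.genera[g].items():
            cols[genus] = group_shares[g].to_numpy() * frac
    return pd.DataFrame(cols)


def _taxonomy(cfg: LevelConfig, level: str, carbon_factors: Mapping[str, float]) -> pd.DataFrame:
    rows = []
    for g, split in cfg.genera.items():
        for genus in split:
            rows.append({
                "taxon": genus,
                "group": g,
                "trophic_level": level,
                "genome_copy_number": GENOME_COPY_NUMBERS.get(genus, np.nan),
                "carbon_factor": carbon_factors.get(g, np.nan),
            })
    return pd.DataFrame(rows).set_index("taxon")


def simulate_communities(dates, config: CampaignConfig,
                         rng: np.random.Generator | None = None,
                         carbon_factors: Mapping[str, float] | None = None,
                         ) -> dict[str, dict]:
    """Three trophic-level community tables plus total-biomass series.

    Per level the return bundle holds the genus-level ``table`` (counts,
    biovolume or wet weight, matching the field measurement), the
    ``total_biomass`` carbon series (mg C m-3), the bacterioplankton
    ``cell_counts`` series (cells mL-1) where applicable, and the ground
    truth per-date genus/group shares.
    """
    from .carbon import DEFAULT_PHYTO_CARBON_FACTORS
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("dates must be nonempty")
    rng = rng or _rngs(config)["communities"]
    carbon_factors = dict(carbon_factors or DEFAULT_PHYTO_CARBON_FACTORS)
    out: dict[str, dict] = {}
    for level in sorted(config.community_params):
        cfg = config.community_params[level]
        if cfg.monthly:
            lvl_dates = pd.DatetimeIndex(
                pd.Series(dates, index=dates).groupby([dates.year, dates.month]).first()
            ).sort_values()
        else:
            lvl_dates = dates
        days = np.array([julian_day(d) for d in lvl_dates], dtype=float)

        group_true = _group_share_matrix(cfg, days)
        genus_true = _genus_shares(cfg, group_true)
        genus_cols = list(genus_true.columns)
        if cfg.concentration is None or not np.isfinite(cfg.concentration):
            genus_real = genus_true.to_numpy()
        else:
            alpha = np.maximum(genus_true.to_numpy() * cfg.concentration, 1e-9)
            genus_real = np.vstack([rng.dirichlet(a) for a in alpha])

        total = cfg.total_biomass.value(days)
        if cfg.total_biomass.noise_sd > 0:
            total = total + rng.normal(0.0, cfg.total_biomass.noise_sd, size=len(days))
        total = np.maximum(np.asarray(total, dtype=float), cfg.biomass_floor)

        carbon_per_genus = genus_real * total[:, None]  # mg C m-3
        tax = _taxonomy(cfg, level, carbon_factors)

        if cfg.value_kind == "counts":
            copies = tax["genome_copy_number"].reindex(genus_cols).fillna(2.0).to_numpy()
            biased = genus_real * copies[None, :]
            biased /= biased.sum(axis=1, keepdims=True)
            values = np.rint(biased * READ_DEPTH)
        elif cfg.value_kind == "biovolume":
            fac = np.array([carbon_factors[tax.loc[g, "group"]] for g in genus_cols])
            values = carbon_per_genus / (fac[None, :] * 1e-3)
        elif cfg.value_kind == "wet_weight":
            values = carbon_per_genus / ZOO_CARBON_FRACTION
        else:
            raise ValueError(f"unknown value kind {cfg.value_kind!r}")

        table = CommunityTable(
            data=pd.DataFrame(values, index=lvl_dates, columns=genus_cols),
            taxonomy=tax,
            value_kind=cfg.value_kind,
            trophic_level=level,
        )
        bundle: dict = {
            "table": table,
            "total_biomass": SampleSeries(
                station_id=config.station_id,
                variable=f"{level}_biomass",
                units="mg C/m3",
                data=pd.Series(total, index=lvl_dates),
            ),
            "true_group_shares": group_true.set_index(lvl_dates),
            "true_genus_shares": genus_true.set_index(lvl_dates),
        }
        if cfg.value_kind == "counts":
            bundle["cell_counts"] = SampleSeries(
                station_id=config.station_id,
                variable="bacterial_abundance",
                units="cells/mL",
                data=pd.Series(total * _CELLS_PER_MGC, index=lvl_dates),
            )
        out[level] = bundle
    return out


@dataclass
class Campaign:
    """A generated campaign with its ground truth."""

    config: CampaignConfig
    dates: pd.DatetimeIndex
    abiotic: dict[str, SampleSeries]
    casts: list[CtdProfile]
    true_mld: pd.Series
    communities: dict[str, dict]

    @staticmethod
    def _days_and_seasons(dates) -> tuple[np.ndarray, np.ndarray]:
        """Julian days and seasons, either uniform over the year (``dates``
        None) or at the given sampling dates (the truth of the realized
        sampling design, which matters when the seasonal curve varies
        strongly within a season)."""
        if dates is None:
            days = np.arange(1, 366, dtype=float)
            seasons = np.array([
                assign_season(pd.Timestamp(2015, 1, 1) + pd.Timedelta(days=int(d) - 1))
                for d in days
            ])
        else:
            days = np.array([julian_day(d) for d in dates], dtype=float)
            seasons = np.array([assign_season(d) for d in dates])
        return days, seasons

    def true_seasonal_group_shares(self, level: str, dates=None) -> pd.DataFrame:
        """Season-mean normalized group shares of the noise-free generator."""
        cfg = self.config.community_params[level]
        days, seasons = self._days_and_seasons(dates)
        shares = _group_share_matrix(cfg, days)
        return shares.groupby(seasons).mean()

    def true_seasonal_pool_means(self, dates=None) -> pd.DataFrame:
        """Season-mean carbon (mg C m-3) of the four noise-free budget pools."""
        days, seasons = self._days_and_seasons(dates)
        bact_cfg = self.config.community_params["bacterioplankton"]
        zoo_cfg = self.config.community_params["mesozooplankton"]
        phy_cfg = self.config.community_params["phytoplankton"]
        bact = np.maximum(bact_cfg.total_biomass.value(days), bact_cfg.biomass_floor)
        zoo = np.maximum(zoo_cfg.total_biomass.value(days), zoo_cfg.biomass_floor)
        phy_total = np.maximum(phy_cfg.total_biomass.value(days), phy_cfg.biomass_floor)
        shares = _group_share_matrix(phy_cfg, days)
        lito_share = shares["Litostomatea"].to_numpy() if "Litostomatea" in shares else 0.0
        pools = pd.DataFrame({
            "bacterioplankton": bact,
            "phytoplankton": phy_total * (1.0 - lito_share),
            "litostomatea": phy_total * lito_share,
            "mesozooplankton": zoo,
        })
        return pools.groupby(seasons).mean()


def simulate_campaign(config: CampaignConfig | None = None, seed: int | None = None) -> Campaign:
    """Generate a full campaign (dates, abiotic, casts, communities)."""
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    elif seed is not None:
        config = replace(config, seed=seed)
    rngs = _rngs(config)
    dates = generate_sampling_dates(config, rngs["dates"])
    if len(dates) == 0:
        raise ValueError("degenerate campaign: no sampling dates")
    abiotic = simulate_abiotic(dates, config, rngs["abiotic"])
    casts, true_mld = simulate_ctd_profiles(dates, config, rngs["profiles"])
    communities = simulate_communities(dates, config, rngs["communities"])
    return Campaign(config=config, dates=dates, abiotic=abiotic,
                    casts=casts, true_mld=true_mld, communities=communities)


def write_campaign(campaign: Campaign, outdir, provenance: str | None = None) -> None:
    """Write a campaign as the CSV formats the analysis readers consume."""
    outdir = Path(outdir)
    (outdir / "abiotic").mkdir(parents=True, exist_ok=True)
    (outdir / "ctd").mkdir(exist_ok=True)
    (outdir / "communities").mkdir(exist_ok=True)
    for var, series in campaign.abiotic.items():
        write_series_csv(series, outdir / "abiotic" / f"{var}.csv", provenance)
    for cast in campaign.casts:
        write_ctd_csv(cast, outdir / "ctd" / f"ctd_{cast.cast_date.date().isoformat()}.csv",
                      provenance)
    truth = campaign.true_mld.copy()
    truth.index = [pd.Timestamp(d).date().isoformat() for d in truth.index]
    truth.index.name = "date"
    truth.to_csv(outdir / "ctd" / "true_mld.csv", float_format="%.10g", lineterminator="\n")
    for level, bundle in campaign.communities.items():
        write_community_csv(
            bundle["table"],
            outdir / "communities" / f"{level}.csv",
            taxonomy_path=outdir / "communities" / f"{level}_taxonomy.csv",
            provenance=provenance,
        )
        write_series_csv(bundle["total_biomass"],
                         outdir / "communities" / f"{level}_biomass.csv", provenance)
        if "cell_counts" in bundle:
            write_series_csv(bundle["cell_counts"],
                             outdir / "communities" / "bacterial_abundance.csv", provenance)
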