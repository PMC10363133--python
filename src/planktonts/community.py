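"""Community-table transformations and temporal similarity analysis.

A community table is a samples x taxa matrix of non-negative values
(counts, relative abundances, or biomass) with a taxonomy sidecar mapping
each taxon to its group, trophic level, and optional 16S copies-per-genome
and carbon conversion factor.  The operations here cover copy-number
normalization of amplicon counts, taxon exclusion with compositional
re-closure, group aggregation with an audit of minor members, Bray-Curtis
(dis)similarity, and the monthly-binned time-lag similarity curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CommunityTable",
    "DAYS_PER_MONTH",
    "copy_number_normalize",
    "exclude_taxa",
    "aggregate_groups",
    "to_relative",
    "bray_curtis_dissimilarity",
    "bray_curtis_similarity",
    "time_lag_similarity",
    "read_community_csv",
    "write_community_csv",
]

logger = logging.getLogger(__name__)

#: mean Gregorian month length in days, used for lag binning
DAYS_PER_MONTH = 30.44

TAXONOMY_COLUMNS = ("group", "trophic_level", "genome_copy_number", "carbon_factor")


@dataclass
class CommunityTable:
    """Samples x taxa value matrix with a taxonomy sidecar.

    ``data`` rows are indexed by sampling date, columns by unique taxon
    ids (genus-level labels in the standard pipeline).  ``value_kind``
    records what the numbers mean: ``counts``, ``relative``, ``biomass``,
    ``biovolume`` or ``wet_weight``.
    """

    data: pd.DataFrame
    taxonomy: pd.DataFrame
    value_kind: str
    trophic_level: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("taxa ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("community values must be non-negative")
        self.data = self.data.astype(float)
        missing = [t for t in self.data.columns if t not in self.taxonomy.index]
        if missing:
            raise ValueError(f"taxa missing from taxonomy sidecar: {missing}")

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    @property
    def dates(self) -> pd.Index:
        return self.data.index

    def copy_with(self, data: pd.DataFrame, value_kind: str | None = None,
                  note: str | None = None) -> "CommunityTable":
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return CommunityTable(
            data=data,
            taxonomy=self.taxonomy.loc[list(data.columns)].copy(),
            value_kind=value_kind or self.value_kind,
            trophic_level=self.trophic_level,
            provenance=prov,
        )


def copy_number_normalize(
    table: CommunityTable,
    copies: pd.Series | None = None,
    default_copies: float | None = None,
) -> CommunityTable:
    """Genome-size-corrected relative abundances from amplicon counts.

    Each taxon's count is divided by its 16S copies-per-genome before
    closing the composition, so a_i = (c_i / k_i) / sum_j (c_j / k_j).
    Taxa lacking a copy number fall back to ``default_copies`` (the
    dataset median when unset) with a logged warning.
    """
    if copies is None:
        copies = table.taxonomy["genome_copy_number"]
    copies = copies.reindex(table.taxa).astype(float)
    missing = copies.index[copies.isna()]
    if len(missing):
        fallback = default_copies if default_copies is not None else float(copies.median())
        if np.isnan(fallback):
            raise ValueError("no copy numbers available and no default given")
        logger.warning("no 16S copy number for %d taxa (%s...); using fallback %.3g",
                       len(missing), list(missing[:3]), fallback)
        copies = copies.fillna(fallback)
    if (copies[table.data.sum(axis=0) > 0] < 1).any():
        raise ValueError("copies per genome must be >= 1 for observed taxa")
    corrected = table.data.div(copies, axis=1)
    totals = corrected.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.data.index[totals == 0])
        raise ValueError(f"all-zero samples have undefined composition: {bad}")
    rel = corrected.div(totals, axis=0)
    return table.copy_with(rel, value_kind="relative",
                           note="copy_number_normalized")


def exclude_taxa(table: CommunityTable,
                 predicate: Callable[[str, pd.Series], bool]) -> CommunityTable:
    """Drop taxa matched by ``predicate(taxon_id, taxonomy_row)``.

    Compositional tables are re-closed to sum to one afterwards; counts
    and biomass tables keep the remaining values untouched.  Removing
    every taxon is an error.
    """
    drop = [t for t in table.taxa if predicate(t, table.taxonomy.loc[t])]
    if len(drop) == len(table.taxa):
        raise ValueError("predicate would remove every taxon")
    if not drop:
        return table.copy_with(table.data.copy(), note="exclude_taxa: no match")
    kept = table.data.drop(columns=drop)
    if table.value_kind == "relative":
        totals = kept.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("exclusion left all-zero compositional samples")
        kept = kept.div(totals, axis=0)
    return table.copy_with(kept, note=f"excluded taxa: {sorted(drop)}")


def aggregate_groups(
    table: CommunityTable,
    mapping: pd.Series | None = None,
    minor_threshold: float = 0.02,
) -> tuple[CommunityTable, list[str]]:
    """Sum taxa into their groups; audit 'Other' members above a share cap.

    ``mapping`` defaults to the sidecar's ``group`` column; unmapped taxa
    go to 'Other' with a warning.  The audit lists members of a group
    labelled 'Other*' whose overall mean share reaches ``minor_threshold``
    (the convention being that such catch-all groups should only pool
    members individually below ~2 % of relative biomass).
    """
    if mapping is None:
        mapping = table.taxonomy["group"]
    mapping = mapping.reindex(table.taxa)
    if mapping.isna().any():
        unmapped = list(mapping.index[mapping.isna()])
        logger.warning("unmapped taxa assigned to 'Other': %s", unmapped)
        mapping = mapping.fillna("Other")
    grouped = table.data.T.groupby(mapping.to_numpy()).sum().T

    # audit the <2% rule for catch-all groups on the relative scale
    totals = table.data.sum(axis=1)
    rel = table.data.div(totals.replace(0, np.nan), axis=0)
    mean_share = rel.mean(axis=0)
    audit = [
        str(taxon)
        for taxon in table.taxa
        if str(mapping[taxon]).lower().startswith("other")
        and mean_share[taxon] >= minor_threshold
    ]

    tax = pd.DataFrame(
        {
            "group": grouped.columns,
            "trophic_level": table.trophic_level,
            "genome_copy_number": np.nan,
            "carbon_factor": np.nan,
        },
        index=pd.Index(grouped.columns, name="taxon"),
    )
    out = CommunityTable(
        data=grouped,
        taxonomy=tax,
        value_kind=table.value_kind,
        trophic_level=table.trophic_level,
        provenance=list(table.provenance) + ["aggregated to groups"],
    )
    return out, audit


def to_relative(table: CommunityTable) -> CommunityTable:
    """Close each sample to sum to one (relative abundance / biomass)."""
    totals = table.data.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero samples have undefined composition")
    return table.copy_with(table.data.div(totals, axis=0), value_kind="relative",
                           note="closed to relative")


def bray_curtis_dissimilarity(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the same taxa")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("community vectors must be non-negative")
    denom = (x + y).sum()
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("zero-sum community vector")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity, 1 - dissimilarity."""
    return 1.0 - bray_curtis_dissimilarity(x, y)


def time_lag_similarity(
    table: CommunityTable,
    month_days: float = DAYS_PER_MONTH,
    return_pairs: bool = False,
):
    """Mean Bray-Curtis similarity of sample pairs binned by lag month.

    Every unordered pair of distinct samplings contributes one similarity
    at lag ``delta`` days; pairs fall in bin ``m`` when
    ``(m-1)*month_days < delta <= m*month_days`` (bin 1 holds all pairs
    within one average month of each other).  Bins with no pairs are
    omitted.  Returns a frame (lag_months, mean_similarity, n_pairs); with
    ``return_pairs`` also the pair-level audit table.
    """
    if len(table.dates) < 2:
        raise ValueError("need at least 2 samples for a lag curve")
    dates = pd.DatetimeIndex(table.dates)
    values = table.data.to_numpy()
    if (values.sum(axis=1) == 0).any():
        raise ValueError("zero-sum samples cannot enter Bray-Curtis")
    sim = 1.0 - squareform(pdist(values, metric="braycurtis"))
    i, j = np.triu_indices(len(dates), k=1)
    lag_days = np.abs((dates[j] - dates[i]).days.to_numpy()).astype(float)
    lag_month = np.maximum(1, np.ceil(lag_days / month_days)).astype(int)
    sims = sim[i, j]
    curve = (
        pd.DataFrame({"lag_months": lag_month, "similarity": sims})
        .groupby("lag_months")["similarity"]
        .agg(mean_similarity="mean", n_pairs="size")
        .reset_index()
    )
    if not return_pairs:
        return curve
    pairs = pd.DataFrame(
        {
            "sample_a": dates[i],
            "sample_b": dates[j],
            "lag_days": lag_days,
            "similarity": sims,
        }
    )
    return curve, pairs


def write_community_csv(table: CommunityTable, path, taxonomy_path=None,
                        provenance: str | None = None) -> None:
    """Write the wide samples x taxa CSV plus the taxonomy sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write(f"# trophic_level={table.trophic_level} value_kind={table.value_kind}\n")
        df = table.data.copy()
        df.index = [pd.Timestamp(d).date().isoformat() for d in df.index]
        df.index.name = "date"
        df.to_csv(fh, float_format="%.10g", lineterminator="\n")
    if taxonomy_path is not None:
        tax = table.taxonomy.copy()
        tax.index.name = "taxon"
        tax.to_csv(taxonomy_path, float_format="%.10g", lineterminator="\n")


def read_community_csv(path, taxonomy_path) -> CommunityTable:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, comment="#", index_col="date", parse_dates=["date"])
    df.index.name = None
    tax = pd.read_csv(taxonomy_path, index_col="taxon")
    return CommunityTable(
        data=df,
        taxonomy=tax,
        value_kind=meta.get("value_kind", "counts"),
        trophic_level=meta.get("trophic_level", ""),
    )
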