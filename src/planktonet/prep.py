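"""Count-table preprocessing: rarefaction, prevalence and size-fraction
filters, seasonally aware imputation, month-normalized relative abundance,
and resident-OTU selection.

The preprocessing contract is the one common to monthly observatory
datasets: every sample is subsampled to the same read depth (here the
default is 4907 reads, the depth of the shallowest sample in the emulated
study design), OTUs seen in fewer than 10% of samples are dropped, OTUs
appearing in both size fractions with a >2:1 read ratio are removed from
the minority fraction, missing months are imputed with a seasonally aware
weighted moving average, and relative abundances are normalized so that
all OTUs of a calendar month, summed across the ten years and all four
tables, add to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountTable:
    """Integer read counts (OTUs x monthly samples) for one domain and
    size fraction.  Columns are calendar months (pandas PeriodIndex)."""

    counts: pd.DataFrame
    domain: str
    size_fraction: str

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample dates within a table")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def months(self) -> pd.Index:
        return self.counts.columns

    def replace_counts(self, counts: pd.DataFrame) -> "CountTable":
        return CountTable(counts=counts, domain=self.domain, size_fraction=self.size_fraction)


@dataclass
class PrepConfig:
    rarefaction_depth: int = 4907
    prevalence_min_fraction: float = 0.10
    resident_min_months: int = 36
    ratio_threshold: float = 2.0
    resident_whitelist: list[str] = field(default_factory=list)
    impute_window: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0 or self.ratio_threshold < 1.0:
            raise ValueError("thresholds must be positive (ratio threshold >= 1)")
        if not 0.0 < self.prevalence_min_fraction < 1.0:
            raise ValueError("prevalence_min_fraction must lie in (0, 1)")


def rarefy_counts(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Equivalent to drawing a multivariate hypergeometric sample per column;
    a sample with fewer than ``depth`` reads is an error (naming the
    sample), matching the convention that the depth is chosen as the
    shallowest sample's total.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for j, col in enumerate(counts.T):
        total = int(col.sum())
        if total < depth:
            raise ValueError(
                f"sample {table.counts.columns[j]} has {total} reads, fewer than depth {depth}"
            )
        if total == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
    return table.replace_counts(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def filter_prevalence(table: CountTable, min_fraction: float) -> CountTable:
    """Keep OTUs present (count > 0) in at least ceil(min_fraction * n) samples."""
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0, 1)")
    if table.counts.empty:
        raise ValueError("empty count table")
    n = table.counts.shape[1]
    need = math.ceil(min_fraction * n)
    present = (table.counts > 0).sum(axis=1)
    return table.replace_counts(table.counts.loc[present >= need])


def resolve_size_fractions(
    pico: CountTable, nano: CountTable, ratio_threshold: float = 2.0
) -> tuple[CountTable, CountTable]:
    """Apply the 2:1 read-ratio rule to OTUs shared between size fractions.

    For every OTU with reads in both fractions, the total read ratio is
    computed; when it strictly exceeds ``ratio_threshold`` the OTU is
    zeroed out of the fraction with fewer reads.  OTUs confined to one
    fraction are untouched, and an OTU is never removed from both.
    """
    if ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must be >= 1")
    pico_counts = pico.counts.copy()
    nano_counts = nano.counts.copy()
    shared = pico_counts.index.intersection(nano_counts.index)
    for otu in shared:
        tp = int(pico_counts.loc[otu].sum())
        tn = int(nano_counts.loc[otu].sum())
        if tp == 0 or tn == 0:
            continue
        hi, lo = max(tp, tn), min(tp, tn)
        if hi / lo > ratio_threshold:
            if tp < tn:
                pico_counts.loc[otu] = 0
            else:
                nano_counts.loc[otu] = 0
    return pico.replace_counts(pico_counts), nano.replace_counts(nano_counts)


def impute_seasonal(
    series: pd.Series, period: int = 12, window: int = 2
) -> tuple[pd.Series, pd.Series]:
    """Seasonally aware weighted-moving-average imputation of a monthly series.

    The per-calendar-month mean (computed from observed values) is
    subtracted, the residual gaps are filled with a linearly weighted
    moving average (window ``window`` on each side, weights decaying
    linearly with distance, widened until an observed neighbour is found),
    and the seasonal means are added back.  Observed values are returned
    unchanged.  Returns ``(filled_series, imputed_mask)``.
    """
    values = series.astype(float)
    mask = values.isna()
    if not mask.any():
        return values, mask
    idx = values.index
    month_of = (
        idx.month.to_numpy() if hasattr(idx, "month") else (np.arange(len(values)) % period) + 1
    )
    month_means = {}
    for m in np.unique(month_of):
        obs = values.to_numpy()[(month_of == m) & ~mask.to_numpy()]
        if obs.size == 0:
            raise ValueError(f"calendar month {m} has no observed values to impute from")
        month_means[m] = obs.mean()
    seasonal = np.array([month_means[m] for m in month_of])
    resid = values.to_numpy() - seasonal
    filled = resid.copy()
    missing_idx = np.flatnonzero(mask.to_numpy())
    observed = ~mask.to_numpy()
    n = len(resid)
    for i in missing_idx:
        k = window
        while True:
            lo, hi = max(0, i - k), min(n, i + k + 1)
            neigh = np.arange(lo, hi)
            neigh = neigh[(neigh != i) & observed[neigh]]
            if neigh.size:
                w = k + 1 - np.abs(neigh - i)
                w = np.maximum(w, 1)
                filled[i] = float(np.average(resid[neigh], weights=w))
                break
            k += window
            if k > n:  # pragma: no cover - guarded by the month-mean check
                filled[i] = 0.0
                break
    out = pd.Series(filled + seasonal, index=idx, name=series.name)
    out[~mask] = values[~mask]
    return out, mask


def impute_table(table: CountTable, full_months: pd.Index, window: int = 2) -> CountTable:
    """Reindex a table onto the full month axis and impute missing months
    per OTU series (imputed values are real-valued read abundances)."""
    counts = table.counts.reindex(columns=full_months).astype(float)
    if not counts.isna().any().any():
        return table.replace_counts(counts)
    filled = counts.apply(
        lambda row: impute_seasonal(row, window=window)[0], axis=1, result_type="expand"
    )
    filled.columns = full_months
    filled = filled.clip(lower=0.0)
    return table.replace_counts(filled)


def aggregate_relative_abundance(tables: list[CountTable]) -> pd.DataFrame:
    """Relative read abundance normalized within calendar-month groups.

    All tables are stacked on a shared month axis and every sample is
    divided by the grand total of its calendar month (summed over the ten
    years, both domains and both size fractions), so the values of one
    calendar month across all years and OTUs sum to one.  Requires all
    tables rarefied to the same depth.
    """
    if not tables:
        raise ValueError("no tables given")
    # guard against grossly unequal sequencing depths; small deviations from
    # the rarefaction depth are expected after OTU-level filtering/imputation
    sample_totals = np.concatenate(
        [t.counts.sum(axis=0).to_numpy(dtype=float) for t in tables if t.counts.shape[1]]
    )
    if sample_totals.size and sample_totals.min() > 0:
        if sample_totals.max() / sample_totals.min() > 1.5:
            raise ValueError(
                "tables appear rarefied to unequal depths "
                f"(sample totals range {sample_totals.min():.0f}-{sample_totals.max():.0f})"
            )

    stacked = pd.concat([t.counts for t in tables], axis=0)
    if stacked.index.duplicated().any():
        raise ValueError("duplicate OTU ids across tables")
    months = stacked.columns
    month_of = months.month.to_numpy() if hasattr(months, "month") else None
    rel = stacked.astype(float).copy()
    if month_of is None:
        rel /= rel.to_numpy().sum()
        return rel
    for m in np.unique(month_of):
        cols = months[month_of == m]
        grand = stacked[cols].to_numpy().sum()
        if grand <= 0:
            raise ValueError(f"calendar month {m} has zero total reads")
        rel[cols] = stacked[cols] / grand
    return rel


def select_residents(
    abundance: pd.DataFrame, min_months: int = 36, whitelist: list[str] | None = None
) -> list[str]:
    """OTUs present (> 0) in at least ``min_months`` months, plus whitelist."""
    whitelist = set(whitelist or ())
    present = (abundance > 0).sum(axis=1)
    resident = set(abundance.index[present >= min_months])
    resident |= whitelist & set(abundance.index)
    return sorted(resident)


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """z-score each environmental variable (sample SD); errors on constants."""
    out = {}
    for name in env.columns:
        col = env[name].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"environmental variable {name!r} is constant")
        out[name] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=env.index)


@dataclass
class PrepResult:
    abundance: pd.DataFrame  # resident OTUs x all months (relative abundance)
    residents: list[str]
    tables: list[CountTable]  # post-filter, post-imputation tables
    env: pd.DataFrame  # standardized environmental variables
    imputed_months: dict[str, list] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def prepare(
    tables: list[CountTable], env: pd.DataFrame, config: PrepConfig | None = None
) -> PrepResult:
    """Full preprocessing chain on four domain x fraction count tables.

    Order of operations: rarefy -> prevalence filter -> seasonal imputation
    of missing months -> size-fraction ratio rule -> month-normalized
    relative abundance -> resident selection -> environmental z-scoring.
    Presence for the resident rule is counted on the post-imputation series.
    """
    config = config or PrepConfig()
    log: list[str] = []
    full_months = env.index
    rng_seeds = np.random.SeedSequence(config.seed).spawn(len(tables))

    processed: list[CountTable] = []
    imputed_months: dict[str, list] = {}
    for table, seed_seq in zip(tables, rng_seeds):
        key = f"{table.domain}_{table.size_fraction}"
        t = rarefy_counts(table, config.rarefaction_depth, seed=int(seed_seq.generate_state(1)[0] % (2**31)))
        before = t.counts.shape[0]
        t = filter_prevalence(t, config.prevalence_min_fraction)
        log.append(f"{key}: prevalence filter kept {t.counts.shape[0]}/{before} OTUs")
        missing = [m for m in full_months if m not in t.counts.columns]
        t = impute_table(t, full_months, window=config.impute_window)
        if missing:
            imputed_months[key] = list(missing)
            log.append(f"{key}: imputed {len(missing)} missing months")
        processed.append(t)

    by_domain: dict[str, dict[str, int]] = {}
    for i, t in enumerate(processed):
        by_domain.setdefault(t.domain, {})[t.size_fraction] = i
    for domain, fr in by_domain.items():
        if "pico" in fr and "nano" in fr:
            p, n = resolve_size_fractions(
                processed[fr["pico"]], processed[fr["nano"]], config.ratio_threshold
            )
            processed[fr["pico"]], processed[fr["nano"]] = p, n
            log.append(f"{domain}: applied {config.ratio_threshold}:1 size-fraction rule")

    abundance = aggregate_relative_abundance(processed)
    residents = select_residents(
        abundance, config.resident_min_months, config.resident_whitelist
    )
    log.append(f"residents: {len(residents)}/{abundance.shape[0]} OTUs")
    return PrepResult(
        abundance=abundance.loc[residents],
        residents=residents,
        tables=processed,
        env=standardize_env(env),
        imputed_months=imputed_months,
        log=log,
    )
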