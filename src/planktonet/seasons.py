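"""Season delineation, indicator-value seasonal preference, and
abundance-weighted niche null models.

Seasons follow a hydrographic rule rather than the calendar: a month is
*summer* when water temperature exceeds 17 C and photoperiod exceeds
14 h, *winter* when temperature is below 17 C and photoperiod below 11 h,
*autumn* when it is warm (>17 C) but days are short (<14 h), and *spring*
when it is cool (<17 C) but days exceed 11 h.  Values exactly on a
boundary are undefined by the rule; they raise unless the closed-lower
tie-break is enabled, in which case the boundary value is counted with
the upper region (T>=17, D>=14, D>=11).

The indicator value (IndVal) of an OTU for season j is
``A_ij * B_ij * 100`` where A (specificity) is the OTU's mean abundance
in j divided by the sum of its per-season mean abundances, and B
(fidelity) is the fraction of j's samples where the OTU occurs.  The
niche null model compares the abundance-weighted mean of an
environmental variable against the permutation distribution obtained by
shuffling abundances across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEASONS = ("winter", "spring", "summer", "autumn")

TEMP_SPLIT = 17.0  # degrees C
DAYLEN_SHORT = 11.0  # hours
DAYLEN_LONG = 14.0  # hours


def assign_season(
    temperature: float, daylength: float, tie_break: str | None = None
) -> str:
    """Season of one month from water temperature (C) and photoperiod (h)."""
    if not (np.isfinite(temperature) and np.isfinite(daylength)):
        raise ValueError("temperature and daylength must be finite")
    closed_lower = tie_break == "closed-lower"
    if not closed_lower and (
        temperature == TEMP_SPLIT
        or daylength in (DAYLEN_SHORT, DAYLEN_LONG)
    ):
        raise ValueError(
            f"boundary value (T={temperature}, D={daylength}) is undefined by the "
            "season rules; enable the 'closed-lower' tie-break to resolve it"
        )
    warm = temperature >= TEMP_SPLIT if closed_lower else temperature > TEMP_SPLIT
    if warm:
        long_day = daylength >= DAYLEN_LONG if closed_lower else daylength > DAYLEN_LONG
        return "summer" if long_day else "autumn"
    short_day = daylength < DAYLEN_SHORT
    return "winter" if short_day else "spring"


def label_months(env: pd.DataFrame, tie_break: str | None = None) -> pd.Series:
    """Season label per month from the raw (unstandardized) environment."""
    labels = [
        assign_season(t, d, tie_break=tie_break)
        for t, d in zip(env["temperature"], env["daylength"])
    ]
    return pd.Series(labels, index=env.index, name="season")


def _indval_matrix(abund: np.ndarray, groups: np.ndarray, group_ids: np.ndarray) -> np.ndarray:
    """IndVal (0..100) per OTU x group; rows with zero total are NaN."""
    n_otus = abund.shape[0]
    k = len(group_ids)
    means = np.empty((n_otus, k))
    occ = np.empty((n_otus, k))
    for j, g in enumerate(group_ids):
        cols = groups == g
        means[:, j] = abund[:, cols].mean(axis=1)
        occ[:, j] = (abund[:, cols] > 0).mean(axis=1)
    total = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / total, np.nan)
    return a * occ * 100.0


def indval(
    abundance: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-OTU indicator values over the season groups with permutation p.

    The test statistic is the maximum IndVal over seasons; the p-value is
    the +1-smoothed fraction of label permutations attaining at least the
    observed maximum.  All-zero OTUs are reported with NaN values.
    """
    groups = labels.loc[abundance.columns].to_numpy()
    group_ids = np.array(sorted(set(groups)))
    if len(group_ids) < 2:
        raise ValueError("need at least two seasons present")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    abund = abundance.to_numpy(dtype=float)
    obs = _indval_matrix(abund, groups, group_ids)
    obs_max = np.nanmax(np.where(np.isnan(obs), -np.inf, obs), axis=1)
    obs_max[np.isinf(obs_max)] = np.nan

    rng = np.random.default_rng(seed)
    exceed = np.zeros(abund.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        pm = _indval_matrix(abund, perm, group_ids)
        pmax = np.nanmax(np.where(np.isnan(pm), -np.inf, pm), axis=1)
        exceed += pmax >= obs_max - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    best_idx = np.where(
        np.isnan(obs_max), -1, np.nanargmax(np.where(np.isnan(obs), -np.inf, obs), axis=1)
    )
    out = pd.DataFrame(obs, index=abundance.index, columns=[f"indval_{g}" for g in group_ids])
    out["best_season"] = [group_ids[i] if i >= 0 else "NA" for i in best_idx]
    out["p"] = np.where(np.isnan(obs_max), np.nan, pvals)
    return out


@dataclass
class NicheResult:
    otu: str
    variable: str
    weighted_mean: float
    null_mean: float
    lower_cl: float
    upper_cl: float
    p: float
    classification: str  # above | below | none


def niche_preference(
    abundances: np.ndarray | pd.Series,
    env_values: np.ndarray | pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    otu: str = "",
    variable: str = "",
) -> NicheResult:
    """Abundance-weighted environmental mean against a permutation null.

    The null distribution permutes abundances across samples; confidence
    limits are the 2.5/97.5 percentiles, the p-value is the two-sided
    +1-smoothed permutation probability, and the classification is
    ``above``/``below`` when the observed weighted mean falls outside the
    limits, ``none`` otherwise.
    """
    a = np.asarray(abundances, dtype=float)
    e = np.asarray(env_values, dtype=float)
    if a.shape != e.shape:
        raise ValueError("abundance and environmental series lengths differ")
    if a.sum() <= 0:
        raise ValueError("total abundance must be positive")
    if np.ptp(e) == 0:
        raise ValueError("environmental variable is constant")
    obs = float(np.sum(a * e) / np.sum(a))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    s = a.sum()
    for i in range(n_perm):
        perm = rng.permutation(a)
        null[i] = np.sum(perm * e) / s
    lower, upper = np.percentile(null, [2.5, 97.5])
    p_hi = (np.sum(null >= obs) + 1.0) / (n_perm + 1.0)
    p_lo = (np.sum(null <= obs) + 1.0) / (n_perm + 1.0)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    if obs > upper:
        cls = "above"
    elif obs < lower:
        cls = "below"
    else:
        cls = "none"
    return NicheResult(
        otu=otu,
        variable=variable,
        weighted_mean=obs,
        null_mean=float(null.mean()),
        lower_cl=float(lower),
        upper_cl=float(upper),
        p=float(p),
        classification=cls,
    )


def niche_table(
    abundance: pd.DataFrame,
    env: pd.DataFrame,
    variables: tuple[str, ...] = ("temperature", "daylength"),
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Niche preference of every OTU for the requested variables."""
    rows = []
    child = np.random.SeedSequence(seed).spawn(len(variables))
    for var, seq in zip(variables, child):
        var_seed = int(seq.generate_state(1)[0] % (2**31))
        e = env.loc[abundance.columns, var]
        for otu in abundance.index:
            a = abundance.loc[otu]
            if a.sum() <= 0:
                continue
            res = niche_preference(a, e, n_perm=n_perm, seed=var_seed, otu=otu, variable=var)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
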