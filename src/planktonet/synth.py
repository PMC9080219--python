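"""Synthetic monthly plankton community generator with planted ground truth.

Emulates the sampling design of a decade-long coastal observatory: 120
monthly samples, two organismal size fractions (picoplankton 0.2-3 um,
nanoplankton 3-20 um) sequenced separately for bacteria and protists,
a fixed rarefied read depth per sample, seasonally structured OTU
dynamics driven by temperature and photoperiod, and blocks of missing
nanoplankton months.

Three kinds of structure are planted and recorded in a truth object so
every downstream stage can be scored:

* *direct pairs* -- two OTUs sharing a smooth latent driver that is
  independent of every environmental variable (a stand-in for an
  ecological interaction);
* *environmentally driven pairs* -- two OTUs responding to the same
  environmental variable with independent noise and no other shared
  driver (the class the indirect-edge stage must remove);
* *seasonal niches* -- OTUs whose latent abundance is a smooth unimodal
  bump around a preferred season.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from planktonet.prep import CountTable

TABLE_KEYS = ("bacteria_pico", "bacteria_nano", "protist_pico", "protist_nano")
_PREFIX = {
    "bacteria_pico": "bp",
    "bacteria_nano": "bn",
    "protist_pico": "ep",
    "protist_nano": "en",
}

SEASON_PEAK_MONTH = {"winter": 1.0, "spring": 4.0, "summer": 7.0, "autumn": 10.0}

# (mean, annual amplitude, calendar month of maximum, noise sd); amplitude 0
# means the variable is pure red noise around its mean.  Fifteen variables,
# mirroring a typical coastal observatory contextual dataset.
DEFAULT_ENV_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "temperature": (18.2, 5.5, 8.0, 0.5),
    "salinity": (38.0, 0.15, 2.0, 0.1),
    "chlorophyll_a": (0.7, 0.35, 3.0, 0.15),
    "phosphate": (0.12, 0.04, 1.0, 0.02),
    "ammonium": (0.5, 0.0, 1.0, 0.2),
    "nitrite": (0.15, 0.05, 2.0, 0.04),
    "nitrate": (1.2, 0.8, 2.0, 0.25),
    "silicate": (1.1, 0.4, 1.0, 0.2),
    "secchi_depth": (12.0, 3.0, 7.0, 1.0),
    "doc": (80.0, 8.0, 8.0, 4.0),
    "poc": (6.0, 1.5, 4.0, 0.8),
    "bacterial_abundance": (9.0e5, 2.5e5, 7.0, 8.0e4),
    "synechococcus_abundance": (4.0e4, 2.5e4, 9.0, 6.0e3),
    "pnf_abundance": (2.5e3, 1.0e3, 5.0, 3.0e2),
    "hnf_abundance": (1.2e3, 4.0e2, 8.0, 1.5e2),
}

# day of year of the 15th of each calendar month (non-leap year)
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])


def daylength_cbm(day_of_year: float, latitude: float, p: float = 0.8333) -> float:
    """Photoperiod (hours) from the CBM day-length model (Forsythe et al. 1995).

    ``p`` is the daylength definition coefficient in degrees; the default
    corresponds to sunrise/sunset including atmospheric refraction.
    """
    theta = 0.2163108 + 2.0 * math.atan(0.9671396 * math.tan(0.00860 * (day_of_year - 186)))
    phi = math.asin(0.39795 * math.cos(theta))
    lat = math.radians(latitude)
    arg = (math.sin(math.radians(p)) + math.sin(lat) * math.sin(phi)) / (
        math.cos(lat) * math.cos(phi)
    )
    arg = min(1.0, max(-1.0, arg))
    return 24.0 - (24.0 / math.pi) * math.acos(arg)


def month_index(n_months: int, start: str = "2004-01") -> pd.PeriodIndex:
    return pd.period_range(start=start, periods=n_months, freq="M")


@dataclass
class SynthConfig:
    """Parameters of the synthetic community.

    Defaults mirror the emulated sampling design: 120 monthly samples over
    ten years, rarefied depth 4907 reads, four count tables
    (bacteria/protists x pico/nano), and nanoplankton gaps of 27 consecutive
    months plus two isolated months.
    """

    n_otus_per_table: int = 40
    n_months: int = 120
    read_depth: int = 4907
    seasonal_fraction: float = 0.5
    n_direct_pairs: int = 20
    n_env_driven_pairs: int = 20
    noise_sd: float = 0.25
    negative_fraction: float = 0.05
    coupling: float = 1.2
    latitude: float = 41.67
    start_month: str = "2004-01"
    # month indices absent from nanoplankton tables; None selects the default
    # gap pattern, an explicit empty dict disables missing months
    missing_blocks: dict[str, list[int]] | None = None
    env_driver_pool: tuple[str, ...] = (
        "temperature",
        "nitrate",
        "chlorophyll_a",
        "secchi_depth",
        "silicate",
        "doc",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 12:
            raise ValueError("n_months must be at least 12")
        for name in ("n_otus_per_table", "read_depth", "n_direct_pairs", "n_env_driven_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.seasonal_fraction <= 1.0:
            raise ValueError("seasonal_fraction must lie in [0, 1]")
        if self.missing_blocks is None:
            self.missing_blocks = default_missing_blocks(self.n_months)

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


def default_missing_blocks(n_months: int) -> dict[str, list[int]]:
    """27 consecutive missing nanoplankton months plus 2 isolated ones.

    Mirrors the emulated observatory, where a contiguous stretch of
    nanoplankton samples (and two further single months) could not be used.
    All indices are clipped to the simulated span.
    """
    block = [m for m in range(76, 103) if m < n_months]
    isolated = [m for m in (2, 13) if m < n_months]
    months = sorted(block + isolated)
    return {"bacteria_nano": list(months), "protist_nano": list(months)}


@dataclass
class SynthTruth:
    """Planted structure: what the pipeline should (and should not) recover."""

    direct_pairs: dict[frozenset, int]  # pair -> sign (+1/-1)
    env_driven_pairs: dict[frozenset, str]  # pair -> driving variable name
    niche_labels: dict[str, str]  # otu -> season name ("none" possible)

    def __post_init__(self) -> None:
        if set(self.direct_pairs) & set(self.env_driven_pairs):
            raise ValueError("direct and environmentally driven pairs must be disjoint")


def generate_environment(
    n_months: int,
    latitude: float = 41.67,
    seed: int = 0,
    start: str = "2004-01",
    profiles: dict | None = None,
) -> pd.DataFrame:
    """Monthly environmental series: deterministic photoperiod, seasonal
    sinusoids plus seeded red noise for the remaining variables.

    Returns a DataFrame indexed by calendar month (PeriodIndex) with one
    column per variable; ``daylength`` is evaluated with the CBM photoperiod
    model on day 15 of each month.
    """
    if n_months < 12:
        raise ValueError("n_months must be at least 12")
    rng = np.random.default_rng(seed)
    idx = month_index(n_months, start)
    months_of_year = idx.month.to_numpy()  # 1..12
    profiles = dict(DEFAULT_ENV_PROFILES if profiles is None else profiles)

    data = {}
    data["daylength"] = np.array(
        [daylength_cbm(_MID_MONTH_DOY[m - 1], latitude) for m in months_of_year]
    )
    for name, (mean, amp, peak_month, noise) in profiles.items():
        seasonal = amp * np.cos(2.0 * np.pi * (months_of_year - peak_month) / 12.0)
        red = _ar1(rng, n_months, rho=0.6) * noise if noise > 0 else np.zeros(n_months)
        series = mean + seasonal + red
        if name != "temperature":
            series = np.maximum(series, 0.01 * abs(mean) if mean else 0.0)
        data[name] = series
    env = pd.DataFrame(data, index=idx)
    # keep temperature and daylength first for readability
    lead = [c for c in ("temperature", "daylength") if c in env.columns]
    env = env[lead + [c for c in env.columns if c not in lead]]
    return env


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.8) -> np.ndarray:
    """Standardized stationary AR(1) series."""
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    scale = math.sqrt(1.0 - rho**2)
    for t in range(1, n):
        z[t] = rho * z[t - 1] + scale * eps[t]
    return z


def _circular_month_distance(month: np.ndarray, peak: float) -> np.ndarray:
    d = np.abs(month - peak)
    return np.minimum(d, 12.0 - d)


def generate_latent_dynamics(
    config: SynthConfig, env: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], SynthTruth]:
    """Latent (noise-free up to lognormal jitter) abundance matrices plus truth.

    Planted direct pairs and environmentally driven pairs occupy dedicated
    OTU slots assigned round-robin across the four tables; the remaining
    OTUs are seasonal (Gaussian bump over circular month-of-year distance)
    with probability ``seasonal_fraction``, else smooth red-noise background.
    """
    if len(env) < config.n_months:
        raise ValueError("environmental series does not cover the configured months")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    idx = month_index(config.n_months, config.start_month)
    months_of_year = idx.month.to_numpy().astype(float)

    otu_ids = {
        key: [f"{_PREFIX[key]}_{i:04d}" for i in range(config.n_otus_per_table)]
        for key in TABLE_KEYS
    }
    all_otus = [(key, otu) for key in TABLE_KEYS for otu in otu_ids[key]]
    n_total = len(all_otus)
    needed = 2 * (config.n_direct_pairs + config.n_env_driven_pairs)
    if needed > n_total:
        raise ValueError(
            f"{config.n_direct_pairs} direct + {config.n_env_driven_pairs} env-driven "
            f"pairs need {needed} OTUs but only {n_total} are available"
        )

    # seeded shuffle so planted pairs span domains and size fractions without
    # systematically straddling any particular pair of tables
    order = [all_otus[i] for i in rng.permutation(n_total)]

    latent = {key: np.zeros((config.n_otus_per_table, config.n_months)) for key in TABLE_KEYS}
    row_of = {
        (key, otu): r for key in TABLE_KEYS for r, otu in enumerate(otu_ids[key])
    }

    def put(slot, series):
        key, otu = slot
        latent[key][row_of[(key, otu)]] = series

    def jitter(n):
        return np.exp(config.noise_sd * rng.standard_normal(n))

    def base_scale():
        return float(np.exp(rng.normal(0.0, 0.75)))

    direct_pairs: dict[frozenset, int] = {}
    env_pairs: dict[frozenset, str] = {}
    niche: dict[str, str] = {}

    cursor = 0
    for _ in range(config.n_direct_pairs):
        a, b = order[cursor], order[cursor + 1]
        cursor += 2
        driver = _ar1(rng, config.n_months, rho=0.8)
        sign = -1 if rng.random() < config.negative_fraction else 1
        put(a, base_scale() * np.exp(config.coupling * driver) * jitter(config.n_months))
        put(b, base_scale() * np.exp(sign * config.coupling * driver) * jitter(config.n_months))
        direct_pairs[frozenset((a[1], b[1]))] = sign
        niche[a[1]] = "none"
        niche[b[1]] = "none"

    env_z = {
        v: (env[v].to_numpy()[: config.n_months] - env[v].mean()) / env[v].std()
        for v in config.env_driver_pool
        if v in env.columns
    }
    pool = list(env_z)
    for j in range(config.n_env_driven_pairs):
        a, b = order[cursor], order[cursor + 1]
        cursor += 2
        var = pool[j % len(pool)]
        z = env_z[var]
        sign = -1 if rng.random() < config.negative_fraction else 1
        put(a, base_scale() * np.exp(config.coupling * z) * jitter(config.n_months))
        put(b, base_scale() * np.exp(sign * config.coupling * z) * jitter(config.n_months))
        env_pairs[frozenset((a[1], b[1]))] = var
        niche[a[1]] = "none"
        niche[b[1]] = "none"

    seasons = list(SEASON_PEAK_MONTH)
    for slot in order[cursor:]:
        if rng.random() < config.seasonal_fraction:
            season = seasons[rng.integers(len(seasons))]
            peak = SEASON_PEAK_MONTH[season]
            width = 1.2
            bump = np.exp(
                -(_circular_month_distance(months_of_year, peak) ** 2) / (2.0 * width**2)
            )
            amp = base_scale() * 3.0
            put(slot, amp * (bump + 0.05) * jitter(config.n_months))
            niche[slot[1]] = season
        else:
            z = _ar1(rng, config.n_months, rho=0.6)
            put(slot, base_scale() * np.exp(0.5 * z) * jitter(config.n_months))
            niche[slot[1]] = "none"

    frames = {
        key: pd.DataFrame(latent[key], index=otu_ids[key], columns=idx) for key in TABLE_KEYS
    }
    truth = SynthTruth(direct_pairs=direct_pairs, env_driven_pairs=env_pairs, niche_labels=niche)
    return frames, truth


def sample_counts(
    latent: dict[str, pd.DataFrame], config: SynthConfig
) -> list[CountTable]:
    """Multinomial read sampling at fixed depth; months in the configured
    missing blocks are absent from the affected tables."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tables = []
    for key in TABLE_KEYS:
        frame = latent[key]
        mat = frame.to_numpy(dtype=float)
        if (mat < 0).any():
            raise ValueError("latent abundances must be non-negative")
        missing = set(config.missing_blocks.get(key, ()))
        keep_cols = [j for j in range(frame.shape[1]) if j not in missing]
        counts = np.zeros((mat.shape[0], len(keep_cols)), dtype=int)
        for out_j, j in enumerate(keep_cols):
            col = mat[:, j]
            total = col.sum()
            if total <= 0:
                raise ValueError(f"all-zero latent column at month index {j} in {key}")
            counts[:, out_j] = rng.multinomial(config.read_depth, col / total)
        domain, fraction = key.split("_")
        tables.append(
            CountTable(
                counts=pd.DataFrame(
                    counts, index=frame.index, columns=frame.columns[keep_cols]
                ),
                domain=domain,
                size_fraction=fraction,
            )
        )
    return tables


def simulate_dataset(
    config: SynthConfig,
) -> tuple[list[CountTable], pd.DataFrame, SynthTruth]:
    """Environment, count tables, and truth from one seeded configuration."""
    env = generate_environment(
        config.n_months, config.latitude, seed=config.seed, start=config.start_month
    )
    latent, truth = generate_latent_dynamics(config, env)
    tables = sample_counts(latent, config)
    return tables, env, truth


def _as_pairset(edges) -> set[frozenset]:
    out = set()
    for e in edges:
        if isinstance(e, frozenset):
            out.add(e)
        else:
            a, b = e
            out.add(frozenset((a, b)))
    return out


def evaluate_recovery(
    predicted_edges,
    truth: SynthTruth,
    removed_edges=None,
) -> dict[str, float]:
    """Precision/recall of the planted classes.

    ``predicted_edges`` are the OTU-OTU edges of the final (core) network;
    ``removed_edges`` are the edges deleted by the indirect-edge stage, used
    to score recall of the planted environmentally driven pairs.
    """
    if not truth.direct_pairs and not truth.env_driven_pairs:
        raise ValueError("truth object contains no planted pairs")
    predicted = _as_pairset(predicted_edges)
    removed = _as_pairset(removed_edges) if removed_edges is not None else set()

    out: dict[str, float] = {}
    direct = set(truth.direct_pairs)
    if direct:
        hit = len(direct & predicted)
        out["direct_recall"] = hit / len(direct)
        out["direct_precision"] = hit / len(predicted) if predicted else float("nan")
        out["direct_false_removal"] = len(direct & removed) / len(direct)
    envp = set(truth.env_driven_pairs)
    if envp:
        out["env_driven_recall"] = len(envp & removed) / len(envp)
        out["env_driven_leak"] = len(envp & predicted) / len(envp)
    return out
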