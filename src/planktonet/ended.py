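"""Detection and removal of environmentally driven OTU-OTU associations.

An OTU-OTU edge whose two endpoints are both associated with the same
environmental variable forms a *triplet* (A, B, E).  Four criteria are
evaluated per triplet:

* **sign pattern** -- the edge sign equals the product of the two
  OTU-environment signs, as expected when E drives both OTUs;
* **overlap** -- the three LSA alignment intervals share a large portion
  (default >= 60%) of the OTU-OTU interval;
* **interaction information** -- II = MI(A;B|E) - MI(A;B) (bits, plug-in
  estimates on equal-frequency bins) is significantly negative, i.e. E
  explains away the A-B dependence (redundancy);
* **data processing inequality** -- MI(A;B) <= min(MI(A;E), MI(B;E)),
  the ordering implied by the Markov chain A - E - B.

An edge is removed only when all four criteria agree for at least one
environmental variable; OTU-environment edges are never removed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EndedConfig:
    overlap_threshold_pct: float = 60.0
    n_bins: int | None = None  # default ceil(1 + log2 n)
    ii_n_perm: int = 200
    ii_alpha: float = 0.05
    seed: int = 0


@dataclass
class Triplet:
    node_a: str
    node_b: str
    env_var: str
    edge_idx: int  # row index of the A-B association
    ae_idx: int
    be_idx: int


def enumerate_triplets(associations: pd.DataFrame) -> list[Triplet]:
    """One triplet per (OTU-OTU edge, environmental variable) where both
    OTU-environment associations are present in the table."""
    env_partners: dict[str, dict[str, int]] = {}
    for idx, row in associations.iterrows():
        if {row["kind_a"], row["kind_b"]} == {"otu", "env"}:
            otu, var = (
                (row["node_a"], row["node_b"])
                if row["kind_a"] == "otu"
                else (row["node_b"], row["node_a"])
            )
            env_partners.setdefault(otu, {})[var] = idx
    triplets: list[Triplet] = []
    otu_mask = (associations["kind_a"] == "otu") & (associations["kind_b"] == "otu")
    for idx in associations.index[otu_mask]:
        a = associations.at[idx, "node_a"]
        b = associations.at[idx, "node_b"]
        shared = sorted(set(env_partners.get(a, {})) & set(env_partners.get(b, {})))
        for var in shared:
            triplets.append(
                Triplet(
                    node_a=a,
                    node_b=b,
                    env_var=var,
                    edge_idx=idx,
                    ae_idx=env_partners[a][var],
                    be_idx=env_partners[b][var],
                )
            )
    return triplets


def sign_pattern(sign_ab: int, sign_ae: int, sign_be: int) -> bool:
    """True when the edge sign is consistent with environmental driving."""
    return int(sign_ab) == int(sign_ae) * int(sign_be)


def _interval_intersection(*intervals: tuple[int, int]) -> int:
    lo = max(s for s, _ in intervals)
    hi = min(e for _, e in intervals)
    return max(0, hi - lo + 1)


def interval_overlap(
    ab: tuple[int, int], ae: tuple[int, int], be: tuple[int, int], threshold_pct: float = 60.0
) -> tuple[float, bool]:
    """Percentage of the A-B alignment interval covered by the triple
    intersection with the two OTU-environment intervals."""
    ab_len = ab[1] - ab[0] + 1
    if ab_len <= 0:
        raise ValueError("empty A-B interval")
    pct = 100.0 * _interval_intersection(ab, ae, be) / ab_len
    return pct, pct >= threshold_pct


def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels; errors when fewer than 2 distinct bins
    can be formed."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    labels = np.searchsorted(edges, x, side="left")
    if len(np.unique(labels)) < 2:
        raise ValueError("too few distinct values to form 2 bins")
    return labels


def _mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete label arrays."""
    ka, kb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def _cmi_bits(a: np.ndarray, b: np.ndarray, e: np.ndarray) -> float:
    """Conditional mutual information MI(A;B|E) in bits."""
    return float(_cmi_bits_many(a, b, e[None, :])[0])


def _cmi_bits_many(a: np.ndarray, b: np.ndarray, e_rows: np.ndarray) -> np.ndarray:
    """MI(A;B|E) in bits for each row of ``e_rows`` (vectorized over rows)."""
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    ke = int(e_rows.max()) + 1
    m, n = e_rows.shape
    code = (a * kb + b)[None, :] * ke + e_rows
    offsets = (np.arange(m) * ka * kb * ke)[:, None]
    counts = np.bincount(
        (code + offsets).ravel(), minlength=m * ka * kb * ke
    ).reshape(m, ka, kb, ke)
    p = counts / n
    p_e = p.sum(axis=(1, 2), keepdims=True)
    p_ae = p.sum(axis=2, keepdims=True)
    p_be = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p * p_e / (p_ae * p_be)
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, ratio, 1.0)), 0.0)
    return terms.sum(axis=(1, 2, 3))


def default_n_bins(n: int) -> int:
    return max(2, math.ceil(1 + math.log2(n)))


def interaction_information(
    a,
    b,
    e,
    n_bins: int | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """II = MI(A;B|E) - MI(A;B) with a permutation test for negativity.

    The null permutes E across samples, keeping the A-B dependence intact;
    the p-value is the +1-smoothed fraction of permutations with II* at
    least as negative as observed.  Returns ``(ii, p, flag)`` with flag set
    when II < 0 and p < 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    e = np.asarray(e, dtype=float)
    n = len(a)
    k = n_bins or default_n_bins(n)
    da = discretize_equal_frequency(a, k)
    db = discretize_equal_frequency(b, k)
    de = discretize_equal_frequency(e, k)
    mi_ab = _mi_bits(da, db)
    ii = _cmi_bits(da, db, de) - mi_ab
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, len(de))), axis=1)
    ii_star = _cmi_bits_many(da, db, de[idx]) - mi_ab
    exceed = int(np.sum(ii_star <= ii + 1e-12))
    p = (exceed + 1.0) / (n_perm + 1.0)
    return float(ii), float(p), bool(ii < 0 and p < 0.05)


def data_processing_inequality(a, b, e, n_bins: int | None = None) -> bool:
    """True when MI(A;B) <= min(MI(A;E), MI(B;E))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    e = np.asarray(e, dtype=float)
    k = n_bins or default_n_bins(len(a))
    da = discretize_equal_frequency(a, k)
    db = discretize_equal_frequency(b, k)
    de = discretize_equal_frequency(e, k)
    mi_ab = _mi_bits(da, db)
    return bool(mi_ab <= min(_mi_bits(da, de), _mi_bits(db, de)))


def remove_indirect(
    associations: pd.DataFrame,
    series: pd.DataFrame,
    env: pd.DataFrame,
    config: EndedConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove OTU-OTU edges flagged as environmentally driven.

    ``associations`` is the edge table entering the network stage;
    ``series`` the OTU abundance matrix (OTUs x months) and ``env`` the
    environmental table (months x variables) used for the information
    criteria.  Returns ``(filtered_associations, triplet_report)``; the
    report has one row per evaluated triplet with every score and flag.
    An edge with no triplet is retained unconditionally.
    """
    config = config or EndedConfig()
    triplets = enumerate_triplets(associations)
    n = series.shape[1]
    k = config.n_bins or default_n_bins(n)

    bin_cache: dict[str, np.ndarray | None] = {}

    def get_bins(name: str) -> np.ndarray | None:
        if name not in bin_cache:
            values = (
                series.loc[name].to_numpy(dtype=float)
                if name in series.index
                else env[name].to_numpy(dtype=float)
            )
            try:
                bin_cache[name] = discretize_equal_frequency(values, k)
            except ValueError:
                bin_cache[name] = None
        return bin_cache[name]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    env_perm_cache: dict[str, np.ndarray] = {}

    def get_env_perms(var: str, de: np.ndarray) -> np.ndarray:
        if var not in env_perm_cache:
            idx = np.argsort(rng.random((config.ii_n_perm, n)), axis=1)
            env_perm_cache[var] = de[idx]
        return env_perm_cache[var]

    sign_col = associations["sign"].to_dict()
    a_start = associations["a_start"].to_dict()
    a_end = associations["a_end"].to_dict()
    mi_cache: dict[tuple[str, str], float] = {}

    def mi_of(na: str, nb: str) -> float:
        key = (na, nb) if na <= nb else (nb, na)
        if key not in mi_cache:
            mi_cache[key] = _mi_bits(get_bins(na), get_bins(nb))
        return mi_cache[key]

    rows = []
    removed_idx: set[int] = set()
    for trip in triplets:
        sp = sign_pattern(
            sign_col[trip.edge_idx], sign_col[trip.ae_idx], sign_col[trip.be_idx]
        )
        overlap_pct, ov = interval_overlap(
            (a_start[trip.edge_idx], a_end[trip.edge_idx]),
            (a_start[trip.ae_idx], a_end[trip.ae_idx]),
            (a_start[trip.be_idx], a_end[trip.be_idx]),
            config.overlap_threshold_pct,
        )
        da = get_bins(trip.node_a)
        db = get_bins(trip.node_b)
        de = get_bins(trip.env_var)
        if da is None or db is None or de is None:
            ii, ii_p, ii_flag, dpi = float("nan"), float("nan"), False, False
        else:
            mi_ab = mi_of(trip.node_a, trip.node_b)
            ii = _cmi_bits(da, db, de) - mi_ab
            dpi = bool(
                mi_ab
                <= min(mi_of(trip.node_a, trip.env_var), mi_of(trip.node_b, trip.env_var))
            )
            # the permutation p is only needed where removal is still
            # possible: the other three criteria hold and II is negative
            if sp and ov and dpi and ii < 0:
                perms = get_env_perms(trip.env_var, de)
                ii_star = _cmi_bits_many(da, db, perms) - mi_ab
                exceed = int(np.sum(ii_star <= ii + 1e-12))
                ii_p = (exceed + 1.0) / (config.ii_n_perm + 1.0)
                ii_flag = bool(ii_p < config.ii_alpha)
            else:
                ii_p = float("nan")
                ii_flag = False
        removed = bool(sp and ov and ii_flag and dpi)
        if removed:
            removed_idx.add(trip.edge_idx)
        rows.append(
            {
                "node_a": trip.node_a,
                "node_b": trip.node_b,
                "env_var": trip.env_var,
                "sign_pattern": sp,
                "overlap_pct": overlap_pct,
                "overlap": ov,
                "ii": ii,
                "ii_p": ii_p,
                "ii_flag": ii_flag,
                "dpi": dpi,
                "removed": removed,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "node_a", "node_b", "env_var", "sign_pattern", "overlap_pct",
            "overlap", "ii", "ii_p", "ii_flag", "dpi", "removed",
        ],
    )
    filtered = associations.drop(index=sorted(removed_idx)).reset_index(drop=True)
    filtered.attrs.update(associations.attrs)
    report.attrs["summary"] = (
        f"edges evaluated {associations.shape[0]} / "
        f"flagged {len(removed_idx)} / removed {len(removed_idx)}"
    )
    return filtered, report
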