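"""Local similarity analysis (LSA) over monthly abundance and environmental
series.

The local similarity score between two normalized series x and y is the
maximal contiguous-subinterval sum of their elementwise products (optionally
with a bounded alignment delay), divided by the full series length n.  It is
computed by the classic dynamic program

    P(i,j) = max(0, P(i-1,j-1) + x_i * y_j)
    N(i,j) = max(0, N(i-1,j-1) - x_i * y_j)        |i - j| <= max_delay

with LS = max(P)/n when it exceeds max(N)/n and -max(N)/n otherwise.  The
theoretical p-value uses the asymptotic law of the maximal segment sum of a
mean-zero random walk: sqrt(n)|LS| converges to the supremum of |W(t)| on
[0,1] (by Levy's identity the running maximum of the reflected walk), whose
distribution has the classical theta-series CDF.  A mixed testing strategy
runs the seeded permutation test only for pairs whose theoretical p-value
passes a screening threshold; because a permutation p is floored at
1/(n_perm+1), a saturated permutation test (zero exceedances) is refined by
the theoretical tail so that stringent Bonferroni cut-offs (adjusted
p < 0.001 over many thousands of pairs) remain reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class LsaConfig:
    max_delay: int = 0
    n_perm: int = 1000
    screen_alpha: float = 0.05
    normalization: str = "rank_normal"  # rank_normal | median_mad | zscore
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if not 0.0 < self.screen_alpha < 1.0:
            raise ValueError("screen_alpha must lie in (0, 1)")
        if self.normalization not in ("median_mad", "zscore", "rank_normal"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def normalize_series(raw, method: str = "median_mad") -> np.ndarray:
    """Normalize one series: robust z-score (median/MAD), classical z-score
    (population SD), or rank-normal (ranks through the standard normal
    quantile function)."""
    x = np.asarray(raw, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if method == "median_mad":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            raise ValueError("zero dispersion (MAD) in series")
        return (x - med) / mad
    if method == "zscore":
        sd = x.std()
        if sd == 0:
            raise ValueError("zero dispersion (SD) in series")
        return (x - x.mean()) / sd
    if method == "rank_normal":
        ranks = sps.rankdata(x, method="average")
        return sps.norm.ppf(ranks / (x.size + 1.0))
    raise ValueError(f"unknown normalization {method!r}")


def _scan_best_segment(v: np.ndarray):
    """Kadane-style scan over rows of ``v`` (m, n): maximal segment sum with
    its interval; ties keep the earliest start (strict improvement only)."""
    v = np.atleast_2d(v)
    m, n = v.shape
    cur = np.zeros(m)
    cur_start = np.zeros(m, dtype=int)
    best = np.zeros(m)
    best_start = np.zeros(m, dtype=int)
    best_end = np.full(m, -1, dtype=int)
    for t in range(n):
        fresh = cur == 0.0
        cur_start = np.where(fresh, t, cur_start)
        cur = cur + v[:, t]
        np.maximum(cur, 0.0, out=cur)
        better = cur > best
        if better.any():
            best = np.where(better, cur, best)
            best_start = np.where(better, cur_start, best_start)
            best_end = np.where(better, t, best_end)
    return best, best_start, best_end


def _batch_ls_delay0(products: np.ndarray):
    """LS score, sign and interval per row of an (m, n) product matrix."""
    products = np.atleast_2d(products)
    n = products.shape[1]
    pos, ps, pe = _scan_best_segment(products)
    neg, ns, ne = _scan_best_segment(-products)
    take_pos = pos > neg
    ls = np.where(take_pos, pos, -neg) / n
    start = np.where(take_pos, ps, ns)
    end = np.where(take_pos, pe, ne)
    return ls, start, end


def local_similarity(x, y, max_delay: int = 0):
    """LS score of two equal-length normalized series with bounded delay.

    Returns ``(ls, delay, (a_start, a_end), (b_start, b_end))`` with 1-based
    inclusive month intervals; ``delay`` is the offset of y relative to x.
    The dynamic program decomposes into independent Kadane scans along each
    alignment diagonal; ties are broken toward smaller |delay|, then toward
    negative delay, then earlier start.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    n = x.size
    if max_delay < 0 or (n >= 2 and max_delay > n - 2):
        raise ValueError("max_delay must lie in [0, n-2]")
    best = None
    for ad in range(0, max_delay + 1):
        for d in ([0] if ad == 0 else [-ad, ad]):
            if d >= 0:
                prod = x[: n - d] * y[d:]
            else:
                prod = x[-d:] * y[: n + d]
            ls_arr, s_arr, e_arr = _batch_ls_delay0(prod[None, :])
            ls = ls_arr[0] * prod.size / n  # normalize by full length n
            s, e = int(s_arr[0]), int(e_arr[0])
            if best is None or abs(ls) > abs(best[0]):
                if d >= 0:
                    ia = (s + 1, e + 1)
                    ib = (s + d + 1, e + d + 1)
                else:
                    ia = (s - d + 1, e - d + 1)
                    ib = (s + 1, e + 1)
                best = (float(ls), d, ia, ib)
    return best


def _sup_abs_brownian_cdf(x: np.ndarray, terms: int = 64) -> np.ndarray:
    """P(sup_{0<=t<=1} |W(t)| <= x), theta-series form."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    positive = x > 0
    if positive.any():
        xs = x[positive]
        k = np.arange(terms)[:, None]
        series = (-1.0) ** k / (2 * k + 1) * np.exp(
            -((2 * k + 1) ** 2) * np.pi**2 / (8.0 * xs[None, :] ** 2)
        )
        out[positive] = np.clip((4.0 / np.pi) * series.sum(axis=0), 0.0, 1.0)
    return out


def theoretical_pvalue(ls, n: int, var: float = 1.0):
    """Upper-tail probability of the maximal-segment statistic sqrt(n)|LS|
    under independence.

    ``var`` is the variance of the elementwise product of the two normalized
    series (1 for z-scored series; larger for median/MAD scaling), used to
    bring the statistic onto the standard Brownian scale.
    """
    if n < 10:
        raise ValueError("asymptotic p-value needs n >= 10")
    ls = np.asarray(ls, dtype=float)
    x = np.sqrt(n) * np.abs(ls) / np.sqrt(var)
    p = 1.0 - _sup_abs_brownian_cdf(x)
    p = np.clip(p, 1e-300, 1.0)
    return float(p) if p.ndim == 0 else p


def _scan_max_abs_numpy(products: np.ndarray) -> np.ndarray:
    m, n = products.shape
    cur_p = np.zeros(m)
    cur_n = np.zeros(m)
    best = np.zeros(m)
    for t in range(n):
        col = products[:, t]
        cur_p += col
        np.maximum(cur_p, 0.0, out=cur_p)
        cur_n -= col
        np.maximum(cur_n, 0.0, out=cur_n)
        np.maximum(best, cur_p, out=best)
        np.maximum(best, cur_n, out=best)
    return best


try:  # optional JIT for the permutation-heavy inner loop
    from numba import njit

    @njit(cache=False)
    def _scan_max_abs_jit(products):  # pragma: no cover - thin JIT wrapper
        m, n = products.shape
        out = np.zeros(m)
        for i in range(m):
            cur_p = 0.0
            cur_n = 0.0
            best = 0.0
            for t in range(n):
                v = products[i, t]
                cur_p = max(cur_p + v, 0.0)
                cur_n = max(cur_n - v, 0.0)
                if cur_p > best:
                    best = cur_p
                if cur_n > best:
                    best = cur_n
            out[i] = best
        return out

    def _scan_max_abs(products: np.ndarray) -> np.ndarray:
        """Maximal |segment sum| per row, without interval tracking."""
        return _scan_max_abs_jit(np.ascontiguousarray(products))

    @njit(cache=False)
    def _perm_exceed_jit(xs, ys, perms, obs):  # pragma: no cover - JIT wrapper
        m = xs.shape[0]
        n_perm, n = perms.shape
        out = np.zeros(m, dtype=np.int64)
        for i in range(m):
            x = xs[i]
            y = ys[i]
            o = (obs[i] - 1e-12) * n
            c = 0
            for j in range(n_perm):
                cur_p = 0.0
                cur_n = 0.0
                best = 0.0
                for t in range(n):
                    v = x[t] * y[perms[j, t]]
                    cur_p = max(cur_p + v, 0.0)
                    cur_n = max(cur_n - v, 0.0)
                    if cur_p > best:
                        best = cur_p
                    if cur_n > best:
                        best = cur_n
                if best >= o:
                    c += 1
            out[i] = c
        return out

except ImportError:  # pragma: no cover - numba always present in CI image
    _scan_max_abs = _scan_max_abs_numpy
    _perm_exceed_jit = None


def _perm_abs_ls(x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator):
    """|LS*| for ``n_perm`` permutations of y (delay 0), vectorized."""
    n = x.size
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    return _scan_max_abs(x[None, :] * y[idx]) / n


def _batch_permutation_pvalues(
    xs: np.ndarray,
    ys: np.ndarray,
    obs_abs_ls: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 64,
) -> np.ndarray:
    """Permutation p-values for many pairs sharing one seeded set of
    permutations; ``xs``/``ys`` are (m, n) matrices of normalized series."""
    m, n = xs.shape
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    if _perm_exceed_jit is not None:
        exceed = _perm_exceed_jit(
            np.ascontiguousarray(xs), np.ascontiguousarray(ys), perms, obs_abs_ls
        )
        return (exceed + 1.0) / (n_perm + 1.0)
    out = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(m, lo + chunk)
        yp = ys[lo:hi][:, perms]  # (c, n_perm, n)
        products = (xs[lo:hi, None, :] * yp).reshape(-1, n)
        null = _scan_max_abs(products).reshape(hi - lo, n_perm) / n
        exceed = (null >= obs_abs_ls[lo:hi, None] - 1e-12).sum(axis=1)
        out[lo:hi] = (exceed + 1.0) / (n_perm + 1.0)
    return out


def permutation_pvalue(
    x, y, n_perm: int = 1000, seed: int = 0, max_delay: int = 0
) -> float:
    """Seeded permutation p-value: p = (1 + #{|LS*| >= |LS|}) / (n_perm + 1)."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if max_delay == 0:
        obs = abs(local_similarity(x, y, 0)[0])
        null = _perm_abs_ls(x, y, n_perm, rng)
        exceed = int(np.sum(null >= obs - 1e-12))
    else:
        obs = abs(local_similarity(x, y, max_delay)[0])
        exceed = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            if abs(local_similarity(x, yp, max_delay)[0]) >= obs - 1e-12:
                exceed += 1
    return (exceed + 1.0) / (n_perm + 1.0)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties (NaN if a
    series is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def mixed_pvalue(x, y, config: LsaConfig | None = None) -> float:
    """Mixed-strategy p-value for one raw pair: normalize, score, screen on
    the theoretical tail, and refine by permutation when screened."""
    config = config or LsaConfig()
    nx_ = normalize_series(x, config.normalization)
    ny = normalize_series(y, config.normalization)
    ls, _, _, _ = local_similarity(nx_, ny, config.max_delay)
    var = float(nx_.var() * ny.var())
    p_theory = theoretical_pvalue(ls, len(nx_), var=var)
    if p_theory >= config.screen_alpha:
        return p_theory
    pp = permutation_pvalue(nx_, ny, config.n_perm, seed=config.seed, max_delay=config.max_delay)
    floor = 1.0 / (config.n_perm + 1.0)
    if pp <= floor + 1e-15:
        return min(p_theory, floor)
    return pp


def build_association_table(
    series: pd.DataFrame,
    env: pd.DataFrame | None = None,
    config: LsaConfig | None = None,
) -> pd.DataFrame:
    """Score every OTU-OTU and OTU-environment pair.

    ``series`` holds OTU abundance series (rows = OTUs, columns = months);
    ``env`` holds environmental variables (rows = months, columns =
    variables).  Series that cannot be normalized under the configured
    scheme (zero dispersion) are dropped with a note in the table attrs.
    Returns a DataFrame with one row per evaluated pair, sorted by node ids,
    carrying LS score, delay, aligned intervals (1-based inclusive),
    theoretical/permutation/mixed p-values, Bonferroni q and Spearman rho.
    """
    config = config or LsaConfig()
    months = series.columns
    raw: dict[str, np.ndarray] = {
        str(otu): series.loc[otu].to_numpy(dtype=float) for otu in series.index
    }
    kinds = {name: "otu" for name in raw}
    if env is not None:
        env_aligned = env.loc[months] if len(env.index.intersection(months)) == len(months) else env
        for var in env_aligned.columns:
            raw[str(var)] = env_aligned[var].to_numpy(dtype=float)
            kinds[str(var)] = "env"

    normalized: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, values in raw.items():
        try:
            normalized[name] = normalize_series(values, config.normalization)
        except ValueError:
            dropped.append(name)
    names = sorted(normalized)
    n = len(months)

    pairs = [
        (a, b)
        for i, a in enumerate(names)
        for b in names[i + 1 :]
        if not (kinds[a] == "env" and kinds[b] == "env")
    ]
    n_tests = len(pairs)
    if n_tests == 0:
        return pd.DataFrame(
            columns=[
                "node_a", "node_b", "kind_a", "kind_b", "ls", "sign", "delay",
                "a_start", "a_end", "b_start", "b_end",
                "p_theory", "p_perm", "p", "q", "spearman",
            ]
        )

    variances = {name: float(normalized[name].var()) for name in names}
    rank_matrix = np.vstack(
        [sps.rankdata(raw[name], method="average") for name in names]
    )
    rank_corr = np.corrcoef(rank_matrix)
    name_pos = {name: i for i, name in enumerate(names)}

    if config.max_delay == 0:
        products = np.vstack([normalized[a] * normalized[b] for a, b in pairs])
        ls, start, end = _batch_ls_delay0(products)
        delays = np.zeros(n_tests, dtype=int)
        a_start, a_end = start + 1, end + 1
        b_start, b_end = a_start.copy(), a_end.copy()
    else:
        ls = np.empty(n_tests)
        delays = np.empty(n_tests, dtype=int)
        a_start = np.empty(n_tests, dtype=int)
        a_end = np.empty(n_tests, dtype=int)
        b_start = np.empty(n_tests, dtype=int)
        b_end = np.empty(n_tests, dtype=int)
        for i, (a, b) in enumerate(pairs):
            s, d, ia, ib = local_similarity(normalized[a], normalized[b], config.max_delay)
            ls[i], delays[i] = s, d
            a_start[i], a_end[i] = ia
            b_start[i], b_end[i] = ib

    pair_var = np.array([variances[a] * variances[b] for a, b in pairs])
    p_theory = np.clip(
        1.0 - _sup_abs_brownian_cdf(np.sqrt(n) * np.abs(ls) / np.sqrt(pair_var)),
        1e-300,
        1.0,
    )

    p_perm = np.full(n_tests, np.nan)
    p_mixed = p_theory.copy()
    floor = 1.0 / (config.n_perm + 1.0)
    screened = np.flatnonzero(p_theory < config.screen_alpha)
    if screened.size:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        if config.max_delay == 0:
            xs = np.vstack([normalized[pairs[i][0]] for i in screened])
            ys = np.vstack([normalized[pairs[i][1]] for i in screened])
            pp = _batch_permutation_pvalues(
                xs, ys, np.abs(ls[screened]), config.n_perm, rng
            )
        else:
            pp = np.array(
                [
                    permutation_pvalue(
                        normalized[pairs[i][0]],
                        normalized[pairs[i][1]],
                        config.n_perm,
                        seed=int(rng.integers(2**31)),
                        max_delay=config.max_delay,
                    )
                    for i in screened
                ]
            )
        p_perm[screened] = pp
        saturated = pp <= floor + 1e-15
        # saturated permutation test: theoretical tail refines below the
        # permutation resolution so stringent Bonferroni cuts stay reachable
        p_mixed[screened] = np.where(
            saturated, np.minimum(p_theory[screened], floor), pp
        )

    q = np.minimum(1.0, p_mixed * n_tests)
    spearman = np.array([rank_corr[name_pos[a], name_pos[b]] for a, b in pairs])

    out = pd.DataFrame(
        {
            "node_a": [a for a, _ in pairs],
            "node_b": [b for _, b in pairs],
            "kind_a": [kinds[a] for a, _ in pairs],
            "kind_b": [kinds[b] for _, b in pairs],
            "ls": ls,
            "sign": np.where(ls >= 0, 1, -1),
            "delay": delays,
            "a_start": a_start,
            "a_end": a_end,
            "b_start": b_start,
            "b_end": b_end,
            "p_theory": p_theory,
            "p_perm": p_perm,
            "p": p_mixed,
            "q": q,
            "spearman": spearman,
        }
    )
    out = out.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_tests"] = n_tests
    out.attrs["dropped_series"] = dropped
    return out
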