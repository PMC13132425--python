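"""MIC association screening with FDR control and forward selection.

The maximal information coefficient (MIC) is the largest normalized
mutual information achievable by any grid drawn over the scatter of
(x, y), among grids whose cell budget ``x_bins * y_bins`` does not
exceed ``n**alpha_exponent``. It detects general — in particular
nonlinear — association and lies in [0, 1]. The implementation follows
the MINE approximation: for each number of rows the y-axis is
equipartitioned, the x-axis partition is then optimized exactly by
dynamic programming over "clumps" (runs of x-adjacent points sharing a
row), with the clump count capped at ``max_clumps`` times the column
budget; both orientations of the data are searched and the best
normalized cell wins.

Screening attaches permutation p-values to each feature's MIC and
adjusts them two ways: the Benjamini-Hochberg step-up (valid under
independence) and a dependency-penalized variant that multiplies the BH
values by the harmonic sum c(m) = sum_{i<=m} 1/i (the classical
arbitrary-dependency correction), here called M-FDR. Forward selection
then admits features in descending-MIC order among the M-FDR
significant set, retaining each only while its coefficient in a working
regression-with-ARMA-errors model stays significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core_data import FEATURE_KEYS, TimeSeriesDataset

__all__ = [
    "mic",
    "mic_pvalue",
    "adjust_bh",
    "adjust_mfdr",
    "screen_features",
    "forward_select",
    "ScreenResult",
]


# --------------------------------------------------------------------------
# MINE kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _equipartition(b_sorted: np.ndarray, q: int) -> np.ndarray:
    """Assign ~n/q points per row over sorted values, never splitting ties."""
    n = b_sorted.shape[0]
    rows = np.empty(n, np.int64)
    i = 0
    row = 0
    size = 0
    desired = n / q
    while i < n:
        j = i + 1
        while j < n and b_sorted[j] == b_sorted[i]:
            j += 1
        s = j - i
        if size > 0 and row < q - 1 and abs(size + s - desired) >= abs(size - desired):
            row += 1
            size = 0
            desired = (n - i) / (q - row)
        for k in range(i, j):
            rows[k] = row
        size += s
        i = j
    return rows


@njit(cache=True)
def _optimize_axis(rows_a: np.ndarray, tie_a: np.ndarray, q: int, kmax: int,
                   max_clumps: int) -> np.ndarray:
    """Best mutual information per column count.

    ``rows_a``: row id of each point in x-sorted order; ``tie_a``:
    tie-group id of each point (nondecreasing). Returns I[l] for
    l = 0..kmax where I[l] (l >= 2) is the maximum of I(P;Q) over
    x-partitions into at most l columns respecting clump boundaries.
    """
    n = rows_a.shape[0]

    # ---- clumps: maximal x-runs within a single row; mixed tie groups
    # (same x, several rows) always form their own clump
    clump_end = np.empty(n, np.int64)
    m = 0
    prev_pure = -2          # -2 none, -1 mixed, >=0 row id of previous pure clump
    i = 0
    while i < n:
        j = i + 1
        while j < n and tie_a[j] == tie_a[i]:
            j += 1
        r0 = rows_a[i]
        pure = True
        for k in range(i + 1, j):
            if rows_a[k] != r0:
                pure = False
                break
        if pure and prev_pure == r0 and m > 0:
            clump_end[m - 1] = j
        else:
            clump_end[m] = j
            m += 1
            prev_pure = r0 if pure else -1
        i = j

    # ---- superclumps: cap partition atoms at max_clumps * kmax
    k_hat = max_clumps * kmax
    if m > k_hat:
        new_end = np.empty(k_hat, np.int64)
        new_m = 0
        for ci in range(m):
            if clump_end[ci] >= (new_m + 1) * n / k_hat or ci == m - 1:
                if new_m < k_hat:
                    new_end[new_m] = clump_end[ci]
                    new_m += 1
                else:
                    new_end[new_m - 1] = clump_end[ci]
        clump_end = new_end[:new_m]
        m = new_m

    # ---- cumulative row counts at clump boundaries
    cum = np.zeros((m + 1, q), np.float64)
    npts = np.zeros(m + 1, np.int64)
    start = 0
    for t in range(1, m + 1):
        for r in range(q):
            cum[t, r] = cum[t - 1, r]
        for p in range(start, clump_end[t - 1]):
            cum[t, rows_a[p]] += 1.0
        npts[t] = clump_end[t - 1]
        start = clump_end[t - 1]

    # ---- column costs: cost[s, t] = (#points in (s,t]) * H(rows | column)
    cost = np.empty((m + 1, m + 1), np.float64)
    for s in range(m):
        for t in range(s + 1, m + 1):
            cnt_all = npts[t] - npts[s]
            h = cnt_all * np.log(cnt_all)
            for r in range(q):
                cr = cum[t, r] - cum[s, r]
                if cr > 0.0:
                    h -= cr * np.log(cr)
            cost[s, t] = h

    # ---- DP over number of columns
    kk = min(kmax, m)
    G = np.full((m + 1, kk + 1), np.inf)
    for t in range(1, m + 1):
        G[t, 1] = cost[0, t]
    for l in range(2, kk + 1):
        for t in range(l, m + 1):
            best = np.inf
            for s in range(l - 1, t):
                v = G[s, l - 1] + cost[s, t]
                if v < best:
                    best = v
            G[t, l] = best

    # entropy of the full row distribution
    hq = 0.0
    for r in range(q):
        if cum[m, r] > 0.0:
            hq -= (cum[m, r] / n) * np.log(cum[m, r] / n)

    out = np.zeros(kmax + 1, np.float64)
    run = 0.0
    for l in range(2, kmax + 1):
        if l <= kk and np.isfinite(G[m, l]):
            v = hq - G[m, l] / n
            if v > run:
                run = v
        out[l] = run
    return out


def _tie_groups(sorted_vals: np.ndarray) -> np.ndarray:
    g = np.empty(len(sorted_vals), np.int64)
    g[0] = 0
    g[1:] = np.cumsum(sorted_vals[1:] != sorted_vals[:-1])
    return g


def mic(x, y, alpha_exponent: float = 0.6, max_clumps: int = 15) -> float:
    """Maximal information coefficient of two equal-length vectors.

    Parameters follow the canonical MINE defaults: grid budget
    ``n**alpha_exponent`` and clump factor 15. Symmetric in (x, y);
    returns a value in [0, 1]. A constant input carries no information:
    returns 0.0 with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("MIC requires at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("MIC inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant input vector: MIC is 0 by convention", stacklevel=2)
        return 0.0

    B = max(n ** alpha_exponent, 4.0)
    best = 0.0
    for a, b in ((x, y), (y, x)):
        aidx = np.argsort(a, kind="mergesort")
        bidx = np.argsort(b, kind="mergesort")
        a_sorted = a[aidx]
        b_sorted = b[bidx]
        tie_a = _tie_groups(a_sorted)
        rows_pt = np.empty(n, np.int64)
        for q in range(2, int(B // 2) + 1):
            rows_sorted = _equipartition(b_sorted, q)
            q_eff = int(rows_sorted[-1]) + 1
            if q_eff < 2:
                continue
            kmax = int(B // q_eff)
            if kmax < 2:
                continue
            rows_pt[bidx] = rows_sorted
            rows_a = rows_pt[aidx]
            I = _optimize_axis(rows_a, tie_a, q_eff, kmax, max_clumps)
            for l in range(2, kmax + 1):
                v = I[l] / np.log(min(l, q_eff))
                if v > best:
                    best = v
    return float(min(best, 1.0))


def mic_pvalue(mic_obs: float, x, y, n_permutations: int = 999,
               seed: int | np.random.Generator = 0,
               alpha_exponent: float = 0.6, max_clumps: int = 15) -> float:
    """Permutation p-value for an observed MIC.

    p = (1 + #{MIC(x, permuted y) >= mic_obs}) / (n_permutations + 1),
    permuting y with a seeded generator; deterministic given the seed.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            if mic(x, perm, alpha_exponent, max_clumps) >= mic_obs:
                hits += 1
    return (1 + hits) / (n_permutations + 1)


# --------------------------------------------------------------------------
# FDR adjustments
# --------------------------------------------------------------------------

def _step_up(p: np.ndarray, penalty: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    adj = penalty * m * ranked / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (independent tests)."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return _step_up(p, 1.0)


def adjust_mfdr(p) -> np.ndarray:
    """Dependency-penalized step-up adjustment (M-FDR).

    BH multiplied by the harmonic sum c(m) = sum_{i=1..m} 1/i, valid
    under arbitrary dependence among the tests; never smaller than the
    BH adjustment.
    """
    p = np.asarray(p, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    c_m = np.sum(1.0 / np.arange(1, len(p) + 1))
    return _step_up(p, c_m)


# --------------------------------------------------------------------------
# Screening + forward selection
# --------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-feature MIC, raw and adjusted p-values, and selection flags."""

    table: pd.DataFrame
    alpha: float = 0.05
    alpha_exponent: float = 0.6
    max_clumps: int = 15
    n_permutations: int = 999

    def __post_init__(self) -> None:
        t = self.table
        if np.any((t["mic"] < 0) | (t["mic"] > 1)):
            raise ValueError("MIC values must lie in [0, 1]")
        if np.any(t["bh_adj_p"] + 1e-12 < t["raw_p"]) or np.any(
            t["mfdr_adj_p"] + 1e-12 < t["bh_adj_p"]
        ):
            raise ValueError("adjusted p-values must dominate: raw <= BH <= M-FDR")

    @property
    def significant_mfdr(self) -> list[str]:
        t = self.table
        return list(t.loc[t["mfdr_adj_p"] < self.alpha, "feature"])

    @property
    def significant_bh(self) -> list[str]:
        t = self.table
        return list(t.loc[t["bh_adj_p"] < self.alpha, "feature"])


def screen_features(
    ds: TimeSeriesDataset,
    alpha: float = 0.05,
    alpha_exponent: float = 0.6,
    max_clumps: int = 15,
    n_permutations: int = 999,
    seed: int = 0,
) -> ScreenResult:
    """MIC-screen all 17 features against the arrival counts.

    Returns a table shaped like a feature-characteristics report:
    feature key, MIC, raw permutation p, BH- and M-FDR-adjusted p, and
    significance flags at ``alpha``.
    """
    y = ds.arrivals
    feats = ds.features()
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(FEATURE_KEYS))
    for key, child in zip(FEATURE_KEYS, ss):
        x = feats[key].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mic(x, y, alpha_exponent, max_clumps)
        p = mic_pvalue(
            m, x, y, n_permutations, np.random.default_rng(child),
            alpha_exponent, max_clumps,
        )
        rows.append({"feature": key, "mic": m, "raw_p": p})
    table = pd.DataFrame(rows)
    table["bh_adj_p"] = adjust_bh(table["raw_p"].to_numpy())
    table["mfdr_adj_p"] = adjust_mfdr(table["raw_p"].to_numpy())
    table["selected_bh"] = table["bh_adj_p"] < alpha
    table["selected_mfdr"] = table["mfdr_adj_p"] < alpha
    return ScreenResult(
        table, alpha=alpha, alpha_exponent=alpha_exponent,
        max_clumps=max_clumps, n_permutations=n_permutations,
    )


def forward_select(
    ds: TimeSeriesDataset,
    screen: ScreenResult,
    alpha: float = 0.05,
    base_order: tuple[int, int, int] = (1, 1, 2),
) -> list[str]:
    """MIC-ordered forward selection against a working ARIMAX.

    Candidates are the M-FDR-significant features in descending-MIC
    order (ties broken by feature index). Each is added to the working
    regression-with-ARMA-errors model and retained only if its Wald
    p-value stays below ``alpha``.
    """
    from .linear_models import ArimaxSpec, fit_arimax

    t = screen.table
    cand = t.loc[t["mfdr_adj_p"] < alpha].copy()
    if cand.empty:
        warnings.warn("no M-FDR-significant candidates: empty selection", stacklevel=2)
        return []
    cand["idx"] = cand["feature"].str.lstrip("X").astype(int)
    cand = cand.sort_values(["mic", "idx"], ascending=[False, True])

    retained: list[str] = []
    for key in cand["feature"]:
        trial = retained + [key]
        try:
            fit = fit_arimax(ds, ArimaxSpec(*base_order, exog_keys=tuple(trial)))
        except Exception:
            continue
        pvals = fit.exog_pvalues
        if all(pvals[k] < alpha for k in trial):
            retained = trial
    return retained
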