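"""Pointwise statistics and nonparametric cluster-based permutation tests.

Maps over channel x frequency x time are tested pointwise (paired t between
valence conditions, or Pearson r between per-subject power differences and
a behavioral covariate) and corrected for multiple comparisons by the
cluster-mass permutation procedure: suprathreshold points are grouped into
connected clusters (neighbouring channels at the same frequency/time bin,
or adjacent frequency/time bins at the same channel, same sign), each
cluster's mass is the sum of its member statistics, and observed masses are
compared per tail against the Monte Carlo distribution of the maximal
cluster mass under random within-subject condition swaps (equivalently sign
flips of the differences) or random covariate re-pairings.

Positive and negative tails are tested separately, each at alpha (default
0.025).  Cluster-forming thresholds are either parametric critical values
or per-point quantiles of the same permutation distribution
("nonparametric-individual", the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterResult",
    "paired_t_map",
    "correlation_map",
    "forming_threshold",
    "find_clusters",
    "cluster_permutation",
]


@dataclass
class StatMap:
    """Pointwise statistic over channels x frequencies x times."""

    values: np.ndarray = field(repr=False)
    kind: str  # "paired_t" | "pearson_r"
    n: int
    channels: tuple | None = None
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None

    @property
    def df(self) -> int:
        return self.n - 1 if self.kind == "paired_t" else self.n - 2


@dataclass
class Cluster:
    """One suprathreshold cluster: member points, tail and mass."""

    members: np.ndarray  # (k, 3) int indices into (channel, freq, time)
    sign: int
    mass: float
    p: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    clusters: list
    null_max_pos: np.ndarray = field(repr=False)
    null_max_neg: np.ndarray = field(repr=False)
    stat_map: StatMap = field(repr=False)
    n_permutations: int = 0
    alpha: float = 0.025
    threshold_mode: str = "nonparametric_individual"
    seed: int | None = None

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float | None = None) -> list:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p is not None and c.p <= a]


# ---------------------------------------------------------------------------
# pointwise statistics


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray, channels=None,
                 freqs=None, times=None) -> StatMap:
    """Pointwise paired t over subjects: t = mean(d) / (sd(d)/sqrt(n)).

    Inputs are subject-stacked maps (n_subjects, channels, freqs, times)
    with the same subjects in the same order.  Points with zero variance of
    the difference come back NaN (flagged, not an error).
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition stacks must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return StatMap(t, "paired_t", n, channels, freqs, times)


def correlation_map(diff_maps: np.ndarray, covariate: np.ndarray,
                    channels=None, freqs=None, times=None) -> StatMap:
    """Pointwise Pearson r between per-subject differences and a covariate."""
    d = np.asarray(diff_maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 subjects")
    if cov.shape != (n,):
        raise ValueError("covariate must be one scalar per subject")
    if np.std(cov) == 0:
        raise ValueError("covariate has zero variance")
    zc = (cov - cov.mean()) / cov.std(ddof=1)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zd = (d - d.mean(axis=0)) / sd
        r = np.tensordot(zc, zd, axes=(0, 0)) / (n - 1)
    r[sd == 0] = np.nan
    return StatMap(r, "pearson_r", n, channels, freqs, times)


# ---------------------------------------------------------------------------
# thresholds


def forming_threshold(null_samples=None, mode: str = "nonparametric_individual",
                      alpha: float = 0.025, kind: str = "paired_t",
                      n: int | None = None):
    """Two-sided cluster-forming thresholds (lower, upper).

    parametric
        Student-t critical values at ``alpha`` per tail (for Pearson r the
        t critical value is mapped back to the r scale, df = n - 2).
    nonparametric_individual
        per-point alpha and 1-alpha empirical quantiles of each point's own
        permutation distribution (``null_samples`` of shape
        (n_permutations, ...points)).
    """
    if mode == "parametric":
        if n is None:
            raise ValueError("parametric thresholds need the sample size n")
        if kind == "paired_t":
            crit = stats.t.ppf(1.0 - alpha, df=n - 1)
        elif kind == "pearson_r":
            tcrit = stats.t.ppf(1.0 - alpha, df=n - 2)
            crit = tcrit / np.sqrt(n - 2 + tcrit ** 2)
        else:
            raise ValueError(f"unknown statistic kind {kind!r}")
        return -crit, crit
    if mode != "nonparametric_individual":
        raise ValueError(f"unknown threshold mode {mode!r}")
    if null_samples is None:
        raise ValueError("nonparametric thresholds need permutation samples")
    null_samples = np.asarray(null_samples, dtype=float)
    n_perm = null_samples.shape[0]
    if n_perm * alpha < 1.0:
        raise ValueError(
            f"{n_perm} permutations cannot resolve the {alpha} quantile")
    lo = np.quantile(null_samples, alpha, axis=0)
    hi = np.quantile(null_samples, 1.0 - alpha, axis=0)
    if np.any(lo == hi):
        warnings.warn("degenerate forming threshold at some points "
                      "(identical permutation samples)", RuntimeWarning)
    return lo, hi


# ---------------------------------------------------------------------------
# connected components over channel x frequency x time


def _grid_neighbour_lists(shape, adjacency: np.ndarray) -> list:
    """Neighbour lists for every point of a (C, F, T) grid.

    Connectivity: channel neighbours at the same (f, t), adjacent frequency
    bins at the same (c, t), adjacent time bins at the same (c, f).
    """
    n_ch, n_f, n_t = shape
    ch_nbrs = [np.flatnonzero(adjacency[c]) for c in range(n_ch)]
    nbrs = []
    for c in range(n_ch):
        base_ch = ch_nbrs[c] * (n_f * n_t)
        for f in range(n_f):
            for t in range(n_t):
                flat = []
                if t > 0:
                    flat.append((c * n_f + f) * n_t + t - 1)
                if t < n_t - 1:
                    flat.append((c * n_f + f) * n_t + t + 1)
                if f > 0:
                    flat.append((c * n_f + f - 1) * n_t + t)
                if f < n_f - 1:
                    flat.append((c * n_f + f + 1) * n_t + t)
                nbrs.append(np.concatenate([
                    np.asarray(flat, dtype=np.int64),
                    base_ch + (f * n_t + t)]))
    return nbrs


def _components(signed: np.ndarray, nbrs: list, values: np.ndarray | None = None):
    """Connected components of a flat signed mask; yields (member ids, sign, mass)."""
    visited = np.zeros(signed.shape[0], dtype=bool)
    out = []
    for p in np.flatnonzero(signed):
        if visited[p]:
            continue
        sign = signed[p]
        visited[p] = True
        stack = [p]
        comp = []
        while stack:
            q = stack.pop()
            comp.append(q)
            cand = nbrs[q]
            sel = cand[(~visited[cand]) & (signed[cand] == sign)]
            visited[sel] = True
            stack.extend(sel.tolist())
        comp = np.asarray(comp, dtype=np.int64)
        mass = float(values[comp].sum()) if values is not None else float(sign) * len(comp)
        out.append((comp, int(sign), mass))
    return out


def find_clusters(mask_signed: np.ndarray, adjacency: np.ndarray,
                  stat: np.ndarray | None = None) -> list:
    """Connected same-sign clusters of a signed suprathreshold mask.

    ``mask_signed`` is a (channels, freqs, times) array in {-1, 0, +1};
    ``stat`` (same shape) provides the member statistics summed into each
    cluster's mass (defaults to signed extent).
    """
    mask_signed = np.asarray(mask_signed)
    shape = mask_signed.shape
    nbrs = _grid_neighbour_lists(shape, adjacency)
    values = None if stat is None else np.asarray(stat, dtype=float).ravel()
    comps = _components(mask_signed.ravel().astype(np.int8), nbrs, values)
    return [Cluster(np.array(np.unravel_index(ids, shape)).T, sign, mass)
            for ids, sign, mass in comps]


# ---------------------------------------------------------------------------
# the permutation test


def _signed_mask(values: np.ndarray, lo, hi) -> np.ndarray:
    signed = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        signed[values > hi] = 1
        signed[values < lo] = -1
    return signed


def cluster_permutation(data, design: str = "paired", n_perm: int = 2000,
                        alpha: float = 0.025,
                        threshold_mode: str = "nonparametric_individual",
                        seed: int = 0, adjacency: np.ndarray | None = None,
                        channels=None, freqs=None, times=None) -> ClusterResult:
    """Monte Carlo cluster-mass permutation test.

    Parameters
    ----------
    data
        design="paired": a tuple ``(cond_a, cond_b)`` of subject-stacked
        maps (n_subjects, channels, freqs, times); the null is generated by
        random within-subject condition swaps (sign flips of the
        differences).
        design="covariate": a tuple ``(diff_maps, covariate)``; the null is
        generated by random re-pairing of the covariate with the subjects.
    n_perm, alpha
        Monte Carlo randomizations (default 2000) and per-tail cluster
        alpha (default 0.025); the smallest attainable p is 1/(n_perm + 1).

    Points that are undefined (NaN, e.g. epoch-edge bins) or have zero
    variance are excluded from clustering entirely.
    """
    if n_perm < 1.0 / alpha:
        raise ValueError("too few permutations for the requested alpha")
    if adjacency is None:
        raise ValueError("channel adjacency is required")
    rng = np.random.default_rng(seed)

    if design == "paired":
        a, b = data
        stat_map = paired_t_map(a, b, channels, freqs, times)
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    elif design == "covariate":
        d, cov = data
        d = np.asarray(d, dtype=float)
        stat_map = correlation_map(d, cov, channels, freqs, times)
    else:
        raise ValueError(f"unknown design {design!r}")

    shape = stat_map.values.shape
    n = d.shape[0]
    flat_stat = stat_map.values.reshape(-1)
    defined = np.isfinite(flat_stat) & ~np.isnan(d.reshape(n, -1)).any(axis=0)
    dflat = d.reshape(n, -1)[:, defined]

    # permutation statistic maps, vectorized over permutations
    if design == "paired":
        signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
        mean_p = signs @ dflat / n
        ss = (dflat ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_p = (ss - n * mean_p ** 2) / (n - 1)
            var_p = np.clip(var_p, 0.0, None)
            perm_stats = mean_p / np.sqrt(var_p / n)
    else:
        cov = np.asarray(data[1], dtype=float)
        zc = (cov - cov.mean()) / cov.std(ddof=1)
        sd = dflat.std(axis=0, ddof=1)
        zd = (dflat - dflat.mean(axis=0)) / sd
        perms = np.stack([zc[rng.permutation(n)] for _ in range(n_perm)])
        perm_stats = perms @ zd / (n - 1)
    perm_stats[~np.isfinite(perm_stats)] = 0.0

    if threshold_mode == "parametric":
        lo, hi = forming_threshold(mode="parametric", alpha=alpha,
                                   kind=stat_map.kind, n=n)
        lo = np.full(defined.sum(), lo)
        hi = np.full(defined.sum(), hi)
    else:
        lo, hi = forming_threshold(perm_stats, mode=threshold_mode, alpha=alpha)

    # neighbour lists on the full grid, restricted to defined points
    nbrs_full = _grid_neighbour_lists(shape, adjacency)
    full_id = np.flatnonzero(defined)
    compact = np.full(defined.shape[0], -1, dtype=np.int64)
    compact[full_id] = np.arange(full_id.size)
    nbrs = []
    for fid in full_id:
        cand = compact[nbrs_full[fid]]
        nbrs.append(cand[cand >= 0])

    # observed clusters
    obs = flat_stat[defined]
    comps = _components(_signed_mask(obs, lo, hi), nbrs, obs)

    # null distribution of the maximal cluster mass, per tail
    null_max_pos = np.zeros(n_perm)
    null_max_neg = np.zeros(n_perm)
    for i in range(n_perm):
        row = perm_stats[i]
        pcomps = _components(_signed_mask(row, lo, hi), nbrs, row)
        for _, sign, mass in pcomps:
            if sign > 0:
                null_max_pos[i] = max(null_max_pos[i], mass)
            else:
                null_max_neg[i] = min(null_max_neg[i], mass)

    clusters = []
    for ids, sign, mass in comps:
        if sign > 0:
            p = (1.0 + np.sum(null_max_pos >= mass)) / (n_perm + 1.0)
        else:
            p = (1.0 + np.sum(null_max_neg <= mass)) / (n_perm + 1.0)
        members = np.array(np.unravel_index(full_id[ids], shape)).T
        clusters.append(Cluster(members, sign, mass, p=float(p)))
    clusters.sort(key=lambda c: (c.p, -abs(c.mass)))

    return ClusterResult(clusters, null_max_pos, null_max_neg, stat_map,
                         n_permutations=n_perm, alpha=alpha,
                         threshold_mode=threshold_mode, seed=seed)
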