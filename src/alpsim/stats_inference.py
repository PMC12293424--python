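"""Nonparametric repeated-measures inference for the ALPS time series.

With nine subjects and seven time points, normality cannot be defended, so
the analysis is rank-based throughout: a Friedman test per ROI pair screens
for any effect of time; paired Wilcoxon signed-rank tests compare each sleep
time point against the awake baseline; the six post hoc p-values per pair
are Benjamini-Hochberg adjusted (the multiplicity family is the six
sleep-vs-awake comparisons within one pair); effect sizes are Wilcoxon's
r = |z| / sqrt(n).

ROI selection keeps pairs whose Friedman test is significant AND whose index
elevation at the peak time point is at least partly carried by an increase of
the x-direction (perivascular) diffusivity — an index rise driven purely by a
drop of the perpendicular diffusivities is not accepted as perivascular.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alps_core import AlpsSeries, DiffusivityQuad, decompose_components

__all__ = [
    "friedman_test",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "bh_adjust",
    "select_significant_rois",
    "run_full_analysis",
    "StatsReport",
]


def friedman_test(
    matrix,
    method: str = "chi2",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple:
    """Friedman test for k repeated measures on n subjects.

    ``matrix`` is subjects x time points, no missing cells (series with gaps
    are excluded upstream rather than imputed).  Within-subject ranks use
    midranks for ties; the statistic is the tie-corrected

        T = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A - C),

    with A the sum of squared ranks and C = n k (k+1)^2 / 4, which reduces to
    the classic 12/(nk(k+1)) form without ties.  p-values come from the
    chi-squared approximation with k-1 df (``method="chi2"``), from seeded
    within-subject permutations (``"permutation"``), or from exhaustive
    enumeration of all (k!)^n rank assignments (``"exact"``, tiny cases only).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported; drop the subject")
    n, k = x.shape

    def statistic(data):
        ranks = np.apply_along_axis(sps.rankdata, 1, data)
        col_sums = ranks.sum(axis=0)
        a = np.sum(ranks**2)
        c = n * k * (k + 1) ** 2 / 4.0
        if a == c:  # all within-subject ranks tied everywhere
            return 0.0
        return (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2) / (a - c)

    t_obs = statistic(x)
    if t_obs == 0.0 and np.all(x == x[:, :1]):
        return 0.0, 1.0
    if method == "chi2":
        p = float(sps.chi2.sf(t_obs, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = x[np.arange(n)[:, None], np.argsort(rng.random((n, k)), axis=1)]
            if statistic(perm) >= t_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    elif method == "exact":
        if math.factorial(k) ** n > 500000:
            raise ValueError("exact enumeration infeasible at this size")
        count = total = 0
        perms = list(itertools.permutations(range(k)))
        for assignment in itertools.product(perms, repeat=n):
            perm = np.stack([x[i, list(pi)] for i, pi in enumerate(assignment)])
            total += 1
            if statistic(perm) >= t_obs - 1e-12:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(t_obs), float(min(p, 1.0))


@dataclass
class WilcoxonResult:
    w: float  # sum of positive ranks
    p: float  # two-sided
    r: float  # effect size |z|/sqrt(n), signed by the median difference
    z: float
    n: int  # pairs after dropping zero differences
    method: str


def wilcoxon_signed_rank(
    awake, sleep_t, exact_max_n: int = 15
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test of sleep vs awake.

    Differences are sleep - awake; zero differences are dropped.  For
    n <= ``exact_max_n`` the two-sided p is exact, from enumeration of all
    2^n sign assignments of the (midrank-tied) ranks:
    p = min(1, 2 * min(P(W <= w), P(W >= w))).  Larger n uses the normal
    approximation with tie and continuity corrections.

    The effect size is Wilcoxon's r = |z| / sqrt(n), signed by the median
    difference; on the exact path z is the normal equivalent of the exact p.
    """
    awake = np.asarray(awake, dtype=float)
    sleep_t = np.asarray(sleep_t, dtype=float)
    if awake.shape != sleep_t.shape or awake.ndim != 1:
        raise ValueError("paired 1-D samples required")
    d = sleep_t - awake
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("no_information: all differences are zero")
    if d.size < 5:
        raise ValueError("fewer than 5 non-zero pairs; test uninformative")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        # all sign patterns via the bit matrix; W = sum of ranks with + sign
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        dist = bits @ ranks
        p = min(1.0, 2 * min(np.mean(dist <= w + 1e-9), np.mean(dist >= w - 1e-9)))
        z = float(sps.norm.isf(min(p, 1.0) / 2)) if p < 1 else 0.0
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # variance with tie correction over groups of tied |d|
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            counts**3 - counts
        ) / 48.0
        cc = 0.5 * np.sign(w - mu)
        z = (w - mu - cc) / math.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
        z = abs(z)
        method = "normal"
    r = (z / math.sqrt(n)) * (1.0 if np.median(d) > 0 else -1.0)
    return WilcoxonResult(w, float(p), float(r), float(z), n, method)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, q_(i) = p_(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def select_significant_rois(pair_reports: dict, alpha: float = 0.05) -> list:
    """Pairs with a significant Friedman test whose peak-time index elevation
    carries a strictly positive x-diffusivity (numerator) change.

    ``pair_reports`` maps pair id to a dict with ``friedman_p`` and the
    component ``decomposition`` frame (columns delta_num/delta_den/
    delta_index, one row per sleep time).
    """
    selected = []
    for pid, rep in pair_reports.items():
        if rep["friedman_p"] >= alpha:
            continue
        dec = rep["decomposition"]
        peak = dec["delta_index"].idxmax()
        if dec.loc[peak, "delta_num"] > 0:
            selected.append(pid)
    return selected


@dataclass
class StatsReport:
    """Full inferential summary of a cohort of ALPS series."""

    table: pd.DataFrame  # one row per pair x sleep time point
    friedman: pd.DataFrame  # one row per pair
    selected: list
    included_subjects: list
    decompositions: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary_dict(self) -> dict:
        return {
            "included_subjects": self.included_subjects,
            "selected_pairs": self.selected,
            "friedman": self.friedman.to_dict(orient="records"),
        }


def run_full_analysis(
    cohort: list,
    grid=None,
    alpha: float = 0.05,
    window=range(1, 8),
    friedman_method: str = "chi2",
    seed: int = 0,
) -> StatsReport:
    """Inclusion filter, Friedman screen, post hoc tests, FDR, effect sizes
    and component decomposition for a cohort of per-subject ALPS series.

    ``cohort`` is a list of :class:`AlpsSeries`; ``grid`` the consensus
    annotation grid (optional — without it every subject is analysed).  The
    post hoc family is the set of sleep-vs-awake comparisons within one ROI
    pair.  Deterministic given ``seed`` (used only by the permutation
    Friedman option).
    """
    from .sleep_annotation import include_subjects

    by_subject = {s.subject: s for s in cohort}
    if grid is not None:
        included = [s for s in include_subjects(grid, window) if s in by_subject]
    else:
        included = list(by_subject)
    if len(included) < 2:
        raise ValueError("fewer than 2 included subjects")
    series = [by_subject[s] for s in included]

    times = series[0].times
    pair_ids = sorted(set.intersection(*(set(s.quads) for s in series)))
    if not pair_ids:
        raise ValueError("no ROI pair is available in every included subject")

    rows = []
    fried_rows = []
    decomps = {}
    pair_reports = {}
    for pid in pair_ids:
        idx = np.stack([s.indices(pid) for s in series])  # subjects x times
        f_stat, f_p = friedman_test(idx, method=friedman_method, seed=seed)

        # cohort-mean quads drive the component decomposition
        mean_quads = []
        for ti in range(len(times)):
            arr = np.mean([s.quads[pid][ti].as_array() for s in series], axis=0)
            mean_quads.append(DiffusivityQuad(*arr))
        dec = decompose_components(mean_quads, times)
        decomps[pid] = dec
        pair_reports[pid] = {"friedman_p": f_p, "decomposition": dec}

        raw_p, eff_r = [], []
        for ti in range(1, len(times)):
            res = wilcoxon_signed_rank(idx[:, 0], idx[:, ti])
            raw_p.append(res.p)
            eff_r.append(res.r)
        adj_p = bh_adjust(raw_p)
        mean = idx.mean(axis=0)
        se = idx.std(axis=0, ddof=1) / math.sqrt(idx.shape[0])
        for j, t in enumerate(times[1:]):
            rows.append(
                {
                    "pair_id": pid,
                    "time_min": t,
                    "n": len(series),
                    "mean_index": mean[j + 1],
                    "se_index": se[j + 1],
                    "pct_change": 100.0 * (mean[j + 1] - mean[0]) / mean[0],
                    "p_raw": raw_p[j],
                    "p_adj": adj_p[j],
                    "effect_r": eff_r[j],
                    "delta_num_pct": 100.0 * dec["delta_num"].iloc[j],
                    "delta_den_pct": 100.0 * dec["delta_den"].iloc[j],
                }
            )
        fried_rows.append(
            {
                "pair_id": pid,
                "friedman_stat": f_stat,
                "friedman_p": f_p,
                "awake_mean_index": mean[0],
                "awake_se_index": se[0],
            }
        )

    selected = select_significant_rois(pair_reports, alpha=alpha)
    return StatsReport(
        table=pd.DataFrame(rows),
        friedman=pd.DataFrame(fried_rows),
        selected=selected,
        included_subjects=included,
        decompositions=decomps,
    )
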