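"""Injury-regulation and differential-regulation statistics.

Per line, an element's injury regulation (*SNL-reg*) is measured two ways:

* subtraction metric: ``(SNL - sham) / ((SNL + sham) / 2)``, a symmetric,
  dimensionless quantity bounded in (-2, 2);
* signed fold change / log2 ratio: ``SNL/sham`` for up-regulation and
  ``-(sham/SNL)`` for down-regulation, with ``log2(SNL/sham)`` used
  whenever arithmetic on fold changes is required.

Differential regulation (*diff-reg*) contrasts the two lines: each line's
SNL-reg is estimated from every (SNL pool, sham pool) pair (k x k
estimates, 9 at the default 3-replicate design), and the two estimate sets
are compared with a two-tailed Welch t-test plus an optional permutation
null. p-values are corrected per matrix with Benjamini-Hochberg; the
classical FDR limit (largest p_(i) <= i*alpha/m) is reported alongside so
the rejection rule "uncorrected p <= FDR limit" is available.

Note the pairwise estimate sets within one line share pools and are
therefore positively dependent; the t-test treats them as independent
samples, which understates the standard error of the line means. This is
inherent to the pairwise-estimate design (see docs/methods.md). The
pool-level permutation mode (``permutation_mode="pools"``) re-randomizes
line labels of whole pools instead and does not suffer from this.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import PoolDesign

METRIC_SUBTRACTION = "subtraction"
METRIC_LOG2 = "log2"
DEFAULT_RPM_FLOOR = 0.5
DEFAULT_PERMUTATION_RUNS = 100_000
_EXHAUSTIVE_LIMIT = 20_000


# ---------------------------------------------------------------------------
# point metrics


def snl_reg_subtraction(snl_mean, sham_mean):
    """Subtraction metric (SNL - sham) / ((SNL + sham) / 2).

    Positive for up-regulation, negative for down-regulation, zero for no
    change. Undefined (NaN) only when both means are zero.
    """
    snl = np.asarray(snl_mean, dtype=float)
    sham = np.asarray(sham_mean, dtype=float)
    denom = (snl + sham) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (snl - sham) / np.where(denom > 0, denom, 1.0), np.nan)
    return out if out.ndim else float(out)


def fold_change_signed(snl_mean, sham_mean):
    """Signed fold change: SNL/sham if up, -(sham/SNL) if down.

    By convention no change maps to +1. NaN where either mean is zero.
    """
    snl = np.asarray(snl_mean, dtype=float)
    sham = np.asarray(sham_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = snl / np.where(sham > 0, sham, np.nan)
        down = -sham / np.where(snl > 0, snl, np.nan)
        out = np.where(snl >= sham, up, down)
    out = np.where((snl > 0) & (sham > 0), out, np.nan)
    return out if out.ndim else float(out)


def log2_ratio(snl_mean, sham_mean, floor: float = DEFAULT_RPM_FLOOR):
    """log2(SNL/sham) with an RPM floor applied inside the ratio only."""
    snl = np.maximum(np.asarray(snl_mean, dtype=float), floor)
    sham = np.maximum(np.asarray(sham_mean, dtype=float), floor)
    out = np.log2(snl / sham)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up q-values and the FDR limit.

    Returns ``(q, fdr_limit)`` where ``fdr_limit`` is the largest ordered
    p-value satisfying ``p_(i) <= i * alpha / m`` (0.0 when none does), so
    that ``p <= fdr_limit`` is exactly the BH rejection rule at ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), 0.0
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    m = p.size
    p_sorted = np.sort(p)
    ok = p_sorted <= (np.arange(1, m + 1) * alpha / m)
    fdr_limit = float(p_sorted[ok][-1]) if ok.any() else 0.0
    return q, fdr_limit


# ---------------------------------------------------------------------------
# welch helper


def _welch_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch t-test robust to (near-)zero-variance degeneracy.

    Variance below the square of ~1e-12 of the data scale is float noise
    from demeaning constant values and is treated as exactly zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    eps = (1e-12 * scale) ** 2
    if va <= eps and vb <= eps:
        delta = a.mean() - b.mean()
        if abs(delta) <= 1e-12 * scale:
            return 0.0, 1.0
        return math.copysign(math.inf, delta), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _one_tailed_from_two(t: float, p_two: float, direction: float) -> float:
    """Fold a two-tailed p into the tail of the observed direction."""
    if direction == 0:
        return 1.0
    if math.isinf(t):
        return 0.0 if (t > 0) == (direction > 0) else 1.0
    if (t > 0) == (direction > 0) and t != 0:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


# ---------------------------------------------------------------------------
# SNL-reg per line


def snl_reg_test(
    matrix: pd.DataFrame,
    design: PoolDesign,
    line: str,
    alpha: float = 0.05,
    floor: float = DEFAULT_RPM_FLOOR,
) -> pd.DataFrame:
    """Per-element injury regulation for one line, with one-tailed tests.

    Point estimates come from the condition means; the one-tailed Welch
    t-test compares the SNL replicate pools against the sham pools in the
    direction of the observed change (an element with equal means gets
    p = 1). Both metrics (subtraction and log2 ratio / signed fold) are
    reported for every element; q-values are BH over the matrix.
    """
    sham_pools = design.present(matrix.columns, line, "sham")
    snl_pools = design.present(matrix.columns, line, "SNL")
    if len(sham_pools) < 2 or len(snl_pools) < 2:
        raise ValueError(f"line {line}: need >= 2 pools per condition")
    sham = matrix[sham_pools].to_numpy(dtype=float)
    snl = matrix[snl_pools].to_numpy(dtype=float)
    sham_mean = sham.mean(axis=1)
    snl_mean = snl.mean(axis=1)
    est = snl_reg_subtraction(snl_mean, sham_mean)
    fold = fold_change_signed(snl_mean, sham_mean)
    l2 = log2_ratio(snl_mean, sham_mean, floor)

    p = np.ones(matrix.shape[0])
    for i in range(matrix.shape[0]):
        if np.isnan(est[i]):
            continue  # both means zero: logged downstream, skipped here
        direction = np.sign(snl_mean[i] - sham_mean[i])
        t, p_two = _welch_two_sided(snl[i], sham[i])
        p[i] = _one_tailed_from_two(t, p_two, direction)

    valid = ~np.isnan(est)
    q = np.full(matrix.shape[0], np.nan)
    fdr_limit = 0.0
    if valid.any():
        q[valid], fdr_limit = bh_fdr(p[valid], alpha)
    out = pd.DataFrame(
        {
            "line": line,
            "sham_mean": sham_mean,
            "snl_mean": snl_mean,
            "snl_reg_subtraction": est,
            "fold_change_signed": fold,
            "log2_ratio": l2,
            "direction": np.sign(snl_mean - sham_mean),
            "p_one_tailed": p,
            "q_fdr": q,
        },
        index=matrix.index,
    )
    out.attrs["fdr_limit"] = fdr_limit
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# diff-reg


def pairwise_estimates(
    snl_values: np.ndarray,
    sham_values: np.ndarray,
    metric: str = METRIC_SUBTRACTION,
    floor: float = DEFAULT_RPM_FLOOR,
) -> np.ndarray:
    """All (SNL pool, sham pool) SNL-reg estimates; invalid pairs dropped.

    For the subtraction metric a pair is invalid when both pool values are
    zero. The log2 metric applies the RPM floor so every pair is valid.
    """
    s = np.asarray(snl_values, dtype=float)[:, None]
    h = np.asarray(sham_values, dtype=float)[None, :]
    if metric == METRIC_SUBTRACTION:
        grid = snl_reg_subtraction(np.broadcast_to(s, (len(s), h.shape[1])),
                                   np.broadcast_to(h, (len(s), h.shape[1])))
    elif metric == METRIC_LOG2:
        grid = log2_ratio(np.broadcast_to(s, (len(s), h.shape[1])),
                          np.broadcast_to(h, (len(s), h.shape[1])), floor)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    grid = np.asarray(grid, dtype=float).ravel()
    return grid[~np.isnan(grid)]


def diff_reg_permutation(
    estimates_a: np.ndarray,
    estimates_b: np.ndarray,
    n_runs: int = DEFAULT_PERMUTATION_RUNS,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Permutation p for the absolute difference of estimate-set means.

    The two sets are pooled and re-split at their original sizes. With
    ``method="exact"`` (or "auto" on small inputs) every split is
    enumerated and the p-value is the exact fraction of splits whose
    |difference of means| reaches the observed one. Sampled mode uses the
    add-one correction ``(1 + hits) / (n_runs + 1)`` so p never reaches 0.
    """
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both estimate sets must be non-empty")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    observed = abs(a.mean() - b.mean())
    total = math.comb(n, n1)
    tol = 1e-12 * max(1.0, observed)
    if method == "exact" or (method == "auto" and total <= _EXHAUSTIVE_LIMIT):
        grand = pooled.sum()
        hits = 0
        for idx in itertools.combinations(range(n), n1):
            m1 = pooled[list(idx)].sum() / n1
            m2 = (grand - m1 * n1) / (n - n1)
            if abs(m1 - m2) >= observed - tol:
                hits += 1
        return hits / total
    if method not in ("auto", "sampled"):
        raise ValueError(f"unknown permutation method {method!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 10_000
    done = 0
    while done < n_runs:
        size = min(chunk, n_runs - done)
        perm = rng.permuted(np.broadcast_to(pooled, (size, n)).copy(), axis=1)
        m1 = perm[:, :n1].mean(axis=1)
        m2 = perm[:, n1:].mean(axis=1)
        hits += int((np.abs(m1 - m2) >= observed - tol).sum())
        done += size
    return (1 + hits) / (n_runs + 1)


def _pool_label_permutation(
    snl_by_line: dict[str, np.ndarray],
    sham_by_line: dict[str, np.ndarray],
    lines: tuple[str, str],
    metric: str,
    floor: float,
    n_runs: int,
    seed: int | None,
) -> float:
    """Permutation of line labels of whole pools (within condition)."""
    la, lb = lines
    snl_all = np.concatenate([snl_by_line[la], snl_by_line[lb]])
    sham_all = np.concatenate([sham_by_line[la], sham_by_line[lb]])
    ka, kb = len(snl_by_line[la]), len(sham_by_line[la])

    def stat(snl_idx: tuple[int, ...], sham_idx: tuple[int, ...]) -> float:
        snl_a = snl_all[list(snl_idx)]
        sham_a = sham_all[list(sham_idx)]
        snl_b = np.delete(snl_all, list(snl_idx))
        sham_b = np.delete(sham_all, list(sham_idx))
        ea = pairwise_estimates(snl_a, sham_a, metric, floor)
        eb = pairwise_estimates(snl_b, sham_b, metric, floor)
        if ea.size == 0 or eb.size == 0:
            return np.nan
        return ea.mean() - eb.mean()

    observed = abs(stat(tuple(range(ka)), tuple(range(kb))))
    snl_splits = list(itertools.combinations(range(len(snl_all)), ka))
    sham_splits = list(itertools.combinations(range(len(sham_all)), kb))
    total = len(snl_splits) * len(sham_splits)
    tol = 1e-12 * max(1.0, observed)
    if total <= _EXHAUSTIVE_LIMIT:
        hits = 0
        valid = 0
        for si in snl_splits:
            for hi in sham_splits:
                d = stat(si, hi)
                if np.isnan(d):
                    continue
                valid += 1
                if abs(d) >= observed - tol:
                    hits += 1
        return hits / valid if valid else 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_runs):
        si = tuple(rng.choice(len(snl_all), ka, replace=False))
        hi = tuple(rng.choice(len(sham_all), kb, replace=False))
        d = stat(si, hi)
        if not np.isnan(d) and abs(d) >= observed - tol:
            hits += 1
    return (1 + hits) / (n_runs + 1)


def diff_reg_table(
    matrix: pd.DataFrame,
    design: PoolDesign,
    metric: str = METRIC_SUBTRACTION,
    alpha: float = 0.05,
    floor: float = DEFAULT_RPM_FLOOR,
    permutation_runs: int = 0,
    permutation_mode: str = "estimates",
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential regulation (first line minus second line) per element.

    For each element and line all SNL x sham pairwise SNL-reg estimates
    are formed under ``metric``; ``diff`` is the difference of the two
    line means and is tested with a two-tailed Welch t-test on the two
    estimate sets. With ``permutation_runs > 0`` a permutation p-value is
    added, either re-splitting the pooled pairwise estimates
    (``permutation_mode="estimates"``) or re-assigning whole pools to
    lines within condition (``"pools"``). Elements with fewer than 2
    valid pairs in either line are skipped (NaN row, excluded from BH).
    """
    if len(design.lines) != 2:
        raise ValueError("diff-reg is defined for exactly two lines")
    line_a, line_b = design.lines
    pools: dict[tuple[str, str], list[str]] = {}
    for line in design.lines:
        for cond in ("sham", "SNL"):
            pl = design.present(matrix.columns, line, cond)
            if len(pl) < 2:
                raise ValueError(f"group {line}_{cond}: need >= 2 pools")
            pools[(line, cond)] = pl

    n = matrix.shape[0]
    cols: dict[str, np.ndarray] = {
        f"mean_{line_a}": np.full(n, np.nan),
        f"sd_{line_a}": np.full(n, np.nan),
        f"mean_{line_b}": np.full(n, np.nan),
        f"sd_{line_b}": np.full(n, np.nan),
        "n_pairs_" + line_a: np.zeros(n),
        "n_pairs_" + line_b: np.zeros(n),
        "diff": np.full(n, np.nan),
        "t_p_two_tailed": np.full(n, np.nan),
    }
    perm = np.full(n, np.nan)
    rng = np.random.default_rng(seed)

    for i, element in enumerate(matrix.index):
        row = matrix.loc[element]
        ests = {}
        ok = True
        snl_vals, sham_vals = {}, {}
        for line in design.lines:
            snl_vals[line] = row[pools[(line, "SNL")]].to_numpy(dtype=float)
            sham_vals[line] = row[pools[(line, "sham")]].to_numpy(dtype=float)
            e = pairwise_estimates(snl_vals[line], sham_vals[line], metric, floor)
            ests[line] = e
            if e.size < 2:
                ok = False
        if not ok:
            continue
        ea, eb = ests[line_a], ests[line_b]
        cols[f"mean_{line_a}"][i] = ea.mean()
        cols[f"sd_{line_a}"][i] = ea.std(ddof=1)
        cols[f"mean_{line_b}"][i] = eb.mean()
        cols[f"sd_{line_b}"][i] = eb.std(ddof=1)
        cols["n_pairs_" + line_a][i] = ea.size
        cols["n_pairs_" + line_b][i] = eb.size
        cols["diff"][i] = ea.mean() - eb.mean()
        _, cols["t_p_two_tailed"][i] = _welch_two_sided(ea, eb)
        if permutation_runs > 0:
            sub_seed = int(rng.integers(2**31 - 1))
            if permutation_mode == "estimates":
                perm[i] = diff_reg_permutation(ea, eb, permutation_runs, sub_seed)
            elif permutation_mode == "pools":
                perm[i] = _pool_label_permutation(
                    snl_vals, sham_vals, (line_a, line_b), metric, floor,
                    permutation_runs, sub_seed,
                )
            else:
                raise ValueError(f"unknown permutation mode {permutation_mode!r}")

    out = pd.DataFrame(cols, index=matrix.index)
    if permutation_runs > 0:
        out["perm_p"] = perm
    valid = ~out["t_p_two_tailed"].isna()
    q = np.full(n, np.nan)
    fdr_limit = 0.0
    if valid.any():
        q[valid.to_numpy()], fdr_limit = bh_fdr(out.loc[valid, "t_p_two_tailed"], alpha)
    out["q_fdr"] = q
    if permutation_runs > 0:
        q_perm = np.full(n, np.nan)
        valid_p = ~out["perm_p"].isna()
        if valid_p.any():
            q_perm[valid_p.to_numpy()], _ = bh_fdr(out.loc[valid_p, "perm_p"], alpha)
        out["perm_q_fdr"] = q_perm
    out.attrs["fdr_limit"] = fdr_limit
    out.attrs["alpha"] = alpha
    out.attrs["metric"] = metric
    out.attrs["lines"] = (line_a, line_b)
    return out


# ---------------------------------------------------------------------------
# baseline contrast


def baseline_compare(
    matrix: pd.DataFrame,
    design: PoolDesign,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Baseline (sham vs sham) expression contrast between the two lines.

    Reports the first-line / second-line ratio of sham means, a two-tailed
    Welch t-test on the sham pool values, and BH q-values.
    """
    if len(design.lines) != 2:
        raise ValueError("baseline comparison is defined for exactly two lines")
    line_a, line_b = design.lines
    pa = design.present(matrix.columns, line_a, "sham")
    pb = design.present(matrix.columns, line_b, "sham")
    if len(pa) < 2 or len(pb) < 2:
        raise ValueError("need >= 2 sham pools per line")
    a = matrix[pa].to_numpy(dtype=float)
    b = matrix[pb].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.nan)
    p = np.ones(matrix.shape[0])
    for i in range(matrix.shape[0]):
        _, p[i] = _welch_two_sided(a[i], b[i])
    q, fdr_limit = bh_fdr(p, alpha)
    out = pd.DataFrame(
        {
            f"{line_a}_sham_mean": mean_a,
            f"{line_b}_sham_mean": mean_b,
            "ratio": ratio,
            "p_two_tailed": p,
            "q_fdr": q,
        },
        index=matrix.index,
    )
    out.attrs["fdr_limit"] = fdr_limit
    return out


def volcano_frame(diff_table: pd.DataFrame, q_column: str = "q_fdr") -> pd.DataFrame:
    """(diff, -log10 q) pairs with finite values for plotting/export."""
    sub = diff_table.dropna(subset=["diff", q_column])
    tiny = np.finfo(float).tiny
    return pd.DataFrame(
        {
            "diff": sub["diff"],
            "neg_log10_q": -np.log10(np.clip(sub[q_column].to_numpy(), tiny, None)),
        },
        index=sub.index,
    )
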