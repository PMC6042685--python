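"""Nonparametric statistics for behavioral nociception data.

The assay readouts are (i) latency to nocifensive escape locomotion,
censored at the 11 s stimulation cap (non-responders carry 11 s and enter
rank tests as a tie block at the cap), and (ii) binary response proportions.
Pairwise comparisons use the two-sided Mann-Whitney U test; proportions use
Fisher's exact test, Bonferroni-corrected over the comparisons performed;
many-to-one comparisons of several genotypes against one control use
Steel's test, the rank analogue of Dunnett's test.

Steel's test here is defined by a joint permutation reference: per contrast
the standardized (tie-corrected) rank sum of the treatment group within the
control-plus-group subsample gives z_i; the familywise-adjusted p-value of
group i is the permutation probability that max_j |Z*_j| >= |z_i| under
joint relabeling of all animals.  A classic asymptotic variant (equicorrelated
multivariate normal with rho_ij = sqrt(lambda_i lambda_j),
lambda_i = n_i/(n0+n_i)) is provided for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .io_core import BehaviorTable, ValidationError

log = logging.getLogger("nociquant")


@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alternative: str = "two-sided"
    adjustment: str = "none"
    group: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float
    censored_count: int = 0
    outcome: str = "latency"


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize(table: BehaviorTable, outcome: str = "latency") -> list[GroupSummary]:
    """Mean ± SE per genotype.

    Latencies enter at face value including censored 11 s rows (SE = sd/√n);
    proportions use p̂ with binomial SE = √(p̂(1−p̂)/n).
    """
    df = table.data
    col = {"latency": "latency_s", "response": "responded"}.get(outcome)
    if col is None or col not in df.columns:
        raise ValidationError(f"outcome {outcome!r} not available in table")
    out = []
    for genotype, sub in df.groupby("genotype", sort=False):
        vals = sub[col].dropna()
        if len(vals) == 0:
            log.warning("genotype %s has no %s data; skipped", genotype, outcome)
            continue
        if outcome == "latency":
            x = vals.to_numpy(dtype=float)
            se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
            out.append(GroupSummary(
                label=str(genotype), n=len(x), mean=float(x.mean()), se=se,
                censored_count=int(sub.get("censored", pd.Series(False)).sum()),
                outcome=outcome,
            ))
        else:
            x = vals.astype(bool).to_numpy()
            p_hat = float(x.mean())
            se = float(np.sqrt(p_hat * (1 - p_hat) / len(x)))
            out.append(GroupSummary(
                label=str(genotype), n=len(x), mean=p_hat, se=se,
                outcome=outcome,
            ))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the pooled sample is small (N ≤ 20) and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Ties — including stacks of censored 11 s latencies — are mid-ranked.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be nonempty")
    exact = (len(x) + len(y) <= 20) and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatResult(
        method="mann-whitney-u (exact)" if exact else "mann-whitney-u (asymptotic)",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n=(len(x), len(y)),
    )


# ---------------------------------------------------------------------------
# Steel's many-to-one test
# ---------------------------------------------------------------------------

def _tie_term_rows(sorted_vals: np.ndarray) -> np.ndarray:
    """Σ(t³ − t) over tie groups, per row of a row-sorted matrix."""
    R, N = sorted_vals.shape
    new_group = np.ones((R, N), dtype=bool)
    new_group[:, 1:] = sorted_vals[:, 1:] != sorted_vals[:, :-1]
    group_id = np.cumsum(new_group, axis=1)  # 1..G per row
    offsets = (np.arange(R) * (N + 1))[:, None]
    flat = (group_id + offsets).ravel()
    counts = np.bincount(flat, minlength=R * (N + 1)).reshape(R, N + 1).astype(float)
    return (counts**3 - counts).sum(axis=1)


def _standardized_rank_sums(values: np.ndarray, n0: int, sizes: Sequence[int]
                            ) -> np.ndarray:
    """z_i per contrast for each row of ``values`` (columns: control first,
    then groups in order).  Rank sums are computed within each
    control-plus-group subsample with mid-ranks and tie-corrected variance."""
    R = values.shape[0]
    k = len(sizes)
    z = np.empty((R, k))
    col0 = values[:, :n0]
    start = n0
    for i, ni in enumerate(sizes):
        sub = np.concatenate([col0, values[:, start : start + ni]], axis=1)
        start += ni
        N = n0 + ni
        ranks = sps.rankdata(sub, axis=1)
        W = ranks[:, n0:].sum(axis=1)
        E = ni * (N + 1) / 2.0
        tie = _tie_term_rows(np.sort(sub, axis=1))
        V = n0 * ni / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z[:, i] = np.where(V > 0, (W - E) / np.sqrt(V), 0.0)
    return z


def steel_test(
    control: Sequence[float],
    treatment_groups: Sequence[Sequence[float]],
    n_resamples: int = 100_000,
    seed: int | None = None,
    method: str = "permutation",
) -> list[StatResult]:
    """Steel's many-to-one rank test of each group against a shared control.

    ``method="permutation"`` (the reference definition) jointly permutes all
    observations and compares each observed \\|z_i\\| against the permutation
    distribution of ``max_j |Z*_j|``, which controls the familywise error
    across the k contrasts; p-values use the add-one estimator.
    ``method="asymptotic"`` evaluates the classic multivariate-normal
    approximation instead.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatment_groups]
    if len(groups) == 0:
        raise ValidationError("steel_test needs at least one treatment group")
    if len(control) == 0 or any(len(g) == 0 for g in groups):
        raise ValidationError("control and every group must be nonempty")
    n0 = len(control)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([control, *groups])
    obs_z = _standardized_rank_sums(pooled[None, :], n0, sizes)[0]

    if method == "asymptotic":
        p_adj = _steel_asymptotic_p(np.abs(obs_z), n0, sizes)
        label = "steel (asymptotic)"
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        max_abs = np.empty(n_resamples)
        chunk = max(1, min(n_resamples, 20_000))
        done = 0
        while done < n_resamples:
            r = min(chunk, n_resamples - done)
            perm = rng.permuted(np.tile(pooled, (r, 1)), axis=1)
            zs = _standardized_rank_sums(perm, n0, sizes)
            max_abs[done : done + r] = np.abs(zs).max(axis=1)
            done += r
        p_adj = [
            (1.0 + np.count_nonzero(max_abs >= abs(z) - 1e-12)) / (n_resamples + 1.0)
            for z in obs_z
        ]
        label = "steel (joint permutation)"
    else:
        raise ValidationError(f"unknown method {method!r}")

    return [
        StatResult(
            method=label,
            statistic=float(obs_z[i]),
            p_value=float(min(p_adj[i], 1.0)),
            n=(n0, sizes[i]),
            adjustment="steel-joint",
            group=f"group_{i}",
        )
        for i in range(len(groups))
    ]


def _steel_asymptotic_p(abs_z: np.ndarray, n0: int, sizes: Sequence[int]
                        ) -> np.ndarray:
    """P(max_j |Z_j| >= |z_i|) under the MVN null with Steel's correlation
    rho_ij = sqrt(lambda_i lambda_j), lambda_i = n_i/(n0+n_i)."""
    k = len(sizes)
    lam = np.array([ni / (n0 + ni) for ni in sizes])
    corr = np.sqrt(np.outer(lam, lam))
    np.fill_diagonal(corr, 1.0)
    mvn = sps.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    out = np.empty(len(abs_z))
    for i, z in enumerate(abs_z):
        if k == 1:
            inside = float(sps.norm.cdf(z) - sps.norm.cdf(-z))
        else:
            inside = float(mvn.cdf(np.full(k, z), lower_limit=np.full(k, -z)))
        out[i] = min(max(1.0 - inside, 0.0), 1.0)
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test and Bonferroni
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> StatResult:
    """Two-sided Fisher's exact test on a 2×2 count table.

    p is the sum of hypergeometric probabilities, margins fixed, of all
    tables no more probable than the one observed.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("degenerate margin in 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return StatResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        n=tuple(int(v) for v in t.sum(axis=1)),
    )


def bonferroni(p_values: Sequence[float] | float, m: int | None = None
               ) -> np.ndarray | float:
    """Bonferroni adjustment: min(1, p·m); m defaults to the number of
    p-values supplied."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValidationError("m must be at least the number of p-values")
    adj = np.minimum(1.0, p * m)
    return float(adj[0]) if scalar else adj


# ---------------------------------------------------------------------------
# Table-level drivers (CLI surface)
# ---------------------------------------------------------------------------

def run_behavior_tests(
    table: BehaviorTable,
    outcome: str,
    control: str,
    test: str,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compare every non-control genotype against the control genotype.

    ``test`` is ``"steel"``, ``"mw"`` (pairwise Mann-Whitney) or ``"fisher"``
    (proportions, Bonferroni-corrected over the comparisons made).  Returns a
    tidy DataFrame of StatResult rows.
    """
    df = table.data
    if control not in set(df["genotype"]):
        raise ValidationError(f"control genotype {control!r} not in table")
    col = {"latency": "latency_s", "response": "responded"}[outcome]
    others = [g for g in table.genotypes if g != control]
    ctrl_vals = df.loc[df["genotype"] == control, col].dropna()
    rows: list[StatResult] = []
    if test == "steel":
        groups = [df.loc[df["genotype"] == g, col].dropna().to_numpy(dtype=float)
                  for g in others]
        results = steel_test(ctrl_vals.to_numpy(dtype=float), groups,
                             n_resamples=n_resamples, seed=seed)
        for g, r in zip(others, results):
            r.group = g
            rows.append(r)
    elif test == "mw":
        for g in others:
            r = mann_whitney_u(
                ctrl_vals.to_numpy(dtype=float),
                df.loc[df["genotype"] == g, col].dropna().to_numpy(dtype=float),
            )
            r.group = g
            rows.append(r)
    elif test == "fisher":
        raw = []
        for g in others:
            gv = df.loc[df["genotype"] == g, col].dropna().astype(bool)
            cv = ctrl_vals.astype(bool)
            t = [[int(cv.sum()), int((~cv).sum())],
                 [int(gv.sum()), int((~gv).sum())]]
            r = fisher_exact(t)
            r.group = g
            raw.append(r)
        adj = bonferroni([r.p_value for r in raw])
        for r, a in zip(raw, np.atleast_1d(adj)):
            r.p_value = float(a)
            r.adjustment = f"bonferroni({len(raw)})"
            rows.append(r)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "method": [r.method for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_control": [r.n[0] for r in rows],
            "n_group": [r.n[1] for r in rows],
            "adjustment": [r.adjustment for r in rows],
        }
    )
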