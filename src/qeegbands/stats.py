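"""Nonparametric tests, resampling mixed-design ANOVA, and FDR correlations.

The omnibus test for the 3 (group, between) x 2 (visit, within) layout is
a Wald-type statistic on the six cell means with a heteroscedasticity-
robust covariance estimate, calibrated by resampling group-centred
subject profiles with replacement. It is a documented stand-in for
published resampling repeated-measures ANOVA packages: same design, same
hypotheses, seeded and type-I calibrated, but no claim of internal
equivalence with any particular implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "AnovaResult",
    "CorrelationCell",
    "significance_marker",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "resampling_mixed_anova",
    "benjamini_hochberg",
    "spearman_with_fdr",
]

DEFAULT_ANOVA_SEED = 20000523
DEFAULT_ANOVA_ITER = 10000

#: Printed-convention marker thresholds (strict inequalities).
_MARKERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "•"))


def significance_marker(p: float) -> str:
    """Map a p-value to the figure-legend marker convention."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    for cut, marker in _MARKERS:
        if p < cut:
            return marker
    return "n.s."


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome with its significance marker."""

    method: str
    statistic: float
    p: float
    n: tuple[int, ...]
    marker: str = field(default="")

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p-value must lie in [0, 1], got {self.p}")
        if not self.marker:
            object.__setattr__(self, "marker", significance_marker(self.p))


@dataclass(frozen=True)
class AnovaResult:
    """Resampling mixed-ANOVA p-values for group, visit and interaction."""

    p_group: float
    p_visit: float
    p_interaction: float
    stat_group: float
    stat_visit: float
    stat_interaction: float
    n_iter: int
    seed: int
    n_subjects: tuple[int, ...]
    statistic_type: str = "wald-type / centred subject bootstrap"


@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman correlation with raw and FDR-adjusted p-values."""

    rho: float
    p_raw: float
    p_adj: float
    n_pairs: int


# ---------------------------------------------------------------------------
# rank tests


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference)."""
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    h, p = sps.kruskal(*samples)
    return TestResult("kruskal-wallis", float(h), float(p), tuple(s.size for s in samples))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null when the combined sample is small (n <= 25) and tie-free,
    otherwise the tie- and continuity-corrected normal approximation.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if combined.size <= 25 and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(f"wilcoxon-rank-sum ({method})", float(res.statistic), float(res.pvalue),
                      (x.size, y.size))


def wilcoxon_signed_rank(x1, x2) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic convention); exact null for
    small samples (the backend enumerates sign flips, midranks included),
    else the corrected normal approximation. If every difference is zero
    the test degenerates to p = 1 with a warning.
    """
    x1 = _as_sample(x1, "x1")
    x2 = _as_sample(x2, "x2")
    if x1.size != x2.size:
        raise ValueError(f"paired samples differ in length: {x1.size} vs {x2.size}")
    diffs = x2 - x1
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test is degenerate")
        return TestResult("wilcoxon-signed-rank (degenerate)", 0.0, 1.0, (x1.size,))
    method = "exact" if nonzero.size <= 25 else "asymptotic"
    res = sps.wilcoxon(x1, x2, zero_method="wilcox", alternative="two-sided",
                       correction=True, method=method)
    return TestResult(f"wilcoxon-signed-rank ({method})", float(res.statistic),
                      float(min(res.pvalue, 1.0)), (x1.size,))


# ---------------------------------------------------------------------------
# resampling mixed-design ANOVA (3 between x 2 within)

# Cell-mean order: (g1,V1), (g1,V2), (g2,V1), (g2,V2), (g3,V1), (g3,V2).
_C_GROUP = np.array([
    [0.5, 0.5, -0.5, -0.5, 0.0, 0.0],
    [0.5, 0.5, 0.0, 0.0, -0.5, -0.5],
])
_C_VISIT = np.array([[1.0, -1.0, 1.0, -1.0, 1.0, -1.0]]) / 3.0
_C_INTERACTION = np.array([
    [1.0, -1.0, -1.0, 1.0, 0.0, 0.0],
    [1.0, -1.0, 0.0, 0.0, -1.0, 1.0],
])


def _pivot_visits(table: pd.DataFrame, value_col: str | None) -> list[np.ndarray]:
    """Tidy (subject_id, group, visit, value) -> per-group (n_g x 2) arrays."""
    if value_col is None:
        candidates = [c for c in ("relative_power", "value") if c in table.columns]
        if not candidates:
            raise ValueError("no value column found; expected 'relative_power' or 'value'")
        value_col = candidates[0]
    wide = table.pivot_table(index=["group", "subject_id"], columns="visit",
                             values=value_col, aggfunc="mean")
    for visit in ("V1", "V2"):
        if visit not in wide.columns:
            raise ValueError(f"visit {visit!r} absent from table")
    incomplete = wide[wide[["V1", "V2"]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with a missing visit: "
            f"{[s for _, s in incomplete.index]}"
        )
        wide = wide.dropna(subset=["V1", "V2"])
    blocks = []
    for group, sub in wide.groupby(level="group", sort=True):
        arr = sub[["V1", "V2"]].to_numpy()
        if arr.shape[0] < 2:
            raise ValueError(f"group {group!r} has fewer than 2 complete subjects")
        blocks.append(arr)
    if len(blocks) < 2:
        raise ValueError("need at least 2 groups with complete subjects")
    return blocks


def _wald_stats(mu: np.ndarray, cov_blocks: np.ndarray, contrasts) -> np.ndarray:
    """Batched Wald-type statistics.

    mu : (iters, 6) cell means; cov_blocks : (iters, 3, 2, 2) per-group
    covariance of the cell means. Returns (len(contrasts), iters).
    """
    iters = mu.shape[0]
    sigma = np.zeros((iters, 6, 6))
    for g in range(cov_blocks.shape[1]):
        sigma[:, 2 * g : 2 * g + 2, 2 * g : 2 * g + 2] = cov_blocks[:, g]
    out = np.empty((len(contrasts), iters))
    for k, c in enumerate(contrasts):
        t = mu @ c.T  # (iters, r)
        v = np.einsum("ri,nij,sj->nrs", c, sigma, c)  # (iters, r, r)
        try:
            sol = np.linalg.solve(v, t[..., None])[..., 0]
        except np.linalg.LinAlgError:
            sol = np.squeeze(np.linalg.pinv(v) @ t[..., None], axis=-1)
        out[k] = np.einsum("nr,nr->n", t, sol)
    return out


def resampling_mixed_anova(
    table: pd.DataFrame,
    n_iter: int = DEFAULT_ANOVA_ITER,
    seed: int = DEFAULT_ANOVA_SEED,
    value_col: str | None = None,
) -> AnovaResult:
    """Seeded resampling Wald-type ANOVA on a group x visit layout.

    ``table`` is tidy with columns ``subject_id``, ``group``, ``visit``
    (V1/V2) and one value column. Subjects missing a visit are dropped
    with a warning; groups with fewer than two complete subjects raise.
    The null distribution resamples group-centred subject profiles with
    replacement within each group (a centred nonparametric bootstrap);
    p-values are the fraction of bootstrap statistics at or above the
    observed one, fully reproducible given ``seed``.
    """
    blocks = _pivot_visits(table, value_col)
    n_groups = len(blocks)
    if n_groups == 3:
        contrasts = (_C_GROUP, _C_VISIT, _C_INTERACTION)
    else:
        # general balanced construction for a != 3 (used by tests)
        a = n_groups
        cg = np.zeros((a - 1, 2 * a))
        for r in range(a - 1):
            cg[r, 0:2] = 0.5
            cg[r, 2 * (r + 1) : 2 * (r + 1) + 2] = -0.5
        cv = np.tile([1.0, -1.0], a)[None, :] / a
        ci = np.zeros((a - 1, 2 * a))
        for r in range(a - 1):
            ci[r, 0:2] = [1.0, -1.0]
            ci[r, 2 * (r + 1) : 2 * (r + 1) + 2] = [-1.0, 1.0]
        contrasts = (cg, cv, ci)

    ns = np.array([b.shape[0] for b in blocks])
    means = np.stack([b.mean(axis=0) for b in blocks])  # (a, 2)
    mu_obs = means.reshape(1, -1)
    cov_obs = np.stack([np.cov(b, rowvar=False) / b.shape[0] for b in blocks])[None, ...]
    q_obs = _wald_stats(mu_obs, cov_obs, contrasts)[:, 0]

    rng = np.random.default_rng(seed)
    mu_boot = np.empty((n_iter, 2 * len(blocks)))
    cov_boot = np.empty((n_iter, len(blocks), 2, 2))
    for g, block in enumerate(blocks):
        n = block.shape[0]
        resid = block - block.mean(axis=0)  # (n, 2), centred: global null holds
        idx = rng.integers(0, n, size=(n_iter, n))
        sample = resid[idx]  # (n_iter, n, 2)
        m = sample.mean(axis=1)
        dev = sample - m[:, None, :]
        s = np.einsum("nia,nib->nab", dev, dev) / (n - 1)
        mu_boot[:, 2 * g : 2 * g + 2] = m
        cov_boot[:, g] = s / n
    q_boot = _wald_stats(mu_boot, cov_boot, contrasts)
    p_group, p_visit, p_inter = (q_boot >= q_obs[:, None]).mean(axis=1)

    return AnovaResult(
        p_group=float(p_group), p_visit=float(p_visit), p_interaction=float(p_inter),
        stat_group=float(q_obs[0]), stat_visit=float(q_obs[1]), stat_interaction=float(q_obs[2]),
        n_iter=n_iter, seed=seed, n_subjects=tuple(int(n) for n in ns),
    )


# ---------------------------------------------------------------------------
# correlations with FDR


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_with_fdr(
    scores: pd.DataFrame,
    powers: pd.DataFrame,
    zones: list[str] | None = None,
    bands: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman correlations between band/zone powers and test scores.

    Subject-visit rows are pooled across visits and groups. ``scores``
    carries ``subject_id``, ``visit`` and one column per test; ``powers``
    is the tidy band-power table. Per cell, incomplete pairs are deleted
    pairwise; cells with fewer than ``min_pairs`` complete pairs are
    flagged unavailable (NaN) and excluded from the single-family
    Benjamini-Hochberg adjustment across all remaining cells.

    Returns a tidy frame: band, zone, test, rho, p_raw, p_adj, n_pairs.
    """
    test_cols = [c for c in scores.columns if c not in ("subject_id", "visit", "group")]
    if not test_cols:
        raise ValueError("score table has no test columns")
    wide = powers.pivot_table(index=["subject_id", "visit"], columns=["band", "zone"],
                              values="relative_power", aggfunc="mean")
    score_wide = scores.set_index(["subject_id", "visit"])[test_cols]
    common = wide.index.intersection(score_wide.index)
    wide, score_wide = wide.loc[common], score_wide.loc[common]

    records = []
    band_list = bands or list(dict.fromkeys(powers["band"]))
    zone_list = zones or list(dict.fromkeys(powers["zone"]))
    for band in band_list:
        for zone in zone_list:
            if (band, zone) not in wide.columns:
                continue
            power_col = wide[(band, zone)]
            for test in test_cols:
                pair = pd.concat([power_col, score_wide[test]], axis=1).dropna()
                n_pairs = len(pair)
                if n_pairs < min_pairs:
                    records.append((band, zone, test, np.nan, np.nan, np.nan, n_pairs))
                    continue
                rho, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                records.append((band, zone, test, float(rho), float(p), np.nan, n_pairs))
    out = pd.DataFrame(records, columns=["band", "zone", "test", "rho", "p_raw", "p_adj", "n_pairs"])
    valid = out["p_raw"].notna()
    if valid.any():
        out.loc[valid, "p_adj"] = benjamini_hochberg(out.loc[valid, "p_raw"].to_numpy())
    return out
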