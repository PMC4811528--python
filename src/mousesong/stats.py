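"""The study's statistical layer.

Count summaries with the documented exclusion and zero policies, Wilcoxon
post-hoc comparisons with Bonferroni correction, the between-trial
consistency correlation, a PERMANOVA whose permutations are restricted to
the female dyads (the repeated-measures unit), Fisher linear discriminant
analysis with loadings and proportion of trace, and chi-square tests of
syllable-type usage on the merged taxonomy.

The PERMANOVA partitions the squared inter-point distances of the
(standardized) feature matrix into among-group and residual components,

    pseudo-F = (SS_among / (a - 1)) / (SS_within / (N - a)),

and calibrates it against group labels permuted independently *within each
dyad*, never across dyads, so the null distribution respects the repeated
measurements.  With one block, one feature and Euclidean distance the
pseudo-F equals the classical one-way ANOVA F exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from mousesong.context import COUNT_REGIONS, PairNightCounts
from mousesong.errors import ValidationError


# ---------------------------------------------------------------------------
# Count summaries


@dataclass
class SummaryResult:
    mean: float
    sd: float | None
    n: int
    grouping: str = ""

    def __str__(self) -> str:
        sd = f" ± {self.sd:.2f}" if self.sd is not None else ""
        return f"{self.grouping}: {self.mean:.2f}{sd} (n = {self.n})"


def summarize_counts(
    rows: list[PairNightCounts],
    night: int,
    region: str | None = None,
    zero_policy: str = "keep",
    include_mb: bool = False,
    apply_exclusions: bool = True,
) -> SummaryResult:
    """Mean and sample sd of per-pair song counts for one night.

    With ``region=None`` the value per pair is the night total; a specific
    region selects that column.  ``zero_policy='drop_zero'`` omits pairs
    with no songs in the selection (used for per-region summaries, where a
    pair that never sang in a region contributes no observation).
    ``include_mb`` adds the separately listed male-bedding songs to night
    totals.  Excluded pair-nights are dropped; pairs without a session in
    that night (three-night protocol) contribute nothing.
    """
    if region is not None and region not in COUNT_REGIONS:
        raise ValidationError(f"unknown region {region!r}")
    if zero_policy not in ("keep", "drop_zero"):
        raise ValidationError("zero_policy must be 'keep' or 'drop_zero'")
    values = []
    for r in rows:
        if r.night != night:
            continue
        if apply_exclusions and r.excluded:
            continue
        v = r.counts.get(region, 0) if region else r.total
        if region is None and include_mb:
            v += r.mb
        if zero_policy == "drop_zero" and v == 0:
            continue
        values.append(float(v))
    if not values:
        raise ValidationError(f"no counts selected for night {night}")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    label = f"night {night}" + (f", region {region}" if region else "")
    return SummaryResult(mean=float(arr.mean()), sd=sd, n=arr.size,
                         grouping=label)


# ---------------------------------------------------------------------------
# Wilcoxon post-hocs


def pairwise_wilcoxon(
    groups: dict[str, np.ndarray],
    paired: bool = False,
    alpha: float = 0.05,
    m_comparisons: int | None = None,
) -> pd.DataFrame:
    """All pairwise Wilcoxon tests with a Bonferroni verdict.

    Paired data use the signed-rank test, independent samples the rank-sum
    (Mann-Whitney) test; scipy picks the exact null for small samples
    without ties and the tie-corrected normal approximation otherwise.
    The verdict column flags p < alpha / m over the m comparisons run.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    pairs = list(combinations(names, 2))
    m = m_comparisons if m_comparisons is not None else len(pairs)
    threshold = alpha / m
    recs = []
    for a, b in pairs:
        x = np.asarray(groups[a], float)
        y = np.asarray(groups[b], float)
        if paired:
            if x.size != y.size:
                raise ValidationError(
                    f"paired groups {a!r}/{b!r} differ in length"
                )
            if np.all(x == y):
                p = 1.0
            else:
                p = float(sps.wilcoxon(x, y).pvalue)
        else:
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        recs.append({"group_a": a, "group_b": b, "p": p,
                     "significant": p < threshold})
    out = pd.DataFrame(recs)
    out.attrs["alpha"] = alpha
    out.attrs["m"] = m
    out.attrs["threshold"] = threshold
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    return alpha / m


# ---------------------------------------------------------------------------
# Trial consistency


def trial_consistency(
    rows: list[PairNightCounts], nights: tuple[int, ...] = (1, 2, 3)
) -> tuple[float, float]:
    """Pearson correlation between first-trial and repetition song totals.

    Totals run over nights 1-3, the length of the repetition protocol.
    Only pairs with repetition data enter; fewer than 3 such pairs leave
    the correlation meaningless and raise.
    """
    first: dict[str, float] = {}
    second: dict[str, float] = {}
    for r in rows:
        if r.night not in nights or r.repetition_total is None:
            continue
        first[r.pair_id] = first.get(r.pair_id, 0.0) + r.total
        second[r.pair_id] = second.get(r.pair_id, 0.0) + r.repetition_total
    pairs = sorted(first)
    if len(pairs) < 3:
        raise ValidationError(
            f"need >= 3 pairs with repetition data, got {len(pairs)}"
        )
    x = np.array([first[p] for p in pairs])
    y = np.array([second[p] for p in pairs])
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Restricted-permutation PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p: float
    n_perm: int
    seed: int | None
    degenerate: bool = False

    def __str__(self) -> str:
        return (f"pseudo-F({self.df_between}) = {self.pseudo_F:.2f}, "
                f"p = {self.p:.4g} ({self.n_perm} permutations)")


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _gower_distance(X: np.ndarray) -> np.ndarray:
    """Range-normalized Manhattan distance (Gower for all-numeric data)."""
    rng = np.ptp(X, axis=0)
    rng = np.where(rng > 0, rng, 1.0)
    Z = X / rng
    return np.abs(Z[:, None, :] - Z[None, :, :]).mean(axis=2)


def _pseudo_f(D2: np.ndarray, labels: np.ndarray,
              uniq: np.ndarray) -> tuple[float, float, float]:
    """Pseudo-F from the distance-matrix partition (any metric)."""
    n = len(labels)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    a = uniq.size
    if ss_within <= 0:
        return np.nan, ss_among, ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among, ss_within


def _pseudo_f_euclidean(Z: np.ndarray, codes: np.ndarray,
                        n_groups: int) -> tuple[float, float, float]:
    """Pseudo-F via group centroids — identical to the Euclidean
    distance-matrix partition (the squared inter-point distances within a
    group sum to n_g times the squared deviations from its centroid), but
    O(n p) per evaluation instead of O(n^2)."""
    n = Z.shape[0]
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, Z.shape[1]))
    np.add.at(sums, codes, Z)
    means = sums / counts[:, None]
    ss_total = float(((Z - Z.mean(axis=0)) ** 2).sum())
    ss_within = float((Z ** 2).sum() - (counts[:, None] * means ** 2).sum())
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.nan, ss_among, ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among, ss_within


def permanova_restricted(
    X: np.ndarray,
    groups,
    blocks=None,
    n_perm: int = 5000,
    seed: int | None = None,
    distance: str = "euclidean",
    standardize: bool = True,
) -> PermanovaResult:
    """PERMANOVA with permutations restricted to blocks (female dyads).

    ``X`` holds one observation per row; ``groups`` is the factor under
    test and ``blocks`` the unit within which labels may be shuffled.
    Features mix units (ms, kHz, counts), so they are z-scored before the
    Euclidean distance by default; ``distance='gower'`` uses the
    range-normalized Manhattan distance instead.  The p-value is
    (#{F_perm >= F_obs} + 1) / (n_perm + 1); identical observations
    everywhere make F undefined and return p = 1 with the degenerate flag.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    groups = np.asarray(groups)
    n = X.shape[0]
    if groups.shape[0] != n:
        raise ValidationError("groups must align with rows of X")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValidationError("need at least two groups")
    if blocks is None:
        blocks = np.zeros(n, dtype=int)
    blocks = np.asarray(blocks)
    if blocks.shape[0] != n:
        raise ValidationError("blocks must align with rows of X")
    block_idx = [np.flatnonzero(blocks == b) for b in np.unique(blocks)]
    if all(idx.size < 2 for idx in block_idx):
        raise ValidationError(
            "all blocks are singletons: no permutation is possible"
        )
    Z = _standardize(X) if standardize else X
    _, codes = np.unique(groups, return_inverse=True)
    a = uniq.size
    if distance == "euclidean":
        euclid = True
        f_obs, ss_among, ss_within = _pseudo_f_euclidean(Z, codes, a)
    elif distance == "gower":
        euclid = False
        D2 = _gower_distance(Z) ** 2
        f_obs, ss_among, ss_within = _pseudo_f(D2, groups, uniq)
    else:
        raise ValidationError("distance must be 'euclidean' or 'gower'")
    df_b, df_w = a - 1, n - a
    if not np.isfinite(f_obs):
        return PermanovaResult(np.nan, df_b, df_w, 1.0, n_perm, seed,
                               degenerate=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = codes.copy()
    base_sorted = [np.sort(codes[idx]) for idx in block_idx]
    for _ in range(n_perm):
        for idx in block_idx:
            perm[idx] = rng.permutation(perm[idx])
        for idx, base in zip(block_idx, base_sorted):
            # the restriction itself, checked per draw
            assert np.array_equal(np.sort(perm[idx]), base)
        if euclid:
            f_p, _, _ = _pseudo_f_euclidean(Z, perm, a)
        else:
            f_p, _, _ = _pseudo_f(D2, perm, uniq)
        if np.isfinite(f_p) and f_p >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), df_b, df_w, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Fisher LDA


@dataclass
class LdaResult:
    loadings: pd.DataFrame
    trace_proportions: np.ndarray
    projections: np.ndarray
    group_means: pd.DataFrame

    @property
    def n_discriminants(self) -> int:
        return self.loadings.shape[1]


def fisher_lda(
    X: np.ndarray,
    groups,
    feature_names: list[str] | None = None,
    ridge: float = 1e-8,
) -> LdaResult:
    """Fisher discriminants of the within/between scatter problem.

    Solves Sb w = λ Sw w; the proportion-of-trace column reports each
    discriminant's eigenvalue share of the total discriminatory variance,
    and the loadings are scaled so each discriminant has unit pooled
    within-group variance (the convention of the classical implementations
    in this field).  A singular within-class scatter is ridge-regularized
    with a warning.
    """
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    n, p = X.shape
    if groups.shape[0] != n:
        raise ValidationError("groups must align with rows of X")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValidationError("need at least two groups")
    if n <= p:
        raise ValidationError("need more observations than features")
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means = {}
    for g in uniq:
        Xg = X[groups == g]
        mg = Xg.mean(axis=0)
        means[g] = mg
        C = Xg - mg
        Sw += C.T @ C
        d = (mg - grand)[:, None]
        Sb += Xg.shape[0] * (d @ d.T)
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "within-class scatter is singular; ridge-regularizing",
            RuntimeWarning, stacklevel=2,
        )
        Sw = Sw + ridge * max(np.trace(Sw) / p, 1.0) * np.eye(p)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    k = min(p, uniq.size - 1)
    evals = np.clip(evals[order][:k], 0.0, None)
    W = evecs[:, order][:, :k]
    # unit pooled within-group variance per discriminant
    pooled = Sw / (n - uniq.size)
    scale = np.sqrt(np.einsum("ij,jk,ki->i", W.T, pooled, W))
    scale = np.where(scale > 0, scale, 1.0)
    W = W / scale
    total = evals.sum()
    props = evals / total if total > 0 else np.full(k, 1.0 / k)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    cols = [f"LD{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(W, index=feature_names, columns=cols)
    projections = (X - grand) @ W
    gm = pd.DataFrame({g: means[g] for g in uniq}, index=feature_names).T
    return LdaResult(loadings=loadings, trace_proportions=props,
                     projections=projections, group_means=gm)


# ---------------------------------------------------------------------------
# Chi-square on merged syllable-type usage


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p: float

    def __str__(self) -> str:
        return f"X^2({self.df}) = {self.statistic:.1f}, p = {self.p:.4g}"


def chisq_type_usage(counts: pd.DataFrame | np.ndarray) -> ChisqResult:
    """Pearson chi-square on a region x merged-type contingency table.

    Expects the merged taxonomy (two-jump subtypes folded into JMP) so no
    cell class is vanishingly rare.  All-zero rows or columns carry no
    information and are dropped with a warning.
    """
    table = pd.DataFrame(counts).astype(float)
    if (table.values < 0).any():
        raise ValidationError("counts must be non-negative")
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping all-zero rows {list(zero_rows)} / columns "
            f"{list(zero_cols)}", RuntimeWarning, stacklevel=2,
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need a table of at least 2 x 2 after dropping")
    res = sps.chi2_contingency(table.values, correction=False)
    return ChisqResult(statistic=float(res.statistic), df=int(res.dof),
                       p=float(res.pvalue))
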