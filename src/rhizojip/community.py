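"""Community diversity, ordination, permutation tests, correlation and
LDA-effect-size biomarker discovery for rhizosphere abundance tables.

The stage mirrors the standard metagenomic downstream toolkit: ACE richness
(Chao-Lee), Bray-Curtis dissimilarity + principal coordinates, ANOSIM with
seedable permutations (exhaustive when feasible), core-taxon Venn counting,
top-N genus profiling, Spearman taxon-trait correlation with joint
Benjamini-Hochberg adjustment, and a two-group LEfSe-style biomarker screen
(Kruskal-Wallis gate followed by a bootstrapped linear-discriminant effect
size on per-million abundances, reported on the log10 scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, logger

PER_MILLION = 1.0e6


# ---------------------------------------------------------------------------
# scaling & alpha diversity
# ---------------------------------------------------------------------------


def total_sum_scale(table: AbundanceTable, scale: float = 1.0) -> AbundanceTable:
    """Scale each sample to a constant row sum (1 by default, 1e6 for LDA)."""
    sums = table.row_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"empty sample (zero total count): {zero.index[0]!r}")
    return AbundanceTable(table.values.div(sums, axis=0) * scale)


@dataclass
class ACEBreakdown:
    """Chao-Lee abundance-based coverage estimator with its intermediates."""

    s_obs: int
    s_abund: int
    s_rare: int
    n_rare: int
    f_i: np.ndarray
    c_ace: float
    gamma2: float
    ace: float
    fallback: bool = False


def ace_index(counts, rare_threshold: int = 10) -> ACEBreakdown:
    """ACE richness estimate from a single sample's count vector.

    Taxa with counts in [1, rare_threshold] are "rare"; coverage
    C = 1 - F1/N_rare. When no rare taxa exist or coverage is zero the
    estimate falls back to S_obs with ``fallback=True``.
    """
    x = np.asarray(counts)
    if not np.all(np.equal(np.mod(x, 1), 0)) or (x < 0).any():
        raise ValueError("counts must be non-negative integers")
    x = x[x > 0].astype(int)
    s_obs = x.size
    rare = x[x <= rare_threshold]
    s_rare = rare.size
    s_abund = s_obs - s_rare
    n_rare = int(rare.sum())
    f_i = np.bincount(rare, minlength=rare_threshold + 1)[1:]
    f1 = int(f_i[0]) if f_i.size else 0

    if s_rare == 0 or n_rare == 0:
        return ACEBreakdown(s_obs, s_abund, s_rare, n_rare, f_i, 1.0, 0.0,
                            float(s_obs), fallback=True)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("ACE undefined (all rare taxa are singletons); "
                       "falling back to S_obs")
        return ACEBreakdown(s_obs, s_abund, s_rare, n_rare, f_i, c_ace, 0.0,
                            float(s_obs), fallback=True)
    i = np.arange(1, rare_threshold + 1)
    sum_iif = float((i * (i - 1) * f_i).sum())
    if n_rare > 1:
        gamma2 = max(s_rare / c_ace * sum_iif / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    ace = s_abund + s_rare / c_ace + f1 / c_ace * gamma2
    return ACEBreakdown(s_obs, s_abund, s_rare, n_rare, f_i, c_ace, gamma2,
                        float(ace))


def ace_table(table: AbundanceTable, rare_threshold: int = 10) -> pd.DataFrame:
    """ACE per sample (columns: sample_id, s_obs, ace, fallback)."""
    rows = []
    for sid in table.samples:
        b = ace_index(table.values.loc[sid].to_numpy(), rare_threshold)
        rows.append({"sample_id": sid, "s_obs": b.s_obs, "ace": b.ace,
                     "fallback": b.fallback})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y)."""
    x = table.values.to_numpy(float)
    if (x.sum(axis=1) == 0).any():
        sid = table.samples[int(np.argmax(x.sum(axis=1) == 0))]
        raise ValueError(f"all-zero sample {sid!r}: Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes, columns PC1..PCk
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    variance_explained: np.ndarray  # percent of positive-eigenvalue total
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def pcoa(distances: pd.DataFrame) -> OrdinationResult:
    """Classical scaling (PCoA) of a symmetric zero-diagonal distance matrix.

    Eigendecomposition of the Gower-centred -D^2/2 matrix; axes ordered by
    eigenvalue. Variance explained uses only the positive-eigenvalue total;
    negative eigenvalues are reported separately, not corrected.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    names = (
        list(distances.index)
        if isinstance(distances, pd.DataFrame)
        else list(range(n))
    )
    cols = [f"PC{i + 1}" for i in range(lam.size)]
    var_pct = 100.0 * lam / lam.sum() if lam.size else lam
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=names, columns=cols),
        eigenvalues=lam,
        variance_explained=var_pct,
        negative_eigenvalues=evals[evals < -tol],
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    method: str  # "exhaustive" or "montecarlo"


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return (r_b - r_w) / (m / 2.0)


def _count_label_permutations(counts) -> float:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def anosim(
    distances: pd.DataFrame,
    grouping,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> AnosimResult:
    """ANOSIM R with a permutation p value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 ranked distances. When the number of distinct label
    permutations is at most 10,000 the null distribution is enumerated
    exhaustively (p = proportion of labelings with R >= observed); otherwise
    Monte-Carlo with the add-one rule p = (1 + #{R_perm >= R_obs}) / (1 + B).
    """
    labels = np.asarray(list(grouping))
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("grouping length must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("ANOSIM requires >= 2 members per group")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu, ju])
    within_obs = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within_obs)

    n_distinct = _count_label_permutations(counts)
    if n_distinct <= 10_000:
        from sympy.utilities.iterables import multiset_permutations

        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            lab = np.asarray(perm)
            r = _anosim_r(ranks, lab[iu] == lab[ju])
            count_ge += r >= r_obs - 1e-12
            total += 1
        return AnosimResult(r_obs, count_ge / total, total, seed, "exhaustive")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
    within = perms[:, iu] == perms[:, ju]  # (B, M) boolean
    n_within = within_obs.sum()
    m = ranks.size
    sum_w = within @ ranks
    sum_all = ranks.sum()
    r_perm = ((sum_all - sum_w) / (m - n_within) - sum_w / n_within) / (m / 2.0)
    count_ge = int((r_perm >= r_obs - 1e-12).sum())
    p = (1 + count_ge) / (1 + n_permutations)
    logger.debug("ANOSIM Monte-Carlo with seed %s", seed)
    return AnosimResult(r_obs, p, n_permutations, seed, "montecarlo")


# ---------------------------------------------------------------------------
# core taxa & profiling
# ---------------------------------------------------------------------------


@dataclass
class CoreTaxaResult:
    per_group_richness: dict[str, int]
    present: dict[str, set]
    n_core: int
    n_union: int
    core_pct: float


def core_taxa(
    table: AbundanceTable, design: pd.DataFrame, detection: float = 1
) -> CoreTaxaResult:
    """Per-group presence sets and the shared-core count over all groups.

    A taxon is present in a group when its group-summed count reaches the
    detection threshold. core_pct = 100 * |intersection| / |union|.
    """
    merged = table.values.copy()
    merged["__group"] = design.set_index("sample_id").loc[table.samples, "group"].values
    sums = merged.groupby("__group").sum()
    present = {
        g: set(sums.columns[(sums.loc[g] >= detection).to_numpy()])
        for g in sums.index
    }
    sets = list(present.values())
    core = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    pct = 100.0 * len(core) / len(union) if union else float("nan")
    return CoreTaxaResult(
        {g: len(s) for g, s in present.items()}, present, len(core), len(union), pct
    )


def top_n_taxa(table: AbundanceTable, n: int = 50, rank: str = "genus") -> list[str]:
    """Top-n taxa at a rank by total relative abundance; ties lexicographic."""
    at = table.at_rank(rank)
    rel = at.values.div(at.row_sums(), axis=0)
    totals = rel.sum(axis=0)
    order = sorted(totals.index, key=lambda name: (-totals[name], name))
    return order[:n]


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """taxon x indicator grids of rank correlation, raw p, BH q and flags."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    flags: pd.DataFrame  # stars from raw p (mirrors heatmap annotation)
    method: str = "spearman"


def _rank_correlation_grid(x: np.ndarray, y: np.ndarray, method: str):
    """Columnwise correlation of x (n x a) against y (n x b) with t-approx p."""
    n = x.shape[0]
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
        y = stats.rankdata(y, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xc.T @ yc) / np.outer(sx, sy)
    rho[np.outer(sx == 0, np.ones(sy.size, bool))] = np.nan
    rho[np.outer(np.ones(sx.size, bool), sy == 0)] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return rho, p


def correlate_taxa_physiology(
    table: AbundanceTable,
    physiology: pd.DataFrame,
    design: pd.DataFrame,
    method: str = "spearman",
    top_n: int | None = None,
    rank: str | None = None,
) -> CorrelationResult:
    """Rank-correlation screen of taxa against physiological indicators.

    Optionally aggregates to a taxonomic rank and keeps the top-n most
    abundant taxa first. BH adjustment is applied jointly across the whole
    taxon x indicator grid; constant vectors yield missing correlations that
    are excluded from the adjustment.
    """
    if rank is not None:
        keep = top_n_taxa(table, n=top_n or len(table.taxa), rank=rank)
        table = AbundanceTable(table.at_rank(rank).values[keep])
    elif top_n is not None:
        totals = total_sum_scale(table).values.sum(axis=0)
        keep = sorted(totals.index, key=lambda t: (-totals[t], t))[:top_n]
        table = AbundanceTable(table.values[keep])

    phys_wide = physiology.pivot(index="sample_id", columns="indicator", values="value")
    shared = [s for s in table.samples if s in phys_wide.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples for a correlation screen")
    rel = total_sum_scale(table.subset_samples(shared))
    y = phys_wide.loc[shared]

    rho, p = _rank_correlation_grid(
        rel.values.to_numpy(float), y.to_numpy(float), method
    )
    taxa, indicators = rel.taxa, list(y.columns)
    rho_df = pd.DataFrame(rho, index=taxa, columns=indicators)
    p_df = pd.DataFrame(p, index=taxa, columns=indicators)

    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask].ravel(), method="fdr_bh")[1]
    q_df = pd.DataFrame(q, index=taxa, columns=indicators)

    def star(v: float) -> str:
        if np.isnan(v):
            return ""
        return "**" if v < 0.01 else "*" if v < 0.05 else ""

    flags = p_df.map(star)
    return CorrelationResult(rho_df, p_df, q_df, flags, method)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------


def kruskal_wallis_screen(
    table: AbundanceTable, grouping, alpha: float = 0.05
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per taxon with chi-square p values.

    Vectorised over taxa. All-tied taxa get p = 1 and never pass.
    Returns columns taxon, H, p, passed.
    """
    labels = np.asarray(list(grouping))
    x = table.values.to_numpy(float)
    n = x.shape[0]
    if n != len(labels):
        raise ValueError("grouping length must match sample count")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    ranks = stats.rankdata(x, axis=0)
    h = np.zeros(x.shape[1])
    for g in uniq:
        sel = labels == g
        h += ranks[sel].sum(axis=0) ** 2 / sel.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction: divide by 1 - sum(t^3 - t) / (n^3 - n), per taxon
    corr = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        _, t = np.unique(x[:, j], return_counts=True)
        corr[j] = 1.0 - float((t**3 - t).sum()) / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = h / corr
    p = stats.chi2.sf(h, df=len(uniq) - 1)
    all_tied = corr <= 0
    h[all_tied] = np.nan
    p[all_tied] = 1.0
    return pd.DataFrame(
        {"taxon": table.taxa, "H": h, "p": p, "passed": p < alpha}
    )


@dataclass
class BiomarkerResult:
    taxon: str
    p: float
    enriched_group: str
    lda_score: float  # log10 effect size; NaN when stage 1 fails
    passes: bool


def lda_effect_size(
    table: AbundanceTable,
    grouping,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    subsample: float = 2.0 / 3.0,
    seed: int = 0,
    shrinkage: float = 1e-3,
) -> list[BiomarkerResult]:
    """Two-group LEfSe-style biomarker discovery.

    Stage 1 gates taxa through a Kruskal-Wallis screen at ``alpha``. Stage 2
    scales survivors to per-million, then over ``n_boot`` bootstrap rounds
    subsamples ``subsample`` of each class (without replacement), fits a
    one-dimensional linear discriminant (with a small covariance shrinkage
    ridge for degenerate within-class variance), and scores each survivor as
    the average of its raw class-mean difference and its share of the
    discriminant-projected class-mean difference. The effect size is log10
    of the bootstrap mean, floored at 1 (so scores are >= 0); a biomarker
    passes iff p < alpha and score > ``lda_threshold``. The enriched group
    is the class with the higher mean abundance.
    """
    labels = np.asarray(list(grouping))
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("biomarker discovery compares exactly two groups")
    n_a, n_b = (labels == uniq[0]).sum(), (labels == uniq[1]).sum()
    if min(n_a, n_b) < 3:
        raise ValueError("need >= 3 samples per group")

    screen = kruskal_wallis_screen(table, labels, alpha=alpha)
    ppm = total_sum_scale(table, scale=PER_MILLION)
    x_all = ppm.values.to_numpy(float)
    survivors = np.flatnonzero(screen["passed"].to_numpy())

    scores = np.full(len(table.taxa), np.nan)
    if survivors.size:
        xs = x_all[:, survivors]
        rng = np.random.default_rng(seed)
        idx_a = np.flatnonzero(labels == uniq[0])
        idx_b = np.flatnonzero(labels == uniq[1])
        k_a = max(2, int(np.floor(subsample * n_a)))
        k_b = max(2, int(np.floor(subsample * n_b)))
        boot_scores = []
        for _ in range(n_boot):
            sel = np.concatenate(
                [rng.choice(idx_a, k_a, replace=False),
                 rng.choice(idx_b, k_b, replace=False)]
            )
            xb, yb = xs[sel], labels[sel]
            lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
            try:
                lda.fit(xb, yb)
            except np.linalg.LinAlgError:  # pragma: no cover - ridge guards this
                logger.warning("LDA fit failed on a bootstrap round; skipped")
                continue
            w = lda.coef_.ravel()
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            w_unit = w / norm
            mean_diff = xb[yb == uniq[0]].mean(axis=0) - xb[yb == uniq[1]].mean(axis=0)
            proj_diff = abs(float(mean_diff @ w_unit))
            boot_scores.append((np.abs(mean_diff) + np.abs(w_unit) * proj_diff) / 2.0)
        if boot_scores:
            mean_scores = np.mean(boot_scores, axis=0)
            scores[survivors] = np.log10(np.maximum(mean_scores, 1.0))

    mean_a = x_all[labels == uniq[0]].mean(axis=0)
    mean_b = x_all[labels == uniq[1]].mean(axis=0)
    enriched = np.where(mean_a >= mean_b, uniq[0], uniq[1])

    results = []
    for j, taxon in enumerate(table.taxa):
        p = float(screen["p"].iloc[j])
        score = float(scores[j])
        passes = bool(p < alpha and not np.isnan(score) and score > lda_threshold)
        results.append(
            BiomarkerResult(taxon, p, str(enriched[j]), score, passes)
        )
    return results


def biomarker_table(results: list[BiomarkerResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
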