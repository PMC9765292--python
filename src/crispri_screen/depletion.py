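"""Guide-level log2 fold changes and gene-level depletion scores.

For a contrast (treatment vs control) every included guide — single
target, coding-feature targeting — gets

    lfc = log2((n_treat + pseudocount) / (n_ctrl + pseudocount))

on normalized counts, and a rank percentile u = rank(lfc)/n over the
included pool (average ranks on ties). The signed gene score is the
median of its guides' lfc values. Significance comes from a robust
rank aggregation: with a gene's sorted percentiles u(1) <= ... <= u(k),

    rho = min_{j : u(j) <= alpha} BetaCDF(u(j); j, k - j + 1)

(rho = 1 when no percentile clears alpha), i.e. the best order-statistic
evidence that the gene's guides sit unusually low in the ranking. The
permutation null re-assigns percentiles from the pooled ranking to gene
slots of the same size; p = (1 + #{rho_perm <= rho_obs}) / (B + 1),
Benjamini-Hochberg adjusted within each tail. The enrichment tail uses
the reversed percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from crispri_screen.counts import NormalizedCounts
from crispri_screen.design import GuideLibrary


@dataclass
class ContrastConfig:
    treatment: str
    control: str
    pseudocount: float = 1.0
    alpha: float = 0.25
    n_permutations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def included_guide_genes(library: GuideLibrary) -> pd.Series:
    """spacer -> locus_tag for guides admitted to gene-level statistics.

    Multi-target spacers and intergenic guides are excluded. A guide
    passing the strand rule for several overlapping features is assigned
    to the feature with the largest protospacer overlap.
    """
    mapping: dict[str, str] = {}
    for g in library.guides:
        if g.multi_target or g.target_class != "cds_rule_pass" or not g.targets:
            continue
        best = max(g.targets, key=lambda t: (t[1], t[0]))
        mapping[g.spacer] = best[0]
    return pd.Series(mapping, name="gene")


def guide_lfc(
    norm: NormalizedCounts, cfg: ContrastConfig, library: GuideLibrary
) -> pd.DataFrame:
    """Per-guide lfc and rank percentiles for one condition contrast.

    Returns a DataFrame indexed by spacer with columns ``gene``, ``lfc``,
    ``u_neg`` (depletion percentile) and ``u_pos`` (enrichment
    percentile).
    """
    for cond in (cfg.treatment, cfg.control):
        if cond not in norm.matrix.columns:
            raise KeyError(f"condition column {cond!r} missing from normalized counts")
    genes = included_guide_genes(library)
    common = norm.matrix.index.intersection(genes.index)
    if common.empty:
        raise ValueError("no included guides present in the count matrix")
    t = norm.matrix.loc[common, cfg.treatment].to_numpy(dtype=float)
    c = norm.matrix.loc[common, cfg.control].to_numpy(dtype=float)
    lfc = np.log2((t + cfg.pseudocount) / (c + cfg.pseudocount))
    n = len(lfc)
    u_neg = sps.rankdata(lfc, method="average") / n
    u_pos = sps.rankdata(-lfc, method="average") / n
    return pd.DataFrame(
        {"gene": genes.loc[common].to_numpy(), "lfc": lfc, "u_neg": u_neg, "u_pos": u_pos},
        index=pd.Index(common, name="spacer"),
    )


def gene_depletion_score(stats: pd.DataFrame) -> pd.Series:
    """Signed per-gene score: the median of member guide lfc values."""
    return stats.groupby("gene")["lfc"].median().rename("score")


def rho_scores(U: np.ndarray, alpha: float) -> np.ndarray:
    """Rank-aggregation rho for each row of percentiles U (shape m x k)."""
    S = np.sort(np.atleast_2d(U), axis=1)
    k = S.shape[1]
    j = np.arange(1, k + 1)
    B = sps.beta.cdf(S, j, k - j + 1)
    B = np.where(S <= alpha, B, np.inf)
    rho = B.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def _null_rho(
    pool: np.ndarray, k: int, alpha: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null rho distribution for genes of size k: percentiles re-assigned
    (without replacement) from the pooled ranking."""
    n = len(pool)
    if n_perm * n <= 20_000_000:
        # vectorized partial permutation: first k of a random ordering
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        draws = pool[idx]
    else:
        draws = np.empty((n_perm, k))
        for b in range(n_perm):
            draws[b] = rng.choice(pool, size=k, replace=False)
    return rho_scores(draws, alpha)


def rra_significance(stats: pd.DataFrame, cfg: ContrastConfig) -> pd.DataFrame:
    """Per-gene rank-aggregation rho, permutation p and BH FDR, both tails."""
    if stats.empty:
        raise ValueError("no guide statistics supplied")
    rng = np.random.default_rng(cfg.rng_seed)
    genes = stats.groupby("gene")
    sizes = genes.size()
    records: dict[str, dict[str, float]] = {
        g: {"n_guides": int(k)} for g, k in sizes.items()
    }

    for tail, col in (("neg", "u_neg"), ("pos", "u_pos")):
        pool = stats[col].to_numpy(dtype=float)
        null_cache: dict[int, np.ndarray] = {}
        obs: dict[str, float] = {}
        for gene, sub in genes:
            u = sub[col].to_numpy(dtype=float)
            obs[gene] = float(rho_scores(u[None, :], cfg.alpha)[0])
        for k in sorted(set(sizes)):
            null = _null_rho(pool, int(k), cfg.alpha, cfg.n_permutations, rng)
            null_cache[int(k)] = np.sort(null)
        names = list(obs)
        rho = np.array([obs[g] for g in names])
        p = np.empty_like(rho)
        for i, g in enumerate(names):
            null = null_cache[int(sizes[g])]
            p[i] = (1 + np.searchsorted(null, rho[i], side="right")) / (
                cfg.n_permutations + 1
            )
        fdr = sps.false_discovery_control(p, method="bh")
        for i, g in enumerate(names):
            records[g][f"rho_{tail}"] = rho[i]
            records[g][f"p_{tail}"] = p[i]
            records[g][f"fdr_{tail}"] = fdr[i]

    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "gene"
    return out.sort_index()


def score_contrast(
    norm: NormalizedCounts,
    library: GuideLibrary,
    cfg: ContrastConfig,
    with_significance: bool = True,
) -> pd.DataFrame:
    """Full gene table for one contrast: score (median lfc) plus, when
    requested, rank-aggregation significance columns."""
    stats = guide_lfc(norm, cfg, library)
    score = gene_depletion_score(stats)
    if with_significance:
        sig = rra_significance(stats, cfg)
        out = sig.join(score)
    else:
        out = pd.DataFrame({"n_guides": stats.groupby("gene").size(), "score": score})
        out.index.name = "gene"
    cols = ["n_guides", "score"] + [c for c in out.columns if c not in ("n_guides", "score")]
    return out[cols].sort_index()
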