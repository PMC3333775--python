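"""Stage-II gene set tests on a table of gene-to-phenotype scores.

Two complementary nulls:

* **competitive** — are scores of genes in set s larger than scores of the
  remaining annotated genes? One-sided Mann-Whitney rank test. Valid only on
  the *intersection* gene universe: the deviance score grows with the number
  of predictors, so genes measured on fewer platforms would be unfairly
  ranked against genes measured everywhere.

* **self-contained** — are the observed scores of the genes in s larger than
  their own scores under phenotype-label permutation? For each of B permuted
  re-scorings, the one-sample Wilcoxon signed-rank statistic of the paired
  differences (observed minus permuted) is computed; the B statistics are
  averaged and referred to the normal approximation of the signed-rank null
  (mean n(n+1)/4, variance n(n+1)(2n+1)/24). Because each gene is compared
  against its own permutation distribution, the union universe is allowed:
  the number of platforms per gene is identical in observed and null tables
  by construction.

Both tests are rank-based and therefore invariant to any strictly monotone
transform of the score scale. One-sided alternatives throughout: scores are
non-negative association strengths, enrichment means larger scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetCollection, MultiOmicStudy
from .exceptions import InputError
from .gene_scores import GeneScoreTable, ModelSpec, ScoreEngine

__all__ = [
    "SetResult",
    "PermutationNull",
    "competitive_test",
    "competitive_all",
    "build_permutation_null",
    "selfcontained_test",
    "selfcontained_all",
]

RESULT_COLUMNS = ["set_id", "method", "n_genes", "statistic", "p"]


@dataclass
class SetResult:
    """One set-level test outcome."""

    set_id: str
    method: str
    n_genes_used: int
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InputError(f"p-value {self.p_value} outside [0, 1]")


def _as_score_series(scores, method: str) -> pd.Series:
    if isinstance(scores, GeneScoreTable):
        if method == "INT" or method in scores.platforms:
            series = scores.scores(method)
        else:
            raise KeyError(method)
        return series
    return pd.Series(scores).dropna()


def _check_intersection(scores) -> None:
    if isinstance(scores, GeneScoreTable):
        n_plat = scores.frame["n_platforms"]
        if n_plat.nunique() > 1:
            raise InputError(
                "competitive test requires scores computed on the intersection "
                "universe (genes measured on all platforms); this table mixes "
                f"platform counts {sorted(n_plat.unique())}"
            )


def _mannwhitney_batch(
    values: np.ndarray,
    member: np.ndarray,
    continuity: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided (greater) Mann-Whitney over S sets sharing one ranking.

    ``member`` is a boolean (S, N) matrix. Returns (U, p) arrays using the
    normal approximation with tie correction.
    """
    n_total = values.size
    ranks = stats.rankdata(values)
    n1 = member.sum(axis=1).astype(float)
    n2 = n_total - n1
    r_in = member @ ranks
    u = r_in - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    cc = 0.5 if continuity else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mean - cc) / np.sqrt(var)
    p = stats.norm.sf(z)
    p = np.where(var <= 0, 0.5, p)
    return u, p


def competitive_test(
    scores,
    collection: GeneSetCollection,
    set_id: str,
    method: str = "INT",
    exact_threshold: int = 8,
    continuity: bool = False,
) -> SetResult | None:
    """One-sided Mann-Whitney test of set ``set_id`` against the remaining
    annotated genes.

    Exact enumeration (via scipy) when ``min(n_in, n_out) <= exact_threshold``
    and there are no ties; normal approximation with tie correction
    otherwise. Returns None (skipped) when the set has no scored gene or no
    scored non-member exists.
    """
    _check_intersection(scores)
    series = _as_score_series(scores, method)
    annotated = series.index.intersection(collection.universe)
    members = frozenset(collection.genes(set_id))
    in_mask = annotated.isin(members)
    x = series.loc[annotated[in_mask]].to_numpy(dtype=float)
    y = series.loc[annotated[~in_mask]].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        return None
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= exact_threshold and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        u, p = float(res.statistic), float(res.pvalue)
    else:
        member = np.zeros((1, pooled.size), dtype=bool)
        member[0, : x.size] = True
        u_arr, p_arr = _mannwhitney_batch(pooled, member, continuity)
        u, p = float(u_arr[0]), float(min(max(p_arr[0], 0.0), 1.0))
    return SetResult(set_id, method, x.size, u, p)


def competitive_all(
    scores,
    collection: GeneSetCollection,
    method: str = "INT",
    exact_threshold: int = 8,
    continuity: bool = False,
) -> pd.DataFrame:
    """Competitive test of every set in the collection (shared ranking).

    Returns a SetResultTable DataFrame with columns
    ``set_id, method, n_genes, statistic, p``. Sets with no scored gene or
    empty complement are skipped.
    """
    _check_intersection(scores)
    series = _as_score_series(scores, method)
    annotated = series.index.intersection(collection.universe)
    values = series.loc[annotated].to_numpy(dtype=float)
    member = collection.membership_matrix(annotated).to_numpy()
    n1 = member.sum(axis=1)
    keep = (n1 >= 1) & (n1 < len(annotated))
    u, p = _mannwhitney_batch(values, member[keep], continuity)
    p = np.clip(p, 0.0, 1.0)
    set_ids = [s for s, k in zip(collection.set_ids, keep) if k]
    frame = pd.DataFrame(
        {
            "set_id": set_ids,
            "method": method,
            "n_genes": n1[keep].astype(int),
            "statistic": u,
            "p": p,
        }
    )
    # re-do small tie-free instances exactly
    no_ties = np.unique(values).size == values.size
    if no_ties:
        for i, (sid, n_in) in enumerate(zip(set_ids, n1[keep])):
            if min(n_in, len(annotated) - n_in) <= exact_threshold:
                res = competitive_test(
                    series, collection, sid, method, exact_threshold, continuity
                )
                frame.loc[i, ["statistic", "p"]] = res.statistic, res.p_value
    return frame


@dataclass
class PermutationNull:
    """B full re-scorings of a study under shuffled phenotype labels.

    Computed once per analysis and shared across all sets. ``tables`` maps a
    method ('INT' or platform id) to a (B, G) score array aligned with
    ``gene_ids``.
    """

    B: int
    seed: int
    universe_mode: str
    gene_ids: pd.Index
    tables: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.B < 1:
            raise InputError("need at least one permutation")


def build_permutation_null(
    study: MultiOmicStudy,
    universe: str = "union",
    B: int = 500,
    seed: int = 0,
    spec: ModelSpec | None = None,
    methods: Sequence[str] | None = None,
) -> PermutationNull:
    """Score the study under B independent label shuffles (seed-reproducible).

    Label shuffles preserve class counts. The standardized designs are built
    once and reused across permutations.
    """
    engine = ScoreEngine(study, universe, spec)
    y = study.phenotype.labels.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if methods is None:
        methods = ["INT", *study.platform_ids]
    gene_ids = pd.Index(engine.gene_ids, name="gene")
    tables = {m: np.full((B, len(gene_ids)), np.nan) for m in methods}
    for b in range(B):
        perm_scores, _ = engine.score_labels(rng.permutation(y), methods)
        for m in methods:
            tables[m][b] = perm_scores[m]
    return PermutationNull(
        B=B, seed=seed, universe_mode=universe, gene_ids=gene_ids, tables=tables
    )


def _signed_rank_stats(diffs: np.ndarray) -> np.ndarray:
    """W for each row of paired differences; zero diffs take half weight."""
    ranks = stats.rankdata(np.abs(diffs), axis=1)
    pos = (diffs > 0) * 1.0 + (diffs == 0) * 0.5
    return (ranks * pos).sum(axis=1)


def selfcontained_test(
    scores,
    null: PermutationNull,
    collection: GeneSetCollection,
    set_id: str,
    method: str = "INT",
) -> SetResult | None:
    """Permutation-averaged signed-rank test of set ``set_id``.

    For each permutation b the signed-rank statistic W_b of the paired
    differences (observed minus permuted score, over the set's genes) is
    computed; the mean over permutations is referred to the upper tail of
    the signed-rank normal approximation. Requires >= 2 genes scored in both
    the observed and null tables; returns None otherwise.
    """
    series = _as_score_series(scores, method)
    if method not in null.tables:
        raise InputError(f"permutation null holds no scores for method {method!r}")
    genes = [g for g in collection.genes(set_id) if g in series.index]
    pos = null.gene_ids.get_indexer(genes)
    genes = [g for g, i in zip(genes, pos) if i >= 0]
    pos = pos[pos >= 0]
    n = len(genes)
    if n < 2:
        return None
    obs = series.loc[genes].to_numpy(dtype=float)
    nulls = null.tables[method][:, pos]
    ok = ~np.isnan(nulls).any(axis=1)
    diffs = obs[None, :] - nulls[ok]
    w = _signed_rank_stats(diffs)
    w_bar = float(w.mean())
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    p = float(stats.norm.sf((w_bar - mean) / sd))
    return SetResult(set_id, method, n, w_bar, p)


def selfcontained_all(
    scores,
    null: PermutationNull,
    collection: GeneSetCollection,
    method: str = "INT",
) -> pd.DataFrame:
    """Self-contained test of every set; skipped sets are omitted."""
    rows = []
    for sid in collection.set_ids:
        res = selfcontained_test(scores, null, collection, sid, method)
        if res is not None:
            rows.append(
                (res.set_id, res.method, res.n_genes_used, res.statistic, res.p_value)
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
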