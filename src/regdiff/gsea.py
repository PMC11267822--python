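"""Preranked gene-set enrichment on the log2-median-ratio ranking.

Genes are ordered by descending LMR (group A high first) and each
gene set is scored with the Kolmogorov-Smirnov running-sum enrichment
score (ES): walking down the ranking, set members ("hits") push the
sum up by a normalized increment, non-members pull it down by
1/(N - k), and the ES is the running-sum value of maximal absolute
deviation from zero.  With ``weight_exponent`` = 0 the hit increment
is the unweighted 1/k; with 1 (the default, matching the convention
of the standard GSEA software) it is |score| / sum of hit |score|s.

Significance comes from a gene-tag permutation null: random gene sets
of identical size are drawn uniformly from the ranked genes, and the
p-value is the same-sign tail frequency of the null ES.  The
normalized enrichment score (NES) divides the observed ES by the mean
|null ES| of the same sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by descending ranking score, with deterministic ties.

    Ties are broken by lexicographic gene id order so the ranking — and
    therefore every downstream ES — is reproducible.
    """

    gene_ids: np.ndarray  # ordered, unique
    scores: np.ndarray  # aligned with gene_ids, descending

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise InputError("ranked list contains duplicate gene ids")
        if np.any(np.diff(self.scores) > 0):
            raise InputError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    leading_edge: frozenset[str]
    n_hits: int


def rank_by_lmr(stats: pd.DataFrame, score_col: str = "lmr") -> RankedList:
    """Order genes by descending LMR, ties by gene id."""
    if score_col not in stats.columns:
        raise InputError(f"stats table lacks column {score_col!r}")
    df = stats[[score_col]].copy()
    df["_gene"] = df.index.astype(str)
    df = df.sort_values([score_col, "_gene"], ascending=[False, True], kind="stable")
    n_ties = int(stats[score_col].duplicated().sum())
    if n_ties:
        logger.info("%d tied scores broken lexicographically", n_ties)
    return RankedList(df["_gene"].to_numpy(), df[score_col].to_numpy(dtype=float))


def _es_from_hits(
    scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: int
) -> tuple[float, np.ndarray]:
    """ES and full running sum for a boolean hit mask over the ranking."""
    n = scores.size
    k = int(hit_mask.sum())
    if weight_exponent == 0:
        hit_incr = np.full(n, 1.0 / k)
    else:
        w = np.abs(scores) ** weight_exponent
        total = w[hit_mask].sum()
        if total == 0:  # all hit scores are exactly 0: fall back to unweighted
            hit_incr = np.full(n, 1.0 / k)
        else:
            hit_incr = w / total
    steps = np.where(hit_mask, hit_incr, -1.0 / (n - k))
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    return float(running[extremum]), running


def enrichment_score(
    ranked: RankedList, gene_set: frozenset[str] | set[str], weight_exponent: int = 1
) -> tuple[float, np.ndarray]:
    """KS running-sum enrichment score of a gene set against a ranking.

    Returns (es, running_sum).  The set must intersect the ranked
    genes but not cover them all (otherwise no misses exist and the
    score is undefined).
    """
    if weight_exponent not in (0, 1):
        raise ConfigError("weight_exponent must be 0 or 1")
    hit_mask = np.isin(ranked.gene_ids, list(gene_set))
    k = int(hit_mask.sum())
    if k == 0:
        raise InputError("gene set has empty intersection with the ranked genes")
    if k == len(ranked):
        raise InputError("gene set covers every ranked gene; ES undefined")
    return _es_from_hits(ranked.scores, hit_mask, weight_exponent)


def leading_edge_genes(
    ranked: RankedList, gene_set: frozenset[str] | set[str], weight_exponent: int = 1
) -> frozenset[str]:
    """Hits at or before the running-sum extremum (after it for ES < 0)."""
    hit_mask = np.isin(ranked.gene_ids, list(gene_set))
    es, running = enrichment_score(ranked, gene_set, weight_exponent)
    extremum = int(np.argmax(np.abs(running)))
    if es >= 0:
        sel = hit_mask & (np.arange(len(ranked)) <= extremum)
    else:
        sel = hit_mask & (np.arange(len(ranked)) >= extremum)
    return frozenset(ranked.gene_ids[sel])


def gsea_significance(
    ranked: RankedList,
    gene_set: frozenset[str] | set[str],
    weight_exponent: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation p-value and NES for one gene set.

    The null ES distribution comes from ``n_perm`` random gene sets of
    the same effective size drawn uniformly from the ranked genes.
    p = (#{same-sign null with |null| >= |es|} + 1) / (#same-sign + 1);
    NES = es / mean(|same-sign null es|).
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    hit_mask = np.isin(ranked.gene_ids, list(gene_set))
    k = int(hit_mask.sum())
    es, _ = enrichment_score(ranked, gene_set, weight_exponent)

    rng = np.random.default_rng(seed)
    n = len(ranked)
    null_es = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        mask[:] = False
        mask[rng.choice(n, size=k, replace=False)] = True
        null_es[i], _ = _es_from_hits(ranked.scores, mask, weight_exponent)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        logger.warning("no same-sign null ES values; p-value saturated at 1")
        p = 1.0
        nes = es
    else:
        p = (int(np.sum(np.abs(null_es[same_sign]) >= abs(es))) + 1) / (n_same + 1)
        nes = es / float(np.mean(np.abs(null_es[same_sign])))
    leading = leading_edge_genes(ranked, gene_set, weight_exponent)
    return EnrichmentResult(
        set_name="", es=es, nes=float(nes), p_value=float(p),
        leading_edge=leading, n_hits=k,
    )


def run_gsea(
    stats: pd.DataFrame,
    collection: GeneSetCollection,
    weight_exponent: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    score_col: str = "lmr",
) -> pd.DataFrame:
    """Score every set in a collection against the LMR ranking.

    Sets with no overlap with the ranked genes are reported with NA
    values and a logged warning rather than aborting the batch.
    Returns a DataFrame indexed by set name (set size, es, nes, p,
    leading edge size and members).
    """
    ranked = rank_by_lmr(stats, score_col=score_col)
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(collection.sets))
    for sub_seed, (name, members) in zip(seeds, collection.sets.items()):
        try:
            res = gsea_significance(
                ranked, members, weight_exponent=weight_exponent,
                n_perm=n_perm, seed=int(sub_seed.generate_state(1)[0] % (2**31)),
            )
        except InputError as exc:
            logger.warning("gene set %s skipped: %s", name, exc)
            rows.append({"set_name": name, "n_hits": 0, "es": np.nan, "nes": np.nan,
                         "p_value": np.nan, "leading_edge": ""})
            continue
        rows.append({
            "set_name": name, "n_hits": res.n_hits, "es": res.es, "nes": res.nes,
            "p_value": res.p_value,
            "leading_edge": ",".join(sorted(res.leading_edge)),
        })
    return pd.DataFrame(rows).set_index("set_name")
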