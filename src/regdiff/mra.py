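"""Resampling-based master regulator (MR) discovery.

For each TF, the observed count of its targets among the DEGs is
compared with an empirical null built by repeatedly drawing |DEG|
genes uniformly without replacement from the measured gene universe
and counting regulon overlap.  Because draws are without replacement,
the marginal null for each TF is exactly hypergeometric — which the
test suite exploits as an independent oracle — but the p-value is
computed from the resampling distribution itself, one-tailed with
add-one smoothing.  Benjamini-Hochberg controls the FDR across TFs,
and master regulators are the top-k TFs passing both an FDR threshold
and a minimum target count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError
from .io import TFTargetMap

logger = logging.getLogger(__name__)

_BATCH = 2000  # permutations per vectorized batch


def mr_permutation_test(
    tf_map: TFTargetMap,
    deg_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Resampling enrichment of every regulon among the DEGs.

    Returns an MRTable DataFrame indexed by TF with columns
    n_targets_universe (regulon ∩ universe), n_targets_deg (regulon ∩
    DEG), p_empirical (one-tailed, add-one smoothed) and fdr_bh.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    deg_set = frozenset(deg_set)
    universe_list = sorted(universe)
    n_universe = len(universe_list)
    if not deg_set <= frozenset(universe_list):
        raise InputError("DEG set is not a subset of the universe")
    n_deg = len(deg_set)
    if n_deg > n_universe:
        raise InputError("more DEGs than universe genes")
    if n_universe == 0:
        raise InputError("empty gene universe")

    gene_index = {g: i for i, g in enumerate(universe_list)}
    tf_names = tf_map.tf_names
    member = np.zeros((len(tf_names), n_universe), dtype=bool)
    for row, tf in enumerate(tf_names):
        idx = [gene_index[g] for g in tf_map[tf] if g in gene_index]
        member[row, idx] = True
        if not idx:
            logger.warning("TF %s has no targets in the universe; p = 1", tf)

    deg_mask = np.zeros(n_universe, dtype=bool)
    deg_mask[[gene_index[g] for g in deg_set]] = True
    observed = member.astype(np.int64) @ deg_mask.astype(np.int64)  # per-TF overlap counts

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tf_names), dtype=np.int64)
    member_f = member.astype(np.float32).T  # universe x tf, for fast gathers
    # batch size bounded so scratch arrays stay within ~2e7 elements
    per_perm = max(n_universe, max(n_deg, 1) * max(len(tf_names), 1))
    batch = int(np.clip(20_000_000 // per_perm, 1, _BATCH))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        if n_deg == 0:
            null_counts = np.zeros((b, len(tf_names)))
        else:
            # b draws of n_deg indices without replacement: smallest random keys
            keys = rng.random((b, n_universe))
            draws = np.argpartition(keys, n_deg - 1, axis=1)[:, :n_deg]
            null_counts = member_f[draws].sum(axis=1)  # b x n_tf
        exceed += (null_counts >= observed[None, :]).sum(axis=0)
        done += b

    p_emp = (exceed + 1) / (n_perm + 1)
    fdr = bh_fdr(p_emp)
    return pd.DataFrame(
        {
            "n_targets_universe": member.sum(axis=1).astype(int),
            "n_targets_deg": observed.astype(int),
            "p_empirical": p_emp,
            "fdr_bh": fdr,
        },
        index=pd.Index(tf_names, name="tf"),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_mrs(
    table: pd.DataFrame,
    fdr_cut: float = 0.01,
    min_targets: int = 5,
    top_k: int = 10,
    count_col: str = "n_targets_deg",
) -> list[str]:
    """Master regulators: FDR < cut, more than ``min_targets`` DEG
    targets, top-k by (FDR, empirical p, TF name).

    ``count_col`` selects which target count the ``min_targets`` rule
    applies to: among DEGs (default) or across the whole universe.
    """
    if count_col not in ("n_targets_deg", "n_targets_universe"):
        raise ConfigError(f"unknown count column {count_col!r}")
    passing = table[(table["fdr_bh"] < fdr_cut) & (table[count_col] > min_targets)]
    ordered = sorted(
        passing.index,
        key=lambda t: (passing.at[t, "fdr_bh"], passing.at[t, "p_empirical"], str(t)),
    )
    return list(ordered[:top_k])
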