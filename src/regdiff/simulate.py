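"""Synthetic two-group cohort generator.

Emulates the statistical structure of a bulk transcriptome disparity
cohort: log2-scale intensities for a few thousand genes across two
groups of roughly equal size, a planted fraction of directly
differential genes, TF regulons with chained pairwise overlap so that
co-regulated targets exist, and a subset of TFs whose activity differs
between the groups, shifting every one of their targets.

The generative model is linear-additive on the log2 scale:

    x[g, s] = baseline[g]
              + sum_t  R[g, t] * a[t, group(s)]
              + delta[g] * 1[group(s) == A]
              + Normal(0, sigma_g)

where ``R`` is the regulon membership indicator, ``a`` the latent
per-group TF activity (``tf_activity_shift`` in group A for active
TFs, 0 otherwise) and ``delta`` the direct differential effect
(``+effect_size`` for genes planted up in A, ``-effect_size`` for
genes planted up in B).  TF activity is a per-group constant rather
than a per-sample random effect, so expected activity-score
differences have a closed form.

All randomness flows from a single seed; per-stage sub-streams are
spawned deterministically so that, e.g., regulon structure does not
change when only the noise draw is consumed differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, SampleAnnotation, TFTargetMap

DEFAULT_GLEASON_FREQS = {"lt7": 0.25, "eq7": 0.55, "gt7": 0.20}
DEFAULT_SUBTYPE_FREQS = {"PCS1": 0.02, "PCS2": 0.59, "PCS3": 0.39}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are a desk-scale stand-in for a several-hundred-sample
    microarray disparity cohort: 2000 genes, 60+60 samples, 10%
    directly differential genes with a 1.0 log2-unit shift, 10 TFs of
    which 3 are differentially active, regulons of 30-60 targets with
    30% overlap chaining between consecutive TFs, and 0.5 log2-units
    of residual noise.
    """

    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (60, 60)
    n_tfs: int = 10
    n_active_tfs: int = 3
    regulon_size_range: tuple[int, int] = (30, 60)
    regulon_overlap: float = 0.3
    frac_de_genes: float = 0.10
    effect_size: float = 1.0
    tf_activity_shift: float = 0.8
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    baseline_sd_range: tuple[float, float] | None = None
    strata_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "gleason_category": dict(DEFAULT_GLEASON_FREQS),
            "subtype": dict(DEFAULT_SUBTYPE_FREQS),
        }
    )
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name in ("n_genes", "n_tfs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(n <= 1 for n in self.n_samples_per_group):
            raise ConfigError("each group needs at least 2 samples")
        if not 0.0 <= self.frac_de_genes <= 1.0:
            raise ConfigError("frac_de_genes must be in [0, 1]")
        if not 0.0 <= self.regulon_overlap <= 1.0:
            raise ConfigError("regulon_overlap must be in [0, 1]")
        if self.n_active_tfs > self.n_tfs:
            raise ConfigError("n_active_tfs cannot exceed n_tfs")
        if self.effect_size > 0 and 0 < self.frac_de_genes * self.n_genes < 1:
            raise ConfigError("frac_de_genes * n_genes < 1 with a nonzero effect size")
        lo, hi = self.regulon_size_range
        if lo <= 0 or hi < lo or hi > self.n_genes:
            raise ConfigError("invalid regulon_size_range")
        for col, freqs in self.strata_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"strata frequencies for {col!r} sum to {total}, not 1")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery tests.

    ``de_genes`` contains every gene with a nonzero expected group
    difference — both directly planted genes and targets of active TFs
    — with its direction; ``effect_sizes`` the per-gene expected
    log2-scale difference (group A minus group B).
    """

    de_genes: dict[str, str]  # gene id -> "up_in_A" | "up_in_B"
    active_tfs: dict[str, float]  # tf id -> activity difference (A - B)
    effect_sizes: dict[str, float]  # gene id -> expected A-minus-B shift

    @property
    def de_gene_set(self) -> frozenset[str]:
        return frozenset(self.de_genes)


def _build_regulons(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw regulons with chained overlap between consecutive TFs.

    TF i shares a ``regulon_overlap`` fraction of its targets with TF
    i-1; the remainder is drawn fresh from the whole gene pool.  The
    chain guarantees non-trivial co-regulation edges downstream.
    """
    sizes = rng.integers(cfg.regulon_size_range[0], cfg.regulon_size_range[1] + 1, size=cfg.n_tfs)
    regulons: dict[str, np.ndarray] = {}
    prev: np.ndarray | None = None
    for i in range(cfg.n_tfs):
        size = int(sizes[i])
        members: list[int] = []
        if prev is not None and cfg.regulon_overlap > 0:
            n_shared = min(int(round(cfg.regulon_overlap * size)), len(prev))
            if n_shared:
                members.extend(rng.choice(prev, size=n_shared, replace=False).tolist())
        pool = np.setdiff1d(np.arange(cfg.n_genes), np.asarray(members, dtype=int))
        n_fresh = size - len(members)
        members.extend(rng.choice(pool, size=n_fresh, replace=False).tolist())
        idx = np.unique(np.asarray(members, dtype=int))
        regulons[f"TF{i + 1:02d}"] = idx
        prev = idx
    return regulons


def generate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, TFTargetMap, SyntheticTruth]:
    """Simulate an expression matrix, annotations, regulons and truth.

    Deterministic given ``config.seed``: two calls with the same config
    produce bitwise-identical matrices.
    """
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed)
    rng_structure, rng_effects, rng_noise, rng_strata = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    n_a, n_b = cfg.n_samples_per_group
    label_a, label_b = cfg.group_labels
    sample_ids = [f"S{i + 1:04d}" for i in range(n_a + n_b)]
    groups = np.array([label_a] * n_a + [label_b] * n_b)

    regulons = _build_regulons(cfg, rng_structure)
    tf_names = list(regulons)
    active = tf_names[: cfg.n_active_tfs]

    # direct differential genes: half planted up in A, half up in B
    n_de = int(round(cfg.frac_de_genes * cfg.n_genes))
    de_idx = rng_effects.choice(cfg.n_genes, size=n_de, replace=False)
    delta = np.zeros(cfg.n_genes)
    half = n_de // 2
    delta[de_idx[:n_de - half]] = cfg.effect_size
    delta[de_idx[n_de - half:]] = -cfg.effect_size

    # TF activity contribution in group A
    tf_shift = np.zeros(cfg.n_genes)
    for tf in active:
        tf_shift[regulons[tf]] += cfg.tf_activity_shift

    effect = delta + tf_shift  # expected A-minus-B difference per gene

    baseline = rng_structure.uniform(*cfg.baseline_mean_range, size=cfg.n_genes)
    if cfg.baseline_sd_range is not None:
        sigma = rng_structure.uniform(*cfg.baseline_sd_range, size=cfg.n_genes)
    else:
        sigma = np.full(cfg.n_genes, cfg.noise_sd)

    values = baseline[:, None] + np.where(groups == label_a, effect[:, None], 0.0)
    values = values + rng_noise.normal(0.0, 1.0, size=(cfg.n_genes, n_a + n_b)) * sigma[:, None]

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    ann = SampleAnnotation(
        pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))
    )
    ann = generate_strata(ann, cfg, rng=rng_strata)

    tf_map = TFTargetMap(
        {tf: frozenset(gene_ids[i] for i in idx) for tf, idx in regulons.items()}
    )
    truth = SyntheticTruth(
        de_genes={
            gene_ids[i]: ("up_in_A" if effect[i] > 0 else "up_in_B")
            for i in np.nonzero(effect)[0]
        },
        active_tfs={tf: cfg.tf_activity_shift for tf in active},
        effect_sizes={gene_ids[i]: float(effect[i]) for i in np.nonzero(effect)[0]},
    )
    return expr.validate(), ann.validate(expr), tf_map, truth


def generate_strata(
    annotation: SampleAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SampleAnnotation:
    """Assign independent categorical strata by the configured frequencies.

    Each sample draws each stratum independently of its group, so
    strata are balanced across groups in expectation.  Deterministic
    given ``config.seed`` when no generator is passed.
    """
    cfg = config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    table = annotation.table.copy()
    n = len(table)
    for col, freqs in cfg.strata_freqs.items():
        levels = list(freqs)
        probs = np.array([freqs[lv] for lv in levels], dtype=float)
        table[col] = rng.choice(levels, size=n, p=probs)
    return SampleAnnotation(table, group_col=annotation.group_col)
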