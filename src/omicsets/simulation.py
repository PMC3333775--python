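"""Spike-in simulation benchmark.

The benchmark starts from a *null backbone*: a multi-platform study in which
no gene is associated with the phenotype because the binary labels are
assigned at random. Ten gene sets are then "spiked in": within each chosen
set, and independently for every platform, each gene is altered with
probability gamma (the expected altered fraction) by adding a constant shift
Delta_k to the class-1 samples. Delta_k is calibrated per set so that a
two-sample t-test on a normal gene with the set's average standard deviation
would have power beta (the signal strength) at level alpha. Methods are then
asked to recover the spiked sets, and ranked by ROC/AUC and top-k discovery
counts.

Two backbone constructions are supported:

* :func:`generate_backbone` — a fully synthetic study: expression-like
  platforms draw i.i.d. standard normal genes; copy-number-like platforms
  can carry AR(1) spatial autocorrelation along the genome ordering; paired
  platforms of the same modality (E1/E2, C1/C2) can share a same-gene
  latent component at correlation ``rho_pair``. Defaults produce four
  independent standard-normal platforms on 99 samples split 49/50.
* :func:`permute_labels_backbone` — label permutation of a user-supplied
  real study, which preserves gene-gene and cross-platform correlations
  exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import (
    GeneSetCollection,
    GenomicMatrix,
    MultiOmicStudy,
    PhenotypeVector,
    build_study,
    gene_universe,
)
from .exceptions import InputError
from .gene_scores import ModelSpec, ScoreEngine
from .meta_combine import combine_tables
from .set_tests import (
    build_permutation_null,
    competitive_all,
    selfcontained_all,
)

__all__ = [
    "BackboneConfig",
    "SpikeInConfig",
    "CollectionSpec",
    "SpikeTruth",
    "RepetitionResult",
    "SimulationResult",
    "generate_backbone",
    "permute_labels_backbone",
    "synthetic_collection",
    "band_collection",
    "calibrate_delta",
    "spike_in",
    "run_scenario",
]

logger = logging.getLogger(__name__)

SINGLE_METHODS = ("E1", "E2", "C1", "C2")
META_METHODS = ("AvgP", "MinP")


@dataclass
class BackboneConfig:
    """Null backbone geometry and correlation structure.

    ``platforms`` maps platform id to modality kind (``"expression"`` or
    ``"cn"``). Platforms of the same kind share a same-gene latent component
    at correlation ``rho_pair``; CN-like platforms additionally carry AR(1)
    correlation along the gene order with decay length
    ``cn_autocorr_length`` genes (0 = independent).
    """

    n_samples: int = 99
    n_class1: int = 49
    n_genes: int = 10_000
    platforms: dict[str, str] = field(
        default_factory=lambda: {"E1": "expression", "E2": "expression",
                                 "C1": "cn", "C2": "cn"}
    )
    rho_pair: float = 0.0
    cn_autocorr_length: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_pair < 1.0):
            raise InputError("rho_pair must be in [0, 1)")
        if self.n_samples < 4:
            raise InputError("n_samples must be >= 4")
        if not (0 < self.n_class1 < self.n_samples):
            raise InputError("n_class1 must leave both classes non-empty")
        for kind in self.platforms.values():
            if kind not in ("expression", "cn"):
                raise InputError(f"unknown platform kind {kind!r}")


def _ar1_field(rng: np.random.Generator, n_genes: int, n_samples: int,
               length: float) -> np.ndarray:
    """Unit-variance field with AR(1) correlation exp(-lag/length) along genes."""
    z = rng.standard_normal((n_genes, n_samples))
    if length <= 0 or n_genes < 2:
        return z
    phi = float(np.exp(-1.0 / length))
    out = np.empty_like(z)
    out[0] = z[0]
    scale = np.sqrt(1.0 - phi * phi)
    for g in range(1, n_genes):
        out[g] = phi * out[g - 1] + scale * z[g]
    return out


def generate_backbone(config: BackboneConfig) -> MultiOmicStudy:
    """Draw a synthetic null study per ``config`` (seed-reproducible)."""
    rng = np.random.default_rng(config.seed)
    width = max(5, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    samples = [f"s{i:03d}" for i in range(config.n_samples)]

    def draw(kind: str) -> np.ndarray:
        length = config.cn_autocorr_length if kind == "cn" else 0.0
        return _ar1_field(rng, config.n_genes, config.n_samples, length)

    kinds = set(config.platforms.values())
    shared = {k: draw(k) for k in kinds}
    rho = config.rho_pair
    matrices = []
    for pid, kind in config.platforms.items():
        own = draw(kind)
        vals = np.sqrt(rho) * shared[kind] + np.sqrt(1.0 - rho) * own if rho else own
        matrices.append(GenomicMatrix.from_arrays(pid, genes, samples, vals))

    labels = np.zeros(config.n_samples, dtype=np.int8)
    labels[: config.n_class1] = 1
    rng.shuffle(labels)
    phenotype = PhenotypeVector.binary(pd.Series(labels, index=pd.Index(samples)))
    return build_study(matrices, phenotype)


def permute_labels_backbone(study: MultiOmicStudy, seed: int | None = None) -> MultiOmicStudy:
    """Shuffle phenotype labels of a study, preserving class counts.

    The matrices are untouched, so all gene-gene and cross-platform
    correlations of the original data carry over to the null.
    """
    if study.phenotype.kind != "binary":
        raise InputError("label permutation requires a binary phenotype")
    rng = np.random.default_rng(seed)
    labels = study.phenotype.labels
    shuffled = pd.Series(
        rng.permutation(labels.to_numpy()), index=labels.index
    )
    return MultiOmicStudy(
        matrices=study.matrices,
        phenotype=PhenotypeVector.binary(shuffled),
        availability=study.availability,
    )


def _default_size_sampler(rng: np.random.Generator) -> int:
    """Log-uniform set size on [10, 100], mimicking canonical-pathway sizes."""
    return int(np.round(np.exp(rng.uniform(np.log(10), np.log(100)))))


def synthetic_collection(
    universe: Sequence[str],
    n_sets: int = 200,
    size_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int | None = None,
) -> GeneSetCollection:
    """Disjoint random gene sets over ``universe``.

    Sizes come from ``size_sampler`` (default: log-uniform on [10, 100]);
    genes are assigned uniformly at random without replacement, so no two
    sets share a gene and within-set correlation matches between-set
    correlation by construction.
    """
    rng = np.random.default_rng(seed)
    sampler = size_sampler or _default_size_sampler
    sizes = [max(1, sampler(rng)) for _ in range(n_sets)]
    if sum(sizes) > len(universe):
        raise InputError(
            f"total set size {sum(sizes)} exceeds universe of {len(universe)} genes"
        )
    shuffled = list(rng.permutation(np.asarray(universe, dtype=object)))
    sets: dict[str, list[str]] = {}
    width = len(str(n_sets))
    start = 0
    for i, size in enumerate(sizes):
        sets[f"set{i + 1:0{width}d}"] = shuffled[start : start + size]
        start += size
    return GeneSetCollection(sets, universe=pd.Index(universe))


def band_collection(universe: Sequence[str], band_size: int) -> GeneSetCollection:
    """Contiguous non-overlapping blocks partitioning the ordered universe.

    Emulates chromosome-band positional sets: with CN autocorrelation on,
    genes within a band are spatially correlated.
    """
    if band_size < 1:
        raise InputError("band_size must be >= 1")
    universe = list(universe)
    sets = {}
    n_bands = (len(universe) + band_size - 1) // band_size
    width = len(str(n_bands))
    for i in range(n_bands):
        block = universe[i * band_size : (i + 1) * band_size]
        sets[f"band{i + 1:0{width}d}"] = block
    return GeneSetCollection(sets, universe=pd.Index(universe))


def calibrate_delta(
    avg_sd: float,
    n1: int,
    n2: int,
    beta: float,
    alpha: float = 0.05,
) -> float:
    """Mean shift giving a two-sided two-sample t-test power ``beta``.

    Solves power(Delta) = beta by root-finding on the noncentral-t power
    function with df = n1 + n2 - 2 and noncentrality
    Delta / (sd * sqrt(1/n1 + 1/n2)).
    """
    if n1 < 2 or n2 < 2:
        raise InputError("need at least 2 samples per class")
    if avg_sd <= 0:
        raise InputError("avg_sd must be positive")
    if not (alpha < beta < 1):
        raise InputError(f"beta must lie in (alpha, 1), got beta={beta}, alpha={alpha}")
    df = n1 + n2 - 2
    se = avg_sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def power(delta: float) -> float:
        ncp = delta / se
        return float(
            stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        )

    hi = se * 2.0
    while power(hi) < beta:
        hi *= 2.0
        if hi > 1e6 * se:  # pragma: no cover - unreachable for beta < 1
            raise InputError("power calibration failed to bracket a root")
    return float(optimize.brentq(lambda d: power(d) - beta, 0.0, hi, xtol=1e-10))


@dataclass
class SpikeInConfig:
    """Spike-in parameters: which fraction of set genes is altered (gamma)
    and how strongly (beta, via the t-test power calibration at alpha)."""

    n_spiked_sets: int = 10
    gamma: float = 0.1
    beta: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise InputError("gamma must be in [0, 1]")
        if not (self.alpha < self.beta < 1.0):
            raise InputError("beta must be in (alpha, 1)")
        if self.n_spiked_sets < 1:
            raise InputError("n_spiked_sets must be >= 1")


@dataclass
class SpikeTruth:
    """Ground truth of one spike-in: which sets were spiked, which genes were
    altered on which platform, and the per-set shift applied."""

    spiked_set_ids: list[str]
    altered: dict[str, dict[str, list[str]]]  # platform -> set -> genes
    delta: dict[str, float]  # set -> Delta_k
    spiked_union: frozenset  # union of *all* genes of the spiked sets

    def altered_union(self) -> frozenset:
        out: set = set()
        for per_set in self.altered.values():
            for genes in per_set.values():
                out.update(genes)
        return frozenset(out)


def spike_in(
    study: MultiOmicStudy,
    collection: GeneSetCollection,
    config: SpikeInConfig,
    seed: int | None = None,
) -> tuple[MultiOmicStudy, SpikeTruth]:
    """Spike phenotype association into randomly chosen sets of a null study.

    For each chosen set k, the number of altered genes on each platform is
    drawn Binomial(|set genes measured|, gamma) *independently per platform*,
    and Delta_k (calibrated from the set's average gene standard deviation)
    is added to the class-1 samples of the altered genes. All other entries
    are bit-identical to the input. A spiked set whose draws come up empty on
    every platform stays labeled true (no re-draw), which conservatively
    deflates measured power.
    """
    if study.phenotype.kind != "binary":
        raise InputError("spike-in requires a binary phenotype")
    rng = np.random.default_rng(seed)
    chosen = [
        str(s)
        for s in rng.choice(collection.set_ids, size=config.n_spiked_sets, replace=False)
    ]
    labels = study.phenotype.labels.to_numpy()
    class1 = labels == 1
    n1, n2 = int(class1.sum()), int((~class1).sum())

    new_values = {m.platform_id: m.values.to_numpy().copy() for m in study.matrices}
    gene_pos = {
        m.platform_id: {g: i for i, g in enumerate(m.gene_ids)} for m in study.matrices
    }

    delta: dict[str, float] = {}
    altered: dict[str, dict[str, list[str]]] = {m.platform_id: {} for m in study.matrices}
    spiked_union: set = set()
    for sid in chosen:
        genes = collection.genes(sid)
        spiked_union.update(genes)
        sds = []
        for m in study.matrices:
            pos = [gene_pos[m.platform_id][g] for g in genes if g in gene_pos[m.platform_id]]
            if pos:
                sds.append(m.values.to_numpy()[pos].std(axis=1, ddof=1))
        avg_sd = float(np.concatenate(sds).mean())
        delta[sid] = calibrate_delta(avg_sd, n1, n2, config.beta, config.alpha)
        for m in study.matrices:
            measurable = [g for g in genes if g in gene_pos[m.platform_id]]
            k = rng.binomial(len(measurable), config.gamma)
            picked = sorted(
                str(g) for g in rng.choice(measurable, size=k, replace=False)
            ) if k else []
            altered[m.platform_id][sid] = picked
            if picked:
                rows = [gene_pos[m.platform_id][g] for g in picked]
                new_values[m.platform_id][np.ix_(rows, np.flatnonzero(class1))] += delta[sid]

    matrices = [
        GenomicMatrix.from_arrays(
            m.platform_id, list(m.gene_ids), list(m.sample_ids),
            new_values[m.platform_id],
        )
        for m in study.matrices
    ]
    truth = SpikeTruth(
        spiked_set_ids=chosen,
        altered=altered,
        delta=delta,
        spiked_union=frozenset(spiked_union),
    )
    spiked = MultiOmicStudy(
        matrices=matrices, phenotype=study.phenotype, availability=study.availability
    )
    return spiked, truth


@dataclass
class CollectionSpec:
    """How to build the gene set collection of each repetition."""

    kind: str = "synthetic"  # "synthetic" | "band"
    n_sets: int = 200
    size_min: int = 10
    size_max: int = 100
    band_size: int = 50

    def build(self, universe: Sequence[str], seed: int | None) -> GeneSetCollection:
        if self.kind == "synthetic":
            lo, hi = np.log(self.size_min), np.log(self.size_max)

            def sampler(rng: np.random.Generator) -> int:
                return int(np.round(np.exp(rng.uniform(lo, hi))))

            return synthetic_collection(universe, self.n_sets, sampler, seed)
        if self.kind == "band":
            return band_collection(universe, self.band_size)
        raise InputError(f"unknown collection kind {self.kind!r}")


@dataclass
class RepetitionResult:
    tables: dict[str, pd.DataFrame]  # method -> SetResultTable
    truth: SpikeTruth
    collection: GeneSetCollection
    seed_entropy: int


@dataclass
class SimulationResult:
    """Per-repetition set-level results for each method, plus truth."""

    reps: list[RepetitionResult]
    backbone: BackboneConfig
    collection_spec: CollectionSpec
    spike: SpikeInConfig
    methods: list[str]
    seed: int
    n_failed: int = 0


def run_scenario(
    backbone: BackboneConfig,
    collection_spec: CollectionSpec,
    beta: float,
    gamma: float,
    n_reps: int = 100,
    methods: Sequence[str] | None = None,
    seed: int = 0,
    base_study: MultiOmicStudy | None = None,
    test: str = "competitive",
    permutations: int = 100,
    spec: ModelSpec | None = None,
) -> SimulationResult:
    """Run one (beta, gamma) grid point of the spike-in benchmark.

    Each repetition draws a fresh backbone (or a fresh label permutation of
    ``base_study`` when supplied), a fresh collection, a fresh spike-in, and
    computes the requested methods' set-level P-values. ``methods`` may
    contain platform ids, ``"INT"`` and the meta combinations
    ``"AvgP"``/``"MinP"`` (which force all single-platform tests to run).
    Fully reproducible from ``seed``; a failed repetition is logged and
    excluded, with the count reported.
    """
    if methods is None:
        methods = ["INT", *backbone.platforms, *META_METHODS]
    methods = list(methods)
    platform_ids = list(
        backbone.platforms if base_study is None else base_study.platform_ids
    )
    need_meta = any(m in META_METHODS for m in methods)
    platform_methods = [m for m in methods if m in platform_ids]
    if need_meta:
        platform_methods = platform_ids
    score_methods = (["INT"] if "INT" in methods else []) + platform_methods

    spike_cfg = SpikeInConfig(gamma=gamma, beta=beta)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    reps: list[RepetitionResult] = []
    n_failed = 0
    for r, child in enumerate(children):
        try:
            reps.append(
                _run_repetition(
                    child, backbone, collection_spec, spike_cfg, base_study,
                    score_methods, methods, test, permutations, spec,
                )
            )
        except Exception:  # noqa: BLE001 - a bad repetition must not kill the run
            logger.exception("repetition %d failed; excluded", r)
            n_failed += 1
    return SimulationResult(
        reps=reps,
        backbone=backbone,
        collection_spec=collection_spec,
        spike=spike_cfg,
        methods=methods,
        seed=seed,
        n_failed=n_failed,
    )


def _run_repetition(
    child: np.random.SeedSequence,
    backbone: BackboneConfig,
    collection_spec: CollectionSpec,
    spike_cfg: SpikeInConfig,
    base_study: MultiOmicStudy | None,
    score_methods: list[str],
    methods: list[str],
    test: str,
    permutations: int,
    spec: ModelSpec | None,
) -> RepetitionResult:
    sub = child.spawn(4)
    seeds = [np.random.default_rng(s).integers(2**31) for s in sub]
    if base_study is None:
        study = generate_backbone(replace(backbone, seed=int(seeds[0])))
    else:
        study = permute_labels_backbone(base_study, int(seeds[0]))
    universe = gene_universe(study, "intersection")
    collection = collection_spec.build(universe, int(seeds[1]))
    spiked, truth = spike_in(study, collection, spike_cfg, int(seeds[2]))

    engine = ScoreEngine(spiked, "intersection", spec)
    y = spiked.phenotype.labels.to_numpy(dtype=float)
    table = engine.table(y, score_methods)

    tables: dict[str, pd.DataFrame] = {}
    if test == "competitive":
        for m in score_methods:
            tables[m] = competitive_all(table, collection, method=m)
    elif test == "selfcontained":
        null = build_permutation_null(
            spiked, engine.universe_mode, permutations, int(seeds[3]), spec,
            methods=score_methods,
        )
        for m in score_methods:
            tables[m] = selfcontained_all(table, null, collection, method=m)
    else:
        raise InputError(f"unknown test {test!r}")
    platform_ids = [m for m in score_methods if m != "INT"]
    for meta in META_METHODS:
        if meta in methods:
            tables[meta] = combine_tables(
                [tables[p] for p in platform_ids], method=meta
            )
    tables = {m: tables[m] for m in methods if m in tables}
    return RepetitionResult(
        tables=tables,
        truth=truth,
        collection=collection,
        seed_entropy=int(child.entropy) if child.entropy is not None else 0,
    )
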