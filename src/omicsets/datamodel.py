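"""Core data containers and alignment logic.

The central objects are :class:`GenomicMatrix` (one platform's gene-by-sample
measurements), :class:`PhenotypeVector` (binary class labels or survival
times), :class:`MultiOmicStudy` (several platforms aligned on the same
samples) and :class:`GeneSetCollection` (a membership structure over a gene
universe).

A study knows, for every gene, which platforms measured it: downstream gene
scores use exactly the platforms in that availability set, and the choice of
gene universe (``intersection`` vs ``union``) determines which stage-II set
test is statistically valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegeneratePhenotypeError, InputError

__all__ = [
    "GenomicMatrix",
    "PhenotypeVector",
    "MultiOmicStudy",
    "GeneSetCollection",
    "build_study",
    "gene_universe",
    "dichotomize_survival",
]


@dataclass
class GenomicMatrix:
    """Per-gene continuous measurements from a single platform.

    Parameters
    ----------
    platform_id
        Short label such as ``"E1"`` (expression) or ``"C1"`` (copy number).
    values
        Genes-by-samples DataFrame of continuous summaries. ``NaN`` marks a
        missing measurement; a gene with any missing value is treated as
        unmeasured on this platform.
    """

    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.platform_id:
            raise InputError("platform_id must be a non-empty string")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise InputError(f"duplicate gene ids on {self.platform_id}: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise InputError(f"duplicate sample ids on {self.platform_id}: {dup}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InputError(f"non-numeric values on {self.platform_id}")
        if np.isinf(arr).any():
            raise InputError(f"infinite values on {self.platform_id}")

    @classmethod
    def from_arrays(
        cls,
        platform_id: str,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "GenomicMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(gene_ids, name="gene"),
            columns=pd.Index(sample_ids, name="sample"),
        )
        return cls(platform_id, frame)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def measured_genes(self) -> pd.Index:
        """Genes with a complete (no-NaN) measurement vector."""
        complete = ~self.values.isna().any(axis=1)
        return self.values.index[complete]

    def restrict_samples(self, samples: Sequence[str]) -> "GenomicMatrix":
        return GenomicMatrix(self.platform_id, self.values.loc[:, list(samples)])


@dataclass
class PhenotypeVector:
    """Sample phenotype: binary class labels or right-censored survival."""

    kind: str  # "binary" | "survival"
    labels: pd.Series | None = None  # 0/1 per sample (binary)
    time: pd.Series | None = None  # days (survival)
    event: pd.Series | None = None  # 1 = event observed (survival)

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.labels is None:
                raise InputError("binary phenotype requires labels")
            vals = set(pd.unique(self.labels.dropna()))
            if not vals <= {0, 1}:
                raise InputError(f"binary labels must be 0/1, got {sorted(vals)}")
            if vals != {0, 1}:
                raise DegeneratePhenotypeError("binary phenotype must contain both classes")
        elif self.kind == "survival":
            if self.time is None or self.event is None:
                raise InputError("survival phenotype requires time and event")
            if not self.time.index.equals(self.event.index):
                raise AlignmentError("time and event indexed on different samples")
            if (self.time <= 0).any():
                raise InputError("survival times must be strictly positive")
            if not set(pd.unique(self.event)) <= {0, 1}:
                raise InputError("event indicators must be 0/1")
        else:
            raise InputError(f"unknown phenotype kind {self.kind!r}")

    @classmethod
    def binary(cls, labels: pd.Series) -> "PhenotypeVector":
        return cls(kind="binary", labels=labels.astype(np.int8))

    @classmethod
    def survival(cls, time: pd.Series, event: pd.Series) -> "PhenotypeVector":
        return cls(kind="survival", time=time.astype(float), event=event.astype(np.int8))

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index if self.kind == "binary" else self.time.index

    def restrict(self, samples: Sequence[str]) -> "PhenotypeVector":
        samples = list(samples)
        if self.kind == "binary":
            sub = self.labels.loc[samples]
            vals = set(pd.unique(sub))
            if vals != {0, 1}:
                raise DegeneratePhenotypeError(
                    "phenotype restricted to one class after sample alignment"
                )
            return PhenotypeVector.binary(sub)
        return PhenotypeVector.survival(self.time.loc[samples], self.event.loc[samples])


@dataclass
class MultiOmicStudy:
    """D platforms sharing an identical ordered sample list with a phenotype.

    ``availability`` maps each gene measured anywhere to the tuple of platform
    ids (in platform order) on which it has a complete measurement vector. It
    is derived by :func:`build_study`, never user-set.
    """

    matrices: list[GenomicMatrix]
    phenotype: PhenotypeVector
    availability: Mapping[str, tuple[str, ...]] = field(repr=False)

    @property
    def platform_ids(self) -> list[str]:
        return [m.platform_id for m in self.matrices]

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotype.sample_ids

    @property
    def n_platforms(self) -> int:
        return len(self.matrices)

    def matrix(self, platform_id: str) -> GenomicMatrix:
        for m in self.matrices:
            if m.platform_id == platform_id:
                return m
        raise KeyError(platform_id)


def build_study(
    matrices: Sequence[GenomicMatrix], phenotype: PhenotypeVector
) -> MultiOmicStudy:
    """Align platforms and phenotype on their common samples.

    Samples are restricted to the intersection (ordered as in the phenotype);
    per-gene platform availability is computed. Raises
    :class:`AlignmentError` if the intersection is empty and
    :class:`DegeneratePhenotypeError` if only one class survives alignment.
    """
    if len(matrices) < 1:
        raise InputError("at least one matrix is required")
    ids = [m.platform_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate platform ids: {ids}")
    common = [s for s in phenotype.sample_ids if all(s in m.sample_ids for m in matrices)]
    if len(common) < 2:
        raise AlignmentError(
            f"sample intersection across platforms and phenotype has "
            f"{len(common)} samples (need >= 2)"
        )
    pheno = phenotype.restrict(common)
    aligned = [m.restrict_samples(common) for m in matrices]
    availability: dict[str, tuple[str, ...]] = {}
    for m in aligned:
        for g in m.measured_genes:
            availability[g] = availability.get(g, ()) + (m.platform_id,)
    return MultiOmicStudy(matrices=aligned, phenotype=pheno, availability=availability)


def gene_universe(study: MultiOmicStudy, mode: str = "intersection") -> list[str]:
    """Ordered gene universe of a study.

    ``intersection``: genes measured on all D platforms (required by the
    competitive set test). ``union``: genes measured on at least one platform
    (allowed for the self-contained test). Lexicographic order.
    """
    if mode not in ("intersection", "union"):
        raise InputError(f"mode must be 'intersection' or 'union', got {mode!r}")
    d = study.n_platforms
    if mode == "union":
        return sorted(study.availability)
    return sorted(g for g, plats in study.availability.items() if len(plats) == d)


def dichotomize_survival(
    times: pd.Series,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
) -> tuple[PhenotypeVector, list[str]]:
    """Extreme discordant phenotype design: dichotomize survival by quantiles.

    Samples with time strictly below the ``lower_q`` empirical quantile are
    labeled 1 (short-term survivors), those strictly above the ``upper_q``
    quantile 0 (long-term survivors); the middle — including ties at either
    threshold — is excluded. Quantiles use linear interpolation
    (``numpy.quantile`` default).

    Returns the binary phenotype on the kept samples plus the excluded
    sample ids.
    """
    if not (0 < lower_q <= upper_q < 1):
        raise InputError("require 0 < lower_q <= upper_q < 1")
    if len(times) < 4:
        raise InputError("need at least 4 samples to dichotomize")
    t = times.astype(float)
    lo = float(np.quantile(t.to_numpy(), lower_q))
    hi = float(np.quantile(t.to_numpy(), upper_q))
    short = t.index[t < lo]
    long_ = t.index[t > hi]
    kept = short.append(long_)
    if len(short) == 0 or len(long_) == 0:
        raise DegeneratePhenotypeError(
            "dichotomization left fewer than two phenotype classes"
        )
    labels = pd.Series(0, index=kept, dtype=np.int8)
    labels.loc[short] = 1
    excluded = [s for s in t.index if s not in set(kept)]
    return PhenotypeVector.binary(labels), excluded


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe; GMT-backed.

    ``sets`` preserves insertion (file) order; within a set genes are unique
    and sets are non-empty. The universe is every gene appearing in any set
    unless supplied explicitly.
    """

    sets: dict[str, list[str]]
    universe: pd.Index | None = None

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"gene set {sid!r} is empty")
            if len(set(genes)) != len(genes):
                raise InputError(f"gene set {sid!r} contains duplicate genes")
        if self.universe is None:
            seen: dict[str, None] = {}
            for genes in self.sets.values():
                for g in genes:
                    seen.setdefault(g)
            self.universe = pd.Index(seen)
        else:
            self.universe = pd.Index(self.universe)
            members = set().union(*(set(g) for g in self.sets.values()))
            missing = members - set(self.universe)
            if missing:
                raise InputError(
                    f"{len(missing)} set genes missing from the explicit universe"
                )

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)

    def genes(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def membership(self, gene: str, set_id: str) -> bool:
        """Indicator m_gs: is ``gene`` a member of ``set_id``?"""
        return gene in self._member_index()[set_id]

    def _member_index(self) -> dict[str, frozenset]:
        cached = getattr(self, "_members", None)
        if cached is None:
            cached = {sid: frozenset(g) for sid, g in self.sets.items()}
            object.__setattr__(self, "_members", cached)
        return cached

    def membership_matrix(self, genes: Sequence[str]) -> pd.DataFrame:
        """Boolean sets-by-genes indicator matrix M restricted to ``genes``."""
        genes = pd.Index(genes)
        mat = np.zeros((len(self.sets), len(genes)), dtype=bool)
        pos = {g: i for i, g in enumerate(genes)}
        for row, (sid, members) in enumerate(self.sets.items()):
            idx = [pos[g] for g in members if g in pos]
            mat[row, idx] = True
        return pd.DataFrame(mat, index=pd.Index(self.set_ids, name="set"), columns=genes)

    def subset(self, set_ids: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({sid: list(self.sets[sid]) for sid in set_ids},
                                 universe=self.universe)
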