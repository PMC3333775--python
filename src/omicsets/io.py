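"""Readers and writers for the standard text formats.

Matrices and phenotypes travel as TSV/CSV (genes in rows, header of sample
ids; phenotype as two-column ``sample<TAB>label`` or three-column
``sample<TAB>time<TAB>event``). Gene set collections use the GMT dialect
(tab-separated: name, description, genes...). All tabular outputs carry a
single ``#`` comment line with the tool version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .datamodel import GeneSetCollection, GenomicMatrix, PhenotypeVector
from .exceptions import GMTParseError, InputError
from .gene_scores import GeneScoreTable

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_phenotype",
    "write_phenotype",
    "read_gmt",
    "write_gmt",
    "write_score_table",
    "read_score_table",
    "write_set_results",
    "read_set_results",
    "write_manifest",
]

logger = logging.getLogger(__name__)

try:
    TOOL_VERSION = version("omicsets")
except PackageNotFoundError:  # pragma: no cover - not installed
    TOOL_VERSION = "unknown"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _header_comment(handle) -> None:
    handle.write(f"# omicsets {TOOL_VERSION}\n")


def read_matrix(path: str | Path, platform_id: str | None = None) -> GenomicMatrix:
    """Read a genes-by-samples matrix (first column gene id, header samples)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return GenomicMatrix(platform_id or path.stem, frame.astype(float))


def write_matrix(matrix: GenomicMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _header_comment(fh)
        matrix.values.to_csv(fh, sep=_sep_for(path), index_label="gene")


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Two columns (sample, label) -> binary; three (sample, time, event) -> survival."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    if frame.shape[1] == 1:
        return PhenotypeVector.binary(frame.iloc[:, 0])
    if frame.shape[1] == 2:
        return PhenotypeVector.survival(frame.iloc[:, 0], frame.iloc[:, 1])
    raise InputError(
        f"phenotype table must have 2 or 3 columns, got {frame.shape[1] + 1}"
    )


def write_phenotype(phenotype: PhenotypeVector, path: str | Path) -> None:
    path = Path(path)
    if phenotype.kind == "binary":
        frame = phenotype.labels.rename("label").to_frame()
    else:
        frame = pd.DataFrame({"time": phenotype.time, "event": phenotype.event})
    with open(path, "w") as fh:
        _header_comment(fh)
        frame.to_csv(fh, sep=_sep_for(path), index_label="sample")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate genes within a set are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected name, description and >=1 gene, "
                    f"got {len(fields)} fields"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: set {name!r} has no genes")
            if name in sets:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) in set %s dropped",
                    path, lineno, len(genes) - len(unique), name,
                )
            sets[name] = unique
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for sid in collection.set_ids:
            fh.write("\t".join([sid, description, *collection.genes(sid)]) + "\n")


def write_score_table(table: GeneScoreTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _header_comment(fh)
        table.frame.to_csv(fh, sep=_sep_for(path), index_label="gene")


def read_score_table(path: str | Path) -> GeneScoreTable:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    platforms = [c[2:] for c in frame.columns if c.startswith("s_") and c != "s_INT"]
    return GeneScoreTable(frame=frame, platforms=platforms)


def write_set_results(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _header_comment(fh)
        table.to_csv(fh, sep=_sep_for(path), index=False)


def read_set_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), comment="#",
                       dtype={"set_id": str})


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, config: dict, inputs: list[str | Path],
                   seed: int | None = None) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "tool": "omicsets",
        "version": TOOL_VERSION,
        "seed": seed,
        "config": config,
        "inputs": {str(p): sha256_of(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
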