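"""Readers and writers: sequence files, cluster assignments, ground truth,
reports, dataset manifests and run configuration.

Formats are deliberately plain: FASTA/FASTQ for interoperability,
one-read-per-line text (a common shape for storage-archive read dumps)
as a first-class citizen, and tab-separated two-column files for cluster
assignments and ground truth.  All writers are atomic (write to a
temporary file, then rename), so an interrupted run never leaves a
truncated file that still parses.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO

from .engine import Clustering, GradHCParams
from .sequence_model import Read, ReadSet, _VALID

logger = logging.getLogger(__name__)

_FORMAT_BY_EXT = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".fq": "fastq", ".fastq": "fastq",
    ".txt": "txt", ".reads": "txt",
}


def detect_format(path: str | Path) -> str:
    p = Path(path)
    suffixes = p.suffixes
    ext = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else p.suffix
    try:
        return _FORMAT_BY_EXT[ext.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer sequence format from {p.name!r}; pass fmt explicitly"
        ) from None


@contextmanager
def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, mode) as fh:  # type: ignore[arg-type]
        yield fh


def _ingest(records: Iterable[tuple[str, str]]) -> ReadSet:
    """Apply the alphabet policy: case-fold, reject non-ACGT reads with a warning."""
    kept: list[Read] = []
    rejected = 0
    for rid, seq in records:
        seq = seq.upper()
        if not _VALID.issuperset(seq):
            rejected += 1
            logger.warning("rejecting read %r: non-ACGT symbols", rid)
            continue
        kept.append(Read(rid, seq))
    if rejected:
        logger.warning("rejected %d read(s) with non-ACGT symbols", rejected)
    if not kept:
        logger.warning("no valid reads ingested")
    return ReadSet(kept)


def read_sequences(path: str | Path, fmt: str | None = None) -> ReadSet:
    """Load reads from FASTA, FASTQ or one-read-per-line text.

    Record ids are used when the format has them; plain-text reads get
    0-based line indices.  Input order is preserved.  Reads containing
    symbols outside {A,C,G,T} (after case-folding) are rejected with a
    logged warning rather than silently altered.
    """
    fmt = fmt or detect_format(path)
    if fmt == "txt":
        with _open_text(path) as fh:
            records = [
                (str(i), line.strip()) for i, line in enumerate(fh) if line.strip()
            ]
        return _ingest(records)
    if fmt in ("fasta", "fastq"):
        with _open_text(path) as fh:
            return _ingest((rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt))
    raise ValueError(f"unsupported format {fmt!r}")


@contextmanager
def _atomic_write(path: str | Path):
    """Write-then-rename so readers never observe a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_sequences(reads: ReadSet, path: str | Path, fmt: str | None = None) -> None:
    """Write reads as FASTA or one-read-per-line text."""
    fmt = fmt or detect_format(path)
    with _atomic_write(path) as fh:
        if fmt == "txt":
            for read in reads:
                fh.write(read.seq + "\n")
        elif fmt == "fasta":
            for read in reads:
                fh.write(f">{read.id}\n{read.seq}\n")
        else:
            raise ValueError(f"unsupported output format {fmt!r}")


def write_clustering(
    clustering: Mapping[str, int],
    path: str | Path,
    *,
    seed: int | None = None,
    params_digest: str | None = None,
) -> None:
    """Tab-separated read-id / cluster-id rows with a commented header."""
    from . import __version__

    with _atomic_write(path) as fh:
        fh.write(f"# gradhc {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if params_digest is not None:
            fh.write(f"# params: {params_digest}\n")
        fh.write("# read_id\tcluster_id\n")
        for rid in clustering:
            fh.write(f"{rid}\t{clustering[rid]}\n")


def read_clustering(path: str | Path) -> Clustering:
    assign: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rid, cid = parts
            if rid in assign:
                raise ValueError(f"{path}:{lineno}: duplicate read id {rid!r}")
            assign[rid] = int(cid)
    return Clustering(assign)


# Ground truth uses the identical two-column shape.
write_ground_truth = write_clustering
read_ground_truth = read_clustering


def write_report(report: dict, path: str | Path) -> None:
    with _atomic_write(path) as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with _atomic_write(path) as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_params(path: str | Path) -> GradHCParams:
    """GradHCParams from a YAML mapping of field name -> value."""
    with _open_text(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping of parameter names")
    return GradHCParams(**data)


def dump_params(params: GradHCParams, path: str | Path) -> None:
    with _atomic_write(path) as fh:
        yaml.safe_dump(params.__dict__, fh, sort_keys=False)


def params_digest(params: GradHCParams) -> str:
    import hashlib

    blob = json.dumps(params.__dict__, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
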