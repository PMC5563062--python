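"""Sequence and table IO: FASTA/FASTQ via Biopython, TSV interchange, YAML config.

Every TSV written by a pipeline stage starts with ``#`` comment lines
naming the producing stage and its parameters, so a run can be audited
from its outputs alone.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Read

_FORMATS = {".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
            ".fq": "fastq", ".fastq": "fastq"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer sequence format from {path.name!r}") from None


def read_sequences(path, fmt: str | None = None) -> list[Read]:
    """Read FASTA/FASTQ into (id, seq) records; qualities are discarded."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sequence file not found: {path}")
    fmt = _infer_format(path, fmt)
    try:
        records = [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} in {path}: {exc}") from exc
    if not records:
        warnings.warn(f"{path} contains no sequence records", stacklevel=2)
    return records


def write_sequences(records, path, fmt: str | None = None) -> None:
    """Write (id, seq) records as FASTA, or FASTQ with flat quality 40."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    out = []
    for rec in records:
        rid, seq = (rec.id, rec.seq) if hasattr(rec, "id") else rec
        sr = SeqRecord(Seq(seq), id=rid, description="")
        if fmt == "fastq":
            sr.letter_annotations["phred_quality"] = [40] * len(seq)
        out.append(sr)
    SeqIO.write(out, path, fmt)


def write_tsv(df: pd.DataFrame, path, stage: str, params: dict | None = None,
              index: bool = True) -> None:
    """TSV with a commented provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n")
        for k, v in (params or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
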