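"""Readers and writers for the pipeline's plain-text formats.

FASTA via Bio.SeqIO (80-column wrap, duplicate ids rejected), tab-separated
tables with ``NA`` for missing values and schema validation, BED6 for
binding sites and motif hits (0-based half-open, as BED natively is), and
YAML for configs/manifests.
"""

from __future__ import annotations

import hashlib
import os
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

_SEQ_CHARS = set("ACGTUNacgtun")


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered id -> sequence mapping; duplicate ids and empty or
    non-nucleotide sequences are parse errors naming the record."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"empty sequence for record {rec.id!r}")
        bad = set(seq) - _SEQ_CHARS
        if bad:
            raise ParseError(f"record {rec.id!r}: illegal character(s) {sorted(bad)}")
        records[rec.id] = seq.upper()
    return records


def write_fasta(records: Mapping[str, str], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in records.items()]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(recs)


def read_table(path, schema: Mapping[str, type] | None = None) -> pd.DataFrame:
    """TSV with a header row and ``NA`` for missing; typed per ``schema``."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     comment="#")
    if schema:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ParseError(f"missing column(s) {sorted(missing)}")
        for col, dtype in schema.items():
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"column {col!r}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def write_bed6(intervals: Iterable, path) -> None:
    """BED6 from BindingSite/MergedSite/CREHit-like objects (0-based half-open).

    name = mirna|site_type|predictors for binding sites, the matched motif
    for CRE hits; score = number of supporting predictors (or 0).
    """
    with open(path, "w") as fh:
        for iv in intervals:
            if hasattr(iv, "mirna"):
                preds = sorted(getattr(iv, "predictors", []) or
                               ([iv.predictor] if getattr(iv, "predictor", "") else []))
                types = sorted(getattr(iv, "site_types", []) or
                               [getattr(iv, "site_type", "")])
                name = f"{iv.mirna}|{','.join(types)}|{','.join(preds)}"
                score = len(preds)
            else:
                name = getattr(iv, "matched", "hit")
                score = 0
            fh.write(f"{iv.gene}\t{iv.start}\t{iv.end}\t{name}\t{score}\t+\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml_atomic(data: Mapping, path) -> None:
    """Write YAML to a temp file and rename into place (atomic on POSIX)."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True, default_flow_style=False)
    os.replace(tmp, path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
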