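"""Readers and writers: EvoPrint text, FASTA, TSV/JSON tables.

Every table writer emits a leading comment line with the tool version and
the parameters that produced the output.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .cscdb import csc_from_payload, csc_to_payload
from .errors import ParseError
from .evoprint import CSC, EvoPrint, parse_evoprint


def read_evoprint(path: str | Path, region_id: str | None = None) -> EvoPrint:
    """Read one EvoPrint from a text file (optional ``> region_id`` header).

    Falls back to the file stem as region_id when no header is present.
    """
    text = Path(path).read_text()
    try:
        return parse_evoprint(text, region_id=region_id)
    except ParseError as exc:
        if "region_id" in str(exc):
            return parse_evoprint(text, region_id=Path(path).stem)
        raise


def read_fasta(path: str | Path) -> list[EvoPrint]:
    """Read FASTA records as EvoPrints, preserving the records' case."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(parse_evoprint(str(rec.seq), region_id=rec.id))
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def write_csc_json(csc: CSC, path: str | Path) -> None:
    Path(path).write_text(csc_to_payload(csc) + "\n")


def read_csc_json(path: str | Path) -> CSC:
    return csc_from_payload(Path(path).read_text())


def _header(params: dict) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# cscdecoder v{__version__} {kv}\n"


def write_table(df: pd.DataFrame, path: str | Path, params: dict) -> None:
    """TSV with a version/parameter comment header."""
    with open(path, "w") as fh:
        fh.write(_header(params))
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: str | Path, params: dict) -> None:
    payload = {"tool": f"cscdecoder v{__version__}", "params": params,
               "data": obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
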