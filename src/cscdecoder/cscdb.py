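"""Embedded CSC database: storage, element catalog, and step-1 search.

Clusters are stored in a single-file SQLite database together with their
CSBs and precomputed RPS elements, plus an element catalog recording, for
every RPS element seen in any stored cluster, its total occurrence count
across the database and the number of clusters carrying two or more
copies.  The initial search identifies database CSCs that share conserved
multi-copy elements with the input cluster, or that satisfy user-supplied
mandatory-element constraints.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConstraintError, DatabaseError
from .evoprint import CSB, CSC, DEFAULT_MIN_ELEMENT_LEN, SEQ_CLASSES
from .rps import canonical, count_occurrences, self_align

_SCHEMA = """
CREATE TABLE IF NOT EXISTS cscs (
    name TEXT PRIMARY KEY,
    region_id TEXT,
    icr_cutoff INTEGER,
    span_bases INTEGER,
    conserved_bases INTEGER,
    n_csbs INTEGER,
    seq_class TEXT,
    duplicate_of TEXT,
    payload TEXT
);
CREATE TABLE IF NOT EXISTS rps_elements (
    csc_name TEXT,
    sequence TEXT,
    length INTEGER,
    copy_count INTEGER,
    is_palindrome INTEGER,
    is_subrepeat INTEGER
);
CREATE TABLE IF NOT EXISTS catalog (
    sequence TEXT PRIMARY KEY,
    total_count INTEGER,
    csc_multi_count INTEGER
);
CREATE INDEX IF NOT EXISTS idx_rps_seq ON rps_elements(sequence);
"""


@dataclass(frozen=True)
class SearchConstraint:
    """A mandatory element with a minimum copy number and class filter."""

    element: str
    min_copies: int = 1
    seq_class_filter: frozenset[str] = frozenset()

    def __post_init__(self):
        if len(self.element) < DEFAULT_MIN_ELEMENT_LEN:
            raise ConstraintError(
                f"mandatory element {self.element!r} is shorter than "
                f"{DEFAULT_MIN_ELEMENT_LEN} bp")
        if self.min_copies < 1:
            raise ConstraintError("min_copies must be at least 1")
        bad = set(self.seq_class_filter) - set(SEQ_CLASSES)
        if bad:
            raise ConstraintError(f"unknown sequence classes: {sorted(bad)}")


def csc_to_payload(csc: CSC) -> str:
    return json.dumps({
        "name": csc.name,
        "region_id": csc.region_id,
        "icr_cutoff": csc.icr_cutoff,
        "seq_class": csc.seq_class,
        "duplicate_of": csc.duplicate_of,
        "text": csc.text,
        "csbs": [{"sequence": c.sequence, "start": c.start,
                  "eligible": c.eligible} for c in csc.csbs],
    })


def csc_from_payload(payload: str) -> CSC:
    d = json.loads(payload)
    return CSC(
        name=d["name"], region_id=d["region_id"],
        icr_cutoff=d["icr_cutoff"],
        csbs=[CSB(sequence=c["sequence"], start=c["start"],
                  eligible=c["eligible"]) for c in d["csbs"]],
        text=d["text"], seq_class=d["seq_class"],
        duplicate_of=d.get("duplicate_of"),
    )


class CSCDatabase:
    """Handle over the SQLite store; created via :func:`build_database`
    or :meth:`open`."""

    def __init__(self, conn: sqlite3.Connection):
        self._conn = conn

    @classmethod
    def open(cls, path: str | Path) -> "CSCDatabase":
        conn = sqlite3.connect(str(path))
        conn.executescript(_SCHEMA)
        return cls(conn)

    def close(self) -> None:
        self._conn.close()

    # -- storage ---------------------------------------------------------

    def names(self) -> list[str]:
        return [r[0] for r in self._conn.execute(
            "SELECT name FROM cscs ORDER BY name")]

    def get_csc(self, name: str) -> CSC:
        row = self._conn.execute(
            "SELECT payload FROM cscs WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise DatabaseError(f"no CSC named {name!r} in database")
        return csc_from_payload(row[0])

    def rps_elements(self, name: str) -> list[tuple[str, int, int, bool, bool]]:
        """(sequence, length, copy_count, is_palindrome, is_subrepeat)."""
        return [
            (s, l, c, bool(p), bool(sr))
            for s, l, c, p, sr in self._conn.execute(
                "SELECT sequence, length, copy_count, is_palindrome, "
                "is_subrepeat FROM rps_elements WHERE csc_name = ? "
                "ORDER BY length DESC, sequence", (name,))
        ]

    def catalog(self) -> dict[str, tuple[int, int]]:
        """Element catalog: sequence -> (total_count, csc_multi_count)."""
        return {
            s: (t, m) for s, t, m in self._conn.execute(
                "SELECT sequence, total_count, csc_multi_count FROM catalog")
        }

    # -- queries ---------------------------------------------------------

    def element_stats(self, element: str) -> tuple[int, int]:
        """(total occurrences, clusters with ≥2 copies) by direct scan.

        Counts both orientations at distinct starts over every stored
        cluster's eligible CSBs; independent of whether the element was
        catalogued as an RPS element.
        """
        if len(element) < DEFAULT_MIN_ELEMENT_LEN:
            raise ConstraintError(
                f"element {element!r} is shorter than "
                f"{DEFAULT_MIN_ELEMENT_LEN} bp")
        total = 0
        multi = 0
        for name in self.names():
            n = count_occurrences(self.get_csc(name), element)
            total += n
            if n >= 2:
                multi += 1
        return total, multi

    def search(self, input_csc: CSC,
               constraints: list[SearchConstraint] = (),
               min_len: int = DEFAULT_MIN_ELEMENT_LEN) -> list[str]:
        """Step-1 search: candidate CSC names, in stored name order.

        With constraints, a cluster qualifies when every constraint's
        element is present at or above its minimum copy number (both
        orientations) and the cluster's class passes every non-empty
        class filter.  Without constraints, a cluster qualifies when it
        contains at least one occurrence of at least one of the input's
        multi-copy RPS elements.
        """
        hits = []
        if constraints:
            for name in self.names():
                csc = self.get_csc(name)
                ok = True
                for c in constraints:
                    if (c.seq_class_filter
                            and csc.seq_class not in c.seq_class_filter):
                        ok = False
                        break
                    if count_occurrences(csc, c.element) < c.min_copies:
                        ok = False
                        break
                if ok:
                    hits.append(name)
            return hits
        multi = [el.sequence for el in self_align(input_csc, min_len=min_len)
                 if el.copy_count >= 2]
        if not multi:
            return []
        for name in self.names():
            csc = self.get_csc(name)
            if any(count_occurrences(csc, e) >= 1 for e in multi):
                hits.append(name)
        return hits


def build_database(cscs: list[CSC], store: str | Path,
                   min_len: int = DEFAULT_MIN_ELEMENT_LEN) -> CSCDatabase:
    """Populate a database file with clusters, CSBs, RPS records and the
    element catalog.  Rebuilding from the same clusters reproduces the
    same catalog (idempotent).  Duplicate cluster names are an error.
    """
    names = [c.name for c in cscs]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise DatabaseError(f"duplicate CSC names: {', '.join(dupes)}")

    path = Path(store)
    if path.exists():
        path.unlink()  # rebuild from scratch for idempotence
    db = CSCDatabase.open(path)
    conn = db._conn
    element_seqs: set[str] = set()
    with conn:
        for csc in cscs:
            elements = self_align(csc, min_len=min_len)
            conn.execute(
                "INSERT INTO cscs VALUES (?,?,?,?,?,?,?,?,?)",
                (csc.name, csc.region_id, csc.icr_cutoff, csc.span,
                 csc.conserved_bases, csc.n_csbs, csc.seq_class,
                 csc.duplicate_of, csc_to_payload(csc)))
            for el in elements:
                conn.execute(
                    "INSERT INTO rps_elements VALUES (?,?,?,?,?,?)",
                    (csc.name, el.sequence, el.length, el.copy_count,
                     int(el.is_palindrome), int(el.is_subrepeat)))
                element_seqs.add(el.sequence)
        # catalog: direct occurrence counts across every stored cluster
        for seq in sorted(element_seqs):
            total = 0
            multi = 0
            for csc in cscs:
                n = count_occurrences(csc, seq)
                total += n
                if n >= 2:
                    multi += 1
            conn.execute("INSERT INTO catalog VALUES (?,?,?)",
                         (canonical(seq), total, multi))
    return db
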