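"""One-on-one CSB alignment between an input CSC and a database CSC.

Shared elements are maximal exact matches of at least 6 bp between the two
CSB sets, both orientations, reported in canonical orientation.  Each
element is categorized with respect to the *input* CSC:

* ``repeat``    — a full-length, non-sub-repeat RPS element of the input;
* ``subrepeat`` — a shorter (≥6 bp) repeat contained within longer input
  repeats (including pieces of input repeats broken by the database side);
* ``unique``    — present just once in the input CSBs.

Matching is exact; no mismatches or gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CSCDecoderError, UndefinedScoreError
from .evoprint import CSC, DEFAULT_MIN_ELEMENT_LEN
from .rps import (
    Occurrence,
    _extension_options,
    _window_occurrences,
    self_align,
)

CATEGORIES = ("repeat", "subrepeat", "unique")


@dataclass
class SharedElement:
    """A maximal exact match present in both CSCs."""

    sequence: str  #: canonical orientation
    category: str
    occurrences_input: list[Occurrence]
    occurrences_db: list[Occurrence]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def copies_in_input(self) -> int:
        return len(self.occurrences_input)

    @property
    def copies_in_db(self) -> int:
        return len(self.occurrences_db)


@dataclass
class PairAlignment:
    """Shared-element inventory between an input CSC and a database CSC."""

    input_csc: CSC
    db_csc: CSC
    shared: list[SharedElement]

    @property
    def input_name(self) -> str:
        return self.input_csc.name

    @property
    def db_name(self) -> str:
        return self.db_csc.name

    @property
    def longest_shared(self) -> int:
        """Longest shared element length (0 if none)."""
        return max((e.length for e in self.shared), default=0)

    def longest_shared_repeat(self) -> int:
        """Longest shared element restricted to repeat/sub-repeat types."""
        return max((e.length for e in self.shared
                    if e.category in ("repeat", "subrepeat")), default=0)

    @property
    def db_covered_bases(self) -> int:
        return len(self._covered("db"))

    @property
    def input_covered_bases(self) -> int:
        return len(self._covered("input"))

    def _covered(self, side: str) -> set[tuple[int, int]]:
        pos: set[tuple[int, int]] = set()
        for el in self.shared:
            occs = (el.occurrences_db if side == "db"
                    else el.occurrences_input)
            for occ in occs:
                for k in range(el.length):
                    pos.add((occ.csb_index, occ.offset + k))
        return pos


def align_pair(input_csc: CSC, db_csc: CSC,
               min_len: int = DEFAULT_MIN_ELEMENT_LEN,
               input_elements=None) -> PairAlignment:
    """Enumerate and categorize the shared elements of two CSCs.

    A canonical sequence is a shared candidate when it occurs in the
    eligible CSBs of both sides (any orientation).  A candidate is dropped
    when a single one-base extension, itself shared, contains every
    occurrence on both sides — what survives is the set of maximal exact
    matches plus shorter repeats whose occurrence sets genuinely differ
    from any extension.

    ``input_elements`` may pass a precomputed ``self_align(input_csc)``
    result to avoid recomputation.
    """
    for side, csc in (("input", input_csc), ("db", db_csc)):
        if not csc.eligible_csbs():
            raise CSCDecoderError(
                f"{side} CSC {csc.name!r} has no CSB of {min_len} bp or more")

    elig_in = [(i, c.sequence) for i, c in input_csc.eligible_csbs()]
    elig_db = [(i, c.sequence) for i, c in db_csc.eligible_csbs()]
    by_index_in = dict(elig_in)
    by_index_db = dict(elig_db)
    max_len = min(max(len(s) for _, s in elig_in),
                  max(len(s) for _, s in elig_db))

    shared_by_len: dict[int, dict[str, tuple[list, list]]] = {}
    for length in range(min_len, max_len + 2):
        occ_in = _window_occurrences(elig_in, length)
        occ_db = _window_occurrences(elig_db, length)
        shared_by_len[length] = {
            seq: (occ_in[seq], occ_db[seq])
            for seq in occ_in.keys() & occ_db.keys()
        }

    if input_elements is None:
        input_elements = self_align(input_csc, min_len=min_len)
    rps_map = {el.sequence: el for el in input_elements}

    shared: list[SharedElement] = []
    for length in range(min_len, max_len + 1):
        longer = shared_by_len.get(length + 1, {})
        for seq, (oi, od) in shared_by_len[length].items():
            opts = [_extension_options(by_index_in, o, length) for o in oi]
            opts += [_extension_options(by_index_db, o, length) for o in od]
            common = set.intersection(*opts) if opts else set()
            if any(c2 in longer for c2 in common):
                continue
            shared.append(
                SharedElement(
                    sequence=seq,
                    category=_categorize(seq, len(oi), rps_map),
                    occurrences_input=sorted(
                        oi, key=lambda o: (o.csb_index, o.offset)),
                    occurrences_db=sorted(
                        od, key=lambda o: (o.csb_index, o.offset)),
                )
            )
    shared.sort(key=lambda e: (-e.length, e.sequence))
    return PairAlignment(input_csc=input_csc, db_csc=db_csc, shared=shared)


def _categorize(seq: str, copies_in_input: int, rps_map) -> str:
    """Category with respect to the input CSC's RPS classification."""
    el = rps_map.get(seq)
    if el is not None:
        return "subrepeat" if el.is_subrepeat else "repeat"
    if copies_in_input == 1:
        return "unique"
    # repeated in the input yet not a reported element there: a piece of a
    # longer input repeat whose full length is not shared
    return "subrepeat"


def percent_coverage(pa: PairAlignment) -> float:
    """Percent of the database CSC's conserved bases covered by matches.

    100 × (db bases inside ≥1 shared-element occurrence) / (db conserved
    bases, short ineligible runs included) — hence a self-comparison gives
    exactly 100 only when every CSB is eligible.
    """
    total = pa.db_csc.conserved_bases
    if total == 0:
        raise UndefinedScoreError(
            f"db CSC {pa.db_name!r} has zero conserved bases")
    return 100.0 * pa.db_covered_bases / total


@dataclass(frozen=True)
class Fragment:
    """One aligning input fragment reported under a database CSB."""

    db_offset: int
    sequence: str  #: canonical orientation
    length: int
    input_csb: int
    orientation: str  #: 'forward' if strands agree, else 'reverse'
    category: str


def annotate_csbs(pa: PairAlignment) -> dict[int, list[Fragment]]:
    """Per-database-CSB listing of aligning input fragments.

    For every shared-element occurrence on the database side, one fragment
    is emitted per input occurrence of the same element, citing the input
    CSB number and the relative orientation (forward when both sides match
    the element on the same strand).  CSBs with no match map to empty
    lists.
    """
    out: dict[int, list[Fragment]] = {
        i: [] for i in range(len(pa.db_csc.csbs))
    }
    for el in pa.shared:
        for od in el.occurrences_db:
            for oi in el.occurrences_input:
                # palindromes read identically on both strands; they are
                # stored forward on both sides, so rel comes out 'forward'
                rel = ("forward" if od.orientation == oi.orientation
                       else "reverse")
                out[od.csb_index].append(
                    Fragment(
                        db_offset=od.offset,
                        sequence=el.sequence,
                        length=el.length,
                        input_csb=oi.csb_index,
                        orientation=rel,
                        category=el.category,
                    )
                )
    for frags in out.values():
        frags.sort(key=lambda f: (f.db_offset, -f.length, f.input_csb))
    return out
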