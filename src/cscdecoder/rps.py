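"""Repeat and palindromic sequence (RPS) element discovery.

A CSC's conserved blocks are aligned against themselves in both
orientations to find every *RPS element*: a sequence of at least 6 bp that
either occurs two or more times (counting reverse-complement hits) or is a
DNA palindrome.  Elements are reported in canonical orientation (the
lexicographically smaller of the sequence and its reverse complement) and
maximal: no reported element can be extended by one base with every one of
its occurrences preserved.  Shorter repeats whose occurrence sets differ
from any extension are reported alongside the longer elements they partly
nest in, and flagged as *sub-repeats* when fewer than two occurrences are
independent of longer elements.

Windows containing N are never matched; N bases still count toward
conserved-base totals per their case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import CSCDecoderError, UndefinedScoreError
from .evoprint import CSC, DEFAULT_MIN_ELEMENT_LEN

_DNA = set("ACGTacgt")
_MATCH = set("ACGT")  # N and ambiguity codes never participate in matching


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed. Case-preserving; ACGT/N only."""
    for ch in seq:
        if ch.upper() not in "ACGTN":
            raise CSCDecoderError(f"cannot reverse-complement letter {ch!r}")
    return str(Seq(seq).reverse_complement())


def canonical(seq: str) -> str:
    """Canonical orientation: min(seq, reverse complement)."""
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def is_palindrome(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement.

    Odd-length DNA sequences can never satisfy this.
    """
    if len(seq) % 2 == 1:
        return False
    return seq == reverse_complement(seq)


@dataclass(frozen=True)
class Occurrence:
    """One placement of an element: CSB index, offset within the CSB, strand.

    Palindromes match both strands at one locus; they are recorded once,
    forward.
    """

    csb_index: int
    offset: int
    orientation: str  # '+' or '-'


@dataclass
class RPSElement:
    """A repeat or palindromic element found by CSC self-alignment."""

    sequence: str  #: canonical orientation
    occurrences: list[Occurrence]
    is_palindrome: bool
    is_subrepeat: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def copy_count(self) -> int:
        return len(self.occurrences)


def _window_occurrences(csbs: list[tuple[int, str]], length: int
                        ) -> dict[str, list[Occurrence]]:
    """Map canonical sequence -> occurrences of that length across CSBs.

    ``csbs`` holds (csb_index, uppercase sequence) for eligible blocks.
    Windows containing a non-ACGT letter are skipped.  A palindromic window
    is recorded once, forward.
    """
    out: dict[str, list[Occurrence]] = {}
    for idx, s in csbs:
        for off in range(len(s) - length + 1):
            w = s[off : off + length]
            if not _MATCH.issuperset(w):
                continue
            c = canonical(w)
            orient = "+" if w == c else "-"
            out.setdefault(c, []).append(Occurrence(idx, off, orient))
    return out


def _extension_options(csbs_by_index: dict[int, str], occ: Occurrence,
                       length: int) -> set[str]:
    """Canonical forms of the (length+1)-windows containing one occurrence."""
    s = csbs_by_index[occ.csb_index]
    opts: set[str] = set()
    if occ.offset - 1 >= 0:
        w = s[occ.offset - 1 : occ.offset + length]
        if _MATCH.issuperset(w):
            opts.add(canonical(w))
    if occ.offset + length + 1 <= len(s):
        w = s[occ.offset : occ.offset + length + 1]
        if _MATCH.issuperset(w):
            opts.add(canonical(w))
    return opts


def _is_candidate(seq: str, occs: list[Occurrence]) -> bool:
    return len(occs) >= 2 or (is_palindrome(seq) and len(occs) >= 1)


def self_align(csc: CSC, min_len: int = DEFAULT_MIN_ELEMENT_LEN
               ) -> list[RPSElement]:
    """Discover all RPS elements of a CSC by intra-CSC CSB self-alignment.

    Returns elements ordered by length (descending), then canonical
    sequence.  An element is reported when it occurs at least twice
    (both orientations counted, distinct starts) or is a palindrome, and
    is *maximal*: no single-base extension that is itself a repeat or
    palindrome contains every occurrence.
    """
    elig = [(i, c.sequence) for i, c in csc.eligible_csbs()]
    if not elig:
        return []
    by_index = dict(elig)
    max_len = max(len(s) for _, s in elig)
    if max_len < min_len:
        return []

    candidates: dict[int, dict[str, list[Occurrence]]] = {}
    for length in range(min_len, max_len + 2):
        occs = _window_occurrences(elig, length)
        candidates[length] = {
            seq: lst for seq, lst in occs.items() if _is_candidate(seq, lst)
        }

    elements: list[RPSElement] = []
    for length in range(min_len, max_len + 1):
        longer = candidates.get(length + 1, {})
        for seq, occs in candidates[length].items():
            # absorbed if one longer candidate covers every occurrence
            opts = [_extension_options(by_index, o, length) for o in occs]
            common = set.intersection(*opts) if opts else set()
            if any(c2 in longer for c2 in common):
                continue
            elements.append(
                RPSElement(
                    sequence=seq,
                    occurrences=sorted(
                        occs, key=lambda o: (o.csb_index, o.offset)),
                    is_palindrome=is_palindrome(seq),
                )
            )
    elements.sort(key=lambda e: (-e.length, e.sequence))
    return classify_subrepeats(elements)


def _contained(inner: Occurrence, inner_len: int,
               outer: Occurrence, outer_len: int) -> bool:
    return (inner.csb_index == outer.csb_index
            and outer.offset <= inner.offset
            and inner.offset + inner_len <= outer.offset + outer_len)


def classify_subrepeats(elements: list[RPSElement]) -> list[RPSElement]:
    """Flag sub-repeats: elements mostly nested inside longer elements.

    An element is a sub-repeat when at least one of its occurrences lies
    inside an occurrence of a longer element and fewer than two of its
    occurrences are independent of all longer elements.  Flags are set in
    place; the list is returned for convenience.
    """
    for el in elements:
        nested = 0
        for occ in el.occurrences:
            if any(
                _contained(occ, el.length, o2, other.length)
                for other in elements if other.length > el.length
                for o2 in other.occurrences
            ):
                nested += 1
        independent = el.copy_count - nested
        el.is_subrepeat = nested >= 1 and independent < 2
    return elements


def covered_positions(elements: list[RPSElement]) -> set[tuple[int, int]]:
    """(csb_index, offset) pairs lying inside at least one occurrence."""
    pos: set[tuple[int, int]] = set()
    for el in elements:
        for occ in el.occurrences:
            for k in range(el.length):
                pos.add((occ.csb_index, occ.offset + k))
    return pos


def repeat_coverage_fraction(csc: CSC, elements: list[RPSElement]) -> float:
    """Fraction of the CSC's conserved bases inside ≥1 RPS occurrence."""
    total = csc.conserved_bases
    if total == 0:
        raise UndefinedScoreError(
            f"CSC {csc.name!r} has zero conserved bases")
    return len(covered_positions(elements)) / total


def count_occurrences(csc: CSC, element: str) -> int:
    """Occurrences of ``element`` in the CSC's eligible CSBs.

    Both orientations are counted at distinct starts; a palindromic hit
    counts once.
    """
    c = canonical(element.upper())
    r = reverse_complement(c)
    n = 0
    L = len(c)
    for _, csb in csc.eligible_csbs():
        s = csb.sequence
        for off in range(len(s) - L + 1):
            w = s[off : off + L]
            if w == c or w == r:
                n += 1
    return n
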