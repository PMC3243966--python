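"""EvoPrint parsing and conserved-sequence-cluster (CSC) extraction.

An *EvoPrint* is a single-sequence readout of multi-species conservation:
the reference sequence of one genomic region with conserved bases in
UPPERCASE and non-conserved bases in lowercase.  Maximal uppercase runs are
*conserved sequence blocks* (CSBs); groups of CSBs delimited by long
stretches of non-conserved DNA (*inter-clustal regions*, ICRs) form
*conserved sequence clusters* (CSCs), the candidate-enhancer unit that all
downstream comparisons operate on.

Coordinates are 0-based half-open internally; human-readable reports are
1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import ParseError

#: IUPAC nucleotide one-letter codes (both cases accepted on input).
IUPAC_DNA = set("ACGTRYSWKMBDHVN")

DEFAULT_MIN_ELEMENT_LEN = 6
DEFAULT_ICR_CUTOFF = 150
#: The three cutting stringencies used to build a multi-cut catalog.
MULTI_CUT_CUTOFFS = (150, 200, 250)

SEQ_CLASSES = ("noncoding", "coding", "utr3", "unknown")


@dataclass(frozen=True)
class EvoPrint:
    """A case-coded conservation readout of one genomic region."""

    region_id: str
    sequence: str
    source_note: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def conserved_bases(self) -> int:
        """Number of uppercase (conserved) bases."""
        return sum(1 for b in self.sequence if b.isupper())

    def serialize(self, width: int = 60) -> str:
        """Round-trippable text form: ``> region_id`` header + wrapped bases."""
        lines = [f"> {self.region_id}"]
        for i in range(0, len(self.sequence), width):
            lines.append(self.sequence[i : i + width])
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CSB:
    """A conserved sequence block: one maximal uppercase run.

    ``start`` is the 0-based offset on the parent EvoPrint.  Blocks shorter
    than the minimum element length still count toward conserved-base totals
    but are ineligible for element matching.
    """

    sequence: str
    start: int
    eligible: bool

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        """Exclusive end offset on the parent EvoPrint."""
        return self.start + len(self.sequence)


@dataclass
class CSC:
    """A conserved sequence cluster: ordered CSBs delimited by ICRs."""

    name: str
    region_id: str
    icr_cutoff: int
    csbs: list[CSB]
    text: str  #: EvoPrint slice covering [span_start, span_end)
    seq_class: str = "unknown"
    duplicate_of: str | None = None

    @property
    def span_start(self) -> int:
        return self.csbs[0].start

    @property
    def span_end(self) -> int:
        return self.csbs[-1].end

    @property
    def span(self) -> int:
        """Bases from first CSB start to last CSB end."""
        return self.span_end - self.span_start

    @property
    def conserved_bases(self) -> int:
        return sum(c.length for c in self.csbs)

    @property
    def n_csbs(self) -> int:
        return len(self.csbs)

    def eligible_csbs(self) -> list[tuple[int, CSB]]:
        """(index, CSB) pairs for blocks long enough for element matching."""
        return [(i, c) for i, c in enumerate(self.csbs) if c.eligible]

    def with_class(self, seq_class: str) -> "CSC":
        if seq_class not in SEQ_CLASSES:
            raise ParseError(
                f"unknown sequence class {seq_class!r}; expected one of {SEQ_CLASSES}"
            )
        return replace(self, seq_class=seq_class)


_HEADER_RE = re.compile(r"^\s*>\s*(?P<rid>\S+).*$")


def parse_evoprint(text: str, region_id: str | None = None,
                   source_note: str = "") -> EvoPrint:
    """Parse case-coded EvoPrint text into an :class:`EvoPrint`.

    Whitespace and line breaks are stripped; an optional leading
    ``> region_id`` header line is honoured (an explicit ``region_id``
    argument wins).  Any non-IUPAC character is a :class:`ParseError`
    naming the offending position (1-based, counted over the bases).
    """
    lines = text.splitlines()
    header_id = None
    body_lines = []
    for ln in lines:
        m = _HEADER_RE.match(ln)
        if m and header_id is None and not body_lines:
            header_id = m.group("rid")
        else:
            body_lines.append(ln)
    seq = "".join("".join(body_lines).split())
    if not seq:
        raise ParseError("empty EvoPrint input (no bases after stripping)")
    for pos, ch in enumerate(seq):
        if ch.upper() not in IUPAC_DNA:
            raise ParseError(
                f"non-DNA character {ch!r} at base position {pos + 1}"
            )
    rid = region_id or header_id
    if rid is None:
        raise ParseError("no region_id given and no '>' header found")
    return EvoPrint(region_id=rid, sequence=seq, source_note=source_note)


def extract_csbs(ep: EvoPrint, min_len: int = DEFAULT_MIN_ELEMENT_LEN) -> list[CSB]:
    """All maximal uppercase runs, in order of position.

    Runs shorter than ``min_len`` are retained (they count toward
    conserved-base totals) but flagged ineligible for element matching.
    """
    out: list[CSB] = []
    for m in re.finditer(r"[A-Z]+", ep.sequence):
        seq = m.group(0)
        out.append(CSB(sequence=seq, start=m.start(),
                       eligible=len(seq) >= min_len))
    return out


def cut_cscs(ep: EvoPrint, icr_cutoff: int = DEFAULT_ICR_CUTOFF,
             min_len: int = DEFAULT_MIN_ELEMENT_LEN,
             seq_class: str = "unknown") -> list[CSC]:
    """Cut an EvoPrint into CSCs at the given ICR cutoff.

    Consecutive CSBs separated by ``icr_cutoff`` or more non-conserved
    bases (counted strictly between blocks) fall into different clusters.
    Clusters are named ``<region_id>-<i>`` with consecutive 1-based
    indices.  An EvoPrint with no conserved base yields an empty list.
    """
    csbs = extract_csbs(ep, min_len=min_len)
    if not csbs:
        return []
    groups: list[list[CSB]] = [[csbs[0]]]
    for prev, cur in zip(csbs, csbs[1:]):
        gap = cur.start - prev.end
        if gap >= icr_cutoff:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    out = []
    for i, grp in enumerate(groups, start=1):
        text = ep.sequence[grp[0].start : grp[-1].end]
        out.append(CSC(name=f"{ep.region_id}-{i}", region_id=ep.region_id,
                       icr_cutoff=icr_cutoff, csbs=grp, text=text,
                       seq_class=seq_class))
    return out


def multi_cut(ep: EvoPrint, cutoffs: tuple[int, ...] = MULTI_CUT_CUTOFFS,
              min_len: int = DEFAULT_MIN_ELEMENT_LEN,
              seq_class: str = "unknown") -> list[CSC]:
    """Cut at every cutoff and merge the results into one catalog.

    A higher-cutoff cluster whose span is identical to a lower-cutoff
    cluster is dropped; retained higher-cutoff variants are renamed
    ``<base>~<cutoff>`` with ``duplicate_of`` set to the base name, so the
    catalog's names stay unique while recording the multi-cut notation.
    """
    cutoffs = tuple(sorted(cutoffs))
    out: list[CSC] = []
    seen_spans: set[tuple[int, int]] = set()
    for ci, cutoff in enumerate(cutoffs):
        for csc in cut_cscs(ep, icr_cutoff=cutoff, min_len=min_len,
                            seq_class=seq_class):
            key = (csc.span_start, csc.span_end)
            if key in seen_spans:
                continue
            seen_spans.add(key)
            if ci > 0:
                csc = replace(csc, duplicate_of=csc.name,
                              name=f"{csc.name}~{cutoff}")
            out.append(csc)
    return out
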