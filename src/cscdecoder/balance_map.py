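"""Repeat balance maps: per-base copy-number-balance coloring.

For a pairwise comparison, every conserved base of the database CSC is
classified by how well the copy number of the repeat element covering it
agrees between the two CSCs:

* ``balanced``     (green)  — equal copy numbers;
* ``off_by_1``     (yellow) — unbalanced by one copy;
* ``off_by_2``     (purple) — by two copies;
* ``off_by_3plus`` (red)    — by three or more;
* ``unique_shared`` (gray)  — covered only by a sequence present once in
  the input CSBs;
* ``uncovered``            — conserved but aligning to nothing.

Overlap resolution: a repeat class always beats ``unique_shared``; among
overlapping repeats the longer element wins; at equal length the more
balanced (smaller copy-number difference) wins; remaining ties break by
lexicographic canonical sequence, making the map independent of element
processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CSCDecoderError
from .evoprint import CSC
from .pairwise import PairAlignment

CLASSES = ("balanced", "off_by_1", "off_by_2", "off_by_3plus",
           "unique_shared", "uncovered")

#: HTML background palette, following the published legend's color names.
PALETTE = {
    "balanced": "green",
    "off_by_1": "yellow",
    "off_by_2": "purple",
    "off_by_3plus": "red",
    "unique_shared": "gray",
}


def _diff_class(diff: int) -> str:
    if diff == 0:
        return "balanced"
    if diff == 1:
        return "off_by_1"
    if diff == 2:
        return "off_by_2"
    return "off_by_3plus"


@dataclass
class BalanceMap:
    """Per-base balance classes over a database CSC's conserved bases."""

    db_name: str
    #: one list of class labels per CSB, aligned with the CSC's CSB order
    per_base: list[list[str]]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for csb in self.per_base:
            for label in csb:
                counts[label] += 1
        return counts

    @property
    def aligning_bases(self) -> int:
        return sum(n for c, n in self.class_counts().items()
                   if c != "uncovered")


def color_classes(pa: PairAlignment) -> BalanceMap:
    """Classify every conserved base of the database CSC.

    The copy-number difference is computed per shared element type and
    applied to all of that type's occurrence bases on the database side.
    """
    csbs = pa.db_csc.csbs
    # per base: best repeat claim (length, -diff, seq) and unique flag
    best: list[list[tuple | None]] = [[None] * c.length for c in csbs]
    unique_touch: list[list[bool]] = [[False] * c.length for c in csbs]

    for el in pa.shared:
        if el.category in ("repeat", "subrepeat"):
            diff = abs(el.copies_in_input - el.copies_in_db)
            # larger tuple wins: longer, then more balanced, then
            # lexicographically smaller canonical sequence
            claim = (el.length, -diff, _LexInv(el.sequence), diff)
            for occ in el.occurrences_db:
                row = best[occ.csb_index]
                for k in range(el.length):
                    p = occ.offset + k
                    if row[p] is None or claim > row[p]:
                        row[p] = claim
        else:  # unique
            for occ in el.occurrences_db:
                for k in range(el.length):
                    unique_touch[occ.csb_index][occ.offset + k] = True

    per_base: list[list[str]] = []
    for ci, csb in enumerate(csbs):
        labels = []
        for p in range(csb.length):
            claim = best[ci][p]
            if claim is not None:
                labels.append(_diff_class(claim[3]))
            elif unique_touch[ci][p]:
                labels.append("unique_shared")
            else:
                labels.append("uncovered")
        per_base.append(labels)
    return BalanceMap(db_name=pa.db_name, per_base=per_base)


class _LexInv(str):
    """String with inverted ordering, so max() prefers the lexicographically
    smaller sequence."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def balance_pie(bm: BalanceMap) -> dict[str, float]:
    """Class fractions over aligning bases, plus the uncovered fraction.

    Fractions of the five aligning classes sum to 1 whenever any base
    aligns; ``uncovered`` is reported as a fraction of *all* conserved
    bases.  With zero aligning bases only the uncovered fraction (1.0)
    is returned.
    """
    counts = bm.class_counts()
    total = sum(counts.values())
    aligning = bm.aligning_bases
    out: dict[str, float] = {}
    if aligning:
        for c in CLASSES[:-1]:
            out[c] = counts[c] / aligning
    out["uncovered"] = counts["uncovered"] / total if total else 0.0
    return out


def render_map(csc: CSC, bm: BalanceMap, format: str = "text") -> str:
    """Render the CSC's EvoPrint text with per-base class markup.

    ``text``: runs of a class are wrapped ``[class]...[/class]``;
    lowercase and uncovered bases carry no markup, so stripping all
    bracketed tags recovers the EvoPrint text exactly.  ``html``: the
    same runs become ``<span>`` elements with the legend palette.
    """
    if format not in ("text", "html"):
        raise CSCDecoderError(f"unknown render format {format!r}")
    if bm.db_name != csc.name:
        raise CSCDecoderError(
            f"balance map is for {bm.db_name!r}, not CSC {csc.name!r}")
    # class per absolute EvoPrint offset (within the CSC span)
    cls_at: dict[int, str] = {}
    for csb, labels in zip(csc.csbs, bm.per_base):
        for k, label in enumerate(labels):
            if label != "uncovered":
                cls_at[csb.start + k] = label

    parts: list[str] = []
    open_cls: str | None = None

    def close():
        nonlocal open_cls
        if open_cls is not None:
            parts.append(f"[/{open_cls}]" if format == "text"
                         else "</span>")
            open_cls = None

    base0 = csc.span_start
    for i, ch in enumerate(csc.text):
        label = cls_at.get(base0 + i)
        if label != open_cls:
            close()
            if label is not None:
                if format == "text":
                    parts.append(f"[{label}]")
                else:
                    parts.append(
                        f'<span class="{label}" '
                        f'style="background-color:{PALETTE[label]}">')
                open_cls = label
        parts.append(ch)
    close()
    body = "".join(parts)
    if format == "html":
        return ("<html><body><pre>\n" + body + "\n</pre></body></html>\n")
    return body
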