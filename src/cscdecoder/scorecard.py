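"""Similarity scorecard: eight indices ranking database CSCs.

For each candidate the scorecard reports, against the input CSC:

1. RPS balance index — length-weighted ratio of copy-number-matched to
   copy-number-mismatched shared repeat elements (infinite when every
   shared repeat is matched in frequency);
2. Pearson correlation coefficient of shared-element copy-number vectors;
3. number of shared repeats (repeat + sub-repeat types);
4. total shared element types (repeats plus uniquely shared sequences);
5. percent coverage of the database CSC's conserved bases;
6. number of user-required elements present at their required copies;
7. longest shared sequence;
8. total conserved bases of the database CSC.

Undefined scores (no shared elements / no shared repeats) are carried as
``None`` and sort last; an infinite balance index is carried as ``inf``
and sorts above all finite values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .errors import CSCDecoderError
from .evoprint import CSC, DEFAULT_MIN_ELEMENT_LEN
from .pairwise import PairAlignment, align_pair, percent_coverage
from .rps import count_occurrences, self_align

SCORE_KEYS = (
    "rps_balance_index",
    "correlation_coefficient",
    "shared_repeats",
    "total_shared_elements",
    "percent_coverage",
    "required_elements",
    "longest_shared",
    "conserved_bases",
)

#: TSV column order, mirroring the published scorecard table.
COLUMN_ORDER = (
    "cluster_name",
    "rps_balance_index",
    "correlation_coefficient",
    "shared_repeats",
    "total_shared_elements",
    "percent_coverage",
    "required_elements",
    "longest_shared",
    "conserved_bases",
)


@dataclass
class ScoreRow:
    cluster_name: str
    rps_balance_index: float | None  #: may be math.inf; None when undefined
    correlation_coefficient: float | None
    shared_repeats: int
    total_shared_elements: int
    percent_coverage: float
    required_elements: int
    longest_shared: int
    conserved_bases: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in COLUMN_ORDER}


def correlation_coefficient(pa: PairAlignment) -> float | None:
    """Pearson correlation of (copies-in-input, copies-in-db) pairs.

    One pair per distinct shared element type, unique elements included as
    (1, copies-in-db).  When either vector is constant the formula is
    undefined; by convention the score is 1.0 when the two vectors are
    equal and 0.0 otherwise.  Returns None when there is no shared
    element.
    """
    if not pa.shared:
        return None
    x = np.array([e.copies_in_input for e in pa.shared], dtype=float)
    y = np.array([e.copies_in_db for e in pa.shared], dtype=float)
    if np.array_equal(x, y):
        return 1.0  # exact, sidestepping float round-off on self rows
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def rps_balance_index(pa: PairAlignment) -> float | None:
    """Length-weighted matched/unmatched ratio over shared repeat types.

    M = Σ length over repeat/sub-repeat types whose copy numbers agree on
    both sides; U = the same sum over types that disagree.  Returns M/U,
    ``inf`` when U = 0 (every shared repeat balanced), and None when the
    pair shares no repeat type at all.
    """
    matched = 0
    unmatched = 0
    any_rps = False
    for el in pa.shared:
        if el.category not in ("repeat", "subrepeat"):
            continue
        any_rps = True
        if el.copies_in_input == el.copies_in_db:
            matched += el.length
        else:
            unmatched += el.length
    if not any_rps:
        return None
    if unmatched == 0:
        return math.inf
    return matched / unmatched


def score_pair(pa: PairAlignment, constraints=(),
               longest: str = "any") -> ScoreRow:
    """Compute one scorecard row from a pairwise alignment.

    ``longest`` selects the longest-shared-sequence convention: ``"any"``
    (longest shared element of any category, default) or
    ``"repeats_only"`` (longest repeat/sub-repeat type).
    """
    if longest not in ("any", "repeats_only"):
        raise CSCDecoderError(f"unknown longest-shared mode {longest!r}")
    required = sum(
        1 for c in constraints
        if count_occurrences(pa.db_csc, c.element) >= c.min_copies
    )
    return ScoreRow(
        cluster_name=pa.db_name,
        rps_balance_index=rps_balance_index(pa),
        correlation_coefficient=correlation_coefficient(pa),
        shared_repeats=sum(
            1 for e in pa.shared if e.category in ("repeat", "subrepeat")),
        total_shared_elements=len(pa.shared),
        percent_coverage=percent_coverage(pa),
        required_elements=required,
        longest_shared=(pa.longest_shared if longest == "any"
                        else pa.longest_shared_repeat()),
        conserved_bases=pa.db_csc.conserved_bases,
    )


def score_candidates(db, input_csc: CSC, candidates, constraints=(),
                     min_len: int = DEFAULT_MIN_ELEMENT_LEN,
                     longest: str = "any") -> list[ScoreRow]:
    """One ScoreRow per candidate CSC name, in candidate order.

    ``db`` is a :class:`cscdecoder.cscdb.CSCDatabase`; candidates normally
    come from its ``search``.
    """
    input_elements = self_align(input_csc, min_len=min_len)
    rows = []
    for name in candidates:
        db_csc = db.get_csc(name)
        pa = align_pair(input_csc, db_csc, min_len=min_len,
                        input_elements=input_elements)
        rows.append(score_pair(pa, constraints=constraints, longest=longest))
    return rows


_NAME_RE = re.compile(r"^(?P<stem>.*?)-(?P<num>\d+)(?P<rest>.*)$")


def _natural_name_key(name: str):
    m = _NAME_RE.match(name)
    if m:
        return (m.group("stem"), int(m.group("num")), m.group("rest"))
    return (name, -1, "")


def rank(rows: list[ScoreRow], key: str,
         descending: bool = True) -> list[ScoreRow]:
    """Stable sort of scorecard rows by one index or by cluster name.

    Undefined scores (None) always sort last; for the balance index the
    infinite flag sorts above every finite value.  ``cluster_name`` sorts
    naturally (file stem, then numeric suffix) and ignores ``descending``
    direction conventions other than reversal.
    """
    valid = SCORE_KEYS + ("cluster_name",)
    if key not in valid:
        raise CSCDecoderError(
            f"unknown sort key {key!r}; valid keys: {', '.join(valid)}")
    if key == "cluster_name":
        # name sorts are naturally ascending; descending=True keeps the
        # ascending convention so neighbouring CSCs group together
        return sorted(rows, key=lambda r: _natural_name_key(r.cluster_name),
                      reverse=not descending)
    def sort_key(r: ScoreRow):
        v = getattr(r, key)
        if v is None:
            return (1, 0.0)  # undefined last regardless of direction
        return (0, -v if descending else v)
    return sorted(rows, key=sort_key)
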