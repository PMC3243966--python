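"""Synthetic EvoPrints with planted, fully known element ground truth.

The generator emits case-coded EvoPrint text whose uppercase-run layout is
prescribed and whose conserved blocks contain each planted element exactly
its specified number of times — and nothing else: backgrounds are built so
that no unintended repeat of 6 bp or more exists within a side and no
unintended match of 6 bp or more is shared between the two sides of a
pair.  Because a repeated (or shared) sequence of ≥6 bp necessarily
repeats one of its 6-bp windows, and an even palindrome of ≥6 bp contains
a palindromic central 6-mer, it suffices to draw background bases so that
every new 6-bp window (in canonical orientation) is globally unique and
non-palindromic.  A brute-force enumeration re-checks the finished pair
against the planted tables before anything is returned.

Planted element sequences must therefore satisfy three constraints (a
``GenerationError`` is raised otherwise): pairwise-disjoint canonical
6-mer sets, no duplicated 6-mer within an element, and no palindromic
6-bp window unless the element itself is that 6-bp palindrome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .evoprint import CSC, DEFAULT_MIN_ELEMENT_LEN, EvoPrint, cut_cscs, parse_evoprint
from .rps import canonical, is_palindrome, reverse_complement

_K = 6  # window size from which all repeat/palindrome structure follows
_CSB_RETRY_CAP = 1000
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedElement:
    """One element to plant: sequence plus per-side copy numbers.

    ``orientations_*`` may fix each copy's strand ('+'/'-'); ``None``
    draws strands at random.
    """

    sequence: str
    copies_a: int = 0
    copies_b: int = 0
    orientations_a: tuple[str, ...] | None = None
    orientations_b: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SideLayout:
    """Uppercase-run lengths and the lowercase gaps between them."""

    csb_lengths: tuple[int, ...]
    gap_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.gap_lengths) != max(len(self.csb_lengths) - 1, 0):
            raise GenerationError(
                "need exactly one gap between consecutive CSBs")
        if any(l <= 0 for l in self.csb_lengths + self.gap_lengths):
            raise GenerationError("CSB and gap lengths must be positive")


@dataclass(frozen=True)
class PlantSpec:
    elements: tuple[PlantedElement, ...]
    layout_a: SideLayout
    layout_b: SideLayout
    seed: int
    background_gc: float = 0.43  # Drosophila-like; cosmetic
    region_a: str = "synthA"
    region_b: str = "synthB"
    flank: int = 12  # lowercase bases on each end


@dataclass
class GroundTruth:
    """Exact expected pipeline output for a generated pair (A = input)."""

    self_elements_a: dict[str, int]
    self_elements_b: dict[str, int]
    shared: list[dict]
    scorecard: dict
    balance_counts: dict[str, int]


def _element_windows(seq: str) -> list[str]:
    return [canonical(seq[i : i + _K]) for i in range(len(seq) - _K + 1)]


def _junction_pools(seq: str) -> tuple[set[str], set[str]]:
    """The two 4-option junction-window pools of an element.

    Every planted copy, whatever its orientation, consumes one canonical
    window of the form suffix₅+base and one of the form base+prefix₅;
    these pools bound how many clean copies an element supports.
    """
    p1 = {canonical(seq[-5:] + b) for b in "ACGT"}
    p2 = {canonical(b + seq[:5]) for b in "ACGT"}
    return p1, p2


def _copy_capacity(seq: str, internal: set[str]) -> int:
    """Max clean copies across both sides, given all elements' windows."""
    p1, p2 = _junction_pools(seq)
    avail1 = {w for w in p1 if w not in internal and not is_palindrome(w)}
    avail2 = {w for w in p2 if w not in internal and not is_palindrome(w)}
    if is_palindrome(seq):
        # both ends of a palindromic copy draw from the same pool
        return len(avail1 | avail2) // 2
    return min(len(avail1), len(avail2))


def validate_spec(spec: PlantSpec) -> None:
    seen: dict[str, str] = {}
    for el in spec.elements:
        s = el.sequence.upper()
        if len(s) < DEFAULT_MIN_ELEMENT_LEN or not set(s) <= set("ACGT"):
            raise GenerationError(
                f"planted element {el.sequence!r} must be ≥"
                f"{DEFAULT_MIN_ELEMENT_LEN} bp of A/C/G/T")
        wins = _element_windows(s)
        if len(set(wins)) != len(wins):
            raise GenerationError(
                f"element {s!r} repeats a {_K}-mer internally")
        for i, w in enumerate(wins):
            if is_palindrome(w) and not (len(s) == _K and is_palindrome(s)):
                raise GenerationError(
                    f"element {s!r} contains palindromic window {w!r}")
            if w in seen and seen[w] != s:
                raise GenerationError(
                    f"elements {seen[w]!r} and {s!r} share window {w!r}")
            seen[w] = s
        for ors, copies in ((el.orientations_a, el.copies_a),
                            (el.orientations_b, el.copies_b)):
            if ors is not None and len(ors) != copies:
                raise GenerationError(
                    f"element {s!r}: orientation list does not match "
                    "copy number")
            if ors is not None and set(ors) - {"+", "-"}:
                raise GenerationError("orientations must be '+' or '-'")
    internal = set(seen)
    for el in spec.elements:
        s = el.sequence.upper()
        # more copies than junction-window options forces two copies to
        # share a flanking base, i.e. an unplanned longer repeat
        cap = _copy_capacity(s, internal)
        if el.copies_a + el.copies_b > cap:
            raise GenerationError(
                f"element {s!r} supports at most {cap} clean copies across "
                f"both sides (requested {el.copies_a}+{el.copies_b})")


def _draw_lower(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p)).lower()


def _place_copies(rng, layout: SideLayout, copies: list[str]
                  ) -> list[list[str]]:
    """Assign decorated copy sequences to CSBs, capacity-checked.

    Returns one list of decorated copy strings per CSB.  Capacity
    requires one spacer base between copies sharing a CSB.
    """
    per_csb: list[list[str]] = [[] for _ in layout.csb_lengths]
    order = list(rng.permutation(len(copies)))
    for ci in order:
        seq = copies[ci]
        feasible = [
            i for i, L in enumerate(layout.csb_lengths)
            if L >= DEFAULT_MIN_ELEMENT_LEN
            and sum(len(s) for s in per_csb[i]) + len(per_csb[i])
            + len(seq) <= L
        ]
        if not feasible:
            raise GenerationError(
                f"no CSB can hold planted copy {seq!r}; enlarge the layout")
        per_csb[int(rng.choice(feasible))].append(seq)
    return per_csb


def _decorate_copy(rng, oriented: str, used: set[str]) -> str:
    """Fix the two flanking bases of one planted copy.

    Each copy consumes one junction window (five planted bases plus the
    flank) at each end; the flanks are chosen here, up front, so every
    junction window is globally unique and non-palindromic.  Running out
    of options means the element is planted more often than its junction
    pools allow.
    """
    decorated = oriented
    for end in ("left", "right"):
        opts = []
        for b in "ACGT":
            w = (b + oriented[:5]) if end == "left" else (oriented[-5:] + b)
            c = canonical(w)
            if c not in used and not is_palindrome(w):
                opts.append((b, c))
        if not opts:
            raise GenerationError(
                f"no clean {end} flank left for a copy of {oriented!r}; "
                "too many copies of this element (or a clashing element)")
        b, c = opts[int(rng.integers(len(opts)))]
        used.add(c)
        decorated = (b + decorated) if end == "left" else (decorated + b)
    return decorated


def _compose_csb(rng, length: int, copies: list[str], used: set[str],
                 gc: float) -> str:
    """Fill one uppercase CSB with its planted copies and clean background.

    ``copies`` are decorated (flanks already fixed and their junction
    windows already in ``used``).  Every 6-bp window not wholly inside a
    single decorated copy must be new (not in ``used``) and
    non-palindromic; free bases are redrawn and the whole CSB restarted
    (up to the retry cap) until that holds.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _attempt in range(_CSB_RETRY_CAP):
        order = list(rng.permutation(len(copies)))
        k = len(copies)
        slack = length - sum(len(c) for c in copies) - max(k - 1, 0)
        # split slack into k+1 random non-negative parts
        if k:
            cuts = sorted(rng.integers(0, slack + 1, size=k))
            parts = ([cuts[0]]
                     + [cuts[i] - cuts[i - 1] for i in range(1, k)]
                     + [slack - cuts[-1]])
        else:
            parts = [slack]
        # fixed-position map: pos -> (char, copy_id) for planted bases
        fixed: dict[int, tuple[str, int]] = {}
        pos = parts[0]
        for j, ci in enumerate(order):
            if j > 0:
                pos += 1 + parts[j]  # spacer + background chunk
            for off, ch in enumerate(copies[ci]):
                fixed[pos + off] = (ch, ci)
            pos += len(copies[ci])

        chars: list[str] = []
        owners: list[int] = []  # decorated copy id per position, -1 free
        local_new: set[str] = set()
        ok = True
        i = 0
        while i < length and ok:
            if i in fixed:
                ch, owner = fixed[i]
                chars.append(ch)
                owners.append(owner)
                if not _window_ok(chars, owners, used, local_new):
                    ok = False
                i += 1
            else:
                placed = False
                for _trial in range(40):
                    ch = str(rng.choice(_BASES, p=p))
                    chars.append(ch)
                    owners.append(-1)
                    if _window_ok(chars, owners, used, local_new):
                        placed = True
                        break
                    chars.pop()
                    owners.pop()
                if not placed:
                    ok = False
                i += 1
        if ok:
            used |= local_new
            return "".join(chars)
    raise GenerationError(
        f"could not compose a clean {length}-bp CSB within "
        f"{_CSB_RETRY_CAP} attempts")


def _window_ok(chars: list[str], owners: list[int], used: set[str],
               local_new: set[str]) -> bool:
    """Check (and record) the trailing 6-bp window of the partial CSB.

    Windows wholly inside one decorated copy are the copy's internal
    windows and its two pre-validated junction windows — expected, so
    skipped; every other window must be globally new and non-palindromic.
    """
    n = len(chars)
    if n < _K:
        return True
    w = "".join(chars[n - _K :])
    own = owners[n - _K :]
    first = own[0]
    if first != -1 and all(o == first for o in own):
        return True
    c = canonical(w)
    if c in used or c in local_new or is_palindrome(w):
        return False
    local_new.add(c)
    return True


def _generate_pair(spec: PlantSpec) -> tuple[str, str]:
    """Build both sides' EvoPrint texts sharing one 6-mer exclusion set."""
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    used: set[str] = set()
    for el in spec.elements:
        used.update(_element_windows(el.sequence.upper()))

    # decorate every copy of both sides first: junction windows must be
    # claimed before any background base can consume them
    copies_by_side: dict[str, list[str]] = {}
    for side in ("a", "b"):
        copies: list[str] = []
        for el in spec.elements:
            n = el.copies_a if side == "a" else el.copies_b
            ors = el.orientations_a if side == "a" else el.orientations_b
            for ci in range(n):
                orient = (ors[ci] if ors is not None
                          else str(rng.choice(["+", "-"])))
                s = el.sequence.upper()
                oriented = s if orient == "+" else reverse_complement(s)
                copies.append(_decorate_copy(rng, oriented, used))
        copies_by_side[side] = copies

    texts = []
    for side, layout, region in (("a", spec.layout_a, spec.region_a),
                                 ("b", spec.layout_b, spec.region_b)):
        per_csb = _place_copies(rng, layout, copies_by_side[side])
        pieces = [_draw_lower(rng, spec.flank, spec.background_gc)]
        for i, L in enumerate(layout.csb_lengths):
            if i > 0:
                pieces.append(_draw_lower(rng, layout.gap_lengths[i - 1],
                                          spec.background_gc))
            pieces.append(_compose_csb(rng, L, per_csb[i], used,
                                       spec.background_gc))
        pieces.append(_draw_lower(rng, spec.flank, spec.background_gc))
        texts.append(f"> {region}\n" + "".join(pieces) + "\n")
    _verify_pair(spec, texts[0], texts[1])
    return texts[0], texts[1]


def make_evoprint(spec: PlantSpec, side: str) -> str:
    """EvoPrint text for one side of the pair ('A' or 'B').

    Both sides are always generated together (deterministically from
    ``spec.seed``) so that the two sides of one spec are mutually clean;
    this returns the requested one.
    """
    a, b = _generate_pair(spec)
    if side.upper() == "A":
        return a
    if side.upper() == "B":
        return b
    raise GenerationError(f"side must be 'A' or 'B', not {side!r}")


# ---------------------------------------------------------------------------
# brute-force no-leak enumerator (independent of the production modules)


def _brute_occurrences(csbs: list[str], length: int):
    out: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(csbs):
        for off in range(len(s) - length + 1):
            w = s[off : off + length]
            out.setdefault(canonical(w), []).append((i, off))
    return out


def brute_force_elements(csbs: list[str],
                         min_len: int = DEFAULT_MIN_ELEMENT_LEN
                         ) -> dict[str, int]:
    """Exhaustive RPS enumeration: canonical sequence -> copy count.

    Direct transcription of the definitions (every length, every window,
    single-extension absorption); used as the generator's post-check.
    """
    elig = [s for s in csbs if len(s) >= min_len]
    if not elig:
        return {}
    max_len = max(len(s) for s in elig)
    occ = {L: _brute_occurrences(elig, L)
           for L in range(min_len, max_len + 2)}
    cands = {
        L: {s: o for s, o in occ[L].items()
            if len(o) >= 2 or is_palindrome(s)}
        for L in occ
    }
    out: dict[str, int] = {}
    for L in range(min_len, max_len + 1):
        for s, olist in cands[L].items():
            absorbed = False
            for s2, o2 in cands.get(L + 1, {}).items():
                if all(
                    any(i == i2 and off2 <= off
                        and off + L <= off2 + L + 1
                        for (i2, off2) in o2)
                    for (i, off) in olist
                ):
                    absorbed = True
                    break
            if not absorbed:
                out[s] = len(olist)
    return out


def brute_force_shared(csbs_a: list[str], csbs_b: list[str],
                       min_len: int = DEFAULT_MIN_ELEMENT_LEN
                       ) -> dict[str, tuple[int, int]]:
    """Exhaustive shared-element enumeration: canonical -> (copies per side)."""
    ea = [s for s in csbs_a if len(s) >= min_len]
    eb = [s for s in csbs_b if len(s) >= min_len]
    if not ea or not eb:
        return {}
    max_len = min(max(len(s) for s in ea), max(len(s) for s in eb))
    occ_a = {L: _brute_occurrences(ea, L) for L in range(min_len, max_len + 2)}
    occ_b = {L: _brute_occurrences(eb, L) for L in range(min_len, max_len + 2)}
    shared = {
        L: {s: (occ_a[L][s], occ_b[L][s])
            for s in occ_a[L].keys() & occ_b[L].keys()}
        for L in occ_a
    }
    out: dict[str, tuple[int, int]] = {}
    for L in range(min_len, max_len + 1):
        for s, (oa, ob) in shared[L].items():
            absorbed = False
            for s2, (oa2, ob2) in shared.get(L + 1, {}).items():
                if (
                    all(any(i == i2 and off2 <= off
                            and off + L <= off2 + L + 1
                            for (i2, off2) in oa2)
                        for (i, off) in oa)
                    and all(any(i == i2 and off2 <= off
                                and off + L <= off2 + L + 1
                                for (i2, off2) in ob2)
                            for (i, off) in ob)
                ):
                    absorbed = True
                    break
            if not absorbed:
                out[s] = (len(oa), len(ob))
    return out


def _uppercase_runs(text: str) -> list[str]:
    runs, cur = [], []
    for ch in text:
        if ch.isupper():
            cur.append(ch)
        elif cur:
            runs.append("".join(cur))
            cur = []
    if cur:
        runs.append("".join(cur))
    return runs


def _expected_tables(spec: PlantSpec):
    self_a: dict[str, int] = {}
    self_b: dict[str, int] = {}
    shared: list[dict] = []
    for el in spec.elements:
        c = canonical(el.sequence.upper())
        pal = is_palindrome(c)
        if el.copies_a >= 2 or (pal and el.copies_a >= 1):
            self_a[c] = el.copies_a
        if el.copies_b >= 2 or (pal and el.copies_b >= 1):
            self_b[c] = el.copies_b
        if el.copies_a >= 1 and el.copies_b >= 1:
            shared.append({
                "sequence": c,
                "length": len(c),
                "copies_in_input": el.copies_a,
                "copies_in_db": el.copies_b,
                "category": ("repeat" if el.copies_a >= 2 or pal
                             else "unique"),
            })
    shared.sort(key=lambda d: (-d["length"], d["sequence"]))
    return self_a, self_b, shared


def _verify_pair(spec: PlantSpec, text_a: str, text_b: str) -> None:
    runs_a = _uppercase_runs(text_a)
    runs_b = _uppercase_runs(text_b)
    self_a, self_b, shared = _expected_tables(spec)
    got_a = brute_force_elements(runs_a)
    got_b = brute_force_elements(runs_b)
    got_shared = brute_force_shared(runs_a, runs_b)
    want_shared = {d["sequence"]: (d["copies_in_input"], d["copies_in_db"])
                   for d in shared}
    if got_a != self_a or got_b != self_b or got_shared != want_shared:
        raise GenerationError(
            "generated pair failed the brute-force no-leak check "
            f"(self A {got_a} vs {self_a}; self B {got_b} vs {self_b}; "
            f"shared {got_shared} vs {want_shared})")


def _pearson(x: list[int], y: list[int]) -> float | None:
    if not x:
        return None
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((v - mx) ** 2 for v in x)
    syy = sum((v - my) ** 2 for v in y)
    if sxx == 0 or syy == 0:
        return 1.0 if x == y else 0.0
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def make_related_pair(spec: PlantSpec) -> tuple[str, str, GroundTruth]:
    """Generate a pair plus its exact expected pipeline output.

    Side A plays the input enhancer, side B the database cluster.  The
    expected scorecard and balance-map counts are computed here in closed
    form, independently of the scoring modules.
    """
    for g in spec.layout_a.gap_lengths + spec.layout_b.gap_lengths:
        if g >= 150:
            raise GenerationError(
                "related-pair layouts must keep each side a single CSC "
                "(all gaps < 150 bp)")
    text_a, text_b = _generate_pair(spec)
    self_a, self_b, shared = _expected_tables(spec)

    conserved_b = sum(spec.layout_b.csb_lengths)
    covered_b = sum(d["length"] * d["copies_in_db"] for d in shared)
    repeats = [d for d in shared if d["category"] == "repeat"]
    matched = sum(d["length"] for d in repeats
                  if d["copies_in_input"] == d["copies_in_db"])
    unmatched = sum(d["length"] for d in repeats
                    if d["copies_in_input"] != d["copies_in_db"])
    if not repeats:
        balance = None
    elif unmatched == 0:
        balance = math.inf
    else:
        balance = matched / unmatched
    scorecard = {
        "rps_balance_index": balance,
        "correlation_coefficient": _pearson(
            [d["copies_in_input"] for d in shared],
            [d["copies_in_db"] for d in shared]),
        "shared_repeats": len(repeats),
        "total_shared_elements": len(shared),
        "percent_coverage": 100.0 * covered_b / conserved_b,
        "required_elements": 0,
        "longest_shared": max((d["length"] for d in shared), default=0),
        "conserved_bases": conserved_b,
    }

    balance_counts = {c: 0 for c in
                      ("balanced", "off_by_1", "off_by_2", "off_by_3plus",
                       "unique_shared", "uncovered")}
    for d in shared:
        bases = d["length"] * d["copies_in_db"]
        if d["category"] == "repeat":
            diff = abs(d["copies_in_input"] - d["copies_in_db"])
            cls = ("balanced" if diff == 0 else
                   "off_by_1" if diff == 1 else
                   "off_by_2" if diff == 2 else "off_by_3plus")
            balance_counts[cls] += bases
        else:
            balance_counts["unique_shared"] += bases
    balance_counts["uncovered"] = conserved_b - covered_b

    gt = GroundTruth(self_elements_a=self_a, self_elements_b=self_b,
                     shared=shared, scorecard=scorecard,
                     balance_counts=balance_counts)
    return text_a, text_b, gt


def pair_to_cscs(text_a: str, text_b: str) -> tuple[CSC, CSC]:
    """Parse a generated pair and cut each side into its single CSC."""
    eps = [parse_evoprint(t) for t in (text_a, text_b)]
    out = []
    for ep in eps:
        cscs = cut_cscs(ep)
        if len(cscs) != 1:
            raise GenerationError(
                f"side {ep.region_id!r} cut into {len(cscs)} CSCs, expected 1")
        out.append(cscs[0])
    return out[0], out[1]


# ---------------------------------------------------------------------------
# randomized spec factories (the study conditions for property suites)


def random_planted_elements(rng: np.random.Generator, n: int,
                            lengths=(6, 7, 8, 9, 10, 12)
                            ) -> list[str]:
    """Draw ``n`` mutually clean element sequences (rejection sampled)."""
    out: list[str] = []
    taken: set[str] = set()  # internal windows + junction pools so far
    for _ in range(n):
        for _try in range(1000):
            L = int(rng.choice(lengths))
            s = "".join(rng.choice(_BASES, size=L))
            wins = _element_windows(s)
            if len(set(wins)) != len(wins):
                continue
            if any(is_palindrome(w) for w in wins):
                continue
            p1, p2 = _junction_pools(s)
            # pools must stay private (4 options each) so that up to four
            # copies can always find a fresh flanking base
            if len(p1) < 4 or len(p2) < 4 or p1 & p2:
                continue
            if any(is_palindrome(w) for w in p1 | p2):
                continue
            footprint = set(wins) | p1 | p2
            if taken & footprint:
                continue
            if _copy_capacity(s, set(wins)) < 4:
                continue  # e.g. a pool window recurring inside the element
            out.append(s)
            taken |= footprint
            break
        else:
            raise GenerationError("could not draw a clean element")
    return out


def random_plant_spec(seed: int, n_elements: int = 5) -> PlantSpec:
    """A randomized related-pair spec with 5+ element types at varying
    copy numbers — the standard condition for round-trip suites."""
    rng = np.random.default_rng(seed)
    seqs = random_planted_elements(rng, n_elements)
    elements = []
    for i, s in enumerate(seqs):
        ca = int(rng.integers(1, 4))
        cb = int(rng.integers(1, min(3, 4 - ca) + 1))
        elements.append(PlantedElement(sequence=s, copies_a=ca, copies_b=cb))
    layout = lambda: SideLayout(  # noqa: E731
        csb_lengths=tuple(int(rng.integers(35, 66)) for _ in range(5)),
        gap_lengths=tuple(int(rng.integers(10, 60)) for _ in range(4)),
    )
    return PlantSpec(elements=tuple(elements), layout_a=layout(),
                     layout_b=layout(), seed=int(seed))
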