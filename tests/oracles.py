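"""Independent brute-force oracles used only by the tests.

Deliberately naive transcriptions of the element definitions — every
window length enumerated, absorption checked by literal positional
containment — kept free of any code from the package under test.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def pal(s: str) -> bool:
    return len(s) % 2 == 0 and s == rc(s)


def _windows(csbs, length):
    """canonical -> set of (csb_index, offset); N windows skipped."""
    out = {}
    for i, s in csbs:
        for off in range(len(s) - length + 1):
            w = s[off : off + length]
            if "N" in w:
                continue
            out.setdefault(canon(w), set()).add((i, off))
    return out


def _contained_in_any(occ, L, occs2, L2):
    i, off = occ
    return any(i == i2 and off2 <= off and off + L <= off2 + L2
               for (i2, off2) in occs2)


def oracle_self_elements(csb_seqs, min_len=6):
    """All RPS elements of one CSB set: canonical -> occurrence set."""
    csbs = [(i, s) for i, s in enumerate(csb_seqs) if len(s) >= min_len]
    if not csbs:
        return {}
    max_len = max(len(s) for _, s in csbs)
    cands = {}
    for L in range(min_len, max_len + 2):
        cands[L] = {s: o for s, o in _windows(csbs, L).items()
                    if len(o) >= 2 or pal(s)}
    out = {}
    for L in range(min_len, max_len + 1):
        for s, occs in cands[L].items():
            absorbed = any(
                all(_contained_in_any(o, L, o2, L + 1) for o in occs)
                for o2 in cands.get(L + 1, {}).values()
            )
            if not absorbed:
                out[s] = occs
    return out


def oracle_shared_elements(csb_seqs_a, csb_seqs_b, min_len=6):
    """Maximal shared elements: canonical -> (occ set A, occ set B)."""
    ea = [(i, s) for i, s in enumerate(csb_seqs_a) if len(s) >= min_len]
    eb = [(i, s) for i, s in enumerate(csb_seqs_b) if len(s) >= min_len]
    if not ea or not eb:
        return {}
    max_len = min(max(len(s) for _, s in ea), max(len(s) for _, s in eb))
    shared = {}
    for L in range(min_len, max_len + 2):
        wa = _windows(ea, L)
        wb = _windows(eb, L)
        shared[L] = {s: (wa[s], wb[s]) for s in wa.keys() & wb.keys()}
    out = {}
    for L in range(min_len, max_len + 1):
        for s, (oa, ob) in shared[L].items():
            absorbed = any(
                all(_contained_in_any(o, L, oa2, L + 1) for o in oa)
                and all(_contained_in_any(o, L, ob2, L + 1) for o in ob)
                for (oa2, ob2) in shared.get(L + 1, {}).values()
            )
            if not absorbed:
                out[s] = (oa, ob)
    return out
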