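"""Hand-written reference matcher for the dose grammar.

Implements, literally and without the `re` module, the pattern

    [(]? [\\d]* [.]? [\\d]+ [\\s]* (MG|MCG|MEQ case-insensitive) [)]?

with the leftmost, greedy-with-backtracking semantics of a conventional
regex engine, plus finditer-style non-overlapping scanning.  Used as the
independent oracle the production extractor is checked against.
"""
from __future__ import annotations

from typing import Optional

_WHITESPACE = " \t\n\r\f\v"
_UNITS = ("MG", "MCG", "MEQ")  # alternation order of the grammar


def _digits_end(s: str, i: int) -> int:
    while i < len(s) and s[i].isdigit():
        i += 1
    return i


def match_at(s: str, i: int) -> Optional[tuple[int, str, str]]:
    """Try to match the grammar starting exactly at ``i``.

    Returns (end, value_text, unit) for the match a backtracking engine
    would produce, or None.  Choice order mirrors greedy quantifiers and
    the alternation order, with earlier components taking precedence.
    """
    paren_options = [1, 0] if s[i : i + 1] == "(" else [0]
    for p_open in paren_options:
        a = i + p_open
        for d1 in range(_digits_end(s, a), a - 1, -1):  # [\d]* greedy
            dot_options = [1, 0] if s[d1 : d1 + 1] == "." else [0]
            for dot in dot_options:  # [.]? greedy
                c = d1 + dot
                for d2 in range(_digits_end(s, c), c, -1):  # [\d]+ greedy
                    w = d2
                    while w < len(s) and s[w] in _WHITESPACE:
                        w += 1
                    for ws_end in range(w, d2 - 1, -1):  # [\s]* greedy
                        for unit in _UNITS:
                            if s[ws_end : ws_end + len(unit)].upper() == unit:
                                g = ws_end + len(unit)
                                end = g + (1 if s[g : g + 1] == ")" else 0)
                                return end, s[a:d2], unit
    return None


def find_all(s: str) -> list[tuple[tuple[int, int], float, str]]:
    """Non-overlapping left-to-right matches: [(span, value, unit), ...].

    Zero-valued matches ("0 MG") satisfy the grammar but are not doses;
    like the production extractor, they are dropped after consuming their
    span, leaving the scan semantics untouched.
    """
    out = []
    i = 0
    while i <= len(s):
        m = match_at(s, i)
        if m is None:
            i += 1
            continue
        end, value_text, unit = m
        if float(value_text) > 0:
            out.append(((i, end), float(value_text), unit))
        i = end
    return out
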