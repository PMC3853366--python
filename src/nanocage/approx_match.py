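"""Approximate string matching primitives for 5' tag filtering and alignment.

Semi-global matching: the whole pattern is aligned against any substring of
the text (both text ends are free).  This is the operation underlying
contaminant screening, oligonucleotide-artifact detection and the built-in
exhaustive aligner.

Two routes are provided:

* :func:`edit_distance_semiglobal` — a vectorised Wagner–Fischer recurrence,
  valid for any pattern length.
* :func:`myers_search` — Myers' (1999) bit-parallel column update for
  patterns up to 64 symbols, the mechanism used on the hot paths.

Conventions shared by both: unit costs for substitution/insertion/deletion;
``N`` never matches anything, including another ``N`` (conservative for
contaminant detection); input is upper-cased on ingest; end positions are
0-based offsets one past the last matched text symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

WORD_SIZE = 64


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MatchResult:
    """Best semi-global match(es) of a pattern in a text.

    Attributes
    ----------
    min_distance:
        Minimum edit distance over all alignments of the whole pattern to
        any substring of the text.
    end_positions:
        Strictly increasing 0-based text offsets, one past the end of each
        best-scoring match.  Empty when a search was capped at ``k`` errors
        and no hit at ``<= k`` exists.
    """

    min_distance: int
    end_positions: list[int] = field(default_factory=list)


def _normalize(seq: str) -> str:
    return seq.upper()


def edit_distance_semiglobal(pattern: str, text: str) -> MatchResult:
    """Semi-global edit distance of ``pattern`` against ``text``.

    Both ends of the text are free: the distance is minimised over all
    substrings of ``text``.  Returns the minimum distance and every end
    offset achieving it.

    The row recurrence is vectorised over text positions; the horizontal
    (insertion) dependency is closed with a prefix-minimum scan, so the
    result is exactly the Wagner–Fischer matrix minimum over the last row.

    Raises
    ------
    ValueError
        If the pattern is empty.
    """
    pattern = _normalize(pattern)
    text = _normalize(text)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    n = len(text)
    if n == 0:
        return MatchResult(len(pattern), [0])

    tarr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    t_is_n = tarr == ord("N")
    idx = np.arange(n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)  # D[0, j] = 0: free text start
    for pc in pattern:
        if pc == "N":
            cost = np.ones(n, dtype=np.int64)
        else:
            cost = ((tarr != ord(pc)) | t_is_n).astype(np.int64)
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = prev[0] + 1
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + cost)
        # insertion closure: D[i, j] = min_{j' <= j} tmp[j'] + (j - j')
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    dmin = int(prev.min())
    ends = np.nonzero(prev == dmin)[0].tolist()
    return MatchResult(dmin, ends)


def _build_peq(pattern: str) -> dict[int, int]:
    peq: dict[int, int] = {}
    for i, c in enumerate(pattern):
        if c == "N":
            continue  # pattern N matches nothing
        peq[ord(c)] = peq.get(ord(c), 0) | (1 << i)
    return peq


def myers_search(
    pattern: str,
    text: str,
    k: int,
    *,
    first_hit: bool = False,
) -> MatchResult:
    """Bit-parallel semi-global search for ``pattern`` in ``text``.

    Implements Myers' column-wise bit-vector recurrence: the DP column is
    held in two machine words (positive/negative delta vectors) and updated
    in O(1) word operations per text symbol.  The hit set is identical to
    :func:`edit_distance_semiglobal` restricted to distance ``<= k``.

    ``min_distance`` is always the true minimum over the whole text;
    ``end_positions`` lists the offsets achieving it when it is ``<= k``
    and is empty otherwise.  With ``first_hit`` the scan stops at the first
    end position scoring ``<= k`` (used by boolean screens).

    Raises
    ------
    ValueError
        If the pattern is empty, longer than 64 symbols (use
        :func:`edit_distance_semiglobal` for long patterns), or ``k`` is not
        below the pattern length.
    """
    pattern = _normalize(pattern)
    text = _normalize(text)
    m = len(pattern)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if m > WORD_SIZE:
        raise ValueError(
            f"pattern length {m} exceeds the {WORD_SIZE}-bit word; "
            "use edit_distance_semiglobal for longer patterns"
        )
    if not 0 <= k < m:
        raise ValueError("k must satisfy 0 <= k < len(pattern)")
    if not text:
        return MatchResult(m, [])

    peq = _build_peq(pattern)
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    pv = mask
    mv = 0
    score = m
    best = m
    ends: list[int] = []
    for j, c in enumerate(text):
        eq = peq.get(ord(c), 0)
        d0 = ((((eq & pv) + pv) ^ pv) | eq | mv) & mask
        hp = (mv | ~(d0 | pv)) & mask
        hn = pv & d0
        if hp & high:
            score += 1
        elif hn & high:
            score -= 1
        # shifted-in boundary bits are 0: the top DP row is constant 0
        hp = (hp << 1) & mask
        hn = (hn << 1) & mask
        pv = (hn | ~(d0 | hp)) & mask
        mv = hp & d0
        if score < best:
            best = score
            ends = [j + 1] if best <= k else []
        elif score == best and best <= k:
            ends.append(j + 1)
        if first_hit and best <= k:
            return MatchResult(best, ends)
    return MatchResult(best, ends if best <= k else [])


def hamming_mismatches(a: str, b: str) -> int:
    """Count mismatching positions between equal-length strings.

    ``N`` differs from every symbol, including another ``N``.
    """
    a = _normalize(a)
    b = _normalize(b)
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _semiglobal_dispatch(pattern: str, text: str, k: int, first_hit: bool) -> MatchResult:
    if len(pattern) <= WORD_SIZE:
        return myers_search(pattern, text, k, first_hit=first_hit)
    res = edit_distance_semiglobal(pattern, text)
    if res.min_distance > k:
        return MatchResult(res.min_distance, [])
    return res


def seeded_search(
    pattern: str,
    text: str,
    k: int,
    *,
    first_hit: bool = False,
) -> MatchResult:
    """Exact semi-global search accelerated by pigeonhole seeding.

    Splits the pattern into ``k + 1`` chunks; any alignment with at most
    ``k`` errors contains at least one chunk verbatim, so exact chunk
    occurrences (found at C speed) delimit candidate windows which are then
    verified with the bit-parallel matcher.  The hit set at distance
    ``<= k`` is identical to scanning the full text; when no hit exists at
    ``<= k`` the reported ``min_distance`` is only guaranteed to exceed
    ``k`` (it is the minimum over the verified windows, or ``k + 1``).
    """
    pattern = _normalize(pattern)
    text = _normalize(text)
    m = len(pattern)
    n = len(text)
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if m > n + k:
        # pattern cannot fit even with k deletions; fall through to scan
        return _semiglobal_dispatch(pattern, text, k, first_hit)
    if k == 0:
        ends = []
        start = text.find(pattern)
        while start != -1:
            ends.append(start + m)
            if first_hit:
                return MatchResult(0, ends)
            start = text.find(pattern, start + 1)
        return MatchResult(0, ends) if ends else MatchResult(k + 1, [])

    n_chunks = k + 1
    chunk_len = m // n_chunks
    if chunk_len < 4:
        # seeds too short to prune anything: plain scan
        return _semiglobal_dispatch(pattern, text, k, first_hit)

    # candidate windows [lo, hi) of text, merged
    windows: list[tuple[int, int]] = []
    for ci in range(n_chunks):
        off = ci * chunk_len
        chunk = pattern[off : off + chunk_len]
        pos = text.find(chunk)
        while pos != -1:
            anchor = pos - off
            windows.append((max(0, anchor - k), min(n, anchor + m + k)))
            pos = text.find(chunk, pos + 1)
    if not windows:
        return MatchResult(k + 1, [])
    windows.sort()
    merged: list[list[int]] = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    best = k + 1
    ends: list[int] = []
    for lo, hi in merged:
        res = _semiglobal_dispatch(pattern, text[lo:hi], k, first_hit)
        if res.min_distance < best:
            best = res.min_distance
            ends = [lo + e for e in res.end_positions]
        elif res.min_distance == best:
            ends.extend(lo + e for e in res.end_positions)
        if first_hit and best <= k:
            break
    ends = sorted(set(ends))
    return MatchResult(best, ends if best <= k else [])
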