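"""Independent brute-force oracles used only by the test suite.

These are deliberately naive (full Wagner-Fischer matrices, explicit
connected components) and share no code with the package implementations
they check.
"""

from __future__ import annotations


def wf_semiglobal(pattern: str, text: str) -> tuple[int, list[int]]:
    """Full Wagner-Fischer semi-global DP: free text start and end.

    Returns (min distance, sorted end offsets achieving it).  N matches
    nothing, unit costs.
    """
    pattern = pattern.upper()
    text = text.upper()
    m, n = len(pattern), len(text)
    if n == 0:
        return m, [0]
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            tc = text[j - 1]
            cost = 0 if (pc == tc and pc != "N") else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    d = min(prev)
    return d, [j for j, v in enumerate(prev) if v == d]


def wf_hits(pattern: str, text: str, k: int) -> tuple[int, list[int]]:
    """Semi-global best distance and its end offsets, empty if best > k."""
    d, ends = wf_semiglobal(pattern, text)
    return d, (ends if d <= k else [])


def connected_component_clusters(
    positions: list[int], max_gap: int
) -> list[list[int]]:
    """Single-linkage clusters of sorted positions via explicit graph walk.

    Two positions are adjacent iff their gap is <= max_gap; clusters are the
    connected components, returned in coordinate order.
    """
    pos = sorted(positions)
    clusters: list[list[int]] = []
    for p in pos:
        placed = False
        for comp in clusters:
            if any(abs(p - q) <= max_gap for q in comp):
                comp.append(p)
                placed = True
                break
        if not placed:
            clusters.append([p])
    # merge components linked transitively (possible with unsorted append order)
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(p - q) <= max_gap
                    for p in clusters[i]
                    for q in clusters[j]
                ):
                    clusters[i].extend(clusters.pop(j))
                    merged = True
                    break
            if merged:
                break
    return sorted([sorted(c) for c in clusters])
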