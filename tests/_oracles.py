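"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles, separately from the
package implementation, so tests compare two independent routes to the same
quantity.
"""

from __future__ import annotations

from itertools import permutations

GENETIC_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            GENETIC_CODE[_a + _b + _c] = _AAS[16 * _i + 4 * _j + _k]


# ---------------------------------------------------------------------------
# Nei-Gojobori by direct enumeration
# ---------------------------------------------------------------------------


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon (stops nonsyn)."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                syn += 1.0
    return syn / 3.0, 3.0 - syn / 3.0


def ng_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """Path-averaged synonymous/nonsynonymous differences between two codons."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(permutations(diff))
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = (
                GENETIC_CODE[cur] != "*"
                and GENETIC_CODE[nxt] != "*"
                and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
            )
            if syn:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
    return sd / len(paths), nd / len(paths)


def ng_estimate(seq1: str, seq2: str) -> dict:
    """Whole-pair Nei-Gojobori counts by per-codon enumeration."""
    import math

    S = N = sd = nd = 0.0
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            continue
        s1, _ = ng_site_counts(c1)
        s2, _ = ng_site_counts(c2)
        S += (s1 + s2) / 2
        N += 3 - (s1 + s2) / 2
        ds, dn = ng_diff_counts(c1, c2)
        sd += ds
        nd += dn
    ps, pn = sd / S if S else 0.0, nd / N if N else 0.0
    ks = None if ps >= 0.75 else -0.75 * math.log(1 - 4 * ps / 3)
    ka = None if pn >= 0.75 else -0.75 * math.log(1 - 4 * pn / 3)
    return {"S": S, "N": N, "sd": sd, "nd": nd, "ps": ps, "pn": pn, "ks": ks, "ka": ka}


# ---------------------------------------------------------------------------
# exhaustive chain search
# ---------------------------------------------------------------------------


def _all_chains(points: list[tuple[int, int]], max_gap: int, sign: int):
    """Every valid chain (any length) over the points, by depth-first search."""
    pts = sorted(points)
    key = {p: (p[0], sign * p[1]) for p in pts}

    def ok(p, q):
        ga = key[q][0] - key[p][0] - 1
        gb = key[q][1] - key[p][1] - 1
        return 0 <= ga <= max_gap and 0 <= gb <= max_gap

    def extend(chain):
        yield list(chain)
        last = chain[-1]
        for q in pts:
            if q > last and ok(last, q):
                chain.append(q)
                yield from extend(chain)
                chain.pop()

    for p in pts:
        yield from extend([p])


def _chain_gap(chain, sign):
    gap = 0
    for p, q in zip(chain, chain[1:]):
        gap += (q[0] - p[0] - 1) + (sign * q[1] - sign * p[1] - 1)
    return gap


def exhaustive_blocks(points, max_gap, min_anchors):
    """Greedy best-chain extraction by exhaustive enumeration, per orientation.

    Mirrors the chaining contract: per orientation, repeatedly pick the chain
    with most anchors (ties: least total gap, then lexicographically smallest
    anchor sequence), remove its anchors, stop below min_anchors.  Returns
    {orientation: [chain, ...]}.
    """
    out = {}
    for orientation, sign in (("+", 1), ("-", -1)):
        remaining = set(points)
        chains = []
        while remaining:
            best = None
            for chain in _all_chains(sorted(remaining), max_gap, sign):
                score = (-len(chain), _chain_gap(chain, sign), tuple(chain))
                if best is None or score < best[0]:
                    best = (score, chain)
            if best is None or len(best[1]) < min_anchors:
                break
            chains.append(best[1])
            remaining -= set(best[1])
        out[orientation] = chains
    return out


# ---------------------------------------------------------------------------
# P-index by literal spreadsheet arithmetic
# ---------------------------------------------------------------------------


def p_index_spreadsheet(windows_by_chrom: dict[str, list[tuple[float, float]]],
                        low=0.1, high=3.0) -> float:
    total = sum(len(v) for v in windows_by_chrom.values())
    p = 0.0
    for windows in windows_by_chrom.values():
        signed = 0.0
        included = 0
        for a, b in windows:
            mean = (a + b) / 2
            d = abs(a - b) / mean if mean > 0 else 0.0
            if low < d < high:
                included += 1
                signed += 1.0 if a > b else -1.0
        contribution = abs(signed) / included if included else 0.0
        p += (len(windows) / total) * contribution
    return p
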