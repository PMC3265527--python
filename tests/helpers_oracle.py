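"""Independent brute-force oracles used by the duplex and mapper tests.

These deliberately re-derive the scoring rules from first principles
(explicit enumeration, positionwise arithmetic) so they share no search
code with the implementations they check.
"""

from __future__ import annotations

WC = {"AU", "UA", "CG", "GC"}
GU = {"GU", "UG"}


def oracle_pair_ok(a, b, model):
    p = a + b
    return p in WC or (model.allow_GU and p in GU)


def oracle_score(mirna, site, pairs, model):
    """Energy of an explicit antiparallel pairing, derived independently."""
    pairs = sorted(pairs)
    e = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a = i2 - i1 - 1  # unpaired miRNA bases between the two pairs
        b = j1 - j2 - 1  # unpaired site bases
        if a == 0 and b == 0:
            e += model.pair_stack_energies[mirna[i1] + mirna[i2] + site[j1] + site[j2]]
        elif a == 0 or b == 0:
            e += model.bulge_open + model.bulge_extend * (a + b - 1)
        else:
            e += model.internal_loop_penalty * (a + b)
    return e


def oracle_duplex_min(mirna, site, model):
    """Minimum energy over *all* antiparallel non-crossing pairings.

    Recursively decides, for each miRNA position in 5'->3' order, whether
    it is unpaired or paired to some admissible site position 3' of . . .
    (strictly lower site index than) the previous pair.
    """
    n, m = len(mirna), len(site)
    best = [0.0]

    def rec(i, jmax, pairs):
        if i == n:
            if len(pairs) >= 2:
                e = oracle_score(mirna, site, pairs, model)
                if e < best[0]:
                    best[0] = e
            return
        rec(i + 1, jmax, pairs)
        for j in range(jmax):
            if oracle_pair_ok(mirna[i], site[j], model):
                pairs.append((i, j))
                rec(i + 1, j, pairs)
                pairs.pop()

    rec(0, m, [])
    return best[0]


def naive_weighted_hamming(b, m, n):
    hd = 0
    for i in range(n):
        if i >= n - 8:
            hd += 1 if b[i] != m[i] else -1
        else:
            hd += 1 if b[i] != m[i] else 0
    return hd


def naive_scan(virtual_seqs, utr_seq, n, threshold):
    """Naive full rescan: every (window, virtual site) pair, merged per window."""
    best = {}
    for vs in virtual_seqs:
        for start in range(len(utr_seq) - n + 1):
            hd = naive_weighted_hamming(vs, utr_seq[start:start + n], n)
            if hd < threshold:
                prev = best.get(start)
                if prev is None or (hd, vs) < prev:
                    best[start] = (hd, vs)
    return {start: hd for start, (hd, _) in best.items()}
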