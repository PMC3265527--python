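"""Mapping virtual binding sites onto UTRs with a seed-weighted Hamming distance.

Every length-N window of a 3'UTR (sense strand, all offsets) is compared
positionwise with each virtual site.  Out-seed positions contribute the
plain Hamming indicator d1 (0 match / 1 mismatch); positions in the
site-side seed block S = {N-8, .., N-1} contribute the weighted indicator
dw (-1 match / +1 mismatch), so a perfect seed block is rewarded rather
than merely tolerated.  Windows with distance strictly below a threshold
become *candidate target binding sites*.

The default threshold follows the reference-configuration rule stated with
the method — the out-seed mismatch count of a site that has a perfectly
complementary seed block and at least 4 further out-seed matches,
``(N-8) - 4`` (= 10 at N = 22).  A stricter alternative applies the
weighted distance itself to that reference configuration, giving
``(N-8-4) - 8`` (= 2 at N = 22); both are exposed in
:class:`MappingConfig` because the two readings are mutually inconsistent
and the printed number corresponds to the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mirevo.core_seq import MiRNA, UTRSequence
from mirevo.ga import VirtualSite

_BASE_CODE = {b: i for i, b in enumerate("ACGU")}


def d1(b: str, m: str) -> int:
    """Plain Hamming indicator: 1 on mismatch, 0 on match."""
    return 0 if b == m else 1


def dw(b: str, m: str) -> int:
    """Seed-weighted indicator: -1 on match, +1 on mismatch."""
    return -1 if b == m else 1


def weighted_hamming(b: str, m: str, mirna_n: int) -> int:
    """Weighted Hamming distance between a virtual site and a UTR window.

    ``HD = sum_{i not in S} d1(b_i, m_i) + sum_{i in S} dw(b_i, m_i)`` with
    the site-side seed block ``S = {N-8, .., N-1}``.  Both strings must
    have length ``mirna_n``.
    """
    if len(b) != mirna_n or len(m) != mirna_n:
        raise ValueError(
            f"length mismatch: |b|={len(b)}, |m|={len(m)}, N={mirna_n}"
        )
    seed_start = mirna_n - 8
    hd = 0
    for i in range(seed_start):
        hd += d1(b[i], m[i])
    for i in range(seed_start, mirna_n):
        hd += dw(b[i], m[i])
    return hd


def threshold_for_length(n: int, strict: bool = False) -> int:
    """Acceptance threshold for a miRNA of length N.

    Default: the printed reference-configuration rule ``(N-8) - 4``, the
    number of out-seed mismatches left when the seed block is perfectly
    complementary and 4 out-seed positions match (10 for N = 22).  With
    ``strict=True`` the weighted distance of that same configuration is
    used instead: ``(N-8-4)*1 + 8*(-1)`` (2 for N = 22).
    """
    if n < 13:
        raise ValueError(f"threshold undefined for N={n} < 13")
    loose = (n - 8) - 4
    return loose - 8 if strict else loose


@dataclass
class MappingConfig:
    strict_threshold: bool = False
    report_all_hits: bool = False  # if True, skip per-window merging

    def threshold(self, n: int) -> int:
        return threshold_for_length(n, strict=self.strict_threshold)


@dataclass(frozen=True)
class CandidateTargetSite:
    """A UTR window accepted by the weighted-Hamming scan."""

    mirna_id: str
    gene_id: str
    start: int
    end: int
    site_sequence: str
    hd: int
    source_virtual_site: str


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_utr(
    candidates: list[VirtualSite],
    utr: UTRSequence,
    mirna: MiRNA,
    cfg: MappingConfig | None = None,
) -> list[CandidateTargetSite]:
    """All UTR windows with weighted Hamming distance below threshold.

    Windows hit by several virtual sites are reported once with the minimum
    distance (ties: lexicographically smallest source), unless
    ``cfg.report_all_hits``.  Output is sorted by start coordinate.
    Returns an empty list (with a warning) if the UTR is shorter than N.
    """
    cfg = cfg or MappingConfig()
    n = mirna.n
    if utr.length < n:
        warnings.warn(
            f"UTR {utr.gene_id!r} ({utr.length} nt) shorter than miRNA length {n}; no scan"
        )
        return []
    thr = cfg.threshold(n)
    useq = _encode(utr.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(useq, n)
    # weights: out-seed mismatches count 1, seed mismatches count 2; a
    # constant -8 accounts for the 8 dw match rewards.
    w = np.ones(n, dtype=np.int64)
    w[n - 8:] = 2

    best: dict[int, tuple[int, str]] = {}
    all_hits: list[CandidateTargetSite] = []
    for vs in candidates:
        b = _encode(vs.sequence)
        if len(b) != n:
            raise ValueError(f"virtual site length {len(b)} != miRNA length {n}")
        hds = (windows != b) @ w - 8
        for start in np.flatnonzero(hds < thr):
            start = int(start)
            hd = int(hds[start])
            if cfg.report_all_hits:
                all_hits.append(
                    CandidateTargetSite(
                        mirna.id, utr.gene_id, start, start + n,
                        utr.sequence[start:start + n], hd, vs.sequence,
                    )
                )
            else:
                prev = best.get(start)
                if prev is None or (hd, vs.sequence) < prev:
                    best[start] = (hd, vs.sequence)
    if cfg.report_all_hits:
        return sorted(all_hits, key=lambda c: (c.start, c.hd, c.source_virtual_site))
    return [
        CandidateTargetSite(
            mirna.id, utr.gene_id, start, start + n,
            utr.sequence[start:start + n], hd, src,
        )
        for start, (hd, src) in sorted(best.items())
    ]
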