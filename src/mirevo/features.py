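"""The 25-dimensional feature vector of a candidate target site.

Features 1-6 describe the miRNA:site duplex (unpaired-base counts and
region energies).  Features 7-25 describe the site's environment on the
mRNA: AU enrichment of the flanks, AU-rich-element pentamer, downstream
G/C motifs, folding free energies of the upstream flank, downstream flank
and site neighborhood (a proxy for the energetic cost of opening the site,
with ddG = duplex energy minus neighborhood energy), positional features,
and base compositions of the mRNA and of the site itself.

Window folding goes through a pluggable ``fold_backend``; the built-in
default is a deterministic Nussinov-style minimum-energy pairing (GC -3,
AU -2, GU -1 kcal/mol, minimum hairpin loop 3), JIT-compiled when numba is
available.  Absolute folded energies are backend-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from functools import lru_cache

import numpy as np

from mirevo.core_seq import MiRNA, UTRSequence, base_fractions
from mirevo.duplex import DuplexResult
from mirevo.mapper import CandidateTargetSite

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair energies for the built-in fold: GC -3, AU -2, GU -1; 0 = disallowed
_PAIR_E = np.zeros((4, 4))
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0

_MIN_HAIRPIN = 3


def _nussinov_kernel(code, pair_e, min_hairpin):  # pragma: no cover - numba body
    L = code.shape[0]
    E = np.zeros((L, L))
    for d in range(min_hairpin + 1, L):
        for i in range(L - d):
            j = i + d
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            e = pair_e[code[i], code[j]]
            if e < 0.0:
                v = E[i + 1, j - 1] + e
                if v < best:
                    best = v
            for k in range(i + 1, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return E[0, L - 1]


try:  # JIT for throughput; the plain-Python body is the reference semantics
    from numba import njit

    _nussinov_fast = njit(cache=False)(_nussinov_kernel)
except Exception:  # pragma: no cover
    _nussinov_fast = _nussinov_kernel


@lru_cache(maxsize=200_000)
def nussinov_fold(seq: str) -> float:
    """Minimum folding free energy (kcal/mol) of a single-stranded window."""
    if len(seq) < _MIN_HAIRPIN + 2:
        return 0.0
    code = np.array([_CODE[b] for b in seq], dtype=np.int8)
    return float(_nussinov_fast(code, _PAIR_E, _MIN_HAIRPIN))


@dataclass
class NeighborhoodConfig:
    """Site-environment extraction parameters.

    ``flank_len`` nucleotides of context are taken on each side of the site
    (truncated at UTR boundaries).  ``motif_window``/``motif_min_count``
    define the downstream G/C motif: some window of ``motif_window`` nt
    containing at least ``motif_min_count`` identical G (resp. C) bases.
    """

    flank_len: int = 70
    fold_backend: object = None  # callable(str) -> float; default Nussinov
    motif_window: int = 6
    motif_min_count: int = 4

    def __post_init__(self):
        if self.flank_len < 10:
            raise ValueError("flank_len must be >= 10")

    def fold(self, seq: str) -> float:
        backend = self.fold_backend or nussinov_fold
        return backend(seq) if seq else 0.0


@dataclass(frozen=True)
class FeatureVector:
    bu_seed: float
    bu_13_16: float
    bu_out_seed: float
    energy_duplex: float
    energy_seed: float
    energy_out_seed: float
    flank_au_ratio: float
    are_pentamer: float
    g_motif_down: float
    c_motif_down: float
    dg_neighborhood: float
    dg_upstream: float
    dg_downstream: float
    ddg: float
    relative_position: float
    position_in_utr: float
    utr_length: float
    mrna_frac_a: float
    mrna_frac_c: float
    mrna_frac_g: float
    mrna_frac_u: float
    site_frac_a: float
    site_frac_c: float
    site_frac_g: float
    site_frac_u: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))


def au_content_ratio(up_flank: str, down_flank: str, utr: UTRSequence) -> float:
    """AU fraction of the concatenated flanks over the whole-UTR AU fraction."""
    utr_au = sum(1 for b in utr.sequence if b in "AU") / utr.length
    if utr_au == 0.0:
        warnings.warn(f"UTR {utr.gene_id!r} has zero AU content; ratio reported as 0")
        return 0.0
    flanks = up_flank + down_flank
    if not flanks:
        return 0.0
    flank_au = sum(1 for b in flanks if b in "AU") / len(flanks)
    return flank_au / utr_au


def gc_motifs_downstream(
    down_flank: str, window: int = 6, min_count: int = 4
) -> tuple[int, int]:
    """(G motif, C motif) presence flags in the downstream flank.

    A motif is present when some length-``window`` subsequence of the flank
    contains at least ``min_count`` copies of the base.
    """
    flags = []
    for base in "GC":
        hit = 0
        for i in range(len(down_flank) - window + 1):
            if down_flank[i:i + window].count(base) >= min_count:
                hit = 1
                break
        flags.append(hit)
    return flags[0], flags[1]


def ddG(d: DuplexResult, dg_neighborhood: float) -> float:
    """Duplex free energy minus the site-neighborhood folding free energy."""
    return d.energy_duplex - dg_neighborhood


def extract_features(
    site: CandidateTargetSite,
    utr: UTRSequence,
    mirna: MiRNA,
    d: DuplexResult,
    cfg: NeighborhoodConfig | None = None,
) -> FeatureVector:
    """Populate all 25 features for one candidate target site."""
    cfg = cfg or NeighborhoodConfig()
    if not (0 <= site.start < site.end <= utr.length):
        raise ValueError(
            f"site [{site.start}, {site.end}) outside UTR {utr.gene_id!r} "
            f"of length {utr.length}"
        )
    seq = utr.sequence
    up = seq[max(0, site.start - cfg.flank_len):site.start]
    down = seq[site.end:site.end + cfg.flank_len]
    site_seq = seq[site.start:site.end]

    dg_up = cfg.fold(up)
    dg_down = cfg.fold(down)
    dg_neigh = cfg.fold(up + site_seq + down)
    g_motif, c_motif = gc_motifs_downstream(down, cfg.motif_window, cfg.motif_min_count)
    mrna_frac = base_fractions(seq)
    site_frac = base_fractions(site_seq)

    return FeatureVector(
        bu_seed=float(d.bu_seed),
        bu_13_16=float(d.bu_13_16),
        bu_out_seed=float(d.bu_out_seed),
        energy_duplex=d.energy_duplex,
        energy_seed=d.energy_seed,
        energy_out_seed=d.energy_out_seed,
        flank_au_ratio=au_content_ratio(up, down, utr),
        are_pentamer=float("AUUUA" in seq),
        g_motif_down=float(g_motif),
        c_motif_down=float(c_motif),
        dg_neighborhood=dg_neigh,
        dg_upstream=dg_up,
        dg_downstream=dg_down,
        ddg=ddG(d, dg_neigh),
        relative_position=site.start / utr.length,
        position_in_utr=float(site.start),
        utr_length=float(utr.length),
        mrna_frac_a=mrna_frac["A"],
        mrna_frac_c=mrna_frac["C"],
        mrna_frac_g=mrna_frac["G"],
        mrna_frac_u=mrna_frac["U"],
        site_frac_a=site_frac["A"],
        site_frac_c=site_frac["C"],
        site_frac_g=site_frac["G"],
        site_frac_u=site_frac["U"],
    )
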