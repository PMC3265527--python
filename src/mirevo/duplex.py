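"""Optimal miRNA:site hybridization and its region decomposition.

The miRNA:site duplex is modelled as an *intermolecular-only*, non-crossing,
antiparallel pairing scored with a nearest-neighbor model: adjacent base
pairs contribute a (negative) stacking free energy, interruptions are
charged as affine bulges (unpaired bases on one strand) or linear internal
loops (unpaired bases on both strands).  No intramolecular structure is
allowed.  The minimum-free-energy pairing is found by dynamic programming
in O(N*M) time using running prefix minima for the loop transitions; the
kernel is JIT-compiled when numba is available (the plain-Python execution
of the same code is the reference semantics).

The total energy and the unpaired-base (BU) counts are decomposed into the
miRNA regions that drive both the genetic-algorithm fitness functions and
six of the SVM features: the seed (miRNA positions 1-8), the 13-16 block,
and the out-seed region (everything outside the seed, which *contains*
13-16; the 13-16 numbers are also reported separately).  Each energy term
is attributed to the region of its 5'-most miRNA base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mirevo.core_seq import MiRNA, normalize_rna

INF = math.inf

WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
GU_PAIRS = frozenset({"GU", "UG"})

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# Watson-Crick nearest-neighbor stacking free energies (kcal/mol, 37 C),
# keyed "m1 m2 s1 s2" for the helix step 5'-m1 m2-3' paired antiparallel
# to 3'-s1 s2-5' (m1.s1 and m2.s2 are the two pairs).
_WC_STACKS = {
    "AAUU": -0.93, "AUUA": -1.10, "AGUC": -2.08, "ACUG": -2.24,
    "UAAU": -1.33, "UUAA": -0.93, "UGAC": -2.11, "UCAG": -2.35,
    "GACU": -2.35, "GUCA": -2.24, "GGCC": -3.26, "GCCG": -3.42,
    "CAGU": -2.11, "CUGA": -2.08, "CGGC": -2.36, "CCGG": -3.26,
}

# Steps involving a G.U wobble pair get a flat, deliberately weak value,
# kept weaker than every WC-WC stack so that mutating a Watson-Crick pair
# into a wobble can never lower the duplex energy.
_GU_STACK = -0.5


def _default_stack_table() -> dict[str, float]:
    table = dict(_WC_STACKS)
    pairs = sorted(WC_PAIRS | GU_PAIRS)
    for p1 in pairs:
        for p2 in pairs:
            key = p1[0] + p2[0] + p1[1] + p2[1]
            if key not in table:
                table[key] = _GU_STACK
    return table


@dataclass(frozen=True)
class EnergyModel:
    """Pluggable duplex energy parameters (kcal/mol).

    ``pair_stack_energies`` maps a helix step ``m1+m2+s1+s2`` (miRNA bases
    5'->3', then their site partners) to a stacking free energy.  Bulges
    are affine (``bulge_open + bulge_extend*(t-1)`` for ``t`` unpaired
    bases on one strand); internal loops cost ``internal_loop_penalty``
    per unpaired base.  An external thermodynamic backend can be adapted
    by supplying a different table.
    """

    pair_stack_energies: dict = field(default_factory=_default_stack_table)
    bulge_open: float = 3.0
    bulge_extend: float = 0.6
    internal_loop_penalty: float = 0.8
    allow_GU: bool = True

    def __post_init__(self):
        if any(v >= 0 for v in self.pair_stack_energies.values()):
            raise ValueError("all stacking energies must be < 0")
        if min(self.bulge_open, self.bulge_extend, self.internal_loop_penalty) < 0:
            raise ValueError("loop penalties must be >= 0")

    def pairable(self, a: str, b: str) -> bool:
        p = a + b
        return p in WC_PAIRS or (self.allow_GU and p in GU_PAIRS)

    def stack(self, m1: str, m2: str, s1: str, s2: str) -> float:
        return self.pair_stack_energies[m1 + m2 + s1 + s2]

    def _tables(self):
        """Integer-coded pairable/stack tables for the DP kernel (cached)."""
        cached = getattr(self, "_table_cache", None)
        if cached is None:
            pairable = np.zeros((4, 4), dtype=np.bool_)
            admissible = WC_PAIRS | (GU_PAIRS if self.allow_GU else frozenset())
            for p in admissible:
                pairable[_CODE[p[0]], _CODE[p[1]]] = True
            stack = np.zeros((4, 4, 4, 4))
            for key, val in self.pair_stack_energies.items():
                a, b, c, d = (_CODE[x] for x in key)
                stack[a, b, c, d] = val
            cached = (pairable, stack)
            object.__setattr__(self, "_table_cache", cached)
        return cached

    @classmethod
    def from_file(cls, path) -> "EnergyModel":
        """Load parameters from a ``key = value`` text file.

        Recognized keys: ``stack.<M1><M2><S1><S2>``, ``bulge_open``,
        ``bulge_extend``, ``internal_loop_penalty``, ``allow_gu``.
        Unspecified stacks fall back to the built-in table.
        """
        table = _default_stack_table()
        kw = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key.startswith("stack."):
                    table[key[6:].upper()] = float(val)
                elif key == "allow_gu":
                    kw["allow_GU"] = val.lower() in ("1", "true", "yes")
                else:
                    kw[key] = float(val)
        return cls(pair_stack_energies=table, **kw)


@dataclass(frozen=True)
class DuplexResult:
    """Energies and unpaired-base counts of an optimal miRNA:site duplex.

    ``pairing`` holds ``(miRNA index, site index)`` tuples, miRNA indices
    strictly increasing and site indices strictly decreasing (antiparallel,
    non-crossing).  ``energy_seed + energy_out_seed == energy_duplex``;
    ``energy_13_16``/``bu_13_16`` are sub-parts of the out-seed numbers,
    reported separately.
    """

    energy_duplex: float
    energy_seed: float
    energy_out_seed: float
    energy_13_16: float
    bu_seed: int
    bu_13_16: int
    bu_out_seed: int
    pairing: tuple
    mirna_len: int
    site_len: int


def _dp_kernel(mcode, rcode, pairable, stack, op, ext, il):
    """Minimum-energy non-crossing pairing of mcode vs reversed-site rcode.

    Returns (best energy, best i, best j, backpointer arrays).  Backpointer
    value -1 marks the 5' start of a chain.  Written in array form so the
    same body runs under numba and plain Python.
    """
    N = mcode.shape[0]
    M = rcode.shape[0]
    big = 1e30
    H = np.full((N, M), big)
    bpi = np.full((N, M), -1, dtype=np.int64)
    bpj = np.full((N, M), -1, dtype=np.int64)
    rmin_v = np.full((N, M), big)
    rmin_a = np.full((N, M), -1, dtype=np.int64)
    cmin_v = np.full((N, M), big)
    cmin_a = np.full((N, M), -1, dtype=np.int64)
    d_v = np.full((N, M), big)
    d_ai = np.full((N, M), -1, dtype=np.int64)
    d_aj = np.full((N, M), -1, dtype=np.int64)

    best = big
    bi = -1
    bj = -1
    for i in range(N):
        for j in range(M):
            h = big
            pi = -1
            pj = -1
            if pairable[mcode[i], rcode[j]]:
                h = 0.0
                if i > 0 and j > 0 and H[i - 1, j - 1] < big:
                    cand = H[i - 1, j - 1] + stack[
                        mcode[i - 1], mcode[i], rcode[j - 1], rcode[j]
                    ]
                    if cand < h:
                        h, pi, pj = cand, i - 1, j - 1
                if i > 0 and j >= 2 and rmin_v[i - 1, j - 2] < big:
                    cand = rmin_v[i - 1, j - 2] + op + ext * (j - 2)
                    if cand < h:
                        h, pi, pj = cand, i - 1, rmin_a[i - 1, j - 2]
                if i >= 2 and j > 0 and cmin_v[i - 2, j - 1] < big:
                    cand = cmin_v[i - 2, j - 1] + op + ext * (i - 2)
                    if cand < h:
                        h, pi, pj = cand, cmin_a[i - 2, j - 1], j - 1
                if i >= 2 and j >= 2 and d_v[i - 2, j - 2] < big:
                    cand = d_v[i - 2, j - 2] + il * (i + j - 2)
                    if cand < h:
                        h, pi, pj = cand, d_ai[i - 2, j - 2], d_aj[i - 2, j - 2]
                H[i, j] = h
                bpi[i, j] = pi
                bpj[i, j] = pj
                if h < best:
                    best, bi, bj = h, i, j
            # running prefix minima over valid cells
            rv = h - ext * j if h < big else big
            if j > 0 and rmin_v[i, j - 1] <= rv:
                rmin_v[i, j] = rmin_v[i, j - 1]
                rmin_a[i, j] = rmin_a[i, j - 1]
            else:
                rmin_v[i, j] = rv
                rmin_a[i, j] = j
            cv = h - ext * i if h < big else big
            if i > 0 and cmin_v[i - 1, j] <= cv:
                cmin_v[i, j] = cmin_v[i - 1, j]
                cmin_a[i, j] = cmin_a[i - 1, j]
            else:
                cmin_v[i, j] = cv
                cmin_a[i, j] = i
            dv = h - il * (i + j) if h < big else big
            ai = i
            aj = j
            if i > 0 and d_v[i - 1, j] < dv:
                dv, ai, aj = d_v[i - 1, j], d_ai[i - 1, j], d_aj[i - 1, j]
            if j > 0 and d_v[i, j - 1] < dv:
                dv, ai, aj = d_v[i, j - 1], d_ai[i, j - 1], d_aj[i, j - 1]
            d_v[i, j] = dv
            d_ai[i, j] = ai
            d_aj[i, j] = aj
    return best, bi, bj, bpi, bpj


try:
    from numba import njit

    _dp_fast = njit(cache=False)(_dp_kernel)
except Exception:  # pragma: no cover
    _dp_fast = _dp_kernel


def _region_sets(n: int):
    seed = frozenset(range(0, min(8, n)))
    p1316 = frozenset(i for i in range(12, 16) if i < n)
    out = frozenset(range(n)) - seed
    return seed, p1316, out


def _loop_cost(a: int, b: int, model: EnergyModel) -> float:
    """Penalty for a loop with `a` unpaired miRNA and `b` unpaired site bases."""
    if a == 0 and b == 0:
        return 0.0
    if a == 0 or b == 0:
        t = a + b
        return model.bulge_open + model.bulge_extend * (t - 1)
    return model.internal_loop_penalty * (a + b)


def score_pairing(mirna_seq: str, site_seq: str, pairing, model: EnergyModel):
    """Score an explicit pairing; return ``(energy, [(attr_index, term), ...])``.

    ``pairing`` is a sequence of ``(i, j)`` site-coordinate pairs; it is
    validated (admissible pairs, strictly monotone antiparallel).  Each
    stacking or loop term is reported with the miRNA index of its 5'-most
    base, for region attribution.
    """
    pairs = sorted(pairing)
    for i, j in pairs:
        if not model.pairable(mirna_seq[i], site_seq[j]):
            raise ValueError(
                f"inadmissible pair {mirna_seq[i]}.{site_seq[j]} at ({i},{j})"
            )
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            raise ValueError("pairing is not antiparallel non-crossing")
    energy = 0.0
    terms = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        if a == 0 and b == 0:
            term = model.stack(mirna_seq[i1], mirna_seq[i2], site_seq[j1], site_seq[j2])
        else:
            term = _loop_cost(a, b, model)
        energy += term
        terms.append((i1, term))
    return energy, terms


def hybridize(mirna, site: str, model: EnergyModel | None = None) -> DuplexResult:
    """Minimum-free-energy intermolecular pairing of a miRNA and a site.

    Parameters
    ----------
    mirna : MiRNA or str
        The miRNA (5'->3').
    site : str
        The candidate site on the mRNA (5'->3'); its 3' end faces the
        miRNA 5' seed in the antiparallel duplex.
    model : EnergyModel, optional
        Defaults to the built-in nearest-neighbor table.

    Returns an open (all-unpaired, energy 0) result when no pairing has
    negative free energy.
    """
    m = mirna.sequence if isinstance(mirna, MiRNA) else normalize_rna(mirna)
    s = normalize_rna(site)
    if len(s) == 0:
        raise ValueError("empty site sequence")
    if model is None:
        model = EnergyModel()
    n_mi, n_site = len(m), len(s)
    if isinstance(mirna, MiRNA) and not (n_mi - 4 <= n_site <= n_mi + 4):
        raise ValueError(
            f"site length {n_site} outside [{n_mi - 4}, {n_mi + 4}] "
            f"for miRNA length {n_mi}"
        )

    r = s[::-1]  # align antiparallel: increasing index on both strands
    mcode = np.array([_CODE[b] for b in m], dtype=np.int8)
    rcode = np.array([_CODE[b] for b in r], dtype=np.int8)
    pairable, stack = model._tables()
    best, bi, bj, bpi, bpj = _dp_fast(
        mcode,
        rcode,
        pairable,
        stack,
        model.bulge_open,
        model.bulge_extend,
        model.internal_loop_penalty,
    )
    if bi < 0 or best >= 0:
        return _make_result(m, s, (), model)
    chain = []
    i, j = bi, bj
    while i >= 0:
        chain.append((i, j))
        i, j = int(bpi[i][j]), int(bpj[i][j])
    pairing = tuple(sorted((i, n_site - 1 - j) for i, j in chain))
    return _make_result(m, s, pairing, model)


def _make_result(m: str, s: str, pairing, model: EnergyModel) -> DuplexResult:
    energy, terms = score_pairing(m, s, pairing, model) if pairing else (0.0, [])
    n = len(m)
    seed, p1316, out = _region_sets(n)
    e_seed = sum(t for i, t in terms if i in seed)
    e_out = sum(t for i, t in terms if i in out)
    e_1316 = sum(t for i, t in terms if i in p1316)
    paired = {i for i, _ in pairing}
    return DuplexResult(
        energy_duplex=energy,
        energy_seed=e_seed,
        energy_out_seed=e_out,
        energy_13_16=e_1316,
        bu_seed=len(seed - paired),
        bu_13_16=len(p1316 - paired),
        bu_out_seed=len(out - paired),
        pairing=pairing,
        mirna_len=n,
        site_len=len(s),
    )


def region_decompose(result: DuplexResult, mirna=None):
    """Region energies and BU counts of a :func:`hybridize` result.

    Returns ``(energy_seed, energy_13_16, energy_out_seed, bu_seed,
    bu_13_16, bu_out_seed)``.  The decomposition is computed during
    :func:`hybridize`; this accessor re-exposes it in a fixed order.
    """
    return (
        result.energy_seed,
        result.energy_13_16,
        result.energy_out_seed,
        result.bu_seed,
        result.bu_13_16,
        result.bu_out_seed,
    )
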