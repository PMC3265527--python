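"""Synthetic fixtures: miRNAs, UTRs with implanted sites, and labelled records.

The generator emulates the statistical structure the predictor assumes in
real data, so every stage can be exercised without downloads:

* *Positive* UTRs carry one implanted near-complementary site per assigned
  miRNA: the reverse complement of the miRNA with the seed-binding block
  kept perfect and out-seed positions mutated at a configurable rate
  (3'-compensatory, seed-degenerate implants are available behind a flag),
  with AU-enriched flanks rewritten around the site.
* *Non-regulated* UTRs are random sequences rejected-and-resampled until
  they contain no exact 8-mer seed complement of any study miRNA; every
  ab-initio candidate found on them is a hard negative by construction.
* The labelled dataset is split 70/30 by *miRNA* (train and held-out sets
  share no miRNA), with negatives drawn both from candidate windows on
  positive UTRs away from the implant ("experimental-style" decoys) and
  from the negative-expansion pipeline on the non-regulated couples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mirevo.classifier import TrainingRecord, expand_negatives
from mirevo.core_seq import MiRNA, UTRSequence, reverse_complement
from mirevo.duplex import EnergyModel, hybridize
from mirevo.features import NeighborhoodConfig, extract_features
from mirevo.ga import GAConfig, run_ga
from mirevo.mapper import MappingConfig, scan_utr

BASES = "ACGU"


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_mirnas: int = 20
    mirna_len: int = 22
    n_positive_utrs: int = 100
    n_nonregulated_utrs: int = 100
    utr_len_range: tuple = (250, 400)
    seed_mismatch_rate: float = 0.15  # out-seed mismatch rate of implants
    seed_degenerate: bool = False  # allow mismatches inside the seed block
    flank_au_enrichment: float = 0.75  # target AU fraction of positive flanks
    flank_len: int = 70
    # Direct-validation negatives are scarce relative to positives (the
    # motivation for negative expansion); each positive UTR contributes a
    # decoy negative record with this probability.
    experimental_negative_rate: float = 0.15
    expanded_per_couple: int = 5
    test_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.seed_mismatch_rate <= 1 and 0 <= self.flank_au_enrichment <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.mirna_len < 17 or min(self.utr_len_range) < self.mirna_len:
            raise ValueError("lengths too short")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(4, size=length))


def make_mirnas(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[MiRNA]:
    """Uniform random miRNAs of ``cfg.mirna_len``; reproducible per seed."""
    rng = rng or np.random.default_rng(cfg.rng_seed)
    return [
        MiRNA(id=f"mir-{i + 1:03d}", sequence=_random_seq(rng, cfg.mirna_len))
        for i in range(cfg.n_mirnas)
    ]


def _au_rewrite(rng: np.random.Generator, length: int, au_fraction: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < au_fraction:
            out.append("A" if rng.random() < 0.5 else "U")
        else:
            out.append("G" if rng.random() < 0.5 else "C")
    return "".join(out)


def implant_site(
    utr: UTRSequence,
    mirna: MiRNA,
    mismatch_rate: float,
    flank_au: float,
    rng: np.random.Generator,
    flank_len: int = 70,
    seed_degenerate: bool = False,
) -> tuple[UTRSequence, int, int]:
    """Write a near-complementary site into a UTR and AU-enrich its flanks.

    The implant is the reverse complement of the miRNA with out-seed site
    positions (``0..N-9``) mutated at ``mismatch_rate``; the seed-binding
    block (last 8 nt of the site) stays perfectly complementary unless
    ``seed_degenerate``.  Returns the modified UTR and the 0-based
    half-open site coordinates.
    """
    n = mirna.n
    if utr.length < n:
        raise ValueError(f"UTR {utr.gene_id!r} too short for a {n}-nt site")
    site = list(reverse_complement(mirna.sequence))
    mutable = range(n) if seed_degenerate else range(n - 8)
    for i in mutable:
        if rng.random() < mismatch_rate:
            site[i] = rng.choice([b for b in BASES if b != site[i]])
    start = int(rng.integers(0, utr.length - n + 1))
    end = start + n
    seq = list(utr.sequence)
    seq[start:end] = site
    up_from = max(0, start - flank_len)
    seq[up_from:start] = _au_rewrite(rng, start - up_from, flank_au)
    down_to = min(utr.length, end + flank_len)
    seq[end:down_to] = _au_rewrite(rng, down_to - end, flank_au)
    return UTRSequence(utr.gene_id, "".join(seq)), start, end


def make_nonregulated_utrs(
    cfg: SimConfig,
    mirnas: list[MiRNA],
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> list[UTRSequence]:
    """Random UTRs containing no exact 8-mer seed complement of any miRNA."""
    rng = rng or np.random.default_rng(cfg.rng_seed)
    forbidden = [reverse_complement(m.sequence[:8]) for m in mirnas]
    utrs = []
    for i in range(cfg.n_nonregulated_utrs):
        for attempt in range(max_attempts):
            length = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
            seq = _random_seq(rng, length)
            if not any(f in seq for f in forbidden):
                utrs.append(UTRSequence(f"nonreg-{i + 1:04d}", seq))
                break
        else:
            raise RuntimeError(
                "could not sample a seed-complement-free UTR; "
                "reduce miRNA count or lengthen the alphabet mixing"
            )
    return utrs


@dataclass
class SyntheticDataset:
    """A labelled miRNA-disjoint benchmark dataset."""

    mirnas: list
    positive_utrs: list  # [(UTRSequence, mirna_id, start, end)]
    nonregulated_utrs: list
    couples: list  # (mirna_id, gene_id) non-regulation evidence pairs
    train_records: list
    test_records: list
    truth: dict  # gene_id -> (mirna_id, start, end)
    train_mirna_ids: set
    test_mirna_ids: set
    missed_positives: dict = field(default_factory=dict)  # split -> [gene_id]
    virtual_sites: dict = field(default_factory=dict)


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def make_labeled_dataset(
    cfg: SimConfig,
    energy_model: EnergyModel | None = None,
    ga_cfg: GAConfig | None = None,
    map_cfg: MappingConfig | None = None,
    feat_cfg: NeighborhoodConfig | None = None,
) -> SyntheticDataset:
    """Generate miRNAs and UTRs, run the ab-initio stage, and label records.

    Positives are candidate windows overlapping an implanted site by at
    least half a site length; candidate windows on positive UTRs away from
    the implant become experimental-style decoy negatives (capped per
    UTR); the non-regulated couples feed the negative-expansion pipeline.
    The 70/30 train/held-out split is by miRNA.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    energy_model = energy_model or EnergyModel()
    ga_cfg = ga_cfg or GAConfig(rng_seed=int(rng.integers(2**31 - 1)))
    map_cfg = map_cfg or MappingConfig()
    feat_cfg = feat_cfg or NeighborhoodConfig(flank_len=cfg.flank_len)

    mirnas = make_mirnas(cfg, rng)
    nonreg = make_nonregulated_utrs(cfg, mirnas, rng)
    couples = [
        (mirnas[j % len(mirnas)].id, u.gene_id) for j, u in enumerate(nonreg)
    ]

    positive_utrs = []
    truth = {}
    for i in range(cfg.n_positive_utrs):
        mirna = mirnas[i % len(mirnas)]
        length = int(rng.integers(cfg.utr_len_range[0], cfg.utr_len_range[1] + 1))
        utr = UTRSequence(f"pos-{i + 1:04d}", _random_seq(rng, length))
        utr, start, end = implant_site(
            utr,
            mirna,
            cfg.seed_mismatch_rate,
            cfg.flank_au_enrichment,
            rng,
            cfg.flank_len,
            cfg.seed_degenerate,
        )
        positive_utrs.append((utr, mirna.id, start, end))
        truth[utr.gene_id] = (mirna.id, start, end)

    # miRNA-disjoint 70/30 split
    ids = [m.id for m in mirnas]
    rng.shuffle(ids)
    n_test = max(1, int(round(cfg.test_fraction * len(ids))))
    test_ids, train_ids = set(ids[:n_test]), set(ids[n_test:])

    # ab-initio stage: GA once per miRNA, then map
    vsites = {}
    mirna_by_id = {m.id: m for m in mirnas}
    for m in mirnas:
        vsites[m.id] = run_ga(m, energy_model, ga_cfg)

    records = []
    missed = {"train": [], "test": []}
    half_site = cfg.mirna_len // 2
    for utr, mirna_id, start, end in positive_utrs:
        mirna = mirna_by_id[mirna_id]
        hits = scan_utr(vsites[mirna_id], utr, mirna, map_cfg)
        on_site = [h for h in hits if _overlap(h.start, h.end, start, end) >= half_site]
        off_site = [h for h in hits if _overlap(h.start, h.end, start, end) == 0]
        split = "test" if mirna_id in test_ids else "train"
        if on_site:
            hit = min(on_site, key=lambda h: (h.hd, abs(h.start - start)))
            d = hybridize(mirna, hit.site_sequence, energy_model)
            records.append(
                TrainingRecord(
                    features=extract_features(hit, utr, mirna, d, feat_cfg),
                    label=1,
                    mirna_id=mirna_id,
                    gene_id=utr.gene_id,
                    provenance="experimental",
                )
            )
        else:
            missed[split].append(utr.gene_id)
        off_site = sorted(off_site, key=lambda h: (h.hd, h.start))
        n_decoys = 1 if rng.random() < cfg.experimental_negative_rate else 0
        for hit in off_site[:n_decoys]:
            d = hybridize(mirna, hit.site_sequence, energy_model)
            records.append(
                TrainingRecord(
                    features=extract_features(hit, utr, mirna, d, feat_cfg),
                    label=0,
                    mirna_id=mirna_id,
                    gene_id=utr.gene_id,
                    provenance="experimental",
                )
            )

    records += expand_negatives(
        mirnas,
        nonreg,
        energy_model,
        ga_cfg,
        map_cfg,
        feat_cfg,
        couples=couples,
        max_per_pair=cfg.expanded_per_couple,
        virtual_sites=vsites,
    )

    train = [r for r in records if r.mirna_id in train_ids]
    test = [r for r in records if r.mirna_id in test_ids]
    return SyntheticDataset(
        mirnas=mirnas,
        positive_utrs=positive_utrs,
        nonregulated_utrs=nonreg,
        couples=couples,
        train_records=train,
        test_records=test,
        truth=truth,
        train_mirna_ids=train_ids,
        test_mirna_ids=test_ids,
        missed_positives=missed,
        virtual_sites=vsites,
    )
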