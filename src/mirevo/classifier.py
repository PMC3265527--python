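"""SVM stage: scaling, training, prediction, and negative-record expansion.

Candidate target sites surviving the ab-initio stage are classified as
functional or not by an SVM (default: RBF kernel, C = 4, gamma = 0.2, the
optimized operating point) over min-max scaled features.  Because direct
experimental negatives are scarce, the training negative set is expanded:
the ab-initio stage is run on UTRs known to be *non-regulated* by a given
miRNA, and every candidate it produces there is labelled negative.  These
expanded negatives pass the same energetic filter as true sites, so they
are hard examples with MRE-like structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.svm import SVC

from mirevo.core_seq import MiRNA, UTRSequence
from mirevo.duplex import EnergyModel, hybridize
from mirevo.features import FEATURE_NAMES, FeatureVector, NeighborhoodConfig, extract_features
from mirevo.ga import GAConfig, run_ga
from mirevo.mapper import MappingConfig, scan_utr

_MODEL_FORMAT_VERSION = 1


@dataclass
class SVMParams:
    kernel: str = "rbf"  # one of linear, poly2, rbf
    C: float = 4.0
    gamma: float = 0.2

    def __post_init__(self):
        if self.kernel not in ("linear", "poly2", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be > 0")


@dataclass(frozen=True)
class TrainingRecord:
    features: FeatureVector
    label: int  # 1 positive, 0 negative
    mirna_id: str
    gene_id: str
    provenance: str = "experimental"  # or "expanded_negative"


@dataclass
class MinMaxScaler:
    """Affine per-feature map sending the training min to -1 and max to +1.

    Degenerate (constant) features map to 0; unseen values extrapolate
    without clipping.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = 2.0 * (X[:, ok] - self.mins[ok]) / span[ok] - 1.0
        return out


def fit_scaler(X: np.ndarray) -> MinMaxScaler:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 records to fit the scaler")
    return MinMaxScaler(mins=X.min(axis=0), maxs=X.max(axis=0))


@dataclass
class TrainedModel:
    scaler: MinMaxScaler
    svm: SVC
    params: SVMParams
    feature_order: tuple = field(default_factory=lambda: FEATURE_NAMES)
    format_version: int = _MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": self.format_version,
                "scaler": self.scaler,
                "svm": self.svm,
                "params": self.params,
                "feature_order": self.feature_order,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model archive version {blob.get('format_version')} unsupported "
                f"(expected {_MODEL_FORMAT_VERSION})"
            )
        return cls(
            scaler=blob["scaler"],
            svm=blob["svm"],
            params=blob["params"],
            feature_order=tuple(blob["feature_order"]),
        )


def _records_to_xy(records: list[TrainingRecord]):
    X = np.array([r.features.to_array() for r in records])
    y = np.array([r.label for r in records], dtype=int)
    return X, y


def train_svm(
    records: list[TrainingRecord],
    params: SVMParams | None = None,
    rng_seed: int = 0,
    class_weight=None,
) -> TrainedModel:
    """Fit the scaler and SVM on labelled records (both classes required)."""
    params = params or SVMParams()
    X, y = _records_to_xy(records)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    scaler = fit_scaler(X)
    kernel_kw = {
        "linear": dict(kernel="linear"),
        "poly2": dict(kernel="poly", degree=2),
        "rbf": dict(kernel="rbf"),
    }[params.kernel]
    svm = SVC(
        C=params.C,
        gamma=params.gamma,
        class_weight=class_weight,
        random_state=rng_seed,
        **kernel_kw,
    )
    svm.fit(scaler.transform(X), y)
    return TrainedModel(scaler=scaler, svm=svm, params=params)


def predict(
    model: TrainedModel,
    feature_vectors: list[FeatureVector],
    feature_order=FEATURE_NAMES,
    decision_threshold: float = 0.0,
):
    """Labels and decision values for candidate feature vectors.

    The raw SVM decision value is exposed so the operating point can be
    shifted for sensitivity/precision sweeps; the label is
    ``decision > decision_threshold``.
    """
    if tuple(feature_order) != tuple(model.feature_order):
        raise ValueError("feature order mismatch between model and input")
    if not feature_vectors:
        return np.array([], dtype=int), np.array([])
    X = np.array([fv.to_array() for fv in feature_vectors])
    dec = model.svm.decision_function(model.scaler.transform(X))
    labels = (dec > decision_threshold).astype(int)
    return labels, dec


def expand_negatives(
    mirnas: list[MiRNA],
    nonregulated_utrs: list[UTRSequence],
    energy_model: EnergyModel | None = None,
    ga_cfg: GAConfig | None = None,
    map_cfg: MappingConfig | None = None,
    feat_cfg: NeighborhoodConfig | None = None,
    couples: list[tuple[str, str]] | None = None,
    max_per_pair: int | None = None,
    virtual_sites: dict | None = None,
) -> list[TrainingRecord]:
    """Ab-initio predictions on non-regulated UTRs, labelled negative.

    ``couples`` restricts the scan to specific (miRNA id, gene id) pairs
    with non-regulation evidence; by default every miRNA is run against
    every UTR.  ``max_per_pair`` keeps only the lowest-distance candidates
    of each pair.  ``virtual_sites`` can supply precomputed GA candidate
    sets keyed by miRNA id (and is filled in as a cache otherwise).
    """
    energy_model = energy_model or EnergyModel()
    ga_cfg = ga_cfg or GAConfig()
    map_cfg = map_cfg or MappingConfig()
    feat_cfg = feat_cfg or NeighborhoodConfig()
    utr_by_gene = {u.gene_id: u for u in nonregulated_utrs}
    if couples is None:
        couples = [(m.id, u.gene_id) for m in mirnas for u in nonregulated_utrs]
    mirna_by_id = {m.id: m for m in mirnas}
    vsites = virtual_sites if virtual_sites is not None else {}

    records = []
    for mirna_id, gene_id in couples:
        mirna = mirna_by_id[mirna_id]
        utr = utr_by_gene[gene_id]
        if mirna_id not in vsites:
            vsites[mirna_id] = run_ga(mirna, energy_model, ga_cfg)
        hits = scan_utr(vsites[mirna_id], utr, mirna, map_cfg)
        hits = sorted(hits, key=lambda c: (c.hd, c.start))
        if max_per_pair is not None:
            hits = hits[:max_per_pair]
        for site in hits:
            d = hybridize(mirna, site.site_sequence, energy_model)
            fv = extract_features(site, utr, mirna, d, feat_cfg)
            records.append(
                TrainingRecord(
                    features=fv,
                    label=0,
                    mirna_id=mirna_id,
                    gene_id=gene_id,
                    provenance="expanded_negative",
                )
            )
    return records


def mirna_disjoint_split(
    records: list[TrainingRecord], test_fraction: float = 0.3, rng_seed: int = 0
):
    """Split records so that train and test share no miRNA."""
    rng = np.random.default_rng(rng_seed)
    ids = sorted({r.mirna_id for r in records})
    rng.shuffle(ids)
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = set(ids[:n_test])
    train = [r for r in records if r.mirna_id not in test_ids]
    test = [r for r in records if r.mirna_id in test_ids]
    assert not ({r.mirna_id for r in train} & {r.mirna_id for r in test})
    return train, test
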