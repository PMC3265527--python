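"""End-to-end orchestration: generate -> map -> features -> predict -> evaluate.

Two entry points:

* :func:`run_pipeline` drives the whole predictor over FASTA inputs and a
  trained model, persisting intermediate TSV artifacts — this is what the
  ``run`` CLI subcommand wraps.
* :func:`benchmark_synthetic` builds the synthetic benchmark dataset,
  trains the SVM stage with and without expanded negatives, and measures
  end-to-end recovery of implanted sites, false-positive rate and the
  composite two-stage metrics on the miRNA-disjoint held-out split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirevo.classifier import SVMParams, TrainedModel, predict, train_svm
from mirevo.core_seq import MiRNA, UTRSequence, read_fasta
from mirevo.duplex import EnergyModel, hybridize
from mirevo.evaluate import ConfusionCounts, composite_metrics
from mirevo.features import FEATURE_NAMES, NeighborhoodConfig, extract_features
from mirevo.ga import GAConfig, run_ga
from mirevo.mapper import MappingConfig, scan_utr
from mirevo.synthetic import SimConfig, make_labeled_dataset

log = logging.getLogger("mirevo")


@dataclass
class RunConfig:
    """File-level configuration of a full prediction run."""

    mirna_fasta: str
    utr_fasta: str
    model_path: str
    out_dir: str
    ga: GAConfig = field(default_factory=GAConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    neighborhood: NeighborhoodConfig = field(default_factory=NeighborhoodConfig)
    energy: EnergyModel = field(default_factory=EnergyModel)


class MissingModelError(FileNotFoundError):
    """Raised when prediction is requested without a trained model."""


def candidates_to_frame(cands) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "gene_id": c.gene_id,
                "start": c.start,
                "end": c.end,
                "hd": c.hd,
                "site_sequence": c.site_sequence,
                "source_virtual_site": c.source_virtual_site,
            }
            for c in cands
        ],
        columns=[
            "mirna_id", "gene_id", "start", "end", "hd",
            "site_sequence", "source_virtual_site",
        ],
    )


def features_for_candidates(cands, utrs_by_gene, mirnas_by_id, energy, feat_cfg):
    rows = []
    for c in cands:
        mirna = mirnas_by_id[c.mirna_id]
        d = hybridize(mirna, c.site_sequence, energy)
        fv = extract_features(c, utrs_by_gene[c.gene_id], mirna, d, feat_cfg)
        rows.append(fv.to_array())
    return np.array(rows).reshape(len(cands), len(FEATURE_NAMES))


def run_pipeline(cfg: RunConfig):
    """Execute the full two-stage prediction; returns (predictions, report).

    Writes ``sites.fasta`` (virtual sites), ``candidates.tsv``,
    ``features.tsv`` and ``predictions.tsv`` under ``cfg.out_dir`` and logs
    per-stage counts.  Raises :class:`MissingModelError` if the trained
    model archive does not exist.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_path = Path(cfg.model_path)
    if not model_path.exists():
        raise MissingModelError(
            f"trained model not found at {model_path}; create one with the "
            f"`train` command first"
        )
    model = TrainedModel.load(model_path)

    mirnas = [MiRNA(i, s) for i, s in read_fasta(cfg.mirna_fasta)]
    utrs = [UTRSequence(i, s) for i, s in read_fasta(cfg.utr_fasta)]
    utrs_by_gene = {u.gene_id: u for u in utrs}
    mirnas_by_id = {m.id: m for m in mirnas}

    with open(out / "sites.fasta", "w") as fh:
        vsites = {}
        for m in mirnas:
            vsites[m.id] = run_ga(m, cfg.energy, cfg.ga)
            for k, v in enumerate(vsites[m.id]):
                fh.write(f">{m.id}|vs{k}|fitness={v.fitness:.4f}\n{v.sequence}\n")
    n_sites = sum(len(v) for v in vsites.values())
    log.info("generate: %d virtual sites for %d miRNAs", n_sites, len(mirnas))

    cands = []
    for m in mirnas:
        for u in utrs:
            cands.extend(scan_utr(vsites[m.id], u, m, cfg.mapping))
    cand_df = candidates_to_frame(cands)
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)
    log.info("map: %d candidate target sites", len(cands))

    X = features_for_candidates(cands, utrs_by_gene, mirnas_by_id, cfg.energy, cfg.neighborhood)
    feat_df = pd.concat(
        [cand_df[["mirna_id", "gene_id", "start", "end"]],
         pd.DataFrame(X, columns=list(FEATURE_NAMES))],
        axis=1,
    )
    feat_df.to_csv(out / "features.tsv", sep="\t", index=False)

    from mirevo.features import FeatureVector

    fvs = [FeatureVector(*row) for row in X]
    labels, dec = predict(model, fvs)
    pred_df = cand_df[["mirna_id", "gene_id", "start", "end", "hd"]].copy()
    pred_df["decision_value"] = dec
    pred_df["predicted"] = labels
    pred_df.to_csv(out / "predictions.tsv", sep="\t", index=False)
    log.info("predict: %d / %d candidates called positive",
             int(labels.sum()) if len(labels) else 0, len(cands))
    report = {
        "n_mirnas": len(mirnas),
        "n_utrs": len(utrs),
        "n_virtual_sites": n_sites,
        "n_candidates": len(cands),
        "n_predicted_positive": int(labels.sum()) if len(labels) else 0,
    }
    return pred_df, report


def benchmark_synthetic(
    cfg: SimConfig | None = None,
    svm_params: SVMParams | None = None,
    energy_model: EnergyModel | None = None,
    ga_cfg: GAConfig | None = None,
    map_cfg: MappingConfig | None = None,
    feat_cfg: NeighborhoodConfig | None = None,
) -> dict:
    """Train and evaluate the two-stage predictor on the synthetic benchmark.

    Returns a dict with end-to-end ``recovery`` of implanted sites (charging
    sites the ab-initio stage missed), held-out ``fp_rate``, specificity of
    models trained with and without expanded negatives, and the composite
    two-stage :class:`MetricReport`.
    """
    cfg = cfg or SimConfig()
    svm_params = svm_params or SVMParams()
    ds = make_labeled_dataset(cfg, energy_model, ga_cfg, map_cfg, feat_cfg)

    model = train_svm(ds.train_records, svm_params, rng_seed=cfg.rng_seed)
    experimental_only = [
        r for r in ds.train_records if r.provenance != "expanded_negative"
    ]
    model_noexp = train_svm(experimental_only, svm_params, rng_seed=cfg.rng_seed)

    test_pos = [r for r in ds.test_records if r.label == 1]
    test_neg = [r for r in ds.test_records if r.label == 0]
    pos_labels, _ = predict(model, [r.features for r in test_pos])
    neg_labels, _ = predict(model, [r.features for r in test_neg])
    neg_labels_noexp, _ = predict(model_noexp, [r.features for r in test_neg])

    tp = int(pos_labels.sum())
    fn_ml = len(test_pos) - tp
    fp = int(neg_labels.sum())
    tn = len(test_neg) - fp
    fn_ab = len(ds.missed_positives["test"])
    n_implants_test = sum(
        1 for _, mirna_id, _, _ in ds.positive_utrs if mirna_id in ds.test_mirna_ids
    )
    counts = ConfusionCounts(tp_ml=tp, fp_ml=fp, tn_ml=tn, fn_ml=fn_ml,
                             tn_ab=0, fn_ab=fn_ab)
    fp_rate = fp / len(test_neg) if test_neg else float("nan")
    spec_with = tn / len(test_neg) if test_neg else float("nan")
    spec_without = (
        (len(test_neg) - int(neg_labels_noexp.sum())) / len(test_neg)
        if test_neg else float("nan")
    )
    return {
        "dataset": ds,
        "recovery": tp / n_implants_test if n_implants_test else float("nan"),
        "fp_rate": fp_rate,
        "specificity_with_expansion": spec_with,
        "specificity_without_expansion": spec_without,
        "confusion": counts,
        "report": composite_metrics(counts),
        "n_implants_test": n_implants_test,
        "n_test_negatives": len(test_neg),
        "fn_ab": fn_ab,
    }
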