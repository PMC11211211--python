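"""End-to-end pipeline: simulate -> extract -> train -> predict -> evaluate.

Transcripts are partitioned into train/validation/test so that no read or
site is shared between splits; site-level evaluation aggregates the test
reads' probabilities with both schemes and scores them against the
site-modification truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from m6aduet.aggregate import aggregate_sites
from m6aduet.features import FeatureConfig, extract_site_read_features
from m6aduet.metrics import MetricReport, compute_metrics
from m6aduet.model import DualResNet, ModelConfig, TrainingResult, predict_read_level, train_model
from m6aduet.simulate import SimConfig, SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    training: TrainingResult
    read_metrics: MetricReport
    site_metrics_mil: MetricReport | None
    site_metrics_freq: MetricReport | None
    n_sites_test: int
    n_reads_test: int
    n_uncalled_mil: int
    read_probs: np.ndarray = field(repr=False, default=None)
    read_labels: np.ndarray = field(repr=False, default=None)


def split_transcripts(
    transcript_ids: list[str],
    seed: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> tuple[list[str], list[str], list[str]]:
    """Shuffle transcripts and split by the given train/val/test fractions
    (each split gets at least one transcript)."""
    ids = sorted(set(transcript_ids))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x73706C]))
    rng.shuffle(ids)
    n = len(ids)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError(f"too few transcripts ({n}) to split into train/val/test")
    return ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]


def _site_classes(ds: SimulatedDataset, tx_ids: list[str]) -> set[int]:
    return {
        t["site_modified"]
        for (tx, _), t in ds.site_truth.items()
        if tx in tx_ids
    }


def run_pipeline(
    sim_cfg: SimConfig,
    model_cfg: ModelConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    *,
    seed: int | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Run the full pipeline on a simulated dataset and score it.

    ``seed`` (default: ``sim_cfg.seed``) drives the transcript split and,
    unless explicit configs are passed, feature sampling, initialization,
    training order and MIL read sampling.
    """
    seed = sim_cfg.seed if seed is None else seed
    model_cfg = model_cfg or ModelConfig(seed=seed)
    feature_cfg = feature_cfg or FeatureConfig(seed=seed)

    ds = simulate_dataset(sim_cfg)
    tx_ids = sorted(ds.references)
    train_tx, val_tx, test_tx = split_transcripts(tx_ids, seed)
    # site-level evaluation needs both classes among test sites; rotate the
    # assignment if a degenerate draw put only one class there
    for _ in range(len(tx_ids)):
        if len(_site_classes(ds, test_tx)) > 1 or len(ds.site_truth) < 2:
            break
        tx_ids = tx_ids[1:] + tx_ids[:1]
        train_tx, val_tx, test_tx = split_transcripts(tx_ids, seed)

    labels = ds.read_labels
    feats = list(
        extract_site_read_features(ds.reads, ds.alignments, ds.sites, feature_cfg, labels=labels)
    )
    by_split = {"train": [], "val": [], "test": []}
    split_of = {tx: "train" for tx in train_tx}
    split_of.update({tx: "val" for tx in val_tx})
    split_of.update({tx: "test" for tx in test_tx})
    for f in feats:
        by_split[split_of[f.transcript_id]].append(f)
    logger.info(
        "features: %d train / %d val / %d test",
        len(by_split["train"]), len(by_split["val"]), len(by_split["test"]),
    )

    model = DualResNet(model_cfg)
    training = train_model(model, by_split["train"], by_split["val"], verbose=verbose)

    test_feats = by_split["test"]
    preds = predict_read_level(model, test_feats)
    probs = np.array([p.pr for p in preds])
    y = np.array([f.label for f in test_feats], dtype=int)
    read_metrics = compute_metrics(probs, y)

    site_truth = {
        (tx, pos): t["site_modified"]
        for (tx, pos), t in ds.site_truth.items()
        if tx in test_tx
    }
    mil_called, mil_uncalled = aggregate_sites(preds, "mil", seed=seed)
    freq_called, _ = aggregate_sites(preds, "frequency")

    def site_report(called):
        pts = [sp.pt for sp in called if (sp.transcript_id, sp.position) in site_truth]
        ys = [site_truth[(sp.transcript_id, sp.position)] for sp in called
              if (sp.transcript_id, sp.position) in site_truth]
        if len(set(ys)) < 2:
            return None
        return compute_metrics(np.array(pts), np.array(ys))

    return PipelineResult(
        training=training,
        read_metrics=read_metrics,
        site_metrics_mil=site_report(mil_called),
        site_metrics_freq=site_report(freq_called),
        n_sites_test=len(site_truth),
        n_reads_test=len(test_feats),
        n_uncalled_mil=len(mil_uncalled),
        read_probs=probs,
        read_labels=y,
    )
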