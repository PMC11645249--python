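"""Desk-scale end-to-end experiment harness.

Reproduces the full method at laptop scale: simulate a synthetic genome
with the default mammalian-like composition, train the tiny network
(phase one without the HMM, then HMM-coupled fine-tuning), run the tiled
two-strand prediction with the boundary second pass, and score the result
against the planted truth.  Both the acceptance script and the end-to-end
tests drive this module, so the numbers they report come from one code
path.

Problem sizes are chosen for a single CPU: a 1 Mb genome, the ~50k
parameter ``tiny`` preset, 9 999-base seamless training windows and a few
thousand optimisation steps; at inference the tiny model is evaluated at
its training context length (``network_chunk``) while the HMM decodes
whole tiles.  The same functions accept larger settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .evaluation import evaluate
from .hmm import HMMParameters, build_transitions
from .io_formats import GenomeRecord, encode_input
from .label_codec import LabelSequence
from .nn.network import NetworkConfig, SequenceClassifier, build_network
from .nn.training import TrainingConfig, fine_tune_with_hmm, train_pre_hmm
from .pipeline import predict_strand_labels, run_genome_prediction
from .simulate import SimulationConfig, simulate_genome, windows_from_genome

logger = logging.getLogger(__name__)

__all__ = ["DeskRunConfig", "train_desk_model", "desk_end_to_end", "boundary_straddle_check"]


@dataclass
class DeskRunConfig:
    """Settings for one desk-scale run, all derived from a single seed."""

    seed: int = 1
    simulation: SimulationConfig = None
    preset: str = "tiny"
    window_length: int = 9999
    pretrain_steps: int = 4000
    finetune_steps: int = 150
    pretrain_lr: float = 3e-3
    finetune_lr: float = 3e-4
    batch_size: int = 4
    genic_fraction: float = 0.7
    tile_length: int = 500_004
    float32: bool = True  # single precision for the training loops

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def train_desk_model(
    config: DeskRunConfig,
) -> Tuple[SequenceClassifier, HMMParameters, GenomeRecord, object, Dict[str, LabelSequence]]:
    """Simulate, pre-train and fine-tune; returns everything downstream needs.

    Training windows are seamless tiles of the simulated genome (both
    strands); the evaluation below asks the trained model to reannotate
    that genome exactly.
    """
    record, annotation, labels = simulate_genome(config.simulation)
    sampler = windows_from_genome(record, labels, config.window_length)
    from .nn import autodiff as ad

    previous_dtype = ad.default_dtype()
    if config.float32:
        ad.set_default_dtype(np.float32)
    try:
        net, params = _train(config, record, sampler)
    finally:
        ad.set_default_dtype(previous_dtype)
    return net, params, record, annotation, labels


def _train(config: DeskRunConfig, record, sampler):
    net = build_network(NetworkConfig(preset=config.preset, seed=config.seed))
    params = build_transitions(config.simulation.mean_lengths)

    pre = TrainingConfig(
        window_length=config.window_length,
        batch_size=config.batch_size,
        learning_rate=config.pretrain_lr,
        max_steps=config.pretrain_steps,
        genic_fraction=config.genic_fraction,
        lr_final_fraction=0.05,
        seed=config.seed,
    )
    history = train_pre_hmm(net, sampler, config=pre)
    logger.info("pre-HMM training: final loss %.4f", history.losses[-1])

    if config.finetune_steps > 0:
        ft = TrainingConfig(
            window_length=config.window_length,
            batch_size=config.batch_size,
            learning_rate=config.finetune_lr,
            max_steps=config.finetune_steps,
            genic_fraction=config.genic_fraction,
            lr_final_fraction=0.1,
            seed=config.seed + 1,
        )
        fine_tune_with_hmm(net, params, sampler, config=ft)
    return net, params


def desk_end_to_end(config: Optional[DeskRunConfig] = None) -> Dict[str, float]:
    """Full pipeline -> exon/gene precision, recall and F1 plus run counts."""
    config = config or DeskRunConfig()
    net, params, record, annotation, labels = train_desk_model(config)
    genes, report = run_genome_prediction(
        [record], net, params, tile_length=config.tile_length,
        network_chunk=config.window_length,
    )
    metrics = evaluate(genes, annotation)
    out = {
        "n_true_genes": float(len(annotation)),
        "n_predicted_genes": float(len(genes)),
        "exon_f1": metrics.exon.f1,
        "exon_recall": metrics.exon.recall,
        "exon_precision": metrics.exon.precision,
        "gene_f1": metrics.gene.f1,
        "gene_recall": metrics.gene.recall,
        "gene_precision": metrics.gene.precision,
        "n_spliced_stop_removed": float(report["n_spliced_stop_removed"]),
    }
    out["_objects"] = (net, params, record, annotation, labels)  # for reuse
    return out


def boundary_straddle_check(
    net: SequenceClassifier,
    params: HMMParameters,
    record: GenomeRecord,
    annotation,
    network_chunk: Optional[int] = 9999,
) -> Dict[str, bool]:
    """Verify a tile-boundary-straddling gene needs the second pass.

    Chooses a tile length that puts an internal tile boundary in the middle
    of a forward-strand gene, then decodes that strand with and without the
    boundary second pass.
    """
    from .label_codec import decode_state_path

    # a gene near the genome middle keeps the two flanking tiles comparable
    # in size, so the second-pass replacement window covers it whole
    target = min(
        (t for t in annotation.transcripts if t.strand == "+"),
        key=lambda t: abs((t.start + t.end) // 2 - record.length // 2),
    )
    tile_length = (target.start + target.end) // 2
    results = {}
    for second_pass in (True, False):
        path, _ = predict_strand_labels(
            record, "+", net, params, tile_length=tile_length,
            second_pass=second_pass, network_chunk=network_chunk,
        )
        genes = decode_state_path(path, record, strict=False)
        recovered = any(tuple(g.cds) == tuple(target.cds) for g in genes)
        results["with_second_pass" if second_pass else "without_second_pass"] = recovered
    return results
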