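"""Train the tiny network on a synthetic genome and predict genes.

A scaled-down version of the full experiment (smaller genome, fewer
optimisation steps, no HMM fine-tuning) so it finishes in a couple of
minutes; the full-scale run lives in ``locusnet.experiments`` and
``scripts/acceptance.py``.
"""

import time

from locusnet.evaluation import evaluate
from locusnet.experiments import DeskRunConfig, train_desk_model
from locusnet.pipeline import run_genome_prediction
from locusnet.simulate import SimulationConfig

config = DeskRunConfig(
    seed=1,
    simulation=SimulationConfig(genome_length=400_000, coding_fraction=0.02, seed=1),
    pretrain_steps=600,
    finetune_steps=0,
)

t0 = time.time()
net, params, record, annotation, labels = train_desk_model(config)
print(f"trained {config.pretrain_steps} steps in {time.time() - t0:.0f}s "
      f"on a {record.length:,} bp genome with {len(annotation)} genes")

t0 = time.time()
genes, report = run_genome_prediction([record], net, params)
print(f"predicted {len(genes)} genes in {time.time() - t0:.0f}s "
      f"({report['n_second_pass']} tile boundaries re-decoded)")

metrics = evaluate(genes, annotation)
print(f"exon level: P {metrics.exon.precision:.2f} R {metrics.exon.recall:.2f} "
      f"F1 {metrics.exon.f1:.2f}")
print(f"gene level: P {metrics.gene.precision:.2f} R {metrics.gene.recall:.2f} "
      f"F1 {metrics.gene.f1:.2f}")
print("gene-level F1 counts a gene only when every exon boundary is exact.")
print("a run this short only begins to learn; accuracy climbs steeply between")
print("~1000 and ~4000 steps — scripts/acceptance.py runs the full recipe")
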