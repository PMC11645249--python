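"""Simulate a small genome with planted genes and inspect its structure.

Builds a 100 kb synthetic genome with mammalian-like composition targets,
prints the genomic composition actually realised, and dumps the exon
structure of the first gene together with its per-base labels.
"""

import numpy as np

import locusnet.alphabet as ab
from locusnet.simulate import SimulationConfig, simulate_genome

config = SimulationConfig(
    genome_length=100_000,
    coding_fraction=0.03,   # denser than the 1% default so a 100 kb toy has genes
    intron_fraction=0.20,
    seed=7,
)
record, annotation, labels = simulate_genome(config)

lab = labels["+"].labels
minus = labels["-"].labels[::-1]
coding_idx = np.array(ab.ALPHABET.exon_class_indices)
coding = (np.isin(lab, coding_idx) | np.isin(minus, coding_idx)).mean()
intron = (np.isin(lab, [ab.I0, ab.I1, ab.I2]) | np.isin(minus, [ab.I0, ab.I1, ab.I2])).mean()

print(f"genome: {record.length:,} bp, {len(annotation)} genes, "
      f"{record.repeat_track.mean():.1%} softmasked")
print(f"composition: {coding:.1%} coding / {intron:.1%} intron / "
      f"{1 - coding - intron:.1%} intergenic")

tr = annotation.transcripts[0]
print(f"\nfirst gene {tr.gene_id} ({tr.strand} strand), CDS {tr.cds_length} bp:")
for (a, b), phase in zip(tr.cds, tr.phases()):
    print(f"  exon {a:>7,}-{b:<7,} ({b - a:>4} bp, phase {phase})")

# the label track around the gene start: START marks the A of ATG
s = tr.start if tr.strand == "+" else record.length - tr.end
track = labels[tr.strand].labels[s : s + 12]
print("\nlabels at the gene 5' end:", [ab.STATE_NAMES[q] for q in track])
print("(frame indices are the codon position of each base; introns carry the")
print(" codon position of the next coding base)")
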