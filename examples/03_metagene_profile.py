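"""G4-centered metagene profile under decay-deficient vs control conditions.

Simulates strand-specific coverage at depth 50 for a control library and a
"decay-deficient" library in which transcripts accumulate 5-fold upstream
(5' side) of every G4 -- the footprint of a 3'->5' exonuclease stalling at
the structure.  The treated/control ratio profile, centered on motif
centers and oriented along the motif-carrying transcript, shows the
asymmetry.
"""
import numpy as np

from mtg4 import metagene
from mtg4.g4scan import G4Motif
from mtg4 import synthetic as syn

cfg = syn.preset_coverage(seed=1)
genome, truth = syn.make_genome(cfg)
motifs = [G4Motif(s, e, st, "", 4, []) for s, e, st in truth.motifs]
control = syn.simulate_coverage(genome, truth, "control", cfg, stream=0)
deficient = syn.simulate_coverage(genome, truth, "deficient", cfg, stream=2)

prof = metagene(deficient, control, motifs, halfwidth=500)
up = prof.ratio[(prof.offsets >= -300) & (prof.offsets <= -50)].mean()
down = prof.ratio[(prof.offsets >= 50) & (prof.offsets <= 300)].mean()
print(f"{prof.n_motifs} G4 anchors, halfwidth {prof.halfwidth} nt")
print(f"mean treated/control ratio upstream  [-300,-50]: {up:.2f}")
print(f"mean treated/control ratio downstream [+50,+300]: {down:.2f}")
print(f"upstream/downstream fold: {up / down:.2f}")
# The >= 2-fold upstream excess reproduces the accumulation-of-RNA-upstream-
# of-G4 signature; downstream of the motif the ratio stays at the library
# baseline (the global scale < 1 reflects library-size normalization when
# one condition gains reads).
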