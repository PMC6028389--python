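"""Is a genome's G4 count explained by its length, AT content and GC skew?

Generates a small G4-dense genome (20 planted motifs on an AT-rich
background), then builds the composition-matched null: 999 random genomes
of the same length, AT fraction and GC skew, each scanned on both strands.
The observed count is ranked against the replicates (add-one empirical p).
"""
from mtg4 import null_distribution
from mtg4 import synthetic as syn

cfg = syn.SimConfig(rng_seed=5, genome_length=2000, n_planted_g4=20,
                    motif_spacing=95, at_fraction=0.7, gc_skew=0.0)
genome, _ = syn.make_genome(cfg)

nd = null_distribution(genome, n=999, mode="constraint", rng_seed=7)
print(f"observed G4 count:        {nd.observed}")
print(f"null mean +/- sd:         {nd.null_mean:.2f} +/- {nd.null_sd:.2f}")
print(f"z-score:                  {nd.z:.1f}")
print(f"empirical p (add-one):    {nd.p_empirical:.4g}")
# p = 1/(n+1): no random genome of matched composition reaches the observed
# count, so the G4 excess is not explained by base composition alone --
# the same reasoning applied to real mitochondrial genomes.
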