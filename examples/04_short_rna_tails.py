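"""Reconstruct full-length short RNAs and call non-templated CCA tails.

Simulates a 2x75 paired-end short-RNA library over species of known genomic
ends and 3' tails, merges each pair through the >= 5-nt overlap rule,
groups merged molecules into coordinate-defined species, and classifies any
3' sequence the genome cannot template (the tRNA-type CCA mark).
"""
from collections import Counter

from mtg4 import call_species, merge_pair
from mtg4 import synthetic as syn

cfg = syn.preset_shortrna(seed=2)
genome, truth = syn.make_genome(cfg)
species = syn.make_species(genome, cfg)
pairs, truth = syn.simulate_read_pairs(species, cfg, truth)

merged, rejected = [], 0
for pair in pairs:
    m = merge_pair(pair, min_overlap=5)
    if m is None:
        rejected += 1
    else:
        merged.append(m.sequence)
print(f"{len(pairs)} read pairs: {len(merged)} merged, {rejected} rejected "
      "(mates overlapping by < 5 nt cannot prove a full-length molecule)")

called, unaligned = call_species(merged, genome, min_count=2)
tails = Counter(s.tail.label for s in called)
print(f"{len(called)} species called ({dict(tails)})")
sp = next(s for s in called if s.tail.label == "CCA")
length = abs(sp.three_prime - sp.five_prime) + 1
print(f"example: {length}-nt species at {sp.five_prime}-{sp.three_prime} "
      f"({sp.strand}), {sp.read_count} supporting pairs, "
      f"non-templated 3' {sp.tail.suffix}")
# A CCA call means the genomic sequence past the 3' end differs from the
# molecule's last bases -- the hallmark of post-transcriptional tRNA-style
# marking on a non-tRNA species.
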