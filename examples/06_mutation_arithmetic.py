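"""Frameshift-allele arithmetic on a synthetic coding sequence.

Shows the two allele archetypes: a C-terminal truncation described by
residue counts, and a small deletion that shifts the reading frame and
creates a premature stop codon.
"""

import numpy as np

from finwave.mutation import apply_deletion, translate_to_stop, truncation_length

# splice-type allele: described purely by residue arithmetic
print("splice allele: 2552 aa full length, 282 aa lost ->",
      truncation_length(2552, 282), "aa protein")

# frameshift allele: 4-nt deletion in a synthetic 300-nt CDS
rng = np.random.default_rng(0)
stops = {"TAA", "TAG", "TGA"}
codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in stops]
cds = "ATG" + "".join(rng.choice(codons) for _ in range(98)) + "TAA"
full = translate_to_stop(cds)
print(f"intact CDS: {len(cds)} nt -> {full.n_residues} aa "
      f"(stop found: {full.stop_found})")

mutated = apply_deletion(cds, pos=30, n=4)
trunc = translate_to_stop(mutated)
print(f"after 4-nt deletion at position 30: {len(mutated)} nt -> "
      f"{trunc.n_residues} aa (stop found: {trunc.stop_found})")
print("\nThe deletion shifts the frame after codon 10, so downstream "
      "codons are scrambled and a premature stop appears early — the "
      "hallmark of a strong loss-of-function allele.")
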