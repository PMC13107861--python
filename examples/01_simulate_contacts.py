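"""Simulate a single cell: a confined multi-chromosome polymer and the
sparse binary contact map it would yield in a single-cell Hi-C experiment.

Prints the contact count, pair density and the intra/inter-chromosomal
split — the regime (binary, ~1% density, intra >> inter) the
reconstruction method is designed for.
"""

import schic3d as sc

spec = sc.reference_spec(seed=0)          # 3 chromosomes x 200 beads at 1 Mbp
truth = sc.simulate_genome_structure(spec)
contacts = sc.simulate_sc_contacts(truth, spec)
matrix = sc.bin_contacts(contacts, spec.binning)

n = matrix.n_beads
intra, inter = matrix.intra_inter_counts()
print(f"beads: {n}, raw contacts: {len(contacts)}")
print(f"binary bead pairs: {matrix.n_contacts} "
      f"({matrix.n_contacts / (n * (n - 1) / 2):.2%} of all pairs)")
print(f"intra: {intra}, inter: {inter}  "
      f"-> C_ratio = {sc.compute_ratio_coefficient(intra, inter):.4f}")
# The matrix is 0/1 only: multiple captures of the same bead pair collapse
# to a single entry, mirroring the binarization the method applies to real
# single-cell maps.
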