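"""Build the 456-dimensional feature vector for one lysine site.

Each candidate lysine is described by two windows: a 7-residue structural
window (8 properties per residue -> 56 features) and a 41-residue PSSM
window condensed by the profile-bigram transform into a 20x20 amino-acid
pair matrix (-> 400 features).  Sites near a protein terminus are padded by
mirroring interior residues.
"""

import numpy as np

import phoglysite as pg

dataset = pg.simulate_dataset(
    pg.SimulationConfig(n_proteins=3, length_range=(50, 80), seed=1)
)
site = dataset.sites[0]
print(f"site: protein {site.protein_id}, lysine at position {site.position}")

segment = pg.extract_segment(
    site, dataset.pssms[site.protein_id], dataset.structs[site.protein_id]
)
print(f"structural window: {segment.structural_window.shape}  (positions "
      f"{segment.source_indices_structural})")
print(f"PSSM window:       {segment.pssm_window.shape}")

vector = pg.build_feature_vector(segment)
names = pg.feature_names()
print(f"\nfeature vector length: {len(vector)}")
print(f"first structural feature  {names[0]} = {vector[0]:.3f}  (A^2)")
print(f"first bigram feature      {names[56]} = {vector[56]:.4f}")

# the bigram block conserves probability mass: 40 consecutive row pairs
print(f"bigram block sum = {vector[56:].sum():.12f}  (expected 40, one per "
      "consecutive window row pair)")

# a site near the N-terminus still gets full-width windows: missing
# upstream rows are filled by mirroring interior residues
protein, pos = min(
    ((p, k) for p in dataset.proteins for k in pg.find_lysines(p)),
    key=lambda pk: pk[1],
)
edge = pg.SiteLabel(protein.id, pos, 0)
seg_edge = pg.extract_segment(
    edge, dataset.pssms[protein.id], dataset.structs[protein.id]
)
assert seg_edge.pssm_window.shape == (41, 20)
print(f"\nsite at position {pos}: window still 41 rows, source indices start "
      f"{seg_edge.source_indices_pssm[:8]}... (mirror-padded)")
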