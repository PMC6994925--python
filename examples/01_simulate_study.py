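"""Generate a synthetic paired lipidome/transcriptome study.

Builds the five-group, two-timepoint dietary design (SD control, HFD
prediabetes, HFD-STZ diabetes, plus the two dietary-reversal groups at the
late timepoint), plants a TG/DG disease effect and a joint latent factor,
and prints what was planted where.
"""

import lipidlink as ll

design = ll.StudyDesign(n_per_group=10)
config = ll.SimulationConfig(seed=1)
study = ll.simulate_study(design, config)

print(f"samples: {study.lipids.n_samples} "
      f"({design.n_per_group}/group; reversal groups only at 24wk)")
print(f"lipid matrix: {study.lipids.n_features} raw rows "
      f"({config.n_lipids} unique species + ion-mode duplicates + standards)")
print(f"gene counts:  {study.genes.n_features} genes")

truth = study.truth
print(f"\nplanted disease effect: +{config.disease_effect_size} log2 on "
      f"{len(truth['lipidome']['affected_lipids'])} TG/DG species and "
      f"{len(truth['transcriptome']['affected_genes'])} genes "
      f"(restored in the DR groups)")
print(f"planted joint factor: {len(truth['joint']['joint_lipids'])} TG lipids "
      f"x {len(truth['joint']['joint_genes'])} genes, "
      f"score correlated with disease status")
print(f"annotation table: {len(study.annotation)} gene-lipid pairs; "
      f"{len(study.gene_sets)} GMT gene sets")
# The truth dict is what downstream recovery is scored against.
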