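"""Rank TF binding changes for one synthetic variant with known ground truth.

Builds a 61 bp 'destroy' scenario: a strong motif's consensus site spans the
variant position on the reference allele and the variant substitutes the
least favourable base at the site's most informative position, buried in a
collection of 50 random decoy motifs. The pipeline should place the true TF
at the top of the positive (binding-lost) list.
"""

import numpy as np

from bindshift import (
    build_integration_matrix,
    make_planted_case,
    mutation_score,
    pca_integrate,
    pwm_to_energy,
    scan_variant,
)

case = make_planted_case(np.random.default_rng(11), "destroy", n_decoys=50)
print(f"variant: {case.ref_seq[case.snp_pos]}>{case.mut_seq[case.snp_pos]} "
      f"at window position {case.snp_pos}, true motif {case.true_motif.consensus()}")

energies = [pwm_to_energy(p) for p in case.all_pwms()]
table = scan_variant(energies, case.ref_seq, case.mut_seq, R=100, seed=11)
prediction = pca_integrate(build_integration_matrix(table))

print(f"\nmotifs passing the direct-binding filter: {len(prediction.scores)} / {len(energies)}")
print("\ntop of the positive list (binding lost in the mutant):")
for frame_row in prediction.to_frame().query("direction == '+'").head(5).itertuples():
    print(f"  rank {frame_row.rank}  {frame_row.tf_name:10s} "
          f"score {frame_row.integrated_score:8.4f}  mean delta {frame_row.mean_delta:8.4f}")

print(f"\ntrue TF rank in the positive list: {prediction.tf_rank('TRUE_TF', 'positive')}")
print(f"functional-mutation score (top-20 mean |delta dbA|): "
      f"{mutation_score(prediction, table):.4f}")
print("\nA rank of 1 means the destroyed site's TF is the pipeline's first call;")
print("the mutation score is large when some TF's binding changes strongly.")
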