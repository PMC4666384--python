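"""The batch pipeline on files: genome FASTA + variant TSV + PWM collection.

Writes a small synthetic genome with one planted site, a variant table and
a JASPAR-format PWM collection to a temporary directory, then runs the
end-to-end pipeline the way the CLI does and prints the per-variant
summary.
"""

import tempfile
from pathlib import Path

import numpy as np

from bindshift import (
    PipelineConfig,
    Variant,
    load_variants,
    make_planted_case,
    read_pwm_collection,
    run_pipeline,
)
from bindshift.motifs import write_jaspar
from bindshift.synthetic import write_fasta
from bindshift.variants import write_variants_tsv

rng = np.random.default_rng(31)
case = make_planted_case(rng, "destroy", n_decoys=20)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    # embed the 61 bp reference window mid-chromosome
    pad = "".join(rng.choice(list("ACGT"), size=150))
    write_fasta(tmp / "genome.fa", [("chr1", pad + case.ref_seq + pad)])
    variant = Variant(chrom="chr1", pos=len(pad) + case.snp_pos + 1,
                      ref_allele=case.ref_seq[case.snp_pos],
                      alt_allele=case.mut_seq[case.snp_pos], id="rs_demo")
    write_variants_tsv([variant], tmp / "variants.tsv")
    write_jaspar(tmp / "pwms.jaspar", case.all_pwms())

    pwms = read_pwm_collection(tmp / "pwms.jaspar")
    variants = load_variants(tmp / "variants.tsv")
    result = run_pipeline(variants, pwms, genome=tmp / "genome.fa",
                          config=PipelineConfig(R=100, seed=31))

print(result.summary.to_string(index=False))
res = result.results["rs_demo"]
print(f"\ntop positive-list TF: {res.prediction.tf_positive[0]} "
      f"(expected TRUE_TF, whose site the variant destroys)")
print("The summary's mutation_score column is the top-20 mean |delta dbA|;")
print("verified regulatory variants score higher than neutral ones.")
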