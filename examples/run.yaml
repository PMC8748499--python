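# Example run configuration for `sigdriver run-all --config run.yaml`.
# Generate the referenced files first with `sigdriver simulate --seed 7 --out data/`.

variants: data/variants.tsv        # MAF-like TSV: tumor_id, chrom, pos, ref, alt
profiles: data/profiles.tsv        # tumor_id, entity, sex
genome: data/genome.fa             # reference FASTA
signatures: data/signatures.tsv    # classes x signatures probabilities
# exposures: data/exposures.tsv    # optional: externally computed exposures (skips fitting)
# panel: data/panel.tsv            # optional: panel of normals (chrom, pos, alt, fraction)

context_mode: trinucleotide        # or nxsxn
mode: normal                       # entity restriction: normal (5%) or wide (2%)
seed: 7
out: results/run

# any key from the threshold registry can be overridden here, e.g.:
thresholds:
  resampling_B: 999
  alpha: 0.05
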