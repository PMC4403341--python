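# Demo pipeline configuration on desk-scale synthetic fixtures.
# The recovery cutoff is widened from the genome-scale default (0.25% of
# ~1.2M regions) to 10% of this toy catalog so the cutoff window still
# contains a meaningful number of ranks.
seed: 7
out_dir: pipeline_out
cutoff_frac: 0.10
n_links: 16
chrom_mb: 20
n_extra_regions: 80
n_extra_de_genes: 16
n_null_genes: 120
n_decoy_pwms: 8
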