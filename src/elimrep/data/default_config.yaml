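# Packaged default pipeline configuration: the study karyotype (2n = 52
# germline / 2n = 36 somatic) at desk scale, error-free 10x reads, and the
# 100-fold k-mer enrichment criterion with k = 21.
seed: 0
germline_2n: 52
somatic_2n: 36
e_chromosome_length: 50000
retained_chromosome_length: 100000
eliminated_fraction_target: 0.21
family_seed: 0
dispersed_per_bp: 0.0001
coverage: 10.0
read_length: 100
error_rate: 0.0
k: 21
ratio_threshold: 100.0
min_germline_count: 10
clones_per_family: 20
clone_mutation_rate: 0.01
bin_bp: 2000
reference_probe: EEEb1
fiber_bin_bp: 50
fiber_region_bp: 16000
n_permutations: 1000
pcr_template_copies: 3
pcr_max_len: 3000
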