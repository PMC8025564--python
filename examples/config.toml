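# Full run configuration with every recognized key, set to the package
# defaults.  Any key may be omitted; omitted keys take these values.

# Numeric values behind the High/Low parameter levels.
[levels.te_progeny]
low = 1
high = 2

[levels.te_excision_rate]
low = 0.08
high = 0.16

[levels.te_death_rate]
low = 0.04
high = 0.08

# 'proportional' = unbiased targeting: insertions hit non-coding loci at the
# genome's current non-coding fraction.
[levels.insertion_bias]
low = "proportional"
high = 0.9

[levels.corrected_mutation_rate]
low = 1e-4
high = 1e-3

[levels.non_coding_dna]
low = 0.3
high = 0.7

[levels.mutation_effect]
low = 0.01
high = 0.1

[levels.carrying_capacity]
low = 100
high = 500

# Global model constants not on any High/Low axis.
[defaults]
genome_length = 1000
initial_te_per_host = 5
transposition_rate = 0.05
s_deleterious = 0.01
s_beneficial = 0.30
max_generations = 1500

# The experimental design: which cells to run.
[design]
scenarios = [
    "HLLL-LHLH",
    "LLHH-LHHH",
    "LLLH-LHHL",
    "LLLH-LLHH",
    "LLLL-LHHH",
    "LLLL-LLHL",
]
beneficial_pcts = [0, 20]
replicates = 3
max_generations = 1500
base_seed = 1

[output]
directory = "results"
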