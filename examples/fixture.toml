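# Shipped fixture configuration: a complete synthetic two-species run.
# Reference species "melsim" carries six planted stem-loop precursors in a
# 10 kb genome; "pseudo" is derived from it at the canonical recovery
# setting (10% transitions, 5% transversions). Two precursors' 5p arms are
# 4-fold up in "pseudo".

[run]
out_dir = "mirevo_out"
seed = 1
log_level = "INFO"

[simulate]
genome_length = 10000
n_precursors = 6
library_depth = 2000
species = ["melsim", "pseudo"]

[diffexp]
alpha = 0.05
correction = "bh"
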