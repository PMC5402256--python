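"""Named default parameters of the analysis, collected in one place."""

# layer construction
COOCCURRENCE_THRESHOLD = 45  # edge iff pair co-occurs strictly more often
CDI_KNOWN_THRESHOLD = 0.5  # a word is known once half the children produce it
MONTHS = tuple(range(16, 31))  # CDI reporting window

# ensembles
N_NULL_SAMPLES = 100  # configuration-model samples per layer
N_SWAPS_PER_EDGE = 10  # double-edge swaps per edge per null sample
N_AOA_ORDERINGS = 30  # normative orderings sampled from the norms
N_HOLDOUT_CONFIGS = 50  # Monte Carlo hold-out repetitions in optimization
HOLDOUT_FRACTION = 0.2  # words removed per hold-out repetition

# significance
GAUSSIAN_MIN_T = 60  # Gaussian p-values only after this many acquired words
ALPHA = 0.025  # one-sided significance level (critical Z = 1.96)
N_DIRECT_SAMPLES = 100_000  # random orderings for direct sampling below the cutoff
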