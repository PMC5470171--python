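"""Default parameters for the synthetic study and the estimators.

The growth presets emulate an Arabidopsis first-leaf-pair experiment in
which a wild-type-like genotype keeps proliferating until 15 days after
stratification (DAS) while overexpression-like genotypes arrest early
(10 or 12 DAS), after which cells only expand until maturity around
24 DAS.  Rates are chosen at magnitudes typical for young Arabidopsis
leaves: division rates of a few tenths per day (cell-cycle times of
roughly 1.5-2 days) and relative cell-expansion rates of a similar order.
"""

# Time axis of the growth study (integer days after stratification).
DEFAULT_DAYS = tuple(range(6, 29))

# Leaves measured per day.
DEFAULT_REPLICATES = 6

# Lognormal measurement noise (coefficient of variation of areas).
DEFAULT_NOISE_CV = 0.05

# Division-rate threshold (day^-1) below which proliferation is
# considered to have ceased; used by the proliferation-exit estimator.
DEFAULT_EXIT_THRESHOLD = 0.02

# Smoothing window (days) for local quadratic regression on log series.
DEFAULT_WINDOW = 5

# Genotype presets for the synthetic growth study.  Keys are the
# GrowthParams fields that differ from the shared baseline.
GROWTH_BASELINE = dict(
    n0=400.0,          # epidermal pavement cells at day 6
    r_div=0.40,        # day^-1 during proliferation (Tc ~ 1.7 d)
    r_exp=0.35,        # day^-1 relative cell expansion after arrest
    a0=75.0,           # um^2 mean pavement-cell area at day 6
    t_mature=24.0,     # cell size maturity
    noise_cv=DEFAULT_NOISE_CV,
    n_replicates=DEFAULT_REPLICATES,
)

GROWTH_PRESETS = {
    # keeps producing new cells until 15 DAS
    "WT-like": dict(GROWTH_BASELINE, t_arrest=15.0),
    # proliferation arrested from 10 DAS onward
    "OE-like": dict(GROWTH_BASELINE, t_arrest=10.0),
    # intermediate line, arrest around 12 DAS
    "OE-mild": dict(GROWTH_BASELINE, t_arrest=12.0),
}

# Expression statistics defaults.
DEFAULT_TARGET_DEPTH = 10_000_000   # scale-to-depth target (reads)
DEFAULT_ALPHA = 0.05                # FDR threshold
DEFAULT_FC_THRESHOLD = 0.75         # |log2 fold change| must exceed this
DEFAULT_PSEUDOCOUNT = 1.0           # added to scaled means before log2
DEFAULT_QT_DIAMETER = 0.8           # 1 - Pearson r
DEFAULT_QT_MIN_SIZE = 15
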