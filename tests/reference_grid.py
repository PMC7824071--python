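"""Reference coverage-study grid for the chi-based limit of agreement.

Published simulation-study values (10,000 samples per cell, sigma = 1):
closed-form multiplier, empirical 95% quantiles of the scale-normalised
subject SDs (in-sample pooled, and held-out), and coverages of the limit
for the in-sample and held-out subjects.
"""

REFERENCE_GRID = {
    (2, 10): {"formula": 1.959964, "q95_original": 1.907143, "q95_new": 2.188023,
              "coverage_original": 0.9575, "coverage_new": 0.9247},
    (2, 20): {"formula": 1.959964, "q95_original": 1.939001, "q95_new": 2.069437,
              "coverage_original": 0.9528, "coverage_new": 0.9400},
    (2, 100): {"formula": 1.959964, "q95_original": 1.954703, "q95_new": 1.963274,
               "coverage_original": 0.9506, "coverage_new": 0.9497},
    (3, 10): {"formula": 1.730818, "q95_original": 1.681992, "q95_new": 1.880320,
              "coverage_original": 0.9594, "coverage_new": 0.9253},
    (3, 20): {"formula": 1.730818, "q95_original": 1.709057, "q95_new": 1.780882,
              "coverage_original": 0.9542, "coverage_new": 0.9404},
    (3, 100): {"formula": 1.730818, "q95_original": 1.726664, "q95_new": 1.741569,
               "coverage_original": 0.9507, "coverage_new": 0.9488},
    (4, 10): {"formula": 1.613973, "q95_original": 1.572103, "q95_new": 1.706937,
              "coverage_original": 0.9595, "coverage_new": 0.9297},
    (4, 20): {"formula": 1.613973, "q95_original": 1.609547, "q95_new": 1.654243,
              "coverage_original": 0.9539, "coverage_new": 0.9417},
    (4, 100): {"formula": 1.613973, "q95_original": 1.612125, "q95_new": 1.624840,
               "coverage_original": 0.9510, "coverage_new": 0.9479},
    (5, 10): {"formula": 1.540108, "q95_original": 1.525253, "q95_new": 1.594541,
              "coverage_original": 0.9597, "coverage_new": 0.9361},
    (5, 20): {"formula": 1.540108, "q95_original": 1.536958, "q95_new": 1.57577,
              "coverage_original": 0.9541, "coverage_new": 0.9408},
    (5, 100): {"formula": 1.540108, "q95_original": 1.534751, "q95_new": 1.552975,
               "coverage_original": 0.9508, "coverage_new": 0.9462},
}
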