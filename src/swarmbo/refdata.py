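"""Published reference logs from the VGG visual-field-defect tuning study.

These are the printed per-iteration validation accuracies (in percent) of
VGG-16 and VGG-19 fine-tuning runs, each driven by Bayesian optimization
under a different acquisition strategy (plain EI/PI/UCB/LCB, EI enhanced by
one of four swarm metaheuristics, and a CMA-ES comparator), 11 iterations
per run.  They serve as worked examples for the aggregation arithmetic in
:mod:`swarmbo.metrics` and as the source of the built-in search-space
bounds and the shared first-iteration configuration.

Values are transcribed as printed; a handful of the study's own summary
numbers are not reproducible from these columns under any convention (see
docs/methods.md) and are not used as checks.
"""

from __future__ import annotations

VARIANTS = ("CMA-ES", "EI", "EI-PSO", "EI-ABC", "EI-HHO", "EI-SFO",
            "PI", "UCB", "LCB")

#: Per-iteration validation accuracy (%) of the VGG-16 runs, 11 iterations.
VGG16_ACCURACY = {
    "CMA-ES": [20.55, 20.55, 20.55, 20.55, 20.55, 20.55, 20.55, 20.55,
               20.55, 15.67, 20.55],
    "EI":     [20.55, 95.97, 20.55, 20.55, 19.96, 20.55, 20.55, 96.74,
               20.55, 18.81, 97.92],
    "EI-PSO": [20.55, 94.75, 71.57, 17.16, 20.55, 97.80, 19.03, 20.55,
               19.41, 19.96, 20.55],
    "EI-ABC": [20.55, 19.45, 20.55, 15.93, 83.31, 20.00, 97.84, 20.55,
               71.19, 14.41, 20.55],
    "EI-HHO": [20.55, 19.41, 20.55, 20.55, 20.55, 19.36, 97.03, 20.55,
               20.55, 98.26, 96.53],
    "EI-SFO": [20.55, 94.87, 52.92, 20.55, 92.84, 98.60, 19.45, 16.65,
               20.55, 20.55, 20.55],
    "PI":     [20.55, 15.68, 20.55, 20.55, 95.85, 20.55, 96.23, 20.55,
               18.52, 19.36, 20.55],
    "UCB":    [97.88, 20.55, 96.31, 96.86, 20.55, 19.07, 16.19, 20.55,
               20.55, 20.55, 17.46],
    "LCB":    [98.26, 94.28, 18.31, 20.55, 20.55, 20.55, 17.33, 98.22,
               16.91, 20.55, 93.43],
}

#: Per-iteration validation accuracy (%) of the VGG-19 runs, 11 iterations.
VGG19_ACCURACY = {
    "CMA-ES": [20.55, 17.80, 20.55, 97.03, 17.58, 17.58, 20.55, 93.64,
               20.55, 20.55, 92.16],
    "EI":     [20.55, 19.11, 20.55, 20.55, 19.96, 20.55, 18.22, 17.37,
               20.55, 20.55, 18.52],
    "EI-PSO": [20.55, 18.26, 20.55, 19.96, 92.67, 95.64, 20.55, 20.55,
               20.55, 20.55, 19.96],
    "EI-ABC": [97.63, 20.55, 94.19, 20.55, 20.55, 20.55, 20.55, 20.55,
               94.53, 20.55, 92.12],
    "EI-HHO": [20.55, 20.55, 92.88, 20.55, 20.00, 20.55, 20.55, 20.55,
               20.55, 19.41, 20.55],
    "EI-SFO": [20.55, 20.00, 94.87, 18.77, 20.55, 17.58, 20.00, 19.37,
               95.55, 95.89, 98.35],
    "PI":     [20.55, 20.55, 18.98, 20.55, 97.67, 76.99, 97.12, 71.31,
               20.55, 19.96, 19.41],
    "UCB":    [20.55, 16.95, 20.55, 93.64, 20.55, 20.55, 20.55, 20.55,
               15.47, 20.55, 93.60],
    "LCB":    [20.55, 98.00, 19.36, 18.18, 20.55, 20.55, 20.55, 20.55,
               19.96, 20.55, 32.46],
}

#: The full VGG-16 EI run: one configuration dict + accuracy per iteration.
#: (The study's shared iteration-1 configuration is the first row.)
VGG16_EI_TRIALS = [
    ({"feature_map": 64, "filter_size": 3, "activation": "ReLU",
      "pool_size": 2, "optimizer": "ADAM", "learning_rate": 0.001,
      "batch_size": 32, "epoch": 200, "dropout_rate": 0.2,
      "upper_layer": "FALSE", "lower_layer": "FALSE"}, 20.55),
    ({"feature_map": 58, "filter_size": 2, "activation": "ReLU",
      "pool_size": 1, "optimizer": "RMSprop", "learning_rate": 0.0009,
      "batch_size": 24, "epoch": 29, "dropout_rate": 0.5,
      "upper_layer": "TRUE", "lower_layer": "FALSE"}, 95.97),
    ({"feature_map": 38, "filter_size": 2, "activation": "Sigmoid",
      "pool_size": 1, "optimizer": "ADAM", "learning_rate": 0.0022,
      "batch_size": 10, "epoch": 51, "dropout_rate": 0.2,
      "upper_layer": "TRUE", "lower_layer": "TRUE"}, 20.55),
    ({"feature_map": 33, "filter_size": 1, "activation": "Sigmoid",
      "pool_size": 1, "optimizer": "Adadelta", "learning_rate": 0.0031,
      "batch_size": 26, "epoch": 40, "dropout_rate": 0.8,
      "upper_layer": "FALSE", "lower_layer": "FALSE"}, 20.55),
    ({"feature_map": 38, "filter_size": 2, "activation": "Sigmoid",
      "pool_size": 1, "optimizer": "SGD", "learning_rate": 0.0117,
      "batch_size": 13, "epoch": 23, "dropout_rate": 0.7,
      "upper_layer": "TRUE", "lower_layer": "FALSE"}, 19.96),
    ({"feature_map": 46, "filter_size": 2, "activation": "Sigmoid",
      "pool_size": 2, "optimizer": "RMSprop", "learning_rate": 0.0019,
      "batch_size": 18, "epoch": 34, "dropout_rate": 0.6,
      "upper_layer": "TRUE", "lower_layer": "FALSE"}, 20.55),
    ({"feature_map": 41, "filter_size": 2, "activation": "Sigmoid",
      "pool_size": 2, "optimizer": "ADAM", "learning_rate": 0.0003,
      "batch_size": 11, "epoch": 76, "dropout_rate": 0.9,
      "upper_layer": "FALSE", "lower_layer": "FALSE"}, 20.55),
    ({"feature_map": 35, "filter_size": 2, "activation": "ReLU",
      "pool_size": 1, "optimizer": "ADAM", "learning_rate": 0.0007,
      "batch_size": 29, "epoch": 94, "dropout_rate": 0.1,
      "upper_layer": "FALSE", "lower_layer": "FALSE"}, 96.74),
    ({"feature_map": 47, "filter_size": 1, "activation": "ReLU",
      "pool_size": 2, "optimizer": "RMSprop", "learning_rate": 0.0068,
      "batch_size": 2, "epoch": 167, "dropout_rate": 0.9,
      "upper_layer": "TRUE", "lower_layer": "TRUE"}, 20.55),
    ({"feature_map": 56, "filter_size": 2, "activation": "ReLU",
      "pool_size": 1, "optimizer": "RMSprop", "learning_rate": 0.0264,
      "batch_size": 6, "epoch": 97, "dropout_rate": 0.4,
      "upper_layer": "TRUE", "lower_layer": "FALSE"}, 18.81),
    ({"feature_map": 64, "filter_size": 2, "activation": "ReLU",
      "pool_size": 2, "optimizer": "SGD", "learning_rate": 0.0226,
      "batch_size": 27, "epoch": 200, "dropout_rate": 0.9,
      "upper_layer": "TRUE", "lower_layer": "TRUE"}, 97.92),
]

#: Shared first-iteration configuration of every acquisition variant.
INITIAL_CONFIG = dict(VGG16_EI_TRIALS[0][0])

#: Class distribution of the pooled visual-field-defect dataset (1268 images).
VF_CLASS_COUNTS = {
    "central_scotoma": 204,
    "hemianopia": 223,
    "quadrantanopia": 160,
    "tunnel": 226,
    "superior_inferior": 181,
    "normal": 274,
}

#: Per-class correct-classification rates (%) read off the test-set
#: confusion matrices of the best tuned models, ordered
#: (central, superior, hemianopia, quadrantanopia, normal, tunnel).
VGG16_PER_CLASS_RATES = [100, 100, 100, 93, 98, 96]
VGG19_PER_CLASS_RATES = [100, 100, 100, 96, 99, 95]
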