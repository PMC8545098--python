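"""Classifier benchmark on the default synthetic community.

Reproduces the study conditions of the enrichment model's validation:
600 labelled contig gradient profiles (class mix 30/10/35/15/10 %
strong/weak/unenriched/bimodal/undetermined, 50× mean depth, NB
dispersion 0.5, σ₀ = 0.005), an 80/20 stratified split, and holdout
metrics averaged over 10 seeds.
"""

from __future__ import annotations

import pandas as pd

from . import classifier
from .synthetic import BenchmarkConfig, generate_training_set


def run_single(config: BenchmarkConfig, seed: int) -> classifier.MetricsReport:
    """One benchmark replicate: generate, split, train, evaluate."""
    features, labels, _ = generate_training_set(config, seed)
    x_tr, y_tr, x_val, y_val = classifier.split_train_validation(
        features, labels, holdout_fraction=config.holdout_fraction, seed=seed
    )
    model = classifier.train(x_tr, y_tr, seed=seed)
    calls = classifier.predict(model, x_val)
    return classifier.evaluate(calls["call"], y_val)


def run_benchmark(
    config: BenchmarkConfig | None = None,
    n_seeds: int = 10,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Holdout metrics per seed; seeds are base_seed, base_seed+1, ...

    Returns one row per seed with overall accuracy and the per-class
    one-vs-rest sensitivities/specificities (all as fractions).
    """
    config = config or BenchmarkConfig()
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        report = run_single(config, seed)
        row = {"seed": seed, "accuracy": report.accuracy}
        for c, v in report.sensitivity.items():
            row[f"sens_{c}"] = v
        for c, v in report.specificity.items():
            row[f"spec_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")
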