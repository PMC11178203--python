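"""Synthetic trial corpora with known ground truth.

Each simulated trial is a draw from the two-hypothesis model under which
the error-probability formulas are exact: with probability ``pr_true`` the
trial carries a true standardized effect and its test statistic is a
central Student's t deviate (``nu = n1 + n2 - 2``) shifted by the effect
rescaled to the t scale (equal-variance rescaling); otherwise the statistic
is a central t deviate.  The reported effect and standard error are then
reconstructed from the statistic (``b = stat * se`` for continuous
outcomes, ``b = exp(stat * se)`` for dichotomous ones), so a pipeline
reading only (b, se, outcome type, arm sizes) recovers exactly the
statistic that was drawn.

Because the generative model coincides with the model behind the error
formulas, realized false-positive and false-negative rates on these corpora
are sharp calibration checks of the per-trial thresholds.  The generator
does not emulate patient-level data, dropout, reporting bias, or the
empirical arm-size and effect distributions of any real trial registry.

Default study conditions: a 50% prior of a true effect and a medium true
effect (d = 0.5), matching the corpus-analysis assumptions; arm sizes
log-uniform between 50 and 500 so every trial's total is >= 100 and the
assumed minimum acceptable effect used by the pipeline (0.5) equals the
generating effect, which is what makes the power calibration exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticCorpusConfig", "generate_corpus", "write_corpus", "TRUTH_COLUMNS"]

#: ground-truth columns, written only to the sidecar file
TRUTH_COLUMNS = ("truth", "true_effect")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generative parameters for a fake trial corpus.

    ``seed`` is mandatory; each trial consumes its own deterministic
    substream spawned from it, so trial i is identical whether the corpus
    has 100 or 100,000 trials.
    """

    n_trials: int
    seed: int
    pr_true: float = 0.5
    effect_size_true: float = 0.5
    arm_min: int = 50
    arm_max: int = 500
    dichotomous_frac: float = 0.3
    #: log-mean and log-sd of the (lognormal) standard-error draw
    se_log_mean: float = math.log(0.15)
    se_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0.0 <= self.pr_true <= 1.0:
            raise ValueError("pr_true must lie in [0, 1]")
        if self.arm_min < 2 or self.arm_max < self.arm_min:
            raise ValueError("need 2 <= arm_min <= arm_max")
        if not 0.0 <= self.dichotomous_frac <= 1.0:
            raise ValueError("dichotomous_frac must lie in [0, 1]")
        if self.effect_size_true < 0:
            raise ValueError("effect_size_true must be non-negative")


def generate_corpus(config: SyntheticCorpusConfig) -> pd.DataFrame:
    """Draw a corpus of synthetic trials.

    Returns a DataFrame with the corpus columns (trial_id, b, se,
    outcome_type, n1, n2) plus the ground-truth columns ``truth`` (true
    effect present) and ``true_effect`` (0.0 for null trials).
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    log_lo, log_hi = math.log(config.arm_min), math.log(config.arm_max + 1)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        truth = rng.random() < config.pr_true
        n1 = int(math.exp(rng.uniform(log_lo, log_hi)))
        n2 = int(math.exp(rng.uniform(log_lo, log_hi)))
        n1, n2 = min(n1, config.arm_max), min(n2, config.arm_max)
        dichotomous = rng.random() < config.dichotomous_frac
        nu = n1 + n2 - 2
        effect = config.effect_size_true if truth else 0.0
        delta = effect / math.sqrt(1.0 / n1 + 1.0 / n2)
        stat = rng.standard_t(nu) + delta
        se = float(rng.lognormal(config.se_log_mean, config.se_log_sd))
        b = math.exp(stat * se) if dichotomous else stat * se
        rows.append({
            "trial_id": f"synth-{i:06d}", "b": b, "se": se,
            "outcome_type": "dichotomous" if dichotomous else "continuous",
            "n1": n1, "n2": n2, "truth": truth, "true_effect": effect,
        })
    return pd.DataFrame(rows, columns=["trial_id", "b", "se", "outcome_type",
                                       "n1", "n2", *TRUTH_COLUMNS])


def write_corpus(trials: pd.DataFrame, path) -> tuple[Path, Path]:
    """Write a corpus CSV plus a ground-truth sidecar.

    The corpus file carries only the columns the pipeline reads; the truth
    flags go to ``<stem>_truth.csv`` alongside it so downstream analysis
    cannot accidentally condition on them.  Returns both paths.
    """
    path = Path(path)
    sidecar = path.with_name(path.stem + "_truth" + (path.suffix or ".csv"))
    corpus_cols = [c for c in trials.columns if c not in TRUTH_COLUMNS]
    trials[corpus_cols].to_csv(path, index=False)
    trials[["trial_id", *TRUTH_COLUMNS]].to_csv(sidecar, index=False)
    return path, sidecar
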