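"""Synthetic categorical surveys with planted confounders.

Emulates the statistical skeleton of a large school-health questionnaire:
a few broadly influential variables (the planted "confounders", playing
the role a variable like gender plays in real survey data), a block of
variables that depend on them, a block of pure-noise variables, and a
stratum label replicating the population into independent subsets that
share the same conditional probability tables.

Dependence is an additive log-odds (logit) effect: a dependent variable
with L levels observed under confounder level c has level logits

    logit_l = beta * c * l / (L - 1)        (l = 0 .. L-1)

so for binary variables P(X=1 | C=c) = sigmoid(beta * c), and beta = 0
recovers full mutual independence.  A ``divergence`` knob adds
stratum-specific Gaussian logit noise to create heterogeneous strata for
sensitivity tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .encoding import CategoricalTable

STRATUM_COLUMN = "stratum"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the standard study conditions:

    3 strata of 2,000 subjects, one binary confounder driving 12 binary
    dependent variables at effect size beta = 2 (log-odds), plus 12
    independent binary noise variables and no missingness.
    """

    n_subjects: int = 2000
    n_strata: int = 3
    n_confounders: int = 1
    n_dependent: int = 12
    n_noise: int = 12
    n_levels: int = 2
    beta: float = 2.0
    missing_rate: float = 0.0
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_strata", "n_confounders",
                     "n_dependent", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def variable_names(self) -> list[str]:
        return (
            [f"conf_{i + 1}" for i in range(self.n_confounders)]
            + [f"dep_{i + 1}" for i in range(self.n_dependent)]
            + [f"noise_{i + 1}" for i in range(self.n_noise)]
        )


def ground_truth(config: SimConfig) -> set[str]:
    """Names of the planted confounder variables."""
    return {f"conf_{i + 1}" for i in range(config.n_confounders)}


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_survey(config: SimConfig) -> CategoricalTable:
    """Draw a survey table from the planted-dependency model; fully seeded.

    Confounders and noise variables are uniform categorical; each
    dependent variable is tied (round-robin) to one confounder through
    the shared logit CPT.  Missing answers are injected independently per
    cell at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_levels
    frames = []
    for s in range(config.n_strata):
        n = config.n_subjects
        cols: dict[str, np.ndarray] = {}
        conf_codes = {}
        for i in range(config.n_confounders):
            c = rng.integers(0, L, size=n)
            conf_codes[i] = c
            cols[f"conf_{i + 1}"] = c
        for i in range(config.n_dependent):
            name = f"dep_{i + 1}"
            if config.n_confounders > 0:
                c = conf_codes[i % config.n_confounders]
                logits = (
                    config.beta
                    * c[:, None]
                    * (np.arange(L)[None, :] / (L - 1))
                )
            else:
                logits = np.zeros((n, L))
            if config.divergence > 0:
                # stratum-specific CPT perturbation, deterministic per run
                pert_rng = np.random.default_rng(
                    (config.seed, s, 1000 + i)
                )
                logits = logits + pert_rng.normal(
                    0.0, config.divergence, size=L
                )[None, :]
            probs = _softmax_rows(logits)
            u = rng.random(n)
            cols[name] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        for i in range(config.n_noise):
            cols[f"noise_{i + 1}"] = rng.integers(0, L, size=n)
        df = pd.DataFrame(
            {k: v.astype(str) for k, v in cols.items()},
            columns=config.variable_names(),
        )
        df[STRATUM_COLUMN] = f"S{s + 1}"
        frames.append(df)
    full = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        values = full[config.variable_names()].to_numpy(dtype=object)
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan
        full[config.variable_names()] = values
    stratum = full.pop(STRATUM_COLUMN)
    return CategoricalTable(full, stratum)


def write_survey_csv(config: SimConfig, csv_path, truth_path=None) -> None:
    """Write the simulated table (stratum column included) and, optionally,
    a JSON truth file naming the planted confounders and CPT parameters."""
    table = simulate_survey(config)
    out = table.data.copy()
    if table.stratum is not None:
        out[STRATUM_COLUMN] = table.stratum
    out.to_csv(csv_path, index=False)
    if truth_path is not None:
        truth = {
            "confounders": sorted(ground_truth(config)),
            "dependent": [f"dep_{i + 1}" for i in range(config.n_dependent)],
            "noise": [f"noise_{i + 1}" for i in range(config.n_noise)],
            "config": asdict(config),
        }
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def recovery_score(top_nodes: list[str], truth_vars: set[str],
                   n_truth_dummies: int) -> float:
    """Fraction of the top-k list occupied by planted-confounder dummies:
    ``|top-k ∩ truth dummies| / min(k, total truth dummy count)``."""
    if not top_nodes or n_truth_dummies == 0:
        return 0.0
    hits = sum(1 for node in top_nodes
               if node.partition("=")[0] in truth_vars)
    return hits / min(len(top_nodes), n_truth_dummies)
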