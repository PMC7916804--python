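"""Synthetic fixture generation: trees plus simulated trait pairs.

Everything the inference machinery consumes can be generated here without
external data: balanced Grafen trees of the sizes used in the validation
study, birth-death trees with incomplete sampling, and trait CSVs
simulated under any of the four models at fixed parameters or from priors.
Outputs are deterministic under the seed and carry a JSON sidecar with the
generating parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import models as _models
from . import sde
from .phylo import (Phylogeny, balanced_tree, birth_death_tree,
                    scale_to_unit_height, write_newick)

__all__ = ["TRUE_PARAMS_VALIDATION", "generate_fixtures", "make_tree"]

#: the "true" parameter values used throughout the simulation validation
TRUE_PARAMS_VALIDATION = {
    "alpha_y": 0.5, "alpha_x": 0.125, "theta_x": 0.0,
    "sigma_x": 2.5, "sigma_y": 1.0,
    "beta1": 0.0, "beta2": 1.0, "beta3": -0.5,
}

#: birth-death regime of the cross-validation study
BIRTH_DEATH_SETTING = {"birth_rate": 2.0, "death_rate": 0.5,
                       "age": 2.0, "tip_sampling_prob": 0.5}


def make_tree(kind: str, n_tips: int, seed: int = 0) -> Phylogeny:
    """A unit-height tree: 'balanced' (Grafen) or 'birthdeath'."""
    if kind == "balanced":
        return balanced_tree(n_tips, "grafen")
    if kind == "birthdeath":
        return scale_to_unit_height(
            birth_death_tree(n_tips, seed=seed, **BIRTH_DEATH_SETTING))
    raise ValueError(f"unknown tree kind {kind!r}")


def generate_fixtures(kind: str, n_tips: int, model_id: str,
                      params_or_priors, seed: int, out_dir,
                      prefix: str = "fixture") -> dict[str, Path]:
    """Write a Newick tree, a trait CSV and a parameter JSON sidecar.

    ``params_or_priors`` is either a mapping of parameter values (used as
    is; missing entries filled from TRUE_PARAMS_VALIDATION) or a PriorSpec
    (one draw is taken and logged in the sidecar).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = make_tree(kind, n_tips, seed=seed)

    if isinstance(params_or_priors, _models.PriorSpec):
        rng = np.random.default_rng(int(seed))
        params = {k: float(v) for k, v in params_or_priors.sample(rng).items()}
        source = "prior draw"
    else:
        params = {k: TRUE_PARAMS_VALIDATION[k] for k in _models.PARAMS_FOR[model_id]}
        params.update({k: float(v) for k, v in dict(params_or_priors).items()})
        source = "fixed values"
    params = {k: params[k] for k in _models.PARAMS_FOR[model_id]}

    X, Y = _models.simulate_tips_batch(model_id, params, tree, int(seed))
    data = _models.TraitData(list(tree.tip_labels), X[0], Y[0])

    paths = {"tree": out_dir / f"{prefix}_tree.nwk",
             "traits": out_dir / f"{prefix}_traits.csv",
             "params": out_dir / f"{prefix}_params.json"}
    write_newick(tree, paths["tree"])
    _models.write_trait_csv(data, paths["traits"])
    sidecar = {"model": model_id, "tree_kind": kind, "n_tips": n_tips,
               "seed": int(seed), "parameter_source": source,
               "parameters": params,
               "root_state": {"rho_y": 0.0, "rho_x": 0.0, "rho_theta": 0.0}}
    paths["params"].write_text(json.dumps(sidecar, indent=2) + "\n")
    return paths
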