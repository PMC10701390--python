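"""Predictive-ability evaluation and the experiment orchestrator.

Predictive ability is the Pearson correlation between predicted and observed
values computed within each environment; the overall value per fit is the
arithmetic mean across environments ("mean over environments first").
Stratified abilities repeat the computation restricted to ancestry groups or
families. Undefined correlations (constant vectors, strata with < 2 pairs)
are flagged and excluded from means rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gp_models, sparse_design
from ._seeds import derive_seed
from .gp_models import KernelSet, McmcConfig, build_grm, build_kernels, fit_gibbs
from .sparse_design import Allocation, DesignSpec
from .synthetic_nam import NamPopulation

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Invalid evaluation request."""


def pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise EvaluationError(
            f"length mismatch: {pred.shape} vs {obs.shape}"
        )
    if pred.size < 2:
        raise EvaluationError("need at least 2 pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


def ability_table(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    strata: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-environment (and mean) predictive ability for each stratum.

    ``predictions`` holds (ril_id, env_id, y_pred); ``truth`` holds
    (ril_id, env_id, value). ``strata`` maps stratum name -> RIL-id set; the
    stratum ``"all"`` over every evaluated cell is always included. Rows
    with fewer than two pairs or constant vectors get ``undefined=True``
    and NaN r; the ``"mean"`` row averages the defined per-environment rows.
    """
    merged = predictions.merge(truth, on=["ril_id", "env_id"], how="left")
    if merged["value"].isna().any():
        missing = merged[merged["value"].isna()].iloc[0]
        raise EvaluationError(
            f"no truth value for cell ({missing['ril_id']}, {missing['env_id']})"
        )
    groups: dict[str, set[str] | None] = {"all": None}
    if strata:
        groups.update(strata)
    rows = []
    envs = sorted(merged["env_id"].unique())
    for name, members in groups.items():
        sub = merged if members is None else merged[merged["ril_id"].isin(members)]
        per_env = []
        for env in envs:
            cell = sub[sub["env_id"] == env]
            if len(cell) < 2:
                rows.append((name, env, float("nan"), len(cell), True))
                continue
            r = pearson(cell["y_pred"].to_numpy(), cell["value"].to_numpy())
            undefined = not np.isfinite(r)
            rows.append((name, env, r, len(cell), undefined))
            if not undefined:
                per_env.append(r)
        mean_r = float(np.mean(per_env)) if per_env else float("nan")
        rows.append((name, "mean", mean_r, len(per_env), len(per_env) == 0))
    return pd.DataFrame(
        rows, columns=["stratum", "env_id", "r", "n_pairs", "undefined"]
    )


def env_pair_correlations(
    pheno: pd.DataFrame, sample_rils: Sequence[str] | None = None
) -> dict:
    """Between-environment phenotype correlations for a RIL sample.

    Returns one Pearson r per unordered environment pair (J(J-1)/2 values)
    plus their median and quartiles. Every sampled RIL must be observed in
    every environment.
    """
    sub = pheno
    if sample_rils is not None:
        sub = pheno[pheno["ril_id"].isin(set(sample_rils))]
    wide = sub.pivot(index="ril_id", columns="env_id", values="value")
    if wide.shape[1] < 2:
        raise EvaluationError("need at least 2 environments")
    if wide.isna().any().any():
        raise EvaluationError("sample RILs must be observed in all environments")
    envs = list(wide.columns)
    pairs = []
    for a in range(len(envs)):
        for bdx in range(a + 1, len(envs)):
            r = pearson(wide[envs[a]].to_numpy(), wide[envs[bdx]].to_numpy())
            pairs.append({"env_a": envs[a], "env_b": envs[bdx], "r": r})
    values = np.array([p["r"] for p in pairs], dtype=float)
    finite = values[np.isfinite(values)]
    q = (
        np.percentile(finite, [25, 50, 75])
        if finite.size
        else np.array([np.nan] * 3)
    )
    return {
        "pairs": pairs,
        "n_pairs": len(pairs),
        "median": float(q[1]),
        "q25": float(q[0]),
        "q75": float(q[2]),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    table: pd.DataFrame
    provenance: dict
    failures: list[dict]


def _observed_vector(
    pheno_wide: pd.DataFrame, alloc: Allocation, records: pd.DataFrame,
    env_labels: Mapping[int, str],
) -> np.ndarray:
    """Phenotype vector over all records, NaN outside the allocation."""
    y = np.full(len(records), np.nan)
    value = pheno_wide  # indexed by (ril_id, env_id)
    rec_key = list(zip(records["ril_id"], records["env_id"]))
    pos = {k: i for i, k in enumerate(rec_key)}
    for j in alloc.envs:
        env = env_labels[j]
        for ril in alloc.training(j):
            y[pos[(ril, env)]] = value.loc[ril, env]
    return y


def run_experiment(
    pop: NamPopulation,
    pheno: pd.DataFrame,
    specs: Sequence[DesignSpec],
    models: Sequence[str] = ("M1", "M2", "M3"),
    mcmc: McmcConfig | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    strata: str = "ancestry",
) -> ExperimentResult:
    """Replicate x composition x model sweep on one dataset.

    For each replicate a fresh base allocation is drawn; every spec is
    derived from it, each model is fitted on the observed cells, and the
    evaluated prediction cells are scored against the truth table. Failures
    of individual grid cells are logged and flagged, not raised.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    env_ids = sorted(pheno["env_id"].unique())
    n_env = len(env_ids)
    env_labels = dict(enumerate(env_ids))
    qc = gp_models.qc_filter(pop.genotypes.astype(float))
    G = build_grm(qc.X)
    records = gp_models.make_records(pop.ril_ids, pop.family_ids, env_ids)
    kernels_all = build_kernels(sorted({t for m in models for t in gp_models.MODEL_TERMS[m]},
                                       key=("E", "L", "F", "G", "GE", "FE").index),
                                records, G)
    pheno_wide = pheno.pivot(index="ril_id", columns="env_id", values="value")
    truth = pheno[["ril_id", "env_id", "value"]]

    stratum_sets: dict[str, set[str]] | None = None
    if strata == "ancestry":
        fam_tab = pop.family_table()
        stratum_sets = {
            grp: set(fam_tab.loc[fam_tab["ancestry_group"] == grp, "ril_id"])
            for grp in sorted(fam_tab["ancestry_group"].unique())
        }

    rows = []
    failures: list[dict] = []
    for rep in range(n_replicates):
        base_seed = derive_seed(seed, "allocate", rep)
        base = sparse_design.allocate_base(pop.ril_ids, n_env, base_seed)
        for spec in specs:
            spec_r = DesignSpec(
                n_per_env=spec.n_per_env,
                n_overlap=spec.n_overlap,
                n_env=spec.n_env,
                replicate_seed=derive_seed(seed, "compose", rep),
                group_size=spec.group_size,
            )
            try:
                alloc = sparse_design.derive_composition(base, spec_r)
                y = _observed_vector(pheno_wide, alloc, records, env_labels)
                cells = [
                    (ril, env_labels[j])
                    for j in alloc.envs
                    for ril in alloc.evaluated_prediction(j)
                ]
                for model in models:
                    ks = kernels_all.subset(gp_models.MODEL_TERMS[model])
                    cfg = McmcConfig(
                        n_iter=mcmc.n_iter,
                        burn_in=mcmc.burn_in,
                        thin=mcmc.thin,
                        seed=derive_seed(seed, f"mcmc-{model}", rep),
                        prior_df=mcmc.prior_df,
                        signal_share=mcmc.signal_share,
                    )
                    fit = fit_gibbs(y, ks, cfg)
                    preds = gp_models.predict_missing(fit, cells)
                    tab = ability_table(preds, truth, stratum_sets)
                    tab.insert(0, "model", model)
                    tab.insert(0, "n_overlap", spec.n_overlap)
                    tab.insert(0, "n_per_env", spec.n_per_env)
                    tab.insert(0, "replicate", rep)
                    rows.append(tab)
            except Exception as exc:  # per-cell failures flagged, run continues
                logger.exception(
                    "grid cell failed: rep=%s spec=%s", rep, spec.label
                )
                failures.append(
                    {"replicate": rep, "spec": spec.label, "error": str(exc)}
                )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "replicate", "n_per_env", "n_overlap", "model",
                "stratum", "env_id", "r", "n_pairs", "undefined",
            ]
        )
    )
    provenance = {
        "seed": int(seed),
        "n_replicates": int(n_replicates),
        "models": list(models),
        "specs": [s.label for s in specs],
        "mcmc": {
            "n_iter": mcmc.n_iter,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
            "prior_df": mcmc.prior_df,
            "signal_share": mcmc.signal_share,
        },
        "n_env": n_env,
        "n_rils": pop.n_rils,
        "n_markers_kept": int(qc.p),
    }
    return ExperimentResult(table=table, provenance=provenance, failures=failures)


def mean_ability(table: pd.DataFrame, stratum: str = "all") -> pd.DataFrame:
    """Replicate-level mean-over-environments rows, then the mean over
    replicates, per (n_per_env, n_overlap, model)."""
    sub = table[(table["stratum"] == stratum) & (table["env_id"] == "mean")]
    return (
        sub.groupby(["n_per_env", "n_overlap", "model"], as_index=False)["r"]
        .mean()
        .rename(columns={"r": "mean_r"})
    )
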