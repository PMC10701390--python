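"""Multi-kernel Bayesian genomic prediction with GxE and family-x-E terms.

Three nested models over RIL-in-environment records:

    M1: y = mu + E + L + g            (environment, line identity, genomic)
    M2: M1 + gE                       (genomic x environment reaction norm)
    M3: M2 + F + FE                   (family main effect and family x env)

Each random term has covariance sigma2_t * K_t with K_t one of: a grouping
kernel (same environment / same RIL / same family), the genomic relationship
matrix G = XX'/p mapped through the RIL incidence, or a Hadamard product of
the genomic/family kernel with the environment kernel. Fitting is Gibbs
sampling in the eigenbasis of each kernel with scaled-inverse-chi-square
variance priors; records with missing phenotypes contribute no information
(they are integrated out by data augmentation) but receive predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("E", "L", "G"),
    "M2": ("E", "L", "G", "GE"),
    "M3": ("E", "L", "F", "G", "GE", "FE"),
}


class ModelError(ValueError):
    """Invalid model-fitting request."""


# ---------------------------------------------------------------------------
# marker QC and the genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrixQC:
    """Centered/standardized marker matrix after missingness and MAF filters."""

    X: np.ndarray                       # (n, p_kept), column mean 0 / var 1
    p: int
    kept: np.ndarray                    # original column indices retained
    dropped_markers: list[tuple[int, str]]
    col_means: np.ndarray               # imputation/centering means (dosage scale)
    col_sds: np.ndarray


def qc_filter(
    raw: np.ndarray,
    max_missing: float = 0.20,
    min_maf: float = 0.03,
) -> GenotypeMatrixQC:
    """Filter markers, mean-impute leftover gaps, center and standardize.

    Markers with a missing fraction above ``max_missing`` or a minor allele
    frequency below ``min_maf`` (computed on non-missing dosages) are
    dropped, as are zero-variance columns; the survivors are mean-imputed
    per marker, centered and scaled to unit variance (divisor n).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ModelError("genotype matrix must be 2-D")
    n, p = raw.shape
    miss = np.isnan(raw)
    valid = ~miss
    present = np.maximum(valid.sum(axis=0), 1)
    freq = np.where(valid, raw, 0.0).sum(axis=0) / (2.0 * present)
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = miss.mean(axis=0)

    dropped: list[tuple[int, str]] = []
    keep_mask = np.ones(p, dtype=bool)
    for j in range(p):
        if miss_frac[j] > max_missing:
            dropped.append((j, "missingness"))
            keep_mask[j] = False
        elif maf[j] < min_maf:
            dropped.append((j, "maf"))
            keep_mask[j] = False

    X = raw[:, keep_mask].copy()
    col_mean = np.nanmean(X, axis=0) if X.size else np.zeros(0)
    gaps = np.isnan(X)
    if gaps.any():
        X[gaps] = np.broadcast_to(col_mean, X.shape)[gaps]
    sd = X.std(axis=0) if X.size else np.zeros(0)
    kept_idx = np.flatnonzero(keep_mask)
    nonconst = sd > 0
    for j in kept_idx[~nonconst]:
        dropped.append((int(j), "zero variance"))
    X = (X[:, nonconst] - col_mean[nonconst]) / sd[nonconst]
    kept_idx = kept_idx[nonconst]
    if X.shape[1] == 0:
        raise ModelError("all markers were dropped by QC")
    return GenotypeMatrixQC(
        X=X,
        p=X.shape[1],
        kept=kept_idx,
        dropped_markers=dropped,
        col_means=col_mean[nonconst],
        col_sds=sd[nonconst],
    )


def build_grm(X: np.ndarray, p: int | None = None) -> np.ndarray:
    """Genomic relationship matrix G = XX'/p from standardized dosages."""
    X = np.asarray(X, dtype=float)
    if p is None:
        p = X.shape[1]
    if p == 0:
        raise ModelError("cannot build a GRM from zero markers")
    return (X @ X.T) / p


# ---------------------------------------------------------------------------
# record index and covariance structures
# ---------------------------------------------------------------------------

def make_records(
    ril_ids: Sequence[str],
    family_ids: Sequence[str],
    env_ids: Sequence[str],
) -> pd.DataFrame:
    """Full record index: one row per (RIL, environment) cell, RIL-major."""
    n, J = len(ril_ids), len(env_ids)
    return pd.DataFrame(
        {
            "ril_id": np.repeat(list(ril_ids), J),
            "family_id": np.repeat(list(family_ids), J),
            "env_id": np.tile(list(env_ids), n),
            "ril_idx": np.repeat(np.arange(n), J),
        }
    )


@dataclass
class KernelSet:
    """Labelled covariance structures over one record index.

    Eigendecompositions are computed lazily per label and cached so several
    models (and several allocations sharing the record index) reuse them.
    """

    labels: tuple[str, ...]
    matrices: dict[str, np.ndarray]
    records: pd.DataFrame
    _eigs: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        init=False, default_factory=dict, repr=False
    )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def eig(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) with tiny negatives clipped to zero."""
        if label not in self._eigs:
            K = self.matrices[label]
            d, U = np.linalg.eigh(K)
            tol = max(1e-10 * max(d.max(), 1.0), 0.0)
            if d.min() < -1e-6 * max(d.max(), 1.0):
                raise ModelError(f"structure {label!r} is not PSD")
            d = np.where(d < tol, 0.0, d)
            self._eigs[label] = (d, U)
        return self._eigs[label]

    def subset(self, labels: Sequence[str]) -> "KernelSet":
        missing = [t for t in labels if t not in self.matrices]
        if missing:
            raise ModelError(f"kernel set lacks terms {missing}")
        sub = KernelSet(
            labels=tuple(labels),
            matrices={t: self.matrices[t] for t in labels},
            records=self.records,
        )
        sub._eigs = self._eigs  # shared cache
        return sub


def build_kernels(
    model: str | Sequence[str],
    records: pd.DataFrame,
    G: np.ndarray,
) -> KernelSet:
    """Covariance structures for one model over a record index.

    ``E``/``L``/``F`` are same-level grouping kernels; ``G`` maps the GRM
    through the RIL incidence; ``GE`` and ``FE`` are Hadamard products of
    the genomic/family kernel with the environment kernel (interaction
    effects only correlate records within the same environment).
    """
    labels = MODEL_TERMS[model] if isinstance(model, str) else tuple(model)
    env = records["env_id"].to_numpy()
    fam = records["family_id"].to_numpy()
    ril_idx = records["ril_idx"].to_numpy()
    if ril_idx.max(initial=-1) >= G.shape[0]:
        raise ModelError("record ril_idx exceeds GRM dimension")

    same_env = (env[:, None] == env[None, :]).astype(float)
    mats: dict[str, np.ndarray] = {}
    for label in labels:
        if label == "E":
            mats[label] = same_env
        elif label == "L":
            mats[label] = (ril_idx[:, None] == ril_idx[None, :]).astype(float)
        elif label == "F":
            mats[label] = (fam[:, None] == fam[None, :]).astype(float)
        elif label == "G":
            mats[label] = G[np.ix_(ril_idx, ril_idx)]
        elif label == "GE":
            mats[label] = G[np.ix_(ril_idx, ril_idx)] * same_env
        elif label == "FE":
            mats[label] = (fam[:, None] == fam[None, :]).astype(float) * same_env
        else:
            raise ModelError(f"unknown kernel label {label!r}")
    return KernelSet(labels=labels, matrices=mats, records=records.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    signal_share: float = 0.5   # share of var(y) split equally across terms

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ModelError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")


@dataclass
class FitResult:
    """Posterior means and predictions for every record."""

    mu: float
    effects: dict[str, np.ndarray]
    var_components: dict[str, float]
    yhat: np.ndarray
    records: pd.DataFrame
    n_retained: int
    config: McmcConfig
    labels: tuple[str, ...]


def fit_gibbs(
    y: np.ndarray,
    kernels: KernelSet,
    config: McmcConfig | None = None,
    fixed_variances: Mapping[str, float] | None = None,
    fit_intercept: bool = True,
) -> FitResult:
    """Gibbs-sample the multi-kernel Gaussian model.

    ``y`` has one entry per record; NaN marks unobserved cells, which are
    integrated out by sampling them from the current model each sweep and
    therefore receive predictions. Each effect block is sampled in the
    eigenbasis of its kernel, where the full-data conditional is diagonal.
    ``fixed_variances`` may pin any subset of component variances (use key
    ``"resid"`` for the residual); the corresponding updates are skipped.
    """
    if config is None:
        config = McmcConfig()
    fixed = dict(fixed_variances or {})
    y = np.asarray(y, dtype=float).copy()
    n = y.shape[0]
    if n != kernels.n_records:
        raise ModelError("phenotype length does not match the record index")
    obs = np.isfinite(y)
    if not obs.any():
        raise ModelError("no observed records")
    mis = ~obs

    labels = kernels.labels
    eigs = {t: kernels.eig(t) for t in labels}
    rng = np.random.default_rng(config.seed)

    y_obs = y[obs]
    var_y = float(np.var(y_obs)) if y_obs.size > 1 else 1.0
    var_y = max(var_y, 1e-12)
    df0 = config.prior_df
    n_terms = len(labels)
    # prior mode of each term's variance = signal_share * var(y) / n_terms
    mode_t = config.signal_share * var_y / max(n_terms, 1)
    S_t = {t: mode_t * (df0 + 2.0) / df0 for t in labels}
    S_e = (1.0 - config.signal_share) * var_y * (df0 + 2.0) / df0

    mu = float(np.mean(y_obs)) if fit_intercept else 0.0
    sig2 = {t: fixed.get(t, mode_t) for t in labels}
    sig2_e = fixed.get("resid", max((1.0 - config.signal_share) * var_y, 1e-12))

    u = {t: np.zeros(n) for t in labels}
    b = {t: np.zeros(n) for t in labels}
    y_aug = y.copy()
    y_aug[mis] = mu
    e = y_aug - mu                       # running residual y_aug - mu - sum(u)

    keep = 0
    acc_mu = 0.0
    acc_u = {t: np.zeros(n) for t in labels}
    acc_sig2 = {t: 0.0 for t in labels}
    acc_sig2_e = 0.0
    acc_fit = np.zeros(n)

    for it in range(config.n_iter):
        # impute missing cells from the current model
        if mis.any():
            fitted_mis = y_aug[mis] - e[mis]
            new_mis = fitted_mis + rng.normal(size=int(mis.sum())) * np.sqrt(sig2_e)
            e[mis] += new_mis - y_aug[mis]
            y_aug[mis] = new_mis
        # intercept
        if fit_intercept:
            e += mu
            mu = float(rng.normal(np.mean(e), np.sqrt(sig2_e / n)))
            e -= mu
        # effect blocks, one kernel at a time, in eigen coordinates
        for t in labels:
            d, U = eigs[t]
            e += u[t]
            r = U.T @ e
            c = np.where(d > 0, d * sig2[t] / (d * sig2[t] + sig2_e), 0.0)
            b_t = c * r + rng.normal(size=n) * np.sqrt(c * sig2_e)
            u[t] = U @ b_t
            b[t] = b_t
            e -= u[t]
            if t not in fixed:
                pos = d > 0
                ss = float(np.sum(b_t[pos] ** 2 / d[pos]))
                rank = int(pos.sum())
                sig2[t] = (df0 * S_t[t] + ss) / rng.chisquare(df0 + rank)
        if "resid" not in fixed:
            sig2_e = (df0 * S_e + float(e @ e)) / rng.chisquare(df0 + n)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep += 1
            acc_mu += mu
            acc_sig2_e += sig2_e
            acc_fit += y_aug - e
            for t in labels:
                acc_u[t] += u[t]
                acc_sig2[t] += sig2[t]

    if keep == 0:
        raise ModelError("no retained samples; check n_iter/burn_in/thin")
    effects = {t: acc_u[t] / keep for t in labels}
    var_components = {t: acc_sig2[t] / keep for t in labels}
    var_components["resid"] = acc_sig2_e / keep
    return FitResult(
        mu=acc_mu / keep,
        effects=effects,
        var_components=var_components,
        yhat=acc_fit / keep,
        records=kernels.records,
        n_retained=keep,
        config=config,
        labels=labels,
    )


def predict_missing(
    fit: FitResult, cells: Sequence[tuple[str, str]] | np.ndarray
) -> pd.DataFrame:
    """Predictions for requested (ril_id, env_id) cells of the record index."""
    rec = fit.records
    key = pd.MultiIndex.from_frame(rec[["ril_id", "env_id"]])
    lookup = pd.Series(np.arange(len(rec)), index=key)
    idx = []
    for ril, env in cells:
        try:
            idx.append(int(lookup[(ril, env)]))
        except KeyError:
            raise ModelError(f"cell ({ril!r}, {env!r}) not in the record index")
    idx = np.asarray(idx, dtype=int)
    return pd.DataFrame(
        {
            "ril_id": rec["ril_id"].to_numpy()[idx],
            "env_id": rec["env_id"].to_numpy()[idx],
            "y_pred": fit.yhat[idx],
        }
    )
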