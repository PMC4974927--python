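"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs / log-linear distribution over background cells

    q(c) = exp(sum_j lambda_j f_j(c)) / Z

whose weights maximize the L1-penalized presence log-likelihood

    mean_presence[ lambda . f ] - log Z(lambda) - sum_j reg_j |lambda_j|.

At zero regularization the stationarity condition is the maximum-entropy
constraint: the q-expected value of every feature equals its presence-sample
mean.  With an L1 penalty the KKT condition relaxes this to
|E_q[f_j] - mean_presence[f_j]| <= reg_j per feature.

Features are linear and quadratic terms of the five climate variables
(elevation is excluded as a predictor), min-max scaled to [0, 1] on the
background sample.  Model quality is assessed by replicated 4:1
calibration/validation splits scored by AUC, and the binarization threshold
is the score maximizing sensitivity + specificity (equivalently the true
skill statistic, TSS) over the pooled validation predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.metrics import roc_auc_score

from .errors import (
    ConvergenceError,
    DegenerateFeatureError,
    EligibilityError,
    ProjectionError,
    SchemaError,
)
from .grids import CLIMATE_VARS, ClimateStack, RangeMap, SuitabilityMap

MIN_OCCUPIED_CELLS = 10  # inclusion rule: >= 10 distinct occupied cells


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaling:
    """Per-variable min/max over the training background; frozen at fit time
    and reused unchanged when projecting onto other stacks (values outside
    the training range are clamped to [0, 1])."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, climate: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Climate matrix (n, 5) -> feature matrix (n, 10): linear then quadratic."""
        lin = (climate - self.mins) / (self.maxs - self.mins)
        if clamp:
            lin = np.clip(lin, 0.0, 1.0)
        return np.hstack([lin, lin**2])


def occupied_cells(stack: ClimateStack, occ: pd.DataFrame) -> np.ndarray:
    """Distinct flat cell indices occupied by the occurrence points."""
    grid = stack.grid
    cells = set()
    for lon, lat in zip(occ["lon"].to_numpy(), occ["lat"].to_numpy()):
        r, c = grid.cell_of(float(lon), float(lat))
        cells.add(r * grid.n_cols + c)
    return np.array(sorted(cells), dtype=int)


def standardize_features(
    stack: ClimateStack,
    occ: pd.DataFrame,
    n_background: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, FeatureScaling, np.ndarray, np.ndarray]:
    """Build scaled presence/background feature matrices.

    Background cells are drawn uniformly without replacement from unmasked
    cells (all of them if fewer than ``n_background``).  Each of the five
    climate variables is min-max scaled to [0, 1] using the background range,
    then linear and quadratic features are formed (10 features total).

    Returns (presence_features, background_features, scaling,
    presence_cells, background_cells) with cells as flat indices.
    """
    pres_cells = occupied_cells(stack, occ)
    if pres_cells.size < MIN_OCCUPIED_CELLS:
        raise EligibilityError(
            f"species '{occ['species'].iloc[0] if len(occ) else '?'}' occupies "
            f"{pres_cells.size} distinct cells; at least "
            f"{MIN_OCCUPIED_CELLS} required"
        )
    valid = stack.unmasked_indices()
    n_bg = min(int(n_background), valid.size)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5081]))
    bg_cells = np.sort(rng.choice(valid, size=n_bg, replace=False))

    climate = stack.climate_matrix()
    bg_climate = climate[bg_cells]
    mins, maxs = bg_climate.min(axis=0), bg_climate.max(axis=0)
    for k, v in enumerate(CLIMATE_VARS):
        if maxs[k] == mins[k]:
            raise DegenerateFeatureError(
                f"climate variable '{v}' is constant over the background"
            )
    scaling = FeatureScaling(mins=mins, maxs=maxs)
    return (
        scaling.transform(climate[pres_cells]),
        scaling.transform(bg_climate),
        scaling,
        pres_cells,
        bg_cells,
    )


# ---------------------------------------------------------------------------
# maxent fit
# ---------------------------------------------------------------------------

def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    regularization: float | np.ndarray = 0.0,
    max_iter: int = 1000,
    grad_tol: float = 1e-3,
) -> np.ndarray:
    """Fit Gibbs weights by maximizing the L1-penalized presence likelihood.

    ``regularization`` is a scalar or per-feature vector of non-negative L1
    penalties on the same (per-presence-average) scale as the log-likelihood.
    Exact L1 is handled by splitting lambda = u - v with u, v >= 0 and
    box-constrained L-BFGS-B; at reg = 0 plain L-BFGS-B on lambda is used.

    Raises ConvergenceError (carrying the final projected-gradient norm) if
    the optimizer stops far from stationarity.
    """
    pres_F = np.asarray(presence_features, dtype=float)
    bg_F = np.asarray(background_features, dtype=float)
    if pres_F.shape[0] < MIN_OCCUPIED_CELLS:
        raise EligibilityError(
            f"need at least {MIN_OCCUPIED_CELLS} presence rows, got {pres_F.shape[0]}"
        )
    n_feat = pres_F.shape[1]
    reg = np.broadcast_to(np.asarray(regularization, dtype=float), (n_feat,)).copy()
    if np.any(reg < 0):
        raise SchemaError("regularization must be non-negative")
    pres_mean = pres_F.mean(axis=0)

    def nll_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        eta = bg_F @ lam
        logz = logsumexp(eta)
        q = np.exp(eta - logz)
        # negative mean presence log-likelihood
        val = logz - float(pres_mean @ lam)
        grad = bg_F.T @ q - pres_mean
        return val, grad

    opts = {"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10}

    def _minimize(fun, x0, bounds=None):
        # one warm restart: L-BFGS-B occasionally stops on a flat relative
        # reduction before reaching stationarity; restarting from the
        # incumbent reliably polishes it off
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options=opts)
        return minimize(fun, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
                        options=opts)

    if np.all(reg == 0):
        res = _minimize(nll_grad, np.zeros(n_feat))
        lam = res.x
        _, g = nll_grad(lam)
        gnorm = float(np.max(np.abs(g)))
        if gnorm > grad_tol:
            raise ConvergenceError(
                f"maxent fit did not converge: |grad|_inf = {gnorm:.3e}", gnorm
            )
        return lam

    def obj_split(uv: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = uv[:n_feat], uv[n_feat:]
        val, g = nll_grad(u - v)
        return val + float(reg @ (u + v)), np.concatenate([g + reg, -g + reg])

    res = _minimize(obj_split, np.zeros(2 * n_feat),
                    bounds=[(0.0, None)] * (2 * n_feat))
    uv = res.x
    lam = uv[:n_feat] - uv[n_feat:]
    lam[np.abs(lam) < 1e-8] = 0.0  # numerically inactive weights
    # KKT stationarity for the L1 problem: |grad_j| <= reg_j at lam_j = 0,
    # grad_j = -sign(lam_j) reg_j otherwise
    _, g = nll_grad(lam)
    viol = np.where(
        lam == 0.0, np.maximum(np.abs(g) - reg, 0.0), np.abs(g + np.sign(lam) * reg)
    )
    gnorm = float(np.max(viol))
    if gnorm > grad_tol:
        raise ConvergenceError(
            f"maxent fit did not converge: KKT violation = {gnorm:.3e}", gnorm
        )
    return lam


# Linear+quadratic feature-class beta schedule over presence sample size,
# log-linearly interpolated; the community default for this feature class.
_BETA_SCHEDULE = ((10, 1.3), (17, 0.8), (30, 0.5), (100, 0.25))


def _beta_lq(m: int) -> float:
    pts = _BETA_SCHEDULE
    if m <= pts[0][0]:
        return pts[0][1]
    if m >= pts[-1][0]:
        return pts[-1][1]
    for (m0, b0), (m1, b1) in zip(pts, pts[1:]):
        if m0 <= m <= m1:
            w = (np.log(m) - np.log(m0)) / (np.log(m1) - np.log(m0))
            return float(b0 + w * (b1 - b0))
    raise AssertionError("unreachable")


def default_regularization(background_features: np.ndarray, n_presence: int,
                           beta: float = 1.0) -> np.ndarray:
    """Feature-wise default L1 penalty: beta * beta_lq(m) * std(f_j) / sqrt(m).

    The penalty scales with each feature's background spread, decays with the
    presence sample size m, and carries the linear+quadratic feature-class
    multiplier interpolated from the community default schedule.  ``beta`` is
    a global multiplier on the whole schedule (default 1.0).
    """
    std = np.asarray(background_features, dtype=float).std(axis=0)
    m = max(n_presence, 1)
    return float(beta) * _beta_lq(m) * std / np.sqrt(m)


# ---------------------------------------------------------------------------
# evaluation and thresholding
# ---------------------------------------------------------------------------

def auc_score(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-statistic AUC (ties counted half): P(presence score > background)."""
    y = np.concatenate(
        [np.ones(len(presence_scores)), np.zeros(len(background_scores))]
    )
    s = np.concatenate([presence_scores, background_scores])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def select_threshold(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Threshold maximizing sensitivity + specificity (max TSS).

    Every distinct observed score is a candidate; a cell is predicted present
    when score >= threshold.  Ties are broken toward the lower threshold.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise SchemaError("both score sets must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    best_t, best_v = candidates[0], -np.inf
    for t in candidates:
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(bg < t))
        v = sens + spec
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return float(best_t)


@dataclass
class ReplicateFit:
    """One calibration-replicate model: weights and its background centering."""

    weights: np.ndarray
    center: float  # mean background linear predictor at training time


@dataclass
class SdmFit:
    """Fitted per-species model: replicate ensemble, scaling, threshold, AUCs."""

    species_id: str
    scaling: FeatureScaling
    replicates: list[ReplicateFit]
    replicate_aucs: np.ndarray
    threshold: float
    regularization: np.ndarray
    background_cells: np.ndarray
    presence_cells: np.ndarray
    feature_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            [f"{v}" for v in CLIMATE_VARS] + [f"{v}^2" for v in CLIMATE_VARS]
        )
    )

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.replicate_aucs))


def _replicate_suitability(rep: ReplicateFit, features: np.ndarray) -> np.ndarray:
    """Suitability in (0, 1): logistic of the centered linear predictor."""
    return expit(features @ rep.weights - rep.center)


def replicate_evaluate(
    stack: ClimateStack,
    occ: pd.DataFrame,
    n_replicates: int = 100,
    split_ratio: float = 0.8,
    seed: int = 0,
    n_background: int = 10_000,
    beta: float = 1.0,
) -> tuple[list[ReplicateFit], np.ndarray, np.ndarray, np.ndarray, FeatureScaling,
           np.ndarray, np.ndarray]:
    """Replicated split-sample fitting and evaluation.

    Per replicate the distinct presence cells are randomly partitioned into
    calibration and validation subsets (default ratio 4:1), a model is fitted
    on the calibration subset, and the validation presences are scored
    against the fixed background by AUC.  Replicates with fewer than two
    validation cells are skipped with a warning, never silently.

    Returns (replicate_fits, replicate_aucs, pooled_validation_scores,
    pooled_background_scores, scaling, presence_cells, background_cells).
    """
    pres_F, bg_F, scaling, pres_cells, bg_cells = standardize_features(
        stack, occ, n_background=n_background, seed=seed
    )
    m = pres_F.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9173]))
    fits: list[ReplicateFit] = []
    aucs: list[float] = []
    pooled_val: list[np.ndarray] = []
    pooled_bg: list[np.ndarray] = []
    for _ in range(int(n_replicates)):
        perm = rng.permutation(m)
        n_cal = int(round(split_ratio * m))
        n_cal = min(max(n_cal, 1), m - 1) if m > 1 else m
        cal, val = perm[:n_cal], perm[n_cal:]
        if val.size < 2:
            warnings.warn(
                "replicate skipped: fewer than 2 validation points", stacklevel=2
            )
            continue
        reg = default_regularization(bg_F, cal.size, beta=beta)
        lam = fit_maxent(pres_F[cal], bg_F, regularization=reg)
        center = float(np.mean(bg_F @ lam))
        rep = ReplicateFit(weights=lam, center=center)
        val_scores = _replicate_suitability(rep, pres_F[val])
        bg_scores = _replicate_suitability(rep, bg_F)
        fits.append(rep)
        aucs.append(auc_score(val_scores, bg_scores))
        pooled_val.append(val_scores)
        pooled_bg.append(bg_scores)
    if not fits:
        raise EligibilityError("all replicates were skipped; species not modelled")
    return (
        fits,
        np.array(aucs),
        np.concatenate(pooled_val),
        np.concatenate(pooled_bg),
        scaling,
        pres_cells,
        bg_cells,
    )


def fit_species(
    stack: ClimateStack,
    occ: pd.DataFrame,
    n_replicates: int = 100,
    split_ratio: float = 0.8,
    seed: int = 0,
    n_background: int = 10_000,
    beta: float = 1.0,
) -> SdmFit:
    """Full per-species fit: replicate ensemble + pooled-TSS threshold."""
    (fits, aucs, pooled_val, pooled_bg, scaling,
     pres_cells, bg_cells) = replicate_evaluate(
        stack, occ, n_replicates=n_replicates, split_ratio=split_ratio,
        seed=seed, n_background=n_background, beta=beta,
    )
    threshold = select_threshold(pooled_val, pooled_bg)
    species_id = str(occ["species"].iloc[0])
    scaled_bg = scaling.transform(
        stack.climate_matrix()[bg_cells]
    )
    reg = default_regularization(
        scaled_bg, int(round(split_ratio * pres_cells.size)), beta=beta
    )
    return SdmFit(
        species_id=species_id,
        scaling=scaling,
        replicates=fits,
        replicate_aucs=aucs,
        threshold=float(threshold),
        regularization=reg,
        background_cells=bg_cells,
        presence_cells=pres_cells,
    )


# ---------------------------------------------------------------------------
# projection and binarization
# ---------------------------------------------------------------------------

def project(fit: SdmFit, stack: ClimateStack) -> SuitabilityMap:
    """Project a fitted model onto a (baseline or future) climate stack.

    The training min-max scaling is reused unchanged; projected features are
    clamped to the training [0, 1] range.  Final suitability is the mean of
    the replicate suitability surfaces (each a logistic of that replicate's
    centered linear predictor), so it is monotone in the ensemble score and
    lies in (0, 1).
    """
    missing = [v for v in CLIMATE_VARS if v not in stack.layers]
    if missing:
        raise ProjectionError(f"stack missing climate variables: {missing}")
    features = fit.scaling.transform(stack.climate_matrix(), clamp=True)
    acc = np.zeros(features.shape[0])
    for rep in fit.replicates:
        acc += _replicate_suitability(rep, features)
    values = (acc / len(fit.replicates)).reshape(stack.grid.shape)
    values = np.where(stack.mask, values, 0.0)
    return SuitabilityMap(
        species_id=fit.species_id, scenario=stack.scenario,
        grid=stack.grid, values=values, mask=stack.mask,
    )


def binarize(s: SuitabilityMap, threshold: float) -> RangeMap:
    """Binary range map: present where suitability >= threshold (unmasked cells)."""
    if not (0.0 < threshold < 1.0):
        raise SchemaError(f"threshold must be in (0, 1), got {threshold}")
    presence = (s.values >= threshold) & s.mask
    return RangeMap(
        species_id=s.species_id, scenario=s.scenario, grid=s.grid, presence=presence
    )
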