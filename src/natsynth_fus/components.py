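"""Voxel component decomposition and cross-species component prediction.

The decomposition models each voxel's response as a weighted sum of a small
number of component response patterns shared across voxels.  Like ICA it
seeks maximally non-Gaussian weight distributions, but it measures
non-Gaussianity directly as the (differential) entropy of a histogram of
the weights across voxels — practical here because imaging datasets have
many voxels.  Concretely: the data are reduced to their top-K principal
subspace, and a K x K orthogonal rotation is optimized (Jacobi-style
pairwise rotations with golden-section line search, multiple seeded
restarts) to minimize the summed histogram entropy of the K weight columns.

Cross-species prediction regresses each target component's response profile
on all source components with 9-fold cross-validated ridge regression,
nested 9-fold selection of the penalty over a wide log-spaced grid, folds
built from natural/synthetic sound pairs so the two versions of a sound can
never straddle train and test.  Prediction accuracy is the NSE, and
explained variance is the signed square of (1 - NSE) — (1 - NSE) equals the
Pearson correlation for signals with equal mean and variance, so its square
plays the role of r^2, with the sign preserved so anti-predictions are not
counted as explained variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import nse as nse_mod

__all__ = [
    "ComponentSet",
    "decompose",
    "histogram_entropy",
    "PredictionResult",
    "crossspecies_predict",
    "explained_variance",
    "explained_variance_decomposition",
    "component_category_profile",
]

log = logging.getLogger(__name__)

HIST_BINS = 100
N_RESTARTS = 10
RIDGE_GRID = 2.0 ** np.linspace(-100, 100, 201)


@dataclass
class ComponentSet:
    """Paired (response profile, voxel weight) factors.

    Weights are normalized to unit RMS per component, so a component's
    response magnitude carries its share of explained variance;
    ``total_variance`` holds those shares rescaled to sum to 1.
    """

    profiles: np.ndarray        # (n_features, K); features = sounds or samples
    weights: np.ndarray         # (n_voxels, K), unit RMS per column
    total_variance: np.ndarray  # (K,), sums to 1
    identifiable: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.profiles.shape[1]

    def reconstruction(self) -> np.ndarray:
        """(n_voxels, n_features) rank-K reconstruction of the data."""
        return self.weights @ self.profiles.T


def histogram_entropy(values: np.ndarray, bins: int = HIST_BINS) -> float:
    """Differential entropy of a sample, estimated from a histogram.

    Bins are equal-width over the robust (1st-99th percentile) range with
    add-one smoothing; the log bin width term makes the estimate scale-aware
    (a rotation redistributes variance between columns, and entropy must
    reflect that).
    """
    lo, hi = np.percentile(values, [1, 99])
    if hi <= lo:
        return -np.inf
    idx = np.floor((values - lo) * (bins / (hi - lo))).astype(np.intp)
    keep = (idx >= 0) & (idx < bins)
    counts = np.bincount(idx[keep], minlength=bins)
    p = (counts + 1.0) / (counts.sum() + bins)
    width = (hi - lo) / bins
    return float(-(p * np.log(p)).sum() + np.log(width))


def _pair_entropy(W: np.ndarray, i: int, j: int, theta: float, bins: int) -> float:
    c, s = np.cos(theta), np.sin(theta)
    a = c * W[:, i] + s * W[:, j]
    b = -s * W[:, i] + c * W[:, j]
    return histogram_entropy(a, bins) + histogram_entropy(b, bins)


def _golden_min(fun, lo: float, hi: float, tol: float = 1e-3) -> float:
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _rotate_min_entropy(W0: np.ndarray, rng: np.random.Generator,
                        bins: int = HIST_BINS, max_sweeps: int = 30,
                        tol: float = 1e-6):
    """Jacobi sweeps of pairwise rotations minimizing summed column entropy."""
    K = W0.shape[1]
    Q = np.eye(K)
    W = W0.copy()
    total = sum(histogram_entropy(W[:, k], bins) for k in range(K))
    for _ in range(max_sweeps):
        improved = 0.0
        for i in range(K - 1):
            for j in range(i + 1, K):
                f = lambda th: _pair_entropy(W, i, j, th, bins)
                before = f(0.0)
                # the pair objective is pi/2-periodic and can be multimodal
                # over one period: coarse grid first, golden refine after
                grid = np.linspace(-np.pi / 4, np.pi / 4, 17)
                vals = [f(th) for th in grid]
                g = int(np.argmin(vals))
                lo = grid[max(g - 1, 0)]
                hi = grid[min(g + 1, grid.size - 1)]
                theta = _golden_min(f, lo, hi)
                after = f(theta)
                if after < before - tol:
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.eye(K)
                    G[i, i] = G[j, j] = c
                    G[i, j], G[j, i] = -s, s   # col i <- c*wi + s*wj
                    W = W @ G
                    Q = Q @ G
                    improved += before - after
        total -= improved
        if improved < 1e-4:
            break
    return Q, total


def decompose(D: np.ndarray, k: int, seed: int = 0, bins: int = HIST_BINS,
              n_restarts: int = N_RESTARTS) -> ComponentSet:
    """Histogram-entropy decomposition of a voxel x feature data matrix.

    The data are PCA-reduced to ``k`` dimensions; within that subspace an
    orthogonal rotation minimizing the summed histogram entropy of the
    voxel-weight columns is found by Jacobi pairwise rotations with
    ``n_restarts`` seeded random restarts (best objective kept).  Output is
    deterministic for a fixed seed.

    If no rotation is meaningfully better than any other (Gaussian weights),
    the result is flagged ``identifiable=False``.
    """
    D = np.asarray(D, dtype=float)
    V = D.shape[0]
    if k > min(D.shape):
        raise ValueError(f"k={k} exceeds rank bound {min(D.shape)}")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    # whitened voxel weights (unit variance, uncorrelated): an orthogonal
    # rotation of these spans all candidate unmixings of the K-subspace
    W0 = U[:, :k] * np.sqrt(V)
    P0 = Vt[:k].T * (s[:k] / np.sqrt(V))   # (features, k)
    rng = np.random.default_rng(seed)
    best = None
    if k == 1:
        bestQ = np.eye(1)
    else:
        for _ in range(n_restarts):
            A = rng.standard_normal((k, k))
            Q0, _r = np.linalg.qr(A)
            Q, obj = _rotate_min_entropy(W0 @ Q0, rng, bins)
            if best is None or obj < best[1]:
                best = (Q0 @ Q, obj)
        bestQ = best[0]
    W = W0 @ bestQ
    P = P0 @ bestQ
    # identifiability requires at least one clearly non-Gaussian weight
    # distribution; sample kurtosis of a Gaussian has s.d. ~ sqrt(24/V)
    kurt = stats.kurtosis(W / W.std(axis=0, keepdims=True), axis=0)
    identifiable = bool(np.max(np.abs(kurt)) > max(0.5, 5 * np.sqrt(24 / V)))
    if not identifiable:
        log.warning("weight distributions look Gaussian (max |excess "
                    "kurtosis| %.3f); decomposition unidentifiable",
                    float(np.max(np.abs(kurt))))
    # sign convention: positive weight skewness
    sign = np.where(stats.skew(W, axis=0) < 0, -1.0, 1.0)
    W, P = W * sign, P * sign
    # unit-RMS weights; magnitude moves into the profiles
    rms = np.sqrt((W ** 2).mean(axis=0))
    rms = np.where(rms > 0, rms, 1.0)
    W = W / rms
    P = P * rms
    share = (P ** 2).sum(axis=0)
    total = share / share.sum() if share.sum() > 0 else share
    return ComponentSet(profiles=P, weights=W, total_variance=total,
                        identifiable=identifiable, meta={"seed": seed})


# ---------------------------------------------------------------------------
# cross-species ridge prediction
# ---------------------------------------------------------------------------

def _pair_folds(sound_table: pd.DataFrame, n_folds: int, rng) -> np.ndarray:
    """Fold label per sound; both members of a natural/synthetic pair share
    a fold."""
    pairs = np.sort(sound_table["pair"].unique())
    perm = rng.permutation(pairs)
    fold_of_pair = {p: i % n_folds for i, p in enumerate(perm)}
    return sound_table["pair"].map(fold_of_pair).to_numpy()


def _ridge_path(Xtr, ytr, Xte, lambdas):
    """Ridge predictions on Xte for every lambda at once (SVD trick)."""
    xm, ym = Xtr.mean(axis=0), ytr.mean()
    Xc, yc = Xtr - xm, ytr - ym
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    Uty = U.T @ yc
    d = s[:, None] / (s[:, None] ** 2 + lambdas[None, :])   # (r, L)
    coef = Vt.T @ (d * Uty[:, None])                        # (p, L)
    return ym + (Xte - xm) @ coef                           # (n_te, L)


def _cv_ridge_predict(X, y, folds, lambdas, inner_folds: int = 9):
    """Out-of-fold ridge predictions with nested penalty selection."""
    yhat = np.empty_like(y, dtype=float)
    chosen = []
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        Xtr, ytr = X[tr], y[tr]
        inner = folds[tr]
        # inner CV over the training folds (they already partition the data)
        sse = np.zeros(lambdas.size)
        for g in np.unique(inner):
            itr, ite = inner != g, inner == g
            pred = _ridge_path(Xtr[itr], ytr[itr], Xtr[ite], lambdas)
            sse += ((pred - ytr[ite][:, None]) ** 2).sum(axis=0)
        best = int(np.argmin(sse))
        if best in (0, lambdas.size - 1):
            log.warning("ridge penalty selected at grid edge (lambda=2^%g)",
                        np.log2(lambdas[best]))
        chosen.append(lambdas[best])
        yhat[te] = _ridge_path(Xtr, ytr, X[te], lambdas[best:best + 1])[:, 0]
    return yhat, np.asarray(chosen)


def explained_variance(nse_value):
    """Signed square of (1 - NSE): negative (1 - NSE) stays negative."""
    e = 1.0 - np.asarray(nse_value, dtype=float)
    out = np.sign(e) * e ** 2
    return out if out.ndim else float(out)


@dataclass
class PredictionResult:
    predicted_profiles: np.ndarray   # (n_sounds, K_target)
    nse_synth: np.ndarray            # per target component, synthetic sounds
    nse_diff: np.ndarray             # per target, natural-minus-synthetic
    ev_synth: np.ndarray
    ev_diff: np.ndarray
    bootstrap: pd.DataFrame          # per-component CI columns
    chosen_lambdas: np.ndarray
    sound_table: pd.DataFrame


def _subset_indices(sound_table: pd.DataFrame):
    nat = sound_table[sound_table["is_natural"]].sort_values("pair").index.to_numpy()
    syn = sound_table[~sound_table["is_natural"]].sort_values("pair").index.to_numpy()
    return nat, syn


def crossspecies_predict(source_profiles: np.ndarray, target_profiles: np.ndarray,
                         sound_table: pd.DataFrame, n_folds: int = 9,
                         seed: int = 0, n_boot: int = 1000,
                         lambdas: np.ndarray = RIDGE_GRID) -> PredictionResult:
    """Predict each target component from all source components.

    ``source_profiles`` and ``target_profiles`` are (n_sounds, K) response
    profiles on a shared sound axis described by ``sound_table``.  Accuracy
    is reported separately for the synthetic-sound responses and for the
    natural-minus-synthetic differences, as NSE and signed explained
    variance, with seeded bootstrap (resampling sound pairs) percentile
    intervals.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(source_profiles, dtype=float)
    Y = np.atleast_2d(np.asarray(target_profiles, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    folds = _pair_folds(sound_table, n_folds, rng)
    K_t = Y.shape[1]
    preds = np.empty_like(Y)
    lams = []
    for k in range(K_t):
        preds[:, k], lam = _cv_ridge_predict(X, Y[:, k], folds, lambdas)
        lams.append(lam)
    nat, syn = _subset_indices(sound_table)

    def metrics(pred, targ):
        n_synth = np.array([nse_mod.nse(pred[syn, k], targ[syn, k])
                            for k in range(K_t)])
        n_diff = np.array([nse_mod.nse(pred[nat, k] - pred[syn, k],
                                       targ[nat, k] - targ[syn, k])
                           for k in range(K_t)])
        return n_synth, n_diff

    nse_synth, nse_diff = metrics(preds, Y)
    boot_rows = []
    n_pairs = nat.size
    for b in range(n_boot):
        take = rng.integers(0, n_pairs, size=n_pairs)
        idx = np.concatenate([nat[take], syn[take]])
        sub_tab = sound_table.iloc[idx]
        subnat = np.arange(n_pairs)
        subsyn = np.arange(n_pairs, 2 * n_pairs)
        p, t = preds[idx], Y[idx]
        for k in range(K_t):
            ns = nse_mod.nse(p[subsyn, k], t[subsyn, k])
            nd = nse_mod.nse(p[subnat, k] - p[subsyn, k],
                             t[subnat, k] - t[subsyn, k])
            boot_rows.append({"component": k, "ev_synth": explained_variance(ns),
                              "ev_diff": explained_variance(nd)})
    boot = pd.DataFrame(boot_rows)
    ci = boot.groupby("component").quantile([0.025, 0.975]).unstack()
    ci.columns = [f"{a}_{'lo' if q == 0.025 else 'hi'}" for a, q in ci.columns]
    return PredictionResult(
        predicted_profiles=preds,
        nse_synth=nse_synth, nse_diff=nse_diff,
        ev_synth=explained_variance(nse_synth),
        ev_diff=explained_variance(nse_diff),
        bootstrap=ci.reset_index(),
        chosen_lambdas=np.asarray(lams),
        sound_table=sound_table.reset_index(drop=True),
    )


def explained_variance_decomposition(pred1: np.ndarray, pred2: np.ndarray,
                                     targ1: np.ndarray, targ2: np.ndarray,
                                     sound_table: pd.DataFrame,
                                     total_variance: np.ndarray | None = None,
                                     gate: float = nse_mod.RELIABILITY_GATE) -> pd.DataFrame:
    """Noise-corrected explained-variance table per target component.

    ``pred1``/``pred2`` and ``targ1``/``targ2`` are two independent
    measurements (e.g., two animals, or two subject groups) of the predicted
    and measured profiles, (n_sounds, K).  For each component the explained
    variance of the synthetic-sound responses and of the natural-minus-
    synthetic differences is computed from the noise-corrected NSE, unless
    the target's own test-retest NSE exceeds ``gate`` (then the raw NSE of
    the averaged measurements is used, flagged ``corrected=False``).  Total
    variance per component is noise-corrected via
    (var(r1 + r2) - var(r1 - r2)) / 4 and multiplied into the EV.
    """
    nat, syn = _subset_indices(sound_table)
    K = np.atleast_2d(targ1).shape[1] if targ1.ndim > 1 else 1
    targ1, targ2 = np.atleast_2d(targ1.T).T, np.atleast_2d(targ2.T).T
    pred1, pred2 = np.atleast_2d(pred1.T).T, np.atleast_2d(pred2.T).T
    rows = []
    for k in range(K):
        for name, idx_fn in (("synth", lambda a: a[syn, k]),
                             ("diff", lambda a: a[nat, k] - a[syn, k])):
            t1, t2 = idx_fn(targ1), idx_fn(targ2)
            p1, p2 = idx_fn(pred1), idx_fn(pred2)
            retest = nse_mod.nse(t1, t2)
            corrected = bool(np.isfinite(retest) and retest < gate)
            if corrected:
                val = nse_mod.noise_corrected_nse(p1, p2, t1, t2)
            else:
                val = nse_mod.nse(0.5 * (p1 + p2), 0.5 * (t1 + t2))
            tv = nse_mod.noise_corrected_variance(t1, t2)
            ev = explained_variance(val)
            rows.append({"component": k, "subset": name, "nse": val,
                         "ev": ev, "total_variance": tv,
                         "ev_times_variance": ev * tv,
                         "corrected": corrected, "test_retest_nse": retest})
    table = pd.DataFrame(rows)
    if total_variance is not None:
        tv = np.asarray(total_variance, dtype=float)
        table["component_variance_share"] = tv[table["component"].to_numpy()]
    return table


def component_category_profile(profiles: np.ndarray,
                               sound_table: pd.DataFrame) -> pd.DataFrame:
    """Per-component per-category mean response, with the natural-vs-
    synthetic contrast for each category."""
    P = np.atleast_2d(np.asarray(profiles, dtype=float).T).T
    rows = []
    for k in range(P.shape[1]):
        for cat in sorted(sound_table["category"].unique()):
            sel = sound_table["category"] == cat
            nat = sel & sound_table["is_natural"]
            syn = sel & ~sound_table["is_natural"]
            rows.append({
                "component": k, "category": cat,
                "mean": float(P[sel.to_numpy(), k].mean()),
                "mean_natural": float(P[nat.to_numpy(), k].mean()) if nat.any() else np.nan,
                "mean_synthetic": float(P[syn.to_numpy(), k].mean()) if syn.any() else np.nan,
            })
    out = pd.DataFrame(rows)
    out["natural_minus_synthetic"] = out["mean_natural"] - out["mean_synthetic"]
    return out
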