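"""Partial least squares path modeling (PLS-PM).

Implements the classical Lohmöller iteration for reflective (mode A) blocks:
manifest variables are standardized, latent scores are iteratively refined by
alternating outer estimation (scores as weighted sums of their own block's
manifests) and inner estimation (scores as signed/weighted sums of adjacent
latents' scores) until the outer weights stabilize. Structural (path)
coefficients are then ordinary least squares regressions of each endogenous
latent score on its predecessors' scores.

The inner weighting scheme defaults to ``centroid`` (adjacency sign of the
score correlation); ``factorial`` (correlation) and ``path`` (regression
coefficients for predecessors, correlations for successors) are available.
Latent scores use population (1/n) standardization, and each latent's sign
is oriented so that its mean loading is positive, which removes the PLS sign
indeterminacy.

Effects decompose over the DAG: direct = path coefficient, indirect = sum of
coefficient products over all directed paths of length >= 2, total = direct
+ indirect. Significance is assessed by a nonparametric bootstrap (resample
samples with replacement, refit, percentile intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PathModel", "PLSPMResult", "fit_plspm", "effects_decomposition", "bootstrap_paths"]


class ConvergenceError(RuntimeError):
    def __init__(self, msg, last_delta=None):
        super().__init__(msg)
        self.last_delta = last_delta


@dataclass(frozen=True)
class PathModel:
    """Structural model: DAG over latents plus manifest blocks.

    ``path_matrix[i, j] = 1`` encodes an arrow latent_j -> latent_i and must
    be strictly lower triangular in the latent order (DAG by construction).
    """

    latent_names: tuple[str, ...]
    path_matrix: np.ndarray
    blocks: dict[str, tuple[str, ...]]
    scheme: str = "centroid"

    def __post_init__(self):
        pm = np.asarray(self.path_matrix, dtype=float)
        L = len(self.latent_names)
        if pm.shape != (L, L):
            raise ValueError("path matrix shape does not match latent count")
        if np.any(np.triu(pm) != 0):
            raise ValueError("path matrix must be strictly lower triangular (DAG order)")
        if set(self.blocks) != set(self.latent_names):
            raise ValueError("blocks must cover exactly the latent names")
        seen = {}
        for latent, manifests in self.blocks.items():
            if len(manifests) == 0:
                raise ValueError(f"latent {latent!r} has an empty block")
            for mv in manifests:
                if mv in seen:
                    raise ValueError(f"manifest {mv!r} appears in blocks {seen[mv]!r} and {latent!r}")
                seen[mv] = latent
        if self.scheme not in ("centroid", "factorial", "path"):
            raise ValueError(f"unknown inner scheme {self.scheme!r}")
        object.__setattr__(self, "path_matrix", pm)
        object.__setattr__(self, "latent_names", tuple(self.latent_names))
        object.__setattr__(self, "blocks", {k: tuple(v) for k, v in self.blocks.items()})

    @property
    def n_latents(self) -> int:
        return len(self.latent_names)

    def adjacency(self) -> np.ndarray:
        pm = self.path_matrix != 0
        return pm | pm.T

    def predecessors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.path_matrix[i] != 0)

    def endogenous(self) -> list[int]:
        return [i for i in range(self.n_latents) if self.path_matrix[i].any()]


@dataclass
class PLSPMResult:
    model: PathModel
    outer_weights: dict[str, np.ndarray]
    loadings: dict[str, np.ndarray]
    latent_scores: pd.DataFrame
    path_coefficients: np.ndarray
    r_squared: dict[str, float]
    gof: float
    n_iterations_used: int
    effects: pd.DataFrame | None = None
    bootstrap: pd.DataFrame | None = None

    def path(self, source: str, target: str) -> float:
        i = self.model.latent_names.index(target)
        j = self.model.latent_names.index(source)
        return float(self.path_coefficients[i, j])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)  # population (1/n) convention
    if (sd == 0).any():
        raise ValueError("zero-variance manifest variable")
    return (x - x.mean(axis=0)) / sd


def _extract_blocks(data: pd.DataFrame, model: PathModel) -> dict[str, np.ndarray]:
    all_manifests = [mv for lat in model.latent_names for mv in model.blocks[lat]]
    missing = [mv for mv in all_manifests if mv not in data.columns]
    if missing:
        raise ValueError(f"manifest variables missing from data: {missing}")
    return {lat: data[list(model.blocks[lat])].to_numpy(dtype=float)
            for lat in model.latent_names}


def fit_plspm(data: pd.DataFrame, model: PathModel, max_iter: int = 300,
              tol: float = 1e-7) -> PLSPMResult:
    """Fit a PLS path model to a samples x manifests table (mode A blocks)."""
    return _fit_core(_extract_blocks(data, model), model, index=data.index,
                     max_iter=max_iter, tol=tol)


def _fit_core(raw_blocks: dict[str, np.ndarray], model: PathModel, index=None,
              max_iter: int = 300, tol: float = 1e-7,
              coefficients_only: bool = False):
    n = next(iter(raw_blocks.values())).shape[0]
    L = model.n_latents
    adjacency = model.adjacency()
    if not adjacency.any(axis=1).all():
        isolated = [model.latent_names[i] for i in np.flatnonzero(~adjacency.any(axis=1))]
        raise ValueError(f"latents with no structural connection: {isolated}")

    X = {lat: _standardize(x) for lat, x in raw_blocks.items()}
    w = {lat: np.ones(len(model.blocks[lat])) for lat in model.latent_names}

    def scores(weights):
        Y = np.empty((n, L))
        for k, lat in enumerate(model.latent_names):
            y = X[lat] @ weights[lat]
            sd = y.std()
            if sd == 0:
                raise ConvergenceError(f"degenerate score for latent {lat!r}")
            Y[:, k] = (y - y.mean()) / sd
        return Y

    def norm_w(weights):
        out = {}
        for lat, wv in weights.items():
            v = wv / np.linalg.norm(wv)
            if v.sum() < 0:
                v = -v
            out[lat] = v
        return out

    last_delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Y = scores(w)
        C = (Y.T @ Y) / n
        # inner estimation
        E = np.zeros((L, L))
        if model.scheme == "centroid":
            E[adjacency] = np.sign(C[adjacency])
        elif model.scheme == "factorial":
            E[adjacency] = C[adjacency]
        else:  # path scheme
            for i in range(L):
                pred = model.predecessors(i)
                if pred.size:
                    E[i, pred] = np.linalg.solve(C[np.ix_(pred, pred)], C[pred, i])
                succ = np.flatnonzero(model.path_matrix[:, i] != 0)
                E[i, succ] = C[i, succ]
        Z = Y @ E.T
        # outer estimation, mode A: weights are manifest/inner-proxy covariances
        w_new = {}
        for k, lat in enumerate(model.latent_names):
            z = Z[:, k]
            sd = z.std()
            if sd == 0:
                raise ConvergenceError(f"degenerate inner proxy for latent {lat!r}")
            z = (z - z.mean()) / sd
            w_new[lat] = (X[lat].T @ z) / n
        a, bnorm = norm_w(w), norm_w(w_new)
        last_delta = max(np.abs(a[lat] - bnorm[lat]).max() for lat in model.latent_names)
        w = w_new
        if last_delta < tol:
            break
    else:
        raise ConvergenceError(f"PLS-PM did not converge in {max_iter} iterations "
                               f"(last max weight change {last_delta:.3g})", last_delta)

    Y = scores(w)
    # orient each latent so its mean loading is positive
    loadings = {}
    for k, lat in enumerate(model.latent_names):
        lo = (X[lat].T @ Y[:, k]) / n
        if lo.mean() < 0:
            Y[:, k] = -Y[:, k]
            w[lat] = -w[lat]
            lo = -lo
        loadings[lat] = lo

    C = (Y.T @ Y) / n
    B = np.zeros((L, L))
    r2 = {}
    for i in model.endogenous():
        pred = model.predecessors(i)
        S = C[np.ix_(pred, pred)]
        if np.linalg.cond(S) > 1e8:
            names = [model.latent_names[j] for j in pred]
            raise ValueError(f"collinear predecessors for {model.latent_names[i]!r}: {names}")
        beta = np.linalg.solve(S, C[pred, i])
        B[i, pred] = beta
        r2[model.latent_names[i]] = float(beta @ C[pred, i])

    if coefficients_only:
        return B

    communalities = np.concatenate([loadings[lat] ** 2 for lat in model.latent_names])
    mean_r2 = np.mean(list(r2.values())) if r2 else 0.0
    gof = float(np.sqrt(communalities.mean() * mean_r2))

    result = PLSPMResult(
        model=model,
        outer_weights=w,
        loadings=loadings,
        latent_scores=pd.DataFrame(Y, index=index, columns=list(model.latent_names)),
        path_coefficients=B,
        r_squared=r2,
        gof=gof,
        n_iterations_used=n_iter,
    )
    result.effects = effects_decomposition(result)
    return result


def effects_decomposition(result: PLSPMResult) -> pd.DataFrame:
    """Direct/indirect/total effects by summing path products over the DAG.

    Because the path matrix is strictly lower triangular (nilpotent), the
    total-effect matrix is the finite sum B + B^2 + ... + B^(L-1).
    """
    B = result.path_coefficients
    L = B.shape[0]
    total = np.zeros_like(B)
    power = np.eye(L)
    for _ in range(L - 1):
        power = power @ B
        total += power
    indirect = total - B
    names = result.model.latent_names
    rows = []
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            if B[i, j] == 0 and total[i, j] == 0:
                continue
            rows.append({"from": names[j], "to": names[i],
                         "direct": float(B[i, j]), "indirect": float(indirect[i, j]),
                         "total": float(total[i, j])})
    return pd.DataFrame(rows, columns=["from", "to", "direct", "indirect", "total"])


def bootstrap_paths(data: pd.DataFrame, model: PathModel, n_boot: int = 500,
                    seed: int | None = None, max_iter: int = 300,
                    tol: float = 1e-7) -> pd.DataFrame:
    """Bootstrap the path coefficients: resample samples with replacement,
    refit, and summarize each structural path with (mean, se, percentile CI,
    two-sided percentile p). Non-convergent resamples are dropped and
    counted; more than 20% of them is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    paths = [(i, j) for i in range(model.n_latents) for j in model.predecessors(i)]
    raw_blocks = _extract_blocks(data, model)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            B = _fit_core({lat: x[idx] for lat, x in raw_blocks.items()}, model,
                          max_iter=max_iter, tol=tol, coefficients_only=True)
        except (ConvergenceError, ValueError):
            failures += 1
            continue
        draws.append([B[i, j] for i, j in paths])
    if failures > 0.2 * n_boot:
        raise ConvergenceError(f"{failures}/{n_boot} bootstrap resamples failed to converge")
    draws = np.asarray(draws)
    names = model.latent_names
    rows = []
    for k, (i, j) in enumerate(paths):
        col = draws[:, k]
        lo, hi = np.percentile(col, [2.5, 97.5])
        p = 2.0 * min((col <= 0).mean(), (col >= 0).mean())
        rows.append({
            "from": names[j], "to": names[i],
            "mean": float(col.mean()), "se": float(col.std(ddof=1)),
            "ci_low": float(lo), "ci_high": float(hi),
            "p": float(min(p, 1.0)),
            "n_boot_used": int(draws.shape[0]),
        })
    return pd.DataFrame(rows, columns=["from", "to", "mean", "se", "ci_low", "ci_high", "p", "n_boot_used"])
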