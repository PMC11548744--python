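"""Hartley-modulating-function (HMF) identification of a linear network.

The model is the continuous-time linear gene-regulatory system

    dE/dt = K · E,

where E stacks the scaled expression of every (organ, gene) node and
K[r, j] is the interaction coefficient with which node j drives the
rate of change of node r (1/week).  Multiplying the model by a
modulating function φ_m that vanishes, together with its derivative, at
both ends of the observation window [0, T] and integrating by parts
turns each target node's equation into a linear regression

    b_m = Σ_j A_{m j} k_j ,   b_m = -∫ φ'_m E_target dt ,
                              A_{m j} = ∫ φ_m E_j dt ,

so K is estimated without numerically differentiating noisy data.

The modulating family used here is the Hartley (cas-kernel) combination

    φ_m(t) = Σ_{k=0}^{N} (-1)^k C(N,k) cas((m+k) ω0 t),  ω0 = 2π/T,

whose boundary conditions hold exactly for any order N >= 2 by the
alternating binomial identities Σ(-1)^k C(N,k) = 0 and
Σ(-1)^k k C(N,k) = 0.  The moment integrals can equivalently be read
off discrete Hartley components of the data (the basis' own endpoint
terms cancel), which provides an independent spectral cross-check of
the quadrature.

With far fewer modulating equations than candidate regulators the
regression is underdetermined; an elastic net supplies sparsity, and
the penalty is selected by simulating each candidate K forward from the
first-age state and scoring root-mean-square error against the scaled
data at the observed ages, jointly over all nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .dynamics import UnstableSimulationError, integrate_linear_ode
from .synthetic import TrajectorySet

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# data preparation

def summarize_replicates(norm: pd.DataFrame, meta: pd.DataFrame,
                         strain: str) -> TrajectorySet:
    """Replicate-mean trajectory per (organ, gene) for one strain.

    Missing replicates fall out of the mean; nodes observed at fewer
    than 2 ages are excluded (logged).
    """
    sub_meta = meta[meta["strain"] == strain]
    ages = sorted(sub_meta["age_weeks"].unique())
    if len(ages) < 2:
        raise ValueError("need >=2 time points per node")
    rows, labels = [], []
    for organ, samples in sub_meta.groupby("organ").groups.items():
        cols = [s for s in samples if s in norm.columns]
        sm = sub_meta.loc[cols]
        for gene in norm.index:
            means = []
            for age in ages:
                age_cols = [c for c in cols if sm.loc[c, "age_weeks"] == age]
                vals = norm.loc[gene, age_cols]
                means.append(vals.mean(skipna=True))
            arr = np.asarray(means, dtype=float)
            if np.sum(np.isfinite(arr)) < 2:
                log.info("node (%s, %s) has <2 ages present; excluded", organ, gene)
                continue
            rows.append(arr)
            labels.append((organ, gene))
    idx = pd.MultiIndex.from_tuples(labels, names=["organ", "gene"])
    return TrajectorySet(times=np.asarray(ages, dtype=float),
                         values=pd.DataFrame(np.vstack(rows), index=idx))


def minmax_scale(traj: TrajectorySet) -> tuple[TrajectorySet, pd.DataFrame]:
    """Scale each node to [0, 1] across its time points.

    Constant nodes map to 0.5 and are flagged (degenerate for fitting).
    Returns the scaled set and a per-node frame of (min, max, constant).
    """
    vals = traj.values.to_numpy(dtype=float)
    lo = np.nanmin(vals, axis=1)
    hi = np.nanmax(vals, axis=1)
    const = hi <= lo
    rng = np.where(const, 1.0, hi - lo)
    scaled = (vals - lo[:, None]) / rng[:, None]
    scaled[const] = 0.5
    if const.any():
        log.warning("%d constant nodes mapped to 0.5", int(const.sum()))
    params = pd.DataFrame({"min": lo, "max": hi, "constant": const},
                          index=traj.values.index)
    return (TrajectorySet(times=traj.times,
                          values=pd.DataFrame(scaled, index=traj.values.index)),
            params)


@dataclass
class DenseTrajectories:
    """Node trajectories on a uniform grid over the shifted window [0, T]."""

    t: np.ndarray                       # n_grid points, t[0]=0, t[-1]=T
    values: np.ndarray                  # (n_nodes, n_grid)
    labels: list[tuple[str, str]]

    @property
    def T(self) -> float:
        return float(self.t[-1])


def interpolate_dense(traj: TrajectorySet, n_grid: int = 257,
                      clip: tuple[float, float] | None = (0.0, 1.0)
                      ) -> DenseTrajectories:
    """Natural cubic spline through each node's time-point means.

    The time axis is shifted so the first age is t = 0 and
    T = last age − first age.  ``clip`` bounds the dense values (used
    after min-max scaling); pass None to leave splines unbounded.
    """
    times = traj.times
    if n_grid < times.size:
        raise ValueError("n_grid must be >= number of time points")
    t0 = times[0]
    t_dense = np.linspace(0.0, times[-1] - t0, n_grid)
    vals = traj.values.to_numpy(dtype=float)
    out = np.empty((vals.shape[0], n_grid))
    for i, row in enumerate(vals):
        ok = np.isfinite(row)
        cs = CubicSpline(times[ok] - t0, row[ok], bc_type="natural")
        out[i] = cs(t_dense)
    if clip is not None:
        np.clip(out, clip[0], clip[1], out=out)
    return DenseTrajectories(t=t_dense, values=out,
                             labels=list(traj.values.index))


# --------------------------------------------------------------------------
# modulating-function basis and projections

def cas(x: np.ndarray) -> np.ndarray:
    """Hartley kernel cas(x) = cos(x) + sin(x)."""
    return np.cos(x) + np.sin(x)


def dcas(x: np.ndarray) -> np.ndarray:
    """d/dx cas(x) = cos(x) − sin(x)."""
    return np.cos(x) - np.sin(x)


@dataclass
class HMFBasis:
    """M Hartley modulating functions of order N sampled on [0, T]."""

    M: int
    N: int
    T: float
    t: np.ndarray            # n_grid uniform points
    phi: np.ndarray          # (M, n_grid)
    dphi: np.ndarray         # (M, n_grid), analytic derivative

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi / self.T


def hmf_basis(M: int = 8, N: int = 3, T: float = 16.0,
              n_grid: int = 257) -> HMFBasis:
    """Build φ_m, m = 1..M, of order N on a uniform n_grid over [0, T].

    N >= 2 guarantees φ_m and dφ_m/dt vanish at both window ends.
    """
    if N < 2:
        raise ValueError("order N must be >= 2 for boundary conditions")
    if M < 1:
        raise ValueError("M must be >= 1")
    t = np.linspace(0.0, T, n_grid)
    w0 = 2.0 * np.pi / T
    phi = np.zeros((M, n_grid))
    dphi = np.zeros((M, n_grid))
    for m in range(1, M + 1):
        for k in range(N + 1):
            c = (-1.0) ** k * comb(N, k)
            freq = (m + k) * w0
            phi[m - 1] += c * cas(freq * t)
            dphi[m - 1] += c * freq * dcas(freq * t)
    return HMFBasis(M=M, N=N, T=T, t=t, phi=phi, dphi=dphi)


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.empty_like(t)
    w[1:-1] = (t[2:] - t[:-2]) / 2.0
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    return w


def project(basis: HMFBasis, dense: DenseTrajectories | np.ndarray,
            method: str = "trapezoid") -> tuple[np.ndarray, np.ndarray]:
    """Moments ∫φ_m E dt and derivative moments −∫φ'_m E dt per node.

    The derivative moments equal the projection of dE/dt onto φ_m by
    integration by parts (boundary terms vanish by the basis
    invariants).  ``method='hartley'`` computes the same integrals from
    discrete Hartley components of the data — an independent spectral
    path used for cross-checking.
    """
    values = dense.values if isinstance(dense, DenseTrajectories) else np.atleast_2d(dense)
    if isinstance(dense, DenseTrajectories):
        if dense.t.size != basis.t.size or abs(dense.T - basis.T) > 1e-9:
            raise ValueError("grid mismatch between basis and trajectories")
    elif values.shape[1] != basis.t.size:
        raise ValueError("grid mismatch between basis and trajectories")

    if method == "trapezoid":
        w = _trapezoid_weights(basis.t)
        moments = (basis.phi * w) @ values.T          # (M, n_nodes)
        dmoments = -(basis.dphi * w) @ values.T
        return moments, dmoments
    if method == "hartley":
        return _project_hartley(basis, values)
    raise ValueError(f"unknown projection method {method!r}")


def _project_hartley(basis: HMFBasis, values: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Spectral path: moments from discrete Hartley components.

    Uses the P = n_grid−1 periodic samples (the endpoint duplicates the
    fundamental period).  For the basis combination the rectangle-rule
    endpoint terms cancel exactly because Σ(-1)^k C(N,k) = 0 and
    Σ(-1)^k (m+k) C(N,k) = 0, so this matches the trapezoid path to
    rounding error — by an independent route through the FFT.
    """
    P = basis.t.size - 1
    T, w0 = basis.T, basis.omega0
    F = np.fft.fft(values[:, :P], axis=1)             # (n_nodes, P)
    cas_comp = F.real - F.imag                        # Σ f cas(2π n j / P)
    dcas_comp = F.real + F.imag                       # Σ f (cos − sin)
    n_nodes = values.shape[0]
    moments = np.zeros((basis.M, n_nodes))
    dmoments = np.zeros((basis.M, n_nodes))
    for m in range(1, basis.M + 1):
        for k in range(basis.N + 1):
            c = (-1.0) ** k * comb(basis.N, k)
            n = m + k
            if n >= P:
                raise ValueError("basis frequency exceeds grid Nyquist")
            moments[m - 1] += c * (T / P) * cas_comp[:, n]
            dmoments[m - 1] -= c * n * w0 * (T / P) * dcas_comp[:, n]
    return moments, dmoments


# --------------------------------------------------------------------------
# regression assembly and sparse solution

@dataclass
class RegressionSystem:
    """Per-target HMF regression: b = A k for one target node."""

    A: np.ndarray                # (M, n_nodes) regulator moments
    b: np.ndarray                # (M,) derivative moments of the target
    target: int
    labels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def underdetermined(self) -> bool:
        return self.A.shape[0] < self.A.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.A))


def assemble_regression(moments: np.ndarray, dmoments: np.ndarray,
                        target: int,
                        labels: list[tuple[str, str]] | None = None
                        ) -> RegressionSystem:
    """Build the target node's system; every node (self included) is a
    candidate regulator."""
    return RegressionSystem(A=moments.copy(), b=dmoments[:, target].copy(),
                            target=target, labels=labels or [])


def solve_elastic_net(A: np.ndarray, b: np.ndarray, alpha: float,
                      l1_ratio: float = 0.5) -> np.ndarray:
    """Elastic net on column-standardized A, coefficients back-scaled.

    Columns are scaled to unit standard deviation (no centering: the
    model has no intercept); alpha = 0 falls back to least squares.
    """
    sd = A.std(axis=0, ddof=0)
    keep = sd > 0
    As = A[:, keep] / sd[keep]
    coef = np.zeros(A.shape[1])
    if not keep.any():
        log.warning("all-zero design; returning zero row")
        return coef
    if alpha == 0.0:
        w, *_ = np.linalg.lstsq(As, b, rcond=None)
    else:
        en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                        max_iter=10_000, tol=1e-7)
        with warnings.catch_warnings():
            # duality gaps of ~1e-9 are far below the precision that
            # matters here; silence the convergence nag
            warnings.simplefilter("ignore", ConvergenceWarning)
            en.fit(As, b)
        w = en.coef_
    coef[keep] = w / sd[keep]
    return coef


def fit_elastic_net(system: RegressionSystem, l1_ratio: float = 0.5,
                    penalty_grid: np.ndarray | list[float] | None = None
                    ) -> dict[float, np.ndarray]:
    """Candidate coefficient rows for one target across the penalty grid."""
    grid = np.asarray(penalty_grid if penalty_grid is not None
                      else default_penalty_grid())
    if grid.size == 0:
        raise ValueError("penalty_grid must be non-empty")
    return {float(a): solve_elastic_net(system.A, system.b, float(a), l1_ratio)
            for a in grid}


def default_penalty_grid(n: int = 22) -> np.ndarray:
    """Logarithmic elastic-net penalty grid, 1e-6 .. 1e1.

    The floor sits low enough that on clean, well-excited data the
    simulation-RMSE selection can approach the least-squares limit;
    the ceiling shrinks every coefficient to zero.
    """
    return np.logspace(-6, 1, n)


@dataclass
class InteractionMatrix:
    """Fitted K with labels and fit diagnostics."""

    K: pd.DataFrame              # (organ,gene) x (organ,gene), 1/week
    diagnostics: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[tuple[str, str]]:
        return list(self.K.index)

    def to_array(self) -> np.ndarray:
        return self.K.to_numpy()


def simulate_affine(K: np.ndarray, c: np.ndarray | None, E0: np.ndarray,
                    times: np.ndarray) -> np.ndarray:
    """Integrate dE/dt = K·E + c via the augmented homogeneous system."""
    if c is None or not np.any(c):
        return integrate_linear_ode(K, E0, times)
    n = K.shape[0]
    Ka = np.zeros((n + 1, n + 1))
    Ka[:n, :n] = K
    Ka[:n, n] = c
    out = integrate_linear_ode(Ka, np.append(E0, 1.0), times)
    return out[:, :n]


def intercept_from_boundary(K: np.ndarray, dense: DenseTrajectories) -> np.ndarray:
    """Per-node constant of the affine model dy/dt = K·y + c.

    The modulating basis integrates constants to zero, so c is invisible
    to the HMF regression; it is recovered exactly from the boundary
    identity y(T) − y(0) = K ∫y dt + c·T.  Min-max scaling of the data
    is an affine (not linear) change of variables, which is what makes
    the constant term appear in the first place.
    """
    w = _trapezoid_weights(dense.t)
    Y = dense.values
    int_y = Y @ w
    return (Y[:, -1] - Y[:, 0] - K @ int_y) / dense.T


def simulation_rmse(K: np.ndarray, E0: np.ndarray, eval_times: np.ndarray,
                    eval_values: np.ndarray,
                    c: np.ndarray | None = None) -> float:
    """RMSE of the forward-simulated model against data at observed times.

    Unstable candidates score infinity.
    """
    try:
        sim = simulate_affine(K, c, E0, eval_times)   # (ages, nodes)
    except UnstableSimulationError:
        return np.inf
    resid = sim.T - eval_values
    ok = np.isfinite(resid)
    if not ok.any():
        return np.inf
    return float(np.sqrt(np.mean(resid[ok] ** 2)))


def fit_network(dense: DenseTrajectories | list[DenseTrajectories],
                basis: HMFBasis,
                eval_times: np.ndarray, eval_values: np.ndarray | list[np.ndarray],
                l1_ratio: float = 0.5,
                penalty_grid: np.ndarray | None = None,
                method: str = "trapezoid") -> InteractionMatrix:
    """Estimate K from dense trajectories with simulation-based selection.

    For every penalty on the grid an elastic-net row is fitted per
    target and the rows assembled into a candidate K; the winning
    penalty minimizes the whole-model simulation RMSE against
    ``eval_values`` (nodes x times, the scaled data at the observed
    ages), simulated from the first observed state.

    ``dense`` (and correspondingly ``eval_values``) may be a list of
    experiments — independent trajectories of the same network, e.g.
    different initial states.  Their moment blocks are stacked into one
    regression per target and the selection RMSE is averaged across
    experiments.  A single decaying trajectory rarely identifies K
    (exponential families are numerically near-collinear); multiple
    excitations restore a well-posed problem.
    """
    grid = np.asarray(penalty_grid if penalty_grid is not None
                      else default_penalty_grid())
    dense_list = dense if isinstance(dense, list) else [dense]
    eval_list = eval_values if isinstance(eval_values, list) else [eval_values]
    if len(dense_list) != len(eval_list):
        raise ValueError("dense and eval_values experiment counts differ")
    blocks = [project(basis, d, method=method) for d in dense_list]
    moments = np.vstack([m for m, _ in blocks])
    dmoments = np.vstack([dm for _, dm in blocks])
    n = dense_list[0].values.shape[0]
    rmse_path, candidates, intercepts = [], [], []
    for alpha in grid:
        K = np.vstack([solve_elastic_net(moments, dmoments[:, r], float(alpha),
                                         l1_ratio) for r in range(n)])
        c = np.mean([intercept_from_boundary(K, d) for d in dense_list], axis=0)
        rmse = float(np.mean([simulation_rmse(K, ev[:, 0], eval_times, ev, c)
                              for ev in eval_list]))
        candidates.append(K)
        intercepts.append(c)
        rmse_path.append(rmse)
    rmse_path = np.asarray(rmse_path)
    if np.all(np.isinf(rmse_path)):
        log.warning("all candidate networks unstable; keeping most penalized")
        best = len(grid) - 1
    else:
        best = int(np.argmin(rmse_path))
    idx = pd.MultiIndex.from_tuples(dense_list[0].labels,
                                    names=["organ", "gene"])
    K_df = pd.DataFrame(candidates[best], index=idx, columns=idx)
    diagnostics = {
        "intercept": [float(v) for v in intercepts[best]],
        "selected_penalty": float(grid[best]),
        "penalty_grid": [float(a) for a in grid],
        "rmse_path": [float(r) for r in rmse_path],
        "rmse": float(rmse_path[best]),
        "l1_ratio": l1_ratio,
        "M": basis.M, "N": basis.N,
        "n_experiments": len(dense_list),
        "underdetermined": basis.M * len(dense_list) < n,
        "projection": method,
    }
    return InteractionMatrix(K=K_df, diagnostics=diagnostics)


@dataclass
class HmfConfig:
    """Tunable parameters of the HMF identification."""

    M: int = 8                   # number of modulating functions
    N: int = 3                   # basis order (>= 2)
    n_grid: int = 257            # dense quadrature grid
    l1_ratio: float = 0.5        # elastic-net mixing
    penalty_grid: tuple[float, ...] = tuple(default_penalty_grid())
    projection: str = "trapezoid"
    clip: tuple[float, float] | None = (0.0, 1.0)


def estimate_network(norm: pd.DataFrame, meta: pd.DataFrame, strain: str,
                     config: HmfConfig | None = None) -> InteractionMatrix:
    """End-to-end fit for one strain: replicate means → min-max scaling →
    dense spline → HMF projection → per-target elastic net → joint
    simulation-RMSE model selection."""
    cfg = config or HmfConfig()
    traj = summarize_replicates(norm, meta, strain)
    if traj.times.size < 3:
        raise ValueError("need >=3 distinct ages to identify dynamics")
    scaled, scale_params = minmax_scale(traj)
    dense = interpolate_dense(scaled, n_grid=cfg.n_grid, clip=cfg.clip)
    basis = hmf_basis(M=cfg.M, N=cfg.N, T=dense.T, n_grid=cfg.n_grid)
    eval_times = traj.times - traj.times[0]
    eval_values = scaled.values.to_numpy()
    fitted = fit_network(dense, basis, eval_times, eval_values,
                         l1_ratio=cfg.l1_ratio,
                         penalty_grid=np.asarray(cfg.penalty_grid),
                         method=cfg.projection)
    fitted.diagnostics["strain"] = strain
    fitted.diagnostics["ages_weeks"] = [float(a) for a in traj.times]
    fitted.diagnostics["n_constant_nodes"] = int(scale_params["constant"].sum())
    return fitted


def simulate_fitted_model(K: InteractionMatrix | pd.DataFrame | np.ndarray,
                          E0: np.ndarray,
                          t_span: tuple[float, float] = (8.0, 24.0),
                          n_out: int = 161,
                          intercept: np.ndarray | None = None) -> TrajectorySet:
    """Integrate the fitted model over an age span (weeks).

    Shares the integrator with the synthetic simulator; the returned
    times are ages (the model runs on the shifted clock internally).
    Passing an :class:`InteractionMatrix` reuses the affine intercept
    recovered during fitting (the scaled-data model is dE/dt = K·E + c);
    a bare matrix simulates the homogeneous system unless ``intercept``
    is given.
    """
    if isinstance(K, InteractionMatrix):
        labels, Km = K.labels, K.to_array()
        if intercept is None and "intercept" in K.diagnostics:
            intercept = np.asarray(K.diagnostics["intercept"], dtype=float)
    elif isinstance(K, pd.DataFrame):
        labels, Km = list(K.index), K.to_numpy()
    else:
        Km = np.asarray(K)
        labels = [("node", str(i)) for i in range(Km.shape[0])]
    ages = np.linspace(t_span[0], t_span[1], n_out)
    states = simulate_affine(Km, intercept, np.asarray(E0, dtype=float),
                             ages - ages[0])
    idx = pd.MultiIndex.from_tuples(labels, names=["organ", "gene"])
    return TrajectorySet(times=ages, values=pd.DataFrame(states.T, index=idx))
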