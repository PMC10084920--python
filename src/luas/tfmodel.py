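"""Four-transcription-factor counteracting network model.

Two adenomatous-lineage TFs (NKX2-1 = N, FOXA2 = F) counteract two
squamous-lineage TFs (TP63 = P, SOX2 = S): within-lineage mutual activation,
cross-lineage repression. Production of each TF is a multiplicative Hill
gate (partner activation x product of the two cross-lineage repressions)
plus a basal rate, with first-order degradation:

    dN/dt = b + alpha_A * H+(F) * H-(P) * H-(S) - d*N
    dF/dt = b + alpha_A * H+(N) * H-(P) * H-(S) - d*F
    dP/dt = b + alpha_S * H+(S) * H-(N) * H-(F) - d*P
    dS/dt = b + alpha_S * H+(P) * H-(N) * H-(F) - d*S

with H+(y) = y^n / (K_act^n + y^n) and H-(y) = K_rep^n / (K_rep^n + y^n).
The squamous maximal rate alpha_S is the bifurcation parameter: sweeping it
takes the system from an adenomatous-monostable regime through bistability
(adenomatous and squamous attractors coexist) to squamous monostability.

Stochastic dynamics use Euler-Maruyama with additive isotropic noise and a
reflecting boundary at zero; the potential landscape is U = -ln(Pss), with
Pss the steady-state density over the projection
u = (N+F)/2 - (P+S)/2 (adeno-minus-squam score), v = (N+F+P+S)/4 (total).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import root
from scipy.stats import qmc

__all__ = [
    "TFParams",
    "FixedPoint",
    "BifurcationDiagram",
    "SDEEnsemble",
    "LandscapeGrid",
    "drift",
    "jacobian",
    "find_fixed_points",
    "bifurcation_scan",
    "simulate_sde",
    "estimate_landscape",
    "project_uv",
]

U_TOL = 0.1  # |u| above this calls a state lineage-specific


@dataclass(frozen=True)
class TFParams:
    """Model parameterization (arbitrary concentration/time units).

    Defaults are chosen so the alpha_S scan exhibits the three-regime
    sequence; they are model choices, not fitted constants.
    """

    alpha_A: float = 2.0
    alpha_S: float = 2.0
    basal: float = 0.3
    K_act: float = 0.5
    K_rep: float = 1.0
    n: int = 2
    d: float = 1.0
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("degradation rate d must be positive")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("Hill coefficient n must be a positive integer")
        if min(self.alpha_A, self.alpha_S, self.basal, self.K_act, self.K_rep) < 0:
            raise ValueError("rates and constants must be nonnegative")
        if self.sigma < 0:
            raise ValueError("noise amplitude sigma must be nonnegative")

    @property
    def x_max(self) -> float:
        """Upper bound of reachable concentrations."""
        return (self.basal + max(self.alpha_A, self.alpha_S)) / self.d


def _hill_act(y: np.ndarray, K: float, n: int) -> np.ndarray:
    yn = np.power(y, n)
    return yn / (K**n + yn)


def _hill_rep(y: np.ndarray, K: float, n: int) -> np.ndarray:
    Kn = K**n
    return Kn / (Kn + np.power(y, n))


def drift(x: np.ndarray, theta: TFParams) -> np.ndarray:
    """Deterministic drift; accepts a single state (4,) or a batch (m, 4)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("TF concentrations must be nonnegative")
    single = x.ndim == 1
    X = np.atleast_2d(x)
    N, F, P, S = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    Ka, Kr, n = theta.K_act, theta.K_rep, theta.n
    rep_sq = _hill_rep(P, Kr, n) * _hill_rep(S, Kr, n)  # squamous pair represses
    rep_ad = _hill_rep(N, Kr, n) * _hill_rep(F, Kr, n)
    out = np.empty_like(X)
    out[:, 0] = theta.basal + theta.alpha_A * _hill_act(F, Ka, n) * rep_sq - theta.d * N
    out[:, 1] = theta.basal + theta.alpha_A * _hill_act(N, Ka, n) * rep_sq - theta.d * F
    out[:, 2] = theta.basal + theta.alpha_S * _hill_act(S, Ka, n) * rep_ad - theta.d * P
    out[:, 3] = theta.basal + theta.alpha_S * _hill_act(P, Ka, n) * rep_ad - theta.d * S
    return out[0] if single else out


def jacobian(x: np.ndarray, theta: TFParams, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the drift at x."""
    x = np.asarray(x, dtype=float)
    scale = max(float(np.max(np.abs(x))), 1.0)
    h = rel_step * scale
    J = np.empty((4, 4))
    for j in range(4):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (drift(xp, theta) - drift(xm, theta)) / (xp[j] - xm[j])
    return J


def project_uv(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2D projection: u = adeno minus squam mean, v = overall mean."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    u = (X[:, 0] + X[:, 1]) / 2.0 - (X[:, 2] + X[:, 3]) / 2.0
    v = X.mean(axis=1)
    return u, v


@dataclass(frozen=True)
class FixedPoint:
    x: tuple[float, float, float, float]
    stable: bool

    @property
    def u(self) -> float:
        return (self.x[0] + self.x[1]) / 2.0 - (self.x[2] + self.x[3]) / 2.0


def find_fixed_points(
    theta: TFParams,
    n_starts: int = 200,
    tol: float = 1e-8,
    dedup_radius: float = 1e-3,
    seed: int = 0,
) -> list[FixedPoint]:
    """Multi-start root finding on the drift from Latin-hypercube starts.

    Converged roots are deduplicated within ``dedup_radius``; stability is
    read off the real parts of the finite-difference Jacobian eigenvalues.
    Returns an empty list (with a warning) if no start converges.
    """
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = sampler.random(n_starts) * theta.x_max
    # always probe the corners of the lineage axes and the center
    hi = theta.x_max
    extra = np.array(
        [
            [hi, hi, 0.0, 0.0],
            [0.0, 0.0, hi, hi],
            [hi / 2] * 4,
            [theta.basal / theta.d] * 4,
        ]
    )
    starts = np.vstack([starts, extra])

    def fun(z: np.ndarray) -> np.ndarray:
        return drift(np.abs(z), theta)

    found: list[np.ndarray] = []
    for x0 in starts:
        sol = root(fun, x0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        xs = np.abs(sol.x)
        if np.max(np.abs(drift(xs, theta))) >= tol:
            continue
        if any(np.linalg.norm(xs - f) < dedup_radius for f in found):
            continue
        found.append(xs)
    if not found:
        import warnings

        warnings.warn("no fixed point found from any start", stacklevel=2)
        return []
    out = []
    for xs in sorted(found, key=lambda z: -((z[0] + z[1]) - (z[2] + z[3]))):
        eig = np.linalg.eigvals(jacobian(xs, theta))
        out.append(FixedPoint(x=tuple(float(v) for v in xs), stable=bool(np.all(eig.real < 0))))
    return out


@dataclass
class BifurcationDiagram:
    """Stable/unstable fixed points and regime label along an alpha_S grid."""

    alpha_s: np.ndarray
    fixed_points: list[list[FixedPoint]]
    regimes: list[str]

    def regime_sequence(self) -> list[str]:
        """Distinct consecutive regimes in scan order."""
        seq: list[str] = []
        for r in self.regimes:
            if not seq or seq[-1] != r:
                seq.append(r)
        return seq

    def bifurcation_values(self) -> list[float]:
        """Midpoints of the grid intervals where the regime changes."""
        vals = []
        for i in range(1, len(self.regimes)):
            if self.regimes[i] != self.regimes[i - 1]:
                vals.append(float((self.alpha_s[i] + self.alpha_s[i - 1]) / 2.0))
        return vals


def _regime_label(fps: list[FixedPoint]) -> str:
    stable = [fp for fp in fps if fp.stable]
    has_adeno = any(fp.u > U_TOL for fp in stable)
    has_squam = any(fp.u < -U_TOL for fp in stable)
    if has_adeno and has_squam:
        return "bistable"
    if has_adeno:
        return "adenomatous_monostable"
    if has_squam:
        return "squamous_monostable"
    return "neutral"


def bifurcation_scan(
    theta_base: TFParams,
    alpha_s_grid: np.ndarray,
    n_starts: int = 80,
    seed: int = 0,
) -> BifurcationDiagram:
    """Classify the dynamical regime at each alpha_S grid value."""
    grid = np.asarray(alpha_s_grid, dtype=float)
    fps_all: list[list[FixedPoint]] = []
    regimes: list[str] = []
    for a in grid:
        fps = find_fixed_points(replace(theta_base, alpha_S=float(a)), n_starts=n_starts, seed=seed)
        fps_all.append(fps)
        regimes.append(_regime_label(fps))
    return BifurcationDiagram(alpha_s=grid, fixed_points=fps_all, regimes=regimes)


@dataclass
class SDEEnsemble:
    """Recorded trajectory ensemble: states has shape (n_traj, n_rec, 4)."""

    states: np.ndarray
    times: np.ndarray
    theta: TFParams


def simulate_sde(
    theta: TFParams,
    x0: np.ndarray,
    T: float,
    dt: float = 1e-2,
    n_traj: int = 1,
    seed: int = 0,
    record_every: int = 10,
) -> SDEEnsemble:
    """Euler-Maruyama ensemble with additive noise and reflection at 0.

    ``x0`` is a single state (4,) shared by all trajectories or an
    (n_traj, 4) array of starts. With sigma = 0 this is deterministic Euler.
    """
    if dt * theta.d >= 0.1:
        raise ValueError(
            f"dt*d = {dt * theta.d:.3g} >= 0.1 violates the explicit-Euler "
            "stability heuristic; reduce dt"
        )
    x0 = np.asarray(x0, dtype=float)
    X = np.tile(x0, (n_traj, 1)) if x0.ndim == 1 else x0.copy()
    if X.shape != (n_traj, 4):
        raise ValueError("x0 must have shape (4,) or (n_traj, 4)")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    rec_idx = range(0, n_steps + 1, record_every)
    n_rec = len(rec_idx)
    out = np.empty((n_traj, n_rec, 4))
    times = np.empty(n_rec)
    k = 0
    sq = theta.sigma * np.sqrt(dt)
    for step in range(n_steps + 1):
        if step % record_every == 0:
            out[:, k] = X
            times[k] = step * dt
            k += 1
        if step == n_steps:
            break
        X = X + drift(X, theta) * dt
        if theta.sigma > 0:
            X = X + sq * rng.standard_normal(X.shape)
        np.abs(X, out=X)  # reflecting boundary at 0
    return SDEEnsemble(states=out, times=times, theta=theta)


@dataclass
class LandscapeGrid:
    """Steady-state density and potential over the (u, v) projection."""

    u_edges: np.ndarray
    v_edges: np.ndarray
    Pss: np.ndarray  # shape (n_u, n_v), sums to 1
    U: np.ndarray
    eps_p: float

    @property
    def u_centers(self) -> np.ndarray:
        return (self.u_edges[:-1] + self.u_edges[1:]) / 2.0

    @property
    def v_centers(self) -> np.ndarray:
        return (self.v_edges[:-1] + self.v_edges[1:]) / 2.0

    def minima(self, occupancy: float = 1e-3) -> list[tuple[float, float]]:
        """(u, v) centers of local potential minima among occupied cells."""
        occ = self.Pss >= occupancy
        mins: list[tuple[float, float, float]] = []
        nu, nv = self.Pss.shape
        for i in range(nu):
            for j in range(nv):
                if not occ[i, j]:
                    continue
                val = self.U[i, j]
                neigh = [
                    self.U[a, b]
                    for a in range(max(i - 1, 0), min(i + 2, nu))
                    for b in range(max(j - 1, 0), min(j + 2, nv))
                    if (a, b) != (i, j)
                ]
                if all(val <= nb for nb in neigh):
                    mins.append((val, self.u_centers[i], self.v_centers[j]))
        mins.sort()
        return [(u, v) for _, u, v in mins]

    def global_minimum(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmin(self.U), self.U.shape)
        return float(self.u_centers[i]), float(self.v_centers[j])


def estimate_landscape(
    ensemble: SDEEnsemble,
    grid_shape: tuple[int, int] = (40, 40),
    u_range: tuple[float, float] | None = None,
    v_range: tuple[float, float] | None = None,
    burn_in_fraction: float = 0.2,
    eps_p: float = 1e-12,
) -> LandscapeGrid:
    """Potential landscape U = -ln(Pss + eps) from an ensemble.

    Pss is the normalized 2D histogram of post-burn-in states projected to
    (u, v); the global minimum of U coincides with the mode of Pss.
    """
    n_rec = ensemble.states.shape[1]
    start = int(np.floor(burn_in_fraction * n_rec))
    post = ensemble.states[:, start:, :].reshape(-1, 4)
    if post.size == 0:
        raise ValueError("no post-burn-in samples in the ensemble")
    u, v = project_uv(post)
    ur = u_range if u_range is not None else (float(u.min()), float(u.max()))
    vr = v_range if v_range is not None else (float(v.min()), float(v.max()))
    H, u_edges, v_edges = np.histogram2d(
        u, v, bins=grid_shape, range=[list(ur), list(vr)]
    )
    Pss = H / H.sum()
    U = -np.log(Pss + eps_p)
    return LandscapeGrid(u_edges=u_edges, v_edges=v_edges, Pss=Pss, U=U, eps_p=eps_p)
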